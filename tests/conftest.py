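"""Shared fixtures: small seeded synthetic cohorts generated at test time."""

import numpy as np
import pytest

from paintcog.nn import TrainConfig
from paintcog.synthetic import CohortConfig, PanssModel, StrokeDist, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 HC + 30 SCZ at 64x64 with the default group effects."""
    cfg = CohortConfig(n_hc=20, n_scz=30, canvas_size=(64, 64), n_regions=3, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Groups drawn from identical distributions: no color/stroke effect."""
    cfg = CohortConfig(n_hc=14, n_scz=14, canvas_size=(64, 64), n_regions=3, seed=23)
    stroke = {g: cfg.stroke_effect["HC"] for g in ("HC", "SCZ")}
    ce = type(cfg.color_effect)(hc_mean=7.0, scz_mean=7.0, sd=1.5)
    cfg = CohortConfig(n_hc=14, n_scz=14, canvas_size=(64, 64), n_regions=3,
                       seed=23, stroke_effect=stroke, color_effect=ce)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def scored_cohort():
    """100 patients, every PANSS present, low score noise, wide stroke-length
    spread so scores are strongly image-determined; 64x64 canvas."""
    stroke = {"HC": StrokeDist(45.0, 6.0, 12.0, 4.0, 0.15, 0.06, 90, 10.0),
              "SCZ": StrokeDist(30.0, 12.0, 55.0, 8.0, 0.65, 0.08, 70, 10.0)}
    cfg = CohortConfig(n_hc=0, n_scz=100, canvas_size=(64, 64), n_regions=3,
                       seed=7, stroke_effect=stroke,
                       panss_model=PanssModel(noise_sd=0.5, missing_prob=0.0))
    return generate_cohort(cfg)


@pytest.fixture
def quick_train():
    return TrainConfig(max_epochs=4, batch_size=32, seed=0)
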