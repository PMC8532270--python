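"""End-to-end orchestration: generate -> features -> statistics -> networks.

``run_pipeline`` composes the library stages under one seeded config and
writes a structured JSON report (plus per-stage CSVs) with full provenance
(config, seeds, package version).  Every stage can be toggled; a failed
stage is reported without discarding completed outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import PaintingClassifier
from .color_features import GroupColorModel, color_histogram
from .nn import TrainConfig
from .panss_regressor import PanssRegression
from .stats_compare import ContingencyTable2x2, chi_square_2x2, pooled_t, summarize
from .stroke_features import GroupStrokeModel, edge_map, hough_accumulator
from .synthetic import Cohort, CohortConfig, generate_cohort, read_cohort, write_cohort

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "demographic_table"]

log = logging.getLogger("paintcog")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    cohort_config: CohortConfig | None = None
    cohort_dir: str | None = None          # load instead of generating
    out_dir: str = "paintcog_out"
    stages: dict = field(default_factory=lambda: {
        "demographics": True, "color": True, "stroke": True,
        "classify": True, "panss": True,
    })
    seed: int = 0
    # classification options
    classifier_variant: str = "small"
    classifier_input: tuple = (64, 64)
    classifier_runs: int = 10
    oversample_factor: int = 13
    classifier_plan: dict | None = None
    classifier_train: dict = field(default_factory=lambda: {
        "max_epochs": 10, "batch_size": 64})
    # stroke options
    theta_step: float = 1.0
    r_step: float = 1.0
    edge_threshold: float = 0.2
    # regression options
    panss_targets: tuple = ("p", "n", "g", "total")
    panss_train: dict = field(default_factory=dict)


@dataclass
class PipelineReport:
    provenance: dict
    demographics: dict | None = None
    color: dict | None = None
    stroke: dict | None = None
    classification: dict | None = None
    regression: dict | None = None
    errors: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)

    def text_summary(self) -> str:
        lines = [f"paintcog pipeline report (seed {self.provenance['seed']})"]
        if self.demographics:
            d = self.demographics
            lines.append(f"  age t = {d['age_t']:.3f} (p = {d['age_p']:.3g}); "
                         f"sex chi2 = {d['sex_chi2']:.3f} (p = {d['sex_p']:.3g})")
            lines.append(f"  patient PANSS total mean = {d['panss_means']['total'][0]:.2f}")
        if self.color:
            lines.append(f"  color: {self.color['n_significant']} / 64 bins significant "
                         f"at p < {self.color['alpha']}")
        if self.stroke:
            s = self.stroke
            lines.append(f"  stroke: {s['n_significant_p']} accumulator cells at "
                         f"p < {s['p_threshold']}, {s['n_strong_correlation']} with "
                         f"|r| >= {s['r_threshold']}")
        if self.classification:
            c = self.classification
            lines.append(f"  classification: mean accuracy {c['mean_accuracy']:.2f}% "
                         f"+/- {c['sd_accuracy']:.2f} over {c['n_runs']} runs")
        if self.regression:
            for t, r in self.regression.items():
                lines.append(f"  PANSS {t}: test RMSE {r['rmse']:.2f} "
                             f"(mean-predictor {r['baseline_rmse']:.2f})")
        for stage, err in self.errors.items():
            lines.append(f"  [failed] {stage}: {err}")
        return "\n".join(lines)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def demographic_table(cohort: Cohort) -> dict:
    """Group comparison of the metadata: age t-test, sex chi-square, PANSS means."""
    meta = cohort.metadata()
    for col in ("age", "sex", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks column {col!r}")
    scz = meta[meta.group == "SCZ"]
    hc = meta[meta.group == "HC"]
    if len(scz) < 2 or len(hc) < 2:
        raise ValueError("need at least two subjects per group")
    t, df, p = pooled_t(summarize(scz.age), summarize(hc.age))
    table = ContingencyTable2x2(
        a=int((scz.sex == "F").sum()), b=int((scz.sex == "M").sum()),
        c=int((hc.sex == "F").sum()), d=int((hc.sex == "M").sum()))
    chi2, _, chi_p = chi_square_2x2(table)
    valid = scz[~scz.panss_missing]
    panss_means = {}
    for label, col in (("p", "panss_p"), ("n", "panss_n"), ("g", "panss_g"),
                       ("total", "panss_total")):
        if len(valid):
            panss_means[label] = (float(valid[col].mean()), float(valid[col].std(ddof=1)))
        else:
            panss_means[label] = (float("nan"), float("nan"))
    return {
        "n_scz": int(len(scz)), "n_hc": int(len(hc)),
        "age_t": float(t), "age_df": float(df), "age_p": float(p),
        "age_mean_scz": float(scz.age.mean()), "age_sd_scz": float(scz.age.std(ddof=1)),
        "age_mean_hc": float(hc.age.mean()), "age_sd_hc": float(hc.age.std(ddof=1)),
        "sex_chi2": float(chi2), "sex_p": float(chi_p),
        "sex_table": [table.a, table.b, table.c, table.d],
        "panss_means": panss_means,
        "n_panss_valid": int(len(valid)),
    }


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "stages": dict(config.stages),
        "cohort_dir": config.cohort_dir,
    }
    report = PipelineReport(provenance=provenance)

    if config.cohort_dir:
        log.info("loading cohort from %s", config.cohort_dir)
        cohort = read_cohort(config.cohort_dir)
    else:
        cc = config.cohort_config or CohortConfig(seed=config.seed)
        provenance["cohort_config"] = json.loads(cc.to_json())
        log.info("generating cohort: %d HC, %d SCZ", cc.n_hc, cc.n_scz)
        cohort = generate_cohort(cc)
        write_cohort(cohort, out / "cohort")
    labels = cohort.labels()
    ids = [s.id for s in cohort.subjects]

    if config.stages.get("demographics"):
        try:
            report.demographics = demographic_table(cohort)
        except Exception as e:  # noqa: BLE001 - stage isolation
            log.exception("demographics stage failed")
            report.errors["demographics"] = str(e)

    if config.stages.get("color"):
        try:
            log.info("color features: %d subjects", len(ids))
            hists = [color_histogram(cohort.images[i]) for i in ids]
            hist_df = pd.DataFrame([h.counts for h in hists], index=ids,
                                   columns=[f"bin{b}" for b in range(64)])
            hist_df.to_csv(out / "color_histograms.csv")
            res = GroupColorModel(hists, labels).fit()
            res.summary().to_csv(out / "color_report.csv", index=False)
            report.color = {"alpha": res.alpha,
                            "n_significant": int(res.significant.sum()),
                            "n_defined": int(res.defined.sum())}
        except Exception as e:  # noqa: BLE001
            log.exception("color stage failed")
            report.errors["color"] = str(e)

    if config.stages.get("stroke"):
        try:
            log.info("stroke features (Hough accumulators)")
            grids = [hough_accumulator(edge_map(cohort.images[i], config.edge_threshold),
                                       config.theta_step, config.r_step) for i in ids]
            res = GroupStrokeModel(grids, labels).fit()
            report.stroke = res.summary()
            np.savetxt(out / "stroke_tstat.csv", res.tstat, delimiter=",")
        except Exception as e:  # noqa: BLE001
            log.exception("stroke stage failed")
            report.errors["stroke"] = str(e)

    if config.stages.get("classify"):
        try:
            log.info("classification: %d runs, %s variant",
                     config.classifier_runs, config.classifier_variant)
            clf = PaintingClassifier(
                cohort, variant=config.classifier_variant,
                input_size=config.classifier_input,
                plan_counts=config.classifier_plan,
                oversample_factor=config.oversample_factor,
                train_config=TrainConfig(**config.classifier_train))
            res = clf.fit(n_runs=config.classifier_runs, seed=config.seed)
            report.classification = res.to_json_dict()
            pd.DataFrame(res.loss_curves).T.to_csv(out / "classifier_loss.csv",
                                                   index_label="epoch")
        except Exception as e:  # noqa: BLE001
            log.exception("classification stage failed")
            report.errors["classify"] = str(e)

    if config.stages.get("panss"):
        report.regression = {}
        for target in config.panss_targets:
            try:
                log.info("PANSS regression: target %s", target)
                kwargs = dict(config.panss_train)
                cfg = TrainConfig(**kwargs) if kwargs else None
                reg = PanssRegression(cohort, target=target, config=cfg)
                res = reg.fit(seed=config.seed)
                res.pairs.to_csv(out / f"panss_{target}_pairs.csv", index=False)
                report.regression[target] = {
                    "rmse": res.rmse, "baseline_rmse": res.baseline_rmse,
                    "n_train": res.n_train, "n_test": res.n_test}
            except Exception as e:  # noqa: BLE001
                log.exception("regression stage failed for %s", target)
                report.errors[f"panss_{target}"] = str(e)

    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.text_summary() + "\n")
    log.info("report written to %s", out / "report.json")
    return report
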