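"""Seeded synthetic cohort of template paintings and subject metadata.

Emulates a coloring-task study: each subject fills a shared outline
template using strokes from a 12-pen palette.  Patients (SCZ) use fewer
distinct colors and draw shorter, more disordered strokes concentrated
toward the canvas center than healthy controls (HC); symptom scores
(PANSS positive / negative / general psychopathology, and their total)
depend linearly on the painting features plus Gaussian noise, clipped to
the instrument's bounds, and are missing for a configurable fraction of
subjects.

The template is a set of abstract closed regions (axis-aligned rectangles
with 1-px black outlines on a white canvas); only the statistical structure
of color and stroke usage matters downstream, not the artwork semantics.
Generation is reproducible byte-for-byte: one master seed, with a
per-subject substream derived from a stable hash of the subject id so
results do not depend on generation order.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import line as _draw_line

from .color_features import BACKGROUND_BIN, OUTLINE_BIN, quantize_rgb

__all__ = [
    "PaletteSpec",
    "DEFAULT_PALETTE",
    "TemplateSpec",
    "TemplatePlacementError",
    "StrokeParams",
    "StrokeDist",
    "ColorEffect",
    "PanssModel",
    "PanssScores",
    "SubjectProfile",
    "SubjectRecord",
    "CohortConfig",
    "Cohort",
    "make_template",
    "sample_subject",
    "assign_panss",
    "render_painting",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

WHITE = (255, 255, 255)
BLACK = (0, 0, 0)

# PANSS bounds: 7 positive items, 7 negative, 16 general, each scored 1-7
P_BOUNDS = (7, 49)
N_BOUNDS = (7, 49)
G_BOUNDS = (16, 112)


@dataclass(frozen=True)
class PaletteSpec:
    """The 12 pen colors plus canvas background and outline colors.

    Every pen color must land in its own 64-bin quantization cell, distinct
    from the background (white) and outline (black) cells, so color counts
    are identifiable in histogram space.
    """

    colors: tuple = ()
    background: tuple = WHITE
    outline: tuple = BLACK

    def __post_init__(self):
        if len(self.colors) != 12:
            raise ValueError("palette must contain exactly 12 pen colors")
        rgbs = [tuple(c) for _, c in self.colors]
        if len(set(rgbs)) != 12:
            raise ValueError("pen colors must be distinct")
        bins = [quantize_rgb(*c) for c in rgbs]
        if len(set(bins)) != 12:
            raise ValueError("pen colors must occupy distinct quantization bins")
        bg = quantize_rgb(*self.background)
        ol = quantize_rgb(*self.outline)
        if bg != BACKGROUND_BIN or ol != OUTLINE_BIN:
            raise ValueError("background must quantize to bin 63 and outline to bin 0")
        if bg in bins or ol in bins:
            raise ValueError("pen colors must not share a bin with background/outline")

    @property
    def rgb(self) -> np.ndarray:
        return np.array([c for _, c in self.colors], dtype=np.uint8)

    @property
    def bins(self) -> list[int]:
        return [quantize_rgb(*c) for _, c in self.colors]


DEFAULT_PALETTE = PaletteSpec(colors=(
    ("red", (200, 40, 40)),
    ("orange", (230, 140, 30)),
    ("yellow", (240, 220, 40)),
    ("green", (60, 170, 60)),
    ("dark_green", (20, 100, 30)),
    ("cyan", (60, 200, 200)),
    ("blue", (50, 90, 200)),
    ("dark_blue", (30, 40, 140)),
    ("purple", (140, 60, 180)),
    ("pink", (240, 130, 180)),
    ("brown", (140, 90, 50)),
    ("gray", (130, 130, 130)),
))


class TemplatePlacementError(RuntimeError):
    """Raised when the requested regions cannot be placed on the canvas."""


@dataclass(frozen=True)
class TemplateSpec:
    """Outline template: closed rectangular regions on a white canvas.

    ``regions`` holds inclusive pixel boxes (x0, y0, x1, y1); interiors are
    pairwise disjoint with at least a 2-px gap.  ``outline_mask`` marks the
    1-px region borders.
    """

    size: tuple  # (width, height)
    regions: tuple
    outline_mask: np.ndarray

    def interior_masks(self) -> list[np.ndarray]:
        w, h = self.size
        masks = []
        for (x0, y0, x1, y1) in self.regions:
            m = np.zeros((h, w), dtype=bool)
            m[y0 + 1:y1, x0 + 1:x1] = True
            masks.append(m)
        return masks

    def render_blank(self) -> np.ndarray:
        w, h = self.size
        img = np.full((h, w, 3), 255, dtype=np.uint8)
        img[self.outline_mask.astype(bool)] = 0
        return img


def make_template(size: tuple, n_regions: int, seed: int) -> TemplateSpec:
    """Place ``n_regions`` disjoint outlined rectangles on the canvas."""
    w, h = size
    if w < 64 or h < 64:
        raise ValueError("canvas must be at least 64x64")
    if n_regions < 1:
        raise ValueError("need at least one region")
    rng = np.random.default_rng(seed)
    lo = max(10, min(w, h) // 8)
    hi = max(lo + 1, min(w, h) // 2)
    placed: list[tuple] = []
    attempts = 0
    while len(placed) < n_regions:
        attempts += 1
        if attempts > 500 * n_regions:
            raise TemplatePlacementError(
                f"could not place {n_regions} regions on a {w}x{h} canvas")
        rw = int(rng.integers(lo, hi))
        rh = int(rng.integers(lo, hi))
        if rw >= w - 2 or rh >= h - 2:
            continue
        x0 = int(rng.integers(1, w - rw - 1))
        y0 = int(rng.integers(1, h - rh - 1))
        box = (x0, y0, x0 + rw, y0 + rh)
        # 2-px clearance so outlines never merge
        if all(box[0] > b[2] + 2 or b[0] > box[2] + 2
               or box[1] > b[3] + 2 or b[1] > box[3] + 2 for b in placed):
            placed.append(box)
    outline = np.zeros((h, w), dtype=np.uint8)
    for (x0, y0, x1, y1) in placed:
        outline[y0, x0:x1 + 1] = 1
        outline[y1, x0:x1 + 1] = 1
        outline[y0:y1 + 1, x0] = 1
        outline[y0:y1 + 1, x1] = 1
    return TemplateSpec(size=(w, h), regions=tuple(placed), outline_mask=outline)


@dataclass(frozen=True)
class StrokeParams:
    """Per-subject stroke geometry."""

    mean_length: float      # px
    angle_dispersion: float  # degrees, SD of stroke direction about horizontal
    center_bias: float       # probability a stroke anchors in the central disk
    n_strokes: int

    def __post_init__(self):
        if not (0.0 <= self.center_bias <= 1.0):
            raise ValueError("center_bias must lie in [0, 1]")
        if self.mean_length <= 0 or self.n_strokes < 1 or self.angle_dispersion < 0:
            raise ValueError("invalid stroke parameters")


@dataclass(frozen=True)
class StrokeDist:
    """Group-level distribution from which StrokeParams are drawn."""

    mean_length: float
    sd_length: float
    angle_dispersion: float
    sd_dispersion: float
    center_bias: float
    sd_center_bias: float
    n_strokes: int
    sd_n_strokes: float

    def draw(self, rng: np.random.Generator) -> StrokeParams:
        return StrokeParams(
            mean_length=max(4.0, rng.normal(self.mean_length, self.sd_length)),
            angle_dispersion=max(0.0, rng.normal(self.angle_dispersion, self.sd_dispersion)),
            center_bias=float(np.clip(rng.normal(self.center_bias, self.sd_center_bias), 0, 1)),
            n_strokes=max(1, int(round(rng.normal(self.n_strokes, self.sd_n_strokes)))),
        )


@dataclass(frozen=True)
class ColorEffect:
    """Group means of the number of distinct pen colors a subject uses."""

    hc_mean: float = 9.0
    scz_mean: float = 5.0
    sd: float = 1.5


@dataclass(frozen=True)
class PanssModel:
    """Linear dependence of PANSS subscales on painting features.

    Features, in order: (n_colors, mean stroke length, angle dispersion,
    center bias).  Each subscale = intercept + weights . features +
    N(0, noise_sd), clipped to the subscale bounds; total = P + N + G.
    """

    weights: dict = field(default_factory=lambda: {
        "P": (16.3, (-1.0, 0.0, 0.0, 0.0)),
        "N": (20.5, (0.0, -0.2, 0.0, 0.0)),
        "G": (14.5, (0.0, 0.0, 0.1, 10.0)),
    })
    noise_sd: float = 4.0
    missing_prob: float = 37.0 / 281.0

    def __post_init__(self):
        if not (0.0 <= self.missing_prob <= 1.0):
            raise ValueError("missing_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class PanssScores:
    p: int
    n: int
    g: int
    total: int

    def __post_init__(self):
        if not (P_BOUNDS[0] <= self.p <= P_BOUNDS[1]):
            raise ValueError("positive subscale out of bounds")
        if not (N_BOUNDS[0] <= self.n <= N_BOUNDS[1]):
            raise ValueError("negative subscale out of bounds")
        if not (G_BOUNDS[0] <= self.g <= G_BOUNDS[1]):
            raise ValueError("general psychopathology subscale out of bounds")
        if self.total != self.p + self.n + self.g:
            raise ValueError("total must equal P + N + G")


@dataclass(frozen=True)
class SubjectProfile:
    id: str
    group: str  # "HC" | "SCZ"
    n_colors: int
    stroke_params: StrokeParams
    age: float
    sex: str  # "F" | "M"
    panss: PanssScores | None = None

    def __post_init__(self):
        if self.group not in ("HC", "SCZ"):
            raise ValueError("group must be HC or SCZ")
        if not (1 <= self.n_colors <= 12):
            raise ValueError("n_colors must lie in [1, 12]")

    def painting_features(self) -> np.ndarray:
        sp = self.stroke_params
        return np.array([self.n_colors, sp.mean_length,
                         sp.angle_dispersion, sp.center_bias], dtype=float)


@dataclass(frozen=True)
class SubjectRecord:
    """Serializable per-subject metadata row."""

    id: str
    group: str
    age: float
    sex: str
    panss_p: float  # NaN when missing
    panss_n: float
    panss_g: float
    panss_total: float
    panss_missing: bool


# demographics used for age/sex sampling (means/SDs and female fractions of
# the study population the generator emulates)
_AGE_DIST = {"SCZ": (60.98, 9.789, 20, 79), "HC": (56.00, 10.505, 30, 80)}
_FEMALE_PROB = {"SCZ": 70 / 246, "HC": 14 / 35}


@dataclass(frozen=True)
class CohortConfig:
    n_hc: int = 35
    n_scz: int = 281
    canvas_size: tuple = (224, 224)
    n_regions: int = 5
    color_effect: ColorEffect = field(default_factory=ColorEffect)
    stroke_effect: dict = field(default_factory=lambda: {
        "HC": StrokeDist(45.0, 6.0, 12.0, 4.0, 0.15, 0.06, 90, 10.0),
        "SCZ": StrokeDist(22.0, 5.0, 55.0, 8.0, 0.65, 0.08, 70, 10.0),
    })
    panss_model: PanssModel = field(default_factory=PanssModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_hc < 0 or self.n_scz < 0:
            raise ValueError("cohort sizes must be non-negative")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        d["canvas_size"] = tuple(d["canvas_size"])
        d["color_effect"] = ColorEffect(**d["color_effect"])
        d["stroke_effect"] = {k: StrokeDist(**v) for k, v in d["stroke_effect"].items()}
        pm = d["panss_model"]
        pm["weights"] = {k: (v[0], tuple(v[1])) for k, v in pm["weights"].items()}
        d["panss_model"] = PanssModel(**pm)
        return cls(**d)


@dataclass
class Cohort:
    subjects: list
    images: dict          # id -> (H, W, 3) uint8 array
    config: CohortConfig
    profiles: dict = field(default_factory=dict)  # id -> SubjectProfile (ground truth)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.subjects])

    def labels(self) -> np.ndarray:
        """Binary group coding, 1 = SCZ."""
        return np.array([1 if s.group == "SCZ" else 0 for s in self.subjects])

    def ids_by_group(self) -> dict:
        out: dict = {"HC": [], "SCZ": []}
        for s in self.subjects:
            out[s.group].append(s.id)
        return out


def _subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    # stable per-subject substream: independent of generation order
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(subject_id.encode())]))


def sample_subject(group: str, config: CohortConfig, rng: np.random.Generator,
                   subject_id: str = "S000") -> SubjectProfile:
    """Draw one subject's latent painting behavior from the group model.

    PANSS is attached separately via :func:`assign_panss`; with probability
    ``missing_prob`` it stays absent (the subject never completed the scale).
    """
    if group not in ("HC", "SCZ"):
        raise ValueError("group must be HC or SCZ")
    ce = config.color_effect
    mean = ce.hc_mean if group == "HC" else ce.scz_mean
    n_colors = int(np.clip(round(rng.normal(mean, ce.sd)), 1, 12))
    sp = config.stroke_effect[group].draw(rng)
    mu, sd, lo, hi = _AGE_DIST[group]
    age = float(np.clip(rng.normal(mu, sd), lo, hi))
    sex = "F" if rng.random() < _FEMALE_PROB[group] else "M"
    profile = SubjectProfile(id=subject_id, group=group, n_colors=n_colors,
                             stroke_params=sp, age=age, sex=sex)
    if rng.random() >= config.panss_model.missing_prob:
        scores = assign_panss(profile, profile.painting_features(),
                              config.panss_model, rng)
        profile = dataclasses.replace(profile, panss=scores)
    return profile


def assign_panss(profile: SubjectProfile, painting_features, panss_model: PanssModel,
                 rng: np.random.Generator) -> PanssScores:
    """Score one subject: linear in painting features, noisy, clipped."""
    f = np.asarray(painting_features, dtype=float)
    vals = {}
    for key, bounds in (("P", P_BOUNDS), ("N", N_BOUNDS), ("G", G_BOUNDS)):
        intercept, w = panss_model.weights[key]
        raw = intercept + float(np.dot(w, f)) + rng.normal(0.0, panss_model.noise_sd)
        vals[key] = int(np.clip(round(raw), *bounds))
    return PanssScores(p=vals["P"], n=vals["N"], g=vals["G"],
                       total=vals["P"] + vals["N"] + vals["G"])


def _stroke_pixels(x0: float, y0: float, angle_deg: float, length: float,
                   width: int, shape: tuple):
    """Rasterize a straight stroke through (x0, y0); returns (rows, cols)."""
    h, w = shape
    th = np.deg2rad(angle_deg)
    dx, dy = np.cos(th), np.sin(th)
    half = length / 2.0
    # perpendicular offsets give 1-3 px thickness
    px, py = -dy, dx
    rows_all, cols_all = [], []
    for k in range(width):
        off = k - (width - 1) / 2.0
        xa = x0 + off * px - half * dx
        ya = y0 + off * py - half * dy
        xb = x0 + off * px + half * dx
        yb = y0 + off * py + half * dy
        rr, cc = _draw_line(int(round(ya)), int(round(xa)), int(round(yb)), int(round(xb)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rows_all.append(rr[keep])
        cols_all.append(cc[keep])
    return np.concatenate(rows_all), np.concatenate(cols_all)


def render_painting(profile: SubjectProfile, template: TemplateSpec,
                    palette: PaletteSpec, rng: np.random.Generator) -> np.ndarray:
    """Paint the template with the profile's color and stroke statistics.

    Strokes are straight segments (1-3 px wide) whose direction is Gaussian
    about horizontal with the profile's angular dispersion, clipped to the
    interior of the region their anchor falls in; anchors concentrate in
    the canvas-central disk with probability ``center_bias``.  Exactly
    ``n_colors`` distinct pen colors end up present.
    """
    img = template.render_blank()
    h, w = img.shape[:2]
    interiors = template.interior_masks()
    region_pixels = [np.argwhere(m) for m in interiors]  # (row, col) arrays
    region_pixels = [p for p in region_pixels if len(p)]
    if not region_pixels:
        return img
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    radius = min(w, h) / 4.0
    central = [p[( (p[:, 1] - cx) ** 2 + (p[:, 0] - cy) ** 2 ) <= radius**2]
               for p in region_pixels]

    chosen = rng.choice(12, size=profile.n_colors, replace=False)
    colors = palette.rgb[chosen]
    sp = profile.stroke_params
    n_strokes = max(sp.n_strokes, profile.n_colors)
    anchors: dict[int, tuple] = {}
    for s in range(n_strokes):
        ci = s % profile.n_colors  # round-robin so every color is attempted
        use_central = rng.random() < sp.center_bias
        candidates = [i for i, c in enumerate(central) if len(c)] if use_central else \
                     list(range(len(region_pixels)))
        if not candidates:
            candidates = list(range(len(region_pixels)))
            use_central = False
        ri = int(rng.choice(candidates))
        pool = central[ri] if use_central and len(central[ri]) else region_pixels[ri]
        r0, c0 = pool[int(rng.integers(len(pool)))]
        angle = rng.normal(0.0, sp.angle_dispersion)
        length = max(3.0, rng.normal(sp.mean_length, sp.mean_length / 4.0))
        width = int(rng.integers(1, 4))
        rr, cc = _stroke_pixels(c0, r0, angle, length, width, (h, w))
        keep = interiors[ri][rr, cc]  # stay inside the anchored region
        rr, cc = rr[keep], cc[keep]
        img[rr, cc] = colors[ci]
        anchors.setdefault(ci, (r0, c0))

    # later strokes may have buried a color entirely; restore one anchor pixel
    flat_bins = quantize_rgb(img[..., 0], img[..., 1], img[..., 2])
    reserved = set()
    for ci in range(profile.n_colors):
        target_bin = palette.bins[chosen[ci]]
        present = np.any(flat_bins == target_bin)
        if not present:
            r0, c0 = anchors.get(ci, tuple(region_pixels[0][0]))
            while (r0, c0) in reserved:
                c0 += 1
            img[r0, c0] = colors[ci]
            flat_bins[r0, c0] = target_bin
        reserved.add(anchors.get(ci, (0, 0)))
    return img


def generate_cohort(config: CohortConfig,
                    palette: PaletteSpec = DEFAULT_PALETTE) -> Cohort:
    """Generate the full cohort: one shared template, one painting each."""
    template = make_template(config.canvas_size, config.n_regions, config.seed)
    subjects: list[SubjectRecord] = []
    images: dict[str, np.ndarray] = {}
    profiles: dict[str, SubjectProfile] = {}
    plan = [("HC", i) for i in range(config.n_hc)] + \
           [("SCZ", i) for i in range(config.n_scz)]
    for group, i in plan:
        sid = f"{group}{i + 1:04d}"
        rng = _subject_rng(config.seed, sid)
        profile = sample_subject(group, config, rng, subject_id=sid)
        img = render_painting(profile, template, palette, rng)
        images[sid] = img
        profiles[sid] = profile
        if profile.panss is None:
            rec = SubjectRecord(sid, group, round(profile.age, 2), profile.sex,
                                float("nan"), float("nan"), float("nan"),
                                float("nan"), True)
        else:
            ps = profile.panss
            rec = SubjectRecord(sid, group, round(profile.age, 2), profile.sex,
                                float(ps.p), float(ps.n), float(ps.g),
                                float(ps.total), False)
        subjects.append(rec)
    return Cohort(subjects=subjects, images=images, config=config, profiles=profiles)


_CSV_COLUMNS = ["id", "group", "age", "sex", "panss_p", "panss_n", "panss_g",
                "panss_total", "panss_missing"]


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write one PNG per subject plus ``metadata.csv`` and ``config.json``."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for sid, arr in cohort.images.items():
        Image.fromarray(arr, mode="RGB").save(img_dir / f"{sid}.png")
    meta = cohort.metadata()[_CSV_COLUMNS]
    meta.to_csv(out / "metadata.csv", index=False)
    (out / "config.json").write_text(cohort.config.to_json())
    return out


def read_cohort(directory) -> Cohort:
    """Round-trip loader for :func:`write_cohort` output."""
    root = Path(directory)
    meta = pd.read_csv(root / "metadata.csv")
    config = CohortConfig.from_json((root / "config.json").read_text())
    subjects = []
    images = {}
    for row in meta.itertuples(index=False):
        subjects.append(SubjectRecord(
            id=row.id, group=row.group, age=float(row.age), sex=row.sex,
            panss_p=float(row.panss_p), panss_n=float(row.panss_n),
            panss_g=float(row.panss_g), panss_total=float(row.panss_total),
            panss_missing=bool(row.panss_missing)))
        with Image.open(root / "images" / f"{row.id}.png") as im:
            images[row.id] = np.asarray(im.convert("RGB"))
    return Cohort(subjects=subjects, images=images, config=config)
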