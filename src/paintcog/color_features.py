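"""64-bin RGB color histograms and per-color group association.

The RGB cube is partitioned uniformly into 4 levels per channel (4^3 = 64
cells); a painting's color signature is the pixel count per cell.  Group
association is mass-univariate: per bin, the point-biserial correlation of
pixel counts with the patient/control label, thresholded at an uncorrected
alpha, with a Benjamini-Hochberg-adjusted column reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_compare import bh_fdr, point_biserial

__all__ = [
    "N_BINS",
    "BACKGROUND_BIN",
    "OUTLINE_BIN",
    "ColorHistogram",
    "quantize_rgb",
    "color_histogram",
    "colors_used",
    "GroupColorModel",
    "GroupColorResults",
    "group_color_analysis",
]

N_BINS = 64
#: white canvas quantizes to the top cell, black outline to the bottom one
BACKGROUND_BIN = 63
OUTLINE_BIN = 0


@dataclass(frozen=True)
class ColorHistogram:
    """Pixel counts over the 64 quantization bins of one image."""

    counts: np.ndarray
    total_pixels: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_BINS,) or np.any(c < 0):
            raise ValueError("counts must be 64 non-negative integers")
        if int(c.sum()) != self.total_pixels:
            raise ValueError("histogram does not conserve pixel count")


def quantize_rgb(r, g, b):
    """Map 8-bit RGB channels to a bin in 0..63.

    Each channel is cut into 4 uniform levels (0-63, 64-127, 128-191,
    192-255); the bin index is ``16*level_r + 4*level_g + level_b``.
    Accepts scalars or arrays.
    """
    r = np.asarray(r)
    g = np.asarray(g)
    b = np.asarray(b)
    for name, ch in (("r", r), ("g", g), ("b", b)):
        if np.any(ch < 0) or np.any(ch > 255):
            raise ValueError(f"channel {name} outside [0, 255]")
    idx = 16 * (r.astype(np.int64) // 64) + 4 * (g.astype(np.int64) // 64) + b.astype(np.int64) // 64
    return idx if idx.ndim else int(idx)


def color_histogram(image) -> ColorHistogram:
    """64-bin histogram of an RGB raster (H x W x 3, uint8-valued)."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3 or arr.size == 0:
        raise ValueError("expected a non-empty H x W x 3 RGB raster")
    bins = quantize_rgb(arr[..., 0], arr[..., 1], arr[..., 2])
    counts = np.bincount(bins.ravel(), minlength=N_BINS)
    return ColorHistogram(counts=counts, total_pixels=int(counts.sum()))


def colors_used(histogram: ColorHistogram, min_pixels: int = 1,
                exclude=(BACKGROUND_BIN, OUTLINE_BIN)) -> int:
    """Number of distinct painted colors: bins with >= ``min_pixels`` pixels.

    Background (white) and outline (black) bins are excluded by default;
    unpainted canvas would otherwise dominate the count.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    counts = np.asarray(histogram.counts).copy()
    counts[list(exclude)] = 0
    return int(np.count_nonzero(counts >= min_pixels))


@dataclass
class GroupColorResults:
    """Per-bin association of color usage with group membership.

    Attributes
    ----------
    correlation, pvalue, qvalue : arrays of length 64 (NaN where undefined)
    significant : boolean mask, raw p < alpha among defined bins
    group_means : DataFrame of mean pixel counts per group per bin
    """

    correlation: np.ndarray
    pvalue: np.ndarray
    qvalue: np.ndarray
    significant: np.ndarray
    alpha: float
    group_means: pd.DataFrame
    n_subjects: int = 0
    defined: np.ndarray = field(default=None)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin": np.arange(N_BINS),
                "correlation": self.correlation,
                "pvalue": self.pvalue,
                "qvalue": self.qvalue,
                "significant": self.significant,
            }
        )
        for g in self.group_means.index:
            df[f"mean_{g}"] = self.group_means.loc[g].to_numpy()
        return df

    def to_json_dict(self) -> dict:
        s = self.summary()
        return {
            "alpha": self.alpha,
            "n_subjects": self.n_subjects,
            "n_significant": int(self.significant.sum()),
            "bins": s.where(pd.notna(s), None).to_dict(orient="records"),
        }


class GroupColorModel:
    """Mass-univariate color-vs-group association model.

    Parameters
    ----------
    histograms : sequence of ColorHistogram (or (n, 64) count array)
    group_labels : binary labels, 1 = patient, 0 = control
    """

    def __init__(self, histograms, group_labels):
        if hasattr(histograms[0], "counts"):
            counts = np.stack([np.asarray(h.counts) for h in histograms])
        else:
            counts = np.asarray(histograms, dtype=float)
        labels = np.asarray(group_labels)
        if counts.shape[0] != labels.size:
            raise ValueError("one histogram per label required")
        uniq, freq = np.unique(labels, return_counts=True)
        if uniq.size != 2 or freq.min() < 2:
            raise ValueError("need at least 2 subjects in each of two groups")
        self.counts = counts.astype(float)
        self.labels = (labels == uniq.max()).astype(int)
        self._label_names = [str(u) for u in uniq]

    def fit(self, alpha: float = 0.05) -> GroupColorResults:
        n, m = self.counts.shape
        r = np.full(m, np.nan)
        p = np.full(m, np.nan)
        for j in range(m):
            col = self.counts[:, j]
            if np.ptp(col) == 0:  # constant across subjects: undefined
                continue
            r[j], p[j] = point_biserial(col, self.labels)
        defined = ~np.isnan(p)
        q = np.full(m, np.nan)
        if defined.any():
            q[defined] = bh_fdr(p[defined])
        significant = np.zeros(m, dtype=bool)
        significant[defined] = p[defined] < alpha
        means = pd.DataFrame(
            {lbl: self.counts[self.labels == code].mean(axis=0)
             for code, lbl in enumerate(self._label_names)}
        ).T
        return GroupColorResults(
            correlation=r, pvalue=p, qvalue=q, significant=significant,
            alpha=alpha, group_means=means, n_subjects=n, defined=defined,
        )


def group_color_analysis(histograms, group_labels, alpha: float = 0.05) -> GroupColorResults:
    """Functional wrapper: fit :class:`GroupColorModel` in one call."""
    return GroupColorModel(histograms, group_labels).fit(alpha=alpha)
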