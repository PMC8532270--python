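"""Stroke analysis via the Hough transform accumulator space.

Strokes are straight line segments; in Hesse normal form a line is
``r = x*cos(theta) + y*sin(theta)`` with ``r`` the signed perpendicular
distance from the origin (top-left pixel, x = column, y = row) and ``theta``
the normal angle.  Every edge pixel votes, for each angle bin, into the
nearest ``r`` bin; collinear pixels pile votes into a shared cell, so the
accumulator is a per-subject signature of stroke direction and position.

Group comparison is mass-univariate over accumulator cells: pooled
two-sample t per cell with both a fixed p < 0.001 mask and a
Benjamini-Hochberg q-value column, plus a point-biserial correlation map
masked at |r| >= 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy import ndimage as _ndi
from scipy import stats as _sps

from .stats_compare import bh_fdr

__all__ = [
    "EdgeMap",
    "HoughGrid",
    "edge_map",
    "hough_accumulator",
    "hough_peak",
    "GroupStrokeModel",
    "StrokeGroupResults",
    "group_stroke_analysis",
]


@dataclass(frozen=True)
class EdgeMap:
    """Binary raster of edge pixels, same dimensions as the source image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or not np.isin(m, (0, 1)).all():
            raise ValueError("edge map must be a 2-D raster of 0/1 values")

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.mask))

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge pixel coordinates as (x, y) = (column, row) arrays."""
        ys, xs = np.nonzero(self.mask)
        return xs, ys


@dataclass(frozen=True)
class HoughGrid:
    """Accumulator H[r, theta] with explicit bin centers.

    ``theta_bins`` are degrees over [-90, 90); ``r_bins`` are pixels over
    [-D, D] with D the image diagonal.  Total votes equal
    ``n_edge_pixels * len(theta_bins)`` exactly.
    """

    H: np.ndarray
    r_bins: np.ndarray
    theta_bins: np.ndarray

    def __post_init__(self) -> None:
        if self.H.shape != (len(self.r_bins), len(self.theta_bins)):
            raise ValueError("accumulator shape must be (n_r, n_theta)")
        if np.any(self.H < 0):
            raise ValueError("votes must be non-negative")

    @property
    def total_votes(self) -> int:
        return int(self.H.sum())


def edge_map(image, threshold_frac: float = 0.2) -> EdgeMap:
    """Edge pixels by thresholded 3x3 Sobel gradient magnitude of luminance.

    A pixel is an edge when its gradient magnitude is at least
    ``threshold_frac`` times the image maximum; a uniform image (zero max
    gradient) yields an empty edge map.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        # Rec.601 luma
        lum = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    else:
        lum = arr
    gx = _ndi.sobel(lum, axis=1, mode="nearest")
    gy = _ndi.sobel(lum, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak == 0:
        return EdgeMap(np.zeros_like(lum, dtype=np.uint8))
    return EdgeMap((mag >= threshold_frac * peak).astype(np.uint8))


def _bin_centers(shape, theta_step: float, r_step: float):
    h, w = shape
    diag = math.hypot(w - 1, h - 1)
    n_theta = int(round(180.0 / theta_step))
    theta = -90.0 + theta_step * np.arange(n_theta)
    n_side = int(math.ceil(diag / r_step))
    r = r_step * np.arange(-n_side, n_side + 1)
    return r, theta


def hough_accumulator(edges: EdgeMap, theta_step: float = 1.0, r_step: float = 1.0) -> HoughGrid:
    """Vote every edge pixel into the accumulator, one r bin per theta bin.

    For each edge pixel (x, y) and each theta bin center, the distance
    ``r = x*cos(theta) + y*sin(theta)`` is assigned to the nearest r bin.
    ``r`` is quantized to 1e-9 px first so that knife-edge halfway cases
    (exact at angles like +/-60 or +/-90 degrees on integer pixel grids)
    are well-defined; those ties break toward the smaller r.  Vote count is
    conserved exactly: ``sum(H) = n_edge_pixels * n_theta_bins``.
    """
    if theta_step <= 0 or r_step <= 0:
        raise ValueError("bin widths must be positive")
    r_bins, theta_bins = _bin_centers(edges.mask.shape, theta_step, r_step)
    H = np.zeros((len(r_bins), len(theta_bins)), dtype=np.int64)
    xs, ys = edges.points()
    if xs.size == 0:
        return HoughGrid(H=H, r_bins=r_bins, theta_bins=theta_bins)
    th = np.deg2rad(theta_bins)
    r0 = r_bins[0]
    n_r = len(r_bins)
    for j, (c, s) in enumerate(zip(np.cos(th), np.sin(th))):
        r = np.round(xs * c + ys * s, 9)
        # nearest bin, half-way ties resolved toward the smaller r
        idx = np.ceil((r - r0) / r_step - 0.5).astype(np.int64)
        np.clip(idx, 0, n_r - 1, out=idx)
        H[:, j] = np.bincount(idx, minlength=n_r)
    return HoughGrid(H=H, r_bins=r_bins, theta_bins=theta_bins)


def hough_peak(grid: HoughGrid):
    """Accumulator argmax: the dominant line as ``(r*, theta*, votes)``.

    Ties are broken by the smallest theta, then the smallest r.  Returns
    ``None`` for an all-zero grid (no edge evidence).
    """
    votes = int(grid.H.max(initial=0))
    if votes == 0:
        return None
    ris, tis = np.nonzero(grid.H == votes)
    order = np.lexsort((ris, tis))  # primary: theta, secondary: r
    ri, ti = ris[order[0]], tis[order[0]]
    return float(grid.r_bins[ri]), float(grid.theta_bins[ti]), votes


@dataclass
class StrokeGroupResults:
    """Per-cell group comparison over a stack of accumulators.

    ``tstat``, ``pvalue``, ``qvalue``, ``correlation`` are maps shaped like
    the accumulator (NaN where a cell had zero variance); ``mask_p`` flags
    cells with raw p < p_threshold and ``mask_r`` those with
    |correlation| >= r_threshold.
    """

    tstat: np.ndarray
    pvalue: np.ndarray
    qvalue: np.ndarray
    correlation: np.ndarray
    mask_p: np.ndarray
    mask_r: np.ndarray
    p_threshold: float
    r_threshold: float
    r_bins: np.ndarray
    theta_bins: np.ndarray

    def summary(self) -> dict:
        defined = ~np.isnan(self.pvalue)
        return {
            "n_cells": int(self.pvalue.size),
            "n_defined": int(defined.sum()),
            "p_threshold": self.p_threshold,
            "r_threshold": self.r_threshold,
            "n_significant_p": int(self.mask_p.sum()),
            "n_significant_q": int(np.nansum(self.qvalue < self.p_threshold)) if defined.any() else 0,
            "n_strong_correlation": int(self.mask_r.sum()),
        }


class GroupStrokeModel:
    """Mass-univariate accumulator-space comparison of two groups.

    Parameters
    ----------
    grids : sequence of HoughGrid sharing identical bin edges
    group_labels : binary labels, 1 = patient, 0 = control
    """

    def __init__(self, grids, group_labels):
        labels = np.asarray(group_labels)
        if len(grids) != labels.size:
            raise ValueError("one grid per label required")
        ref = grids[0]
        for g in grids[1:]:
            if (g.H.shape != ref.H.shape
                    or not np.array_equal(g.r_bins, ref.r_bins)
                    or not np.array_equal(g.theta_bins, ref.theta_bins)):
                raise ValueError("all grids must share identical bin edges")
        uniq, freq = np.unique(labels, return_counts=True)
        if uniq.size != 2 or freq.min() < 2:
            raise ValueError("need at least 2 subjects in each of two groups")
        self.shape = ref.H.shape
        self.r_bins = ref.r_bins
        self.theta_bins = ref.theta_bins
        self.X = np.stack([g.H.ravel() for g in grids]).astype(float)
        self.labels = (labels == uniq.max()).astype(int)

    def fit(self, p_threshold: float = 0.001, r_threshold: float = 0.3) -> StrokeGroupResults:
        y = self.labels
        a = self.X[y == 1]
        b = self.X[y == 0]
        na, nb = a.shape[0], b.shape[0]
        df = na + nb - 2
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        diff = a.mean(axis=0) - b.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        zero_var = sp2 == 0
        t[zero_var & (diff == 0)] = 0.0
        undefined = zero_var  # constant cells carry no group information
        t[undefined] = np.nan
        p = 2.0 * _sps.t.sf(np.abs(t), df)

        # point-biserial correlation map (vectorized Pearson with 0/1 labels)
        xc = self.X - self.X.mean(axis=0)
        yc = (y - y.mean()).astype(float)
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (yc @ xc) / denom
        corr[denom == 0] = np.nan

        q = np.full_like(p, np.nan)
        defined = ~np.isnan(p)
        if defined.any():
            q[defined] = bh_fdr(p[defined])
        mask_p = np.zeros(p.size, dtype=bool)
        mask_p[defined] = p[defined] < p_threshold
        mask_r = np.zeros(p.size, dtype=bool)
        cdef = ~np.isnan(corr)
        mask_r[cdef] = np.abs(corr[cdef]) >= r_threshold

        shape = self.shape
        return StrokeGroupResults(
            tstat=t.reshape(shape), pvalue=p.reshape(shape), qvalue=q.reshape(shape),
            correlation=corr.reshape(shape), mask_p=mask_p.reshape(shape),
            mask_r=mask_r.reshape(shape), p_threshold=p_threshold,
            r_threshold=r_threshold, r_bins=self.r_bins, theta_bins=self.theta_bins,
        )


def group_stroke_analysis(grids, group_labels, p_threshold: float = 0.001,
                          r_threshold: float = 0.3) -> StrokeGroupResults:
    """Functional wrapper: fit :class:`GroupStrokeModel` in one call."""
    return GroupStrokeModel(grids, group_labels).fit(p_threshold=p_threshold,
                                                     r_threshold=r_threshold)
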