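"""Gamma-index comparison of planned and measured dose maps.

For each reference pixel r_c above the low-dose threshold,

    gamma(r_c) = min over measured pixels r_m of
                 sqrt( |r_c - r_m|**2 / DTA**2
                       + (D_ref(r_c) - D_meas(r_m))**2 / dD_norm**2 )

with distances in mm.  The dose-difference normalization dD_norm is
``DD% * max(D_ref)`` (global mode), ``DD% * D_ref(r_c)`` (local), or a
fixed dose in Gy (absolute).  A pixel passes when gamma <= 1; the pass
rate counts only evaluated (above-threshold) pixels.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .image_io import DoseMap

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "gamma_matrix",
    "pass_rate",
    "gamma_histogram",
]


@dataclasses.dataclass
class GammaCriteria:
    """DD/DTA criteria and evaluation options for the gamma test."""

    dd_percent: float = 3.0
    dta_mm: float = 3.0
    threshold_percent: float = 5.0
    normalization: str = "global"  # 'global' | 'local' | 'absolute'
    search_radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.dd_percent <= 0:
            raise ValueError("dd_percent must be positive")
        if self.dta_mm <= 0:
            raise ValueError("dta_mm must be positive")
        if self.threshold_percent < 0:
            raise ValueError("threshold_percent must be non-negative")
        if self.normalization not in ("global", "local", "absolute"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.search_radius_factor <= 0:
            raise ValueError("search_radius_factor must be positive")


@dataclasses.dataclass
class GammaResult:
    """Per-pixel gamma values on the reference grid plus summary statistics."""

    gamma: np.ndarray
    evaluated_mask: np.ndarray
    pass_rate: float
    criteria: GammaCriteria

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated_mask.sum())


def _measured_on_reference_grid(reference: DoseMap, measured: DoseMap) -> np.ndarray:
    """Bilinearly sample the measured map at the reference pixel centers.

    Reference positions outside the measured grid become NaN (no candidate
    there).  Raises if the grids do not overlap at all.
    """
    same = (
        measured.shape == reference.shape
        and measured.pixel_spacing_mm == reference.pixel_spacing_mm
        and measured.origin_mm == reference.origin_mm
    )
    if same:
        return measured.dose_gy.astype(float)
    rows, cols = reference.shape
    ri = (
        reference.origin_mm[0]
        + np.arange(rows) * reference.pixel_spacing_mm[0]
        - measured.origin_mm[0]
    ) / measured.pixel_spacing_mm[0]
    ci = (
        reference.origin_mm[1]
        + np.arange(cols) * reference.pixel_spacing_mm[1]
        - measured.origin_mm[1]
    ) / measured.pixel_spacing_mm[1]
    grid = np.meshgrid(ri, ci, indexing="ij")
    out = ndimage.map_coordinates(
        measured.dose_gy, grid, order=1, mode="constant", cval=np.nan
    )
    if np.all(np.isnan(out)):
        raise ValueError("reference and measured grids do not overlap")
    return out


def gamma_matrix(reference: DoseMap, measured: DoseMap, criteria: GammaCriteria) -> GammaResult:
    """Discrete gamma matrix: min over measured pixels within the search radius.

    The measured map is resampled onto the reference grid if their
    geometries differ.  The search is truncated at
    ``search_radius_factor * DTA`` — the zero-displacement candidate is
    always included, so every evaluated pixel receives a finite gamma.
    Evaluation is pixel-center discrete (no sub-pixel interpolation inside
    the minimization).
    """
    d_ref = reference.dose_gy.astype(float)
    d_meas = _measured_on_reference_grid(reference, measured)
    d_max = float(d_ref.max())
    if d_max <= 0:
        raise ValueError("reference map has no positive dose to normalize against")

    eval_mask = d_ref >= criteria.threshold_percent / 100.0 * d_max
    if criteria.normalization == "local":
        eval_mask &= d_ref > 0

    if criteria.normalization == "global":
        denom = criteria.dd_percent / 100.0 * d_max
        denom_arr = None
    elif criteria.normalization == "absolute":
        denom = criteria.dd_percent
        denom_arr = None
    else:  # local
        denom = None
        denom_arr = criteria.dd_percent / 100.0 * np.where(d_ref > 0, d_ref, np.inf)

    dr, dc = reference.pixel_spacing_mm
    radius = criteria.search_radius_factor * criteria.dta_mm
    ni = int(math.floor(radius / dr))
    nj = int(math.floor(radius / dc))
    rows, cols = d_ref.shape
    dta2 = criteria.dta_mm**2

    g2 = np.full(d_ref.shape, np.inf)
    for di in range(-ni, ni + 1):
        for dj in range(-nj, nj + 1):
            dist2 = (di * dr) ** 2 + (dj * dc) ** 2
            if dist2 > radius**2 and not (di == 0 and dj == 0):
                continue
            r0, r1 = max(0, -di), min(rows, rows - di)
            c0, c1 = max(0, -dj), min(cols, cols - dj)
            if r0 >= r1 or c0 >= c1:
                continue
            rs = (slice(r0, r1), slice(c0, c1))
            ms = (slice(r0 + di, r1 + di), slice(c0 + dj, c1 + dj))
            diff = d_ref[rs] - d_meas[ms]
            dn = denom if denom_arr is None else denom_arr[rs]
            cand = dist2 / dta2 + (diff / dn) ** 2
            g2[rs] = np.fmin(g2[rs], cand)

    no_candidate = ~np.isfinite(g2)
    eval_mask &= ~no_candidate
    gamma = np.sqrt(np.where(np.isfinite(g2), g2, np.nan))

    n_eval = int(eval_mask.sum())
    rate = float((gamma[eval_mask] <= 1.0).sum() / n_eval) if n_eval else float("nan")
    return GammaResult(gamma=gamma, evaluated_mask=eval_mask, pass_rate=rate, criteria=criteria)


def pass_rate(result: GammaResult) -> float:
    """Fraction of evaluated pixels with gamma <= 1 (inclusive)."""
    n_eval = result.n_evaluated
    if n_eval == 0:
        raise ValueError("no evaluated pixels (threshold removed everything)")
    return float((result.gamma[result.evaluated_mask] <= 1.0).sum() / n_eval)


def gamma_histogram(result: GammaResult, n_bins: int = 50):
    """Histogram of gamma over evaluated pixels; counts sum to n_evaluated."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if result.n_evaluated == 0:
        raise ValueError("no evaluated pixels to histogram")
    values = result.gamma[result.evaluated_mask]
    hi = max(float(values.max()), 1e-12)  # gamma is non-negative by construction
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, hi))
    return edges, counts
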