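"""Film response extraction: transmittance/optical density, ROI statistics,
net responses with propagated uncertainties, and scan denoising.

The scanner reports an integer pixel value PV per channel; transmittance is
``T = PV / (2**bits - 1)`` and optical density is ``OD = -log10(T)``.  The
dose-induced response of a film piece is the net change between the
pre-irradiation and post-irradiation scans, ``netT = T_f - T_i`` and
``netOD = OD_f - OD_i``; for darkening film both are negative/positive
respectively in sign as computed — no sign flip is applied, the calibration
parameters absorb it.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .image_io import ScannedFilm

__all__ = [
    "RoiStats",
    "NetResponse",
    "pixel_to_transmittance",
    "transmittance_to_od",
    "roi_statistics",
    "net_response",
    "weighted_net_od",
    "denoise",
]

_LN10 = math.log(10.0)


@dataclasses.dataclass
class RoiStats:
    """Per-channel mean and population standard deviation of raw PV in a ROI."""

    mean_pv: np.ndarray  # (3,)
    std_pv: np.ndarray  # (3,)
    n_pixels: int

    def __post_init__(self) -> None:
        self.mean_pv = np.asarray(self.mean_pv, dtype=float)
        self.std_pv = np.asarray(self.std_pv, dtype=float)
        if self.n_pixels < 1:
            raise ValueError("ROI must contain at least one pixel")
        if np.any(self.std_pv < 0):
            raise ValueError("std_pv must be non-negative")


@dataclasses.dataclass
class NetResponse:
    """Net film response per channel with propagated uncertainties."""

    net_t: np.ndarray  # (3,), dimensionless, T_f - T_i
    net_od: np.ndarray  # (3,), dimensionless, OD_f - OD_i
    sigma_net_od: np.ndarray  # (3,), >= 0
    sigma_net_t: np.ndarray  # (3,), >= 0

    def response(self, kind: str) -> np.ndarray:
        if kind == "net_t":
            return self.net_t
        if kind == "net_od":
            return self.net_od
        raise ValueError(f"unknown response kind {kind!r}")

    def sigma(self, kind: str) -> np.ndarray:
        """Uncertainty on the same scale as ``response(kind)``."""
        if kind == "net_t":
            return self.sigma_net_t
        if kind == "net_od":
            return self.sigma_net_od
        raise ValueError(f"unknown response kind {kind!r}")


def pixel_to_transmittance(pv, bit_depth: int):
    """Convert pixel value(s) to transmittance ``T = PV / (2**bit_depth - 1)``.

    PV = 0 (dead pixel) is clamped to 1 count so that the subsequent optical
    density stays finite; the clamp shows up as noise rather than a crash.
    """
    max_val = (1 << bit_depth) - 1
    pv = np.asarray(pv, dtype=float)
    if np.any(pv < 0) or np.any(pv > max_val):
        raise ValueError(f"pixel value outside [0, {max_val}]")
    t = np.maximum(pv, 1.0) / max_val
    return t if t.ndim else float(t)


def transmittance_to_od(t):
    """Optical density ``OD = -log10(T)``."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("transmittance must be positive")
    od = -np.log10(t)
    return od if od.ndim else float(od)


def roi_statistics(film: ScannedFilm, roi: tuple[int, int, int, int]) -> RoiStats:
    """Per-channel PV statistics over a rectangular ROI.

    ``roi`` is ``(row0, col0, height, width)`` in pixels.  The standard
    deviation is the population one (divide by n): ROIs in practice hold
    thousands of pixels and the fixed convention keeps results exact.
    """
    row0, col0, height, width = (int(v) for v in roi)
    rows, cols = film.shape
    if height < 1 or width < 1:
        raise ValueError("ROI must be non-empty")
    if row0 < 0 or col0 < 0 or row0 + height > rows or col0 + width > cols:
        raise ValueError(
            f"ROI {roi} exceeds image bounds {rows}x{cols}"
        )
    block = film.pixels[row0 : row0 + height, col0 : col0 + width].astype(float)
    return RoiStats(
        mean_pv=block.mean(axis=(0, 1)),
        std_pv=block.std(axis=(0, 1)),  # population
        n_pixels=height * width,
    )


def net_response(pre: RoiStats, post: RoiStats, bit_depth: int) -> NetResponse:
    """Net response between pre- and post-irradiation ROI statistics.

    netT and netOD are computed channel-wise from the mean PVs; uncertainties
    follow first-order propagation of the PV scatter:

        sigma_netOD = (1/ln 10) * sqrt((sPV_f/PV_f)**2 + (sPV_i/PV_i)**2)
        sigma_netT  = sqrt(sPV_f**2 + sPV_i**2) / (2**bits - 1)
    """
    if np.any(pre.mean_pv <= 0) or np.any(post.mean_pv <= 0):
        raise ValueError("mean PV must be positive (optical density undefined at 0)")
    t_i = pixel_to_transmittance(pre.mean_pv, bit_depth)
    t_f = pixel_to_transmittance(post.mean_pv, bit_depth)
    net_t = t_f - t_i
    net_od = transmittance_to_od(t_f) - transmittance_to_od(t_i)
    rel_f = post.std_pv / post.mean_pv
    rel_i = pre.std_pv / pre.mean_pv
    sigma_od = np.sqrt(rel_f**2 + rel_i**2) / _LN10
    max_val = (1 << bit_depth) - 1
    sigma_t = np.sqrt(post.std_pv**2 + pre.std_pv**2) / max_val
    return NetResponse(net_t=net_t, net_od=net_od,
                       sigma_net_od=sigma_od, sigma_net_t=sigma_t)


def weighted_net_od(values: list[tuple[float, float]]) -> tuple[float, float]:
    """Inverse-variance weighted average of replicate netOD measurements.

    Weights are ``w_i = (1/s_i**2) / sum_j (1/s_j**2)`` and the combined
    uncertainty is ``sqrt(1 / sum_j (1/s_j**2))`` — the minimum-variance
    unbiased combination.  If every sigma is zero the plain mean is
    returned with zero uncertainty; mixing zero and non-zero sigmas is
    ill-posed and rejected.
    """
    if len(values) == 0:
        raise ValueError("need at least one measurement")
    net = np.array([v[0] for v in values], dtype=float)
    sig = np.array([v[1] for v in values], dtype=float)
    if np.any(sig < 0):
        raise ValueError("sigmas must be non-negative")
    if np.all(sig == 0):
        return float(net.mean()), 0.0
    if np.any(sig == 0):
        raise ValueError("mixed zero and non-zero sigmas make the weights ill-posed")
    inv_var = 1.0 / sig**2
    mean = float(np.sum(inv_var * net) / np.sum(inv_var))
    return mean, float(math.sqrt(1.0 / np.sum(inv_var)))


def _adaptive_wiener(image: np.ndarray, window: int) -> np.ndarray:
    """Locally adaptive Wiener (Lee) filter.

    Shrinks each pixel toward the local window mean by the factor
    ``max(lvar - noise, 0) / lvar``, with the noise power estimated as the
    mean of the local variances over the image.  A constant image (noise
    power 0) passes through unchanged.
    """
    lmean = ndimage.uniform_filter(image, size=window, mode="reflect")
    lsq = ndimage.uniform_filter(image * image, size=window, mode="reflect")
    lvar = np.maximum(lsq - lmean * lmean, 0.0)
    noise = lvar.mean()
    if noise == 0:
        return image.copy()
    gain = np.where(lvar > noise, (lvar - noise) / np.where(lvar > 0, lvar, 1.0), 0.0)
    return lmean + gain * (image - lmean)


def denoise(image: np.ndarray, median_size: int = 3, wiener_window: int = 5) -> np.ndarray:
    """Two-stage scan denoising: median (spike removal) then adaptive Wiener.

    Both window sizes must be odd; a size of 1 disables that stage.  The
    output has the same shape as the input and constant images are
    preserved exactly.
    """
    for name, size in (("median_size", median_size), ("wiener_window", wiener_window)):
        if size < 1 or size % 2 == 0:
            raise ValueError(f"{name} must be an odd integer >= 1, got {size}")
    out = np.asarray(image, dtype=float)
    if median_size > 1:
        out = ndimage.median_filter(out, size=median_size, mode="reflect")
    if wiener_window > 1:
        out = _adaptive_wiener(out, wiener_window)
    return out
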