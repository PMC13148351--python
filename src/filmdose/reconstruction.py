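"""Dose reconstruction from scanned films.

Single-channel reconstruction applies the calibration law pixel by pixel to
the net response of one color channel.  The multichannel method additionally
separates the dose-dependent color change from dose-independent disturbances
(film thickness variation, scanner non-uniformity, dust): at each pixel a
scalar ``t`` scales the measured optical density of every channel, and the
value ``t_min`` that makes the three per-channel dose predictions agree —
minimizing ``g(t) = sum_{i<j} (D_i(t) - D_j(t))**2`` — is found by
Newton–Raphson.  The map of ``t_min`` values images the disturbances, and
the reconstructed dose is the mean of the three channel doses at ``t_min``.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .calibration import CalibrationModel
from .image_io import DoseMap, ScannedFilm

__all__ = [
    "MultichannelResult",
    "single_channel_dose",
    "multichannel_dose",
    "multichannel_objective",
    "solve_disturbance",
]

log = logging.getLogger(__name__)

_LN10 = math.log(10.0)
_CHANNELS = ("R", "G", "B")


@dataclasses.dataclass
class MultichannelResult:
    """Outcome of a multichannel reconstruction.

    ``t_map`` is the per-pixel disturbance scaling factor; ``converged``
    flags pixels where the optimizer found an interior minimum.  Pixels that
    did not converge are filled with the red-channel single-channel dose and
    left flagged — they are never silently interpolated.
    """

    dose: DoseMap
    t_map: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray

    @property
    def n_nonconverged(self) -> int:
        return int((~self.converged).sum())


# ---------------------------------------------------------------------------
# response bookkeeping
# ---------------------------------------------------------------------------

def _film_od(film: ScannedFilm) -> np.ndarray:
    """Per-pixel optical density of all three channels, shape (rows, cols, 3)."""
    pv = np.maximum(film.pixels.astype(float), 1.0)  # dead-pixel clamp
    return -np.log10(pv / film.max_value)


def _pre_od(pre, film: ScannedFilm) -> tuple[np.ndarray, bool]:
    """Normalize the pre-irradiation reference to per-channel OD.

    ``pre`` may be a pre-scan :class:`ScannedFilm` (per-pixel reference,
    assumed co-registered, returned with ``scale_pre=True`` so the
    disturbance scaling applies to it too), a scalar transmittance, or a
    3-vector of per-channel transmittances (trusted disturbance-free
    references, ``scale_pre=False``).
    """
    if isinstance(pre, ScannedFilm):
        if pre.shape != film.shape:
            raise ValueError("pre-scan shape does not match film shape")
        return _film_od(pre), True
    t = np.asarray(pre, dtype=float)
    if t.ndim == 0:
        t = np.full(3, float(t))
    if t.shape != (3,):
        raise ValueError("scalar reference must be one or three transmittance values")
    if np.any(t <= 0) or np.any(t > 1):
        raise ValueError("reference transmittance must lie in (0, 1]")
    return -np.log10(t), False


def _net_response(model: CalibrationModel, od_f, od_i, t, scale_pre: bool):
    """Net response r(t) and its first two t-derivatives for one channel.

    The disturbance parameter scales the measured post-scan OD,
    ``OD_f -> OD_f * t`` (and the pre-scan OD as well when the reference is
    itself a scan).  For ``net_od`` models the response is the OD
    difference; for ``net_t`` models the transmittances are recomputed from
    the scaled ODs.
    """
    t = np.asarray(t, dtype=float)
    if model.response_kind == "net_od":
        od_i_eff = od_i * t if scale_pre else od_i
        r = od_f * t - od_i_eff
        r1 = od_f - (od_i if scale_pre else 0.0)
        r1 = np.broadcast_to(np.asarray(r1, dtype=float), r.shape)
        r2 = np.zeros_like(r)
        return r, r1, r2
    # net_t
    t_f = 10.0 ** (-od_f * t)
    if scale_pre:
        t_i = 10.0 ** (-od_i * t)
        r = t_f - t_i
        r1 = -_LN10 * od_f * t_f + _LN10 * od_i * t_i
        r2 = (_LN10 * od_f) ** 2 * t_f - (_LN10 * od_i) ** 2 * t_i
    else:
        r = t_f - 10.0 ** (-od_i)
        r1 = -_LN10 * od_f * t_f
        r2 = (_LN10 * od_f) ** 2 * t_f
    return r, r1, r2


def _channel_dose_dt(model, od_f, od_i, t, scale_pre):
    """Dose D(t) and derivatives dD/dt, d2D/dt2 for one channel (chain rule)."""
    r, r1, r2 = _net_response(model, od_f, od_i, t, scale_pre)
    d, dd, ddd = model.dose_derivatives(r)
    return d, dd * r1, ddd * r1**2 + dd * r2


def _as_model_dict(models) -> dict[str, CalibrationModel]:
    if isinstance(models, dict):
        out = {ch: models[ch] for ch in _CHANNELS if ch in models}
    else:
        out = {m.channel: m for m in models}
    missing = [ch for ch in _CHANNELS if ch not in out]
    if missing:
        raise ValueError(f"missing calibration model for channel(s) {missing}")
    return out


def multichannel_objective(od_post, models, od_pre, t, scale_pre: bool = False):
    """Channel-agreement objective ``g(t) = sum_{i<j} (D_i(t) - D_j(t))**2``.

    ``od_post`` has shape (..., 3); ``od_pre`` is broadcastable per channel;
    ``t`` broadcasts against the leading dimensions.  Exposed for
    inspection and for brute-force verification of the per-pixel optimizer.
    """
    models = _as_model_dict(models)
    od_post = np.asarray(od_post, dtype=float)
    od_pre = np.asarray(od_pre, dtype=float)
    doses = []
    for k, ch in enumerate(_CHANNELS):
        oi = od_pre[..., k] if od_pre.ndim and od_pre.shape[-1] == 3 else od_pre
        r, _, _ = _net_response(models[ch], od_post[..., k], oi, t, scale_pre)
        d, _, _ = models[ch].dose_derivatives(r)
        doses.append(d)
    g = np.zeros_like(np.asarray(doses[0], dtype=float))
    for i in range(3):
        for j in range(i + 1, 3):
            g = g + (doses[i] - doses[j]) ** 2
    return g


# ---------------------------------------------------------------------------
# single channel
# ---------------------------------------------------------------------------

def single_channel_dose(
    film: ScannedFilm,
    model: CalibrationModel,
    channel: str,
    pre=1.0,
) -> DoseMap:
    """Pixel-by-pixel dose map from one color channel.

    ``pre`` is the pre-irradiation reference: a pre-scan film, a scalar
    transmittance, or three per-channel transmittances (default 1.0, i.e.
    responses taken relative to an ideal clear reference — supply the real
    unexposed-film value for absolute work).  Negative model outputs are
    clamped to zero (and logged).
    """
    channel = channel.upper()
    if channel not in _CHANNELS:
        raise ValueError(f"channel must be one of {_CHANNELS}, got {channel!r}")
    if model.channel != channel:
        raise ValueError(
            f"model is calibrated for channel {model.channel}, requested {channel}"
        )
    k = _CHANNELS.index(channel)
    od_f = _film_od(film)[:, :, k]
    od_pre, _ = _pre_od(pre, film)
    od_i = od_pre[:, :, k] if od_pre.ndim == 3 else od_pre[k]
    if model.response_kind == "net_t":
        resp = 10.0 ** (-od_f) - 10.0 ** (-od_i)
    else:
        resp = od_f - od_i
    dose, _, _ = model.dose_derivatives(resp)
    n_neg = int((dose < 0).sum())
    if n_neg:
        log.info("single_channel_dose: clamped %d negative pixels to 0 Gy", n_neg)
    return DoseMap(np.clip(dose, 0.0, None), film.pixel_spacing_mm)


# ---------------------------------------------------------------------------
# multichannel
# ---------------------------------------------------------------------------

def _golden_section(fun, lo: float, hi: float, n_active: int, n_iter: int = 80):
    """Vectorized golden-section minimization of ``fun`` over [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a = np.full(n_active, lo)
    b = np.full(n_active, hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(n_iter):
        take_c = fc < fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c_new = b - invphi * (b - a)
        d_new = a + invphi * (b - a)
        # only one endpoint moved per side; re-evaluate both for simplicity
        c, d = c_new, d_new
        fc, fd = fun(c), fun(d)
    return 0.5 * (a + b)


def solve_disturbance(
    od_post: np.ndarray,
    models,
    od_pre,
    scale_pre: bool = False,
    t_bounds: tuple[float, float] = (0.5, 1.5),
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel disturbance factor minimizing the channel-agreement objective.

    ``od_post`` is (n, 3) measured post-irradiation OD; ``od_pre`` is the
    reference OD, (3,) or (n, 3).  Newton–Raphson on ``g'(t)`` from
    ``t0 = 1`` with at most ``max_iter`` iterations and step tolerance
    ``tol``; pixels where Newton leaves ``t_bounds`` or meets non-convex
    curvature fall back to a golden-section search over ``t_bounds``.
    Returns ``(t, iterations, converged)``; a pixel whose minimum sits on
    the bounds (no interior minimum) is flagged non-converged.
    """
    models = _as_model_dict(models)
    mlist = [models[ch] for ch in _CHANNELS]
    od_f = np.asarray(od_post, dtype=float)
    if od_f.ndim != 2 or od_f.shape[1] != 3:
        raise ValueError("od_post must have shape (n, 3)")
    n = od_f.shape[0]
    od_i = np.asarray(od_pre, dtype=float)
    if od_i.ndim == 1:
        od_i = np.broadcast_to(od_i, (n, 3))

    def g_derivs(t, idx):
        d = np.empty((idx.size, 3))
        d1 = np.empty((idx.size, 3))
        d2 = np.empty((idx.size, 3))
        for k, m in enumerate(mlist):
            d[:, k], d1[:, k], d2[:, k] = _channel_dose_dt(
                m, od_f[idx, k], od_i[idx, k], t, scale_pre
            )
        g1 = np.zeros(idx.size)
        g2 = np.zeros(idx.size)
        for i in range(3):
            for j in range(i + 1, 3):
                dij = d[:, i] - d[:, j]
                dij1 = d1[:, i] - d1[:, j]
                dij2 = d2[:, i] - d2[:, j]
                g1 += 2.0 * dij * dij1
                g2 += 2.0 * (dij1**2 + dij * dij2)
        return g1, g2

    def g_value(t, idx):
        d = np.empty(t.shape + (3,))
        for k, m in enumerate(mlist):
            r, _, _ = _net_response(m, od_f[idx, k], od_i[idx, k], t, scale_pre)
            d[..., k], _, _ = m.dose_derivatives(r)
        g = np.zeros(t.shape)
        for i in range(3):
            for j in range(i + 1, 3):
                g += (d[..., i] - d[..., j]) ** 2
        return g

    lo, hi = t_bounds
    t = np.ones(n)
    iters = np.zeros(n, dtype=int)
    done = np.zeros(n, dtype=bool)
    needs_fallback = np.zeros(n, dtype=bool)

    active = np.arange(n)
    for _ in range(max_iter):
        if active.size == 0:
            break
        g1, g2 = g_derivs(t[active], active)
        # stationary to float precision: the implied Newton step is < 1e-9
        flat = np.abs(g1) < 1e-9 * np.maximum(1.0, np.abs(g2))
        bad = (~np.isfinite(g1)) | (~np.isfinite(g2)) | (g2 <= 0)
        step = np.where(bad | flat, 0.0, g1 / np.where(g2 != 0, g2, 1.0))
        t_new = t[active] - step
        out = (t_new < lo) | (t_new > hi)
        t[active] = np.where(out, t[active], t_new)
        iters[active] += 1
        conv = flat | (np.abs(step) < tol) & ~bad & ~out
        done[active[conv]] = True
        needs_fallback[active[bad & ~flat]] = True
        needs_fallback[active[out]] = True
        keep = ~(conv | bad | out)
        active = active[keep]
    # exhausted iterations -> fall back rather than trust a wandering iterate
    needs_fallback[active] = True

    fb = np.flatnonzero(needs_fallback & ~done)
    boundary = np.zeros(n, dtype=bool)
    if fb.size:
        t_fb = _golden_section(lambda tt: g_value(tt, fb), lo, hi, fb.size)
        t[fb] = t_fb
        done[fb] = True
        edge_tol = 1e-3 * (hi - lo)
        boundary[fb] = (t_fb < lo + edge_tol) | (t_fb > hi - edge_tol)

    converged = done & ~boundary
    return t, iters, converged


def multichannel_dose(
    film: ScannedFilm,
    models,
    pre=1.0,
    t_bounds: tuple[float, float] = (0.5, 1.5),
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MultichannelResult:
    """Multichannel dose reconstruction with disturbance separation.

    Solves for the per-pixel disturbance factor ``t_min`` (see
    :func:`solve_disturbance`) and reports the arithmetic mean of the three
    channel doses evaluated at ``t_min``.  Non-converged pixels are filled
    with the red-channel single-channel dose and flagged.
    """
    mdict = _as_model_dict(models)
    kinds = {m.response_kind for m in mdict.values()}
    if len(kinds) != 1:
        raise ValueError("all three channel models must share one response kind")
    od_post = _film_od(film)
    od_pre, scale_pre = _pre_od(pre, film)
    shape = film.shape
    n = shape[0] * shape[1]
    od_f = od_post.reshape(n, 3)
    od_i = od_pre.reshape(n, 3) if od_pre.ndim == 3 else od_pre

    t, iters, converged = solve_disturbance(
        od_f, mdict, od_i, scale_pre=scale_pre,
        t_bounds=t_bounds, max_iter=max_iter, tol=tol,
    )
    if od_i.ndim == 1:
        od_i = np.broadcast_to(od_i, (n, 3))

    mlist = [mdict[ch] for ch in _CHANNELS]
    d_final = np.empty((n, 3))
    for k, m in enumerate(mlist):
        r, _, _ = _net_response(m, od_f[:, k], od_i[:, k], t, scale_pre)
        d_final[:, k], _, _ = m.dose_derivatives(r)
    dose = d_final.mean(axis=1)

    if (~converged).any():
        red = mlist[0]
        r_red, _, _ = _net_response(red, od_f[:, 0], od_i[:, 0], np.ones(n), scale_pre)
        d_red, _, _ = red.dose_derivatives(r_red)
        dose = np.where(converged, dose, d_red)
        t = np.where(converged, t, 1.0)
        log.info("multichannel_dose: %d pixels non-converged, filled with red channel",
                 int((~converged).sum()))

    dose_map = DoseMap(np.clip(dose.reshape(shape), 0.0, None), film.pixel_spacing_mm)
    return MultichannelResult(
        dose=dose_map,
        t_map=t.reshape(shape),
        iterations=iters.reshape(shape),
        converged=converged.reshape(shape),
    )
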