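"""Per-channel dose-response calibration models and their fitting.

Two model families are supported, both written as dose as a function of the
net film response (response on the x-axis, dose on the y-axis):

* rational in net transmittance:  ``D = A*netT / (1 - B*netT)`` — the film
  manufacturer's suggested form for EBT-type film;
* power polynomial in net optical density:  ``D = A*netOD + B*netOD**n``.

Fits use Levenberg–Marquardt least squares; response uncertainties enter as
dose weights after projection through the local slope,
``sigma_D ≈ |dD/dr| * sigma_r``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy import optimize

__all__ = [
    "CalibrationModel",
    "rational_dose",
    "polynomial_dose",
    "fit_model",
    "invert_dose",
    "invert_dose_array",
    "save_models",
    "load_models",
]

_POLE_EPS = 1e-12


def rational_dose(params, net_t):
    """Evaluate the rational model ``D = A*netT / (1 - B*netT)``."""
    a, b = params
    net_t = np.asarray(net_t, dtype=float)
    denom = 1.0 - b * net_t
    if np.any(np.abs(denom) < _POLE_EPS):
        raise ZeroDivisionError("rational model evaluated at its pole (1 - B*netT = 0)")
    out = a * net_t / denom
    return out if out.ndim else float(out)


def polynomial_dose(params, net_od):
    """Evaluate the power-polynomial model ``D = A*netOD + B*netOD**n``."""
    a, b, n = params
    net_od = np.asarray(net_od, dtype=float)
    if np.any(net_od < 0) and abs(n - round(n)) > 1e-9:
        raise ValueError("negative netOD with fractional exponent is undefined")
    out = a * net_od + b * np.sign(net_od) * np.abs(net_od) ** n
    return out if out.ndim else float(out)


@dataclasses.dataclass
class CalibrationModel:
    """A fitted dose-response law for one color channel.

    ``params`` is (A, B) for the rational family, (A, B, n) for the
    polynomial one; ``response_kind`` names the x-variable (``net_t`` or
    ``net_od``).  ``dose_range_gy`` bounds the domain over which the model
    was calibrated and may be inverted.
    """

    model_kind: str  # 'rational' | 'polynomial'
    channel: str  # 'R' | 'G' | 'B'
    params: tuple[float, ...]
    param_sigma: tuple[float, ...] = ()
    response_kind: str = "net_t"
    dose_range_gy: tuple[float, float] = (0.0, 10.0)
    reduced_chi2: float = float("nan")
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.model_kind not in ("rational", "polynomial"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        n_expected = 2 if self.model_kind == "rational" else 3
        if len(self.params) != n_expected:
            raise ValueError(
                f"{self.model_kind} model needs {n_expected} parameters, got {len(self.params)}"
            )
        if self.channel not in ("R", "G", "B"):
            raise ValueError(f"channel must be R, G or B, got {self.channel!r}")
        if self.response_kind not in ("net_t", "net_od"):
            raise ValueError(f"unknown response kind {self.response_kind!r}")
        lo, hi = self.dose_range_gy
        if not lo < hi:
            raise ValueError("dose_range_gy must be increasing")
        self.params = tuple(float(p) for p in self.params)
        self.param_sigma = tuple(float(s) for s in self.param_sigma)

    # -- evaluation ------------------------------------------------------
    def dose(self, response):
        """Dose (Gy) at the given net response value(s)."""
        if self.model_kind == "rational":
            return rational_dose(self.params, response)
        return polynomial_dose(self.params, response)

    def dose_derivatives(self, response):
        """Return (D, dD/dr, d2D/dr2) at the given response value(s)."""
        r = np.asarray(response, dtype=float)
        if self.model_kind == "rational":
            a, b = self.params
            denom = 1.0 - b * r
            d = a * r / denom
            d1 = a / denom**2
            d2 = 2.0 * a * b / denom**3
        else:
            a, b, n = self.params
            ra = np.abs(r)
            sgn = np.sign(r)
            d = a * r + b * sgn * ra**n
            d1 = a + b * n * ra ** (n - 1.0)
            d2 = b * n * (n - 1.0) * sgn * np.where(ra > 0, ra ** (n - 2.0), 0.0)
        return d, d1, d2

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "channel": self.channel,
            "params": list(self.params),
            "param_sigma": list(self.param_sigma),
            "response_kind": self.response_kind,
            "dose_range_gy": list(self.dose_range_gy),
            "reduced_chi2": self.reduced_chi2,
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            model_kind=d["model_kind"],
            channel=d["channel"],
            params=tuple(d["params"]),
            param_sigma=tuple(d.get("param_sigma", ())),
            response_kind=d.get("response_kind", "net_t"),
            dose_range_gy=tuple(d.get("dose_range_gy", (0.0, 10.0))),
            reduced_chi2=d.get("reduced_chi2", float("nan")),
            r_squared=d.get("r_squared", float("nan")),
        )


def save_models(models: dict[str, CalibrationModel], path: str | Path) -> None:
    """Serialize a channel->model mapping to a JSON document."""
    doc = {ch: m.to_dict() for ch, m in models.items()}
    Path(path).write_text(json.dumps(doc, indent=2))


def load_models(path: str | Path) -> dict[str, CalibrationModel]:
    doc = json.loads(Path(path).read_text())
    return {ch: CalibrationModel.from_dict(d) for ch, d in doc.items()}


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _rational_init(resp: np.ndarray, dose: np.ndarray) -> tuple[float, float]:
    """Exact two-point solve for (A, B) from the extreme nonzero-dose points."""
    nz = dose > 0
    if nz.sum() >= 2:
        i1 = int(np.argmin(np.where(nz, dose, np.inf)))
        i2 = int(np.argmax(dose))
        r1, d1 = resp[i1], dose[i1]
        r2, d2 = resp[i2], dose[i2]
        if r1 != 0 and r2 != 0 and d1 != d2:
            b = (d1 / r1 - d2 / r2) / (d1 - d2)
            a = d1 * (1.0 - b * r1) / r1
            if math.isfinite(a) and math.isfinite(b) and a != 0:
                return a, b
    # fallback: slope through the largest point, no curvature
    i2 = int(np.argmax(np.abs(resp)))
    slope = dose[i2] / resp[i2] if resp[i2] != 0 else 1.0
    return slope, 0.0


def _polynomial_init(resp: np.ndarray, dose: np.ndarray, fixed_n: float | None) -> tuple[float, float, float]:
    nz = (resp > 0) & (dose > 0)
    if nz.sum() < 2:
        return 1.0, 1.0, fixed_n if fixed_n is not None else 2.0
    r, d = resp[nz], dose[nz]
    i_lo = int(np.argmin(d))
    a0 = d[i_lo] / r[i_lo]  # low-dose linear slope
    resid = d - a0 * r
    pos = resid > 0
    n0 = fixed_n if fixed_n is not None else 2.0
    b0 = 1.0
    if pos.sum() >= 2 and fixed_n is None:
        # log-log slope of the residual gives the exponent
        coef = np.polyfit(np.log(r[pos]), np.log(resid[pos]), 1)
        if math.isfinite(coef[0]) and 1.0 < coef[0] < 6.0:
            n0 = float(coef[0])
            b0 = float(math.exp(coef[1]))
    elif pos.any():
        i_hi = int(np.argmax(d))
        if resid[i_hi] > 0:
            b0 = float(resid[i_hi] / r[i_hi] ** n0)
    return a0, b0, n0


def fit_model(
    kind: str,
    points: list[tuple[float, float, float]],
    fixed_n: float | None = None,
    channel: str = "R",
    response_kind: str | None = None,
    dose_range_gy: tuple[float, float] | None = None,
) -> CalibrationModel:
    """Fit a calibration model to ``(response, sigma_response, dose_gy)`` points.

    Weighted Levenberg–Marquardt least squares on dose residuals.  Response
    uncertainties are projected onto the dose axis through the slope of a
    first unweighted pass (``sigma_D = |dD/dr| * sigma_r``) and used as
    weights in a second pass; if every sigma is zero the fit is unweighted.
    Raises on under-determined input or a non-converged optimizer.
    """
    if kind not in ("rational", "polynomial"):
        raise ValueError(f"unknown model kind {kind!r}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (response, sigma_response, dose_gy) triples")
    resp, sigma_r, dose = pts[:, 0], pts[:, 1], pts[:, 2]
    n_free = 2 if kind == "rational" else (2 if fixed_n is not None else 3)
    if len(pts) < n_free + 1:
        raise ValueError(f"need at least {n_free + 1} points to fit {n_free} parameters")
    if len(np.unique(dose)) < n_free:
        raise ValueError("calibration doses must be distinct")
    if np.any(sigma_r < 0):
        raise ValueError("response sigmas must be non-negative")

    if kind == "rational":
        p0 = list(_rational_init(resp, dose))

        def func(r, a, b):
            return a * r / (1.0 - b * r)

    else:
        a0, b0, n0 = _polynomial_init(resp, dose, fixed_n)
        if fixed_n is not None:
            p0 = [a0, b0]

            def func(r, a, b):
                return a * r + b * np.abs(r) ** fixed_n * np.sign(r)

        else:
            p0 = [a0, b0, n0]

            def func(r, a, b, n):
                return a * r + b * np.abs(r) ** n * np.sign(r)

    def _run(sigma_d):
        try:
            popt, pcov, info, msg, ier = optimize.curve_fit(
                func,
                resp,
                dose,
                p0=p0,
                sigma=sigma_d,
                absolute_sigma=sigma_d is not None,
                method="lm",
                maxfev=20000,
                full_output=True,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"calibration fit did not converge: {exc}") from exc
        if ier not in (1, 2, 3, 4):
            raise RuntimeError(f"calibration fit did not converge: {msg}")
        return popt, pcov

    weighted = bool(np.any(sigma_r > 0))
    popt, pcov = _run(None)
    if weighted:
        if np.any(sigma_r == 0):
            raise ValueError("mixed zero and non-zero response sigmas")
        # project response sigma onto the dose axis via the pass-1 slope
        if kind == "rational":
            a, b = popt
            slope = a / (1.0 - b * resp) ** 2
        else:
            a, b, n = (popt[0], popt[1], fixed_n) if fixed_n is not None else popt
            slope = a + b * n * np.abs(resp) ** (n - 1.0)
        sigma_d = np.abs(slope) * sigma_r
        sigma_d = np.where(sigma_d > 0, sigma_d, sigma_d[sigma_d > 0].min() if np.any(sigma_d > 0) else 1.0)
        p0 = list(popt)
        popt, pcov = _run(sigma_d)
    else:
        sigma_d = None

    params = tuple(popt) if (kind == "rational" or fixed_n is None) else (popt[0], popt[1], float(fixed_n))
    sigmas = tuple(float(s) for s in np.sqrt(np.maximum(np.diag(pcov), 0.0)))
    if kind == "polynomial" and fixed_n is not None:
        sigmas = (*sigmas, 0.0)

    pred = func(resp, *popt)
    resid = dose - pred
    dof = max(len(pts) - len(popt), 1)
    if weighted:
        chi2 = float(np.sum((resid / sigma_d) ** 2)) / dof
    else:
        chi2 = float(np.sum(resid**2)) / dof
    ss_tot = float(np.sum((dose - dose.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    if dose_range_gy is None:
        dose_range_gy = (float(dose.min()), float(dose.max()))
    return CalibrationModel(
        model_kind=kind,
        channel=channel,
        params=params,
        param_sigma=sigmas,
        response_kind=response_kind or ("net_t" if kind == "rational" else "net_od"),
        dose_range_gy=dose_range_gy,
        reduced_chi2=chi2,
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def _check_monotone(model: CalibrationModel, r_lo: float, r_hi: float) -> None:
    grid = np.linspace(r_lo, r_hi, 257)
    _, d1, _ = model.dose_derivatives(grid)
    if np.any(d1 > 0) and np.any(d1 < 0):
        raise ValueError("model is not monotone over the calibrated range")


def _response_bracket(model: CalibrationModel, dose_gy: float) -> tuple[float, float]:
    """Find a response interval whose model doses bracket ``dose_gy``."""
    a = model.params[0]
    direction = -1.0 if a < 0 else 1.0  # darkening film: negative netT, A < 0
    lo, hi = 0.0, direction * 1e-3
    for _ in range(64):
        if (model.dose(hi) - dose_gy) * (model.dose(lo) - dose_gy) <= 0:
            return (lo, hi) if lo < hi else (hi, lo)
        lo, hi = hi, hi * 1.8
        if model.model_kind == "rational":
            _, b = model.params
            if b != 0 and direction * hi * b >= 0 and abs(hi) >= 1.0 / abs(b):
                hi = direction * (1.0 / abs(b) - 1e-9)
    raise ValueError(f"could not bracket dose {dose_gy} Gy for inversion")


def invert_dose(model: CalibrationModel, dose_gy: float) -> float:
    """Response value at which the model predicts ``dose_gy``.

    The rational model is inverted in closed form, ``r = D / (A + B*D)``;
    other models by root bracketing + Brent iteration to |dD| < 1e-9 Gy.
    Doses outside the model's calibrated range are rejected.
    """
    lo, hi = model.dose_range_gy
    if not (lo - 1e-12 <= dose_gy <= hi + 1e-12):
        raise ValueError(
            f"dose {dose_gy} Gy outside calibrated range [{lo}, {hi}] Gy"
        )
    if dose_gy == 0.0:
        return 0.0
    if model.model_kind == "rational":
        a, b = model.params
        denom = a + b * dose_gy
        if abs(denom) < _POLE_EPS:
            raise ZeroDivisionError("rational inverse pole: A + B*D = 0")
        return float(dose_gy / denom)
    r_lo, r_hi = _response_bracket(model, dose_gy)
    _check_monotone(model, r_lo, r_hi)
    sol = optimize.brentq(lambda r: model.dose(r) - dose_gy, r_lo, r_hi, xtol=1e-14, rtol=1e-15)
    return float(sol)


def invert_dose_array(model: CalibrationModel, dose_gy: np.ndarray) -> np.ndarray:
    """Vectorized model inversion for dose grids.

    Rational models invert in closed form; otherwise a dense monotone lookup
    table over the calibrated range is interpolated and polished with two
    Newton steps (residual well below 1e-9 Gy for smooth models).
    """
    dose = np.asarray(dose_gy, dtype=float)
    lo, hi = model.dose_range_gy
    if np.any(dose < lo - 1e-12) or np.any(dose > hi + 1e-12):
        raise ValueError(f"dose outside calibrated range [{lo}, {hi}] Gy")
    if model.model_kind == "rational":
        a, b = model.params
        return dose / (a + b * dose)
    d_max = float(dose.max())
    r_hi = invert_dose(model, d_max) if d_max > 0 else 0.0
    grid_r = np.linspace(min(0.0, r_hi), max(0.0, r_hi), 4097)
    grid_d = model.dose(grid_r)
    order = np.argsort(grid_d)
    r = np.interp(dose, grid_d[order], grid_r[order])
    for _ in range(2):  # Newton polish
        d, d1, _ = model.dose_derivatives(r)
        step = np.where(np.abs(d1) > 1e-12, (d - dose) / np.where(d1 != 0, d1, 1.0), 0.0)
        r = r - step
    return r
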