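"""Synthetic film and plan generation.

Every pipeline stage is testable without physical films: planned dose maps
(uniform square field with logistic penumbra, stacked-square pyramid) are
pushed backwards through a known calibration law to produce 16-bit RGB
scanner images, with three controllable corruption mechanisms that emulate
a real flatbed scan:

* additive Gaussian PV noise (fraction of the local pixel value),
* salt spikes (isolated full-scale pixels, as from dust or dead sensors),
* a smooth multiplicative, dose-independent disturbance field on the
  optical density — the quantity the multichannel method is built to
  separate out.

All generators are bit-reproducible given their spec and seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .calibration import CalibrationModel, invert_dose_array
from .image_io import DoseMap, ScannedFilm

__all__ = [
    "PhantomSpec",
    "ScannerNoiseSpec",
    "default_models",
    "default_polynomial_models",
    "reference_transmittance",
    "make_dose_phantom",
    "film_from_dose",
    "make_registration_case",
]

DOSE_RANGE_GY = (0.0, 20.0)
FIELD_SIZE_RANGE_MM = (50.0, 220.0)
DEFAULT_BASE_OD = 0.05  # unexposed-film optical density per channel


def default_models() -> dict[str, CalibrationModel]:
    """Fixture truth: rational netT models, one per channel.

    The parameters are package constants chosen so the red channel has the
    steepest low-dose response (|A| smallest), followed by green then blue,
    mirroring the sensitivity ordering of real EBT-type film; they are not
    measurements.  All are monotone on netT in (-1, 0] with A < 0, B > 0.
    """
    spec = {"R": (-30.0, 0.2), "G": (-45.0, 0.3), "B": (-70.0, 0.4)}
    return {
        ch: CalibrationModel(
            model_kind="rational",
            channel=ch,
            params=params,
            response_kind="net_t",
            dose_range_gy=DOSE_RANGE_GY,
        )
        for ch, params in spec.items()
    }


def default_polynomial_models() -> dict[str, CalibrationModel]:
    """Fixture truth for the netOD power-polynomial family (package constants)."""
    spec = {"R": (8.0, 40.0, 2.3), "G": (12.0, 55.0, 2.4), "B": (20.0, 90.0, 2.5)}
    return {
        ch: CalibrationModel(
            model_kind="polynomial",
            channel=ch,
            params=params,
            response_kind="net_od",
            dose_range_gy=DOSE_RANGE_GY,
        )
        for ch, params in spec.items()
    }


def reference_transmittance(base_od: float = DEFAULT_BASE_OD) -> float:
    """Transmittance of the unexposed film, ``10**(-base_od)``."""
    return float(10.0 ** (-base_od))


@dataclasses.dataclass
class PhantomSpec:
    """Description of a planned verification field.

    ``dose_gy`` is a scalar for a uniform square, or the nested level doses
    (inner-most last) for a pyramid.  Doses must lie within the 0.5–20 Gy
    applicability window; field sizes within 50–220 mm.
    """

    kind: str  # 'uniform_square' | 'pyramid'
    dose_gy: float | list[float]
    field_size_mm: float = 100.0
    penumbra_sigma_mm: float = 2.0
    grid_spacing_mm: float = 1.0
    margin_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_square", "pyramid"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        doses = np.atleast_1d(np.asarray(self.dose_gy, dtype=float))
        if self.kind == "uniform_square" and doses.size != 1:
            raise ValueError("uniform_square takes a single dose")
        if self.kind == "pyramid" and doses.size < 2:
            raise ValueError("pyramid needs at least two level doses")
        lo, hi = 0.5, 20.0
        if np.any(doses < lo) or np.any(doses > hi):
            raise ValueError(f"doses must lie within [{lo}, {hi}] Gy")
        if self.kind == "pyramid" and np.any(np.diff(doses) <= 0):
            raise ValueError("pyramid level doses must increase inward")
        f_lo, f_hi = FIELD_SIZE_RANGE_MM
        if not f_lo <= self.field_size_mm <= f_hi:
            raise ValueError(f"field size must lie within [{f_lo}, {f_hi}] mm")
        if self.penumbra_sigma_mm <= 0 or self.grid_spacing_mm <= 0 or self.margin_mm < 0:
            raise ValueError("penumbra, spacing must be positive; margin non-negative")


@dataclasses.dataclass
class ScannerNoiseSpec:
    """Stochastic scanner model: PV noise, salt spikes, OD disturbance field."""

    gaussian_sigma_fraction: float = 0.0
    spike_probability: float = 0.0
    disturbance_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_probability <= 1.0:
            raise ValueError("spike_probability must lie in [0, 1]")
        if self.gaussian_sigma_fraction < 0 or self.disturbance_amplitude < 0:
            raise ValueError("noise amplitudes must be non-negative")


def _edge_profile(coord_mm: np.ndarray, half_size_mm: float, sigma_mm: float) -> np.ndarray:
    """Logistic field-edge profile: ~1 inside |x| < L/2, ~0 outside."""
    return expit((half_size_mm - np.abs(coord_mm)) / sigma_mm)


def make_dose_phantom(spec: PhantomSpec) -> DoseMap:
    """Deterministic planned dose map for the given phantom spec.

    A uniform square is ``D * S(x) * S(y)`` with S the logistic edge
    profile; a pyramid is a stack of nested squares, each adding its dose
    increment, so the innermost plateau carries the last listed level dose.
    """
    extent = spec.field_size_mm + 2.0 * spec.margin_mm
    n = max(3, int(round(extent / spec.grid_spacing_mm)))
    x = (np.arange(n) - (n - 1) / 2.0) * spec.grid_spacing_mm
    xx, yy = np.meshgrid(x, x, indexing="ij")
    if spec.kind == "uniform_square":
        half = spec.field_size_mm / 2.0
        s = _edge_profile(xx, half, spec.penumbra_sigma_mm) * _edge_profile(
            yy, half, spec.penumbra_sigma_mm
        )
        dose = float(np.atleast_1d(spec.dose_gy)[0]) * s
    else:
        levels = np.asarray(spec.dose_gy, dtype=float)
        increments = np.diff(np.concatenate([[0.0], levels]))
        m = levels.size
        dose = np.zeros_like(xx)
        for k, inc in enumerate(increments):
            half = spec.field_size_mm * (m - k) / m / 2.0
            dose += inc * _edge_profile(xx, half, spec.penumbra_sigma_mm) * _edge_profile(
                yy, half, spec.penumbra_sigma_mm
            )
    return DoseMap(dose, (spec.grid_spacing_mm, spec.grid_spacing_mm))


def _disturbance_field(shape: tuple[int, int], amplitude: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative OD field: quadratic surface, peak deviation = amplitude."""
    coeffs = rng.standard_normal(6)
    if amplitude == 0.0:
        return np.ones(shape)
    y = np.linspace(-1.0, 1.0, shape[0])
    x = np.linspace(-1.0, 1.0, shape[1])
    yy, xx = np.meshgrid(y, x, indexing="ij")
    p = (
        coeffs[0]
        + coeffs[1] * xx
        + coeffs[2] * yy
        + coeffs[3] * xx**2
        + coeffs[4] * xx * yy
        + coeffs[5] * yy**2
    )
    p = p / np.abs(p).max()
    return 1.0 + amplitude * p


def _embed_dose(dose: np.ndarray, canvas_shape: tuple[int, int],
                offset_px: tuple[int, int], angle_deg: float) -> np.ndarray:
    rot = dose
    if angle_deg != 0:
        rot = np.clip(
            ndimage.rotate(dose, angle_deg, reshape=False, order=1, mode="constant", cval=0.0),
            0.0,
            None,
        )
    r0, c0 = (int(v) for v in offset_px)
    h, w = rot.shape
    ch, cw = canvas_shape
    if r0 < 0 or c0 < 0 or r0 + h > ch or c0 + w > cw:
        raise ValueError(
            f"embedding at offset {offset_px} exceeds canvas {canvas_shape}"
        )
    canvas = np.zeros(canvas_shape)
    canvas[r0 : r0 + h, c0 : c0 + w] = rot
    return canvas


def film_from_dose(
    dose: DoseMap,
    models,
    noise: ScannerNoiseSpec,
    embed: tuple[tuple[int, int], tuple[int, int], float] | None = None,
    base_od: float = DEFAULT_BASE_OD,
) -> ScannedFilm:
    """Render a dose map as a 16-bit RGB scanner image.

    Per channel the calibration model is inverted to the net response, the
    post-irradiation OD is formed on top of ``base_od``, multiplied by the
    smooth disturbance field, converted back to transmittance, scaled to
    counts, and corrupted with Gaussian PV noise and salt spikes.  Counts
    are quantized with round-half-even and clipped to [0, 65535].

    ``embed`` = (canvas_shape, offset_px, angle_deg) first pastes the
    (optionally rotated) dose map into a larger zero-dose canvas, emulating
    a film smaller than the scanner bed.
    """
    if isinstance(models, dict):
        mdict = models
    else:
        mdict = {m.channel: m for m in models}
    for ch in "RGB":
        if ch not in mdict:
            raise ValueError(f"missing calibration model for channel {ch}")

    arr = dose.dose_gy
    if embed is not None:
        canvas_shape, offset_px, angle_deg = embed
        arr = _embed_dose(arr, tuple(canvas_shape), tuple(offset_px), float(angle_deg))

    rng = np.random.default_rng(noise.seed)
    s_field = _disturbance_field(arr.shape, noise.disturbance_amplitude, rng)

    max_val = 65535.0
    channels = []
    for ch in "RGB":
        model = mdict[ch]
        resp = invert_dose_array(model, arr)
        if model.response_kind == "net_t":
            t_f = 10.0 ** (-base_od) + resp
            if np.any(t_f <= 0):
                raise ValueError("dose exceeds the representable transmittance range")
            od_f = -np.log10(t_f)
        else:
            od_f = base_od + resp
        od_f = od_f * s_field
        pv = max_val * 10.0 ** (-od_f)
        if noise.gaussian_sigma_fraction > 0:
            pv = pv * (1.0 + noise.gaussian_sigma_fraction * rng.standard_normal(pv.shape))
        if noise.spike_probability > 0:
            pv = np.where(rng.random(pv.shape) < noise.spike_probability, max_val, pv)
        channels.append(np.clip(np.rint(pv), 0, max_val).astype(np.uint16))

    pixels = np.stack(channels, axis=-1)
    return ScannedFilm(pixels=pixels, bit_depth=16, pixel_spacing_mm=dose.pixel_spacing_mm)


def make_registration_case(
    plan: DoseMap,
    offset_px: tuple[int, int],
    angle_deg: float,
    noise: ScannerNoiseSpec,
    canvas_shape: tuple[int, int] | None = None,
    models=None,
    base_od: float = DEFAULT_BASE_OD,
) -> tuple[ScannedFilm, dict]:
    """A film with the plan embedded at a known transform, plus the truth record."""
    if models is None:
        models = default_models()
    if canvas_shape is None:
        canvas_shape = (plan.shape[0] + 2 * offset_px[0] + 2, plan.shape[1] + 2 * offset_px[1] + 2)
    film = film_from_dose(
        plan, models, noise,
        embed=(canvas_shape, offset_px, float(angle_deg)),
        base_od=base_od,
    )
    truth = {
        "offset_px": tuple(int(v) for v in offset_px),
        "angle_deg": float(angle_deg),
        "canvas_shape": tuple(int(v) for v in canvas_shape),
        "seed": noise.seed,
    }
    return film, truth
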