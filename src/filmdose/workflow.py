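"""End-to-end QA orchestration: calibrate, reconstruct, register, compare.

A :class:`RunConfig` (single YAML or JSON document) names the input files
and the per-stage parameters; :func:`run_calibrate` turns replicate
calibration films into fitted per-channel models, and :func:`run_compare`
executes the full pipeline — reconstruct, denoise, orient, register, crop,
resample, gamma — writing machine-readable reports along the way.  Every
stage logs its parameters; defaults follow common film-QA practice
(rational model, red channel, 0–10 Gy fit range, global 3%/3 mm with a 5%
threshold).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import film_response, reconstruction, registration
from .calibration import CalibrationModel, fit_model, load_models, save_models
from .gamma import GammaCriteria, gamma_histogram, gamma_matrix
from .image_io import DoseMap, read_rtdose, read_tiff_film, resample_to_grid, write_rtdose

__all__ = ["RunConfig", "run_calibrate", "run_compare"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Validated QA-run configuration (one section per pipeline stage)."""

    paths: dict = dataclasses.field(default_factory=dict)
    calibration: dict = dataclasses.field(default_factory=dict)
    reconstruction: dict = dataclasses.field(default_factory=dict)
    registration: dict = dataclasses.field(default_factory=dict)
    gamma: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        doc = yaml.safe_load(path.read_text())
        if not isinstance(doc, dict):
            raise ValueError(f"{path.name}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path.name}: unknown config sections {sorted(unknown)}")
        return cls(**{k: doc.get(k, {}) for k in known})

    def output_dir(self) -> Path:
        out = Path(self.paths.get("output_dir", "."))
        out.mkdir(parents=True, exist_ok=True)
        return out


def _read_film(path: str, dpi) -> "object":
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"film file not found: {p}")
    return read_tiff_film(p, dpi=dpi)


def run_calibrate(config: RunConfig) -> tuple[dict[str, CalibrationModel], dict]:
    """Fit per-channel calibration models from replicate film scans.

    The calibration section lists dose levels, each with post-irradiation
    film paths and matching pre-irradiation scans (one shared pre-scan per
    level is also accepted).  Per level and channel, replicate net
    responses are combined by inverse-variance weighting before the fit.
    Writes ``models.json`` and ``calibration_report.json`` to the output
    directory and returns (models, report).
    """
    cal = config.calibration
    levels = cal.get("levels", [])
    if len(levels) < 4:
        raise ValueError(f"need at least 4 dose levels, got {len(levels)}")
    kind = cal.get("model_kind", "rational")
    response_kind = cal.get("response_kind", "net_t" if kind == "rational" else "net_od")
    roi = tuple(cal.get("roi", (0, 0, 10, 10)))
    dpi = cal.get("dpi")
    fit_range = tuple(cal.get("dose_range_gy", (0.0, 10.0)))
    fixed_n = cal.get("fixed_n")

    missing = [
        f
        for level in levels
        for f in list(level.get("films", [])) + list(level.get("pre_films", []))
        if not Path(f).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing calibration films: {missing}")

    points = {ch: [] for ch in "RGB"}
    level_report = []
    for level in levels:
        dose = float(level["dose_gy"])
        films = level.get("films", [])
        pres = level.get("pre_films", [])
        if not films or not pres:
            raise ValueError(f"dose level {dose} Gy lists no films or no pre-scans")
        if len(pres) == 1:
            pres = pres * len(films)
        replicates = {ch: [] for ch in "RGB"}
        for post_path, pre_path in zip(films, pres):
            post = _read_film(post_path, dpi)
            pre = _read_film(pre_path, dpi)
            stats_post = film_response.roi_statistics(post, roi)
            stats_pre = film_response.roi_statistics(pre, roi)
            net = film_response.net_response(stats_pre, stats_post, post.bit_depth)
            resp = net.response(response_kind)
            sig = net.sigma(response_kind)
            for k, ch in enumerate("RGB"):
                replicates[ch].append((float(resp[k]), float(sig[k])))
        for ch in "RGB":
            mean, sigma = film_response.weighted_net_od(replicates[ch])
            points[ch].append((mean, sigma, dose))
        level_report.append({"dose_gy": dose, "n_replicates": len(films)})
        log.info("calibration level %.3f Gy: %d replicates", dose, len(films))

    models = {}
    for ch in "RGB":
        models[ch] = fit_model(
            kind,
            points[ch],
            fixed_n=fixed_n,
            channel=ch,
            response_kind=response_kind,
            dose_range_gy=fit_range,
        )
        log.info(
            "fitted %s model for channel %s: params=%s chi2=%.4g R2=%.6f",
            kind, ch, models[ch].params, models[ch].reduced_chi2, models[ch].r_squared,
        )

    out = config.output_dir()
    save_models(models, out / "models.json")
    report = {
        "model_kind": kind,
        "response_kind": response_kind,
        "dose_range_gy": list(fit_range),
        "levels": level_report,
        "channels": {ch: models[ch].to_dict() for ch in "RGB"},
    }
    (out / "calibration_report.json").write_text(json.dumps(report, indent=2))
    return models, report


def _criteria_from_config(section: dict) -> GammaCriteria:
    return GammaCriteria(
        dd_percent=float(section.get("dd_percent", 3.0)),
        dta_mm=float(section.get("dta_mm", 3.0)),
        threshold_percent=float(section.get("threshold_percent", 5.0)),
        normalization=section.get("normalization", "global"),
        search_radius_factor=float(section.get("search_radius_factor", 3.0)),
    )


def run_compare(config: RunConfig, models: dict[str, CalibrationModel] | None = None):
    """Full plan-vs-film comparison; returns (GammaResult, report dict).

    Stages: read film -> dose reconstruction (single or multichannel) ->
    denoise -> scanner-orientation correction -> NCC registration (or a
    manual override) -> crop to the matched region -> resample to the plan
    grid -> gamma analysis.  Outputs ``measured_dose.dcm``,
    ``gamma_report.json`` and the histogram data.
    """
    paths = config.paths
    if models is None:
        models_path = paths.get("models")
        if not models_path or not Path(models_path).exists():
            raise FileNotFoundError(f"calibration models file not found: {models_path}")
        models = load_models(models_path)

    film_path = paths.get("film")
    plan_path = paths.get("plan")
    if not film_path or not Path(film_path).exists():
        raise FileNotFoundError(f"film file not found: {film_path}")
    if not plan_path or not Path(plan_path).exists():
        raise FileNotFoundError(f"plan file not found: {plan_path}")

    rec = config.reconstruction
    film = read_tiff_film(film_path, dpi=rec.get("dpi"))
    log.info("film loaded: %s px, spacing %s mm", film.shape, film.pixel_spacing_mm)

    pre_path = paths.get("pre_film")
    if pre_path:
        pre = read_tiff_film(pre_path, dpi=rec.get("dpi"))
    else:
        pre = rec.get("reference_transmittance", 1.0)

    method = rec.get("method", "single")
    channel = rec.get("channel", "R")
    n_nonconverged = 0
    if method == "single":
        dose_map = reconstruction.single_channel_dose(film, models[channel], channel, pre)
    elif method == "multichannel":
        result = reconstruction.multichannel_dose(film, models, pre)
        dose_map = result.dose
        n_nonconverged = result.n_nonconverged
    else:
        raise ValueError(f"unknown reconstruction method {method!r}")
    log.info("reconstruction (%s): dose range %.3f-%.3f Gy", method,
             dose_map.dose_gy.min(), dose_map.dose_gy.max())

    median_size = int(rec.get("median_size", 3))
    wiener_window = int(rec.get("wiener_window", 5))
    dose_arr = film_response.denoise(dose_map.dose_gy, median_size, wiener_window)

    reg = config.registration
    dose_arr = registration.preprocess_film(
        dose_arr,
        flip_vertical=bool(reg.get("flip_vertical", True)),
        rotate_180=bool(reg.get("rotate_180", True)),
    )
    film_dose = DoseMap(np.clip(dose_arr, 0.0, None), dose_map.pixel_spacing_mm)

    plan = read_rtdose(plan_path)
    log.info("plan loaded: %s px, spacing %s mm", plan.shape, plan.pixel_spacing_mm)

    manual_offset = reg.get("manual_offset")
    if manual_offset is not None:
        plan_common = resample_to_grid(plan, film_dose.pixel_spacing_mm)
        reg_result = registration.RegistrationResult(
            offset_px=tuple(int(v) for v in manual_offset),
            angle_deg=float(reg.get("manual_angle", 0.0)),
            ncc_score=float("nan"),
            score_map=np.zeros((1, 1)),
        )
    else:
        angles = reg.get("angles_deg", registration.DEFAULT_ANGLES_DEG)
        reg_result = registration.match_template(plan, film_dose, angles)
        plan_common = resample_to_grid(plan, film_dose.pixel_spacing_mm)
        floor = float(reg.get("min_score", 0.3))
        if reg_result.ncc_score < floor:
            raise RuntimeError(
                f"registration score {reg_result.ncc_score:.3f} below floor {floor}; "
                "supply registration.manual_offset/manual_angle to override"
            )
        log.info("registration: offset %s px, angle %.1f deg, NCC %.4f",
                 reg_result.offset_px, reg_result.angle_deg, reg_result.ncc_score)

    crop = registration.crop_matched(film_dose, reg_result, plan_common.shape)
    measured = resample_to_grid(crop, plan.pixel_spacing_mm)
    measured = DoseMap(measured.dose_gy, measured.pixel_spacing_mm, plan.origin_mm)

    criteria = _criteria_from_config(config.gamma)
    result = gamma_matrix(plan, measured, criteria)
    edges, counts = gamma_histogram(result, int(config.gamma.get("n_bins", 50)))
    log.info("gamma %s%%/%smm (%s, %.0f%% threshold): pass rate %.4f over %d pixels",
             criteria.dd_percent, criteria.dta_mm, criteria.normalization,
             criteria.threshold_percent, result.pass_rate, result.n_evaluated)

    out = config.output_dir()
    write_rtdose(measured, out / "measured_dose.dcm")
    report = {
        "reconstruction": {"method": method, "channel": channel,
                           "median_size": median_size, "wiener_window": wiener_window,
                           "n_nonconverged": n_nonconverged},
        "registration": {"offset_px": list(reg_result.offset_px),
                         "angle_deg": reg_result.angle_deg,
                         "ncc_score": reg_result.ncc_score},
        "gamma": {
            "dd_percent": criteria.dd_percent,
            "dta_mm": criteria.dta_mm,
            "threshold_percent": criteria.threshold_percent,
            "normalization": criteria.normalization,
            "search_radius_factor": criteria.search_radius_factor,
            "pass_rate": result.pass_rate,
            "n_evaluated": result.n_evaluated,
            "histogram_edges": edges.tolist(),
            "histogram_counts": counts.tolist(),
        },
    }
    (out / "gamma_report.json").write_text(json.dumps(report, indent=2))
    return result, report
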