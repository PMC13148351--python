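"""Film-to-plan registration by normalized cross-correlation (NCC).

The planned dose map acts as a template searched for inside the (larger)
dose-converted film.  For every valid placement the NCC score

    E(u) = sum_i (T_i - mean(T)) (W_i - mean(W))
           / sqrt( sum_i (T_i - mean(T))**2 * sum_i (W_i - mean(W))**2 )

is computed with the local window mean, making the match invariant to
affine intensity changes.  A small-angle rotation sweep (default
0, ±1, ±2, ±3 degrees) absorbs scanner-bed misalignment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .image_io import DoseMap, resample_to_grid

__all__ = [
    "RegistrationResult",
    "preprocess_film",
    "ncc_map",
    "match_template",
    "crop_matched",
    "DEFAULT_ANGLES_DEG",
]

# paper-style sweep, ordered so that ties resolve to the smaller |angle|
DEFAULT_ANGLES_DEG = (0.0, -1.0, 1.0, -2.0, 2.0, -3.0, 3.0)


@dataclasses.dataclass
class RegistrationResult:
    """Location of the planned map inside the film grid."""

    offset_px: tuple[int, int]  # (row, col) of the matched region's top-left
    angle_deg: float  # template rotation that maximized the NCC
    ncc_score: float
    score_map: np.ndarray  # NCC over all placements at the best angle


def preprocess_film(film_dose: np.ndarray, flip_vertical: bool = True,
                    rotate_180: bool = True) -> np.ndarray:
    """Scanner-orientation correction: vertical flip then 180-degree rotation.

    Both transforms default on (they mirror a film placed face-down on the
    scanner bed) and are individually togglable for other setups.  Works on
    2-D grids and on (rows, cols, channels) stacks.
    """
    out = np.asarray(film_dose)
    if out.size == 0:
        raise ValueError("empty grid")
    if flip_vertical:
        out = out[::-1]
    if rotate_180:
        out = out[::-1, ::-1]
    return np.ascontiguousarray(out)


def ncc_map(template: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of ``template`` at every valid placement.

    Returns a map of shape ``(H - h + 1, W - w + 1)`` with values in
    [-1, 1].  The template mean is global; the image mean is taken over the
    local window under each placement.  Placements over a zero-variance
    window score 0 (uniform background is a legitimate candidate, not an
    error); a zero-variance template is rejected.
    """
    template = np.asarray(template, dtype=float)
    image = np.asarray(image, dtype=float)
    if template.ndim != 2 or image.ndim != 2:
        raise ValueError("template and image must be 2-D")
    th, tw = template.shape
    ih, iw = image.shape
    if th > ih or tw > iw:
        raise ValueError(f"template {template.shape} larger than image {image.shape}")
    t0 = template - template.mean()
    t_ss = float((t0 * t0).sum())
    if t_ss == 0:
        raise ValueError("template has zero variance")

    out = np.empty((ih - th + 1, iw - tw + 1))
    windows = np.lib.stride_tricks.sliding_window_view(image, (th, tw))
    # row-chunked exact evaluation: windows is a view, each chunk copy is small
    for i in range(out.shape[0]):
        win = windows[i].astype(float, copy=True)  # (Q, th, tw)
        win -= win.mean(axis=(1, 2), keepdims=True)
        num = np.einsum("qhw,hw->q", win, t0)
        den = np.einsum("qhw,qhw->q", win, win) * t_ss
        out[i] = np.where(den > 0, num / np.sqrt(np.where(den > 0, den, 1.0)), 0.0)
    return out


def _rotate_template(template: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bilinear rotation about the template center, shape preserved.

    Out-of-bounds corners are filled with the template's border mean so the
    fill is intensity-neutral for the NCC at small angles.
    """
    if angle_deg == 0:
        return template
    border = np.concatenate(
        [template[0], template[-1], template[1:-1, 0], template[1:-1, -1]]
    )
    return ndimage.rotate(
        template, angle_deg, reshape=False, order=1,
        mode="constant", cval=float(border.mean()),
    )


def match_template(
    plan: DoseMap,
    film_dose: DoseMap,
    angles_deg=DEFAULT_ANGLES_DEG,
) -> RegistrationResult:
    """Locate the planned map inside the film by NCC with a rotation sweep.

    Both maps are brought to the film's pixel spacing first, so offsets are
    expressed in film pixels.  Ties between placements are broken toward
    the smaller |angle|, then the smaller row, then the smaller column.
    """
    plan_common = resample_to_grid(plan, film_dose.pixel_spacing_mm)
    film_arr = film_dose.dose_gy
    tmpl = plan_common.dose_gy
    if tmpl.shape[0] > film_arr.shape[0] or tmpl.shape[1] > film_arr.shape[1]:
        raise ValueError(
            f"plan extent {plan_common.shape} exceeds film extent {film_dose.shape}"
        )
    angles = sorted((float(a) for a in angles_deg), key=lambda a: (abs(a), a))
    best = None
    for angle in angles:
        score = ncc_map(_rotate_template(tmpl, angle), film_arr)
        idx = int(np.argmax(score))  # row-major: smallest row then col on ties
        peak = float(score.flat[idx])
        if best is None or peak > best[0]:
            best = (peak, angle, np.unravel_index(idx, score.shape), score)
    peak, angle, (row, col), score = best
    return RegistrationResult(
        offset_px=(int(row), int(col)),
        angle_deg=angle,
        ncc_score=peak,
        score_map=score,
    )


def crop_matched(
    film_dose: DoseMap,
    result: RegistrationResult,
    plan_shape: tuple[int, int],
) -> DoseMap:
    """Extract the matched sub-grid from the film, in the plan's frame.

    The crop has the plan's shape and the film's spacing; if the best match
    used a rotated template the crop is inverse-rotated so its axes align
    with the plan's.
    """
    row, col = result.offset_px
    h, w = (int(v) for v in plan_shape)
    rows, cols = film_dose.shape
    if row < 0 or col < 0 or row + h > rows or col + w > cols:
        raise ValueError(f"crop at {result.offset_px} with shape {plan_shape} exceeds film bounds")
    crop = film_dose.dose_gy[row : row + h, col : col + w]
    if result.angle_deg != 0:
        crop = ndimage.rotate(crop, -result.angle_deg, reshape=False, order=1, mode="nearest")
    sp = film_dose.pixel_spacing_mm
    origin = (
        film_dose.origin_mm[0] + row * sp[0],
        film_dose.origin_mm[1] + col * sp[1],
    )
    return DoseMap(np.clip(crop, 0.0, None), sp, origin)
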