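"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the most literal possible evaluation (explicit loops,
no search truncation, no shared code with the package internals).
"""

import numpy as np


def ncc_brute(template: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Literal double-loop normalized cross-correlation with local window means."""
    th, tw = template.shape
    ih, iw = image.shape
    t_mean = template.mean()
    t0 = template - t_mean
    out = np.empty((ih - th + 1, iw - tw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            win = image[i : i + th, j : j + tw]
            w0 = win - win.mean()
            den = np.sqrt((t0**2).sum() * (w0**2).sum())
            out[i, j] = (t0 * w0).sum() / den if den > 0 else 0.0
    return out


def gamma_brute(
    d_ref: np.ndarray,
    d_meas: np.ndarray,
    spacing_mm: tuple[float, float],
    dd_percent: float,
    dta_mm: float,
    normalization: str = "global",
) -> np.ndarray:
    """Exhaustive gamma: min over ALL measured pixels, no search radius."""
    rows, cols = d_ref.shape
    dr, dc = spacing_mm
    d_max = d_ref.max()
    out = np.empty_like(d_ref, dtype=float)
    mi, mj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    for i in range(rows):
        for j in range(cols):
            if normalization == "global":
                denom = dd_percent / 100.0 * d_max
            elif normalization == "absolute":
                denom = dd_percent
            else:
                denom = dd_percent / 100.0 * d_ref[i, j]
            dist2 = ((mi - i) * dr) ** 2 + ((mj - j) * dc) ** 2
            g2 = dist2 / dta_mm**2 + (d_ref[i, j] - d_meas) ** 2 / denom**2
            out[i, j] = np.sqrt(g2.min())
    return out
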