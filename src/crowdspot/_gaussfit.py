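"""Least-squares fitting of an isotropic 2-D Gaussian to an image window.

Shared primitive behind SNR measurement and spot-size extraction.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares


class GaussianFit(NamedTuple):
    sigma: float
    amplitude: float
    offset: float
    x: float
    y: float
    flagged: bool  # True when the fit fell back to second moments


def _second_moment_sigma(window: np.ndarray) -> float:
    """Moment-based width estimate used when the fit does not converge."""
    w = window - window.min()
    total = w.sum()
    if total <= 0:
        return 1.0
    yy, xx = np.indices(w.shape)
    cy = (yy * w).sum() / total
    cx = (xx * w).sum() / total
    var = ((yy - cy) ** 2 * w + (xx - cx) ** 2 * w).sum() / (2.0 * total)
    return float(np.sqrt(max(var, 0.25)))


def fit_gaussian(
    image: np.ndarray,
    x: float,
    y: float,
    window_halfwidth: int = 6,
    center_tol: float = 2.0,
) -> GaussianFit:
    """Fit ``offset + A * exp(-r^2 / (2 sigma^2))`` centered near ``(x, y)``.

    The center is refined within ``±center_tol`` pixels of the nominal
    location.  A flat or non-converging window returns a flagged record
    whose sigma comes from the second-moment fallback.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cx, cy = int(round(x)), int(round(y))
    r = int(window_halfwidth)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    if x1 - x0 < 3 or y1 - y0 < 3:
        raise ValueError(f"fit window around ({x}, {y}) falls outside the image")
    window = image[y0:y1, x0:x1]
    yy, xx = np.indices(window.shape)
    xx = xx + x0
    yy = yy + y0

    offset0 = float(np.median(window))
    amp0 = float(window.max() - offset0)
    sigma0 = max(1.0, r / 4.0)

    if amp0 <= 1e-12 * max(1.0, abs(offset0)):
        # flat window: nothing to fit
        return GaussianFit(_second_moment_sigma(window), 0.0, offset0, x, y, True)

    def residuals(p):
        px, py, ps, pa, po = p
        model = po + pa * np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * ps**2))
        return (model - window).ravel()

    lower = [x - center_tol, y - center_tol, 0.3, 0.0, -np.inf]
    upper = [x + center_tol, y + center_tol, 4.0 * r, np.inf, np.inf]
    p0 = [x, y, sigma0, max(amp0, 1e-6), offset0]
    p0 = np.clip(p0, lower, upper)
    try:
        sol = least_squares(residuals, p0, bounds=(lower, upper), max_nfev=200)
    except Exception:
        return GaussianFit(_second_moment_sigma(window), amp0, offset0, x, y, True)
    if not sol.success:
        return GaussianFit(_second_moment_sigma(window), amp0, offset0, x, y, True)
    px, py, ps, pa, po = sol.x
    return GaussianFit(float(ps), float(pa), float(po), float(px), float(py), False)
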