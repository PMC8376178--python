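"""Synthetic fluorescence spot image generation.

Builds test images for annotation experiments: a noisy (optionally
textured) background plus isotropic 2-D Gaussian spots whose size
(sigma), count, spacing (minimum nearest-neighbor distance) and
signal-to-noise ratio are all user-controlled.  SNR is defined
throughout as the Gaussian amplitude above the local background divided
by the robust standard deviation (1.4826 x MAD) of the background in an
annulus around the spot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .errors import BoundaryError, PackingError
from ._gaussfit import fit_gaussian
from .records import SpotRecord

# densest possible packing of equal circles in the plane; used for the
# feasibility pre-check before rejection sampling
_HEX_PACKING = math.pi / (2.0 * math.sqrt(3.0))


@dataclass
class SynthConfig:
    """Parameters of one synthetic spot image.

    ``snr_mean``/``snr_spread`` give the normal distribution that
    per-spot target SNRs are drawn from; ``sigma`` is a scalar or a
    per-spot sequence of Gaussian widths (pixels); ``min_nnd`` is the
    minimum allowed center-to-center spacing (pixels).
    """

    n_spots: int = 100
    snr_mean: float = 15.0
    snr_spread: float = 0.0
    sigma: float | Sequence[float] = 1.5
    min_nnd: float = 12.0
    noise_mean: float = 100.0
    noise_std: float = 10.0
    texture_scale: float = 0.0
    invert: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")
        if self.snr_mean <= 0 or self.snr_spread < 0:
            raise ValueError("snr_mean must be > 0 and snr_spread >= 0")
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(sig <= 0):
            raise ValueError("sigma must be positive")

    def sigmas(self) -> np.ndarray:
        """Per-spot sigma array of length n_spots."""
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if sig.size == 1:
            return np.full(self.n_spots, sig[0])
        if sig.size != self.n_spots:
            raise ValueError("per-spot sigma list must have length n_spots")
        return sig


def generate_background(
    width: int,
    height: int,
    noise_mean: float = 100.0,
    noise_std: float = 10.0,
    texture_scale: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Flat-field background with Gaussian noise and optional smooth texture.

    ``texture_scale`` > 0 mixes in a Gaussian-smoothed random field of that
    correlation length (pixels), emulating autofluorescence mottle; the
    total standard deviation is rescaled back to ``noise_std``.
    """
    if width <= 0 or height <= 0:
        raise ValueError(f"image dimensions must be positive, got {width}x{height}")
    rng = np.random.default_rng(seed)
    img = rng.normal(0.0, 1.0, size=(height, width))
    if texture_scale > 0:
        texture = gaussian_filter(rng.normal(0.0, 1.0, size=(height, width)), texture_scale)
        tstd = texture.std()
        if tstd > 0:
            img = img + texture / tstd  # equal-power mix of white and textured noise
    std = img.std()
    if std > 0 and noise_std > 0:
        img = img * (noise_std / std)
    else:
        img = np.zeros_like(img)
    img = img + noise_mean
    return np.clip(img, 0.0, None)


def sample_spot_locations(
    config: SynthConfig,
    width: int,
    height: int,
    max_attempts_per_spot: int = 10_000,
) -> list[tuple[float, float]]:
    """Rejection-sample spot centers: uniform, >= 3 sigma from every border
    and pairwise spacing >= ``min_nnd``.

    Raises ``PackingError`` when the layout is geometrically infeasible or
    the attempt budget (``max_attempts_per_spot * n_spots`` proposals) is
    exhausted.
    """
    n = config.n_spots
    if n == 0:
        return []
    sigmas = config.sigmas()
    margin = 3.0 * float(np.max(sigmas))
    lo_x, hi_x = margin, width - 1 - margin
    lo_y, hi_y = margin, height - 1 - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise PackingError(
            f"border margin 3*sigma={margin:.1f} px leaves no interior in a {width}x{height} image"
        )
    usable = (hi_x - lo_x + config.min_nnd) * (hi_y - lo_y + config.min_nnd)
    if config.min_nnd > 0:
        capacity = usable * _HEX_PACKING / (math.pi * (config.min_nnd / 2.0) ** 2)
        if n > capacity:
            raise PackingError(
                f"{n} spots with min_nnd={config.min_nnd} cannot pack into "
                f"{width}x{height} (hexagonal capacity ~{capacity:.0f})"
            )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    pts: list[tuple[float, float]] = []
    arr = np.empty((0, 2))
    budget = max_attempts_per_spot * n
    min_sq = config.min_nnd**2
    while len(pts) < n:
        if budget <= 0:
            raise PackingError(
                f"rejection sampling exhausted placing spot {len(pts) + 1}/{n} "
                f"with min_nnd={config.min_nnd} in {width}x{height}"
            )
        budget -= 1
        p = (rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y))
        if len(pts) and np.min(((arr - p) ** 2).sum(axis=1)) < min_sq:
            continue
        pts.append(p)
        arr = np.vstack([arr, p])
    return pts


def _local_background_sigma(image: np.ndarray, x: float, y: float, sigma: float) -> float:
    """Robust std (1.4826 x MAD) of the annulus [4 sigma, 8 sigma] around (x, y)."""
    h, w = image.shape
    r_in, r_out = 4.0 * sigma, 8.0 * sigma
    if x + r_out < 0 or x - r_out > w - 1 or y + r_out < 0 or y - r_out > h - 1:
        raise BoundaryError(f"annulus around ({x}, {y}) lies fully outside the image")
    x0, x1 = max(0, int(math.floor(x - r_out))), min(w, int(math.ceil(x + r_out)) + 1)
    y0, y1 = max(0, int(math.floor(y - r_out))), min(h, int(math.ceil(y + r_out)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rr = np.hypot(xx - x, yy - y)
    mask = (rr >= r_in) & (rr <= r_out)
    if not mask.any():
        raise BoundaryError(f"annulus around ({x}, {y}) contains no in-image pixels")
    vals = image[y0:y1, x0:x1][mask]
    return 1.4826 * float(np.median(np.abs(vals - np.median(vals))))


def measure_snr(image: np.ndarray, x: float, y: float, sigma: float) -> float:
    """SNR of the spot at (x, y): fitted amplitude / robust background std.

    The amplitude comes from a Gaussian fit in a window of half-width
    ``ceil(4 sigma)``; the background std from the [4 sigma, 8 sigma]
    annulus.  Scale-invariant by construction.
    """
    image = np.asarray(image, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = image.shape
    if not (0 <= x < w and 0 <= y < h):
        raise BoundaryError(f"({x}, {y}) outside {w}x{h} image")
    fit = fit_gaussian(image, x, y, window_halfwidth=max(3, math.ceil(4.0 * sigma)))
    amp = max(fit.amplitude, 0.0)
    sigma_bg = _local_background_sigma(image, x, y, sigma)
    if sigma_bg == 0.0:
        scale = max(1.0, float(np.abs(image).max()))
        return math.inf if amp > 1e-9 * scale else 0.0
    return amp / sigma_bg


def render_spots(
    background: np.ndarray,
    locations: Sequence[tuple[float, float]],
    config: SynthConfig,
) -> tuple[np.ndarray, list[SpotRecord]]:
    """Add Gaussian spots to a copy of ``background``.

    Each spot's amplitude is calibrated as ``target_snr * sigma_bg`` with
    ``sigma_bg`` the robust background std measured in the spot's own
    annulus on the *pristine* background (so spot addition cannot bias the
    calibration).  On a noiseless background (sigma_bg = 0) the amplitude
    equals the target SNR numerically, so noise-free renders remain usable
    for size-fit round trips.
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background image is empty")
    h, w = background.shape
    out = background.copy()
    if len(locations) == 0:
        return out, []
    sigmas = config.sigmas()
    if len(sigmas) != len(locations):
        sigmas = np.full(len(locations), sigmas[0])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    targets = rng.normal(config.snr_mean, config.snr_spread, size=len(locations))
    targets = np.clip(targets, 0.1, None)
    spots: list[SpotRecord] = []
    for (x, y), sig, snr_t in zip(locations, sigmas, targets):
        if not (0 <= x < w and 0 <= y < h):
            raise BoundaryError(f"spot location ({x}, {y}) outside {w}x{h} image")
        sigma_bg = _local_background_sigma(background, x, y, sig)
        amp = snr_t * sigma_bg if sigma_bg > 0 else float(snr_t)
        r = int(math.ceil(5.0 * sig))
        x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out[y0:y1, x0:x1] += amp * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sig**2)
        )
        spots.append(SpotRecord(x=float(x), y=float(y), sigma=float(sig), amplitude=float(amp), snr=float(snr_t)))
    return out, spots


def invert_image(image: np.ndarray) -> np.ndarray:
    """Dark-spots-on-light rendering: max(image) - image."""
    image = np.asarray(image, dtype=float)
    return image.max() - image


def simulate_image(
    config: SynthConfig, width: int = 256, height: int = 256
) -> tuple[np.ndarray, list[SpotRecord]]:
    """Full simulation: background + placed and calibrated spots.

    Deterministic given ``config`` (including its seed); applies the
    ``invert`` option last.
    """
    bg = generate_background(
        width,
        height,
        noise_mean=config.noise_mean,
        noise_std=config.noise_std,
        texture_scale=config.texture_scale,
        seed=config.seed,
    )
    locs = sample_spot_locations(config, width, height)
    img, spots = render_spots(bg, locs, config)
    if config.invert:
        img = invert_image(img)
    return img, spots


def to_display_uint8(image: np.ndarray, p_lo: float = 0.1, p_hi: float = 99.9) -> np.ndarray:
    """Linear rescale to 8-bit with percentile clipping for display/export."""
    image = np.asarray(image, dtype=float)
    lo, hi = np.percentile(image, [p_lo, p_hi])
    if hi <= lo:
        return np.zeros_like(image, dtype=np.uint8)
    scaled = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
    return (scaled * 255.0 + 0.5).astype(np.uint8)


def min_pairwise_distance(points) -> float:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return math.inf
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(d[:, 1].min())
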