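"""Spot detection: preprocessing, normalized cross-correlation candidate
search, subpixel Gaussian refinement, and z-consistency validation.

Candidates are local maxima of the normalized cross-correlation between
a frame and a Gaussian template; each candidate is refined by fitting a
2D Gaussian (amplitude, centre, width, offset) in a small window, by
maximum likelihood under Poisson noise with a least-squares fallback.
For z-stacks, detections must appear at nearly identical lateral
positions across at least ``min_slices`` consecutive slices to count as
a real spot; a validated chain collapses to the brightest slice's
localization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import uniform_filter
from skimage.feature import match_template, peak_local_max

from .io import ImageStack

__all__ = [
    "Spot",
    "preprocess",
    "detect_candidates",
    "refine_gaussian",
    "validate_z",
    "detect_spots",
    "spots_to_table",
]


@dataclass
class Spot:
    """Subpixel localization of one fluorescent spot."""

    frame: int
    z_index: int
    x_um: float
    y_um: float
    amplitude: float  # peak signal above local background
    local_background: float
    sigma_px: float
    quality: float  # correlation score of the seeding candidate
    channel: str = ""
    compartment: str = "none"
    cell_id: int = -1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be > 0")

    @property
    def total_intensity(self) -> float:
        """Integrated Gaussian mass, ``amplitude * 2 pi sigma^2``."""
        return self.amplitude * 2.0 * math.pi * self.sigma_px**2


def preprocess(
    stack: ImageStack,
    *,
    max_z_projection: bool = False,
    bleach_correction: bool = False,
    background_subtraction: bool = False,
    bg_window_px: int = 25,
) -> ImageStack:
    """Standard movie preprocessing; returns a new calibrated stack.

    Z-projection takes the per-pixel maximum over z.  Bleach correction
    fits a mono-exponential to the frame-mean time series and divides
    each frame by the fit renormalized to frame 0.  Background
    subtraction removes a boxcar-smoothed (window much larger than the
    PSF) per-frame background, floored at 0.
    """
    pixels = stack.pixels.astype(float)
    if max_z_projection:
        pixels = pixels.max(axis=1, keepdims=True)
    if bleach_correction:
        n = pixels.shape[0]
        if n < 2:
            raise ValueError("bleach correction needs a multi-frame movie")
        means = pixels.mean(axis=(1, 2, 3))
        t = np.arange(n, dtype=float)

        def model(tt, a, rate):
            return a * np.exp(-rate * tt)

        try:
            popt, _ = optimize.curve_fit(
                model, t, means, p0=(float(means[0]), 1e-3), maxfev=5000
            )
            a_hat, rate_hat = popt
        except RuntimeError:
            a_hat, rate_hat = float(means[0]), 0.0
        correction = np.exp(-rate_hat * t)  # fit / fit(0)
        pixels = pixels / correction[:, None, None, None]
    if background_subtraction:
        for ti in range(pixels.shape[0]):
            for zi in range(pixels.shape[1]):
                bg = uniform_filter(pixels[ti, zi], size=bg_window_px, mode="nearest")
                pixels[ti, zi] = np.clip(pixels[ti, zi] - bg, 0.0, None)
    return ImageStack(
        pixels=pixels,
        pixel_size_um=stack.pixel_size_um,
        z_step_um=0.0 if max_z_projection else stack.z_step_um,
        frame_interval_s=stack.frame_interval_s,
        channel_label=stack.channel_label,
    )


def _gaussian_template(sigma: float) -> np.ndarray:
    half = max(2, int(math.ceil(3.0 * sigma)))
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    return g[:, None] * g[None, :]


def detect_candidates(
    image: np.ndarray,
    psf_sigma_px: float = 1.5,
    corr_threshold: float = 0.5,
) -> list[tuple[int, int, float]]:
    """Candidate spot pixels from normalized cross-correlation.

    Returns ``(y, x, score)`` tuples for local maxima of the NCC map
    above ``corr_threshold``, with non-maximum suppression within
    ``2 * psf_sigma_px``.  Output is ordered by descending score with
    (y, x) lexicographic tie-break, so detection is deterministic.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    if not 0.0 < corr_threshold < 1.0:
        raise ValueError("corr_threshold must be in (0, 1)")
    image = np.asarray(image, dtype=float)
    corr = match_template(image, _gaussian_template(psf_sigma_px), pad_input=True)
    corr = np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)
    min_dist = max(1, int(math.ceil(2.0 * psf_sigma_px)))
    peaks = peak_local_max(
        corr,
        min_distance=min_dist,
        threshold_abs=corr_threshold,
        exclude_border=False,
    )
    cands = [(int(y), int(x), float(corr[y, x])) for y, x in peaks]
    cands.sort(key=lambda c: (-c[2], c[0], c[1]))
    return cands


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    yy, xx = coords
    return (
        offset + amp * np.exp(-(((xx - x0) ** 2) + ((yy - y0) ** 2)) / (2.0 * sigma**2))
    ).ravel()


def refine_gaussian(
    image: np.ndarray,
    candidates,
    *,
    psf_sigma_px: float = 1.5,
    window: int = 7,
    method: str = "mle",
    pixel_size_um: float = 0.0433,
    frame: int = 0,
    z_index: int = 0,
    channel: str = "",
) -> list[Spot]:
    """Refine candidate positions by 2D Gaussian fitting.

    Fits (amplitude, x, y, sigma, offset) in a ``window x window`` patch
    around each candidate, by Poisson maximum likelihood (``method=
    'mle'``, initialized from a least-squares fit) or plain least
    squares (``method='lsq'``).  Candidates whose window exceeds the
    image bounds are skipped; fits that do not converge, run out of the
    window, or have non-positive amplitude are discarded.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    half = window // 2
    spots: list[Spot] = []
    for cand in candidates:
        cy, cx = int(cand[0]), int(cand[1])
        score = float(cand[2]) if len(cand) > 2 else 0.0
        if cy - half < 0 or cy + half >= ny or cx - half < 0 or cx + half >= nx:
            continue  # window outside bounds: skipped, counted by caller
        patch = image[cy - half : cy + half + 1, cx - half : cx + half + 1]
        yy, xx = np.mgrid[cy - half : cy + half + 1, cx - half : cx + half + 1]
        offset0 = float(patch.min())
        amp0 = max(float(patch.max() - offset0), 1e-6)
        p0 = (amp0, float(cx), float(cy), psf_sigma_px, offset0)
        bounds = (
            [0.0, cx - half, cy - half, 0.3, 0.0],
            [np.inf, cx + half, cy + half, float(window), np.inf],
        )
        try:
            popt, _ = optimize.curve_fit(
                _gauss2d, (yy, xx), patch.ravel(), p0=p0, bounds=bounds, maxfev=5000
            )
        except (RuntimeError, ValueError):
            continue
        if method == "mle":
            # Poisson negative log-likelihood, seeded by the LSQ fit
            data = patch.ravel()

            def nll(p):
                mu = _gauss2d((yy, xx), *p)
                mu = np.clip(mu, 1e-9, None)
                return float(np.sum(mu - data * np.log(mu)))

            res = optimize.minimize(
                nll,
                popt,
                method="L-BFGS-B",
                bounds=list(zip(bounds[0], bounds[1])),
            )
            if res.success:
                popt = res.x
        amp, x0, y0, sigma, offset = (float(v) for v in popt)
        if amp <= 1e-6 or sigma <= 0:
            continue
        if abs(x0 - cx) > half or abs(y0 - cy) > half:
            continue
        # reject fits indistinguishable from flat background
        if amp < 1e-3 * max(offset, 1.0):
            continue
        spots.append(
            Spot(
                frame=frame,
                z_index=z_index,
                x_um=x0 * pixel_size_um,
                y_um=y0 * pixel_size_um,
                amplitude=amp,
                local_background=offset,
                sigma_px=sigma,
                quality=score,
                channel=channel,
            )
        )
    return spots


def validate_z(
    spots: list[Spot],
    min_slices: int = 3,
    match_radius_px: float = 2.0,
    *,
    pixel_size_um: float = 0.0433,
) -> list[Spot]:
    """Keep spots persisting across consecutive z slices.

    Detections in adjacent z slices are chained when their lateral
    distance is at most ``match_radius_px``; chains spanning at least
    ``min_slices`` consecutive slices collapse to a single spot at the
    brightest slice's position (best focus).  Shorter chains are
    rejected.
    """
    if min_slices < 1:
        raise ValueError("min_slices must be >= 1")
    radius_um = match_radius_px * pixel_size_um
    by_z: dict[int, list[Spot]] = {}
    for s in spots:
        by_z.setdefault(int(s.z_index), []).append(s)
    chains: list[list[Spot]] = []
    open_chains: list[list[Spot]] = []
    for z in sorted(by_z):
        slice_spots = sorted(by_z[z], key=lambda s: (s.y_um, s.x_um))
        # close chains that did not continue into slice z-1
        still_open = []
        for ch in open_chains:
            if ch[-1].z_index < z - 1:
                chains.append(ch)
            else:
                still_open.append(ch)
        open_chains = still_open
        cands = []
        for ci, ch in enumerate(open_chains):
            if ch[-1].z_index != z - 1:
                continue
            for si, s in enumerate(slice_spots):
                d = math.hypot(s.x_um - ch[-1].x_um, s.y_um - ch[-1].y_um)
                if d <= radius_um:
                    cands.append((d, ci, si))
        cands.sort()
        used_c: set[int] = set()
        used_s: set[int] = set()
        for d, ci, si in cands:
            if ci in used_c or si in used_s:
                continue
            used_c.add(ci)
            used_s.add(si)
            open_chains[ci].append(slice_spots[si])
        for si, s in enumerate(slice_spots):
            if si not in used_s:
                open_chains.append([s])
    chains.extend(open_chains)

    validated = []
    for ch in chains:
        if len(ch) >= min_slices:
            best = max(ch, key=lambda s: s.amplitude)
            validated.append(
                Spot(
                    frame=best.frame,
                    z_index=best.z_index,
                    x_um=best.x_um,
                    y_um=best.y_um,
                    amplitude=best.amplitude,
                    local_background=best.local_background,
                    sigma_px=best.sigma_px,
                    quality=float(len(ch)),
                    channel=best.channel,
                    compartment=best.compartment,
                    cell_id=best.cell_id,
                )
            )
    validated.sort(key=lambda s: (s.frame, s.y_um, s.x_um))
    return validated


def detect_spots(
    stack: ImageStack,
    *,
    psf_sigma_px: float = 1.5,
    corr_threshold: float = 0.5,
    window: int = 7,
    method: str = "mle",
    min_z_slices: int | None = None,
    z_match_radius_px: float = 2.0,
    channel: str = "",
) -> list[Spot]:
    """Full per-stack detection: candidates, refinement, z-validation.

    For multi-slice stacks, pass ``min_z_slices`` to require persistence
    across consecutive z slices (collapsing each chain to one spot).
    """
    all_spots: list[Spot] = []
    for t in range(stack.n_frames):
        frame_spots: list[Spot] = []
        for z in range(stack.n_slices):
            image = stack.frame(t, z)
            cands = detect_candidates(image, psf_sigma_px, corr_threshold)
            frame_spots.extend(
                refine_gaussian(
                    image,
                    cands,
                    psf_sigma_px=psf_sigma_px,
                    window=window,
                    method=method,
                    pixel_size_um=stack.pixel_size_um,
                    frame=t,
                    z_index=z,
                    channel=channel,
                )
            )
        if min_z_slices is not None and stack.n_slices > 1:
            frame_spots = validate_z(
                frame_spots,
                min_slices=min_z_slices,
                match_radius_px=z_match_radius_px,
                pixel_size_um=stack.pixel_size_um,
            )
        all_spots.extend(frame_spots)
    return all_spots


def spots_to_table(spots: list[Spot]) -> pd.DataFrame:
    """Spot list as a tidy table (one row per spot)."""
    return pd.DataFrame(
        [
            {
                "frame": s.frame,
                "z_index": s.z_index,
                "x_um": s.x_um,
                "y_um": s.y_um,
                "amplitude": s.amplitude,
                "local_background": s.local_background,
                "sigma_px": s.sigma_px,
                "quality": s.quality,
                "channel": s.channel,
                "compartment": s.compartment,
                "cell_id": s.cell_id,
            }
            for s in spots
        ],
        columns=[
            "frame", "z_index", "x_um", "y_um", "amplitude", "local_background",
            "sigma_px", "quality", "channel", "compartment", "cell_id",
        ],
    )
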