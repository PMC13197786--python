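"""Transcription-site bursting: trace extraction, ON/OFF segmentation,
dwell-time kinetics and activity metrics.

A transcription site is called ON in a frame when its (by default
window-3 smoothed) intensity exceeds ``factor`` (1.5) times the local
nuclear background, and an ON run must last at least
``min_on_duration_min`` (1.5 min, one frame at 90-s sampling).  Dwells
touching either end of the recording are marked censored and excluded
from kinetic fits by default, since their true duration is only bounded
below.  ON/OFF duration distributions are summarised as survival
("inverse cumulative") histograms and fitted with a single exponential
``A * exp(-t / tau)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "IntensityTrace",
    "StateSequence",
    "ExpFit",
    "KSResult",
    "DwellTimeModel",
    "DwellTimeResults",
    "track_site_intensity",
    "segment_states",
    "extract_dwells",
    "fit_dwell_exponential",
    "compare_ks",
    "activity_metrics",
    "count_nascent",
]


@dataclass
class IntensityTrace:
    """Fluorescence intensity of one transcription site over time."""

    site_id: int
    cell_id: int
    frames: np.ndarray
    raw_intensity: np.ndarray
    local_background: np.ndarray
    frame_interval_s: float
    positions: np.ndarray | None = None  # (n, 2) of (x, y) px, optional
    dish_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.raw_intensity = np.asarray(self.raw_intensity, dtype=float)
        self.local_background = np.asarray(self.local_background, dtype=float)
        n = len(self.frames)
        if not (len(self.raw_intensity) == len(self.local_background) == n):
            raise ValueError("trace arrays must have equal lengths")
        if np.any(self.local_background <= 0):
            raise ValueError("local background must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    def smoothed(self, window: int = 3) -> np.ndarray:
        """Centred rolling mean, window shrinking at the trace edges."""
        return (
            pd.Series(self.raw_intensity)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class StateSequence:
    """Per-frame ON/OFF states and the dwells they partition into."""

    site_id: int
    cell_id: int
    states: np.ndarray  # '<U3' array of 'ON'/'OFF'
    dwells: pd.DataFrame  # state, start_frame, n_frames, duration_min, censored
    frame_interval_s: float
    dish_id: int = 0

    @property
    def ever_on(self) -> bool:
        return bool(np.any(self.states == "ON"))

    def onset_time_min(self) -> float | None:
        """Time of the first ON frame (minutes), None if never ON."""
        on = np.nonzero(self.states == "ON")[0]
        if len(on) == 0:
            return None
        return float(on[0] * self.frame_interval_s / 60.0)


def _disk_offsets(radius: int) -> np.ndarray:
    offs = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    return np.asarray(offs)


def track_site_intensity(
    movie,
    seed_positions,
    nucleus_mask: np.ndarray,
    *,
    search_radius_px: int = 3,
    aperture_radius_px: int = 3,
    bg_exclusion_radius_px: int = 5,
    hold_margin_sigma: float = 3.0,
    cell_id: int = 0,
    dish_id: int = 0,
) -> list[IntensityTrace]:
    """Follow seeded transcription sites through a (z-projected) movie.

    Per frame, each site position moves to the brightest pixel within
    ``search_radius_px`` of its previous position; it is held fixed when
    no pixel there exceeds the background level by
    ``hold_margin_sigma`` shot-noise standard deviations, so the
    position does not random-walk away while the site is OFF.  The raw
    intensity is the pixel sum
    in a disk of ``aperture_radius_px``; the local background is the
    mean nuclear intensity outside exclusion disks around all sites,
    scaled to the same aperture area so the two are directly comparable.
    """
    pixels = movie.pixels if hasattr(movie, "pixels") else np.asarray(movie)
    if pixels.ndim == 4:
        if pixels.shape[1] != 1:
            raise ValueError("movie must be z-projected (single z slice)")
        pixels = pixels[:, 0]
    n_frames, ny, nx = pixels.shape
    mask = np.asarray(nucleus_mask, dtype=bool)
    if mask.shape != (ny, nx):
        raise ValueError("nucleus mask shape must match the movie frame")
    seeds = [(float(x), float(y)) for x, y in seed_positions]
    for x, y in seeds:
        if not mask[int(round(y)), int(round(x))]:
            raise ValueError(f"seed position ({x:.1f}, {y:.1f}) outside the nucleus")
    ap_offsets = _disk_offsets(aperture_radius_px)
    n_ap = len(ap_offsets)
    frame_interval = getattr(movie, "frame_interval_s", 1.0)

    positions = [list(s) for s in seeds]
    raws = [[] for _ in seeds]
    bgs = [[] for _ in seeds]
    pos_hist = [[] for _ in seeds]
    yy, xx = np.mgrid[0:ny, 0:nx]
    for t in range(n_frames):
        frame = pixels[t]
        bg_mask = mask.copy()
        for (sx, sy) in positions:
            bg_mask &= (xx - sx) ** 2 + (yy - sy) ** 2 > bg_exclusion_radius_px**2
        bg_level = float(frame[bg_mask].mean()) if bg_mask.any() else float(frame[mask].mean())
        for si, (sx, sy) in enumerate(positions):
            ix, iy = int(round(sx)), int(round(sy))
            y0, y1 = max(0, iy - search_radius_px), min(ny, iy + search_radius_px + 1)
            x0, x1 = max(0, ix - search_radius_px), min(nx, ix + search_radius_px + 1)
            window = frame[y0:y1, x0:x1]
            my, mx = np.unravel_index(np.argmax(window), window.shape)
            if window[my, mx] > bg_level + hold_margin_sigma * math.sqrt(max(bg_level, 1.0)):
                sx, sy = float(x0 + mx), float(y0 + my)
                positions[si] = [sx, sy]
            ys = np.clip(int(round(sy)) + ap_offsets[:, 0], 0, ny - 1)
            xs = np.clip(int(round(sx)) + ap_offsets[:, 1], 0, nx - 1)
            raws[si].append(float(frame[ys, xs].sum()))
            bgs[si].append(bg_level * n_ap)
            pos_hist[si].append((sx, sy))
    traces = []
    for si in range(len(seeds)):
        traces.append(
            IntensityTrace(
                site_id=si,
                cell_id=cell_id,
                frames=np.arange(n_frames),
                raw_intensity=np.asarray(raws[si]),
                local_background=np.asarray(bgs[si]),
                frame_interval_s=frame_interval,
                positions=np.asarray(pos_hist[si]),
                dish_id=dish_id,
            )
        )
    return traces


def extract_dwells(states: np.ndarray, frame_interval_s: float) -> pd.DataFrame:
    """Run-length encode a state sequence into dwells with censor flags.

    Dwells partition the trace; the first and last run touch a recording
    boundary and are censored.  Durations are ``n_frames`` times the
    frame interval, in minutes.
    """
    states = np.asarray(states)
    n = len(states)
    rows = []
    start = 0
    for i in range(1, n + 1):
        if i == n or states[i] != states[start]:
            rows.append(
                {
                    "state": str(states[start]),
                    "start_frame": start,
                    "n_frames": i - start,
                    "duration_min": (i - start) * frame_interval_s / 60.0,
                    "censored": (start == 0) or (i == n),
                }
            )
            start = i
    return pd.DataFrame(rows, columns=["state", "start_frame", "n_frames", "duration_min", "censored"])


def segment_states(
    trace: IntensityTrace,
    factor: float = 1.5,
    min_on_duration_min: float = 1.5,
    smooth_window: int = 3,
    *,
    use_smoothed: bool = False,
) -> StateSequence:
    """Threshold a trace into ON/OFF dwells.

    A frame is ON when the raw intensity strictly exceeds ``factor``
    times the local background; ON runs shorter than
    ``min_on_duration_min`` are demoted to OFF (no minimum applies to
    OFF runs).  ``use_smoothed`` thresholds the window-``smooth_window``
    rolling mean instead; note that smoothing erases dwells of a single
    frame, merging the flanking dwells of the opposite state, which
    inflates fitted time constants when dwells near the frame interval
    are common.  The comparison is scale-invariant: multiplying trace
    and background by a common constant does not change the
    segmentation.
    """
    if len(trace) < smooth_window:
        raise ValueError("trace shorter than the smoothing window")
    signal = trace.smoothed(smooth_window) if use_smoothed else trace.raw_intensity
    on = signal > factor * trace.local_background
    states = np.where(on, "ON", "OFF").astype("<U3")
    # demote short ON runs
    dt_min = trace.frame_interval_s / 60.0
    min_frames = int(math.ceil(min_on_duration_min / dt_min - 1e-9))
    dwells = extract_dwells(states, trace.frame_interval_s)
    for row in dwells.itertuples(index=False):
        if row.state == "ON" and row.n_frames < min_frames:
            states[row.start_frame : row.start_frame + row.n_frames] = "OFF"
    dwells = extract_dwells(states, trace.frame_interval_s)
    return StateSequence(
        site_id=trace.site_id,
        cell_id=trace.cell_id,
        states=states,
        dwells=dwells,
        frame_interval_s=trace.frame_interval_s,
        dish_id=trace.dish_id,
    )


@dataclass
class ExpFit:
    """Single-exponential fit to a dwell-time survival histogram."""

    tau_min: float
    amplitude: float
    residual_norm: float
    n_events: int
    poor_fit: bool = False


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def survival_histogram(durations_min: np.ndarray) -> pd.DataFrame:
    """Inverse cumulative histogram: S(t) = #{dwells >= t} at observed t."""
    durations = np.sort(np.asarray(durations_min, dtype=float))
    ts = np.unique(durations)
    counts = len(durations) - np.searchsorted(durations, ts, side="left")
    return pd.DataFrame({"duration_min": ts, "survival": counts})


class DwellTimeModel:
    """Single-exponential dwell-time model for one state's durations.

    Fits ``A * exp(-t / tau)`` to the survival histogram of uncensored
    dwell durations by nonlinear least squares.  Because exponential
    dwells are memoryless, a minimum-duration cut shifts the survival
    curve without tilting it, so tau is recovered regardless of the ON
    minimum-duration rule.
    """

    def __init__(self, durations_min, censored=None, *, include_censored: bool = False):
        durations = np.asarray(durations_min, dtype=float)
        if censored is None:
            censored = np.zeros(len(durations), dtype=bool)
        censored = np.asarray(censored, dtype=bool)
        if not include_censored:
            durations = durations[~censored]
        self.durations_min = durations
        self.n_events = len(durations)

    def fit(self, min_events: int = 10) -> "DwellTimeResults":
        if self.n_events < min_events:
            raise ValueError(
                f"too few uncensored dwells for a fit: {self.n_events} < {min_events}"
            )
        surv = survival_histogram(self.durations_min)
        t = surv["duration_min"].to_numpy()
        s = surv["survival"].to_numpy(dtype=float)
        poor = False
        if len(t) < 3:
            # degenerate support (e.g. all durations identical)
            tau = float(np.mean(self.durations_min))
            return DwellTimeResults(
                ExpFit(tau, float(s[0]), float(np.inf), self.n_events, poor_fit=True), surv
            )
        tau0 = max(float(np.mean(self.durations_min)), 1e-6)
        popt, _ = optimize.curve_fit(
            lambda x, a, tau: a * np.exp(-x / tau),
            t,
            s,
            p0=(float(s[0] * np.exp(t[0] / tau0)), tau0),
            maxfev=10000,
        )
        a_hat, tau_hat = float(popt[0]), float(popt[1])
        if tau_hat <= 0:
            raise RuntimeError("exponential fit converged to non-positive tau")
        resid = s - a_hat * np.exp(-t / tau_hat)
        rms = float(np.sqrt(np.mean(resid**2)))
        poor = rms > 0.2 * float(np.mean(s))
        return DwellTimeResults(ExpFit(tau_hat, a_hat, rms, self.n_events, poor_fit=poor), surv)


@dataclass
class DwellTimeResults:
    fit: ExpFit
    survival: pd.DataFrame

    @property
    def tau_min(self) -> float:
        return self.fit.tau_min

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Dwell-time single-exponential fit",
            f"  events (uncensored): {f.n_events}",
            f"  tau:                 {f.tau_min:.3g} min",
            f"  amplitude:           {f.amplitude:.3g}",
            f"  rms residual:        {f.residual_norm:.3g}"
            + ("  [poor fit]" if f.poor_fit else ""),
        ]
        return "\n".join(lines)

    def plot_survival(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.survival["duration_min"]
        ax.semilogy(t, self.survival["survival"], "o", label="observed")
        tt = np.linspace(0, float(t.max()), 200)
        ax.semilogy(tt, self.fit.amplitude * np.exp(-tt / self.fit.tau_min), "-",
                    label=f"tau = {self.fit.tau_min:.1f} min")
        ax.set_xlabel("duration (min)")
        ax.set_ylabel("dwells >= t")
        ax.legend()
        return ax


def fit_dwell_exponential(
    durations_min,
    censored=None,
    *,
    include_censored: bool = False,
    min_events: int = 10,
) -> DwellTimeResults:
    """Fit a single exponential to a dwell-duration survival histogram."""
    return DwellTimeModel(
        durations_min, censored, include_censored=include_censored
    ).fit(min_events=min_events)


def compare_ks(dwells_a, dwells_b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of dwell distributions."""
    a = np.asarray(dwells_a, dtype=float)
    b = np.asarray(dwells_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


def activity_metrics(
    sequences: list[StateSequence],
    *,
    max_alleles: int = 4,
    n_frames: int | None = None,
) -> dict:
    """Cell/dish-level transcription activity summaries.

    A cell is active if at least one of its sites is ever ON.  The
    active-cell fraction is computed per dish and then averaged across
    dishes; the per-frame active-site fraction is the mean over cells of
    (sites ON / ``max_alleles``); onset is the time of each site's first
    ON frame, histogrammed at the frame interval.
    """
    if not sequences:
        return {
            "active_cell_fraction": float("nan"),
            "per_dish": pd.DataFrame(columns=["dish_id", "n_cells", "active_fraction"]),
            "active_site_fraction": pd.DataFrame(columns=["frame", "time_min", "fraction"]),
            "onset_times_min": np.array([]),
        }
    dt_min = sequences[0].frame_interval_s / 60.0
    if n_frames is None:
        n_frames = max(len(s.states) for s in sequences)

    by_cell: dict[tuple[int, int], list[StateSequence]] = {}
    for s in sequences:
        by_cell.setdefault((s.dish_id, s.cell_id), []).append(s)

    dish_rows = []
    by_dish: dict[int, list[bool]] = {}
    for (dish, cell), seqs in sorted(by_cell.items()):
        by_dish.setdefault(dish, []).append(any(s.ever_on for s in seqs))
    for dish, flags in sorted(by_dish.items()):
        dish_rows.append(
            {"dish_id": dish, "n_cells": len(flags), "active_fraction": float(np.mean(flags))}
        )
    per_dish = pd.DataFrame(dish_rows)
    active_cell_fraction = float(per_dish["active_fraction"].mean())

    frac = np.zeros(n_frames)
    for t in range(n_frames):
        vals = []
        for seqs in by_cell.values():
            n_on = sum(1 for s in seqs if t < len(s.states) and s.states[t] == "ON")
            vals.append(min(n_on, max_alleles) / max_alleles)
        frac[t] = float(np.mean(vals))
    active_site = pd.DataFrame(
        {"frame": np.arange(n_frames), "time_min": np.arange(n_frames) * dt_min, "fraction": frac}
    )

    onsets = np.asarray(
        [s.onset_time_min() for s in sequences if s.onset_time_min() is not None]
    )
    if len(onsets):
        edges = np.arange(0.0, onsets.max() + 2 * dt_min, dt_min)
        hist, _ = np.histogram(onsets, bins=edges)
        onset_hist = pd.DataFrame({"time_min": edges[:-1], "count": hist})
    else:
        onset_hist = pd.DataFrame(columns=["time_min", "count"])
    return {
        "active_cell_fraction": active_cell_fraction,
        "per_dish": per_dish,
        "active_site_fraction": active_site,
        "onset_times_min": onsets,
        "onset_histogram": onset_hist,
    }


def count_nascent(
    site_intensity,
    single_mrna_reference_intensity: float,
    background=None,
) -> np.ndarray:
    """Nascent-transcript count: site intensity over the single-mRNA unit.

    ``site_intensity`` may already be background-subtracted (pass
    ``background=None``) or raw with a matching background to subtract.
    Negative counts are clamped to zero.
    """
    if not single_mrna_reference_intensity > 0:
        raise ValueError("single-molecule reference intensity must be > 0")
    intensity = np.asarray(site_intensity, dtype=float)
    if background is not None:
        intensity = intensity - np.asarray(background, dtype=float)
    return np.clip(intensity / single_mrna_reference_intensity, 0.0, None)
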