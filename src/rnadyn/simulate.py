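"""Synthetic-data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here with
known ground truth, emulating the statistical structure the analyses
assume:

* 2D single-molecule motion in four classes (stationary, corralled,
  diffusive, directed) with localization noise, at fast (30 ms) frames;
* two-state (telegraph) transcription-site intensity traces sampled at
  90-s frames, with exact exponential ON/OFF dwells and Poisson
  initiation of nascent transcripts while ON;
* two-channel smFISH spot fields with a controllable true tagging
  fraction, Gaussian partner offsets and Poisson distractors;
* diffraction-limited spot movies (integrated Gaussian PSF, Poisson
  shot noise, Gaussian read noise);
* exponential mRNA-decay replicate measurements and matching qPCR Ct
  tables.

All generators are deterministic given their seed, and every simulated
entity is recorded in a :class:`GroundTruth` so downstream recovery can
be scored without re-deriving labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .bursting import IntensityTrace, StateSequence, extract_dwells
from .io import CellROI, ImageStack
from .tracking import Trajectory

__all__ = [
    "MotionParams",
    "TelegraphParams",
    "GroundTruth",
    "sim_trajectories",
    "render_movie",
    "render_trajectory_movie",
    "sim_telegraph_traces",
    "sim_smfish_cells",
    "sim_decay",
    "sim_decay_qpcr",
]

MOTION_CLASSES = ("stationary", "corralled", "diffusive", "directed")


@dataclass
class GroundTruth:
    """Per-entity true labels/parameters for a simulation run."""

    seed: int
    entities: pd.DataFrame
    extras: dict = field(default_factory=dict)


@dataclass
class MotionParams:
    """Generative parameters for one motion class.

    ``confinement_radius_um`` is required for corralled motion and
    ``velocity_um_s`` for directed motion; both are rejected as missing
    otherwise absent parameters at validation.
    """

    motion_class: str
    D_um2_s: float = 0.0
    confinement_radius_um: float | None = None
    velocity_um_s: float | None = None
    loc_noise_sigma_um: float = 0.03
    n_frames: int = 30
    dt_s: float = 0.03

    def __post_init__(self) -> None:
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(f"unknown motion class {self.motion_class!r}")
        if self.D_um2_s < 0 or self.loc_noise_sigma_um < 0:
            raise ValueError("D and localization noise must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.motion_class == "corralled":
            if self.confinement_radius_um is None or self.confinement_radius_um <= 0:
                raise ValueError("corralled motion requires confinement_radius_um > 0")
        if self.motion_class == "directed":
            if self.velocity_um_s is None or self.velocity_um_s < 0:
                raise ValueError("directed motion requires velocity_um_s >= 0")


def _simulate_one_track(p: MotionParams, rng: np.random.Generator) -> np.ndarray:
    """True (noise-free) positions, shape (n_frames, 2), in um."""
    n = p.n_frames
    step_sd = math.sqrt(2.0 * p.D_um2_s * p.dt_s)
    if p.motion_class == "stationary":
        pos = np.zeros((n, 2))
    elif p.motion_class == "diffusive":
        steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    elif p.motion_class == "directed":
        theta = rng.uniform(0.0, 2.0 * math.pi)
        drift = p.velocity_um_s * p.dt_s * np.array([math.cos(theta), math.sin(theta)])
        steps = rng.normal(0.0, step_sd, size=(n - 1, 2)) + drift
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    else:  # corralled: Brownian reflected at a circular boundary
        R = float(p.confinement_radius_um)
        pos = np.zeros((n, 2))
        cur = np.zeros(2)
        for i in range(1, n):
            cur = cur + rng.normal(0.0, step_sd, size=2)
            r = np.hypot(*cur)
            while r > R:
                cur *= (2.0 * R - r) / r  # radial reflection
                r = np.hypot(*cur)
            pos[i] = cur
    return pos


def sim_trajectories(
    params: MotionParams | list[MotionParams],
    n_per_class: int = 1,
    seed: int = 0,
    *,
    pixel_size_um: float = 0.0433,
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate 2D trajectories with localization noise.

    Increments per axis have variance ``2 * D * dt`` for free diffusion;
    corralled motion reflects at a circular boundary; directed motion
    adds a constant drift with a random fixed direction per trajectory.
    Isotropic Gaussian localization noise is added to every point.
    """
    if isinstance(params, MotionParams):
        params = [params]
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    trajectories: list[Trajectory] = []
    records = []
    tid = 0
    for p in params:
        for _ in range(n_per_class):
            pos = _simulate_one_track(p, rng)
            noisy = pos + rng.normal(0.0, p.loc_noise_sigma_um, size=pos.shape)
            n = p.n_frames
            trajectories.append(
                Trajectory(
                    traj_id=tid,
                    frames=np.arange(n),
                    x_um=noisy[:, 0],
                    y_um=noisy[:, 1],
                    interpolated=np.zeros(n, dtype=bool),
                    dt_s=p.dt_s,
                    pixel_size_um=pixel_size_um,
                )
            )
            records.append(
                {
                    "traj_id": tid,
                    "motion_class": p.motion_class,
                    "D_um2_s": p.D_um2_s,
                    "confinement_radius_um": p.confinement_radius_um,
                    "velocity_um_s": p.velocity_um_s,
                    "loc_noise_sigma_um": p.loc_noise_sigma_um,
                }
            )
            tid += 1
    return trajectories, GroundTruth(seed=seed, entities=pd.DataFrame(records))


def _integrated_gaussian_patch(x: float, y: float, sigma: float, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Unit-mass 2D Gaussian integrated over unit pixels centred at integers."""
    s = sigma * math.sqrt(2.0)
    gx = 0.5 * (special.erf((xx + 0.5 - x) / s) - special.erf((xx - 0.5 - x) / s))
    gy = 0.5 * (special.erf((yy + 0.5 - y) / s) - special.erf((yy - 0.5 - y) / s))
    return gy[:, None] * gx[None, :]


def render_movie(
    spots_over_time: pd.DataFrame,
    *,
    shape: tuple[int, int],
    n_frames: int | None = None,
    psf_sigma_px: float = 1.5,
    background: float = 100.0,
    read_noise_sd: float = 2.0,
    poisson_noise: bool = True,
    seed: int = 0,
    pixel_size_um: float = 0.0433,
    frame_interval_s: float = 1.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render emitters as integrated Gaussian spots on a noisy camera.

    ``spots_over_time`` has columns ``frame, x_px, y_px, amplitude``
    where ``amplitude`` is the total photon mass of the spot in that
    frame.  Poisson shot noise applies to signal plus background, then
    additive Gaussian read noise (clipped at zero to keep the frame a
    physical intensity image).
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    spots = pd.DataFrame(spots_over_time)
    for col in ("frame", "x_px", "y_px", "amplitude"):
        if col not in spots.columns and len(spots):
            raise ValueError(f"spots_over_time missing column {col!r}")
    ny, nx = shape
    if len(spots):
        ok = (
            (spots["x_px"] >= 0)
            & (spots["x_px"] <= nx - 1)
            & (spots["y_px"] >= 0)
            & (spots["y_px"] <= ny - 1)
        )
        if not ok.all():
            raise ValueError("emitter position outside the frame")
    if n_frames is None:
        n_frames = int(spots["frame"].max()) + 1 if len(spots) else 1
    rng = np.random.default_rng(seed)
    half = int(math.ceil(5 * psf_sigma_px))
    movie = np.full((n_frames, 1, ny, nx), float(background))
    for row in spots.itertuples(index=False):
        t = int(row.frame)
        if t >= n_frames:
            continue
        cx, cy = float(row.x_px), float(row.y_px)
        x0 = max(0, int(math.floor(cx)) - half)
        x1 = min(nx, int(math.floor(cx)) + half + 1)
        y0 = max(0, int(math.floor(cy)) - half)
        y1 = min(ny, int(math.floor(cy)) + half + 1)
        patch = _integrated_gaussian_patch(
            cx, cy, psf_sigma_px, np.arange(y0, y1, dtype=float), np.arange(x0, x1, dtype=float)
        )
        movie[t, 0, y0:y1, x0:x1] += float(row.amplitude) * patch
    if poisson_noise:
        movie = rng.poisson(movie).astype(float)
    if read_noise_sd > 0:
        movie = movie + rng.normal(0.0, read_noise_sd, size=movie.shape)
    movie = np.clip(movie, 0.0, None)
    stack = ImageStack(
        pixels=movie,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_label="synthetic",
    )
    return stack, GroundTruth(seed=seed, entities=spots.copy())


def render_trajectory_movie(
    trajectories: list[Trajectory],
    *,
    shape: tuple[int, int],
    amplitude: float = 2000.0,
    offset_px: tuple[float, float] = (0.0, 0.0),
    **render_kwargs,
) -> tuple[ImageStack, GroundTruth]:
    """Render simulated trajectories as a spot movie (positions um -> px)."""
    rows = []
    for t in trajectories:
        px = t.pixel_size_um
        for i in range(len(t)):
            rows.append(
                {
                    "frame": int(t.frames[i]),
                    "x_px": t.x_um[i] / px + offset_px[0],
                    "y_px": t.y_um[i] / px + offset_px[1],
                    "amplitude": amplitude,
                    "traj_id": t.traj_id,
                }
            )
    return render_movie(pd.DataFrame(rows), shape=shape, **render_kwargs)


@dataclass
class TelegraphParams:
    """Two-state transcription model sampled at the imaging frame rate.

    While ON, nascent transcripts initiate as a Poisson process at
    ``initiation_rate_per_min`` and each remains fluorescent at the site
    for ``site_dwell_min`` (stem-loops in the 3'UTR become fluorescent
    only near the end of elongation, so residence is short).  Defaults
    put the mean ON plateau at twice the background so the standard
    1.5x-background ON threshold sits at half the burst amplitude.
    """

    mean_on_min: float = 8.2
    mean_off_min: float = 7.0
    initiation_rate_per_min: float = 40.0
    site_dwell_min: float = 0.5
    unit_intensity: float = 10.0
    background_level: float = 200.0
    noise_sd: float = 20.0
    frame_interval_s: float = 90.0
    duration_min: float = 75.0

    def __post_init__(self) -> None:
        if self.mean_on_min <= 0 or self.mean_off_min <= 0:
            raise ValueError("dwell means must be > 0")
        if self.initiation_rate_per_min < 0:
            raise ValueError("initiation rate must be >= 0")
        for name in ("site_dwell_min", "unit_intensity", "background_level",
                     "frame_interval_s", "duration_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _simulate_telegraph_site(p: TelegraphParams, rng: np.random.Generator):
    """Exact event-driven two-state simulation of one site.

    Returns (frame times in min, nascent count per frame, true state per
    frame, list of (state, start_min, end_min) intervals).  Dwells are
    exactly exponential before frame discretization.
    """
    duration = p.duration_min
    t = 0.0
    state = "OFF"  # observation starts after a quiescent period
    intervals = []
    initiations: list[float] = []
    while t < duration:
        mean = p.mean_on_min if state == "ON" else p.mean_off_min
        dwell = rng.exponential(mean)
        end = t + dwell
        intervals.append((state, t, min(end, duration)))
        if state == "ON" and p.initiation_rate_per_min > 0:
            n_init = rng.poisson(p.initiation_rate_per_min * (min(end, duration) - t))
            if n_init:
                initiations.extend(rng.uniform(t, min(end, duration), size=n_init))
        t = end
        state = "ON" if state == "OFF" else "OFF"
    dt_min = p.frame_interval_s / 60.0
    frame_times = np.arange(0.0, duration, dt_min)
    init = np.sort(np.asarray(initiations))
    counts = np.zeros(len(frame_times), dtype=int)
    if len(init):
        # transcript i is present on [init_i, init_i + site_dwell)
        lo = np.searchsorted(init, frame_times - p.site_dwell_min, side="right")
        hi = np.searchsorted(init, frame_times, side="right")
        counts = hi - lo
    states = np.empty(len(frame_times), dtype=object)
    starts = np.array([iv[1] for iv in intervals])
    labels = [iv[0] for iv in intervals]
    idx = np.clip(np.searchsorted(starts, frame_times, side="right") - 1, 0, len(labels) - 1)
    for i, j in enumerate(idx):
        states[i] = labels[j]
    return frame_times, counts, states, intervals


def sim_telegraph_traces(
    params: TelegraphParams,
    n_sites: int = 1,
    seed: int = 0,
) -> tuple[list[IntensityTrace], GroundTruth]:
    """Simulate transcription-site intensity traces with true state labels.

    The ground truth records, per site, the true per-frame state and the
    complete list of generative ON/OFF intervals (exact, continuous-time
    durations, with boundary intervals marked censored).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    traces = []
    state_rows = []
    dwell_rows = []
    for sid in range(n_sites):
        frame_times, counts, states, intervals = _simulate_telegraph_site(params, rng)
        n = len(frame_times)
        raw = (
            params.background_level
            + params.unit_intensity * counts
            + rng.normal(0.0, params.noise_sd, size=n)
        )
        traces.append(
            IntensityTrace(
                site_id=sid,
                cell_id=sid,
                frames=np.arange(n),
                raw_intensity=raw,
                local_background=np.full(n, params.background_level),
                frame_interval_s=params.frame_interval_s,
            )
        )
        for i in range(n):
            state_rows.append({"site_id": sid, "frame": i, "true_state": states[i],
                               "nascent_count": int(counts[i])})
        for k, (st, t0, t1) in enumerate(intervals):
            dwell_rows.append(
                {
                    "site_id": sid,
                    "state": st,
                    "start_min": t0,
                    "duration_min": t1 - t0,
                    "censored": (k == 0) or (k == len(intervals) - 1),
                }
            )
    truth = GroundTruth(
        seed=seed,
        entities=pd.DataFrame(state_rows),
        extras={"dwells": pd.DataFrame(dwell_rows), "params": params},
    )
    return traces, truth


def _disk_mask(shape, cx, cy, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def sim_smfish_cells(
    n_cells: int = 10,
    counts_per_compartment: tuple[float, float] = (20.0, 40.0),
    tagging_fraction: float = 0.75,
    partner_offset_sigma_um: float = 0.05,
    distractor_density_per_um2: float = 0.05,
    seed: int = 0,
    *,
    nucleus_radius_um: float = 5.0,
    cell_radius_um: float = 10.0,
    mask_pixel_um: float = 0.1,
    make_masks: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[CellROI], GroundTruth]:
    """Simulate two-channel smFISH spot fields for ``n_cells`` cells.

    Each cell is a circular nucleus inside an annular cytoplasm.
    Channel-A spots (e.g. CDS probe) are placed uniformly per
    compartment with Poisson-distributed counts; a fraction
    ``tagging_fraction`` of them receive a channel-B partner displaced
    by an isotropic Gaussian offset; independent channel-B distractors
    appear at ``distractor_density_per_um2`` over the cell area.

    Returns (spots_A, spots_B, rois, truth); spot tables hold
    ``cell_id, compartment, x_um, y_um`` in per-cell coordinates
    (cell centre at ``(cell_radius, cell_radius)``).
    """
    if not 0.0 <= tagging_fraction <= 1.0:
        raise ValueError("tagging_fraction must be in [0, 1]")
    if distractor_density_per_um2 < 0:
        raise ValueError("distractor density must be >= 0")
    if nucleus_radius_um >= cell_radius_um:
        raise ValueError("nucleus must fit inside the cell")
    rng = np.random.default_rng(seed)
    mean_nuc, mean_cyt = counts_per_compartment
    c = cell_radius_um  # cell centre coordinate

    def _uniform_in_annulus(n, r0, r1):
        r = np.sqrt(rng.uniform(r0**2, r1**2, size=n))
        th = rng.uniform(0, 2 * math.pi, size=n)
        return np.column_stack([c + r * np.cos(th), c + r * np.sin(th)])

    a_rows, b_rows, truth_rows = [], [], []
    rois: list[CellROI] = []
    a_id = b_id = 0
    for cid in range(n_cells):
        for compartment, mean, r0, r1 in (
            ("nucleus", mean_nuc, 0.0, nucleus_radius_um),
            ("cytoplasm", mean_cyt, nucleus_radius_um, cell_radius_um),
        ):
            n_spots = rng.poisson(mean)
            pos = _uniform_in_annulus(n_spots, r0, r1)
            tagged = rng.random(n_spots) < tagging_fraction
            for i in range(n_spots):
                partner = -1
                if tagged[i]:
                    off = rng.normal(0.0, partner_offset_sigma_um, size=2)
                    b_rows.append(
                        {
                            "spot_id": b_id,
                            "cell_id": cid,
                            "compartment": compartment,
                            "x_um": pos[i, 0] + off[0],
                            "y_um": pos[i, 1] + off[1],
                            "kind": "partner",
                        }
                    )
                    partner = b_id
                    b_id += 1
                a_rows.append(
                    {
                        "spot_id": a_id,
                        "cell_id": cid,
                        "compartment": compartment,
                        "x_um": pos[i, 0],
                        "y_um": pos[i, 1],
                    }
                )
                truth_rows.append(
                    {
                        "spot_id": a_id,
                        "cell_id": cid,
                        "compartment": compartment,
                        "tagged": bool(tagged[i]),
                        "partner_id": partner,
                    }
                )
                a_id += 1
        # channel-B distractors over the whole cell disk
        n_distr = rng.poisson(distractor_density_per_um2 * math.pi * cell_radius_um**2)
        pos = _uniform_in_annulus(n_distr, 0.0, cell_radius_um)
        for i in range(n_distr):
            r = np.hypot(pos[i, 0] - c, pos[i, 1] - c)
            b_rows.append(
                {
                    "spot_id": b_id,
                    "cell_id": cid,
                    "compartment": "nucleus" if r <= nucleus_radius_um else "cytoplasm",
                    "x_um": pos[i, 0],
                    "y_um": pos[i, 1],
                    "kind": "distractor",
                }
            )
            b_id += 1
        if make_masks:
            npx = int(math.ceil(2 * cell_radius_um / mask_pixel_um)) + 1
            cpx = c / mask_pixel_um
            nuc = _disk_mask((npx, npx), cpx, cpx, nucleus_radius_um / mask_pixel_um)
            cell = _disk_mask((npx, npx), cpx, cpx, cell_radius_um / mask_pixel_um)
            rois.append(CellROI(cell_id=cid, nucleus_mask=nuc, cytoplasm_mask=cell & ~nuc))
    cols_a = ["spot_id", "cell_id", "compartment", "x_um", "y_um"]
    cols_b = cols_a + ["kind"]
    spots_a = pd.DataFrame(a_rows, columns=cols_a)
    spots_b = pd.DataFrame(b_rows, columns=cols_b)
    truth = GroundTruth(seed=seed, entities=pd.DataFrame(
        truth_rows, columns=["spot_id", "cell_id", "compartment", "tagged", "partner_id"]))
    return spots_a, spots_b, rois, truth


def sim_decay(
    half_life_min: float,
    timepoints_min,
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
    *,
    normalize: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate relative-expression decay replicates.

    Values follow ``exp(-ln2 * t / half_life)`` times mean-one lognormal
    noise with coefficient of variation ``noise_cv``; when ``normalize``
    the table is rescaled so the earliest-timepoint mean is exactly 1.
    Returns a long table (timepoint_min, replicate, value).
    """
    if half_life_min <= 0:
        raise ValueError("half_life_min must be > 0")
    timepoints = np.asarray(list(timepoints_min), dtype=float)
    if timepoints.size == 0:
        raise ValueError("timepoints_min must be non-empty")
    if np.any(timepoints < 0):
        raise ValueError("timepoints must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    rows = []
    for t in timepoints:
        true = math.exp(-math.log(2.0) * t / half_life_min)
        for rep in range(n_replicates):
            noise = math.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
            rows.append({"timepoint_min": t, "replicate": rep, "value": true * noise})
    curve = pd.DataFrame(rows)
    if normalize:
        t0 = curve["timepoint_min"].min()
        curve["value"] /= curve.loc[curve["timepoint_min"] == t0, "value"].mean()
    truth = GroundTruth(seed=seed, entities=pd.DataFrame(
        [{"half_life_min": half_life_min, "noise_cv": noise_cv}]))
    return curve, truth


def sim_decay_qpcr(
    half_life_min: float,
    timepoints_min,
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
    *,
    group: str = "WT",
    ct_control: float = 12.0,
    baseline_dct: float = 8.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a qPCR Ct table whose ddCt expression decays exponentially.

    ``ct_target - ct_control`` equals ``baseline_dct - log2(expression)``
    so the ddCt transform of the table reproduces the underlying decay.
    """
    curve, truth = sim_decay(
        half_life_min, timepoints_min, n_replicates, noise_cv, seed, normalize=False
    )
    rows = []
    for row in curve.itertuples(index=False):
        dct = baseline_dct - math.log2(row.value)
        rows.append(
            {
                "sample_group": group,
                "timepoint_min": row.timepoint_min,
                "replicate_id": int(row.replicate),
                "ct_target": ct_control + dct,
                "ct_control": ct_control,
            }
        )
    return pd.DataFrame(rows), truth
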