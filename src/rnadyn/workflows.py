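"""Reference end-to-end recovery workflows on synthetic data.

Each workflow generates data with the synthetic generators at the study
conditions (sample sizes, frame intervals, noise levels and ground-truth
parameters of the imaging experiments the pipeline was built for), runs
the full analysis chain, and reports the recovered quantity next to the
ground truth.  They serve both as executable documentation and as the
basis of the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bursting import fit_dwell_exponential, segment_states, track_site_intensity
from .decay import fit_halflife, relative_expression
from .detection import detect_candidates
from .diffusion import compute_msd, fit_diffusion
from .simulate import (
    MotionParams,
    TelegraphParams,
    render_movie,
    sim_decay_qpcr,
    sim_smfish_cells,
    sim_telegraph_traces,
    sim_trajectories,
)
from .smfish import colocalize

__all__ = [
    "halflife_recovery",
    "dwell_time_recovery",
    "diffusion_recovery",
    "colocalization_recovery",
    "active_cell_recovery",
]

DRB_TIMEPOINTS_MIN = (15.0, 30.0, 60.0, 90.0, 120.0, 150.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def halflife_recovery(
    seed: int,
    half_life_min: float = 25.0,
    *,
    timepoints_min=DRB_TIMEPOINTS_MIN,
    n_experiments: int = 3,
    n_replicates: int = 3,
    noise_cv: float = 0.10,
) -> dict:
    """mRNA half-life recovered from synthetic qPCR decay experiments.

    Simulates transcription-blocked decay sampled at the standard DRB
    timepoints in triplicate, converts Ct tables to relative expression
    by ddCt, fits a single exponential per experiment, and reports the
    mean recovered half-life across experiments.
    """
    halves = []
    for s in _child_seeds(seed, n_experiments):
        records, _ = sim_decay_qpcr(
            half_life_min, timepoints_min, n_replicates=n_replicates,
            noise_cv=noise_cv, seed=s,
        )
        curves = relative_expression(records)
        halves.append(fit_halflife(curves["WT"]).half_life_min)
    return {
        "true_half_life_min": half_life_min,
        "half_life_min": float(np.mean(halves)),
        "per_experiment": halves,
        "n": n_experiments * n_replicates * len(tuple(timepoints_min)),
    }


def dwell_time_recovery(
    seed: int,
    mean_on_min: float = 8.2,
    mean_off_min: float = 7.0,
    *,
    n_sites: int = 100,
    duration_min: float = 160.0,
) -> dict:
    """ON/OFF time constants recovered from a telegraph simulation.

    Simulates transcription-site traces at 90-s frames with detectable
    burst contrast, segments them with the 1.5x-background threshold and
    1.5-min minimum ON duration, and fits single exponentials to the
    survival histograms of the uncensored dwell durations.
    """
    params = TelegraphParams(
        mean_on_min=mean_on_min, mean_off_min=mean_off_min, duration_min=duration_min
    )
    traces, _ = sim_telegraph_traces(params, n_sites=n_sites, seed=seed)
    on_d, off_d = [], []
    for trace in traces:
        dwells = segment_states(trace).dwells
        ok = dwells[~dwells["censored"]]
        on_d.extend(ok.loc[ok["state"] == "ON", "duration_min"])
        off_d.extend(ok.loc[ok["state"] == "OFF", "duration_min"])
    fit_on = fit_dwell_exponential(on_d)
    fit_off = fit_dwell_exponential(off_d)
    return {
        "true_tau_on_min": mean_on_min,
        "true_tau_off_min": mean_off_min,
        "tau_on_min": fit_on.tau_min,
        "tau_off_min": fit_off.tau_min,
        "n_on_events": fit_on.fit.n_events,
        "n_off_events": fit_off.fit.n_events,
    }


def diffusion_recovery(
    seed: int,
    D_um2_s: float,
    n_cells: int,
    *,
    n_trajectories_per_cell: int = 30,
    n_frames: int = 30,
    dt_s: float = 0.03,
    loc_noise_sigma_um: float = 0.03,
) -> dict:
    """Ensemble diffusion coefficient recovered from Brownian tracks.

    Per cell, simulates 2D Brownian trajectories with localization
    noise, computes the time-averaged MSD per trajectory, fits D at lags
    2-4 dt weighted by the per-lag errors, averages per cell and then
    across cells (cells are the replication unit).
    """
    params = MotionParams(
        "diffusive", D_um2_s=D_um2_s, loc_noise_sigma_um=loc_noise_sigma_um,
        n_frames=n_frames, dt_s=dt_s,
    )
    cell_means = []
    for s in _child_seeds(seed, n_cells):
        trajs, _ = sim_trajectories(params, n_per_class=n_trajectories_per_cell, seed=s)
        ds = [fit_diffusion(compute_msd(t, 7)).D_um2_s for t in trajs]
        cell_means.append(float(np.mean(ds)))
    cell_means = np.asarray(cell_means)
    return {
        "true_D_um2_s": D_um2_s,
        "D_um2_s": float(cell_means.mean()),
        "sem_D_um2_s": float(cell_means.std(ddof=1) / np.sqrt(n_cells)),
        "n_cells": n_cells,
        "n_trajectories": n_cells * n_trajectories_per_cell,
    }


def colocalization_recovery(
    seed: int,
    tagging_fraction: float = 0.75,
    *,
    n_cells: int = 100,
    partner_offset_sigma_um: float = 0.05,
    distractor_density_per_um2: float = 0.05,
    radius_um: float = 0.3,
    compartment: str = "nucleus",
) -> dict:
    """Colocalized fraction recovered from two-channel smFISH fields.

    Generates cells whose channel-A spots carry a channel-B partner with
    probability ``tagging_fraction`` (plus random distractors), matches
    the channels per cell by one-to-one nearest neighbours at the
    diffraction-limit radius, and pools the matched fraction.
    """
    spots_a, spots_b, _, _ = sim_smfish_cells(
        n_cells=n_cells,
        tagging_fraction=tagging_fraction,
        partner_offset_sigma_um=partner_offset_sigma_um,
        distractor_density_per_um2=distractor_density_per_um2,
        seed=seed,
        make_masks=False,
    )
    matched = total = 0
    for cid, grp in spots_a.groupby("cell_id"):
        a = grp[grp["compartment"] == compartment]
        b = spots_b[(spots_b["cell_id"] == cid) & (spots_b["compartment"] == compartment)]
        if len(a) == 0:
            continue
        if len(b) == 0:
            total += len(a)
            continue
        res = colocalize(a, b, radius_um)
        matched += len(res.pairs)
        total += res.n_a
    fraction = matched / total if total else float("nan")
    return {
        "true_fraction": tagging_fraction,
        "fraction_colocalized": fraction,
        "percent_colocalized": 100.0 * fraction,
        "n_spots": total,
        "n_cells": n_cells,
    }


def _simulate_cell_movie(
    active: bool,
    seed: int,
    *,
    shape: tuple[int, int],
    n_frames: int,
    photons_per_transcript: float,
    background: float,
    params: TelegraphParams,
):
    rng = np.random.default_rng(seed)
    rows = []
    if active:
        n_sites = int(rng.integers(1, 5))
        traces_truth_seed = int(rng.integers(2**31 - 1))
        _, truth = sim_telegraph_traces(params, n_sites=n_sites, seed=traces_truth_seed)
        margin = 16
        pos = rng.uniform(margin, min(shape) - margin, size=(n_sites, 2))
        counts = truth.entities
        for sid in range(n_sites):
            sub = counts[(counts["site_id"] == sid) & (counts["frame"] < n_frames)]
            for row in sub.itertuples(index=False):
                if row.nascent_count > 0:
                    rows.append(
                        {
                            "frame": int(row.frame),
                            "x_px": pos[sid, 0],
                            "y_px": pos[sid, 1],
                            "amplitude": photons_per_transcript * row.nascent_count,
                        }
                    )
    movie, _ = render_movie(
        pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "amplitude"]),
        shape=shape,
        n_frames=n_frames,
        background=background,
        read_noise_sd=2.0,
        seed=int(rng.integers(2**31 - 1)),
        frame_interval_s=params.frame_interval_s,
    )
    return movie


def active_cell_recovery(
    seed: int,
    p_active: float = 0.88,
    *,
    n_cells: int = 60,
    shape: tuple[int, int] = (128, 128),
    n_frames: int = 50,
    photons_per_transcript: float = 320.0,
    background: float = 200.0,
    corr_threshold: float = 0.5,
    max_alleles: int = 4,
) -> dict:
    """Active-cell fraction recovered from rendered live-cell movies.

    Each simulated cell is transcriptionally active with probability
    ``p_active``; an active cell carries 1-4 telegraph transcription
    sites rendered as diffraction-limited spots over a noisy nuclear
    background at 90-s frames.  The full detection chain runs per cell:
    candidate sites are found on the time-mean projection, tracked
    through the movie, and segmented; a cell counts as active when any
    tracked site is ever ON.
    """
    params = TelegraphParams()
    seeds = _child_seeds(seed, 2 * n_cells)
    mask = np.ones(shape, dtype=bool)
    true_active = 0
    detected_active = 0
    for i in range(n_cells):
        is_active = (np.random.default_rng(seeds[i]).random() < p_active)
        true_active += int(is_active)
        movie = _simulate_cell_movie(
            is_active,
            seeds[n_cells + i],
            shape=shape,
            n_frames=n_frames,
            photons_per_transcript=photons_per_transcript,
            background=background,
            params=params,
        )
        mean_projection = movie.pixels[:, 0].mean(axis=0)
        cands = detect_candidates(mean_projection, 1.5, corr_threshold)
        if not cands:
            continue
        site_seeds = [(c[1], c[0]) for c in cands[:max_alleles]]
        traces = track_site_intensity(movie, site_seeds, mask)
        if any(segment_states(t).ever_on for t in traces):
            detected_active += 1
    return {
        "true_fraction": true_active / n_cells,
        "p_active": p_active,
        "active_cell_fraction": detected_active / n_cells,
        "n_cells": n_cells,
    }
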