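import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rnadyn import (
    AnalysisConfig,
    DiffusionModel,
    MotionParams,
    Trajectory,
    classify_motion,
    compute_msd,
    fit_diffusion,
    sim_trajectories,
    summarize_ensemble,
)


def _traj(x, y, dt=0.03, interp=None):
    n = len(x)
    return Trajectory(
        traj_id=0,
        frames=np.arange(n),
        x_um=np.asarray(x, float),
        y_um=np.asarray(y, float),
        interpolated=np.zeros(n, bool) if interp is None else np.asarray(interp, bool),
        dt_s=dt,
        pixel_size_um=0.0433,
    )


def brute_force_msd(positions, lag):
    """Independent oracle: explicit double loop over ordered pairs."""
    vals = []
    for i in range(len(positions) - lag):
        d = positions[i + lag] - positions[i]
        vals.append(float(d @ d))
    return float(np.mean(vals))


class TestComputeMsd:
    def test_stationary_track_has_zero_msd(self):
        t = _traj([1.0] * 10, [2.0] * 10)
        prof = compute_msd(t)
        np.testing.assert_allclose(prof.msd_um2, 0.0)

    def test_collinear_track_hand_values(self):
        # points (0,0),(1,0),(2,0),(3,0): MSD(n) = n^2
        t = _traj([0, 1, 2, 3], [0, 0, 0, 0])
        prof = compute_msd(t)
        np.testing.assert_allclose(prof.msd_um2, [1.0, 4.0, 9.0], rtol=1e-14)
        np.testing.assert_array_equal(prof.n_pairs, [3, 2, 1])

    def test_matches_brute_force_oracle_on_random_tracks(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            t = _traj(rng.normal(0, 1, n), rng.normal(0, 1, n))
            prof = compute_msd(t)
            for k, lag_s in enumerate(prof.lags_s):
                lag = int(round(lag_s / t.dt_s))
                assert prof.msd_um2[k] == pytest.approx(
                    brute_force_msd(t.positions, lag), abs=1e-12
                )

    def test_interpolated_points_excluded_from_pairs(self):
        t = _traj([0, 100, 2, 3], [0, 0, 0, 0], interp=[False, True, False, False])
        prof = compute_msd(t)
        # lag-1 pairs touching the interpolated point are dropped
        assert prof.msd_um2[0] == pytest.approx(1.0)
        assert prof.n_pairs[0] == 1

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=2, max_value=30), st.integers(min_value=0, max_value=2**31 - 1))
    def test_msd_nonnegative_and_pairs_decreasing(self, n, seed):
        r = np.random.default_rng(seed)
        prof = compute_msd(_traj(r.normal(0, 1, n), r.normal(0, 1, n)))
        assert np.all(prof.msd_um2 >= 0)
        assert np.all(np.diff(prof.n_pairs) <= 0)


class TestFitDiffusion:
    def test_exact_line_recovers_d_and_zero_intercept(self):
        dt = 0.03
        lags = np.arange(1, 8) * dt
        msd = 4 * 0.05 * lags
        prof = type("P", (), {})()
        from rnadyn.diffusion import MSDProfile

        prof = MSDProfile(lags_s=lags, msd_um2=msd, se_um2=np.zeros(7),
                          n_pairs=np.arange(7, 0, -1), dt_s=dt)
        est = fit_diffusion(prof, (2, 3, 4))
        assert est.D_um2_s == pytest.approx(0.05, abs=1e-12)
        assert est.intercept_um2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_goes_to_intercept(self):
        from rnadyn.diffusion import MSDProfile

        dt = 0.03
        lags = np.arange(1, 8) * dt
        prof = MSDProfile(lags_s=lags, msd_um2=4 * 0.05 * lags + 0.004,
                          se_um2=np.zeros(7), n_pairs=np.arange(7, 0, -1), dt_s=dt)
        est = fit_diffusion(prof, (2, 3, 4))
        assert est.D_um2_s == pytest.approx(0.05, abs=1e-12)
        assert est.intercept_um2 == pytest.approx(0.004, abs=1e-12)

    def test_too_few_lags_rejected(self):
        from rnadyn.diffusion import MSDProfile

        prof = MSDProfile(lags_s=np.array([0.03]), msd_um2=np.array([0.01]),
                          se_um2=np.array([0.0]), n_pairs=np.array([5]), dt_s=0.03)
        with pytest.raises(ValueError):
            fit_diffusion(prof, (2, 3, 4))

    def test_ensemble_recovery_is_unbiased(self, rng):
        D = 0.05
        p = MotionParams("diffusive", D_um2_s=D, loc_noise_sigma_um=0.0,
                         n_frames=100, dt_s=0.03)
        trajs, _ = sim_trajectories(p, n_per_class=500, seed=31)
        ds = [fit_diffusion(compute_msd(t, 7)).D_um2_s for t in trajs]
        assert np.mean(ds) == pytest.approx(D, rel=0.10)

    def test_estimator_spread_shrinks_with_sample_size(self):
        p = MotionParams("diffusive", D_um2_s=0.05, loc_noise_sigma_um=0.0,
                         n_frames=30, dt_s=0.03)
        means = {}
        for n in (100, 1000):
            trajs, _ = sim_trajectories(p, n_per_class=n, seed=32)
            ds = np.array([fit_diffusion(compute_msd(t, 7)).D_um2_s for t in trajs])
            means[n] = ds.mean() if False else ds.std() / np.sqrt(n)
        assert means[1000] < means[100]

    def test_intercept_matches_localization_noise(self):
        # static localization error sigma adds ~4 sigma^2 to every MSD lag
        sigma = 0.03
        p = MotionParams("diffusive", D_um2_s=0.05, loc_noise_sigma_um=sigma,
                         n_frames=100, dt_s=0.03)
        trajs, _ = sim_trajectories(p, n_per_class=300, seed=33)
        intercepts = [fit_diffusion(compute_msd(t, 7)).intercept_um2 for t in trajs]
        assert np.mean(intercepts) == pytest.approx(4 * sigma**2, rel=0.15)


# archetype parameter sets: each class well inside its decision region
# (confinement crossover ~2 frames so the 5-7 dt window sees the plateau;
# free D large enough that the MSD clears the stationary threshold)
def _archetypes(noise_um, n_frames=1000):
    return [
        MotionParams("stationary", loc_noise_sigma_um=noise_um, n_frames=n_frames),
        MotionParams("corralled", D_um2_s=0.2, confinement_radius_um=0.2,
                     loc_noise_sigma_um=noise_um, n_frames=n_frames),
        MotionParams("diffusive", D_um2_s=0.2, loc_noise_sigma_um=noise_um,
                     n_frames=n_frames),
        MotionParams("directed", D_um2_s=0.01, velocity_um_s=3.0,
                     loc_noise_sigma_um=noise_um, n_frames=n_frames),
    ]


ARCHETYPES_CLEAN = _archetypes(0.0)
ARCHETYPES_NOISY = _archetypes(0.03)


class TestClassifyMotion:
    def _label(self, traj):
        prof = compute_msd(traj, 7)
        est = fit_diffusion(prof, (2, 3, 4))
        return classify_motion(traj, prof, est, AnalysisConfig())

    def test_noise_free_archetypes_all_correct(self):
        trajs, truth = sim_trajectories(ARCHETYPES_CLEAN, n_per_class=10, seed=41)
        labels = [self._label(t).state for t in trajs]
        assert labels == list(truth.entities["motion_class"])

    def test_stationary_rule_fires_on_pure_noise(self):
        p = MotionParams("stationary", loc_noise_sigma_um=0.02, n_frames=50)
        trajs, _ = sim_trajectories(p, n_per_class=5, seed=42)
        for t in trajs:
            lab = self._label(t)
            assert lab.state == "stationary"
            assert "stationary" in lab.trace["rule"]

    def test_directed_rule_needs_net_displacement(self):
        # straight run of 2 um total
        n = 21
        t = _traj(np.linspace(0, 2.0, n), np.zeros(n))
        lab = self._label(t)
        assert lab.state == "directed"
        assert lab.trace["net_displacement_um"] == pytest.approx(2.0)

    def test_confined_track_plateaus_to_corralled(self):
        # confinement with a ~2-frame crossover: MSD rises over the fit
        # window and plateaus by lags 5-7, so the late slope drops below
        # the fitted D
        p = MotionParams("corralled", D_um2_s=0.2, confinement_radius_um=0.2,
                         loc_noise_sigma_um=0.0, n_frames=1000)
        trajs, _ = sim_trajectories(p, n_per_class=10, seed=43)
        labels = [self._label(t) for t in trajs]
        assert [l.state for l in labels].count("corralled") == 10
        assert all(
            l.trace["late_slope_D_um2_s"] < l.trace["fit_D_um2_s"] for l in labels
        )

    def test_tight_confinement_below_threshold_is_stationary(self):
        # an R = 0.15 um corral plateaus at R^2 = 0.0225 um^2, under the
        # 0.025 stationary threshold, so the stationary rule fires first
        p = MotionParams("corralled", D_um2_s=0.05, confinement_radius_um=0.15,
                         loc_noise_sigma_um=0.0, n_frames=200)
        trajs, _ = sim_trajectories(p, n_per_class=10, seed=46)
        labels = [self._label(t).state for t in trajs]
        assert all(l in ("stationary", "corralled") for l in labels)
        assert labels.count("stationary") >= 5

    def test_noisy_archetypes_mostly_correct(self):
        trajs, truth = sim_trajectories(ARCHETYPES_NOISY, n_per_class=25, seed=44)
        pred = np.array([self._label(t).state for t in trajs])
        true = truth.entities["motion_class"].to_numpy()
        assert np.mean(pred == true) >= 0.8


class TestEnsemble:
    def test_single_state_fraction_is_one(self):
        rec = pd.DataFrame(
            {"cell_id": [1, 1, 2], "compartment": ["nucleus"] * 3,
             "state": ["diffusive"] * 3, "D_um2_s": [0.04, 0.05, 0.06]}
        )
        out = summarize_ensemble(rec)
        frac = out["state_fractions"]
        assert frac.loc[frac["state"] == "diffusive", "fraction"].iloc[0] == 1.0
        assert frac.groupby("compartment")["fraction"].sum().iloc[0] == pytest.approx(1.0)

    def test_compartment_mean_is_mean_of_cell_means(self):
        rec = pd.DataFrame(
            {"cell_id": [1, 1, 2], "compartment": ["cytoplasm"] * 3,
             "state": ["diffusive"] * 3, "D_um2_s": [0.03, 0.05, 0.06]}
        )
        out = summarize_ensemble(rec)["compartment_summary"]
        assert out["mean_D_um2_s"].iloc[0] == pytest.approx((0.04 + 0.06) / 2)

    def test_mixture_fractions_recovered(self):
        archetypes = [
            MotionParams("stationary", loc_noise_sigma_um=0.02, n_frames=60),
            MotionParams("diffusive", D_um2_s=0.3, loc_noise_sigma_um=0.02, n_frames=60),
        ]
        trajs, _ = sim_trajectories(archetypes, n_per_class=40, seed=45)
        for i, t in enumerate(trajs):
            t.cell_id = i % 5
            t.compartment = "nucleus"
        res = DiffusionModel(trajs).fit()
        frac = res.ensemble["state_fractions"]
        stat = float(frac.loc[frac["state"] == "stationary", "fraction"].iloc[0])
        assert stat == pytest.approx(0.5, abs=0.10)

    def test_summary_text_mentions_compartments(self, brownian_trajectories):
        trajs, _ = brownian_trajectories
        for t in trajs:
            t.compartment = "nucleus"
            t.cell_id = t.traj_id % 4
        res = DiffusionModel(trajs).fit()
        text = res.summary()
        assert "nucleus" in text and "um^2/s" in text
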