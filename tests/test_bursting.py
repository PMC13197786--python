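import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rnadyn import (
    IntensityTrace,
    TelegraphParams,
    activity_metrics,
    compare_ks,
    count_nascent,
    extract_dwells,
    fit_dwell_exponential,
    render_movie,
    segment_states,
    sim_telegraph_traces,
    track_site_intensity,
)


def _trace(values, background=100.0, dt_s=90.0):
    values = np.asarray(values, float)
    return IntensityTrace(
        site_id=0, cell_id=0,
        frames=np.arange(len(values)),
        raw_intensity=values,
        local_background=np.full(len(values), background),
        frame_interval_s=dt_s,
    )


class TestSegmentStates:
    def test_background_trace_is_all_off_censored(self):
        seq = segment_states(_trace([100.0] * 10))
        assert set(seq.states) == {"OFF"}
        assert len(seq.dwells) == 1
        assert bool(seq.dwells["censored"].iloc[0])

    def test_three_frame_burst_is_one_uncensored_on_dwell(self):
        vals = [100] * 3 + [200] * 3 + [100] * 3
        seq = segment_states(_trace(vals))
        on = seq.dwells[seq.dwells["state"] == "ON"]
        assert len(on) == 1
        assert on["duration_min"].iloc[0] == pytest.approx(4.5)
        assert not bool(on["censored"].iloc[0])

    def test_single_frame_above_threshold_is_minimal_on_dwell(self):
        # one frame at 1.6x background meets the 1.5-min minimum at 90-s frames
        vals = [100] * 4 + [160] + [100] * 4
        seq = segment_states(_trace(vals), use_smoothed=False)
        on = seq.dwells[seq.dwells["state"] == "ON"]
        assert len(on) == 1
        assert on["duration_min"].iloc[0] == pytest.approx(1.5)

    def test_smoothing_erases_single_frame_spike(self):
        # the window-3 rolling mean of an isolated 1.6x spike stays below 1.5x
        vals = [100] * 4 + [160] + [100] * 4
        seq = segment_states(_trace(vals), use_smoothed=True)
        assert set(seq.states) == {"OFF"}

    def test_short_on_runs_demoted_by_minimum_duration(self):
        vals = [100, 200, 100, 200, 200, 100]
        seq = segment_states(_trace(vals), min_on_duration_min=3.0, use_smoothed=False)
        on = seq.dwells[seq.dwells["state"] == "ON"]
        assert len(on) == 1  # only the 2-frame (3 min) run survives
        assert on["n_frames"].iloc[0] == 2

    def test_scale_invariance(self):
        vals = np.array([100, 100, 250, 260, 240, 100, 100], float)
        a = segment_states(_trace(vals))
        b = segment_states(_trace(vals * 7.5, background=750.0))
        np.testing.assert_array_equal(a.states, b.states)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=3, max_value=60), st.integers(min_value=0, max_value=2**31 - 1))
    def test_dwells_partition_the_trace(self, n, seed):
        r = np.random.default_rng(seed)
        vals = r.uniform(50, 300, n)
        seq = segment_states(_trace(vals))
        assert int(seq.dwells["n_frames"].sum()) == n
        total_min = seq.dwells["duration_min"].sum()
        assert total_min == pytest.approx(n * 1.5)
        # durations are integer multiples of the frame interval
        assert np.allclose(seq.dwells["duration_min"] % 1.5, 0.0)


class TestExtractDwells:
    def test_censoring_flags_at_boundaries(self):
        states = np.array(["OFF", "ON", "ON", "OFF", "ON"])
        d = extract_dwells(states, 90.0)
        assert list(d["censored"]) == [True, False, False, True]
        assert list(d["n_frames"]) == [1, 2, 1, 1]


class TestDwellFit:
    def test_exact_exponential_grid_recovers_tau(self):
        # construct durations whose survival is exactly 100*exp(-t/8)
        taus = 8.0
        ts = np.arange(1.5, 30.0, 1.5)
        surv = np.round(100 * np.exp(-ts / taus)).astype(int)
        durations = []
        for t, s_now, s_next in zip(ts, surv, list(surv[1:]) + [0]):
            durations += [t] * (s_now - s_next)
        res = fit_dwell_exponential(durations)
        assert res.tau_min == pytest.approx(8.0, abs=0.05)

    def test_monte_carlo_recovery_with_frame_discretization(self, rng):
        # memorylessness: discretizing exponential dwells to the frame grid
        # shifts the survival curve but leaves its slope (tau) unchanged
        true_tau, dt = 8.0, 1.5
        raw = rng.exponential(true_tau, size=2500)
        frames = np.round(raw / dt)
        discretized = frames[frames >= 1] * dt  # sub-frame dwells are unobserved
        assert len(discretized) >= 2000
        res = fit_dwell_exponential(discretized)
        assert res.tau_min == pytest.approx(true_tau, rel=0.05)

    def test_too_few_events_refused(self):
        with pytest.raises(ValueError, match="too few"):
            fit_dwell_exponential([3.0] * 9)

    def test_degenerate_identical_durations_flagged(self):
        res = fit_dwell_exponential([4.5] * 50)
        assert res.fit.poor_fit

    def test_censored_dwells_excluded_by_default(self):
        durations = [3.0] * 20 + [100.0] * 15
        censored = [False] * 20 + [True] * 15
        res = fit_dwell_exponential(durations, censored)
        assert res.fit.n_events == 20

    def test_summary_reports_tau(self, rng):
        res = fit_dwell_exponential(rng.exponential(8.0, 200))
        assert "tau" in res.summary()


class TestCompareKs:
    def test_identical_samples_statistic_zero(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_ks(a, list(a))
        assert res.statistic == 0.0

    def test_disjoint_supports_statistic_one(self):
        res = compare_ks([1, 2, 3], [10, 20, 30])
        assert res.statistic == 1.0

    def test_matches_brute_force_ecdf_sweep(self, rng):
        def brute_ks(a, b):
            pts = np.concatenate([a, b])
            return max(
                abs(np.mean(a <= x) - np.mean(b <= x)) for x in pts
            )

        for _ in range(20):
            a = rng.exponential(5.0, size=int(rng.integers(5, 30)))
            b = rng.exponential(7.0, size=int(rng.integers(5, 30)))
            res = compare_ks(a, b)
            assert res.statistic == pytest.approx(brute_ks(a, b), abs=1e-12)

    def test_null_rarely_rejects(self, rng):
        # same-distribution samples: p > 0.05 in >= 90% of runs
        hits = 0
        n_runs = 40
        for _ in range(n_runs):
            a = rng.exponential(8.0, 800)
            b = rng.exponential(8.0, 800)
            if compare_ks(a, b).p_value > 0.05:
                hits += 1
        assert hits / n_runs >= 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_ks([], [1.0])


class TestActivityMetrics:
    def _seq(self, states, cell_id, dish_id=0, site_id=0):
        from rnadyn import StateSequence

        states = np.asarray(states, dtype="<U3")
        return StateSequence(
            site_id=site_id, cell_id=cell_id, states=states,
            dwells=extract_dwells(states, 90.0),
            frame_interval_s=90.0, dish_id=dish_id,
        )

    def test_all_cells_active_gives_fraction_one(self):
        seqs = [self._seq(["OFF", "ON", "OFF"], cell_id=c) for c in range(5)]
        out = activity_metrics(seqs)
        assert out["active_cell_fraction"] == 1.0

    def test_per_cell_site_fraction(self):
        seqs = [
            self._seq(["ON"], cell_id=1, site_id=0),
            self._seq(["ON"], cell_id=1, site_id=1),
            self._seq(["OFF"], cell_id=1, site_id=2),
        ]
        out = activity_metrics(seqs, max_alleles=4, n_frames=1)
        assert out["active_site_fraction"]["fraction"].iloc[0] == pytest.approx(0.5)

    def test_onset_time_of_first_on_frame(self):
        states = ["OFF"] * 10 + ["ON", "ON"]
        seq = self._seq(states, cell_id=1)
        assert seq.onset_time_min() == pytest.approx(15.0)

    def test_per_dish_averaging(self):
        seqs = [
            self._seq(["ON", "OFF"], cell_id=1, dish_id=0),
            self._seq(["OFF", "OFF"], cell_id=2, dish_id=0),
            self._seq(["ON", "OFF"], cell_id=3, dish_id=1),
        ]
        out = activity_metrics(seqs)
        # dish 0: 1/2 active; dish 1: 1/1 -> mean of dish means = 0.75
        assert out["active_cell_fraction"] == pytest.approx(0.75)


class TestCountNascent:
    def test_unit_reference_counts(self):
        counts = count_nascent([0.0, 500.0, 1000.0], 500.0)
        np.testing.assert_allclose(counts, [0.0, 1.0, 2.0])

    def test_negative_values_clamped(self):
        counts = count_nascent([-50.0], 500.0)
        assert counts[0] == 0.0

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            count_nascent([1.0], 0.0)

    def test_rendered_multimer_counts_against_unit_reference(self):
        # 7 overlapping unit emitters vs an isolated unit emitter
        unit = 800.0
        spots = pd.DataFrame(
            [{"frame": 0, "x_px": 20.0, "y_px": 20.0, "amplitude": 7 * unit},
             {"frame": 0, "x_px": 50.0, "y_px": 50.0, "amplitude": unit}]
        )
        stack, _ = render_movie(spots, shape=(70, 70), background=50.0,
                                read_noise_sd=0.0, poisson_noise=False)
        img = stack.frame(0)

        def disk_sum(cx, cy, r=5):
            yy, xx = np.mgrid[0:70, 0:70]
            m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
            return float((img[m] - 50.0).sum())

        reference = disk_sum(50, 50)
        count = count_nascent([disk_sum(20, 20)], reference)[0]
        assert count == pytest.approx(7.0, abs=0.5)


class TestTelegraphRecovery:
    def test_tau_recovery_through_segmentation_and_fit(self):
        # full inference chain at 90-s sampling with detectable contrast
        params = TelegraphParams(mean_on_min=8.2, mean_off_min=7.0, duration_min=160.0)
        traces, _ = sim_telegraph_traces(params, n_sites=100, seed=13)
        on_d, off_d = [], []
        for tr in traces:
            dwells = segment_states(tr).dwells
            ok = dwells[~dwells["censored"]]
            on_d += list(ok.loc[ok["state"] == "ON", "duration_min"])
            off_d += list(ok.loc[ok["state"] == "OFF", "duration_min"])
        assert len(on_d) >= 800
        assert fit_dwell_exponential(on_d).tau_min == pytest.approx(8.2, rel=0.15)
        assert fit_dwell_exponential(off_d).tau_min == pytest.approx(7.0, rel=0.15)


class TestTrackSiteIntensity:
    def test_constant_site_yields_flat_trace_matching_mass(self):
        amp = 8000.0
        rows = [{"frame": f, "x_px": 30.0, "y_px": 30.0, "amplitude": amp}
                for f in range(5)]
        stack, _ = render_movie(pd.DataFrame(rows), shape=(64, 64), background=100.0,
                                read_noise_sd=0.0, poisson_noise=False,
                                frame_interval_s=90.0)
        mask = np.ones((64, 64), bool)
        traces = track_site_intensity(stack, [(30.0, 30.0)], mask)
        tr = traces[0]
        signal = tr.raw_intensity - tr.local_background
        # pixelated aperture of radius 3 px captures ~86% of a sigma=1.5 Gaussian
        capture = 1.0 - np.exp(-(3.0**2) / (2 * 1.5**2))
        np.testing.assert_allclose(signal, amp * capture, rtol=0.05)
        assert np.ptp(signal) / signal.mean() < 0.02

    def test_empty_movie_trace_is_background_level(self):
        stack, _ = render_movie(pd.DataFrame(columns=["frame", "x_px", "y_px", "amplitude"]),
                                shape=(64, 64), n_frames=4, background=100.0,
                                read_noise_sd=0.0, poisson_noise=False)
        mask = np.ones((64, 64), bool)
        traces = track_site_intensity(stack, [(30.0, 30.0)], mask)
        signal = traces[0].raw_intensity - traces[0].local_background
        np.testing.assert_allclose(signal, 0.0, atol=1e-6)

    def test_drifting_site_followed_within_one_pixel(self):
        rows = [{"frame": f, "x_px": 20.0 + f, "y_px": 20.0, "amplitude": 8000.0}
                for f in range(10)]
        stack, _ = render_movie(pd.DataFrame(rows), shape=(64, 64), background=100.0,
                                read_noise_sd=0.0, poisson_noise=False)
        mask = np.ones((64, 64), bool)
        traces = track_site_intensity(stack, [(20.0, 20.0)], mask)
        xs = traces[0].positions[:, 0]
        np.testing.assert_allclose(xs, 20.0 + np.arange(10), atol=1.0)

    def test_seed_outside_nucleus_rejected(self):
        stack, _ = render_movie(pd.DataFrame(columns=["frame", "x_px", "y_px", "amplitude"]),
                                shape=(32, 32), n_frames=2, background=100.0)
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:20] = True
        with pytest.raises(ValueError):
            track_site_intensity(stack, [(2.0, 2.0)], mask)
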