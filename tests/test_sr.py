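"""SR selection, rise/slope measurement, CP, and ramp-model checks."""

import numpy as np
import pytest
from scipy import stats

from rampfix.behavior import FixationInterval
from rampfix.sta_analysis import CellTrace
from rampfix.sr_analysis import (
    RampModel,
    choice_probability,
    derivative_threshold_from_slopes,
    empirical_opposite_guess_accuracy,
    estimate_kappa,
    evaluate_ramp_model,
    ideal_observer_direction,
    ideal_observer_timing,
    interpolate_fixation_activity,
    measure_rise_time,
    measure_slope,
    ramp_holdout_cc,
    ramp_predict,
    roc_area,
    select_sr_cells,
)
from rampfix.synthetic_data import (
    BehaviorConfig,
    SRCellConfig,
    gen_archetype_cell,
    gen_eye_trace,
    gen_population_rise_traces,
    gen_sr_cell,
)


class TestSelectSRCells:
    def test_synthetic_sr_and_archetypes(self, session, sr_cells):
        tonic = gen_archetype_cell(
            "tonic", "L", session.truth, noise_sd=0.02, seed=41, cell_id="tonic"
        )
        burst = gen_archetype_cell(
            "burst", "R", session.truth, noise_sd=0.02, seed=42, cell_id="burst"
        )
        table = select_sr_cells(sr_cells + [tonic, burst], session.events)
        table = table.set_index("cell_id")
        for i in range(8):
            row = table.loc[f"sr{i}"]
            assert row["sr_flag"]
            assert row["preferred_direction"] == ("L" if i % 2 == 0 else "R")
        assert not table.loc["tonic", "sr_flag"]
        assert not table.loc["burst", "sr_flag"]

    def test_monotone_ramp_gives_rho_one(self, session):
        # fluorescence is a strictly increasing function of time relative
        # to the upcoming saccade, so the rank correlation is exactly 1
        t = np.arange(0.0, session.truth.duration_s, 1.0)
        sacc = np.array([e.onset_time_s for e in session.events])
        next_sacc = sacc[np.minimum(np.searchsorted(sacc, t, side="left"), sacc.size - 1)]
        rel = t - next_sacc  # negative, increasing toward 0
        cell = CellTrace(
            time_s=t, F=rel + 80.0, deconv=np.zeros_like(t), cell_id="m"
        )
        table = select_sr_cells([cell], session.events)
        assert max(table.loc[0, "rho_L"], table.loc[0, "rho_R"]) == pytest.approx(1.0)


class TestRiseAndSlope:
    def test_onset_at_threshold_crossing(self):
        t = np.arange(0.0, 12.0, 0.5)
        deconv = np.clip((t - 4.0) * 0.5, 0.0, None)
        cell = CellTrace(time_s=t, F=deconv + 1.0, deconv=deconv, cell_id="c")
        fx = FixationInterval(0.0, 10.0, "R", "L")
        ev = measure_rise_time(cell, fx, threshold=0.1)
        assert abs(ev.onset_s - 4.0) <= 0.5

    def test_normalized_rise_arithmetic(self):
        t = np.arange(0.0, 12.0, 0.1)
        deconv = np.where(t >= 2.0, 1.0, 0.0)
        cell = CellTrace(time_s=t, F=deconv + 1.0, deconv=deconv, cell_id="c")
        ev = measure_rise_time(cell, FixationInterval(0.0, 10.0, "R", "L"), threshold=0.1)
        assert ev.normalized_rise == pytest.approx(-0.8, abs=0.02)
        assert (
            ev.rise_time_before_saccade_s + ev.rise_time_after_previous_s
            == pytest.approx(10.0)
        )

    def test_no_event_when_subthreshold(self):
        t = np.arange(0.0, 10.0, 0.5)
        cell = CellTrace(time_s=t, F=np.ones_like(t), deconv=np.zeros_like(t), cell_id="c")
        assert measure_rise_time(cell, FixationInterval(0.0, 9.0, "L", "R"), 0.1) is None

    def test_saccade_locked_onsets_have_tighter_pre_saccadic_timing(self, session):
        # rises locked 3 s before each saccade: variance of rise-before
        # is far smaller than variance of rise-after-previous
        truth = session.truth
        forced = {k: 3.0 for k in range(truth.saccade_times_s.size - 1)}
        cfg = SRCellConfig(preferred_direction="L", forced_rise_durations=forced, seed=77)
        cell = gen_sr_cell(cfg, truth, cell_id="locked")
        before, after = [], []
        for fx in session.truth_fixations():
            if fx.following_direction != "L":
                continue
            ev = measure_rise_time(cell, fx, threshold=0.05)
            if ev is None:
                continue
            before.append(ev.rise_time_before_saccade_s)
            after.append(ev.rise_time_after_previous_s)
        assert len(before) > 20
        assert np.var(before) < 0.25 * np.var(after)

    def test_exact_line_slope(self):
        t = np.arange(0.0, 10.0, 0.5)
        cell = CellTrace(time_s=t, F=2 * t + 1.0, deconv=2.0 * t, cell_id="c")
        slope, cc = measure_slope(cell, 0.0, 9.0)
        assert slope == pytest.approx(2.0)
        assert cc == pytest.approx(1.0)

    def test_pure_noise_usually_excluded(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 6.0, 0.5)
        excluded = 0
        n = 200
        for _ in range(n):
            y = np.abs(rng.normal(0, 1, t.size))
            cell = CellTrace(time_s=t, F=y + 10.0, deconv=y, cell_id="c")
            _, cc = measure_slope(cell, 0.0, 5.5)
            excluded += cc <= 0.4
        assert excluded / n >= 0.4

    def test_too_few_samples_returns_none(self):
        t = np.arange(0.0, 10.0, 1.0)
        cell = CellTrace(time_s=t, F=t + 1.0, deconv=t, cell_id="c")
        assert measure_slope(cell, 4.2, 5.1) is None

    def test_slope_recovery_and_anticorrelation_with_duration(self, session):
        """Fixed-threshold generator: slopes recover kappa/rise and are
        negatively rank-correlated with rise duration."""
        truth = session.truth
        cell = gen_sr_cell(SRCellConfig(preferred_direction="L", seed=55), truth, "rec")
        slopes, durations = [], []
        for fx in session.truth_fixations():
            if fx.following_direction != "L":
                continue
            ev = measure_rise_time(cell, fx, threshold=0.05)
            if ev is None:
                continue
            res = measure_slope(cell, ev.onset_s, fx.end_s)
            if res is None or res[1] <= 0.4:
                continue
            slopes.append(res[0])
            durations.append(ev.rise_time_before_saccade_s)
        slopes, durations = np.array(slopes), np.array(durations)
        ratio = slopes * durations
        assert np.median(ratio) == pytest.approx(1.0, abs=0.05)
        rho, p = stats.spearmanr(slopes, durations)
        assert rho < 0 and p < 0.01


class TestChoiceProbability:
    def test_roc_identical_distributions(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert roc_area(x, x.copy()) == pytest.approx(0.5)

    def test_roc_fully_separated(self):
        assert roc_area(np.array([5.0, 6.0]), np.array([1.0, 2.0])) == 1.0

    def test_roc_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            s = rng.integers(0, 5, rng.integers(3, 10)).astype(float)
            n = rng.integers(0, 5, rng.integers(3, 10)).astype(float)
            brute = np.mean(
                [(si > ni) + 0.5 * (si == ni) for si in s for ni in n]
            )
            assert roc_area(s, n) == pytest.approx(brute)

    def test_cp_invariant_to_monotone_transform(self, session, sr_cells):
        from dataclasses import replace

        def activities(transform):
            out = {}
            for i, c in enumerate(sr_cells[:4]):
                acts = [
                    replace(a, values=transform(a.values))
                    for a in (
                        interpolate_fixation_activity(c, f) for f in session.fixations
                    )
                ]
                out[c.cell_id] = ("L" if i % 2 == 0 else "R", acts)
            return out

        cp_raw = choice_probability(activities(lambda x: x))
        cp_exp = choice_probability(activities(np.expm1))
        np.testing.assert_allclose(cp_raw.cp, cp_exp.cp, atol=1e-12)

    def test_cp_rises_toward_saccade_on_sr_population(self, session, sr_cells):
        act = {}
        for i, c in enumerate(sr_cells):
            act[c.cell_id] = (
                "L" if i % 2 == 0 else "R",
                [interpolate_fixation_activity(c, f) for f in session.fixations],
            )
        curve = choice_probability(act)
        assert curve.cp[0] > 0.9            # just before the saccade
        assert curve.cp[0] > curve.cp[-1]   # grows toward the saccade
        assert np.all((curve.cp >= 0) & (curve.cp <= 1))


class TestRampModel:
    def test_exact_linear_ramp_zero_error(self):
        dt = 1.0 / 3.0
        t = dt * np.arange(31)
        y = 2.0 * t  # reaches kappa = 20 at the last sample
        model = RampModel(kappa=20.0, derivative_threshold=1.0)
        rp = ramp_predict(y, model)
        np.testing.assert_allclose(rp.predicted_remaining_s, rp.actual_remaining_s, atol=1e-9)

    def test_constant_derivative_prediction(self):
        dt = 1.0 / 3.0
        y = 2.0 * dt * np.arange(16)
        model = RampModel(kappa=10.0, derivative_threshold=1.0)
        rp = ramp_predict(y, model)
        np.testing.assert_allclose(
            rp.predicted_remaining_s + rp.t_since_onset_s, 5.0, atol=1e-9
        )

    def test_no_prediction_below_threshold(self):
        y = 0.01 * np.arange(20)
        assert ramp_predict(y, RampModel(kappa=1.0, derivative_threshold=5.0)) is None

    def test_low_noise_populations_track_actual_times(self):
        durations = np.arange(3.5, 21.0, 1.0)
        all_slopes, pops = [], {}
        for i, d in enumerate(durations):
            traces, slopes = gen_population_rise_traces(d, 200, seed=100 + i)
            all_slopes.append(slopes)
            pops[d] = traces.mean(axis=0)
        thr = derivative_threshold_from_slopes(np.concatenate(all_slopes))
        model = RampModel(kappa=1.0, derivative_threshold=thr)
        preds, acts = [], []
        for d in durations:
            rp = ramp_predict(pops[d], model)
            preds.append(rp.predicted_remaining_s)
            acts.append(rp.actual_remaining_s)
        cc, err = evaluate_ramp_model(np.concatenate(preds), np.concatenate(acts))
        assert cc > 0.9

    def test_holdout_fit_quality(self):
        # population averages of staggered-onset ramps are convex rather
        # than exactly linear, so the linear model correlates strongly
        # but not perfectly with held-out activity
        traces, _ = gen_population_rise_traces(8.0, 100, seed=3)
        cc = ramp_holdout_cc(traces, kappa=1.0, n_splits=50, seed=4)
        assert cc > 0.75

    def test_kappa_estimate_converges(self, session):
        # finely sampled, noise-free SR cell: mean activity at saccade
        # approaches the generator threshold
        cfg = SRCellConfig(preferred_direction="L", ca_sample_rate_hz=5.0, seed=66)
        cell = gen_sr_cell(cfg, session.truth, cell_id="fine")
        vals = []
        for fx in session.truth_fixations():
            if fx.following_direction != "L":
                continue
            ev = measure_rise_time(cell, fx, threshold=0.05)
            if ev is not None:
                vals.append(ev.deconv_at_saccade)
        assert estimate_kappa(np.array(vals)) == pytest.approx(1.0, abs=0.05)


class TestEvaluate:
    def test_identity(self):
        a = np.linspace(1.0, 10.0, 20)
        cc, err = evaluate_ramp_model(a, a)
        assert cc == pytest.approx(1.0)
        assert err == 0.0

    def test_permutation_destroys_correlation(self):
        rng = np.random.default_rng(7)
        a = np.linspace(1.0, 10.0, 200)
        ccs = [
            evaluate_ramp_model(rng.permutation(a), a)[0] for _ in range(50)
        ]
        assert abs(np.mean(ccs)) < 0.05

    def test_constant_predictions_flagged(self):
        a = np.linspace(1.0, 5.0, 10)
        with pytest.warns(UserWarning, match="zero-variance"):
            cc, _ = evaluate_ramp_model(np.full(10, 3.0), a)
        assert cc == 0.0


class TestIdealObservers:
    def test_direction_analytic(self):
        assert ideal_observer_direction(0.23) == pytest.approx(0.77)
        assert ideal_observer_direction(0.5) == pytest.approx(0.5)

    def test_direction_empirical_matches_binomial(self):
        cfg = BehaviorConfig(duration_s=10_000.0, seed=21)
        _, truth = gen_eye_trace(cfg)
        acc = empirical_opposite_guess_accuracy(truth.directions)
        n = truth.directions.size - 1
        assert abs(acc - 0.77) < 3 * np.sqrt(0.23 * 0.77 / n)

    def test_degenerate_distribution_exact_under_all_costs(self):
        durs = np.full(50, 10.0)
        for cost in ("MSE", "MAD", "all_or_none"):
            assert ideal_observer_timing(durs, 4.0, cost=cost) == pytest.approx(6.0)

    def test_mse_conditional_mean(self):
        assert ideal_observer_timing(np.array([8.0, 12.0]), 0.0, "MSE") == pytest.approx(10.0)

    def test_exponential_memorylessness(self):
        rng = np.random.default_rng(8)
        durs = rng.exponential(10.0, 200_000)
        guesses = [ideal_observer_timing(durs, e, "MSE") for e in (0.0, 5.0, 10.0)]
        assert np.ptp(guesses) / np.mean(guesses) < 0.05

    def test_no_remaining_durations_rejected(self):
        with pytest.raises(ValueError):
            ideal_observer_timing(np.array([3.0, 4.0]), 10.0)
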