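"""Encoding models: EV arithmetic, prevalence fits, covariates, gates."""

import numpy as np
import pandas as pd
import pytest

from seqprev import encoding, parsing
from seqprev.encoding import (
    cross_validated_ev,
    explained_variance,
    fit_context_mixed_model,
    fit_paired_regression,
    fit_prevalence_model,
    history_matched_subset,
    movement_vigor,
    trajectory_pc1,
)
from seqprev.synthetic import _manual_trials, make_fixture


class TestExplainedVariance:
    def test_hand_arithmetic_fixture(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        yhat = [1.1, 1.9, 3.2, 3.9, 5.1]
        # SSE = 0.01+0.01+0.04+0.01+0.01 = 0.08; SStot about mean 3 = 10
        assert abs(explained_variance(y, yhat) - (1 - 0.08 / 10)) < 1e-12

    def test_perfect_fit(self, rng):
        y = rng.random(20)
        assert explained_variance(y, y) == 1.0

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            explained_variance(np.ones(5), np.ones(5))

    def test_mean_predictor_clamps_to_zero(self, rng):
        y = rng.standard_normal(100)
        X = np.ones((100, 1))  # intercept-only model predicts training mean
        assert cross_validated_ev(y, X, seed=0) == 0.0

    def test_cv_ev_never_exceeds_one(self, rng):
        y = rng.standard_normal(60)
        X = rng.standard_normal((60, 3))
        cv, folds = cross_validated_ev(y, X, seed=1, return_folds=True)
        assert cv <= 1.0 and np.all(folds <= 1.0)

    def test_cv_ev_matches_analytic_snr(self, rng):
        beta, sigma = 1.0, 0.6
        x = rng.normal(0, 1.0, 400)
        y = beta * x + rng.normal(0, sigma, 400)
        expected = beta**2 / (beta**2 + sigma**2)
        assert abs(cross_validated_ev(y, x, seed=0) - expected) < 0.1


class TestPrevalenceModel:
    def test_zero_slope_gives_zero_ev(self, rng):
        prev = rng.uniform(0, 0.5, 200)
        activity = rng.normal(2.0, 0.5, (200, 5))
        fits = fit_prevalence_model(activity, prev, seed=0)
        assert fits["ALL"].best_ev < 0.08

    def test_slope_recovery_per_context(self, rng):
        ctx = np.array(["DOM"] * 150 + ["EXP"] * 100)
        prev = np.where(
            ctx == "DOM", rng.normal(0.33, 0.08, 250), rng.normal(0.1, 0.05, 250)
        )
        slopes = {"DOM": 2.0, "EXP": -1.0}
        activity = np.stack(
            [
                np.array([slopes[c] for c in ctx]) * prev
                + rng.normal(0, 0.1, 250)
                for _ in range(5)
            ],
            axis=1,
        )
        fits = fit_prevalence_model(activity, prev, ctx, seed=0)
        # slope SE ~ 0.1 at this n / noise level; allow 4 SE
        for c, b in slopes.items():
            assert np.allclose(fits[c].slope_per_window, b, atol=0.4)
            signal = b**2 * prev[ctx == c].var()
            analytic = signal / (signal + 0.1**2)
            assert abs(fits[c].best_ev - analytic) < 0.15

    def test_constant_prevalence_rejected(self, rng):
        activity = rng.random((40, 5))
        with pytest.raises(ValueError, match="constant"):
            fit_prevalence_model(activity, np.full(40, 0.3), seed=0)


class TestContextMixedModel:
    @staticmethod
    def simulate(rng, intercept_gap=0.0, slope_gap=0.0, n=200, noise=0.3):
        ctx = np.array(["DOM"] * (n // 2) + ["EXP"] * (n // 2))
        prev = np.where(
            ctx == "DOM", rng.normal(0.33, 0.1, n), rng.normal(0.12, 0.06, n)
        )
        slope = 1.0 + np.where(ctx == "EXP", slope_gap, 0.0)
        y = slope * prev + np.where(ctx == "EXP", intercept_gap, 0.0)
        return y + rng.normal(0, noise, n), prev, ctx

    def test_context_intercept_improves_fit(self, rng):
        wins = 0
        for s in range(20):
            r = np.random.default_rng(1000 + s)
            y, prev, ctx = self.simulate(r, intercept_gap=0.8)
            out = fit_context_mixed_model(y, prev, ctx, seed=s)
            wins += out["context_intercept"] > out["prevalence_only"]
        assert wins >= 18

    def test_context_slope_improves_fit(self, rng):
        wins = 0
        for s in range(20):
            r = np.random.default_rng(2000 + s)
            y, prev, ctx = self.simulate(r, slope_gap=3.0, noise=0.15)
            out = fit_context_mixed_model(y, prev, ctx, seed=s)
            wins += out["context_slope"] >= out["prevalence_only"]
        assert wins >= 18

    def test_null_ties_variants(self):
        diffs = []
        for s in range(20):
            r = np.random.default_rng(3000 + s)
            y, prev, ctx = self.simulate(r)
            out = fit_context_mixed_model(y, prev, ctx, seed=s)
            diffs.append(out["context_intercept"] - out["prevalence_only"])
        m = np.mean(diffs)
        ci = 2.1 * np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert m - ci <= 0 <= m + ci or abs(m) < 0.02

    def test_single_context_rejected(self, rng):
        with pytest.raises(ValueError, match="2 contexts"):
            fit_context_mixed_model(
                rng.random(20), rng.random(20), ["DOM"] * 20
            )


class TestMovementCovariates:
    def test_vigor_from_known_timestamps(self):
        trials = _manual_trials([("LLR" * 2, 0, "LLR")])
        trials.loc[0, "t_center_in"] = 0.0
        trials.loc[2, "t_side_in"] = 2.4
        (inst, *_) = parsing.find_pattern_matches(trials["choice"].tolist(), "LLR")

        class I:
            trial_indices = (0, 1, 2)

        assert movement_vigor(I(), trials) == pytest.approx(2.4)

    def test_vigor_positive_on_parsed_instances(self, sim_session):
        bundle, _ = sim_session
        for inst in parsing.parse_session(bundle.trials)[:50]:
            assert movement_vigor(inst, bundle.trials) > 0

    def test_long_break_instances_filtered_upstream(self):
        bundle = make_fixture("golden_parsing_3")
        for inst in parsing.parse_session(bundle.trials):
            assert inst.center_to_side_max <= 3.0


class TestTrajectoryPC1:
    @staticmethod
    def xy_table(trials, offsets):
        """50 Hz XY samples; x offset per trial index from ``offsets``."""
        span = trials["t_side_out"].iloc[-1] + 1
        t = np.arange(0, span, 0.02)
        trial_of_t = np.searchsorted(trials["t_center_in"].to_numpy(), t) - 1
        trial_of_t = np.clip(trial_of_t, 0, len(trials) - 1)
        x = np.array([offsets.get(i, 0.0) for i in trial_of_t])
        return pd.DataFrame({"time": t, "x": x, "y": np.zeros_like(t)})

    def test_identical_trajectories_give_zero_scores(self):
        trials = _manual_trials([("LLR" * 10, 0, "LLR")])
        instances = parsing.select_dominant_instances(trials, "LLR")
        xy = self.xy_table(trials, {})
        scores = trajectory_pc1(xy, instances, trials)
        assert np.allclose(scores, 0)

    def test_two_clusters_separate_up_to_sign(self):
        trials = _manual_trials([("LLR" * 20, 0, "LLR")])
        instances = parsing.select_dominant_instances(trials, "LLR")
        offsets = {
            t: (1.0 if (inst_i % 2 == 0) else -1.0)
            for inst_i, inst in enumerate(instances)
            for t in inst.trial_indices
        }
        xy = self.xy_table(trials, offsets)
        scores = trajectory_pc1(xy, instances, trials)
        even, odd = scores[::2], scores[1::2]
        assert np.sign(even).std() == 0 and np.sign(odd).std() == 0
        assert np.sign(even[0]) != np.sign(odd[0])

    def test_scores_centered_with_variance_on_varying_paths(self, rng):
        trials = _manual_trials([("LLR" * 15, 0, "LLR")])
        instances = parsing.select_dominant_instances(trials, "LLR")
        offsets = {t: rng.normal() for t in range(len(trials))}
        xy = self.xy_table(trials, offsets)
        scores = trajectory_pc1(xy, instances, trials)
        assert abs(scores.mean()) < 1e-9
        assert scores.var() > 0


class TestPairedRegression:
    def test_recovers_dominant_predictor(self, rng):
        prev = rng.normal(0, 1, 300)
        other = rng.normal(0, 1, 300)
        activity = np.stack(
            [1.0 * prev + 0.0 * other + rng.normal(0, 0.4, 300) for _ in range(5)],
            axis=1,
        )
        res = fit_paired_regression(activity, prev, other, other_name="vigor")
        assert abs(res.weights["prevalence"]) > 5 * abs(res.weights["vigor"])
        expected = np.corrcoef(activity[:, res.window], prev)[0, 1]
        assert abs(abs(res.weights["prevalence"]) - abs(expected)) < 0.1

    def test_symmetric_generation_gives_equal_weights(self, rng):
        prev = rng.normal(0, 1, 500)
        other = rng.normal(0, 1, 500)
        activity = (prev + other + rng.normal(0, 0.3, 500))[:, None]
        res = fit_paired_regression(activity, prev, other)
        assert abs(res.weights["prevalence"] - res.weights["other"]) < 0.1

    def test_collinear_pair_gated(self, rng):
        prev = rng.normal(0, 1, 100)
        with pytest.raises(ValueError):
            fit_paired_regression(rng.random((100, 5)), prev, prev.copy())

    def test_decorated_but_correlated_pair_outside_band(self, rng):
        prev = rng.normal(0, 1, 2000)
        other = 0.95 * prev + np.sqrt(1 - 0.95**2) * rng.normal(0, 1, 2000)
        with pytest.raises(ValueError, match="outside admissible band"):
            fit_paired_regression(rng.random((2000, 5)), prev, other)


class TestHistoryMatchedSubset:
    def test_pure_concatenation_drops_first_of_run(self):
        bundle = make_fixture("golden_parsing_1")
        dom = parsing.select_dominant_instances(bundle.trials, "RRL")
        subset = history_matched_subset(dom, bundle.trials)
        assert [i.start for i in subset] == [3, 6, 9, 12, 15, 18, 21, 24, 27, 30]

    def test_isolated_instances_excluded(self):
        bundle = make_fixture("two_context")
        exp = parsing.select_exploratory_instances(bundle.trials, "RRL", "LLR")
        assert history_matched_subset(exp, bundle.trials) == []
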