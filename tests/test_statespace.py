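"""State-space construction, distance statistics, and context separation."""

import numpy as np
import pandas as pd
import pytest

from seqprev import parsing, statespace
from seqprev.statespace import (
    InstanceActivityTensor,
    WindowSpec,
    bin_instance_activity,
    build_state_space,
    context_centroid_distance,
    context_modulation_fraction,
    pairwise_distance_matrix,
    shuffle_null,
    transition_score,
)
from seqprev.synthetic import _manual_trials


def make_tensor(values, labels):
    """Tensor straight from a values array (tests of the statistics only)."""
    values = np.asarray(values, dtype=float)
    n, u, w = values.shape
    meta = pd.DataFrame({"context": labels})
    return InstanceActivityTensor(
        values=values,
        unit_ids=tuple(range(u)),
        instances=tuple(range(n)),
        meta=meta,
        spec=WindowSpec(),
    )


def gaussian_state(rng, n, d, labels=None, offset=0.0, noise=1.0):
    X = rng.normal(0, noise, (n, d))
    if labels is not None and offset:
        X[np.asarray(labels) == "B"] += offset
    return statespace.EnsembleState(
        matrix=X, registry=tuple((i // 5, i % 5) for i in range(d))
    )


class TestBinning:
    def test_counts_and_sqrt(self):
        trials = _manual_trials([("LLR" * 4, 0, "LLR")])
        (inst, *_) = parsing.select_dominant_instances(trials, "LLR")
        # 4 spikes inside the step-1 side window, none elsewhere
        anchor = trials["t_side_in"].iat[inst.trial_indices[0]]
        spikes = {0: np.array([anchor - 0.2, anchor - 0.1, anchor, anchor + 0.2]),
                  1: np.array([])}
        tensor = bin_instance_activity(spikes, [inst], trials)
        assert tensor.values[0, 0, 0] == 2.0  # sqrt(4)
        assert np.all(tensor.values[0, 1, :] == 0.0)  # silent unit

    def test_variance_stabilization(self, rng):
        trials = _manual_trials([("LLR" * 400, 0, "LLR")])
        span = trials["t_side_out"].iloc[-1] + 1
        rate = 10.0  # ~5 expected counts per 500 ms window
        spikes = {0: np.sort(rng.uniform(0, span, rng.poisson(rate * span)))}
        instances = parsing.select_dominant_instances(trials, "LLR")
        tensor = bin_instance_activity(spikes, instances, trials)
        v = np.var(tensor.values[:, 0, :].ravel(), ddof=1)
        assert 0.2 <= v <= 0.35  # asymptote 0.25 for sqrt Poisson counts

    def test_missing_timestamp_drops_instance(self):
        trials = _manual_trials([("LLR" * 4, 0, "LLR")])
        instances = parsing.select_dominant_instances(trials, "LLR")
        trials.loc[instances[1].trial_indices[2], "t_side_in"] = np.nan
        with pytest.warns(UserWarning, match="dropped 1 instance"):
            tensor = bin_instance_activity({0: np.array([1.0])}, instances, trials)
        assert tensor.n_instances == len(instances) - 1


class TestStateSpace:
    def test_shape_and_registry_roundtrip(self, rng):
        tensor = make_tensor(rng.random((7, 3, 5)), ["DOMINANT"] * 7)
        state = build_state_space(tensor)
        assert state.matrix.shape == (7, 15)
        for col, (uid, w) in enumerate(state.registry):
            assert state.column_of(uid, w) == col
            assert np.allclose(state.matrix[:, col], tensor.values[:, uid, w])

    def test_unit_permutation_preserves_distances(self, rng):
        values = rng.random((10, 4, 5))
        t1 = make_tensor(values, ["DOMINANT"] * 10)
        t2 = make_tensor(values[:, ::-1, :], ["DOMINANT"] * 10)
        d1 = pairwise_distance_matrix(build_state_space(t1))
        d2 = pairwise_distance_matrix(build_state_space(t2))
        assert np.allclose(d1, d2)


class TestDistances:
    def test_identical_rows_zero(self):
        state = statespace.EnsembleState(
            matrix=np.ones((3, 10)), registry=tuple((0, i) for i in range(10))
        )
        assert np.allclose(pairwise_distance_matrix(state), 0)

    def test_unit_normalized_distance(self):
        # one unit, window vectors all-zero vs all-one: distance sqrt(5)/sqrt(5)
        state = statespace.EnsembleState(
            matrix=np.array([[0.0] * 5, [1.0] * 5]),
            registry=tuple((0, i) for i in range(5)),
        )
        d = pairwise_distance_matrix(state)
        assert abs(d[0, 1] - 1.0) < 1e-12

    def test_metric_properties(self, rng):
        state = gaussian_state(rng, 30, 20)
        d = pairwise_distance_matrix(state)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        for _ in range(100):
            i, j, k = rng.integers(0, 30, 3)
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestCentroidDistance:
    def test_random_labels_give_small_distance(self, rng):
        labels = np.array(["A", "B"] * 500)
        state = gaussian_state(rng, 1000, 50)
        assert context_centroid_distance(state, labels) < 0.1

    def test_pure_offset_recovered(self):
        X = np.zeros((8, 10))
        labels = np.array(["A"] * 4 + ["B"] * 4)
        X[4:] += 0.7
        X += np.array([0.01, -0.01, 0.02, -0.02] * 2)[:, None]  # break ties
        state = statespace.EnsembleState(
            matrix=X, registry=tuple((0, i) for i in range(10))
        )
        assert abs(context_centroid_distance(state, labels) - 0.7) < 1e-12

    def test_median_centroid_robust_to_outlier(self, rng):
        X = rng.normal(0, 0.1, (11, 6))
        labels = np.array(["A"] * 5 + ["B"] * 6)
        state = statespace.EnsembleState(
            matrix=X.copy(), registry=tuple((0, i) for i in range(6))
        )
        base = context_centroid_distance(state, labels)
        X2 = X.copy()
        X2[0] += 100.0  # extreme outlier in an odd-sized cloud
        state2 = statespace.EnsembleState(matrix=X2, registry=state.registry)
        median_shift = abs(context_centroid_distance(state2, labels) - base)
        mean_shift = abs(
            np.linalg.norm(X2[:5].mean(0) - X2[5:].mean(0)) / np.sqrt(6)
            - np.linalg.norm(X[:5].mean(0) - X[5:].mean(0)) / np.sqrt(6)
        )
        assert median_shift < 1.0 < mean_shift

    def test_insufficient_label_rejected(self, rng):
        state = gaussian_state(rng, 5, 4)
        with pytest.raises(ValueError, match="at least 2"):
            context_centroid_distance(state, ["A", "A", "A", "A", "B"])


class TestShuffleNull:
    def test_fixed_seed_reproducible(self, rng):
        labels = np.array(["A"] * 10 + ["B"] * 10)
        state = gaussian_state(rng, 20, 15)
        n1, o1, p1 = shuffle_null(state, labels, 200, seed=5)
        n2, o2, p2 = shuffle_null(state, labels, 200, seed=5)
        assert np.array_equal(n1, n2) and o1 == o2 and p1 == p2

    def test_context_offset_exceeds_null(self, rng):
        labels = np.array(["A"] * 50 + ["B"] * 50)
        state = gaussian_state(rng, 100, 100, labels, offset=1.0, noise=0.3)
        null, observed, pct = shuffle_null(state, labels, 1000, seed=1)
        assert observed > null.max()
        assert pct == 1.0

    def test_minimum_shuffles_enforced(self, rng):
        state = gaussian_state(rng, 10, 5)
        with pytest.raises(ValueError):
            shuffle_null(state, ["A"] * 5 + ["B"] * 5, 10)


class TestTransitionScore:
    def test_identical_clouds_zero(self, rng):
        rows = rng.random((4, 5))
        values = np.vstack([rows, rows])
        labels = ["A"] * 4 + ["B"] * 4
        assert transition_score(values, labels).score == 0.0

    def test_closed_form_offset_clouds(self):
        v = 0.04
        base = np.array([-1.0, -1 / 3, 1 / 3, 1.0])
        base = base / np.std(base, ddof=1) * np.sqrt(v)
        cloud = np.tile(base[:, None], (1, 5))
        delta = 0.5
        values = np.vstack([cloud, cloud + delta])
        labels = ["A"] * 4 + ["B"] * 4
        score = transition_score(values, labels).score
        assert abs(score - np.sqrt(5) * delta / np.sqrt(v)) < 1e-9

    def test_translation_invariance(self, rng):
        values = rng.random((12, 5))
        labels = ["A"] * 6 + ["B"] * 6
        s1 = transition_score(values, labels).score
        s2 = transition_score(values + 42.0, labels).score
        assert abs(s1 - s2) < 1e-12

    def test_zero_variance_rejected(self):
        values = np.vstack([np.zeros((3, 5)), np.ones((3, 5))])
        with pytest.raises(ValueError, match="zero within-cloud"):
            transition_score(values, ["A"] * 3 + ["B"] * 3)


class TestContextModulation:
    def test_saturation_with_large_offset(self, rng):
        a = rng.normal(0, 0.1, (30, 10, 5))
        b = rng.normal(5, 0.1, (30, 10, 5))
        tensor = make_tensor(np.vstack([a, b]), ["A"] * 30 + ["B"] * 30)
        per_w, any_w, _ = context_modulation_fraction(tensor)
        assert np.all(per_w == 1.0) and any_w == 1.0

    def test_null_rate_near_alpha(self, rng):
        tensor = make_tensor(
            rng.normal(0, 1, (60, 40, 5)), ["A"] * 30 + ["B"] * 30
        )
        per_w, any_w, _ = context_modulation_fraction(tensor, alpha=0.05)
        # binomial(40, 0.05) per window: mean 2 significant units
        assert per_w.mean() < 0.18
        # any-window rate should sit near 1 - 0.95^5 ~ 0.23
        assert any_w < 0.5


class TestSeparationStructure:
    def test_within_context_tighter_than_between(self, rng):
        labels = np.array(["A"] * 40 + ["B"] * 40)
        state = gaussian_state(rng, 80, 50, labels, offset=0.6, noise=0.4)
        d = pairwise_distance_matrix(state)
        same = (labels[:, None] == labels[None, :]) & ~np.eye(80, dtype=bool)
        within = d[same].mean()
        between = d[labels[:, None] != labels[None, :]].mean()
        assert within < between

    def test_no_offset_gives_equal_distances(self, rng):
        labels = np.array(["A"] * 40 + ["B"] * 40)
        state = gaussian_state(rng, 80, 50, labels, offset=0.0, noise=0.4)
        d = pairwise_distance_matrix(state)
        same = (labels[:, None] == labels[None, :]) & ~np.eye(80, dtype=bool)
        within = d[same].mean()
        between = d[labels[:, None] != labels[None, :]].mean()
        assert abs(within - between) < 0.02

    def test_separated_dominant_epochs_cluster_together(self):
        """Dominant instances from two temporally separated epochs of the
        same sequence sit closer to each other than to exploratory ones."""
        from seqprev.synthetic import AgentConfig, NeuronConfig, TimingParams, simulate_session

        bundle, _ = simulate_session(
            AgentConfig(n_trials=1200, block_length_range=(250, 300), seed=31),
            TimingParams(seed=32),
            NeuronConfig(n_units=15, seed=33),
        )
        instances = [
            i
            for i in parsing.parse_session(bundle.trials)
            if i.seq == "RRL"
            and i.context in (parsing.DOMINANT, parsing.EXPLORATORY)
        ]
        tensor = bin_instance_activity(bundle.spikes, instances, bundle.trials)
        labels = tensor.labels()
        blocks = np.array(
            [bundle.trials["block_id"].iat[i.trial_indices[0]]
             for i in tensor.instances]
        )
        dom_blocks = np.unique(blocks[labels == parsing.DOMINANT])
        assert len(dom_blocks) >= 2, "expected two dominant RRL epochs"
        assert (labels == parsing.EXPLORATORY).sum() >= 2
        state = build_state_space(tensor)
        d = pairwise_distance_matrix(state)
        first = (labels == parsing.DOMINANT) & (blocks == dom_blocks[0])
        second = (labels == parsing.DOMINANT) & (blocks == dom_blocks[1])
        exp = labels == parsing.EXPLORATORY
        dom_dom = d[np.ix_(first, second)].mean()
        dom_exp = d[np.ix_(first | second, exp)].mean()
        assert dom_dom < dom_exp
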