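"""Peri-event spike-count state spaces and context-separation statistics.

Each instance of sequence execution is represented, per neuron, by the square
root of spike counts in five 500 ms windows centered on port-entry events
(side entry of step 1; center and side entries of steps 2 and 3 — the window
before the first center entry is excluded to avoid feedback from preceding
choices).  The square root approximately variance-stabilizes Poisson counts
so fast-spiking units do not drown out sparse ones.  The ensemble state space
stacks the five dimensions of every simultaneously recorded unit (5N
dimensions); Euclidean distances are divided by the square root of the
dimension count so sessions with different ensemble sizes live on a
comparable scale.

Cluster centroids are per-dimension medians.  The context separation of the
ensemble is the distance between the dominant and exploratory centroids,
judged against a label-shuffle null; the per-unit "transition score" is the
centroid distance in the unit's own five-dimensional space normalized by the
root mean within-cloud variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ranksums

__all__ = [
    "WindowSpec",
    "InstanceActivityTensor",
    "EnsembleState",
    "TransitionScore",
    "DEFAULT_ANCHORS",
    "bin_instance_activity",
    "build_state_space",
    "pairwise_distance_matrix",
    "context_centroid_distance",
    "shuffle_null",
    "transition_score",
    "context_modulation_fraction",
]

#: (step, event) anchors for a 3-step sequence; steps are 1-based
DEFAULT_ANCHORS = (
    (1, "side_in"),
    (2, "center_in"),
    (2, "side_in"),
    (3, "center_in"),
    (3, "side_in"),
)


@dataclass(frozen=True)
class WindowSpec:
    """Analysis windows: ``width`` seconds centered on each anchor event."""

    anchors: tuple = DEFAULT_ANCHORS
    width: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")
        if not self.anchors:
            raise ValueError("at least one anchor is required")

    @property
    def n_windows(self) -> int:
        return len(self.anchors)


@dataclass
class InstanceActivityTensor:
    """sqrt spike counts, instances x units x windows, plus instance metadata."""

    values: np.ndarray
    unit_ids: tuple
    instances: tuple
    meta: pd.DataFrame
    spec: WindowSpec

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def unit_slice(self, unit_id) -> np.ndarray:
        """(instances x windows) slice for one unit."""
        return self.values[:, self.unit_ids.index(unit_id), :]

    def counts(self) -> np.ndarray:
        """Raw spike counts (squares of the stored values)."""
        return self.values**2

    def labels(self) -> np.ndarray:
        return self.meta["context"].to_numpy()


@dataclass
class EnsembleState:
    """Instances x (windows * units) matrix with a column registry."""

    matrix: np.ndarray
    registry: tuple = field(repr=False)  # column -> (unit_id, window)

    def column_of(self, unit_id, window: int) -> int:
        return self.registry.index((unit_id, window))


def _anchor_times(trials: pd.DataFrame, indices, spec: WindowSpec) -> np.ndarray:
    cols = {"center_in": "t_center_in", "side_in": "t_side_in",
            "center_out": "t_center_out", "side_out": "t_side_out"}
    times = np.empty(spec.n_windows)
    for w, (step, event) in enumerate(spec.anchors):
        trial = indices[step - 1]
        times[w] = trials[cols[event]].iat[trial]
    return times


def bin_instance_activity(
    spikes: dict,
    instances,
    trials: pd.DataFrame,
    spec: WindowSpec | None = None,
    extra_meta: dict | None = None,
) -> InstanceActivityTensor:
    """Square-root spike counts in the analysis windows of each instance.

    ``spikes`` maps unit id to a sorted array of spike times.  Windows are
    ``[anchor - width/2, anchor + width/2)`` and are counted independently
    (overlap between adjacent windows is permitted).  Instances with a
    missing (NaN) anchor timestamp are dropped with a recorded reason.
    """
    spec = spec or WindowSpec()
    unit_ids = tuple(sorted(spikes))
    if not unit_ids:
        raise ValueError("at least one unit is required")
    kept, anchor_rows, dropped = [], [], []
    for inst in instances:
        t = _anchor_times(trials, inst.trial_indices, spec)
        if not np.all(np.isfinite(t)):
            dropped.append((inst, "missing anchor timestamp"))
            continue
        kept.append(inst)
        anchor_rows.append(t)
    if dropped:
        import warnings

        warnings.warn(
            f"dropped {len(dropped)} instance(s) with missing anchor timestamps"
        )
    anchors = np.asarray(anchor_rows).reshape(len(kept), spec.n_windows)
    lo = anchors - spec.width / 2.0
    hi = anchors + spec.width / 2.0
    values = np.empty((len(kept), len(unit_ids), spec.n_windows))
    for u, uid in enumerate(unit_ids):
        st = np.sort(np.asarray(spikes[uid], dtype=float))
        counts = np.searchsorted(st, hi, side="left") - np.searchsorted(
            st, lo, side="left"
        )
        values[:, u, :] = np.sqrt(counts)
    meta = pd.DataFrame(
        {
            "seq": [i.seq for i in kept],
            "start": [i.trial_indices[0] for i in kept],
            "context": [i.context for i in kept],
            "step3_side_dwell": [i.step3_side_dwell for i in kept],
            "rewarded_final": [i.rewarded_final for i in kept],
        }
    )
    for k, v in (extra_meta or {}).items():
        meta[k] = v
    return InstanceActivityTensor(
        values=values,
        unit_ids=unit_ids,
        instances=tuple(kept),
        meta=meta,
        spec=spec,
    )


def build_state_space(tensor: InstanceActivityTensor) -> EnsembleState:
    """Flatten the tensor to instances x (n_windows * n_units).

    Column ``u * n_windows + w`` holds window ``w`` of unit ``u``; the
    registry records the mapping for inverse lookup.
    """
    if tensor.n_units == 0:
        raise ValueError("state space requires at least one unit")
    n, u, w = tensor.values.shape
    matrix = tensor.values.reshape(n, u * w)
    registry = tuple(
        (uid, win) for uid in tensor.unit_ids for win in range(w)
    )
    return EnsembleState(matrix=matrix, registry=registry)


def pairwise_distance_matrix(state: EnsembleState) -> np.ndarray:
    """Per-dimension RMS Euclidean distance between all instance pairs.

    Distances are divided by sqrt(dimension count), placing sessions with
    different ensemble sizes on a comparable scale.
    """
    d = state.matrix.shape[1]
    return squareform(pdist(state.matrix, metric="euclidean")) / np.sqrt(d)


def _centroid(rows: np.ndarray) -> np.ndarray:
    return np.median(rows, axis=0)


def context_centroid_distance(state: EnsembleState, labels) -> float:
    """Normalized Euclidean distance between per-dimension-median centroids.

    Requires exactly two label values, each with at least two instances.
    """
    labels = np.asarray(labels)
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 label values, got {list(names)}")
    groups = [state.matrix[labels == name] for name in names]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each label needs at least 2 instances")
    delta = _centroid(groups[0]) - _centroid(groups[1])
    return float(np.linalg.norm(delta) / np.sqrt(state.matrix.shape[1]))


def shuffle_null(
    state: EnsembleState,
    labels,
    n_shuffles: int = 1000,
    seed: int = 0,
):
    """Label-shuffle null for the context centroid distance.

    Permutations preserve the label counts.  Returns ``(null, observed,
    percentile)`` where ``percentile`` is the fraction of null values the
    observed distance exceeds.
    """
    if n_shuffles < 100:
        raise ValueError("use at least 100 shuffles")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = context_centroid_distance(state, labels)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = context_centroid_distance(state, rng.permutation(labels))
    percentile = float(np.mean(null < observed))
    return null, observed, percentile


@dataclass(frozen=True)
class TransitionScore:
    unit_id: object
    score: float


def transition_score(unit_values: np.ndarray, labels, unit_id=None) -> TransitionScore:
    """Per-unit separation of the two context clouds.

    ``unit_values`` is instances x windows for one unit.  The score is the
    Euclidean distance between the per-dimension-median centroids divided by
    the root mean within-cloud variance:
    ``||c_A - c_B|| / sqrt((mean_w var_A + mean_w var_B) / 2)``.
    """
    labels = np.asarray(labels)
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 label values, got {list(names)}")
    groups = [unit_values[labels == name] for name in names]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each cloud needs at least 2 instances")
    dist = np.linalg.norm(_centroid(groups[0]) - _centroid(groups[1]))
    mean_vars = [np.mean(np.var(g, axis=0, ddof=1)) for g in groups]
    denom = np.sqrt(sum(mean_vars) / 2.0)
    if denom == 0:
        raise ValueError("zero within-cloud variance in both clouds")
    return TransitionScore(unit_id=unit_id, score=float(dist / denom))


def context_modulation_fraction(
    tensor: InstanceActivityTensor,
    labels=None,
    alpha: float = 0.05,
):
    """Fraction of units with significant context modulation per window.

    Applies a Wilcoxon rank-sum test per unit per window between the two
    contexts at level ``alpha`` (no multiple-comparison correction; the
    fractions are reported per window, plus the any-window fraction).
    Returns ``(per_window_fraction, any_window_fraction, flags)`` where
    ``flags`` is units x windows boolean.
    """
    labels = tensor.labels() if labels is None else np.asarray(labels)
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 label values, got {list(names)}")
    a = tensor.values[labels == names[0]]
    b = tensor.values[labels == names[1]]
    n_units, n_win = tensor.values.shape[1:]
    flags = np.zeros((n_units, n_win), dtype=bool)
    for u in range(n_units):
        for w in range(n_win):
            x, y = a[:, u, w], b[:, u, w]
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            flags[u, w] = ranksums(x, y).pvalue < alpha
    per_window = flags.mean(axis=0)
    any_window = float(flags.any(axis=1).mean())
    return per_window, any_window, flags
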