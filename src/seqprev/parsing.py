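"""Parsing a continuous choice stream into labeled sequence instances.

A sequence instance is a set of consecutive trials whose choices spell a
target pattern (e.g. ``RRL``).  Instances are attributed to behavioral
contexts:

- ``DOMINANT``: executed while that sequence locally dominated the animal's
  choices in a block where it was the latent rewarded target,
- ``DOMINANT_TAIL``: executed while dominance persisted past an unsignalled
  change of the latent target,
- ``EXPLORATORY``: executed while a *different* sequence was dominant,
  admitted either because it did not overlap a dominant-sequence match or
  because it was "rescued" by concatenation or by dwell-time marking of the
  final step,
- ``OFF_TARGET_DOMINANT``: dominated the choices of a block whose latent
  target was a different sequence,
- ``DISCARDED``: an exploratory candidate rejected by the overlap rule.

Dominance is operationalized as a run of at least three back-to-back
non-overlapping concatenated instances.  Once established in a target-matched
block, dominance persists to the end of that block; past the block boundary
the epoch keeps a "tail" for as long as the concatenation continues, ending
when more than two consecutive trials are incompatible with it (a trial is
incompatible when the choices since the last completed instance are not a
prefix of the sequence repeated).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DOMINANT",
    "DOMINANT_TAIL",
    "EXPLORATORY",
    "OFF_TARGET_DOMINANT",
    "DISCARDED",
    "TARGET_MATCHED",
    "BEHAVIOR_ONLY",
    "SequenceInstance",
    "DominanceEpoch",
    "find_pattern_matches",
    "establish_dominance_epochs",
    "select_dominant_instances",
    "select_exploratory_instances",
    "select_off_target_instances",
    "apply_global_filters",
    "session_passes_filter",
    "parse_session",
    "instances_to_frame",
]

DOMINANT = "DOMINANT"
DOMINANT_TAIL = "DOMINANT_TAIL"
EXPLORATORY = "EXPLORATORY"
OFF_TARGET_DOMINANT = "OFF_TARGET_DOMINANT"
DISCARDED = "DISCARDED"

TARGET_MATCHED = "TARGET_MATCHED"
BEHAVIOR_ONLY = "BEHAVIOR_ONLY"

#: timing thresholds (seconds) from the instance-selection procedure
STEP3_DWELL_RESCUE_S = 0.5
STEP3_SIDE_TO_CENTER_RESCUE_S = 1.0
CENTER_TO_SIDE_BREAK_S = 3.0
DOMINANCE_RUN_LENGTH = 3
TAIL_MAX_INCOMPATIBLE = 2


@dataclass(frozen=True)
class SequenceInstance:
    """One execution of a choice sequence over consecutive trials."""

    seq: str
    trial_indices: tuple
    context: str
    step3_side_dwell: float = np.nan
    step3_side_to_center: float = np.nan
    center_to_side_max: float = np.nan
    rewarded_final: bool = False

    @property
    def start(self) -> int:
        return self.trial_indices[0]

    @property
    def end(self) -> int:
        """Half-open end trial."""
        return self.trial_indices[-1] + 1


@dataclass(frozen=True)
class DominanceEpoch:
    """Half-open trial interval during which ``seq`` dominated choices."""

    seq: str
    start_trial: int
    end_trial: int
    basis: str = TARGET_MATCHED

    def __post_init__(self) -> None:
        if self.end_trial <= self.start_trial:
            raise ValueError("epoch must have end_trial > start_trial")

    def contains(self, indices) -> bool:
        return indices[0] >= self.start_trial and indices[-1] < self.end_trial


def _validate_seq(seq: str, min_len: int = 3) -> str:
    seq = str(seq)
    if set(seq) - {"L", "R"} or len(seq) < min_len:
        raise ValueError(
            f"sequence must be over L/R with length >= {min_len}, got {seq!r}"
        )
    return seq


def find_pattern_matches(choices, seq: str):
    """Every start position where the stream spells ``seq`` (overlaps allowed)."""
    seq = _validate_seq(seq)
    arr = list(choices)
    k = len(seq)
    starts = [
        i for i in range(len(arr) - k + 1) if "".join(arr[i : i + k]) == seq
    ]
    return [tuple(range(s, s + k)) for s in starts]


def _is_concat_prefix(window: str, seq: str) -> bool:
    """True if ``window`` is a prefix of ``seq`` repeated indefinitely."""
    reps = (len(window) // len(seq)) + 1
    return (seq * reps).startswith(window)


def _extend_epoch(choices: str, seq: str, start: int) -> int:
    """Walk forward from a qualifying run start; return the half-open epoch end.

    Terminates when ``TAIL_MAX_INCOMPATIBLE + 1`` consecutive trials are
    incompatible with continuing the concatenation; the epoch ends at the
    first trial of that incompatible streak.
    """
    n = len(choices)
    last_comp = start - 1  # last trial of the most recent completed instance
    streak_start = None
    t = start
    while t < n:
        window = choices[last_comp + 1 : t + 1]
        if _is_concat_prefix(window, seq):
            streak_start = None
            if len(window) % len(seq) == 0:
                last_comp = t
        else:
            if streak_start is None:
                streak_start = t
            if t - streak_start + 1 > TAIL_MAX_INCOMPATIBLE:
                return streak_start
        t += 1
    return n if streak_start is None else streak_start


def _run_starts(choices: str, seq: str, lo: int, hi: int):
    """Start positions of runs of >= DOMINANCE_RUN_LENGTH back-to-back
    concatenated instances fully inside ``[lo, hi)``."""
    k = len(seq)
    need = k * DOMINANCE_RUN_LENGTH
    out = []
    for s in range(lo, hi - need + 1):
        if choices[s : s + need] == seq * DOMINANCE_RUN_LENGTH:
            out.append(s)
    return out


def establish_dominance_epochs(
    trials: pd.DataFrame, seq: str, basis: str = TARGET_MATCHED
):
    """Non-overlapping dominance epochs for ``seq``.

    With ``basis=TARGET_MATCHED`` the qualifying run must start in a block
    whose latent target is ``seq``; the epoch then extends past the block
    boundary (the "tail").  With ``basis=BEHAVIOR_ONLY`` the whole session is
    searched regardless of the latent target.
    """
    seq = _validate_seq(seq)
    choices = "".join(trials["choice"].tolist())
    n = len(choices)
    epochs = []
    if basis == TARGET_MATCHED:
        targets = trials["latent_target"].tolist()
        cursor = 0
        for lo, hi in _target_blocks(targets, seq):
            starts = _run_starts(choices, seq, max(lo, cursor), hi)
            if not starts:
                continue
            start = starts[0]
            term = _extend_epoch(choices, seq, start)
            # dominance persists to the block end; a tail exists only if the
            # concatenation was still alive at the boundary
            end = hi if term <= hi else term
            epochs.append(
                DominanceEpoch(seq=seq, start_trial=start, end_trial=end, basis=basis)
            )
            cursor = end
    elif basis == BEHAVIOR_ONLY:
        pos = 0
        while True:
            starts = _run_starts(choices, seq, pos, n)
            if not starts:
                break
            start = starts[0]
            end = _extend_epoch(choices, seq, start)
            epochs.append(
                DominanceEpoch(seq=seq, start_trial=start, end_trial=end, basis=basis)
            )
            pos = end
    else:
        raise ValueError(f"unknown dominance basis: {basis!r}")
    return epochs


def _target_blocks(targets, seq):
    """Half-open (start, end) runs of trials whose latent target equals seq."""
    regions = []
    start = None
    for i, t in enumerate(targets):
        if t == seq and start is None:
            start = i
        elif t != seq and start is not None:
            regions.append((start, i))
            start = None
    if start is not None:
        regions.append((start, len(targets)))
    return regions


def _make_instance(trials: pd.DataFrame, seq: str, indices, context: str):
    i_last = indices[-1]
    dwell = float(
        trials["t_side_out"].iat[i_last] - trials["t_side_in"].iat[i_last]
    )
    if i_last + 1 < len(trials):
        side_to_center = float(
            trials["t_center_in"].iat[i_last + 1] - trials["t_side_out"].iat[i_last]
        )
    else:
        side_to_center = np.nan
    c2s = float(
        max(
            trials["t_side_in"].iat[i] - trials["t_center_in"].iat[i]
            for i in indices
        )
    )
    return SequenceInstance(
        seq=seq,
        trial_indices=tuple(indices),
        context=context,
        step3_side_dwell=dwell,
        step3_side_to_center=side_to_center,
        center_to_side_max=c2s,
        rewarded_final=bool(trials["rewarded"].iat[i_last]),
    )


def _resolve_overlaps(instances):
    """Greedy left-to-right resolution of same-sequence overlapping instances."""
    out = []
    next_free = -1
    for inst in sorted(instances, key=lambda x: x.trial_indices[0]):
        if inst.trial_indices[0] > next_free:
            out.append(inst)
            next_free = inst.trial_indices[-1]
    return out


def select_dominant_instances(trials: pd.DataFrame, seq: str):
    """All matches of ``seq`` inside its target-matched dominance epochs.

    Matches executed after the latent target changed, but still inside the
    epoch tail, are labeled ``DOMINANT_TAIL``.  Global filters are applied.
    """
    seq = _validate_seq(seq)
    epochs = establish_dominance_epochs(trials, seq, basis=TARGET_MATCHED)
    matches = find_pattern_matches(trials["choice"].tolist(), seq)
    targets = trials["latent_target"].tolist()
    selected = []
    for idx in matches:
        if not any(ep.contains(idx) for ep in epochs):
            continue
        tail = targets[idx[-1]] != seq
        selected.append(
            _make_instance(trials, seq, idx, DOMINANT_TAIL if tail else DOMINANT)
        )
    selected = _resolve_overlaps(selected)
    return apply_global_filters(selected, trials)


def select_exploratory_instances(
    trials: pd.DataFrame,
    seq: str,
    dominant_seq: str,
    keep_discarded: bool = False,
):
    """Instances of ``seq`` executed while ``dominant_seq`` was dominant.

    Candidates that share any trial with a raw match of the dominant sequence
    are removed, then rescued iff immediately preceded by another completed
    instance of ``seq``, or the final-step side dwell exceeds 0.5 s, or the
    final-step side-to-center duration exceeds 1 s.  With ``keep_discarded``
    the rejected candidates are returned too, labeled ``DISCARDED``.
    """
    seq = _validate_seq(seq)
    dominant_seq = _validate_seq(dominant_seq)
    epochs = establish_dominance_epochs(trials, dominant_seq, basis=TARGET_MATCHED)
    choices = "".join(trials["choice"].tolist())
    k = len(seq)
    candidates = [
        idx
        for idx in find_pattern_matches(trials["choice"].tolist(), seq)
        if any(ep.contains(idx) for ep in epochs)
    ]
    dominant_trials = set()
    for idx in find_pattern_matches(trials["choice"].tolist(), dominant_seq):
        dominant_trials.update(idx)

    survivors, discarded = [], []
    for idx in candidates:
        inst = _make_instance(trials, seq, idx, EXPLORATORY)
        if not (set(idx) & dominant_trials):
            survivors.append(inst)
            continue
        s = idx[0]
        preceded = s - k >= 0 and choices[s - k : s] == seq
        marked = (
            inst.step3_side_dwell > STEP3_DWELL_RESCUE_S
            or (
                np.isfinite(inst.step3_side_to_center)
                and inst.step3_side_to_center > STEP3_SIDE_TO_CENTER_RESCUE_S
            )
        )
        if preceded or marked:
            survivors.append(inst)
        else:
            discarded.append(replace(inst, context=DISCARDED))
    survivors = apply_global_filters(_resolve_overlaps(survivors), trials)
    if keep_discarded:
        return survivors + discarded
    return survivors


def select_off_target_instances(trials: pd.DataFrame, seq: str):
    """Instances of ``seq`` dominating a block whose latent target differs.

    Uses behavior-only dominance (ignoring the latent target) and keeps the
    matches whose final trial falls in a block with a different target.
    """
    seq = _validate_seq(seq)
    epochs = establish_dominance_epochs(trials, seq, basis=BEHAVIOR_ONLY)
    targets = trials["latent_target"].tolist()
    matches = find_pattern_matches(trials["choice"].tolist(), seq)
    selected = [
        _make_instance(trials, seq, idx, OFF_TARGET_DOMINANT)
        for idx in matches
        if any(ep.contains(idx) for ep in epochs) and targets[idx[-1]] != seq
    ]
    selected = _resolve_overlaps(selected)
    return apply_global_filters(selected, trials)


def _quad_runs(choices: str, pat: str):
    """Trial sets of maximal runs of >= 2 concatenated copies of ``pat``."""
    runs = []
    m = len(pat)
    i = 0
    while i <= len(choices) - 2 * m:
        reps = 0
        while choices[i + reps * m : i + (reps + 1) * m] == pat:
            reps += 1
        if reps >= 2:
            runs.append(set(range(i, i + reps * m)))
            i += reps * m
        else:
            i += 1
    return runs


def apply_global_filters(instances, trials: pd.DataFrame):
    """Remove instances inside LLRR/RRLL concatenation runs or with long breaks.

    An instance is dropped when all of its trials lie inside a run of two or
    more concatenated ``LLRR`` (or ``RRLL``) patterns, or when any of its
    center-in to side-in intervals exceeds 3 s.
    """
    choices = "".join(trials["choice"].tolist())
    quad_trials = []
    for pat in ("LLRR", "RRLL"):
        quad_trials.extend(_quad_runs(choices, pat))
    out = []
    for inst in instances:
        idx = set(inst.trial_indices)
        if any(idx <= run for run in quad_trials):
            continue
        if inst.center_to_side_max > CENTER_TO_SIDE_BREAK_S:
            continue
        out.append(inst)
    return out


def session_passes_filter(
    trials: pd.DataFrame,
    min_instances: int = 200,
    min_rate: float = 0.15,
):
    """Session admission gate.

    Passes iff the larger of the LLR / RRL non-overlapping match counts is at
    least ``min_instances`` and the sequence production rate (completed
    latent-target instances x sequence length / total trials) exceeds
    ``min_rate``.  Returns ``(passed, reason)``.
    """
    if len(trials) == 0:
        return False, "empty session"
    choices = trials["choice"].tolist()
    counts = {
        seq: len(_resolve_overlaps(
            [SequenceInstance(seq, idx, DOMINANT) for idx in
             find_pattern_matches(choices, seq)]
        ))
        for seq in ("LLR", "RRL")
    }
    if max(counts.values()) < min_instances:
        return False, (
            f"instance count: max(LLR={counts['LLR']}, RRL={counts['RRL']}) "
            f"< {min_instances}"
        )
    stream = "".join(choices)
    targets = trials["latent_target"].tolist()
    produced = 0
    for seq in sorted(set(targets)):
        for lo, hi in _target_blocks(targets, seq):
            block = stream[lo:hi]
            k = len(seq)
            i = 0
            while i <= len(block) - k:
                if block[i : i + k] == seq:
                    produced += k
                    i += k
                else:
                    i += 1
    rate = produced / len(trials)
    if rate <= min_rate:
        return False, f"production rate: {rate:.3f} <= {min_rate}"
    return True, f"pass (counts={counts}, rate={rate:.3f})"


def parse_session(trials: pd.DataFrame, seqs=("LLR", "RRL")):
    """Full parse of a session: dominant, tail, and exploratory instances.

    For each sequence in ``seqs``, dominant(+tail) instances are selected in
    its own target-matched epochs and exploratory instances are selected
    within the dominance epochs of every other sequence in ``seqs``.
    """
    if len(trials) == 0:
        raise ValueError("cannot parse an empty session")
    instances = []
    for seq in seqs:
        instances.extend(select_dominant_instances(trials, seq))
        for other in seqs:
            if other != seq:
                instances.extend(
                    select_exploratory_instances(trials, seq, dominant_seq=other)
                )
    instances.sort(key=lambda x: (x.trial_indices[0], x.seq))
    return instances


def instances_to_frame(instances) -> pd.DataFrame:
    """Instance table: one row per instance, documented columns."""
    return pd.DataFrame(
        {
            "seq": [i.seq for i in instances],
            "start": [i.trial_indices[0] for i in instances],
            "end": [i.trial_indices[-1] + 1 for i in instances],
            "context": [i.context for i in instances],
            "step3_side_dwell": [i.step3_side_dwell for i in instances],
            "step3_side_to_center": [i.step3_side_to_center for i in instances],
            "center_to_side_max": [i.center_to_side_max for i in instances],
            "rewarded_final": [i.rewarded_final for i in instances],
        }
    )
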