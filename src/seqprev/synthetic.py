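"""Synthetic behavior, event timing, and spike trains with known ground truth.

The generator emulates the statistical structure of a self-guided sequence
task: blocks of 250-500 trials with an unsignalled latent target sequence
drawn from a small set (e.g. {LLR, RRL}), an agent that adopts the new
target after a discovery lag and then concatenates it, sporadic exploratory
bouts of alternative sequences (more likely shortly after a reward
omission), 10-30% reward omission on correct completions, dwell-time
lengthening of the final side-port visit on unrewarded completions, and
Poisson spiking whose log-rate is a linear function of sequence step,
behavioral context, local sequence prevalence (with context-specific
slopes), reward prevalence, and a movement covariate.

Everything is deterministic under a fixed seed, and the generative
parameters are returned as a :class:`GroundTruth` so downstream estimators
can be checked by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seqprev.io import SessionBundle
from seqprev.prevalence import KernelSpec, sequence_prevalence

__all__ = [
    "AgentConfig",
    "TimingParams",
    "NeuronConfig",
    "GroundTruth",
    "simulate_behavior",
    "simulate_timing",
    "simulate_ensemble",
    "simulate_session",
    "make_fixture",
    "FIXTURES",
]

EXPLOIT = "exploit"
EXPLORE = "explore"


def _check_sequences(seqs) -> tuple:
    seqs = tuple(str(s) for s in seqs)
    if not seqs:
        raise ValueError("sequence_set must be non-empty")
    for s in seqs:
        if len(s) < 3 or set(s) - {"L", "R"}:
            raise ValueError(
                f"sequences must be over L/R with length >= 3, got {s!r}"
            )
    return seqs


@dataclass(frozen=True)
class AgentConfig:
    """Behavioral generator settings; defaults are the study conditions."""

    sequence_set: tuple = ("LLR", "RRL")
    block_length_range: tuple = (250, 500)
    switch_lag_mean: float = 15.0  # trials to adopt a new target
    explore_rate_baseline: float = 0.02  # bout start probability per sequence
    explore_boost_after_omission: float = 4.0
    explore_boost_duration: int = 6  # trials the boost lasts after an omission
    explore_bout_mean_reps: float = 1.5  # geometric mean bout length (instances)
    omission_prob: float = 0.2
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence_set", _check_sequences(self.sequence_set))
        lo, hi = self.block_length_range
        if not (0 < lo <= hi):
            raise ValueError("block_length_range must be a positive (lo, hi) pair")
        if not 0 <= self.omission_prob <= 1:
            raise ValueError("omission_prob must be in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def simulate_behavior(cfg: AgentConfig) -> pd.DataFrame:
    """Generate the trial table of a session.

    Returns one row per trial with the emitted ``choice``, the latent
    ``block_id`` / ``latent_target``, the reward bookkeeping (``correct`` is
    a completion of the current target; ``rewarded`` further survives the
    omission lottery), and generator annotations used downstream as ground
    truth: ``agent_seq`` (the sequence the agent intended), ``agent_step``
    (1-based step within it), ``agent_mode`` (exploit/explore), and
    ``instance_start`` (first trial of the intended instance).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials
    lo, hi = cfg.block_length_range

    # latent block structure
    block_id = np.empty(n, dtype=int)
    latent = np.empty(n, dtype=object)
    boundaries = [0]
    targets = []
    t = 0
    b = 0
    while t < n:
        length = int(rng.integers(lo, hi + 1))
        prev = targets[-1] if targets else None
        options = [s for s in cfg.sequence_set if s != prev] or list(
            cfg.sequence_set
        )
        targets.append(options[int(rng.integers(len(options)))])
        block_id[t : t + length] = b
        latent[t : t + length] = targets[-1]
        t += length
        boundaries.append(min(t, n))
        b += 1

    choice = np.empty(n, dtype=object)
    correct = np.zeros(n, dtype=bool)
    rewarded = np.zeros(n, dtype=bool)
    agent_seq = np.empty(n, dtype=object)
    agent_step = np.empty(n, dtype=int)
    agent_mode = np.empty(n, dtype=object)
    instance_start = np.empty(n, dtype=int)

    adopted = targets[0]
    adopt_at = 0  # trial index at which the agent adopts the pending target
    pending = targets[0]
    mode = EXPLOIT
    bout_left = 0
    boost_until = -1
    queue: list = []
    cur_seq = adopted
    cur_start = 0
    history: list = []

    for t in range(n):
        # schedule adoption of a new target at block transitions
        if t > 0 and block_id[t] != block_id[t - 1]:
            pending = latent[t]
            lag = (
                0
                if cfg.switch_lag_mean == 0
                else int(rng.poisson(cfg.switch_lag_mean))
            )
            adopt_at = t + lag
        if pending != adopted and t >= adopt_at:
            adopted = pending
            # discovery interrupts whatever was being executed
            queue = []
            mode = EXPLOIT
            bout_left = 0

        if not queue:
            # sequence boundary: choose what to execute next
            if mode == EXPLORE and bout_left > 0:
                bout_left -= 1
            else:
                mode = EXPLOIT
            if mode == EXPLOIT:
                p = cfg.explore_rate_baseline
                if t <= boost_until:
                    p *= cfg.explore_boost_after_omission
                alternatives = [s for s in cfg.sequence_set if s != adopted]
                if alternatives and rng.random() < min(p, 1.0):
                    mode = EXPLORE
                    cur_seq = alternatives[int(rng.integers(len(alternatives)))]
                    # geometric bout length (number of instances)
                    p_geo = 1.0 / max(cfg.explore_bout_mean_reps, 1.0)
                    bout_left = int(rng.geometric(p_geo)) - 1
                else:
                    cur_seq = adopted
            queue = list(cur_seq)
            cur_start = t

        c = queue.pop(0)
        choice[t] = c
        history.append(c)
        agent_seq[t] = cur_seq
        agent_step[t] = len(cur_seq) - len(queue)
        agent_mode[t] = mode
        instance_start[t] = cur_start

        target = latent[t]
        k = len(target)
        if t + 1 >= k and "".join(history[t + 1 - k : t + 1]) == target:
            correct[t] = True
            if rng.random() >= cfg.omission_prob:
                rewarded[t] = True
            else:
                boost_until = t + cfg.explore_boost_duration

    return pd.DataFrame(
        {
            "choice": choice,
            "correct": correct,
            "rewarded": rewarded,
            "block_id": block_id,
            "latent_target": latent,
            "agent_seq": agent_seq,
            "agent_step": agent_step,
            "agent_mode": agent_mode,
            "instance_start": instance_start,
        }
    )


@dataclass(frozen=True)
class TimingParams:
    """Port-event timing distributions (seconds).

    Side-port dwell means depend on the outcome: rewarded completions dwell
    longest (reward consumption), unrewarded completions of the intended
    sequence — omitted target completions and exploratory completions —
    dwell longer than pass-through visits ("sequence marking").
    """

    center_dwell_mean: float = 0.2
    center_dwell_sd: float = 0.04
    transit_mean: float = 0.3
    transit_sd: float = 0.05
    side_dwell_mean: float = 0.3
    side_dwell_sd: float = 0.05
    side_dwell_completion_mean: float = 0.7
    side_dwell_reward_mean: float = 1.0
    min_duration: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "center_dwell_mean",
            "transit_mean",
            "side_dwell_mean",
            "side_dwell_completion_mean",
            "side_dwell_reward_mean",
            "min_duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("center_dwell_sd", "transit_sd", "side_dwell_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_timing(trials: pd.DataFrame, params: TimingParams | None = None) -> pd.DataFrame:
    """Attach strictly increasing port-entry/exit timestamps to a trial table.

    Durations are normal draws clipped at ``min_duration``; with zero SDs
    every duration equals its configured mean exactly.
    """
    params = params or TimingParams()
    rng = np.random.default_rng(params.seed)
    n = len(trials)

    def draw(mean, sd, size):
        return np.clip(rng.normal(mean, sd, size), params.min_duration, None)

    center_dwell = draw(params.center_dwell_mean, params.center_dwell_sd, n)
    transit_in = draw(params.transit_mean, params.transit_sd, n)
    transit_out = draw(params.transit_mean, params.transit_sd, n)

    completed = trials["correct"].to_numpy(dtype=bool)
    rewarded = trials["rewarded"].to_numpy(dtype=bool)
    if "agent_seq" in trials.columns:
        intended_final = (
            trials["agent_step"].to_numpy()
            == trials["agent_seq"].map(len).to_numpy()
        )
    else:
        intended_final = completed
    dwell_mean = np.full(n, params.side_dwell_mean)
    dwell_mean[intended_final & ~rewarded] = params.side_dwell_completion_mean
    dwell_mean[completed & ~rewarded] = params.side_dwell_completion_mean
    dwell_mean[rewarded] = params.side_dwell_reward_mean
    side_dwell = np.clip(
        rng.normal(dwell_mean, params.side_dwell_sd), params.min_duration, None
    )

    t_center_in = np.empty(n)
    t = 0.0
    out = trials.copy()
    t_center_out = np.empty(n)
    t_side_in = np.empty(n)
    t_side_out = np.empty(n)
    for i in range(n):
        t_center_in[i] = t
        t_center_out[i] = t_center_in[i] + center_dwell[i]
        t_side_in[i] = t_center_out[i] + transit_in[i]
        t_side_out[i] = t_side_in[i] + side_dwell[i]
        t = t_side_out[i] + transit_out[i]
    out["t_center_in"] = t_center_in
    out["t_center_out"] = t_center_out
    out["t_side_in"] = t_side_in
    out["t_side_out"] = t_side_out
    return out


@dataclass(frozen=True)
class NeuronConfig:
    """Poisson population settings.

    SDs parameterize the across-unit spread of log-rate coefficients;
    prevalence slopes are drawn independently per context so the generated
    population has context-specific prevalence tuning.
    """

    n_units: int = 20
    baseline_rate: float = 5.0  # Hz
    step_tuning_sd: float = 0.3
    choice_tuning_sd: float = 0.4  # L vs R selectivity (both windows of a trial)
    sequence_tuning_sd: float = 0.3  # selectivity for the intended sequence
    context_offset_sd: float = 0.3
    prevalence_slope_sd: float = 1.0
    reward_prev_slope_sd: float = 0.0
    movement_slope_sd: float = 0.0
    rate_ceiling: float = 100.0  # Hz
    window_width: float = 0.5  # seconds, matches the analysis windows
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.baseline_rate <= 0 or self.rate_ceiling <= 0:
            raise ValueError("rates must be positive")


@dataclass
class GroundTruth:
    """Generative parameters and per-trial covariates of one simulation."""

    baseline_rate: float
    step_tuning: np.ndarray  # (units, steps, 2 ports)
    choice_tuning: np.ndarray  # (units, 2): L, R
    sequence_tuning: dict  # seq -> (units,) offsets
    context_offsets: np.ndarray  # (units, 2): exploit, explore
    prevalence_slopes: np.ndarray  # (units, 2): per-context slope
    reward_prev_slopes: np.ndarray
    movement_slopes: np.ndarray
    context: np.ndarray  # per trial, 0 exploit / 1 explore
    trial_prevalence: np.ndarray  # covariate actually used per trial
    prevalence: dict = field(default_factory=dict)  # seq -> per-trial series


def simulate_ensemble(
    trials: pd.DataFrame,
    ncfg: NeuronConfig,
    prevalence_series,
    reward_prevalence_series=None,
):
    """Draw Poisson spike trains for a simulated population.

    The log firing rate of unit *i* in the peri-event windows of trial *t*
    (0.5 s around center-in and side-in) is::

        log baseline + step_tuning(step, port) + context_offset(ctx)
        + prevalence_slope(ctx) * prev + reward_slope * rew + move_slope * m

    where ``prev`` is the prevalence of the agent's intended sequence read
    one trial before the intended instance began.  Rates are clipped at
    ``rate_ceiling``; outside the windows units fire at baseline.
    ``prevalence_series`` is either one per-trial array or a dict mapping
    sequence to per-trial array (selected by the agent's intended sequence).
    Returns ``(spikes, ground_truth)``.
    """
    n = len(trials)
    rng = np.random.default_rng(ncfg.seed)
    if isinstance(prevalence_series, dict):
        for seq, v in prevalence_series.items():
            if len(v) != n:
                raise ValueError(
                    f"prevalence series for {seq} has length {len(v)} != {n}"
                )
        series_by_seq = {k: np.asarray(v, float) for k, v in prevalence_series.items()}
        get_series = lambda seq: series_by_seq[seq]  # noqa: E731
    else:
        arr = np.asarray(prevalence_series, dtype=float)
        if len(arr) != n:
            raise ValueError(f"prevalence series has length {len(arr)} != {n}")
        series_by_seq = {None: arr}
        get_series = lambda seq: arr  # noqa: E731
    if reward_prevalence_series is not None:
        rew_series = np.asarray(reward_prevalence_series, dtype=float)
        if len(rew_series) != n:
            raise ValueError("reward prevalence series misaligned with trials")
    else:
        rew_series = np.zeros(n)

    steps = trials["agent_step"].to_numpy() if "agent_step" in trials else np.ones(n, int)
    seqs = trials["agent_seq"].to_numpy() if "agent_seq" in trials else np.array([None] * n)
    starts = (
        trials["instance_start"].to_numpy()
        if "instance_start" in trials
        else np.arange(n)
    )
    modes = (
        trials["agent_mode"].to_numpy()
        if "agent_mode" in trials
        else np.array([EXPLOIT] * n)
    )
    ctx = (modes == EXPLORE).astype(int)
    max_step = int(steps.max())

    step_tuning = rng.normal(0, ncfg.step_tuning_sd, (ncfg.n_units, max_step, 2))
    choice_tuning = rng.normal(0, ncfg.choice_tuning_sd, (ncfg.n_units, 2))
    seq_names = sorted({s for s in seqs if s is not None})
    sequence_tuning = {
        s: rng.normal(0, ncfg.sequence_tuning_sd, ncfg.n_units)
        for s in seq_names
    }
    context_offsets = rng.normal(0, ncfg.context_offset_sd, (ncfg.n_units, 2))
    prevalence_slopes = rng.normal(
        0, ncfg.prevalence_slope_sd, (ncfg.n_units, 2)
    )
    reward_slopes = rng.normal(0, ncfg.reward_prev_slope_sd, ncfg.n_units)
    movement_slopes = rng.normal(0, ncfg.movement_slope_sd, ncfg.n_units)

    prev_cov = np.empty(n)
    for t in range(n):
        s = int(starts[t])
        prev_cov[t] = get_series(seqs[t])[s - 1] if s > 0 else 0.0
    rew_cov = np.array(
        [rew_series[int(s) - 1] if s > 0 else 0.0 for s in starts]
    )
    move = trials["t_side_in"].to_numpy() - trials["t_center_in"].to_numpy()
    move_cov = move - move.mean()

    # window geometry: center and side window per trial, in time order
    half = ncfg.window_width / 2.0
    anchors = np.empty(2 * n)
    anchors[0::2] = trials["t_center_in"].to_numpy()
    anchors[1::2] = trials["t_side_in"].to_numpy()
    w_start = anchors - half
    w_end = anchors + half
    # clip overlapping windows so the rate is piecewise constant
    w_start = np.maximum(w_start, np.concatenate([[-np.inf], w_end[:-1]]))
    w_start = np.clip(w_start, 0.0, None)
    w_dur = np.clip(w_end - w_start, 0.0, None)
    t_end = float(trials["t_side_out"].iloc[-1]) + 0.5
    gap_start = np.concatenate([[0.0], w_end])
    gap_end = np.concatenate([w_start, [t_end]])
    gap_dur = np.clip(gap_end - gap_start, 0.0, None)

    port = np.empty(2 * n, dtype=int)
    port[0::2] = 0
    port[1::2] = 1
    step_idx = np.repeat(steps - 1, 2)
    trial_idx = np.repeat(np.arange(n), 2)

    choice_idx = (trials["choice"].to_numpy() == "R").astype(int)
    seq_idx_of_trial = np.array(
        [seq_names.index(s) if s in seq_names else -1 for s in seqs]
    )
    seq_tuning_matrix = (
        np.column_stack([sequence_tuning[s] for s in seq_names])
        if seq_names
        else np.zeros((ncfg.n_units, 1))
    )

    log_base = np.log(ncfg.baseline_rate)
    spikes = {}
    for u in range(ncfg.n_units):
        seq_term = np.where(
            seq_idx_of_trial >= 0,
            seq_tuning_matrix[u][np.clip(seq_idx_of_trial, 0, None)],
            0.0,
        )
        log_rate = (
            log_base
            + step_tuning[u, step_idx, port]
            + choice_tuning[u, choice_idx[trial_idx]]
            + seq_term[trial_idx]
            + context_offsets[u, ctx[trial_idx]]
            + prevalence_slopes[u, ctx[trial_idx]] * prev_cov[trial_idx]
            + reward_slopes[u] * rew_cov[trial_idx]
            + movement_slopes[u] * move_cov[trial_idx]
        )
        rate = np.clip(np.exp(log_rate), 0.0, ncfg.rate_ceiling)
        counts_w = rng.poisson(rate * w_dur)
        times_w = np.repeat(w_start, counts_w) + rng.random(
            counts_w.sum()
        ) * np.repeat(w_dur, counts_w)
        counts_g = rng.poisson(ncfg.baseline_rate * gap_dur)
        times_g = np.repeat(gap_start, counts_g) + rng.random(
            counts_g.sum()
        ) * np.repeat(gap_dur, counts_g)
        spikes[u] = np.sort(np.concatenate([times_w, times_g]))

    gt = GroundTruth(
        baseline_rate=ncfg.baseline_rate,
        step_tuning=step_tuning,
        choice_tuning=choice_tuning,
        sequence_tuning=sequence_tuning,
        context_offsets=context_offsets,
        prevalence_slopes=prevalence_slopes,
        reward_prev_slopes=reward_slopes,
        movement_slopes=movement_slopes,
        context=ctx,
        trial_prevalence=prev_cov,
        prevalence={k: v for k, v in series_by_seq.items() if k is not None},
    )
    return spikes, gt


def simulate_session(
    agent_cfg: AgentConfig | None = None,
    timing: TimingParams | None = None,
    ncfg: NeuronConfig | None = None,
    kernel: KernelSpec | None = None,
    name: str = "synthetic",
):
    """Full simulated session: behavior + timing + spikes + ground truth.

    Prevalence series are computed for every sequence in the agent's set and
    fed to the ensemble as the per-intended-sequence covariate.  Returns
    ``(SessionBundle, GroundTruth)``.
    """
    agent_cfg = agent_cfg or AgentConfig()
    timing = timing or TimingParams(seed=agent_cfg.seed + 1)
    ncfg = ncfg or NeuronConfig(seed=agent_cfg.seed + 2)
    kernel = kernel or KernelSpec()
    trials = simulate_timing(simulate_behavior(agent_cfg), timing)
    series = {
        seq: sequence_prevalence(trials, seq, kernel).values
        for seq in agent_cfg.sequence_set
    }
    spikes, gt = simulate_ensemble(trials, ncfg, series)
    bundle = SessionBundle(
        trials=trials,
        spikes=spikes,
        metadata={"name": name, "generator": "seqprev.synthetic", "seed": agent_cfg.seed},
    )
    return bundle, gt


# ---------------------------------------------------------------------------
# deterministic fixtures with hand-checkable parsing outcomes


def _manual_trials(
    segments,
    dwell_overrides=None,
    c2s_overrides=None,
    base_dwell: float = 0.3,
    transit: float = 0.1,
    center_dwell: float = 0.2,
):
    """Build a trial table from (choices, block_id, target) segments with
    fully deterministic arithmetic timing."""
    choice, block_id, latent = [], [], []
    for choices, b, target in segments:
        for c in choices:
            choice.append(c)
            block_id.append(b)
            latent.append(target)
    n = len(choice)
    dwell_overrides = dwell_overrides or {}
    c2s_overrides = c2s_overrides or {}
    rows = {
        k: np.empty(n)
        for k in ("t_center_in", "t_center_out", "t_side_in", "t_side_out")
    }
    t = 0.0
    correct = np.zeros(n, dtype=bool)
    stream = "".join(choice)
    for i in range(n):
        rows["t_center_in"][i] = t
        rows["t_center_out"][i] = t + center_dwell
        c2s = c2s_overrides.get(i, transit)
        rows["t_side_in"][i] = rows["t_center_out"][i] + c2s
        dwell = dwell_overrides.get(i, base_dwell)
        rows["t_side_out"][i] = rows["t_side_in"][i] + dwell
        t = rows["t_side_out"][i] + transit
        k = len(latent[i])
        if i + 1 >= k and stream[i + 1 - k : i + 1] == latent[i]:
            correct[i] = True
    return pd.DataFrame(
        {
            "choice": choice,
            "correct": correct,
            "rewarded": correct,  # fixtures omit nothing
            "block_id": block_id,
            "latent_target": latent,
            **rows,
        }
    )


def _fixture_golden_1() -> SessionBundle:
    """Dominant RRL block with a post-switch tail, then dominant LLR.

    60 trials.  Expected parse (see the ``expected`` registry entry):
    RRL dominant at starts 0..24 step 3, RRL tail at 27 and 30, LLR dominant
    at 36..57 step 3, no exploratory instances.
    """
    trials = _manual_trials(
        [
            ("RRL" * 9, 0, "RRL"),  # 0..26
            ("RRL" * 2 + "LLL" + "LLR" * 8, 1, "LLR"),  # 27..59
        ]
    )
    return SessionBundle(trials=trials, metadata={"name": "golden_parsing_1"})


def _fixture_golden_2() -> SessionBundle:
    """LLR-dominant session with exploratory RRLs exercising the rescue rule.

    42 trials: a lone non-overlapping RRL (admitted outright), an
    overlapping RRL with step-3 dwell 0.6 s (rescued), and an overlapping
    RRL with dwell 0.3 s (discarded).
    """
    trials = _manual_trials(
        [
            (
                "LLR" * 5  # 0..14
                + "RRL"  # 15..17 lone exploratory
                + "LLR"  # 18..20
                + "LLRRL"  # 21..25: RRL at 23 overlaps LLR at 21
                + "LLR"  # 26..28
                + "LLRRL"  # 29..33: RRL at 31 overlaps LLR at 29
                + "LLR" * 2  # 34..39
                + "LL",  # 40..41
                0,
                "LLR",
            )
        ],
        dwell_overrides={25: 0.6, 33: 0.3},
    )
    return SessionBundle(trials=trials, metadata={"name": "golden_parsing_2"})


def _fixture_golden_3() -> SessionBundle:
    """LLR-dominant session exercising the LLRR-run and 3 s break filters.

    48 trials: an LLRR x2 concatenation whose embedded LLR/RRL matches are
    removed, and an LLR whose center-to-side interval is 3.5 s (removed).
    """
    trials = _manual_trials(
        [
            (
                "LLR" * 3  # 0..8
                + "LLRR" * 2  # 9..16: quad run
                + "LLR"  # 17..19 (RRL at 15 overlaps into here)
                + "LLR"  # 20..22: break on trial 20
                + "LLR" * 8  # 23..46
                + "L",  # 47
                0,
                "LLR",
            )
        ],
        c2s_overrides={20: 3.5},
    )
    return SessionBundle(trials=trials, metadata={"name": "golden_parsing_3"})


def _fixture_two_context() -> SessionBundle:
    """Two blocks (RRL then LLR) with 3 exploratory RRLs straddling the
    0.5 s dwell threshold (0.6 rescued, 0.45 discarded, 0.7 rescued)."""
    trials = _manual_trials(
        [
            ("RRL" * 7, 0, "RRL"),  # 0..20
            (
                "LLR" * 3  # 21..29
                + "LLRRL"  # 30..34: RRL at 32, dwell 0.6
                + "LLR" * 3  # 35..43
                + "LLRRL"  # 44..48: RRL at 46, dwell 0.45
                + "LLR" * 3  # 49..57
                + "LLRRL"  # 58..62: RRL at 60, dwell 0.7
                + "LLR" * 6,  # 63..80
                1,
                "LLR",
            ),
        ],
        dwell_overrides={34: 0.6, 48: 0.45, 62: 0.7},
    )
    rng = np.random.default_rng(1234)
    span = float(trials["t_side_out"].iloc[-1]) + 0.5
    spikes = {u: np.sort(rng.uniform(0, span, 300)) for u in range(3)}
    return SessionBundle(
        trials=trials, spikes=spikes, metadata={"name": "two_context"}
    )


def _fixture_empty() -> SessionBundle:
    trials = pd.DataFrame(
        {
            c: pd.Series(dtype=t)
            for c, t in [
                ("choice", str),
                ("correct", bool),
                ("rewarded", bool),
                ("block_id", int),
                ("latent_target", str),
                ("t_center_in", float),
                ("t_center_out", float),
                ("t_side_in", float),
                ("t_side_out", float),
            ]
        }
    )
    return SessionBundle(trials=trials, metadata={"name": "empty"})


#: fixture registry: builder plus hand-enumerated expected parse outcomes
FIXTURES: dict = {
    "golden_parsing_1": {
        "build": _fixture_golden_1,
        "expected": {
            ("RRL", "DOMINANT"): [0, 3, 6, 9, 12, 15, 18, 21, 24],
            ("RRL", "DOMINANT_TAIL"): [27, 30],
            ("RRL", "EXPLORATORY"): [],
            ("LLR", "DOMINANT"): [36, 39, 42, 45, 48, 51, 54, 57],
            ("LLR", "DOMINANT_TAIL"): [],
            ("LLR", "EXPLORATORY"): [],
        },
    },
    "golden_parsing_2": {
        "build": _fixture_golden_2,
        "expected": {
            ("LLR", "DOMINANT"): [0, 3, 6, 9, 12, 18, 21, 26, 29, 34, 37],
            ("LLR", "DOMINANT_TAIL"): [],
            ("RRL", "EXPLORATORY"): [15, 23],
            ("RRL", "DISCARDED"): [31],
        },
    },
    "golden_parsing_3": {
        "build": _fixture_golden_3,
        "expected": {
            ("LLR", "DOMINANT"): [0, 3, 6, 17, 23, 26, 29, 32, 35, 38, 41, 44],
            ("LLR", "DOMINANT_TAIL"): [],
            ("RRL", "EXPLORATORY"): [],
            ("RRL", "DISCARDED"): [11, 15],
        },
    },
    "two_context": {
        "build": _fixture_two_context,
        "expected": {
            ("RRL", "DOMINANT"): [0, 3, 6, 9, 12, 15, 18],
            ("RRL", "EXPLORATORY"): [32, 60],
            ("RRL", "DISCARDED"): [46],
            ("LLR", "DOMINANT"): [
                21, 24, 27, 30, 35, 38, 41, 44, 49, 52, 55, 58, 63, 66, 69,
                72, 75, 78,
            ],
        },
    },
    "empty": {"build": _fixture_empty, "expected": {}},
}


def make_fixture(name: str) -> SessionBundle:
    """Build a named deterministic fixture session (<= 100 trials)."""
    try:
        entry = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return entry["build"]()
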