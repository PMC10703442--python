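"""Trial-history prevalence statistics.

Sequence prevalence summarizes how often a given choice sequence was completed
in the recent past: a per-trial binary event vector (1 on the final trial of
each completion, 0 elsewhere) is convolved with a *causal* half-Gaussian
kernel (zero mean, SD 20 trials by default), yielding a per-trial statistic in
[0, 1] when the kernel is normalized to unit sum.  Reward prevalence applies
the same kernel to rewarded trials, either all rewards or only rewards earned
by the specific sequence.

The condition index guards regressions on prevalence pairs against
collinearity: sqrt of the ratio of the largest to the smallest eigenvalue of
the 2x2 covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KernelSpec",
    "PrevalenceSeries",
    "half_gaussian_kernel",
    "event_vector",
    "sequence_prevalence",
    "reward_prevalence",
    "instance_prevalence",
    "condition_index",
]

#: event-definition labels
SEQ_COMPLETION = "SEQ_COMPLETION"
REWARD_ANY = "REWARD_ANY"
REWARD_SEQ_SPECIFIC = "REWARD_SEQ_SPECIFIC"


@dataclass(frozen=True)
class KernelSpec:
    """Causal half-Gaussian kernel over trial lags.

    Parameters
    ----------
    sd:
        Standard deviation in trials (> 0).
    support:
        Largest lag with non-zero weight, in trials.  Defaults to ``3 * sd``
        (< 1.2% of half-Gaussian mass lies beyond 3 SD).
    offset:
        Signed shift in trials applied to the event vector before weighting.
        ``offset = 0`` is purely causal; a positive offset shifts the window
        toward future trials (used as a control).
    normalized:
        Normalize the weights to unit sum so prevalence lives in [0, 1].
    """

    sd: float = 20.0
    support: int | None = None
    offset: int = 0
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"kernel sd must be > 0, got {self.sd}")
        if self.support is None:
            object.__setattr__(self, "support", int(np.ceil(3 * self.sd)))
        if self.support < self.sd:
            raise ValueError("kernel support must be >= sd")


@dataclass
class PrevalenceSeries:
    """Per-trial prevalence values with the kernel and event rule that made them."""

    values: np.ndarray
    kernel: KernelSpec
    event_definition: str
    seq: str | None = None
    events: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.values)


def half_gaussian_kernel(spec: KernelSpec) -> np.ndarray:
    """Weights g(tau) for lags tau = 0..support.

    g(tau) is proportional to exp(-tau^2 / (2 sd^2)); weights are normalized
    to unit sum when ``spec.normalized``.
    """
    tau = np.arange(spec.support + 1, dtype=float)
    g = np.exp(-(tau**2) / (2.0 * spec.sd**2))
    if spec.normalized:
        g = g / g.sum()
    return g


def completion_mask(choices, seq: str) -> np.ndarray:
    """Boolean mask over trials: True where the last ``len(seq)`` choices spell ``seq``.

    Overlapping completions all count; this is the event rule used both for
    reward eligibility and for prevalence.
    """
    seq = _validate_seq(seq)
    arr = np.asarray(list(choices))
    n, k = len(arr), len(seq)
    mask = np.zeros(n, dtype=bool)
    if n < k:
        return mask
    window = np.array(list(seq))
    hits = np.all(
        np.lib.stride_tricks.sliding_window_view(arr, k) == window, axis=1
    )
    mask[k - 1 :] = hits
    return mask


def event_vector(trials: pd.DataFrame, seq: str) -> np.ndarray:
    """Binary per-trial vector: 1 on the last trial of each completion of ``seq``."""
    return completion_mask(trials["choice"].to_numpy(), seq).astype(float)


def _convolve_causal(b: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """values[t] = sum_tau g(tau) * b[t - tau + offset], in-range indices only."""
    g = half_gaussian_kernel(spec)
    n = len(b)
    # full causal convolution (length n + support), then the signed shift;
    # out-of-range event indices contribute nothing
    conv = np.convolve(b, g)
    out = np.zeros(n)
    idx = np.arange(n) + spec.offset
    ok = (idx >= 0) & (idx < len(conv))
    out[ok] = conv[idx[ok]]
    return out


def sequence_prevalence(
    trials: pd.DataFrame, seq: str, spec: KernelSpec | None = None
) -> PrevalenceSeries:
    """Kernel-weighted local prevalence of completions of ``seq``, per trial.

    Completions count regardless of behavioral context (dominant or
    exploratory).  Raises ``ValueError`` if the sequence is longer than the
    session (no completion is possible).
    """
    spec = spec or KernelSpec()
    seq = _validate_seq(seq)
    if len(trials) < len(seq):
        raise ValueError(
            f"sequence of length {len(seq)} cannot complete in "
            f"{len(trials)} trials"
        )
    b = event_vector(trials, seq)
    return PrevalenceSeries(
        values=_convolve_causal(b, spec),
        kernel=spec,
        event_definition=SEQ_COMPLETION,
        seq=seq,
        events=b,
    )


def reward_prevalence(
    trials: pd.DataFrame,
    spec: KernelSpec | None = None,
    mode: str = REWARD_ANY,
    seq: str | None = None,
) -> PrevalenceSeries:
    """Kernel-weighted prevalence of rewarded trials.

    ``mode=REWARD_ANY`` marks every rewarded trial; ``mode=REWARD_SEQ_SPECIFIC``
    marks only trials rewarded upon completing ``seq`` (which is then required).
    """
    spec = spec or KernelSpec()
    rewarded = trials["rewarded"].to_numpy().astype(bool)
    if mode == REWARD_ANY:
        b = rewarded.astype(float)
    elif mode == REWARD_SEQ_SPECIFIC:
        if seq is None:
            raise ValueError("seq is required for REWARD_SEQ_SPECIFIC mode")
        b = (rewarded & completion_mask(trials["choice"].to_numpy(), seq)).astype(
            float
        )
    else:
        raise ValueError(f"unknown reward prevalence mode: {mode!r}")
    return PrevalenceSeries(
        values=_convolve_causal(b, spec),
        kernel=spec,
        event_definition=mode,
        seq=seq,
        events=b,
    )


def instance_prevalence(instance, series: PrevalenceSeries) -> float:
    """Prevalence read out one trial before the instance begins.

    An instance therefore never contributes to its own prevalence value.
    Instances starting at trial 0 read 0 by convention.
    """
    start = int(instance.trial_indices[0])
    if start <= 0:
        return 0.0
    return float(series.values[start - 1])


def condition_index(x, y, tol: float = 1e-12) -> float:
    """sqrt(lambda_max / lambda_min) of the covariance matrix of (x, y).

    A value of 1 indicates a perfectly decorrelated, equal-variance pair;
    large values flag collinearity.  Raises ``ValueError`` on constant or
    (near-)collinear input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    cov = np.cov(np.vstack([x, y]))
    lam = np.linalg.eigvalsh(cov)
    lmin, lmax = float(lam[0]), float(lam[-1])
    if lmin <= tol * max(lmax, 1.0):
        raise ValueError(
            "singular predictor pair (constant or collinear input); "
            f"eigenvalues {lmin:.3g}, {lmax:.3g}"
        )
    return float(np.sqrt(lmax / lmin))


def _validate_seq(seq: str) -> str:
    seq = str(seq)
    if not seq or set(seq) - {"L", "R"}:
        raise ValueError(f"sequence must be a non-empty string over L/R, got {seq!r}")
    return seq
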