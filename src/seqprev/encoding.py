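"""Single-neuron encoding models scored by cross-validated explained variance.

The central statistic is the coefficient of determination on held-out data,

    EV = 1 - sum((y - yfit)^2) / sum((y - mean(y))^2),

computed per cross-validation fold (the total variance is taken about the
held-out mean), averaged across the five folds, with negative averages —
which reflect overfitting — clamped to zero for reporting.

Models relate a unit's windowed activity to the local sequence prevalence,
optionally with the global context (dominant/exploratory) as a per-context
intercept and/or a context-specific slope, and compare prevalence against
movement covariates (execution time, trajectory PC1) and reward prevalence
in paired regressions on z-scored variables gated by the condition index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from seqprev.prevalence import condition_index

__all__ = [
    "EVResult",
    "RegressionWeights",
    "explained_variance",
    "cross_validated_ev",
    "fit_prevalence_model",
    "fit_context_mixed_model",
    "movement_vigor",
    "trajectory_pc1",
    "fit_paired_regression",
    "history_matched_subset",
]

#: default cvEV threshold above which a neuron counts as prevalence-modulated
PREVALENCE_EV_GATE = 0.2
#: admissible condition-index band for paired regressions
CONDITION_INDEX_BAND = (1.0, 4.0)


def explained_variance(y, yfit) -> float:
    """Unclamped EV of predictions against observations (may be negative)."""
    y = np.asarray(y, dtype=float)
    yfit = np.asarray(yfit, dtype=float)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("explained variance is undefined for constant y")
    sse = float(np.sum((y - yfit) ** 2))
    return 1.0 - sse / sstot


def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xd = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return beta


def _ols_predict(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X]) @ beta


def cross_validated_ev(
    y,
    X,
    folds: int = 5,
    stratify_labels=None,
    seed: int = 0,
    return_folds: bool = False,
):
    """Mean held-out EV of an OLS fit of ``y`` on ``X``, clamped at zero.

    Uses a single (stratified when ``stratify_labels`` is given) K-fold
    split; the clamp is applied to the fold average, not to individual folds.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) < folds:
        raise ValueError(f"need at least {folds} observations")
    if np.ptp(y) == 0:
        raise ValueError("explained variance is undefined for constant y")
    if stratify_labels is not None:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, np.asarray(stratify_labels))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X)
    fold_ev = []
    for train, test in split:
        beta = _ols_fit(X[train], y[train])
        fold_ev.append(explained_variance(y[test], _ols_predict(beta, X[test])))
    fold_ev = np.asarray(fold_ev)
    cv = max(float(fold_ev.mean()), 0.0)
    if return_folds:
        return cv, fold_ev
    return cv


@dataclass
class EVResult:
    """Per-window cvEV values (clamped to [0, 1]) and the best window."""

    per_window: np.ndarray
    context: str | None = None
    slope_per_window: np.ndarray | None = None  # full-data OLS slopes

    @property
    def best_window(self) -> int:
        return int(np.argmax(self.per_window))

    @property
    def best_ev(self) -> float:
        return float(np.max(self.per_window))


def fit_prevalence_model(
    activity: np.ndarray,
    prevalence,
    contexts=None,
    folds: int = 5,
    min_per_context: int = 10,
    seed: int = 0,
):
    """OLS of a unit's windowed activity on instance prevalence, per context.

    ``activity`` is instances x windows for one unit.  Fits are independent
    per window and per behavioral context (contexts with fewer than
    ``min_per_context`` instances are skipped).  Pass ``contexts=None`` to
    fit all instances as a single group.  Returns ``{context: EVResult}``.
    """
    activity = np.asarray(activity, dtype=float)
    prevalence = np.asarray(prevalence, dtype=float)
    if contexts is None:
        contexts = np.array(["ALL"] * len(prevalence))
    contexts = np.asarray(contexts)
    out = {}
    for ctx in np.unique(contexts):
        mask = contexts == ctx
        if mask.sum() < max(min_per_context, folds):
            continue
        prev_c = prevalence[mask]
        if np.ptp(prev_c) == 0:
            raise ValueError(
                f"prevalence is constant within context {ctx!r}; EV undefined"
            )
        evs = np.empty(activity.shape[1])
        slopes = np.empty(activity.shape[1])
        for w in range(activity.shape[1]):
            y = activity[mask, w]
            slopes[w] = _ols_fit(prev_c[:, None], y)[1]
            if np.ptp(y) == 0:
                evs[w] = 0.0
                continue
            evs[w] = cross_validated_ev(y, prev_c, folds=folds, seed=seed)
        out[ctx] = EVResult(per_window=evs, context=str(ctx), slope_per_window=slopes)
    if not out:
        raise ValueError("no context had enough instances to fit")
    return out


def _context_design(prevalence, contexts, variant: str) -> np.ndarray:
    prevalence = np.asarray(prevalence, dtype=float)
    names = np.unique(contexts)
    dummies = np.column_stack([(contexts == c).astype(float) for c in names[1:]])
    if variant == "prevalence_only":
        return prevalence[:, None]
    if variant == "context_intercept":
        return np.column_stack([prevalence, dummies])
    if variant == "context_slope":
        slopes = dummies * prevalence[:, None]
        return np.column_stack([prevalence, dummies, slopes])
    raise ValueError(f"unknown model variant {variant!r}")


def fit_context_mixed_model(
    activity,
    prevalence,
    contexts,
    folds: int = 5,
    seed: int = 0,
):
    """Prevalence models with and without context terms, stratified cvEV.

    Fits the family {prevalence only; + per-context intercept; + context-
    specific slope}.  With two or three context levels the random intercept
    is operationally a per-context offset and is fit as such.  Returns
    ``{variant: cvEV}``.
    """
    activity = np.asarray(activity, dtype=float)
    contexts = np.asarray(contexts)
    if len(np.unique(contexts)) < 2:
        raise ValueError("context models require at least 2 contexts")
    out = {}
    for variant in ("prevalence_only", "context_intercept", "context_slope"):
        X = _context_design(prevalence, contexts, variant)
        out[variant] = cross_validated_ev(
            activity, X, folds=folds, stratify_labels=contexts, seed=seed
        )
    return out


def movement_vigor(instance, trials: pd.DataFrame) -> float:
    """Sequence execution time: first-step center-in to last-step side-in (s)."""
    first, last = instance.trial_indices[0], instance.trial_indices[-1]
    t0 = trials["t_center_in"].iat[first]
    t1 = trials["t_side_in"].iat[last]
    if not (np.isfinite(t0) and np.isfinite(t1)):
        raise ValueError("missing timestamps for vigor computation")
    return float(t1 - t0)


def trajectory_pc1(
    xy: pd.DataFrame,
    instances,
    trials: pd.DataFrame,
    spec=None,
    samples_per_window: int = 20,
) -> np.ndarray:
    """First principal component of the movement trajectory per instance.

    X and Y position snippets from the five analysis windows are resampled
    to a fixed length (linear interpolation, ``samples_per_window`` points
    per window per coordinate), concatenated into one vector per instance,
    centered across instances, and projected onto the leading principal
    axis.  PC1 is defined up to sign.
    """
    from seqprev.statespace import WindowSpec, _anchor_times

    spec = spec or WindowSpec()
    t = xy["time"].to_numpy(dtype=float)
    x = xy["x"].to_numpy(dtype=float)
    y = xy["y"].to_numpy(dtype=float)
    rows = []
    for inst in instances:
        anchors = _anchor_times(trials, inst.trial_indices, spec)
        parts = []
        for a in anchors:
            lo, hi = a - spec.width / 2, a + spec.width / 2
            if not np.any((t >= lo) & (t < hi)):
                raise ValueError(
                    f"empty trajectory window at t={a:.3f}s for instance "
                    f"starting at trial {inst.trial_indices[0]}"
                )
            grid = np.linspace(lo, hi, samples_per_window)
            parts.append(np.interp(grid, t, x))
            parts.append(np.interp(grid, t, y))
        rows.append(np.concatenate(parts))
    M = np.asarray(rows)
    M = M - M.mean(axis=0)
    # leading right singular vector = leading principal axis
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    return M @ vt[0]


@dataclass
class RegressionWeights:
    """Paired-regression weights on z-scored variables."""

    weights: dict
    intercept: float
    window: int
    ev_per_window: np.ndarray = field(repr=False, default=None)  # type: ignore

    def relative_contributions(self) -> dict:
        return {k: abs(v) for k, v in self.weights.items()}


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (v - v.mean()) / sd


def fit_paired_regression(
    activity: np.ndarray,
    prevalence,
    other,
    other_name: str = "other",
    cond_band: tuple = CONDITION_INDEX_BAND,
) -> RegressionWeights:
    """Multiple regression of activity on prevalence plus one other predictor.

    All variables are z-scored so the absolute weights read as relative
    contributions.  The predictor pair must pass the condition-index gate
    (``cond_band``, default [1, 4]); the model is fit in all windows of
    ``activity`` (instances x windows) and the window with the highest
    in-sample EV is reported.
    """
    activity = np.asarray(activity, dtype=float)
    prevalence = np.asarray(prevalence, dtype=float)
    other = np.asarray(other, dtype=float)
    ci = condition_index(prevalence, other)
    if not (cond_band[0] <= ci <= cond_band[1]):
        raise ValueError(
            f"condition index {ci:.2f} outside admissible band {cond_band}; "
            "session excluded from paired regression"
        )
    X = np.column_stack([_zscore(prevalence), _zscore(other)])
    best = None
    evs = np.empty(activity.shape[1])
    for w in range(activity.shape[1]):
        yz = _zscore(activity[:, w])
        beta = _ols_fit(X, yz)
        evs[w] = explained_variance(yz, _ols_predict(beta, X))
        if best is None or evs[w] > evs[best[0]]:
            best = (w, beta)
    w, beta = best
    return RegressionWeights(
        weights={"prevalence": float(beta[1]), other_name: float(beta[2])},
        intercept=float(beta[0]),
        window=w,
        ev_per_window=evs,
    )


def history_matched_subset(instances, trials: pd.DataFrame):
    """Instances immediately preceded by a completed instance of the same
    sequence (matched immediate history; prevalence still varies within)."""
    choices = "".join(trials["choice"].tolist())
    out = []
    for inst in instances:
        s, k = inst.trial_indices[0], len(inst.seq)
        if s - k >= 0 and choices[s - k : s] == inst.seq:
            out.append(inst)
    return out
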