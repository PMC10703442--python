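"""Decoding sequence prevalence from ensemble activity.

Three linear readout families estimate the local sequence prevalence at the
time of the t-th sequence instance from windowed spike counts:

- the general model, one weight per (neuron, window) pair,
- per-window models, one independent readout per analysis window, and
- the constrained shared-weight model, which forces the same weight for a
  neuron in all five windows by stacking the windows as extra observations
  of one regression — the model a temporally fixed downstream decoder could
  implement.

Features are raw spike counts by default (a flag switches to sqrt counts for
sensitivity analyses).  Neurons receive a significance score per window from
the general model and are sorted into classes 0-5 by the number of
significant windows; class-0 neurons are removed, and a session is admitted
only when at least five neurons remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.model_selection import KFold

from seqprev.encoding import explained_variance

__all__ = [
    "DecoderSpec",
    "DecoderFit",
    "NeuronClass",
    "assign_neuron_classes",
    "fit_window_decoder",
    "fit_shared_weight_decoder",
    "exclude_class5_and_refit",
    "prevalence_projection",
    "in_sample_evs",
]

GENERAL_IK = "GENERAL_IK"
PER_WINDOW_K = "PER_WINDOW_K"
SHARED_WEIGHT = "SHARED_WEIGHT"

RIDGE_ALPHAS = np.logspace(-2, 3, 12)


@dataclass(frozen=True)
class DecoderSpec:
    model_form: str = SHARED_WEIGHT
    folds: int = 5
    seed: int = 0
    alpha: float = 0.05  # per-(unit,window) significance level
    significance: str = "marginal"  # or "general" (partial t-tests, see note)
    min_units: int = 5  # session admission threshold (classes 1-5)
    sqrt_features: bool = False
    neuron_classes_included: tuple = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class NeuronClass:
    unit_id: object
    cls: int  # number of windows with a significant prevalence contribution


@dataclass
class DecoderFit:
    model_form: str
    weights: np.ndarray  # (units, windows) for GENERAL, (units,) for SHARED
    bias: float
    cv_ev: float
    cv_ev_per_window: np.ndarray | None = None
    unit_ids: tuple = ()
    window: int | None = None  # for PER_WINDOW_K

    @property
    def worst_window_cv_ev(self) -> float:
        if self.cv_ev_per_window is None:
            raise ValueError("per-window cvEV not available for this model")
        return float(np.min(self.cv_ev_per_window))


def _features(tensor, spec: DecoderSpec) -> np.ndarray:
    """(instances, units, windows) features on the configured scale."""
    return tensor.values if spec.sqrt_features else tensor.counts()


def _needs_ridge(n: int, p: int) -> bool:
    return p > n / 2


def _linear_fit(X: np.ndarray, y: np.ndarray):
    """OLS, or ridge with an inner-CV penalty when the fit is ill-posed."""
    if _needs_ridge(len(X), X.shape[1]):
        model = RidgeCV(alphas=RIDGE_ALPHAS)
    else:
        model = Ridge(alpha=0.0, solver="svd")
    return model.fit(X, y)


def _cv_predictions(X: np.ndarray, y: np.ndarray, spec: DecoderSpec):
    """Held-out predictions per fold: yields (test_index, yhat_test)."""
    if len(y) < spec.folds:
        raise ValueError(f"need at least {spec.folds} instances")
    kf = KFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    for train, test in kf.split(X):
        model = _linear_fit(X[train], y[train])
        yield test, model.predict(X[test])


def _cv_ev(X: np.ndarray, y: np.ndarray, spec: DecoderSpec) -> float:
    evs = [
        explained_variance(y[test], yhat)
        for test, yhat in _cv_predictions(X, y, spec)
    ]
    return max(float(np.mean(evs)), 0.0)


def _window_significance(
    feats: np.ndarray, prevalence: np.ndarray, alpha: float,
    method: str = "marginal",
) -> np.ndarray:
    """(units, windows) boolean significance scores.

    ``marginal`` (default) runs a univariate regression t-test per
    (unit, window) pair.  ``general`` uses partial coefficient t-tests from
    the full model; note that a unit tuned in every window has mutually
    collinear window features, so partial tests systematically understate
    its per-window contributions — the marginal score matches the intended
    "does this neuron in this window track prevalence" reading.
    """
    n, n_units, n_win = feats.shape
    p = n_units * n_win
    if method == "general" and n > p + 5:
        X = np.column_stack([np.ones(n), feats.reshape(n, p)])
        beta, _, rank, _ = np.linalg.lstsq(X, prevalence, rcond=None)
        resid = prevalence - X @ beta
        dof = n - rank
        sigma2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv), 1e-300, None))
        tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
        return (pvals[1:] < alpha).reshape(n_units, n_win)
    sig = np.zeros((n_units, n_win), dtype=bool)
    for u in range(n_units):
        for w in range(n_win):
            x = feats[:, u, w]
            if np.ptp(x) == 0:
                continue
            res = stats.linregress(x, prevalence)
            sig[u, w] = res.pvalue < alpha
    return sig


def assign_neuron_classes(tensor, prevalence, spec: DecoderSpec | None = None):
    """Sort neurons into classes 0-5 by significant windows; gate the session.

    Returns ``(classes, admitted)`` where ``admitted`` is True iff at least
    ``spec.min_units`` neurons fall outside class 0.
    """
    spec = spec or DecoderSpec()
    prevalence = np.asarray(prevalence, dtype=float)
    feats = _features(tensor, spec)
    sig = _window_significance(feats, prevalence, spec.alpha, spec.significance)
    classes = [
        NeuronClass(unit_id=uid, cls=int(sig[u].sum()))
        for u, uid in enumerate(tensor.unit_ids)
    ]
    admitted = sum(c.cls > 0 for c in classes) >= spec.min_units
    return classes, admitted


def _unit_mask(tensor, classes, included) -> np.ndarray:
    cls_by_id = {c.unit_id: c.cls for c in classes}
    return np.array(
        [cls_by_id.get(uid, 0) in included for uid in tensor.unit_ids]
    )


def fit_window_decoder(
    tensor, window: int, prevalence, spec: DecoderSpec | None = None,
    classes=None,
) -> DecoderFit:
    """Independent linear readout of prevalence from one analysis window."""
    spec = spec or DecoderSpec()
    prevalence = np.asarray(prevalence, dtype=float)
    feats = _features(tensor, spec)
    mask = (
        _unit_mask(tensor, classes, set(spec.neuron_classes_included))
        if classes is not None
        else np.ones(feats.shape[1], dtype=bool)
    )
    X = feats[:, mask, window]
    cv = _cv_ev(X, prevalence, spec)
    model = _linear_fit(X, prevalence)
    return DecoderFit(
        model_form=PER_WINDOW_K,
        weights=np.asarray(model.coef_),
        bias=float(model.intercept_),
        cv_ev=cv,
        unit_ids=tuple(np.asarray(tensor.unit_ids)[mask]),
        window=window,
    )


def fit_shared_weight_decoder(
    tensor, prevalence, spec: DecoderSpec | None = None, classes=None
) -> DecoderFit:
    """Constrained readout: one weight per neuron shared across all windows.

    The five windows are stacked as extra observations of the same
    regression (5x the rows, the same prevalence value per instance).
    Cross-validation folds are drawn over instances so all rows of one
    instance stay on the same side of the split.  Reports the overall cvEV,
    the cvEV of the shared readout evaluated in each window, and (via
    ``worst_window_cv_ev``) the worst window.
    """
    spec = spec or DecoderSpec()
    prevalence = np.asarray(prevalence, dtype=float)
    feats = _features(tensor, spec)
    mask = (
        _unit_mask(tensor, classes, set(spec.neuron_classes_included))
        if classes is not None
        else np.ones(feats.shape[1], dtype=bool)
    )
    feats = feats[:, mask, :]
    n, n_units, n_win = feats.shape
    if n < spec.folds:
        raise ValueError(f"need at least {spec.folds} instances")
    # rows: window-major stacking of instances
    X_stack = np.vstack([feats[:, :, w] for w in range(n_win)])
    y_stack = np.tile(prevalence, n_win)
    kf = KFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    overall, per_window = [], []
    for train, test in kf.split(feats[:, :, 0]):
        rows_tr = np.concatenate([train + w * n for w in range(n_win)])
        model = _linear_fit(X_stack[rows_tr], y_stack[rows_tr])
        yhat_w = np.stack(
            [model.predict(feats[test][:, :, w]) for w in range(n_win)]
        )
        overall.append(
            explained_variance(
                np.tile(prevalence[test], n_win), yhat_w.ravel()
            )
        )
        per_window.append(
            [
                explained_variance(prevalence[test], yhat_w[w])
                for w in range(n_win)
            ]
        )
    cv = max(float(np.mean(overall)), 0.0)
    cv_w = np.clip(np.mean(per_window, axis=0), 0.0, None)
    model = _linear_fit(X_stack, y_stack)
    return DecoderFit(
        model_form=SHARED_WEIGHT,
        weights=np.asarray(model.coef_),
        bias=float(model.intercept_),
        cv_ev=cv,
        cv_ev_per_window=cv_w,
        unit_ids=tuple(np.asarray(tensor.unit_ids)[mask]),
    )


def exclude_class5_and_refit(
    tensor, classes, prevalence, spec: DecoderSpec | None = None
) -> DecoderFit:
    """Shared-weight fit restricted to neurons of classes 1-4.

    Removes the neurons that are themselves significant in all five windows,
    forcing the decoder to combine complementary neurons.
    """
    spec = spec or DecoderSpec()
    remaining = _unit_mask(tensor, classes, {1, 2, 3, 4}).sum()
    if remaining < spec.min_units:
        raise ValueError(
            f"only {remaining} units left after removing class-5 neurons "
            f"(need {spec.min_units})"
        )
    spec14 = DecoderSpec(
        model_form=SHARED_WEIGHT,
        folds=spec.folds,
        seed=spec.seed,
        alpha=spec.alpha,
        min_units=spec.min_units,
        sqrt_features=spec.sqrt_features,
        neuron_classes_included=(1, 2, 3, 4),
    )
    return fit_shared_weight_decoder(tensor, prevalence, spec14, classes=classes)


def fit_general_model(
    tensor, prevalence, spec: DecoderSpec | None = None
) -> DecoderFit:
    """The general model: one weight per (neuron, window) pair."""
    spec = spec or DecoderSpec()
    prevalence = np.asarray(prevalence, dtype=float)
    feats = _features(tensor, spec)
    n, n_units, n_win = feats.shape
    X = feats.reshape(n, n_units * n_win)
    cv = _cv_ev(X, prevalence, spec)
    model = _linear_fit(X, prevalence)
    return DecoderFit(
        model_form=GENERAL_IK,
        weights=np.asarray(model.coef_).reshape(n_units, n_win),
        bias=float(model.intercept_),
        cv_ev=cv,
        unit_ids=tuple(tensor.unit_ids),
    )


def prevalence_projection(tensor, decoder: DecoderFit, spec: DecoderSpec | None = None):
    """Two-axis projection of instance states for visualization.

    Axis 1 is the decoder weight vector (normalized); axis 2 is the leading
    principal axis of the residual variance, orthogonal to axis 1.  Returns
    ``(coords, axes)`` with ``coords`` instances x 2.
    """
    spec = spec or DecoderSpec()
    feats = _features(tensor, spec)
    n, n_units, n_win = feats.shape
    X = feats.reshape(n, n_units * n_win)
    if decoder.model_form == SHARED_WEIGHT:
        w = np.repeat(decoder.weights, n_win)
    else:
        w = np.asarray(decoder.weights).reshape(-1)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("zero-norm decoder weight vector; projection undefined")
    w = w / norm
    Xc = X - X.mean(axis=0)
    c1 = Xc @ w
    resid = Xc - np.outer(c1, w)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    axis2 = vt[0]
    coords = np.column_stack([c1, resid @ axis2])
    return coords, np.vstack([w, axis2])


def in_sample_evs(tensor, prevalence, spec: DecoderSpec | None = None) -> dict:
    """In-sample OLS EV of the three nested model families.

    Used to verify the nesting inequality shared <= per-window(k) <= general:
    returns ``{"general": ev, "per_window": (5,), "shared_per_window": (5,),
    "shared_overall": ev}``.
    """
    spec = spec or DecoderSpec()
    prevalence = np.asarray(prevalence, dtype=float)
    feats = _features(tensor, spec)
    n, n_units, n_win = feats.shape

    def ols_ev(X, y):
        Xd = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        return explained_variance(y, Xd @ beta)

    general = ols_ev(feats.reshape(n, -1), prevalence)
    per_window = np.array(
        [ols_ev(feats[:, :, w], prevalence) for w in range(n_win)]
    )
    X_stack = np.vstack([feats[:, :, w] for w in range(n_win)])
    y_stack = np.tile(prevalence, n_win)
    Xd = np.column_stack([np.ones(len(X_stack)), X_stack])
    beta, *_ = np.linalg.lstsq(Xd, y_stack, rcond=None)
    shared_overall = explained_variance(y_stack, Xd @ beta)
    shared_per_window = np.array(
        [
            explained_variance(
                prevalence,
                np.column_stack([np.ones(n), feats[:, :, w]]) @ beta,
            )
            for w in range(n_win)
        ]
    )
    return {
        "general": general,
        "per_window": per_window,
        "shared_per_window": shared_per_window,
        "shared_overall": shared_overall,
    }
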