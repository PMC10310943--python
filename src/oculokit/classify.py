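"""Ridge-regularized logistic classification of PD vs HC.

Six oculomotor parameters (fixation intrusion rate; short-eccentricity
first gain, mean velocity, mean latency and saccades-to-target; and the
large-eccentricity first gain error) feed a logistic regression with an L2
penalty, evaluated by repeated stratified random subsampling: per split,
features are standardized on the training fold, the model fit, and the
held-out subjects scored. The report carries the vertically-averaged ROC
curve, percentile confidence intervals over splits, and pooled
confusion-matrix sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import rankdata

__all__ = [
    "DEFAULT_FEATURES",
    "FeatureSpec",
    "ClassifierReport",
    "fit_ridge_logistic",
    "roc_auc",
    "subsample_evaluate",
]

DEFAULT_FEATURES = (
    "fix_intrusion_rate",
    "pro_short_first_gain",
    "pro_short_mean_velocity",
    "pro_short_latency",
    "pro_short_n_saccades",
    "pro_large_first_gain_error",
)


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered feature set plus the ridge strength and decision threshold."""

    names: tuple[str, ...] = DEFAULT_FEATURES
    ridge_strength: float = 1.0
    threshold: float = 0.5

    def matrix(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Complete-case feature matrix and binary labels (PD = 1)."""
        missing = [n for n in self.names if n not in table.columns]
        if missing:
            raise ValueError(f"feature column(s) not in table: {missing}")
        sub = table[list(self.names) + ["group"]].dropna()
        X = sub[list(self.names)].to_numpy(dtype=float)
        y = (sub["group"] == "PD").to_numpy(dtype=float)
        return X, y


@dataclass
class ClassifierReport:
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    tpr_lo: np.ndarray
    tpr_hi: np.ndarray
    auc_mean: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    confusion: dict[str, int] = field(default_factory=dict)
    n_subsamples: int = 0

    def to_dict(self) -> dict:
        return {
            "auc_mean": self.auc_mean,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "confusion": self.confusion,
            "n_subsamples": self.n_subsamples,
            "roc": {
                "fpr": self.fpr_grid.tolist(),
                "mean_tpr": self.mean_tpr.tolist(),
                "tpr_lo": self.tpr_lo.tolist(),
                "tpr_hi": self.tpr_hi.tolist(),
            },
        }


def fit_ridge_logistic(
    X: np.ndarray, y: np.ndarray, ridge_strength: float = 1.0
) -> tuple[np.ndarray, float]:
    """Fit logistic regression minimizing mean NLL + (λ/2)·||w||².

    The intercept is unpenalized. Features should be standardized so the
    isotropic penalty is meaningful. Returns (weights, intercept); the
    optimizer runs to a 1e-8 gradient tolerance, which the L2 penalty makes
    attainable even on separable data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes (0 and 1)")
    n, d = X.shape

    def objective(theta):
        w, b = theta[:d], theta[d]
        z = X @ w + b
        # log(1 + e^-|z|) + max(z,0) is the stable log(1+e^z)
        nll = np.mean(np.logaddexp(0.0, z) - y * z)
        p = 1.0 / (1.0 + np.exp(-z))
        grad_w = X.T @ (p - y) / n + ridge_strength * w
        grad_b = np.mean(p - y)
        return (
            nll + 0.5 * ridge_strength * w @ w,
            np.concatenate([grad_w, [grad_b]]),
        )

    res = minimize(
        objective,
        np.zeros(d + 1),
        jac=True,
        method="L-BFGS-B",
        options={"gtol": 1e-10, "ftol": 1e-14, "maxiter": 2000},
    )
    return res.x[:d], float(res.x[d])


def predict_proba(X: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.asarray(X, dtype=float) @ w + b)))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney pair statistic
    (ties count one half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _roc_curve(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR) sweeping the threshold from high to low."""
    order = np.argsort(-scores, kind="mergesort")
    y = y[order].astype(bool)
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return fpr, tpr


def subsample_evaluate(
    table: pd.DataFrame,
    spec: FeatureSpec | None = None,
    n_subsamples: int = 1000,
    split_fraction: float = 0.7,
    seed: int = 0,
) -> ClassifierReport:
    """Repeated stratified random-subsampling evaluation.

    For each subsample: stratified train/test split (``split_fraction`` of
    each class to train), per-feature standardization fit on the training
    fold only, ridge-logistic fit, held-out scoring. The mean ROC is the
    vertical average of per-split ROC curves on a fixed FPR grid; AUC and
    sensitivity/specificity CIs are the 2.5/97.5 percentiles over splits;
    the point sensitivity/specificity come from the pooled test confusion
    counts at the probability threshold.
    """
    spec = spec or FeatureSpec()
    X, y = spec.matrix(table)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 4 or n_neg < 4:
        raise ValueError("need at least 4 subjects per class")
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    k_pos = max(2, int(round(split_fraction * n_pos)))
    k_neg = max(2, int(round(split_fraction * n_neg)))
    k_pos = min(k_pos, n_pos - 1)
    k_neg = min(k_neg, n_neg - 1)

    grid = np.linspace(0.0, 1.0, 101)
    tprs = np.empty((n_subsamples, grid.size))
    aucs = np.empty(n_subsamples)
    sens = np.empty(n_subsamples)
    specs = np.empty(n_subsamples)
    tp = fp = tn = fn = 0

    for i in range(n_subsamples):
        tr = np.concatenate(
            [
                rng.choice(idx_pos, size=k_pos, replace=False),
                rng.choice(idx_neg, size=k_neg, replace=False),
            ]
        )
        te = np.setdiff1d(np.arange(y.size), tr)
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        w, b = fit_ridge_logistic(Xtr, y[tr], spec.ridge_strength)
        p = predict_proba(Xte, w, b)
        aucs[i] = roc_auc(p, y[te])
        fpr, tpr = _roc_curve(p, y[te])
        tprs[i] = np.interp(grid, fpr, tpr)
        pred = p >= spec.threshold
        yt = y[te].astype(bool)
        tp_i = int(np.sum(pred & yt))
        fn_i = int(np.sum(~pred & yt))
        tn_i = int(np.sum(~pred & ~yt))
        fp_i = int(np.sum(pred & ~yt))
        tp, fn, tn, fp = tp + tp_i, fn + fn_i, tn + tn_i, fp + fp_i
        sens[i] = tp_i / max(tp_i + fn_i, 1)
        specs[i] = tn_i / max(tn_i + fp_i, 1)

    mean_tpr = tprs.mean(axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return ClassifierReport(
        fpr_grid=grid,
        mean_tpr=mean_tpr,
        tpr_lo=np.percentile(tprs, 2.5, axis=0),
        tpr_hi=np.percentile(tprs, 97.5, axis=0),
        auc_mean=float(aucs.mean()),
        auc_ci=(float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))),
        sensitivity=tp / max(tp + fn, 1),
        sensitivity_ci=(
            float(np.percentile(sens, 2.5)),
            float(np.percentile(sens, 97.5)),
        ),
        specificity=tn / max(tn + fp, 1),
        specificity_ci=(
            float(np.percentile(specs, 2.5)),
            float(np.percentile(specs, 97.5)),
        ),
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        n_subsamples=n_subsamples,
    )
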