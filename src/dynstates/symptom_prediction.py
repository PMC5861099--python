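"""Binary symptom prediction from state-specific network strength.

Pipeline: per-edge Pearson correlation with the label selects positive and
negative edge sets (p <= 0.05, split by sign); a subject's "network
strength" is the sum of their z values over one set; strength plus
covariates enter an elastic-net logistic regression, evaluated with
leave-one-subject-out cross-validation (selection and fitting repeated
inside every fold), trapezoidal ROC/AUC, label-permutation tests, and
frozen-model holdout evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "EdgeFeatureSet",
    "ElasticNetLogisticModel",
    "RocResult",
    "select_edge_features",
    "network_strength",
    "predicted_probability",
    "fit_elastic_net_logistic",
    "fit_predict_loocv",
    "roc_auc",
    "permutation_auc_test",
    "train_model_bundle",
    "holdout_evaluate",
    "binarize_panss",
    "stratified_split",
]

DEFAULT_LAMBDA_GRID = np.logspace(-3, 1, 9)


@dataclass
class EdgeFeatureSet:
    state: str
    positive_edges: np.ndarray
    negative_edges: np.ndarray
    r: np.ndarray  # per-edge selection correlation (full edge vector)
    p: np.ndarray
    p_threshold: float = 0.05

    def edges(self, sign: str) -> np.ndarray:
        if sign == "positive":
            return self.positive_edges
        if sign == "negative":
            return self.negative_edges
        raise ValueError("sign must be 'positive' or 'negative'")


@dataclass
class ElasticNetLogisticModel:
    """Logistic weights on (network strength, covariates), raw scale."""

    beta0: float
    beta1: float
    gamma: np.ndarray
    alpha: float  # elastic-net mixing (1 = lasso, 0 = ridge)
    lam: float  # penalty strength
    state: str = ""
    sign: str = "positive"


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    p_value: float | None = None
    n_permutations: int = 0
    null_auc: np.ndarray = field(default_factory=lambda: np.empty(0))


def _pearson_with_label(X: np.ndarray, y: np.ndarray):
    """Vectorized per-column Pearson r with the label, plus two-sided t p-values."""
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    constant = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.where(constant, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(constant, 1.0, p)
    return r, p, constant


def select_edge_features(
    train_profiles: np.ndarray,
    labels,
    state: str = "",
    p_threshold: float = 0.05,
) -> EdgeFeatureSet:
    """Edges correlated with the binary label at p <= threshold, split by sign.

    Must be run on training subjects only; constant edges are excluded with
    a warning.
    """
    X = np.asarray(train_profiles, dtype=float)
    y = np.asarray(labels, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 3:
        raise ValueError("need >= 3 training subjects per class")
    r, p, constant = _pearson_with_label(X, y)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant edge(s) excluded from selection",
            stacklevel=2,
        )
    keep = (p <= p_threshold) & ~constant
    return EdgeFeatureSet(
        state=state,
        positive_edges=np.flatnonzero(keep & (r > 0)),
        negative_edges=np.flatnonzero(keep & (r < 0)),
        r=r,
        p=p,
        p_threshold=p_threshold,
    )


def network_strength(
    profile: np.ndarray, feature_set: EdgeFeatureSet, sign: str
) -> tuple[float, bool]:
    """Sum of the subject's z values over the chosen sign's edge set.

    Returns (strength, empty_flag); an empty set yields strength 0, flagged.
    """
    edges = feature_set.edges(sign)
    if len(edges) == 0:
        return 0.0, True
    profile = np.asarray(profile, dtype=float)
    if edges.max() >= profile.shape[-1]:
        raise ValueError("profile is missing selected edges")
    return float(profile[edges].sum()), False


def predicted_probability(
    model: ElasticNetLogisticModel, strength: float, covariates=None
) -> float:
    """p-hat = logistic(beta0 + beta1*s + gamma.c)."""
    c = np.zeros(0) if covariates is None else np.asarray(covariates, dtype=float)
    if len(c) != len(model.gamma):
        raise ValueError("covariate vector length does not match model")
    eta = model.beta0 + model.beta1 * strength + float(model.gamma @ c)
    if not np.isfinite(eta):
        raise ValueError("non-finite linear predictor")
    return float(expit(eta))


def _fit_raw(X, y, alpha, lam, max_iter=5000):
    n = len(y)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        C=1.0 / max(lam * n, 1e-12),
        max_iter=max_iter,
        tol=1e-6,
    )
    clf.fit(X, y)
    return clf


def fit_elastic_net_logistic(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lambda_grid: Sequence[float] | None = None,
    cv: int = 5,
    seed: int = 0,
    state: str = "",
    sign: str = "positive",
) -> ElasticNetLogisticModel:
    """Elastic-net logistic regression with lambda chosen by inner CV.

    Features are standardized internally; stored weights are transformed
    back to the raw feature scale, so ``predicted_probability`` applies them
    directly.  The intercept is unpenalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    n_min = int(np.bincount(y).min())
    n_splits = min(cv, n_min)
    if n_splits >= 2 and len(lambda_grid) > 1:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        losses = np.zeros(len(lambda_grid))
        for tr, te in skf.split(Xs, y):
            for i, lam in enumerate(lambda_grid):
                clf = _fit_raw(Xs[tr], y[tr], alpha, lam, max_iter=2000)
                prob = clf.predict_proba(Xs[te])[:, 1]
                losses[i] += log_loss(y[te], prob, labels=[0, 1])
        lam = float(lambda_grid[int(np.argmin(losses))])
    else:
        lam = float(lambda_grid[len(lambda_grid) // 2])

    clf = _fit_raw(Xs, y, alpha, lam)
    w_std = clf.coef_[0]
    b_std = float(clf.intercept_[0])
    w_raw = w_std / sd
    b_raw = b_std - float((w_std * mu / sd).sum())
    return ElasticNetLogisticModel(
        beta0=b_raw,
        beta1=float(w_raw[0]),
        gamma=w_raw[1:],
        alpha=alpha,
        lam=lam,
        state=state,
        sign=sign,
    )


def _feature_matrix(strengths: np.ndarray, covariates) -> np.ndarray:
    if covariates is None:
        return strengths[:, None]
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([strengths, C])


def fit_predict_loocv(
    profiles: np.ndarray,
    labels,
    covariates=None,
    state: str = "",
    sign: str = "positive",
    p_threshold: float = 0.05,
    alpha: float = 0.5,
    lambda_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Held-out probability per subject via leave-one-subject-out CV.

    Edge selection and model fitting are repeated inside every fold using
    only the n-1 training subjects, so no information leaks to the held-out
    subject.
    """
    X = np.asarray(profiles, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    probs = np.empty(n)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("a LOOCV fold lost an entire class")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs = select_edge_features(X[tr], y_tr, state=state, p_threshold=p_threshold)
        s_tr = np.array([network_strength(X[j], fs, sign)[0] for j in tr])
        model = fit_elastic_net_logistic(
            _feature_matrix(s_tr, None if cov is None else cov[tr]),
            y_tr,
            alpha=alpha,
            lambda_grid=lambda_grid,
            seed=seed,
            state=state,
            sign=sign,
        )
        s_i, _ = network_strength(X[i], fs, sign)
        probs[i] = predicted_probability(
            model, s_i, None if cov is None else cov[i]
        )
    return probs


def roc_auc(scores, labels) -> RocResult:
    """ROC curve over unique thresholds; AUC by trapezoidal integration.

    Equals the tie-adjusted concordance probability
    P(score_pos > score_neg) + 0.5 P(equal).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    thresholds = np.unique(s)[::-1]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred = s >= thr
        sens[i] = (pred & (y == 1)).sum() / n_pos
        spec[i] = (~pred & (y == 0)).sum() / n_neg
    fpr = np.concatenate([[0.0], 1 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc
    )


def permutation_auc_test(
    score_fn: Callable[[np.ndarray], np.ndarray],
    labels,
    n_permutations: int = 5000,
    seed: int = 0,
    observed_auc: float | None = None,
) -> tuple[float, np.ndarray]:
    """Label-permutation AUC test; the full pipeline reruns per permutation.

    ``score_fn`` maps a label vector to subject scores (e.g. the LOOCV
    pipeline).  p uses the add-one formula.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(labels, dtype=int)
    if observed_auc is None:
        observed_auc = roc_auc(score_fn(y), y).auc
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        null[b] = roc_auc(score_fn(yp), yp).auc
    p = (1 + int(np.sum(null >= observed_auc))) / (1 + n_permutations)
    return float(p), null


@dataclass
class ModelBundle:
    """Frozen feature set + weights for one (state, sign) model."""

    feature_set: EdgeFeatureSet
    model: ElasticNetLogisticModel


def train_model_bundle(
    profiles: np.ndarray,
    labels,
    covariates=None,
    state: str = "",
    sign: str = "positive",
    p_threshold: float = 0.05,
    alpha: float = 0.5,
    lambda_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Select edges and fit the final model on the full training set."""
    X = np.asarray(profiles, dtype=float)
    y = np.asarray(labels, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs = select_edge_features(X, y, state=state, p_threshold=p_threshold)
    s = np.array([network_strength(x, fs, sign)[0] for x in X])
    model = fit_elastic_net_logistic(
        _feature_matrix(s, covariates),
        y,
        alpha=alpha,
        lambda_grid=lambda_grid,
        seed=seed,
        state=state,
        sign=sign,
    )
    return ModelBundle(feature_set=fs, model=model)


def holdout_evaluate(
    bundle: ModelBundle,
    holdout_profiles: np.ndarray,
    holdout_labels,
    holdout_covariates=None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RocResult:
    """Apply frozen feature sets and weights to unseen subjects.

    The permutation null permutes holdout labels only; the model is never
    refit.
    """
    X = np.asarray(holdout_profiles, dtype=float)
    y = np.asarray(holdout_labels, dtype=int)
    cov = (
        None
        if holdout_covariates is None
        else np.asarray(holdout_covariates, dtype=float)
    )
    scores = np.array(
        [
            predicted_probability(
                bundle.model,
                network_strength(x, bundle.feature_set, bundle.model.sign)[0],
                None if cov is None else cov[i],
            )
            for i, x in enumerate(X)
        ]
    )
    result = roc_auc(scores, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        null[b] = roc_auc(scores, yp).auc
    result.p_value = (1 + int(np.sum(null >= result.auc))) / (1 + n_permutations)
    result.n_permutations = n_permutations
    result.null_auc = null
    return result


def binarize_panss(
    scores, subscale_mean: float, subscale_sd: float
) -> tuple[np.ndarray, float]:
    """Binarize at mean - 1 SD: below the cutoff is low (0), at/above is high (1)."""
    if subscale_sd <= 0:
        raise ValueError("subscale SD must be positive")
    # round away float representation error so a score printed equal to the
    # cutoff (e.g. 11.95 = 18.46 - 6.51) lands on the "high" side
    cutoff = round(subscale_mean - subscale_sd, 10)
    scores = np.asarray(scores, dtype=float)
    return (scores >= cutoff).astype(int), float(cutoff)


def stratified_split(
    labels, test_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified shuffle split; returns (train_idx, test_idx).

    The total test count is round(n * test_fraction); per-class counts are
    allocated by largest remainder so the overall split is exact (130
    subjects at 70/30 give 91 train / 39 test).
    """
    y = np.asarray(labels)
    n = len(y)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(round(n * test_fraction))
    classes = np.unique(y)
    exact = {c: (y == c).sum() * test_fraction for c in classes}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    remainder = sorted(classes, key=lambda c: exact[c] - counts[c], reverse=True)
    i = 0
    while sum(counts.values()) < n_test:
        counts[remainder[i % len(remainder)]] += 1
        i += 1
    rng = np.random.default_rng(seed)
    test_idx = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        test_idx.extend(idx[: counts[c]])
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx
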