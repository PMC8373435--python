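"""Classifiers and evaluation: LDA, RBF-SVM, leave-one-participant-out
cross-validation (LOPO-CV), SVM grid search, and sequential forward
selection (SFS).

LDA is implemented in closed form with class means, pooled covariance, and
an optional penalty/prior log-odds term; scalar (Ledoit–Wolf) shrinkage
toward the identity is applied automatically when the pooled covariance is
ill-conditioned. The SVM is the standard soft-margin RBF machine (libsvm via
scikit-learn) wrapped with a fixed label convention so the decision-function
sign is deterministic.

Accuracy is always the LOPO-CV participant-level accuracy: one fold per
participant, accuracy = correctly classified / total, so its granularity is
1/N (e.g. one misclassification at N = 50 moves the error rate by exactly
2 %).
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence

import numpy as np
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.svm import SVC


class ClassificationError(ValueError):
    """Invalid input to a classifier or evaluation routine."""


def _check_binary(y: np.ndarray) -> tuple:
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ClassificationError(
            f"need exactly two classes, got {len(classes)}: {classes}"
        )
    return tuple(classes)


def _positive_negative(classes: tuple, positive) -> tuple:
    if positive is None:
        positive = classes[-1]
    if positive not in classes:
        raise ClassificationError(f"positive label {positive!r} not among {classes}")
    negative = classes[0] if classes[1] == positive else classes[1]
    return positive, negative


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

#: Condition number above which scalar shrinkage of the pooled covariance
#: is applied automatically.
COND_THRESHOLD = 1e8


@dataclasses.dataclass
class LDAModel:
    """Closed-form linear discriminant.

    The signed score of a test point x is

        w' x − ½ w' (μ_P + μ_N) − ln(C_P π_N / (C_N π_P)),   w = Σ⁻¹ (μ_P − μ_N)

    with μ the class means, Σ the (possibly shrunk) pooled covariance,
    C the per-class penalty weights (equal by default, so the penalty part
    of the log term vanishes), and π the class priors. Positive score →
    positive class.
    """

    positive: object
    negative: object
    mu_p: np.ndarray
    mu_n: np.ndarray
    cov: np.ndarray
    priors: tuple[float, float]     # (π_P, π_N)
    penalties: tuple[float, float]  # (C_P, C_N)
    shrinkage: float                # scalar shrinkage actually applied

    def __post_init__(self) -> None:
        diff = self.mu_p - self.mu_n
        w = np.linalg.solve(self.cov, diff)
        pi_p, pi_n = self.priors
        c_p, c_n = self.penalties
        self._w = w
        self._threshold = 0.5 * w @ (self.mu_p + self.mu_n) + np.log(
            (c_p * pi_n) / (c_n * pi_p)
        )


def lda_fit(
    X: np.ndarray,
    y: Sequence,
    *,
    positive=None,
    priors: str | tuple[float, float] = "empirical",
    penalties: tuple[float, float] = (1.0, 1.0),
    shrinkage: str | float = "auto",
) -> LDAModel:
    """Fit the closed-form LDA.

    ``priors`` is ``"empirical"`` (training frequencies), ``"equal"``, or an
    explicit (π_P, π_N) pair. ``shrinkage="auto"`` applies Ledoit–Wolf scalar
    shrinkage toward a scaled identity only when the pooled covariance has a
    condition number above ``COND_THRESHOLD``; ``shrinkage=0`` disables it
    and raises on singular covariances.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ClassificationError("X must be 2-D (participants x features)")
    y = np.asarray(list(y))
    classes = _check_binary(y)
    pos, neg = _positive_negative(classes, positive)
    Xp, Xn = X[y == pos], X[y == neg]
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    centered = np.vstack([Xp - mu_p, Xn - mu_n])
    n, d = X.shape
    denom = max(n - 2, 1)
    cov = centered.T @ centered / denom
    cov = np.atleast_2d(cov)

    lam = 0.0
    cond = np.linalg.cond(cov)
    if shrinkage == "auto":
        if not np.isfinite(cond) or cond > COND_THRESHOLD:
            lam = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
            lam = max(lam, 1e-4)
    elif float(shrinkage) > 0:
        lam = float(shrinkage)
    if lam > 0:
        mu = np.trace(cov) / d
        cov = (1 - lam) * cov + lam * mu * np.eye(d)
    elif not np.isfinite(cond) or cond > 1e12:
        raise ClassificationError(
            "pooled covariance is singular; enable shrinkage (shrinkage='auto')"
        )

    if priors == "empirical":
        pri = (len(Xp) / n, len(Xn) / n)
    elif priors == "equal":
        pri = (0.5, 0.5)
    else:
        pri = (float(priors[0]), float(priors[1]))
    if not (pri[0] > 0 and pri[1] > 0):
        raise ClassificationError("priors must be positive")
    return LDAModel(
        positive=pos, negative=neg, mu_p=mu_p, mu_n=mu_n, cov=cov,
        priors=pri, penalties=(float(penalties[0]), float(penalties[1])),
        shrinkage=lam,
    )


def lda_decide(model: LDAModel, X: np.ndarray) -> np.ndarray | float:
    """Signed LDA score(s); > 0 predicts the positive class."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    scores = np.atleast_2d(X) @ model._w - model._threshold
    return float(scores[0]) if single else scores


def lda_predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    scores = np.atleast_1d(lda_decide(model, np.atleast_2d(X)))
    return np.where(scores > 0, model.positive, model.negative)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SVMModel:
    """Soft-margin RBF SVM with a fixed ±1 label convention.

    The decision function is the kernel expansion over support vectors,
    Σ α_i y_i K(x_i, x) + b with K(x_i, x) = exp(−γ‖x_i − x‖²); positive
    score → positive class.
    """

    positive: object
    negative: object
    C: float
    gamma: float
    svc: SVC

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        """α_i y_i for the support vectors."""
        return self.svc.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])


def svm_fit(
    X: np.ndarray,
    y: Sequence,
    C: float = 1.0,
    gamma: float = 1.0,
    *,
    positive=None,
    tol: float = 1e-6,
) -> SVMModel:
    """Fit a soft-margin RBF SVM (labels mapped to ±1, positive class +1)."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ClassificationError("features contain non-finite values")
    if not (C > 0 and gamma > 0):
        raise ClassificationError(f"C and gamma must be positive, got ({C}, {gamma})")
    y = np.asarray(list(y))
    classes = _check_binary(y)
    pos, neg = _positive_negative(classes, positive)
    y_signed = np.where(y == pos, 1, -1)
    svc = SVC(C=C, gamma=gamma, kernel="rbf", tol=tol)
    svc.fit(X, y_signed)
    return SVMModel(positive=pos, negative=neg, C=C, gamma=gamma, svc=svc)


def svm_decide(model: SVMModel, X: np.ndarray) -> np.ndarray | float:
    """Signed SVM score(s); > 0 predicts the positive class."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    scores = model.svc.decision_function(np.atleast_2d(X))
    return float(scores[0]) if single else scores


def svm_predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    scores = np.atleast_1d(svm_decide(model, np.atleast_2d(X)))
    return np.where(scores > 0, model.positive, model.negative)


# ---------------------------------------------------------------------------
# Parameter grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ParamGrid:
    """Ordered (C, γ) candidate lists for the SVM grid search."""

    Cs: tuple[float, ...]
    gammas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.Cs or not self.gammas:
            raise ClassificationError("parameter grid must be non-empty")
        if min(self.Cs) <= 0 or min(self.gammas) <= 0:
            raise ClassificationError("all grid values must be positive")

    def __len__(self) -> int:
        return len(self.Cs) * len(self.gammas)

    def points(self):
        """Iterate (C, γ) with C ascending, then γ ascending."""
        return itertools.product(sorted(self.Cs), sorted(self.gammas))

    @classmethod
    def from_exponents(cls, exponents: Sequence[int]) -> "ParamGrid":
        vals = tuple(2.0 ** e for e in exponents)
        return cls(Cs=vals, gammas=vals)

    @classmethod
    def default(cls) -> "ParamGrid":
        """Odd powers of two from 2⁻²⁹ to 2²⁹ for both C and γ (30 × 30)."""
        return cls.from_exponents(range(-29, 30, 2))

    @classmethod
    def small(cls) -> "ParamGrid":
        """Reduced grid (odd exponents −9…9, 10 × 10) for desk-scale runs."""
        return cls.from_exponents(range(-9, 10, 2))


# ---------------------------------------------------------------------------
# LOPO-CV
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CVResult:
    """Per-fold LOPO-CV outcomes; accuracy = correct / total."""

    folds: tuple[tuple[object, object, object], ...]  # (participant, true, predicted)

    @property
    def accuracy(self) -> float:
        correct = sum(1 for _, t, p in self.folds if t == p)
        return correct / len(self.folds)

    @property
    def n(self) -> int:
        return len(self.folds)


def _fit_predict(classifier: str, params, Xtr, ytr, Xte, positive):
    if classifier == "lda":
        kwargs = dict(params or {})
        model = lda_fit(Xtr, ytr, positive=positive, **kwargs)
        return lda_predict(model, Xte)
    if classifier == "svm":
        params = params or {}
        model = svm_fit(
            Xtr, ytr,
            C=params.get("C", 1.0), gamma=params.get("gamma", 1.0),
            positive=positive,
        )
        return svm_predict(model, Xte)
    raise ClassificationError(f"unknown classifier {classifier!r}")


def lopo_cv(
    X: np.ndarray,
    y: Sequence,
    classifier: str = "lda",
    *,
    params: dict | None = None,
    std_mode: str = "global",
    hc_mask: Sequence[bool] | None = None,
    participant_ids: Sequence | None = None,
    positive=None,
) -> CVResult:
    """Leave-one-participant-out cross-validation.

    One fold per participant. With ``std_mode="fold-train"``, each feature
    column is re-standardized per fold using only the healthy controls in
    that fold's training set (``hc_mask`` flags the HC rows); the default
    ``"global"`` mode uses ``X`` as given (matching a cohort-wide
    standardization performed beforehand).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(list(y))
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ClassificationError("X must be (participants x features) matching y")
    n = X.shape[0]
    if n < 3:
        raise ClassificationError("LOPO-CV needs at least 3 participants")
    classes = _check_binary(y)
    for c in classes:
        if np.sum(y == c) < 2:
            raise ClassificationError(f"class {c!r} needs at least 2 members")
    if std_mode not in ("global", "fold-train"):
        raise ClassificationError(f"unknown std_mode {std_mode!r}")
    if std_mode == "fold-train":
        if hc_mask is None:
            raise ClassificationError("fold-train standardization needs hc_mask")
        hc_mask = np.asarray(hc_mask, dtype=bool)
        if hc_mask.shape != (n,):
            raise ClassificationError("hc_mask must have one flag per participant")
    ids = list(participant_ids) if participant_ids is not None else list(range(n))

    folds = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        ytr = y[train]
        if len(set(ytr.tolist())) < 2:
            raise ClassificationError(
                f"training set of fold {ids[i]!r} contains a single class"
            )
        Xtr, Xte = X[train], X[~train]
        if std_mode == "fold-train":
            ref = Xtr[hc_mask[train]]
            if ref.shape[0] < 2:
                raise ClassificationError(
                    f"fold {ids[i]!r}: fewer than 2 training HCs for standardization"
                )
            mu = ref.mean(axis=0)
            sd = ref.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ClassificationError(
                    f"fold {ids[i]!r}: zero HC standard deviation in a feature"
                )
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        pred = _fit_predict(classifier, params, Xtr, ytr, Xte, positive)
        folds.append((ids[i], y[i], np.atleast_1d(pred)[0]))
    return CVResult(folds=tuple(folds))


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GridSearchResult:
    C: float
    gamma: float
    accuracy: float


def grid_search_svm(
    X: np.ndarray,
    y: Sequence,
    grid: ParamGrid | None = None,
    **lopo_kwargs,
) -> GridSearchResult:
    """Exhaustive LOPO-CV over the (C, γ) grid.

    Returns the argmax accuracy; ties are broken toward the smallest C, then
    the smallest γ (the grid is scanned in that order with a strict
    improvement rule).
    """
    grid = grid or ParamGrid.default()
    best: GridSearchResult | None = None
    for C, gamma in grid.points():
        acc = lopo_cv(
            X, y, "svm", params={"C": C, "gamma": gamma}, **lopo_kwargs
        ).accuracy
        if best is None or acc > best.accuracy:
            best = GridSearchResult(C=C, gamma=gamma, accuracy=acc)
        if best.accuracy == 1.0:  # cannot be improved; strict > keeps ties fixed
            break
    return best


# ---------------------------------------------------------------------------
# Sequential forward selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SFSTrace:
    """Result of a greedy forward-selection run.

    ``order`` is the full ranking of the feature indices (a permutation of
    0…N_s−1); ``step_scores[k]`` is the LOPO-CV accuracy of the prefix of
    length k+1. ``best_subset`` is the shortest prefix achieving the maximum
    score.
    """

    order: tuple[int, ...]
    step_scores: tuple[float, ...]
    best_subset: tuple[int, ...]
    best_score: float
    params: tuple[float, float] | None = None  # (C, γ) for SVM
    feature_names: tuple[str, ...] | None = None

    @property
    def best_feature_names(self) -> tuple[str, ...] | None:
        if self.feature_names is None:
            return None
        return tuple(self.feature_names[i] for i in self.best_subset)


def _greedy_chain(n_features: int, score_subset) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Greedy forward chain; candidate ties resolve to the lowest feature
    index (features are presented in montage region order)."""
    chain: list[int] = []
    scores: list[float] = []
    remaining = list(range(n_features))
    while remaining:
        best_f, best_acc = None, -np.inf
        for f in remaining:  # ascending index order -> deterministic ties
            acc = score_subset(tuple(chain + [f]))
            if acc > best_acc:
                best_f, best_acc = f, acc
        chain.append(best_f)
        remaining.remove(best_f)
        scores.append(best_acc)
    return tuple(chain), tuple(scores)


def _best_prefix(scores: Sequence[float]) -> tuple[int, float]:
    best_k = int(np.argmax(scores))  # first occurrence -> shortest prefix
    return best_k, float(scores[best_k])


def sfs_select(
    X: np.ndarray,
    y: Sequence,
    classifier: str = "lda",
    *,
    grid: ParamGrid | None = None,
    feature_names: Sequence[str] | None = None,
    **lopo_kwargs,
) -> SFSTrace:
    """Sequential forward selection scored by LOPO-CV accuracy.

    For LDA a single greedy chain is built. For the SVM, feature selection
    and hyperparameter search are carried out together: a full greedy chain
    is built for every grid point (C, γ), and the global argmax of accuracy
    over (grid point, prefix length) determines both the selected subset and
    the hyperparameters. Ties prefer smaller C, then smaller γ, then the
    shorter prefix.
    """
    X = np.asarray(X, dtype=np.float64)
    n_features = X.shape[1]
    if n_features < 1:
        raise ClassificationError("need at least one candidate feature")
    names = tuple(feature_names) if feature_names is not None else None
    if names is not None and len(names) != n_features:
        raise ClassificationError("feature_names must match the feature count")

    if classifier == "lda":
        def score_subset(subset: tuple[int, ...]) -> float:
            return lopo_cv(X[:, subset], y, "lda", **lopo_kwargs).accuracy

        order, scores = _greedy_chain(n_features, score_subset)
        k, best = _best_prefix(scores)
        return SFSTrace(
            order=order, step_scores=scores,
            best_subset=order[: k + 1], best_score=best,
            params=None, feature_names=names,
        )

    if classifier != "svm":
        raise ClassificationError(f"unknown classifier {classifier!r}")

    grid = grid or ParamGrid.default()
    best_trace: SFSTrace | None = None
    for C, gamma in grid.points():
        def score_subset(subset: tuple[int, ...], _C=C, _g=gamma) -> float:
            return lopo_cv(
                X[:, subset], y, "svm", params={"C": _C, "gamma": _g}, **lopo_kwargs
            ).accuracy

        order, scores = _greedy_chain(n_features, score_subset)
        k, best = _best_prefix(scores)
        if best_trace is None or best > best_trace.best_score:
            best_trace = SFSTrace(
                order=order, step_scores=scores,
                best_subset=order[: k + 1], best_score=best,
                params=(C, gamma), feature_names=names,
            )
        if best_trace.best_score == 1.0:  # unbeatable under strict >
            break
    return best_trace
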