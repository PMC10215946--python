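"""SVM-wrapper feature selection with whale-optimization search.

The wrapper cost of a candidate feature subset is

    fitness = α·(1 − acc_cv/100) + (1 − α)·(n_selected / D)

where acc_cv is the stratified k-fold cross-validated accuracy (percent) of
a linear SVM trained on the masked columns, α = 0.99 by default, and D the
total feature count.  Fold assignment is fixed per run seed, so the cost is
a deterministic function of the mask — identical masks are cached.

``EWOAFeatureSelector`` and ``WOAFeatureSelector`` are sklearn-compatible
SelectorMixin estimators: ``fit(X, y)`` runs the binary optimizer on the
training matrix, after which ``support_`` / ``get_support()`` expose the
selected subset and ``transform`` masks columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .optim import SelectionMask, binary_ewoa_optimize, binary_woa_optimize

__all__ = [
    "FitnessRecord",
    "SVMWrapperCost",
    "wrapper_cost",
    "EWOAFeatureSelector",
    "WOAFeatureSelector",
    "mask_to_tsv",
    "trace_to_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitnessRecord:
    """Wrapper evaluation of one feature subset."""

    mask: SelectionMask
    cv_accuracy: float  # percent
    selected_count: int
    fitness: float


class SVMWrapperCost:
    """Deterministic, cached SVM-wrapper cost over feature masks.

    Folds are drawn once from ``seed`` (stratified, shuffled) and reused for
    every mask, so the cost is a pure function of the mask.  If a fold draw
    ever misses a class the folds are redrawn with a warning.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        alpha: float = 0.99,
        cv: int = 5,
        svm_c: float = 1.0,
        seed: int = 0,
    ):
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y))
        self.X, self.y = X, y
        self.alpha = float(alpha)
        self.cv = int(cv)
        self.svm_c = float(svm_c)
        self.n_features = X.shape[1]
        self._cache: dict[bytes, FitnessRecord] = {}
        self.n_evaluations = 0
        self._folds = self._draw_folds(seed)

    def _draw_folds(self, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
        classes = np.unique(self.y)
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=seed + attempt)
            folds = list(skf.split(self.X, self.y))
            ok = all(
                len(np.intersect1d(classes, self.y[tr])) == classes.size
                for tr, _ in folds
            )
            if ok:
                if attempt:
                    logger.warning("redrew CV folds %d time(s): fold missing a class", attempt)
                return folds
        raise ValueError("could not draw stratified folds containing every class")

    def cv_accuracy(self, mask: SelectionMask) -> float:
        cols = mask.indices()
        correct = 0
        for train_idx, test_idx in self._folds:
            clf = SVC(kernel="linear", C=self.svm_c)
            clf.fit(self.X[np.ix_(train_idx, cols)], self.y[train_idx])
            pred = clf.predict(self.X[np.ix_(test_idx, cols)])
            correct += int((pred == self.y[test_idx]).sum())
        return 100.0 * correct / self.y.size

    def __call__(self, mask: SelectionMask) -> FitnessRecord:
        key = mask.key()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        acc = self.cv_accuracy(mask)
        fitness = self.alpha * (1.0 - acc / 100.0) + (1.0 - self.alpha) * (
            mask.selected_count / self.n_features
        )
        record = FitnessRecord(
            mask=mask,
            cv_accuracy=acc,
            selected_count=mask.selected_count,
            fitness=fitness,
        )
        self._cache[key] = record
        self.n_evaluations += 1
        return record


def wrapper_cost(
    mask: SelectionMask | np.ndarray,
    X_train: np.ndarray,
    y_train: np.ndarray,
    *,
    alpha: float = 0.99,
    cv: int = 5,
    svm_c: float = 1.0,
    seed: int = 0,
) -> FitnessRecord:
    """One-off wrapper evaluation of a mask on a training split."""
    if not isinstance(mask, SelectionMask):
        mask = SelectionMask(np.asarray(mask, dtype=bool))
    return SVMWrapperCost(X_train, y_train, alpha, cv, svm_c, seed)(mask)


class _BaseWhaleSelector(SelectorMixin, BaseEstimator):
    """Shared fit logic for the WOA-family wrapper selectors."""

    def __init__(
        self,
        n_whales: int = 10,
        max_iter: int = 50,
        alpha: float = 0.99,
        cv: int = 5,
        svm_c: float = 1.0,
        transfer: str = "sigmoid",
        threshold: float = 0.5,
        random_state: int | None = None,
    ):
        self.n_whales = n_whales
        self.max_iter = max_iter
        self.alpha = alpha
        self.cv = cv
        self.svm_c = svm_c
        self.transfer = transfer
        self.threshold = threshold
        self.random_state = random_state

    def _optimize(self, cost, dimension: int, seed: int):  # pragma: no cover
        raise NotImplementedError

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaseWhaleSelector":
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y))
        seed = 0 if self.random_state is None else int(self.random_state)
        cost = SVMWrapperCost(
            X, y, alpha=self.alpha, cv=self.cv, svm_c=self.svm_c, seed=seed
        )
        mask, record, history = self._optimize(cost, X.shape[1], seed)
        self.n_features_in_ = X.shape[1]
        self.support_ = mask.bits.copy()
        self.mask_ = mask
        self.record_ = record
        self.best_fitness_ = record.fitness
        self.cv_accuracy_ = record.cv_accuracy
        self.n_features_selected_ = record.selected_count
        self.history_ = history
        self.n_cost_evaluations_ = cost.n_evaluations
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class EWOAFeatureSelector(_BaseWhaleSelector):
    """Binary enhanced-WOA wrapper feature selection (linear-SVM cost).

    Parameters mirror the study protocol defaults: 10 whales, 50
    iterations, pool of 20 candidates, 20% migration, α = 0.99.
    """

    def __init__(
        self,
        n_whales: int = 10,
        max_iter: int = 50,
        pool_size: int = 20,
        migration_rate: float = 0.2,
        radius: float = 0.1,
        alpha: float = 0.99,
        cv: int = 5,
        svm_c: float = 1.0,
        transfer: str = "sigmoid",
        threshold: float = 0.5,
        random_state: int | None = None,
    ):
        super().__init__(
            n_whales=n_whales,
            max_iter=max_iter,
            alpha=alpha,
            cv=cv,
            svm_c=svm_c,
            transfer=transfer,
            threshold=threshold,
            random_state=random_state,
        )
        self.pool_size = pool_size
        self.migration_rate = migration_rate
        self.radius = radius

    def _optimize(self, cost, dimension: int, seed: int):
        return binary_ewoa_optimize(
            dimension,
            cost,
            n_whales=self.n_whales,
            max_iter=self.max_iter,
            pool_size=self.pool_size,
            migration_rate=self.migration_rate,
            radius=self.radius,
            transfer=self.transfer,
            threshold=self.threshold,
            seed=seed,
        )


class WOAFeatureSelector(_BaseWhaleSelector):
    """Conventional binary WOA wrapper feature selection (baseline)."""

    def _optimize(self, cost, dimension: int, seed: int):
        return binary_woa_optimize(
            dimension,
            cost,
            n_whales=self.n_whales,
            max_iter=self.max_iter,
            transfer=self.transfer,
            threshold=self.threshold,
            seed=seed,
        )


def mask_to_tsv(mask: SelectionMask, provenance, path) -> None:
    """Write a selection mask as delimited text: one feature per row."""
    with open(path, "w") as fh:
        fh.write("modality\tchannel\tstatistic\tselected\n")
        for (modality, channel, stat), bit in zip(provenance, mask.bits):
            fh.write(f"{modality}\t{channel}\t{stat}\t{int(bit)}\n")


def trace_to_tsv(history, path) -> None:
    """Write an optimizer best-so-far fitness trace as delimited text."""
    with open(path, "w") as fh:
        fh.write("iteration\tbest_fitness\n")
        for i, f in enumerate(history, start=1):
            fh.write(f"{i}\t{f!r}\n")
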