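"""Evaluation protocol: 80/20 splits, repeated runs, method comparison.

Each run draws a fresh stratified 80/20 train/test split, fits per-modality
min–max normalization on the training rows only, runs feature selection on
the training split, refits a linear SVM on the masked training data, and
scores accuracy on the held-out 20%.  No information from the test rows
reaches normalization, selection, or training.  Per-run accuracies and
selected-feature counts are summarized as mean ± std, and two methods are
compared with a two-sample t-test (Welch by default) on their per-run
accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .features import extract_features, fuse_features, normalize_per_modality
from .optim import SelectionMask
from .preprocessing import preprocess_eeg, preprocess_fnirs
from .simulate import GroundTruth, MultimodalTrialSet

__all__ = [
    "RunSummary",
    "svm_train",
    "svm_decide",
    "classification_accuracy",
    "run_experiment",
    "compare_methods",
]

METHODS = ("none", "woa", "ewoa")


def svm_train(X: np.ndarray, y: np.ndarray, svm_c: float = 1.0) -> SVC:
    """Fit the linear maximum-margin classifier f(x) = w·x + b."""
    return SVC(kernel="linear", C=svm_c).fit(np.asarray(X, dtype=float), y)


def svm_decide(model: SVC, x: np.ndarray) -> np.ndarray:
    """Predicted class labels for one or more feature vectors."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return model.predict(x)


def classification_accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Percent of correctly classified trials."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if true.size == 0:
        raise ValueError("cannot compute accuracy of an empty label set")
    if predicted.shape != true.shape:
        raise ValueError("predicted and true labels differ in length")
    return 100.0 * float((predicted == true).sum()) / true.size


@dataclass
class RunSummary:
    """Per-run accuracies and feature counts with summary statistics."""

    method: str
    accuracies: np.ndarray  # percent, one per run
    feature_counts: np.ndarray
    masks: list[SelectionMask] = field(default_factory=list)
    run_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        self.feature_counts = np.asarray(self.feature_counts, dtype=float)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.accuracies.size > 1 else 0.0

    @property
    def mean_feature_count(self) -> float:
        return float(self.feature_counts.mean())

    @property
    def std_feature_count(self) -> float:
        return (
            float(self.feature_counts.std(ddof=1))
            if self.feature_counts.size > 1
            else 0.0
        )

    def recall_of(self, informative: np.ndarray) -> np.ndarray:
        """Per-run recall of a planted informative-feature index set."""
        informative = np.asarray(informative, dtype=int)
        if not self.masks:
            raise ValueError("no masks recorded (baseline method)")
        return np.array(
            [m.bits[informative].mean() for m in self.masks], dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "run": np.arange(self.accuracies.size),
                "accuracy_percent": self.accuracies,
                "n_features": self.feature_counts,
            }
        )
        summary = pd.DataFrame(
            {
                "run": ["mean", "std"],
                "accuracy_percent": [self.mean_accuracy, self.std_accuracy],
                "n_features": [self.mean_feature_count, self.std_feature_count],
            }
        )
        return pd.concat([df, summary], ignore_index=True)


def _make_selector(method: str, optimizer_cfg: dict, wrapper_cfg: dict, seed: int):
    from .selection import EWOAFeatureSelector, WOAFeatureSelector

    common = dict(
        n_whales=optimizer_cfg.get("n_whales", 10),
        max_iter=optimizer_cfg.get("max_iter", 50),
        transfer=optimizer_cfg.get("transfer", "sigmoid"),
        threshold=optimizer_cfg.get("threshold", 0.5),
        alpha=wrapper_cfg.get("alpha", 0.99),
        cv=wrapper_cfg.get("cv_folds", 5),
        svm_c=wrapper_cfg.get("svm_c", 1.0),
        random_state=seed,
    )
    if method == "ewoa":
        return EWOAFeatureSelector(
            pool_size=optimizer_cfg.get("pool_size", 20),
            migration_rate=optimizer_cfg.get("migration_rate", 0.2),
            radius=optimizer_cfg.get("neighborhood_radius", 0.1),
            **common,
        )
    if method == "woa":
        return WOAFeatureSelector(**common)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_experiment(
    trialset: MultimodalTrialSet,
    method: str = "ewoa",
    *,
    n_runs: int = 10,
    seed: int = 0,
    train_fraction: float = 0.8,
    optimizer: dict | None = None,
    wrapper: dict | None = None,
    preprocess: bool = True,
    resplit: bool = True,
    leaky_normalization: bool = False,
    shuffle_labels: bool = False,
) -> RunSummary:
    """Repeated stratified 80/20 evaluation of one selection method.

    ``method`` is "ewoa", "woa", or "none" (all features, no selection).
    With ``resplit`` (default) every run draws a fresh split; otherwise the
    split is fixed and only the optimizer is re-seeded.
    ``leaky_normalization`` fits the min–max scaling on all trials instead
    of the training rows only (for studying that protocol flaw).
    ``shuffle_labels`` permutes labels once (null-calibration checks).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    optimizer = dict(optimizer or {})
    wrapper = dict(wrapper or {})

    ts = trialset
    if preprocess:
        ts = preprocess_fnirs(preprocess_eeg(ts))
    fnirs_fm, eeg_fm = extract_features(ts)
    labels = ts.labels.copy()

    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_runs + 1)]
    if shuffle_labels:
        labels = np.random.default_rng(run_seeds[-1]).permutation(labels)

    n_trials = labels.size
    all_rows = np.arange(n_trials)
    fixed_split = None
    if not resplit:
        fixed_split = train_test_split(
            all_rows,
            test_size=1.0 - train_fraction,
            stratify=labels,
            random_state=run_seeds[0],
        )

    accuracies, counts, masks = [], [], []
    for r in range(n_runs):
        rs = run_seeds[r]
        if resplit:
            train_rows, test_rows = train_test_split(
                all_rows,
                test_size=1.0 - train_fraction,
                stratify=labels,
                random_state=rs,
            )
        else:
            train_rows, test_rows = fixed_split

        norm_rows = all_rows if leaky_normalization else train_rows
        fnirs_n = normalize_per_modality(fnirs_fm, norm_rows)
        eeg_n = normalize_per_modality(eeg_fm, norm_rows)
        fused = fuse_features(fnirs_n, eeg_n)
        X, y = fused.values, labels

        if method == "none":
            mask_bits = np.ones(X.shape[1], dtype=bool)
        else:
            selector = _make_selector(method, optimizer, wrapper, rs)
            selector.fit(X[train_rows], y[train_rows])
            mask_bits = selector.support_
            masks.append(selector.mask_)

        cols = np.flatnonzero(mask_bits)
        model = svm_train(
            X[np.ix_(train_rows, cols)], y[train_rows], wrapper.get("svm_c", 1.0)
        )
        pred = svm_decide(model, X[np.ix_(test_rows, cols)])
        accuracies.append(classification_accuracy(pred, y[test_rows]))
        counts.append(int(mask_bits.sum()))

    return RunSummary(
        method=method,
        accuracies=np.array(accuracies),
        feature_counts=np.array(counts),
        masks=masks,
        run_seeds=run_seeds[:n_runs],
    )


def compare_methods(
    a: RunSummary, b: RunSummary, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-run accuracies (Welch by default)."""
    xa, xb = a.accuracies, b.accuracies
    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
        # degenerate: both samples constant; t-statistic is 0/0 in scipy
        same = xa.mean() == xb.mean()
        return (0.0, 1.0) if same else (np.inf * np.sign(xa.mean() - xb.mean()), 0.0)
    t, p = spstats.ttest_ind(xa, xb, equal_var=equal_var)
    return float(t), float(p)
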