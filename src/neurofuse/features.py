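"""Temporal statistical features, per-modality normalization, and fusion.

Each 10 s trial contributes five statistics per channel, in fixed order:
mean, slope, peak, skewness, kurtosis.

* mean: arithmetic mean of the window.
* slope: ordinary least-squares coefficient of the sample values against
  time in seconds (signal-units per second).
* peak: signed maximum (the highest value, not the largest magnitude).
* skewness / kurtosis: population (biased) moment estimators
  E[(Y−μ)³]/σ³ and E[(Y−μ)⁴]/σ⁴ — kurtosis is non-excess (normal → 3).

Feature matrices carry per-column provenance (modality, channel,
statistic).  Normalization is min–max per column, learned on training rows
only and stored for reuse; fusion concatenates the fNIRS block before the
EEG block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler

from .simulate import STATISTICS, MultimodalTrialSet

__all__ = [
    "FeatureMatrix",
    "temporal_mean",
    "temporal_slope",
    "temporal_peak",
    "temporal_skewness",
    "temporal_kurtosis",
    "extract_features",
    "ModalityNormalizer",
    "normalize_per_modality",
    "fuse_features",
]

logger = logging.getLogger(__name__)


def temporal_mean(window: np.ndarray) -> float:
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(window.mean())


def temporal_slope(window: np.ndarray, fs: float) -> float:
    """OLS slope of value vs time (seconds)."""
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("slope needs at least 2 samples")
    t = np.arange(window.size) / fs
    tc = t - t.mean()
    return float((tc @ window) / (tc @ tc))


def temporal_peak(window: np.ndarray) -> float:
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(window.max())


def _check_variance(window: np.ndarray) -> None:
    if np.ptp(window) == 0:
        raise ValueError("skewness/kurtosis undefined for zero-variance window")


def temporal_skewness(window: np.ndarray) -> float:
    window = np.asarray(window, dtype=float)
    _check_variance(window)
    return float(spstats.skew(window, bias=True))


def temporal_kurtosis(window: np.ndarray) -> float:
    window = np.asarray(window, dtype=float)
    _check_variance(window)
    return float(spstats.kurtosis(window, fisher=False, bias=True))


@dataclass
class FeatureMatrix:
    """Trials × features table with per-feature provenance.

    provenance entries are (modality, channel_name, statistic) triples;
    ``normalization`` holds the per-column (min, max) learned on training
    rows, or None when the matrix is raw.
    """

    values: np.ndarray
    provenance: list[tuple[str, str, str]]
    labels: np.ndarray
    normalization: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if len(self.provenance) != self.values.shape[1]:
            raise ValueError("provenance length must equal n_features")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must equal n_trials")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_names(self) -> list[str]:
        return [f"{m}:{c}:{s}" for m, c, s in self.provenance]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names())
        df.insert(0, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = df.pop("label").to_numpy(dtype=int)
        prov = [tuple(c.split(":", 2)) for c in df.columns]
        return cls(values=df.to_numpy(dtype=float), provenance=prov, labels=labels)


def _extract_modality(
    data: np.ndarray, fs: float, modality: str, channel_names: list[str], labels: np.ndarray
) -> FeatureMatrix:
    n_trials, n_channels, n_samples = data.shape
    flat = data.reshape(n_trials * n_channels, n_samples)
    if np.any(np.ptp(flat, axis=1) == 0):
        bad = int(np.flatnonzero(np.ptp(flat, axis=1) == 0)[0])
        raise ValueError(
            f"zero-variance window in {modality} trial {bad // n_channels}, "
            f"channel {bad % n_channels}: skewness/kurtosis undefined"
        )
    t = np.arange(n_samples) / fs
    tc = t - t.mean()
    mean = flat.mean(axis=1)
    slope = (flat @ tc) / (tc @ tc)
    peak = flat.max(axis=1)
    skew = spstats.skew(flat, axis=1, bias=True)
    kurt = spstats.kurtosis(flat, axis=1, fisher=False, bias=True)
    # (trials*channels, 5) -> (trials, channels*5) keeping per-channel blocks
    stacked = np.stack([mean, slope, peak, skew, kurt], axis=1)
    values = stacked.reshape(n_trials, n_channels * len(STATISTICS))
    prov = [
        (modality, channel_names[c], stat)
        for c in range(n_channels)
        for stat in STATISTICS
    ]
    return FeatureMatrix(values=values, provenance=prov, labels=labels.copy())


def extract_features(
    trialset: MultimodalTrialSet,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Per-trial, per-channel statistics for both modalities.

    Returns (fnirs_features, eeg_features); column counts are
    5 × n_channels each (e.g. 180 and 150 at the default geometry).
    """
    fnirs = _extract_modality(
        trialset.fnirs_hbo,
        trialset.fs_fnirs,
        "fNIRS",
        trialset.fnirs_channel_names,
        trialset.labels,
    )
    eeg = _extract_modality(
        trialset.eeg,
        trialset.fs_eeg,
        "EEG",
        trialset.eeg_channel_names,
        trialset.labels,
    )
    return fnirs, eeg


class ModalityNormalizer(TransformerMixin, BaseEstimator):
    """Per-column min–max scaling fit on training rows only.

    Thin estimator over sklearn's MinMaxScaler: fit learns per-column
    (min, max) from the rows it is given; transform applies the same affine
    map to any rows, so held-out rows may fall outside [0, 1].  Constant
    training columns map to 0 (a warning is logged).
    """

    def fit(self, X: np.ndarray, y=None) -> "ModalityNormalizer":
        X = np.asarray(X, dtype=float)
        self._scaler = MinMaxScaler(clip=False).fit(X)
        n_const = int(np.sum(self._scaler.data_range_ == 0))
        if n_const:
            logger.warning("%d constant training column(s) scaled to 0", n_const)
        self.data_min_ = self._scaler.data_min_
        self.data_max_ = self._scaler.data_max_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._scaler.transform(np.asarray(X, dtype=float))


def normalize_per_modality(
    fm: FeatureMatrix, training_rows: np.ndarray
) -> FeatureMatrix:
    """Min–max normalize all rows using statistics from ``training_rows``."""
    training_rows = np.asarray(training_rows, dtype=int)
    if training_rows.size == 0:
        raise ValueError("training_rows must be non-empty")
    norm = ModalityNormalizer().fit(fm.values[training_rows])
    return FeatureMatrix(
        values=norm.transform(fm.values),
        provenance=list(fm.provenance),
        labels=fm.labels.copy(),
        normalization=(norm.data_min_.copy(), norm.data_max_.copy()),
    )


def fuse_features(fnirs_fm: FeatureMatrix, eeg_fm: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation, fNIRS block first (f_fNIRS : f_EEG)."""
    if fnirs_fm.values.shape[0] != eeg_fm.values.shape[0]:
        raise ValueError("row counts differ between modalities")
    if not np.array_equal(fnirs_fm.labels, eeg_fm.labels):
        raise ValueError("trial labels are not aligned between modalities")
    return FeatureMatrix(
        values=np.hstack([fnirs_fm.values, eeg_fm.values]),
        provenance=list(fnirs_fm.provenance) + list(eeg_fm.provenance),
        labels=fnirs_fm.labels.copy(),
    )
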