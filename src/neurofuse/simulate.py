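"""Synthetic two-class EEG + fNIRS motor-imagery trial sets.

The generator emulates the geometry of a typical hybrid motor-imagery
recording: 30 EEG channels sampled at 200 Hz and 36 fNIRS ΔHbO channels
sampled at 10 Hz, 10 s trials, 30 trials per class (left- vs right-hand
imagery analogue).  Class information is planted in a known subset of
channels — an ERD-like attenuation of the 8–30 Hz rhythm in EEG and a
hemodynamic-response amplitude difference in fNIRS — so downstream feature
selection can be scored against ground truth.

Signal phenomenology:

* EEG channel = 1/f background + band-limited 8–30 Hz oscillation.  On
  informative channels the oscillation amplitude for class 1 is attenuated
  by ``eeg_effect`` (event-related desynchronization).
* fNIRS channel = gamma-shaped hemodynamic response ramp + very slow drift
  (< 0.01 Hz) + ~1 Hz cardiac sinusoid + band-limited (< 1.2 Hz)
  measurement noise.  On informative channels the response amplitude for
  class 1 is scaled by ``1 + fnirs_effect``.

Everything is driven by a single integer seed; identical seeds give
bit-identical arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GroundTruth",
    "MultimodalTrialSet",
    "generate_trialset",
    "strong_effect_config",
    "save_bundle",
    "load_bundle",
]

#: order of per-channel temporal statistics used throughout the package
STATISTICS = ("mean", "slope", "peak", "skewness", "kurtosis")

# statistics through which a pure amplitude effect is expressed after the
# standard preprocessing chains: the 8-30 Hz band-pass zeroes EEG mean/slope
# and skew/kurt are scale-invariant, so EEG amplitude shows up in the peak;
# the 0.01 Hz high-pass removes the per-trial fNIRS mean, leaving slope/peak.
_AFFECTED_STATS = {"eeg": ("peak",), "fnirs": ("slope", "peak")}


@dataclass(frozen=True)
class GroundTruth:
    """Which channels carry class information, and how strongly.

    eeg_effect is the fractional attenuation of the 8-30 Hz oscillation for
    class 1 on informative EEG channels (0 = no effect, 0.5 = halved).
    fnirs_effect is the relative amplitude increase of the hemodynamic
    response for class 1 on informative fNIRS channels.
    """

    informative_eeg_channels: tuple[int, ...] = (8, 23)
    informative_fnirs_channels: tuple[int, ...] = (2, 19)
    eeg_effect: float = 0.5
    fnirs_effect: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eeg_effect < 0 or self.fnirs_effect < 0:
            raise ValueError("effect sizes must be >= 0")

    def validate_channels(self, n_eeg: int, n_fnirs: int) -> None:
        if any(c < 0 or c >= n_eeg for c in self.informative_eeg_channels):
            raise ValueError("informative EEG channel index out of range")
        if any(c < 0 or c >= n_fnirs for c in self.informative_fnirs_channels):
            raise ValueError("informative fNIRS channel index out of range")

    def informative_feature_indices(
        self, n_fnirs_channels: int = 36, n_eeg_channels: int = 30
    ) -> np.ndarray:
        """Planted feature indices in the fused (fNIRS block first) matrix.

        A feature is planted when its channel is informative and its
        statistic actually carries the amplitude effect after preprocessing
        (fNIRS: slope and peak; EEG: peak).
        """
        n_stats = len(STATISTICS)
        idx: list[int] = []
        for ch in self.informative_fnirs_channels:
            for stat in _AFFECTED_STATS["fnirs"]:
                idx.append(ch * n_stats + STATISTICS.index(stat))
        offset = n_fnirs_channels * n_stats
        for ch in self.informative_eeg_channels:
            for stat in _AFFECTED_STATS["eeg"]:
                idx.append(offset + ch * n_stats + STATISTICS.index(stat))
        return np.asarray(sorted(idx), dtype=int)


@dataclass
class MultimodalTrialSet:
    """Paired EEG / fNIRS trial arrays with labels and sampling metadata."""

    eeg: np.ndarray  # (n_trials, n_eeg_channels, n_eeg_samples), microvolts
    fnirs_hbo: np.ndarray  # (n_trials, n_fnirs_channels, n_fnirs_samples), ΔHbO
    fs_eeg: float
    fs_fnirs: float
    labels: np.ndarray  # (n_trials,) in {0, 1}
    eeg_channel_names: list[str] = field(default_factory=list)
    fnirs_channel_names: list[str] = field(default_factory=list)
    trial_duration: float = 10.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.fnirs_hbo = np.asarray(self.fnirs_hbo, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.eeg.ndim != 3 or self.fnirs_hbo.ndim != 3:
            raise ValueError("trial arrays must be 3-D (trials, channels, samples)")
        n = self.eeg.shape[0]
        if self.fnirs_hbo.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("EEG, fNIRS and labels must agree on n_trials")
        for arr, fs, name in (
            (self.eeg, self.fs_eeg, "eeg"),
            (self.fnirs_hbo, self.fs_fnirs, "fnirs_hbo"),
        ):
            expected = int(round(self.trial_duration * fs))
            if arr.shape[2] != expected:
                raise ValueError(
                    f"{name}: {arr.shape[2]} samples != duration*fs = {expected}"
                )
        if not self.eeg_channel_names:
            self.eeg_channel_names = [f"EEG{i:02d}" for i in range(self.eeg.shape[1])]
        if not self.fnirs_channel_names:
            self.fnirs_channel_names = [
                f"HbO{i:02d}" for i in range(self.fnirs_hbo.shape[1])
            ]

    @property
    def n_trials(self) -> int:
        return self.eeg.shape[0]

    def copy(self) -> "MultimodalTrialSet":
        return MultimodalTrialSet(
            eeg=self.eeg.copy(),
            fnirs_hbo=self.fnirs_hbo.copy(),
            fs_eeg=self.fs_eeg,
            fs_fnirs=self.fs_fnirs,
            labels=self.labels.copy(),
            eeg_channel_names=list(self.eeg_channel_names),
            fnirs_channel_names=list(self.fnirs_channel_names),
            trial_duration=self.trial_duration,
        )


def _band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    f_lo: float,
    f_hi: float,
    exponent: float = 0.0,
) -> np.ndarray:
    """Gaussian noise with power restricted to [f_lo, f_hi], amplitude ∝ f^-exponent.

    Synthesized in the frequency domain with random complex coefficients,
    normalized to unit standard deviation.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    with np.errstate(divide="ignore"):
        shape = np.where(freqs > 0, freqs, np.inf) ** (-exponent)
    amp[band] = shape[band]
    coeff = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    coeff[0] = 0.0
    x = np.fft.irfft(coeff, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _hrf_shape(t: np.ndarray, peak_time: float = 5.0, shape: float = 6.0) -> np.ndarray:
    """Gamma-variate hemodynamic response, normalized to unit maximum."""
    tau = peak_time / (shape - 1.0)
    h = (t / tau) ** (shape - 1.0) * np.exp(-(t / tau))
    return h / h.max()


def generate_trialset(
    n_trials_per_class: int = 30,
    ground_truth: GroundTruth | None = None,
    *,
    n_eeg_channels: int = 30,
    n_fnirs_channels: int = 36,
    trial_duration: float = 10.0,
    fs_eeg: float = 200.0,
    fs_fnirs: float = 10.0,
    eeg_background_sd: float = 10.0,
    eeg_osc_rms: float = 4.0,
    fnirs_response_amp: float = 1.0,
    fnirs_noise_sd: float = 0.45,
    fnirs_drift_amp: float = 0.3,
    fnirs_cardiac_amp: float = 0.1,
    amplitude_jitter: float = 0.15,
    seed: int = 0,
) -> tuple[MultimodalTrialSet, GroundTruth]:
    """Generate a two-class multimodal trial set with planted effects.

    Returns the trial set and the (possibly default) ground truth actually
    used.  Trials are interleaved class 0/1 so any contiguous split stays
    roughly balanced.  Amplitude scales: EEG in microvolts (a ~4 µV rhythm
    over a ~4 µV 1/f floor), fNIRS in arbitrary ΔHbO concentration units
    with a unit-amplitude response.
    """
    if n_trials_per_class < 2:
        raise ValueError("need at least 2 trials per class")
    if ground_truth is None:
        ground_truth = GroundTruth(seed=seed)
    elif ground_truth.seed != seed:
        ground_truth = replace(ground_truth, seed=seed)
    ground_truth.validate_channels(n_eeg_channels, n_fnirs_channels)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_trials = 2 * n_trials_per_class
    n_eeg_samples = int(round(trial_duration * fs_eeg))
    n_fnirs_samples = int(round(trial_duration * fs_fnirs))
    labels = np.tile([0, 1], n_trials_per_class)

    t_fnirs = np.arange(n_fnirs_samples) / fs_fnirs
    hrf = _hrf_shape(t_fnirs)

    eeg = np.empty((n_trials, n_eeg_channels, n_eeg_samples))
    fnirs = np.empty((n_trials, n_fnirs_channels, n_fnirs_samples))

    inf_eeg = set(ground_truth.informative_eeg_channels)
    inf_fnirs = set(ground_truth.informative_fnirs_channels)

    for i in range(n_trials):
        lab = labels[i]
        for c in range(n_eeg_channels):
            bg = eeg_background_sd * _band_limited_noise(
                rng, n_eeg_samples, fs_eeg, 0.5, fs_eeg / 2, exponent=0.5
            )
            osc = _band_limited_noise(rng, n_eeg_samples, fs_eeg, 8.0, 30.0)
            amp = eeg_osc_rms * (1.0 + amplitude_jitter * rng.standard_normal())
            if c in inf_eeg and lab == 1:
                amp *= 1.0 - ground_truth.eeg_effect
            eeg[i, c] = bg + amp * osc
        for c in range(n_fnirs_channels):
            amp = fnirs_response_amp * (
                1.0 + amplitude_jitter * rng.standard_normal()
            )
            if c in inf_fnirs and lab == 1:
                amp *= 1.0 + ground_truth.fnirs_effect
            drift = fnirs_drift_amp * np.sin(
                2 * np.pi * 0.005 * t_fnirs + rng.uniform(0, 2 * np.pi)
            )
            cardiac = fnirs_cardiac_amp * np.sin(
                2 * np.pi * (1.0 + 0.05 * rng.standard_normal()) * t_fnirs
                + rng.uniform(0, 2 * np.pi)
            )
            noise = fnirs_noise_sd * _band_limited_noise(
                rng, n_fnirs_samples, fs_fnirs, 0.02, 1.2
            )
            fnirs[i, c] = amp * hrf + drift + cardiac + noise

    ts = MultimodalTrialSet(
        eeg=eeg,
        fnirs_hbo=fnirs,
        fs_eeg=fs_eeg,
        fs_fnirs=fs_fnirs,
        labels=labels,
        trial_duration=trial_duration,
    )
    return ts, ground_truth


def strong_effect_config() -> dict:
    """Generator settings for the strong-contrast planted condition.

    Per-feature standardized effect sizes come out around d ≈ 3–5: a single
    planted feature nearly separates the classes, the regime in which
    wrapper selection collapses to very small subsets while the all-features
    classifier is handicapped by the 324 noise columns.
    """
    return {
        "ground_truth": GroundTruth(eeg_effect=0.7, fnirs_effect=1.5),
        "eeg_background_sd": 4.0,
        "fnirs_noise_sd": 0.20,
    }


# ---------------------------------------------------------------------------
# canonical on-disk bundle: one .npz array container + a TSV metadata sidecar


def save_bundle(directory, trialset: MultimodalTrialSet, ground_truth: GroundTruth | None = None) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(
        d / "arrays.npz",
        eeg=trialset.eeg,
        fnirs_hbo=trialset.fnirs_hbo,
        labels=trialset.labels,
    )
    rows = [
        ("fs_eeg", repr(trialset.fs_eeg)),
        ("fs_fnirs", repr(trialset.fs_fnirs)),
        ("trial_duration", repr(trialset.trial_duration)),
        ("eeg_channel_names", ",".join(trialset.eeg_channel_names)),
        ("fnirs_channel_names", ",".join(trialset.fnirs_channel_names)),
    ]
    if ground_truth is not None:
        rows.append(
            (
                "ground_truth",
                json.dumps(
                    {
                        "informative_eeg_channels": list(
                            ground_truth.informative_eeg_channels
                        ),
                        "informative_fnirs_channels": list(
                            ground_truth.informative_fnirs_channels
                        ),
                        "eeg_effect": ground_truth.eeg_effect,
                        "fnirs_effect": ground_truth.fnirs_effect,
                        "seed": ground_truth.seed,
                    }
                ),
            )
        )
    with open(d / "meta.tsv", "w") as fh:
        for key, val in rows:
            fh.write(f"{key}\t{val}\n")


def load_bundle(directory) -> tuple[MultimodalTrialSet, GroundTruth | None]:
    from pathlib import Path

    d = Path(directory)
    npz_path = d / "arrays.npz"
    meta_path = d / "meta.tsv"
    if not npz_path.exists():
        raise FileNotFoundError(f"bundle missing array container: {npz_path}")
    if not meta_path.exists():
        raise FileNotFoundError(f"bundle missing metadata sidecar: {meta_path}")
    with np.load(npz_path) as npz:
        missing = {"eeg", "fnirs_hbo", "labels"} - set(npz.files)
        if missing:
            raise KeyError(f"bundle missing modality array(s): {sorted(missing)}")
        eeg = npz["eeg"]
        fnirs = npz["fnirs_hbo"]
        labels = npz["labels"]
    meta: dict[str, str] = {}
    with open(meta_path) as fh:
        for line in fh:
            if line.strip():
                key, _, val = line.rstrip("\n").partition("\t")
                meta[key] = val
    ts = MultimodalTrialSet(
        eeg=eeg,
        fnirs_hbo=fnirs,
        fs_eeg=float(meta["fs_eeg"]),
        fs_fnirs=float(meta["fs_fnirs"]),
        labels=labels,
        eeg_channel_names=meta["eeg_channel_names"].split(","),
        fnirs_channel_names=meta["fnirs_channel_names"].split(","),
        trial_duration=float(meta["trial_duration"]),
    )
    gt = None
    if "ground_truth" in meta:
        g = json.loads(meta["ground_truth"])
        gt = GroundTruth(
            informative_eeg_channels=tuple(g["informative_eeg_channels"]),
            informative_fnirs_channels=tuple(g["informative_fnirs_channels"]),
            eeg_effect=g["eeg_effect"],
            fnirs_effect=g["fnirs_effect"],
            seed=g["seed"],
        )
    return ts, gt
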