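"""Trial-wise signal conditioning: re-referencing, filtering, EOG regression.

EEG chain: common average reference → 0.5–50 Hz band-pass → optional EOG
regression → 8–30 Hz third-order Butterworth band-pass (the mu/beta band
where motor-imagery ERD lives).  fNIRS chain: 0.01 Hz high-pass →
0.1 Hz third-order low-pass, suppressing drift and cardiac/respiratory
components while keeping the slow hemodynamic response.

All filters are zero-phase (forward–backward second-order sections) with
even-reflection padding over the whole epoch, so short 10 s trials survive
the very low 0.01 Hz cutoff without phase distortion of slope features.
Note forward–backward application doubles the effective order: the −3 dB
point of the composed response is checked against |H(f)|².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .simulate import MultimodalTrialSet

__all__ = [
    "FilterSpec",
    "common_average_reference",
    "butterworth_filter",
    "filter_magnitude_response",
    "regress_out_eog",
    "resample_signal",
    "preprocess_eeg",
    "preprocess_fnirs",
]

logger = logging.getLogger(__name__)

_KINDS = {"lowpass", "highpass", "bandpass"}


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description (cutoffs in Hz)."""

    kind: str
    cutoffs: tuple[float, ...]
    order: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {sorted(_KINDS)}, got {self.kind!r}")
        n_expected = 2 if self.kind == "bandpass" else 1
        if len(self.cutoffs) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} cutoff(s)")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be positive")
        if self.kind == "bandpass" and not self.cutoffs[0] < self.cutoffs[1]:
            raise ValueError("bandpass requires low < high cutoff")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        nyq = fs / 2.0
        for c in self.cutoffs:
            if c >= nyq:
                raise ValueError(
                    f"cutoff {c} Hz is at or above Nyquist ({nyq} Hz) for fs={fs}"
                )
        wn = self.cutoffs[0] if len(self.cutoffs) == 1 else list(self.cutoffs)
        return sps.butter(self.order, wn, btype=self.kind, fs=fs, output="sos")


# standard chains
EEG_BROADBAND = FilterSpec("bandpass", (0.5, 50.0), order=3)
EEG_MI_BAND = FilterSpec("bandpass", (8.0, 30.0), order=3)
EOG_BAND = FilterSpec("bandpass", (0.5, 5.0), order=3)
FNIRS_HIGHPASS = FilterSpec("highpass", (0.01,), order=3)
FNIRS_LOWPASS = FilterSpec("lowpass", (0.1,), order=3)


def common_average_reference(eeg: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous across-channel mean.

    Accepts (channels, samples) or (trials, channels, samples); the channel
    axis is the second-to-last.  After CAR the across-channel mean is zero
    at every time sample.
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.shape[-2] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return eeg - eeg.mean(axis=-2, keepdims=True)


def butterworth_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply a Butterworth filter along the last axis.

    Zero-phase mode runs sosfiltfilt with even-reflection padding of the
    whole epoch (padlen = n-1), which keeps the filter linear and
    time-reversal symmetric even for cutoffs far below 1/epoch.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n <= 3 * spec.order:
        raise ValueError(
            f"signal too short ({n} samples) for order-{spec.order} filtering"
        )
    sos = spec.sos(fs)
    if spec.zero_phase:
        # mirror the whole epoch at both ends: edge transients of the slow
        # cutoffs decay inside the padding and forward/backward edge
        # handling stays symmetric under time reversal
        return sps.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=n - 1)
    return sps.sosfilt(sos, x, axis=-1)


def filter_magnitude_response(
    spec: FilterSpec, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """|H(f)| of the designed (single-pass) filter at the given frequencies.

    For zero-phase application the effective magnitude is this squared.
    """
    _, h = sps.sosfreqz(spec.sos(fs), worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h)


def regress_out_eog(eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Remove the EOG reference from each channel by least-squares projection.

    β_c = <eeg_c, eog> / <eog, eog>; the residual is orthogonal to the
    reference.  The reference should already be band-passed to the ocular
    band (0.5–5 Hz).  A zero-variance reference passes the data through
    with a warning.
    """
    eeg = np.asarray(eeg, dtype=float)
    eog = np.asarray(eog, dtype=float).ravel()
    if eeg.shape[-1] != eog.size:
        raise ValueError("EEG and EOG must have the same number of samples")
    denom = float(eog @ eog)
    if denom <= 0 or not np.isfinite(denom):
        logger.warning("EOG reference has zero variance; skipping regression")
        return eeg.copy()
    beta = (eeg @ eog) / denom  # (..., channels)
    return eeg - beta[..., None] * eog


def resample_signal(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling along the last axis, preserving in-band content."""
    from fractions import Fraction

    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_out > fs_in:
        logger.info("resampling %g -> %g Hz is upsampling (interpolation)", fs_in, fs_out)
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return sps.resample_poly(
        np.asarray(x, dtype=float),
        frac.numerator,
        frac.denominator,
        axis=-1,
        padtype="line",
    )


def preprocess_eeg(
    trialset: MultimodalTrialSet,
    eog: np.ndarray | None = None,
    *,
    broadband: FilterSpec = EEG_BROADBAND,
    mi_band: FilterSpec = EEG_MI_BAND,
) -> MultimodalTrialSet:
    """CAR → 0.5–50 Hz → optional EOG regression → 8–30 Hz band-pass.

    ``eog`` is an optional per-trial reference, shape (n_trials, n_samples);
    it is band-passed to 0.5–5 Hz before regression.
    """
    out = trialset.copy()
    x = common_average_reference(out.eeg)
    x = butterworth_filter(x, out.fs_eeg, broadband)
    if eog is not None:
        eog = np.asarray(eog, dtype=float)
        if eog.shape != (out.n_trials, x.shape[-1]):
            raise ValueError("eog must be (n_trials, n_eeg_samples)")
        eog_f = butterworth_filter(eog, out.fs_eeg, EOG_BAND)
        x = np.stack(
            [regress_out_eog(x[i], eog_f[i]) for i in range(out.n_trials)]
        )
    out.eeg = butterworth_filter(x, out.fs_eeg, mi_band)
    return out


def preprocess_fnirs(
    trialset: MultimodalTrialSet,
    *,
    highpass: FilterSpec = FNIRS_HIGHPASS,
    lowpass: FilterSpec = FNIRS_LOWPASS,
) -> MultimodalTrialSet:
    """0.01 Hz high-pass → 0.1 Hz low-pass on the ΔHbO trials."""
    out = trialset.copy()
    x = butterworth_filter(out.fnirs_hbo, out.fs_fnirs, highpass)
    out.fnirs_hbo = butterworth_filter(x, out.fs_fnirs, lowpass)
    return out
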