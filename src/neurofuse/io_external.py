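"""Optional readers for standard acquisition formats (EDF, SNIRF).

These map continuous recordings into the package's trial-set container by
epoching around event onsets.  They require mne (the ``io`` extra) and are
not needed for the synthetic workflow.
"""

from __future__ import annotations

import numpy as np

from .simulate import MultimodalTrialSet

__all__ = ["read_eeg_edf", "read_fnirs_snirf", "epoch_continuous"]


def _require_mne():
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF/SNIRF requires mne; install the 'io' extra"
        ) from exc
    return mne


def epoch_continuous(
    data: np.ndarray, fs: float, onsets_s: np.ndarray, duration_s: float
) -> np.ndarray:
    """Cut (channels, samples) continuous data into (trials, channels, window)."""
    n_win = int(round(duration_s * fs))
    trials = []
    for onset in np.asarray(onsets_s, dtype=float):
        start = int(round(onset * fs))
        if start < 0 or start + n_win > data.shape[1]:
            raise ValueError(f"onset {onset}s falls outside the recording")
        trials.append(data[:, start : start + n_win])
    return np.stack(trials)


def read_eeg_edf(path, onsets_s, labels, duration_s: float = 10.0) -> dict:
    """Read an EDF recording and epoch it into EEG trials.

    Returns a dict with ``eeg``, ``fs_eeg``, ``labels`` and channel names,
    ready to combine with an fNIRS counterpart into a MultimodalTrialSet.
    """
    mne = _require_mne()
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return {
        "eeg": epoch_continuous(data, raw.info["sfreq"], onsets_s, duration_s),
        "fs_eeg": float(raw.info["sfreq"]),
        "labels": np.asarray(labels, dtype=int),
        "eeg_channel_names": list(raw.ch_names),
    }


def read_fnirs_snirf(path, onsets_s, labels, duration_s: float = 10.0) -> dict:
    """Read a SNIRF recording (HbO channels) and epoch it into fNIRS trials."""
    mne = _require_mne()
    raw = mne.io.read_raw_snirf(path, preload=True, verbose="error")
    picks = [i for i, ch in enumerate(raw.ch_names) if "hbo" in ch.lower()]
    if not picks:
        picks = list(range(len(raw.ch_names)))
    data = raw.get_data(picks=picks)
    return {
        "fnirs_hbo": epoch_continuous(data, raw.info["sfreq"], onsets_s, duration_s),
        "fs_fnirs": float(raw.info["sfreq"]),
        "labels": np.asarray(labels, dtype=int),
        "fnirs_channel_names": [raw.ch_names[i] for i in picks],
    }
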