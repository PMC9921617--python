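"""Epoch data model and elementary EEG signal operations.

The decoding pipeline works on short multichannel EEG segments ("epochs")
in microvolts.  This module provides the epoch container plus the four
primitive operations every later stage builds on: mastoid re-referencing,
causal Butterworth band-pass filtering, amplitude-threshold artifact
rejection, and frontal blink detection.

All filtering is causal (forward-only).  The same code path is used for
offline training and simulated online decoding, so labels produced in the
two settings agree exactly for identical input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "Epoch",
    "Thresholds",
    "rereference",
    "bandpass",
    "reject_artifact",
    "detect_blink",
]

#: Default mastoid reference pair.
DEFAULT_REFERENCES = ("TP9", "TP10")


@dataclass(frozen=True)
class Epoch:
    """One multichannel EEG segment, channels x samples, in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    channel_names
        Ordered, unique channel labels following the 10-20 convention.
    sampling_rate
        Sampling rate in Hz.
    """

    data: np.ndarray
    channel_names: tuple
    sampling_rate: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(data)):
            raise ValueError("epoch contains non-finite values")
        names = tuple(self.channel_names)
        if len(names) != data.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {data.shape[0]} data rows"
            )
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return the sample vector of a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch") from None
        return self.data[idx]

    def with_data(self, data: np.ndarray, channel_names=None) -> "Epoch":
        names = self.channel_names if channel_names is None else tuple(channel_names)
        return Epoch(data=data, channel_names=names, sampling_rate=self.sampling_rate)


@dataclass(frozen=True)
class Thresholds:
    """Amplitude thresholds for the artifact gate and blink detector.

    ``artifact_max`` rejects whole epochs whose absolute amplitude exceeds
    it on any channel (strict inequality).  ``blink_max`` flags a blink
    when the 4-40 Hz filtered Fz amplitude exceeds it.  ``settle_time``
    seconds at the start of a *filtered* trace are excluded from maximum
    checks to avoid start-up ringing of the causal filter.
    """

    artifact_max: float = 200.0
    blink_max: float = 100.0
    blink_band: tuple = (4.0, 40.0)
    blink_channel: str = "Fz"
    filter_order: int = 5
    settle_time: float = 0.2

    def __post_init__(self):
        if not (self.artifact_max > 0 and self.blink_max > 0):
            raise ValueError("thresholds must be positive")
        low, high = self.blink_band
        if not 0 < low < high:
            raise ValueError("blink_band must satisfy 0 < low < high")


def rereference(epoch: Epoch, reference_channels=DEFAULT_REFERENCES) -> Epoch:
    """Re-reference to the mean of two reference channels and drop them.

    Every non-reference channel gets ``mean(ref1, ref2)`` subtracted;
    the reference channels are removed from the output epoch.
    """
    refs = tuple(reference_channels)
    for ref in refs:
        if ref not in epoch.channel_names:
            raise ValueError(f"reference channel {ref!r} missing from epoch")
    ref_rows = np.stack([epoch.channel(r) for r in refs])
    ref_mean = ref_rows.mean(axis=0)
    keep = [i for i, name in enumerate(epoch.channel_names) if name not in refs]
    data = epoch.data[keep] - ref_mean
    names = tuple(epoch.channel_names[i] for i in keep)
    return epoch.with_data(data, names)


def _design_bandpass(low: float, high: float, order: int, sampling_rate: float):
    nyq = sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for sampling rate {sampling_rate} Hz"
        )
    return sps.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")


def bandpass(epoch: Epoch, low: float, high: float, order: int = 5) -> Epoch:
    """Causal Butterworth band-pass, applied per channel."""
    sos = _design_bandpass(low, high, order, epoch.sampling_rate)
    return epoch.with_data(sps.sosfilt(sos, epoch.data, axis=1))


def reject_artifact(epoch: Epoch, thresholds: Thresholds = Thresholds()) -> bool:
    """True iff the epoch holds an artifact: max |amplitude| strictly over
    ``artifact_max`` on any channel/sample.  Rejected epochs are not
    classified downstream."""
    if epoch.n_samples == 0:
        raise ValueError("empty epoch")
    return bool(np.max(np.abs(epoch.data)) > thresholds.artifact_max)


def detect_blink(epoch: Epoch, thresholds: Thresholds = Thresholds()) -> bool:
    """True iff the band-passed blink channel exceeds ``blink_max``.

    The blink channel (Fz by default) is band-passed 4-40 Hz with a causal
    5th-order Butterworth filter; the first ``settle_time`` seconds are
    excluded from the maximum to ignore the filter transient.
    """
    name = thresholds.blink_channel
    if name not in epoch.channel_names:
        raise ValueError(f"blink channel {name!r} missing from epoch")
    low, high = thresholds.blink_band
    sos = _design_bandpass(low, high, thresholds.filter_order, epoch.sampling_rate)
    filtered = sps.sosfilt(sos, epoch.channel(name))
    skip = int(round(thresholds.settle_time * epoch.sampling_rate))
    skip = min(skip, max(filtered.size - 1, 0))
    return bool(np.max(np.abs(filtered[skip:])) > thresholds.blink_max)
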