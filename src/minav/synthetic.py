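"""Synthetic EEG with the statistical structure the decoder assumes.

Trials emulate sensorimotor-rhythm physiology: a 1/f-shaped broadband
background on every channel, plus narrow-band mu (8-12 Hz) and beta
(14-25 Hz) oscillations on the central/parietal channels.  Imagined
movement produces event-related desynchronisation (ERD): during
left-hand imagery the contralateral C4 oscillation amplitude is scaled
by ``(1 - erd_depth)``, right-hand imagery scales C3, and two-hand
flexion scales both.  Blink transients and large-amplitude artifacts
can be injected on demand.

Everything is driven by one seeded generator, so a fixed ``rng_seed``
reproduces every sample bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import Epoch

__all__ = [
    "SyntheticConfig",
    "LabeledTrial",
    "generate_trial",
    "inject_blink",
    "inject_artifact",
    "generate_dataset",
    "CLASS_LABELS",
]

CLASS_LABELS = ("rest", "flexion", "left", "right")

DEFAULT_MONTAGE = ("Fz", "C3", "Cz", "C4", "P3", "P4", "TP9", "TP10")

#: Channels carrying mu/beta oscillations (sensorimotor strip).
OSCILLATORY_CHANNELS = ("C3", "Cz", "C4", "P3", "P4")

#: Which oscillatory channels are attenuated per imagery class.
ERD_TARGETS = {"rest": (), "flexion": ("C3", "C4"), "left": ("C4",), "right": ("C3",)}

#: Relative blink amplitude per channel (volume-conduction surrogate).
BLINK_SPREAD = {"Fz": 1.0, "C3": 0.25, "Cz": 0.3, "C4": 0.25, "P3": 0.1, "P4": 0.1}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Durations are in seconds, amplitudes in microvolts.  ``erd_depth`` is
    the fractional amplitude reduction of the modulated oscillation: the
    task/rest band-power ratio of the pure oscillatory component is
    ``(1 - erd_depth)**2``.
    """

    sampling_rate: float = 250.0
    montage: tuple = DEFAULT_MONTAGE
    reference_channels: tuple = ("TP9", "TP10")
    trial_counts: int = 70
    flexion_duration: float = 6.0
    lr_duration: float = 2.0
    rest_duration: float = 6.0
    break_duration: float = 4.0
    instruction_duration: float = 2.0
    erd_depth: float = 0.5
    background_amplitude: float = 10.0   # uV RMS, 1/f-shaped
    mu_amplitude: float = 6.0            # uV RMS, 8-12 Hz
    beta_amplitude: float = 4.0          # uV RMS, 14-25 Hz
    blink_amplitude: float = 150.0       # uV peak at Fz
    blink_duration: float = 0.2          # s; short enough to pass a 4 Hz high-pass
    artifact_amplitude: float = 250.0    # uV peak
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        for name in (
            "flexion_duration",
            "lr_duration",
            "rest_duration",
            "break_duration",
            "instruction_duration",
            "blink_duration",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.sampling_rate > 2 * 44.0:
            raise ValueError("sampling rate must exceed twice the 44 Hz band edge")
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage channels must be unique")

    def duration_for(self, label: str) -> float:
        if label in ("flexion",):
            return self.flexion_duration
        if label in ("left", "right"):
            return self.lr_duration
        if label == "rest":
            return self.rest_duration
        raise ValueError(f"unknown class label {label!r}")


@dataclass(frozen=True)
class LabeledTrial:
    """One labeled epoch with its session index and task markers."""

    epoch: Epoch
    label: str
    session: int
    markers: tuple  # (onset_sample, offset_sample)

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise with unit RMS via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * shape, n)
    return x / np.sqrt(np.mean(x**2))


def _band_noise(n: int, band, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise with unit RMS (narrow-band rhythm model)."""
    nyq = fs / 2.0
    sos = sps.butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_trial(
    config: SyntheticConfig,
    label: str,
    rng: np.random.Generator | None = None,
) -> LabeledTrial:
    """Generate one labeled trial.

    ERD is multiplicative on the oscillation amplitude of the channels
    contralateral to the imagined hand; the broadband background is never
    modulated.  ``erd_depth = 0`` yields trials statistically identical
    to rest.
    """
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASS_LABELS}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    fs = config.sampling_rate
    n = int(round(config.duration_for(label) * fs))
    targets = ERD_TARGETS[label]
    gain = 1.0 - config.erd_depth

    data = np.empty((len(config.montage), n))
    for i, name in enumerate(config.montage):
        x = config.background_amplitude * _pink_noise(n, rng)
        if name in OSCILLATORY_CHANNELS:
            scale = gain if name in targets else 1.0
            x = x + scale * config.mu_amplitude * _band_noise(n, (8, 12), fs, rng)
            x = x + scale * config.beta_amplitude * _band_noise(n, (14, 25), fs, rng)
        data[i] = x

    epoch = Epoch(data=data, channel_names=config.montage, sampling_rate=fs)
    return LabeledTrial(epoch=epoch, label=label, session=0, markers=(0, n))


def _raised_cosine(n: int) -> np.ndarray:
    # smooth 0 -> 1 -> 0 bump, unit peak
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / n))


def _blink_waveform(n: int) -> np.ndarray:
    """Biphasic blink transient, unit peak.

    One windowed sine cycle: the sharp down-up morphology a frontal
    blink shows after high-pass filtering, with little energy below the
    4 Hz edge of the blink-detection band, so most of the peak survives
    the 4-40 Hz filter.
    """
    t = np.arange(n) + 0.5
    w = np.sin(2.0 * np.pi * t / n) * _raised_cosine(n)
    return w / np.max(np.abs(w))


def inject_blink(epoch: Epoch, at: float, config: SyntheticConfig) -> Epoch:
    """Add a blink transient starting at ``at`` seconds.

    The transient is a biphasic bump of ``blink_duration`` seconds with
    peak ``blink_amplitude`` on Fz and attenuated copies on the
    frontal-adjacent channels.  Returns a new epoch.
    """
    fs = epoch.sampling_rate
    width = int(round(config.blink_duration * fs))
    start = int(round(at * fs))
    if at < 0 or start + width > epoch.n_samples:
        raise ValueError(
            f"blink at {at} s does not fit inside a {epoch.duration:.2f} s epoch"
        )
    bump = config.blink_amplitude * _blink_waveform(width)
    data = epoch.data.copy()
    for i, name in enumerate(epoch.channel_names):
        factor = BLINK_SPREAD.get(name, 0.0)
        if factor:
            data[i, start : start + width] += factor * bump
    return epoch.with_data(data)


def inject_artifact(
    epoch: Epoch,
    at: float,
    config: SyntheticConfig,
    channel: str = "Fz",
    width_s: float = 0.08,
) -> Epoch:
    """Add a high-amplitude transient (peak ``artifact_amplitude``) on one
    channel — the kind of epoch the artifact gate must refuse to classify."""
    fs = epoch.sampling_rate
    width = max(int(round(width_s * fs)), 2)
    start = int(round(at * fs))
    if at < 0 or start + width > epoch.n_samples:
        raise ValueError(f"artifact at {at} s out of range")
    idx = epoch.channel_names.index(channel)
    data = epoch.data.copy()
    data[idx, start : start + width] += config.artifact_amplitude * _raised_cosine(width)
    return epoch.with_data(data)


def generate_dataset(config: SyntheticConfig) -> list:
    """Generate the full labeled dataset with session structure.

    ``trial_counts`` trials per class; flexion and rest trials belong to
    recording sessions 1-2, left/right trials to sessions 3-4 (first half
    of each class in the earlier session).  Deterministic under a fixed
    ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    session_base = {"rest": 1, "flexion": 1, "left": 3, "right": 3}
    trials = []
    half = config.trial_counts / 2.0
    for label in CLASS_LABELS:
        for i in range(config.trial_counts):
            trial = generate_trial(config, label, rng)
            session = session_base[label] + (1 if i >= half else 0)
            trials.append(
                LabeledTrial(
                    epoch=trial.epoch,
                    label=label,
                    session=session,
                    markers=trial.markers,
                )
            )
    return trials
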