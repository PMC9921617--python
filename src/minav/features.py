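"""Sliding-window statistical features over spatially filtered EEG.

Five statistics are computed per window and channel:

* ``p``   — logarithmic sum of power, ``log(mean(x^2) + 1)``
* ``v``   — logarithmic variance, ``log(mean((x - mu)^2) + 1)``
* ``ZCR`` — zero crossing rate, ``(1 / (2 WL)) * sum |sgn(x_n) - sgn(x_{n-1})|``
  with ``sgn(x) = 1`` for ``x >= 0`` and ``-1`` otherwise
* ``SA``  — sum of absolute values
* ``p2p`` — peak-to-peak value, ``max - min``

A window of 200 samples with a hop of 15 slides over each of the 40
CSP-compressed channels, so each time step carries 5 x 40 = 200 feature
values.  Feature order is channel-major: the 5 statistics of channel 0,
then channel 1, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureWindowSpec", "window_features", "sliding_features", "FEATURE_NAMES"]

FEATURE_NAMES = ("p", "v", "zcr", "sa", "p2p")


@dataclass(frozen=True)
class FeatureWindowSpec:
    """Window geometry for feature extraction (samples)."""

    window_length: int = 200
    hop: int = 15

    def __post_init__(self):
        if not self.window_length > self.hop > 0:
            raise ValueError("require window_length > hop > 0")

    def n_steps(self, n_samples: int) -> int:
        """Number of complete windows in a signal of ``n_samples``."""
        if n_samples < self.window_length:
            raise ValueError(
                f"signal of {n_samples} samples shorter than one "
                f"window ({self.window_length})"
            )
        return (n_samples - self.window_length) // self.hop + 1


def _sgn(x: np.ndarray) -> np.ndarray:
    # sgn(0) = +1 by convention; resolves the all-zero window to ZCR = 0
    return np.where(x >= 0, 1.0, -1.0)


def window_features(window: np.ndarray) -> np.ndarray:
    """The five statistics of a single 1-D window, in canonical order."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("window must be a non-empty 1-D array")
    p = np.log(np.mean(x**2) + 1.0)
    v = np.log(np.mean((x - x.mean()) ** 2) + 1.0)
    s = _sgn(x)
    zcr = np.sum(np.abs(s[1:] - s[:-1])) / (2.0 * x.size)
    sa = np.sum(np.abs(x))
    p2p = np.max(x) - np.min(x)
    return np.array([p, v, zcr, sa, p2p])


def sliding_features(
    signal: np.ndarray, spec: FeatureWindowSpec = FeatureWindowSpec()
) -> np.ndarray:
    """Feature sequence for a multichannel signal.

    Parameters
    ----------
    signal
        Array ``(n_channels, n_samples)`` — typically the 40-channel CSP
        output.
    spec
        Window geometry.

    Returns
    -------
    ndarray
        ``(n_steps, 5 * n_channels)`` feature matrix.  Windows start at
        ``0, hop, 2*hop, ...``; incomplete trailing windows are dropped.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    n_ch, n_samples = x.shape
    n_steps = spec.n_steps(n_samples)
    w = spec.window_length

    # (n_ch, n_steps, w) windows without copying
    view = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)
    wins = view[:, :: spec.hop][:, :n_steps]

    mean = wins.mean(axis=2)
    p = np.log(np.mean(wins**2, axis=2) + 1.0)
    v = np.log(np.mean((wins - mean[..., None]) ** 2, axis=2) + 1.0)
    s = np.where(wins >= 0, 1.0, -1.0)
    zcr = np.abs(np.diff(s, axis=2)).sum(axis=2) / (2.0 * w)
    sa = np.abs(wins).sum(axis=2)
    p2p = wins.max(axis=2) - wins.min(axis=2)

    # stack to (n_ch, n_steps, 5) then flatten channel-major per step
    feats = np.stack([p, v, zcr, sa, p2p], axis=2)
    return feats.transpose(1, 0, 2).reshape(n_steps, 5 * n_ch)
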