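"""Filter-bank common spatial patterns (FBCSP).

The 6-channel EEG is decomposed into 20 frequency bands: 19 overlapping
narrow bands of 4 Hz width, stepped by 2 Hz from 4 Hz up to the band
starting at 40 Hz, plus one 4-40 Hz broadband — giving 120 band-filtered
channels.  Within each band a two-class CSP problem is solved on the
averaged, trace-normalised trial covariances; the two extreme
generalised eigenvectors compress 6 channels to 2, so the CSP stage
outputs 40 channels.

CSP here is the standard simultaneous-diagonalisation form: filters ``w``
solve ``C_a w = lambda (C_a + C_b) w``; the eigenvector with the largest
(smallest) eigenvalue maximises the variance ratio of class a (class b).
Patterns — the mixing columns used for topographic interpretation — are
the columns of the inverse transpose of the full filter matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal as sps

from .signals import Epoch

__all__ = [
    "FilterBankSpec",
    "CSPBank",
    "design_filter_bank",
    "apply_filter_bank",
    "fit_csp",
    "fit_csp_bank",
    "apply_csp_bank",
]

N_DECODE_CHANNELS = 6


@dataclass(frozen=True)
class FilterBankSpec:
    """Ordered band edges (Hz) plus the Butterworth order."""

    bands: tuple
    order: int = 5

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def design_filter_bank(sampling_rate: float = 250.0, order: int = 5) -> FilterBankSpec:
    """The 20-band decomposition: 4 Hz-wide bands stepped by 2 Hz from
    4 Hz to the band starting at 40 Hz, then a 4-40 Hz broadband."""
    highest_edge = 44.0
    if not sampling_rate > 2 * highest_edge:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz too low for a {highest_edge} Hz band edge"
        )
    bands = [(float(lo), float(lo + 4)) for lo in range(4, 41, 2)]
    bands.append((4.0, 40.0))
    return FilterBankSpec(bands=tuple(bands), order=order)


def apply_filter_bank(epoch: Epoch, spec: FilterBankSpec) -> np.ndarray:
    """Band-pass all channels through every band of the bank.

    Returns an array ``(n_bands * n_channels, n_samples)`` ordered
    band-major (all channels of band 0, then band 1, ...).  With the
    default 6-channel montage and 20 bands this is the 120-channel
    representation.
    """
    if epoch.n_channels != N_DECODE_CHANNELS:
        raise ValueError(
            f"expected {N_DECODE_CHANNELS} channels, got {epoch.n_channels}"
        )
    nyq = epoch.sampling_rate / 2.0
    out = np.empty((spec.n_bands * epoch.n_channels, epoch.n_samples))
    for b, (lo, hi) in enumerate(spec.bands):
        sos = sps.butter(spec.order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
        out[b * epoch.n_channels : (b + 1) * epoch.n_channels] = sps.sosfilt(
            sos, epoch.data, axis=1
        )
    return out


def _mean_normalized_cov(trials: np.ndarray, shrinkage: float) -> np.ndarray:
    """Average of per-trial, trace-normalised sample covariances with a
    small ridge — makes the fit invariant to per-trial global gain."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("trials must be (n_trials, n_channels, n_samples)")
    covs = np.einsum("tcs,tds->tcd", trials, trials)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("degenerate (zero-power) trial in CSP fit")
    cov = (covs / traces[:, None, None]).mean(axis=0)
    n = cov.shape[0]
    return cov + shrinkage * np.trace(cov) / n * np.eye(n)


def fit_csp(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    shrinkage: float = 1e-6,
):
    """Fit a two-class CSP filter pair.

    Parameters
    ----------
    trials_a, trials_b
        Arrays ``(n_trials, n_channels, n_samples)`` for the two classes;
        at least two trials per class.
    shrinkage
        Ridge added to each class covariance, as a fraction of the mean
        eigenvalue.

    Returns
    -------
    filters : ndarray ``(n_channels, 2)``
        Column 0 maximises the variance ratio of class a, column 1 of
        class b (the two extreme generalised eigenvectors).
    patterns : ndarray ``(n_channels, 2)``
        Corresponding mixing patterns.
    eigenvalues : ndarray ``(2,)``
        Generalised eigenvalues (share of class-a variance), in the same
        column order.
    """
    if len(trials_a) < 2 or len(trials_b) < 2:
        raise ValueError("need at least two trials per class")
    cov_a = _mean_normalized_cov(trials_a, shrinkage)
    cov_b = _mean_normalized_cov(trials_b, shrinkage)
    composite = cov_a + cov_b
    try:
        eigvals, eigvecs = linalg.eigh(cov_a, composite)
    except linalg.LinAlgError as exc:  # pragma: no cover - ridge makes this rare
        raise ValueError("singular composite covariance in CSP fit") from exc
    # eigh returns ascending eigenvalues; last maximises class a, first class b
    order = [-1, 0]
    filters = eigvecs[:, order]
    # patterns: columns of (W^T)^{-1} for the full unmixing W
    patterns_full = np.linalg.pinv(eigvecs.T)
    patterns = patterns_full[:, order]
    return filters, patterns, eigvals[order]


@dataclass
class CSPBank:
    """Per-band CSP filter pairs for one two-class problem."""

    spec: FilterBankSpec
    filters: list            # n_bands arrays (n_channels, 2)
    patterns: list           # n_bands arrays (n_channels, 2)
    eigenvalues: list        # n_bands arrays (2,)
    class_labels: tuple      # (label_a, label_b)
    n_channels: int = N_DECODE_CHANNELS

    @property
    def n_out(self) -> int:
        return 2 * self.spec.n_bands


def fit_csp_bank(
    multiband_a: np.ndarray,
    multiband_b: np.ndarray,
    spec: FilterBankSpec,
    class_labels=("a", "b"),
    n_channels: int = N_DECODE_CHANNELS,
    shrinkage: float = 1e-6,
) -> CSPBank:
    """Fit one CSP pair per band from band-major multiband trials.

    ``multiband_a`` / ``multiband_b`` are ``(n_trials, n_bands * n_channels,
    n_samples)`` stacks as produced by :func:`apply_filter_bank`.
    """
    multiband_a = np.asarray(multiband_a, dtype=float)
    multiband_b = np.asarray(multiband_b, dtype=float)
    n_bands = spec.n_bands
    for arr in (multiband_a, multiband_b):
        if arr.shape[1] != n_bands * n_channels:
            raise ValueError("multiband channel count does not match band spec")
    filters, patterns, eigenvalues = [], [], []
    for b in range(n_bands):
        sl = slice(b * n_channels, (b + 1) * n_channels)
        w, a, lam = fit_csp(multiband_a[:, sl], multiband_b[:, sl], shrinkage)
        filters.append(w)
        patterns.append(a)
        eigenvalues.append(lam)
    return CSPBank(
        spec=spec,
        filters=filters,
        patterns=patterns,
        eigenvalues=eigenvalues,
        class_labels=tuple(class_labels),
        n_channels=n_channels,
    )


def apply_csp_bank(multiband: np.ndarray, bank: CSPBank) -> np.ndarray:
    """Project a band-major multiband signal through the fitted bank.

    ``multiband`` is ``(n_bands * n_channels, n_samples)``; the result is
    ``(2 * n_bands, n_samples)`` — 40 channels for the 20-band bank.
    """
    if not bank.filters:
        raise ValueError("CSP bank is not fitted")
    multiband = np.asarray(multiband, dtype=float)
    n_bands, n_ch = bank.spec.n_bands, bank.n_channels
    if multiband.shape[0] != n_bands * n_ch:
        raise ValueError(
            f"expected {n_bands * n_ch} multiband channels, got {multiband.shape[0]}"
        )
    out = np.empty((2 * n_bands, multiband.shape[1]))
    for b in range(n_bands):
        block = multiband[b * n_ch : (b + 1) * n_ch]
        out[2 * b : 2 * b + 2] = bank.filters[b].T @ block
    return out
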