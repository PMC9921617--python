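"""End-to-end decoding: re-reference -> artifact gate -> filter bank ->
CSP -> sliding features -> sequence classifier.

Two binary decoders are trained per dataset: a *flexion-rest* decoder on
6 s epochs (two-hand flexion starts walking) and a *left-right* decoder
on 2 s epochs (single-hand clenching controls rotation).  Both share the
montage, sampling rate, filter bank and thresholds.

The online path replays samples through a ring buffer updated in 0.5 s
quanta; :func:`decode_step` extracts the most recent epoch, applies the
artifact gate and classifies.  Offline and online classification share
one code path, so identical epochs receive identical labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classifier import SequenceClassifier, TrainingConfig, evaluate
from .fbcsp import (
    CSPBank,
    FilterBankSpec,
    apply_csp_bank,
    apply_filter_bank,
    design_filter_bank,
    fit_csp_bank,
)
from .features import FeatureWindowSpec, sliding_features
from .signals import DEFAULT_REFERENCES, Epoch, Thresholds, reject_artifact, rereference

__all__ = [
    "DecoderConfig",
    "FittedDecoder",
    "DecoderPipeline",
    "OnlineBuffer",
    "Decision",
    "fit_offline",
    "decode_step",
]

FLEXION_REST = "flexion_rest"
LEFT_RIGHT = "left_right"


@dataclass(frozen=True)
class DecoderConfig:
    """Everything needed to train and run the two decoders."""

    reference_channels: tuple = DEFAULT_REFERENCES
    thresholds: Thresholds = field(default_factory=Thresholds)
    window: FeatureWindowSpec = field(default_factory=FeatureWindowSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    filter_order: int = 5
    flexion_epoch_s: float = 6.0
    lr_epoch_s: float = 2.0
    update_interval_s: float = 0.5
    n_train: int = 50
    n_test: int = 20
    split_seed: int = 0

    def __post_init__(self):
        if not (self.flexion_epoch_s > 0 and self.lr_epoch_s > 0):
            raise ValueError("epoch lengths must be positive")


@dataclass
class FittedDecoder:
    """One fitted binary decoder (CSP bank + feature scaler + classifier)."""

    csp_bank: CSPBank
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    classifier: SequenceClassifier
    class_labels: tuple
    epoch_samples: int
    holdout: dict = field(default_factory=dict)


@dataclass
class DecoderPipeline:
    """The two fitted decoders plus everything they share."""

    flexion_rest: FittedDecoder
    left_right: FittedDecoder
    filter_bank: FilterBankSpec
    config: DecoderConfig
    sampling_rate: float
    montage: tuple

    def _decoder(self, which: str) -> FittedDecoder:
        if which == FLEXION_REST:
            return self.flexion_rest
        if which == LEFT_RIGHT:
            return self.left_right
        raise ValueError(f"unknown decoder {which!r}")

    def features_for(self, epoch6: Epoch, which: str) -> np.ndarray:
        """Standardised feature sequence of a re-referenced 6-channel epoch."""
        dec = self._decoder(which)
        multiband = apply_filter_bank(epoch6, self.filter_bank)
        csp_out = apply_csp_bank(multiband, dec.csp_bank)
        seq = sliding_features(csp_out, self.config.window)
        return (seq - dec.scaler_mean) / dec.scaler_std

    def classify_epoch(self, epoch: Epoch, which: str) -> "Decision":
        """Artifact gate + classification of one raw (referenced) epoch."""
        ref = rereference(epoch, self.config.reference_channels)
        if reject_artifact(ref, self.config.thresholds):
            return Decision(kind="artifact")
        dec = self._decoder(which)
        seq = self.features_for(ref, which)
        label, probs = dec.classifier.predict(seq)
        return Decision(kind="label", label=label, probability=float(probs.max()))


@dataclass(frozen=True)
class Decision:
    """Outcome of one decode step: a class label, an artifact rejection,
    or no decision (underfilled buffer)."""

    kind: str  # "label" | "artifact" | "no_decision"
    label: str | None = None
    probability: float | None = None


class OnlineBuffer:
    """Ring buffer of the most recent samples, fed in 0.5 s quanta."""

    def __init__(self, channel_names, sampling_rate: float, capacity_s: float = 8.0,
                 update_interval_s: float = 0.5):
        self.channel_names = tuple(channel_names)
        self.sampling_rate = float(sampling_rate)
        self.capacity = int(round(capacity_s * sampling_rate))
        self.update_interval_s = update_interval_s
        self._data = np.zeros((len(self.channel_names), 0))
        self.clock = 0.0  # seconds of signal consumed

    def append(self, block: np.ndarray):
        block = np.atleast_2d(np.asarray(block, dtype=float))
        if block.shape[0] != len(self.channel_names):
            raise ValueError("block channel count does not match buffer montage")
        self._data = np.concatenate([self._data, block], axis=1)[:, -self.capacity :]
        self.clock += block.shape[1] / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    def extract(self, seconds: float) -> Epoch | None:
        """Most recent ``seconds`` of signal, or None if underfilled."""
        n = int(round(seconds * self.sampling_rate))
        if self.n_samples < n:
            return None
        return Epoch(
            data=self._data[:, -n:].copy(),
            channel_names=self.channel_names,
            sampling_rate=self.sampling_rate,
        )


def decode_step(buffer: OnlineBuffer, pipeline: DecoderPipeline, which: str) -> Decision:
    """Classify the most recent epoch in the buffer.

    Returns a ``Decision`` whose ``kind`` is ``no_decision`` when the
    buffer does not yet hold a full epoch, ``artifact`` when the
    amplitude gate fires, and ``label`` otherwise.  Never raises on
    finite input.
    """
    cfg = pipeline.config
    seconds = cfg.flexion_epoch_s if which == FLEXION_REST else cfg.lr_epoch_s
    epoch = buffer.extract(seconds)
    if epoch is None:
        return Decision(kind="no_decision")
    return pipeline.classify_epoch(epoch, which)


# --------------------------------------------------------------------- train


def _split(trials, n_train, n_test, rng):
    idx = rng.permutation(len(trials))
    if len(trials) < n_train + n_test:
        n_train = int(round(len(trials) * 5 / 7))
        n_test = len(trials) - n_train
    train = [trials[i] for i in idx[:n_train]]
    test = [trials[i] for i in idx[n_train : n_train + n_test]]
    return train, test


def _fit_pair(
    trials_by_label: dict,
    pair: tuple,
    config: DecoderConfig,
    spec: FilterBankSpec,
    sampling_rate: float,
    seed_offset: int,
) -> FittedDecoder:
    rng = np.random.default_rng(config.split_seed + seed_offset)
    split = {}
    for label in pair:
        split[label] = _split(trials_by_label[label], config.n_train, config.n_test, rng)

    def preprocess(trial):
        epoch = rereference(trial.epoch, config.reference_channels)
        if reject_artifact(epoch, config.thresholds):
            return None
        return apply_filter_bank(epoch, spec)

    train_mb = {l: [m for t in split[l][0] if (m := preprocess(t)) is not None]
                for l in pair}
    for l in pair:
        if len(train_mb[l]) < 2:
            raise ValueError(f"fewer than two clean training trials for class {l!r}")

    bank = fit_csp_bank(
        np.stack(train_mb[pair[0]]), np.stack(train_mb[pair[1]]), spec,
        class_labels=pair,
    )

    def to_sequence(multiband):
        return sliding_features(apply_csp_bank(multiband, bank), config.window)

    X_train, y_train = [], []
    for l in pair:
        for mb in train_mb[l]:
            X_train.append(to_sequence(mb))
            y_train.append(l)
    X_train = np.stack(X_train)
    mean = X_train.reshape(-1, X_train.shape[2]).mean(axis=0)
    std = X_train.reshape(-1, X_train.shape[2]).std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    X_train = (X_train - mean) / std

    clf = SequenceClassifier(config.training).fit(X_train, np.array(y_train))

    X_test, y_test = [], []
    for l in pair:
        for t in split[l][1]:
            mb = preprocess(t)
            if mb is None:
                continue
            X_test.append((to_sequence(mb) - mean) / std)
            y_test.append(l)
    holdout = evaluate(clf, np.stack(X_test), np.array(y_test)) if X_test else {}

    epoch_samples = int(round(
        (config.flexion_epoch_s if "flexion" in pair else config.lr_epoch_s)
        * sampling_rate
    ))
    return FittedDecoder(
        csp_bank=bank,
        scaler_mean=mean,
        scaler_std=std,
        classifier=clf,
        class_labels=pair,
        epoch_samples=epoch_samples,
        holdout=holdout,
    )


def fit_offline(trials, config: DecoderConfig = DecoderConfig()) -> DecoderPipeline:
    """Train both decoders from a labeled trial collection.

    CSP banks and feature scalers are fitted on the training split only;
    held-out accuracies are stored on each fitted decoder
    (``pipeline.flexion_rest.holdout["accuracy"]`` etc.).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("empty dataset")
    by_label: dict = {}
    for t in trials:
        by_label.setdefault(t.label, []).append(t)
    for needed in ("rest", "flexion", "left", "right"):
        if needed not in by_label:
            raise ValueError(f"dataset is missing class {needed!r}")

    sampling_rate = trials[0].epoch.sampling_rate
    montage = trials[0].epoch.channel_names
    spec = design_filter_bank(sampling_rate, order=config.filter_order)

    fr = _fit_pair(by_label, ("flexion", "rest"), config, spec, sampling_rate, 0)
    lr = _fit_pair(by_label, ("left", "right"), config, spec, sampling_rate, 1)
    return DecoderPipeline(
        flexion_rest=fr,
        left_right=lr,
        filter_bank=spec,
        config=config,
        sampling_rate=sampling_rate,
        montage=montage,
    )
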