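"""HDF5 persistence for datasets and fitted pipelines, plus the MNE bridge.

Datasets store one group per trial (epoch array, label, session, markers)
with the generator configuration as root attributes.  Fitted pipelines
store the CSP banks, feature scalers and classifier weights of both
decoders in a single file.  Continuous recordings in EDF are read through
MNE when it is installed (``pip install minav[edf]``); ``to_mne_raw``
converts a trial collection to a continuous ``mne.io.Raw`` for export
through any MNE-supported writer.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .classifier import SequenceClassifier, TrainingConfig
from .decoder import DecoderConfig, DecoderPipeline, FittedDecoder
from .fbcsp import CSPBank, FilterBankSpec
from .features import FeatureWindowSpec
from .signals import Epoch, Thresholds
from .synthetic import LabeledTrial, SyntheticConfig

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_pipeline",
    "load_pipeline",
    "read_edf",
    "to_mne_raw",
]


def save_dataset(path, trials, config: SyntheticConfig | None = None):
    """Write labeled trials (and optionally the generator config) to HDF5."""
    with h5py.File(path, "w") as fh:
        if config is not None:
            fh.attrs["config"] = json.dumps(dataclasses.asdict(config))
        for i, trial in enumerate(trials):
            grp = fh.create_group(f"trial_{i:05d}")
            grp.create_dataset("epoch", data=trial.epoch.data)
            grp.attrs["channel_names"] = list(trial.epoch.channel_names)
            grp.attrs["sampling_rate"] = trial.epoch.sampling_rate
            grp.attrs["label"] = trial.label
            grp.attrs["session"] = trial.session
            grp.attrs["markers"] = list(trial.markers)


def load_dataset(path):
    """Read trials back; returns ``(trials, config_or_None)``."""
    trials = []
    with h5py.File(path, "r") as fh:
        config = None
        if "config" in fh.attrs:
            payload = json.loads(fh.attrs["config"])
            for key in ("montage", "reference_channels"):
                if key in payload:
                    payload[key] = tuple(payload[key])
            config = SyntheticConfig(**payload)
        for name in sorted(fh.keys()):
            grp = fh[name]
            epoch = Epoch(
                data=grp["epoch"][()],
                channel_names=tuple(str(c) for c in grp.attrs["channel_names"]),
                sampling_rate=float(grp.attrs["sampling_rate"]),
            )
            trials.append(
                LabeledTrial(
                    epoch=epoch,
                    label=str(grp.attrs["label"]),
                    session=int(grp.attrs["session"]),
                    markers=tuple(int(m) for m in grp.attrs["markers"]),
                )
            )
    return trials, config


# ------------------------------------------------------------------ pipeline


def _write_decoder(grp, dec: FittedDecoder):
    grp.attrs["class_labels"] = list(dec.class_labels)
    grp.attrs["epoch_samples"] = dec.epoch_samples
    grp.attrs["holdout"] = json.dumps(dec.holdout)
    grp.create_dataset("scaler_mean", data=dec.scaler_mean)
    grp.create_dataset("scaler_std", data=dec.scaler_std)
    csp = grp.create_group("csp")
    csp.create_dataset("filters", data=np.stack(dec.csp_bank.filters))
    csp.create_dataset("patterns", data=np.stack(dec.csp_bank.patterns))
    csp.create_dataset("eigenvalues", data=np.stack(dec.csp_bank.eigenvalues))
    clf = grp.create_group("classifier")
    model = dec.classifier
    clf.attrs["classes"] = list(model.classes_)
    clf.attrs["config"] = json.dumps(dataclasses.asdict(model.config))
    clf.attrs["n_features"] = model.n_features_
    clf.attrs["n_steps"] = model.n_steps_
    for scope in ("fwd", "bwd"):
        sub = clf.create_group(scope)
        for key, value in model.params[scope].items():
            sub.create_dataset(key, data=value)
    clf.create_dataset("Wout", data=model.params["Wout"])
    clf.create_dataset("bout", data=model.params["bout"])


def _read_decoder(grp, spec: FilterBankSpec) -> FittedDecoder:
    clf_grp = grp["classifier"]
    config = TrainingConfig(**json.loads(clf_grp.attrs["config"]))
    model = SequenceClassifier(config)
    model.classes_ = tuple(str(c) for c in clf_grp.attrs["classes"])
    model.n_features_ = int(clf_grp.attrs["n_features"])
    model.n_steps_ = int(clf_grp.attrs["n_steps"])
    model.params = {
        scope: {k: clf_grp[scope][k][()] for k in clf_grp[scope]}
        for scope in ("fwd", "bwd")
    }
    model.params["Wout"] = clf_grp["Wout"][()]
    model.params["bout"] = clf_grp["bout"][()]
    labels = tuple(str(l) for l in grp.attrs["class_labels"])
    bank = CSPBank(
        spec=spec,
        filters=list(grp["csp"]["filters"][()]),
        patterns=list(grp["csp"]["patterns"][()]),
        eigenvalues=list(grp["csp"]["eigenvalues"][()]),
        class_labels=labels,
    )
    return FittedDecoder(
        csp_bank=bank,
        scaler_mean=grp["scaler_mean"][()],
        scaler_std=grp["scaler_std"][()],
        classifier=model,
        class_labels=labels,
        epoch_samples=int(grp.attrs["epoch_samples"]),
        holdout=json.loads(grp.attrs["holdout"]),
    )


def save_pipeline(path, pipeline: DecoderPipeline):
    """Serialise a fitted pipeline (both decoders + shared settings)."""
    cfg = pipeline.config
    with h5py.File(path, "w") as fh:
        fh.attrs["sampling_rate"] = pipeline.sampling_rate
        fh.attrs["montage"] = list(pipeline.montage)
        fh.attrs["bands"] = json.dumps(list(pipeline.filter_bank.bands))
        fh.attrs["filter_order"] = pipeline.filter_bank.order
        fh.attrs["config"] = json.dumps(
            {
                "reference_channels": list(cfg.reference_channels),
                "thresholds": dataclasses.asdict(cfg.thresholds),
                "window": dataclasses.asdict(cfg.window),
                "training": dataclasses.asdict(cfg.training),
                "filter_order": cfg.filter_order,
                "flexion_epoch_s": cfg.flexion_epoch_s,
                "lr_epoch_s": cfg.lr_epoch_s,
                "update_interval_s": cfg.update_interval_s,
                "n_train": cfg.n_train,
                "n_test": cfg.n_test,
                "split_seed": cfg.split_seed,
            }
        )
        _write_decoder(fh.create_group("flexion_rest"), pipeline.flexion_rest)
        _write_decoder(fh.create_group("left_right"), pipeline.left_right)


def load_pipeline(path) -> DecoderPipeline:
    with h5py.File(path, "r") as fh:
        bands = tuple(tuple(b) for b in json.loads(fh.attrs["bands"]))
        spec = FilterBankSpec(bands=bands, order=int(fh.attrs["filter_order"]))
        raw = json.loads(fh.attrs["config"])
        raw["thresholds"] = Thresholds(
            **{**raw["thresholds"],
               "blink_band": tuple(raw["thresholds"]["blink_band"])}
        )
        raw["window"] = FeatureWindowSpec(**raw["window"])
        raw["training"] = TrainingConfig(**raw["training"])
        raw["reference_channels"] = tuple(raw["reference_channels"])
        config = DecoderConfig(**raw)
        return DecoderPipeline(
            flexion_rest=_read_decoder(fh["flexion_rest"], spec),
            left_right=_read_decoder(fh["left_right"], spec),
            filter_bank=spec,
            config=config,
            sampling_rate=float(fh.attrs["sampling_rate"]),
            montage=tuple(str(c) for c in fh.attrs["montage"]),
        )


# ----------------------------------------------------------------------- EDF


def read_edf(path, channels=None) -> Epoch:
    """Read a continuous EDF recording into a single long epoch (microvolts).

    Requires MNE (``pip install minav[edf]``).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        raw.pick(list(channels))
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Epoch(
        data=data,
        channel_names=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
    )


def to_mne_raw(trials):
    """Concatenate trials into a continuous ``mne.io.RawArray`` so users
    can export through any MNE-supported writer.  Requires MNE."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("conversion requires the optional 'mne' dependency") from exc
    first = trials[0].epoch
    data = np.concatenate([t.epoch.data for t in trials], axis=1) * 1e-6
    info = mne.create_info(
        list(first.channel_names), sfreq=first.sampling_rate, ch_types="eeg"
    )
    return mne.io.RawArray(data, info, verbose="error")
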