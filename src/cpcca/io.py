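"""Epoch/dataset data model and on-disk formats.

A dataset lives in a directory with a ``manifest.yaml`` at its root and
one delimited-text file per trial::

    manifest.yaml        # subject_id, fs, channel_labels, stimulus_set,
                         # and a trial table (file, stimulus_hz, trial_index)
    trial_1.csv          # h rows x i columns, comma-separated, no header
    trial_2.csv
    ...

Trial files store one channel per row in manifest channel order, values
written with 8 significant digits (relative storage tolerance ~1e-8).
EDF reading is optional and requires :mod:`mne`; stimulus labels come
from annotations named ``stim_<freq>`` or a ``<stem>_labels.csv`` sidecar
with columns ``onset_s,duration_s,stimulus_hz``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import ValidationError

__all__ = ["EEGEpoch", "Dataset", "read_dataset", "write_dataset"]

#: Occipital/parietal montage used throughout: the electrode sites over
#: visual cortex where the SSVEP response is strongest.
DEFAULT_CHANNELS: Tuple[str, ...] = ("O1", "O2", "P7", "P8")

_FREQ_ATOL = 1e-6


def _match_freq(f: float, stimulus_set: Sequence[float]) -> Optional[float]:
    for s in stimulus_set:
        if abs(s - f) <= _FREQ_ATOL:
            return s
    return None


@dataclass(frozen=True)
class EEGEpoch:
    """One trial: channels x samples matrix with its labels.

    ``data`` is h x i (microvolts by convention; all downstream methods
    are amplitude-invariant after centering).  ``stimulus_hz`` is None
    for unlabeled test epochs.
    """

    data: np.ndarray = field(repr=False)
    fs: float
    channel_labels: Tuple[str, ...]
    stimulus_hz: Optional[float] = None
    trial_index: int = 1

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if data.ndim != 2:
            raise ValidationError("epoch data must be 2-D (channels x samples)")
        h, i = data.shape
        if h < 1 or i < 2:
            raise ValidationError(f"epoch needs >=1 channel and >=2 samples, got {h}x{i}")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if len(self.channel_labels) != h:
            raise ValidationError(
                f"{len(self.channel_labels)} channel labels for {h} data rows"
            )
        if not np.isfinite(data).all():
            raise ValidationError("epoch data must be finite")
        if self.trial_index < 1:
            raise ValidationError("trial_index must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_channels(self, labels: Sequence[str]) -> "EEGEpoch":
        """Subset channels, always preserving this epoch's channel order."""
        want = set(labels)
        missing = want - set(self.channel_labels)
        if missing:
            raise ValidationError(f"channels not in epoch: {sorted(missing)}")
        idx = [k for k, lab in enumerate(self.channel_labels) if lab in want]
        return replace(
            self,
            data=self.data[idx],
            channel_labels=tuple(self.channel_labels[k] for k in idx),
        )

    def window(self, n_samples: int) -> np.ndarray:
        """First ``n_samples`` columns (an evaluation-time view)."""
        if n_samples < 2 or n_samples > self.n_samples:
            raise ValidationError(
                f"window of {n_samples} samples invalid for epoch of {self.n_samples}"
            )
        return self.data[:, :n_samples]


@dataclass(frozen=True)
class Dataset:
    """Ordered epochs sharing fs / montage, plus the stimulus set."""

    epochs: Tuple[EEGEpoch, ...]
    stimulus_set: Tuple[float, ...]
    subject_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "epochs", tuple(self.epochs))
        object.__setattr__(
            self, "stimulus_set", tuple(float(f) for f in self.stimulus_set)
        )
        if len(self.stimulus_set) < 2:
            raise ValidationError("stimulus_set needs at least 2 frequencies")
        if len(set(self.stimulus_set)) != len(self.stimulus_set):
            raise ValidationError("stimulus_set contains duplicates")
        if not self.epochs:
            raise ValidationError("dataset has no epochs")
        ref = self.epochs[0]
        for k, ep in enumerate(self.epochs):
            if ep.fs != ref.fs:
                raise ValidationError(
                    f"trial {k + 1}: fs {ep.fs} differs from {ref.fs}"
                )
            if ep.channel_labels != ref.channel_labels:
                raise ValidationError(f"trial {k + 1}: channel labels differ")
            if ep.stimulus_hz is not None and _match_freq(
                ep.stimulus_hz, self.stimulus_set
            ) is None:
                raise ValidationError(
                    f"trial {k + 1}: stimulus {ep.stimulus_hz} Hz not in stimulus_set"
                )

    @property
    def fs(self) -> float:
        return self.epochs[0].fs

    @property
    def channel_labels(self) -> Tuple[str, ...]:
        return self.epochs[0].channel_labels

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def select_channels(self, labels: Sequence[str]) -> "Dataset":
        return replace(
            self, epochs=tuple(ep.select_channels(labels) for ep in self.epochs)
        )

    def epochs_for(self, f: float) -> List[EEGEpoch]:
        target = _match_freq(f, self.stimulus_set)
        if target is None:
            raise ValidationError(f"{f} Hz is not in the stimulus set")
        return [
            ep
            for ep in self.epochs
            if ep.stimulus_hz is not None and abs(ep.stimulus_hz - target) <= _FREQ_ATOL
        ]

    def arrays(self):
        """(X, y) view: X of shape (n_epochs, h, i), y stimulus labels.

        Only labeled epochs are included; lengths are truncated to the
        shortest epoch so the stack is rectangular.
        """
        labeled = [ep for ep in self.epochs if ep.stimulus_hz is not None]
        if not labeled:
            raise ValidationError("dataset has no labeled epochs")
        n = min(ep.n_samples for ep in labeled)
        X = np.stack([ep.data[:, :n] for ep in labeled])
        y = np.array([ep.stimulus_hz for ep in labeled])
        return X, y


def write_dataset(ds: Dataset, path) -> None:
    """Write a dataset directory (manifest.yaml + trial_<k>.csv files)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    trials = []
    for k, ep in enumerate(ds.epochs, start=1):
        fname = f"trial_{k}.csv"
        np.savetxt(root / fname, ep.data, fmt="%.8e", delimiter=",")
        row = {"file": fname, "trial_index": int(ep.trial_index)}
        row["stimulus_hz"] = None if ep.stimulus_hz is None else float(ep.stimulus_hz)
        trials.append(row)
    manifest = {
        "subject_id": ds.subject_id,
        "fs": float(ds.fs),
        "channel_labels": list(ds.channel_labels),
        "stimulus_set": [float(f) for f in ds.stimulus_set],
        "trials": trials,
    }
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _read_manifest(root: Path, channels: Optional[Sequence[str]]) -> Dataset:
    mpath = root / "manifest.yaml"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.yaml under {root}")
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    for key in ("fs", "channel_labels", "stimulus_set", "trials"):
        if key not in manifest:
            raise ValidationError(f"manifest missing key {key!r}")
    if not manifest["trials"]:
        raise ValidationError("manifest lists no trials")
    labels = [str(c) for c in manifest["channel_labels"]]
    stimulus_set = [float(f) for f in manifest["stimulus_set"]]
    epochs = []
    for k, row in enumerate(manifest["trials"], start=1):
        data = np.loadtxt(root / row["file"], delimiter=",", ndmin=2)
        if data.shape[0] != len(labels):
            raise ValidationError(
                f"trial {k}: {data.shape[0]} rows but {len(labels)} channels declared"
            )
        stim = row.get("stimulus_hz")
        if stim is not None:
            matched = _match_freq(float(stim), stimulus_set)
            if matched is None:
                raise ValidationError(
                    f"trial {k}: stimulus {stim} Hz not in declared stimulus_set"
                )
            stim = matched
        ep = EEGEpoch(
            data=data,
            fs=float(manifest["fs"]),
            channel_labels=labels,
            stimulus_hz=stim,
            trial_index=int(row.get("trial_index", k)),
        )
        if channels is not None:
            ep = ep.select_channels(channels)
        epochs.append(ep)
    return Dataset(
        epochs=epochs,
        stimulus_set=stimulus_set,
        subject_id=str(manifest.get("subject_id", "")),
    )


def _read_edf(path: Path, channels: Optional[Sequence[str]]) -> Dataset:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("EDF support requires the 'mne' package") from exc

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # mne loads volts; store microvolts

    events = []  # (onset_s, duration_s, stimulus_hz)
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if str(desc).startswith("stim_"):
            events.append((float(onset), float(duration), float(str(desc)[5:])))
    if not events:
        sidecar = path.with_name(path.stem + "_labels.csv")
        if sidecar.exists():
            with open(sidecar) as fh:
                for row in csv.DictReader(fh):
                    events.append(
                        (
                            float(row["onset_s"]),
                            float(row["duration_s"]),
                            float(row["stimulus_hz"]),
                        )
                    )
    if not events:
        raise ValidationError(
            f"{path}: no 'stim_<freq>' annotations and no labels sidecar"
        )

    stimulus_set = sorted({f for (_, _, f) in events})
    epochs = []
    for k, (onset, duration, f) in enumerate(events, start=1):
        a = int(round(onset * fs))
        b = a + int(round(duration * fs))
        if b > data.shape[1]:
            raise ValidationError(f"trial {k}: annotation extends past recording end")
        ep = EEGEpoch(
            data=data[:, a:b],
            fs=fs,
            channel_labels=labels,
            stimulus_hz=f,
            trial_index=k,
        )
        if channels is not None:
            ep = ep.select_channels(channels)
        epochs.append(ep)
    return Dataset(epochs=epochs, stimulus_set=stimulus_set, subject_id=path.stem)


def read_dataset(path, format: str = "manifest", channels: Optional[Sequence[str]] = None) -> Dataset:
    """Load a dataset from a manifest directory or an EDF recording.

    Parameters
    ----------
    path : path-like
        Dataset directory (manifest format) or ``.edf`` file.
    format : {"manifest", "edf"}
    channels : sequence of str, optional
        Channel subset to keep; order of the recording is preserved.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such path: {p}")
    if format == "manifest":
        return _read_manifest(p, channels)
    if format == "edf":
        return _read_edf(p, channels)
    raise ValidationError(f"unknown format {format!r} (expected 'manifest' or 'edf')")
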