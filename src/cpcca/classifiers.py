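"""SSVEP target-identification methods: PSDA, standard CCA, and CP-CCA.

All three are scikit-learn style classifiers over epoch stacks of shape
``(n_epochs, n_channels, n_samples)`` with stimulus frequencies (Hz) as
class labels:

* :class:`PSDAClassifier` — channel-averaged periodogram power at each
  candidate frequency (and optionally its harmonics); no training.
* :class:`CCAClassifier` — maximal canonical correlation between the
  multichannel epoch and a sine-cosine reference per frequency; no
  training.
* :class:`CPCCAClassifier` — channel-projection CCA.  Training stacks the
  n single-channel trials recorded under one stimulus frequency into an
  n x i matrix, runs CCA against the sine-cosine reference, and keeps the
  projected variate as a learned per-(channel, frequency) reference.  At
  test time each channel is scored by its absolute Pearson correlation
  with the learned reference and the per-channel scores are summed.

Ties are always resolved toward the lowest candidate frequency.  A
functional interface over :class:`~cpcca.io.EEGEpoch` /
:class:`~cpcca.io.Dataset` objects wraps the estimators
(:func:`cca_classify`, :func:`psda_classify`, :func:`cpcca_train`,
:func:`cpcca_classify`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cca import DEFAULT_RIDGE, cca
from .errors import ValidationError
from .io import DEFAULT_CHANNELS, Dataset, EEGEpoch
from .references import ReferenceBank, make_bank, make_reference

__all__ = [
    "PSDAClassifier",
    "CCAClassifier",
    "CPCCAClassifier",
    "CPCCAModel",
    "ClassificationResult",
    "cca_classify",
    "psda_classify",
    "cpcca_train",
    "cpcca_classify",
    "bandpass_filter",
]


@dataclass(frozen=True)
class ClassificationResult:
    """Decision for one epoch: predicted frequency plus all scores."""

    predicted_hz: float
    scores: Dict[float, float]
    window_samples: int
    per_channel_scores: Optional[Dict[Tuple[str, float], float]] = field(default=None)


def bandpass_filter(data: np.ndarray, fs: float, band: Tuple[float, float] = (4.0, 45.0)) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValidationError(f"band {band} invalid for fs={fs}")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def _pick(freqs: np.ndarray, scores: np.ndarray) -> float:
    """Argmax with ties (to numerical precision) going to the lowest frequency."""
    best = scores.max()
    tied = np.isclose(scores, best, rtol=1e-9, atol=1e-12)
    return float(freqs[np.flatnonzero(tied)[0]])


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson r| between two 1-D signals; 0 if either is constant."""
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(min(abs(a @ b) / (na * nb), 1.0))


def _check_epochs_array(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:  # single epoch
        X = X[None]
    if X.ndim != 3:
        raise ValidationError(
            f"expected epochs of shape (n_epochs, n_channels, n_samples), got {X.shape}"
        )
    if X.shape[2] < 2:
        raise ValidationError("epochs need at least 2 samples")
    if not np.isfinite(X).all():
        raise ValidationError("epoch data must be finite")
    return X


class _SSVEPClassifier(ClassifierMixin, BaseEstimator):
    """Shared plumbing: class handling, windowing, optional band-pass."""

    def __init__(self, fs=128.0, frequencies=None, window_seconds=None, bandpass=None):
        self.fs = fs
        self.frequencies = frequencies
        self.window_seconds = window_seconds
        self.bandpass = bandpass

    def _resolve_classes(self, y) -> np.ndarray:
        if self.frequencies is not None:
            freqs = np.sort(np.asarray(self.frequencies, dtype=float))
            if freqs.size < 2:
                raise ValidationError("need at least 2 candidate frequencies")
            if np.unique(freqs).size != freqs.size:
                raise ValidationError("duplicate candidate frequencies")
        elif y is not None:
            freqs = np.unique(np.asarray(y, dtype=float))
            if freqs.size < 2:
                raise ValidationError("y contains fewer than 2 distinct frequencies")
        else:
            raise ValidationError("provide `frequencies` or labels y at fit time")
        return freqs

    def _window(self, n_samples: int) -> int:
        if self.window_seconds is None:
            return n_samples
        w = int(round(self.window_seconds * self.fs))
        if w < 2 or w > n_samples:
            raise ValidationError(
                f"window of {self.window_seconds} s ({w} samples) invalid for "
                f"epochs of {n_samples} samples"
            )
        return w

    def _prepare(self, X) -> np.ndarray:
        X = _check_epochs_array(X)
        if self.bandpass is not None:
            X = bandpass_filter(X, self.fs, tuple(self.bandpass))
        return X

    # Subclasses implement decision_scores(X); predict is shared.
    def predict(self, X):
        check_is_fitted(self, "classes_")
        S = self.decision_scores(X)
        return np.array([_pick(self.classes_, row) for row in S])

    def fit(self, X=None, y=None):
        self.classes_ = self._resolve_classes(y)
        return self


class CCAClassifier(_SSVEPClassifier):
    """Standard CCA frequency recognition against sine-cosine references.

    Each candidate frequency is scored by the maximal canonical
    correlation between the (windowed) multichannel epoch and its
    reference matrix of ``n_harmonics`` sine-cosine pairs; the predicted
    frequency attains the maximal score.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    frequencies : sequence of float, optional
        Candidate stimulus frequencies; inferred from ``y`` at fit time
        if omitted.
    n_harmonics : int, default 4
        Harmonics in each reference matrix.
    ridge : float
        Relative ridge for the CCA solver.
    window_seconds : float, optional
        Analysis window (from epoch start); full epoch if None.
    """

    def __init__(
        self,
        fs=128.0,
        frequencies=None,
        n_harmonics=4,
        ridge=DEFAULT_RIDGE,
        time_origin="one_based",
        window_seconds=None,
        bandpass=None,
    ):
        super().__init__(fs, frequencies, window_seconds, bandpass)
        self.n_harmonics = n_harmonics
        self.ridge = ridge
        self.time_origin = time_origin

    def _bank(self, n_samples: int) -> ReferenceBank:
        return make_bank(
            self.classes_, self.n_harmonics, self.fs, n_samples, self.time_origin
        )

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = self._prepare(X)
        w = self._window(X.shape[2])
        bank = self._bank(w)
        S = np.empty((X.shape[0], self.classes_.size))
        for n, ep in enumerate(X):
            for k, f in enumerate(self.classes_):
                S[n, k] = cca(ep[:, :w], bank[f], ridge=self.ridge).rho
        return S


class PSDAClassifier(_SSVEPClassifier):
    """Power-spectral-density peak classification.

    Periodograms are computed per channel on the analysis window (zero-
    padded so the frequency grid is at least as fine as
    ``resolution_hz``), averaged across channels, and each candidate
    frequency is scored by the summed power within ``bin_tolerance_hz``
    of its fundamental and of any scored harmonics below Nyquist.
    """

    def __init__(
        self,
        fs=128.0,
        frequencies=None,
        harmonics_scored=1,
        bin_tolerance_hz=0.1,
        resolution_hz=0.05,
        window_seconds=None,
        bandpass=None,
    ):
        super().__init__(fs, frequencies, window_seconds, bandpass)
        self.harmonics_scored = harmonics_scored
        self.bin_tolerance_hz = bin_tolerance_hz
        self.resolution_hz = resolution_hz

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        if self.harmonics_scored < 1:
            raise ValidationError("harmonics_scored must be >= 1")
        X = self._prepare(X)
        w = self._window(X.shape[2])
        if w < self.fs:
            raise ValidationError(
                f"PSDA needs a window of >= 1 s ({self.fs:g} samples), got {w}"
            )
        if self.classes_.max() >= self.fs / 2:
            raise ValidationError("candidate frequency at or above Nyquist")
        nfft = max(w, int(np.ceil(self.fs / self.resolution_hz)))
        df = self.fs / nfft
        if self.bin_tolerance_hz < df / 2:
            raise ValidationError(
                f"bin_tolerance_hz={self.bin_tolerance_hz} is below half the "
                f"spectral resolution ({df:.4g} Hz); decrease resolution_hz "
                "to zero-pad further"
            )
        freqs, _ = sps.periodogram(np.zeros(w), fs=self.fs, nfft=nfft)
        S = np.empty((X.shape[0], self.classes_.size))
        for n, ep in enumerate(X):
            _, pxx = sps.periodogram(ep[:, :w], fs=self.fs, nfft=nfft, detrend="constant")
            mean_pxx = pxx.mean(axis=0)
            for k, f in enumerate(self.classes_):
                score = 0.0
                for q in range(1, self.harmonics_scored + 1):
                    if q * f >= self.fs / 2:
                        break
                    sel = np.abs(freqs - q * f) <= self.bin_tolerance_hz
                    score += mean_pxx[sel].sum()
                S[n, k] = score
        return S


class CPCCAClassifier(_SSVEPClassifier):
    """Channel-projection CCA with learned per-channel references.

    Fitting runs, for every (channel, frequency) pair, a CCA between the
    n x i matrix of that channel's training trials and the sine-cosine
    reference (``n_harmonics`` defaults to 2: fundamental plus second
    harmonic).  The projected variate — a single time series carrying the
    phase-locked component common to the trials — is stored, centered and
    scaled to unit variance, as the learned reference.  Prediction sums,
    over channels, the absolute Pearson correlation between the test
    channel and the learned reference, and takes the argmax over
    frequencies.

    Attributes
    ----------
    classes_ : ndarray
        Candidate frequencies, ascending.
    references_ : ndarray, shape (n_channels, n_classes, n_train_samples)
        Learned references, zero mean and unit variance each.
    n_train_trials_ : tuple of int
        Training trials per class.
    train_window_samples_ : int
        Reference length; prediction windows may not exceed it.
    """

    def __init__(
        self,
        fs=128.0,
        frequencies=None,
        n_harmonics=2,
        ridge=DEFAULT_RIDGE,
        time_origin="one_based",
        window_seconds=None,
        bandpass=None,
        channel_labels=None,
    ):
        super().__init__(fs, frequencies, window_seconds, bandpass)
        self.n_harmonics = n_harmonics
        self.ridge = ridge
        self.time_origin = time_origin
        self.channel_labels = channel_labels

    def fit(self, X, y):
        X = self._prepare(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("X and y length mismatch")
        self.classes_ = self._resolve_classes(y)
        n_epochs, h, i = X.shape
        if self.channel_labels is not None and len(self.channel_labels) != h:
            raise ValidationError(
                f"{len(self.channel_labels)} channel_labels for {h} data channels"
            )
        counts = []
        refs = np.empty((h, self.classes_.size, i))
        for k, f in enumerate(self.classes_):
            sel = np.isclose(y, f, atol=1e-6)
            n_f = int(sel.sum())
            if n_f == 0:
                raise ValidationError(f"no training trials for {f} Hz")
            counts.append(n_f)
            Y = make_reference(f, self.n_harmonics, self.fs, i, self.time_origin)
            for c in range(h):
                trials = X[sel, c, :]  # n_f x i stack of one channel
                refs[c, k] = cca(trials, Y, ridge=self.ridge).x_hat
        self.references_ = refs
        self.n_train_trials_ = tuple(counts)
        self.train_window_samples_ = i
        self.n_channels_ = h
        return self

    def decision_scores(self, X) -> np.ndarray:
        return self.per_channel_scores(X).sum(axis=1)

    def per_channel_scores(self, X) -> np.ndarray:
        """Scores rho_{h,f} of shape (n_epochs, n_channels, n_classes)."""
        check_is_fitted(self, "references_")
        X = self._prepare(X)
        if X.shape[1] != self.n_channels_:
            raise ValidationError(
                f"epoch has {X.shape[1]} channels, model trained with {self.n_channels_}"
            )
        w = self._window(X.shape[2])
        if w > self.train_window_samples_:
            raise ValidationError(
                f"window of {w} samples exceeds stored reference length "
                f"{self.train_window_samples_}"
            )
        S = np.empty((X.shape[0], self.n_channels_, self.classes_.size))
        for n, ep in enumerate(X):
            for c in range(self.n_channels_):
                for k in range(self.classes_.size):
                    S[n, c, k] = _abs_pearson(ep[c, :w], self.references_[c, k, :w])
        return S


# ---------------------------------------------------------------------------
# Functional interface over EEGEpoch / Dataset, plus model persistence.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CPCCAModel:
    """Persistable CP-CCA model: one learned reference per (channel, frequency)."""

    optimal_refs: Dict[Tuple[str, float], np.ndarray] = field(repr=False)
    n_train_trials: Tuple[int, ...]
    train_window_samples: int
    n_harmonics_train: int
    fs: float
    channel_labels: Tuple[str, ...]
    stimulus_set: Tuple[float, ...]

    def __post_init__(self):
        expected = {(c, f) for c in self.channel_labels for f in self.stimulus_set}
        if set(self.optimal_refs) != expected:
            raise ValidationError("optimal_refs must cover channels x stimulus_set")
        for key, ref in self.optimal_refs.items():
            if len(ref) != self.train_window_samples:
                raise ValidationError(f"reference {key} has wrong length")

    def to_estimator(self) -> CPCCAClassifier:
        est = CPCCAClassifier(
            fs=self.fs,
            frequencies=self.stimulus_set,
            n_harmonics=self.n_harmonics_train,
            channel_labels=self.channel_labels,
        )
        est.classes_ = np.sort(np.asarray(self.stimulus_set, dtype=float))
        est.references_ = np.stack(
            [
                np.stack([np.asarray(self.optimal_refs[(c, f)]) for f in est.classes_])
                for c in self.channel_labels
            ]
        )
        est.n_train_trials_ = tuple(self.n_train_trials)
        est.train_window_samples_ = self.train_window_samples
        est.n_channels_ = len(self.channel_labels)
        return est

    @classmethod
    def from_estimator(cls, est: CPCCAClassifier) -> "CPCCAModel":
        check_is_fitted(est, "references_")
        labels = (
            tuple(est.channel_labels)
            if est.channel_labels is not None
            else tuple(f"ch{k}" for k in range(est.n_channels_))
        )
        refs = {
            (c, float(f)): est.references_[ci, fi]
            for ci, c in enumerate(labels)
            for fi, f in enumerate(est.classes_)
        }
        return cls(
            optimal_refs=refs,
            n_train_trials=est.n_train_trials_,
            train_window_samples=est.train_window_samples_,
            n_harmonics_train=est.n_harmonics,
            fs=est.fs,
            channel_labels=labels,
            stimulus_set=tuple(float(f) for f in est.classes_),
        )

    def save(self, path) -> None:
        """Serialize to a JSON file (header + per-pair reference arrays)."""
        payload = {
            "format": "cpcca-model-v1",
            "fs": self.fs,
            "n_harmonics_train": self.n_harmonics_train,
            "train_window_samples": self.train_window_samples,
            "n_train_trials": list(self.n_train_trials),
            "channel_labels": list(self.channel_labels),
            "stimulus_set": list(self.stimulus_set),
            "references": [
                {"channel": c, "stimulus_hz": f, "values": np.asarray(v).tolist()}
                for (c, f), v in sorted(self.optimal_refs.items())
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "CPCCAModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "cpcca-model-v1":
            raise ValidationError(f"{path}: not a cpcca model file")
        refs = {
            (r["channel"], float(r["stimulus_hz"])): np.asarray(r["values"], dtype=float)
            for r in payload["references"]
        }
        return cls(
            optimal_refs=refs,
            n_train_trials=tuple(payload["n_train_trials"]),
            train_window_samples=int(payload["train_window_samples"]),
            n_harmonics_train=int(payload["n_harmonics_train"]),
            fs=float(payload["fs"]),
            channel_labels=tuple(payload["channel_labels"]),
            stimulus_set=tuple(float(f) for f in payload["stimulus_set"]),
        )


def _default_subset(available: Sequence[str], requested) -> Tuple[str, ...]:
    if requested is not None:
        return tuple(requested)
    if set(DEFAULT_CHANNELS) <= set(available):
        return tuple(c for c in available if c in DEFAULT_CHANNELS)
    return tuple(available)


def cca_classify(
    epoch: EEGEpoch,
    bank: ReferenceBank,
    window_samples: Optional[int] = None,
    channels: Optional[Sequence[str]] = None,
    ridge: float = DEFAULT_RIDGE,
) -> ClassificationResult:
    """Classify one epoch by standard CCA against a prebuilt reference bank."""
    w = bank.n_samples if window_samples is None else int(window_samples)
    if bank.n_samples != w:
        raise ValidationError(
            f"bank built for {bank.n_samples} samples, window asks {w}"
        )
    if bank.fs != epoch.fs:
        raise ValidationError(f"bank fs {bank.fs} != epoch fs {epoch.fs}")
    ep = epoch.select_channels(_default_subset(epoch.channel_labels, channels))
    data = ep.window(w)
    freqs = np.sort(np.asarray(bank.frequencies))
    scores = {float(f): cca(data, bank[float(f)], ridge=ridge).rho for f in freqs}
    return ClassificationResult(
        predicted_hz=_pick(freqs, np.array([scores[float(f)] for f in freqs])),
        scores=scores,
        window_samples=w,
    )


def psda_classify(
    epoch: EEGEpoch,
    stimulus_set: Sequence[float],
    window_samples: Optional[int] = None,
    harmonics_scored: int = 1,
    bin_tolerance_hz: float = 0.1,
    resolution_hz: float = 0.05,
    channels: Optional[Sequence[str]] = None,
) -> ClassificationResult:
    """Classify one epoch by channel-averaged periodogram peak power."""
    w = epoch.n_samples if window_samples is None else int(window_samples)
    ep = epoch.select_channels(_default_subset(epoch.channel_labels, channels))
    est = PSDAClassifier(
        fs=epoch.fs,
        frequencies=stimulus_set,
        harmonics_scored=harmonics_scored,
        bin_tolerance_hz=bin_tolerance_hz,
        resolution_hz=resolution_hz,
    ).fit()
    S = est.decision_scores(ep.window(w)[None])[0]
    scores = {float(f): float(s) for f, s in zip(est.classes_, S)}
    return ClassificationResult(
        predicted_hz=_pick(est.classes_, S), scores=scores, window_samples=w
    )


def cpcca_train(
    train: Dataset,
    channel_labels: Optional[Sequence[str]] = None,
    n_harmonics_train: int = 2,
    window_samples: Optional[int] = None,
    ridge: float = DEFAULT_RIDGE,
    time_origin: str = "one_based",
) -> CPCCAModel:
    """Learn CP-CCA references from a labeled dataset.

    ``channel_labels`` defaults to the O1/O2/P7/P8 montage when present.
    References are learned at the full trial length (or ``window_samples``)
    and truncated at classification time.
    """
    subset = _default_subset(train.channel_labels, channel_labels)
    ds = train.select_channels(subset)
    X, y = ds.arrays()
    if window_samples is not None:
        if window_samples > X.shape[2]:
            raise ValidationError("window_samples exceeds trial length")
        X = X[:, :, :window_samples]
    for f in ds.stimulus_set:
        if not np.isclose(y, f, atol=1e-6).any():
            raise ValidationError(f"no training trials for {f} Hz")
    est = CPCCAClassifier(
        fs=ds.fs,
        frequencies=ds.stimulus_set,
        n_harmonics=n_harmonics_train,
        ridge=ridge,
        time_origin=time_origin,
        channel_labels=subset,
    ).fit(X, y)
    return CPCCAModel.from_estimator(est)


def cpcca_classify(
    epoch: EEGEpoch, model: CPCCAModel, window_samples: Optional[int] = None
) -> ClassificationResult:
    """Classify one epoch with a trained CP-CCA model."""
    ep = epoch.select_channels(model.channel_labels)
    # select_channels preserves epoch order; realign to the model's order
    order = [ep.channel_labels.index(c) for c in model.channel_labels]
    data = ep.data[order]
    w = min(epoch.n_samples, model.train_window_samples) if window_samples is None else int(window_samples)
    est = model.to_estimator()
    if w < 2 or w > epoch.n_samples:
        raise ValidationError(f"window of {w} samples invalid for epoch")
    per = est.per_channel_scores(data[:, :w][None])[0]  # h x m
    S = per.sum(axis=0)
    scores = {float(f): float(s) for f, s in zip(est.classes_, S)}
    per_channel = {
        (c, float(f)): float(per[ci, fi])
        for ci, c in enumerate(model.channel_labels)
        for fi, f in enumerate(est.classes_)
    }
    return ClassificationResult(
        predicted_hz=_pick(est.classes_, S),
        scores=scores,
        window_samples=w,
        per_channel_scores=per_channel,
    )
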