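"""Evaluation protocols: cross-validation sweeps, ITR, and online sessions.

Offline evaluation uses leave-one-trial-out cross-validation: fold k
holds out trial k of every stimulus class as test data and (for CP-CCA)
trains on the remaining trials.  Sweeps repeat this over window lengths,
training-set sizes, and channel subsets.

The information transfer rate follows the Wolpaw formulation

    R = (60 / T) * [log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1))]

in bits per minute, where N is the number of equiprobable targets, P the
selection accuracy, and T the selection time in seconds (window plus any
gaze-shift interval).  The 0*log 0 convention applies at P in {0, 1}.

Online command sessions are modeled with error correction: completing a
task that needs ``n_required`` correct commands with ``e`` errors costs
``n_required + 2e`` commands in total (each error adds the wrong command
plus a corrective cancel), of which ``n_required + e`` are judged correct,
so accuracy is (n_required + e) / (n_required + 2e).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import CCAClassifier, CPCCAClassifier, PSDAClassifier
from .errors import ValidationError
from .io import DEFAULT_CHANNELS, Dataset

__all__ = [
    "ITRParams",
    "itr",
    "SessionLedger",
    "online_session",
    "EvaluationReport",
    "loto_cv",
    "window_sweep",
    "train_size_sweep",
    "channel_subset_eval",
    "HELICOPTER_STUDY_ERRORS",
    "helicopter_study_table",
]


# --------------------------------------------------------------------------
# Information transfer rate
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ITRParams:
    n_targets: int = 5
    accuracy: float = 1.0
    selection_seconds: float = 4.5

    def __post_init__(self):
        if self.n_targets < 2:
            raise ValidationError("n_targets must be >= 2")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValidationError("accuracy must be in [0, 1]")
        if self.selection_seconds <= 0:
            raise ValidationError("selection_seconds must be positive")


def itr(accuracy: float, selection_seconds: float, n_targets: int = 5) -> float:
    """Wolpaw information transfer rate in bits per minute.

    Chance-level accuracy (P = 1/N) carries zero bits; sub-chance
    accuracy yields negative values, which are reported as computed.
    """
    p = ITRParams(n_targets=n_targets, accuracy=accuracy, selection_seconds=selection_seconds)
    N, P, T = p.n_targets, p.accuracy, p.selection_seconds
    bits = math.log2(N)
    if P > 0:
        bits += P * math.log2(P)
    if P < 1:
        bits += (1 - P) * math.log2((1 - P) / (N - 1))
    return 60.0 / T * bits


# --------------------------------------------------------------------------
# Online command sessions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionLedger:
    """Bookkeeping of one online command session with error correction."""

    n_required: int
    error_count: int
    total_commands: int
    correct_commands: int
    accuracy_pct: float
    itr_bits_per_min: float
    selection_seconds: float

    def __post_init__(self):
        if self.total_commands != self.n_required + 2 * self.error_count:
            raise ValidationError("total = n_required + 2*errors violated")
        if self.correct_commands != self.n_required + self.error_count:
            raise ValidationError("correct = n_required + errors violated")
        if not 50.0 < self.accuracy_pct <= 100.0:
            raise ValidationError("session accuracy must lie in (50%, 100%]")


def online_session(
    n_required: int,
    error_count: int,
    selection_seconds: float = 4.5,
    n_targets: int = 5,
) -> SessionLedger:
    """Ledger of an online session needing ``n_required`` correct commands."""
    if n_required < 1:
        raise ValidationError("n_required must be >= 1")
    if error_count < 0:
        raise ValidationError("error_count must be >= 0")
    total = n_required + 2 * error_count
    correct = n_required + error_count
    acc = correct / total
    return SessionLedger(
        n_required=n_required,
        error_count=error_count,
        total_commands=total,
        correct_commands=correct,
        accuracy_pct=100.0 * acc,
        itr_bits_per_min=itr(acc, selection_seconds, n_targets),
        selection_seconds=selection_seconds,
    )


#: Error counts of the ten subjects in the 3-DOF helicopter control study
#: (18 required correct commands per task, 5 targets, 4 s window + 0.5 s
#: gaze-shift interval -> T = 4.5 s per selection).
HELICOPTER_STUDY_ERRORS = (0, 3, 1, 5, 3, 2, 4, 5, 5, 3)


def helicopter_study_table(
    errors: Sequence[int] = HELICOPTER_STUDY_ERRORS,
    n_required: int = 18,
    selection_seconds: float = 4.5,
    n_targets: int = 5,
) -> pd.DataFrame:
    """Per-subject session table for the helicopter control study.

    Columns: commands, accuracy_pct, itr_bits_per_min — rounded to the
    2-decimal reporting precision.  Summary means/SDs are computed over
    the rounded per-subject values (the convention of the study report).
    """
    rows = []
    for k, e in enumerate(errors, start=1):
        led = online_session(n_required, e, selection_seconds, n_targets)
        acc = round(led.accuracy_pct, 2)
        rows.append(
            {
                "subject": f"S{k}",
                "commands": led.total_commands,
                "accuracy_pct": acc,
                # ITR evaluated at the reported (2-decimal) accuracy
                "itr_bits_per_min": round(itr(acc / 100.0, selection_seconds, n_targets), 2),
            }
        )
    return pd.DataFrame(rows).set_index("subject")


# --------------------------------------------------------------------------
# Offline cross-validation and sweeps
# --------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Tidy results table plus confusion counts and the config that made it.

    ``rows`` has one row per (method, window_seconds, n_train, subset,
    fold) with columns n_test, n_correct, accuracy.  ``confusion`` maps a
    condition label to an m x m DataFrame (true x predicted counts).
    """

    rows: pd.DataFrame
    confusion: Dict[str, pd.DataFrame] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(self.rows["n_correct"].sum() / self.rows["n_test"].sum())

    def mean_table(self) -> pd.DataFrame:
        """Mean accuracy and ITR per condition (ITR at T = window_seconds)."""
        g = (
            self.rows.groupby(["method", "window_seconds", "n_train", "subset"])[
                ["n_test", "n_correct"]
            ]
            .sum()
            .reset_index()
        )
        g["accuracy"] = g["n_correct"] / g["n_test"]
        n_targets = self.config.get("n_targets", 5)
        g["itr_bits_per_min"] = [
            itr(a, t, n_targets) for a, t in zip(g["accuracy"], g["window_seconds"])
        ]
        return g

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _make_estimator(method: str, ds: Dataset, window_seconds, hyperparams: dict):
    hp = dict(hyperparams or {})
    common = dict(
        fs=ds.fs,
        frequencies=ds.stimulus_set,
        window_seconds=window_seconds,
    )
    if method == "cca":
        return CCAClassifier(**common, **hp)
    if method == "psda":
        return PSDAClassifier(**common, **hp)
    if method == "cpcca":
        return CPCCAClassifier(**common, channel_labels=ds.channel_labels, **hp)
    raise ValidationError(f"unknown method {method!r} (expected psda, cca, or cpcca)")


def _folds(ds: Dataset):
    """Align trials across classes: fold k holds out trial k of each class."""
    by_class = {f: ds.epochs_for(f) for f in ds.stimulus_set}
    counts = {f: len(v) for f, v in by_class.items()}
    if len(set(counts.values())) != 1:
        raise ValidationError(f"unequal trial counts per class: {counts}")
    n_trials = next(iter(counts.values()))
    if n_trials < 2:
        raise ValidationError("need at least 2 trials per class for LOTO CV")
    for f in by_class:
        by_class[f] = sorted(by_class[f], key=lambda ep: ep.trial_index)
    return by_class, n_trials


def _subset_label(channel_subset) -> str:
    return "+".join(channel_subset)


def _resolve_subset(ds: Dataset, channel_subset):
    if channel_subset is None:
        if set(DEFAULT_CHANNELS) <= set(ds.channel_labels):
            channel_subset = [c for c in ds.channel_labels if c in DEFAULT_CHANNELS]
        else:
            channel_subset = list(ds.channel_labels)
    if not channel_subset:
        raise ValidationError("channel subset is empty")
    return list(channel_subset)


def loto_cv(
    ds: Dataset,
    method: str,
    window_seconds: Optional[float] = None,
    channel_subset: Optional[Sequence[str]] = None,
    hyperparams: Optional[dict] = None,
) -> EvaluationReport:
    """Leave-one-trial-out cross-validation of one method on one dataset.

    With n trials per class this runs n folds; fold k tests trial k of
    every class.  CP-CCA is retrained per fold on the held-in trials;
    CCA and PSDA need no training and simply classify the held-out
    epochs.  Deterministic given the dataset.
    """
    channel_subset = _resolve_subset(ds, channel_subset)
    sub = ds.select_channels(channel_subset)
    by_class, n_trials = _folds(sub)
    freqs = list(sub.stimulus_set)
    window = window_seconds if window_seconds is not None else sub.epochs[0].n_samples / sub.fs

    records = []
    m = len(freqs)
    conf = np.zeros((m, m), dtype=int)
    for k in range(n_trials):
        test_eps = [by_class[f][k] for f in freqs]
        X_test = np.stack([ep.data for ep in test_eps])
        y_test = np.array(freqs)
        est = _make_estimator(method, sub, window, hyperparams)
        if method == "cpcca":
            train_eps = [ep for f in freqs for j, ep in enumerate(by_class[f]) if j != k]
            X_tr = np.stack([ep.data for ep in train_eps])
            y_tr = np.array([ep.stimulus_hz for ep in train_eps])
            est.window_seconds = None  # train at full length
            est.fit(X_tr, y_tr)
            est.window_seconds = window
        else:
            est.fit()
        pred = est.predict(X_test)
        correct = 0
        for t, p in zip(y_test, pred):
            ti = freqs.index(float(t))
            pi = int(np.argmin(np.abs(np.array(freqs) - p)))
            conf[ti, pi] += 1
            correct += int(abs(p - t) <= 1e-6)
        records.append(
            {
                "method": method,
                "window_seconds": window,
                "n_train": n_trials - 1 if method == "cpcca" else 0,
                "subset": _subset_label(channel_subset),
                "fold": k + 1,
                "n_test": len(test_eps),
                "n_correct": correct,
                "accuracy": correct / len(test_eps),
            }
        )
    rows = pd.DataFrame.from_records(records)
    label = f"{method}|w={window:g}|{_subset_label(channel_subset)}"
    confusion = {
        label: pd.DataFrame(conf, index=freqs, columns=freqs)
    }
    return EvaluationReport(
        rows=rows,
        confusion=confusion,
        config={
            "method": method,
            "window_seconds": window,
            "channel_subset": channel_subset,
            "hyperparams": dict(hyperparams or {}),
            "n_targets": m,
            "subject_id": sub.subject_id,
        },
    )


def _max_window_seconds(ds: Dataset) -> float:
    return min(ep.n_samples for ep in ds.epochs) / ds.fs


def window_sweep(
    ds: Dataset,
    methods: Sequence[str] = ("psda", "cca", "cpcca"),
    windows_seconds: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
    channel_subset: Optional[Sequence[str]] = None,
    hyperparams: Optional[Dict[str, dict]] = None,
) -> EvaluationReport:
    """LOTO-CV accuracy grid over methods x window lengths."""
    limit = _max_window_seconds(ds)
    for w in windows_seconds:
        if w > limit + 1e-9:
            raise ValidationError(f"window {w} s exceeds trial length {limit:g} s")
    parts, conf, cfgs = [], {}, []
    for method in methods:
        hp = (hyperparams or {}).get(method)
        for w in windows_seconds:
            rep = loto_cv(ds, method, w, channel_subset, hp)
            parts.append(rep.rows)
            conf.update(rep.confusion)
            cfgs.append(rep.config)
    return EvaluationReport(
        rows=pd.concat(parts, ignore_index=True),
        confusion=conf,
        config={"grid": cfgs, "n_targets": len(ds.stimulus_set)},
    )


def train_size_sweep(
    ds: Dataset,
    n_train_list: Sequence[int] = (2, 3, 4, 5, 6, 7, 8, 9),
    window_seconds: Optional[float] = None,
    channel_subset: Optional[Sequence[str]] = None,
    n_repeats: int = 20,
    seed: int = 0,
    hyperparams: Optional[dict] = None,
) -> EvaluationReport:
    """CP-CCA accuracy versus number of training trials.

    For each n, ``n_repeats`` seeded draws pick n trial indices per class
    for training; the remaining trials are classified and accuracies are
    averaged over repeats.  Trial indices are drawn once per repeat and
    shared across classes, preserving the aligned-trial design.
    """
    channel_subset = _resolve_subset(ds, channel_subset)
    sub = ds.select_channels(channel_subset)
    by_class, n_trials = _folds(sub)
    freqs = list(sub.stimulus_set)
    if max(n_train_list) >= n_trials:
        raise ValidationError(
            f"n_train must stay below the {n_trials} trials available per class"
        )
    if min(n_train_list) < 1:
        raise ValidationError("n_train must be >= 1")
    window = window_seconds if window_seconds is not None else _max_window_seconds(sub)
    rng = np.random.default_rng(seed)
    records = []
    for n in n_train_list:
        for rep in range(n_repeats):
            train_idx = rng.choice(n_trials, size=n, replace=False)
            train_mask = np.zeros(n_trials, dtype=bool)
            train_mask[train_idx] = True
            train_eps = [ep for f in freqs for j, ep in enumerate(by_class[f]) if train_mask[j]]
            test_eps = [ep for f in freqs for j, ep in enumerate(by_class[f]) if not train_mask[j]]
            est = CPCCAClassifier(
                fs=sub.fs,
                frequencies=freqs,
                channel_labels=sub.channel_labels,
                **(hyperparams or {}),
            )
            est.fit(
                np.stack([ep.data for ep in train_eps]),
                np.array([ep.stimulus_hz for ep in train_eps]),
            )
            est.window_seconds = window
            pred = est.predict(np.stack([ep.data for ep in test_eps]))
            truth = np.array([ep.stimulus_hz for ep in test_eps])
            correct = int((np.abs(pred - truth) <= 1e-6).sum())
            records.append(
                {
                    "method": "cpcca",
                    "window_seconds": window,
                    "n_train": n,
                    "subset": _subset_label(channel_subset),
                    "fold": rep + 1,
                    "n_test": len(test_eps),
                    "n_correct": correct,
                    "accuracy": correct / len(test_eps),
                }
            )
    return EvaluationReport(
        rows=pd.DataFrame.from_records(records),
        config={
            "n_train_list": list(n_train_list),
            "window_seconds": window,
            "n_repeats": n_repeats,
            "seed": seed,
            "n_targets": len(freqs),
        },
    )


def channel_subset_eval(
    ds: Dataset,
    subsets: Sequence[Sequence[str]],
    method: str = "cpcca",
    window_seconds: Optional[float] = None,
    hyperparams: Optional[dict] = None,
) -> EvaluationReport:
    """LOTO-CV accuracy per channel subset (montage comparison)."""
    if not subsets:
        raise ValidationError("no channel subsets given")
    parts, conf, cfgs = [], {}, []
    for subset in subsets:
        rep = loto_cv(ds, method, window_seconds, list(subset), hyperparams)
        parts.append(rep.rows)
        conf.update(rep.confusion)
        cfgs.append(rep.config)
    return EvaluationReport(
        rows=pd.concat(parts, ignore_index=True),
        confusion=conf,
        config={"grid": cfgs, "n_targets": len(ds.stimulus_set)},
    )
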