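"""Sine-cosine reference matrices for SSVEP frequency recognition.

For a stimulus frequency ``f`` and harmonic count ``j``, the reference is
the ``2j x i`` matrix stacking ``sin(2*pi*q*f*t), cos(2*pi*q*f*t)`` for
harmonics ``q = 1..j``, evaluated on the sample grid ``t = k/fs``.  The
grid is one-based (``k = 1..i``) by default; a zero-based grid
(``k = 0..i-1``) is offered for interoperability with other toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["ReferenceBank", "make_reference", "make_bank"]


@dataclass(frozen=True)
class ReferenceBank:
    """Per-frequency sine-cosine reference matrices of identical shape."""

    refs: Dict[float, np.ndarray] = field(repr=False)
    n_harmonics: int
    fs: float
    n_samples: int
    time_origin: str = "one_based"

    @property
    def frequencies(self) -> tuple:
        return tuple(self.refs)

    def __getitem__(self, f: float) -> np.ndarray:
        return self.refs[f]


def _time_grid(fs: float, n_samples: int, time_origin: str) -> np.ndarray:
    if time_origin == "one_based":
        k = np.arange(1, n_samples + 1)
    elif time_origin == "zero_based":
        k = np.arange(n_samples)
    else:
        raise ValidationError(
            f"time_origin must be 'one_based' or 'zero_based', got {time_origin!r}"
        )
    return k / fs


def make_reference(
    f: float,
    n_harmonics: int,
    fs: float,
    n_samples: int,
    time_origin: str = "one_based",
) -> np.ndarray:
    """Build the ``2*n_harmonics x n_samples`` reference matrix for ``f``.

    Rows are ordered sin(1f), cos(1f), ..., sin(jf), cos(jf).  Every
    harmonic must lie strictly below the Nyquist frequency ``fs/2``.
    """
    if f <= 0:
        raise ValidationError("stimulus frequency must be positive")
    if n_harmonics < 1:
        raise ValidationError("n_harmonics must be >= 1")
    if n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    if fs <= 0:
        raise ValidationError("fs must be positive")
    for q in range(1, n_harmonics + 1):
        if q * f >= fs / 2:
            raise ValidationError(
                f"harmonic {q} of {f} Hz is {q * f:g} Hz, at or above Nyquist "
                f"{fs / 2:g} Hz"
            )
    t = _time_grid(fs, n_samples, time_origin)
    rows = []
    for q in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * q * f * t
        rows.append(np.sin(w))
        rows.append(np.cos(w))
    return np.vstack(rows)


def make_bank(
    stimulus_set: Sequence[float],
    n_harmonics: int,
    fs: float,
    n_samples: int,
    time_origin: str = "one_based",
) -> ReferenceBank:
    """One reference matrix per stimulus frequency, identical shapes."""
    freqs = [float(f) for f in stimulus_set]
    if len(freqs) != len(set(freqs)):
        raise ValidationError("stimulus_set contains duplicate frequencies")
    if not freqs:
        raise ValidationError("stimulus_set is empty")
    refs = {
        f: make_reference(f, n_harmonics, fs, n_samples, time_origin) for f in freqs
    }
    return ReferenceBank(
        refs=refs,
        n_harmonics=int(n_harmonics),
        fs=float(fs),
        n_samples=int(n_samples),
        time_origin=time_origin,
    )
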