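"""Behavioral indices for rodent aging studies.

Implements the three scalar readouts used throughout the pipeline:

* novel-object-recognition (NOR) discrimination index,
  ``DI = (Tn - To) / Tt``;
* Y-maze spontaneous alternation percentage,
  ``SAB = 100 * n / (N - 2)`` where ``n`` counts consecutive arm-entry
  triplets visiting three distinct arms;
* trapezoid area under intake / glucose-tolerance curves.

The module consumes already-scored discrete data (exploration seconds,
arm-entry sequences); video tracking and pose estimation are upstream
and out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "ExplorationTimes",
    "ArmEntrySequence",
    "discrimination_index",
    "spontaneous_alternation",
    "curve_auc",
]

ARM_ALPHABET = frozenset("ABC")

#: slack allowed when checking Tn + To <= Tt
_TIME_TOL = 1e-6


@dataclass(frozen=True)
class ExplorationTimes:
    """Object-exploration seconds from one NOR session.

    ``t_total`` is an independent measurement (total object exploration
    time), not defined as ``t_new + t_old``; consistency is only checked
    with tolerance and a violation warns rather than fails.
    """

    t_new: float
    t_old: float
    t_total: float

    def __post_init__(self) -> None:
        if self.t_new < 0 or self.t_old < 0:
            raise DomainError("exploration times must be non-negative")
        if self.t_total <= 0:
            raise DomainError("t_total must be positive")


@dataclass(frozen=True)
class ArmEntrySequence:
    """Ordered Y-maze arm entries over the three-arm alphabet {A, B, C}."""

    entries: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = set(self.entries) - ARM_ALPHABET
        if bad:
            raise DomainError(f"arm labels outside {{A,B,C}}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)


def discrimination_index(t_new: float, t_old: float, t_total: float) -> float:
    """NOR discrimination index ``(Tn - To) / Tt`` in [-1, 1].

    Parameters
    ----------
    t_new, t_old, t_total
        Seconds exploring the novel object, the familiar object, and all
        objects. ``t_total`` must be positive.

    Raises
    ------
    DomainError
        If ``t_total <= 0`` or a time is negative.
    """
    times = ExplorationTimes(t_new, t_old, t_total)
    if times.t_new + times.t_old > times.t_total + _TIME_TOL:
        warnings.warn(
            f"t_new + t_old = {times.t_new + times.t_old:g} exceeds "
            f"t_total = {times.t_total:g}; DI computed anyway",
            stacklevel=2,
        )
    return (times.t_new - times.t_old) / times.t_total


def spontaneous_alternation(entries: Sequence[str] | ArmEntrySequence) -> float:
    """Y-maze spontaneous alternation percentage.

    A correct alternation is an overlapping window of three consecutive
    entries into three *different* arms. With ``N`` total entries and
    ``n`` correct alternations the score is ``100 * n / (N - 2)``.

    Raises
    ------
    DomainError
        If fewer than 3 entries (denominator undefined) or labels fall
        outside {A, B, C}.
    """
    if not isinstance(entries, ArmEntrySequence):
        entries = ArmEntrySequence(tuple(entries))
    seq = entries.entries
    n_total = len(seq)
    if n_total < 3:
        raise DomainError(f"need at least 3 arm entries, got {n_total}")
    n_alt = sum(
        len({seq[i], seq[i + 1], seq[i + 2]}) == 3 for i in range(n_total - 2)
    )
    return 100.0 * n_alt / (n_total - 2)


def curve_auc(times: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoid area under a sampled curve (e.g. liquid intake, GTT).

    ``times`` must be strictly increasing and match ``values`` in length
    (>= 2 points). Units are value x time.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
        raise DomainError(
            f"times and values must be 1-D of equal length, got {t.size} and {v.size}"
        )
    if t.size < 2:
        raise DomainError("need at least 2 points for a trapezoid integral")
    if np.any(np.diff(t) <= 0):
        raise DomainError("times must be strictly increasing (no duplicates)")
    return float(np.trapezoid(v, t))
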