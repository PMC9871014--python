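"""State and action label spaces, and categorical probability-vector validation.

A belief over diagnoses, a transition row, and a policy row are all the same
mathematical object: a point on the probability simplex aligned with an ordered
label space. Validation is centralised here so every downstream object
(belief tables, transition models, policies) enforces identical invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

#: Default tolerance on |sum(p) - 1|. Elicited probabilities (e.g. clinician
#: differentials written to two decimals) rarely sum exactly to 1.
DEFAULT_SUM_TOL = 1e-8


def _check_labels(labels: Sequence[str], kind: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if not labels:
        raise ValidationError(f"{kind} requires at least one label")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"{kind} labels must be unique; duplicated: {dupes}")
    return labels


@dataclass(frozen=True)
class StateSpace:
    """An ordered set of mutually exclusive patient states (e.g. diagnoses).

    The ordering is part of the object's identity: every probability vector
    referencing this space is aligned with ``labels`` positionally.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]) -> None:
        object.__setattr__(self, "labels", _check_labels(tuple(labels), "StateSpace"))

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(
                f"unknown state {label!r}; known states: {list(self.labels)}"
            ) from None


@dataclass(frozen=True)
class ActionSpace:
    """An ordered set of candidate actions (e.g. treatment regimens)."""

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]) -> None:
        object.__setattr__(self, "labels", _check_labels(tuple(labels), "ActionSpace"))

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(
                f"unknown action {label!r}; known actions: {list(self.labels)}"
            ) from None


def validate_prob_vector(
    values: Sequence[float] | np.ndarray,
    tolerance: float = DEFAULT_SUM_TOL,
    renormalize: bool = False,
    context: str = "probability vector",
) -> np.ndarray:
    """Validate (and optionally renormalize) a categorical probability vector.

    Parameters
    ----------
    values
        Non-empty sequence of probabilities.
    tolerance
        Maximum allowed deviation of ``sum(values)`` from 1. Deviations within
        tolerance pass; larger deviations raise.
    renormalize
        If true and the sum deviates from 1 by at most ``tolerance``, entries
        are divided by their sum so the result sums to exactly 1 in floating
        point. Negative entries are never repaired.
    context
        Name used in error messages (e.g. a sample id or a transition row).

    Returns
    -------
    numpy.ndarray
        A float64 copy of ``values`` satisfying the simplex invariants.
    """
    arr = np.asarray(values, dtype=np.float64).copy()
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{context}: must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{context}: entries must be finite")
    if np.any(arr < 0):
        bad = arr[arr < 0]
        raise ValidationError(f"{context}: negative entries not allowed ({bad.tolist()})")
    total = float(arr.sum())
    if abs(total - 1.0) > tolerance:
        raise ValidationError(
            f"{context}: entries sum to {total!r}, deviating from 1 by more "
            f"than tolerance {tolerance!r}"
        )
    if renormalize and total != 1.0:
        arr /= total
    return arr
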