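"""Per-sample categorical belief tables and their CSV representation.

A :class:`BeliefTable` holds one model's test-set outputs: for every sample a
probability distribution over a shared, ordered state space. The clinician
reference (the differential-diagnosis probabilities elicited without ML
assistance) is represented by the same type.

CSV layout: header ``sample_id,<state 1>,...,<state K>[,true_state]``, UTF-8,
"." decimal separator. The header's column order defines the state ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .spaces import DEFAULT_SUM_TOL, StateSpace, validate_prob_vector

TRUE_STATE_COLUMN = "true_state"
SAMPLE_ID_COLUMN = "sample_id"


@dataclass(frozen=True)
class BeliefTable:
    """Per-sample belief distributions over a shared state space.

    Parameters
    ----------
    state_space
        Ordered diagnosis/outcome labels shared by every row.
    sample_ids
        Unique sample identifiers, one per row.
    beliefs
        Array of shape ``(n_samples, n_states)``; each row a probability
        vector aligned with ``state_space.labels``.
    model_name
        Human-readable name of the model that produced the beliefs.
    true_states
        Optional ground-truth state label per sample. Never consumed by the
        actionability metric itself; used only by the stratified diagnostic
        report that exposes confidently-wrong models.
    """

    state_space: StateSpace
    sample_ids: tuple[str, ...]
    beliefs: np.ndarray
    model_name: str = "model"
    true_states: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValidationError(f"duplicate sample_id values: {dupes}")
        object.__setattr__(self, "sample_ids", ids)
        arr = np.asarray(self.beliefs, dtype=np.float64)
        if arr.ndim != 2 or arr.shape != (len(ids), len(self.state_space)):
            raise ValidationError(
                f"beliefs must have shape ({len(ids)}, {len(self.state_space)}); "
                f"got {arr.shape}"
            )
        rows = np.vstack(
            [
                validate_prob_vector(row, context=f"sample {sid!r}")
                for sid, row in zip(ids, arr)
            ]
        )
        rows.setflags(write=False)
        object.__setattr__(self, "beliefs", rows)
        if self.true_states is not None:
            ts = tuple(str(s) for s in self.true_states)
            if len(ts) != len(ids):
                raise ValidationError("true_states must have one entry per sample")
            unknown = sorted({s for s in ts if s not in self.state_space})
            if unknown:
                raise ValidationError(
                    f"true_state labels not in state space: {unknown}"
                )
            object.__setattr__(self, "true_states", ts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def belief_for(self, sample_id: str) -> np.ndarray:
        return self.beliefs[self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame in the on-disk column layout."""
        df = pd.DataFrame(self.beliefs, columns=list(self.state_space.labels))
        df.insert(0, SAMPLE_ID_COLUMN, list(self.sample_ids))
        if self.true_states is not None:
            df[TRUE_STATE_COLUMN] = list(self.true_states)
        return df

    def reorder_states(self, target: StateSpace) -> "BeliefTable":
        """Permute belief columns to match another ordering of the same labels."""
        if set(target.labels) != set(self.state_space.labels):
            raise AlignmentError(
                "cannot reorder: label sets differ "
                f"(symmetric difference: {sorted(set(target.labels) ^ set(self.state_space.labels))})"
            )
        perm = [self.state_space.index(lbl) for lbl in target.labels]
        return BeliefTable(
            state_space=target,
            sample_ids=self.sample_ids,
            beliefs=self.beliefs[:, perm],
            model_name=self.model_name,
            true_states=self.true_states,
        )


def read_belief_table(
    path: str | Path,
    model_name: str | None = None,
    tolerance: float = DEFAULT_SUM_TOL,
    renormalize: bool = False,
) -> BeliefTable:
    """Read a belief table from CSV.

    The header must be ``sample_id,<labels...>[,true_state]``; the column
    order defines the state-space ordering. Every row is validated as a
    probability vector; errors name the offending sample.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={SAMPLE_ID_COLUMN: str})
    if SAMPLE_ID_COLUMN not in df.columns:
        raise ValidationError(
            f"{path}: missing required {SAMPLE_ID_COLUMN!r} header column"
        )
    state_cols = [
        c for c in df.columns if c not in (SAMPLE_ID_COLUMN, TRUE_STATE_COLUMN)
    ]
    if not state_cols:
        raise ValidationError(f"{path}: no state probability columns found")
    ids = df[SAMPLE_ID_COLUMN].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample_id values: {dupes}")
    space = StateSpace(state_cols)
    raw = df[state_cols].to_numpy(dtype=np.float64)
    rows = []
    for sid, row in zip(ids, raw):
        rows.append(
            validate_prob_vector(
                row,
                tolerance=tolerance,
                renormalize=renormalize,
                context=f"{path}: sample {sid!r}",
            )
        )
    true_states = (
        tuple(df[TRUE_STATE_COLUMN].astype(str).tolist())
        if TRUE_STATE_COLUMN in df.columns
        else None
    )
    return BeliefTable(
        state_space=space,
        sample_ids=tuple(ids),
        beliefs=np.vstack(rows),
        model_name=model_name if model_name is not None else path.stem,
        true_states=true_states,
    )


def write_belief_table(table: BeliefTable, path: str | Path) -> None:
    """Write a belief table as CSV with round-trip-exact float formatting."""
    df = table.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def align_tables(
    reference: BeliefTable, candidate: BeliefTable
) -> tuple[BeliefTable, BeliefTable]:
    """Pair two belief tables by sample id on the reference's state ordering.

    Both tables must cover the same state-label *set* (order may differ) and
    the same sample-id set. The candidate's columns are permuted to the
    reference ordering and its rows re-sorted to the reference sample order,
    so downstream per-sample differences always compare the same patient
    under the same label alignment.
    """
    ref_labels = set(reference.state_space.labels)
    cand_labels = set(candidate.state_space.labels)
    if ref_labels != cand_labels:
        raise AlignmentError(
            "state label sets differ; symmetric difference: "
            f"{sorted(ref_labels ^ cand_labels)}"
        )
    ref_ids = set(reference.sample_ids)
    cand_ids = set(candidate.sample_ids)
    if ref_ids != cand_ids:
        missing_in_cand = sorted(ref_ids - cand_ids)
        missing_in_ref = sorted(cand_ids - ref_ids)
        raise AlignmentError(
            f"sample id sets differ; missing from candidate: {missing_in_cand}; "
            f"missing from reference: {missing_in_ref}"
        )
    cand = candidate.reorder_states(reference.state_space)
    if cand.sample_ids != reference.sample_ids:
        order = [cand.sample_ids.index(sid) for sid in reference.sample_ids]
        cand = BeliefTable(
            state_space=cand.state_space,
            sample_ids=reference.sample_ids,
            beliefs=cand.beliefs[order],
            model_name=cand.model_name,
            true_states=(
                tuple(cand.true_states[i] for i in order)
                if cand.true_states is not None
                else None
            ),
        )
    return reference, cand
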