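"""Transition models, policies, and policy-marginalized future-state distributions.

The action phase of the decision process is a one-step Markov model: a
transition tensor ``p*(s' | s, a)`` giving the probability of each next state
for every (current state, action) pair, and a policy ``pi(a | s)`` giving the
distribution over actions in each current state. Marginalizing the policy out
of the transition tensor yields the future-state distribution

    p(s' | s) = sum_a p*(s' | s, a) * pi(a | s),

a convex combination of transition rows, hence itself a valid distribution.

On disk both objects are JSON with explicit ``states`` and ``actions`` lists
and a nested ``table``: transitions keyed by state then action, policies
keyed by state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .spaces import ActionSpace, StateSpace, validate_prob_vector


@dataclass(frozen=True)
class TransitionModel:
    """One-step transition probabilities p*(s_{t+1} | s_t, a_t).

    ``table`` has shape ``(n_states, n_actions, n_states)``; ``table[s, a]``
    is the distribution over next states after taking action ``a`` in state
    ``s`` (the treatment's benefit:risk structure).
    """

    state_space: StateSpace
    action_space: ActionSpace
    table: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=np.float64)
        S, A = len(self.state_space), len(self.action_space)
        if arr.shape != (S, A, S):
            raise ValidationError(
                f"transition table must have shape ({S}, {A}, {S}); got {arr.shape}"
            )
        out = np.empty_like(arr)
        for i, s in enumerate(self.state_space.labels):
            for j, a in enumerate(self.action_space.labels):
                out[i, j] = validate_prob_vector(
                    arr[i, j], context=f"transition row (state={s!r}, action={a!r})"
                )
        out.setflags(write=False)
        object.__setattr__(self, "table", out)

    def row(self, state: str, action: str) -> np.ndarray:
        return self.table[self.state_space.index(state), self.action_space.index(action)]


@dataclass(frozen=True)
class Policy:
    """A (possibly stochastic) policy pi(a_t | s_t).

    ``table`` has shape ``(n_states, n_actions)``; each row is a distribution
    over actions. Deterministic choices are one-hot rows.
    """

    state_space: StateSpace
    action_space: ActionSpace
    table: np.ndarray
    policy_name: str = "policy"

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=np.float64)
        S, A = len(self.state_space), len(self.action_space)
        if arr.shape != (S, A):
            raise ValidationError(
                f"policy table must have shape ({S}, {A}); got {arr.shape}"
            )
        out = np.vstack(
            [
                validate_prob_vector(
                    arr[i], context=f"policy row (state={s!r}, policy={self.policy_name!r})"
                )
                for i, s in enumerate(self.state_space.labels)
            ]
        )
        out.setflags(write=False)
        object.__setattr__(self, "table", out)

    def action_distribution(self, state: str) -> np.ndarray:
        return self.table[self.state_space.index(state)]


def _require_shared_spaces(
    transitions: TransitionModel, policy: Policy
) -> None:
    if transitions.state_space != policy.state_space:
        raise ValidationError(
            "transition model and policy disagree on the state space: "
            f"{transitions.state_space.labels} vs {policy.state_space.labels}"
        )
    if transitions.action_space != policy.action_space:
        raise ValidationError(
            "transition model and policy disagree on the action space: "
            f"{transitions.action_space.labels} vs {policy.action_space.labels}"
        )


def future_state_distribution(
    transitions: TransitionModel, policy: Policy, current_state: str
) -> np.ndarray:
    """Marginalize the policy out of the transition tensor at one state.

    Returns ``p(s' | s) = sum_a p*(s' | s, a) * pi(a | s)`` — the convex
    combination of the state's transition rows weighted by the policy's
    action probabilities.
    """
    _require_shared_spaces(transitions, policy)
    i = transitions.state_space.index(current_state)
    weights = policy.table[i]  # (A,)
    return weights @ transitions.table[i]  # (A,) @ (A, S') -> (S',)


def belief_weighted_future_state(
    transitions: TransitionModel, policy: Policy, belief: Sequence[float]
) -> np.ndarray:
    """Future-state distribution under an uncertain current state.

    Extension beyond the core metric (which conditions on a known current
    state): averages the per-state future distributions under a belief b(s),
    ``p(s') = sum_s b(s) sum_a p*(s' | s, a) pi(a | s)``. Useful when the
    current state is itself only known through a diagnostic belief.
    """
    _require_shared_spaces(transitions, policy)
    b = validate_prob_vector(belief, context="current-state belief")
    if b.size != len(transitions.state_space):
        raise ValidationError(
            f"belief length {b.size} does not match state space size "
            f"{len(transitions.state_space)}"
        )
    per_state = np.einsum("sa,sat->st", policy.table, transitions.table)
    return b @ per_state


# ---------------------------------------------------------------------------
# JSON I/O


def _spaces_from_json(doc: Mapping, path: Path) -> tuple[StateSpace, ActionSpace]:
    for key in ("states", "actions"):
        if key not in doc:
            raise ValidationError(f"{path}: missing required key {key!r}")
    return StateSpace(doc["states"]), ActionSpace(doc["actions"])


def read_transition_model(path: str | Path) -> TransitionModel:
    """Read a transition model from JSON keyed by state then action."""
    path = Path(path)
    doc = json.loads(path.read_text())
    states, actions = _spaces_from_json(doc, path)
    table = np.empty((len(states), len(actions), len(states)))
    tbl = doc.get("table")
    if not isinstance(tbl, Mapping):
        raise ValidationError(f"{path}: missing or malformed 'table'")
    for i, s in enumerate(states.labels):
        if s not in tbl:
            raise ValidationError(f"{path}: table missing state {s!r}")
        for j, a in enumerate(actions.labels):
            if a not in tbl[s]:
                raise ValidationError(f"{path}: table[{s!r}] missing action {a!r}")
            table[i, j] = np.asarray(tbl[s][a], dtype=np.float64)
    return TransitionModel(state_space=states, action_space=actions, table=table)


def write_transition_model(model: TransitionModel, path: str | Path) -> None:
    doc = {
        "states": list(model.state_space.labels),
        "actions": list(model.action_space.labels),
        "table": {
            s: {
                a: model.table[i, j].tolist()
                for j, a in enumerate(model.action_space.labels)
            }
            for i, s in enumerate(model.state_space.labels)
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_policy(path: str | Path) -> Policy:
    """Read a policy from JSON keyed by state."""
    path = Path(path)
    doc = json.loads(path.read_text())
    states, actions = _spaces_from_json(doc, path)
    tbl = doc.get("table")
    if not isinstance(tbl, Mapping):
        raise ValidationError(f"{path}: missing or malformed 'table'")
    table = np.empty((len(states), len(actions)))
    for i, s in enumerate(states.labels):
        if s not in tbl:
            raise ValidationError(f"{path}: table missing state {s!r}")
        table[i] = np.asarray(tbl[s], dtype=np.float64)
    return Policy(
        state_space=states,
        action_space=actions,
        table=table,
        policy_name=str(doc.get("name", path.stem)),
    )


def write_policy(policy: Policy, path: str | Path) -> None:
    doc = {
        "name": policy.policy_name,
        "states": list(policy.state_space.labels),
        "actions": list(policy.action_space.labels),
        "table": {
            s: policy.table[i].tolist()
            for i, s in enumerate(policy.state_space.labels)
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
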