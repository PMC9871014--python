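"""Shared fixtures and independent oracles for the test suite.

The oracle functions here are deliberately written as plain-Python loops
(math.log, triple loops) so they share no code path with the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from actionability import BeliefTable, Policy, StateSpace, ActionSpace, TransitionModel


# ---------------------------------------------------------------------------
# Independent oracles


def entropy_oracle(p, base=2.0) -> float:
    """Direct-summation Shannon entropy, 0 log 0 := 0."""
    total = 0.0
    for x in p:
        if x > 0:
            total -= x * math.log(x, base)
    return total


def cross_entropy_oracle(p, q, base=2.0) -> float:
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            if qi == 0:
                return math.inf
            total -= pi * math.log(qi, base)
    return total


def kl_oracle(p, q, base=2.0) -> float:
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            if qi == 0:
                return math.inf
            total += pi * math.log(pi / qi, base)
    return total


def marginalize_oracle(trans_table, policy_row) -> list[float]:
    """Triple-loop policy marginalization: p(s') = sum_a pi(a) p*(s'|s,a).

    ``trans_table`` is the (A, S') slice for one current state.
    """
    n_actions = len(trans_table)
    n_next = len(trans_table[0])
    out = [0.0] * n_next
    for sp in range(n_next):
        for a in range(n_actions):
            out[sp] += policy_row[a] * trans_table[a][sp]
    return out


def random_simplex(rng, k):
    """Random point on the k-simplex (exponential spacings)."""
    x = rng.exponential(size=k)
    return x / x.sum()


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def four_state_space():
    return StateSpace(["infection", "malignancy", "heart_failure", "drug_fever"])


@pytest.fixture
def uniform_reference(four_state_space):
    """Clinician reference: uniform differential over 4 diagnoses, 6 samples."""
    n = 6
    return BeliefTable(
        state_space=four_state_space,
        sample_ids=tuple(f"p{i}" for i in range(n)),
        beliefs=np.full((n, 4), 0.25),
        model_name="clinician",
    )


@pytest.fixture
def two_state_dynamics():
    """The 2-outcome / 2-action mixture used in the worked examples.

    Action A resolves with 0.9, action B with 0.5; outcomes are
    {resolve, persist}.
    """
    states = StateSpace(["resolve", "persist"])
    actions = ActionSpace(["A", "B"])
    table = np.array([
        [[0.9, 0.1], [0.5, 0.5]],  # from "resolve"
        [[0.9, 0.1], [0.5, 0.5]],  # from "persist" (same rows; simple fixture)
    ])
    transitions = TransitionModel(state_space=states, action_space=actions, table=table)
    mixed = Policy(states, actions, np.array([[0.5, 0.5], [0.5, 0.5]]),
                   policy_name="clinician")
    det_a = Policy(states, actions, np.array([[1.0, 0.0], [1.0, 0.0]]),
                   policy_name="model")
    return transitions, mixed, det_a
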