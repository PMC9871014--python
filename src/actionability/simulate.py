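"""Synthetic clinical-scenario generator.

Emulates the data an actionability study needs but which must otherwise be
elicited from clinicians: a paired reference/candidate belief table over a
set of diagnoses, a transition model describing treatment benefit:risk
structure, and clinician/model policies. Everything is reproducible from a
single seed.

Generative scheme
-----------------
* True states are drawn uniformly over the state space.
* Reference ("clinician") beliefs are symmetric-Dirichlet draws whose
  concentration on the true state is tilted upward, mimicking a clinician
  whose differential is centred on the right diagnosis but diffuse.
* Candidate ("model") beliefs are the reference beliefs sharpened by a
  temperature: ``b_m propto b_c ** (1 / T)``. ``T < 1`` sharpens (a model
  more confident than the clinician), ``T = 1`` reproduces the reference
  exactly, ``T > 1`` flattens. Sharpening never changes the argmax, so the
  candidate agrees with the reference about the leading diagnosis and
  differs only in confidence — which makes the induced entropy reduction
  analytically controllable.
* Transition rows are independent symmetric-Dirichlet draws.
* The reference policy is uniform over actions (a maximally uncertain
  prescriber); the candidate policy deterministically picks, per state, the
  action maximizing the probability of a designated desired next state.

Seeding uses ``numpy.random.SeedSequence`` stream splitting: the global seed
spawns one child stream per concern and one per sample, so increasing
``n_samples`` extends the cohort without perturbing earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beliefs import BeliefTable, write_belief_table
from .dynamics import Policy, TransitionModel, write_policy, write_transition_model
from .errors import ValidationError
from .spaces import ActionSpace, StateSpace


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic scenario.

    Parameters
    ----------
    n_states, n_actions, n_samples
        Sizes of the state space (>= 2), action space (>= 1), and cohort
        (>= 1).
    reference_concentration
        Symmetric Dirichlet concentration of the clinician beliefs; 1 is
        uniform on the simplex, larger values concentrate near uniform
        probabilities, smaller values near the corners.
    candidate_temperature
        Sharpening temperature T applied to the reference beliefs
        (``b ** (1/T)``, renormalized); < 1 sharpens, 1 is the identity,
        > 1 flattens.
    transition_concentration
        Symmetric Dirichlet concentration of each transition row.
    true_state_tilt
        Multiplier applied to the Dirichlet concentration of the true
        state's coordinate when drawing reference beliefs (> 1 biases the
        clinician toward the correct diagnosis).
    desired_state_index
        Index of the next state the candidate policy steers toward
        (``0`` by convention: the first state plays the role of the
        favourable outcome, e.g. resolution).
    seed
        Global seed; all randomness derives from it.
    """

    n_states: int = 4
    n_actions: int = 3
    n_samples: int = 500
    reference_concentration: float = 1.0
    candidate_temperature: float = 0.5
    transition_concentration: float = 1.0
    true_state_tilt: float = 3.0
    desired_state_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if self.n_actions < 1:
            raise ValidationError("n_actions must be >= 1")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        for name in (
            "reference_concentration",
            "candidate_temperature",
            "transition_concentration",
            "true_state_tilt",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.desired_state_index < self.n_states:
            raise ValidationError("desired_state_index out of range")


@dataclass(frozen=True)
class Scenario:
    """All objects produced by :func:`generate_scenario`."""

    reference: BeliefTable
    candidate: BeliefTable
    transitions: TransitionModel
    reference_policy: Policy
    candidate_policy: Policy
    true_states: tuple[str, ...]
    config: ScenarioConfig


def sharpen(beliefs: np.ndarray, temperature: float) -> np.ndarray:
    """Temperature-sharpen belief rows: ``b ** (1/T)`` renormalized.

    ``T == 1`` returns the input unchanged (exactly, no renormalization);
    ``T -> 0`` approaches one-hot on the argmax. The argmax of every row is
    preserved for any T > 0.
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    if temperature == 1.0:
        return np.array(beliefs, dtype=np.float64, copy=True)
    b = np.asarray(beliefs, dtype=np.float64)
    # log-space with per-row max subtraction: stable for extreme temperatures
    # where a direct power would underflow every entry to zero
    with np.errstate(divide="ignore"):
        scaled = np.log(b) / temperature
    scaled -= scaled.max(axis=1, keepdims=True)
    powered = np.exp(scaled)
    return powered / powered.sum(axis=1, keepdims=True)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a full synthetic scenario from a config.

    Returns paired reference/candidate belief tables (both carrying the true
    states), a transition model, the uniform reference policy, the
    one-hot candidate policy, and the true-state labels.
    """
    states = StateSpace([f"s{i}" for i in range(config.n_states)])
    actions = ActionSpace([f"a{i}" for i in range(config.n_actions)])
    root = np.random.SeedSequence(config.seed)
    trans_ss, samples_ss = root.spawn(2)

    # transitions: one Dirichlet row per (state, action)
    trans_rng = np.random.default_rng(trans_ss)
    alpha_t = np.full(config.n_states, config.transition_concentration)
    table = trans_rng.dirichlet(alpha_t, size=(config.n_states, config.n_actions))
    transitions = TransitionModel(state_space=states, action_space=actions, table=table)

    # per-sample streams: adding samples never perturbs earlier draws
    K = config.n_states
    ref_rows = np.empty((config.n_samples, K))
    true_idx = np.empty(config.n_samples, dtype=np.intp)
    for i, child in enumerate(samples_ss.spawn(config.n_samples)):
        rng = np.random.default_rng(child)
        t = rng.integers(0, K)
        alpha = np.full(K, config.reference_concentration)
        alpha[t] *= config.true_state_tilt
        ref_rows[i] = rng.dirichlet(alpha)
        true_idx[i] = t
    true_states = tuple(states.labels[t] for t in true_idx)
    sample_ids = tuple(f"sample_{i:04d}" for i in range(config.n_samples))

    reference = BeliefTable(
        state_space=states,
        sample_ids=sample_ids,
        beliefs=ref_rows,
        model_name="clinician_reference",
        true_states=true_states,
    )
    candidate = BeliefTable(
        state_space=states,
        sample_ids=sample_ids,
        beliefs=sharpen(ref_rows, config.candidate_temperature),
        model_name="candidate_model",
        true_states=true_states,
    )

    reference_policy = Policy(
        state_space=states,
        action_space=actions,
        table=np.full((config.n_states, config.n_actions), 1.0 / config.n_actions),
        policy_name="clinician_uniform",
    )
    # candidate policy: per state, one-hot on the action most likely to reach
    # the desired next state
    best = table[:, :, config.desired_state_index].argmax(axis=1)
    cand_table = np.zeros((config.n_states, config.n_actions))
    cand_table[np.arange(config.n_states), best] = 1.0
    candidate_policy = Policy(
        state_space=states,
        action_space=actions,
        table=cand_table,
        policy_name="model_greedy",
    )
    return Scenario(
        reference=reference,
        candidate=candidate,
        transitions=transitions,
        reference_policy=reference_policy,
        candidate_policy=candidate_policy,
        true_states=true_states,
        config=config,
    )


def write_scenario(scenario: Scenario, directory: str | Path) -> dict[str, Path]:
    """Write all scenario files into a directory.

    Emits ``reference.csv``, ``candidate.csv``, ``transitions.json``,
    ``reference_policy.json``, ``candidate_policy.json``, and ``states.csv``
    (``sample_id,current_state``). Output is byte-identical across runs with
    the same config, and round-trips through the package readers.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": directory / "reference.csv",
            "candidate": directory / "candidate.csv",
            "transitions": directory / "transitions.json",
            "reference_policy": directory / "reference_policy.json",
            "candidate_policy": directory / "candidate_policy.json",
            "states": directory / "states.csv",
        }
        write_belief_table(scenario.reference, paths["reference"])
        write_belief_table(scenario.candidate, paths["candidate"])
        write_transition_model(scenario.transitions, paths["transitions"])
        write_policy(scenario.reference_policy, paths["reference_policy"])
        write_policy(scenario.candidate_policy, paths["candidate_policy"])
        lines = ["sample_id,current_state"]
        lines += [
            f"{sid},{st}"
            for sid, st in zip(scenario.reference.sample_ids, scenario.true_states)
        ]
        paths["states"].write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing scenario into {directory}: {exc}") from exc
    return paths


def read_current_states(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Read a ``sample_id,current_state`` CSV; returns (ids, states)."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "current_state"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return tuple(df["sample_id"]), tuple(df["current_state"])
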