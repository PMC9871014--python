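"""Policy marginalization and the action-phase metric, both modes."""

import json
import math

import numpy as np
import pytest

from actionability import (
    ActionActionability,
    ActionPhaseOptions,
    ActionSpace,
    EntropyOptions,
    Policy,
    StateSpace,
    TransitionModel,
    ValidationError,
    action_actionability,
    belief_weighted_future_state,
    future_state_distribution,
    kl_divergence,
    read_policy,
    read_transition_model,
    write_policy,
    write_transition_model,
)
from conftest import entropy_oracle, marginalize_oracle, random_simplex

BITS = EntropyOptions(log_base=2)


def random_dynamics(rng, n_states, n_actions):
    states = StateSpace([f"s{i}" for i in range(n_states)])
    actions = ActionSpace([f"a{i}" for i in range(n_actions)])
    table = np.stack(
        [
            np.stack([random_simplex(rng, n_states) for _ in range(n_actions)])
            for _ in range(n_states)
        ]
    )
    transitions = TransitionModel(states, actions, table)
    pol = Policy(
        states, actions,
        np.stack([random_simplex(rng, n_actions) for _ in range(n_states)]),
    )
    return transitions, pol


class TestFutureStateDistribution:
    def test_mixture_worked_example(self, two_state_dynamics):
        transitions, mixed, _ = two_state_dynamics
        np.testing.assert_allclose(
            future_state_distribution(transitions, mixed, "resolve"), [0.7, 0.3]
        )

    def test_deterministic_policy_selects_row(self, two_state_dynamics):
        transitions, _, det_a = two_state_dynamics
        np.testing.assert_allclose(
            future_state_distribution(transitions, det_a, "persist"), [0.9, 0.1]
        )

    def test_identical_rows_any_policy(self):
        states = StateSpace(["x", "y"])
        actions = ActionSpace(["A", "B", "C"])
        table = np.tile(np.array([0.6, 0.4]), (2, 3, 1))
        tm = TransitionModel(states, actions, table)
        pol = Policy(states, actions, np.array([[0.2, 0.3, 0.5], [1, 0, 0]]))
        np.testing.assert_allclose(
            future_state_distribution(tm, pol, "x"), [0.6, 0.4], atol=1e-15
        )

    def test_unknown_state_raises(self, two_state_dynamics):
        transitions, mixed, _ = two_state_dynamics
        with pytest.raises(ValidationError, match="unknown state"):
            future_state_distribution(transitions, mixed, "cured")

    def test_mismatched_spaces_raise(self, two_state_dynamics):
        transitions, _, _ = two_state_dynamics
        other = Policy(
            StateSpace(["resolve", "persist"]),
            ActionSpace(["A", "Z"]),
            np.array([[0.5, 0.5], [0.5, 0.5]]),
        )
        with pytest.raises(ValidationError, match="action space"):
            future_state_distribution(transitions, other, "resolve")

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            S = int(rng.integers(2, 5))
            A = int(rng.integers(1, 4))
            transitions, pol = random_dynamics(rng, S, A)
            s = f"s{rng.integers(0, S)}"
            got = future_state_distribution(transitions, pol, s)
            i = transitions.state_space.index(s)
            want = marginalize_oracle(
                transitions.table[i].tolist(), pol.table[i].tolist()
            )
            np.testing.assert_allclose(got, want, atol=1e-12, rtol=0)
            assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_linear_in_policy(self):
        rng = np.random.default_rng(3)
        transitions, p1 = random_dynamics(rng, 3, 3)
        _, p2 = random_dynamics(rng, 3, 3)
        p2 = Policy(transitions.state_space, transitions.action_space, p2.table)
        w = 0.3
        mix = Policy(
            transitions.state_space,
            transitions.action_space,
            w * p1.table + (1 - w) * p2.table,
        )
        for s in transitions.state_space.labels:
            f1 = future_state_distribution(transitions, p1, s)
            f2 = future_state_distribution(transitions, p2, s)
            fm = future_state_distribution(transitions, mix, s)
            np.testing.assert_allclose(fm, w * f1 + (1 - w) * f2, atol=1e-12)

    def test_belief_weighted_extension(self, two_state_dynamics):
        transitions, mixed, _ = two_state_dynamics
        # rows identical across current states, so any belief gives [0.7, 0.3]
        np.testing.assert_allclose(
            belief_weighted_future_state(transitions, mixed, [0.4, 0.6]),
            [0.7, 0.3],
            atol=1e-15,
        )


class TestActionActionability:
    def test_self_entropy_worked_example(self, two_state_dynamics):
        transitions, mixed, det_a = two_state_dynamics
        res = action_actionability(
            transitions, mixed, det_a, ["resolve", "persist", "resolve"]
        )
        # frozen from the direct-summation oracle:
        # H([0.7,0.3]) = 0.8812908992306927, H([0.9,0.1]) = 0.4689955935892812
        assert res.mean_delta == pytest.approx(0.4122953056414115, abs=1e-12)
        assert res.mode == "self_entropy"
        np.testing.assert_allclose(
            res.per_sample_reference_entropy, entropy_oracle([0.7, 0.3]), atol=1e-12
        )

    def test_identical_policies_zero_delta_both_modes(self, two_state_dynamics):
        transitions, mixed, _ = two_state_dynamics
        for mode in ("self_entropy", "as_printed"):
            res = action_actionability(
                transitions, mixed, mixed, ["resolve"],
                options=ActionPhaseOptions(mode=mode),
            )
            assert res.mean_delta == 0.0

    def test_as_printed_is_negative_kl(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            S = int(rng.integers(2, 5))
            A = int(rng.integers(1, 4))
            transitions, p_ref = random_dynamics(rng, S, A)
            _, p_cand = random_dynamics(rng, S, A)
            p_cand = Policy(
                transitions.state_space, transitions.action_space, p_cand.table
            )
            states = [f"s{rng.integers(0, S)}" for _ in range(3)]
            res = action_actionability(
                transitions, p_ref, p_cand, states,
                options=ActionPhaseOptions(mode="as_printed"),
            )
            for rec in res.future_states:
                assert rec.delta <= 1e-12
                assert rec.delta == pytest.approx(
                    -kl_divergence(rec.reference_future, rec.candidate_future, BITS),
                    abs=1e-12,
                )

    def test_self_entropy_role_symmetry(self, two_state_dynamics):
        transitions, mixed, det_a = two_state_dynamics
        fwd = action_actionability(transitions, mixed, det_a, ["resolve"])
        rev = action_actionability(transitions, det_a, mixed, ["resolve"])
        assert fwd.mean_delta == pytest.approx(-rev.mean_delta, abs=1e-15)

    def test_unknown_current_state_raises(self, two_state_dynamics):
        transitions, mixed, det_a = two_state_dynamics
        with pytest.raises(ValidationError, match="unknown state"):
            ActionActionability(transitions, mixed, det_a, ["nope"])

    def test_infinite_delta_flagged(self):
        states = StateSpace(["x", "y"])
        actions = ActionSpace(["A", "B"])
        table = np.array(
            [[[1.0, 0.0], [0.5, 0.5]], [[1.0, 0.0], [0.5, 0.5]]]
        )
        tm = TransitionModel(states, actions, table)
        ref = Policy(states, actions, np.array([[0.5, 0.5], [0.5, 0.5]]))
        cand = Policy(states, actions, np.array([[1.0, 0.0], [1.0, 0.0]]))
        res = action_actionability(
            tm, ref, cand, ["x"], options=ActionPhaseOptions(mode="as_printed")
        )
        assert math.isinf(res.mean_delta)
        assert any("infinite" in w for w in res.warnings)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValidationError, match="mode"):
            ActionPhaseOptions(mode="both")


class TestDynamicsJSON:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        transitions, pol = random_dynamics(rng, 3, 2)
        tp, pp = tmp_path / "t.json", tmp_path / "p.json"
        write_transition_model(transitions, tp)
        write_policy(pol, pp)
        t2, p2 = read_transition_model(tp), read_policy(pp)
        assert t2.state_space == transitions.state_space
        assert t2.action_space == transitions.action_space
        np.testing.assert_allclose(t2.table, transitions.table, atol=1e-12, rtol=0)
        np.testing.assert_allclose(p2.table, pol.table, atol=1e-12, rtol=0)

    def test_missing_key_errors(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"states": ["a", "b"]}))
        with pytest.raises(ValidationError, match="actions"):
            read_transition_model(p)

    def test_invalid_row_names_state_action(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({
            "states": ["a", "b"],
            "actions": ["x"],
            "table": {"a": {"x": [0.5, 0.4]}, "b": {"x": [0.5, 0.5]}},
        }))
        with pytest.raises(ValidationError, match="state='a'"):
            read_transition_model(p)
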