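"""Net benefit / decision-curve companion.

Actionability is an early-development screen; net benefit is the
final-stage clinical-utility metric it feeds into. The standard
decision-curve quantity at threshold probability t is

    NB(t) = TP/n - FP/n * t / (1 - t),

comparing the model's classify-positive-at-t policy against treat-all
(NB = prevalence - (1 - prevalence) * t / (1 - t)) and treat-none (NB = 0).
This formula comes from the decision-curve-analysis literature; it is
included here as the downstream companion, not as part of the entropy
metric itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beliefs import BeliefTable
from .errors import ValidationError


@dataclass(frozen=True)
class NetBenefitCurve:
    """Net benefit at each threshold for model, treat-all, and treat-none."""

    thresholds: np.ndarray
    model_nb: np.ndarray
    treat_all_nb: np.ndarray
    treat_none_nb: np.ndarray
    n: int
    prevalence: float

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "model_nb": self.model_nb.tolist(),
            "treat_all_nb": self.treat_all_nb.tolist(),
            "treat_none_nb": self.treat_none_nb.tolist(),
            "n": self.n,
            "prevalence": self.prevalence,
        }


def net_benefit(binary_probs, outcomes, thresholds) -> NetBenefitCurve:
    """Decision-curve net benefit of a binary risk model.

    Parameters
    ----------
    binary_probs
        Per-sample predicted probability of the positive class, in [0, 1].
    outcomes
        Per-sample binary truth (0/1 or bool).
    thresholds
        Probability thresholds, each strictly inside (0, 1). A sample is
        classified positive when its probability is >= t (inclusive).
    """
    probs = np.asarray(binary_probs, dtype=np.float64)
    y = np.asarray(outcomes)
    if probs.ndim != 1 or y.shape != probs.shape:
        raise ValidationError("binary_probs and outcomes must be equal-length 1-D")
    if np.any((probs < 0) | (probs > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValidationError(f"outcomes must be binary 0/1; got values {uniq.tolist()}")
    y = y.astype(np.float64)
    t = np.asarray(thresholds, dtype=np.float64)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("thresholds must be a non-empty 1-D sequence")
    if np.any((t <= 0) | (t >= 1)):
        raise ValidationError("thresholds must lie strictly inside (0, 1)")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("thresholds must be strictly increasing")

    n = probs.size
    prevalence = float(y.mean())
    pred = probs[None, :] >= t[:, None]  # (T, n)
    tp = (pred & (y[None, :] == 1)).sum(axis=1) / n
    fp = (pred & (y[None, :] == 0)).sum(axis=1) / n
    odds = t / (1.0 - t)
    return NetBenefitCurve(
        thresholds=t,
        model_nb=tp - fp * odds,
        treat_all_nb=prevalence - (1.0 - prevalence) * odds,
        treat_none_nb=np.zeros_like(t),
        n=n,
        prevalence=prevalence,
    )


def binarize_beliefs(table: BeliefTable, positive_state: str) -> np.ndarray:
    """Extract one state's column as the positive-class probability.

    Bridges multiclass beliefs to the binary net-benefit computation by
    treating ``positive_state`` vs everything else as the binary outcome.
    """
    j = table.state_space.index(positive_state)
    return table.beliefs[:, j].copy()


def binary_outcomes(table: BeliefTable, positive_state: str) -> np.ndarray:
    """Binary ground truth (true_state == positive_state) from a table."""
    if table.true_states is None:
        raise ValidationError("table has no true_states; cannot derive outcomes")
    if positive_state not in table.state_space:
        raise ValidationError(f"unknown state {positive_state!r}")
    return (np.asarray(table.true_states) == positive_state).astype(int)


def plot_decision_curve(curve: NetBenefitCurve, ax=None):
    """Plot the decision curve (model vs treat-all vs treat-none)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.thresholds, curve.model_nb, label="model")
    ax.plot(curve.thresholds, curve.treat_all_nb, label="treat all", ls="--")
    ax.plot(curve.thresholds, curve.treat_none_nb, label="treat none", ls=":")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.05, float(curve.model_nb.min()) - 0.05))
    ax.legend()
    return ax
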