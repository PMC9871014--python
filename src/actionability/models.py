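"""Actionability models: entropy reduction at the diagnosis and action phases.

Both metrics quantify a candidate model's tendency to reduce the uncertainty
of a key decision-phase distribution relative to a reference (by default the
clinician-alone judgment), within a one-step POMDP framing:

* **Diagnosis phase** — per test sample, the difference in Shannon entropy
  between the reference belief over diagnoses and the candidate's belief,
  averaged over the cohort. Positive means the candidate sharpens the
  differential diagnosis on average.

* **Action phase** — per test sample, the difference in entropy between the
  future-state distributions induced by the reference policy and by the
  candidate policy through a shared transition model. Two readings of the
  candidate term are supported (see :class:`ActionPhaseOptions`).

The API follows the estimator/results idiom: construct a model object from
data, call :meth:`fit`, inspect the returned :class:`ActionabilityResults`
(per-sample values, cohort mean, bootstrap CI, ``summary()``).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .beliefs import BeliefTable, align_tables
from .dynamics import Policy, TransitionModel, future_state_distribution
from .entropy import DEFAULT_OPTIONS, EntropyOptions, cross_entropy, shannon_entropy
from .errors import ValidationError

#: Candidate belief rows with max probability at or above this are counted as
#: one-hot ("always predicts ... at 100%"); a cohort with more than
#: ``DEGENERATE_FRACTION`` such rows triggers the degenerate-candidate warning.
ONE_HOT_ATOL = 1e-9
DEGENERATE_FRACTION = 0.5

MODE_SELF_ENTROPY = "self_entropy"
MODE_AS_PRINTED = "as_printed"


@dataclass(frozen=True)
class ActionPhaseOptions:
    """Conventions for the action-phase metric.

    ``mode`` selects the candidate term in the per-sample difference
    ``delta = H(p_0) - candidate_term``:

    * ``"self_entropy"`` (default): the Shannon entropy of the candidate's
      future-state distribution, H(p_m) — mirroring the diagnosis phase,
      where each model is scored by its own distribution's entropy.
    * ``"as_printed"``: the cross-entropy -sum p_0 log p_m. Under this
      reading delta = -KL(p_0 || p_m) <= 0 always: the candidate can match
      the reference at best and is otherwise penalized for diverging from
      it. Both readings are provided because the formula and the surrounding
      prose support different interpretations; neither is asserted as
      correct.
    """

    entropy_options: EntropyOptions = DEFAULT_OPTIONS
    mode: str = MODE_SELF_ENTROPY

    def __post_init__(self) -> None:
        if self.mode not in (MODE_SELF_ENTROPY, MODE_AS_PRINTED):
            raise ValidationError(
                f"mode must be {MODE_SELF_ENTROPY!r} or {MODE_AS_PRINTED!r}; "
                f"got {self.mode!r}"
            )


@dataclass(frozen=True)
class FutureStateResult:
    """Per-sample action-phase record."""

    current_state: str
    reference_future: np.ndarray
    candidate_future: np.ndarray
    reference_entropy: float
    candidate_term: float
    delta: float
    mode: str


class ActionabilityResults:
    """Results of an actionability fit.

    Attributes
    ----------
    per_sample_reference_entropy, per_sample_candidate_term : ndarray
        Entropy of the reference distribution and the candidate term
        (entropy, or cross-entropy in the action phase's as-printed mode),
        per sample, in units of the log base.
    per_sample_delta : ndarray
        ``reference - candidate`` per sample.
    mean_delta : float
        Arithmetic mean of the per-sample differences — the cohort-level
        actionability estimate.
    bootstrap_ci : tuple[float, float] | None
        Percentile bootstrap interval for ``mean_delta``, if requested.
    warnings : list[str]
        Diagnostics (degenerate candidate, infinite terms, short bootstrap).
    """

    def __init__(
        self,
        *,
        phase: str,
        reference_name: str,
        candidate_name: str,
        sample_ids: Sequence[str],
        per_sample_reference_entropy: np.ndarray,
        per_sample_candidate_term: np.ndarray,
        options: EntropyOptions,
        mode: str | None = None,
        future_states: list[FutureStateResult] | None = None,
        warnings: list[str] | None = None,
    ) -> None:
        self.phase = phase
        self.reference_name = reference_name
        self.candidate_name = candidate_name
        self.sample_ids = tuple(sample_ids)
        self.per_sample_reference_entropy = np.asarray(per_sample_reference_entropy)
        self.per_sample_candidate_term = np.asarray(per_sample_candidate_term)
        self.per_sample_delta = (
            self.per_sample_reference_entropy - self.per_sample_candidate_term
        )
        self.mean_delta = float(np.mean(self.per_sample_delta))
        self.options = options
        self.mode = mode
        self.future_states = future_states
        self.warnings = list(warnings or [])
        self.bootstrap_ci: tuple[float, float] | None = None
        self.n_boot: int | None = None
        self.bootstrap_seed: int | None = None
        if np.any(np.isinf(self.per_sample_delta)):
            n_inf = int(np.sum(np.isinf(self.per_sample_delta)))
            self.warnings.append(
                f"{n_inf} per-sample difference(s) are infinite (candidate places "
                "zero probability where the reference does not); consider epsilon "
                "smoothing or inspect the candidate's zeros"
            )

    # -- aliases matching the diagnosis-phase vocabulary -------------------
    @property
    def per_sample_candidate_entropy(self) -> np.ndarray:
        """Candidate term per sample (an entropy except in as-printed mode)."""
        return self.per_sample_candidate_term

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample values as a DataFrame indexed by sample id."""
        return pd.DataFrame(
            {
                "reference_entropy": self.per_sample_reference_entropy,
                "candidate_term": self.per_sample_candidate_term,
                "delta": self.per_sample_delta,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def summary(self) -> str:
        """Plain-text summary table."""
        unit = "bits" if self.options.log_base == 2 else (
            "nats" if self.options.log_base == math.e else f"log{self.options.log_base}"
        )
        lines = [
            f"Actionability ({self.phase} phase)",
            "=" * 46,
            f"reference:        {self.reference_name}",
            f"candidate:        {self.candidate_name}",
            f"samples:          {self.n_samples}",
            f"log base:         {self.options.log_base:g} ({unit})",
        ]
        if self.mode is not None:
            lines.append(f"mode:             {self.mode}")
        lines += [
            f"mean reference H: {np.mean(self.per_sample_reference_entropy):.6g} {unit}",
            f"mean candidate:   {np.mean(self.per_sample_candidate_term):.6g} {unit}",
            f"mean delta:       {self.mean_delta:.6g} {unit}",
        ]
        if self.bootstrap_ci is not None:
            lo, hi = self.bootstrap_ci
            lines.append(
                f"95% bootstrap CI: [{lo:.6g}, {hi:.6g}] "
                f"({self.n_boot} resamples, seed {self.bootstrap_seed})"
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ActionabilityResults {self.phase}: mean_delta={self.mean_delta:.6g} "
            f"over {self.n_samples} samples>"
        )


def bootstrap_mean_delta(
    result: ActionabilityResults, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap (2.5/97.5) of the cohort mean difference.

    Resamples sample indices with replacement; reproducible from ``seed``.
    The interval is also stored on ``result``. Fewer than 100 resamples is
    allowed but recorded as a warning on the result.
    """
    deltas = result.per_sample_delta
    if deltas.size < 2:
        raise ValidationError("bootstrap requires at least 2 samples")
    if n_boot < 100:
        result.warnings.append(
            f"bootstrap used only {n_boot} resamples (< 100); interval is unstable"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, deltas.size, size=(n_boot, deltas.size))
    means = deltas[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    result.bootstrap_ci = (float(lo), float(hi))
    result.n_boot = n_boot
    result.bootstrap_seed = seed
    return result.bootstrap_ci


@dataclass(frozen=True)
class StratifiedReport:
    """Diagnosis-phase diagnostics stratified by candidate top-1 correctness.

    A model that is confidently wrong — e.g. one that always predicts a
    single diagnosis at 100% — shows a large mean delta concentrated in the
    ``incorrect`` stratum; this report makes that failure mode visible.
    """

    table: pd.DataFrame
    n_ties: int
    correct_fraction: float

    def __str__(self) -> str:
        return (
            f"{self.table}\n"
            f"top-1 ties (broken toward lowest state index): {self.n_ties}\n"
            f"correct fraction: {self.correct_fraction:.4g}"
        )


def stratified_actionability_report(
    result: ActionabilityResults, candidate: BeliefTable
) -> StratifiedReport:
    """Partition per-sample deltas by whether the candidate's top state is true.

    Requires ``candidate.true_states``. The top-1 state is the argmax of the
    candidate belief; exact ties are broken toward the lowest state index and
    counted in the report.
    """
    if candidate.true_states is None:
        raise ValidationError("stratified report requires true_states on the candidate")
    if tuple(candidate.sample_ids) != result.sample_ids:
        raise ValidationError(
            "candidate table sample ids do not match the result's sample ids"
        )
    beliefs = candidate.beliefs
    top_idx = beliefs.argmax(axis=1)  # argmax already breaks ties toward low index
    n_ties = int(
        np.sum(np.sum(beliefs == beliefs.max(axis=1, keepdims=True), axis=1) > 1)
    )
    labels = np.asarray(candidate.state_space.labels)
    correct = labels[top_idx] == np.asarray(candidate.true_states)
    df = pd.DataFrame(
        {
            "delta": result.per_sample_delta,
            "candidate_entropy": result.per_sample_candidate_term,
            "stratum": np.where(correct, "correct", "incorrect"),
        }
    )
    grouped = (
        df.groupby("stratum", sort=True)
        .agg(
            n=("delta", "size"),
            mean_delta=("delta", "mean"),
            mean_candidate_entropy=("candidate_entropy", "mean"),
        )
    )
    return StratifiedReport(
        table=grouped,
        n_ties=n_ties,
        correct_fraction=float(np.mean(correct)),
    )


class DiagnosisActionability:
    """Diagnosis-phase actionability of a candidate model versus a reference.

    Parameters
    ----------
    reference
        Belief table of the reference model (by default the clinician-alone
        differential; any model's beliefs may serve).
    candidate
        Belief table of the candidate model, covering the same state-label
        set and sample ids (alignment is automatic).
    options
        Log base and zero conventions.

    Examples
    --------
    >>> model = DiagnosisActionability(clinician, ml)      # doctest: +SKIP
    >>> res = model.fit(n_boot=1000, seed=7)               # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(
        self,
        reference: BeliefTable,
        candidate: BeliefTable,
        options: EntropyOptions = DEFAULT_OPTIONS,
    ) -> None:
        self.reference, self.candidate = align_tables(reference, candidate)
        self.options = options

    @classmethod
    def from_csv(
        cls,
        reference_path,
        candidate_path,
        options: EntropyOptions = DEFAULT_OPTIONS,
        **read_kwargs,
    ) -> "DiagnosisActionability":
        from .beliefs import read_belief_table

        return cls(
            read_belief_table(reference_path, **read_kwargs),
            read_belief_table(candidate_path, **read_kwargs),
            options=options,
        )

    def fit(self, n_boot: int | None = None, seed: int = 0) -> ActionabilityResults:
        """Compute per-sample entropy differences and the cohort mean.

        Per sample i: ``delta_i = H(reference_i) - H(candidate_i)``; the
        estimate is the arithmetic mean of the ``delta_i``. Pass ``n_boot``
        for a percentile bootstrap CI on the mean.
        """
        ref_H = np.array(
            [shannon_entropy(row, self.options) for row in self.reference.beliefs]
        )
        cand_H = np.array(
            [shannon_entropy(row, self.options) for row in self.candidate.beliefs]
        )
        warn: list[str] = []
        one_hot = np.sum(self.candidate.beliefs.max(axis=1) >= 1.0 - ONE_HOT_ATOL)
        frac = one_hot / self.candidate.n_samples
        if frac > DEGENERATE_FRACTION:
            warn.append(
                f"degenerate candidate: {frac:.0%} of candidate beliefs are one-hot; "
                "a model that always predicts one diagnosis at 100% maximizes this "
                "metric while possibly being confidently wrong — inspect the "
                "stratified report"
            )
        res = ActionabilityResults(
            phase="diagnosis",
            reference_name=self.reference.model_name,
            candidate_name=self.candidate.model_name,
            sample_ids=self.reference.sample_ids,
            per_sample_reference_entropy=ref_H,
            per_sample_candidate_term=cand_H,
            options=self.options,
            warnings=warn,
        )
        if n_boot is not None:
            bootstrap_mean_delta(res, n_boot=n_boot, seed=seed)
        return res

    def stratified_report(self, result: ActionabilityResults) -> StratifiedReport:
        return stratified_actionability_report(result, self.candidate)


class ActionActionability:
    """Action-phase actionability of a candidate policy versus a reference.

    Per test sample (with known current state s), compares the entropy of the
    future-state distribution induced by the reference policy with the
    candidate term for the candidate policy's distribution, both obtained by
    marginalizing the shared transition model.

    Parameters
    ----------
    transitions
        Shared one-step transition model p*(s' | s, a).
    reference_policy, candidate_policy
        Policies over the same state/action spaces (e.g. the clinician's
        usual treatment choice and the model-recommended one).
    current_states
        One current-state label per test sample.
    sample_ids
        Optional ids (defaults to positional "sample_0", ...).
    options
        Mode (self-entropy vs as-printed cross-entropy) and log base.
    """

    def __init__(
        self,
        transitions: TransitionModel,
        reference_policy: Policy,
        candidate_policy: Policy,
        current_states: Sequence[str],
        sample_ids: Sequence[str] | None = None,
        options: ActionPhaseOptions | None = None,
    ) -> None:
        self.transitions = transitions
        self.reference_policy = reference_policy
        self.candidate_policy = candidate_policy
        self.current_states = [str(s) for s in current_states]
        for s in self.current_states:
            transitions.state_space.index(s)  # raises on unknown state
        if sample_ids is None:
            sample_ids = [f"sample_{i}" for i in range(len(self.current_states))]
        if len(sample_ids) != len(self.current_states):
            raise ValidationError("sample_ids must match current_states in length")
        self.sample_ids = tuple(str(s) for s in sample_ids)
        self.options = options if options is not None else ActionPhaseOptions()

    def fit(self, n_boot: int | None = None, seed: int = 0) -> ActionabilityResults:
        """Compute per-sample future-state entropy differences and their mean."""
        eopt = self.options.entropy_options
        mode = self.options.mode
        # future distributions depend only on the current state; cache per state
        cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        records: list[FutureStateResult] = []
        ref_H = np.empty(len(self.current_states))
        cand_T = np.empty(len(self.current_states))
        for i, s in enumerate(self.current_states):
            if s not in cache:
                p0 = future_state_distribution(
                    self.transitions, self.reference_policy, s
                )
                pm = future_state_distribution(
                    self.transitions, self.candidate_policy, s
                )
                cache[s] = (p0, pm)
            p0, pm = cache[s]
            h0 = shannon_entropy(p0, eopt)
            term = (
                shannon_entropy(pm, eopt)
                if mode == MODE_SELF_ENTROPY
                else cross_entropy(p0, pm, eopt)
            )
            ref_H[i] = h0
            cand_T[i] = term
            records.append(
                FutureStateResult(
                    current_state=s,
                    reference_future=p0,
                    candidate_future=pm,
                    reference_entropy=h0,
                    candidate_term=term,
                    delta=h0 - term,
                    mode=mode,
                )
            )
        res = ActionabilityResults(
            phase="action",
            reference_name=self.reference_policy.policy_name,
            candidate_name=self.candidate_policy.policy_name,
            sample_ids=self.sample_ids,
            per_sample_reference_entropy=ref_H,
            per_sample_candidate_term=cand_T,
            options=eopt,
            mode=mode,
            future_states=records,
        )
        if n_boot is not None:
            bootstrap_mean_delta(res, n_boot=n_boot, seed=seed)
        return res


# ---------------------------------------------------------------------------
# Functional wrappers


def diagnosis_actionability(
    reference: BeliefTable,
    candidate: BeliefTable,
    options: EntropyOptions = DEFAULT_OPTIONS,
) -> ActionabilityResults:
    """One-call diagnosis-phase metric: mean H(reference) - H(candidate)."""
    return DiagnosisActionability(reference, candidate, options=options).fit()


def action_actionability(
    transitions: TransitionModel,
    reference_policy: Policy,
    candidate_policy: Policy,
    current_states: Sequence[str],
    options: ActionPhaseOptions | None = None,
) -> ActionabilityResults:
    """One-call action-phase metric over per-sample current states."""
    return ActionActionability(
        transitions,
        reference_policy,
        candidate_policy,
        current_states,
        options=options,
    ).fit()
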