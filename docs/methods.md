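# Methods

## The metric

Both actionability metrics live in a one-step POMDP abstraction of a
clinical encounter. The hidden state s ∈ S is the patient's true condition
(one of K mutually exclusive diagnoses or outcome states); the observations
o are whatever clinical data are available; an action a ∈ A is a treatment
choice; p\*(s′ | s, a) gives the distribution of next states for each
(state, action) pair; and a policy π(a | s) is a distribution over actions
in each state (one-hot for a deterministic prescriber).

**Diagnosis phase.** Each model under comparison supplies, per test sample,
a categorical belief p(s | o) over the shared state space. The per-sample
score is the difference of Shannon entropies, reference minus candidate,
and the cohort estimate Δˢ is the arithmetic mean of the per-sample
differences. The reference is typically a clinician-alone belief
(elicited differentials), but any model's beliefs can serve — the metric is
a pairwise comparison, not an absolute score.

**Action phase.** Per test sample with current state s, each policy induces
a future-state distribution p(s′ | s) = Σ_a p\*(s′ | s, a) π(a | s) — a
convex combination of transition rows, always a valid distribution. Δᵃ is
the mean over samples of H(p₀) minus a candidate term, where p₀ is the
reference policy's future distribution.

### The two action-phase modes

The candidate term admits two readings, and the package implements both
(`ActionPhaseOptions.mode`) rather than silently choosing:

* `self_entropy` (default): the candidate term is H(p_m), the entropy of
  the candidate policy's own future distribution. This mirrors the
  diagnosis phase — each model is scored by the sharpness of its own
  distribution — and is what "comparing the entropies of the two future
  state distributions" suggests.
* `as_printed`: the candidate term is the cross-entropy −Σ p₀ log p_m,
  weighting the candidate's log-probabilities by the *reference*
  distribution. Algebraically Δᵃ = H(p₀) − CE(p₀, p_m) = −KL(p₀ ‖ p_m),
  which by Gibbs' inequality is ≤ 0 with equality iff p_m = p₀: under this
  reading a candidate policy can never show positive actionability, only a
  penalty for diverging from the reference. The suite asserts this identity
  to 1e-12, and results record which mode produced them.

The two modes coincide exactly when p_m = p₀.

Current states are taken as known per sample (simulation ground truth or a
recorded label). A belief-weighted variant
Σ_s b(s) p(s′ | s) (`belief_weighted_future_state`) is provided for the
case where the current state is itself uncertain; it is an extension beyond
the core metric and nothing calls it by default.

## Conventions and numerical choices

* **Log base** defaults to 2 (bits — "yes/no questions resolved"); base e
  is available through `EntropyOptions`. Entropy and cross-entropy use a
  base-aware kernel (`np.log2` for base 2) rather than natural-log plus
  conversion, so that e.g. the uniform distribution over K states scores
  exactly log₂ K in floating point. KL divergence uses
  `scipy.special.rel_entr`.
* **0 log 0 := 0** throughout, the standard information-theoretic
  convention (the limit of x log x).
* **Unsupported zeros**: cross-entropy returns +inf when the candidate puts
  zero mass where the weighting distribution does not, and results carry a
  warning rather than raising, so cohort summaries surface the issue.
  Optional epsilon-flooring (`EntropyOptions.epsilon` ∈ (0, 1e-3]) gives a
  finite penalty instead; it is off by default because flooring changes the
  metric.
* **Probability validation**: vectors must be non-negative and sum to 1
  within 1e-8 (elicited probabilities rarely sum exactly to 1); an opt-in
  `renormalize` flag divides by the sum when the deviation is within
  tolerance. Negative entries are never repaired. Belief tables are paired
  by sample id (never by row position) and label-matched case-sensitively,
  with the candidate's columns permuted to the reference ordering; all
  entropies are invariant to consistent label permutations.
* **Top-1 stratification ties** are broken toward the lowest state index
  and the tie count is reported.
* **Bootstrap**: percentile (2.5/97.5) over resampled sample indices,
  seeded; fewer than 100 resamples is allowed but flagged. The bootstrap
  quantifies sampling uncertainty of the cohort mean only — it says nothing
  about elicitation error in the reference beliefs.
* **Degenerate-candidate warning**: if more than 50% of candidate beliefs
  are one-hot (max ≥ 1 − 1e-9), results and reports carry a warning,
  operationalizing the always-100% failure mode. The threshold is a
  convention, not an estimate.
* **Net benefit** classifies positive at probability ≥ t (inclusive) and
  reports model, treat-all (prevalence − (1−prevalence)·t/(1−t)), and
  treat-none (≡ 0) curves. The formula is the standard decision-curve one;
  it is included as the downstream companion the actionability screen feeds
  into, and the report juxtaposes the two without combining them — how to
  combine them is an open research question.

## The synthetic scenario generator

The generator emulates the data an actionability study needs but which must
otherwise be elicited from clinicians. Defaults: 4 states, 3 actions,
500 samples, reference concentration 1, candidate temperature 0.5,
transition concentration 1, true-state tilt 3.

* True states are uniform over the state space.
* Clinician (reference) beliefs are symmetric Dirichlet draws with the true
  state's concentration multiplied by the tilt (3), giving differentials
  that are centred on the right diagnosis more often than not but stay
  diffuse — the tilt value is a design choice for "imperfect but better
  than chance" clinician priors.
* Candidate beliefs are the reference beliefs temperature-sharpened:
  b^(1/T) renormalized, computed in log space with per-row max subtraction
  so extreme temperatures cannot underflow. T = 1 returns the reference
  array unchanged (special-cased, so equality and zero-delta are exact);
  T < 1 sharpens without ever changing the argmax. This mechanism was
  chosen over independent Dirichlet draws for the candidate because it
  makes the entropy ordering analytically controllable: expected Δˢ is
  monotone in T, which the suite verifies over a seeded temperature grid.
* Transition rows are symmetric Dirichlet; the reference policy is uniform
  over actions; the candidate policy is one-hot per state on the action
  maximizing the probability of a designated desired next state (index 0 by
  convention, configurable).
* Seeding: the global seed feeds a `SeedSequence` that spawns one child
  stream for the transition draws and one per sample (each sample's stream
  draws its true state then its belief), so enlarging the cohort extends it
  without perturbing earlier samples, and written scenario files are
  byte-identical across runs.

**What the generator does not emulate**: real disease prevalence,
correlated observations, clinician biases, costs, or time-varying state.
Because the candidate is a deterministic sharpening of the reference, the
two are maximally correlated — real model/clinician pairs disagree about
the leading diagnosis far more often. Passing tests therefore demonstrate
the metric's algebraic and statistical behaviour under controlled
conditions, not that any real model is actionable.

## Problem sizes

The default study conditions are 500-sample cohorts over 4 states; the
property suites use 1000 random draws for the entropy/KL/marginalization
oracle comparisons and 50 seeded replicates per temperature for the
simulation-recovery check. The whole suite runs in well under a minute on
one CPU.

## Known limitations

* Entropy reduction is direction-blind: a confidently wrong model scores as
  well as a confidently right one. The stratified report (which needs
  ground-truth labels) is the package's mitigation; the metric itself has
  no ground-truth term.
* Transition probabilities and reference beliefs are accepted as inputs;
  eliciting them well is a hard problem that is out of scope here.
* Only one transition step is modelled — no rollouts, no belief filtering
  over time, no policy optimization.
* Which action-phase reading is "correct" is left to the user; defaults
  pick `self_entropy`, and every result records its mode.
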