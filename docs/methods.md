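# Methods

## The model

A decision maker facing a binary risky choice problem *p* carries a
toolbox *S* of candidate heuristic strategies and selects the one that
best trades expected payoff against cognitive effort:

    s* = argmax_{s ∈ S} ( r_{s,p} − δ · c_{s,p} )

where *r*<sub>s,p</sub> is the strategy's expected payoff on *p* (the
expected value of the gamble it selects), *c*<sub>s,p</sub> is its
expected cognitive cost (a count of elementary information processes,
EIPs), and δ ≥ 0 weights cost against payoff.  The selected strategy's
choice is then executed with a trembling-hand error ε ∈ [0, 0.5]:

    P(A) = P(A | δ, S) · (1 − ε) + P(B | δ, S) · ε

Both *r* and *c* are estimated by simulating each strategy on each
problem repeatedly (default 100 runs) and averaging, because ties inside
the rules are broken at random.  The model treats these simulated
quantities as the decision maker's internal estimates; no learning of
predictive models for *r* and *c* is attempted.

## The eleven strategies

The toolbox candidates are eleven classic risky-choice heuristics:
minimax (MINI), maximax (MAXI), least-likely (LL), most-likely (ML),
better-than-average (BTA), equal-weight (EQW), tallying (TALLY),
probable (PROB), lexicographic (LEX), the priority heuristic (PH), and
weighted-additive (WADD).  All operate on signed payoffs, so "higher"
uniformly means "better":

- **Domain handling.** MINI, MAXI, LL, ML, BTA, EQW, PROB, LEX and WADD
  run unchanged in the loss domain (e.g., maximax picks the least-bad
  maximum).  TALLY's loss formulation (swap gain/loss and higher/lower)
  is algebraically identical to its gain formulation on signed payoffs,
  so one implementation covers both; mixed problems use the same rule.
  PH is mirrored for loss problems — attributes minimum loss,
  probability of minimum loss, maximum loss, with the aspiration level
  at 1/10 of the *absolute* maximum loss — and treats mixed problems
  with the gain form on signed payoffs.
- **Ties.** Option-level indifference is resolved uniformly at random
  with the caller's generator and flagged on the decision.  Internal
  indifference (which outcome is "most likely" in a 50/50 gamble, for ML
  and LEX) is also randomized but not flagged.  LEX falls back to the
  second most likely outcome on a payoff tie and randomizes beyond
  that; a safe option re-uses its single outcome at every depth.
- **PROB** classifies an outcome as probable iff its probability is at
  least 0.5, for any number of outcomes; if every outcome of a gamble is
  cancelled (impossible for two-outcome gambles) its value defaults
  to 0.
- **PH** uses the problem-wide maximum gain for its aspiration level
  (the original convention) and a fixed 1/10 of the probability scale
  for the probability comparison.  Aspiration comparisons carry a 1e-9
  absolute tolerance so that 1/10 scaling of integer payoffs does not
  flip on float rounding.

## Cost accounting

Strategy cost is the length of the EIP trace an execution emits, using
the taxonomy READ, COMPARE, DIFFERENCE, ADD, PRODUCT, ELIMINATE, CHOOSE.
The scheme is defined operationally by the implementations; for a
problem with two two-outcome options it yields:

| strategy | trace | count |
|---|---|---|
| MINI / MAXI | 4 READ + 3 COMPARE + CHOOSE | 8 |
| EQW | 4 READ + 2 ADD + 1 COMPARE + CHOOSE | 8 |
| LL | 4 READ + 2 COMPARE + 2 READ + 1 COMPARE + CHOOSE | 10 |
| ML | 4 READ + 2 COMPARE + 2 READ + 1 COMPARE + CHOOSE | 10 |
| LEX | as ML, + 2 READ + 1 COMPARE on a first-stage tie | 10–13 |
| PH | 11 (stop at minima) / 15 (probabilities) / 18 (maxima) | 11–18 |
| PROB | 4 READ + 4 COMPARE + ELIMINATEs + reads/means of survivors | ~14 |
| BTA | 4 READ + 3 ADD + 1 PRODUCT + 5 COMPARE + CHOOSE | 14 |
| WADD | 8 READ + 4 PRODUCT + 2 ADD + 1 COMPARE + CHOOSE | 16 |
| TALLY | 8 READ + 2 COMPARE + marks + 5 COMPARE + CHOOSE | ~20 |

Safe options shorten traces (one read, no within-option comparison).
Counts depend on problem structure, not payoff magnitudes, except where
PH's stopping point moves.  The scheme is swappable: a YAML mapping from
strategy abbreviation to a fixed count overrides the traced cost, so
alternative cost accountings can be audited without touching code.  What
the model's conclusions rely on is the cost *ordering* (effortful
integration like WADD/TALLY above cheap single-attribute rules like
MINI/MAXI), which any reasonable EIP accounting preserves; absolute
counts under this scheme run from 6 to about 20.

## Likelihood and fitting

Each simulation run selects one strategy per problem (score ties
uniform) and produces a deterministic-or-indifferent prediction, so the
per-run probability of choosing A before the trembling hand is 0, ½,
or 1; the trembling hand maps it into {ε, ½, 1 − ε}.  Per-trial log
probabilities are summed within a run and the sums are **averaged across
runs on the log scale** (not the probabilities) — the averaging scale
matters and is fixed here.  With ε > 0 every observation has positive
probability; ε = 0 with a contradicting deterministic prediction is
reported as an error rather than −∞.

Fitting is an exhaustive grid search.  Two grids are built in:

- `full`: toolbox sizes 1–7 over the 11 candidates, δ from 0 to 20 in
  steps of 0.1, ε from 0.01 to 0.5 in steps of 0.01, 100 simulation
  runs (≈ 1.67 million parameter combinations per participant);
- `desk` (default): sizes 1–4, δ step 0.5, ε step 0.05, 20 runs
  (≈ 230,000 combinations) — the routine configuration used by the
  analysis scripts and tests.

Strategy execution depends on neither δ nor ε, so per-run predictions
are simulated once per problem set and shared across the entire grid;
within a toolbox, δ only permutes selection scores, and identical
selection patterns are likelihood-evaluated once.  Among grid points
tied at the maximum log-likelihood (tolerance 1e-9), smaller toolboxes
are preferred and a remaining tie is resolved at random; the number of
tied points is reported (`n_ties_at_max`) so instability is visible.
Note that a toolbox whose selection pattern is constant in δ (e.g., any
singleton) ties across the whole δ grid, so a fitted δ can be close to
arbitrary within such a region — δ is only identified up to the
selection pattern it induces.  Score ties in Eq-type selection use a
relative tolerance of 1e-9 so that boundary cases (e.g., δ exactly at a
crossing point) count as ties despite float rounding.

## Cumulative prospect theory baseline

The comparison model values a gamble by rank-dependent weighting of
power-transformed outcomes: v(x) = x^α⁺ for gains, v(x) = −λ(−x)^α⁻ for
losses; decision weights are differences of an inverse-S weighting
function w(p) = p^γ / (p^γ + (1−p)^γ)^{1/γ} applied to cumulative
probabilities, with separate γ⁺ and γ⁻; choice is softmax with
sensitivity θ on the value difference.  These functional forms are the
dominant conventions, adopted here as explicit assumptions; they are
pluggable in principle and the six-parameter layout (α split by sign) is
one reading of a six-parameter CPT.  All parameters are bounded to
[0, 2] for fitting: a coarse grid (default 15 steps per dimension,
factorized by parameter role so the sweep stays tractable) seeds the 30
best points for bounded L-BFGS-B refinement.  The weighting function is
computed in log space so the γ → 0 limit degenerates smoothly to an
indicator of certainty instead of overflowing.

## Synthetic data

The generator emulates the target study design: 105 problems — 41 gain,
31 loss, 33 mixed, 9 involving a safe option (allocated across domains
proportionally to domain size), the rest two two-outcome gambles.  The
original problems' payoffs and probabilities are unpublished, so
magnitudes are config defaults chosen as typical for monetary-gamble
experiments: integer outcomes up to 100 money units, probabilities on a
0.05 grid from 0.05 to 0.95.  Problems are rejection-sampled so that
option EVs differ and both coefficients of variation are defined and
differ, keeping decision quality and risk aversion defined everywhere
(ties can be re-enabled for edge-case testing).  Mixed-domain risky
gambles carry one gain and one loss outcome.

Populations are groups of agents with sampled toolboxes (optionally
weighted toward a strategy pool per group), uniform δ and ε.  The
emulated cohort in the analysis scripts uses two groups of 6 agents,
toolboxes of 2–4 strategies, δ ∈ [0, 5] and ε ∈ [0.2, 0.32], with a
"younger" pool leaning on probability-sensitive, risk-averse heuristics
(MINI, LL, PH) and an "older" pool on outcome-only, risk-seeking ones
(EQW, MAXI, BTA, TALLY).  What the generator does **not** emulate:
real participants' attention lapses and learning over trials,
problem-order effects, any dependence of strategy selection on the
domain, or the exact payoff structure of the original problem set —
passing tests therefore demonstrate internal consistency of the
pipeline and recoverability under the model's own assumptions, not
fidelity to any particular empirical dataset.

## Problem sizes used in the checks

Routine tests run on 20–105 problems with the `desk` grid or smaller
micro-grids.  The recovery experiment uses 20 agents × 105 problems ×
the desk grid; the end-to-end reproducibility check uses 4 agents on a
30-problem set; the acceptance script runs the full pipeline with 12
agents × 105 problems plus the prospect-theory analyses.  These sizes
are the package's routine configuration; the `full` grid is available
for study-scale runs.

## Known limitations

- **δ is weakly identified.**  Selection patterns are piecewise constant
  in δ, and the smaller-toolbox tie rule resolves only toolbox ties, so
  the reported δ is a representative of an equivalence region.
- **Strategy mimicry.**  Strategies with similar decision profiles on a
  given problem set (e.g., EQW, BTA and TALLY, which all favor
  outcome-sum advantages) can be recovered for one another; toolbox
  recovery should be read at the level of strategy families and risk
  profiles, not exact identity.
- **CPT parameters are not point-identified from 105 binary choices.**
  Maximum-likelihood recovery experiments here show a flat likelihood
  ridge trading λ against α⁻ (and occasionally θ): the fitted optimum
  reliably achieves a *higher* likelihood than the generating
  parameters while missing λ by 0.5 or more.  With the choice
  sensitivity pinned at θ = 2, outcome magnitudes must be kept small
  (≤ 10 units in the recovery experiment) for choices to remain
  stochastic at all; even then, per-parameter recovery to ±0.3 is not
  consistently achievable for the loss-side parameters at this sample
  size.  This mirrors the known difficulty of single-subject ML
  estimation of loss aversion.  Group-level or hierarchical estimation
  is out of scope.
- **No inferential statistics.**  The report layer emits descriptives
  plus closed-form Cohen's d and Cramér's V; Bayes factors, mixed-model
  regressions and mediation analyses are deliberately not reimplemented.
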