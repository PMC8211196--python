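# Methods

## Model

The package aggregates per-dimension quality appraisals of a study into a
single score and propagates that score into Bayesian updating.

**Aggregation.** Inputs are an appraisal vector **A** ∈ [0, 1]^k (k ≥ 2), a
ranking vector **R** ∈ (0, 1)^k with Σ r_l = 1, and a cautiousness parameter
β > 0. The pipeline weights each appraisal by its importance, applies
softmax at inverse temperature β, rescales by the weighted mean A×R to break
softmax's translation invariance (a uniformly better study must score
better), compresses to a scalar through the product of the softmax
numerators over their common denominator, and normalises into [0, 1]:

    v_f = exp(β(A×R − 1)) · [Σ exp(β r_i)] / [Σ exp(β r_i a_i)] · (A×R)

Proved and numerically enforced properties: v_f ∈ [0, 1]; v_f = 0 iff
A = 0@k and v_f = 1 iff A = 1@k; strict monotonicity in every appraisal
coordinate; for constant appraisals c@k under equal ranking,
v_f = c·exp(β(c−1)(1−1/k)) (non-idempotence). The aggregate tends to the
weighted mean as β → 0⁺ and to 0 (for any imperfect study) as β → ∞.

On the k-dependence of the constant-appraisal curve: since (1 − 1/k)
increases with k, the discount *deepens* monotonically with the number of
equally imperfect dimensions, approaching the limit c·exp(β(c−1)); the
curve approaches the identity map only as β → 0. The tests assert these
directions, which follow from the closed form.

**Assumptions.** The appraisal dimensions are taken to be pairwise different
and mutually independent. Independence is a documented modelling assumption,
not a checked precondition — no statistical test of it is possible on a
single appraisal vector.

**Bayesian layer.** v_f is interpreted as the probability the study can be
taken at face value. A study's likelihood is replaced by the Jeffrey mixture
Q(E|H) = v_f·P(E|H) + (1−v_f)·P(E); posteriors over an exhaustive,
mutually exclusive hypothesis space follow by normalisation, with a product
over studies when several independent studies are available. The evidence
marginal P(E) is a deliberately **free input**: deriving it from priors and
likelihoods would make the mixture collapse to ordinary conditioning and
erase the role of v_f. Consequently the Q(E|H) need not be coherent
marginals of a single probability function; only the returned posteriors are
guaranteed normalised.

The causal-indicator layer computes Q(©|E) for a causal hypothesis ©
mediated by an indicator variable (conditioning on the indicator renders data
and hypothesis independent), with both evidence likelihoods P(E|Ind),
P(E|¬Ind) discounted through the mixture. A comparator posterior treats the
study as conclusive proof of the indicator; it coincides with the discounted
posterior at v_f = 1 whenever P(E|¬Ind) = 0. Whether that idealisation is
kept is the user's choice — `p_e_given_notind` is an ordinary model field.

## Parameters

| parameter | meaning | domain | default |
|---|---|---|---|
| β | cautiousness (softmax inverse temperature); how harshly multiple imperfections compound | (0, 700] | none — user input |
| **R** | dimension importances | (0,1)^k, Σ = 1 | `equal` (1/k each) in the CLI and case-study table |
| v_f | face-value probability of a study | [0, 1] | computed by the pipeline, or user-supplied in the Bayesian layer |
| P(E) | evidence marginal | [0, 1] | none — free input |
| P(©) | causal prior | (0, 1) | none — free input (the case-study examples use 1 % and 0.5 %) |

No normative value of β is prescribed; it encodes a risk attitude and is
strictly user input. β = 0 is rejected by the pipeline (it degenerates to
the weighted mean, exposed separately as `weighted_mean`); β < 0 is rejected
because the final normalisation step then fails to map into [0, 1].

## Numerical choices

- β is capped at 700, just below where exp(β) overflows double precision.
  The fast path evaluates log v_f = β(A×R − 1) + logsumexp(βR) −
  logsumexp(βR∘A) + log(A×R), so large admissible β neither overflows nor
  underflows prematurely.
- A = 0@k returns exactly 0 without evaluating log(0); A = 1@k returns
  exactly 1, guarded explicitly because float ranking weights need not sum
  to exactly 1.
- The literal five-step trace (`ea3_trace`) is kept as an audit path; its
  agreement with the closed form to 1e-12 is a tested invariant.
- Ranking vectors must sum to 1 within 1e-9 and are never silently
  renormalised; `RankingVector.normalised` does it explicitly. Hypothesis
  priors likewise (tolerance 1e-9).
- Studies with v_f = 0 are dropped from the multi-study product: they
  contribute a constant factor P(E_r) that cancels in normalisation, and
  dropping it makes "all evidence worthless ⇒ posterior = prior" exact.
- Degenerate denominators (every hypothesis giving the evidence probability
  0) raise `DegenerateEvidenceError` rather than returning a convention —
  they indicate a modelling fault.
- Sweep monotone-direction detection treats |Δ| < 1e-12 as a tie; a sweep is
  "increasing" only if no decreasing step exists and at least one increasing
  step does. Sweeping one ranking weight rescales the remaining weights
  proportionally so every grid point is an admissible ranking.
- Appraisal CSVs are written with 17 significant digits and parsed with
  Python's `float()` (pandas' own float parser is not round-trip exact), so
  write/read round trips preserve doubles bit-for-bit.
- Case-study indicator constants are stored as exact rationals
  (26 2/7 % = 184/700, 3/7 % = 3/700) and converted to float at use time;
  printed decimal approximations are outputs, not inputs.

## Synthetic data

`generate_synthetic` draws seeded appraisal tables from three families:
uniform on [0, 1]^k, Beta(a, b) per dimension (defaults a = b = 2, a mild
interior mode), and the discrete {0, 0.5, 1} grid that mirrors the coarse
scoring scale of the packaged case study. It emulates the *distribution* of
appraisal scores only: dimensions are drawn independently, so correlated
appraisals (e.g. large surveys tending to have better adjustment), expert
disagreement, and any link between a study's true informativeness and its
scores are not represented. Passing tests on synthetic data therefore
demonstrate the algebraic and monotonicity properties of the pipeline, not
the validity of any particular appraisal practice.

## Problem sizes

Randomised property checks use 1,000 draws per invariant (10 × 1,000
dominated pairs per β for the monotonicity scan), dimensions k ∈ [2, 7] and
β ≤ 30 — comfortably covering the regimes the case study and the closed
forms exercise; the whole suite and the acceptance script run in seconds.

## Known limitations

- One agent, one β: panels of appraisers with different risk attitudes,
  rankings or appraisals are out of scope.
- No elicitation machinery for β, rankings or appraisals; appraising real
  studies is expert judgement outside the package.
- Multi-study pooling assumes independence; dependence-aware pooling is not
  implemented.
- Negative-β variants would need a different normalisation step and are not
  offered.
- When one study bears on several indicators, the package takes one v_f per
  (study, indicator) pair as input; no sharing rule is imposed.
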