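"""Posterior probabilities from quality-discounted study likelihoods.

Two rival hypotheses start at even odds.  A study reports likelihoods 0.8 vs
0.2, but its appraisal aggregate v_f says how far to trust it: each likelihood
is replaced by the mixture vf * P(E|H) + (1 - vf) * P(E) before Bayes'
theorem is applied.
"""

from ea3 import HypothesisSpace, StudyEvidence, posterior_multi, posterior_single

space = HypothesisSpace(["drug harmful", "drug safe"], [0.5, 0.5])

print("vf    P(harmful|E)  P(safe|E)")
for vf in (0.0, 0.25, 0.5, 0.75, 1.0):
    study = StudyEvidence("survey-1", [0.8, 0.2], marginal=0.5, vf=vf)
    post = posterior_single(space, study)
    print(f"{vf:4.2f}  {post[0]:12.4f}  {post[1]:9.4f}")

two = [StudyEvidence(f"survey-{i}", [0.8, 0.2], marginal=0.5, vf=1.0) for i in (1, 2)]
post = posterior_multi(space, two)
print(f"\ntwo independent face-value studies: {post[0]:.4f} vs {post[1]:.4f}")
print(
    "\nAt vf = 0 the study is worthless and the posterior equals the prior; at "
    "vf = 1 it is ordinary Bayesian updating (0.8 vs 0.2); in between the "
    "posterior interpolates.  Two face-value copies of the study compound to "
    "16/17 ~ 0.9412."
)
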