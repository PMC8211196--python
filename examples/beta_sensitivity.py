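"""Sensitivity sweeps: how the aggregate and the causal posterior move.

Sweeps the cautiousness parameter beta for a uniformly half-good study, and
the face-value probability vf for the case-study indicator model, reporting
the detected monotone direction of each curve.
"""

from ea3 import (
    AppraisalVector,
    RankingVector,
    SweepSpec,
    monotonicity_scan,
    paracetamol_constants,
    sweep,
)

beta_sweep = sweep(
    SweepSpec(
        "beta",
        [0.5, 1, 2, 4, 8, 16],
        {"appraisals": AppraisalVector.uniform(0.5, 3), "ranking": RankingVector.equal(3)},
    )
)
print("beta sweep of the all-0.5 study:", beta_sweep.monotone_direction)
for b, v in zip(beta_sweep.grid, beta_sweep.outputs):
    print(f"  beta={b:5.1f}  vf={v:.5f}")

model = paracetamol_constants().indicator_model(p_e_marginal=0.3, prior_c=0.01)
vf_sweep = sweep(SweepSpec("vf", [0, 0.25, 0.5, 0.75, 1], {"model": model}))
print("\nvf sweep of the causal posterior:", vf_sweep.monotone_direction)
for v, q in zip(vf_sweep.grid, vf_sweep.outputs):
    print(f"  vf={v:4.2f}  Q(causal|E)={q:.5f}")

violations = sum(
    monotonicity_scan(RankingVector.equal(3), beta, trials=1000, seed=seed)
    for beta in (0.5, 2, 10)
    for seed in range(3)
)
print(f"\nmonotonicity violations over 9,000 random dominated pairs: {violations}")
print(
    "\nMore cautiousness strictly shrinks an imperfect study's aggregate; more "
    "trust strictly raises the causal posterior; and improving any single "
    "appraisal never lowers the aggregate (zero violations expected)."
)
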