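"""Self-check suite: the aggregate's proved properties, verified numerically.

Runs the package's core guarantees end to end without pytest, so a deployed
installation can audit itself (`ea3 check`): closed-form/pipeline agreement,
the constant-vector closed form, range and endpoint behaviour, strict
monotonicity in every appraisal, and the case-study table reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RankingVector, ea3, ea3_trace, ea3_uniform_closed_form, weighted_mean
from .sensitivity import case_aggregate_table, monotonicity_scan

__all__ = ["CheckResult", "run_checks"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str


def _random_inputs(rng: np.random.Generator, k: int):
    a = rng.uniform(0.0, 1.0, size=k)
    raw = rng.uniform(0.05, 1.0, size=k)
    r = RankingVector.normalised(raw)
    beta = rng.uniform(0.05, 20.0)
    return a, r, beta


def run_checks(seed: int = 0, draws: int = 1000) -> list[CheckResult]:
    """Run every property check; all must pass on a sound build."""
    rng = np.random.default_rng(int(seed))
    results: list[CheckResult] = []

    # literal 5-step trace agrees with the log-space closed form
    worst = 0.0
    for _ in range(draws):
        k = int(rng.integers(2, 7))
        a, r, beta = _random_inputs(rng, k)
        worst = max(worst, abs(ea3_trace(a, r, beta).final - ea3(a, r, beta)))
    results.append(
        CheckResult("trace-vs-closed-form", worst < 1e-12, f"max |delta| = {worst:.3e}")
    )

    # constant appraisals under equal ranking match the closed form
    worst = 0.0
    for c in np.linspace(0.0, 1.0, 11):
        for k in (2, 3, 5, 10):
            for beta in (0.01, 1.0, 5.0, 10.0):
                delta = abs(
                    ea3([c] * k, RankingVector.equal(k), beta)
                    - ea3_uniform_closed_form(c, k, beta)
                )
                worst = max(worst, delta)
    results.append(
        CheckResult("constant-vector-closed-form", worst < 1e-12, f"max |delta| = {worst:.3e}")
    )

    # range and endpoints: v_f in [0,1], 0 iff all-zero, 1 iff all-one
    ok = True
    for _ in range(draws):
        k = int(rng.integers(2, 7))
        a, r, beta = _random_inputs(rng, k)
        vf = ea3(a, r, beta)
        interior = np.any(a > 0.0) and np.any(a < 1.0)
        if not (0.0 <= vf <= 1.0) or (interior and not 0.0 < vf < 1.0):
            ok = False
            break
        if ea3(np.zeros(k), r, beta) != 0.0 or ea3(np.ones(k), r, beta) != 1.0:
            ok = False
            break
    results.append(CheckResult("range-and-endpoints", ok, f"{draws} random draws"))

    # strict monotonicity in every appraisal coordinate
    total = 0
    for beta in (0.5, 2.0, 10.0):
        total += monotonicity_scan(
            RankingVector.equal(3), beta, trials=draws, seed=int(rng.integers(2**31))
        )
    results.append(CheckResult("monotonicity", total == 0, f"{total} violations"))

    # case-study table: pipeline matches the independent closed forms,
    # and the beta->0 limit matches the weighted mean
    max_delta = 0.0
    for beta in (0.5, 1.0, 2.0, 5.0, 10.0):
        max_delta = max(max_delta, float(case_aggregate_table(beta)["abs_delta"].max()))
    table = case_aggregate_table(1e-8)
    limit_delta = float((table["ea3"] - table["weighted_mean"]).abs().max())
    results.append(
        CheckResult(
            "case-study-table",
            max_delta < 1e-12 and limit_delta < 1e-6,
            f"max |delta| = {max_delta:.3e}, beta->0 gap = {limit_delta:.3e}",
        )
    )

    # beta->0 limit equals the weighted mean on random draws
    worst = 0.0
    for _ in range(200):
        k = int(rng.integers(2, 7))
        a, r, _ = _random_inputs(rng, k)
        worst = max(worst, abs(ea3(a, r, 1e-8) - weighted_mean(a, r)))
    results.append(
        CheckResult("weighted-mean-limit", worst < 1e-6, f"max |delta| = {worst:.3e}")
    )

    return results
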