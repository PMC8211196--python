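"""Packaged case study and synthetic appraisal generator.

The case study is the paracetamol–asthma pharmacovigilance question: does
paracetamol use cause asthma in children?  Seven large observational surveys
provide the real-world evidence; each is appraised on three dimensions —
sample size (``SS``), duration of the surveyed period (``D``), and the
methodology for adjustment and stratification (``A``) — on the {0, 0.5, 1}
grid.  One of the surveys (Beasley et al. 2011) is informative about the
"rate of growth" dose-response indicator of causation, whose conditional
probabilities are packaged as exact rationals so that printed decimal
approximations (≈26.3 %, ≈0.4 %) are outputs of the package, never inputs.

A seeded synthetic generator produces appraisal tables of arbitrary size for
testing and simulation: uniform, beta-shaped, or restricted to the same
{0, 0.5, 1} grid the case-study appraisals use.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .bayes import IndicatorModel
from .core import AppraisalVector
from .exceptions import AppraisalValidationError

__all__ = [
    "DIMENSIONS",
    "SurveyRecord",
    "CaseConstants",
    "SyntheticConfig",
    "paracetamol_fixture",
    "paracetamol_surveys",
    "paracetamol_constants",
    "generate_synthetic",
]

#: Appraisal dimensions of the case study, in fixed order: sample size,
#: duration, adjustment/stratification.  Readers map columns by these header
#: names, never by position, to avoid silent transposition.
DIMENSIONS: tuple[str, str, str] = ("SS", "D", "A")


@dataclass(frozen=True)
class SurveyRecord:
    """One appraised survey: citation label plus its appraisal vector."""

    survey_id: str
    appraisals: AppraisalVector


@dataclass(frozen=True)
class CaseConstants:
    """Rate-of-growth indicator constants of the case study, as exact rationals.

    ``p_ind_given_c`` = P(RoG | ©) = 26 2/7 % and ``p_ind_given_notc`` =
    P(RoG | ¬©) = 3/7 %; ``p_e_given_ind`` = P(E1 | RoG) = 0.825 and
    ``p_e_given_notind`` = P(E1 | ¬RoG) = 0 (within the comparator model the
    single study is conclusive evidence that the indicator holds).  The
    evidence marginal P(E1) and the causal prior P(©) are deliberately free:
    call :meth:`indicator_model` to bind them.
    """

    p_ind_given_c: Fraction = Fraction(184, 700)      # 26 + 2/7 percent
    p_ind_given_notc: Fraction = Fraction(3, 700)     # 3/7 percent
    p_e_given_ind: Fraction = Fraction(825, 1000)
    p_e_given_notind: Fraction = Fraction(0)

    def indicator_model(self, p_e_marginal: float, prior_c: float) -> IndicatorModel:
        """Bind the free evidence marginal P(E1) and causal prior P(©)."""
        return IndicatorModel(
            p_ind_given_c=self.p_ind_given_c,
            p_ind_given_notc=self.p_ind_given_notc,
            p_e_given_ind=self.p_e_given_ind,
            p_e_given_notind=self.p_e_given_notind,
            p_e_marginal=p_e_marginal,
            prior_c=prior_c,
        )


# (survey_id, (SS, D, A)) — appraisals on the {0, 0.5, 1} grid.  Lesko &
# Mitchell (1999) and Lesko et al. (2002) share the same triple; Amberbir's
# triple is a permutation of Newson's/Beasley's and under equal ranking the
# pipeline yields the same aggregate for both (asserted in the tests).
_SURVEYS: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("Lesko and Mitchell (1999)", (1.0, 0.0, 0.5)),
    ("Newson et al. (2000)", (1.0, 0.5, 1.0)),
    ("Lesko et al. (2002)", (1.0, 0.0, 0.5)),
    ("Shaheen et al. (2002)", (1.0, 1.0, 1.0)),
    ("Karimi et al. (2006)", (0.5, 0.0, 0.5)),
    ("Amberbir et al. (2011)", (0.5, 1.0, 1.0)),
    ("Beasley et al. (2011)", (1.0, 0.5, 1.0)),
)


def paracetamol_surveys() -> list[SurveyRecord]:
    """The seven appraised surveys of the paracetamol–asthma case study."""
    return [
        SurveyRecord(survey_id=sid, appraisals=AppraisalVector(vals))
        for sid, vals in _SURVEYS
    ]


def paracetamol_constants() -> CaseConstants:
    """The rate-of-growth indicator constants, as exact rationals."""
    return CaseConstants()


def paracetamol_fixture() -> tuple[list[SurveyRecord], CaseConstants]:
    """The full packaged case study: seven surveys plus indicator constants."""
    return paracetamol_surveys(), paracetamol_constants()


_DISTRIBUTIONS = ("uniform", "beta", "grid")
_GRID_VALUES = np.array([0.0, 0.5, 1.0])


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for the synthetic appraisal generator.

    ``distribution`` is one of ``uniform`` (iid U[0, 1] appraisals), ``beta``
    (iid Beta(a, b), shaped to mimic predominantly-good or predominantly-poor
    appraisal profiles), or ``grid`` (the discrete {0, 0.5, 1} scale the case
    study uses).  Output is fully determined by ``seed``.
    """

    k: int = 3
    n_studies: int = 10
    distribution: str = "uniform"
    seed: int = 0
    beta_a: float = 2.0
    beta_b: float = 2.0

    def __post_init__(self):
        if int(self.k) < 2:
            raise AppraisalValidationError(f"k = {self.k!r} must be at least 2")
        if int(self.n_studies) < 1:
            raise AppraisalValidationError(
                f"n_studies = {self.n_studies!r} must be at least 1"
            )
        if self.distribution not in _DISTRIBUTIONS:
            raise AppraisalValidationError(
                f"distribution {self.distribution!r} not one of {_DISTRIBUTIONS}"
            )
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise AppraisalValidationError("beta shape parameters must be positive")


def generate_synthetic(cfg: SyntheticConfig) -> list[SurveyRecord]:
    """Draw ``cfg.n_studies`` appraisal vectors per ``cfg`` (seeded, repeatable)."""
    rng = np.random.default_rng(int(cfg.seed))
    shape = (int(cfg.n_studies), int(cfg.k))
    if cfg.distribution == "uniform":
        values = rng.uniform(0.0, 1.0, size=shape)
    elif cfg.distribution == "beta":
        values = rng.beta(cfg.beta_a, cfg.beta_b, size=shape)
    else:
        values = rng.choice(_GRID_VALUES, size=shape)
    return [
        SurveyRecord(survey_id=f"synthetic-{i:03d}", appraisals=AppraisalVector(row))
        for i, row in enumerate(values)
    ]
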