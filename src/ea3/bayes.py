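"""Bayesian decision layer: posteriors from quality-discounted evidence.

The aggregate ``v_f`` produced by the appraisal pipeline is read as the
probability that a study's evidence can be taken at face value.  Likelihoods
are then replaced by the Jeffrey-style convex mixture

    Q(E | H) = v_f * P(E | H) + (1 - v_f) * P(E),

so that a perfectly appraised study (``v_f = 1``) enters Bayes' theorem with
its reported likelihood and a worthless one (``v_f = 0``) leaves the prior
untouched.  :func:`posterior_single` and :func:`posterior_multi` apply this to
a finite space of exhaustive, mutually exclusive hypotheses; independence
across studies is assumed for the multi-study product form.

The causal-indicator layer models pharmacovigilance assessment: the hypothesis
of interest is © ("drug D causes adverse reaction E") and an indicator
variable Ind (a probabilistic, testable consequence of © such as a
dose-response rate-of-growth signal) mediates between © and the data —
conditioning on Ind renders the data independent of ©.
:func:`causal_posterior` computes Q(© | E) with the study's likelihoods
discounted through the mixture; :func:`face_value_posterior` is the
comparator that takes the single study as conclusive proof of the indicator,
which coincides with :func:`causal_posterior` at ``v_f = 1`` when
P(E | not-Ind) = 0.

A deliberate modelling point: the marginal P(E) is a free input, never
derived from the likelihoods and priors.  Deriving it would make the mixture
collapse to ordinary conditioning and erase the role of ``v_f``; the mixed
quantities Q(E | H) are therefore not required to be coherent marginals of a
single probability function, and only the returned posteriors are guaranteed
normalised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .exceptions import (
    AppraisalValidationError,
    DegenerateEvidenceError,
    DimensionError,
)

__all__ = [
    "HypothesisSpace",
    "StudyEvidence",
    "IndicatorModel",
    "mix_likelihood",
    "posterior_single",
    "posterior_multi",
    "causal_posterior",
    "face_value_posterior",
]

_PRIOR_SUM_TOL = 1e-9


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0 or value > 1.0:
        raise AppraisalValidationError(f"{name} = {value!r} is not a probability in [0, 1]")
    return value


@dataclass(frozen=True)
class HypothesisSpace:
    """Exhaustive, mutually exclusive hypotheses with prior probabilities."""

    labels: tuple[str, ...]
    priors: np.ndarray

    def __init__(self, labels: Sequence[str], priors: Sequence[float] | np.ndarray):
        labels = tuple(str(lab) for lab in labels)
        if len(labels) < 2:
            raise DimensionError(f"need at least 2 hypotheses, got {len(labels)}")
        if len(set(labels)) != len(labels):
            raise AppraisalValidationError("hypothesis labels must be unique")
        arr = np.asarray(priors, dtype=float)
        if arr.shape != (len(labels),):
            raise DimensionError(
                f"{len(labels)} labels but {arr.size} priors"
            )
        for p in arr:
            _check_prob(p, "prior")
        if abs(float(arr.sum()) - 1.0) > _PRIOR_SUM_TOL:
            raise AppraisalValidationError(
                f"priors sum to {float(arr.sum())!r}, not 1 (tolerance {_PRIOR_SUM_TOL})"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "priors", arr)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class StudyEvidence:
    """One study's face-value likelihoods, marginal, and appraisal aggregate.

    ``face_value_likelihoods[h]`` is P(E | H_h) as the study reports it;
    ``marginal`` is the free prior probability P(E) of observing this
    evidence; ``vf`` is the study's appraisal aggregate in [0, 1].
    """

    study_id: str
    face_value_likelihoods: np.ndarray
    marginal: float
    vf: float

    def __init__(
        self,
        study_id: str,
        face_value_likelihoods: Sequence[float] | np.ndarray,
        marginal: float,
        vf: float,
    ):
        arr = np.asarray(face_value_likelihoods, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise DimensionError("face_value_likelihoods must list one probability per hypothesis")
        for p in arr:
            _check_prob(p, f"likelihood of study {study_id!r}")
        arr.flags.writeable = False
        object.__setattr__(self, "study_id", str(study_id))
        object.__setattr__(self, "face_value_likelihoods", arr)
        object.__setattr__(self, "marginal", _check_prob(marginal, "marginal"))
        object.__setattr__(self, "vf", _check_prob(vf, "vf"))


@dataclass(frozen=True)
class IndicatorModel:
    """Causal-indicator layer for a drug-causes-adverse-reaction hypothesis.

    Fields are the conditional probabilities of the indicator given the
    causal hypothesis and its negation, the evidence likelihoods given the
    indicator state, the free evidence marginal P(E), and the prior P(©).
    Complements P(not-Ind | .) are always derived as 1 - P(Ind | .).
    Probabilities may be given as exact :class:`fractions.Fraction` values;
    they are converted to float at use time.
    """

    p_ind_given_c: float
    p_ind_given_notc: float
    p_e_given_ind: float
    p_e_given_notind: float
    p_e_marginal: float
    prior_c: float

    def __init__(
        self,
        p_ind_given_c: float | Fraction,
        p_ind_given_notc: float | Fraction,
        p_e_given_ind: float | Fraction,
        p_e_given_notind: float | Fraction,
        p_e_marginal: float | Fraction,
        prior_c: float | Fraction,
    ):
        object.__setattr__(self, "p_ind_given_c", _check_prob(p_ind_given_c, "p_ind_given_c"))
        object.__setattr__(
            self, "p_ind_given_notc", _check_prob(p_ind_given_notc, "p_ind_given_notc")
        )
        object.__setattr__(self, "p_e_given_ind", _check_prob(p_e_given_ind, "p_e_given_ind"))
        object.__setattr__(
            self, "p_e_given_notind", _check_prob(p_e_given_notind, "p_e_given_notind")
        )
        object.__setattr__(self, "p_e_marginal", _check_prob(p_e_marginal, "p_e_marginal"))
        prior_c = _check_prob(prior_c, "prior_c")
        if prior_c == 0.0 or prior_c == 1.0:
            raise AppraisalValidationError(
                f"prior_c = {prior_c!r} must lie strictly inside (0, 1)"
            )
        object.__setattr__(self, "prior_c", prior_c)


def mix_likelihood(p_like: float, p_marginal: float, vf: float) -> float:
    """Jeffrey mixture ``vf * P(E|H) + (1 - vf) * P(E)``.

    Interpolates between the reported likelihood (face value, vf = 1) and the
    evidence marginal (uninformative, vf = 0); always lies between the two.
    """
    p_like = _check_prob(p_like, "p_like")
    p_marginal = _check_prob(p_marginal, "p_marginal")
    vf = _check_prob(vf, "vf")
    return vf * p_like + (1.0 - vf) * p_marginal


def _mixed_likelihoods(space: HypothesisSpace, study: StudyEvidence) -> np.ndarray:
    if study.face_value_likelihoods.size != space.n:
        raise DimensionError(
            f"study {study.study_id!r} lists {study.face_value_likelihoods.size} "
            f"likelihoods for {space.n} hypotheses"
        )
    return study.vf * study.face_value_likelihoods + (1.0 - study.vf) * study.marginal


def posterior_single(space: HypothesisSpace, study: StudyEvidence) -> np.ndarray:
    """Posterior over hypotheses given one quality-discounted study.

    Entry h is P(H_h) * Q(E|H_h) normalised over hypotheses, with Q the
    mixture of :func:`mix_likelihood`.  At vf = 0 this returns the prior
    exactly; at vf = 1 it is the ordinary Bayes posterior.
    """
    return posterior_multi(space, [study])


def posterior_multi(
    space: HypothesisSpace, studies: Sequence[StudyEvidence]
) -> np.ndarray:
    """Posterior over hypotheses given several independent discounted studies.

    Entry h is proportional to ``P(H_h) * prod_r Q(E_r | H_h)`` evaluated in a
    single normalisation; with one study it reduces to
    :func:`posterior_single`, and it is invariant to the order of the studies.
    """
    if len(studies) == 0:
        raise AppraisalValidationError("need at least one study")
    # a vf = 0 study contributes the constant factor P(E_r) to every
    # hypothesis; it cancels in the normalisation, and dropping it up front
    # keeps the all-worthless case equal to the prior *exactly*
    informative = []
    for study in studies:
        _mixed_likelihoods(space, study)  # still validated for alignment
        if study.vf > 0.0:
            informative.append(study)
    if not informative:
        return space.priors.copy()
    joint = space.priors.astype(float).copy()
    for study in informative:
        joint *= _mixed_likelihoods(space, study)
    total = float(joint.sum())
    if total <= 0.0:
        raise DegenerateEvidenceError(
            "every hypothesis assigns the observed evidence probability 0; "
            "the evidence model is degenerate"
        )
    return joint / total


def _indicator_odds_terms(model: IndicatorModel, vf: float) -> tuple[float, float]:
    q1 = mix_likelihood(model.p_e_given_ind, model.p_e_marginal, vf)
    q0 = mix_likelihood(model.p_e_given_notind, model.p_e_marginal, vf)
    numer = (1.0 - model.prior_c) * (
        model.p_ind_given_notc * q1 + (1.0 - model.p_ind_given_notc) * q0
    )
    denom = model.prior_c * (
        model.p_ind_given_c * q1 + (1.0 - model.p_ind_given_c) * q0
    )
    return numer, denom


def causal_posterior(model: IndicatorModel, vf: float) -> float:
    """Posterior probability Q(© | E) of the causal hypothesis.

    Expands over the indicator states and discounts the evidence likelihoods
    through the Jeffrey mixture:

        Q(©|E) = [1 + P(¬©)(P(Ind|¬©) q1 + P(¬Ind|¬©) q0)
                      / (P(©)(P(Ind|©) q1 + P(¬Ind|©) q0))]^-1,

    with q1 = mix(P(E|Ind), P(E), vf) and q0 = mix(P(E|¬Ind), P(E), vf).
    At vf = 0 it returns the prior P(©); when the indicator is equally likely
    under © and ¬© it is uninformative and the prior is returned for any vf.
    """
    vf = _check_prob(vf, "vf")
    numer, denom = _indicator_odds_terms(model, vf)
    if denom <= 0.0:
        raise DegenerateEvidenceError(
            "the causal hypothesis assigns the evidence probability 0; "
            "posterior odds are undefined"
        )
    return 1.0 / (1.0 + numer / denom)


def face_value_posterior(model: IndicatorModel) -> float:
    """Comparator posterior taking the study as conclusive for the indicator.

    Treats the single study as proof that the indicator holds, so the
    posterior reduces to P(© | Ind) = [1 + P(¬©)/P(©) *
    P(Ind|¬©)/P(Ind|©)]^-1.  Coincides with :func:`causal_posterior` at
    vf = 1 whenever P(E | ¬Ind) = 0.
    """
    if model.p_ind_given_c <= 0.0:
        raise DegenerateEvidenceError(
            "p_ind_given_c = 0: the indicator never occurs under the causal "
            "hypothesis, posterior odds are undefined"
        )
    odds = (
        (1.0 - model.prior_c)
        / model.prior_c
        * model.p_ind_given_notc
        / model.p_ind_given_c
    )
    return 1.0 / (1.0 + odds)
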