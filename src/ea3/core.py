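"""Core aggregation: softmax and the five-step EA3 algorithm.

EA3 compresses a vector of per-dimension evidence-quality appraisals
``A = <a_1 ... a_k>``, each in [0, 1], into a single aggregate ``v_f`` in
[0, 1], given a ranking vector ``R`` of positive dimension importances summing
to one and a cautiousness parameter ``beta > 0`` (the softmax inverse
temperature).  The five steps are

1. weight each appraisal by its importance, ``a_l^[1] = r_l * a_l``;
2. softmax the weighted appraisals at inverse temperature ``beta``;
3. rescale by the weighted mean ``A x R`` (restores sensitivity to uniform
   translations, which softmax alone ignores);
4. compress to a scalar via the product of the softmax numerators over the
   shared denominator, ``v = exp(beta * (A x R)) / sum_i exp(beta r_i a_i)
   * (A x R)``;
5. normalise into the unit interval,
   ``v_f = v * sum_i exp(beta r_i) / exp(beta)``.

The composition admits the closed form

    v_f = exp(beta * (AxR - 1)) * [sum_i exp(beta r_i)]
          / [sum_i exp(beta r_i a_i)] * (AxR),

which :func:`ea3` evaluates in log space so that any admissible ``beta`` up to
the double-precision overflow bound is exact.  :func:`ea3_trace` runs the five
steps literally and records every intermediate; agreement of the two routes is
a tested invariant, not an assumption.

Key properties (all exercised by the test suite): ``v_f`` is strictly
increasing in every appraisal for fixed ``R`` and ``beta``; ``v_f = 0`` iff
all appraisals are 0 and ``v_f = 1`` iff all are 1; the aggregate is *not*
idempotent — for constant appraisals ``c`` under equal ranking it equals
``c * exp(beta * (c - 1) * (1 - 1/k))``, strictly below ``c`` for ``c < 1``,
so several imperfections compound into a worse score than any one of them.
As ``beta -> 0+`` the aggregate tends to the weighted mean ``A x R``; as
``beta -> +inf`` it tends to 0 whenever any appraisal is imperfect (maximal
cautiousness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp, softmax as _scipy_softmax

from .exceptions import AppraisalValidationError, DimensionError, ParameterError

__all__ = [
    "AppraisalVector",
    "RankingVector",
    "StepTrace",
    "BETA_MAX",
    "softmax",
    "ea3",
    "ea3_trace",
    "ea3_uniform_closed_form",
    "weighted_mean",
]

#: Largest admissible cautiousness parameter.  Step 5 divides by exp(beta),
#: which overflows double precision just above 709; the closed form is
#: evaluated in log space, but the literal step-by-step trace is not, so a
#: single bound keeps the two routes on the same domain.
BETA_MAX = 700.0

RANKING_SUM_TOL = 1e-9


def _as_1d(values: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DimensionError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise AppraisalValidationError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class AppraisalVector:
    """The k quality appraisals of one study, each in [0, 1].

    1 is a perfect appraisal on that dimension (e.g. ideal adjustment and
    stratification), 0 the worst possible (e.g. a tiny sample).  At least two
    dimensions are required; aggregating a single appraisal is the identity
    and is served by :func:`weighted_mean`.
    """

    values: np.ndarray

    def __init__(self, values: Sequence[float] | np.ndarray):
        arr = _as_1d(values, "appraisals")
        if arr.size < 2:
            raise DimensionError(f"need at least 2 appraisal dimensions, got {arr.size}")
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            bad = arr[(arr < 0.0) | (arr > 1.0)][0]
            raise AppraisalValidationError(f"appraisal {bad!r} outside [0, 1]")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @classmethod
    def uniform(cls, c: float, k: int) -> "AppraisalVector":
        """The constant vector c@k (all k entries equal to c)."""
        return cls(np.full(int(k), float(c)))

    @property
    def k(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class RankingVector:
    """Importance weights over appraisal dimensions.

    Each weight lies strictly inside (0, 1) and the weights sum to one (within
    1e-9).  The more important a dimension, the larger its weight.  Weights
    are never silently renormalised — use :meth:`normalised` explicitly, since
    silent rescaling would change the aggregate invisibly.
    """

    weights: np.ndarray

    def __init__(self, weights: Sequence[float] | np.ndarray):
        arr = _as_1d(weights, "ranking")
        if arr.size < 2:
            raise DimensionError(f"need at least 2 ranking weights, got {arr.size}")
        if np.any(arr <= 0.0) or np.any(arr >= 1.0):
            bad = arr[(arr <= 0.0) | (arr >= 1.0)][0]
            raise AppraisalValidationError(
                f"ranking weight {bad!r} outside the open interval (0, 1)"
            )
        total = float(arr.sum())
        if abs(total - 1.0) > RANKING_SUM_TOL:
            raise AppraisalValidationError(
                f"ranking weights sum to {total!r}, not 1 (tolerance {RANKING_SUM_TOL}); "
                "use RankingVector.normalised or normalise explicitly"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "weights", arr)

    @classmethod
    def equal(cls, k: int) -> "RankingVector":
        """Equal importance for all k dimensions (weight 1/k each)."""
        return cls(np.full(int(k), 1.0 / int(k)))

    @classmethod
    def normalised(cls, raw: Sequence[float] | np.ndarray) -> "RankingVector":
        """Build a ranking from positive raw weights, rescaled to sum to 1."""
        arr = _as_1d(raw, "ranking")
        if np.any(arr <= 0.0):
            raise AppraisalValidationError("raw ranking weights must be strictly positive")
        return cls(arr / arr.sum())

    @property
    def k(self) -> int:
        return self.weights.size

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class StepTrace:
    """Every intermediate of the five-step pipeline, for audit.

    Attributes mirror the steps: ``weighted`` (step 1), ``softmaxed``
    (step 2; entries in (0, 1), summing to 1), ``rescaled`` (step 3),
    ``geometric`` (the scalar v of step 4), ``final`` (v_f, step 5) and
    ``dot`` (the weighted mean A x R used in steps 3-4).
    """

    weighted: np.ndarray
    softmaxed: np.ndarray
    rescaled: np.ndarray
    geometric: float
    final: float
    dot: float


def _check_beta(beta: float, *, allow_negative: bool = False) -> float:
    beta = float(beta)
    if not math.isfinite(beta):
        raise ParameterError(f"beta must be finite, got {beta!r}")
    if beta == 0.0:
        raise ParameterError(
            "beta = 0 is not admissible: softmax degenerates to the uniform "
            "distribution and the pipeline to the weighted mean; call "
            "weighted_mean for that limit"
        )
    if not allow_negative and beta < 0.0:
        raise ParameterError(
            f"beta must be positive for the aggregation pipeline (got {beta!r}); "
            "negative beta breaks the unit-interval normalisation"
        )
    if abs(beta) > BETA_MAX:
        raise ParameterError(f"|beta| = {abs(beta)!r} exceeds the overflow bound {BETA_MAX}")
    return beta


def _coerce_pair(
    appraisals: AppraisalVector | Sequence[float] | np.ndarray,
    ranking: RankingVector | Sequence[float] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    a = appraisals if isinstance(appraisals, AppraisalVector) else AppraisalVector(appraisals)
    r = ranking if isinstance(ranking, RankingVector) else RankingVector(ranking)
    if a.k != r.k:
        raise DimensionError(
            f"appraisals have {a.k} dimensions but ranking has {r.k}"
        )
    return a.values, r.weights


def softmax(values: Sequence[float] | np.ndarray, beta: float) -> np.ndarray:
    """Normalised exponential of ``beta * values``.

    Maps any real vector of length k >= 2 to a probability vector whose l-th
    entry is proportional to ``exp(beta * values[l])``.  Invariant under
    adding a constant to every entry; *not* invariant under rescaling.
    ``beta`` may be any nonzero real here (the aggregation pipeline itself
    restricts to ``beta > 0``); ``beta = 0`` is rejected so that the uniform
    distribution is always an explicit caller choice.
    """
    arr = _as_1d(values, "softmax input")
    if arr.size < 2:
        raise DimensionError(f"softmax needs at least 2 entries, got {arr.size}")
    beta = _check_beta(beta, allow_negative=True)
    return _scipy_softmax(beta * arr)


def weighted_mean(
    appraisals: AppraisalVector | Sequence[float] | np.ndarray,
    ranking: RankingVector | Sequence[float] | np.ndarray,
) -> float:
    """The ranked weighted mean A x R = sum_l r_l a_l.

    This is the beta -> 0+ limit of the pipeline (maximal optimism: several
    imperfections count no worse than one) and the aggregate used by the
    arithmetic-mean predecessor of EA3.
    """
    a, r = _coerce_pair(appraisals, ranking)
    return float(a @ r)


def ea3(
    appraisals: AppraisalVector | Sequence[float] | np.ndarray,
    ranking: RankingVector | Sequence[float] | np.ndarray,
    beta: float,
) -> float:
    """Aggregate appraisals into v_f in [0, 1] (fast closed-form path).

    Evaluates ``log v_f = beta * (dot - 1) + logsumexp(beta * r)
    - logsumexp(beta * r * a) + log(dot)`` with ``dot = A x R``, so large
    admissible ``beta`` neither overflows nor underflows prematurely.
    ``v_f = 0`` iff every appraisal is 0 and ``v_f = 1`` iff every appraisal
    is 1.  Use :func:`ea3_trace` for the literal step-by-step computation.
    """
    a, r = _coerce_pair(appraisals, ranking)
    beta = _check_beta(beta)
    dot = float(a @ r)
    if dot == 0.0:
        # all appraisals zero: v_f is exactly 0, no log(dot) evaluated
        return 0.0
    if np.all(a == 1.0):
        # all appraisals perfect: v_f is exactly 1 (the endpoint identity),
        # guarded here because float ranking weights need not sum to 1 exactly
        return 1.0
    log_vf = (
        beta * (dot - 1.0)
        + logsumexp(beta * r)
        - logsumexp(beta * r * a)
        + math.log(dot)
    )
    return min(math.exp(log_vf), 1.0)


def ea3_trace(
    appraisals: AppraisalVector | Sequence[float] | np.ndarray,
    ranking: RankingVector | Sequence[float] | np.ndarray,
    beta: float,
) -> StepTrace:
    """Run the five steps literally and return every intermediate.

    The audit path: step 2's softmax output sums to one, step 4 compresses
    via the product of softmax numerators over their shared denominator, and
    step 5 rescales into the unit interval.  Agreement of ``final`` with
    :func:`ea3` (within 1e-12 for moderate beta) is enforced by the test
    suite.
    """
    a, r = _coerce_pair(appraisals, ranking)
    beta = _check_beta(beta)
    weighted = r * a
    softmaxed = _scipy_softmax(beta * weighted)
    dot = float(a @ r)
    rescaled = softmaxed * dot
    denom = float(np.sum(np.exp(beta * weighted)))
    geometric = float(np.prod(np.exp(beta * weighted))) / denom * dot
    final = geometric * float(np.sum(np.exp(beta * r))) / math.exp(beta)
    return StepTrace(
        weighted=weighted,
        softmaxed=softmaxed,
        rescaled=rescaled,
        geometric=geometric,
        final=final,
        dot=dot,
    )


def ea3_uniform_closed_form(c: float, k: int, beta: float) -> float:
    """Aggregate of the constant vector c@k under equal ranking.

    For all-equal appraisals ``c`` and equal importances the pipeline reduces
    to ``c * exp(beta * (c - 1) * (1 - 1/k))`` — strictly below ``c`` for
    ``c < 1``, witnessing that the aggregation is deliberately not
    idempotent: uniform imperfection across several dimensions scores worse
    than the common value.
    """
    c = float(c)
    if not math.isfinite(c) or c < 0.0 or c > 1.0:
        raise AppraisalValidationError(f"c = {c!r} outside [0, 1]")
    k = int(k)
    if k < 2:
        raise DimensionError(f"need k >= 2 dimensions, got {k}")
    beta = _check_beta(beta)
    return c * math.exp(beta * (c - 1.0) * (1.0 - 1.0 / k))
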