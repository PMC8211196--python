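"""Softmax and five-step aggregation pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ea3 import (
    AppraisalVector,
    AppraisalValidationError,
    DimensionError,
    ParameterError,
    RankingVector,
    ea3,
    ea3_trace,
    ea3_uniform_closed_form,
    softmax,
    weighted_mean,
)
from .conftest import random_inputs

E = math.e

unit_floats = st.floats(min_value=0.0, max_value=1.0)


class TestSoftmax:
    def test_direct_evaluation_two_components(self):
        out = softmax([1.0, 0.0], beta=1.0)
        assert out == pytest.approx([E / (E + 1), 1 / (E + 1)], abs=1e-12)

    @pytest.mark.parametrize("c,k,beta", [(0.3, 2, 1.0), (0.0, 5, 7.5), (-4.2, 3, -2.0)])
    def test_constant_input_gives_uniform(self, c, k, beta):
        assert softmax([c] * k, beta) == pytest.approx([1.0 / k] * k, abs=1e-15)

    def test_normalisation_on_random_draws(self, rng):
        # draws cover the scale softmax sees inside the pipeline (weighted
        # appraisals in [0, 1], moderate beta of either sign)
        for _ in range(1000):
            k = int(rng.integers(2, 8))
            values = rng.uniform(-1.0, 1.0, size=k)
            beta = float(rng.uniform(0.1, 10.0)) * rng.choice([-1.0, 1.0])
            out = softmax(values, beta)
            assert abs(out.sum() - 1.0) < 1e-12
            assert np.all(out > 0.0) and np.all(out < 1.0)

    @given(
        values=st.lists(st.floats(min_value=-10, max_value=10), min_size=2, max_size=6),
        shift=st.floats(min_value=-10, max_value=10),
        beta=st.floats(min_value=0.1, max_value=10),
    )
    def test_translation_invariance(self, values, shift, beta):
        base = softmax(values, beta)
        shifted = softmax(np.asarray(values) + shift, beta)
        assert np.max(np.abs(base - shifted)) < 1e-12

    def test_not_scale_invariant(self):
        assert not np.allclose(softmax([2.0, 0.0], 1.0), softmax([1.0, 0.0], 1.0))

    def test_rejects_single_component(self):
        with pytest.raises(DimensionError):
            softmax([0.5], 1.0)

    def test_rejects_beta_zero(self):
        with pytest.raises(ParameterError):
            softmax([0.1, 0.2], 0.0)

    def test_rejects_non_finite_input(self):
        with pytest.raises(AppraisalValidationError):
            softmax([0.1, float("nan")], 1.0)


class TestVectors:
    def test_appraisal_bounds_enforced(self):
        with pytest.raises(AppraisalValidationError):
            AppraisalVector([0.5, 1.2])
        with pytest.raises(AppraisalValidationError):
            AppraisalVector([-0.1, 0.5])

    def test_uniform_constructor(self):
        assert AppraisalVector.uniform(0.5, 4).values.tolist() == [0.5] * 4

    def test_ranking_must_sum_to_one(self):
        with pytest.raises(AppraisalValidationError):
            RankingVector([0.5, 0.4])

    def test_ranking_weights_strictly_inside_unit_interval(self):
        with pytest.raises(AppraisalValidationError):
            RankingVector([1.0, 0.0])

    def test_explicit_normalisation_helper(self):
        r = RankingVector.normalised([2.0, 1.0, 1.0])
        assert r.weights == pytest.approx([0.5, 0.25, 0.25])


class TestEA3:
    def test_all_perfect_appraisals_aggregate_to_one(self, equal3):
        for beta in (0.5, 1.0, 2.0, 5.0, 10.0, 500.0):
            assert ea3([1.0, 1.0, 1.0], equal3, beta) == 1.0

    def test_all_zero_appraisals_aggregate_to_zero(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            _, r, beta = random_inputs(rng, k)
            assert ea3(np.zeros(k), r, beta) == 0.0

    def test_mixed_appraisals_closed_form_value(self, equal3):
        # independently derived: exp(-beta/3) / (1 + 2 exp(beta/6)) at beta=3
        beta = 3.0
        expected = math.exp(-1.0) / (1.0 + 2.0 * math.exp(0.5))
        assert ea3([0.5, 0.0, 0.5], equal3, beta) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.085604, abs=5e-7)

    def test_trace_agrees_with_closed_form(self, rng):
        worst = 0.0
        for _ in range(1000):
            a, r, beta = random_inputs(rng)
            worst = max(worst, abs(ea3_trace(a, r, beta).final - ea3(a, r, beta)))
        assert worst < 1e-12

    def test_trace_softmax_step_is_a_distribution(self, rng):
        for _ in range(100):
            a, r, beta = random_inputs(rng)
            trace = ea3_trace(a, r, beta)
            assert abs(trace.softmaxed.sum() - 1.0) < 1e-12
            assert np.all(trace.softmaxed > 0.0) and np.all(trace.softmaxed < 1.0)
            assert trace.weighted == pytest.approx(r.weights * a)
            assert trace.rescaled == pytest.approx(trace.softmaxed * trace.dot)

    def test_range_and_strict_endpoints(self, rng):
        for _ in range(1000):
            a, r, beta = random_inputs(rng)
            vf = ea3(a, r, beta)
            assert 0.0 <= vf <= 1.0
            if np.any(a > 0.0):
                assert vf > 0.0
            if np.any(a < 1.0):
                assert vf < 1.0

    @given(data=st.data())
    def test_monotone_in_every_appraisal(self, data):
        k = data.draw(st.integers(min_value=2, max_value=5))
        a = np.array(data.draw(st.lists(unit_floats, min_size=k, max_size=k)))
        bumps = np.array(
            data.draw(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=k, max_size=k))
        )
        a_prime = np.clip(a + bumps, 0.0, 1.0)
        if not np.any(a_prime - a > 1e-6):  # a measurable strict improvement
            return
        r = RankingVector.equal(k)
        beta = data.draw(st.floats(min_value=0.1, max_value=30.0))
        assert ea3(a_prime, r, beta) > ea3(a, r, beta)

    def test_large_admissible_beta_is_finite_and_exact(self, equal3):
        vf = ea3([0.9, 0.9, 0.9], equal3, 700.0)
        expected = ea3_uniform_closed_form(0.9, 3, 700.0)
        assert math.isfinite(vf)
        assert vf == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self, equal3):
        with pytest.raises(DimensionError):
            ea3([0.5, 0.5], equal3, 1.0)

    @pytest.mark.parametrize("beta", [0.0, -1.0, 701.0, float("inf")])
    def test_inadmissible_beta_rejected(self, equal3, beta):
        with pytest.raises(ParameterError):
            ea3([0.5, 0.5, 0.5], equal3, beta)

    def test_out_of_range_appraisal_rejected(self, equal3):
        with pytest.raises(AppraisalValidationError):
            ea3([1.5, 0.5, 0.5], equal3, 1.0)


class TestUniformClosedForm:
    def test_direct_evaluation(self):
        assert ea3_uniform_closed_form(0.5, 3, 1.0) == pytest.approx(
            0.5 * math.exp(-1.0 / 3.0), abs=1e-15
        )

    @pytest.mark.parametrize("k", [2, 3, 5, 10])
    @pytest.mark.parametrize("beta", [0.01, 1.0, 5.0, 10.0])
    def test_matches_pipeline_on_constant_vectors(self, k, beta):
        for c in np.linspace(0.0, 1.0, 11):
            closed = ea3_uniform_closed_form(c, k, beta)
            piped = ea3(AppraisalVector.uniform(c, k), RankingVector.equal(k), beta)
            assert abs(closed - piped) < 1e-12

    def test_endpoints(self):
        assert ea3_uniform_closed_form(1.0, 4, 9.0) == 1.0
        assert ea3_uniform_closed_form(0.0, 4, 9.0) == 0.0

    def test_strictly_decreasing_in_beta(self):
        values = [ea3_uniform_closed_form(0.5, 3, b) for b in np.linspace(0.5, 50, 100)]
        assert all(b < a for a, b in zip(values, values[1:]))
        # maximal cautiousness: imperfect studies are driven towards zero
        assert ea3_uniform_closed_form(0.5, 3, 700.0) < 1e-90

    def test_increasing_in_c_and_approaching_identity(self):
        grid = np.linspace(0.0, 1.0, 11)
        vals = [ea3_uniform_closed_form(c, 3, 2.0) for c in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        # small beta pulls the curve towards the identity; growing k deepens
        # the discount towards the limiting c*exp(beta*(c-1))
        assert abs(ea3_uniform_closed_form(0.5, 3, 1e-6) - 0.5) < 1e-6
        gap_k3 = 0.5 - ea3_uniform_closed_form(0.5, 3, 2.0)
        gap_k50 = 0.5 - ea3_uniform_closed_form(0.5, 50, 2.0)
        gap_limit = 0.5 - 0.5 * np.exp(2.0 * (0.5 - 1.0))
        assert 0.0 < gap_k3 < gap_k50 < gap_limit

    def test_out_of_range_c_rejected(self):
        with pytest.raises(AppraisalValidationError):
            ea3_uniform_closed_form(1.1, 3, 1.0)


class TestWeightedMean:
    def test_case_values(self, equal3):
        assert weighted_mean([0.5, 0.0, 0.5], equal3) == pytest.approx(1.0 / 3.0)
        assert weighted_mean([1.0, 0.5, 1.0], equal3) == pytest.approx(5.0 / 6.0)
        assert weighted_mean([1.0, 1.0, 1.0], RankingVector([0.2, 0.3, 0.5])) == 1.0

    def test_is_small_beta_limit_of_pipeline(self, rng):
        for _ in range(200):
            a, r, _ = random_inputs(rng)
            assert abs(ea3(a, r, 1e-8) - weighted_mean(a, r)) < 1e-6

    def test_length_mismatch_rejected(self, equal3):
        with pytest.raises(DimensionError):
            weighted_mean([0.5, 0.5], equal3)
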