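"""Modifier terms, mean functions, likelihoods, and the candidate family."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from treecl.core import (
    DomainError,
    GrowthParams,
    ModelSpec,
    SpecificationError,
    SurvivalParams,
    TreeArrays,
    TreeRecord,
    enumerate_models,
    growth_mean,
    log_likelihood,
    lognormal_modifier,
    param_names,
    sulfur_sigmoid,
    survival_prob,
)
from conftest import random_growth_params, random_survival_params


def make_record(**overrides):
    base = dict(tree_id="t1", species="SP", division="21", plot_id="p1",
                size_m=100.0, dt=8.0, BA=25.0, BAL=10.0, T=285.0, P=10.0,
                N=9.0, S=6.0, growth_G=2.0, survived_y=1)
    base.update(overrides)
    return TreeRecord(**base)


class TestLognormalModifier:
    def test_peaks_at_location(self):
        assert lognormal_modifier(300, 300, 2) == 1.0

    def test_one_ln_width_from_peak(self):
        c1, c2 = 7.0, 0.8
        assert lognormal_modifier(c1 * math.exp(c2), c1, c2) == \
            pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_direct_evaluation(self):
        assert lognormal_modifier(10, 5, 1) == \
            pytest.approx(0.7864497045594053, abs=1e-12)

    def test_symmetric_in_ln_space(self):
        c1, c2 = 12.0, 0.7
        for r in (1.5, 3.0):
            assert lognormal_modifier(c1 * r, c1, c2) == \
                pytest.approx(lognormal_modifier(c1 / r, c1, c2), rel=1e-12)

    def test_rejects_nonpositive_input(self):
        with pytest.raises(DomainError, match="N"):
            lognormal_modifier(-1, 5, 1, symbol="N")

    @given(x=st.floats(0.01, 1e3), c1=st.floats(0.01, 1e3),
           c2=st.floats(0.05, 10))
    @settings(max_examples=200, deadline=None)
    def test_bounded_unit_interval(self, x, c1, c2):
        v = lognormal_modifier(x, c1, c2)
        # (0, 1] mathematically; exactly 0.0 only by floating underflow
        assert 0 <= v <= 1
        if v == 0:
            assert 0.5 * (math.log(x / c1) / c2) ** 2 > 700


class TestSulfurSigmoid:
    def test_no_deposition_no_reduction(self):
        assert sulfur_sigmoid(0.0, 10, 2, 0.2) == 1.0

    def test_halfway_point_at_s1(self):
        for s3 in (0.0, 0.3, 0.8):
            assert sulfur_sigmoid(10.0, 10, 2, s3) == \
                pytest.approx(s3 + (1 - s3) / 2, abs=1e-12)

    def test_hand_evaluation(self):
        assert sulfur_sigmoid(20, 10, 2, 0.2) == pytest.approx(0.36, abs=1e-12)

    def test_rejects_plateau_at_or_above_one(self):
        with pytest.raises(DomainError):
            sulfur_sigmoid(5, 10, 2, 1.0)

    @given(s1=st.floats(0.1, 50), s2=st.floats(0.1, 8),
           s3=st.floats(0, 0.99, exclude_max=True),
           a=st.floats(0, 100), b=st.floats(0, 100))
    @settings(max_examples=300, deadline=None)
    def test_monotone_nonincreasing(self, s1, s2, s3, a, b):
        lo, hi = sorted((a, b))
        assert sulfur_sigmoid(lo, s1, s2, s3) >= \
            sulfur_sigmoid(hi, s1, s2, s3) - 1e-12

    @given(s1=st.floats(0.1, 50), s2=st.floats(0.1, 8),
           s3=st.floats(0, 0.98), S=st.floats(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_bounded_between_plateau_and_one(self, s1, s2, s3, S):
        v = sulfur_sigmoid(S, s1, s2, s3)
        assert s3 <= v <= 1


class TestGrowthMean:
    def test_all_modifiers_at_peak(self):
        spec = ModelSpec("growth", True, "sigmoid")
        p = GrowthParams(a=2, z=0.5, a2=-0.1, a3=0.3, t1=285, t2=1,
                         p1=10, p2=1, n1=9, n2=1, s1=5, s2=2, s3=0.0,
                         sigma=1)
        rec = make_record(size_m=100, BAL=0, BA=1, T=285, P=10, N=9, S=0)
        assert growth_mean(rec, spec, p) == pytest.approx(2 * 10, rel=1e-12)

    def test_excluded_terms_are_inert(self):
        spec = ModelSpec("growth", False, "none")
        p = GrowthParams(a=2, z=0.5, a2=0, a3=0, t1=285, t2=1, p1=10, p2=1,
                         sigma=1)
        base = growth_mean(make_record(N=9, S=6), spec, p)
        moved = growth_mean(make_record(N=30, S=0.5), spec, p)
        assert base == moved

    def test_halfway_sigmoid_example(self):
        spec = ModelSpec("growth", True, "sigmoid")
        p = GrowthParams(a=2, z=0.5, a2=0, a3=0, t1=285, t2=1, p1=10, p2=1,
                         n1=9, n2=1, s1=6, s2=2, s3=0.0, sigma=1)
        rec = make_record(size_m=100, BAL=0, BA=1, T=285, P=10, N=9, S=6)
        assert growth_mean(rec, spec, p) == pytest.approx(10.0, rel=1e-12)

    def test_intercept_only_returns_a(self):
        spec = ModelSpec("growth", False, "none", None, True)
        p = GrowthParams(a=3.5, sigma=1)
        assert growth_mean(make_record(), spec, p) == 3.5

    def test_missing_parameter_raises(self):
        spec = ModelSpec("growth", True, "none")
        p = GrowthParams(a=2, z=0.5, a2=0, a3=0, t1=285, t2=1, p1=10, p2=1,
                         sigma=1)  # n1/n2 absent
        with pytest.raises(SpecificationError, match="n1"):
            growth_mean(make_record(), spec, p)


class TestSurvivalProb:
    def test_zero_elapsed_time(self):
        spec = ModelSpec("survival", False, "none", "B")
        p = SurvivalParams(a=0.95, z1=100, z2=2, ba1=25, ba2=2, bl1=10,
                           bl2=2, t1=285, t2=1, p1=10, p2=1)
        rec = make_record()
        rec.dt = 0.0  # bypasses the record validator deliberately
        assert survival_prob(rec, spec, p) == 1.0

    def test_form_b_all_factors_at_peak(self):
        spec = ModelSpec("survival", True, "sigmoid", "B")
        p = SurvivalParams(a=0.98, z1=100, z2=2, ba1=25, ba2=2, bl1=11,
                           bl2=2, t1=285, t2=1, p1=10, p2=1, n1=9, n2=1,
                           s1=5, s2=2, s3=0.0)
        rec = make_record(size_m=100, BA=25, BAL=10, T=285, P=10, N=9, S=0,
                          dt=10)
        assert survival_prob(rec, spec, p) == \
            pytest.approx(0.8170728068875467, abs=1e-9)

    def test_form_a_zero_size_limit(self):
        spec = ModelSpec("survival", False, "none", "A")
        p = SurvivalParams(a=0.99, zc1=1.0, zc2=0.1, zc3=0.0, zc4=1.0,
                           br1=0.0, br2=1.0, br3=0.0, t1=285, t2=1,
                           p1=10, p2=1)
        rec = make_record(size_m=1e-9)
        assert survival_prob(rec, spec, p) == pytest.approx(0.0, abs=1e-8)


class TestLogLikelihood:
    def test_growth_zero_residual(self):
        spec = ModelSpec("growth", False, "none", None, True)
        sigma = 0.7
        p = GrowthParams(a=2.0, sigma=sigma)
        recs = TreeArrays(size_m=np.array([100.0]), dt=np.array([8.0]),
                          BA=np.array([25.0]), BAL=np.array([10.0]),
                          T=np.array([285.0]), P=np.array([10.0]),
                          N=np.array([9.0]), S=np.array([6.0]),
                          growth_G=np.array([2.0]))
        assert log_likelihood(recs, spec, p) == \
            pytest.approx(-0.5 * math.log(2 * math.pi * sigma**2), abs=1e-12)

    def test_survival_closed_form_sum(self):
        # ten survivors with identical annual survival 0.9^(1/dt) -> p = 0.9
        spec = ModelSpec("survival", False, "none", None, True)
        p = SurvivalParams(a=0.9 ** (1 / 8.0))
        n = 10
        recs = TreeArrays(size_m=np.full(n, 100.0), dt=np.full(n, 8.0),
                          BA=np.full(n, 25.0), BAL=np.full(n, 10.0),
                          T=np.full(n, 285.0), P=np.full(n, 10.0),
                          N=np.full(n, 9.0), S=np.full(n, 6.0),
                          survived_y=np.ones(n))
        assert log_likelihood(recs, spec, p) == \
            pytest.approx(-1.053605156578263, abs=1e-9)

    def test_infeasible_parameters_reject_not_raise(self):
        spec = ModelSpec("survival", False, "none", None, True)
        p = SurvivalParams(a=1.5)
        recs = TreeArrays(size_m=np.array([100.0]), dt=np.array([8.0]),
                          BA=np.array([25.0]), BAL=np.array([10.0]),
                          T=np.array([285.0]), P=np.array([10.0]),
                          N=np.array([9.0]), S=np.array([6.0]),
                          survived_y=np.array([1.0]))
        assert log_likelihood(recs, spec, p) == -math.inf


class TestModelFamily:
    def test_growth_family_has_seven_specs(self):
        specs = enumerate_models("growth")
        assert len(specs) == 7
        assert sum(s.is_intercept_only for s in specs) == 1

    def test_survival_family_has_thirteen_specs(self):
        specs = enumerate_models("survival")
        assert len(specs) == 13
        assert sum(s.is_intercept_only for s in specs) == 1
        forms = {s.competition_form for s in specs if not s.is_intercept_only}
        assert forms == {"A", "B"}

    def test_k_matches_free_parameter_count(self):
        for ep in ("growth", "survival"):
            for spec in enumerate_models(ep):
                assert spec.k == len(param_names(spec))
                if ep == "growth":
                    assert "sigma" in param_names(spec)

    def test_unknown_endpoint(self):
        with pytest.raises(SpecificationError):
            enumerate_models("recruitment")


def oracle_growth_mean(i, recs, spec, params):
    """Independent scalar term-by-term product for record i."""
    def lognorm(x, c1, c2):
        return math.exp(-0.5 * (math.log(x / c1) / c2) ** 2)

    if spec.is_intercept_only:
        return params.a
    v = (params.a * recs.size_m[i] ** params.z
         * math.exp(params.a2 * recs.BAL[i] + params.a3 * math.log(recs.BA[i]))
         * lognorm(recs.T[i], params.t1, params.t2)
         * lognorm(recs.P[i], params.p1, params.p2))
    if spec.has_N:
        v *= lognorm(max(recs.N[i], 0.01), params.n1, params.n2)
    if spec.s_form == "sigmoid":
        v *= params.s3 + (1 - params.s3) / (1 + (recs.S[i] / params.s1) ** params.s2)
    elif spec.s_form == "lognormal":
        v *= lognorm(max(recs.S[i], 0.01), params.s1, params.s2)
    return v


def oracle_survival_prob(i, recs, spec, params):
    def lognorm(x, c1, c2):
        return math.exp(-0.5 * (math.log(x / c1) / c2) ** 2)

    if spec.is_intercept_only:
        return params.a ** recs.dt[i]
    if spec.competition_form == "A":
        v = (params.a
             * (1 - params.zc1 * math.exp(-params.zc2 * recs.size_m[i]))
             * math.exp(-params.zc3 * recs.size_m[i] ** params.zc4)
             * math.exp(-params.br1
                        * (recs.BAL[i] / recs.BA[i]) ** params.br2
                        * recs.BA[i] ** params.br3))
    else:
        v = (params.a * lognorm(recs.size_m[i], params.z1, params.z2)
             * lognorm(recs.BA[i], params.ba1, params.ba2)
             * lognorm(recs.BAL[i] + 1, params.bl1, params.bl2))
    v *= lognorm(recs.T[i], params.t1, params.t2)
    v *= lognorm(recs.P[i], params.p1, params.p2)
    if spec.has_N:
        v *= lognorm(max(recs.N[i], 0.01), params.n1, params.n2)
    if spec.s_form == "sigmoid":
        v *= params.s3 + (1 - params.s3) / (1 + (recs.S[i] / params.s1) ** params.s2)
    elif spec.s_form == "lognormal":
        v *= lognorm(max(recs.S[i], 0.01), params.s1, params.s2)
    return v ** recs.dt[i]


class TestAgainstTermByTermOracle:
    """1,000 random parameter/record draws agree with the scalar oracle."""

    def test_growth_mean(self, rng, random_records):
        specs = [s for s in enumerate_models("growth")]
        for _ in range(100):
            spec = specs[rng.integers(len(specs))]
            params = random_growth_params(rng, spec)
            mu = np.asarray(growth_mean(random_records, spec, params))
            for i in rng.integers(0, len(random_records), size=10):
                assert mu[i] == pytest.approx(
                    oracle_growth_mean(i, random_records, spec, params),
                    rel=1e-12)

    def test_survival_prob(self, rng, random_records):
        specs = [s for s in enumerate_models("survival")]
        for _ in range(100):
            spec = specs[rng.integers(len(specs))]
            params = random_survival_params(rng, spec)
            p = np.asarray(survival_prob(random_records, spec, params))
            for i in rng.integers(0, len(random_records), size=10):
                assert p[i] == pytest.approx(
                    oracle_survival_prob(i, random_records, spec, params),
                    rel=1e-12)

    def test_survival_bracket_bounded_by_a(self, rng, random_records):
        from treecl.core import annual_survival
        for _ in range(50):
            spec = ModelSpec("survival", True, "sigmoid", "B")
            params = random_survival_params(rng, spec)
            s = np.asarray(annual_survival(random_records, spec, params))
            assert np.all(s <= params.a + 1e-12)
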