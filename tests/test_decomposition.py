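"""The variance-partition algebra, HPD intervals and effect calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutsem import (
    classify_relevant,
    hpd_interval,
    is_significant,
    standardize_effect,
    total_genetic_covariances,
    total_genetic_variance,
    transform_covariance,
)
from gutsem.decomposition import starred_from_scalar
from gutsem.sem_core import StructuralCoefficients


def _random_pd(rng):
    a = rng.standard_normal((3, 3))
    return a @ a.T + 1e-3 * np.eye(3)


lam_floats = st.floats(-3.0, 3.0, allow_nan=False)


class TestTransformCovariance:
    def test_zero_lambda_is_identity(self, rng):
        theta = _random_pd(rng)
        np.testing.assert_allclose(transform_covariance(theta, (0.0, 0.0)), theta)

    def test_explicit_scalar_expansion_example(self):
        # identity input, lambda_AL = 2: total variance 1 + 2*2*0 + 4*1 = 5
        out = transform_covariance(np.eye(3), (2.0, 0.0))
        assert out[0, 0] == pytest.approx(5.0)
        assert out[1, 1] == pytest.approx(1.0)
        assert out[2, 2] == pytest.approx(1.0)

    @given(a=lam_floats, r=lam_floats, seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_mediator_variance_invariant_and_symmetry(self, a, r, seed):
        theta = _random_pd(np.random.default_rng(seed))
        out = transform_covariance(theta, (a, r))
        assert out[2, 2] == pytest.approx(theta[2, 2], rel=1e-10)
        np.testing.assert_allclose(out, out.T, atol=1e-10)
        np.linalg.cholesky(out + 1e-9 * np.eye(3))  # PD preserved

    @given(a=lam_floats, r=lam_floats, seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None)
    def test_scalar_expansions_equal_matrix_transform(self, a, r, seed):
        theta = _random_pd(np.random.default_rng(seed))
        lam = (a, r)
        np.testing.assert_allclose(
            starred_from_scalar(theta, lam),
            transform_covariance(theta, lam),
            atol=1e-10,
        )

    def test_accepts_structural_coefficients_object(self, rng):
        theta = _random_pd(rng)
        lam = StructuralCoefficients(0.7, -0.3)
        np.testing.assert_allclose(
            transform_covariance(theta, lam), transform_covariance(theta, (0.7, -0.3))
        )


class TestGeneticVariance:
    def test_zero_lambda_no_indirect(self, rng):
        g0 = _random_pd(rng)
        total, direct, indirect = total_genetic_variance(g0, (0.0, 0.0), "AL")
        assert indirect == 0.0
        assert total == direct == pytest.approx(g0[0, 0])

    def test_worked_arithmetic(self):
        g0 = np.array([[1.0, 0.0, 0.2], [0.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        total, direct, indirect = total_genetic_variance(g0, (0.5, 0.5), "AL")
        assert direct == pytest.approx(1.0)
        assert indirect == pytest.approx(2 * 0.5 * 0.2 + 0.25)
        assert total == pytest.approx(1.45)

    def test_negative_indirect_with_positive_total(self):
        g0 = np.array([[1.0, 0.0, -0.3], [0.0, 1.0, -0.3], [-0.3, -0.3, 1.0]])
        total, _, indirect = total_genetic_variance(g0, (0.1, 0.1), "R")
        assert indirect == pytest.approx(2 * 0.1 * -0.3 + 0.01)
        assert indirect < 0 < total

    @given(a=lam_floats, r=lam_floats, seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_total_equals_matrix_entry_and_partition_is_exact(self, a, r, seed):
        g0 = _random_pd(np.random.default_rng(seed))
        starred = transform_covariance(g0, (a, r))
        for trait, t in (("AL", 0), ("R", 1)):
            total, direct, indirect = total_genetic_variance(g0, (a, r), trait)
            assert total == pytest.approx(starred[t, t], rel=1e-10, abs=1e-12)
            assert total == direct + indirect  # partition exact, bit for bit


class TestGeneticCovariances:
    def test_null_total_covariance_scenario(self, rng):
        # lambda chosen so the mediated path exactly cancels the direct
        # genetic covariance between the trait and the microbial feature
        g0 = _random_pd(rng)
        lam_al = -g0[0, 2] / g0[2, 2]
        out = total_genetic_covariances(g0, (lam_al, 0.0))
        assert out["cov_AL_M_total"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_lambda_totals_equal_directs(self, rng):
        g0 = _random_pd(rng)
        out = total_genetic_covariances(g0, (0.0, 0.0))
        assert out["cov_AL_R_total"] == pytest.approx(out["cov_AL_R_direct"])
        assert out["cov_AL_M_total"] == pytest.approx(out["cov_AL_M_direct"])
        assert out["cov_AL_R_mediated"] == 0.0

    @given(a=lam_floats, r=lam_floats, seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_totals_match_matrix_transform(self, a, r, seed):
        g0 = _random_pd(np.random.default_rng(seed))
        starred = transform_covariance(g0, (a, r))
        out = total_genetic_covariances(g0, (a, r))
        assert out["cov_AL_R_total"] == pytest.approx(starred[0, 1], rel=1e-9, abs=1e-10)
        assert out["cov_AL_M_total"] == pytest.approx(starred[0, 2], rel=1e-9, abs=1e-10)
        assert out["cov_R_M_total"] == pytest.approx(starred[1, 2], rel=1e-9, abs=1e-10)


class TestHeritability:
    def test_all_variance_genetic(self):
        from gutsem.decomposition import heritability

        tiny = 1e-12 * np.eye(3)
        h2 = heritability(tiny, tiny, np.eye(3), 1e-12 * np.ones(3), (0, 0), "AL")
        assert h2 == pytest.approx(1.0)

    def test_quarter(self):
        from gutsem.decomposition import heritability

        h2 = heritability(np.eye(3), np.eye(3), np.eye(3), np.ones(3), (0, 0), "R")
        assert h2 == pytest.approx(0.25)

    @given(a=lam_floats, r=lam_floats, seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_total_mode_matches_matrix_oracle(self, a, r, seed):
        from gutsem.decomposition import heritability

        rng = np.random.default_rng(seed)
        l0, c0, g0 = _random_pd(rng), _random_pd(rng), _random_pd(rng)
        r0 = rng.uniform(0.5, 2.0, 3)
        h2 = heritability(l0, c0, g0, r0, (a, r), "AL", mode="total")
        mats = [transform_covariance(m, (a, r)) for m in (l0, c0, g0, np.diag(r0))]
        expected = mats[2][0, 0] / sum(m[0, 0] for m in mats)
        assert h2 == pytest.approx(expected, rel=1e-10)
        assert 0.0 <= h2 <= 1.0


class TestStandardizeEffect:
    @pytest.mark.parametrize(
        "lam, sd, expected",
        [(-1.929, 5.27, -0.366), (1.859, 5.27, 0.353), (0.0, 5.27, 0.0)],
    )
    def test_worked_examples(self, lam, sd, expected):
        assert round(standardize_effect(lam, sd), 3) == expected

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            standardize_effect(1.0, 0.0)


def _brute_force_hpd(x, prob):
    x = np.sort(np.asarray(x, float))
    n = x.size
    m = int(np.ceil(prob * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if width < best[0]:  # strict: ties keep the lowest start
            best = (width, i)
    i = best[1]
    return float(x[i]), float(x[i + m - 1])


class TestHpdInterval:
    def test_constant_draws_zero_width(self):
        low, high = hpd_interval(np.full(50, 3.25), 0.95)
        assert (low, high) == (3.25, 3.25)

    def test_tie_break_on_uniform_grid(self):
        low, high = hpd_interval(np.arange(1, 101, dtype=float), 0.95)
        assert (low, high) == (1.0, 95.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("prob", [0.5, 0.9, 0.95])
    def test_matches_exhaustive_window_scan(self, seed, prob):
        x = np.random.default_rng(seed).gamma(2.0, size=301)
        assert hpd_interval(x, prob) == _brute_force_hpd(x, prob)

    def test_standard_normal_quantiles(self):
        x = np.random.default_rng(5).standard_normal(100_000)
        low, high = hpd_interval(x, 0.95)
        assert low == pytest.approx(-1.96, abs=0.05)
        assert high == pytest.approx(1.96, abs=0.05)

    def test_contains_median_for_unimodal_majority_windows(self, rng):
        for _ in range(10):
            x = rng.normal(rng.uniform(-3, 3), rng.uniform(0.5, 2), 501)
            low, high = hpd_interval(x, 0.6)
            med = np.median(x)
            assert low <= med <= high

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(10), 0.95)


class TestCalls:
    def test_is_significant(self, rng):
        assert is_significant(rng.uniform(0.5, 2.0, 200))
        assert not is_significant(rng.standard_normal(200))
        assert is_significant(rng.normal(3.0, 1.0, 5000))

    @pytest.mark.parametrize(
        "effect, expected", [(-0.322, True), (0.19, False), (0.2, True), (-0.2, True)]
    )
    def test_relevance_boundary(self, effect, expected):
        assert classify_relevant(effect) is expected


class TestDecomposeSamples:
    def test_partition_identity_holds_in_posterior_means(self, short_chain):
        from gutsem.decomposition import decompose_samples

        res = decompose_samples(short_chain, trait_sd={"AL": 5.91, "R": 5.27})
        s = res.summary
        for t in ("AL", "R"):
            assert s[f"gvar_{t}_total"] == pytest.approx(
                s[f"gvar_{t}_direct"] + s[f"gvar_{t}_indirect"], rel=1e-12
            )
            assert s[f"cov_{t}_M_total"] == pytest.approx(
                s[f"cov_{t}_M_direct"] + s[f"cov_{t}_M_indirect"], rel=1e-9, abs=1e-12
            )
            assert s[f"lambda_{t}_hpd_low"] <= s[f"lambda_{t}_median"] <= s[f"lambda_{t}_hpd_high"]
        assert 0 <= s["h2_M_direct"] <= 1
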