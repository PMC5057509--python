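"""Unit and property tests for the p-value distribution models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from steppower.models import (IndependentProductModel, MomentSummary,
                              NormalPValueModel, SimplifiedStepModel,
                              TwoPieceStepModel, match_mean,
                              match_mean_variance, model_from_dict)

from conftest import MOMENT_TABLE

ALL_MODELS = [
    NormalPValueModel(0.0),
    NormalPValueModel(0.5),
    NormalPValueModel(2.0),
    SimplifiedStepModel(1.0),
    SimplifiedStepModel(2.0),
    SimplifiedStepModel(23.979),
    TwoPieceStepModel(1.728, 0.555),
    TwoPieceStepModel(9.061, 0.059),
]


class TestNormalModel:
    def test_null_shift_is_uniform(self):
        m = NormalPValueModel(0.0)
        assert m.pdf(0.3) == pytest.approx(1.0, abs=1e-12)
        assert m.cdf(0.42) == pytest.approx(0.42, abs=1e-12)
        mom = m.moments()
        assert mom.mean == pytest.approx(0.5, abs=1e-8)
        assert mom.sd == pytest.approx(math.sqrt(1 / 12), abs=1e-8)

    def test_density_closed_form_at_half(self):
        # Phi^{-1}(0.5) = 0, so h(0.5) = phi(delta)/phi(0)
        m = NormalPValueModel(0.5)
        assert m.pdf(0.5) == pytest.approx(norm.pdf(0.5) / norm.pdf(0.0),
                                           rel=1e-12)

    @pytest.mark.parametrize("delta", [0.0, 0.5, 1.0, 2.88])
    def test_density_normalizes(self, delta):
        # substitute p = Phi(x): the integrand is smooth, unlike h(p) near 0
        model = NormalPValueModel(delta)
        val, _ = integrate.quad(lambda x: model.pdf(norm.cdf(x)) * norm.pdf(x),
                                -12, 8, epsabs=1e-12, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("delta", [0.2, 0.5, 1.0, 2.0, 2.88, 3.0])
    def test_mean_matches_closed_form(self, delta):
        # E[P] = Pr(Z1 - Z2 > delta shifted) = Phi(-delta/sqrt(2))
        quad_mean = NormalPValueModel(delta).mean()
        assert quad_mean == pytest.approx(norm.cdf(-delta / math.sqrt(2)),
                                          abs=1e-8)

    @pytest.mark.parametrize("delta", [0.5, 1.0, 2.0])
    def test_second_moment_matches_bivariate_normal(self, delta):
        # E[P^2] = Pr(Z1 > X, Z2 > X) with corr(Z1 - X, Z2 - X) = 1/2
        mom = NormalPValueModel(delta).moments()
        e2_quad = mom.sd ** 2 + mom.mean ** 2
        z = -delta / math.sqrt(2)
        e2_bvn = multivariate_normal(cov=[[1, 0.5], [0.5, 1]]).cdf([z, z])
        assert e2_quad == pytest.approx(e2_bvn, abs=1e-7)

    @pytest.mark.parametrize("delta", sorted(MOMENT_TABLE))
    def test_reference_moment_table(self, delta):
        mean, sd = MOMENT_TABLE[delta][:2]
        mom = NormalPValueModel(delta).moments()
        assert mom.mean == pytest.approx(mean, abs=5e-4)
        assert mom.sd == pytest.approx(sd, abs=5e-4)

    def test_pdf_rejects_boundary(self):
        with pytest.raises(ValueError):
            NormalPValueModel(1.0).pdf(0.0)
        with pytest.raises(ValueError):
            NormalPValueModel(1.0).pdf(1.0)


class TestStepModels:
    @pytest.mark.parametrize("model,p,expected", [
        (SimplifiedStepModel(1.0), 0.7, 1.0),
        (SimplifiedStepModel(2.0), 0.3, 2.0),
        (TwoPieceStepModel(1.728, 0.555), 0.5, 0.555),  # breakpoint ~0.380
    ])
    def test_pdf_values(self, model, p, expected):
        assert model.pdf(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("model,p,expected", [
        (SimplifiedStepModel(2.0), 0.5, 1.0),
        (SimplifiedStepModel(1.0), 0.42, 0.42),
        (TwoPieceStepModel(1.728, 0.555), 1.0, 1.0),
    ])
    def test_cdf_values(self, model, p, expected):
        assert model.cdf(p) == pytest.approx(expected, abs=1e-12)

    def test_simplified_moment_identities(self):
        # mean * 2f = 1 and var * 12 f^2 = 1, exactly
        for f in (1.0, 2.0, 7.5, 23.979):
            mom = SimplifiedStepModel(f).moments()
            assert mom.mean * 2 * f == pytest.approx(1.0, abs=1e-14)
            assert mom.sd ** 2 * 12 * f ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_two_piece_moments_match_quadrature(self):
        model = TwoPieceStepModel(2.937, 0.288)
        mom = model.moments()
        mean_q, _ = integrate.quad(lambda p: p * model.pdf(p), 0, 1,
                                   points=[model.breakpoint])
        e2_q, _ = integrate.quad(lambda p: p * p * model.pdf(p), 0, 1,
                                 points=[model.breakpoint])
        assert mom.mean == pytest.approx(mean_q, abs=1e-10)
        assert mom.sd == pytest.approx(math.sqrt(e2_q - mean_q ** 2), abs=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimplifiedStepModel(0.5)
        with pytest.raises(ValueError):
            TwoPieceStepModel(0.9, 0.5)
        with pytest.raises(ValueError):
            TwoPieceStepModel(1.0, 1.0)

    def test_dirac_uniform_limit(self):
        # as f grows the simplified model concentrates at zero
        means = [SimplifiedStepModel(f).moments().mean for f in (10, 1e3, 1e6)]
        assert means == sorted(means, reverse=True)
        assert means[-1] < 1e-6


class TestCalibration:
    def test_match_mean_null_is_uniform(self):
        assert match_mean(0.0).f == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("delta,expected_f", [(2.88, 23.979), (2.0, 6.357)])
    def test_match_mean_reference_values(self, delta, expected_f):
        assert match_mean(delta).f == pytest.approx(expected_f, abs=5e-4)

    @pytest.mark.parametrize("delta", sorted(MOMENT_TABLE))
    def test_calibration_reproduces_reference_table(self, delta):
        _, _, f, g, brk, f_simp, inv_f = MOMENT_TABLE[delta]
        tp = match_mean_variance(delta)
        assert tp.f == pytest.approx(f, abs=5e-4)
        assert tp.g == pytest.approx(g, abs=5e-4)
        assert tp.breakpoint == pytest.approx(brk, abs=5e-4)
        sm = match_mean(delta)
        assert sm.f == pytest.approx(f_simp, abs=5e-4)
        assert 1.0 / sm.f == pytest.approx(inv_f, abs=5e-4)

    @pytest.mark.parametrize("delta", [0.2, 0.5, 1.0, 2.0, 3.0])
    def test_moment_matching_round_trip(self, delta):
        target = NormalPValueModel(delta).moments()
        got = match_mean_variance(delta).moments()
        assert got.mean == pytest.approx(target.mean, abs=1e-6)
        assert got.sd == pytest.approx(target.sd, abs=1e-6)

    def test_degenerate_null_calibration(self):
        tp = match_mean_variance(0.0)
        assert tp.degenerate
        assert tp.f == pytest.approx(1.0, abs=1e-9)


class TestSampling:
    def test_uniform_sampling_mean(self):
        draws = SimplifiedStepModel(1.0).sample(100_000, seed=7)
        se = math.sqrt(1 / 12 / 100_000)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_simplified_support(self):
        draws = SimplifiedStepModel(2.0).sample(10_000, seed=7)
        assert np.all(draws <= 0.5 + 1e-12)

    def test_normal_sampling_mean(self):
        model = NormalPValueModel(1.0)
        draws = model.sample(100_000, seed=11)
        se = model.moments().sd / math.sqrt(100_000)
        assert abs(draws.mean() - 0.240) < 3 * se + 5e-4

    def test_seed_determinism(self):
        for model in (NormalPValueModel(0.7), TwoPieceStepModel(2.0, 0.3),
                      SimplifiedStepModel(3.0)):
            a = model.sample(100, seed=5)
            b = model.sample(100, seed=5)
            np.testing.assert_array_equal(a, b)

    def test_product_sampling_shape_and_seed(self):
        pm = IndependentProductModel([SimplifiedStepModel(23.979),
                                      NormalPValueModel(0.0)])
        a = pm.sample(500, seed=3)
        b = pm.sample(500, seed=3)
        assert a.shape == (500, 2)
        np.testing.assert_array_equal(a, b)


class TestInvariants:
    @pytest.mark.parametrize("model", ALL_MODELS,
                             ids=lambda m: f"{type(m).__name__}")
    def test_density_normalizes(self, model):
        if hasattr(model, "breakpoint"):
            val, _ = integrate.quad(model.pdf, 0.0, 1.0, epsabs=1e-12,
                                    points=[model.breakpoint])
        else:
            # substitute p = Phi(x) to tame the near-zero spike
            val, _ = integrate.quad(
                lambda x: model.pdf(norm.cdf(x)) * norm.pdf(x),
                -12, 8, epsabs=1e-12, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(p=st.floats(0.001, 0.999),
           delta=st.floats(0.0, 5.0),
           f=st.floats(1.0, 50.0),
           g=st.floats(0.0, 0.99))
    def test_stochastic_dominance(self, p, delta, f, g):
        # any alternative-leaning model puts at least uniform mass below p
        assert NormalPValueModel(delta).cdf(p) >= p - 1e-12
        assert SimplifiedStepModel(f).cdf(p) >= p - 1e-12
        if f > g:
            assert TwoPieceStepModel(f, min(g, 1.0)).cdf(p) >= p - 1e-12

    @pytest.mark.parametrize("model", ALL_MODELS,
                             ids=lambda m: f"{type(m).__name__}")
    def test_serialization_round_trip(self, model):
        clone = model_from_dict(model.to_dict())
        assert type(clone) is type(model)
        assert clone.to_dict() == model.to_dict()

    def test_product_serialization_round_trip(self):
        pm = IndependentProductModel([SimplifiedStepModel(2.0),
                                      NormalPValueModel(1.5)])
        clone = model_from_dict(pm.to_dict())
        assert clone.to_dict() == pm.to_dict()

    def test_moment_summary_validation(self):
        with pytest.raises(ValueError):
            MomentSummary(mean=1.5, sd=0.1)
        with pytest.raises(ValueError):
            MomentSummary(mean=0.5, sd=0.9)
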