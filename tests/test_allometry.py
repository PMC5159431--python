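"""Allometric power laws, Dedrick transformation, biexponential fits."""

import numpy as np
import pytest

from dptpbpk import (
    DedrickModel,
    dedrick_transform,
    fit_biexponential,
    fit_power_law,
    pk_from_biexponential,
    reverse_transform,
)

#: Reconstructed absolute clearances (W kg, CL mL/min) per dose group from
#: the observed per-kg values of the mouse, rat and monkey studies.
CL_POINTS = [
    (0.02, 70.76 * 0.02), (0.02, 67.73 * 0.02),
    (0.25, 96.98 * 0.25), (0.25, 69.28 * 0.25), (0.25, 60.17 * 0.25),
    (3.51, 37.98 * 3.51), (3.51, 33.84 * 3.51), (3.51, 27.25 * 3.51),
]

PRINTED_MIXED = DedrickModel(1.495, 0.164, 0.156, 0.012, beta1=0.857, beta2=0.832)


class TestPowerLaw:
    def test_exact_two_point_line(self):
        fit = fit_power_law([(1.0, 2.0), (10.0, 20.0)])
        assert fit.alpha == pytest.approx(2.0)
        assert fit.beta == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_printed_human_extrapolation(self):
        cl = 44.28 * 70**0.832
        assert cl / 1000 == pytest.approx(1.52, abs=0.01)

    def test_regression_on_reconstructed_clearances(self):
        fit = fit_power_law(CL_POINTS)
        assert 0.83 <= fit.beta <= 0.86
        assert fit.r2 > 0.91

    def test_unit_rescaling_leaves_exponent_invariant(self):
        fit_kg = fit_power_law(CL_POINTS)
        fit_g = fit_power_law([(w * 1000, v) for w, v in CL_POINTS])
        assert fit_g.beta == pytest.approx(fit_kg.beta, rel=1e-12)
        assert fit_g.alpha == pytest.approx(
            fit_kg.alpha / 1000**fit_kg.beta, rel=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(1.0, 2.0)])
        with pytest.raises(ValueError):
            fit_power_law([(1.0, -2.0), (2.0, 3.0)])


class TestDedrickTransform:
    def test_equal_exponents_leave_time_unchanged(self):
        t = np.array([0.0, 10.0, 50.0])
        tp, _ = dedrick_transform(t, t * 0 + 1, 8.5, 2.55, 0.85, 0.85)
        np.testing.assert_allclose(tp, t)

    def test_unit_weight_is_dose_normalization_only(self):
        t = np.array([5.0, 10.0])
        c = np.array([4.0, 2.0])
        tp, cp = dedrick_transform(t, c, 1.0, 2.0, 0.857, 0.832)
        np.testing.assert_allclose(tp, t)
        np.testing.assert_allclose(cp, c / 2.0)

    def test_human_time_compression_arithmetic(self):
        tp, _ = dedrick_transform([111.9], [1.0], 70.0, 16.0, 0.857, 0.832)
        assert tp[0] == pytest.approx(111.9 / 70**0.025, rel=1e-9)
        assert tp[0] == pytest.approx(100.6, abs=0.1)

    def test_round_trip_is_identity(self):
        """Forward transform then reverse transform restores the curve."""
        t = np.linspace(0.0, 240.0, 30)
        c = 0.628 * np.exp(-0.147 * t) + 0.066 * np.exp(-0.011 * t)
        tp, cp = dedrick_transform(t, c, 70.0, 16.0, 0.857, 0.832)
        model = fit_biexponential(tp, cp, 0.857, 0.832)
        a, alpha, b, beta = reverse_transform(model, 70.0, 16.0)
        back = a * np.exp(-alpha * t) + b * np.exp(-beta * t)
        np.testing.assert_allclose(back, c, rtol=1e-6)


class TestBiexponentialFit:
    def test_exact_recovery_of_printed_mixed_profile(self):
        t = np.linspace(0.0, 400.0, 60)
        c = PRINTED_MIXED.predict(t)
        fit = fit_biexponential(t, c, 0.857, 0.832)
        assert fit.a_prime == pytest.approx(1.495, rel=1e-3)
        assert fit.alpha_prime == pytest.approx(0.164, rel=1e-3)
        assert fit.b_prime == pytest.approx(0.156, rel=1e-3)
        assert fit.beta_prime == pytest.approx(0.012, rel=1e-3)
        assert not fit.degenerate

    def test_monoexponential_input_flagged_degenerate(self):
        t = np.linspace(0.0, 100.0, 20)
        fit = fit_biexponential(t, 2.0 * np.exp(-0.05 * t))
        assert fit.degenerate

    def test_median_bias_under_ten_percent_noise(self):
        """200 noisy datasets: median |bias| of each macro-constant < 10%."""
        t = np.linspace(2.0, 400.0, 25)
        clean = PRINTED_MIXED.predict(t)
        rng = np.random.default_rng(2024)
        est = []
        for _ in range(200):
            c = np.maximum(clean * (1 + rng.normal(0, 0.10, t.size)), 1e-9)
            fit = fit_biexponential(t, c, 0.857, 0.832)
            est.append([fit.a_prime, fit.alpha_prime, fit.b_prime, fit.beta_prime])
        med = np.median(est, axis=0)
        truth = np.array([1.495, 0.164, 0.156, 0.012])
        assert np.all(np.abs(med / truth - 1) < 0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_biexponential([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])


class TestReverseTransform:
    def test_printed_human_equation_recovered(self):
        a, alpha, b, beta = reverse_transform(PRINTED_MIXED, 70.0, 16.0)
        assert a == pytest.approx(0.628, rel=0.005)
        assert alpha == pytest.approx(0.147, rel=0.005)
        # the slow phase is printed with 2 significant figures only
        assert b == pytest.approx(0.066, abs=0.0006)
        assert beta == pytest.approx(0.011, abs=0.0003)

    def test_unit_weight_identity_up_to_dose(self):
        a, alpha, b, beta = reverse_transform(PRINTED_MIXED, 1.0, 1.0)
        assert (a, b) == pytest.approx((1.495, 0.156))
        assert (alpha, beta) == pytest.approx((0.164, 0.012))


class TestClosedFormPk:
    def test_printed_human_constants(self):
        pk = pk_from_biexponential(0.628, 0.147, 0.066, 0.011, 16000.0)
        assert pk["auc_0_inf"] == pytest.approx(10.25, abs=0.03)
        assert pk["cl"] / 1000 == pytest.approx(1.56, abs=0.01)
        assert pk["t_half"] == pytest.approx(63.08, abs=0.5)
        assert pk["vss"] == pytest.approx(87.67, rel=0.01)

    def test_monoexponential_limit(self):
        pk = pk_from_biexponential(10.0, 0.1, 0.0, 0.0, 100.0)
        assert pk["auc_0_inf"] == pytest.approx(100.0)
        assert pk["mrt"] == pytest.approx(10.0)

    def test_misordered_rates_rejected(self):
        with pytest.raises(ValueError):
            pk_from_biexponential(1.0, 0.01, 1.0, 0.02, 100.0)
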