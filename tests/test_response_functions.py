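"""Unit tests of the scalar constitutive response functions."""

import numpy as np
import pytest

from myofe import (
    MaterialParams,
    activation,
    f_pe,
    force_length,
    force_velocity,
    matrix_energy,
    sigma_ce,
    sigma_pe,
    sigma_see,
    volumetric_energy,
    volumetric_pressure,
)
from myofe.errors import InvalidDeformationError


class TestMatrixEnergy:
    def test_zero_at_reference(self, params):
        assert matrix_energy(3.0, params) == 0.0

    def test_direct_evaluation(self, params):
        # b = 15, c = 379 Pa: W = c (exp(b * 0.01) - 1)
        assert matrix_energy(3.01, params) == pytest.approx(
            379.0 * (np.exp(0.15) - 1.0), rel=1e-12)

    def test_linear_in_modulus(self, params):
        doubled = params.replace(c=2 * params.c)
        assert matrix_energy(3.2, doubled) == pytest.approx(
            2.0 * matrix_energy(3.2, params), rel=1e-12)

    def test_strictly_increasing(self, params):
        grid = np.linspace(3.0, 4.0, 200)
        vals = matrix_energy(grid, params)
        assert np.all(np.diff(vals) > 0)

    def test_invariant_range_guard(self, params):
        with pytest.raises(ValueError):
            matrix_energy(2.9, params)


class TestVolumetric:
    def test_zero_at_unit_jacobian(self, params):
        assert volumetric_energy(1.0, params) == 0.0
        assert volumetric_pressure(1.0, params) == 0.0

    def test_direct_evaluation(self, params):
        # D = 5e-9 /Pa: (1/D) * (1e-3)^2 = 200 Pa
        assert volumetric_energy(1.001, params) == pytest.approx(200.0,
                                                                 rel=1e-9)
        assert volumetric_pressure(1.001, params) == pytest.approx(
            2.0 / 5.0e-9 * 1e-3, rel=1e-9)

    def test_quadratic_symmetry(self, params):
        eps = 0.004
        assert volumetric_energy(1 + eps, params) == pytest.approx(
            volumetric_energy(1 - eps, params), rel=1e-12)

    def test_nonpositive_jacobian_rejected(self, params):
        with pytest.raises(InvalidDeformationError):
            volumetric_energy(0.0, params)
        with pytest.raises(InvalidDeformationError):
            volumetric_pressure(-0.5, params)


class TestParallelElement:
    @pytest.mark.parametrize("lam", [0.5, 0.8, 1.0])
    def test_slack_in_shortening(self, params, lam):
        assert f_pe(lam, params) == 0.0
        assert sigma_pe(lam, params) == 0.0

    def test_direct_evaluation(self, params):
        assert f_pe(1.2, params) == pytest.approx(4.0 * 0.04, rel=1e-12)
        assert sigma_pe(1.2, params) == pytest.approx(7.0e5 * 0.16,
                                                      rel=1e-12)

    def test_continuous_and_monotone(self, params):
        grid = np.linspace(0.5, 1.6, 500)
        vals = np.asarray(sigma_pe(grid, params))
        assert np.all(np.diff(vals) >= 0.0)
        assert abs(f_pe(1.0 + 1e-12, params)) < 1e-20


class TestSeriesElasticElement:
    def test_zero_at_unit_stretch(self, params):
        assert sigma_see(1.0, params) == 0.0

    def test_direct_evaluation(self, params):
        assert sigma_see(1.1, params) == pytest.approx(
            1.0e3 * (np.e - 1.0), rel=1e-12)

    def test_incremental_identity(self, params, rng):
        # exp-update form must equal direct evaluation at the new stretch
        for _ in range(200):
            lam = rng.uniform(0.9, 1.15)
            dlam = rng.uniform(-0.05, 0.05)
            direct = sigma_see(lam + dlam, params)
            incr = np.exp(params.alpha * dlam) \
                * (sigma_see(lam, params) + params.beta) - params.beta
            assert incr == pytest.approx(direct, rel=1e-12, abs=1e-9)

    def test_strictly_increasing(self, params):
        grid = np.linspace(0.8, 1.3, 400)
        assert np.all(np.diff(sigma_see(grid, params)) > 0)


class TestForceLength:
    def test_peak_at_optimal_stretch(self, params):
        assert force_length(params.lambda_opt, params) == pytest.approx(1.0)

    def test_zero_branches(self, params):
        assert force_length(0.3 * params.lambda_opt, params) == 0.0
        assert force_length(1.7 * params.lambda_opt, params) == 0.0

    @pytest.mark.parametrize("r,expected", [
        (0.4, 0.0), (0.6, 0.36), (1.4, 0.36), (1.6, 0.0)])
    def test_branch_continuity(self, params, r, expected):
        lo = force_length((r - 1e-13) * params.lambda_opt, params)
        hi = force_length((r + 1e-13) * params.lambda_opt, params)
        assert lo == pytest.approx(expected, abs=1e-11)
        assert hi == pytest.approx(expected, abs=1e-11)
        assert abs(lo - hi) < 1e-11

    def test_normalization(self, params):
        r = np.linspace(0.0, 2.0, 2001)
        vals = np.asarray(force_length(r * params.lambda_opt, params))
        assert np.all(vals <= 1.0 + 1e-12)
        peak = r[vals > 1.0 - 1e-12]
        assert peak.size == 1 and peak[0] == pytest.approx(1.0)


class TestForceVelocity:
    def test_unity_at_zero_rate(self, params):
        assert force_velocity(0.0, params) == pytest.approx(1.0)
        # both branches approach 1 at the phase boundary
        assert force_velocity(-1e-12, params) == pytest.approx(1.0,
                                                               abs=1e-10)
        assert force_velocity(+1e-12, params) == pytest.approx(1.0,
                                                               abs=1e-10)

    def test_zero_at_maximal_shortening(self, params):
        assert force_velocity(params.lambda_dot_m_min, params) == 0.0

    def test_clamped_beyond_maximal_shortening(self, params):
        assert force_velocity(1.5 * params.lambda_dot_m_min, params) == 0.0

    def test_eccentric_exceeds_unity_below_asymptote(self, params):
        rates = np.linspace(1e-6, 200.0, 4000)
        vals = np.asarray(force_velocity(rates, params))
        asym = params.d + (params.d - 1.0) / (params.kc * params.ke)
        assert np.all(vals > 1.0)
        assert np.all(vals < asym)
        assert np.all(np.diff(vals) > 0)  # force grows with lengthening rate

    def test_concentric_monotone_decreasing(self, params):
        rates = np.linspace(params.lambda_dot_m_min, 0.0, 500)
        vals = np.asarray(force_velocity(rates, params))
        assert np.all(np.diff(vals) > 0)  # toward 1 at zero rate


class TestActivation:
    def test_baseline_before_onset(self, params):
        sched = params.replace(t0=0.2, t1=1.0, n1=0.1, n2=0.9)
        assert activation(0.0, sched) == sched.n1
        assert activation(0.2, sched) == sched.n1

    def test_half_second_reaches_full_activation(self, params):
        # S = 50 /s: after 0.5 s the gap to n2 is (n2-n1) e^-25
        sched = params.replace(t0=0.0, t1=10.0, n1=0.0, n2=1.0)
        val = activation(0.5, sched)
        assert abs(val - 1.0) <= np.exp(-25.0) * 1.001

    def test_decays_to_baseline(self, params):
        sched = params.replace(t0=0.0, t1=1.0, n1=0.05, n2=0.8)
        assert activation(1e9, sched) == pytest.approx(sched.n1, abs=1e-12)

    @pytest.mark.parametrize("tj", ["t0", "t1"])
    def test_continuity_at_switch_times(self, params, tj):
        sched = params.replace(t0=0.3, t1=1.2, n1=0.1, n2=0.9)
        t = getattr(sched, tj)
        lo = activation(t - 1e-10, sched)
        hi = activation(t + 1e-10, sched)
        assert lo == pytest.approx(hi, abs=1e-7)

    def test_bounded_between_levels(self, params):
        sched = params.replace(t0=0.1, t1=0.8, n1=0.2, n2=0.7)
        t = np.linspace(0.0, 5.0, 2000)
        vals = np.asarray(activation(t, sched))
        assert np.all(vals >= sched.n1 - 1e-12)
        assert np.all(vals <= sched.n2 + 1e-12)


class TestContractileElement:
    def test_zero_without_activation(self, params):
        assert sigma_ce(1.05, 0.0, 0.0, params) == 0.0

    def test_peak_isometric_stress(self, params):
        # all three factors equal 1: sigma = sigma0
        assert sigma_ce(params.lambda_opt, 0.0, 1.0, params) \
            == pytest.approx(7.0e5)

    def test_zero_beyond_overstretch(self, params):
        assert sigma_ce(1.7 * params.lambda_opt, 0.0, 1.0, params) == 0.0

    def test_nonnegative(self, params, rng):
        lam = rng.uniform(0.3, 2.0, 100)
        rate = rng.uniform(-30.0, 30.0, 100)
        act = rng.uniform(0.0, 1.0, 100)
        assert np.all(np.asarray(sigma_ce(lam, rate, act, params)) >= 0.0)
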