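import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import jv

from carotidflow import (
    BloodProperties,
    FlowRegime,
    VelocityWaveform,
    VesselGeometry,
    classify_flow,
    ess_waveform,
    fourier_decompose,
    harmonic_wall_shear,
    reynolds_number,
    viscosity_from_hematocrit,
    womersley_number,
)
from carotidflow.hemodynamics import mean_velocity_estimate


class TestViscosityFromHematocrit:
    def test_plasma_only_limit(self):
        assert viscosity_from_hematocrit(0.0) == pytest.approx(1.2e-3)

    def test_hand_evaluated_quadratic(self):
        # 1.2e-3 * (1 + 2.5*0.45 + 7.35*0.45^2) = 1.2e-3 * 3.613375
        assert viscosity_from_hematocrit(0.45) == pytest.approx(4.33605e-3, rel=1e-9)

    def test_absent_hematocrit_default(self):
        assert viscosity_from_hematocrit(None) == pytest.approx(3.5e-3)

    @pytest.mark.parametrize("hct", [-0.01, 0.66, 1.5])
    def test_out_of_range_rejected(self, hct):
        with pytest.raises(ValueError):
            viscosity_from_hematocrit(hct)


class TestDomainTypes:
    def test_waveform_requires_uniform_sampling(self):
        t = np.linspace(0, 1, 64, endpoint=False)
        t[10] += 1e-4
        with pytest.raises(ValueError, match="uniform"):
            VelocityWaveform(t=t, v=np.ones(64), period=1.0)

    def test_waveform_requires_min_samples(self):
        with pytest.raises(ValueError, match="samples"):
            VelocityWaveform.from_samples(np.ones(16), 1.0)

    def test_waveform_requires_positive_period(self):
        with pytest.raises(ValueError, match="period"):
            VelocityWaveform.from_samples(np.ones(64), 0.0)

    def test_geometry_warns_outside_carotid_range(self):
        with pytest.warns(UserWarning, match="physiological"):
            VesselGeometry(20e-3)

    def test_geometry_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            VesselGeometry(0.0)

    def test_blood_derives_viscosity_from_hematocrit(self):
        b = BloodProperties(hematocrit=0.45)
        assert b.viscosity == pytest.approx(viscosity_from_hematocrit(0.45))

    def test_blood_rejects_contradictory_viscosity(self):
        with pytest.raises(ValueError, match="contradicts"):
            BloodProperties(viscosity=2e-3, hematocrit=0.45)

    def test_blood_rejects_out_of_range_density(self):
        with pytest.raises(ValueError, match="density"):
            BloodProperties(density=900.0)


class TestFourierDecompose:
    def test_dc_only_signal(self):
        w = VelocityWaveform.from_samples(np.full(64, 0.4), 1.0)
        spec = fourier_decompose(w, 4)
        assert spec.c0 == pytest.approx(0.4)
        assert np.allclose(spec.coefficients, 0.0, atol=1e-15)

    def test_single_harmonic_identity(self):
        t = np.arange(64) / 64
        w = VelocityWaveform.from_samples(0.1 * np.cos(2 * np.pi * t), 1.0)
        spec = fourier_decompose(w, 2)
        assert spec.c0 == pytest.approx(0.0, abs=1e-15)
        assert spec.coefficients[0] == pytest.approx(0.05 + 0j, abs=1e-15)
        assert spec.coefficients[1] == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_dft_sum(self, random_waveform):
        # independent O(n^2) oracle for the coefficient definition
        w = random_waveform
        spec = fourier_decompose(w, 8)
        m = w.n_samples
        for n in range(1, 9):
            brute = sum(
                w.v[k] * np.exp(-1j * n * w.omega * w.t[k]) for k in range(m)
            ) / m
            assert spec.coefficients[n - 1] == pytest.approx(brute, abs=1e-12)

    def test_reconstruction_to_machine_precision(self, random_waveform):
        spec = fourier_decompose(random_waveform, 8)
        recon = spec.reconstruct(random_waveform.t)
        np.testing.assert_allclose(recon, random_waveform.v, atol=1e-12)

    def test_harmonic_count_limit(self, random_waveform):
        with pytest.raises(ValueError, match="n_harmonics"):
            fourier_decompose(random_waveform, 32)


class TestWomersleyNumber:
    def test_hand_evaluated_closed_form(self):
        omega = 2 * np.pi * 70 / 60
        alpha = womersley_number(0.003, omega, 1060.0, 3.5e-3)
        assert alpha == pytest.approx(4.47, abs=0.01)

    def test_steady_flow_limit(self):
        assert womersley_number(0.003, 0.0, 1060.0, 3.5e-3) == 0.0

    def test_sqrt_frequency_scaling(self):
        a1 = womersley_number(0.003, 5.0, 1060.0, 3.5e-3)
        a2 = womersley_number(0.003, 10.0, 1060.0, 3.5e-3)
        assert a2 == pytest.approx(np.sqrt(2) * a1, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            womersley_number(-0.003, 5.0, 1060.0, 3.5e-3)


def _womersley_profile_gradient_shear(c_n, alpha, radius, viscosity):
    """Independent oracle: central finite differences of the analytical
    oscillatory velocity profile u(r) = A (1 - J0(L r/R)/J0(L)) at the wall,
    with shear = -mu du/dr."""
    lam = (1j) ** 1.5 * alpha
    a = c_n * jv(0, lam) / (jv(0, lam) - 1.0)

    def u(r):
        return a * (1.0 - jv(0, lam * r / radius) / jv(0, lam))

    h = 1e-5 * radius
    dudr = (u(radius + h) - u(radius - h)) / (2 * h)
    return -viscosity * dudr


class TestHarmonicWallShear:
    def test_small_alpha_collapses_to_poiseuille(self):
        tau = harmonic_wall_shear(0.05, 0.05, 0.003, 3.5e-3)
        quasi = 2 * 3.5e-3 * 0.05 / 0.003
        assert abs(tau) == pytest.approx(quasi, rel=0.01)
        # sign convention: forward harmonic exerts forward shear in the limit
        assert tau.real > 0

    @pytest.mark.parametrize("alpha", [1.0, 3.0, 4.47, 8.0, 12.0])
    def test_matches_profile_gradient_oracle(self, alpha):
        c_n = 0.05 + 0.02j
        tau = harmonic_wall_shear(c_n, alpha, 0.003, 3.5e-3)
        oracle = _womersley_profile_gradient_shear(c_n, alpha, 0.003, 3.5e-3)
        assert tau == pytest.approx(oracle, rel=1e-4)

    def test_zero_coefficient_linearity(self):
        assert harmonic_wall_shear(0.0, 4.47, 0.003, 3.5e-3) == 0.0

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            harmonic_wall_shear(0.05, 0.0, 0.003, 3.5e-3)


class TestEssWaveform:
    def test_steady_poiseuille_closed_form(self):
        w = VelocityWaveform.from_samples(np.full(64, 0.4), 1.0)
        res = ess_waveform(w, VesselGeometry(6e-3), BloodProperties(viscosity=3.5e-3))
        expected = 2 * 3.5e-3 * 0.4 / 0.003 * 10  # Pa -> dyn/cm^2
        assert res.mean_ess == pytest.approx(expected, rel=1e-12)
        assert res.peak_ess == pytest.approx(expected, rel=1e-12)

    def test_zero_flow(self, geometry, blood):
        w = VelocityWaveform.from_samples(np.zeros(64), 1.0)
        res = ess_waveform(w, geometry, blood)
        assert res.mean_ess == 0.0
        assert res.peak_ess == 0.0

    def test_exact_linearity_in_velocity_scale(self, pulse, geometry, blood):
        base = ess_waveform(pulse, geometry, blood)
        scaled = ess_waveform(pulse.scaled(2.0), geometry, blood)
        assert scaled.mean_ess == pytest.approx(2.0 * base.mean_ess, rel=1e-12)
        assert scaled.peak_ess == pytest.approx(2.0 * base.peak_ess, rel=1e-12)
        np.testing.assert_allclose(scaled.tau, 2.0 * base.tau, rtol=1e-12)

    def test_mean_equals_time_average(self, pulse, geometry, blood):
        res = ess_waveform(pulse, geometry, blood)
        assert res.mean_ess == pytest.approx(res.tau.mean(), rel=1e-14)

    def test_harmonic_womersley_sqrt_scaling(self, pulse, geometry, blood):
        res = ess_waveform(pulse, geometry, blood)
        expected = res.alphas[0] * np.sqrt(np.arange(1, res.n_harmonics + 1))
        np.testing.assert_allclose(res.alphas, expected, rtol=1e-9)

    def test_poiseuille_limit_full_waveform(self, pulse):
        # shrink the vessel until all harmonics sit at alpha <= 0.1
        radius = 4e-5
        with pytest.warns(UserWarning):
            geometry = VesselGeometry(2 * radius)
        blood = BloodProperties(viscosity=1e-2, density=1000.0)
        res = ess_waveform(pulse, geometry, blood)
        assert res.alphas[-1] <= 0.1
        quasi = 2 * blood.viscosity * pulse.v / radius * 10
        np.testing.assert_allclose(res.tau, quasi, rtol=0.01)
        assert res.mean_ess == pytest.approx(quasi.mean(), rel=0.01)

    @settings(max_examples=25, deadline=None)
    @given(factor=st.floats(min_value=0.01, max_value=50.0))
    def test_linearity_property(self, factor):
        pulse = _module_pulse()
        geometry = VesselGeometry(6.3e-3)
        blood = BloodProperties(viscosity=3.5e-3)
        base = ess_waveform(pulse, geometry, blood)
        scaled = ess_waveform(pulse.scaled(factor), geometry, blood)
        assert scaled.mean_ess == pytest.approx(factor * base.mean_ess, rel=1e-12)


def _module_pulse():
    from carotidflow import canonical_waveform

    return canonical_waveform(70.0, 128)


class TestReynolds:
    def test_hand_evaluated(self):
        assert reynolds_number(1.1, 0.006, 1060.0, 3.5e-3) == pytest.approx(1999.0, abs=1.0)

    def test_zero_velocity(self):
        assert reynolds_number(0.0, 0.006, 1060.0, 3.5e-3) == 0.0

    def test_inverse_viscosity_proportionality(self):
        re1 = reynolds_number(1.0, 0.006, 1060.0, 3.5e-3)
        re2 = reynolds_number(1.0, 0.006, 1060.0, 1.75e-3)
        assert re2 == pytest.approx(2.0 * re1, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            reynolds_number(1.0, 0.0, 1060.0, 3.5e-3)

    def test_mean_velocity_is_half_centerline_mean(self, pulse):
        assert mean_velocity_estimate(pulse) == pytest.approx(
            np.mean(np.abs(pulse.v)) / 2, rel=1e-14
        )


class TestClassifyFlow:
    @pytest.mark.parametrize(
        "re,regime",
        [
            (150.0, FlowRegime.UNDISTURBED_LAMINAR),
            (199.99, FlowRegime.UNDISTURBED_LAMINAR),
            (200.0, FlowRegime.DISTURBED),
            (1800.0, FlowRegime.DISTURBED),
            (1800.01, FlowRegime.INDETERMINATE),
            (1900.0, FlowRegime.INDETERMINATE),
            (2000.0, FlowRegime.INDETERMINATE),
            (2000.01, FlowRegime.TURBULENT),
            (2500.0, FlowRegime.TURBULENT),
        ],
    )
    def test_thresholds(self, re, regime):
        assert classify_flow(re).regime == regime

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_flow(-1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=0, max_value=1e5), st.floats(min_value=0, max_value=1e5))
    def test_monotone_regime_ordering(self, re1, re2):
        lo, hi = sorted([re1, re2])
        order = FlowRegime.ORDER
        assert order.index(classify_flow(lo).regime) <= order.index(
            classify_flow(hi).regime
        )
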