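import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alignkt import kinetic
from alignkt.modes import ModeSpectrum

PI = math.pi


def landau_rational_n1(m, w):
    """Reconstructed rational closed form of the n=1 Landau matrix
    (spectral normalization, coefficient of M*Sc^2)."""
    num = (4 * w**2 - 3) * m - 4 * w
    den = (2 * w - 1) * (2 * w + 1) * (2 * w - 3) * (2 * w + 3)
    return Fraction(64 * m, 3) * Fraction(num, den)


def landau_rational_n2(m, w):
    """Reconstructed rational closed form of the n=2 Landau matrix."""
    num = (64 * w**6 - 848 * w**4 + 2524 * w**2 - 1155) * m \
        - 320 * w**5 + 2848 * w**3 - 4148 * w
    den = 1
    for k in (1, 3, 5, 7):
        den *= (2 * w - k) * (2 * w + k)
    return Fraction(256 * m, 3) * Fraction(num, den)


def harmonic_sum(n):
    return sum(Fraction(1, 2 * j - 1) for j in range(1, 2 * n + 1))


class TestKernelIntegral:
    @pytest.mark.parametrize("n,m,w,expect", [
        (1, 1, 0, -16 / 3),       # integrand reduces to -sin^2/|sin(D/2)|
        (2, 1, 0, -704 / 105),
        (1, 1, 1, 16 / 5),
    ])
    def test_frozen_values(self, n, m, w, expect):
        assert kinetic.landau_kernel_integral(n, m, w) == \
            pytest.approx(expect, abs=1e-10)

    def test_riemann_sum_oracle(self):
        # independent high-resolution midpoint rule on the raw integrand
        def integrand(d, n, m, w):
            return (np.sin(n * d) / np.abs(np.sin(d / 2))) * (
                2 * n * np.cos(n * d) * np.sin(w * d)
                - (m - 2 * w) * np.sin(n * d) * np.cos(w * d))

        d = (np.arange(2_000_000) + 0.5) * (2 * PI / 2_000_000)
        for (n, m, w) in [(1, 2, 1), (2, 3, -2), (3, 1, 0), (4, 2, 2)]:
            ref = integrand(d, n, m, w).mean() * 2 * PI
            assert kinetic.landau_kernel_integral(n, m, w) == \
                pytest.approx(ref, abs=5e-9)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_w0_column_harmonic_closed_form(self, n):
        # I(n, m, 0) = -4 m sum_{j=1..2n} 1/(2j-1)
        for m in range(-6, 7):
            assert kinetic.landau_kernel_integral(n, m, 0) == \
                pytest.approx(-4 * m * float(harmonic_sum(n)), abs=1e-10)

    @pytest.mark.parametrize("n,oracle", [(1, landau_rational_n1),
                                          (2, landau_rational_n2)])
    def test_rational_closed_forms(self, n, oracle):
        # (4m/3) I(n,m,w) equals the reconstructed rationals, |m|,|w| <= 10
        for m in range(-10, 11):
            for w in range(-10, 11):
                got = 4 * m / 3 * kinetic.landau_kernel_integral(n, m, w)
                expect = float(oracle(m, w))
                assert got == pytest.approx(expect, rel=1e-9, abs=1e-9)


class TestMatrices:
    def test_vlasov_spectral_entries(self):
        V = kinetic.vlasov_matrix(10, 2, 0.1, normalization="spectral")
        i = lambda m: m + 10
        assert V[i(3), i(2)] == pytest.approx(3 * PI * 0.1)
        assert V[i(3), i(-2)] == pytest.approx(-3 * PI * 0.1)
        row3 = V[i(3)].copy()
        row3[[i(2), i(-2)]] = 0
        assert np.all(row3 == 0)
        assert np.all(V[i(0)] == 0)
        assert np.all(kinetic.vlasov_matrix(10, 2, 0.0) == 0)

    def test_density_is_spectral_over_pi(self):
        Vs = kinetic.vlasov_matrix(6, 1, -0.3, normalization="spectral")
        Vd = kinetic.vlasov_matrix(6, 1, -0.3, normalization="density")
        np.testing.assert_allclose(Vd, Vs / PI, atol=1e-15)
        Ls = kinetic.landau_matrix(6, 2, 0.5, -0.1, normalization="spectral")
        Ld = kinetic.landau_matrix(6, 2, 0.5, -0.1, normalization="density")
        np.testing.assert_allclose(Ld, Ls / PI**2, rtol=1e-13)

    def test_landau_reference_elements_spectral(self):
        MSc2 = 0.37
        L1 = kinetic.landau_matrix(4, 1, 0.37, 1.0, normalization="spectral")
        assert L1[1 + 4, 0 + 4] == pytest.approx(-(64 / 9) * MSc2, rel=1e-10)
        assert L1[1 + 4, 1 + 4] == pytest.approx((64 / 15) * MSc2, rel=1e-10)
        L2 = kinetic.landau_matrix(4, 2, 0.37, 1.0, normalization="spectral")
        assert L2[1 + 4, 0 + 4] == pytest.approx(-(2816 / 315) * MSc2, rel=1e-10)

    def test_landau_scaling_in_M_and_Sc(self):
        base = kinetic.landau_matrix(5, 2, 0.2, -0.1)
        np.testing.assert_allclose(kinetic.landau_matrix(5, 2, 0.6, -0.1),
                                   3 * base, rtol=1e-12)
        np.testing.assert_allclose(kinetic.landau_matrix(5, 2, 0.2, -0.3),
                                   9 * base, rtol=1e-12)

    def test_coupling_matrix_structure(self):
        mats = kinetic.coupling_matrix(10, 2, 0.4, -0.15)
        i = lambda m: m + 10
        assert np.all(mats.K[i(0)] == 0)          # density conservation
        # K_{-m,-w} = K_{m,w} (reality preservation)
        np.testing.assert_allclose(mats.K, mats.K[::-1, ::-1], atol=1e-14)
        # V scales with gamma = Sc*M only at w = +-n
        nz = np.nonzero(mats.V[i(3)])[0]
        assert set(nz) == {i(2), i(-2)}
        assert kinetic.coupling_matrix(10, 1, 0.4, 0.0).K == pytest.approx(0)

    @pytest.mark.parametrize("n", [1, 2])
    def test_landau_sign_structure(self, n):
        # second-order part of K_{m,0} negative, K_{m,m} positive, sum negative
        L = kinetic.landau_matrix(10, n, 1.0, 1.0)
        i = lambda m: m + 10
        for m in range(1, 11):
            assert L[i(m), i(0)] < 0
            assert L[i(m), i(m)] > 0
            assert L[i(m), i(0)] + L[i(m), i(m)] < 0

    def test_truncation_guard(self):
        with pytest.raises(ValueError, match="m_max"):
            kinetic.vlasov_matrix(1, 2, 0.1)

    def test_reference_linearized_rate_spectral_arithmetic(self):
        # (1/2)(K11 + K10) assembled in the spectral convention at the polar
        # relaxation parameters gamma=-0.005, MSc2=2.5e-4
        mats = kinetic.coupling_matrix(10, 1, 0.1, -0.05,
                                       normalization="spectral")
        val = 0.5 * (mats.el("K", 1, 1) + mats.el("K", 1, 0))
        expect = 0.5 * (PI * -0.005 + (64 / 15 - 64 / 9) * 2.5e-4)
        assert val == pytest.approx(expect, rel=1e-9)
        assert val == pytest.approx(-0.008209, abs=1e-6)
        # physical (density) rate: Vlasov part scales 1/pi, Landau 1/pi^2
        md = kinetic.coupling_matrix(10, 1, 0.1, -0.05)
        expect_d = 0.5 * (-0.005 + (64 / 15 - 64 / 9) * 2.5e-4 / PI**2)
        assert kinetic.linear_growth_rate(md, 0.0, 1) == \
            pytest.approx(expect_d, rel=1e-9)


class TestModeDynamics:
    def test_isotropic_state_is_stationary(self):
        mats = kinetic.coupling_matrix(6, 1, 0.5, -0.2)
        rhs = kinetic.mode_rhs(ModeSpectrum.isotropic(6), mats, 0.3)
        np.testing.assert_allclose(rhs, 0, atol=1e-15)

    def test_linearized_rate_matches_growth_rate(self):
        mats = kinetic.coupling_matrix(8, 2, 0.5, -0.2)
        eps = 1e-7
        c = np.zeros(9, dtype=complex)
        c[0] = 0.5
        c[2] = eps
        rhs = kinetic.mode_rhs(ModeSpectrum(c), mats, 0.05)
        lam = kinetic.linear_growth_rate(mats, 0.05, 2)
        assert rhs[2] / eps == pytest.approx(lam, rel=1e-5)

    def test_reality_preservation(self):
        mats = kinetic.coupling_matrix(6, 1, 0.5, -0.2)
        c = 0.4 * np.exp(-np.arange(7)) + 0j
        c[0] = 0.5
        rhs = kinetic.mode_rhs(ModeSpectrum(c), mats, 0.0)
        # real spectrum (conjugate-symmetric) stays real
        np.testing.assert_allclose(rhs.imag, 0, atol=1e-15)

    def test_truncation_mismatch(self):
        mats = kinetic.coupling_matrix(6, 1, 0.5, -0.2)
        with pytest.raises(ValueError, match="truncation"):
            kinetic.mode_rhs(ModeSpectrum.isotropic(5), mats, 0.0)

    def test_spectral_matrices_rejected_by_dynamics(self):
        mats = kinetic.coupling_matrix(6, 1, 0.5, -0.2,
                                       normalization="spectral")
        with pytest.raises(ValueError, match="density"):
            kinetic.mode_rhs(ModeSpectrum.isotropic(6), mats, 0.0)

    def test_free_rotational_diffusion_closed_form(self):
        mats = kinetic.coupling_matrix(5, 1, 0.5, 0.0)   # K = 0
        init = ModeSpectrum.wedge(5, 2.0)
        t = np.linspace(0, 3.0, 20)
        ser = kinetic.integrate_modes(init, mats, 0.7, t)
        for m in range(6):
            expect = init[m] * np.exp(-m * m * 0.7 * t)
            np.testing.assert_allclose(ser.coefficients[:, m], expect,
                                       atol=1e-9)

    def test_density_conservation_and_reality_full_run(self):
        # polar relaxation parameters, full scaled-time range
        mats = kinetic.coupling_matrix(10, 1, 0.1, -0.05)
        init = ModeSpectrum.wedge(10, 5 * PI / 6)
        t = np.linspace(0, 160.0, 200)
        ser = kinetic.integrate_modes(init, mats, 0.0, t)
        assert np.max(np.abs(ser.coefficients[:, 0] - 0.5)) < 1e-8
        assert np.max(np.abs(ser.coefficients.imag)) < 1e-12
        # monotone decay of the polar mode for anti-aligning coupling
        p1 = ser.coefficients[:, 1].real
        assert np.all(np.diff(p1) < 0)

    def test_truncation_convergence(self):
        t = np.linspace(0, 160.0, 50)
        out = {}
        for m_max in (10, 20):
            mats = kinetic.coupling_matrix(m_max, 1, 0.1, -0.05)
            init = ModeSpectrum.wedge(m_max, 5 * PI / 6)
            ser = kinetic.integrate_modes(init, mats, 0.0, t)
            out[m_max] = ser.coefficients[:, 1].real
        assert np.max(np.abs(out[10] - out[20])) < 1e-3

    def test_bad_grid_rejected(self):
        mats = kinetic.coupling_matrix(4, 1, 0.5, -0.2)
        with pytest.raises(ValueError):
            kinetic.integrate_modes(ModeSpectrum.isotropic(4), mats, 0.0,
                                    np.array([0.0, 0.0, 1.0]))


class TestEncounterTime:
    def test_closed_form(self):
        assert kinetic.encounter_time(1.0) == pytest.approx(8 / (3 * PI))
        assert kinetic.encounter_time(2.0) == pytest.approx(4 / (3 * PI))

    def test_parallel_headings_undefined(self):
        with pytest.raises(ValueError, match="parallel"):
            kinetic.encounter_time(0.0)

    def test_monte_carlo_oracle(self, rng):
        mean, err = kinetic.mc_encounter_time(rng, 1_000_000)
        assert abs(mean - 8 / (3 * PI)) < 3 * err
        assert err < 3e-3


class TestLinearStability:
    def test_zero_coupling_rate(self):
        mats = kinetic.coupling_matrix(6, 1, 0.5, 0.0)
        for m in (1, 3):
            assert kinetic.linear_growth_rate(mats, 0.4, m) == \
                pytest.approx(-m * m * 0.4)

    def test_landau_shift_lowers_threshold(self):
        # aligning coupling: beta_n > 0, so the full-K instability threshold
        # sits below the mean-field-only one
        for n in (1, 2):
            full = kinetic.coupling_matrix(10, n, 0.5, 0.3)
            assert full.beta_n > 0
            mf = kinetic.CouplingMatrices(
                n=n, m_max=10, M=0.5, Sc=0.3, V=full.V,
                Lmat=np.zeros_like(full.V), K=full.V,
                alpha_n=full.alpha_n, beta_n=0.0)
            assert kinetic.critical_Pe_inv(full, n) < \
                kinetic.critical_Pe_inv(mf, n)

    def test_out_of_range_mode(self):
        mats = kinetic.coupling_matrix(6, 1, 0.5, -0.2)
        with pytest.raises(ValueError):
            kinetic.linear_growth_rate(mats, 0.0, 7)

    def test_both_mean_field_conventions_exposed(self):
        # raw linearized rate n*gamma/2 and the spectral timescale 1/(n pi g)
        assert kinetic.mean_field_rate(2, 0.1) == pytest.approx(0.1)
        assert kinetic.mean_field_timescale(2, 0.1) == \
            pytest.approx(1 / (2 * PI * 0.1))


class TestModeSpectrum:
    def test_validate_density_bound(self):
        c = np.zeros(4, dtype=complex)
        c[0] = 0.5
        c[2] = 0.7
        with pytest.raises(ValueError, match="phat_2"):
            ModeSpectrum(c).validate()

    def test_wedge_matches_empirical_average(self):
        spec = ModeSpectrum.wedge(3, 5 * PI / 6)
        assert spec[1].real == pytest.approx(0.36896, abs=1e-5)
        assert spec[0] == 0.5

    @settings(max_examples=20, deadline=None)
    @given(st.integers(1, 8), st.floats(0.1, 2 * PI))
    def test_wedge_is_valid_spectrum(self, m_max, alpha):
        ModeSpectrum.wedge(m_max, alpha).validate()
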