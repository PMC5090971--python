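"""Diagnostics: MSD and power laws, displacement correlation, the
Metzler–Klafter subdiffusive propagator and its ML fit, normality
testing, and apparent-diffusivity lag scaling."""

import math

import numpy as np
import pytest

from fracperm.diagnostics import (MsdCurve, apparent_diffusivity_scaling,
                                  displacement_correlation, fit_mk_alpha,
                                  mk_propagator, mk_variance, msd,
                                  normality_test, powerlaw_fit, sample_mk)
from fracperm.profiles import Profile
from fracperm.synth import brownian_trajectory, fbm_trajectory, fgn
from fracperm.trajectory import Trajectory


class TestMsd:
    def test_ballistic_closed_form(self):
        v = 3.0
        t = 1e-3 * np.arange(1000)
        tr = Trajectory(1e-3, v * t)
        c = msd(tr, lags=[0.01, 0.05, 0.1])
        np.testing.assert_allclose(c.msd, v ** 2 * c.lags ** 2, rtol=1e-10)

    def test_brownian_recovers_diffusivity(self):
        """MSD/(2Δt) = 480 ± 5% for Δt in [10, 100] ps, walls far away."""
        z = np.arange(-225.0, 225.0001, 1.0)
        D = Profile.from_z(z, np.full(z.size, 480.0), "Å²/ns")
        tr = brownian_trajectory(None, D, dt=5e-4, steps=2_000_000,
                                 sample_every=4, seed=11)
        c = msd(tr, lags=[0.01, 0.02, 0.05, 0.1])
        np.testing.assert_allclose(c.msd / (2 * c.lags), 480.0, rtol=0.05)

    def test_fbm_scaling_exponent(self):
        tr = fbm_trajectory(0.35, scale=0.3, steps=300_000, dt=1e-3, seed=3)
        c = msd(tr, lags=[0.002, 0.005, 0.01, 0.02, 0.05, 0.1])
        e, _, _ = powerlaw_fit(c)
        assert e == pytest.approx(0.70, abs=0.03)

    def test_region_conditioning_modes(self):
        rng = np.random.default_rng(0)
        z = np.cumsum(rng.normal(0, 0.5, 20000))
        tr = Trajectory(1e-3, z)
        for mode in ("endpoints", "whole-path"):
            c = msd(tr, region=(-5, 5), lags=[0.005], region_mode=mode)
            assert c.counts[0] > 0
        with pytest.raises(ValueError):
            msd(tr, region=(1e6, 2e6), lags=[0.005])


class TestPowerlawFit:
    def test_exact_power_law(self):
        lags = np.geomspace(0.001, 1, 20)
        c = MsdCurve(lags, 3.0 * lags ** 0.5, np.full(20, 100))
        e, pref, r = powerlaw_fit(c)
        assert e == pytest.approx(0.5, abs=1e-12)
        assert pref == pytest.approx(3.0, rel=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_brownian_exponent_is_one(self):
        z = np.arange(-225.0, 225.0001, 1.0)
        D = Profile.from_z(z, np.full(z.size, 480.0), "Å²/ns")
        tr = brownian_trajectory(None, D, dt=5e-4, steps=1_000_000,
                                 sample_every=4, seed=4)
        e, _, _ = powerlaw_fit(msd(tr, lags=[0.004, 0.01, 0.02, 0.05, 0.1]))
        assert e == pytest.approx(1.0, abs=0.03)

    def test_nonpositive_values_rejected(self):
        c = MsdCurve(np.array([1, 2, 3.0]), np.array([1.0, 0.0, 2.0]),
                     np.full(3, 10))
        with pytest.raises(ValueError):
            powerlaw_fit(c)


class TestDisplacementCorrelation:
    def test_deterministic_zigzag_fully_anticorrelated(self):
        z = np.tile([0.0, 1.0], 500)
        prof = displacement_correlation(Trajectory(1e-3, z), 1e-3,
                                        z_bins=np.array([-0.5, 1.5]))
        assert prof.C[0] == pytest.approx(-1.0)

    def test_fgn_increments_match_closed_form(self):
        """Consecutive-increment correlation 2^(2H-1) - 1 = -0.188 at
        H = 0.35."""
        H = 0.35
        tr = fbm_trajectory(H, scale=1.0, steps=300_000, dt=1e-3, seed=9)
        prof = displacement_correlation(tr, 1e-3,
                                        z_bins=np.array([-1e9, 1e9]))
        assert prof.C[0] == pytest.approx(2 ** (2 * H - 1) - 1, abs=0.02)

    def test_brownian_correlation_near_zero(self):
        """The ideal classical control shows C ≈ 0 away from the walls."""
        z = np.arange(-45.0, 45.0001, 0.5)
        D = Profile.from_z(z, np.full(z.size, 480.0), "Å²/ns")
        tr = brownian_trajectory(None, D, dt=2e-4, steps=2_000_000,
                                 sample_every=10, seed=14)
        prof = displacement_correlation(tr, 0.008,
                                        z_bins=np.linspace(-45, 45, 19))
        inner = (np.abs(prof.z) < 30) & ~np.isnan(prof.C)
        bound = 3.0 / np.sqrt(prof.counts[inner])
        assert np.all(np.abs(prof.C[inner]) < np.maximum(bound, 0.05))

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            displacement_correlation(Trajectory(1e-3, np.zeros(5)), 0.003)


class TestMkPropagator:
    def test_classical_limit_is_gaussian(self):
        x = np.linspace(-10, 10, 2001)
        K, t = 300.0, 0.01
        w = mk_propagator(x, t, 1.0, K)
        gauss = np.exp(-x ** 2 / (4 * K * t)) / np.sqrt(4 * np.pi * K * t)
        assert np.max(np.abs(w - gauss) / gauss.max()) < 1e-6

    @pytest.mark.parametrize("alpha", [0.5, 0.7, 0.9, 1.0])
    def test_normalization(self, alpha):
        x = np.linspace(-60, 60, 12001)
        w = mk_propagator(x, 1.0, alpha, 1.0)
        assert np.trapezoid(w, x) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("alpha", [0.5, 0.7, 0.9])
    def test_second_moment_identity(self, alpha):
        """Quadrature variance = 2 K t^α / Γ(1+α) within 0.5%."""
        x = np.linspace(-60, 60, 12001)
        w = mk_propagator(x, 1.0, alpha, 1.0)
        var = np.trapezoid(x ** 2 * w, x)
        assert var == pytest.approx(mk_variance(1.0, alpha, 1.0), rel=5e-3)

    def test_cusp_at_origin_for_subdiffusion(self):
        """One-sided log-density slopes at x -> 0± are nonzero for α < 1."""
        eps = 1e-3
        for alpha, has_cusp in ((0.74, True), (1.0, False)):
            w0 = mk_propagator(0.0, 1.0, alpha, 1.0)
            wp = mk_propagator(eps, 1.0, alpha, 1.0)
            slope = (math.log(wp) - math.log(w0)) / eps
            if has_cusp:
                assert abs(slope) > 0.1
            else:
                assert abs(slope) < 1e-2

    def test_tail_matches_high_precision_series(self):
        """Float64 series+asymptotic vs an mpmath reference in the tail."""
        import mpmath as mp

        mp.mp.dps = 60
        for alpha in (0.5, 0.7):
            nu = mp.mpf(alpha) / 2
            for xi in (5.0, 9.0, 12.0):
                ref = sum((-mp.mpf(xi)) ** n / mp.factorial(n)
                          * mp.rgamma(1 - nu * (n + 1)) for n in range(400))
                got = mk_propagator(xi, 1.0, alpha, 1.0)
                assert got == pytest.approx(float(ref) / 2.0, rel=5e-3)

    def test_seam_continuity(self):
        from fracperm.diagnostics import _mk_seam

        for alpha in (0.5, 0.7, 0.9):
            s = _mk_seam(alpha / 2)
            lo = mk_propagator(s * (1 - 1e-6), 1.0, alpha, 1.0)
            hi = mk_propagator(s * (1 + 1e-6), 1.0, alpha, 1.0)
            assert abs(hi / lo - 1) < 0.01


class TestMkFit:
    def test_recovers_alpha_from_own_samples(self):
        """Inverse-CDF samples at α = 0.7 -> α̂ = 0.70 ± 0.05."""
        rng = np.random.default_rng(7)
        x = sample_mk(5000, 0.01, 0.7, 300.0, rng)
        a, K, ll, d = fit_mk_alpha(x, 0.01)
        assert a == pytest.approx(0.70, abs=0.05)
        assert not d["alpha_at_bound"]

    def test_gaussian_data_gives_alpha_near_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, np.sqrt(2 * 300.0 * 0.01), 5000)
        a, K, _, _ = fit_mk_alpha(x, 0.01)
        assert a > 0.95
        assert K == pytest.approx(300.0, rel=0.1)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        x = sample_mk(2000, 0.01, 0.7, 300.0, rng)
        a1, K1, _, _ = fit_mk_alpha(x, 0.01)
        a2, K2, _, _ = fit_mk_alpha(2.0 * x, 0.01)
        assert a2 == pytest.approx(a1, abs=0.02)
        assert K2 / K1 == pytest.approx(4.0, rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_mk_alpha(np.ones(10), 0.01)


class TestNormality:
    def test_gaussian_calibration(self):
        """p > 0.05 in at least 95% of 100 replicate normal samples."""
        rng = np.random.default_rng(10)
        hits = sum(normality_test(rng.normal(size=500))[1] > 0.05
                   for _ in range(100))
        assert hits >= 95

    def test_laplace_power(self):
        """p < 0.01 in at least 95% of replicate Laplace samples."""
        rng = np.random.default_rng(11)
        hits = sum(normality_test(rng.laplace(size=1000))[1] < 0.01
                   for _ in range(100))
        assert hits >= 95

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            normality_test(np.ones(100))


class TestApparentDiffusivityScaling:
    def _profile(self, value):
        z = np.arange(-20, 20.0001, 1.0)
        return Profile.from_z(z, np.full(z.size, value), "Å²/ns")

    def test_known_power_law_maps_to_msd_exponent(self):
        """〈D〉 ~ Δt^-0.24 implies MSD ~ t^0.76."""
        lags = np.array([0.004, 0.008, 0.016, 0.032])
        D_by_lag = {l: self._profile(100.0 * l ** -0.24) for l in lags}
        g, implied, r = apparent_diffusivity_scaling(D_by_lag)
        assert g == pytest.approx(-0.24, abs=1e-10)
        assert implied == pytest.approx(0.76, abs=1e-10)

    def test_lag_independent_D_is_classical(self):
        lags = [0.004, 0.008, 0.016]
        D_by_lag = {l: self._profile(300.0) for l in lags}
        g, implied, _ = apparent_diffusivity_scaling(D_by_lag)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert implied == pytest.approx(1.0, abs=1e-12)

    def test_needs_three_lags(self):
        with pytest.raises(ValueError):
            apparent_diffusivity_scaling({0.004: self._profile(1.0)})
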