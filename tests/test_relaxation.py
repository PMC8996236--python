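import numpy as np
import pytest

from hydrelax.dipolar import MAGIC_ANGLE_DEG
from hydrelax.fitting import MultiExpFit, spectral_density
from hydrelax.relaxation import (
    AnalysisConfig,
    anisotropy_fraction,
    check_uniaxial_symmetry,
    combine_contributions,
    delta_of_beta,
    oscillation_factor,
    r1_rate,
    r2_rate,
    r_perp,
    relaxation_profile,
    slow_cosine_rate,
    transverse_evolution,
)

OMEGA0 = 2 * np.pi * 400e6
B2 = 4.73e10  # (rad/s)^2, rigid-pair coupling squared at r = 1.5139 Å


def isotropic_fits(tau_ps, amplitude=1.2 * B2):
    """Identical single-exponential fits for all m (isotropic motion)."""
    return [
        MultiExpFit(np.array([amplitude]), np.array([tau_ps]), 0.0, 0.0)
        for _ in range(3)
    ]


class TestRates:
    def test_extreme_narrowing_r1_equals_r2(self):
        fits = isotropic_fits(2.45)
        j = [spectral_density(fits[0], w) for w in (0.0, OMEGA0, 2 * OMEGA0)]
        r1 = r1_rate(j[1], j[2])
        r2 = r2_rate(j[0], j[1], j[2])
        assert r1 == pytest.approx(r2, rel=1e-4)
        # (3/2) b² τ for a rigid isotropic pair: bulk-water-like T1 of ~3.4 s
        assert 1 / r1 == pytest.approx(1 / (1.5 * B2 * 2.45e-12), rel=1e-3)

    def test_slow_motion_r2_exceeds_r1(self):
        for tau in (100.0, 400.0, 1000.0):
            fits = isotropic_fits(tau)
            j = [spectral_density(fits[0], w) for w in (0.0, OMEGA0, 2 * OMEGA0)]
            assert r2_rate(j[0], j[1], j[2]) > r1_rate(j[1], j[2])

    def test_zero_input_zero_rates(self):
        assert r1_rate(0.0, 0.0) == 0.0
        assert r2_rate(0.0, 0.0, 0.0) == 0.0

    def test_negative_j_rejected(self):
        with pytest.raises(ValueError):
            r1_rate(-1.0, 0.0)

    def test_frequency_independence_extreme_narrowing(self):
        # paper-regime check: rates flat in ν₀ while ω₀τ ≪ 1
        for tau_ps, nu_max in ((2.45, 400e6), (40.0, 160e6)):
            fits = isotropic_fits(tau_ps)
            rates = []
            for nu in np.linspace(10e6, nu_max, 8):
                w0 = 2 * np.pi * nu
                j = [spectral_density(fits[0], w) for w in (0.0, w0, 2 * w0)]
                rates.append(r1_rate(j[1], j[2]))
            rates = np.array(rates)
            assert (rates.max() - rates.min()) / rates.mean() < 0.01


class TestRPerp:
    j = (0.4, 0.3, 0.2)

    def test_relation_to_r2(self):
        delta = 10.0  # large enough for the oscillatory regime
        rp = r_perp(*self.j, delta)
        r2 = r2_rate(*self.j)
        assert rp + self.j[1] / 8.0 == pytest.approx(r2, abs=1e-12)

    def test_equals_r2_when_j11_vanishes(self):
        rp = r_perp(self.j[0], 0.0, self.j[2], delta=0.0)
        assert rp == pytest.approx(r2_rate(self.j[0], 0.0, self.j[2]), abs=1e-12)

    def test_wrong_regime_raises(self):
        with pytest.raises(ValueError, match="multiexponential"):
            r_perp(*self.j, delta=0.0)

    def test_zero_input(self):
        assert r_perp(0.0, 0.0, 0.0, delta=1.0) == 0.0


class TestOscillation:
    def test_worked_example_85_hz(self):
        delta = 3 * 2 * np.pi * 85.0
        res = oscillation_factor(delta, 0.0)
        assert res.regime == "oscillatory"
        assert res.value / 1e3 == pytest.approx(0.80, abs=0.005)

    def test_delta_zero_multiexponential(self):
        res = oscillation_factor(0.0, 0.5)
        assert res.regime == "multiexponential"
        assert np.isnan(res.value)

    def test_j11_zero_gives_half_delta(self):
        assert oscillation_factor(6.0, 0.0).value == pytest.approx(3.0)

    def test_magic_angle_null_of_delta(self):
        beta = np.linspace(0, 90, 1801)
        d = delta_of_beta(1.0, beta)
        zero_crossing = beta[np.argmin(np.abs(d))]
        assert zero_crossing == pytest.approx(54.74, abs=0.05)
        assert MAGIC_ANGLE_DEG == pytest.approx(54.7356, abs=1e-3)


class TestTransverseEvolution:
    def test_zero_rates_constant(self):
        m = transverse_evolution(np.linspace(0, 1, 10), 0.0, 0.0, 0.0)
        np.testing.assert_allclose(m, 1.0)

    def test_fft_peak_at_oscillation_frequency(self):
        rate, osc = 0.5, 2 * np.pi * 50.0
        t = np.arange(0, 4, 1e-3)
        m = transverse_evolution(t, rate, osc, 0.0)
        spec = np.abs(np.fft.rfft(m))
        freqs = np.fft.rfftfreq(len(t), 1e-3)
        peak = freqs[np.argmax(spec[1:]) + 1]
        assert peak * 2 * np.pi == pytest.approx(osc, rel=0.02)

    def test_slow_cosine_replaced_below_threshold(self):
        t = np.linspace(0, 10, 100)
        a = transverse_evolution(t, 1.0, 0.0, 1e-5)
        np.testing.assert_allclose(a, np.exp(-t))

    def test_multiexponential_regime_uses_cosh(self):
        t = np.linspace(0, 1, 5)
        m = transverse_evolution(t, 1.0, np.nan, 0.0, discriminant=-4.0)
        np.testing.assert_allclose(m, np.exp(-t) * np.cosh(0.25 * 2 * t))

    def test_slow_cosine_rate_formula(self):
        assert slow_cosine_rate(0.8, 0.1) == pytest.approx((0.8 + 0.2) / 8)


class TestAnisotropyFraction:
    def test_constant_profile_zero(self):
        assert anisotropy_fraction(np.array([1.0, 1.0, 1.0])) == 0.0

    def test_factor_two_gives_half(self):
        assert anisotropy_fraction(np.array([1.0, 2.0])) == pytest.approx(0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            anisotropy_fraction(np.array([1.0, 0.0]))


class TestProfilesAndCombination:
    def _profile(self, tau=2.45, amp=1.2 * B2, delta=3 * 2 * np.pi * 85):
        return relaxation_profile(
            isotropic_fits(tau, amp), delta, OMEGA0, np.arange(0, 90.1, 5.0)
        )

    def test_isotropic_profile_beta_flat(self):
        prof = self._profile()
        assert prof.g_r1 < 1e-10 and prof.g_r2 < 1e-10
        np.testing.assert_allclose(prof.r1, prof.r2, rtol=1e-4)

    def test_beta_symmetry_of_rates(self):
        fits = [
            MultiExpFit(np.array([B2 * (1 + 0.3 * m)]), np.array([2.0 + m]), 0, 0)
            for m in range(3)
        ]
        full = relaxation_profile(fits, 100.0, OMEGA0, np.array([30.0, 150.0]))
        assert full.r1[0] == pytest.approx(full.r1[1], rel=1e-10)
        assert full.r2[0] == pytest.approx(full.r2[1], rel=1e-10)

    def test_sum_of_equal_profiles_doubles_rates(self):
        p = self._profile()
        comb = combine_contributions([p, p])
        np.testing.assert_allclose(comb.r1, 2 * p.r1, rtol=1e-12)
        np.testing.assert_allclose(comb.r2, 2 * p.r2, rtol=1e-12)
        assert comb.delta_pas == pytest.approx(2 * p.delta_pas)

    def test_adding_zero_profile_identity(self):
        p = self._profile()
        z = self._profile(amp=0.0, delta=0.0)
        # zero-amplitude fits are rejected at fit time; emulate a null profile
        z.r1[:] = 0; z.r2[:] = 0; z.r_perp[:] = 0; z.slow_cosine[:] = 0
        comb = combine_contributions([p, z])
        np.testing.assert_allclose(comb.r1, p.r1)

    def test_additivity_matches_pooled_pairs(self, small_free_rotor):
        # two independent pair populations: rates of the union equal the sum
        # of the separately computed contributions (cross-correlations vanish)
        from hydrelax.fitting import fit_multiexponential, integrated_correlation_time
        from hydrelax.pipeline import rotor_tcf

        spec, orient = small_free_rotor
        half = orient.shape[1] // 2
        profs = []
        for sl in (slice(0, half), slice(half, None)):
            tcf, _ = rotor_tcf(orient[:, sl], spec.r_hh, 500, spec.dt)
            fits = [
                fit_multiexponential(tcf.tau, tcf.g[m].real, seed=m) for m in range(3)
            ]
            profs.append(
                relaxation_profile(fits, 0.0, OMEGA0, np.array([0.0, 45.0, 90.0]))
            )
        tcf_all, _ = rotor_tcf(orient, spec.r_hh, 500, spec.dt)
        fits = [
            fit_multiexponential(tcf_all.tau, tcf_all.g[m].real, seed=m)
            for m in range(3)
        ]
        pooled = relaxation_profile(fits, 0.0, OMEGA0, np.array([0.0, 45.0, 90.0]))
        # pooled mean TCF is the pair-count-weighted mean → half the sum here
        np.testing.assert_allclose(
            combine_contributions(profs).r1, 2 * pooled.r1, rtol=0.02
        )

    def test_grid_mismatch_rejected(self):
        p = self._profile()
        q = relaxation_profile(isotropic_fits(2.45), 0.0, OMEGA0, np.array([0.0, 10.0]))
        with pytest.raises(ValueError):
            combine_contributions([p, q])


class TestUniaxialityDiagnostic:
    def test_symmetric_ensemble_small_ratios(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(0, 2 * np.pi, 100_000)
        theta = np.full_like(phi, 0.5)
        from hydrelax.dipolar import f_m

        f = f_m(np.full_like(phi, 1.5139), theta, phi)
        rep = check_uniaxial_symmetry(f.mean(axis=1))
        assert rep.ratio_f1 < 0.02 and rep.ratio_f2 < 0.02 and not rep.warning

    def test_biaxial_ensemble_flagged(self):
        # vectors clustered in the x–z plane: ⟨F₂⟩ does not average out
        from hydrelax.dipolar import f_m

        theta = np.linspace(0.2, np.pi - 0.2, 1000)
        phi = np.zeros_like(theta)
        f = f_m(np.full_like(theta, 1.5139), theta, phi)
        rep = check_uniaxial_symmetry(f.mean(axis=1))
        assert rep.ratio_f2 > 0.5 and rep.warning

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            check_uniaxial_symmetry(np.zeros(3))


class TestAnalysisConfig:
    def test_rejects_bad_larmor_and_beta(self):
        with pytest.raises(ValueError):
            AnalysisConfig(larmor_frequency=0.0)
        with pytest.raises(ValueError):
            AnalysisConfig(beta_grid_deg=np.array([-5.0]))

    def test_omega0(self):
        assert AnalysisConfig().omega0 == pytest.approx(2 * np.pi * 400e6)
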