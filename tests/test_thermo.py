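"""Master-reaction thermodynamic model: closed forms, grouping, MCMC."""

import math

import numpy as np
import pytest

from thermospectrum import (
    GeneratorConfig,
    R_GAS,
    StrainThermoParams,
    ThermoMCMCConfig,
    UniversalThermoParams,
    assign_thermal_groups,
    celsius_to_kelvin,
    fit_thermo,
    filter_for_thermo,
    generate_collation,
    log_likelihood,
    log_thermo_rate,
    t_mes,
    thermo_rate,
)
from thermospectrum.thermo import (
    UNIVERSAL_HI,
    UNIVERSAL_LO,
    gauge_map,
    master_reaction_rate,
)

U = UniversalThermoParams(5000.0, 16.0, 373.0, 385.0)


class TestClosedForms:
    def test_zero_residues_halves_the_arrhenius_numerator(self):
        """With n = 0 the folded fraction is exactly 1/2."""
        T = 310.0
        numerator = T * math.exp(-10.0 - 70_000.0 / (R_GAS * T))
        assert master_reaction_rate(T, -10.0, 70_000.0, 0.0, 65.0, U) == pytest.approx(
            numerator / 2.0, rel=1e-12
        )

    def test_large_n_with_stable_protein_reaches_arrhenius_limit(self):
        # at 300 K the folding free energy is positive, so n -> large
        # drives the denominator to 1
        T = 300.0
        numerator = T * math.exp(-10.0 - 70_000.0 / (R_GAS * T))
        val = master_reaction_rate(T, -10.0, 70_000.0, 5_000.0, 65.0, U)
        assert val == pytest.approx(numerator, rel=1e-9)

    def test_against_high_precision_evaluation(self):
        """Frozen 20-digit arbitrary-precision value for one parameter set."""
        val = master_reaction_rate(310.0, -10.0, 70_000.0, 300.0, 65.0, U)
        assert val == pytest.approx(2.2546138235899712e-14, rel=1e-12)

    def test_rate_overflow_safe_across_extreme_states(self):
        """Deeply destabilised states evaluate finitely; the log form never
        overflows even where the linear rate underflows to zero."""
        p = StrainThermoParams(-10.0, 70_000.0, 2000.0, 65.0)
        T = np.linspace(250, 450, 40)
        vals = thermo_rate(T, p, U)
        logs = log_thermo_rate(T, p, U)
        assert np.all(np.isfinite(logs))
        assert np.all(vals >= 0) and np.all(np.isfinite(vals))
        assert np.all(vals[logs > -700] > 0)

    def test_non_positive_temperature_rejected(self):
        p = StrainThermoParams(-10.0, 70_000.0, 300.0, 65.0)
        with pytest.raises(ValueError):
            thermo_rate(-1.0, p, U)


class TestTmes:
    def test_hand_arithmetic(self):
        assert t_mes(UniversalThermoParams(5000, 16, 373, 385), 65.0) == pytest.approx(
            373 - 5000 / 65, rel=1e-15
        )

    def test_zero_enthalpy_gives_convergence_temperature(self):
        assert t_mes(UniversalThermoParams(0.0, 16, 373, 385), 65.0) == 373.0

    def test_doubling_heat_capacity_halves_offset(self):
        off1 = 373.0 - t_mes(UniversalThermoParams(5000, 16, 373, 385), 65.0)
        off2 = 373.0 - t_mes(UniversalThermoParams(5000, 16, 373, 385), 130.0)
        assert off1 == pytest.approx(2 * off2, rel=1e-12)

    def test_zero_heat_capacity_rejected(self):
        with pytest.raises(ValueError):
            t_mes(U, 0.0)


class TestLogLikelihood:
    P = StrainThermoParams(-10.0, 70_000.0, 300.0, 65.0)

    def test_zero_residual_leaves_normaliser_only(self):
        T_c = np.array([25.0])
        F = thermo_rate(celsius_to_kelvin(T_c), self.P, U)
        psi = 1e4
        ll = log_likelihood((T_c, F), self.P, U, psi)
        assert ll == pytest.approx(0.5 * math.log(psi / (2 * math.pi)), rel=1e-12)

    def test_additivity_of_identical_records(self):
        T_c = np.array([25.0])
        r = np.array([1e-4])
        one = log_likelihood((T_c, r), self.P, U, 1e4)
        two = log_likelihood((np.repeat(T_c, 2), np.repeat(r, 2)), self.P, U, 1e4)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_extended_precision_summation(self, rng):
        """Brute-force fsum of per-record Gaussian terms is the oracle."""
        T_c = rng.uniform(5, 45, 12)
        r = 10.0 ** rng.uniform(-6, -2, 12)
        psi = 3333.0
        sqrtF = np.sqrt(thermo_rate(celsius_to_kelvin(T_c), self.P, U))
        terms = [
            0.5 * math.log(psi / (2 * math.pi)) - 0.5 * psi * (math.sqrt(ri) - si) ** 2
            for ri, si in zip(r, sqrtF)
        ]
        assert log_likelihood((T_c, r), self.P, U, psi) == pytest.approx(
            math.fsum(terms), rel=1e-12
        )

    def test_misfit_strictly_decreases_likelihood(self):
        T_c = np.array([25.0])
        F = float(thermo_rate(celsius_to_kelvin(T_c), self.P, U)[0])
        lls = [
            log_likelihood((T_c, np.array([(math.sqrt(F) + eps) ** 2])), self.P, U, 1e4)
            for eps in (0.0, 0.01, 0.02, 0.05)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            log_likelihood((np.array([25.0]), np.array([1e-4])), self.P, U, 0.0)
        with pytest.raises(ValueError):
            log_likelihood((np.array([25.0]), np.array([-1e-4])), self.P, U, 1e4)


class TestThermalGroups:
    def test_uniform_case_splits_evenly(self):
        groups, g = assign_thermal_groups(np.linspace(0, 119, 120), 60)
        assert g == 60
        assert all(np.bincount(groups) == 2)

    def test_identical_topt_collapses_to_one_group(self):
        groups, g = assign_thermal_groups([37.0] * 10, 5)
        assert g == 1
        assert np.all(groups == 0)

    def test_quantile_partition_balance(self, rng):
        """Without ties the quantile partition balances group sizes to ±1."""
        t = rng.uniform(0, 100, 173)
        groups, g = assign_thermal_groups(t, 10)
        sizes = np.bincount(groups, minlength=g)
        assert sizes.max() - sizes.min() <= 1

    def test_fewer_strains_than_groups_warns(self):
        with pytest.warns(UserWarning, match="reducing"):
            groups, g = assign_thermal_groups([10.0, 20.0, 30.0], 60)
        assert g <= 3


class TestGaugeFreedom:
    def test_gauge_map_preserves_every_curve(self, rng):
        """The orbit transformation leaves modelled rates exactly unchanged."""
        u = np.array([4400.0, 16.0, 340.0, 350.0])
        dcp = rng.uniform(20, 150, 8)
        n = rng.uniform(60, 400, 8)
        out = gauge_map(u, dcp, n, math.log(1.3), 20.0)
        assert out is not None
        u2, dcp2, n2, _ = out
        T = np.linspace(260, 390, 27)
        for j in range(8):
            f1 = master_reaction_rate(T, -8.0, 70_000.0, n[j], dcp[j],
                                      UniversalThermoParams.from_array(u))
            f2 = master_reaction_rate(T, -8.0, 70_000.0, n2[j], dcp2[j],
                                      UniversalThermoParams.from_array(u2))
            np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_gauge_map_is_an_involution(self, rng):
        u = np.array([5000.0, 18.0, 350.0, 360.0])
        dcp = rng.uniform(20, 150, 5)
        n = rng.uniform(60, 400, 5)
        fwd = gauge_map(u, dcp, n, 0.2, 12.0)
        assert fwd is not None
        u2, dcp2, n2, _ = fwd
        back = gauge_map(u2, dcp2, n2, -0.2, -12.0)
        assert back is not None
        np.testing.assert_allclose(back[0], u, rtol=1e-12)
        np.testing.assert_allclose(back[1], dcp, rtol=1e-10)
        np.testing.assert_allclose(back[2], n, rtol=1e-10)


def test_unimodality_over_prior_draws(rng):
    """Curves drawn from the prior box with n >= 50 are almost always unimodal.

    Counts strict local maxima of F on a 0.1 K grid over [270, 400] with a
    small relative prominence floor; at least 95% of 1000 draws must have a
    single peak.
    """
    from scipy.signal import find_peaks

    T = np.arange(270.0, 400.0, 0.1)
    failures = 0
    n_draws = 1000
    for _ in range(n_draws):
        u = UniversalThermoParams.from_array(rng.uniform(UNIVERSAL_LO, UNIVERSAL_HI))
        n = rng.uniform(50, 2000)
        dcp = abs(rng.normal(65.0, 100.0)) + 1e-3
        f = master_reaction_rate(T, 0.0, rng.uniform(2e4, 2e5), n, dcp, u)
        peaks, _ = find_peaks(f, prominence=f.max() * 1e-6)
        interior = (np.argmax(f) != 0) and (np.argmax(f) != f.size - 1)
        n_peaks = len(peaks) if interior else len(peaks) + 1
        if n_peaks > 1:
            failures += 1
    assert failures / n_draws <= 0.05


class TestFitThermo:
    @pytest.fixture(scope="class")
    def tiny_fit(self):
        cfg = GeneratorConfig(n_strains=8, points_per_strain=(8, 12), points_mean=None)
        coll, truth = generate_collation(cfg, seed=77)
        elig = filter_for_thermo(coll)
        mcfg = ThermoMCMCConfig(n_iter=6_000, burn_in=2_000, thin=5)
        post = fit_thermo(elig, mcfg, seed=99, n_groups=2)
        return coll, truth, elig, mcfg, post

    def test_determinism_under_fixed_seed(self, tiny_fit):
        coll, truth, elig, mcfg, post = tiny_fit
        again = fit_thermo(elig, mcfg, seed=99, n_groups=2)
        assert np.array_equal(post.strain_draws, again.strain_draws)
        assert np.array_equal(post.universal_draws, again.universal_draws)

    def test_supports_and_positivity_hold_in_every_draw(self, tiny_fit):
        _, _, _, _, post = tiny_fit
        assert np.all(post.universal_draws >= UNIVERSAL_LO - 1e-9)
        assert np.all(post.universal_draws <= UNIVERSAL_HI + 1e-9)
        assert np.all(post.psi_draws > 0)
        assert np.all(post.group_prec_draws > 0)
        assert np.all(post.strain_draws[:, :, 1] > 0)  # activation enthalpy
        assert np.all(post.strain_draws[:, :, 2] >= 1.0)  # residue count

    def test_empty_strain_set_rejected(self):
        with pytest.raises(ValueError):
            fit_thermo([], ThermoMCMCConfig(n_iter=100, burn_in=10), seed=0)

    def test_fitted_curves_track_observations(self, tiny_fit):
        """Posterior-mean curves stay within a factor ~3 of the data at the peak."""
        _, _, elig, _, post = tiny_fit
        for i, s in enumerate(elig):
            peak_obs = float(s.rates.max())
            curve = post.fitted_curve(i, np.array([s.t_opt]))
            assert 0.2 * peak_obs < float(curve[0]) < 5.0 * peak_obs


def test_hierarchical_shrinkage_pulls_noisy_strain_to_group():
    """Partial pooling moves a noisy strain toward its thermal group."""
    cfg = GeneratorConfig(
        n_strains=10, points_per_strain=(6, 8), points_mean=None,
        topt_means=(30.0, 33.0), topt_sds=(2.0, 2.0), psi=400.0,
    )
    coll, truth = generate_collation(cfg, seed=31)
    elig = filter_for_thermo(coll)
    mcfg = ThermoMCMCConfig(n_iter=8_000, burn_in=3_000, thin=5)
    pooled = fit_thermo(elig, mcfg, seed=5, n_groups=1, pooled=True)
    unpooled = fit_thermo(elig, mcfg, seed=5, n_groups=1, pooled=False)

    # distance of strain-level activation enthalpies from the pooled group
    # mean must shrink under pooling for most strains
    centre = pooled.group_mean_draws[:, 0, 1].mean()
    d_pool = np.abs(pooled.strain_mean[:, 1] - centre)
    d_free = np.abs(unpooled.strain_mean[:, 1] - centre)
    assert np.median(d_pool) < np.median(d_free)
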