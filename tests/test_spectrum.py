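"""Exceedance tabulation, trend smoothing and envelope construction."""

import math

import numpy as np
import pandas as pd
import pytest

from thermospectrum import (
    Collation,
    QuantileParams,
    QuantilePosterior,
    StrainThermoParams,
    TemperatureBin,
    ThermoPosterior,
    UniversalThermoParams,
    celsius_to_kelvin,
    mean_parameters_by_group,
    predict_envelope,
    quantile_curve,
    smooth_trends,
    smoothing_spline_df,
    spectrum_summary,
    tabulate_exceedance,
    thermo_rate,
)
from conftest import make_strain

U = UniversalThermoParams(5500.0, 20.0, 366.0, 385.0)


def fake_thermo_posterior(strain_ids, params_rows, universal=U, psi=1e4):
    """Single-draw posterior with exactly known parameters per strain."""
    P = np.asarray(params_rows, dtype=float)[None, :, :]  # (1, S, 4)
    S = P.shape[1]
    return ThermoPosterior(
        strain_ids=list(strain_ids),
        group_idx=np.zeros(S, dtype=int),
        strain_draws=P,
        group_mean_draws=P[:, :1, :3],
        group_prec_draws=np.ones((1, 1, 3)),
        universal_draws=universal.as_array()[None, :],
        psi_draws=np.array([psi]),
    )


def fake_quantile_posterior(params: QuantileParams):
    return QuantilePosterior(
        tau=params.tau,
        draws=params.as_array()[None, :],
        sigma_draws=np.array([1.0]),
        acceptance_rate=0.3,
        temperature_range=(-10.0, 110.0),
    )


def mesophile_params(scale_log=0.0):
    """A strain parameter row peaking near 37 °C under the test universal."""
    return [16.0 + scale_log, 70_000.0, 300.0, 62.0]


class TestTabulateExceedance:
    BIN = TemperatureBin(20.0, 50.0, "(20, 50]")

    def _setup(self, shift):
        strain = make_strain(
            "s1", [(25.0, 0.002), (31.0, 0.006), (37.0, 0.012), (43.0, 0.004)]
        )
        post = fake_thermo_posterior(["s1"], [mesophile_params(shift)])
        q = fake_quantile_posterior(QuantileParams(-6.0, 0.08, -1.5, -0.03, 0.975))
        return [strain], post, {self.BIN.label: {0.975: q}}

    def test_curve_below_quantile_not_flagged(self):
        strains, post, fits = self._setup(shift=-6.0)
        recs = tabulate_exceedance(strains, post, fits, [self.BIN])
        assert len(recs) == 1 and recs[0].exceeds is False

    def test_curve_above_anywhere_is_flagged(self):
        strains, post, fits = self._setup(shift=+4.0)
        recs = tabulate_exceedance(strains, post, fits, [self.BIN])
        assert recs[0].exceeds is True

    def test_flags_match_dense_grid_oracle(self, rng):
        """Exceedance flags agree with a brute-force 0.01 °C comparison."""
        bin_ = self.BIN
        q = QuantileParams(-6.0, 0.08, -1.5, -0.03, 0.975)
        fits = {bin_.label: {0.975: fake_quantile_posterior(q)}}
        for _ in range(25):
            shift = rng.uniform(-6, 5)
            strains, post, _ = self._setup(shift)
            recs = tabulate_exceedance(strains, post, fits, [bin_])
            s = strains[0]
            dense = np.arange(s.t_min, s.t_max + 0.005, 0.01)
            fitted = thermo_rate(
                celsius_to_kelvin(dense),
                StrainThermoParams(*mesophile_params(shift)),
                U,
            )
            oracle = bool(np.any(fitted > quantile_curve(dense, q)))
            assert recs[0].exceeds == oracle

    def test_strain_outside_bin_ignored(self):
        strains, post, fits = self._setup(0.0)
        cold_bin = TemperatureBin(-math.inf, 10.0, "<= 10")
        recs = tabulate_exceedance(strains, post, {"<= 10": fits[self.BIN.label]},
                                   [cold_bin])
        assert recs == []

    def test_missing_fitted_curve_warns_and_skips(self):
        strains, post, fits = self._setup(0.0)
        orphan = make_strain("ghost", [(30.0, 0.01), (37.0, 0.02), (44.0, 0.01)])
        with pytest.warns(UserWarning, match="no fitted curve"):
            recs = tabulate_exceedance(strains + [orphan], post, fits, [self.BIN])
        assert {r.strain_id for r in recs} == {"s1"}

    def test_flags_monotone_in_tau(self):
        """A strain above the high quantile is above the lower one too."""
        strains, post, _ = self._setup(+2.0)
        lo = QuantileParams(-8.085, 0.062, -5.293, -0.003, 0.5)
        hi = QuantileParams(-6.065, 0.085, -1.692, -0.024, 0.975)
        fits = {
            self.BIN.label: {
                0.5: fake_quantile_posterior(lo),
                0.975: fake_quantile_posterior(hi),
            }
        }
        recs = {r.tau: r.exceeds for r in
                tabulate_exceedance(strains, post, fits, [self.BIN])}
        if recs[0.975]:
            assert recs[0.5]


class TestMeanParameters:
    def _records(self, post, bin_, tau=0.975, flags=None):
        from thermospectrum import ExceedanceRecord

        flags = flags or {}
        return [
            ExceedanceRecord(sid, bin_.label, bin_.midpoint, tau, flags.get(sid, True))
            for sid in post.strain_ids
        ]

    def test_single_strain_cell_is_identity(self):
        post = fake_thermo_posterior(["a"], [mesophile_params()])
        bin_ = TemperatureBin(20.0, 50.0, "(20, 50]")
        table = mean_parameters_by_group(self._records(post, bin_), post,
                                         representative="mean")
        row = table.iloc[0]
        np.testing.assert_allclose(
            [row["C"], row["dHA"], row["n"], row["dCp"]], mesophile_params()
        )

    def test_two_strain_cell_averages(self):
        p1, p2 = mesophile_params(-1.0), mesophile_params(+1.0)
        post = fake_thermo_posterior(["a", "b"], [p1, p2])
        bin_ = TemperatureBin(20.0, 50.0, "(20, 50]")
        table = mean_parameters_by_group(self._records(post, bin_), post,
                                         representative="mean")
        assert table.iloc[0]["C"] == pytest.approx((p1[0] + p2[0]) / 2)

    def test_random_cells_match_brute_force(self, rng):
        ids = [f"s{i}" for i in range(6)]
        rows = [mesophile_params(float(rng.normal(0, 1))) for _ in ids]
        post = fake_thermo_posterior(ids, rows)
        bin_ = TemperatureBin(20.0, 50.0, "(20, 50]")
        flags = {sid: bool(rng.random() < 0.5) for sid in ids}
        flags[ids[0]] = True  # keep both groups non-empty deterministically
        flags[ids[1]] = False
        table = mean_parameters_by_group(
            self._records(post, bin_, flags=flags), post, representative="mean",
            aggregate="mean",
        )
        for group, want in (("exceedance", True), ("non_exceedance", False)):
            members = [i for i, sid in enumerate(ids) if flags[sid] == want]
            expect = np.mean([rows[i] for i in members], axis=0)
            got = table[table.group == group].iloc[0]
            np.testing.assert_allclose(
                [got["C"], got["dHA"], got["n"], got["dCp"]], expect
            )


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.arange(20.0)
        assert np.allclose(smoothing_spline_df(x, np.full(20, 3.7), df=5), 3.7)

    def test_linear_series_reproduced(self):
        x = np.arange(25.0)
        y = 2.0 + 0.5 * x
        for df in (2.5, 5, 10):
            np.testing.assert_allclose(smoothing_spline_df(x, y, df), y, atol=1e-8)

    def test_noisy_sine_smoothing_gain(self, rng):
        """df = 10 smooth is closer to the true sine than the raw series."""
        x = np.arange(47.0)
        truth = np.sin(x / 6.0)
        y = truth + rng.normal(0, 0.4, x.size)
        sm = smoothing_spline_df(x, y, df=10)
        assert np.var(sm - truth) < np.var(y - truth)

    def test_smooth_trends_short_series_warns(self):
        trend = pd.DataFrame(
            {
                "bin_midpoint": [20.0, 21.0, 22.0],
                "tau": 0.975,
                "group": "exceedance",
                "C": [16.0, 16.1, 16.2],
                "dHA": [7e4] * 3,
                "n": [300.0] * 3,
                "dCp": [60.0] * 3,
                "n_strains": [3] * 3,
            }
        )
        with pytest.warns(UserWarning, match="unsmoothed"):
            out = smooth_trends(trend, df=10)
        np.testing.assert_allclose(out["C"], trend["C"])

    def test_df_bounds_validated(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            smoothing_spline_df(x, x, df=1.0)
        with pytest.raises(ValueError):
            smoothing_spline_df(x, x, df=50.0)


class TestEnvelope:
    @staticmethod
    def _trend(rows):
        return pd.DataFrame(rows)

    def test_single_bin_envelope_equals_its_curve(self):
        row = {
            "bin_label": "(20, 50]", "bin_midpoint": 35.0, "tau": 0.975,
            "group": "exceedance", "C": 16.0, "dHA": 7e4, "n": 300.0,
            "dCp": 62.0, "n_strains": 4,
        }
        env = predict_envelope(self._trend([row]), U, 0.975)
        params = StrainThermoParams(16.0, 7e4, 300.0, 62.0)
        np.testing.assert_allclose(
            env.rates, thermo_rate(celsius_to_kelvin(env.temperatures), params, U)
        )

    def test_dominated_curve_does_not_alter_envelope(self):
        hi = {
            "bin_label": "A", "bin_midpoint": 35.0, "tau": 0.975,
            "group": "exceedance", "C": 16.0, "dHA": 7e4, "n": 300.0,
            "dCp": 62.0, "n_strains": 4,
        }
        lo = dict(hi, bin_label="B", C=12.0)  # e^-4 lower everywhere
        env_hi = predict_envelope(self._trend([hi]), U, 0.975)
        env_both = predict_envelope(self._trend([hi, lo]), U, 0.975)
        np.testing.assert_allclose(env_both.rates, env_hi.rates)

    def test_envelope_dominates_member_curves(self):
        rows = [
            {
                "bin_label": lab, "bin_midpoint": mid, "tau": 0.975,
                "group": "exceedance", "C": 16.0, "dHA": 7e4, "n": 300.0,
                "dCp": dcp, "n_strains": 2,
            }
            for lab, mid, dcp in (("A", 30.0, 55.0), ("B", 40.0, 62.0), ("C", 50.0, 70.0))
        ]
        env = predict_envelope(self._trend(rows), U, 0.975)
        T_K = celsius_to_kelvin(env.temperatures)
        for row in rows:
            params = StrainThermoParams(row["C"], row["dHA"], row["n"], row["dCp"])
            curve = thermo_rate(T_K, params, U)
            assert np.all(env.rates >= curve - 1e-12)
            assert np.any(np.isclose(env.rates, curve, rtol=1e-9))

    def test_missing_tau_rejected(self):
        row = {
            "bin_label": "A", "bin_midpoint": 35.0, "tau": 0.5,
            "group": "exceedance", "C": 16.0, "dHA": 7e4, "n": 300.0,
            "dCp": 62.0, "n_strains": 1,
        }
        with pytest.raises(ValueError):
            predict_envelope(self._trend([row]), U, 0.975)


class TestSpectrumSummary:
    def test_constructed_peak_recovered(self):
        coll = Collation([
            make_strain("cold", [(10, 0.001), (20, 0.004), (30, 0.002)]),
            make_strain("peak", [(30, 0.01), (42, 0.09), (50, 0.005)]),
            make_strain("hot", [(60, 0.002), (67, 0.02), (75, 0.004)]),
        ])
        out = spectrum_summary(coll, median_params=QuantileParams(*[-8.085, 0.062, -5.293, -0.003], 0.5))
        assert out.peak_temperature == 42
        assert out.secondary_peak_temperature == 67

    def test_monotone_rates_have_no_gap(self):
        pts = [(t, 1e-5 * math.exp(0.08 * t)) for t in range(0, 80, 4)]
        coll = Collation([make_strain("mono", pts)])
        # a median curve far below the data means no attenuated degrees
        low_median = QuantileParams(-20.0, 0.06, -18.0, -0.003, 0.5)
        out = spectrum_summary(coll, median_params=low_median)
        assert out.gap_interval is None

    def test_empty_collation_rejected(self):
        with pytest.raises(ValueError):
            spectrum_summary(Collation([]))
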