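"""Synthetic collations with the statistical structure of the real growth data.

The generator emulates a literature collation of temperature-dependent
specific growth rates: many strains, 1–30 observations each, rates spanning
several orders of magnitude between −10 and 122 °C, a bimodal distribution
of strain T_opt with a trough near 50 °C (the mesophile–thermophile gap),
and a Δ-shaped upper envelope peaking near 42 °C with a secondary structure
near 67 °C.

Strain curves are drawn from the master-reaction thermodynamic model: each
strain's ΔC_P is chosen so its modelled peak sits at a T_opt drawn from the
bimodal mixture, ΔH‡_A and n follow smooth trends in T_opt (activation
enthalpy rising, effective residue count falling with thermophilicity), and
the scaling constant C places the strain's peak rate a random depth below
the designed envelope.  Observed rates add square-root-scale Gaussian noise
with precision ψ, truncated to positive values by resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data_model import Collation, GrowthRecord, StrainCurve
from .thermo import (
    KELVIN_OFFSET,
    UniversalThermoParams,
    _log_rate_arrays,
    canonicalize_gauge,
    celsius_to_kelvin,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "GeneratorError",
    "generate_collation",
    "generate_quantile_testbed",
]


class GeneratorError(RuntimeError):
    """Raised when a configuration cannot produce valid positive rates."""


#: universal parameters used by the default generator; chosen inside the
#: model's prior box so that varying ΔC_P alone moves a strain's peak
#: smoothly from psychrophile to hyperthermophile temperatures.
DEFAULT_UNIVERSAL = UniversalThermoParams(dHstar=4400.0, dSstar=16.0, THstar=340.0, TSstar=350.0)


def _default_dha_trend(t_opt_c: np.ndarray) -> np.ndarray:
    """Activation enthalpy rising with thermophilicity (J/mol)."""
    return 62_000.0 + 280.0 * np.asarray(t_opt_c)


def _default_n_trend(t_opt_c: np.ndarray) -> np.ndarray:
    """Effective residue count falling with thermophilicity."""
    return np.clip(380.0 - 2.4 * np.asarray(t_opt_c), 60.0, None)


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic collation.

    The defaults mirror the structure of the real collation: 1627 strains,
    1–30 observations per strain, temperatures within [−10, 122] °C, strain
    T_opt bimodal with modes near 28 and 70 °C and a thinned trough between
    them, and a log-linear Δ-envelope with its apex at 42 °C (ascending
    slope 0.085 /°C, descending slope −0.024 /°C — the shape of the fitted
    97.5% quantile of the real data).  Peak rates of strains whose T_opt
    falls in the transition window are attenuated, which produces the gap
    of reduced maximum rates and the secondary structure near 67 °C.
    """

    n_strains: int = 1627
    points_per_strain: tuple[int, int] = (1, 30)
    points_mean: float | None = 6.7  # geometric draw, clipped; None = uniform
    temperature_limits: tuple[float, float] = (-10.0, 122.0)  # °C, hard clamp

    # T_opt mixture: two Gaussian components, truncated, then thinned in a
    # transition window to carve the density trough near 50 °C
    topt_means: tuple[float, float] = (28.0, 70.0)
    topt_sds: tuple[float, float] = (11.0, 7.0)
    topt_weights: tuple[float, float] = (0.78, 0.22)
    topt_bounds: tuple[float, float] = (-5.0, 100.0)
    gap_window: tuple[float, float] = (46.0, 64.0)
    gap_keep_prob: float = 0.35

    # designed Δ-envelope for peak rates (log-linear in T, apex at t_sup)
    envelope_t_sup: float = 42.0
    envelope_log_peak: float = -2.495  # log rate/min at the apex (~0.082/min)
    envelope_b: float = 0.085  # ascending slope per °C
    envelope_d: float = -0.024  # descending slope per °C
    rate_gap_window: tuple[float, float] = (45.0, 66.0)
    rate_gap_factor: float = 0.3  # peak-rate attenuation inside the MTG
    depth_scale: float = 1.2  # peak depths below the envelope: exp(−Exp(scale))

    # thermodynamic structure
    universal: UniversalThermoParams = field(default_factory=lambda: DEFAULT_UNIVERSAL)
    dha_trend: Callable = _default_dha_trend
    n_trend: Callable = _default_n_trend
    dha_jitter_sd: float = 2000.0
    n_jitter_sd: float = 12.0
    dcp_jitter_sd: float = 1.5
    psi: float = 1.0e4  # sqrt-scale observation precision (noise sd 0.01)
    viable_fraction: float = 0.01  # observations span where F >= this × peak

    def __post_init__(self) -> None:
        if self.n_strains <= 0:
            raise ValueError("n_strains must be positive")
        lo, hi = self.points_per_strain
        if not (1 <= lo <= hi):
            raise ValueError("points_per_strain must satisfy 1 <= lo <= hi")
        if self.psi <= 0:
            raise ValueError("psi must be positive")


@dataclass
class GroundTruth:
    """True parameters behind a generated collation."""

    strain_params: pd.DataFrame  # strain_id, C, dHA, n, dCp, t_opt_model, peak_rate
    universal: UniversalThermoParams
    psi: float
    t_sup_design: float

    def params_for(self, strain_id: str) -> pd.Series:
        return self.strain_params.set_index("strain_id").loc[strain_id]


def _envelope_log_rate(t_c: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    dt = np.asarray(t_c) - cfg.envelope_t_sup
    return cfg.envelope_log_peak + np.where(dt <= 0, cfg.envelope_b * dt, cfg.envelope_d * dt)


def _dcp_peak_map(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate modelled peak temperature (K) as a function of ΔC_P.

    The peak location of the master-reaction curve is governed almost
    entirely by ΔC_P (which sets where heat denaturation collapses the
    folded fraction), so a one-dimensional monotone table suffices to place
    strain peaks; it is inverted by interpolation.
    """
    dcp_grid = np.geomspace(6.0, 320.0, 140)
    T = np.arange(250.0, 400.0, 0.1)
    logF = _log_rate_arrays(
        T[None, :], 0.0, 70_000.0, 250.0, dcp_grid[:, None], cfg.universal.as_array()
    )
    peaks = T[np.argmax(logF, axis=1)]
    peaks = np.maximum.accumulate(peaks)  # enforce monotone for inversion
    return peaks, dcp_grid


def generate_collation(
    config: GeneratorConfig | None = None, seed: int | np.random.SeedSequence = 0
) -> tuple[Collation, GroundTruth]:
    """Generate a synthetic collation plus its ground truth.

    Deterministic under a fixed seed.  See :class:`GeneratorConfig` for the
    study conditions emulated by the defaults.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    u_vec = cfg.universal.as_array()
    peak_tab, dcp_tab = _dcp_peak_map(cfg)

    # --- strain T_opt: truncated bimodal mixture with a thinned trough -----
    topts = np.empty(cfg.n_strains)
    w = cfg.topt_weights[0] / sum(cfg.topt_weights)
    lo_b, hi_b = cfg.topt_bounds
    g_lo, g_hi = cfg.gap_window
    filled = 0
    while filled < cfg.n_strains:
        m = cfg.n_strains - filled
        comp = rng.random(m) < w
        draw = np.where(
            comp,
            rng.normal(cfg.topt_means[0], cfg.topt_sds[0], m),
            rng.normal(cfg.topt_means[1], cfg.topt_sds[1], m),
        )
        keep = (draw >= lo_b) & (draw <= hi_b)
        in_gap = (draw > g_lo) & (draw < g_hi)
        keep &= ~in_gap | (rng.random(m) < cfg.gap_keep_prob)
        kept = draw[keep]
        topts[filled : filled + kept.size] = kept
        filled += kept.size

    # --- strain parameters from the trends ---------------------------------
    target_K = topts + KELVIN_OFFSET
    dcp = np.interp(target_K, peak_tab, dcp_tab)
    dcp = np.maximum(dcp + rng.normal(0.0, cfg.dcp_jitter_sd, cfg.n_strains), 5.0)
    dha = np.maximum(
        cfg.dha_trend(topts) + rng.normal(0.0, cfg.dha_jitter_sd, cfg.n_strains), 1e4
    )
    n_res = np.maximum(
        cfg.n_trend(topts) + rng.normal(0.0, cfg.n_jitter_sd, cfg.n_strains), 50.0
    )

    # the model's parameters are only defined up to an exact gauge orbit
    # (see thermo.gauge_map); express the ground truth in the same canonical
    # gauge the fitter reports, so that recovery comparisons are meaningful
    u_vec, dcp, n_res, _ = canonicalize_gauge(u_vec, dcp, n_res)
    universal_canon = UniversalThermoParams.from_array(u_vec)

    t_lo_k, t_hi_k = (celsius_to_kelvin(t) for t in cfg.temperature_limits)
    grid = np.arange(t_lo_k, t_hi_k + 0.05, 0.1)
    noise_sd = 1.0 / math.sqrt(cfg.psi)

    strains: list[StrainCurve] = []
    truth_rows = []
    k_lo, k_hi = cfg.points_per_strain
    resp_pool = np.array(["aerobe", "anaerobe", "facultative_anaerobe", "microaerobe"])
    trop_pool = np.array(["autotroph", "heterotroph", "mixotroph"])

    for i in range(cfg.n_strains):
        logF0 = _log_rate_arrays(grid, 0.0, dha[i], n_res[i], dcp[i], u_vec)
        j_peak = int(np.argmax(logF0))
        t_opt_model_c = grid[j_peak] - KELVIN_OFFSET

        # scale the curve so its peak sits a random depth below the envelope
        log_env = float(_envelope_log_rate(t_opt_model_c, cfg))
        if cfg.rate_gap_window[0] < t_opt_model_c < cfg.rate_gap_window[1]:
            log_env += math.log(cfg.rate_gap_factor)
        depth = rng.exponential(cfg.depth_scale)
        C = log_env - depth - logF0[j_peak]
        logF = logF0 + C

        # observation temperatures: equally spaced over the viable range
        viable = np.flatnonzero(logF >= logF[j_peak] + math.log(cfg.viable_fraction))
        t_vlo, t_vhi = grid[viable[0]], grid[viable[-1]]
        if cfg.points_mean is None:
            k = int(rng.integers(k_lo, k_hi + 1))
        else:
            # right-skewed like real collations: many short curves, few long
            k = int(np.clip(rng.geometric(1.0 / cfg.points_mean), k_lo, k_hi))
        t_obs = np.linspace(t_vlo, t_vhi, k + 2)[1:-1] + rng.normal(0.0, 0.3, k)
        t_obs = np.clip(t_obs, t_lo_k, t_hi_k)

        sqrtF = np.exp(
            0.5 * _log_rate_arrays(t_obs, C, dha[i], n_res[i], dcp[i], u_vec)
        )
        eps = rng.normal(0.0, noise_sd, k)
        bad = sqrtF + eps <= 0.0
        for _ in range(1000):
            if not bad.any():
                break
            eps[bad] = rng.normal(0.0, noise_sd, int(bad.sum()))
            bad = sqrtF + eps <= 0.0
        else:
            raise GeneratorError(
                "noise level implies non-positive rates that cannot be resampled"
            )
        rates = (sqrtF + eps) ** 2

        sid = f"syn{i:05d}"
        records = [
            GrowthRecord(sid, float(t - KELVIN_OFFSET), float(r))
            for t, r in zip(t_obs, rates)
        ]
        strains.append(
            StrainCurve(
                sid,
                records,
                respiration=str(rng.choice(resp_pool, p=[0.45, 0.25, 0.25, 0.05])),
                trophic=str(rng.choice(trop_pool, p=[0.3, 0.6, 0.1])),
            )
        )
        truth_rows.append(
            {
                "strain_id": sid,
                "C": C,
                "dHA": dha[i],
                "n": n_res[i],
                "dCp": dcp[i],
                "t_opt_model": t_opt_model_c,
                "peak_rate": math.exp(logF[j_peak]),
            }
        )

    truth = GroundTruth(
        strain_params=pd.DataFrame(truth_rows),
        universal=universal_canon,
        psi=cfg.psi,
        t_sup_design=cfg.envelope_t_sup,
    )
    return Collation(strains), truth


def generate_quantile_testbed(
    a: float,
    b: float,
    c: float,
    d: float,
    tau: float,
    n: int,
    seed: int | np.random.SeedSequence = 0,
    t_range: tuple[float, float] = (-5.0, 105.0),
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Records whose true tau-quantile of log rate is exactly piecewise linear.

    Temperatures are uniform over ``t_range``; log rates are the piecewise
    line a + bT (below the branch intersection) / c + dT (above) plus
    Gaussian noise shifted so its tau-quantile is zero.  Returns
    (temperatures °C, rates per minute) suitable for the quantile fitter.
    """
    if not (b > 0 and d < 0):
        raise ValueError("need ascending slope b > 0 and descending slope d < 0")
    if n < 100:
        raise ValueError("need at least 100 records for a meaningful testbed")
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    from scipy.special import ndtri

    rng = np.random.default_rng(seed)
    t_sup = (c - a) / (b - d)
    T = rng.uniform(t_range[0], t_range[1], n)
    mu = np.where(T <= t_sup, a + b * T, c + d * T)
    eps = noise_sd * (rng.standard_normal(n) - ndtri(tau))
    return T, np.exp(mu + eps)
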