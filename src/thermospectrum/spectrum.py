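"""Combining quantile and thermodynamic fits into the growth-rate spectrum.

The pipeline: fit quantile curves within overlapping T_opt bins, flag
*exceedance strains* (strains whose fitted thermodynamic curve rises above a
bin's quantile curve somewhere inside the strain's observed temperature
range), average the thermodynamic parameters of exceedance and
non-exceedance strains per (bin, quantile), smooth those trends with cubic
smoothing splines at a stated effective degrees of freedom, and finally push
the smoothed exceedance-group parameters back through the thermodynamic
model to predict an upper envelope of growth rates per quantile — the
Δ-shaped spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .data_model import Collation, StrainCurve, TemperatureBin, make_bins
from .quantile import (
    QuantileMCMCConfig,
    QuantileParams,
    QuantilePosterior,
    fit_quantile,
    quantile_curve,
)
from .thermo import (
    StrainThermoParams,
    ThermoPosterior,
    UniversalThermoParams,
    _log_rate_arrays as _tm_log_rate,
    celsius_to_kelvin,
    thermo_rate,
)

__all__ = [
    "ExceedanceRecord",
    "Envelope",
    "SpectrumSummary",
    "fit_bin_quantiles",
    "tabulate_exceedance",
    "mean_parameters_by_group",
    "smoothing_spline_df",
    "smooth_trends",
    "predict_envelope",
    "spectrum_summary",
]

GRID_STEP = 0.1  # °C; finer than any reported temperature precision

PARAM_COLS = ("C", "dHA", "n", "dCp")


@dataclass(frozen=True)
class ExceedanceRecord:
    """Exceedance flag of one strain against one bin's quantile curve."""

    strain_id: str
    bin_label: str
    bin_midpoint: float
    tau: float
    exceeds: bool


@dataclass
class Envelope:
    """Predicted upper rate limit per grid point for one quantile level."""

    tau: float
    temperatures: np.ndarray  # °C, strictly increasing
    rates: np.ndarray  # per minute, strictly positive

    @property
    def peak_temperature(self) -> float:
        return float(self.temperatures[np.argmax(self.rates)])


@dataclass
class SpectrumSummary:
    """Headline geometry of a collation's rate spectrum."""

    peak_temperature: float  # °C of the global maximum observed rate
    secondary_peak_temperature: float | None  # restricted to records > 60 °C
    gap_interval: tuple[float, float] | None  # widest attenuated run in [42, 62]


def fit_bin_quantiles(
    collation: Collation,
    bins: "list[TemperatureBin] | None" = None,
    taus=(0.975,),
    config: QuantileMCMCConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    min_records: int = 30,
) -> dict[str, dict[float, QuantilePosterior]]:
    """Quantile fits per overlapping T_opt bin.

    Each bin's fit uses the records of all strains whose T_opt lies in the
    bin.  Bins with fewer than ``min_records`` records (or a degenerate
    temperature design) are skipped with a warning.
    """
    bins = bins or make_bins()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(bins) * len(list(taus))))
    out: dict[str, dict[float, QuantilePosterior]] = {}
    for b in bins:
        members = [s for s in collation.strains if b.contains(s.t_opt)]
        n_rec = sum(s.n_records for s in members)
        if n_rec < min_records:
            warnings.warn(f"bin {b.label}: only {n_rec} records, skipped", stacklevel=2)
            for _ in taus:
                next(children)
            continue
        fits = {}
        for tau in taus:
            child = next(children)
            try:
                fits[tau] = fit_quantile(members, tau, config, child)
            except ValueError as exc:
                warnings.warn(f"bin {b.label}, tau {tau}: {exc}", stacklevel=2)
        if fits:
            out[b.label] = fits
    return out


def tabulate_exceedance(
    strains: "list[StrainCurve]",
    thermo_post: ThermoPosterior,
    bin_fits: dict[str, dict[float, QuantilePosterior]],
    bins: "list[TemperatureBin] | None" = None,
    grid_step: float = GRID_STEP,
) -> list[ExceedanceRecord]:
    """Flag strains whose fitted curve rises above each bin's quantile curve.

    For every strain whose T_opt lies in a fitted bin, the posterior-mean
    thermodynamic curve is compared with the bin's posterior-mean quantile
    curve on a ``grid_step`` grid over the strain's observed temperature
    range; ``exceeds`` is true if the fitted curve is higher anywhere.
    Strains without a fitted thermodynamic curve are skipped with a warning.
    """
    bins = bins or make_bins()
    by_label = {b.label: b for b in bins}
    index = {sid: i for i, sid in enumerate(thermo_post.strain_ids)}
    out: list[ExceedanceRecord] = []
    for s in strains:
        i = index.get(s.strain_id)
        if i is None:
            warnings.warn(f"strain {s.strain_id}: no fitted curve, skipped", stacklevel=2)
            continue
        grid = np.arange(s.t_min, s.t_max + grid_step / 2, grid_step)
        fitted = thermo_post.fitted_curve(i, grid)
        for label, fits in bin_fits.items():
            b = by_label[label]
            if not b.contains(s.t_opt):
                continue
            for tau, post in fits.items():
                qcurve = quantile_curve(grid, post.mean_params)
                out.append(
                    ExceedanceRecord(
                        strain_id=s.strain_id,
                        bin_label=label,
                        bin_midpoint=b.midpoint,
                        tau=tau,
                        exceeds=bool(np.any(fitted > qcurve)),
                    )
                )
    return out


def _project_curve_params(
    t_grid: np.ndarray, curve: np.ndarray, universal: UniversalThermoParams
) -> np.ndarray:
    """Project a positive growth curve onto the master-reaction model.

    Least-squares fit of (C, ΔH‡_A, n, ΔC_P) to the curve on the log scale,
    restricted to temperatures where the curve is within four decades of its
    peak.  A dense noiseless curve pins all four parameters, which makes
    this projection the stable way to attach a parameter set to an ensemble
    of strains whose individual posteriors are ridge-shaped.
    """
    from scipy.optimize import least_squares

    u_vec = universal.as_array()
    keep = curve >= curve.max() * 1e-4
    T_K = celsius_to_kelvin(t_grid[keep])
    log_y = np.log(curve[keep])

    def resid(theta):
        C, ldHA, ln_n, ldcp = theta
        lf = _tm_log_rate(
            T_K,
            C,
            float(np.exp(np.clip(ldHA, 2.0, 14.0))),
            float(np.exp(np.clip(ln_n, 0.0, 8.5))),
            float(np.exp(np.clip(ldcp, -3.0, 7.0))),
            u_vec,
        )
        return np.clip(lf, -700.0, 700.0) - log_y

    best_cost, best = np.inf, None
    for dha0, n0 in ((60_000.0, 150.0), (75_000.0, 350.0), (90_000.0, 700.0)):
        x0 = np.array([0.0, math.log(dha0), math.log(n0), math.log(65.0)])
        # profile the log-scale intercept for a sane start
        x0[0] = float(np.mean(log_y - resid(x0) - x0[0])) if True else 0.0
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=400)
        except Exception:
            continue
        if np.isfinite(sol.cost) and sol.cost < best_cost:
            best_cost, best = sol.cost, sol.x
    if best is None:
        raise RuntimeError("curve projection failed")
    C, ldHA, ln_n, ldcp = best
    return np.array(
        [
            C,
            float(np.exp(np.clip(ldHA, 2.0, 14.0))),
            float(np.exp(np.clip(ln_n, 0.0, 8.5))),
            float(np.exp(np.clip(ldcp, -3.0, 7.0))),
        ]
    )


def mean_parameters_by_group(
    records: "list[ExceedanceRecord]",
    thermo_post: ThermoPosterior,
    representative: str = "anchor",
    aggregate: str = "median",
) -> pd.DataFrame:
    """Mean thermodynamic parameters per (bin, tau, group).

    Groups are ``exceedance`` and ``non_exceedance``.  ``representative``
    selects how a cell's parameter set is formed from its member strains:

    * ``anchor`` (default) — average the members' anchored point estimates
      (common-start penalized fits).  Individual strain posteriors are long
      ridges — the scaling constant trades off against the activation
      enthalpy and the folding exponent — so draws or marginal means from
      different strains mix incompatible ridge positions; the anchors all
      sit on the same branch, which keeps cell averages on the model
      manifold.
    * ``curve`` — average the members' posterior-mean growth curves and
      project the ensemble curve back onto the model.
    * ``best_fit`` — average each member's highest-density posterior draw.
    * ``mean`` — average the marginal posterior means.

    ``aggregate`` is ``median`` (default) or ``mean``.  The component-wise
    median coincides with the mean for one- and two-strain cells but is
    robust where a cell's membership straddles the mesophile–thermophile
    gap or includes strains flagged far from their own peak: the mean of
    such a cell invents parameters corresponding to no member, while the
    median stays with the majority.  Empty cells are omitted.
    """
    if not records:
        raise ValueError("no exceedance records to summarise")
    index = {sid: i for i, sid in enumerate(thermo_post.strain_ids)}
    if representative == "anchor":
        means = thermo_post.strain_anchor
    elif representative == "best_fit":
        means = thermo_post.strain_best_fit
    elif representative == "mean":
        means = thermo_post.strain_mean
    elif representative != "curve":
        raise ValueError(f"unknown representative {representative!r}")

    rows = []
    key = lambda r: (r.bin_label, r.bin_midpoint, r.tau, r.exceeds)
    cells: dict[tuple, list[int]] = {}
    for r in records:
        cells.setdefault(key(r), []).append(index[r.strain_id])
    curve_cache: dict[int, np.ndarray] = {}
    grid = np.arange(-10.0, 122.0 + 0.25, 0.5)
    for (label, mid, tau, exceeds), idxs in cells.items():
        if representative == "curve":
            for i in idxs:
                if i not in curve_cache:
                    curve_cache[i] = thermo_post.fitted_curve(i, grid, max_draws=120)
            ensemble = np.mean([curve_cache[i] for i in idxs], axis=0)
            try:
                block = _project_curve_params(grid, ensemble, thermo_post.universal_mean)
            except RuntimeError:
                warnings.warn(f"cell {label}, tau {tau}: projection failed, skipped",
                              stacklevel=2)
                continue
        elif aggregate == "median":
            block = np.median(means[idxs], axis=0)
        elif aggregate == "mean":
            block = means[idxs].mean(axis=0)
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        rows.append(
            {
                "bin_label": label,
                "bin_midpoint": mid,
                "tau": tau,
                "group": "exceedance" if exceeds else "non_exceedance",
                **dict(zip(PARAM_COLS, block)),
                "n_strains": len(idxs),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["tau", "group", "bin_midpoint"])
        .reset_index(drop=True)
    )


def _edf(x: np.ndarray, lam: float) -> float:
    """Effective degrees of freedom: trace of the smoothing-spline hat matrix."""
    n = x.size
    tr = 0.0
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        tr += float(make_smoothing_spline(x, e, lam=lam)(x[i]))
    return tr


def smoothing_spline_df(x, y, df: float) -> np.ndarray:
    """Cubic smoothing spline with a target effective degrees of freedom.

    The penalty weight is found by bisection so that the trace of the hat
    matrix equals ``df`` (between 2, a straight line, and n, interpolation);
    the smooth is returned evaluated at the input points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = xs.size
    if not (2.0 <= df <= n):
        raise ValueError(f"df must be in [2, n={n}], got {df}")
    lo, hi = -14.0, 14.0  # log10(lambda); edf decreases in lambda
    span = float(xs[-1] - xs[0])
    scale = span**3 / max(n, 1)  # natural penalty scale for the data spacing
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _edf(xs, scale * 10.0**mid) > df:
            lo = mid
        else:
            hi = mid
    lam = scale * 10.0 ** (0.5 * (lo + hi))
    out = np.empty_like(y)
    out[order] = make_smoothing_spline(xs, ys, lam=lam)(xs)
    return out


def smooth_trends(trend: pd.DataFrame, df: float) -> pd.DataFrame:
    """Spline-smooth each (tau, group, parameter) series across bin midpoints.

    Series with fewer than df + 1 distinct midpoints are returned unsmoothed
    with a warning.  The result carries a ``df`` column tagging the smooth.
    """
    out = trend.copy()
    for (tau, group), block in trend.groupby(["tau", "group"]):
        x = block["bin_midpoint"].to_numpy(dtype=float)
        if np.unique(x).size < df + 1:
            warnings.warn(
                f"tau {tau}, {group}: {np.unique(x).size} midpoints < df+1, "
                "series left unsmoothed",
                stacklevel=2,
            )
            continue
        for col in PARAM_COLS:
            out.loc[block.index, col] = smoothing_spline_df(
                x, block[col].to_numpy(dtype=float), df
            )
    out["df"] = df
    return out


def predict_envelope(
    smoothed: pd.DataFrame,
    universal: UniversalThermoParams,
    tau: float,
    temperatures=None,
    group: str = "exceedance",
) -> Envelope:
    """Predicted rate envelope for one quantile from smoothed parameter trends.

    Each bin contributes the master-reaction curve generated from its
    smoothed ``group``-parameters; the envelope is the pointwise maximum of
    those curves on a shared temperature grid.

    ``universal`` must be the universal block the trend parameters belong
    to: the posterior's ``anchor_universal`` for the default anchored
    representative (parameter values are gauge conventions, and evaluating
    them under a different gauge shifts every curve).
    """
    rows = smoothed[(smoothed["tau"] == tau) & (smoothed["group"] == group)]
    if rows.empty:
        raise ValueError(f"tau {tau} ({group}) absent from the smoothed trend table")
    if temperatures is None:
        temperatures = np.arange(-10.0, 122.0 + GRID_STEP / 2, GRID_STEP)
    temperatures = np.asarray(temperatures, dtype=float)
    T_K = celsius_to_kelvin(temperatures)
    env = np.zeros(temperatures.shape)
    n_used = 0
    for _, row in rows.iterrows():
        params = StrainThermoParams(
            C=float(row["C"]),
            dHA=max(float(row["dHA"]), 1e-9),
            n=max(float(row["n"]), 1.0),
            dCp=float(row["dCp"]),
        )
        curve = thermo_rate(T_K, params, universal)
        j = int(np.argmax(curve))
        if j == 0 or j == curve.size - 1:
            # a growth curve must peak inside the biokinetic range; curves
            # that do not are smoothing artefacts and are dropped
            warnings.warn(
                f"bin {row['bin_label']}: predicted curve peaks at the grid "
                "edge, dropped from the envelope",
                stacklevel=2,
            )
            continue
        env = np.maximum(env, curve)
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable bin curves for the envelope")
    return Envelope(tau=tau, temperatures=temperatures, rates=env)


def spectrum_summary(
    collation: Collation,
    median_params: QuantileParams | None = None,
    gap_window: tuple[float, float] = (42.0, 62.0),
    seed: int | np.random.SeedSequence = 0,
) -> SpectrumSummary:
    """Headline geometry: main peak, secondary peak, and the attenuation gap.

    * peak — temperature of the global maximum observed rate;
    * secondary peak — same, restricted to records above 60 °C (None if no
      such records);
    * gap — the widest run of whole degrees inside ``gap_window`` whose
      per-degree maximum observed rate falls below the 50%-quantile curve
      (degrees with no records carry no evidence and are not counted).
      ``median_params`` may supply the median curve; otherwise a short MCMC
      run fits it here.
    """
    if collation.n_records == 0:
        raise ValueError("empty collation")
    T = np.concatenate([s.temperatures for s in collation.strains])
    r = np.concatenate([s.rates for s in collation.strains])
    peak = float(T[np.argmax(r)])
    hot = T > 60.0
    secondary = float(T[hot][np.argmax(r[hot])]) if hot.any() else None

    if median_params is None:
        cfg = QuantileMCMCConfig(n_iter=6000, burn_in=2000)
        median_params = fit_quantile((T, r), 0.5, cfg, seed).mean_params

    lo, hi = gap_window
    degrees = np.arange(math.floor(lo), math.ceil(hi))
    attenuated = []
    for d in degrees:
        in_deg = (T >= d) & (T < d + 1)
        if not in_deg.any():
            attenuated.append(False)
            continue
        dmax = float(r[in_deg].max())
        attenuated.append(dmax < float(quantile_curve(d + 0.5, median_params)))
    # widest consecutive run of attenuated degrees
    best, cur, start, best_iv = 0, 0, None, None
    for d, flag in zip(degrees, attenuated):
        if flag:
            if cur == 0:
                start = d
            cur += 1
            if cur > best:
                best, best_iv = cur, (float(start), float(d + 1))
        else:
            cur = 0
    return SpectrumSummary(
        peak_temperature=peak,
        secondary_peak_temperature=secondary,
        gap_interval=best_iv,
    )
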