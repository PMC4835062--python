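# Methods

This note describes the models implemented in `thermospectrum`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## The data

The unit of analysis is a *collation*: a table of specific growth rates
(per minute) observed at known temperatures (°C), one row per
(strain, temperature, rate), with strain-level metadata on respiration and
trophic status. Strains are represented by anywhere from a single point to
a full thermal performance curve. Three cardinal temperatures are derived
per strain: `t_min` and `t_max` (observed extremes) and `t_opt`, the
temperature of the fastest observed growth (ties broken to the lowest tied
temperature, which is deterministic and conservative). Generation times g
are converted to rates as r = ln 2 / g, and all rates are normalised to
per-minute before analysis. Zero or negative rates are invalid — the
quantile model lives on the log scale — and are dropped with a report.

Strains eligible for the thermodynamic fit must have at least five records
and a *distinct peak*, operationalised as an interior maximum:
`t_min < t_opt < t_max`. This is the weakest testable reading of
"well-defined peak".

## Quantile curves

The upper structure of the rate spectrum is summarised by quantile curves
of the piecewise-exponential form

    r(T) = exp(a + b·T)   for T ≤ T_sup     (b > 0)
    r(T) = exp(c + d·T)   for T > T_sup     (d < 0)

where `T_sup = (c − a)/(b − d)` is the temperature at which the two
log-linear branches intersect — the apex of the fitted envelope. (A
printed form of this expression with the denominator reversed circulates;
it yields negative apex temperatures for any valid slopes and is treated
as a typo: the branch-intersection form reproduces the ≈42 °C apex implied
by the published coefficient tables.)

Fitting is Bayesian quantile regression: the working likelihood is the
asymmetric-Laplace density at level τ applied to log(rate), the canonical
likelihood whose mode is the check-loss (pinball) minimiser. The scale
parameter receives a diffuse gamma prior on its reciprocal and is updated
by an exact conjugate Gibbs step. The four curve parameters get Gaussian
priors — means (−6.5, 0.1, 1.0, −0.1), precisions 0.01 (sd 10, i.e. nearly
flat) — read as *precisions* for consistency with the thermodynamic
model's prior table. Proposals are random-walk Metropolis with a
Haario-style adaptive covariance (empirical chain covariance × 2.38²/4,
plus a Robbins–Monro global scale tuned to 23.4% acceptance during
burn-in). Proposals violating b > 0, d < 0, or pushing `T_sup` outside the
observed temperature range are rejected outright, so every retained draw
satisfies the constraints. Default chain: 50 000 iterations, 10 000
burn-in; all levels (50…97.5%) can be fitted by a joint driver that gives
each level an independent child seed.

Group contrasts (e.g. strains with T_opt ≤ 50 °C versus > 50 °C) pair
posterior draws across two independent fits and report a central credible
interval of the difference plus an *equality probability*,
2·min(P(diff > 0), P(diff < 0)), with ties split evenly. The two-sided
tail form is our declared definition; the original presentation of such
probabilities does not state one.

## Thermodynamic (master-reaction) model

Growth rate is modelled as a single rate-limiting enzyme-catalysed
reaction: an Arrhenius numerator multiplied by the equilibrium probability
that the enzyme is folded,

    F(T) = T·exp(C − ΔH‡_A/(R·T)) / (1 + exp(−n·ΔG_res(T)/(R·T)))

with per-residue folding free energy in the enthalpy–entropy-compensation
form

    ΔG_res(T) = ΔH* − T·ΔS* + ΔC_P·[(T − T_H*) − T·ln(T/T_S*)].

Strain-level parameters: C (log-scale constant), ΔH‡_A (J/mol, > 0),
n (effective residues, ≥ 1), ΔC_P (J/(K·mol-residue)). Universal
parameters: ΔH*, ΔS*, T_H*, T_S*, uniform on [3000, 7000] × [10, 30] ×
[320, 420]² . Protein stability is maximal at T_mes = T_H* − ΔH*/ΔC_P.
Observations enter on the square-root scale: √r ~ N(√F, ψ⁻¹) with a single
global precision ψ ~ Γ(10⁻³, 10⁻³). Strains are partially pooled within
*thermal groups* — quantile slices of the T_opt distribution (60 for a
full-size collation; desk-scale runs use enough groups to keep roughly a
dozen strains per group, matching the pooling strength of the full-scale
design). Group-level priors follow the published table, including the
10⁻⁸ and 10⁻⁶ precision scale factors on ΔH‡_A and n; ΔC_P gets a fixed
N(65, sd 100) prior with no pooling.

### Sampling

Per-strain blocks use Haario adaptive Metropolis (adaptation from
iteration 1000, covariance × 2.38²/4 + 10⁻¹⁰ jitter, per-strain
Robbins–Monro scale), vectorised across strains since strain blocks are
conditionally independent. Thermal-group means and precisions and ψ have
exact conjugate conditionals and are updated by Gibbs steps (truncated
normal and gamma) — a deliberate substitution for adaptive Metropolis on
those blocks, exact and faster-mixing. The universal block uses
adaptive-direction proposals (difference vectors sampled from a buffer of
the chain's own past universal states, scaled by 2.38/√8) mixed with a
5% "stepping-stone" independence proposal from the prior box.

### Exact gauge degeneracy

The exponent n·ΔG_res(T) is a linear combination of {1, T, T·ln T} only.
Consequently the transformation

    ΔH* → λΔH*,   ΔS* → λΔS*,   T_S* → T_S*′,
    T_H* → T_H* + (ΔH*/ΔS*)·ln(T_S*′/T_S*),
    n_j → n_j·s_j/λ,   ΔC_Pj → ΔC_Pj·λ/s_j,
    s_j = 1 + ΔC_Pj·(T_H*′ − T_H*)/ΔH*

leaves **every** modelled growth curve exactly unchanged (verified
numerically to 10⁻¹³). The universal parameters are therefore only
identified up to a two-parameter orbit; growth data can never pin all
four. The sampler exploits this constructively: a *ridge move* proposes
jumps along the orbit with the analytic Jacobian λ^(2−S)·Π n_j/n_j′, which
costs no likelihood evaluation and lets the chain traverse the
universal/strain trade-off that blocked updates cannot.

Because parameter values along the orbit are conventions, all posterior
draws (and the synthetic generator's ground truth) are reported in a
canonical gauge: T_S* moved to 385 K (the classical entropy-convergence
temperature) and the scale λ set so ΔS* = 20, stepping back toward the
identity wherever a support would be violated.

Two practical consequences, both documented because they shape what the
fits can and cannot deliver:

1. Individual strain posteriors for (C, ΔH‡_A, n) are long, curved ridges
   whenever a strain's rates are small relative to the square-root-scale
   noise (beyond the denaturation cliff the constant part of n·ΔG_res adds
   to ΔH‡_A exactly, and the T-part to C). Marginal posterior means then
   fall *off* the ridge and can regenerate absurd curves. Curve-level
   summaries therefore average F(T) over draws (the posterior-mean curve),
   and cross-strain parameter averaging uses *anchored point estimates*: a
   per-strain penalized least-squares pass from a common starting policy
   (ΔC_P pinned by the observed peak through the crossing equation
   ΔG_res(T_opt) ≈ 0, ΔH‡_A and n started at 70 kJ/mol and 250, weak
   quadratic penalties toward the start) so that every strain sits on the
   same branch of the ridge.
2. Recovery of strain-level n and ΔC_P from synthetic data is only
   meaningful modulo the gauge, and even in the canonical gauge the
   posterior is tilted along the orbit by the hierarchical priors (the
   scale-seeking Γ(10⁻³,10⁻³) precision priors favour compressed n), so
   truth frequently sits 2–4 posterior sd from the posterior mean for
   n and ΔC_P. C, ΔH‡_A and ψ recover reliably. This is a property of the
   model-plus-priors, not of the sampler; it is visible only because the
   ridge move explores the orbit honestly.

Initialisation is a stochastic search over the prior box (restricted to
the physical folding regime, T_H* < T_S* with a positive heat-capacity
bracket at the working temperatures, and to ΔH*/ΔS* ratios compatible
with the coldest observed peak), followed by alternating per-strain /
universal nonlinear least squares on the square-root scale. ψ starts at
its method-of-moments value under that fit.

## Spectrum reconstruction

1. **Binned quantile fits.** The T_opt axis is covered by 47 overlapping
   bins: (−∞, 30], (k, k+30] for k = 1…45, (75, ∞); membership is
   lower < T_opt ≤ upper. The 97.5% (or any) quantile curve is fitted to
   each bin's records; bins with fewer than 30 records are skipped with a
   warning.
2. **Exceedance.** A strain *exceeds* a bin's quantile curve when its
   posterior-mean fitted curve rises above the posterior-mean quantile
   curve anywhere on a 0.1 °C grid over the strain's observed range
   (existential rule, grid finer than any reported temperature precision).
3. **Trends.** Representative thermodynamic parameters of exceedance and
   non-exceedance strains per (bin, τ) cell, aggregating the anchored
   parameter sets (see above) by component-wise median; cells are omitted
   when empty. The median coincides with the mean for one- and two-strain
   cells but matters where a 30 °C-wide bin straddles the
   mesophile–thermophile gap: the mean of members from both sides invents
   a parameter set corresponding to no strain (its regenerated curve peaks
   *inside* the gap, taller than any member), while the median stays with
   the majority side. The same robustness absorbs the occasional strain
   flagged far from its own peak where a gap-straddling bin's descending
   quantile branch collapses.
4. **Smoothing.** Each (τ, group, parameter) series over bin midpoints is
   smoothed by a cubic smoothing spline whose penalty is tuned by
   bisection until the trace of the hat matrix equals the requested
   effective degrees of freedom (5 or 10); series with fewer than df+1
   midpoints are passed through unsmoothed with a warning.
5. **Envelope.** Each bin's smoothed exceedance-group parameters
   regenerate a master-reaction curve; the envelope is their pointwise
   maximum on a shared −10…122 °C grid. Curves that peak at the grid edge
   are smoothing artefacts (a growth curve must peak inside the biokinetic
   range) and are dropped with a warning. The pointwise maximum of a curve
   family is scalloped where neighbouring curves cross; "unimodal" for an
   envelope therefore means no competing peak above a 25% relative
   prominence, with the global maximum unique by construction.

The headline geometry of a collation (`spectrum_summary`) is defined
operationally: the main peak is the temperature of the single fastest
observed record; the secondary peak the same restricted to records above
60 °C; and the mesophile–thermophile gap the widest run of whole degrees
within [42, 62] °C whose per-degree maximum falls below the fitted median
curve (degrees with no records carry no evidence).

## Synthetic data

The generator emulates the statistical structure the analysis assumes.
Strain T_opt is drawn from a two-component Gaussian mixture (modes 28 and
70 °C, sds 11 and 7, weights 0.78/0.22, truncated to [−5, 100]) and
thinned to 35% inside the 46–64 °C transition window, producing the
density trough near 50 °C. Each strain's ΔC_P is set by inverting the
peak-temperature map of the master-reaction model (the peak location is
governed almost entirely by where heat denaturation collapses the folded
fraction), ΔH‡_A rises and n falls with thermophilicity
(62 000 + 280·T_opt J/mol; 380 − 2.4·T_opt residues, floors at 10 kJ and
60), with Gaussian jitter on all three. The generator's universal
parameters (ΔH* = 4400, ΔS* = 16, T_H* = 340, T_S* = 350 before
canonicalisation) were chosen inside the prior box so that ΔC_P alone
moves a strain's peak smoothly from psychrophile to hyperthermophile
temperatures; the textbook protein-folding values put the minimum
attainable peak near 58 °C and cannot host psychrophiles.

The scaling constant places each strain's peak a random depth
(exp(−Exponential(1.2))) below a designed log-linear Δ-envelope: apex
42 °C at 0.082 min⁻¹, ascending slope 0.085 /°C, descending slope
−0.024 /°C (the shape of the fitted 97.5% quantile of the real
collation), with peaks attenuated ×0.3 for T_opt inside 45–66 °C — which
carves the gap of reduced maximum rates and leaves a secondary peak near
67 °C. Observation counts per strain are a clipped geometric draw with
mean 6.7 (1–30 points, matching a literature collation's right-skewed
coverage); temperatures are equally spaced with jitter across the range
where the true curve is within 1% of its peak; rates are
(√F + ε)², ε ~ N(0, ψ⁻¹) with ψ = 10⁴ by default, resampling any
non-positive draws (truncation without a point mass at zero).

What the synthetic tests show: calibration of the quantile machinery,
internal consistency of the thermodynamic fit, and that the full pipeline
regenerates the designed Δ-shape. What they do not show: robustness to
real-data features the generator omits — irregular temperature designs,
heteroscedastic and non-Gaussian measurement error, correlated strains
(the same organism contributed by several studies), digitisation error,
and truncation at detection limits.

## Problem sizes and chain settings

Defaults target a full-size collation (quantiles 50 000 iterations;
thermodynamic fit 100 000 iterations, thinning 10, 60 groups). The
shipped tests and the acceptance script run sizes chosen to keep each
stage's Monte Carlo error comfortably inside the tolerance it is tested
against: quantile calibration at n = 2000 with 25 000 iterations;
parameter recovery on 30 strains / 3 groups with 60 000 iterations; and
the end-to-end spectrum on the generator's full default collation
(1627 strains, ≈630 eligible for the thermodynamic stage, 60 thermal
groups) with 16 000-iteration bin fits and a 40 000-iteration
hierarchical fit — about six minutes on one CPU. At this size the
envelope's apex is reproducible to ±3 °C across seeds; at a quarter of
the size the sparse exceedance cells make the apex location unstable.

## Known limitations

* The universal thermodynamic parameters are not identified from growth
  data (exact two-parameter gauge orbit above); reported values are
  canonical-gauge conventions.
* Strain-level n and ΔC_P inherit the orbit ambiguity and prior tilt;
  their absolute values should be read comparatively (trends with T_opt),
  not as protein properties.
* The envelope construction averages parameters across heterogeneous
  strains inside 30 °C-wide bins; its absolute height is a summary of the
  exceedance ensemble, not a fitted quantile.
* ψ is mildly biased low (~10–20%) at desk scale because hierarchical
  shrinkage inflates equilibrium residuals relative to a point fit; the
  bias shrinks with strain count.
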