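# Methods

## Model

SABRE describes receptor signaling as three sequential stages with
independent parameters. Binding follows a single ensemble-averaged
dissociation constant `Kd` (the ligand does not see separate affinities for
active and inactive conformations, so `Kd` is the constant measured in an
equilibrium binding assay). Activation is a conformational equilibrium:
a fraction `eps` of ligand-bound receptors and a fraction `eps_r0` of
ligand-free receptors are active, giving the active fraction

    f_act = (eps_r0*Kd + eps*L) / (L + Kd).

Transduction amplifies activation through a hyperbolic (odds-ratio)
transform with pathway gain `gamma`:

    f_resp = Lambda / (Lambda + 1/gamma),  Lambda = f_act/(1 - f_act),

algebraically `f_resp = f_act*gamma / (f_act*(gamma-1) + 1)`, taken as the
limit value 1 at `f_act = 1`. Composing the two stages and generalizing the
concentration terms with a Hill exponent `n` yields the closed form
implemented in `sabrefit.model.sabre_response`:

    f_resp = (eps*g*L^n + eps_r0*g*Kd^n)
             / ((eps*g - eps + 1)*L^n + (eps_r0*g - eps_r0 + 1)*Kd^n).

With `eps_r0 = 0` the observable curve is a Hill sigmoid with

    EC50 = Kd / (eps*gamma - eps + 1)^(1/n),
    Emax = eps*gamma / (eps*gamma - eps + 1),

so for a full agonist the gain is a pure left-shift of log10(gamma) decades
— the quantitative content of "receptor reserve". Monotonicity in
concentration is governed by the sign of `eps - eps_r0` (agonist, neutral
antagonist, inverse agonist).

The Hill exponent applies to the concentration-like terms of the composed
response only; `fraction_active` is exposed for `n = 1`, where it is a
physically meaningful intermediate.

### Nested ladder

Fixing parameters at canonical values collapses the general form through
strictly nested models: `n=1` (full), `eps_r0=0` (minimal two-state),
`gamma=1` (Emax), `eps=1` (Clark). `ModelSpec` encodes each parameter kind
as free or fixed together with its sharing group (per compound, per
pathway, per curve, global), and `reduce_model` reports the canonical rung
implied by a constraint set — defined as the rung of the most complex freed
parameter — plus the count of free kinds. Mixed sets (e.g. a freed Hill
slope with `gamma` still fixed at 1) therefore report the rung that first
admits their most complex freed parameter.

### Operational-model correspondence

The fixed-Kd ("special edition") operational model `f = alpha*tau*L /
((tau+1)*L + K_D)` is pointwise identical to the minimal two-state SABRE
curve under `K_D = Kd`, `tau = eps*(gamma-1)`, `alpha = gamma/(gamma-1)`,
with exact inverse `eps = tau*(alpha-1)`, `gamma = alpha/(alpha-1)`. Both
maps are singular at `gamma = 1` (resp. `alpha <= 1`) and raise rather than
return a limit, because the transform is genuinely undefined there. The
reverse map can produce `eps > 1` for arbitrary `(tau, alpha)`; such values
are returned unclipped with a warning since clipping would silently change
the curve.

## Fitting

`fit()` minimizes the unweighted sum of squared residuals on the 0–100 %
response scale over all curves jointly. Parameters are optimized on
transformed scales chosen for conditioning and constraint enforcement:
`log10 Kd` (box [-12, 0]), `eps` and `eps_r0` boxed to [0, 1], `log10 gamma`
(box [0, 6], the lower bound enforcing `gamma >= 1`), `log10 n` (box
[-1, 1], i.e. `n` in [0.1, 10]). The optimizer is trust-region reflective
least squares (via lmfit) with tolerances 1e-13. Initialization is
data-driven: per-compound `Kd` from the largest empirical half-maximum
crossing among that compound's curves (occupancy is never left of response),
`eps` from observed plateaus, `gamma` from the mean log-shift between the
(fixed or initialized) `Kd` and the empirical EC50 of the pathway's curves.
Five deterministic multi-starts (seeded log-normal perturbations of that
initialization; `seed` argument) guard against local minima.

Standard errors are asymptotic, from the Jacobian-based covariance at the
optimum, delta-method back-transformed to the natural scale; "±" values are
reported as standard errors, with 95 % normal-approximation intervals also
available. One pooled r² (SS_tot about the grand mean of all fitted points)
is reported per global fit. Responses exceeding 100 % in noisy data are fit
as-is, never clipped. Fits with `n_d <= n_p` are refused; non-convergence
raises an error carrying the best values seen.

### Gauge degeneracy of fully free response-only fits

With `eps_r0 = 0` and `n = 1`, a fit in which every `Kd`, `eps` and `gamma`
is free (efficacies constant per compound) has an exact one-parameter
degeneracy: for any `c > 0`,

    eps   -> eps / (eps + c*(1-eps))
    gamma -> c * gamma
    Kd    -> Kd * c / (eps + c*(1-eps))

leaves every model curve unchanged (plateaus and EC50s are invariant), so
response data alone determine only gamma *ratios* between pathways.
Measured (fixed) Kds break the degeneracy; without them the `gamma >= 1`
constraint makes the minimal-amplification point of the flat ridge the
canonical representative, and `fit()` normalizes every converged optimum to
it (the transform is exactly SSR-preserving) before a final repolish for a
consistent covariance. Practically this pins the least-amplified readout at
`gamma = 1` and makes multi-readout gain estimates reproducible instead of
landing arbitrarily along the ridge.

### Response versus occupancy

When occupancies are available (computed from measured Kds),
`fit_response_vs_occupancy` fits `f_resp = eps*gamma*f / (eps*(gamma-1)*f + 1)`
directly. Because `L = Kd*f/(1-f)` is a bijection, the residual surface is
identical to the concentration-space fit with the same fixed Kds, and the
two return the same estimates to optimizer tolerance. This operation
accepts `n_d = n_p` (a single (occupancy, response) point determines `gamma`
for a full agonist).

### Model comparison and identifiability

`nested_compare` applies the extra-sum-of-squares F test (default alpha
0.05) between strictly nested fits of the same data, implementing the rule
that the simplest adequate rung should be used. `identifiability_report`
flags fits with fewer than 5 data points per adjustable parameter
(guideline 5–10) and any parameter whose standard error exceeds its
estimate or could not be computed — the signature of an ambiguous fit.

## Simulated designs

`simulate()` generates `response% = 100*f_resp + N(0, noise_sd)` with
`noise_sd = 5` percentage points by default — an absolute-error reading of
"5 % random error", matching the visually uniform scatter of the published
simulated curves across the response range; a relative-error mode
(`noise_mode="relative"`) is exposed as an option. Each curve is sampled at
11 half-log-spaced concentrations spanning log EC50 ± 2.5 of that curve —
a declared default giving well-distributed coverage of baseline, transition
and plateau.

Presets encode the published parameter sets:

| preset | design |
|---|---|
| fig3 | 3 agonists, Emax-type (log EC50 −8/−7/−6; plateaus 100/90/60 %) |
| fig4 | as fig3 with Hill slopes 2.0 and 0.66 (two compounds) |
| fig5 | fig3 curves + measured log Kds −6.7/−6.6/−5.2 attached for fixed-Kd fitting |
| fig6 | 3 compounds (log Kd −6/−7/−5; eps 0.5/0.1/1.0) × 3 readouts (gamma 1/20/500) |
| fig8 | 2 pathways (gamma 4/20); compound 2 biased (eps 0.5 vs 0.1), others balanced |

Pairing choices within the presets: the full agonist carries log EC50 −8
and (in fig5) Kd −6.7 — the only assignment consistent with a shared gain
near 20, since a full agonist's response sits log10(gamma) decades left of
its occupancy. The fig5 design generates Emax-style curves but is fitted
with external Kds and one shared gamma; the generating curves are not
exactly consistent with a single gain, so the fit is a genuine
approximation (pooled r² ≈ 0.97, gain ≈ 20 across seeds) rather than a
round trip. The fig8 preset carries its generating Kds as the "measured"
table, mirroring the experimental biased-agonism design (2 gains + 6
efficacies free, n_p = 8).

What the generator does **not** emulate: real data's heteroscedastic and
correlated errors, plate/batch effects, baseline drift and normalization
error, ligand depletion, and occupancy thresholds at high receptor density.
Passing recovery tests therefore demonstrates correctness of the estimator
under the stated error model, not robustness to those real-world features.

## Biased agonism

`efficacy_ratio_bias` reports per-ligand efficacy ratios `eps_P1/eps_P2`
with first-order error propagation through the fit covariance; the 95 %
interval is formed on the log-ratio scale and a ligand whose interval
covers 1 is flagged unbiased. The efficacy scale of a pathway is anchored
only when some ligand is full-or-near-full agonist there (point estimate
≥ 0.9, or 95 % upper bound reaching 1 — the uncertainty-aware reading of
"close to full"); without an anchor on both pathways the `eps*gamma`
products are compared instead and rows are flagged scale-ambiguous.
`ddlog_emax_ec50` provides the conventional reference-ligand comparators;
for model-generated data with `n = 1` both ΔΔlog(Emax/EC50) and
ΔΔlog(tau/K_D) collapse to differences of log efficacy ratios (gamma and
Kd terms cancel ligand-wise), which the test suite asserts numerically.

## Numerical choices and limitations

- Saturation (`f_act = 1`, infinite concentration) is evaluated as the
  limit value, not an error; the occupancy inverse at `f_occup = 1` is a
  domain error (infinite concentration).
- Concentrations are molar throughout the API; reports display log10 M.
  Responses are dimensionless fractions internally; the 0–100 % convention
  lives only at the I/O boundary.
- CSV round trips preserve 12 significant digits.
- Problem sizes in the test suite and acceptance script (50 seeds per
  stochastic design, 11-point curves) were chosen as the smallest
  replication giving stable seed-medians for the reported quantities.
- Single-curve fits with free `Kd`, `eps` and `gamma` are structurally
  unidentifiable (the gauge above); the gauge normalization then reports
  the `gamma = 1` (Emax-equivalent) representative, consistent with the
  ladder principle of not claiming amplification that the data cannot
  support. Quantifying amplification requires either independent occupancy
  data or a multi-readout design.
- Estimates of very large gains from saturated readouts (e.g. the
  gamma = 500 readout) are plateau-insensitive and recovered only to within
  about half a log unit at the default noise level.
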