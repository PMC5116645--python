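# Methods

## The multi-resource production identity

For one resource *i* over a year, ANPP = available_i · ε_i · RUE_i holds by
definition of the absorption rate ε_i = absorbed_i/available_i ∈ (0, 1] and
the use efficiency RUE_i = ANPP/absorbed_i. Taking geometric means over the
three resources (light, water, nitrogen) preserves the factorisation:
with R_avail = (PAR · Ms · Ns)^{1/3}, ε = (ε_L ε_W ε_N)^{1/3} and
*m*RUE = (LUE · WUE · NUE)^{1/3},

    ANPP = R_avail · ε · mRUE

exactly, because each factor is the geometric mean of three quantities whose
per-resource products each equal ANPP. The geometric mean is the unique
power-mean choice with this property; the composite availability R_avail is
defined accordingly. All quantities are annual accumulations in g m⁻² yr⁻¹;
light measured in MJ m⁻² is converted by mass = energy·1000/caloric value
(default 19.38 kJ g⁻¹, the caloric value of semi-arid grassland dry matter).
Note the asymmetry in ranges: ε_i is a fraction in (0, 1], but RUE_i is a
ratio of production to absorbed mass and can greatly exceed 1 (grassland
NUE is of order 60); the package therefore enforces the (0, 1] bound only
on absorption rates. Zero or negative measurements are rejected at
ingestion (a strictness flag downgrades this to drop-with-warning), never
clamped.

## Path model

The structural model is observed-variable only: endogenous y (absorbed
light, nitrogen uptake, ε, *m*RUE), exogenous x (soil water Ms,
transpiration Tr), y = By + Gx + ζ with exogenous covariance Φ and error
covariance Ψ. B may contain cycles — the ε ⇄ *m*RUE feedback is the case of
interest — and the implied covariance uses (I−B)⁻¹, which exists whenever no
feedback loop has coefficient product 1. Fitting minimises the ML
discrepancy F_ML = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p with L-BFGS-B on the
free parameters, five jittered starts (seeded) to guard against local
minima in non-recursive topologies, and an explicit non-convergence flag.
χ² = (n−1)F_ML; GFI, AGFI, NFI, RMSEA and the χ² tail probability follow
the standard covariance-structure formulas (AGFI and RMSEA are NaN at
df = 0). Fits are standardized by default (performed on the correlation
matrix), since path coefficients are conventionally reported as
standardized β. Per-equation R² is 1 − ψ_ii/σ̂_ii.

**Stability.** The stability index is the maximum over directed cycles of
|∏ coefficients| around the cycle (0 for acyclic B); a model is stable when
it is below 1. For the two-edge loop with β = 0.23 and −0.11 this gives
0.0253 → 0.025 at two significant figures. The spectral-radius alternative
(`method="eigenvalue"`) gives √(0.23·0.11) ≈ 0.159 for the same loop; the
loop-product convention is the default because it is the one under which
the reported index is reproduced, and its sign is dropped (only the
magnitude is meaningful for stability).

**Effect decomposition.** Two conventions are provided and documented to
differ exactly by feedback amplification: "path-sum" (default) sums
coefficient products over simple directed paths, which is the arithmetic of
standard effect tables (e.g. a transpiration → nitrogen-uptake → *m*RUE
indirect effect of 0.32 × 0.66 = 0.21); "series-limit" uses (I−B)⁻¹G and
(I−B)⁻¹ − I, which additionally count walks revisiting loops and require
spectral radius below 1. On acyclic models the two agree to machine
precision (tested). A `mediators` argument restricts path-sum transmission
to paths through a named set of intermediaries — the "indirect effect via
light and nitrogen" style of reading an effect table. Edges reported as
statistically insignificant (here ε → *m*RUE, P = 0.387) are excluded from
the reference decomposition topology by default (`include_ns=False`), the
convention under which the reported two-step products emerge; the full
topology with the feedback loop is retained for fitting and stability.

**Normality diagnostics.** Per-variable moment skewness and kurtosis (raw
b₂ scale, normal reference 3) and Mardia's multivariate b₁,p and b₂,p with
their asymptotic χ² and normal references. b₁,p is computed from the
third-moment tensor of the whitened data (‖M₃‖² identity), which is O(np³)
instead of the O(n²p) pairwise form and so remains cheap at large n.

## LMG relative importance

share_k = Σ_{S ⊆ P\{k}} |S|!(p−1−|S|)!/p! · (R²(S∪{k}) − R²(S)), computed
by enumerating the 2^p subset R² values (exact; capped at p = 12 with a
clear error, ample for the 2–3 predictors used here). Shares are
non-negative, sum to the full-model R², and are invariant to predictor
ordering; percentages normalise by the total R². Inputs are used as
supplied — the pipeline log-transforms upstream, so shares refer to the
log-scale regression (importance percentages are scale-sensitive, and the
log scale is the one on which all analysis here is performed).

## Spurious-correlation Monte Carlo

The seven experiment variables are treated as independent normals with the
experiment's measurement-scale means and SDs — aPAR (10, 0.3), PAR
(11, 0.04), Tr (13, 0.3), Ms (15, 0.2), N_uptake (1.2, 0.05), N_avail
(3.7, 0.17), ANPP (5.3, 0.4) — with non-positive draws rejection-resampled
(they enter logs; the rate is negligible at these CVs and an error is
raised above 10%). Per replicate (n = 126, 1000 replicates by default) the
composites are computed directly from the draws,
ε = ((aPAR/PAR)(Tr/Ms)(N_uptake/N_avail))^{1/3} and
*m*RUE = ANPP/(aPAR·Tr·N_uptake)^{1/3}, and the squared Pearson correlation
between log(common variable) and log(composite) is recorded; the reported
central value is the mean of the per-replicate sample R², which includes
the finite-sample bias and is the quantity a practitioner would observe.
Correlating raw instead of log values changes each pair's mean R² by less
than 0.01 at these CVs (tested); both options are exposed.

**Analytic oracle.** Because each composite is an exact product of powers,
its log is a weighted sum of input logs, so under independence the
population correlation with a shared variable is exactly
ρ = w_c σ_c / √(Σ_v w_v² σ_v²), with σ_v the SD of log X_v (computed by
Gauss–Hermite quadrature over the positive-truncated normal; the delta
method σ_v ≈ sd/mean is its leading order and the approximation is only
meaningful for CV < 0.5, warned beyond). The expected sample R² then uses
the exact bivariate-normal mean of a squared sample correlation,
1 − (n−2)/(n−1)(1−ρ²)·₂F₁(1, 1; (n+1)/2; ρ²), which reduces to
ρ² + (1−ρ²)²/n to leading order and to 1/(n−1) under independence. The
Monte Carlo means agree with this oracle within twice their standard error
for every reported pair, and a variable absent from a composite reproduces
the 1/(n−1) independence baseline.

**Sensitivity scans.** The generic scan setting uses a common variable A
and an independent variable B, mean 20, n = 200, base SD(A) = 1, and a
two-variable ratio composite (A/B for the ε-type, B/A for the *m*RUE-type;
the spurious R² is identical either way, being A's share of the composite's
log variance). Scaling both SDs jointly leaves the correlation unchanged;
raising SD(B) relative to SD(A) shrinks it monotonically; varying n at
fixed SDs leaves the mean unchanged while the replicate spread contracts.
Scenario groups are compared with all-pairs Welch t-tests under Holm
family-wise correction and summarised as a connected-letter display
(maximal cliques of the not-significantly-different relation); the test
choice is a documented convention and swappable.

## Synthetic experiment generator

The generator emulates the randomized-block water-gradient design: 7
precipitation levels (−60% … +60% of a 380 mm ambient), 6 blocks, 3 years,
126 plot-year records. Variables are generated on the log scale (positive,
multiplicative, variance-homogenised by logs) from a standardized
precipitation driver x_p = log(1+δ)/s, where s is the design RMS of
log(1+δ) — the driver is zero at ambient, so noiseless control plots sit
exactly at the baseline log-means. Soil water and transpiration respond to
the driver (default sensitivity 0.8 each) and carry additive block- and
year-intercepts (SD 0.1 each, small against residual noise); nitrogen
uptake follows transpiration (0.32), absorbed light follows soil water
(0.58) and nitrogen uptake (0.35) — the reported resource-coupling
coefficients — and ANPP is log-linear in (Tr, aPAR, N_uptake, Ms) with
default loadings (0.35, 0.30, 0.20, −0.35) chosen so that water raises the
absorption composite while depressing the efficiency composite (surplus
water buys less production per unit absorbed). Each equation's residual SD
is set so its variable has approximately unit variance on the standardized
log scale, making the structural coefficients directly comparable to
fitted standardized β; log-means and log-SDs default to the experiment's
variable settings, whose exponentials give control-plot magnitudes
(ANPP ≈ 200 g m⁻², ε_L ≈ 0.37, ε_W ≈ 0.13, ε_N ≈ 0.08) matching the
reported grassland. `calibrate_to_control` shifts the absorbed/production
baselines in closed form (absorbed_i = ANPP/RUE_i) to hit reported
control-plot efficiencies exactly, erroring if the targets would push an
absorption fraction out of (0, 1).

Rows whose tail draws would put an absorbed quantity above its availability
are redrawn (a hard physical bound; at the default one-log-unit baseline
separations this affects of order 0.05% of rows and does not meaningfully
truncate any distribution); a parameter set that violates the bound at
baseline, or persistently in the tails, raises with the offending resource
named. What the generator does **not** emulate: sub-annual accumulation
(annual totals are drawn directly), any mechanistic rainfall-to-soil-water
mapping (the log-linear response is a placeholder), measurement error
distinct from process noise, or spatial autocorrelation among plots.
Passing tests therefore demonstrate that the estimators recover known
structure under the stated stochastic model — not that the real system has
that structure.

## Numerical choices and problem sizes

Geometric means are computed in log space. Reported-value comparisons round
as published: two decimals for β, three for indices, two significant
figures for the stability index. The parameter-recovery check pools ten
generated tables (n = 1260) and requires each resource-coupling coefficient
back within ±0.05; the single-edge recovery check uses n = 10 000 within
±0.02. Monte Carlo checks use 1000 replicates of n = 126 (the design size);
the sample-size scan runs 1000 replicates at each of n = 500–10 000,
vectorised. All randomness flows through seeded `numpy` generators; every
artifact records its seed and config hash, and identical configurations
rerun byte-identically.

## Known limitations

* The ML fitter targets small observed-variable models (≤ ~10 variables);
  it uses numerical gradients and makes no attempt at analytic derivatives,
  latent variables, multi-group fitting, bootstrap errors or modification
  indices.
* The stability index enumerates simple cycles, which is exponential in
  pathological dense graphs; path-sum decomposition likewise enumerates
  simple paths. Both are instantaneous at the model sizes this package
  addresses.
* The spurious-R² oracle assumes independent inputs and near-normal logs;
  it is a check on the Monte Carlo, not a substitute for it under
  correlated or heavy-tailed inputs.
* LMG enumeration is exact but exponential in p; it is capped at p = 12.
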