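# mrue — multiple-resource-use-efficiency modelling

Ecosystem production is often analysed one resource at a time: water-use
efficiency (WUE = ANPP/Tr), light-use efficiency (LUE = ANPP/aPAR), nitrogen-use
efficiency (NUE = ANPP/N_uptake). `mrue` implements the joint, multi-resource
formulation and the statistical machinery needed to use it honestly:

* **Composite indices.** For each resource *i*, annual aboveground net primary
  production factorises as ANPP = R_avail,i · ε_i · RUE_i, where
  ε_i = absorbed/available is the absorption rate and RUE_i = ANPP/absorbed the
  use efficiency. Across *n* resources the geometric means
  *m*RUE = (∏ RUE_i)^{1/n} and ε = (∏ ε_i)^{1/n}, together with the geometric-mean
  available resource R_avail, preserve the identity ANPP = R_avail · ε · *m*RUE
  exactly. Light is carried in mass-equivalent g m⁻² (MJ m⁻² divided by the
  plant caloric value, default 19.38 kJ g⁻¹ for semi-arid grassland).
* **Non-recursive path analysis.** Observed-variable structural models
  y = By + Gx + ζ fitted by maximum likelihood
  (F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p), allowing directed feedback loops such
  as ε ⇄ *m*RUE; fit indices (χ², GFI, AGFI, NFI, RMSEA), a loop stability
  index, and direct/indirect/total effect decomposition in both the
  path-sum and (I−B)⁻¹ series-limit conventions.
* **LMG relative importance.** Exact decomposition of a regression R² into
  per-predictor shares by averaging sequential R² increments over all
  predictor orderings.
* **Spurious-correlation Monte Carlo.** Because ε and *m*RUE are ratios of the
  very variables they are correlated against, part of any observed R² is
  arithmetic, not ecology. Replicated simulations of independent normal
  inputs quantify that spurious R², with a closed-form oracle and
  sensitivity scans over SDs, SD ratios and sample sizes.
* **Synthetic experiment generator.** A randomized-block precipitation
  gradient (7 levels from −60% to +60% of 380 mm ambient × 6 blocks ×
  3 years, n = 126) with log-scale structural relations among water, light,
  nitrogen and production, so the full pipeline is testable end to end.

## Worked example

```bash
$ mrue generate --out records.csv --seed 1
wrote records.csv (126 records)

$ mrue fit records.csv --seed 1
chi2=0.905 df=3 p=0.824 GFI=0.998 RMSEA=0.000 stability=0.005 converged=True

$ mrue relimp records.csv
total R2=1.0000; wue=33.00%, lue=34.68%, nue=32.32%

$ mrue spurious --common N_uptake --composite eps --seed 1
N_uptake~eps: mean R2=0.3168 (MC-SE 0.00210)
```

Reading the output: the generated 126-record table is fitted with the
six-variable path model (soil water Ms and transpiration Tr exogenous;
absorbed light, nitrogen uptake, ε and *m*RUE endogenous); χ² = 0.905 on
3 df (p = 0.824) with GFI ≈ 1 says the generating topology is recovered
cleanly, and the stability index 0.005 ≪ 1 says any fitted feedback is far
from divergence. The LMG step confirms that log *m*RUE is exactly explained
(R² = 1) by its three log components, splitting importance roughly evenly
for this parameterisation. The last line is the headline caution of the
method: even with **independent** inputs at the experiment's means and SDs,
nitrogen uptake and ε share enough arithmetic that their expected R² is
≈ 0.32 — a bivariate correlation of that size carries no ecological
information.

`mrue pipeline --seed 1` runs the whole chain and writes five CSV artifacts
plus a flat `summary.txt`, each stamped with the seed and config hash;
rerunning the same configuration is byte-identical. The other subcommands
are `compute`, `decompose`, and `scan` (sensitivity scans with
connected-letter significance groupings).

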