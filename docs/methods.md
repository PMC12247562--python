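# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `netgrowth`. Everything quantitative here
is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not verify.

## The growth model and its estimation

Within-network RSFC T-scores over five occasions are modelled by latent
growth curves: `y_i = Λ η_i + ε_i` with `η_i ~ N(α + Γ x_i, Ψ)` and
`ε_i ~ N(0, θ I)`. Loadings are fixed — intercept `(1,1,1,1,1)`, linear
slope at the elapsed years `(0,1,2,4,7)`, quadratic slope at their squares
`(0,1,4,16,49)` — so the latent factors are interpretable as baseline
level and yearly (and yearly-squared) change in T-score units. Residual
means are zero and one residual variance θ is shared across occasions.
Covariates are baseline age (mean-centered, years), sex (0 = female,
1 = male) and education coded `{-1, 0, 1}` with 0 = medium level (a
3-level coding chosen here; only the midpoint anchoring is standard).

Five variants span the complexity range:

| variant | factors | free Ψ | covariate paths | free params |
|---|---|---|---|---|
| 1 | int + lin | none | none | 3 |
| 2 | int + lin | var(int) | → int | 7 |
| 3 | int + lin | var(int), var(lin), cov | → int, lin | 12 |
| 4 | int + lin + quad | var(int) | → int | 8 |
| 5 | int + lin + quad | all vars + covs | → all | 19 |

**FIML.** Each subject contributes the Gaussian log-density of their
observed occasions under the marginal of the implied moments
`Σ = Λ Ψ Λᵀ + θI`, `μ_i = Λ(α + Γ x_i)` — the standard treatment under
missing at random. Subjects are grouped by missingness pattern; because
mean and covariance are both *linear* in the free parameters, the analytic
gradient reduces to a handful of small matrix products per pattern.

**Optimization.** Variances enter untransformed (no log link) so that
inadmissible solutions — negative variances or latent correlations outside
[−1, 1] — can occur and be *detected* (Heywood flag) rather than silently
prevented, mirroring common SEM practice. Start values come from
available-case method of moments. L-BFGS runs to a moderate tolerance and
a Newton polish with the observed-information Hessian (finite differences
of the analytic gradient) drives the max-abs gradient of the per-subject
objective below 1e-8; typical fitted gradient norms are ~1e-10. The same
Hessian supplies standard errors (inverse observed information) and
`estimate ± 1.96·SE` confidence intervals. Non-positive-definite implied
covariances during line search receive a large penalty proportional to the
eigenvalue violation.

**Baselines and fit indices.** The saturated model frees the five occasion
means and the full 5×5 covariance (20 parameters); when the candidate
model includes covariates it additionally frees all 15 per-occasion
covariate slopes (35 parameters, the fixed-x convention of mainstream SEM
software), so a 12-parameter covariate model has df = 23 while a
3-parameter no-covariate model has df = 17. The independence baseline
frees means and variances only. Indices follow the usual definitions:
`χ² = 2(ll_sat − ll_m)`, `CFI = 1 − max(χ²_m − df_m, 0)/max(χ²_b − df_b,
χ²_m − df_m, 0)`, `RMSEA = sqrt(max(χ²_m − df_m, 0)/(df_m·n))` with n =
subjects contributing any data, `BIC = −2 ll + k ln n`. RMSEA at df = 0 is
reported as 0 with a flag.

**Selection.** Converged, non-Heywood fits compete on the count of "good"
indicators (χ²/df ≤ 2, p > .05, CFI > .97, RMSEA ≤ .05, plus absence of a
Heywood case); ties break toward the smallest BIC. The "acceptable" band
(χ²/df ≤ 3, p > .01, CFI > .95, RMSEA ≤ .08) is computed for reporting but
plays no role in selection. Parameter p-values are left at 5% with no
multiplicity correction — correcting them per model would confound atlas
differences with correction differences.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical* structure the analysis
assumes, with defaults mirroring a healthy-aging panel design:

- **Panels**: 5 occasions at years (0,1,2,4,7); default truth has
  intercept 50, slope 0.4, Ψ = diag(25, 1), θ = 4 (T-score metric), an age
  effect of −0.28 T/year on the intercept, and monotone covariate-
  independent dropout at 15% per wave (≈ the retention profile of a
  7-year cohort that keeps roughly half its baseline sample). An optional
  age-dependent dropout mode stresses the MAR assumption.
- **Parcellations**: breadth-first region growing on a Fibonacci-lattice
  unit sphere yields contiguous, roughly equal-sized parcels at two
  granularities (networks, nodes). `coverage < 1` leaves part of the
  surface unlabeled, as real network atlases do (omitted structures);
  this partial coverage is what gives the spin test its contrast — under
  full coverage the network mean of a fixed map is nearly
  rotation-invariant. `perturb_parcellation` reassigns a controlled
  fraction of elements to other networks, producing atlas pairs with
  tunable Dice overlap.
- **BOLD**: node-latent plus element-noise signals; with unit noise SD the
  expected within-node element correlation equals `within_node_r` exactly,
  and an optional network-level latent gives nodes of one network
  correlation `within_network_r` (what the silhouette responds to).
- **Motion**: AR(1) six-parameter traces whose per-scan amplitude is drawn
  uniformly within ±40% of a 0.05 mm / 5e-4 rad base. The bounded
  amplitude distribution matters: the `median + 3·MAD` rule is scale-free,
  and any Gaussian-tailed amplitude would flag ≈2% of clean scans no
  matter the scale. Outlier scans are inflated 10×.

Not emulated: hemodynamics, scanner noise spectra, two-hemisphere
anatomy, cortical folding, spatially varying ReHo baselines, and
between-network anticorrelations. Passing tests therefore demonstrate the
*statistical machinery* — estimation, selection, nulls, pooling — not
fidelity to any particular empirical dataset.

## Overlap, diagnostics, pooling: conventions

- **Dice** uses the intersection form `2|A∩B|/(|A|+|B|)`; both-empty masks
  are an error, a network empty in one variant yields a flagged row.
- **Rank-sum** reports the Mann–Whitney U of the first sample; p is exact
  (permutation distribution) for ≤25 combined observations without ties,
  else the tie-corrected normal approximation without continuity
  correction (so the two-group Kruskal–Wallis decision coincides).
- **KCC/ReHo** ranks each series over time (midranks for ties, no further
  tie correction) and applies
  `W = (ΣR_i² − n R̄²) / ((1/12) K² (n³ − n))`. Neighborhoods are the
  element plus its mesh neighbors (or 26-connected voxels); boundary
  elements use the neighbors that exist with K adjusted, isolated elements
  are masked. Network ReHo is the unweighted mean over member nodes of
  node means.
- **Silhouette** uses dissimilarity `1 − r`; `a_i` averages over
  same-network nodes (divisor n_k − 1), `b_i` over the single closest
  other network; nodes of singleton networks are excluded with a warning.
- **Spin test** applies uniform random 3D rotations; each vertex takes the
  labels of its nearest rotated vertex, approximately preserving parcel
  shapes and sizes. p uses the add-one rule `(1 + #{null ≥ emp})/(1 + R)`
  so it is never exactly zero (R = 100 rotations by default). The rotated
  atlas's nodes are reassigned to networks by majority for the silhouette
  null; spatially autocorrelated nulls make that test conservative.
- **Node-to-network assignment** across incompatible parcellations goes by
  arg-max Dice; exact ties break toward the lowest network label.
- **Pooling** is fixed-effect inverse variance (`w = 1/SE²`); pooling is
  attempted only where all atlases' selected models agree on trajectory
  shape, and an effect pools only if its parameter (with finite SE) exists
  in every selected model. No random-effects model or heterogeneity
  statistics.
- **T-scores** are standardized per atlas × network stratum against the
  baseline mean and sample SD across subjects with a non-missing baseline;
  subjects lacking baseline get the same stratum constants. Per-stratum is
  the only reading that yields mean 50 / SD 10 at baseline for every
  dataset.

## Problem sizes

Defaults were chosen so every simulation is statistically informative at
interactive cost on one core: recovery and selection studies use n = 300
subjects with 50–100 replicates; spin tests use a 642-vertex hemisphere
with 100 rotations; the full pipeline demo uses 150 subjects, four atlas
variants and three networks. All generators scale up by argument.

## Known limitations

- FIML assumes multivariate normality and MAR; the age-dependent dropout
  mode can violate MAR informatively, and no sensitivity analysis is
  built in.
- The saturated model is fit by optimization (no closed form under
  arbitrary missingness); with very small n or extreme missingness it may
  fail to converge, which propagates as "fit indices unavailable" and
  disqualifies the dataset's candidates honestly rather than silently.
- `pool_study` keys trajectory shape on the selected variant's factor
  count only (linear vs quadratic), matching the selection rule's own
  granularity.
- Spin nulls operate on a single synthetic hemisphere; there is no
  mirrored two-hemisphere mode, and real-surface (FreeSurfer) geometry is
  out of scope.
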