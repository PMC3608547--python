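# Methods

## Model

One observation is one reported effect size, converted to Fisher's
*Z*: `y_i = atanh(r_i)` with known sampling variance `v_i = 1/(n_i − 3)`.
The meta-regression is the Gaussian mixed model

```
y_i = x_i'β + u_class(i) + u_family(i) + u_species(i) + u_study(i) + m_i + e_i
u_k  ~ N(0, σ²_k)        per level of each random factor
m_i  ~ N(0, v_i)         measurement effect, variance FIXED at v_i
e_i  ~ N(0, σ²_units)    residual ("units") variance, estimated
```

The nested random factors (study in species in family in class) absorb
the non-independence of multiple effect sizes per study and of related
species; genus and order are omitted because comparative datasets of
this shape carry no replication at those levels.  Fixing the
measurement variance at `v_i` is what "weighting by inverse variance"
means in a mixed-model meta-analysis: precise studies constrain the
latent effect tightly, imprecise ones loosely.

Assumptions: effects are exchangeable within each taxonomic level,
Gaussian on the Z scale, and the `1/(n−3)` variance is treated as
exact.  Conversions from t, F (numerator df 1 only), χ², z and
two-tailed p follow the standard formulas (`r = √(t²/(t²+df))` etc.);
statistics that cannot carry a sign require an explicit direction and
are rejected otherwise, since a silent default would flip conclusions.

### Coding

Two-level moderators are coded −1/+1 so that main effects remain
interpretable in the presence of interactions and level-specific means
are `intercept ∓ coefficient` from a single fit.  Covariates are
Z-transformed (mean 0, SD 1 over observed values, population SD);
missing cells are imputed to 0 *on the standardised scale* so that
models with different covariate sets, and with interaction products,
stay comparable on identical rows for DIC.  Imputation precedes
product formation.  Three-level factors use indicator coding against
the alphabetically first level.

## Priors and sampling

Fixed effects get independent N(0, 1e8).  Each variance gets either an
inverse-gamma prior with scale V = 1 and shape/df ν = 0.002 (the
default: nearly flat on log σ², it converged best in our checks) or a
parameter-expanded prior (u = α·ξ with α ~ N(0, 25²), ξ-variance
IG(V = 1, ν = 1)), which induces a half-Cauchy-like prior on the
standard deviation and behaves better when a component sits near zero.

The sampler is a partially collapsed Gibbs scheme.  The measurement
effect `m` and residual `e` are marginalised out of the β and
random-block conditionals, which therefore use heteroscedastic weights
`1/(v_i + σ²_units)`; `e` is then redrawn from its full conditional
solely to feed the conjugate inverse-gamma update of `σ²_units`.  This
has the same stationary distribution as sampling `m` explicitly, mixes
better, and makes the no-random-effects case with fixed units variance
an *exact* draw from the closed-form conjugate posterior (used as a
test oracle).  Correctness is additionally checked against fine-grid
numerical integration of the marginal posterior on a two-level toy
problem.

Rows are canonically re-sorted inside `fit()` (lexicographic key over
grouping indices, response, variance and design row), so posterior
draws are bitwise invariant to input row permutation.  Chain `c` uses
seed `seed + c`; chains beyond the first start from overdispersed
values.  **Run at least 3 chains for production summaries**: with few
levels (e.g. 5 classes) a single chain can stick near σ² ≈ 0 under the
inverse-gamma prior for many iterations; pooling dispersed chains
removes the artefact, and the Gelman–Rubin statistic flags it when it
occurs.

Schedules: `MCMCSettings.reference_schedule()` is the long production
schedule (3,000,000 iterations, 2,500,000 burn-in, thinning 100 →
5,000 retained draws per chain); `MCMCSettings.desk()` (6,000 / 2,000 /
4, three chains) is the short schedule used throughout the tests and
examples — on the 192-row canonical dataset one desk fit takes about a
second, and all simulation studies in the test suite (20-replicate
recovery, DIC selection, Egger type-I) use it.

## Summaries

* Posterior mean, SD, kernel-density mode, central 95% CI.
* `pMCMC = 2·max(1/N, min(#draws>0, #draws<0)/N)`, capped at 1: a
  two-sided tail probability floored by the finite draw count.
* Reported r-values are back-transformed per draw (`tanh` applied to
  each draw, then summarised); summarising on the Z scale first and
  back-transforming the summary is available as an option
  (`r_scale="mean_z"`), and the two differ only slightly at these
  effect sizes.
* Variance partitioning: each component's posterior-mean variance as a
  percentage of the summed posterior means over {class, family,
  species, study, units}.  The fixed measurement variance is excluded
  from the denominator, so the five columns total 100%.
* `DIC = mean(deviance) + pD`, `pD = mean(deviance) −
  deviance(posterior means)`, with the deviance conditional on the
  location effects: `−2 log N(y | Xβ + Zu, diag(v_i + σ²_units))`.
  Note a consequence measured in our simulations: because the species
  random effects can absorb omitted species-level covariate signal,
  this DIC is conservative for species-level fixed effects — a
  covariate needs roughly |z| ≳ 2.5 before DIC selection prefers it
  reliably.  Model building therefore reports the full DIC table, not
  just the winner.

## Diagnostics

PSR follows the classic two-part formula
`√(((n−1)/n·W + B/n)/W)`; identical chains (B = 0) report 1.0 with a
degeneracy warning, zero within-chain variance reports NaN.  Geweke's Z
compares the mean of the first 10% of a chain with the last 50%,
with segment standard errors from the spectral density at zero (AR
model, AIC-selected order) or naive `s/√n` for independent draws.  The
spectral variant is asymptotic: it is well calibrated at chain lengths
in the thousands (the calibration test uses length 5,000, the
production schedule's retained count), and it deliberately *absorbs* a
pure trend into a near-unit AR root — use the naive variant to
demonstrate trend detection.

## Publication bias

Trim and fill runs on the flattened effect list (the hierarchy is
ignored — a known limitation of the procedure, so it is a screen, not
a correction): iterate {REML centre estimate → signed-rank L0 (or run-
based R0) estimate of the number of suppressed studies k₀ → trim the
k₀ most extreme excess-side points}, to a fixed point (cap 50
iterations), then mirror the trimmed points about the final centre and
re-fit.  Side selection is automatic (the side with the larger
estimated k₀) unless specified.  Recovery of k₀ depends on funnel
geometry: when the deleted studies are imprecise extremes around a
precise core — the realistic funnel — the procedure recovers them
well; with equal variances, the centre estimate is dragged by the
unmatched extremes and k₀ is honestly underestimated (the reference R
implementation behaves identically).

REML for the univariate random-effects model maximises the restricted
likelihood of `y_i ~ N(μ, v_i + τ²)` over τ² ∈ [0, 10·var(y)] by
bounded scalar optimisation (tolerance 1e−10), snapping to τ² = 0 when
the boundary is at least as good.

The Egger test enters the raw SE as a covariate (intercept + SE) with
the same nested random structure, priors and schedule as the main
meta-analysis; asymmetry is flagged when the slope's 95% CI excludes
zero.  Under the null this flag fires at roughly the nominal rate in
our simulations (~90–95% of replicate CIs span zero).

## Phylogenetic variant

`build_relatedness` parses Newick (dendropy), optionally prunes to the
focal species, and sets `A_ij = shared root-to-MRCA path length /
√(depth_i · depth_j)` (for ultrametric trees: shared depth over total
depth), diagonal 1.  The species block then samples from a full
multivariate normal with precision `diag(Σw) + A⁻¹/σ²`; a 1e−8 ridge is
added with a warning if A is singular.  With A = I the fit reduces to
the ordinary i.i.d. species effect (tested), and permuting species
labels together with A leaves the posterior unchanged.

## Synthetic data

The generator emulates the *statistical* structure of a comparative
paternal-care meta-dataset, not the biology: a taxonomy partitioned to
exact totals (default 5/29/48/62/192 — classes/families/species/
studies/effects, extras assigned at random), Gaussian random effects
per level, species-level covariates (multiple paternity uniform on
6.1–97.5%; cost and benefit effect sizes normal around 0.27 and 0.51,
matching typical observed pooled values; proportion of male care
Beta(2,2)), per-effect sample sizes lognormal (median 30, σ = 0.6,
minimum 10), and observed `Zr = latent + N(0, 1/(n−3))`.  Default
variance components split a total of 0.2 as 34.78 / 17.99 / 9.17 /
36.15 / 1.91 percent across class/family/species/study/units, and the
default mean effect is Zr = 0.365 (r = 0.35).  Covariate missingness
defaults (25% multiple paternity, 50% cost, 29% benefit, 30% male
care) mirror the species coverage typical of such compilations.
Covariates are standardised and mean-imputed with *exactly* the
pipeline's own coding before the true β is applied, so recovery tests
compare like with like.

What it does not emulate: correlated missingness, covariate
measurement error, non-Gaussian effect distributions, publication
selection (funnels are symmetric unless constructed otherwise), or any
behavioural mechanism.  Passing recovery tests therefore demonstrates
that the estimation machinery is correct under its own assumptions,
not that those assumptions hold in real compilations.

`generate_statistics` replaces each effect with one derived from a
simulated raw study (two-group t or bivariate-normal correlation) to
round-trip the conversion engine; the small transformation bias of r
under sampling (≈0.01–0.02 at n = 200) is tolerated, not corrected.
`generate_tree` draws Yule (pure-birth) ultrametric trees.

## Numerical choices and degenerate inputs

Variances are floored at 1e−12 inside the sampler; a divergent state
aborts with diagnostics rather than continuing.  Random factors with a
single observed level are dropped with a warning.  Effect sizes with
n ≤ 3 are rejected at ingestion (unusable variance), as are |r| ≥ 1
conversions and taxonomies that fail to nest.  KDE modes fall back to
the value itself for constant draws.  Trim-and-fill flags instability
when k₀ reaches half the studies.

## Limitations

Gaussian responses only; nested (or tree-structured) random effects
only; no cross-classified structures; no HPD intervals (central CIs);
no selection-model or PET-PEESE bias corrections; single-CPU sampler
(a desk fit is ~1 s, the full production schedule is minutes to hours
depending on data size).
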