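# Methods

This note records the models, conventions and numerical choices behind
`porescreen`, in the order the pipeline runs them.

## Interstitial-space physics

A sediment layer's volume budget is $V_T = V_s + V_w + V_a$ (solids, pore
water, gas).  The package adopts the only reading of the measured
quantities under which the gas-space formula is an exact identity:

- $\mathrm{Moi}_m$ (mass water content) = water mass over total wet mass;
- $\rho_{w\&s}$ (mixed-sediment density) = wet mass over the *gas-free*
  volume $V_s + V_w$.

With those definitions,
$100\,(1 - \mathrm{Moi}_v \rho_w / (\mathrm{Moi}_m \rho_{w\&s})) =
100\,V_a/V_T$ algebraically, which the test suite verifies by a round-trip
property over random volume budgets and solids densities.  Measured inputs
carry noise, so slightly negative gas-space values occur in gas-free
layers; they are clamped to zero with the raw value retained and a flag
set, matching how gas-free layers are conventionally tabulated as 0.

Particle evenness is the coefficient of variation of the particle-size
sample.  The sample (n−1) standard deviation is the default (`ddof=1`);
the population form is available via `ddof=0`.  Replicate averages (five
replicates per layer in the packaged survey) skip missing values and
record the count used; a layer with no usable replicates propagates as a
missing cell rather than an error, and all downstream summaries and
correlations use pairwise-complete data.

Percent values in the packaged table are stored at their printed precision
(one decimal for TIS/VWC, two for gas space); where the package rounds for
comparison against tabulated cells it rounds half-up, because the
tabulated cells behave that way (e.g. 66.49 → 66.5).

## OTU-table cleanup

The fixed preprocessing order is: dataset-wide low-abundance filter →
organelle (chloroplast/mitochondria lineage) removal → rarefaction.  The
0.005 % filter is applied to each OTU's share of the grand total, not per
sample — the dataset-wide reading matches common clustering-pipeline
practice — and an OTU exactly at the threshold is kept.  Rarefaction
defaults to the minimum sample total and draws a multivariate
hypergeometric per sample (exact subsampling of reads without
replacement), deterministic given its mandatory seed.  Whether organelle
removal precedes or follows rarefying is not a settled convention;
rarefying last keeps all row sums equal after every removal, so that is
the fixed order here.

Lineage parsing accepts both `p__Name`-prefixed and bare rank-by-position
dialects; anything without a recognizable phylum maps to `Unassigned`.

## Correlation screening

Spearman's ρ is computed as the Pearson correlation of mid-ranks
(tie-corrected).  For n ≤ 9 complete pairs the two-sided p-value is exact:
all n! permutations of one rank vector are enumerated.  Two
implementation notes:

- the permutation null of the rank cross-product depends only on the
  *multiset* of mid-ranks, so OTUs sharing a tie pattern share one null
  distribution; the screen groups OTUs by pattern and computes each null
  once (the full-table screen of 2,000 OTUs costs a few seconds);
- for n > 9 the usual t approximation is used and the choice is recorded
  in the output metadata.

The two-stage gate mirrors the screening design: OTUs with p > 0.05 are
removed first, then Benjamini–Hochberg q-values computed over all tested
OTUs of the (site, factor) family flag entries with q ≥ 0.05.  The family
is per (site, factor) — the least surprising unit, configurable in
principle by screening factors jointly.  `mean_ra`, the quantity the
threshold curves accumulate, is the OTU's relative abundance averaged over
the site's layers: the only site-level scalar consistent with statements
like "more than half of the community is correlated".  The headline
threshold is strict (`|ρ| > 0.8`); ties at the threshold are excluded.
Threshold curves themselves use `|ρ| ≥ t` on a 0.01 grid and by default
include only FDR-passing entries (a flag relaxes this to all p ≤ 0.05
entries).  Factors with fewer than five complete layer pairs at a site are
skipped with a warning rather than screened on too little data.

### Pseudo-correlation diagnostic

The verdict `likely-pseudo` requires three conditions at once:
`|ρ(factor, depth)| ≥ 0.8` across layers, abundance-weighted overlap of
the factor's correlated-OTU set with depth's of at least 0.5, and factor
correlated abundance not exceeding depth's.  The last comparison is
non-strict: a factor identical to depth must be flagged.  Degenerate
situations get their own verdicts — `no-gradient` when depth itself has no
correlated OTUs (no baseline to compare against) and `no-signal` when the
factor's correlated abundance is below 1 % (nothing to explain).  All
thresholds are keyword-configurable.

## Ordination

- **Unweighted UniFrac**: branch length leading to taxa present in exactly
  one of two samples over branch length leading to taxa present in either;
  presence means count > 0 after rarefying.  The all-pairs routine
  computes per-branch presence once in postorder and forms the matrix by a
  single weighted cross-product.  It is a semimetric here; triangle
  violations on exotic trees are possible and are not treated as errors.
- **PCoA**: Gower double-centering of −D²/2 and a symmetric
  eigendecomposition; coordinates scale by √eigenvalue on the positive
  axes.  Negative eigenvalues are reported unchanged — the classical
  metric-scaling behaviour — with no correction by default.
- **PERMANOVA**: one-way, free permutation of sample labels (no strata);
  p = (1 + #{F* ≥ F}) / (1 + permutations), so the smallest attainable p
  at 999 permutations is 0.001.
- **RDA**: species matrix column-centered, not standardized
  (`scale=False`); constraints standardized internally; fitted values from
  a least-squares projection (pseudo-inverse when constraints are
  collinear, with a warning), eigendecomposed by SVD.  Model R² is the
  fitted share of total variance; adjusted R² uses the Ezekiel formula
  with m = rank of the constraint matrix.  Per-factor marginal fits report
  the factor's correlation with the joint model's first two constrained
  axes (the arrow coordinates), the marginal single-constraint R², and a
  permutation p-value (one-sided on R², closed-form single-constraint
  shortcut in the loop).  Two adjusted variants are reported per factor:
  Ezekiel (default) and the global-ratio scaling R²·(adjR²_model /
  R²_model), which matches how some published factor tables appear to have
  been derived; the whole-model permutation is the implemented choice
  where an axis-wise alternative was conceivable.

## Synthetic communities

The generator's defaults describe the survey shape the pipeline targets:
4 sites × 9 layers (midpoints 2.5–42.5 cm), 2,000 OTUs, sequencing depth
50,000 reads per layer, 30 % of OTUs depth-responsive with a 2-nat
(≈7.4-fold) log-abundance change across the profile.

- **Environment.**  VWC maps a Gaussian-copula draw against depth to a
  50–88 % range; the copula Pearson parameter is set by
  r = 2 sin(πρ_s/6) and, for strong targets (|ρ_s| ≥ 0.5), draws are
  rejected until the realized Spearman is within ±0.05 of the target
  (weak/null targets are accepted as drawn, preserving their natural
  sampling spread).  Gas space is uniform on 0–15 % independent of depth
  at gas-bearing sites and structurally zero elsewhere (site 5 in the
  default layout), making it a built-in negative control.  TIS is
  generated as VWC + gas space — the volume identity — rather than
  independently calibrated to its own collinearity target; its realized
  depth correlation lands near −0.9 anyway because gas space is small and
  depth-independent.  Particle size follows per-site targets on the log
  scale; evenness is depth-independent.
- **Community.**  Baseline log-abundances are normal with σ = 2.0 — a
  heavy-tailed pool in which the top OTUs carry percent-level shares, as
  in deep 16S profiles of sediment.  Each responsive OTU adds a strictly
  monotone logistic depth response (random sign, center in the middle half
  of the profile, width 6–15 cm, range normalized to exactly the
  configured effect size) before a softmax to the simplex.
- **Mixing.**  Ebullition is modelled as the convex blend
  (1−m)·layer + m·site-mean, the simplest operator consistent with
  bubble-driven pore-water exchange: m = 0 is identity, m = 1 homogenizes
  a site completely, and mean between-layer L1 distance shrinks exactly
  linearly in m.  Default per-site strengths (site 3: 0.8, site 2: 0.5,
  site 4: 0.2, site 5: 0.0) encode the emission-stage ordering as package
  conventions — no quantitative mixing magnitude is available to anchor
  them.  A nearest-layer diffusion alternative was considered and left
  out; the convex blend is sufficient for the qualitative orderings the
  pipeline tests.
- **Counts.**  Dirichlet-multinomial with concentration
  `dispersion × composition`; the default dispersion 1e5 is
  near-multinomial, i.e. counts carry sampling noise at depth 50,000 plus
  mild extra-multinomial dispersion.  This pairs with σ = 2.0 so that the
  abundance-weighted bulk of the community has per-layer noise small
  against a 2-nat depth response — the regime in which a nine-layer rank
  screen at |ρ| > 0.8 recovers most planted abundance, which is the
  operating point the default configuration is meant to represent.
- **Trees.**  Random pairwise coalescence with exponential branch lengths;
  n leaves, n−1 internal nodes, deterministic per seed.

What the generator does *not* emulate: real taxonomic structure (phylum
labels are sampled from a fixed pool with geometric weights), non-monotone
or interactive factor effects, spatial autocorrelation between adjacent
layers beyond the shared response curves, compositional interactions
beyond softmax closure, and sequencing artefacts (chimeras, contamination,
variable library sizes beyond rarefaction's reach).  Passing recovery
tests therefore show the pipeline detects the structure it assumes, not
that real sediment communities satisfy those assumptions.

## Problem sizes used in validation

The validation suite exercises: oracle agreement on 500 random vectors of
length ≤ 8 (full enumeration); PERMANOVA type-I calibration on 1,000 null
datasets (n = 20, two groups, 199 permutations each); null screening gates
on a 2,000-OTU unresponsive community; planted-response recovery on the
full default community at mixing 0 and 1 plus a five-point mixing grid;
and pseudo-correlation detection over 50 generator seeds at 500 OTUs on a
single gas-free site.  These sizes keep each property statistically
informative while the whole suite completes in minutes.

## Known limitations

- Exact Spearman p-values stop at n = 9 (9! = 362,880 permutations); a
  survey with more layers per site silently switches to the t
  approximation (recorded in output metadata).
- The RDA factor table's permutation test permutes the factor against the
  full community matrix; conditional (partial) permutation given the other
  factors is not implemented, so collinear factors each look individually
  strong — which is precisely the phenomenon the pseudo-correlation
  diagnostic exists to expose.
- Unweighted UniFrac ignores abundance by construction; no weighted
  variant is provided.
- The pipeline treats layers within a site as exchangeable sampling units;
  it does not model vertical autocorrelation when computing p-values.
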