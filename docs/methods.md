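# Methods

## Model

Each trait is analysed with the two-random-effect linear mixed model

    y = Xβ + Zu + Wm + e,
    u ~ N(0, G σ²_u),   m ~ N(0, B σ²_m),   e ~ N(0, I σ²_e),

with one record per animal (Z = W = I). The fixed design X holds an
intercept, sex (2 levels) and a batch factor encoded drop-first: the
6-level rearing batch for most traits, or the 12-level laboratory batch
(two analytical runs per rearing batch) for phagocytosis assays — the
routing is keyed on `PHAGO` appearing in the trait name and is
configuration-overridable. Random effects are assumed independent of each
other and of e; heritability and microbiability are defined on the random
part only,

    h² = σ²_u/(σ²_u+σ²_m+σ²_e),   m² = σ²_m/(σ²_u+σ²_m+σ²_e).

### Kernels

* `G = SS′ / 2Σⱼ pⱼ(1−pⱼ)` with S the dosage matrix centred at twice the
  per-SNP allele frequency (VanRaden method 1). Dosages are re-polarized so
  the counted allele is the minor one; the kernel itself is invariant to the
  flip (tested), the convention only standardizes reported frequencies.
  Missing dosages are mean-imputed per SNP *inside* kernel construction;
  QC never imputes. Monomorphic columns are excluded from matrix and
  denominator with a warning.
* `B = MM′/n` where M is the CSS-normalized ASV table after column
  centring and scaling to unit **sample** SD (ddof = 1; the
  population-vs-sample choice is not identifiable from the published
  description, and sample SD mirrors the ddof convention used everywhere
  else in the package). "n" is the number of retained ASV columns;
  zero-variance columns are dropped with a warning and n reduced. This
  interpretation of "scaled" mirrors the centred-genotype construction of G
  and makes diag(B) ≈ 1. B is built at ASV level; a genus-level B differs
  (tested) and is not used for variance partitioning.

### CSS and clr

CSS divides each sample's counts by the cumulative count up to that
sample's q-th quantile of positive counts, times a scale (default 1000).
The reference quantile defaults to the median (q = 0.5) and is
configurable: the adaptive percentile of metagenomeSeq is data-dependent
and not reproducible without the original data, and a fixed median keeps
the transform deterministic. The clr transform is `log(count + pseudocount)
− row mean of logs` (delegated to scikit-bio), with pseudocount 1 guarding
zeros; clr feeds only the correlation network, CSS feeds only B, and
column-standardized relative abundances feed only the MWAS — three
deliberately separate representations.

## Priors and Gibbs sampler

Variance components get scaled-inverse-χ² priors with ν = 5 and scales set
so the prior *mode* of component k equals `R²_k · var(y)` with the split
R² = (u: 0.25, m: 0.25, e: 0.5). The underlying Bayesian ridge-regression
software this mirrors does not publish per-component hyperparameters, so
these are declared defaults, not inferred ones, and are configurable
(`PriorSpec`).

The sampler reparameterizes each kernel through its eigendecomposition
K = UDU′: the random effect becomes independent ridge coefficients on the
columns of U D^{1/2}. Those columns are mutually orthogonal, so each
coefficient block has a *diagonal* full-conditional covariance and one
sweep costs O(n²) after a one-off O(n³) decomposition. Update order: fixed
effects block (flat prior, multivariate-normal conditional), each kernel's
coefficient block, then the three variances from their scaled-inverse-χ²
full conditionals. Default chain: 30,000 iterations, 3,000 burn-in,
thinning 1; the seed is a required argument. Eigenvalues below 10⁻¹⁰ of
the largest are dropped (rank truncation); eigenvalues below −10⁻⁸
(relative) raise a PSD error, small negatives are clipped to zero.

Correctness is pinned by three independent oracles in the test suite:
Henderson's mixed-model equations for the posterior effect means at fixed
variances; an exact 2-D numerically integrated posterior for (σ²_u, σ²_e)
in the kernel eigenbasis (agreement to ~0.01 in posterior mean h²); and
the conjugate ridge posterior for the MWAS block.

### Summaries

"Posterior mean of h²" is ambiguous between the mean of per-draw ratios and
the ratio of posterior-mean variances; the package reports the **mean of
per-draw ratios** (which also yields threshold probabilities
`P(h² > 0.1 | y)` directly) and carries the ratio-of-means alongside. Per
draw, h² + m² + e² = 1 exactly. Convergence is monitored with Geweke
z-scores whose standard errors come from batch means (20 batches), which
absorb chain autocorrelation without a spectral fit; naive iid standard
errors overstate |z| several-fold on variance chains.

Missing phenotypes are handled by casewise deletion with aligned kernel
row/column subsetting; traits with fewer than 50 complete records are
skipped with a warning.

## MWAS

All p genera (default level; ASV level selectable) enter one model:
y = Xβ₀ + Tb + ε with T the column-standardized relative abundances and
bⱼ ~ N(0, σ²_β) shared. Sex and batch are kept as unpenalized covariates
for consistency with the variance-partition model (switchable off). The
taxon block is drawn jointly (p×p Cholesky per sweep). The Bayes factor per
taxon is the Savage–Dickey density ratio at zero with the **posterior mean
of σ²_β** as the prior variance — an empirical-Bayes plug-in, used because
the hierarchical prior makes the exact prior marginal non-normal while the
published description treats both densities as normal. On a conjugate toy
model with fixed variances the plug-in is exact and matches numerically
integrated marginal-likelihood ratios to better than 3 significant figures
(tested). The reporting threshold BF ≥ 2 matches the smallest association
strength the motivating study tabulates, and is configurable.

## PCIT network

Traits are residualized on sex + batch before correlating (the published
pipeline is silent on this; both modes are supported and tested), then
Pearson correlations are taken pairwise-complete over traits and
clr-genus columns; Pearson is the right match for clr-transformed
compositions. For every ordered trio (x, y, z) the three first-order
partial correlations give the tolerance
ε = ⅓(|r_xy·z/r_xy| + |r_xz·y/r_xz| + |r_yz·x/r_yz|); the pair (x, y) is
eliminated in that trio when |r_xy| < |ε·r_xz| and |r_xy| < |ε·r_yz|. A
pair is significant iff no conditioning variable eliminates it. Ratio
terms with |direct r| < 10⁻⁹ are skipped (tolerance averaged over the
remaining terms; a fully skipped trio eliminates nothing) to avoid
division blow-ups; an off-diagonal |r| = 1 is a hard error naming the
pair. The vectorized implementation is verified identical to an
exhaustive, independently coded triple loop on random instances; that
oracle is normative.

Only significant pairs joining one trait and one genus become network
edges (trait–trait and genus–genus links are discarded); node degree,
keystone trait/genus (degree argmax, lexicographic tie-break) and the
overlap with MWAS associations — the fraction of BF-passing (trait, genus)
pairs also present as edges — are reported.

A property worth knowing: with the trio rule, a pure indirect correlation
r_xy = r_xz·r_yz is eliminated only when the flanking correlation satisfies
r² < 1/3; stronger chains keep their indirect edge. Likewise PCIT retains
roughly 10% of genuinely null pairs (those whose |r| happens to exceed most
flanking correlations), so networks always carry a low-|r| background on
top of the real signal; planted correlations of |r| ≈ 0.35 at n = 400
separate cleanly from that background by magnitude.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Genotypes** — independent biallelic SNPs, MAF ~ U(0.05, 0.5),
  dosages Binomial(2, p) (HWE), optional missingness.
* **Microbiome** — genus baseline weights Zipf(rank⁻¹) over 68 genera by
  default (top-5 genera carry > 40% of counts, matching the dominance
  structure of real pig gut profiles), log-normal ASV jitter within genus,
  per-sample composition Dirichlet(overdispersion × baseline,
  default 100), counts multinomial at a library size uniform in
  10k–60k. A small fraction (3%) of ASVs stays unclassified to exercise
  that code path.
* **Phenotypes** — u and m are drawn by scaled eigenvector mixing of the
  realized G and B (N(0, Kσ²) exactly), e iid, with σ² set so the nominal
  fractions equal the requested h²/m² on a unit total; the fitter samples
  coefficients through its own independent code path. Sparse direct genus
  effects (for MWAS truth) are added on the standardized clr scale; planted
  genus–trait correlations mix a clr-genus component into the standardized
  trait and re-standardize, with the realized correlation recorded. Fixed
  effects (sex, batch or lab-batch) go on top. The truth record stores the
  u/m/e vectors, realized variance fractions, causal pairs and realized
  planted correlations.

Default dimensions mirror the motivating design (389 individuals, 42,641
post-QC SNPs, 2,055 ASVs, 68 genera); every dimension scales down. What
the generator does **not** emulate: pedigree/family structure (all
individuals unrelated), correlation between genetic relatedness and
microbiome similarity, zero-inflation beyond what Dirichlet-multinomial
sampling produces, and any sequence-level error process. Passing tests
therefore demonstrate correct inference under the model's own assumptions,
not robustness to confounded relatedness–microbiome structure in real
cohorts.

## Validation experiments and problem sizes

The recovery battery (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses cohorts of n = 400 individuals, 2,000 SNPs,
150 ASVs in 20 genera, with 6,000-iteration / 1,000 burn-in chains over 10
seeds — sizes at which one full battery runs in a couple of minutes while
leaving Monte-Carlo noise well under the tolerances checked. Observed
performance: h²/m² mean absolute error ≈ 0.03–0.07 at truth (0.30, 0.25);
a microbiome-dominated trait (h² = 0.14, m² = 0.28) ranks m̂² > ĥ² in
7–8 of 10 seeds (the prior pulls ĥ² up toward 0.25, making the ranking
marginal); MWAS recovers ~5/5 planted effects with ~1 false positive per
60 null pairs and a ~2% null pass rate at BF ≥ 2.

**Known identifiability limit.** With unrelated HWE individuals and
p/n = 5 independent SNPs, G is a Marchenko–Pastur bulk around I, so σ²_u
and σ²_e are nearly exchangeable: for a pure-noise trait the likelihood is
almost flat along σ²_u + σ²_e and the posterior stays prior-dominated
(null ĥ² ≈ 0.22, m̂² ≈ 0.13 under the defaults). This was verified against
the exact numerically integrated posterior — it is the true posterior, not
a sampler artefact. A "null traits give near-zero fractions" check is kept
in the acceptance battery and fails by design under these cohort
conditions; real cohorts with family structure (which the generator
deliberately does not model) identify σ²_u far better. The m² side is
better identified because B is rank-deficient (150 ASVs < 400 samples),
leaving 250 contrasts that inform σ²_e alone.

## Degenerate inputs and numerical conventions

* QC filters are pure (no imputation) and ordered: read-depth filter on
  samples strictly before the ASV prevalence/abundance filter; the
  abundance fraction (0.001% encoded as 1e-5) is taken of the grand total
  *after* sample removal. The default mode discards an ASV failing either
  criterion; `literal_and` discards only ASVs failing both. Filtering is
  idempotent on realistic tables; a crafted table in which removed ASVs
  carry enough reads to pull a sample below the depth threshold on
  re-application would not be, since re-filtering recomputes depths on the
  reduced table.
* Constant traits produce CV = 0 with a warning; CV is flagged undefined
  for non-positive means. Fewer than 2 non-missing values is an error.
* All-zero microbiome samples are an error at CSS; the clr pseudocount
  guards zeros.
* Genus aggregation pools unassigned ASVs into `unclassified`, which MWAS
  and the network exclude by default; per-sample totals are conserved.
* Multi-allelic VCF records are skipped with a logged warning and counted
  in the return metadata; dosage values outside {0, 1, 2, NA} are parse
  errors naming row and column.
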