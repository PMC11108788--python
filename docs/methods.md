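# Methods

This note documents the statistical models implemented in `myoaging`,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Compositional model

Cell-type abundance is modeled at the level of the 10x library (the
replicate unit): `N_cs`, the count of cell type *c* in library *s*, is
Poisson with log rate

```
log mu_cs = beta0 + beta_age * z_s
          + u_celltype[c] + u_sample[s] + u_chem[chem(s)] + u_mod[mod(s)]
          + z_s * v_age[c] + u_chem:ct[chem(s),c] + u_mod:ct[mod(s),c]
          + u_sample:ct[s,c]
```

where `z_s` is age in years scaled and centered across libraries, `chem`
is the 10x chemistry (v2/v3) and `mod` the modality (cells vs nuclei).
Every covariate enters as a Gaussian random term; this keeps the model
estimable despite the heavy collinearity between library, chemistry and
modality, and shrinks per-cell-type effects toward the shared age slope.
The fixed part is intercept + age only. A donor-level hierarchy is not in
the default formula (technical replicates are treated as independent
libraries, which can overstate precision — see Limitations); optional
`donor` / `donor_celltype` grouping terms can be added through
`ModelSpec`.

**Estimation.** Laplace approximation in the `glmer` style: for a given
vector of random-effect standard deviations, fixed effects and
random-effect modes jointly maximize the penalized Poisson log-likelihood
by Fisher-scoring Newton steps (Cholesky solves with step halving); the
marginal likelihood of the variance components uses the log-determinant
of the random-effect curvature block at the mode; the log standard
deviations are optimized by L-BFGS-B (bounded to [1e-4, 10], initialized
at 0.1, deterministic). Posterior summaries of any contrast come from the
inverse joint curvature — the Gaussian posterior under which LTSR is
evaluated.

**Effects and significance.** The per-cell-type age effect is
`beta_age + v_age[c] − mean_c(v_age)`, i.e. centered so the grand mean
over cell types equals the shared slope and the value is 0 at no effect
(natural log per 1 SD of age; a log2 column is provided for display).
LTSR is the Gaussian sign probability `Phi(|mean|/sd)`, in [0.5, 1],
thresholded at 0.9. With all variance components pinned at zero the fit
reduces exactly to the ordinary Poisson GLM MLE; this limit is asserted
against an independent statsmodels fit in the tests.

**Neighborhood labeling.** For graph-based differential abundance the
post-labeling rules are implemented standalone: a neighborhood takes its
majority cell-type label when that type contributes ≥ 70% of its cells
(otherwise "mixed", dropped) and no donor contributes > 90% (otherwise
"Donor-specific", dropped); the mixed rule is checked first. The KNN
graph construction and the neighborhood-level NB regression themselves
are out of scope.

## Aging differential expression

Per gene, counts across cells are negative binomial with
`var = mu + mu^2/dispersion` and

```
log mu_i = offset_i + beta0 + beta_age * z_i + u_donor[donor(i)] (+ ...)
```

`offset_i` is the log of the cell's size factor, `z_i` standardized age;
additional technical covariates (chemistry, modality) can be declared as
extra random intercepts. Age is treated as continuous standardized years
(a binary group design would discard within-group age spread); the
reported `log2fc` is the young→aged contrast `beta_age * (z̄_aged −
z̄_young) / ln 2`, the quantity comparable to a per-group fold change.

Four estimation choices matter and are worth stating explicitly:

1. **Dispersion** is estimated per gene by maximum likelihood under the
   fixed-effect NB GLM and then held fixed (floored at 1e-3 for sparse
   genes). Joint optimization inside the mixed model changes calls
   negligibly at many times the cost.
2. **Size factors** are total counts corrected for composition: the
   median per-gene fixed-effect age slope is folded into the size factors
   (the usual most-genes-are-not-DE assumption, in the spirit of TMM /
   median-of-ratios). With total-count offsets alone, strongly changing
   genes drag the apparent age effect of every other gene in the opposite
   direction — visible on a 200-gene panel, negligible at transcriptome
   scale.
3. **Nuisance variance components are pooled across genes**: the donor
   variance is estimated per gene from an intercept-only fit and the
   panel median of those variances is used for all genes (consensus-
   correlation style). With a handful of donors the per-gene estimate
   frequently collapses to zero, which would understate the age-effect
   uncertainty exactly for the genes most at risk of false positives.
4. **The Bayes factor is a proper marginal-likelihood ratio.** The age
   coefficient is a random term `N(0, sigma^2)` whose scale `sigma` is
   integrated over a half-normal prior (scale 0.5 on the natural-log
   per-SD scale, ~1.4-fold per SD at one prior sd) by 10-point log-spaced
   quadrature; the with-age marginal likelihood is compared to the
   without-age fit. The quadrature prior gives the BF its Occam penalty:
   null genes concentrate at BF ≲ 1 while genuinely changing genes reach
   very large BFs.

**LTSR for DE** combines the Bayes factor with the conditional sign
probability: with `p1 = BF/(1+BF)` (equal prior odds),

```
LTSR = p1 * P(sign correct | age term real) + (1 − p1) * 1/2
```

so a gene with no evidence for any age term sits at 0.5 regardless of
its point estimate's sign. A gene is a significant aging DEG when
LTSR > 0.9 **and** it is expressed (count > 0) in more than 5% of aged
cells; no further multiple-testing correction is applied — the LTSR
threshold is the significance rule. The expressed proportion is computed
in the aged group by default (configurable).

## Myonuclei typing

Expression of MYH1/MYH2/MYH7 is library-size normalized (counts per
10,000 — the scale is configurable) and log1p-transformed; a nucleus
expresses a gene when the normalized value **strictly exceeds 0.5**. The
membership subset determines one of seven classes (MYH7+, MYH2+, MYH1+,
and the four hybrids) or "unclassified" when the subset is empty;
nuclei flagged as fragment or rare hybrid snRNA subtypes are unclassified
regardless of expression (flags are applied after normalization). Donor
proportions are computed over classified + unclassified nuclei; a donor
is excluded when the unclassified fraction strictly exceeds 0.75.
Young-vs-aged comparisons use an unpaired two-tailed Student t-test
(Welch by flag) on donor-level proportions, or Mann–Whitney (exact
distribution for group sizes ≤ 8, normal approximation with tie
correction above).

## Cross-species consistency

DEG sets (per cell type and direction) are homolog-mapped — human→mouse
by default; genes without a homolog are dropped and reported, one-to-many
rows expand then deduplicate — and compared by Jaccard index (both-empty
defined as 0 with an explicit flag). Over-representation uses the
one-sided hypergeometric upper tail with BH adjustment within each
(cell type, direction); the default universe is the expressed genes of
that cell type. The co-enrichment score counts cell types where a pathway
is BH-significant (adjusted p < 0.05) in *both* species in the same
direction; up counts plot positive, down negative.

## Ligand–receptor filter

Expression proportion is the fraction of a cluster's cells with raw
count > 0. An interaction is retained iff the ligand proportion in the
emitter and the *minimum* subunit proportion in the receiver both
strictly exceed 0.05. Retention is monotone in the threshold; at
threshold 0 it equals nonzero expression on both sides.

## Quality control

Defaults: cells 500–5,000 genes, 700–50,000 counts, mito ≤ 10%; nuclei
400–5,000 genes, 500–40,000 counts, mito ≤ 5%; doublet score ≤ 0.4 for
both. Gene/count windows are inclusive ("min"/"max"); mito and doublet
rules are strict ("more than"). The nuclei upper count bound is exposed
as configuration (40,000 by default). Removal is attributed sequentially
— doublet → gene range → count range → mito — so kept + per-rule
removals equals the input count; filtering is idempotent. `mito_fraction`
is mito counts over total counts with 0/0 defined as 0. These defaults
describe full-transcriptome droplet data; the pipeline's synthetic-panel
configuration scales the windows down (a 200-gene universe cannot contain
500 expressed genes).

## Synthetic data generator

The generator is the inverse of the fitted models and defines the test
conditions:

* **Composition**: two age groups of donors (ages uniform in 20–40 and
  60–75 years), two libraries per donor (mirroring technical replicates),
  alternating modality per library and chemistry per donor; counts drawn
  Poisson from baseline + age effect × standardized age + Gaussian random
  effects for sample/chemistry/modality and their cell-type interactions.
  Standard conditions used by the tests: 8–10 cell types, 20 donors (40
  libraries), one planted effect of 1.0 natural-log per SD, random-effect
  sds of 0.1 (0.3 for modality).
* **Expression**: NB counts (`var = mu + mu^2/dispersion`, dispersion 2.0
  by default) with per-gene lognormal base means, a lognormal(0, 0.3²)
  per-cell depth factor, donor random intercepts (sd 0.1), spiked genes
  multiplied by `2^log2fc` in aged cells, and per-cluster MYH marker
  programs. Standard panel: 200 genes, 10 spiked at log2FC 1.5, 4 donors
  and 2,000 cells per age group. Mito-fraction and doublet-score columns
  are emitted for QC fixtures. The depth and dispersion distributions of
  real atlas-scale data are not matched — the generator's defaults are
  stated choices, not estimates.
* **Fixture tables**: internally consistent homolog (1:1 and 1:2 rows),
  GMT gene-set and ligand–receptor tables drawn from the synthetic gene
  universe.

Not emulated: ambient RNA, doublet transcriptomes, gene–gene correlation
beyond the donor intercepts, spatial structure, realistic gene-universe
size. Passing tests therefore demonstrate correctness of the estimation
machinery and decision rules under the stated generative assumptions, not
robustness to artifacts the generator does not produce.

## Numerical choices

* Variance components parameterized as log-sd, bounds [1e-4, 10],
  deterministic initialization at 0.1; inner Newton tolerance 1e-10 with
  step halving; outer gradient/function tolerances 1e-8/1e-10. A single
  free component uses bounded scalar minimization (xatol 1e-4).
* Laplace determinant uses the random-effect block only (lme4
  convention); 2π factors cancel between the prior normalizer and the
  Gaussian integral.
* Designs with ≤ 64 coefficients use dense BLAS; larger ones (e.g. the
  composition model's ~400 random coefficients) use sparse products with
  dense Cholesky.
* NB dispersion floor 1e-3; BF log-ratio capped at 500 before
  exponentiation; all-zero genes are flagged degenerate (LTSR 0.5, never
  significant).
* Gene-set scoring uses 25 expression bins and 50 bin-matched control
  genes per set gene by default, seeded; the score is set mean minus
  control mean on the normalized matrix.
* Tables are written with 9-significant-digit floats and stable column
  order; all pipeline randomness derives from named per-stage substreams
  of the global seed, so toggling one stage never perturbs another.

## Problem sizes

The test-suite and acceptance-script runs use the generator's standard
conditions: composition recovery at 20 replicates × (8 cell types × 40
libraries); DE discovery at 10 seeds × (200 genes × 4,000 cells); the
myonuclei classifier on the exhaustive 4³ grid; ORA exactness on
universes ≤ 25 genes against full enumeration; QC on a 1,000-cell fixture
with planted violations; end-to-end determinism on the default pipeline
fixture.

## Limitations

* Library-level replication in the default composition model treats
  technical replicates as independent; donor-level terms are available
  but not default. Under permuted age labels with few donors, chance
  donor-age correlation can still yield confident-looking effects — an
  inherent property of small-n designs, not removed by the model.
* LTSR from a Gaussian (Laplace) posterior ignores variance-component
  uncertainty in the composition model; the DE model accounts for the
  age-scale uncertainty by quadrature but plugs in pooled nuisance
  variances.
* The per-gene model assumes NB counts given donor and depth; zero
  inflation and cell-level correlation structure are not modeled.
* Exact Mann–Whitney p-values ignore ties (scipy's exact method); with
  donor-level proportions ties are rare but possible.
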