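# Methods

## The model

A founder population descends from a small group drawn from a large source
population. Neutral drift through the bottleneck changes allele
frequencies: E[p] is preserved, Var[p_t] = p(1−p)(1−(1−1/2N)^t) for a
diploid bottleneck of size N lasting t generations, and many rare alleles
are lost entirely while the survivors jump to frequencies of order 1/2N or
more. The package measures the visible consequence of this process —
per-variant frequency enrichment relative to a large reference panel — and
feeds the enriched variants into recessive-disease prevalence estimates and
complex-trait association tests.

### Enrichment statistics

Counts are oriented to the allele that is minor in the *reference* panel
(target-minor when the variant is absent from the reference). For minor
counts (a_t, n_t) and (a_r, n_r):

* fold = (a_t/n_t)/(a_r/n_r), undefined at a_r = 0;
* one-sided Fisher p = P(X ≥ a_t) with X hypergeometric at fixed margins
  (enrichment direction only);
* bias-corrected OR = ((a_t+½)/(n_t−a_t+½)) / ((a_r+½)/(n_r−a_r+½)),
  the Haldane–Anscombe correction, finite for every table and the quantity
  reported when the reference count is zero.

Frequency bins: ultra-rare is AC < 4 (count-based, takes precedence);
the remaining bins partition by target MAF with closed-left boundaries
(rare < 0.01 ≤ intermediate < 0.05 ≤ common). The boundary convention is a
package decision; the bin definitions are otherwise open intervals in the
source convention. Significance is the raw one-sided p < 0.05; an optional
Bonferroni column exists but is off by default, matching the convention of
reporting raw per-variant enrichment p-values.

### Hardy–Weinberg mid-p

The exact conditional distribution of the heterozygote count h given N
genotypes and n₁ minor alleles (Levene–Haldane) is computed in log space
over its full parity-restricted support. The mid-p sums outcomes strictly
less probable than the observed one in full and equally probable outcomes
(including the observed) at half weight; probability ties are compared at
1e−12 relative tolerance. Monomorphic sites return p = 1. The default
filter threshold is 1e−6.

### QC boundary conventions

"Between 30% and 70%" allele balance is read as a closed interval (AB
exactly 0.30 or 0.70 is kept); "more than 5% missing" is read strictly
(exactly 5% is kept); depth "less than 10" masks DP ≤ 9. These boundary
readings are package decisions where the filter prose leaves them open.
Only the autosomal filter path is implemented; sex-chromosome and
mitochondrial branches are out of scope. Filters only drop variants or set
genotypes missing — a retained dosage is never altered, and every filter is
idempotent.

### Unrelated-subset selection

Pairwise kinship is the method-of-moments estimator φ̂ = ZZ'/(2m) on
LD-pruned common variants, with Z the (2p̂, √(2p̂(1−p̂)))-standardized
dosage matrix; duplicates sit near 0.5, full sibs near 0.25. Pairs above
the conventional third-degree cutoff 0.0442 form a graph from which the
highest-degree sample is removed repeatedly (ties broken by sample id,
removing the later-sorting id). This greedy pruning approximates the
maximum-unrelated-set objective of dedicated pedigree tools: it is
deterministic and adequate at cohort scale but not guaranteed maximal.
The estimator needs enough variants to separate the third-degree cutoff
from noise (sd ≈ 1/(2√m)); ≥ 5,000 pruned common variants is comfortable.

### Ancestry

PCA standardization uses reference-panel allele frequencies for both fit
and projection, so projection never re-estimates frequencies and study
coordinates stay comparable to the stored reference scores. Projections on
partial variant overlap shrink toward the origin; this is documented, not
corrected. KNN assignment uses Euclidean distance on the top 20 PCs,
k = 10 and an 8-of-10 vote threshold, with distance ties broken by
reference-sample order so assignment is deterministic and invariant to
sample order. The two-stage design (worldwide panel → European subset;
regional panel + Europeans → founder subset) is expressed as two sequential
assignment calls wired by the pipeline driver; both stages use the same
k/threshold/PC defaults, since only the first stage's parameters are
specified in the source convention. Regional assignment applies
priority-ordered PC cutoffs (SAG: PC1 ≥ 0.025; NS: PC1 ≤ −0.025 ∧
PC2 ≥ 0.01); no numeric rule is published for the Gaspesia-Acadian region,
so none ships — `RegionalCutoffs` accepts user rules.

### Prevalence

q = (Σ het carriers + 2 Σ homozygotes)/(2n); prevalence = q², assuming
Hardy–Weinberg, full penetrance and no reproductive compensation (stated in
the output metadata). "1 in N" figures are rounded after taking the
reciprocal. The confidence interval is Clopper–Pearson on the allele count
out of 2n chromosomes with the bounds squared — a defensible default, but
the interval construction behind published CIs of this kind is often
unstated, so the CI is a reference output rather than a reproduction
target. The clinical estimator divides observed cases by registered births
scaled by the population's language fraction (default 0.8) and the
center's catchment coverage (default 0.4).

### Association

* **TDT**: T/U count minor alleles transmitted/untransmitted by
  heterozygous parents, recovered from unphased dosages (the double-het
  case contributes through the child's dosage). χ² = (T−U)²/(T+U);
  β = ln((T+0.5)/(U+0.5)); Var(β) = β²/χ². At T = U the ratio-derived
  variance is undefined and the delta-method variance of the
  continuity-corrected log-ratio, 1/(T+0.5) + 1/(U+0.5), is used instead —
  a package decision at a point where the defining formula has a removable
  singularity.
* **Case/control**: p-values come from the 1-df logistic score test of the
  dosage against a covariate-only null (default covariates: sex + top 4
  PCs); β and SE come from the full logistic fit. This plain score test
  deliberately replaces mixed-model machinery: at cohort scale the residual
  structure is absorbed by the PC covariates, and the score test is exact
  to state and fast to vectorize. Saddlepoint correction is not applied, so
  p-values for very rare variants at strong case/control imbalance are
  anti-conservative; the MAF > 0.001 default filter limits exposure.
  Separation is flagged (β/SE set to NaN) with the score p retained.
  Conditional analysis is run by passing conditioning dosages as extra
  covariates; there is no separate operation.
* **Meta-analysis**: fixed-effect inverse variance; a stratum with
  non-finite variance gets weight zero, so the estimate degenerates to the
  remaining stratum.
* **Gene sets**: masks combine a gene, a nested annotation group
  (LoF ⊂ non-synonymous; synonymous separate) and a MAF ceiling
  (0.001/0.01/0.05). The burden test collapses masked dosages with
  Beta(1,25)-density MAF weights (flat weights available) and reuses the
  score test; minor-allele counts in cases and controls are reported and
  conserved. The variance-component test uses Q = Σ w_j²(g_j'(y−μ))² with
  the null weighted-χ² mixture approximated by Liu–Tang–Zhang moment
  matching; the burden/variance-component optimal mixing search is out of
  scope, the two ends being provided separately.

## The synthetic-data generator

The generator's defaults are the study conditions used by the tests and
the reproduction script:

| parameter | default | why |
|---|---|---|
| `n_variants` | 20,000 | exome-scale unit of work |
| `sfs_shape` | 0.15 | Beta(0.15, 1)/2 source MAFs give a rare-dominated spectrum (~41% of observed variants are singletons in the motivating cohort) |
| `maf_floor` | 2.5e−5 | a real population cannot hold alleles below its frequency resolution; without the floor most of the Beta tail sits at frequencies (≪1e−10) that no panel could observe |
| `founder_size`, `generations` | 200, 15 | diploid bottleneck producing strong rare-variant enrichment (drift F ≈ 3.7%) |
| `fst_regions` | (0.002, 0.015, 0.02) | an urban-center cluster plus two more-drifted regional subclusters |
| `n_cohort` / `n_trios` / `n_cases` / `n_controls` | 2323 / 318 / 1032 / 761 | the motivating cohort's subset sizes |
| `an_ref` | 113,770 | reference panel of gnomAD-NFE exome scale |
| `prevalence` | 0.00825 | IBD-scale population prevalence |
| class mix | syn 0.30 / mis 0.55 / pLoF 0.05 / other 0.10 | exome functional composition |
| class SFS scale | syn 1.0 / mis 0.8 / pLoF 0.3 | purifying selection keeps damaging classes rarer; the scale multiplies the Beta shape downward |

Trios ascertain one affected child; a heterozygous parent transmits the
risk allele with probability OR/(OR+1) at a planted site (the classic
multiplicative-risk transmission probability), 1/2 elsewhere, so children
are Mendelian-consistent by construction. Case/control phenotypes follow a
logistic liability in the planted dosages with the intercept anchored at
the population prevalence; individuals are rejection-sampled to fixed
quotas, and genotypes at non-planted sites (independent of phenotype) are
drawn only for retained individuals. All randomness flows from one integer
seed through `SeedSequence` spawning.

### What the generator does and does not emulate

It reproduces: unbiased drift with the closed-form variance, loss and
fixation, the heavy fold-enrichment tail among bottleneck survivors,
Balding–Nichols substructure, Hardy–Weinberg genotypes with configurable
missingness and read-depth fields, and planted trio/case-control effects.
It does **not** model post-bottleneck population expansion or new mutation
(so the simulated cohort's site-frequency spectrum is less singleton-heavy
than a real expanded founder population, and simulated enrichment
fractions among all observed variants are smaller than observed in real
cohorts), linkage disequilibrium (sites are independent, so LD pruning on
simulated data is a near no-op), sequencing error, or selection. Passing
tests therefore demonstrate the correctness and calibration of the
statistics under the stated model, not that real-data enrichment fractions
will match the simulated ones.

A note on one drift property: under this SFS, ~99% of source-rare sites
(MAF < 0.001) are lost in a 200×15 bottleneck, so the heavy tail is a
property of the *segregating* survivors — among source-rare sites still
present in the founder population, ≥ 10-fold enrichment holds for the
large majority (≈86% at N = 200), increasing as the bottleneck tightens.
Tests assert this conditional form.

## Numerical choices

* Exact-test enumeration is done in log space with `gammaln`, normalized
  over the support; the test suite checks both exact tests against
  exact-rational enumeration oracles at 1e−12.
* Probability ties in the mid-p rule use 1e−12 relative tolerance.
* PCA uses dense SVD (reference panels here are thousands of samples at
  most); mean imputation handles residual missingness.
* LD pruning drops the later-positioned variant of an r²-violating pair;
  ties and order are fully deterministic.
* Missingness fractions are computed as exact count ratios so the 5%
  boundary compares exactly against the 0.05 threshold.
* Degenerate inputs: monomorphic sites give HWE p = 1 and are skipped by
  association tests with a reason; zero-margin 2×2 tables give NaN with a
  warning; empty gene-set masks and empty variant intersections are errors.

## Problem sizes used by the test suite

Monte-Carlo checks run at sizes chosen to keep the default suite fast
while leaving clear statistical margins: TDT calibration at 300 trios ×
2,000 variants; enrichment null calibration at 10⁴ matched common sites;
the bottleneck class-ordering check at 120,000 sites (the pLoF-vs-
synonymous gap is ~1.2 percentage points, ~2.5σ at that size); burden
power and effect-recovery loops at 1,000 cases/1,000 controls over 25–30
seeds; the ancestry scene at 4,000 sites (assignment accuracy saturates at
100% well below that). All are seeded and deterministic.

## Known limitations

* The greedy unrelated-subset is not maximal; a maximum-independent-set
  solver would retain slightly more samples on dense relatedness graphs.
* No projection-shrinkage correction; two-stage assignment accuracy
  depends on panels being genotyped on largely overlapping variants.
* The logistic score test without saddlepoint correction is the documented
  stand-in for mixed-model single-variant machinery.
* The clinical prevalence estimator propagates no uncertainty in the
  language-fraction or coverage scalings.
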