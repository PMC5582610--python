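# Methods

This note records the statistical model behind each stage of `partsig`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter when
comparing output across implementations.

## Study container and normalization

An `ExpressionStudy` is a complete genes × samples matrix with per-sample
subject, tissue and phenotype annotations.  Missing values are refused at
load: every downstream formula (z-scores, pooled SDs, centroids) assumes a
full matrix, and imputation is out of scope.

z-scoring standardizes each gene over **all** samples jointly (sample SD,
ddof = 1).  Zero-variance genes are dropped with a warning rather than set
to zero, keeping later standardizations well defined.  Within-tissue
variability `s[g,t]` is the ddof-1 SD of a gene's z-scores over one
tissue's samples.  It is expressed in units of the gene's global SD but is
*not* itself a z-score, so no standard-normal tail fractions should be
expected; only the per-tissue fractions of genes exceeding 1 or 2 (strict
inequality) and the tissue ranking they imply are reported.

## Nearest shrunken centroid

The classifier follows the canonical soft-thresholding estimator.  Fitting
computes class centroids, the grand centroid, the pooled within-class SD
`s_i` (ddof adjusted by the class count), the fudge constant `s0` (median
of the `s_i`; percentile configurable, explicit override available), the
standardization factors `m_k = sqrt(1/n_k − 1/n)` and the standardized
differences `d_ik`.  Shrinking applies `d′ = sign(d)·max(|d| − Δ, 0)` and
reconstructs shrunken centroids.  Classification minimizes the squared
standardized distance to each shrunken centroid minus `2 log π_k`; priors
default to empirical class frequencies (uniform available), and argmin
ties break to the earliest class in the fixed order (PL, PNL, TL, TNL for
the four phenotypes).

The input is conventionally the z-scored matrix; raw normalized values
work identically because the estimator restandardizes per gene.

### Signature profile

`extract_signature` returns both views of the fitted sparsity:

- per class, the genes with `d′_ik ≠ 0`, with direction and magnitude (a
  gene may appear under several classes — a strongly class-k gene
  necessarily has small compensatory differences in the other classes);
- a **categorical profile** assigning each gene the single class of its
  largest `|d′|`, or *background* when all `d′` are zero.

The categorical profile is what the pathway and motif analyses condition
on, and what recovery benchmarks compare against planted truth; the
per-class lists are the full shrunken structure.

### Shrinkage selection

Two protocols are provided. In **nested** cross-validation the inner
10-fold CV picks, per outer training set, the grid Δ (30 points from 0 to
max |d|) with maximal mean accuracy, smallest Δ on ties. For a single
full-data choice, `select_delta_cv` defaults to the **one-standard-error
rule**: the largest Δ whose mean CV accuracy is within one SE (over folds)
of the best. Accuracy is typically flat over a wide Δ plateau; the 1-SE
rule lands on the sparse end of the plateau, which is the right choice
when the object of interest is a minimal signature rather than a fraction
of a percent of accuracy. `rule="max"` restores the plain maximum.

## Cross-validation and the permutation null

Folds are stratified by phenotype (scikit-learn's `StratifiedKFold`;
remainder samples are distributed so fold sizes differ by at most one per
class), reduced with a warning when the smallest class has fewer samples
than folds.  Samples are treated as independent by default, mirroring the
analysis design being reproduced; a `groups` argument
(`StratifiedGroupKFold`) keeps all samples of one subject in the same fold
for the stricter protocol.  Outer and inner fold RNG streams are
independent, both derived from the run seed.

Predictions pool over folds and repeats into a predicted × true confusion
matrix; per-class accuracy is the diagonal over the column sum and overall
accuracy the trace over the total, reported as percents (the exact
identity `overall = Σ_k (n_k/n)·acc_k` holds by construction).

The permutation test permutes labels uniformly, reruns the complete
(optionally nested) CV per permutation, and counts permutations reaching
the observed accuracy.  With `b` exceedances in `n` permutations the exact
permutation p-value is bounded by the Clopper-Pearson upper limit
(`statsmodels` beta method; for `b = 0` the closed form
`1 − (α/2)^(1/n)`, e.g. 0.036 at n = 100).

## Information-theoretic enrichment

Mutual information is computed in bits on the observed contingency table
between a binary gene attribute (set membership, motif presence) and the
categorical profile, with `0·log 0 = 0`; inputs with a single distinct
value carry no information and return 0.  Conditional MI on the
2 × 2 × C table is `Σ_z p(z)·MI(X;Y|Z=z)`.

Significance is by randomization: the profile is shuffled over genes,
giving a Z-score `(MI_obs − mean)/SD` and an add-one empirical p
`(1 + #{MI_rand ≥ MI_obs})/(1 + n_rand)` (never zero; the attainable
minimum is `1/(1+n_rand)`, so `n_rand` must exceed `1/α − 1` for a level-α
test).  Conditional-MI tests shuffle the profile **within the strata of
the conditioning attribute**, which preserves the conditioning margin and
targets exactly the conditional null.

The pathway pass ranks marginally significant sets by MI and greedily
accepts a set only if its conditional MI given *each* already-accepted set
passes its randomization test — duplicates (CMI = 0) are rejected, and the
filter is idempotent on its own output.  Heat-map cells are signed log10
hypergeometric tails over the gene universe of the analyzed matrix:
positive `−log10 P(X ≥ k)` when the overlap exceeds its expectation,
negative `log10 P(X ≤ k)` otherwise (ties fall to the under side).  The
external background-expression compendium used by the published pathway
tool is deliberately replaced by the profile's own background category.

## Motif discovery

Sequences are handled internally on the DNA alphabet (U read as T; 3'UTR
motifs rendered back with U), scanned single-strand — regulatory-element
orientation is meaningful and the consensus patterns are oriented.  `N` in
input sequences never matches.  Presence is binary per gene (≥ 1 match,
overlaps allowed); match counts are not used.

**Seeds.**  All 4⁷ = 16384 exact 7-mers are scored at once by MI between
their presence vectors and the profile.  Because the whole seed family is
tested, each seed's empirical p is computed against the null distribution
of the **maximum** seed MI over profile shuffles (default 1000).  This
family-wise calibration makes the seed stage honest: on fully random
sequences the probability that *any* seed reaches p < 0.001 is about
0.001, whereas a per-seed null would flag ~16 seeds per region by chance.

**Optimization.**  Each significant seed is placed at every offset inside
a 9-position window (flanks fully degenerate) and hill-climbed: for each
position in turn, all 15 non-empty base subsets are evaluated and the best
strictly-MI-increasing edit kept, iterating until a full pass yields no
gain, under a cap of 4 degenerate positions (prevents drift toward all-N;
the motifs this pipeline is modeled on have at most 4).  The search is
deterministic given the seed and scan order, and final MI never falls
below the seed's.  Near-duplicates are collapsed by the same
conditional-MI criterion as pathways.

**Statistics per motif.**  Randomization Z and empirical p (default 10⁴
shuffles); a jack-knife robustness score — of 10 trials each dropping a
uniform third of the genes, how many retain significance (motifs below
6/10 are conventionally discarded); per-category signed hypergeometric
enrichment with Bonferroni correction over (#motifs × #categories) tests;
motif-pathway association by the same hypergeometric overlap (symmetric in
the two sets); and pairwise co-occurrence.

**Co-occurrence p-values are exact.**  For two binary presence vectors
with fixed margins, every permutation outcome is determined by the
co-presence count, which follows a hypergeometric law; the permutation p
(total probability of counts with MI ≥ observed) is therefore enumerated
exactly rather than sampled.  This also resolves p-values far below the
10⁻⁴ flag threshold that sampling could not.

**Library matching** sweeps a named IUPAC pattern across the motif window;
a position is compatible when the symbol subsets intersect, and a motif
position outside a shorter library pattern counts only if the motif leaves
it fully degenerate.  The score is the best fraction of the 9 window
positions compatible; "no match" (empty or low-scoring library) is a
legitimate outcome.

## qPCR

Technical duplicates are averaged on the Ct scale, then
`ΔCt = Ct_target − Ct_reference` per sample, `ΔΔCt` against the control
group's mean ΔCt per gene, `fold = 2^−ΔΔCt`.  Group summaries are
geometric means of folds (arithmetic means of ΔΔCt), the convention under
the exponential transform, making the control group's summary fold exactly
1.  Adding any constant to all Ct values leaves folds unchanged.  The
control phenotype defaults to TNL (maintained pregnancy), configurable.
A one-way ANOVA across groups is included as reporting plumbing only.

## Synthetic data

The generator emulates the motivating study design: 183 samples from 35
subjects (PL 34 samples / 8 subjects, PNL 55/10, TL 38/7, TNL 56/10)
across eight tissues, with a planted disjoint signature of 50 PL (46 up,
4 down), 6 PNL (up), 6 TL (5 up, 1 down) and 23 TNL (all down) genes at a
common effect size, 2 SD by default.

The base model is per-gene Gaussian: mean ~ N(7, 1) (log2-intensity-like),
SD log-normal (median 0.4).  Tissue structure enters as (i) an additive
per-(gene, tissue) offset with SD 0.5 of the gene's base SD — stable
tissue-specific expression — and (ii) a per-tissue variance multiplier (4
for decidua, chorion and amnion, 2 for placenta, 1 elsewhere) applied to
the noise **and, via its square root, to the planted class effect**.  The
interface tissues therefore carry both the largest within-tissue spread
and the cross-phenotype signal, which is the structure the tissue-ranking
stage is designed to detect; a noise-only multiplier would make those
tissues merely noisy and would bury rather than express the phenotype
differences.  The per-tissue sample allocation is round-robin within each
phenotype (near-balanced; the true per-tissue counts were not published
and are exposed as configuration).  Samples are generated independently —
subject ids are recorded and a within-subject intercept knob exists but
defaults to 0, mirroring the treat-as-independent analysis assumption.

Sequences are uniform random ACGT with planted consensi (one concrete
instance drawn uniformly from the degenerate pattern, uniform position)
inserted with probability 0.9 into the target phenotypes' genes: an
NF-kB-like `GG[AT]AA[AT]TC[CT]` in the promoters of PL/PNL/TNL genes, a
second promoter element `AA[AT]TTGA` in PL/PNL, and a 3'UTR element
`[ACU]CU[CG]C[AG]CA[ACG]` in TNL.  Gene sets overlap a phenotype's
signature at a configurable Jaccard (0.8 by default; the overlap count is
`round(j(m+s)/(1+j))`, refused when infeasible), plus uniform decoys.

**What it does not emulate:** probe-level microarray noise, RMA artifacts,
batch effects, within-subject correlation (unless enabled), heavy-tailed
expression, linked or clustered motif positions, and realistic pathway
overlap structure.  Passing recovery tests therefore demonstrates that the
machinery is correct and calibrated under the stated model, not that real
tissue data would classify at these accuracies.

### Benchmark scales

Tests and the acceptance script use three problem sizes, chosen to keep a
full run in minutes on one CPU while preserving the design's proportions:

- full-scale classifier benchmark: 2000 genes × 183 samples (the gene
  count stands in for the ~20k-gene array; all sample structure is at the
  study's true size), nested 10×10 CV;
- permutation benchmark: 600 genes, 20 permutations of a single-repeat
  nested CV (inner 5-fold, 15-point grid);
- motif benchmark: 600 genes × 300 nt promoter and 3'UTR, categorical
  profile PL 120 / PNL 80 / TL 60 / TNL 120 / background 220, insertion
  probability 0.9.  The published analysis searched the ~73 signature
  genes against a large background compendium; at desk scale the category
  sizes are enlarged so the MI statistics remain informative, which is the
  honest analogue rather than a miniature replica.

## Numerical conventions and degenerate inputs

Sample SD (ddof = 1) everywhere; strict inequalities in the variability
filter; add-one empirical p-values; argmin/argmax ties to the first index
in fixed orders; z-score row constraints hold to 1e-9 and oracle
comparisons to 1e-12.  Single samples, single classes, classes with fewer
than two samples, tissues with fewer than two samples, negative shrinkage,
infeasible overlaps, malformed IUPAC symbols, missing reference Ct and
unknown control groups all raise `ValueError` with the offending item
named.

## Known limitations

The full-dataset z-scoring used before cross-validation follows the
reproduced protocol and leaks a small amount of global scale information
across folds; the nested-CV accuracy is honest about shrinkage selection
but not about normalization.  The hill-climb motif search is a local
optimizer — with weak planted signal it can return a flank-shifted or
partially degenerate variant of the true consensus (benchmarks compare at
a ≥ 8/9-position agreement for this reason).  MI-based enrichment is
universe-dependent: results change if the analyzed gene universe changes.
The qPCR module assumes perfect amplification efficiency (no standard
curves).
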