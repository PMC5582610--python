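# partsig

Phenotype signature discovery for parturition transcriptomes.

Human birth can be viewed as four complementary clinical phenotypes —
preterm with labor (PL), preterm without labor (PNL, delivery medically
indicated), term with labor (TL) and term without labor (TNL).  Profiling
expression across the tissues of the pregnant uterus (maternal and fetal
blood, chorion, amnion, placenta, decidua, fundus and lower-segment
myometrium) and asking which genes *uniquely* identify each phenotype
separates the processes that precede labor from the common final pathway
of labor itself.  `partsig` is a tested, reusable implementation of that
analysis for anyone who wants to run it on their own expression matrix or
study its statistical behavior: tissue variability profiling,
sparse-signature classification with honest cross-validated error
estimates, and information-theoretic enrichment of pathways and
cis-regulatory elements.  A first-class synthetic-data generator plants
known truth at the study's scale so every stage is verifiable end to end.

## The methods

**Tissue variability.** With z-scores
`z[g,i] = (x[g,i] − μ_g)/σ_g` over the full data set, the within-tissue SD
`s[g,t]` measures how far tissue *t*'s samples spread across the four
phenotypes in units of the gene's global SD.  The fraction of genes with
`s[g,t] > 1` (or `> 2`) ranks tissues by cross-phenotype expression
difference.

**Nearest shrunken centroid.** Standardized centroid differences
`d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0))`, `m_k = √(1/n_k − 1/n)`, are
soft-thresholded, `d′_ik = sign(d_ik)·max(|d_ik| − Δ, 0)`, pulling class
centroids toward the grand centroid and zeroing uninformative genes.  A
sample is assigned to `argmin_k Σ_i (x_i − x̄′_ik)²/(s_i + s0)² − 2 log π_k`.
The surviving genes form a sparse per-phenotype signature with direction.

**Evaluation.** Repeated stratified 10×10-fold cross-validation, with Δ
selected per outer training set by an inner 10-fold CV (nested mode) or
fixed.  A permutation null re-runs the full nested CV on label-shuffled
data; when no permutation reaches the observed accuracy the exact
permutation p is bounded by the Clopper-Pearson upper limit
`1 − (α/2)^(1/n_perm)`.

**Pathway and motif information.** Gene sets and degenerate 9-position
motifs (IUPAC subsets per position, discovered from all 4⁷ exact 7-mer
seeds by MI hill climbing) are scored by mutual information with the
categorical signature profile, with randomization Z-scores, conditional-MI
redundancy filters, jack-knife robustness, and signed log10 hypergeometric
over/under-representation per phenotype.

**qPCR.** `2^−ΔΔCt` fold changes against a reference gene and control
group, for the validation arm.

## Worked example

```python
import partsig as ps

design = ps.default_design(n_genes=2000, seed=1)
truth  = ps.default_truth(design, effect=2.0)   # planted 50/6/6/23 signature
study  = ps.generate_study(design, truth)

z = ps.zscore_normalize(study)
y = study.phenotypes.values

delta   = ps.select_delta_cv(z.z, y, folds=10, repeats=2, seed=1)
model   = ps.shrink(ps.fit(z.z, y), delta)
profile = ps.extract_signature(model)
print(profile.summary())
```

prints

```
class   genes(n)
PL      50
PNL     7
TL      7
TNL     23
unique signature genes  85
```

— the planted 50/6/6/23 signature recovered at the CV-selected shrinkage
(Δ = 2.85; the categorical gene→phenotype assignment matches the planted
truth at Jaccard 1.0 for every class).  Nested 10×10 cross-validation on
the same study reports 99.4 % accuracy, against a 25 % uninformed
baseline, and 20/20 label permutations fall below the observed accuracy
(permutation p < 0.168 at that permutation count; 100 permutations would
bound it at 0.036).  The scripts in `examples/` walk through each
capability — simulation, tissue ranking, signature discovery,
cross-validation with the permutation null, pathway enrichment, motif
discovery, qPCR fold changes — each printing the numbers above or their
analogues with a line on how to read them.

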