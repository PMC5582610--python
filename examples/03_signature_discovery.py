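"""Discover the per-phenotype gene signature with the shrunken-centroid model.

Fits class centroids on z-scored expression, picks the shrinkage by
cross-validation (one-standard-error rule) and extracts the sparse
signature: which genes uniquely identify each phenotype and in which
direction.
"""

import partsig as ps

design = ps.default_design(n_genes=2000, seed=1)
truth = ps.default_truth(design, effect=2.0)
study = ps.generate_study(design, truth)
z = ps.zscore_normalize(study)
y = study.phenotypes.values

delta = ps.select_delta_cv(z.z, y, folds=10, repeats=2, seed=1)
model = ps.shrink(ps.fit(z.z, y), delta)
profile = ps.extract_signature(model)

print(f"selected shrinkage delta = {delta:.2f}")
print(profile.summary())
for c in model.classes:
    planted = set(truth.signature[c].index)
    recovered = set(profile.categories.index[profile.categories == c])
    j = len(planted & recovered) / len(planted | recovered)
    print(f"{c}: Jaccard vs planted truth = {j:.2f}")
# per-class gene counts follow the planted 50/6/6/23 design; a Jaccard of
# 1.0 means the signature recovered exactly the planted genes
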