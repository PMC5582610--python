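"""Generate a synthetic parturition study and write its standard files.

Builds the default design (183 samples, 35 subjects, 8 tissues, four
phenotypes) with a planted 50/6/6/23 gene signature at effect size 2 SD,
then writes the expression matrix, sample metadata, gene sets and
regulatory sequences that the other examples consume.
"""

from pathlib import Path

import partsig as ps

OUT = Path("example_output")
OUT.mkdir(exist_ok=True)

design = ps.default_design(n_genes=2000, seed=1)
truth = ps.default_truth(design, effect=2.0)
study = ps.generate_study(design, truth)
study.to_tsv(OUT / "expression.tsv", OUT / "samples.tsv")

gmt = ps.generate_pathways(study.genes, truth, n_sets=20, seed=1)
gmt.to_gmt(OUT / "pathways.gmt")

seqs = ps.generate_sequences(study.genes, truth, promoter_len=300,
                             utr_len=300, seed=1)
seqs.to_fasta(OUT / "promoters.fa", "promoter")
seqs.to_fasta(OUT / "utr3.fa", "utr3")

print(f"expression matrix: {study.values.shape[0]} genes x "
      f"{study.values.shape[1]} samples")
print("samples per phenotype:", study.phenotype_counts().to_dict())
print("planted signature sizes:",
      {k: len(v) for k, v in truth.signature.items()})
# the counts mirror the emulated study design; every downstream example
# can recover the planted structure from these files alone
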