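"""Synthetic parturition expression studies with planted ground truth.

The generator emulates the design of the motivating study: 183 tissue
samples from 35 subjects spanning eight uterine/gestational tissues and the
four parturition phenotypes (PL n=34 samples / 8 subjects, PNL 55/10,
TL 38/7, TNL 56/10), with a sparse planted signature (50 PL, 6 PNL, 6 TL,
23 TNL genes; most PL genes up-regulated, all TNL genes down-regulated),
tissue-dependent variance concentrated at the maternal-fetal interface,
planted gene sets overlapping the signatures, and degenerate regulatory
motifs planted in promoter/3'UTR sequences.  Every downstream stage of the
pipeline can therefore be tested against known truth without any download.

The base expression model is per-gene Gaussian (gene-specific mean and SD)
with an additive per-(gene, tissue) offset and a multiplicative per-tissue
noise-variance factor; signature genes of phenotype k shift their mean by
±effect x SD in samples of class k only.  Samples are generated
independently (subject ids are recorded; a within-subject intercept knob
defaults to 0), mirroring the treat-samples-as-independent analysis
assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import motifs as motiflib
from .study import ExpressionStudy, INTERFACE_TISSUES, PHENOTYPES, TISSUES

__all__ = [
    "StudyDesign", "PlantedTruth", "PlantedMotif", "PlantedPathway",
    "SequenceSet", "PathwayCollection", "default_design", "default_truth",
    "generate_study", "generate_sequences", "generate_pathways",
    "truth_categories", "motif_benchmark",
]

#: default planted consensi: an NF-kB-like promoter element, a second
#: promoter element with no known counterpart, and a 3'UTR element
MOTIF_A = "GG[AT]AA[AT]TC[CT]"
MOTIF_B = "AA[AT]TTGA"
MOTIF_C = "[ACT]CT[CG]C[AG]CA[ACG]"


@dataclass
class StudyDesign:
    """Sampling design of a synthetic study."""

    n_genes: int = 2000
    phenotype_samples: dict = field(
        default_factory=lambda: {"PL": 34, "PNL": 55, "TL": 38, "TNL": 56})
    subjects_per_phenotype: dict = field(
        default_factory=lambda: {"PL": 8, "PNL": 10, "TL": 7, "TNL": 10})
    tissues: tuple = TISSUES
    #: per-tissue multiplicative factor on the noise variance; the
    #: maternal-fetal interface gets the largest cross-phenotype spread
    variance_multipliers: dict = field(
        default_factory=lambda: {
            **{t: 1.0 for t in TISSUES},
            "decidua": 4.0, "chorion": 4.0, "amnion": 4.0, "placenta": 2.0})
    #: SD of the per-(gene, tissue) additive offset, in units of the
    #: gene's base SD
    tissue_offset_sd: float = 0.5
    #: SD of an optional per-(gene, subject) intercept, in base-SD units
    within_subject_sd: float = 0.0
    base_mean: float = 7.0       # log2-intensity-like location
    base_mean_sd: float = 1.0
    base_sd_log_mean: float = float(np.log(0.4))
    base_sd_log_sd: float = 0.3
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(self.phenotype_samples.values())

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for ph, n in self.phenotype_samples.items():
            if n <= 0:
                raise ValueError(f"phenotype {ph!r} has zero samples")
        for ph in self.phenotype_samples:
            if self.subjects_per_phenotype.get(ph, 0) <= 0:
                raise ValueError(f"phenotype {ph!r} has no subjects")


@dataclass
class PlantedMotif:
    """A degenerate consensus planted in one region of target-phenotype genes."""

    consensus: str
    region: str                      # "promoter" or "utr3"
    phenotypes: tuple
    insertion_probability: float = 0.9


@dataclass
class PlantedPathway:
    """A gene set overlapping one phenotype's signature at a target Jaccard."""

    name: str
    phenotype: str
    jaccard: float = 0.8
    size: int | None = None          # defaults to the signature size


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic study.

    ``signature`` maps each phenotype to a DataFrame indexed by gene id
    with columns ``direction`` (+1 up / -1 down) and ``effect`` (mean
    shift in base-SD units, >= 0).
    """

    signature: dict
    planted_motifs: list = field(default_factory=list)
    planted_pathways: list = field(default_factory=list)

    def validate(self, genes=None) -> None:
        seen = {}
        for ph, table in self.signature.items():
            if (table["effect"] < 0).any() or not np.isfinite(
                    table["effect"]).all():
                raise ValueError(f"effects for {ph!r} must be finite and >= 0")
            for g in table.index:
                seen.setdefault(g, []).append(ph)
            if genes is not None:
                unknown = table.index.difference(genes)
                if len(unknown):
                    raise ValueError(
                        f"signature genes not in study: {list(unknown)[:5]}")

    def signature_genes(self, phenotype: str) -> list:
        return list(self.signature.get(phenotype, pd.DataFrame()).index)


def default_design(n_genes: int = 2000, seed: int = 0) -> StudyDesign:
    """The emulated study design at the package's default gene count."""
    return StudyDesign(n_genes=n_genes, seed=seed)


def default_truth(design: StudyDesign, effect: float = 2.0,
                  include_motifs: bool = True,
                  include_pathways: bool = True) -> PlantedTruth:
    """Default planted truth mirroring the study's reported signature.

    50 PL genes (46 up, 4 down), 6 PNL genes (all up), 6 TL genes (5 up,
    1 down) and 23 TNL genes (all down), disjoint, at a common effect
    size; one planted pathway per phenotype at Jaccard 0.8; the three
    default motifs planted in promoter (PL/PNL/TNL and PL/PNL) and 3'UTR
    (TNL) of their target-phenotype genes.
    """
    sizes = {"PL": 50, "PNL": 6, "TL": 6, "TNL": 23}
    n_down = {"PL": 4, "PNL": 0, "TL": 1, "TNL": 23}
    rng = np.random.default_rng([design.seed, 101])
    genes = _gene_ids(design.n_genes)
    chosen = rng.choice(design.n_genes, size=sum(sizes.values()), replace=False)
    signature = {}
    pos = 0
    for ph in PHENOTYPES:
        idx = chosen[pos:pos + sizes[ph]]
        pos += sizes[ph]
        direction = np.ones(len(idx), dtype=int)
        direction[: n_down[ph]] = -1
        signature[ph] = pd.DataFrame(
            {"direction": direction, "effect": effect},
            index=pd.Index([genes[i] for i in idx], name="gene"),
        )
    planted_motifs = []
    if include_motifs:
        planted_motifs = [
            PlantedMotif(MOTIF_A, "promoter", ("PL", "PNL", "TNL")),
            PlantedMotif(MOTIF_B, "promoter", ("PL", "PNL")),
            PlantedMotif(MOTIF_C, "utr3", ("TNL",)),
        ]
    planted_pathways = []
    if include_pathways:
        planted_pathways = [
            PlantedPathway(f"PLANTED_{ph}", ph, jaccard=0.8)
            for ph in PHENOTYPES
        ]
    return PlantedTruth(signature=signature, planted_motifs=planted_motifs,
                        planted_pathways=planted_pathways)


def _gene_ids(n: int) -> list:
    return [f"G{i:05d}" for i in range(n)]


def generate_study(design: StudyDesign, truth: PlantedTruth) -> ExpressionStudy:
    """Draw one expression study from the design with the planted truth.

    Reproducible: the matrix is a pure function of (design, truth,
    design.seed).
    """
    design.validate()
    genes = _gene_ids(design.n_genes)
    truth.validate(genes=pd.Index(genes))
    rng = np.random.default_rng([design.seed, 7])

    # sample table: phenotypes in canonical order, tissues round-robin so
    # each tissue sees all phenotypes, subjects cycled within phenotype
    records = []
    i = 0
    for ph in design.phenotype_samples:
        n = design.phenotype_samples[ph]
        n_subj = design.subjects_per_phenotype[ph]
        for j in range(n):
            records.append({
                "sample": f"S{i:03d}",
                "subject": f"{ph}_subj{j % n_subj:02d}",
                "tissue": design.tissues[j % len(design.tissues)],
                "phenotype": ph,
            })
            i += 1
    samples = pd.DataFrame(records).set_index("sample")

    G, S = design.n_genes, len(samples)
    mu = rng.normal(design.base_mean, design.base_mean_sd, size=G)
    sigma = rng.lognormal(design.base_sd_log_mean, design.base_sd_log_sd,
                          size=G)
    tissue_list = list(design.tissues)
    offsets = rng.normal(0.0, 1.0, size=(G, len(tissue_list)))
    offsets *= design.tissue_offset_sd * sigma[:, None]
    t_idx = np.array([tissue_list.index(t) for t in samples["tissue"]])
    vmult = np.array([design.variance_multipliers.get(t, 1.0)
                      for t in samples["tissue"]])

    x = mu[:, None] + offsets[:, t_idx]
    x += np.sqrt(vmult)[None, :] * sigma[:, None] * rng.normal(size=(G, S))

    if design.within_subject_sd > 0:
        subjects = samples["subject"].to_numpy()
        uniq = pd.unique(subjects)
        subj_eff = rng.normal(0.0, 1.0, size=(G, len(uniq)))
        subj_eff *= design.within_subject_sd * sigma[:, None]
        s_idx = np.array([list(uniq).index(s) for s in subjects])
        x += subj_eff[:, s_idx]

    # planted class effects scale with the tissue factor (sqrt of the
    # variance multiplier): the cross-phenotype differences, not just the
    # noise, concentrate in the high-variability interface tissues
    gene_pos = {g: i for i, g in enumerate(genes)}
    ph_arr = samples["phenotype"].to_numpy()
    sqrt_vmult = np.sqrt(vmult)
    for ph, table in truth.signature.items():
        cols = ph_arr == ph
        for g, row in table.iterrows():
            gi = gene_pos[g]
            x[gi, cols] += (row["direction"] * row["effect"] * sigma[gi]
                            * sqrt_vmult[cols])

    values = pd.DataFrame(x, index=pd.Index(genes, name="gene"),
                          columns=samples.index)
    return ExpressionStudy(values=values, samples=samples)


def truth_categories(truth: PlantedTruth, genes) -> pd.Series:
    """Planted categorical profile: phenotype of each signature gene, else
    ``background``.  Genes planted under several phenotypes take the first
    in canonical order."""
    cats = pd.Series("background", index=pd.Index(genes), name="category")
    for ph in reversed([p for p in truth.signature]):
        cats.loc[cats.index.intersection(truth.signature[ph].index)] = ph
    return cats


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """Per-gene 5' promoter and 3'UTR sequences (DNA, 5'->3')."""

    promoters: dict
    utr3: dict

    @property
    def genes(self) -> list:
        return list(self.promoters)

    def region_dict(self, region: str) -> dict:
        if region == "promoter":
            return self.promoters
        if region == "utr3":
            return self.utr3
        raise ValueError(f"unknown region {region!r}")

    def to_fasta(self, path, region: str) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(s), id=g, description=region)
                   for g, s in self.region_dict(region).items()]
        write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, promoter_path, utr_path) -> "SequenceSet":
        from Bio import SeqIO

        def read(path):
            return {rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(str(path), "fasta")}

        return cls(promoters=read(promoter_path), utr3=read(utr_path))


def generate_sequences(genes, truth: PlantedTruth, promoter_len: int = 1000,
                       utr_len: int = 500, seed: int = 0) -> SequenceSet:
    """Random promoter/3'UTR sequences with the planted motifs inserted.

    Each planted consensus is inserted (one concrete instance drawn
    uniformly from the degenerate pattern, at a uniform random position)
    with its stated probability into the genes of its target phenotypes.
    """
    genes = list(genes)
    rng = np.random.default_rng([seed, 31])
    lengths = {"promoter": promoter_len, "utr3": utr_len}
    for pm in truth.planted_motifs:
        pat_len = motiflib.parse_pattern(pm.consensus).shape[0]
        if pat_len > lengths[pm.region]:
            raise ValueError(
                f"motif {pm.consensus!r} ({pat_len} nt) longer than its "
                f"{pm.region} region ({lengths[pm.region]} nt)")
    if min(promoter_len, utr_len) < 9:
        raise ValueError("regions must be at least 9 nt")

    def random_seq(length):
        return "".join(np.array(list("ACGT"))[rng.integers(4, size=length)])

    promoters = {g: random_seq(promoter_len) for g in genes}
    utrs = {g: random_seq(utr_len) for g in genes}
    store = {"promoter": promoters, "utr3": utrs}
    for pm in truth.planted_motifs:
        pat = motiflib.parse_pattern(pm.consensus)
        targets = set()
        for ph in pm.phenotypes:
            targets.update(truth.signature_genes(ph))
        for g in genes:
            if g not in targets:
                continue
            if rng.random() >= pm.insertion_probability:
                continue
            inst = motiflib.sample_instance(pat, rng)
            seqs = store[pm.region]
            pos = rng.integers(0, len(seqs[g]) - len(inst) + 1)
            seqs[g] = seqs[g][:pos] + inst + seqs[g][pos + len(inst):]
    return SequenceSet(promoters=promoters, utr3=utrs)


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

class PathwayCollection(dict):
    """Named gene sets; a dict of name -> list of gene ids with GMT I/O."""

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.items():
                fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")

    @classmethod
    def from_gmt(cls, path) -> "PathwayCollection":
        out = cls()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[0]:
                    out[parts[0]] = parts[2:]
        return out

    def membership_matrix(self, genes) -> pd.DataFrame:
        genes = pd.Index(genes)
        return pd.DataFrame(
            {name: genes.isin(members) for name, members in self.items()},
            index=genes,
        )


def generate_pathways(genes, truth: PlantedTruth, n_sets: int = 20,
                      set_size_range: tuple = (10, 50),
                      seed: int = 0) -> PathwayCollection:
    """Planted gene sets at their target Jaccard plus uniform decoy sets.

    The planted overlap count is ``round(j*(m+s)/(1+j))`` for a signature
    of size m, a set of size s and target Jaccard j; an overlap outside
    [1, min(m, s)] (or a set larger than the universe allows) is refused.
    """
    genes = list(genes)
    rng = np.random.default_rng([seed, 53])
    out = PathwayCollection()
    for spec in truth.planted_pathways:
        sig = truth.signature_genes(spec.phenotype)
        m = len(sig)
        s = spec.size if spec.size is not None else m
        if s > len(genes):
            raise ValueError(f"set size {s} exceeds universe {len(genes)}")
        a = int(round(spec.jaccard * (m + s) / (1 + spec.jaccard)))
        if not 1 <= a <= min(m, s):
            raise ValueError(
                f"requested Jaccard {spec.jaccard} infeasible for signature "
                f"size {m} and set size {s}")
        inside = list(rng.choice(sig, size=a, replace=False))
        pool = [g for g in genes if g not in set(sig)]
        if s - a > len(pool):
            raise ValueError("not enough non-signature genes for the set")
        outside = list(rng.choice(pool, size=s - a, replace=False))
        out[spec.name] = inside + outside
    lo, hi = set_size_range
    if hi > len(genes):
        raise ValueError("set sizes must not exceed the number of genes")
    for d in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        out[f"DECOY_{d:03d}"] = list(rng.choice(genes, size=size,
                                                replace=False))
    return out


# ---------------------------------------------------------------------------
# motif benchmark
# ---------------------------------------------------------------------------

def motif_benchmark(n_genes: int = 600, promoter_len: int = 300,
                    utr_len: int = 300, insertion_probability: float = 0.9,
                    category_sizes: dict | None = None, plant: bool = True,
                    seed: int = 0):
    """Desk-scale benchmark for the motif pipeline.

    Builds a categorical gene profile (default 120 PL / 80 PNL / 60 TL /
    120 TNL / 220 background genes), plants the three default motifs in
    the regions and phenotypes of their targets (unless ``plant`` is
    False, giving a null data set), and returns
    ``(profile, sequences, truth)``.
    """
    if category_sizes is None:
        category_sizes = {"PL": 120, "PNL": 80, "TL": 60, "TNL": 120}
    if sum(category_sizes.values()) > n_genes:
        raise ValueError("category sizes exceed the number of genes")
    genes = _gene_ids(n_genes)
    rng = np.random.default_rng([seed, 71])
    order = rng.permutation(n_genes)
    signature = {}
    pos = 0
    for ph in category_sizes:
        idx = order[pos:pos + category_sizes[ph]]
        pos += category_sizes[ph]
        signature[ph] = pd.DataFrame(
            {"direction": 1, "effect": 0.0},
            index=pd.Index([genes[i] for i in idx], name="gene"))
    planted = []
    if plant:
        planted = [
            PlantedMotif(MOTIF_A, "promoter", ("PL", "PNL", "TNL"),
                         insertion_probability),
            PlantedMotif(MOTIF_B, "promoter", ("PL", "PNL"),
                         insertion_probability),
            PlantedMotif(MOTIF_C, "utr3", ("TNL",), insertion_probability),
        ]
    truth = PlantedTruth(signature=signature, planted_motifs=planted)
    seqs = generate_sequences(genes, truth, promoter_len=promoter_len,
                              utr_len=utr_len, seed=seed)
    profile = truth_categories(truth, genes)
    return profile, seqs, truth
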