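"""De novo discovery of degenerate cis-regulatory motifs by mutual information.

The search asks whether the presence of a short degenerate element in a
gene's 5' promoter or 3'UTR is informative about which phenotype the gene's
expression identifies.  Candidate seeds are the complete set of exact
7-mers; each significant seed is expanded to a 9-position degenerate motif
(IUPAC subsets per position) by hill climbing on MI, then vetted by a
jack-knife robustness score, collapsed for redundancy with conditional MI,
and characterized by per-category hypergeometric enrichment, motif-pathway
association and pairwise co-occurrence.

Seed significance is assessed family-wise: because all 4^7 = 16384 seeds
are scored per region, each seed's empirical p is computed against the null
distribution of the *maximum* seed MI over profile shuffles, so a fully
random sequence set yields no significant seed at p < 0.001 in almost every
run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import infotheory

__all__ = [
    "Motif", "parse_pattern", "render_pattern", "sample_instance",
    "EncodedRegion", "scan_presence", "seed_scan", "optimize_motif",
    "jackknife_robustness", "motif_category_enrichment",
    "motif_pathway_association", "motif_cooccurrence", "match_known",
    "discover_motifs", "consensus_agreement",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: IUPAC degeneracy codes over the DNA alphabet (U is accepted as T)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_SUBSET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items() if k != "U"}


def parse_pattern(pattern: str) -> np.ndarray:
    """Parse a degenerate consensus into a (L, 4) boolean allowed matrix.

    Accepts IUPAC one-letter codes (RNA ``U`` read as ``T``) and explicit
    bracket groups, e.g. ``GG[AT]AA[AT]TC[CT]``.
    """
    allowed = []
    i = 0
    s = pattern.upper()
    while i < len(s):
        ch = s[i]
        if ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed bracket in pattern {pattern!r}")
            group = s[i + 1:j]
            if not group:
                raise ValueError(f"empty bracket group in pattern {pattern!r}")
            bases = set()
            for g in group:
                if g not in IUPAC:
                    raise ValueError(f"malformed IUPAC symbol {g!r} in {pattern!r}")
                bases.update(IUPAC[g])
            i = j + 1
        else:
            if ch not in IUPAC:
                raise ValueError(f"malformed IUPAC symbol {ch!r} in {pattern!r}")
            bases = set(IUPAC[ch])
            i += 1
        row = np.zeros(4, dtype=bool)
        for b in bases:
            row[_BASE_INDEX[b]] = True
        allowed.append(row)
    return np.array(allowed, dtype=bool)


def render_pattern(allowed: np.ndarray, rna: bool = False) -> str:
    """Render an allowed matrix in bracket notation (``N`` for all four).

    With ``rna=True`` thymine is written as uracil, the convention for
    3'UTR motifs.
    """
    out = []
    for row in np.asarray(allowed, dtype=bool):
        bases = [b for b, ok in zip(_BASES, row) if ok]
        if not bases:
            raise ValueError("position with empty symbol set")
        txt = "".join(bases)
        if rna:
            txt = txt.replace("T", "U")
        if len(bases) == 1:
            out.append(txt)
        elif len(bases) == 4:
            out.append("N")
        else:
            out.append(f"[{txt}]")
    return "".join(out)


def sample_instance(allowed: np.ndarray, rng) -> str:
    """Draw one concrete sequence uniformly from a degenerate consensus."""
    letters = []
    for row in np.asarray(allowed, dtype=bool):
        options = [b for b, ok in zip(_BASES, row) if ok]
        letters.append(options[rng.integers(len(options))])
    return "".join(letters)


@dataclass
class Motif:
    """A degenerate motif with its information statistics."""

    allowed: np.ndarray                    # (L, 4) bool
    region: str                            # "promoter" or "utr3"
    mi: float = float("nan")               # bits
    z: float = float("nan")
    p: float = float("nan")
    robustness: int | None = None          # passing jack-knife trials out of 10
    enrichment: pd.Series | None = None    # per-category signed log10 p
    bonferroni: pd.Series | None = None
    seed_kmer: str | None = None

    @property
    def pattern(self) -> str:
        return render_pattern(self.allowed, rna=(self.region == "utr3"))

    @property
    def pattern_dna(self) -> str:
        return render_pattern(self.allowed, rna=False)

    @property
    def n_degenerate(self) -> int:
        return int(np.sum(self.allowed.sum(axis=1) > 1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Motif({self.pattern}, region={self.region}, MI={self.mi:.4f},"
                f" Z={self.z:.1f}, robustness={self.robustness})")


# ---------------------------------------------------------------------------
# sequence encoding and scanning
# ---------------------------------------------------------------------------

class EncodedRegion:
    """Sequences of one region encoded for fast degenerate-pattern scanning.

    Precomputes, for each base and each of the ``window`` offsets, the
    boolean gene x window-start matrix of positions carrying that base, so
    a candidate motif's presence vector is an OR/AND cascade of cached
    masks.  ``N`` in input sequences never matches.
    """

    def __init__(self, sequences: dict, genes=None, window: int = 9):
        if genes is None:
            genes = list(sequences)
        self.genes = list(genes)
        self.window = window
        seqs = [sequences[g].upper().replace("U", "T") for g in self.genes]
        lengths = [len(s) for s in seqs]
        if min(lengths) < window:
            raise ValueError(
                f"sequences must be at least {window} nt (shortest is "
                f"{min(lengths)})")
        L = max(lengths)
        codes = np.full((len(seqs), L), 4, dtype=np.int8)  # 4 = pad/N
        trans = str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")
        for i, s in enumerate(seqs):
            row = np.frombuffer(s.translate(trans).encode("latin-1"),
                                dtype=np.uint8)
            if row.max(initial=0) > 4:
                raise ValueError(f"non-IUPAC character in sequence for gene "
                                 f"{self.genes[i]!r}")
            codes[i, : len(s)] = row
        self.codes = codes
        self.n_windows = L - window + 1
        # valid window starts per gene (windows that stay inside the sequence)
        starts = np.arange(self.n_windows)[None, :]
        self.valid = starts <= (np.asarray(lengths)[:, None] - window)
        # letter_masks[b][j][g, w] == seq[g, w + j] == b
        self.letter_masks = [
            [codes[:, j:j + self.n_windows] == b for j in range(window)]
            for b in range(4)
        ]

    def presence(self, allowed: np.ndarray) -> np.ndarray:
        """Boolean presence vector over genes for a degenerate pattern."""
        allowed = np.asarray(allowed, dtype=bool)
        if allowed.shape[0] != self.window:
            raise ValueError(
                f"pattern length {allowed.shape[0]} != window {self.window}")
        match = self.valid.copy()
        for j in range(self.window):
            bases = np.flatnonzero(allowed[j])
            if len(bases) == 4:
                continue  # any base matches
            col = self.letter_masks[bases[0]][j].copy()
            for b in bases[1:]:
                col |= self.letter_masks[b][j]
            match &= col
            if not match.any():
                break
        return match.any(axis=1)

    def presence_excluding(self, allowed, skip: int, partial: np.ndarray):
        """Presence with position ``skip`` replaced; ``partial`` is the AND
        of all other positions' masks (hill-climb fast path)."""
        bases = np.flatnonzero(np.asarray(allowed, dtype=bool))
        if len(bases) == 4:
            return partial.any(axis=1)
        col = self.letter_masks[bases[0]][skip].copy()
        for b in bases[1:]:
            col |= self.letter_masks[b][skip]
        return (partial & col).any(axis=1)

    def kmer_presence_matrix(self, k: int = 7) -> np.ndarray:
        """(4^k, genes) boolean: does gene g contain exact k-mer m?"""
        n_kmers = 4 ** k
        G, L = self.codes.shape
        out = np.zeros((n_kmers, G), dtype=bool)
        codes = self.codes.astype(np.int64)
        # rolling integer encoding; windows containing N/pad are invalid
        val = np.zeros((G, L - k + 1), dtype=np.int64)
        ok = np.ones((G, L - k + 1), dtype=bool)
        for j in range(k):
            c = codes[:, j:j + L - k + 1]
            val = val * 4 + np.where(c < 4, c, 0)
            ok &= c < 4
        for g in range(G):
            out[val[g, ok[g]], g] = True
        return out


def scan_presence(motif, sequences, region: str | None = None,
                  genes=None) -> pd.Series:
    """Presence (>= 1 exact degenerate match, single strand) per gene.

    ``motif`` may be a :class:`Motif`, an allowed matrix or a pattern
    string; ``sequences`` a gene -> sequence dict, an
    :class:`EncodedRegion`, or an object with per-region dicts (then
    ``region`` selects ``"promoter"`` or ``"utr3"``).
    """
    if isinstance(motif, Motif):
        allowed = motif.allowed
        region = region or motif.region
    elif isinstance(motif, str):
        allowed = parse_pattern(motif)
    else:
        allowed = np.asarray(motif, dtype=bool)
    enc = _as_encoded(sequences, region, genes, window=allowed.shape[0])
    return pd.Series(enc.presence(allowed), index=enc.genes)


def _as_encoded(sequences, region, genes, window=9) -> EncodedRegion:
    if isinstance(sequences, EncodedRegion):
        if sequences.window != window:
            raise ValueError("encoded region has a different window length")
        return sequences
    if hasattr(sequences, "region_dict"):
        sequences = sequences.region_dict(region)
    if genes is not None:
        missing = [g for g in genes if g not in sequences]
        if missing:
            raise ValueError(f"region sequence missing for gene(s) {missing[:5]}")
    return EncodedRegion(sequences, genes=genes, window=window)


# ---------------------------------------------------------------------------
# seed scan
# ---------------------------------------------------------------------------

def _profile_onehot(profile) -> tuple[np.ndarray, np.ndarray]:
    prof = np.asarray(profile)
    cats, codes = np.unique(prof, return_inverse=True)
    onehot = np.zeros((len(prof), len(cats)), dtype=np.float32)
    onehot[np.arange(len(prof)), codes] = 1.0
    return onehot, cats


def _mi_batch(present_counts: np.ndarray, cat_totals: np.ndarray) -> np.ndarray:
    """MI in bits for many 2 x C tables given present-per-category counts."""
    n = cat_totals.sum()
    a = present_counts                       # (M, C) counts with attribute
    b = cat_totals[None, :] - a              # (M, C) counts without
    counts = np.stack([a, b], axis=1)        # (M, 2, C)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (px * py))
    return np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0).sum(axis=(1, 2))


def seed_scan(sequences, region, profile, k: int = 7, n_rand: int = 1000,
              alpha: float = 1e-3, seed=None, rng=None,
              genes=None) -> pd.DataFrame:
    """Score every exact k-mer seed by MI with the gene profile.

    Returns a DataFrame (index = k-mer) with columns ``mi``, ``z`` and the
    family-wise empirical ``p`` (observed MI versus the null distribution
    of the maximum seed MI under ``n_rand`` profile shuffles), restricted
    to seeds with ``p < alpha`` and sorted by decreasing MI.
    """
    prof = np.asarray(profile)
    if len(np.unique(prof)) < 2:
        raise ValueError("profile must contain at least two categories")
    enc = _as_encoded(sequences, region, genes, window=9)
    if len(prof) != len(enc.genes):
        raise ValueError("profile length does not match number of genes")
    if rng is None:
        rng = np.random.default_rng(seed)
    P = enc.kmer_presence_matrix(k).astype(np.float32)        # (4^k, G)
    onehot, cats = _profile_onehot(prof)
    cat_totals = onehot.sum(axis=0).astype(float)
    obs_counts = P @ onehot                                    # (4^k, C)
    mi = _mi_batch(obs_counts.astype(float), cat_totals)

    null_max = np.empty(n_rand)
    all_mi_mean = np.zeros(P.shape[0])
    all_mi_sq = np.zeros(P.shape[0])
    chunk = 50
    for start in range(0, n_rand, chunk):
        m = min(chunk, n_rand - start)
        perms = np.stack([rng.permutation(onehot) for _ in range(m)], axis=0)
        stacked = perms.transpose(1, 0, 2).reshape(len(prof), -1)  # (G, m*C)
        counts = (P @ stacked).reshape(P.shape[0], m, -1)
        for i in range(m):
            mi_r = _mi_batch(counts[:, i, :].astype(float), cat_totals)
            null_max[start + i] = mi_r.max()
            all_mi_mean += mi_r
            all_mi_sq += mi_r ** 2
    all_mi_mean /= n_rand
    sd = np.sqrt(np.maximum(all_mi_sq / n_rand - all_mi_mean ** 2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mi - all_mi_mean) / sd
    pvals = (1 + (null_max[None, :] >= mi[:, None]).sum(axis=1)) / (1 + n_rand)

    kmers = [_decode_kmer(i, k) for i in range(P.shape[0])]
    table = pd.DataFrame({"mi": mi, "z": z, "p": pvals}, index=kmers)
    table = table[table["p"] < alpha].sort_values("mi", ascending=False)
    return table


def _decode_kmer(idx: int, k: int) -> str:
    letters = []
    for _ in range(k):
        letters.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(letters))


# ---------------------------------------------------------------------------
# motif optimization
# ---------------------------------------------------------------------------

_SUBSETS = [np.array([(i >> b) & 1 for b in range(4)], dtype=bool)
            for i in range(1, 16)]


def optimize_motif(seed_kmer: str, sequences, region, profile,
                   motif_len: int = 9, max_degenerate: int = 4) -> Motif:
    """Expand a significant exact seed into a degenerate motif.

    The seed is placed at each possible offset inside a ``motif_len``
    window (flanks initialized fully degenerate), then hill-climbed: for
    every position in turn all 15 nonempty base subsets are tried and the
    best strictly-MI-increasing edit kept, until a full pass yields no
    gain.  Edits may not exceed ``max_degenerate`` degenerate positions.
    The best final placement is returned; its MI is >= the seed's MI by
    construction.  Deterministic given the seed and the fixed scan order.
    """
    enc = _as_encoded(sequences, region, None, window=motif_len)
    prof = np.asarray(profile)
    if len(prof) != len(enc.genes):
        raise ValueError("profile length does not match number of genes")
    seed_allowed = parse_pattern(seed_kmer)
    k = seed_allowed.shape[0]
    best: tuple[float, np.ndarray] | None = None
    for offset in range(motif_len - k + 1):
        allowed = np.ones((motif_len, 4), dtype=bool)
        allowed[offset:offset + k] = seed_allowed
        mi, allowed = _hill_climb(allowed, enc, prof, max_degenerate)
        if best is None or mi > best[0]:
            best = (mi, allowed)
    mi, allowed = best
    return Motif(allowed=allowed, region=region or "promoter", mi=mi,
                 seed_kmer=seed_kmer)


def _hill_climb(allowed, enc: EncodedRegion, prof, max_degenerate):
    prof_codes, ncat = infotheory._as_codes(prof)
    onehot = np.zeros((len(prof), ncat))
    onehot[np.arange(len(prof)), prof_codes] = 1.0
    cat_totals = onehot.sum(axis=0)

    def mi_of(presence: np.ndarray) -> float:
        counts = presence.astype(float) @ onehot
        return float(_mi_batch(counts[None, :], cat_totals)[0])

    def position_mask(j, subset):
        bases = np.flatnonzero(subset)
        if len(bases) == 4:
            return None  # no constraint
        col = enc.letter_masks[bases[0]][j].copy()
        for b in bases[1:]:
            col |= enc.letter_masks[b][j]
        return col

    window = allowed.shape[0]
    masks = [position_mask(j, allowed[j]) for j in range(window)]
    current_mi = None
    improved = True
    while improved:
        improved = False
        for j in range(window):
            # AND of every position's mask except j
            partial = enc.valid.copy()
            for jj in range(window):
                if jj != j and masks[jj] is not None:
                    partial &= masks[jj]
            degen_others = sum(
                1 for jj in range(window)
                if jj != j and allowed[jj].sum() > 1)
            if current_mi is None:
                cur_mask = masks[j]
                pres = (partial if cur_mask is None else partial & cur_mask
                        ).any(axis=1)
                current_mi = mi_of(pres)
            best_mi, best_subset = current_mi, None
            for subset in _SUBSETS:
                if np.array_equal(subset, allowed[j]):
                    continue
                if subset.sum() > 1 and degen_others + 1 > max_degenerate:
                    continue
                pres = enc.presence_excluding(subset, j, partial)
                cand = mi_of(pres)
                if cand > best_mi:
                    best_mi, best_subset = cand, subset
            if best_subset is not None:
                allowed = allowed.copy()
                allowed[j] = best_subset
                masks[j] = position_mask(j, best_subset)
                current_mi = best_mi
                improved = True
    return current_mi, allowed


# ---------------------------------------------------------------------------
# robustness, enrichment, association, co-occurrence, library matching
# ---------------------------------------------------------------------------

def jackknife_robustness(motif, sequences, profile, trials: int = 10,
                         drop_fraction: float = 1 / 3, n_rand: int = 1000,
                         alpha: float = 1e-3, seed=None, rng=None) -> int:
    """Jack-knife robustness score: passing trials out of ``trials``.

    Each trial removes a uniform random ``drop_fraction`` of the genes and
    re-tests the motif's MI significance by profile randomization on the
    retained genes; the score counts trials with empirical p < ``alpha``.
    Motifs scoring below 6/10 are conventionally discarded.
    """
    if trials < 1:
        raise ValueError("trials must be at least 1")
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    presence = np.asarray(
        scan_presence(motif, sequences,
                      region=getattr(motif, "region", None)))
    prof = np.asarray(profile)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(prof)
    n_drop = int(round(drop_fraction * n))
    score = 0
    for _ in range(trials):
        keep = rng.permutation(n)[n_drop:]
        sig = infotheory.mi_significance(presence[keep], prof[keep],
                                         n_rand=n_rand, rng=rng)
        if sig.p < alpha:
            score += 1
    return score


def motif_category_enrichment(motif, sequences, profile,
                              n_motifs: int = 1) -> tuple[pd.Series, pd.Series]:
    """Signed log10 hypergeometric enrichment per profile category.

    Bonferroni correction uses a family of ``n_motifs x n_categories``
    tests; the flag marks cells with corrected over-representation
    p < 0.05.  Returns ``(signed log10 p, bonferroni flags)`` and stores
    both on the motif.
    """
    presence = np.asarray(
        scan_presence(motif, sequences,
                      region=getattr(motif, "region", None)))
    prof = np.asarray(profile)
    cats = list(pd.unique(prof))
    universe = len(prof)
    size = int(presence.sum())
    scores, flags = {}, {}
    family = n_motifs * len(cats)
    for cat in cats:
        in_cat = prof == cat
        k = int(np.sum(presence & in_cat))
        cell = infotheory.hypergeometric_cell(k, size, int(in_cat.sum()),
                                              universe)
        upper, _ = infotheory.hypergeometric_tails(k, size, int(in_cat.sum()),
                                                   universe)
        scores[cat] = cell
        flags[cat] = bool(upper * family < 0.05) and cell > 0
    scores = pd.Series(scores)
    flags = pd.Series(flags)
    if isinstance(motif, Motif):
        motif.enrichment, motif.bonferroni = scores, flags
    return scores, flags


def motif_pathway_association(motifs, pathways, sequences,
                              genes=None) -> pd.DataFrame:
    """Motif x pathway signed log10 hypergeometric overlap matrix.

    Rows are motif patterns (tagged with region), columns pathway names;
    positive cells mean the motif-bearing genes are over-represented in
    the pathway.  The hypergeometric p is symmetric in the two sets.
    """
    if not motifs or not pathways:
        raise ValueError("need at least one motif and one pathway")
    if genes is None:
        genes = _universe_genes(sequences, motifs[0].region)
    universe = len(genes)
    rows = {}
    for m in motifs:
        presence = scan_presence(m, sequences, region=m.region,
                                 genes=genes).to_numpy()
        size = int(presence.sum())
        label = f"{m.pattern} ({m.region})"
        cells = {}
        for name, members in pathways.items():
            member_vec = np.isin(np.asarray(genes), list(members))
            k = int(np.sum(presence & member_vec))
            cells[name] = infotheory.hypergeometric_cell(
                k, size, int(member_vec.sum()), universe)
        rows[label] = cells
    return pd.DataFrame.from_dict(rows, orient="index")


def _universe_genes(sequences, region):
    if isinstance(sequences, EncodedRegion):
        return sequences.genes
    if hasattr(sequences, "genes"):
        return list(sequences.genes)
    return list(sequences)


@dataclass
class CooccurrencePair:
    """Pairwise co-occurrence statistics of two motif presence vectors."""

    mi: float
    p: float                  # exact permutation p of the 2x2 MI
    cooccurring: bool         # True = co-presence above independence
    pair_class: str           # "homotypic" (same region) or "heterotypic"
    significant: bool         # p below the flag threshold


def motif_cooccurrence(motifs, sequences, genes=None,
                       p_threshold: float = 1e-4) -> pd.DataFrame:
    """Pairwise MI between motif presence vectors with exact permutation p.

    With both margins fixed, every permutation outcome is determined by
    the co-presence count, which is hypergeometric; the permutation p is
    therefore enumerated exactly as the total probability of counts whose
    MI is at least the observed MI.  The sign distinguishes co-occurrence
    (joint presence above the independence expectation) from avoidance.
    Pairs with p below ``p_threshold`` are flagged; same-region pairs are
    homotypic, promoter-3'UTR pairs heterotypic.
    """
    if len(motifs) < 2:
        raise ValueError("need at least two motifs")
    if genes is None:
        genes = _universe_genes(sequences, motifs[0].region)
    presence = [np.asarray(scan_presence(m, sequences, region=m.region,
                                         genes=genes)) for m in motifs]
    labels = [f"{m.pattern} ({m.region})" for m in motifs]
    out = pd.DataFrame(index=labels, columns=labels, dtype=object)
    n = len(genes)
    for i in range(len(motifs)):
        for j in range(len(motifs)):
            pi, pj = presence[i], presence[j]
            a, b = int(pi.sum()), int(pj.sum())
            k_obs = int(np.sum(pi & pj))
            mi_obs = infotheory.mutual_information(pi.astype(int),
                                                   pj.astype(int))
            p_exact = _exact_2x2_mi_p(k_obs, a, b, n)
            pair = CooccurrencePair(
                mi=mi_obs,
                p=p_exact,
                cooccurring=k_obs * n >= a * b,
                pair_class=("homotypic" if motifs[i].region == motifs[j].region
                            else "heterotypic"),
                significant=p_exact < p_threshold,
            )
            out.iloc[i, j] = pair
    return out


def _exact_2x2_mi_p(k_obs: int, a: int, b: int, n: int) -> float:
    """P(MI >= observed) over the fixed-margin permutation null."""
    from scipy import stats

    lo, hi = max(0, a + b - n), min(a, b)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom(n, a, b).pmf(ks)
    mis = np.array([
        infotheory.mi_bits(np.array([[k, a - k], [b - k, n - a - b + k]],
                                    dtype=float))
        for k in ks
    ])
    mi_obs = mis[k_obs - lo]
    return float(pmf[mis >= mi_obs - 1e-12].sum())


def match_known(motif, library: dict) -> pd.DataFrame:
    """Align a discovered motif against a named IUPAC consensus library.

    For each library entry the pattern is swept across the motif window
    (all offsets of full mutual overlap down to single-position overlap on
    either side); the score is the best fraction of the motif's positions
    compatible with the library pattern.  An overlapping position is
    compatible when the symbol subsets intersect; a motif position outside
    the library pattern is compatible only when the motif leaves it fully
    degenerate (an unused flank).  Returns entries ranked by score; an
    empty library yields an empty frame ("no match").
    """
    if isinstance(motif, Motif):
        allowed = motif.allowed
    else:
        allowed = parse_pattern(motif) if isinstance(motif, str) else motif
    L = allowed.shape[0]
    rows = []
    for name, pattern in library.items():
        pat = parse_pattern(pattern)
        k = pat.shape[0]
        best = 0.0
        best_offset = 0
        for off in range(-k + 1, L):
            compatible = 0
            for pos in range(L):
                q = pos - off
                if 0 <= q < k:
                    if np.any(allowed[pos] & pat[q]):
                        compatible += 1
                elif allowed[pos].all():
                    compatible += 1
            frac = compatible / L
            if frac > best:
                best, best_offset = frac, off
        rows.append((name, pattern, best, best_offset))
    return pd.DataFrame(rows, columns=["name", "pattern", "score", "offset"]
                        ).sort_values("score", ascending=False,
                                      ignore_index=True)


def consensus_agreement(found, planted) -> int:
    """Positions (of the found motif's window) agreeing with a planted
    consensus at the best alignment offset.

    A window position overlapping the planted pattern agrees when the
    symbol subsets are equal; a position outside a shorter planted pattern
    is unconstrained and agrees when the found motif leaves it fully
    degenerate (or always, if the found motif is not degenerate there but
    the planted pattern says nothing — we count subset-of-N as agreement
    only for N).  Used to benchmark recovery on planted sequence sets.
    """
    f = found.allowed if isinstance(found, Motif) else (
        parse_pattern(found) if isinstance(found, str) else np.asarray(found))
    p = parse_pattern(planted) if isinstance(planted, str) else np.asarray(planted)
    L, k = f.shape[0], p.shape[0]
    best = 0
    for off in range(-k + 1, L):
        agree = 0
        for pos in range(L):
            q = pos - off
            if 0 <= q < k:
                if np.array_equal(f[pos], p[q]):
                    agree += 1
            else:
                if f[pos].all():  # flank left unconstrained
                    agree += 1
        best = max(best, agree)
    return best


# ---------------------------------------------------------------------------
# discovery driver
# ---------------------------------------------------------------------------

def discover_motifs(sequences, region, profile, k: int = 7,
                    motif_len: int = 9, n_rand_seed: int = 1000,
                    seed_alpha: float = 1e-3, max_seeds: int = 8,
                    n_rand_mi: int = 10_000, n_rand_cmi: int = 1000,
                    cmi_alpha: float = 0.01, robustness_trials: int = 10,
                    max_degenerate: int = 4, seed=None) -> list[Motif]:
    """Full motif-discovery pass over one region.

    Seeds are scanned and family-wise filtered, the top ``max_seeds``
    expanded by hill climbing, near-duplicates collapsed by a conditional
    MI test against already-kept motifs, then each surviving motif gets a
    randomization Z/p (``n_rand_mi`` shuffles) and a jack-knife robustness
    score.  Returned sorted by decreasing MI.
    """
    rng = np.random.default_rng(seed)
    enc = _as_encoded(sequences, region, None, window=motif_len)
    prof = np.asarray(profile)
    seeds = seed_scan(enc, region, prof, k=k, n_rand=n_rand_seed,
                      alpha=seed_alpha, rng=rng)
    kept: list[Motif] = []
    for kmer in seeds.index[:max_seeds]:
        cand = optimize_motif(kmer, enc, region, prof,
                              motif_len=motif_len,
                              max_degenerate=max_degenerate)
        cand.region = region
        pres = np.asarray(scan_presence(cand, enc))
        redundant = False
        for prev in kept:
            prev_pres = np.asarray(scan_presence(prev, enc))
            cmi_obs = infotheory.conditional_mutual_information(
                pres.astype(int), prof, prev_pres.astype(int))
            if not _cmi_significant(pres, prof, prev_pres, cmi_obs,
                                    n_rand_cmi, rng):
                redundant = True
                break
        if redundant:
            continue
        sig = infotheory.mi_significance(pres.astype(int), prof,
                                         n_rand=n_rand_mi, rng=rng)
        cand.mi, cand.z, cand.p = sig.mi, sig.z, sig.p
        cand.robustness = jackknife_robustness(
            cand, enc, prof, trials=robustness_trials, rng=rng)
        kept.append(cand)
    return sorted(kept, key=lambda m: -m.mi)


def _cmi_significant(x, prof, given, cmi_obs, n_rand, rng,
                     alpha: float = 0.01) -> bool:
    """Randomization test of I(x; profile | given) by shuffling the profile
    within the strata of ``given``."""
    prof = np.asarray(prof)
    given = np.asarray(given)
    null = np.empty(n_rand)
    idx_by_stratum = [np.flatnonzero(given == v) for v in np.unique(given)]
    perm_prof = prof.copy()
    for r in range(n_rand):
        for idx in idx_by_stratum:
            perm_prof[idx] = prof[idx][rng.permutation(len(idx))]
        null[r] = infotheory.conditional_mutual_information(
            np.asarray(x).astype(int), perm_prof, given.astype(int))
    p = (1 + int(np.sum(null >= cmi_obs))) / (1 + n_rand)
    return p < alpha
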