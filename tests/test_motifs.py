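"""Degenerate-motif machinery: parsing, scanning, optimization, statistics."""

import numpy as np
import pandas as pd
import pytest

import partsig as ps
from partsig import infotheory as it
from partsig import motifs as mf
from partsig.simulate import MOTIF_A, MOTIF_B, MOTIF_C


def brute_force_presence(pattern: str, seq: str) -> bool:
    """Sliding-window oracle with explicit IUPAC set semantics."""
    allowed = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            allowed.append(set("".join(mf.IUPAC[c] for c in pattern[i + 1:j])))
            i = j + 1
        else:
            allowed.append(set(mf.IUPAC[pattern[i]]))
            i += 1
    L = len(allowed)
    seq = seq.upper().replace("U", "T")
    for start in range(len(seq) - L + 1):
        if all(seq[start + k] in allowed[k] for k in range(L)):
            return True
    return False


class TestPatterns:
    def test_parse_render_roundtrip(self):
        for pat in (MOTIF_A, "ACGTACGTA", "NNNACGTNN", "[AG]C[CT]TTTTTT"):
            assert mf.render_pattern(mf.parse_pattern(pat)) == pat.replace(
                "N", "N")

    def test_rna_rendering_uses_uracil(self):
        allowed = mf.parse_pattern(MOTIF_C)
        assert "U" in mf.render_pattern(allowed, rna=True)
        assert "T" in mf.render_pattern(allowed, rna=False)

    def test_u_read_as_t(self):
        assert np.array_equal(mf.parse_pattern("AU"), mf.parse_pattern("AT"))

    def test_malformed_symbol_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            mf.parse_pattern("ACGX")

    def test_sampled_instances_match_consensus(self, rng):
        allowed = mf.parse_pattern(MOTIF_A)
        for _ in range(20):
            inst = mf.sample_instance(allowed, rng)
            assert brute_force_presence(MOTIF_A, inst)


class TestScanning:
    def test_homopolymer_match(self):
        pres = mf.scan_presence("AAAAAAAAA", {"g": "AAAAAAAAA"})
        assert bool(pres["g"])

    def test_published_consensus_semantics(self):
        seqs = {"hit1": "TT" + "GGTAAATCC" + "TT",
                "hit2": "TT" + "GGAAAATCT" + "TT",
                "miss": "TT" + "GGCAAATCC" + "TT"}
        pres = mf.scan_presence(MOTIF_A, seqs)
        assert bool(pres["hit1"]) and bool(pres["hit2"])
        assert not bool(pres["miss"])

    def test_matches_sliding_window_oracle(self, rng):
        bases = np.array(list("ACGT"))
        seqs = {f"g{i}": "".join(bases[rng.integers(4, size=40)])
                for i in range(100)}
        for pattern in (MOTIF_A, "GC[AT]T[AG]CNNA", "AAAA[CG]AAAA"):
            pres = mf.scan_presence(pattern, seqs)
            for g, seq in seqs.items():
                assert pres[g] == brute_force_presence(pattern, seq), (g,
                                                                       pattern)

    def test_presence_monotone_under_widening(self, rng):
        bases = np.array(list("ACGT"))
        seqs = {f"g{i}": "".join(bases[rng.integers(4, size=60)])
                for i in range(60)}
        allowed = mf.parse_pattern("AC[GT]TACG[AT]A")
        wide = allowed.copy()
        wide[0] = True  # first position fully degenerate
        narrow_pres = mf.scan_presence(allowed, seqs)
        wide_pres = mf.scan_presence(wide, seqs)
        assert (wide_pres[narrow_pres].all())

    def test_missing_region_rejected(self, motif_bench):
        _, seqs, _ = motif_bench
        with pytest.raises(ValueError, match="missing"):
            mf.scan_presence(MOTIF_A, seqs.promoters,
                             genes=list(seqs.genes) + ["ABSENT"])

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="at least 9"):
            mf.scan_presence("AAAAAAAAA", {"g": "AAAA"})


class TestSeedScan:
    def test_enumerates_all_7mers(self, motif_bench):
        _, seqs, _ = motif_bench
        enc = mf.EncodedRegion(
            {g: seqs.promoters[g] for g in list(seqs.genes)[:50]})
        P = enc.kmer_presence_matrix(7)
        assert P.shape == (4 ** 7, 50)

    def test_seed_mi_consistent_with_mutual_information(self, motif_bench):
        profile, seqs, _ = motif_bench
        table = mf.seed_scan(seqs, "promoter", profile.values, n_rand=200,
                             alpha=0.05, seed=0)
        kmer = table.index[0]
        presence = mf.scan_presence(kmer + "NN", seqs, "promoter",
                                    genes=seqs.genes)
        assert table.loc[kmer, "mi"] == pytest.approx(
            it.mutual_information(presence.to_numpy().astype(int),
                                  profile.values), abs=1e-12)

    def test_planted_seed_ranks_first(self, motif_bench):
        profile, seqs, _ = motif_bench
        table = mf.seed_scan(seqs, "promoter", profile.values, n_rand=300,
                             alpha=0.01, seed=1)
        # the strongest seed is a 7-mer substring of a planted consensus
        top = table.index[0]
        assert brute_force_presence(top, "AATTTGA") or \
            brute_force_presence(MOTIF_B, top + "NN") or \
            any(brute_force_presence(MOTIF_A[k:], top) for k in range(3))


class TestOptimization:
    def test_mi_never_below_seed(self, motif_bench):
        profile, seqs, _ = motif_bench
        table = mf.seed_scan(seqs, "promoter", profile.values, n_rand=200,
                             alpha=0.05, seed=2)
        kmer = table.index[0]
        motif = mf.optimize_motif(kmer, seqs, "promoter", profile.values)
        assert motif.mi >= table.loc[kmer, "mi"] - 1e-12

    def test_deterministic(self, motif_bench):
        profile, seqs, _ = motif_bench
        a = mf.optimize_motif("AAATTGA", seqs, "promoter", profile.values)
        b = mf.optimize_motif("AAATTGA", seqs, "promoter", profile.values)
        assert a.pattern == b.pattern and a.mi == b.mi

    def test_degeneracy_cap_respected(self, motif_bench):
        profile, seqs, _ = motif_bench
        motif = mf.optimize_motif("AAATTGA", seqs, "promoter",
                                  profile.values, max_degenerate=4)
        assert motif.n_degenerate <= 4


class TestRobustness:
    def test_perfect_motif_scores_ten(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(600)]
        profile = np.array(["A"] * 300 + ["B"] * 300)
        seqs = {}
        bases = np.array(list("ACGT"))
        for i, g in enumerate(genes):
            s = "".join(bases[rng.integers(4, size=60)])
            if i < 300:
                s = "GGTAAATCC" + s[9:]
            seqs[g] = s.replace("GGTAAATCC", "ACACACACA") if i >= 300 else s
        motif = mf.Motif(mf.parse_pattern("GGTAAATCC"), "promoter")
        score = mf.jackknife_robustness(motif, seqs, profile, n_rand=1000,
                                        seed=1)
        assert score == 10

    def test_null_motif_scores_low(self, rng):
        genes = [f"g{i}" for i in range(300)]
        bases = np.array(list("ACGT"))
        seqs = {g: "".join(bases[rng.integers(4, size=80)]) for g in genes}
        profile = np.array(["A"] * 150 + ["B"] * 150)
        motif = mf.Motif(mf.parse_pattern("AC[AG]TNACGT"), "promoter")
        score = mf.jackknife_robustness(motif, seqs, profile, n_rand=200,
                                        alpha=0.01, seed=3)
        assert score <= 2

    def test_reproducible_given_seed(self, motif_bench):
        profile, seqs, _ = motif_bench
        motif = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        s1 = mf.jackknife_robustness(motif, seqs, profile.values, n_rand=150,
                                     seed=11)
        s2 = mf.jackknife_robustness(motif, seqs, profile.values, n_rand=150,
                                     seed=11)
        assert s1 == s2

    def test_bad_drop_fraction_rejected(self, motif_bench):
        profile, seqs, _ = motif_bench
        motif = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        with pytest.raises(ValueError, match="drop_fraction"):
            mf.jackknife_robustness(motif, seqs, profile.values,
                                    drop_fraction=1.5)


class TestEnrichment:
    def test_category_exclusive_motif_peaks_there(self, motif_bench):
        profile, seqs, truth = motif_bench
        motif = mf.Motif(mf.parse_pattern(MOTIF_C), "utr3")
        scores, flags = mf.motif_category_enrichment(motif, seqs,
                                                     profile.values)
        assert scores.idxmax() == "TNL"
        assert flags["TNL"]

    def test_cells_match_hypergeometric_oracle(self, motif_bench):
        profile, seqs, _ = motif_bench
        motif = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        scores, _ = mf.motif_category_enrichment(motif, seqs, profile.values)
        presence = mf.scan_presence(motif, seqs).to_numpy()
        for cat in scores.index:
            in_cat = (profile == cat).to_numpy()
            expected = it.hypergeometric_cell(
                int((presence & in_cat).sum()), int(presence.sum()),
                int(in_cat.sum()), len(profile))
            assert scores[cat] == pytest.approx(expected, abs=1e-12)

    def test_no_flag_without_raw_significance(self, rng):
        genes = [f"g{i}" for i in range(100)]
        bases = np.array(list("ACGT"))
        seqs = {g: "".join(bases[rng.integers(4, size=40)]) for g in genes}
        profile = np.array(["A"] * 50 + ["B"] * 50)
        motif = mf.Motif(mf.parse_pattern("NNNN[AC]NNNN"), "promoter")
        scores, flags = mf.motif_category_enrichment(motif, seqs, profile,
                                                     n_motifs=3)
        raw_p = 10.0 ** (-scores.abs())
        assert not flags[raw_p >= 0.05].any()


class TestAssociationAndCooccurrence:
    def test_motif_planted_in_pathway_genes_peaks(self, motif_bench):
        profile, seqs, _ = motif_bench
        pathways = {"tnl_like": list(profile.index[profile == "TNL"]),
                    "random": list(profile.index[:60])}
        motif = mf.Motif(mf.parse_pattern(MOTIF_C), "utr3")
        mat = mf.motif_pathway_association([motif], pathways, seqs)
        assert mat.iloc[0].idxmax() == "tnl_like"

    def test_hypergeometric_symmetry(self, motif_bench):
        profile, seqs, _ = motif_bench
        motif = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        presence = mf.scan_presence(motif, seqs)
        members = list(presence.index[presence][:30]) + \
            list(presence.index[~presence][:30])
        mat = mf.motif_pathway_association([motif], {"s": members}, seqs)
        # swapping roles: treat the motif set as the pathway
        k = int((presence & presence.index.isin(members)).sum())
        swapped = it.hypergeometric_cell(k, len(members),
                                         int(presence.sum()), len(presence))
        assert mat.iloc[0, 0] == pytest.approx(swapped, abs=1e-10)

    def test_self_pair_is_maximal_cooccurrence(self, motif_bench):
        profile, seqs, _ = motif_bench
        a = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        b = mf.Motif(mf.parse_pattern(MOTIF_B + "NN"), "promoter")
        mat = mf.motif_cooccurrence([a, b], seqs)
        self_pair = mat.iloc[0, 0]
        cross = mat.iloc[0, 1]
        assert self_pair.cooccurring
        assert self_pair.mi >= cross.mi

    def test_jointly_planted_pair_flagged(self, motif_bench):
        profile, seqs, _ = motif_bench
        a = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        b = mf.Motif(mf.parse_pattern(MOTIF_B + "NN"), "promoter")
        pair = mf.motif_cooccurrence([a, b], seqs).iloc[0, 1]
        assert pair.significant and pair.cooccurring
        assert pair.pair_class == "homotypic"

    def test_independent_motifs_not_flagged(self, rng):
        genes = [f"g{i}" for i in range(400)]
        bases = np.array(list("ACGT"))
        prom, utr = {}, {}
        for g in genes:
            p = "".join(bases[rng.integers(4, size=60)])
            u = "".join(bases[rng.integers(4, size=60)])
            if rng.random() < 0.4:
                p = "GGTAAATCC" + p[9:]
            if rng.random() < 0.4:
                u = "ACTCCACAA" + u[9:]
            prom[g], utr[g] = p, u
        seqs = ps.simulate.SequenceSet(promoters=prom, utr3=utr)
        a = mf.Motif(mf.parse_pattern("GGTAAATCC"), "promoter")
        c = mf.Motif(mf.parse_pattern("ACTCCACAA"), "utr3")
        pair = mf.motif_cooccurrence([a, c], seqs).iloc[0, 1]
        assert not pair.significant
        assert pair.pair_class == "heterotypic"

    def test_single_motif_rejected(self, motif_bench):
        _, seqs, _ = motif_bench
        a = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        with pytest.raises(ValueError, match="two motifs"):
            mf.motif_cooccurrence([a], seqs)


class TestLibraryMatching:
    def test_identical_pattern_scores_one(self):
        motif = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        table = mf.match_known(motif, {"self": MOTIF_A})
        assert table.loc[0, "score"] == 1.0

    def test_shuffled_pattern_scores_below_one(self):
        motif = mf.Motif(mf.parse_pattern("GGTAAATCC"), "promoter")
        table = mf.match_known(motif, {"shuffled": "CCTAAATGG"})
        assert table.loc[0, "score"] < 1.0

    def test_matches_offset_enumeration_oracle(self):
        motif = mf.parse_pattern("GG[AT]AAATCC")
        lib = {"a": "TAAAT", "b": "GG[AT]AA"}
        table = mf.match_known(motif, lib).set_index("name")
        for name, pattern in lib.items():
            pat = mf.parse_pattern(pattern)
            best = 0
            for off in range(-pat.shape[0] + 1, 9):
                score = 0
                for pos in range(9):
                    q = pos - off
                    if 0 <= q < pat.shape[0]:
                        score += bool(np.any(motif[pos] & pat[q]))
                    elif motif[pos].all():
                        score += 1
                best = max(best, score / 9)
            assert table.loc[name, "score"] == pytest.approx(best)

    def test_empty_library_means_no_match(self):
        motif = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        assert mf.match_known(motif, {}).empty

    def test_malformed_library_entry_rejected(self):
        motif = mf.Motif(mf.parse_pattern(MOTIF_A), "promoter")
        with pytest.raises(ValueError, match="'Z'"):
            mf.match_known(motif, {"bad": "ACZGT"})
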