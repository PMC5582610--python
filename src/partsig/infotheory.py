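"""Information-theoretic primitives shared by the pathway and motif analyses.

Mutual information here is always between a *binary* gene attribute (pathway
membership, motif presence) and a *categorical* gene profile (which phenotype
a gene's expression identifies, or background), measured in bits on the
observed contingency table of counts.  Conditional mutual information on the
2 x 2 x C table supports the redundancy filters.  Signed hypergeometric
over/under-representation provides the per-category heat-map cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mutual_information",
    "conditional_mutual_information",
    "mi_significance",
    "MISignificance",
    "hypergeometric_tails",
    "hypergeometric_cell",
]


def _as_codes(values) -> tuple[np.ndarray, int]:
    """Encode a label vector as integer codes 0..K-1 (stable label order)."""
    arr = np.asarray(values)
    labels, codes = np.unique(arr, return_inverse=True)
    return codes.astype(np.intp), len(labels)


def mi_bits(counts: np.ndarray) -> float:
    """Mutual information in bits of a contingency table of counts.

    Cells with zero probability contribute zero (0*log 0 = 0).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return 0.0
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    ratio = pxy[nz] / (px @ py)[nz]
    return float(np.sum(pxy[nz] * np.log2(ratio)))


def mutual_information(membership, profile) -> float:
    """MI in bits between a binary membership vector and a categorical profile.

    Parameters
    ----------
    membership : sequence of {0,1}
        One entry per gene (e.g. pathway membership or motif presence).
    profile : sequence of labels
        One category per gene (the four phenotypes plus background).

    Degenerate inputs with fewer than two distinct values on either side
    carry no information and return 0.
    """
    m = np.asarray(membership)
    p = np.asarray(profile)
    if m.shape[0] != p.shape[0]:
        raise ValueError(
            f"length mismatch: membership has {m.shape[0]} entries, "
            f"profile has {p.shape[0]}"
        )
    mc, nm = _as_codes(m)
    pc, np_ = _as_codes(p)
    if nm < 2 or np_ < 2:
        return 0.0
    counts = np.bincount(mc * np_ + pc, minlength=nm * np_).reshape(nm, np_)
    return mi_bits(counts)


def conditional_mutual_information(x, y, given) -> float:
    """Conditional MI in bits, I(X;Y | Z), from the observed 3-way table.

    Computed as sum_z p(z) * I(X;Y | Z=z).  Used to decide whether a
    candidate pathway or motif is informative beyond one already accepted.
    """
    xc, nx = _as_codes(x)
    yc, ny = _as_codes(y)
    zc, nz = _as_codes(given)
    if len({xc.shape[0], yc.shape[0], zc.shape[0]}) != 1:
        raise ValueError("x, y and given must have equal length")
    n = xc.shape[0]
    cmi = 0.0
    for z in range(nz):
        sel = zc == z
        nsel = int(sel.sum())
        if nsel == 0:
            continue
        counts = np.bincount(xc[sel] * ny + yc[sel], minlength=nx * ny)
        cmi += (nsel / n) * mi_bits(counts.reshape(nx, ny))
    return float(cmi)


@dataclass
class MISignificance:
    """Randomization-test summary for an observed MI value."""

    mi: float
    z: float  # NaN when the shuffled MI values have zero spread
    p: float  # add-one empirical p, (1 + #{rand >= obs}) / (1 + n_rand)
    n_rand: int
    rand_mean: float
    rand_sd: float

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.z)


def mi_significance(membership, profile, n_rand: int = 10_000,
                    seed=None, rng=None) -> MISignificance:
    """Randomization test of MI(membership; profile) by shuffling the profile.

    The categorical profile is permuted uniformly over genes ``n_rand``
    times; the Z-score is (MI_obs - mean)/SD of the shuffled MI values and
    the empirical p uses the add-one convention so it is never zero.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be at least 100")
    m = np.asarray(membership)
    p = np.asarray(profile)
    if m.shape[0] != p.shape[0]:
        raise ValueError("membership and profile must have equal length")
    mc, nm = _as_codes(m)
    pc, ncat = _as_codes(p)
    obs = mi_bits(
        np.bincount(mc * ncat + pc, minlength=nm * ncat).reshape(nm, ncat)
    )
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    base = mc * ncat
    for r in range(n_rand):
        perm = rng.permutation(pc)
        counts = np.bincount(base + perm, minlength=nm * ncat)
        null[r] = mi_bits(counts.reshape(nm, ncat))
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    z = (obs - mean) / sd if sd > 0 else float("nan")
    pval = (1 + int(np.sum(null >= obs))) / (1 + n_rand)
    return MISignificance(mi=obs, z=z, p=pval, n_rand=n_rand,
                          rand_mean=mean, rand_sd=sd)


def hypergeometric_tails(k: int, set_size: int, category_size: int,
                         universe: int) -> tuple[float, float]:
    """Upper and lower tail probabilities of the overlap count ``k``.

    Returns ``(P(X >= k), P(X <= k))`` for X hypergeometric with
    ``universe`` genes, ``set_size`` of them in the gene set, and
    ``category_size`` drawn (the profile category).
    """
    if set_size > universe or category_size > universe:
        raise ValueError("universe smaller than one of the sets")
    if k > min(set_size, category_size) or k < 0:
        raise ValueError("overlap inconsistent with set sizes")
    hg = stats.hypergeom(universe, set_size, category_size)
    upper = float(hg.sf(k - 1))
    lower = float(hg.cdf(k))
    return upper, lower


def hypergeometric_cell(k: int, set_size: int, category_size: int,
                        universe: int) -> float:
    """Signed log10 hypergeometric over/under-representation score.

    Positive values mean over-representation (the overlap ``k`` exceeds its
    expectation ``set_size*category_size/universe``; magnitude is -log10 of
    the upper tail).  Non-positive deviation gives the negative of -log10 of
    the lower tail.
    """
    upper, lower = hypergeometric_tails(k, set_size, category_size, universe)
    expected = set_size * category_size / universe
    if k > expected:
        return -np.log10(max(upper, np.finfo(float).tiny))
    return float(np.log10(max(lower, np.finfo(float).tiny)))


def signed_logp_frame(memberships: dict, profile, categories=None) -> pd.DataFrame:
    """Signed log10 hypergeometric scores for several gene sets x categories.

    ``memberships`` maps a set name to a boolean vector over genes aligned
    with ``profile``.  Returns sets as rows, profile categories as columns.
    """
    prof = np.asarray(profile)
    if categories is None:
        categories = list(pd.unique(prof))
    universe = prof.shape[0]
    rows = {}
    for name, member in memberships.items():
        member = np.asarray(member, dtype=bool)
        if member.shape[0] != universe:
            raise ValueError(f"membership {name!r} has wrong length")
        size = int(member.sum())
        rows[name] = [
            hypergeometric_cell(int(np.sum(member & (prof == cat))),
                                size, int(np.sum(prof == cat)), universe)
            for cat in categories
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(categories))
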