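"""Mutual-information gene-set enrichment over the signature profile.

Each pathway's binary membership vector is tested for information about
the categorical gene profile (which phenotype a gene's expression
identifies, or background): MI with a randomization Z-score and empirical
p, a greedy conditional-MI pass that keeps only pathways informative
beyond those already accepted, and per-category signed hypergeometric
over/under-representation for the heat-map view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from . import infotheory

logger = logging.getLogger(__name__)

__all__ = ["PathwayMIResult", "analyze_pathways", "conditional_mi_filter",
           "enrichment_heatmap"]


@dataclass
class PathwayMIResult:
    """Per-pathway MI statistics and acceptance status."""

    name: str
    mi: float
    z: float
    p: float
    accepted: bool = False
    enrichment: pd.Series | None = None  # per-category signed log10 p


def _memberships(collection, genes) -> dict:
    genes = pd.Index(genes)
    return {name: genes.isin(list(members)).astype(int)
            for name, members in collection.items()}


def conditional_mi_filter(candidates, profile, n_rand: int = 1000,
                          alpha: float = 0.01, seed=None, rng=None) -> list:
    """Greedy redundancy filter on marginally significant pathways.

    ``candidates`` is a list of ``(name, membership)`` pairs assumed to
    pass marginal significance; they are processed in decreasing marginal
    MI.  A candidate is accepted only if its conditional MI with the
    profile, given *each* already-accepted pathway, passes its own
    randomization test (profile shuffled within the strata of the
    conditioning membership).  A duplicate of an accepted pathway has zero
    conditional MI and is rejected.  Running the filter on its own output
    returns it unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    prof = np.asarray(profile)
    ranked = sorted(
        candidates,
        key=lambda nm: -infotheory.mutual_information(nm[1], prof))
    accepted = []
    for name, member in ranked:
        member = np.asarray(member).astype(int)
        ok = True
        for _, prev in accepted:
            cmi_obs = infotheory.conditional_mutual_information(
                member, prof, prev)
            if not _cmi_passes(member, prof, prev, cmi_obs, n_rand, alpha,
                               rng):
                ok = False
                break
        if ok:
            accepted.append((name, member))
    return accepted


def _cmi_passes(member, prof, given, cmi_obs, n_rand, alpha, rng) -> bool:
    strata = [np.flatnonzero(given == v) for v in np.unique(given)]
    perm = prof.copy()
    null = np.empty(n_rand)
    for r in range(n_rand):
        for idx in strata:
            perm[idx] = prof[idx][rng.permutation(len(idx))]
        null[r] = infotheory.conditional_mutual_information(member, perm, given)
    p = (1 + int(np.sum(null >= cmi_obs))) / (1 + n_rand)
    return p < alpha


def analyze_pathways(collection, profile, n_rand: int = 10_000,
                     alpha: float = 0.01, cmi_n_rand: int = 1000,
                     seed=None) -> list[PathwayMIResult]:
    """Full pathway pass: MI significance, redundancy filter, enrichment.

    ``collection`` maps pathway names to gene-id lists; ``profile`` is a
    Series (index = gene id) of categories.  Pathways with randomization
    empirical p < ``alpha`` enter the conditional-MI filter; accepted
    pathways get their per-category signed log10 hypergeometric scores.
    """
    profile = pd.Series(profile)
    rng = np.random.default_rng(seed)
    members = _memberships(collection, profile.index)
    prof = profile.to_numpy()
    results = {}
    significant = []
    for name, member in members.items():
        sig = infotheory.mi_significance(member, prof, n_rand=n_rand, rng=rng)
        results[name] = PathwayMIResult(name=name, mi=sig.mi, z=sig.z, p=sig.p)
        if sig.p < alpha and not sig.degenerate:
            significant.append((name, member))
    accepted = conditional_mi_filter(significant, prof, n_rand=cmi_n_rand,
                                     alpha=alpha, rng=rng)
    accepted_names = [name for name, _ in accepted]
    if accepted_names:
        heat = enrichment_heatmap(
            {name: collection[name] for name in accepted_names}, profile)
        for name in accepted_names:
            results[name].accepted = True
            results[name].enrichment = heat.loc[name]
    else:
        logger.warning("no pathway accepted by the conditional-MI filter")
    return sorted(results.values(), key=lambda r: -r.mi)


def enrichment_heatmap(accepted, profile) -> pd.DataFrame:
    """Pathway x category signed log10 hypergeometric matrix.

    Columns are every profile category including background; positive
    cells mean pathway genes are over-represented in that category.  An
    empty accepted set returns an empty frame with a warning.
    """
    profile = pd.Series(profile)
    if not accepted:
        logger.warning("empty pathway list; returning empty heatmap")
        return pd.DataFrame(columns=pd.unique(profile.to_numpy()))
    members = _memberships(accepted, profile.index)
    return infotheory.signed_logp_frame(members, profile.to_numpy())


def results_frame(results: list[PathwayMIResult]) -> pd.DataFrame:
    """Tabular view of :func:`analyze_pathways` output."""
    return pd.DataFrame(
        [
            {"pathway": r.name, "mi": r.mi, "z": r.z, "p": r.p,
             "accepted": r.accepted}
            for r in results
        ]
    ).set_index("pathway")
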