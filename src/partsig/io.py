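"""Plain-text serialization helpers.

Expression/metadata TSV live on :class:`~partsig.study.ExpressionStudy`,
FASTA on :class:`~partsig.simulate.SequenceSet` and GMT on
:class:`~partsig.simulate.PathwayCollection`; this module adds the
centroid-model bundle (JSON: scalars as keys, matrices as nested lists)
and the signature table TSV.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .nsc import CentroidModel, SignatureProfile

__all__ = ["save_model", "load_model", "write_signature", "read_signature"]


def save_model(model: CentroidModel, path) -> None:
    """Write a fitted (optionally shrunken) model as a JSON text bundle."""
    payload = {
        "genes": list(map(str, model.genes)),
        "classes": [str(c) for c in model.classes],
        "overall_centroid": model.overall_centroid.tolist(),
        "centroids": model.centroids.tolist(),
        "pooled_sd": model.pooled_sd.tolist(),
        "s0": model.s0,
        "n_per_class": model.n_per_class.tolist(),
        "n_total": model.n_total,
        "m_k": model.m_k.tolist(),
        "priors": model.priors.tolist(),
        "d": model.d.tolist(),
        "delta": model.delta,
        "d_shrunk": None if model.d_shrunk is None else model.d_shrunk.tolist(),
        "shrunk_centroids": (None if model.shrunk_centroids is None
                             else model.shrunk_centroids.tolist()),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> CentroidModel:
    with open(path) as fh:
        p = json.load(fh)

    def arr(key):
        return None if p[key] is None else np.asarray(p[key], dtype=float)

    return CentroidModel(
        genes=pd.Index(p["genes"]),
        classes=np.asarray(p["classes"]),
        overall_centroid=arr("overall_centroid"),
        centroids=arr("centroids"),
        pooled_sd=arr("pooled_sd"),
        s0=float(p["s0"]),
        n_per_class=np.asarray(p["n_per_class"], dtype=int),
        n_total=int(p["n_total"]),
        m_k=arr("m_k"),
        priors=arr("priors"),
        d=arr("d"),
        delta=float(p["delta"]),
        d_shrunk=arr("d_shrunk"),
        shrunk_centroids=arr("shrunk_centroids"),
    )


def write_signature(profile: SignatureProfile, path) -> None:
    """Long-format signature TSV: gene, class, direction, |d'|."""
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_signature(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
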