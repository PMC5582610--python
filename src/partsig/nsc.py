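"""Nearest-shrunken-centroid multiclass classifier.

Class centroids (per-gene class means) are pulled toward the overall
centroid by soft thresholding of the standardized centroid differences

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),
    m_k  = sqrt(1/n_k - 1/n),

where ``s_i`` is the pooled within-class SD of gene *i* and ``s0`` a fudge
constant (a percentile of the ``s_i``, the median by default) guarding
against genes with near-zero within-class spread.  Soft thresholding

    d'_ik = sign(d_ik) * max(|d_ik| - delta, 0)

zeroes uninformative genes; the surviving nonzero ``d'`` define a sparse
per-phenotype signature with a direction (up/down versus the other classes).
Samples are classified to the class minimizing the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2  -  2 log pi_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CentroidModel", "SignatureProfile", "fit", "shrink",
           "classify", "extract_signature", "BACKGROUND"]

#: profile label for genes zeroed out of every class signature
BACKGROUND = "background"


@dataclass
class CentroidModel:
    """All fitted statistics of the (possibly shrunken) centroid classifier."""

    genes: pd.Index
    classes: np.ndarray            # fixed order; argmin ties break to first
    overall_centroid: np.ndarray   # (G,)
    centroids: np.ndarray          # (G, K) unshrunken class means
    pooled_sd: np.ndarray          # (G,) pooled within-class SD
    s0: float
    n_per_class: np.ndarray        # (K,)
    n_total: int
    m_k: np.ndarray                # (K,) standardization factors
    priors: np.ndarray             # (K,)
    d: np.ndarray                  # (G, K) standardized differences
    delta: float = 0.0             # shrinkage applied
    d_shrunk: np.ndarray | None = None      # (G, K)
    shrunk_centroids: np.ndarray | None = None  # (G, K)

    @property
    def n_nonzero_genes(self) -> int:
        """Genes with a nonzero shrunken difference in at least one class."""
        d = self.d if self.d_shrunk is None else self.d_shrunk
        return int(np.any(d != 0, axis=1).sum())


@dataclass
class SignatureProfile:
    """Categorical gene profile induced by a shrunken model.

    ``per_class`` holds, for each phenotype, the genes with nonzero
    shrunken difference together with direction and magnitude; a gene may
    appear under more than one class.  ``categories`` assigns every gene a
    single label — the class of its largest |d'|, or ``background`` when
    all d' are zero — which is the profile the pathway and motif analyses
    condition on.
    """

    per_class: dict
    categories: pd.Series
    directions: pd.Series

    @property
    def signature_genes(self) -> pd.Index:
        return self.categories.index[self.categories != BACKGROUND]

    def class_counts(self) -> pd.Series:
        """Signature sizes per class (a gene may count toward several)."""
        return pd.Series({k: len(v) for k, v in self.per_class.items()})

    def summary(self) -> str:
        """Per-class gene counts plus the unique signature size."""
        lines = ["class\tgenes(n)"]
        for k, tab in self.per_class.items():
            lines.append(f"{k}\t{len(tab)}")
        lines.append(f"unique signature genes\t{len(self.signature_genes)}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, class, direction, |d'|."""
        rows = []
        for k, tab in self.per_class.items():
            for gene, row in tab.iterrows():
                rows.append((gene, k, int(row["direction"]), row["magnitude"]))
        return pd.DataFrame(rows, columns=["gene", "class", "direction",
                                           "magnitude"])


def _coerce_matrix(x) -> tuple[np.ndarray, pd.Index]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), x.index
    arr = np.asarray(x, dtype=float)
    return arr, pd.RangeIndex(arr.shape[0])


def fit(x, labels, priors: str = "empirical",
        s0_percentile: float = 50.0, s0: float | None = None,
        classes=None) -> CentroidModel:
    """Fit the unshrunken centroid model.

    Parameters
    ----------
    x : (genes x samples) DataFrame or array
        Normalized expression; z-scored input is the conventional choice
        but raw normalized values work identically.
    labels : class label per sample.
    priors : ``"empirical"`` (class frequencies) or ``"uniform"``.
    s0_percentile : percentile of the pooled SDs used for the fudge
        constant ``s0`` (50 = median).
    s0 : explicit fudge constant overriding the percentile (0 recovers
        plain per-gene standardization).
    classes : optional explicit class order; defaults to sorted labels,
        which for the four phenotypes yields (PL, PNL, TL, TNL).
    """
    mat, genes = _coerce_matrix(x)
    y = np.asarray(labels)
    if mat.shape[1] != y.shape[0]:
        raise ValueError("labels length does not match number of samples")
    if classes is None:
        classes = np.unique(y)
    else:
        classes = np.asarray(classes)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least two classes")
    n = mat.shape[1]
    n_k = np.array([(y == c).sum() for c in classes])
    if (n_k < 2).any():
        bad = classes[n_k < 2]
        raise ValueError(f"class(es) with fewer than 2 samples: {list(bad)}")

    centroids = np.column_stack([mat[:, y == c].mean(axis=1) for c in classes])
    overall = mat.mean(axis=1)
    # pooled within-class SD: sqrt( sum_k sum_{i in k} (x - xbar_k)^2 / (n - K) )
    ss = np.zeros(mat.shape[0])
    for j, c in enumerate(classes):
        resid = mat[:, y == c] - centroids[:, [j]]
        ss += (resid ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss / (n - k))
    if s0 is None:
        if not np.any(pooled_sd > 0):
            raise ValueError("all genes have zero within-class variance")
        s0 = float(np.percentile(pooled_sd, s0_percentile))
    else:
        s0 = float(s0)
    if np.any(pooled_sd + s0 == 0):
        raise ValueError("zero standardization: pooled SD and s0 both zero")
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    d = (centroids - overall[:, None]) / (m_k[None, :] * (pooled_sd + s0)[:, None])

    if priors == "empirical":
        pi = n_k / n
    elif priors == "uniform":
        pi = np.full(k, 1.0 / k)
    else:
        raise ValueError(f"unknown priors {priors!r}")

    return CentroidModel(
        genes=genes, classes=classes, overall_centroid=overall,
        centroids=centroids, pooled_sd=pooled_sd, s0=s0,
        n_per_class=n_k, n_total=n, m_k=m_k, priors=pi, d=d,
    )


def shrink(model: CentroidModel, delta: float) -> CentroidModel:
    """Soft-threshold the standardized differences by ``delta`` (>= 0).

    Returns a new model with ``d'`` and the shrunken centroids
    ``xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik``.
    """
    if delta < 0:
        raise ValueError("shrinkage delta must be non-negative")
    d_shr = np.sign(model.d) * np.maximum(np.abs(model.d) - delta, 0.0)
    scale = model.m_k[None, :] * (model.pooled_sd + model.s0)[:, None]
    shrunk = model.overall_centroid[:, None] + scale * d_shr
    return replace(model, delta=float(delta), d_shrunk=d_shr,
                   shrunk_centroids=shrunk)


def _discriminants(model: CentroidModel, x: np.ndarray) -> np.ndarray:
    cent = (model.shrunk_centroids if model.shrunk_centroids is not None
            else model.centroids)
    denom = (model.pooled_sd + model.s0) ** 2  # (G,)
    # scores: (samples, K)
    diff = x[:, :, None] - cent[None, :, :]          # (S, G, K)
    scores = np.einsum("sgk,g->sk", diff ** 2, 1.0 / denom)
    return scores - 2.0 * np.log(model.priors)[None, :]


def classify(model: CentroidModel, x):
    """Assign samples to the class with the smallest discriminant.

    ``x`` is one profile (length G) or a genes x samples matrix aligned to
    ``model.genes``.  Returns ``(predicted labels, score matrix)``; for a
    single profile the prediction is a scalar.  Ties break to the earliest
    class in ``model.classes``.
    """
    if isinstance(x, pd.DataFrame):
        if not x.index.equals(pd.Index(model.genes)):
            try:
                x = x.loc[model.genes]
            except KeyError as exc:
                raise ValueError("sample is missing model genes") from exc
        arr = x.to_numpy(dtype=float).T  # (S, G)
    elif isinstance(x, pd.Series):
        arr = x.reindex(model.genes).to_numpy(dtype=float)[None, :]
        if np.isnan(arr).any():
            raise ValueError("sample is missing model genes")
    else:
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        else:
            arr = arr.T  # genes x samples -> samples x genes
    if arr.shape[1] != len(model.genes):
        raise ValueError("profile length does not match model genes")
    if np.isnan(arr).any():
        raise ValueError("profile contains missing gene values")
    scores = _discriminants(model, arr)
    pred = model.classes[np.argmin(scores, axis=1)]
    if scores.shape[0] == 1:
        return pred[0], scores[0]
    return pred, scores


def extract_signature(model: CentroidModel) -> SignatureProfile:
    """Per-class signature genes (nonzero d') with direction and magnitude.

    Requires a shrunken model.  The single-category profile assigns each
    gene the class of its largest |d'| (ties to the earliest class), or
    ``background`` when every d' is zero.
    """
    if model.d_shrunk is None:
        raise ValueError("model has not been shrunken; call shrink() first")
    d = model.d_shrunk
    per_class = {}
    for j, c in enumerate(model.classes):
        nz = d[:, j] != 0
        per_class[str(c)] = pd.DataFrame(
            {
                "direction": np.sign(d[nz, j]).astype(int),
                "magnitude": np.abs(d[nz, j]),
            },
            index=model.genes[nz],
        ).sort_values("magnitude", ascending=False)
    absd = np.abs(d)
    any_nz = absd.max(axis=1) > 0
    best = np.argmax(absd, axis=1)
    cats = np.where(any_nz, model.classes[best].astype(object), BACKGROUND)
    dirs = np.where(any_nz, np.sign(d[np.arange(d.shape[0]), best]), 0)
    return SignatureProfile(
        per_class=per_class,
        categories=pd.Series(cats, index=model.genes, name="category"),
        directions=pd.Series(dirs.astype(int), index=model.genes,
                             name="direction"),
    )
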