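"""Full-dataset z-scoring and within-tissue variability profiling.

The pipeline's first analytic step asks *where* in the pregnant uterus the
four parturition phenotypes differ most.  Each gene is z-scored over the full
sample set, then the standard deviation of those z-scores is taken within
each tissue: a tissue whose samples span all four phenotypes will show large
within-tissue spread for genes whose expression tracks phenotype.  The
fraction of genes whose within-tissue SD exceeds 1 (or 2) ranks the tissues;
in the motivating study the maternal-fetal interface (decidua, chorion,
amnion) ranks on top.

Note the within-tissue SD of z-scores is expressed in multiples of the
gene's full-dataset SD but is *not* itself a z-score, so no standard-normal
tail proportions should be expected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = ["ZScoreMatrix", "TissueVariability", "zscore_normalize",
           "tissue_variability", "variability_proportions"]


@dataclass
class ZScoreMatrix:
    """Per-gene standardized expression (row mean 0, row SD 1, ddof=1)."""

    z: pd.DataFrame
    dropped_genes: list = field(default_factory=list)
    samples: pd.DataFrame | None = None


@dataclass
class TissueVariability:
    """Within-tissue SDs of z-scores and the derived per-tissue fractions."""

    s: pd.DataFrame  # genes x tissues
    proportions: pd.DataFrame | None = None  # tissues x thresholds


def zscore_normalize(study) -> ZScoreMatrix:
    """Standardize every gene over all samples jointly.

    ``z[g,i] = (x[g,i] - mean_g) / sd_g`` with the sample SD (ddof=1).
    Zero-variance genes cannot be standardized; they are dropped and listed
    in :attr:`ZScoreMatrix.dropped_genes`.

    Accepts an :class:`~partsig.study.ExpressionStudy` or a bare DataFrame.
    """
    if isinstance(study, ExpressionStudy):
        values, samples = study.values, study.samples
    else:
        values, samples = pd.DataFrame(study), None
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least two samples (SD undefined)")
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    dropped = list(values.index[sd == 0])
    if dropped:
        logger.warning("dropping %d zero-variance genes", len(dropped))
    keep = sd > 0
    z = values.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return ZScoreMatrix(z=z, dropped_genes=dropped, samples=samples)


def tissue_variability(z: ZScoreMatrix, annotations=None) -> TissueVariability:
    """Within-tissue SD (ddof=1) of z-scores, per gene and tissue.

    ``annotations`` is a sample -> tissue mapping (Series or the study's
    sample table); defaults to the table carried on ``z``.  Every tissue
    needs at least two samples for the SD to exist.
    """
    if annotations is None:
        annotations = z.samples
    if annotations is None:
        raise ValueError("no tissue annotations available")
    if isinstance(annotations, pd.DataFrame):
        tissue = annotations["tissue"]
    else:
        tissue = pd.Series(annotations)
    tissue = tissue.reindex(z.z.columns)
    if tissue.isna().any():
        raise ValueError("tissue annotation missing for some samples")
    cols = {}
    for t, ids in tissue.groupby(tissue).groups.items():
        if len(ids) < 2:
            raise ValueError(f"tissue {t!r} has fewer than 2 samples")
        cols[t] = z.z[list(ids)].std(axis=1, ddof=1)
    return TissueVariability(s=pd.DataFrame(cols))


def variability_proportions(tv: TissueVariability,
                            thresholds=(1.0, 2.0)) -> pd.DataFrame:
    """Per-tissue fraction of genes with within-tissue SD strictly above
    each threshold, plus the tissue ranking those fractions imply.

    Returns tissues as rows, one ``s>c`` column per threshold, sorted by
    the first threshold's fraction in decreasing order.  The result is also
    stored on ``tv.proportions``.
    """
    if tv.s.shape[0] == 0:
        raise ValueError("no genes in the variability table")
    out = pd.DataFrame(
        {f"s>{thr:g}": (tv.s > thr).mean(axis=0) for thr in thresholds}
    )
    out = out.sort_values(out.columns[0], ascending=False)
    tv.proportions = out
    return out
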