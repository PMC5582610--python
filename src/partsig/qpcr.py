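"""Relative qPCR quantification by the 2^-ddCt method.

Target-gene cycle thresholds are normalized to a reference gene (GAPDH in
the validation arm) within each sample (dCt), then to the mean dCt of a
control group (ddCt); the fold change is 2^-ddCt.  Technical duplicates
are averaged on the Ct scale before any differencing.  Group summaries use
the geometric mean of folds (equivalently the arithmetic mean of ddCt),
the convention consistent with the exponential transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fold_change_ddct", "group_anova"]

REQUIRED_COLUMNS = ("sample", "group", "gene", "ct")


def _validate(ct: pd.DataFrame) -> pd.DataFrame:
    ct = pd.DataFrame(ct)
    for col in REQUIRED_COLUMNS:
        if col not in ct.columns:
            raise ValueError(f"Ct table lacks required column {col!r}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle counts")
    return ct


def fold_change_ddct(ct: pd.DataFrame, control: str,
                     reference_gene: str = "GAPDH"):
    """Per-sample and per-group fold changes relative to a control group.

    Parameters
    ----------
    ct : long-format table with columns ``sample``, ``group``, ``gene``,
        ``ct`` (one row per well; replicate wells are averaged).
    control : group label whose mean dCt anchors the ddCt (per gene).
    reference_gene : the normalizer measured in every sample.

    Returns
    -------
    (per_sample, per_group) : two DataFrames.  ``per_sample`` has one row
    per sample x target gene with ``dct``, ``ddct`` and ``fold``;
    ``per_group`` the per-group geometric-mean fold and mean ddCt.
    """
    ct = _validate(ct)
    # average technical duplicates on the Ct scale
    ct = (ct.groupby(["sample", "group", "gene"], as_index=False)["ct"]
            .mean())
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    missing = set(targets["sample"]) - set(ref.index)
    if missing:
        raise ValueError(
            f"missing reference ({reference_gene}) Ct for sample(s) "
            f"{sorted(missing)[:5]}")
    if control not in set(ct["group"]):
        raise ValueError(f"unknown control group {control!r}")

    targets["dct"] = targets["ct"].to_numpy() - ref.loc[
        targets["sample"]].to_numpy()
    control_mean = (targets[targets["group"] == control]
                    .groupby("gene")["dct"].mean())
    absent = set(targets["gene"]) - set(control_mean.index)
    if absent:
        raise ValueError(
            f"control group has no measurements for gene(s) {sorted(absent)}")
    targets["ddct"] = targets["dct"].to_numpy() - control_mean.loc[
        targets["gene"]].to_numpy()
    targets["fold"] = 2.0 ** (-targets["ddct"])

    per_group = (targets.groupby(["gene", "group"])
                 .agg(mean_ddct=("ddct", "mean"), n=("ddct", "size"))
                 .reset_index())
    per_group["geometric_mean_fold"] = 2.0 ** (-per_group["mean_ddct"])
    return targets.reset_index(drop=True), per_group


def group_anova(per_sample: pd.DataFrame, value: str = "ddct") -> pd.Series:
    """One-way ANOVA of ddCt across groups, per target gene (reporting
    plumbing for the validation figures, not part of the method core)."""
    out = {}
    for gene, sub in per_sample.groupby("gene"):
        groups = [g[value].to_numpy() for _, g in sub.groupby("group")]
        if len(groups) < 2:
            out[gene] = float("nan")
            continue
        out[gene] = float(stats.f_oneway(*groups).pvalue)
    return pd.Series(out, name="anova_p")
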