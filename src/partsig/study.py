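"""Expression-study container: a gene x sample matrix with sample annotations.

A study bundles the normalized expression matrix (genes as rows, samples as
columns) with the per-sample design: which subject the sample came from, which
tissue it is, and which parturition phenotype (PL, PNL, TL, TNL) the pregnancy
belonged to.  All downstream stages (variability profiling, classification,
cross-validation) consume this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical phenotype order, also the deterministic tie-break order
PHENOTYPES = ("PL", "PNL", "TL", "TNL")

#: the eight sampled tissue compartments of the pregnant uterus
TISSUES = (
    "maternal_blood",
    "chorion",
    "amnion",
    "placenta",
    "decidua",
    "fetal_blood",
    "fundus_myometrium",
    "lower_segment_myometrium",
)

#: tissues forming the maternal-fetal interface
INTERFACE_TISSUES = ("chorion", "amnion", "decidua")

REQUIRED_SAMPLE_COLUMNS = ("subject", "tissue", "phenotype")


@dataclass
class ExpressionStudy:
    """Gene x sample expression values plus the sample design table.

    Parameters
    ----------
    values : pandas.DataFrame
        Expression matrix, genes as the index, sample ids as columns.
        Must be complete (no NaN) — the z-score machinery assumes a full
        matrix, so missing values are refused at construction.
    samples : pandas.DataFrame
        One row per sample (index = sample id) with columns
        ``subject``, ``tissue`` and ``phenotype``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.samples.index.is_unique:
            raise ValueError("sample ids are not unique")
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample table lacks required column {col!r}")
            if self.samples[col].isna().any():
                raise ValueError(f"sample table column {col!r} has missing entries")
        if list(self.values.columns) != list(self.samples.index):
            # allow same set in different order; align matrix to the table
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("matrix columns and sample table ids differ")
            self.values = self.values[self.samples.index]

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def phenotypes(self) -> pd.Series:
        return self.samples["phenotype"]

    @property
    def tissues(self) -> pd.Series:
        return self.samples["tissue"]

    def phenotype_counts(self) -> pd.Series:
        return self.phenotypes.value_counts()

    # -- I/O -------------------------------------------------------------------

    def to_tsv(self, expression_path, metadata_path) -> None:
        """Write the matrix and the sample table as TSV files."""
        self.values.to_csv(expression_path, sep="\t", index_label="gene")
        self.samples.to_csv(metadata_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, expression_path, metadata_path) -> "ExpressionStudy":
        """Load a study from an expression TSV and a metadata TSV.

        Missing values in the matrix are refused (the z-score formulas
        assume a complete matrix).
        """
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
        samples = pd.read_csv(metadata_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values=values, samples=samples)
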