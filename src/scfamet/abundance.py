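"""Gene-length-normalized relative abundances and feature aggregation.

Gene abundance is computed as ``G_i = (r_i / L_i) / sum_j (r_j / L_j)`` after
dropping genes with fewer than ``min_reads`` mapped reads.  Feature-level
abundances (KO, enzyme, species) are sums of the gene abundances annotated to
the same feature; mass with no annotation is reported separately so that the
total is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "normalize_genes",
    "aggregate",
]

GROUPS = ("CTR", "AF")


@dataclass
class AbundanceMatrix:
    """Samples x features relative-abundance table with two-group labels.

    Parameters
    ----------
    values :
        DataFrame indexed by sample id, one column per feature id.
    groups :
        Series mapping sample id to ``"CTR"`` or ``"AF"``.
    """

    values: pd.DataFrame
    groups: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if (self.values.values < -1e-12).any():
            raise ValueError("abundances must be non-negative")
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(self.values.index)
            bad = set(self.groups.dropna().unique()) - set(GROUPS)
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    def group_values(self, group: str) -> pd.DataFrame:
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        return self.values.loc[self.groups == group]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        if self.groups is not None:
            out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        groups = None
        if "group" in df.columns:
            groups = df.pop("group")
        return cls(values=df, groups=groups)


def normalize_genes(table: pd.DataFrame, min_reads: int = 2) -> pd.Series:
    """Length-normalize read counts to relative gene abundances.

    ``table`` needs columns ``gene_id``, ``read_count`` and ``gene_length_bp``.
    Genes with ``read_count < min_reads`` are removed before normalization, so
    the surviving abundances sum to 1.
    """
    for col in ("gene_id", "read_count", "gene_length_bp"):
        if col not in table.columns:
            raise ValueError(f"gene table missing column {col!r}")
    if (table["gene_length_bp"] <= 0).any():
        raise ValueError("gene_length_bp must be positive")
    if (table["read_count"] < 0).any():
        raise ValueError("read_count must be non-negative")

    kept = table[table["read_count"] >= min_reads]
    if kept.empty:
        raise ValueError(
            f"no genes with read_count >= {min_reads}; nothing to normalize"
        )
    rate = kept["read_count"].to_numpy(float) / kept["gene_length_bp"].to_numpy(float)
    g = rate / rate.sum()
    return pd.Series(g, index=pd.Index(kept["gene_id"], name="gene_id"), name="abundance")


def aggregate(
    genes: pd.Series, mapping: Mapping[str, str]
) -> tuple[pd.Series, float]:
    """Sum gene abundances into feature abundances.

    ``mapping`` may be partial; mass of unmapped genes is returned as the
    second element so that ``features.sum() + unmapped == genes.sum()``.
    """
    feature = genes.index.map(lambda g: mapping.get(g))
    mapped = genes[feature.notna()]
    unmapped = float(genes.sum() - mapped.sum())
    if mapped.empty:
        return pd.Series(dtype=float, name="abundance"), unmapped
    out = mapped.groupby(feature[feature.notna()]).sum()
    out.index.name = "feature_id"
    out.name = "abundance"
    return out, unmapped


def close_rows(values: np.ndarray) -> np.ndarray:
    """Renormalize each row to sum to 1 (simplex closure)."""
    totals = values.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("cannot close rows with non-positive totals")
    return values / totals
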