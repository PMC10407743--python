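"""Annotated gene x feature matrix.

Every feature column carries two pieces of metadata — a family (expression,
ppi, embedding, ...) and a tissue of origin — which later drive the
aggregation of additive attributions by feature type and by tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FAMILIES = (
    "expression",
    "preferential_expression",
    "developmental_expression",
    "eqtl",
    "ppi",
    "differential_ppi",
    "embedding",
    "variability",
    "dev_variability",
    "paralog",
    "process_activity",
)


@dataclass
class FeatureTable:
    """Gene x feature values plus per-feature metadata.

    ``values``: DataFrame (genes x features); missing values allowed before
    imputation. ``meta``: DataFrame indexed by feature id with columns
    ``family`` and ``tissue_of_origin``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][:5]
            raise ValueError(f"duplicate feature ids: {list(dup)}")
        if not self.values.columns.equals(self.meta.index):
            raise ValueError("feature metadata does not cover the value columns")
        bad = set(self.meta["family"]) - set(FAMILIES)
        if bad:
            raise ValueError(f"unknown feature families: {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    def select(self, family: str | None = None, tissue: str | None = None) -> "FeatureTable":
        mask = np.ones(len(self.meta), dtype=bool)
        if family is not None:
            mask &= (self.meta["family"] == family).values
        if tissue is not None:
            mask &= (self.meta["tissue_of_origin"] == tissue).values
        cols = self.meta.index[mask]
        return FeatureTable(self.values[cols], self.meta.loc[cols])

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.meta.copy())

    def to_tsv(self, values_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        self.meta.to_csv(meta_path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, values_path: str | Path, meta_path: str | Path) -> "FeatureTable":
        values = pd.read_csv(values_path, sep="\t", index_col="gene")
        meta = pd.read_csv(meta_path, sep="\t", index_col="feature_id")
        return cls(values, meta)


def concat_feature_tables(fragments: list[FeatureTable]) -> FeatureTable:
    """Column-concatenate fragments sharing one gene set.

    Raises on a gene-set mismatch (naming the offending fragment) and on
    duplicated feature ids.
    """
    if not fragments:
        raise ValueError("no fragments to assemble")
    genes = fragments[0].genes
    for i, frag in enumerate(fragments[1:], start=1):
        if not frag.genes.equals(genes):
            raise ValueError(f"fragment {i} has a different gene set than fragment 0")
    values = pd.concat([f.values for f in fragments], axis=1)
    meta = pd.concat([f.meta for f in fragments], axis=0)
    return FeatureTable(values, meta)


def make_fragment(
    values: pd.DataFrame, family: str, tissues: list[str] | str
) -> FeatureTable:
    """Wrap a values block as a fragment with uniform family metadata."""
    if isinstance(tissues, str):
        tissues = [tissues] * values.shape[1]
    meta = pd.DataFrame(
        {"family": family, "tissue_of_origin": tissues}, index=values.columns
    )
    return FeatureTable(values, meta)
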