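"""Per-tissue gene labels from disease-gene-tissue associations.

A gene is positive for tissue ``t`` when at least one of its diseases
manifests in ``t``; everything else is negative. For evaluation, genes are
also grouped into tissue-associated disease genes, other disease genes, and
non-disease genes. Brain-region labels use a curation confidence of 1-3 and
call a gene positive at confidence >= 2. Tissues are modeled only when they
carry strictly more than 60 positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_POSITIVES = 60

GROUP_TISSUE = "tissue_associated"
GROUP_OTHER = "other_disease"
GROUP_NON = "non_disease"


@dataclass
class LabelSlice:
    """Binary labels and evaluation groups for one tissue (or brain region)."""

    tissue: str
    labels: pd.Series  # gene -> {0, 1}
    groups: pd.Series  # gene -> group tag
    provenance: dict[str, list[str]]  # positive gene -> disease ids

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


def label_genes_for_tissue(
    associations: pd.DataFrame, gene_universe: pd.Index, tissue: str
) -> LabelSlice:
    """Label every gene in the universe for one tissue.

    ``associations`` columns: disease_id, gene, tissue. Associations to genes
    outside the universe are skipped with a warning.
    """
    known = associations["gene"].isin(gene_universe)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("skipping %d association(s) to unknown genes", n_unknown)
    assoc = associations[known]
    disease_genes = set(assoc["gene"])
    here = assoc[assoc["tissue"] == tissue]
    positive_genes = set(here["gene"])
    labels = pd.Series(
        [1 if g in positive_genes else 0 for g in gene_universe],
        index=gene_universe,
        name=tissue,
    )
    groups = pd.Series(
        [
            GROUP_TISSUE
            if g in positive_genes
            else (GROUP_OTHER if g in disease_genes else GROUP_NON)
            for g in gene_universe
        ],
        index=gene_universe,
        name="group",
    )
    provenance = {
        g: sorted(here.loc[here["gene"] == g, "disease_id"].unique())
        for g in positive_genes
    }
    return LabelSlice(tissue=tissue, labels=labels, groups=groups, provenance=provenance)


def label_brain_regions(
    brain_associations: pd.DataFrame, gene_universe: pd.Index, region: str
) -> LabelSlice:
    """Brain-region labels: positive iff associated at confidence >= 2."""
    conf = brain_associations["confidence"]
    if not conf.isin([1, 2, 3]).all():
        bad = sorted(conf[~conf.isin([1, 2, 3])].unique())
        raise ValueError(f"confidence levels outside {{1,2,3}}: {bad}")
    known = brain_associations["gene"].isin(gene_universe)
    if (~known).any():
        logger.warning("skipping %d brain association(s) to unknown genes", int((~known).sum()))
    assoc = brain_associations[known]
    here = assoc[(assoc["region"] == region) & (assoc["confidence"] >= 2)]
    positive_genes = set(here["gene"])
    brain_genes = set(assoc["gene"])
    labels = pd.Series(
        [1 if g in positive_genes else 0 for g in gene_universe],
        index=gene_universe,
        name=region,
    )
    groups = pd.Series(
        [
            GROUP_TISSUE
            if g in positive_genes
            else (GROUP_OTHER if g in brain_genes else GROUP_NON)
            for g in gene_universe
        ],
        index=gene_universe,
        name="group",
    )
    provenance = {
        g: sorted(here.loc[here["gene"] == g, "disease_id"].unique())
        for g in positive_genes
    }
    return LabelSlice(tissue=region, labels=labels, groups=groups, provenance=provenance)


def eligible_tissues(
    label_slices: dict[str, LabelSlice], min_positives: int = MIN_POSITIVES
) -> list[str]:
    """Tissues with strictly more than ``min_positives`` positive genes."""
    return [t for t, sl in label_slices.items() if sl.n_positive > min_positives]


def label_all_tissues(
    associations: pd.DataFrame, gene_universe: pd.Index, tissues: list[str]
) -> dict[str, LabelSlice]:
    return {t: label_genes_for_tissue(associations, gene_universe, t) for t in tissues}
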