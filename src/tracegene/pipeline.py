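"""End-to-end orchestration: cohort inputs -> feature table -> labels.

Ties the expression summaries and every feature family together in the
order the framework prescribes: TMM cpm, expressed calls, genes expressed in
no tissue excluded, preferential expression, developmental summaries, then
all feature fragments assembled into one annotated table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import features as ft
from .cohort import CohortBundle
from .expression import (
    DevExpressionSummary,
    NormalizedExpression,
    PreferentialExpression,
    TissueExpressionSummary,
    call_expressed,
    developmental_summaries,
    preferential_expression,
    tissue_medians,
    tmm_normalize,
)
from .feature_table import FeatureTable
from .labels import LabelSlice, label_all_tissues


@dataclass
class ExpressionContext:
    """Per-cohort expression summaries reused across stages."""

    norm: NormalizedExpression
    expressed: pd.DataFrame
    summary: TissueExpressionSummary
    pref: PreferentialExpression
    dev: DevExpressionSummary


def expression_context(bundle: CohortBundle) -> ExpressionContext:
    norm = tmm_normalize(bundle.counts)
    expressed = call_expressed(norm)
    keep = expressed.any(axis=1)
    norm.values = norm.values.loc[keep]
    expressed = expressed.loc[keep]
    summary = tissue_medians(norm)
    pref = preferential_expression(summary)
    dev = developmental_summaries(bundle.dev_expression.loc[
        bundle.dev_expression.index.intersection(norm.values.index)
    ].reindex(norm.values.index))
    return ExpressionContext(
        norm=norm, expressed=expressed, summary=summary, pref=pref, dev=dev
    )


def build_feature_table(
    bundle: CohortBundle,
    ctx: ExpressionContext | None = None,
    embedding_dims: int = 64,
    seed: int = 0,
    variability: pd.DataFrame | None = None,
) -> tuple[FeatureTable, ExpressionContext]:
    """Assemble the full gene x feature table for a cohort.

    ``variability`` optionally adds precomputed adult expression-variability
    columns (genes x tissues) as-is.
    """
    if ctx is None:
        ctx = expression_context(bundle)
    genes = ctx.norm.values.index
    fragments = [
        ft.expression_features(ctx.summary, ctx.pref, ctx.expressed, ctx.dev),
        ft.eqtl_features(bundle.eqtl_q, genes),
        ft.ppi_count_features(bundle.ppi_edges, ctx.expressed, ctx.pref),
        ft.differential_ppi_features(bundle.ppi_edges, ctx.summary),
        ft.embedding_features(
            bundle.ppi_edges, ctx.expressed, dims=embedding_dims, seed=seed
        ),
        ft.paralog_features(ctx.norm, bundle.paralogs, ctx.expressed),
    ]
    activity, gene_terms = ft.process_activity_scores(ctx.summary, bundle.go_annotations)
    fragments.append(ft.process_activity_features(activity, gene_terms, genes))
    if variability is not None:
        block = variability.reindex(genes)
        tissues = list(block.columns)
        block.columns = [f"var|{t}" for t in tissues]
        fragments.append(ft.make_fragment(block, "variability", tissues))
    table = ft.assemble_feature_table(fragments)
    return table, ctx


def cohort_labels(bundle: CohortBundle, genes: pd.Index) -> dict[str, LabelSlice]:
    return label_all_tissues(bundle.associations, genes, list(bundle.config.tissues))
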