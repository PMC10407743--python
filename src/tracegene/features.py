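"""Tissue-based gene feature families.

Builds the gene x feature dataset: per-tissue expression and preferential
expression, developmental expression and variability, eQTL q-values, three
PPI count features (plus mean/median deviations), tissue-differential PPI
summaries, node2vec interactome embeddings, paralog dosage ratios, and
differential process-activity summaries. Structurally undefined cells (no
paralog, no edges, no annotated term, node absent from a tissue interactome)
stay missing and are imputed later; only "not expressed -> 0" cases are
zero-filled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse

from . import embedding as emb
from .expression import (
    DevExpressionSummary,
    NormalizedExpression,
    PreferentialExpression,
    TissueExpressionSummary,
    PREF_THRESHOLD,
)
from .feature_table import FeatureTable, concat_feature_tables, make_fragment

logger = logging.getLogger(__name__)

#: pseudocount (cpm) guarding log-ratios and expression ratios
EPSILON_CPM = 1.0
#: a pair interacting in at most this fraction of tissues is tissue-specific
TISSUE_SPECIFIC_FRACTION = 0.20
#: paralog pairs need at least this reciprocal sequence identity (percent)
PARALOG_MIN_IDENTITY = 40.0
#: eligible GO terms annotate between 3 and 100 genes (inclusive)
GO_TERM_SIZE_RANGE = (3, 100)


# ---------------------------------------------------------------------------
# transcriptomic + eQTL features


def expression_features(
    summary: TissueExpressionSummary,
    pref: PreferentialExpression,
    expressed: pd.DataFrame,
    dev: DevExpressionSummary | None = None,
) -> FeatureTable:
    """Per-tissue expression level (0 when not expressed), preferential
    expression, and the developmental median / variability panels."""
    genes = summary.med_e.index
    tissues = list(summary.med_e.columns)
    frags = []

    expr = summary.med_e.where(expressed.loc[genes, tissues], 0.0)
    expr.columns = [f"expr|{t}" for t in tissues]
    frags.append(make_fragment(expr, "expression", tissues))

    p = pref.pref.loc[genes, tissues].copy()
    p.columns = [f"pref|{t}" for t in tissues]
    frags.append(make_fragment(p, "preferential_expression", tissues))

    if dev is not None:
        med = dev.med_dev.loc[genes]
        flat = med.copy()
        flat.columns = [f"dev|{o}|{tp}" for o, tp in med.columns]
        frags.append(make_fragment(flat, "developmental_expression", "general"))
        cv = dev.cv_dev.loc[genes].copy()
        cv.columns = [f"devcv|{o}" for o in dev.cv_dev.columns]
        frags.append(make_fragment(cv, "dev_variability", "general"))
    return concat_feature_tables(frags)


def eqtl_features(eqtl_q: pd.DataFrame, genes: pd.Index) -> FeatureTable:
    """One feature per tissue: the gene's eGene q-value (missing if absent)."""
    vals = eqtl_q.values[np.isfinite(eqtl_q.values)]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("eQTL q-values must lie in [0, 1]")
    out = eqtl_q.reindex(genes)
    tissues = list(out.columns)
    out.columns = [f"eqtl|{t}" for t in tissues]
    return make_fragment(out, "eqtl", tissues)


# ---------------------------------------------------------------------------
# PPI count features


def _edge_array(ppi_edges: pd.DataFrame, genes: pd.Index) -> np.ndarray:
    """Deduplicated undirected edges as integer index pairs into ``genes``.

    Edges touching genes outside the expression data are dropped with a
    logged count; self loops are dropped too.
    """
    pos = pd.Series(np.arange(len(genes)), index=genes)
    a = ppi_edges.iloc[:, 0].map(pos)
    b = ppi_edges.iloc[:, 1].map(pos)
    known = a.notna() & b.notna()
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("ignoring %d PPI edge(s) with unknown gene(s)", n_unknown)
    e = np.stack([a[known].astype(int), b[known].astype(int)], axis=1)
    e = e[e[:, 0] != e[:, 1]]
    e = np.unique(np.sort(e, axis=1), axis=0)
    return e


def _adjacency(edges: np.ndarray, n: int) -> sparse.csr_matrix:
    if edges.shape[0] == 0:
        return sparse.csr_matrix((n, n))
    data = np.ones(edges.shape[0] * 2)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def ppi_count_features(
    ppi_edges: pd.DataFrame,
    expressed: pd.DataFrame,
    pref: PreferentialExpression,
) -> FeatureTable:
    """Nine PPI features per tissue.

    Primaries: (i) tissue interactors — neighbors expressed in the tissue, 0
    when the gene itself is not expressed there; (ii) preferential tissue
    interactors — neighbors with preferential expression >= 2; (iii)
    tissue-specific interactors — tissue interactors whose pair co-occurs in
    at most 20% of tissues (boundary inclusive). Each primary gets two
    deviation features: value minus its mean, and minus its median, across
    tissues.
    """
    genes = expressed.index
    tissues = list(expressed.columns)
    n = len(genes)
    edges = _edge_array(ppi_edges, genes)
    adj = _adjacency(edges, n)

    ex = expressed.values.astype(float)  # genes x T
    pr = (pref.pref.loc[genes, tissues].values >= PREF_THRESHOLD).astype(float)

    n_interactors = adj @ ex  # neighbors expressed in t
    n_pref = adj @ pr
    n_interactors = np.where(ex > 0, n_interactors, 0.0)
    n_pref = np.where(ex > 0, n_pref, 0.0)

    # tissue-specific pairs: co-expressed in at most 20% of tissues
    if edges.shape[0]:
        co = (
            expressed.values[edges[:, 0]] & expressed.values[edges[:, 1]]
        ).sum(axis=1)
        specific = co <= TISSUE_SPECIFIC_FRACTION * len(tissues)
        adj_spec = _adjacency(edges[specific], n)
    else:
        adj_spec = _adjacency(edges, n)
    n_specific = adj_spec @ ex
    n_specific = np.where((ex > 0) & (n_interactors > 0), n_specific, 0.0)

    frags = []
    for name, mat in [
        ("ppi_tissue_interactors", n_interactors),
        ("ppi_pref_interactors", n_pref),
        ("ppi_specific_interactors", n_specific),
    ]:
        df = pd.DataFrame(mat, index=genes, columns=[f"{name}|{t}" for t in tissues])
        frags.append(make_fragment(df, "ppi", tissues))
        mean_dev = mat - mat.mean(axis=1, keepdims=True)
        med_dev = mat - np.median(mat, axis=1, keepdims=True)
        frags.append(
            make_fragment(
                pd.DataFrame(mean_dev, index=genes, columns=[f"{name}_dmean|{t}" for t in tissues]),
                "ppi",
                tissues,
            )
        )
        frags.append(
            make_fragment(
                pd.DataFrame(med_dev, index=genes, columns=[f"{name}_dmedian|{t}" for t in tissues]),
                "ppi",
                tissues,
            )
        )
    return concat_feature_tables(frags)


# ---------------------------------------------------------------------------
# tissue-differential PPI features


def differential_edge_scores(
    summary: TissueExpressionSummary, edges: np.ndarray
) -> np.ndarray:
    """Per (edge, tissue) differential interaction score.

    An interaction is as available as its scarcer partner: the score is
    log2((min of the endpoints' medians in t + eps) / (median over other
    tissues of that pairwise minimum + eps)).
    """
    med = summary.med_e.values
    pair_min = np.minimum(med[edges[:, 0]], med[edges[:, 1]])  # edges x T
    n_t = pair_min.shape[1]
    scores = np.empty_like(pair_min)
    for j in range(n_t):
        others = np.median(np.delete(pair_min, j, axis=1), axis=1)
        scores[:, j] = np.log2((pair_min[:, j] + EPSILON_CPM) / (others + EPSILON_CPM))
    return scores


def differential_ppi_features(
    ppi_edges: pd.DataFrame, summary: TissueExpressionSummary
) -> FeatureTable:
    """Min/max/median/mean of a gene's incident differential edge scores,
    per tissue; all four missing for genes without edges."""
    genes = summary.med_e.index
    tissues = list(summary.med_e.columns)
    edges = _edge_array(ppi_edges, genes)
    n = len(genes)
    stats = {
        s: np.full((n, len(tissues)), np.nan) for s in ("min", "max", "median", "mean")
    }
    if edges.shape[0]:
        scores = differential_edge_scores(summary, edges)
        endpoint = np.concatenate([edges[:, 0], edges[:, 1]])
        stacked = np.vstack([scores, scores])  # one row per (edge, endpoint)
        order = np.argsort(endpoint, kind="stable")
        endpoint, stacked = endpoint[order], stacked[order]
        uniq, starts = np.unique(endpoint, return_index=True)
        bounds = np.append(starts, endpoint.size)
        for i, g in enumerate(uniq):
            block = stacked[bounds[i] : bounds[i + 1]]
            stats["min"][g] = block.min(axis=0)
            stats["max"][g] = block.max(axis=0)
            stats["median"][g] = np.median(block, axis=0)
            stats["mean"][g] = block.mean(axis=0)
    frags = []
    for s in ("min", "max", "median", "mean"):
        df = pd.DataFrame(
            stats[s], index=genes, columns=[f"dppi_{s}|{t}" for t in tissues]
        )
        frags.append(make_fragment(df, "differential_ppi", tissues))
    return concat_feature_tables(frags)


# ---------------------------------------------------------------------------
# network embedding features


def embedding_features(
    ppi_edges: pd.DataFrame,
    expressed: pd.DataFrame,
    dims: int = emb.DEFAULT_DIMS,
    n_walks: int = emb.DEFAULT_WALKS,
    walk_length: int = emb.DEFAULT_WALK_LENGTH,
    seed: int = 0,
) -> FeatureTable:
    """node2vec vectors for the general interactome and each tissue interactome.

    A tissue interactome is the PPI subgraph induced by the genes expressed in
    that tissue. Genes absent from an interactome get missing cells for its
    ``dims`` columns.
    """
    genes = expressed.index
    tissues = list(expressed.columns)
    edges = _edge_array(ppi_edges, genes)
    frags = []
    for label in ["general"] + tissues:
        if label == "general":
            sub_edges = edges
            nodes = np.arange(len(genes))
        else:
            in_t = expressed[label].values
            keep = in_t[edges[:, 0]] & in_t[edges[:, 1]]
            sub_edges = edges[keep]
            nodes = np.where(in_t)[0]
        if sub_edges.shape[0] == 0:
            raise ValueError(f"interactome {label!r} has no edges; cannot embed")
        # reindex to compact node ids
        remap = -np.ones(len(genes), dtype=int)
        remap[nodes] = np.arange(nodes.size)
        compact = remap[sub_edges]
        vecs = emb.embed_graph(
            nodes.size,
            compact,
            dims=dims,
            n_walks=n_walks,
            walk_length=walk_length,
            seed=seed,
        )
        full = np.full((len(genes), dims), np.nan)
        full[nodes] = vecs
        df = pd.DataFrame(
            full, index=genes, columns=[f"emb|{label}|d{i}" for i in range(dims)]
        )
        frags.append(make_fragment(df, "embedding", label))
    return concat_feature_tables(frags)


# ---------------------------------------------------------------------------
# paralog features


def paralog_features(
    norm: NormalizedExpression,
    paralogs: pd.DataFrame,
    expressed: pd.DataFrame,
) -> FeatureTable:
    """Dosage relationships with paralogs, per tissue.

    Feature 1: median over a tissue's samples of cpm(gene)/cpm(best paralog),
    the best paralog being the highest-identity partner (>= 40%) expressed in
    at least one tissue. Feature 2: the same with the summed cpm of all
    qualifying paralogs in the denominator. Zero denominators are floored at a
    1-cpm pseudocount. Genes without qualifying paralogs stay missing.
    """
    genes = norm.values.index
    tissues = list(expressed.columns)
    if len(paralogs):
        ident = paralogs.iloc[:, 2].astype(float)
        if ((ident < 0) | (ident > 100)).any():
            raise ValueError("paralog identity values must lie in [0, 100]")
    expressed_any = expressed.any(axis=1)

    # symmetric qualifying pairs
    pairs = []
    for _, (ga, gb, ident) in paralogs.iterrows():
        if ident < PARALOG_MIN_IDENTITY:
            continue
        pairs.append((ga, gb, float(ident)))
        pairs.append((gb, ga, float(ident)))
    best: dict[str, str] = {}
    allp: dict[str, list[str]] = {}
    for g, p, ident in sorted(pairs, key=lambda r: (r[0], -r[2], r[1])):
        if g not in genes or p not in genes:
            continue
        allp.setdefault(g, []).append(p)
        if g not in best and expressed_any.get(p, False):
            best[g] = p

    n_samples = norm.values.shape[1]
    cpm = norm.values
    best_ratio = pd.DataFrame(np.nan, index=genes, columns=tissues)
    sum_ratio = pd.DataFrame(np.nan, index=genes, columns=tissues)

    tissue_cols = {
        t: norm.values.columns[norm.tissue_of.loc[norm.values.columns] == t]
        for t in tissues
    }
    if best:
        g_list = [g for g in genes if g in best]
        num = cpm.loc[g_list].values
        den = np.maximum(cpm.loc[[best[g] for g in g_list]].values, EPSILON_CPM)
        ratios = num / den
        rdf = pd.DataFrame(ratios, index=g_list, columns=cpm.columns)
        for t in tissues:
            if len(tissue_cols[t]):
                best_ratio.loc[g_list, t] = np.median(rdf[tissue_cols[t]].values, axis=1)
    if allp:
        g_list = [g for g in genes if g in allp]
        num = cpm.loc[g_list].values
        den = np.zeros((len(g_list), n_samples))
        for i, g in enumerate(g_list):
            den[i] = cpm.loc[allp[g]].values.sum(axis=0)
        ratios = num / np.maximum(den, EPSILON_CPM)
        rdf = pd.DataFrame(ratios, index=g_list, columns=cpm.columns)
        for t in tissues:
            if len(tissue_cols[t]):
                sum_ratio.loc[g_list, t] = np.median(rdf[tissue_cols[t]].values, axis=1)

    best_ratio.columns = [f"paralog_best_ratio|{t}" for t in tissues]
    sum_ratio.columns = [f"paralog_sum_ratio|{t}" for t in tissues]
    return concat_feature_tables(
        [
            make_fragment(best_ratio, "paralog", tissues),
            make_fragment(sum_ratio, "paralog", tissues),
        ]
    )


# ---------------------------------------------------------------------------
# differential process activity


def log2_fold_change(summary: TissueExpressionSummary) -> pd.DataFrame:
    """log2((median in t + eps) / (median over other tissues + eps)) per gene."""
    med = summary.med_e.values
    out = np.empty_like(med, dtype=float)
    for j in range(med.shape[1]):
        others = np.median(np.delete(med, j, axis=1), axis=1)
        out[:, j] = np.log2((med[:, j] + EPSILON_CPM) / (others + EPSILON_CPM))
    return pd.DataFrame(out, index=summary.med_e.index, columns=summary.med_e.columns)


def process_activity_scores(
    summary: TissueExpressionSummary, go_annotations: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Differential activity of each eligible GO term per tissue.

    Terms annotating 3-100 known genes (inclusive) are scored by the mean
    log2 fold-change of their member genes. Returns (term x tissue activity,
    gene -> eligible terms map).
    """
    genes = summary.med_e.index
    lfc = log2_fold_change(summary)
    members: dict[str, list[str]] = {}
    for term, sub in go_annotations.groupby(go_annotations.columns[0]):
        gs = [g for g in sub.iloc[:, 1].unique() if g in genes]
        if GO_TERM_SIZE_RANGE[0] <= len(gs) <= GO_TERM_SIZE_RANGE[1]:
            members[str(term)] = gs
    activity = pd.DataFrame(
        {t: 0.0 for t in summary.med_e.columns}, index=sorted(members)
    )
    for term, gs in members.items():
        activity.loc[term] = lfc.loc[gs].mean(axis=0)
    gene_terms: dict[str, list[str]] = {}
    for term, gs in members.items():
        for g in gs:
            gene_terms.setdefault(g, []).append(term)
    return activity, gene_terms


def process_activity_features(
    activity: pd.DataFrame,
    gene_terms: dict[str, list[str]],
    genes: pd.Index,
) -> FeatureTable:
    """Min/max/median/mean of a gene's term activities per tissue; missing for
    genes without eligible terms."""
    tissues = list(activity.columns)
    stats = {
        s: pd.DataFrame(np.nan, index=genes, columns=tissues)
        for s in ("min", "max", "median", "mean")
    }
    for g in genes:
        terms = gene_terms.get(g)
        if not terms:
            continue
        block = activity.loc[terms].values
        stats["min"].loc[g] = block.min(axis=0)
        stats["max"].loc[g] = block.max(axis=0)
        stats["median"].loc[g] = np.median(block, axis=0)
        stats["mean"].loc[g] = block.mean(axis=0)
    frags = []
    for s in ("min", "max", "median", "mean"):
        df = stats[s]
        df.columns = [f"proc_{s}|{t}" for t in tissues]
        frags.append(make_fragment(df, "process_activity", tissues))
    return concat_feature_tables(frags)


# ---------------------------------------------------------------------------
# assembly


def assemble_feature_table(fragments: list[FeatureTable]) -> FeatureTable:
    """Column-concatenate all fragments (shared gene set enforced)."""
    return concat_feature_tables(fragments)


def expected_feature_count(
    n_tissues: int,
    n_eqtl_tissues: int,
    n_dev_organs: int,
    n_dev_timepoints: int,
    n_cv_organs: int,
    embedding_dims: int = emb.DEFAULT_DIMS,
    n_variability_columns: int = 0,
) -> int:
    """Closed-form column count of the assembled table.

    Per tissue: 2 transcriptomic + 9 PPI + 4 differential-PPI + 2 paralog +
    4 process-activity features; plus one eQTL column per eQTL tissue,
    embeddings for the general and each tissue interactome, the developmental
    grid, per-organ developmental variability, and any precomputed adult
    variability columns.
    """
    return (
        n_tissues * (2 + 9 + 4 + 2 + 4)
        + n_eqtl_tissues
        + embedding_dims * (n_tissues + 1)
        + n_dev_organs * n_dev_timepoints
        + n_cv_organs
        + n_variability_columns
    )
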