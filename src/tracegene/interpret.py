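"""Additive attribution of tissue-risk predictions.

Interpretability models are gradient-boosted trees (the same XGBoost
configuration as the prediction-mode base learner) preceded by an
L1-SVM feature selection with C = 2 capped at 50 features. Shapley additive
attributions come from the exact tree algorithm built into XGBoost
(``pred_contribs``): per gene, the per-feature attributions plus the base
value reproduce the model's margin output. Per-feature importances are mean
absolute attributions normalized to sum to one, which makes them additive
under aggregation by feature family or by tissue of origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .feature_table import FeatureTable
from .learner import (
    SELECTION_C_INTERPRET,
    SELECTION_CAP_INTERPRET,
    L1SvmSelector,
    _fit_quiet,
    make_base_learners,
)


@dataclass
class AttributionReport:
    """Per-gene additive attributions for one fitted model."""

    attributions: pd.DataFrame  # genes x features (all features; unselected = 0)
    base_value: float
    margins: pd.Series  # model margin output per explained gene
    normalized_importance: pd.Series  # per feature, sums to 1
    meta: pd.DataFrame  # feature metadata (family, tissue_of_origin)

    def top_feature(self, gene: str) -> str:
        """Feature with the largest absolute attribution for a gene."""
        return self.attributions.loc[gene].abs().idxmax()


def fit_interpretability_model(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0
) -> tuple[xgb.XGBClassifier, L1SvmSelector]:
    """L1-SVM selection (C = 2, cap 50) followed by the XGB configuration."""
    selector = L1SvmSelector(
        C=SELECTION_C_INTERPRET, cap=SELECTION_CAP_INTERPRET, seed=seed
    ).fit(X.values, y)
    model = make_base_learners(seed)["xgb"]
    _fit_quiet(model, selector.transform(X.values), y)
    return model, selector


def _attribution_report(
    model: xgb.XGBClassifier,
    selector: L1SvmSelector,
    table: FeatureTable,
    explain: pd.DataFrame,
) -> AttributionReport:
    Xs = selector.transform(explain.values)
    dm = xgb.DMatrix(Xs)
    booster = model.get_booster()
    contribs = booster.predict(dm, pred_contribs=True)
    margins = booster.predict(dm, output_margin=True)
    base_value = float(contribs[0, -1])
    attr = np.zeros((explain.shape[0], table.values.shape[1]))
    attr[:, selector.get_support()] = contribs[:, :-1]
    attributions = pd.DataFrame(attr, index=explain.index, columns=table.features)
    mean_abs = attributions.abs().mean(axis=0)
    total = mean_abs.sum()
    normalized = mean_abs / total if total > 0 else mean_abs
    return AttributionReport(
        attributions=attributions,
        base_value=base_value,
        margins=pd.Series(margins, index=explain.index, name="margin"),
        normalized_importance=normalized.rename("normalized_importance"),
        meta=table.meta,
    )


def single_gene_model(
    table: FeatureTable, labels: pd.Series, query_gene: str, seed: int = 0
) -> AttributionReport:
    """Leave-one-out interpretability model for one query gene.

    Trains on every gene except the query (labels for the query's affected
    tissue), then attributes the query's prediction to its features.
    """
    if query_gene not in table.genes:
        raise KeyError(f"query gene {query_gene!r} not in the feature table")
    train_genes = table.genes[table.genes != query_gene]
    X = table.values.loc[train_genes]
    y = labels.loc[train_genes].values.astype(int)
    if y.sum() == 0:
        raise ValueError("no positive genes left after withholding the query")
    model, selector = fit_interpretability_model(X, y, seed=seed)
    return _attribution_report(model, selector, table, table.values.loc[[query_gene]])


def tissue_model_importances(
    table: FeatureTable, labels: pd.Series, seed: int = 0
) -> AttributionReport:
    """Tissue-level model trained on all genes, attributed over all genes."""
    X = table.values
    y = labels.loc[table.genes].values.astype(int)
    model, selector = fit_interpretability_model(X, y, seed=seed)
    return _attribution_report(model, selector, table, X)


def aggregate_importances(
    report: AttributionReport,
    key: str,
    modeled_tissues: list[str] | None = None,
) -> pd.Series:
    """Sum normalized importances by ``family`` or ``tissue_of_origin``.

    With ``key='tissue_of_origin'``, tissues outside ``modeled_tissues`` are
    collapsed into "Other". Groups with no member features are absent from
    the output (not zero rows).
    """
    if key not in ("family", "tissue_of_origin"):
        raise ValueError("key must be 'family' or 'tissue_of_origin'")
    missing = report.normalized_importance.index.difference(report.meta.index)
    if len(missing):
        raise ValueError(f"features without metadata: {list(missing[:5])}")
    groups = report.meta.loc[report.normalized_importance.index, key].copy()
    if key == "tissue_of_origin" and modeled_tissues is not None:
        keep = set(modeled_tissues)
        groups = groups.where(groups.isin(keep), "Other")
    agg = report.normalized_importance.groupby(groups).sum()
    return agg.sort_values(ascending=False)
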