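"""Patient-tailored candidate-gene prioritization.

For a patient with an affected tissue and a candidate gene list, the
patient's candidates are entirely withheld: imputation statistics, power
transforms, scaling, feature selection and every model are fitted on
non-candidate genes only, candidates are pushed through the frozen
preprocessing state and the trained stack, and ranked by their final score
(competition ranking, ties broken lexicographically by gene id).

Two training modes:

* strict per-patient (``rank_patient``) — one model per (patient, tissue),
  exactly the leave-candidates-out protocol;
* pooled batches (``benchmark_patients(..., batch_size=k)``) — patients of
  the same tissue share one model whose training set withholds the union of
  the batch's candidate sets. Training rows still never intersect any batch
  member's candidates, so the per-patient leakage audit holds; it trades a
  somewhat smaller training set for one training per batch instead of one
  per patient, which is what makes large synthetic benchmarks affordable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientCase
from .feature_table import FeatureTable
from .learner import TraceClassifier
from .preprocess import TracePreprocessor

logger = logging.getLogger(__name__)


@dataclass
class RankResult:
    """Ranked candidates of one (patient, tissue) case."""

    patient_id: str
    tissue: str
    scores: pd.Series  # candidate gene -> score (descending = better)
    ranks: pd.Series  # candidate gene -> 1..n
    unscored: list[str]
    verified_gene: str | None = None
    train_genes: frozenset = field(default_factory=frozenset)

    @property
    def n_candidates(self) -> int:
        return len(self.ranks)

    @property
    def verified_rank(self) -> int | None:
        if self.verified_gene is None or self.verified_gene not in self.ranks.index:
            return None
        return int(self.ranks[self.verified_gene])

    def quantile_flags(self) -> dict[str, bool]:
        n = self.n_candidates
        r = self.verified_rank
        if r is None:
            return {}
        return {
            "above_median": r <= math.ceil(n / 2),
            "top_quartile": r <= math.ceil(0.25 * n),
            "top_decile": r <= math.ceil(0.10 * n),
        }

    def leakage_audit(self) -> bool:
        """True iff no candidate gene appears among the training rows."""
        return not (set(self.scores.index) | set(self.unscored)) & set(self.train_genes)


def rank_candidates(scores: pd.Series) -> pd.Series:
    """Competition ranking on descending score, ties broken by gene id."""
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return pd.Series(np.arange(1, len(order) + 1), index=order, name="rank").loc[
        scores.index
    ]


def _score_case(
    case: PatientCase,
    tissue: str,
    clf: TraceClassifier,
    pre: TracePreprocessor,
    table: FeatureTable,
    withheld_processed: FeatureTable,
    train_genes: frozenset,
) -> RankResult:
    in_table = [g for g in case.candidates if g in table.genes]
    unscored = [g for g in case.candidates if g not in table.genes]
    if unscored:
        logger.warning(
            "patient %s: %d candidate(s) absent from the feature table",
            case.patient_id,
            len(unscored),
        )
    X = withheld_processed.values.loc[in_table]
    scores = pd.Series(clf.predict_scores(X.values), index=in_table, name="trace_score")
    return RankResult(
        patient_id=case.patient_id,
        tissue=tissue,
        scores=scores,
        ranks=rank_candidates(scores),
        unscored=unscored,
        verified_gene=case.verified_gene,
        train_genes=train_genes,
    )


def _train_and_score(
    table: FeatureTable,
    labels: pd.Series,
    cases: list[PatientCase],
    tissue: str,
    seed: int,
    n_folds: int = 10,
) -> list[RankResult]:
    """Train one model withholding the union of the cases' candidates."""
    withheld = sorted(
        set(g for case in cases for g in case.candidates) & set(table.genes)
    )
    train_genes = table.genes.difference(withheld)
    y = labels.loc[train_genes].astype(int)
    if y.sum() < 10:
        raise ValueError(
            f"tissue {tissue!r}: only {int(y.sum())} positives left after withholding"
        )
    raw_train = FeatureTable(table.values.loc[train_genes], table.meta)
    pre = TracePreprocessor(seed=seed)
    processed_train = pre.fit_transform(raw_train)
    clf = TraceClassifier(seed=seed, n_folds=n_folds).fit(
        processed_train.values, y.loc[train_genes]
    )
    raw_withheld = FeatureTable(table.values.loc[withheld], table.meta)
    withheld_processed = pre.transform(raw_withheld)
    frozen = frozenset(train_genes)
    return [
        _score_case(case, tissue, clf, pre, table, withheld_processed, frozen)
        for case in cases
    ]


def rank_patient(
    table: FeatureTable,
    labels: pd.Series,
    case: PatientCase,
    tissue: str,
    seed: int = 0,
    n_folds: int = 10,
) -> RankResult:
    """Strict leave-candidates-out scoring of one patient in one tissue.

    ``table`` is the raw (pre-preprocessing) feature table; all fitted
    statistics are derived from non-candidate genes only.
    """
    if tissue not in case.affected_tissues:
        raise ValueError(f"tissue {tissue!r} is not an affected tissue of the case")
    return _train_and_score(table, labels, [case], tissue, seed, n_folds=n_folds)[0]


def benchmark_patients(
    table: FeatureTable,
    labels: dict[str, pd.Series],
    cases: list[PatientCase],
    seed: int = 0,
    batch_size: int | None = None,
    n_folds: int = 10,
) -> list[RankResult]:
    """Rank every (case, affected tissue) pair.

    ``batch_size=None`` trains one model per case (strict mode); otherwise
    cases of the same tissue are pooled into batches of that size.
    """
    by_tissue: dict[str, list[PatientCase]] = {}
    for case in cases:
        for t in case.affected_tissues:
            by_tissue.setdefault(t, []).append(case)
    results = []
    for t in sorted(by_tissue):
        tissue_cases = by_tissue[t]
        size = batch_size or 1
        for i in range(0, len(tissue_cases), size):
            chunk = tissue_cases[i : i + size]
            results.extend(
                _train_and_score(table, labels[t], chunk, t, seed + i, n_folds=n_folds)
            )
    return results


def expression_baseline(
    case: PatientCase, med_e: pd.DataFrame, tissue: str
) -> RankResult:
    """Rank candidates by descending median expression in the tissue."""
    in_table = [g for g in case.candidates if g in med_e.index]
    unscored = [g for g in case.candidates if g not in med_e.index]
    scores = med_e.loc[in_table, tissue].rename("expression")
    return RankResult(
        patient_id=case.patient_id,
        tissue=tissue,
        scores=scores,
        ranks=rank_candidates(scores),
        unscored=unscored,
        verified_gene=case.verified_gene,
    )


def summarize_ranks(results: list[RankResult]) -> dict:
    """Median verified rank and the above-median/top-quartile/top-decile
    fractions across cases."""
    ranks = [r.verified_rank for r in results if r.verified_rank is not None]
    flags = [r.quantile_flags() for r in results if r.verified_rank is not None]
    if not ranks:
        return {"n": 0}
    return {
        "n": len(ranks),
        "median_rank": float(np.median(ranks)),
        "above_median": float(np.mean([f["above_median"] for f in flags])),
        "top_quartile": float(np.mean([f["top_quartile"] for f in flags])),
        "top_decile": float(np.mean([f["top_decile"] for f in flags])),
    }


def compare_rankings(results_a: list[RankResult], results_b: list[RankResult]) -> dict:
    """Paired one-sided Wilcoxon signed-rank test that method A ranks verified
    genes better (lower) than method B, plus per-method rank summaries."""
    key = lambda r: (r.patient_id, r.tissue)  # noqa: E731
    b_by_key = {key(r): r for r in results_b}
    pairs = [
        (ra.verified_rank, b_by_key[key(ra)].verified_rank)
        for ra in results_a
        if key(ra) in b_by_key
        and ra.verified_rank is not None
        and b_by_key[key(ra)].verified_rank is not None
    ]
    if not pairs:
        raise ValueError("no shared patients between the two result sets")
    ra = np.array([p[0] for p in pairs], dtype=float)
    rb = np.array([p[1] for p in pairs], dtype=float)
    if len(pairs) < 6:
        logger.warning("fewer than 6 pairs; using the exact signed-rank distribution")
    if np.all(ra == rb):
        p = 1.0
    else:
        p = float(
            stats.wilcoxon(ra, rb, alternative="less", zero_method="zsplit").pvalue
        )
    return {
        "n_pairs": len(pairs),
        "wilcoxon_p_a_better": p,
        "median_rank_a": float(np.median(ra)),
        "median_rank_b": float(np.median(rb)),
        "summary_a": summarize_ranks(results_a),
        "summary_b": summarize_ranks(results_b),
    }
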