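"""Expression normalization and per-tissue summaries.

This module turns a raw gene x sample count matrix into the quantities the
rest of the pipeline consumes:

* TMM-normalized counts-per-million (cpm), with the low-count filter applied
  before factor estimation,
* per-tissue "expressed" calls (>= 7 cpm in at least half a tissue's samples),
* preferential expression: per gene and tissue, the tissue median centred by
  the median of medians and standardized by their interquartile range,
* developmental medians and coefficients of variation from an
  organ x timepoint expression panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: linear-scale cpm threshold above which a gene counts as expressed in a sample
EXPRESSED_CPM = 7.0
#: genes whose raw count never exceeds this value are dropped before TMM
LOW_COUNT_MAX = 10
#: preferential-expression score above which a gene is "preferentially expressed"
PREF_THRESHOLD = 2.0


@dataclass
class CountMatrix:
    """Raw counts with a sample -> tissue map.

    ``values`` is a genes x samples DataFrame of non-negative integers;
    ``tissue_of`` maps every sample id to exactly one tissue.
    """

    values: pd.DataFrame
    tissue_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        missing = [s for s in self.values.columns if s not in self.tissue_of.index]
        if missing:
            raise ValueError(f"samples without tissue assignment: {missing[:5]}")
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def tissues(self) -> list[str]:
        return sorted(self.tissue_of.loc[self.values.columns].unique())


@dataclass
class NormalizedExpression:
    """TMM-scaled cpm values for the genes surviving the low-count filter."""

    values: pd.DataFrame
    scaling_factors: pd.Series
    tissue_of: pd.Series

    @property
    def retained_genes(self) -> pd.Index:
        return self.values.index


@dataclass
class TissueExpressionSummary:
    """Per (gene, tissue) median cpm."""

    med_e: pd.DataFrame  # genes x tissues


@dataclass
class PreferentialExpression:
    pref: pd.DataFrame  # genes x tissues
    iqr_of_medians: pd.Series  # per gene


@dataclass
class DevExpressionSummary:
    med_dev: pd.DataFrame  # genes x (organ, timepoint) MultiIndex columns
    cv_dev: pd.DataFrame  # genes x organs


def _tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Robinson-Oshlack TMM factor of one sample against the reference.

    30% two-sided trim on M (log ratios), 5% on A (log abundances), then an
    inverse-(asymptotic-)variance weighted mean of the retained M values.
    """
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    # ranks as in edgeR (1-based, average ties)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.nansum(m[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_normalize(counts: CountMatrix) -> NormalizedExpression:
    """Normalize raw counts to TMM-scaled cpm.

    Genes whose count is at most ``LOW_COUNT_MAX`` in every sample are dropped
    before factor estimation. The reference sample is the one whose upper
    quartile of count proportions is closest to the mean upper quartile; TMM
    factors are centred so their geometric mean is one (as in the published
    estimator), and cpm uses the effective library size ``lib * factor``.
    """
    if counts.values.shape[1] < 2:
        raise ValueError("TMM normalization needs at least 2 samples")
    x = counts.values
    keep = (x.values > LOW_COUNT_MAX).any(axis=1)
    if not keep.any():
        raise ValueError("all genes removed by the low-count filter (max count <= 10)")
    x = x.loc[keep]
    lib = x.sum(axis=0).astype(float)
    zero_lib = lib[lib <= 0]
    if len(zero_lib):
        raise ValueError(f"zero library size for sample(s): {list(zero_lib.index)}")

    # reference column: upper quartile of proportions closest to the mean
    q75 = np.array([np.percentile(x[c].values / lib[c], 75) for c in x.columns])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = x.iloc[:, ref_idx].values

    factors = np.array(
        [
            _tmm_factor(x[c].values, ref, lib[c], lib.iloc[ref_idx])
            for c in x.columns
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    factors = pd.Series(factors, index=x.columns, name="tmm_factor")
    eff_lib = lib * factors
    cpm = x.div(eff_lib, axis=1) * 1e6
    return NormalizedExpression(values=cpm, scaling_factors=factors, tissue_of=counts.tissue_of)


def call_expressed(norm: NormalizedExpression) -> pd.DataFrame:
    """Per-tissue boolean expressed calls.

    A gene is expressed in a tissue when at least half of that tissue's samples
    show >= 7 cpm ("at least half" is inclusive: 2 of 4 samples qualifies).
    """
    tissues = sorted(norm.tissue_of.loc[norm.values.columns].unique())
    out = {}
    hits = norm.values.values >= EXPRESSED_CPM
    for t in tissues:
        cols = norm.values.columns[norm.tissue_of.loc[norm.values.columns] == t]
        if len(cols) == 0:
            raise ValueError(f"tissue {t!r} has no samples")
        idx = norm.values.columns.get_indexer(cols)
        n_hit = hits[:, idx].sum(axis=1)
        out[t] = n_hit * 2 >= len(cols)
    return pd.DataFrame(out, index=norm.values.index)


def tissue_medians(norm: NormalizedExpression) -> TissueExpressionSummary:
    """Median cpm per gene and tissue."""
    tissues = sorted(norm.tissue_of.loc[norm.values.columns].unique())
    med = {}
    for t in tissues:
        cols = norm.values.columns[norm.tissue_of.loc[norm.values.columns] == t]
        med[t] = np.median(norm.values[cols].values, axis=1)
    return TissueExpressionSummary(med_e=pd.DataFrame(med, index=norm.values.index))


def preferential_expression(summary: TissueExpressionSummary) -> PreferentialExpression:
    """Standardized tissue preference of each gene.

    pref(g, t) = (med(g, t) - median_t' med(g, t')) / IQR_t' med(g, t'),
    with linear-interpolation (type-7) percentiles. A zero IQR (a gene whose
    medians are identical across tissues) yields pref = 0 with a logged warning
    rather than an infinity.
    """
    med = summary.med_e
    if med.shape[1] < 3:
        raise ValueError("preferential expression needs >= 3 tissues")
    center = np.median(med.values, axis=1)
    q75 = np.percentile(med.values, 75, axis=1)
    q25 = np.percentile(med.values, 25, axis=1)
    iqr = q75 - q25
    zero = iqr == 0
    if zero.any():
        logger.warning("IQR of tissue medians is 0 for %d gene(s); pref set to 0", int(zero.sum()))
    safe_iqr = np.where(zero, 1.0, iqr)
    pref = (med.values - center[:, None]) / safe_iqr[:, None]
    pref[zero, :] = 0.0
    return PreferentialExpression(
        pref=pd.DataFrame(pref, index=med.index, columns=med.columns),
        iqr_of_medians=pd.Series(iqr, index=med.index, name="iqr"),
    )


def developmental_summaries(dev: pd.DataFrame) -> DevExpressionSummary:
    """Medians per (organ, timepoint) and per-organ coefficients of variation.

    ``dev`` has genes as rows and a 3-level MultiIndex column (organ,
    timepoint, sample) of normalized counts. The cv of a gene in an organ is
    the sample standard deviation (n-1) of its timepoint medians divided by
    their mean; it is missing when the mean is zero or the organ has fewer than
    two timepoints.
    """
    if not isinstance(dev.columns, pd.MultiIndex) or dev.columns.nlevels != 3:
        raise ValueError("developmental panel needs (organ, timepoint, sample) columns")
    med = dev.T.groupby(level=[0, 1]).median().T
    organs = med.columns.get_level_values(0).unique()
    cv = {}
    for organ in organs:
        sub = med[organ]
        if sub.shape[1] < 2:
            logger.warning("organ %r has <2 timepoints; cv undefined", organ)
            cv[organ] = np.full(len(med), np.nan)
            continue
        mean = sub.values.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = sub.values.std(axis=1, ddof=1)
            c = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
        cv[organ] = c
    return DevExpressionSummary(
        med_dev=med, cv_dev=pd.DataFrame(cv, index=med.index)
    )
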