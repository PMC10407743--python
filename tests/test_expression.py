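"""Expression-core checks against independent oracles.

The TMM oracle below is a direct, loop-level transcription of the
Robinson-Oshlack estimator, kept deliberately separate from the package's
implementation; the expressed-call and preferential-expression oracles are
brute-force per-gene loops.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tracegene.expression import (
    CountMatrix,
    call_expressed,
    developmental_summaries,
    preferential_expression,
    tissue_medians,
    tmm_normalize,
    TissueExpressionSummary,
)
from .conftest import random_count_matrix


# ---------------------------------------------------------------------------
# independent TMM oracle


def _oracle_tmm_factors(counts: np.ndarray) -> np.ndarray:
    """Straight-from-the-formula TMM: filter, pick reference by upper
    quartile, trim M by 30% and A by 5% two-sided, inverse-variance weighted
    mean of M, then geometric-mean centring."""
    keep = (counts > 10).any(axis=1)
    x = counts[keep].astype(float)
    lib = x.sum(axis=0)
    f75 = np.array([np.percentile(x[:, j] / lib[j], 75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(x.shape[1]):
        o, r = x[:, j], x[:, ref]
        ok = (o > 0) & (r > 0)
        o, r = o[ok], r[ok]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m)
        rank_m = pd.Series(m).rank().values
        rank_a = pd.Series(a).rank().values
        lo_m = np.floor(n * 0.3) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        kp = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        factors.append(2 ** (np.sum(m[kp] / w[kp]) / np.sum(1 / w[kp])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def _count_matrix(values: np.ndarray, tissues: list[str] | None = None) -> CountMatrix:
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    tissues = tissues or ["t0"] * values.shape[1]
    return CountMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        tissue_of=pd.Series(tissues, index=samples),
    )


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([100, 50, 20, 400, 15])
        cm = _count_matrix(np.stack([col, col], axis=1))
        norm = tmm_normalize(cm)
        assert np.allclose(norm.scaling_factors.values, 1.0)
        assert np.allclose(norm.values.iloc[:, 0], norm.values.iloc[:, 1])

    def test_pure_depth_difference_is_removed(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, size=80) + 12
        cm = _count_matrix(np.stack([a, 2 * a], axis=1))
        norm = tmm_normalize(cm)
        assert np.allclose(norm.values.iloc[:, 0], norm.values.iloc[:, 1], rtol=1e-10)

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_factors_match_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.negative_binomial(5, 0.05, size=(200, 6))
        cm = _count_matrix(counts)
        norm = tmm_normalize(cm)
        oracle = _oracle_tmm_factors(counts)
        assert np.allclose(norm.scaling_factors.values, oracle, atol=1e-8)

    def test_low_count_genes_removed_before_estimation(self):
        counts = np.array([[5, 8], [100, 120], [900, 1000]])
        cm = _count_matrix(counts)
        norm = tmm_normalize(cm)
        assert list(norm.values.index) == ["g1", "g2"]

    def test_all_genes_filtered_errors(self):
        cm = _count_matrix(np.array([[1, 2], [3, 4]]))
        with pytest.raises(ValueError, match="low-count"):
            tmm_normalize(cm)

    def test_edger_oracle(self):
        """Cross-check factors against edgeR's calcNormFactors via Rscript."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(5, 0.05, size=(150, 4))
        counts[(counts <= 10).all(axis=1)] += 20  # avoid filter-size mismatch
        cm = _count_matrix(counts)
        norm = tmm_normalize(cm)
        csv = "\n".join(",".join(map(str, row)) for row in counts)
        script = (
            "suppressMessages(library(edgeR));"
            "x <- as.matrix(read.csv('stdin', header=FALSE));"
            "f <- calcNormFactors(DGEList(counts=x))$samples$norm.factors;"
            "cat(sprintf('%.10f', f), sep='\\n')"
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], input=csv, text=True,
                capture_output=True, timeout=120, check=True,
            )
        except (subprocess.SubprocessError, OSError) as exc:
            pytest.skip(f"edgeR unavailable: {exc}")
        oracle = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(norm.scaling_factors.values, oracle, atol=1e-6)


class TestCallExpressed:
    def test_half_boundary_is_inclusive(self):
        # 2 of 4 samples at exactly 7 cpm qualifies
        values = pd.DataFrame(
            [[7.0, 7.0, 0.0, 0.0]], index=["g0"], columns=list("abcd")
        )
        from tracegene.expression import NormalizedExpression

        norm = NormalizedExpression(
            values=values,
            scaling_factors=pd.Series(1.0, index=list("abcd")),
            tissue_of=pd.Series(["t"] * 4, index=list("abcd")),
        )
        assert call_expressed(norm).loc["g0", "t"]

    def test_all_zero_gene_never_expressed(self, small_bundle):
        from tracegene.expression import NormalizedExpression

        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.uniform(0, 20, size=(5, 6)), index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(6)],
        )
        values.iloc[2] = 0.0
        norm = NormalizedExpression(
            values=values,
            scaling_factors=pd.Series(1.0, index=values.columns),
            tissue_of=pd.Series(["t0"] * 3 + ["t1"] * 3, index=values.columns),
        )
        assert not call_expressed(norm).loc["g2"].any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        cm = random_count_matrix(100, {"t0": 5, "t1": 5, "t2": 5}, seed)
        norm = tmm_normalize(cm)
        result = call_expressed(norm)
        for g in norm.values.index:
            for t in ["t0", "t1", "t2"]:
                cols = [s for s in norm.values.columns if norm.tissue_of[s] == t]
                n_hit = sum(norm.values.loc[g, s] >= 7.0 for s in cols)
                assert result.loc[g, t] == (n_hit >= len(cols) / 2)


class TestPreferentialExpression:
    def test_constant_gene_has_zero_pref(self):
        med = pd.DataFrame([[4.0] * 5], index=["g0"], columns=list("abcde"))
        out = preferential_expression(TissueExpressionSummary(med_e=med))
        assert (out.pref.loc["g0"] == 0).all()

    def test_linear_medians_hand_value(self):
        med = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["g0"], columns=list("abcde"))
        out = preferential_expression(TissueExpressionSummary(med_e=med))
        # (5 - 3) / (4 - 2) with type-7 percentiles
        assert out.pref.loc["g0", "e"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_gene_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        med = pd.DataFrame(
            rng.lognormal(2, 1, size=(50, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"t{j}" for j in range(6)],
        )
        out = preferential_expression(TissueExpressionSummary(med_e=med))
        for g in med.index:
            row = med.loc[g].values
            iqr = np.percentile(row, 75) - np.percentile(row, 25)
            for j, t in enumerate(med.columns):
                expect = (row[j] - np.median(row)) / iqr if iqr > 0 else 0.0
                assert out.pref.loc[g, t] == pytest.approx(expect, abs=1e-9)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        med = pd.DataFrame(
            rng.lognormal(2, 1, size=(20, 5)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abcde"),
        )
        base = preferential_expression(TissueExpressionSummary(med_e=med)).pref
        shifted = preferential_expression(TissueExpressionSummary(med_e=med + 3.0)).pref
        scaled = preferential_expression(TissueExpressionSummary(med_e=med * 2.5)).pref
        assert np.allclose(base.values, shifted.values)
        assert np.allclose(base.values, scaled.values)

    def test_max_median_attains_max_pref(self):
        rng = np.random.default_rng(6)
        med = pd.DataFrame(
            rng.lognormal(2, 1, size=(20, 5)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abcde"),
        )
        out = preferential_expression(TissueExpressionSummary(med_e=med))
        for g in med.index:
            assert out.pref.loc[g].idxmax() == med.loc[g].idxmax()

    def test_needs_three_tissues(self):
        med = pd.DataFrame([[1.0, 2.0]], index=["g0"], columns=["a", "b"])
        with pytest.raises(ValueError, match="3 tissues"):
            preferential_expression(TissueExpressionSummary(med_e=med))


class TestDevelopmentalSummaries:
    @staticmethod
    def _panel(values_by_tp: dict[str, list[float]], replicates: int = 1):
        cols, data = [], []
        for tp, vals in values_by_tp.items():
            for r in range(replicates):
                cols.append(("organ1", tp, f"r{r}"))
                data.append(vals)
        return pd.DataFrame(
            np.array(data).T,
            index=[f"g{i}" for i in range(len(next(iter(values_by_tp.values()))))],
            columns=pd.MultiIndex.from_tuples(cols, names=["organ", "timepoint", "sample"]),
        )

    def test_constant_gene_has_zero_cv(self):
        dev = self._panel({"tp0": [4.0], "tp1": [4.0], "tp2": [4.0]})
        out = developmental_summaries(dev)
        assert out.cv_dev.loc["g0", "organ1"] == 0.0

    def test_two_timepoint_hand_value(self):
        dev = self._panel({"tp0": [2.0], "tp1": [4.0]})
        out = developmental_summaries(dev)
        # sample sd of [2, 4] is sqrt(2); mean 3
        assert out.cv_dev.loc["g0", "organ1"] == pytest.approx(np.sqrt(2) / 3)

    def test_all_zero_gene_cv_missing(self):
        dev = self._panel({"tp0": [0.0], "tp1": [0.0]})
        out = developmental_summaries(dev)
        assert np.isnan(out.cv_dev.loc["g0", "organ1"])

    def test_median_over_replicates(self):
        dev = self._panel({"tp0": [1.0]}, replicates=3)
        dev.iloc[0] = [1.0, 5.0, 9.0]
        out = developmental_summaries(dev)
        assert out.med_dev.loc["g0", ("organ1", "tp0")] == 5.0
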