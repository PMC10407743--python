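"""Feature-family checks: brute-force oracles for the PPI counts and process
activities, hand arithmetic for the summary features, structural properties
of the embeddings, and the closed-form column count of the assembled table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tracegene import features as ft
from tracegene.expression import PreferentialExpression, TissueExpressionSummary
from tracegene.feature_table import FeatureTable, make_fragment


def _pref(df: pd.DataFrame) -> PreferentialExpression:
    return PreferentialExpression(
        pref=df, iqr_of_medians=pd.Series(1.0, index=df.index)
    )


class TestPpiCounts:
    def test_three_node_hand_case(self):
        edges = pd.DataFrame({"gene_a": ["A", "A"], "gene_b": ["B", "C"]})
        expressed = pd.DataFrame(
            {"t": [True, True, False], "u": [True, True, True], "v": [True, True, True]},
            index=["A", "B", "C"],
        )
        pref = _pref(pd.DataFrame(0.0, index=["A", "B", "C"], columns=["t", "u", "v"]))
        out = ft.ppi_count_features(edges, expressed, pref)
        assert out.values.loc["A", "ppi_tissue_interactors|t"] == 1
        assert out.values.loc["B", "ppi_tissue_interactors|t"] == 1
        assert out.values.loc["C", "ppi_tissue_interactors|t"] == 0

    def test_tissue_specific_boundary_inclusive(self):
        # 6 tissues: co-expressed in 1/6 (<=20%) counts, in 2/6 (33%) does not
        tissues = [f"t{i}" for i in range(6)]
        genes = ["A", "B", "C"]
        expressed = pd.DataFrame(False, index=genes, columns=tissues)
        expressed.loc["A"] = True
        expressed.loc["B", "t0"] = True  # A-B co-expressed in 1 tissue
        expressed.loc["C", ["t0", "t1"]] = True  # A-C co-expressed in 2
        edges = pd.DataFrame({"gene_a": ["A", "A"], "gene_b": ["B", "C"]})
        pref = _pref(pd.DataFrame(0.0, index=genes, columns=tissues))
        out = ft.ppi_count_features(edges, expressed, pref)
        assert out.values.loc["A", "ppi_specific_interactors|t0"] == 1  # only B
        assert out.values.loc["B", "ppi_specific_interactors|t0"] == 1
        assert out.values.loc["C", "ppi_specific_interactors|t0"] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, tissues = 50, [f"t{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(n)]
        adj = rng.random((n, n)) < 0.1
        adj = np.triu(adj, 1)
        rows, cols = np.where(adj)
        edges = pd.DataFrame({"gene_a": [genes[i] for i in rows],
                              "gene_b": [genes[j] for j in cols]})
        expressed = pd.DataFrame(
            rng.random((n, 6)) < 0.5, index=genes, columns=tissues
        )
        prefval = pd.DataFrame(
            rng.normal(0, 2, size=(n, 6)), index=genes, columns=tissues
        )
        out = ft.ppi_count_features(edges, expressed, _pref(prefval))

        neighbors = {g: set() for g in genes}
        for i, j in zip(rows, cols):
            neighbors[genes[i]].add(genes[j])
            neighbors[genes[j]].add(genes[i])
        n_co = {
            (a, b): int((expressed.loc[a] & expressed.loc[b]).sum())
            for a in genes
            for b in neighbors[a]
        }
        for g in genes:
            prim = {}
            for t in tissues:
                if not expressed.loc[g, t]:
                    prim[t] = (0, 0, 0)
                    continue
                ti = sum(expressed.loc[nb, t] for nb in neighbors[g])
                pi = sum(prefval.loc[nb, t] >= 2.0 for nb in neighbors[g])
                if ti > 0:
                    si = sum(
                        expressed.loc[nb, t] and n_co[(g, nb)] <= 0.2 * 6
                        for nb in neighbors[g]
                    )
                else:
                    si = 0
                prim[t] = (ti, pi, si)
            for k, name in enumerate(
                ["ppi_tissue_interactors", "ppi_pref_interactors", "ppi_specific_interactors"]
            ):
                vals = np.array([prim[t][k] for t in tissues], dtype=float)
                for j, t in enumerate(tissues):
                    assert out.values.loc[g, f"{name}|{t}"] == vals[j]
                    assert out.values.loc[g, f"{name}_dmean|{t}"] == pytest.approx(
                        vals[j] - vals.mean()
                    )
                    assert out.values.loc[g, f"{name}_dmedian|{t}"] == pytest.approx(
                        vals[j] - np.median(vals)
                    )

    def test_count_features_are_nonnegative_integers(self, small_features):
        table, _ = small_features
        for name in ["ppi_tissue_interactors", "ppi_pref_interactors", "ppi_specific_interactors"]:
            cols = [c for c in table.features if c.startswith(name + "|")]
            block = table.values[cols].values
            assert (block >= 0).all()
            assert np.allclose(block, np.round(block))


class TestDifferentialPpi:
    def _summary(self, med):
        return TissueExpressionSummary(med_e=med)

    def test_single_edge_statistics_collapse(self):
        med = pd.DataFrame(
            [[8.0, 1.0, 1.0], [4.0, 1.0, 1.0], [2.0, 2.0, 2.0]],
            index=["A", "B", "C"], columns=["t", "u", "v"],
        )
        edges = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"]})
        out = ft.differential_ppi_features(edges, self._summary(med))
        # pair minimum: 4 in t, 1 elsewhere -> score log2(5/2)
        expect = np.log2(5.0 / 2.0)
        for s in ("min", "max", "median", "mean"):
            assert out.values.loc["A", f"dppi_{s}|t"] == pytest.approx(expect)
        assert np.isnan(out.values.loc["C", "dppi_min|t"])  # isolated gene

    def test_summary_statistics_hand_values(self):
        scores = np.array([-1.0, 0.0, 3.0])
        assert scores.min() == -1 and scores.max() == 3
        assert np.median(scores) == 0 and scores.mean() == pytest.approx(2 / 3)
        # against the implementation on a 4-node star around A
        med = pd.DataFrame(
            [[15.0, 1.0, 1.0], [1.0, 7.0, 1.0], [3.0, 3.0, 3.0], [31.0, 1.0, 1.0]],
            index=["A", "B", "C", "D"], columns=["t", "u", "v"],
        )
        edges = pd.DataFrame({"gene_a": ["A", "A", "A"], "gene_b": ["B", "C", "D"]})
        out = ft.differential_ppi_features(edges, self._summary(med))
        s = ft.differential_edge_scores(
            self._summary(med), np.array([[0, 1], [0, 2], [0, 3]])
        )
        assert out.values.loc["A", "dppi_mean|t"] == pytest.approx(s[:, 0].mean())
        assert out.values.loc["A", "dppi_min|t"] == pytest.approx(s[:, 0].min())


class TestProcessActivity:
    def test_term_size_boundaries(self):
        med = pd.DataFrame(
            np.ones((120, 3)), index=[f"g{i}" for i in range(120)],
            columns=["t", "u", "v"],
        )
        rows = []
        rows += [("small", f"g{i}") for i in range(2)]
        rows += [("ok3", f"g{i}") for i in range(3)]
        rows += [("ok100", f"g{i}") for i in range(100)]
        rows += [("big", f"g{i}") for i in range(101)]
        go = pd.DataFrame(rows, columns=["term", "gene"])
        activity, gene_terms = ft.process_activity_scores(
            TissueExpressionSummary(med_e=med), go
        )
        assert set(activity.index) == {"ok3", "ok100"}

    def test_constant_member_fold_changes_average(self):
        # 3 genes each with 8x median in t vs 1x elsewhere (plus 1 pseudocount)
        med = pd.DataFrame(
            [[17.0, 8.0, 8.0]] * 3 + [[1.0, 1.0, 1.0]] * 2,
            index=[f"g{i}" for i in range(5)], columns=["t", "u", "v"],
        )
        go = pd.DataFrame(
            [("term", "g0"), ("term", "g1"), ("term", "g2")], columns=["term", "gene"]
        )
        activity, _ = ft.process_activity_scores(TissueExpressionSummary(med_e=med), go)
        assert activity.loc["term", "t"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(40)]
        tissues = [f"t{j}" for j in range(5)]
        med = pd.DataFrame(
            rng.lognormal(2, 1, size=(40, 5)), index=genes, columns=tissues
        )
        rows = []
        for k in range(10):
            size = int(rng.integers(3, 10))
            for g in rng.choice(genes, size=size, replace=False):
                rows.append((f"T{k}", g))
        go = pd.DataFrame(rows, columns=["term", "gene"])
        summary = TissueExpressionSummary(med_e=med)
        activity, gene_terms = ft.process_activity_scores(summary, go)
        for term in activity.index:
            members = go.loc[go["term"] == term, "gene"].unique()
            for j, t in enumerate(tissues):
                lfc = []
                for g in members:
                    others = np.median(np.delete(med.loc[g].values, j))
                    lfc.append(np.log2((med.loc[g, t] + 1) / (others + 1)))
                assert activity.loc[term, t] == pytest.approx(np.mean(lfc), abs=1e-9)
        feats = ft.process_activity_features(activity, gene_terms, pd.Index(genes))
        for g in genes:
            terms = gene_terms.get(g, [])
            for t in tissues:
                if not terms:
                    assert np.isnan(feats.values.loc[g, f"proc_mean|{t}"])
                else:
                    vals = activity.loc[terms, t].values
                    assert feats.values.loc[g, f"proc_min|{t}"] == pytest.approx(vals.min())
                    assert feats.values.loc[g, f"proc_median|{t}"] == pytest.approx(
                        np.median(vals)
                    )


class TestParalogs:
    def test_hand_ratio(self, ):
        from tracegene.expression import NormalizedExpression

        values = pd.DataFrame(
            [[4.0, 6.0], [2.0, 2.0]], index=["A", "B"], columns=["s0", "s1"]
        )
        norm = NormalizedExpression(
            values=values,
            scaling_factors=pd.Series(1.0, index=values.columns),
            tissue_of=pd.Series(["t", "t"], index=values.columns),
        )
        expressed = pd.DataFrame(
            {"t": [True, True], "u": [True, True], "v": [True, True]}, index=["A", "B"]
        )
        paralogs = pd.DataFrame(
            {"gene_a": ["A"], "gene_b": ["B"], "identity": [80.0]}
        )
        out = ft.paralog_features(norm, paralogs, expressed)
        # ratios [4/2, 6/2] -> median 2.5; pairs are symmetric, so B gets [1/2, 1/3]
        assert out.values.loc["A", "paralog_best_ratio|t"] == pytest.approx(2.5)
        assert out.values.loc["B", "paralog_best_ratio|t"] == pytest.approx((0.5 + 1 / 3) / 2)

    def test_below_identity_threshold_is_missing(self):
        from tracegene.expression import NormalizedExpression

        values = pd.DataFrame(
            [[4.0, 6.0], [2.0, 2.0]], index=["A", "B"], columns=["s0", "s1"]
        )
        norm = NormalizedExpression(
            values=values,
            scaling_factors=pd.Series(1.0, index=values.columns),
            tissue_of=pd.Series(["t", "t"], index=values.columns),
        )
        expressed = pd.DataFrame({"t": [True, True]}, index=["A", "B"])
        paralogs = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"], "identity": [39.9]})
        out = ft.paralog_features(norm, paralogs, expressed)
        assert out.values.isna().all().all()

    def test_zero_denominator_uses_pseudocount(self):
        from tracegene.expression import NormalizedExpression

        values = pd.DataFrame(
            [[4.0, 6.0], [0.0, 0.0]], index=["A", "B"], columns=["s0", "s1"]
        )
        norm = NormalizedExpression(
            values=values,
            scaling_factors=pd.Series(1.0, index=values.columns),
            tissue_of=pd.Series(["t", "t"], index=values.columns),
        )
        expressed = pd.DataFrame({"t": [True, True]}, index=["A", "B"])
        paralogs = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"], "identity": [90.0]})
        out = ft.paralog_features(norm, paralogs, expressed)
        # denominator floored at 1 cpm -> ratios [4, 6] -> median 5
        assert out.values.loc["A", "paralog_best_ratio|t"] == pytest.approx(5.0)
        assert np.isfinite(out.values.loc["A", "paralog_best_ratio|t"])


class TestEmbedding:
    def test_column_count_is_64_per_interactome(self, small_features):
        table, _ = small_features
        emb_cols = [c for c in table.features if c.startswith("emb|")]
        labels = {c.split("|")[1] for c in emb_cols}
        assert len(emb_cols) == 64 * len(labels)

    def test_barbell_cliques_separate(self):
        from tracegene.embedding import embed_graph

        k = 8
        edges = []
        for i in range(k):
            for j in range(i + 1, k):
                edges.append((i, j))
                edges.append((k + i, k + j))
        edges.append((0, k))  # bridge
        vecs = embed_graph(2 * k, np.array(edges), dims=16, seed=3)
        vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        sim = vecs @ vecs.T
        within, cross = [], []
        for i in range(2 * k):
            for j in range(i + 1, 2 * k):
                (within if (i < k) == (j < k) else cross).append(sim[i, j])
        assert np.mean(within) > np.mean(cross)

    def test_fixed_seed_is_deterministic(self):
        from tracegene.embedding import embed_graph

        edges = np.array([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        a = embed_graph(4, edges, dims=8, seed=5)
        b = embed_graph(4, edges, dims=8, seed=5)
        assert np.array_equal(a, b)

    def test_empty_graph_errors(self):
        from tracegene.embedding import embed_graph

        with pytest.raises(ValueError, match="no edges"):
            embed_graph(3, np.empty((0, 2), dtype=int))


class TestAssembly:
    def test_closed_form_column_count_examples(self):
        assert ft.expected_feature_count(8, 8, 7, 5, 7) == 794
        assert ft.expected_feature_count(3, 3, 7, 5, 7) == 364

    @pytest.mark.parametrize(
        "n_t,n_eqtl,organs,tps,cv",
        [(4, 4, 3, 2, 3), (5, 2, 7, 5, 7), (3, 3, 1, 4, 1), (6, 6, 2, 2, 2), (8, 8, 7, 5, 7)],
    )
    def test_closed_form_formula(self, n_t, n_eqtl, organs, tps, cv):
        expect = n_t * 21 + n_eqtl + 64 * (n_t + 1) + organs * tps + cv
        assert ft.expected_feature_count(n_t, n_eqtl, organs, tps, cv) == expect

    def test_assembled_table_matches_formula(self, small_features, small_bundle):
        table, ctx = small_features
        n_t = len(small_bundle.config.tissues)
        expect = ft.expected_feature_count(
            n_t,
            small_bundle.eqtl_q.shape[1],
            small_bundle.config.n_dev_organs,
            small_bundle.config.n_dev_timepoints,
            small_bundle.config.n_dev_organs,
        )
        assert table.values.shape[1] == expect

    def test_duplicate_feature_ids_rejected(self):
        genes = pd.Index(["g0", "g1"])
        df = pd.DataFrame(np.zeros((2, 1)), index=genes, columns=["x"])
        frag = make_fragment(df, "eqtl", "t")
        with pytest.raises(ValueError, match="duplicate"):
            ft.assemble_feature_table([frag, frag])

    def test_gene_set_mismatch_rejected(self):
        a = make_fragment(
            pd.DataFrame(np.zeros((2, 1)), index=["g0", "g1"], columns=["x"]), "eqtl", "t"
        )
        b = make_fragment(
            pd.DataFrame(np.zeros((2, 1)), index=["g0", "g2"], columns=["y"]), "eqtl", "t"
        )
        with pytest.raises(ValueError, match="fragment 1"):
            ft.assemble_feature_table([a, b])

    def test_metadata_query_returns_family_block(self, small_features):
        table, _ = small_features
        sub = table.select(family="process_activity", tissue="skin")
        assert sub.values.shape[1] == 4

    def test_every_column_has_metadata(self, small_features):
        table, _ = small_features
        assert not table.meta["family"].isna().any()
        assert not table.meta["tissue_of_origin"].isna().any()

    def test_eqtl_features_validate_range(self):
        q = pd.DataFrame([[0.5, 1.5]], index=["g0"], columns=["t", "u"])
        with pytest.raises(ValueError, match="q-values"):
            ft.eqtl_features(q, pd.Index(["g0"]))

    def test_eqtl_missing_stays_missing(self):
        q = pd.DataFrame([[0.003, np.nan]], index=["g0"], columns=["liver", "skin"])
        out = ft.eqtl_features(q, pd.Index(["g0", "g1"]))
        assert out.values.loc["g0", "eqtl|liver"] == 0.003
        assert np.isnan(out.values.loc["g0", "eqtl|skin"])
        assert np.isnan(out.values.loc["g1", "eqtl|liver"])
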