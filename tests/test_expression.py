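"""Expression ingestion, normalization, QC ordination, and the TF filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import cagemara as cm


@pytest.fixture()
def design() -> cm.TimepointDesign:
    return cm.default_design(12, 3)


def write_expression(tmp_path, design, values, newline="\n"):
    cols = ["promoter_id"] + design.sample_ids
    lines = ["\t".join(cols)]
    for rid, row in values.items():
        lines.append("\t".join([rid] + [f"{v:g}" for v in row]))
    path = tmp_path / "expr.tsv"
    path.write_bytes(newline.join(lines).encode())
    return path


class TestReading:
    def test_two_promoter_fixture_shape(self, tmp_path, design):
        path = write_expression(
            tmp_path, design, {"p1": np.ones(36), "p2": np.arange(36.0)}
        )
        table = cm.read_expression_table(path, design)
        assert table.values.shape == (2, 36)

    def test_missing_sample_column_named(self, tmp_path, design):
        cols = ["promoter_id"] + design.sample_ids[:-1]  # drop P9_r3
        path = tmp_path / "expr.tsv"
        path.write_text("\t".join(cols) + "\n" + "\t".join(["p1"] + ["1"] * 35) + "\n")
        with pytest.raises(ValueError, match="missing sample column.*P9_r3"):
            cm.read_expression_table(path, design)

    def test_crlf_equals_lf(self, tmp_path, design):
        vals = {"p1": np.arange(36.0) + 1}
        lf = cm.read_expression_table(
            write_expression(tmp_path, design, vals, "\n"), design
        )
        crlf = cm.read_expression_table(
            write_expression(tmp_path, design, vals, "\r\n"), design
        )
        pd.testing.assert_frame_equal(lf.values, crlf.values)

    def test_duplicate_and_negative_rejected(self, design):
        df = pd.DataFrame(
            np.ones((2, 36)), index=["p1", "p1"], columns=design.sample_ids
        )
        with pytest.raises(ValueError, match="duplicate"):
            cm.ExpressionTable(df, pd.Series(["a", "b"], index=df.index), design)
        df2 = pd.DataFrame(
            -np.ones((1, 36)), index=["p1"], columns=design.sample_ids
        )
        with pytest.raises(ValueError, match="negative"):
            cm.ExpressionTable(df2, pd.Series(["a"], index=df2.index), design)


class TestNormalization:
    def test_tpm_columns_sum_to_a_million(self, design, rng):
        df = pd.DataFrame(
            rng.integers(0, 500, size=(30, 36)).astype(float),
            index=[f"p{i}" for i in range(30)],
            columns=design.sample_ids,
        )
        table = cm.ExpressionTable(df, pd.Series(df.index, index=df.index), design)
        normed = cm.tpm_normalize(table)
        np.testing.assert_allclose(normed.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_idempotent_on_tpm_input(self, design, rng):
        df = pd.DataFrame(
            rng.random((10, 36)), index=[f"p{i}" for i in range(10)],
            columns=design.sample_ids,
        )
        table = cm.tpm_normalize(
            cm.ExpressionTable(df, pd.Series(df.index, index=df.index), design)
        )
        again = cm.tpm_normalize(table)
        np.testing.assert_allclose(again.values.to_numpy(), table.values.to_numpy(),
                                   rtol=1e-6)

    def test_all_zero_column_rejected(self, design):
        df = pd.DataFrame(np.ones((3, 36)), index=list("abc"),
                          columns=design.sample_ids)
        df[design.sample_ids[0]] = 0.0
        table = cm.ExpressionTable(df, pd.Series(df.index, index=df.index), design)
        with pytest.raises(ValueError, match="all-zero"):
            cm.tpm_normalize(table)


class TestScores:
    def test_timepoint_means_and_max(self, design):
        df = pd.DataFrame(
            np.zeros((1, 36)), index=["p1"], columns=design.sample_ids
        )
        df.loc["p1", design.samples_for("E13")] = [2.0, 4.0, 6.0]
        table = cm.ExpressionTable(df, pd.Series(["g1"], index=["p1"]), design)
        means = cm.timepoint_means(table)
        assert means.loc["p1", "E13"] == pytest.approx(4.0)
        assert cm.max_mean_score(means).loc["p1"] == pytest.approx(4.0)

    def test_all_zero_gene_scores_zero(self, design):
        df = pd.DataFrame(np.zeros((1, 36)), index=["p1"], columns=design.sample_ids)
        table = cm.ExpressionTable(df, pd.Series(["g"], index=["p1"]), design)
        assert cm.max_mean_score(cm.timepoint_means(table)).loc["p1"] == 0.0

    def test_replicate_permutation_invariance(self, design, rng):
        vals = rng.random((5, 36))
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(5)],
                          columns=design.sample_ids)
        table = cm.ExpressionTable(df, pd.Series(df.index, index=df.index), design)
        base = cm.max_mean_score(cm.timepoint_means(table))
        # swap replicate columns within each timepoint
        permuted = df.copy()
        for tp in design.timepoints:
            s = design.samples_for(tp)
            permuted[s] = df[[s[2], s[0], s[1]]].to_numpy()
        table2 = cm.ExpressionTable(permuted, table.gene_symbols, design)
        pd.testing.assert_series_equal(
            base, cm.max_mean_score(cm.timepoint_means(table2))
        )


def make_annotations(symbols, known=(), ko=None, eur=None, allen=None):
    return pd.DataFrame(
        {
            "is_known_cerebellar": [s in known for s in symbols],
            "ko_status": [ko.get(s, "no_ko") if ko else "no_ko" for s in symbols],
            "eurexpress": [eur.get(s, False) if eur else False for s in symbols],
            "allen": [allen.get(s, True) if allen else True for s in symbols],
        },
        index=pd.Index(symbols, name="symbol"),
    )


class TestStageFilters:
    def test_known_tf_excluded_regardless_of_score(self):
        symbols = list("abcde")
        scores = pd.Series([100, 5, 4, 3, 2.0], index=symbols)
        ann = make_annotations(symbols, known={"a"})
        report = cm.rank_and_filter_stage1(scores, ann, top_n=5)
        assert "a" not in set(report["symbol"])

    def test_top_n_selection(self):
        scores = pd.Series({"a": 3.0, "b": 1.0, "c": 2.0})
        ann = make_annotations(["a", "b", "c"])
        report = cm.rank_and_filter_stage1(scores, ann, top_n=2)
        assert list(report["symbol"]) == ["a", "c"]

    def test_matches_brute_force_sort_and_slice(self, rng):
        symbols = [f"tf{i:02d}" for i in range(50)]
        scores = pd.Series(rng.integers(0, 20, size=50).astype(float), index=symbols)
        known = set(rng.choice(symbols, size=5, replace=False))
        ann = make_annotations(symbols, known=known)
        report = cm.rank_and_filter_stage1(scores, ann, top_n=10)
        # oracle: stable sort by (-score, symbol) of non-known TFs
        oracle = sorted(
            [s for s in symbols if s not in known],
            key=lambda s: (-scores[s], s),
        )[:10]
        assert list(report["symbol"]) == oracle

    def test_cerebellar_ko_also_excluded(self):
        symbols = ["a", "b"]
        scores = pd.Series([10.0, 1.0], index=symbols)
        ann = make_annotations(symbols, ko={"a": "cerebellar_ko"})
        report = cm.rank_and_filter_stage1(scores, ann, top_n=2)
        assert list(report["symbol"]) == ["b"]

    def test_stage2_keeps_evidence_and_preserves_order(self):
        symbols = list("abcd")
        scores = pd.Series([4.0, 3.0, 2.0, 1.0], index=symbols)
        ann = make_annotations(
            symbols, eur={"b": True}, allen={"a": True, "b": False, "c": False,
                                             "d": False}
        )
        r1 = cm.rank_and_filter_stage1(scores, ann, top_n=4)
        r2 = cm.evidence_filter_stage2(r1)
        assert list(r2["symbol"]) == ["a", "b"]
        assert list(r2["rank"]) == [1, 2]
        # all-false and all-true edge cases
        assert cm.evidence_filter_stage2(
            cm.rank_and_filter_stage1(
                scores, make_annotations(symbols, allen={s: False for s in symbols}),
                top_n=4)
        ).empty
        all_true = cm.rank_and_filter_stage1(
            scores, make_annotations(symbols), top_n=4
        )
        assert len(cm.evidence_filter_stage2(all_true)) == 4

    def test_stage2_subset_of_stage1(self, small_bundle):
        table = small_bundle.expression
        scores = cm.max_mean_score(cm.timepoint_means(table)).groupby(
            table.gene_symbols
        ).max()
        ann = small_bundle.annotations
        r1 = cm.rank_and_filter_stage1(scores.reindex(ann.index), ann, top_n=8)
        r2 = cm.evidence_filter_stage2(r1)
        assert set(r2["symbol"]) <= set(r1["symbol"])


class TestReferenceTable:
    def test_pipeline_reproduces_printed_order(self):
        df = cm.load_reference_candidate_table()
        ann = df.set_index("symbol")[
            ["is_known_cerebellar", "ko_status", "eurexpress", "allen"]
        ]
        scores = df.set_index("symbol")["max"].astype(float)
        report = cm.rank_and_filter_stage1(scores, ann, top_n=20)
        printed = list(df.loc[~df["is_known_cerebellar"], "symbol"])
        assert list(report["symbol"]) == printed
        assert report["max"].is_monotonic_decreasing


class TestOrdination:
    def _table(self, means, design):
        # expand timepoint means to identical replicates
        reps = np.repeat(means, design.n_replicates, axis=1)
        df = pd.DataFrame(reps, index=[f"p{i}" for i in range(means.shape[0])],
                          columns=design.sample_ids)
        return cm.ExpressionTable(df, pd.Series(df.index, index=df.index), design)

    def test_identical_timepoints_merge_first_at_zero(self, design, rng):
        means = rng.random((40, 12)) * 100
        means[:, 1] = means[:, 0]  # E12 duplicates E11
        table = self._table(means, design)
        newick, _ = cm.qc_ordination(table)
        assert "E11" in newick and "E12" in newick
        # the two identical timepoints form a cherry at distance 0
        import io
        from skbio import TreeNode
        tree = TreeNode.read(io.StringIO(newick))
        tip = tree.find("E11")
        sibs = {t.name for t in tip.parent.tips()}
        assert sibs == {"E11", "E12"}
        assert tip.length == pytest.approx(0.0, abs=1e-12)

    def test_monotone_trajectory_has_monotone_pc1(self, design, rng):
        t = np.arange(12.0)
        slopes = rng.normal(size=60)[:, None]
        means = 100 + slopes * t[None, :] * 10 + rng.normal(scale=0.01, size=(60, 12))
        means = np.clip(means, 0, None)
        table = self._table(means, design)
        _, pca = cm.qc_ordination(table)
        rho = abs(spearmanr(pca["PC1"].to_numpy(), t).statistic)
        assert rho == pytest.approx(1.0)
        ev = pca.attrs["explained_variance_ratio"]
        assert 0 < sum(ev) <= 1 + 1e-9

    def test_constant_matrix_is_error(self, design):
        means = np.full((10, 12), 7.0)
        with pytest.raises(ValueError, match="constant"):
            cm.qc_ordination(self._table(means, design))
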