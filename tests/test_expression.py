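"""Fold changes, Pearson co-expression, and correlation clustering."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famnet.expression import (
    ExpressionMatrix,
    correlation_matrix,
    fold_changes,
    pearson,
    read_expression,
    read_series_matrix,
    weight_edges,
)
from famnet.synthetic import SyntheticConfig, generate_expression


def make_matrix(values: dict[str, list[float]], groups: dict[str, str]) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.columns = list(groups)
    return ExpressionMatrix(values=df, groups=groups)


TWO_GROUPS = {"s1": "normal", "s2": "normal", "s3": "tumor", "s4": "tumor"}


class TestReadExpression:
    def test_toy_tsv_verbatim(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\ts2\ts3\nG1\t1\t2\t3\nG2\t4\t5\t6\n")
        (tmp_path / "g.tsv").write_text("s1\ta\ns2\ta\ns3\tb\n")
        m = read_expression(tmp_path / "m.tsv", tmp_path / "g.tsv")
        assert m.values.to_numpy().tolist() == [[1, 2, 3], [4, 5, 6]]
        assert m.groups == {"s1": "a", "s2": "a", "s3": "b"}

    def test_duplicate_gene_rows_collapse_by_mean(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\nG1\t5.0\nG1\t7.0\n")
        (tmp_path / "g.tsv").write_text("s1\ta\n")
        m = read_expression(tmp_path / "m.tsv", tmp_path / "g.tsv")
        assert m.values.loc["G1", "s1"] == 6.0

    def test_sample_without_group_is_an_error(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\ts2\nG1\t1\t2\n")
        (tmp_path / "g.tsv").write_text("s1\ta\n")
        with pytest.raises(ValueError, match="s2"):
            read_expression(tmp_path / "m.tsv", tmp_path / "g.tsv")

    def test_non_numeric_cell_named_in_error(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\nG1\toops\n")
        (tmp_path / "g.tsv").write_text("s1\ta\n")
        with pytest.raises(ValueError, match="G1"):
            read_expression(tmp_path / "m.tsv", tmp_path / "g.tsv")


class TestFoldChanges:
    def test_two_log2_units_is_fourfold_up(self):
        m = make_matrix({"G1": [5.0, 5.0, 7.0, 7.0]}, TWO_GROUPS)
        (fc,) = fold_changes(m, "tumor", "normal")
        assert fc.fold == pytest.approx(4.0)
        assert fc.direction == "up"
        assert fc.signed_fold == pytest.approx(4.0)

    def test_equal_means_is_fold_one(self):
        m = make_matrix({"G1": [5.0, 5.0, 5.0, 5.0]}, TWO_GROUPS)
        (fc,) = fold_changes(m, "tumor", "normal")
        assert fc.fold == 1.0
        assert fc.log2fc == 0.0

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        m = make_matrix(
            {f"G{i}": list(rng.normal(8, 1, 4)) for i in range(5)}, TWO_GROUPS
        )
        fwd = {f.gene: f.log2fc for f in fold_changes(m, "tumor", "normal")}
        rev = {f.gene: f.log2fc for f in fold_changes(m, "normal", "tumor")}
        for g in fwd:
            assert fwd[g] == -rev[g]

    def test_missing_group_is_an_error(self):
        m = make_matrix({"G1": [1.0, 2.0, 3.0, 4.0]}, TWO_GROUPS)
        with pytest.raises(ValueError):
            fold_changes(m, "nonexistent", "normal")

    def test_planted_fold_recovered_at_vanishing_noise(self):
        cfg = SyntheticConfig(
            seed=9,
            noise_sd=1e-12,
            planted_fold_changes={"FAM001": ("EAC", 4.23, "up")},
        )
        df, groups = generate_expression(cfg, ["FAM001", "FAM002"])
        m = ExpressionMatrix(df, groups)
        fc = {f.gene: f for f in fold_changes(m, "EAC", "normal")}
        assert fc["FAM001"].fold == pytest.approx(4.23, abs=1e-6)
        assert fc["FAM002"].fold == pytest.approx(1.0, abs=1e-6)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert pearson([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_hand_computed_r_and_t_transform_p(self):
        r, p, n = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        t = 0.8 * math.sqrt((n - 2) / (1 - 0.8**2))
        assert p == pytest.approx(2 * stats.t.sf(t, n - 2), rel=1e-9)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r_xy = pearson(x, y)[0]
        assert pearson(y, x)[0] == pytest.approx(r_xy, abs=1e-12)
        assert pearson(3.5 * x - 2, 0.1 * y + 7)[0] == pytest.approx(r_xy, abs=1e-12)


class TestWeightEdges:
    def test_identical_profiles_weight_one(self):
        m = make_matrix(
            {"A": [1.0, 2.0, 3.0, 4.0], "B": [1.0, 2.0, 3.0, 4.0]}, TWO_GROUPS
        )
        g = weight_edges(nx.Graph([("A", "B")]), m)
        assert g.edges["A", "B"]["correlation_all"] == pytest.approx(1.0)

    def test_absent_endpoint_flagged_and_edge_retained(self):
        m = make_matrix({"A": [1.0, 2.0, 3.0, 4.0]}, TWO_GROUPS)
        g = weight_edges(nx.Graph([("A", "MISSING")]), m)
        assert g.has_edge("A", "MISSING")
        assert g.edges["A", "MISSING"]["correlation_missing"] is True

    def test_fold_attributes_attached_per_comparison(self):
        m = make_matrix(
            {"A": [5.0, 5.0, 7.0, 7.0], "B": [5.0, 5.0, 4.0, 4.0]}, TWO_GROUPS
        )
        g = weight_edges(
            nx.Graph([("A", "B")]),
            m,
            tumor_groups=("tumor",),
            reference_group="normal",
        )
        assert g.nodes["A"]["fold_tumor"] == pytest.approx(4.0)
        assert g.nodes["B"]["fold_tumor"] == pytest.approx(-2.0)

    def test_planted_block_correlation_recovered_on_edges(self):
        cfg = SyntheticConfig(
            seed=10,
            groups=(("g", 200),),
            correlated_blocks=((("FAM001", "FAM002", "FAM003"), 0.9),),
        )
        genes = ["FAM001", "FAM002", "FAM003"]
        df, groups = generate_expression(cfg, genes)
        m = ExpressionMatrix(df, groups)
        g = weight_edges(
            nx.Graph([("FAM001", "FAM002"), ("FAM002", "FAM003")]), m, group="g"
        )
        rs = [abs(d["correlation_g"]) for _, _, d in g.edges(data=True)]
        assert abs(np.mean(rs) - 0.9) < 0.1


class TestCorrelationMatrix:
    def test_equals_pairwise_pearson_oracle_exactly(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(8)]
        m = make_matrix({g: list(rng.normal(size=4)) for g in genes}, TWO_GROUPS)
        ana = correlation_matrix(m, genes, r_threshold=0.99)
        for i, gi in enumerate(genes):
            for gj in genes[i + 1 :]:
                r = pearson(m.values.loc[gi], m.values.loc[gj])[0]
                assert ana.matrix.loc[gi, gj] == r
                assert ana.matrix.loc[gj, gi] == r
        assert (np.diag(ana.matrix.to_numpy()) == 1.0).all()

    def test_identical_genes_flagged_significant(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        groups = {f"s{i}": "a" for i in range(6)}
        m = make_matrix({"G1": base, "G2": base}, groups)
        ana = correlation_matrix(m, ["G1", "G2"])
        assert ana.matrix.to_numpy() == pytest.approx(np.ones((2, 2)))
        assert len(ana.significant_pairs()) == 1

    def test_null_flags_are_controlled_after_adjustment(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(12)]
        groups = {f"s{i}": "a" for i in range(100)}
        m = make_matrix({g: list(rng.normal(size=100)) for g in genes}, groups)
        ana = correlation_matrix(m, genes, r_threshold=0.0, alpha=0.05)
        raw = (ana.pairs["p"] < 0.05).mean()
        assert raw < 0.2  # ~alpha on average under the null
        assert len(ana.significant_pairs()) <= (ana.pairs["p"] < 0.05).sum()

    def test_planted_two_block_structure_recovered_at_k2(self):
        cfg = SyntheticConfig(
            seed=12,
            groups=(("g", 120),),
            correlated_blocks=(
                (("FAM001", "FAM002", "FAM003"), 0.9),
                (("FAM004", "FAM005", "FAM006"), 0.9),
            ),
        )
        genes = [f"FAM{i:03d}" for i in range(1, 7)]
        df, groups = generate_expression(cfg, genes)
        m = ExpressionMatrix(df, groups)
        ana = correlation_matrix(m, genes)
        from scipy.cluster.hierarchy import fcluster

        flat = fcluster(ana.linkage, t=2, criterion="maxclust")
        blocks = {}
        for g, c in zip(genes, flat):
            blocks.setdefault(c, set()).add(g)
        assert set(map(frozenset, blocks.values())) == {
            frozenset(genes[:3]),
            frozenset(genes[3:]),
        }


class TestSeriesMatrix:
    def test_parse_and_group_extraction(self, tmp_path):
        text = (
            '!Series_title\t"synthetic stand-in"\n'
            '!Sample_geo_accession\t"GSM1"\t"GSM2"\t"GSM3"\n'
            '!Sample_characteristics_ch1\t"normal"\t"normal"\t"tumor"\n'
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\t"GSM3"\n'
            '"P1"\t5.0\t5.2\t7.1\n'
            '"P2"\t6.0\t6.1\t6.2\n'
            "!series_matrix_table_end\n"
        )
        p = tmp_path / "series.txt"
        p.write_text(text)
        m = read_series_matrix(p)
        assert m.values.shape == (2, 3)
        assert m.groups == {"GSM1": "normal", "GSM2": "normal", "GSM3": "tumor"}

    def test_probe_to_gene_collapse(self, tmp_path):
        text = (
            '!Sample_characteristics_ch1\t"a"\n'
            "!series_matrix_table_begin\n"
            "ID_REF\tGSM1\nP1\t5.0\nP2\t7.0\n"
            "!series_matrix_table_end\n"
        )
        p = tmp_path / "series.txt"
        p.write_text(text)
        m = read_series_matrix(p, gene_map={"P1": "G", "P2": "G"})
        assert m.values.loc["G", "GSM1"] == 6.0
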