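import numpy as np
import pandas as pd
import pytest

from molpatch.proteome import (
    ProteinAnnotation,
    curate,
    decile_bins,
    gene_max_expression,
    rank_for_gsea,
    tash,
    tash_all_tissues,
    write_rnk,
)


def ann(gene, length=300, disorder=0.1, thsa=100.0):
    return ProteinAnnotation(
        gene_id=gene, length=length, disorder_fraction=disorder, thsa=thsa
    )


def expr_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "nx"])


class TestCurate:
    def test_length_boundary(self):
        kept = curate([ann("g1", length=800), ann("g2", length=801)])
        assert [a.gene_id for a in kept] == ["g1"]

    def test_disorder_boundary(self):
        kept = curate([ann("g1", disorder=0.5), ann("g2", disorder=0.6)])
        assert [a.gene_id for a in kept] == ["g1"]

    def test_duplicate_gene_keeps_max_thsa(self):
        kept = curate([ann("g1", thsa=100.0), ann("g1", thsa=200.0)])
        assert len(kept) == 1
        assert kept[0].thsa == 200.0

    def test_duplicate_tie_keeps_first(self):
        first = ann("g1", thsa=100.0, length=100)
        second = ann("g1", thsa=100.0, length=200)
        kept = curate([first, second])
        assert kept[0].length == 100

    def test_six_row_toy_table_leaves_three_survivors(self):
        rows = [
            ann("g1", length=400, disorder=0.1, thsa=100.0),   # kept
            ann("g2", length=801, disorder=0.1, thsa=100.0),   # too long
            ann("g3", length=400, disorder=0.7, thsa=100.0),   # too disordered
            ann("g4", length=400, disorder=0.1, thsa=150.0),   # kept (max THSA of g4)
            ann("g4", length=300, disorder=0.1, thsa=120.0),   # duplicate, lower THSA
            ann("g5", length=500, disorder=0.2, thsa=90.0),    # kept
        ]
        kept = curate(rows)
        assert [a.gene_id for a in kept] == ["g1", "g4", "g5"]
        assert kept[1].thsa == 150.0

    def test_idempotent(self):
        rows = [ann("g1"), ann("g1", thsa=200.0), ann("g2", length=900), ann("g3")]
        once = curate(rows)
        assert curate(once) == once

    def test_invalid_disorder_fraction_rejected(self):
        with pytest.raises(ValueError):
            ann("g1", disorder=1.5)


class TestExpression:
    def test_max_over_tissues(self):
        expr = expr_frame([("g1", "a", 1.0), ("g1", "b", 5.0), ("g1", "c", 3.0)])
        assert gene_max_expression(expr)["g1"] == 5.0

    def test_median_variant(self):
        expr = expr_frame([("g1", "a", 1.0), ("g1", "b", 5.0), ("g1", "c", 3.0)])
        assert gene_max_expression(expr, how="median")["g1"] == 3.0

    def test_single_tissue_gene(self):
        expr = expr_frame([("g1", "a", 2.0)])
        assert gene_max_expression(expr)["g1"] == 2.0


class TestDeciles:
    def test_twenty_genes_give_ten_bins_of_two(self):
        values = {f"g{i:02d}": float(i) for i in range(20)}
        bins = decile_bins(values)
        assert sorted(bins.value_counts()) == [2] * 10
        assert bins["g00"] == 1 and bins["g19"] == 10

    def test_ten_genes_ordered_by_value(self):
        values = {f"g{i}": float(9 - i) for i in range(10)}
        bins = decile_bins(values)
        assert bins["g9"] == 1  # lowest value -> decile 1
        assert bins["g0"] == 10

    def test_ties_balanced_by_stable_order(self):
        values = {f"g{i:02d}": 1.0 for i in range(25)}
        bins = decile_bins(values)
        counts = sorted(bins.value_counts())
        assert max(counts) - min(counts) <= 1
        assert bins["g00"] == 1  # stable: earliest gene in lowest bin

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            decile_bins({f"g{i}": float(i) for i in range(9)})


class TestTash:
    def test_hand_check(self):
        expr = expr_frame([("g1", "brain", 2.0), ("g2", "brain", 1.0)])
        h = {"g1": 300.0, "g2": 600.0}
        assert tash(expr, h, "brain") == pytest.approx(400.0)

    def test_single_gene_weights_cancel(self):
        expr = expr_frame([("g1", "liver", 7.3)])
        assert tash(expr, {"g1": 123.0}, "liver") == pytest.approx(123.0)

    def test_constant_h_returns_constant(self):
        expr = expr_frame([("g1", "t", 2.0), ("g2", "t", 9.0), ("g3", "t", 0.5)])
        h = {g: 42.0 for g in ("g1", "g2", "g3")}
        assert tash(expr, h, "t") == pytest.approx(42.0)

    def test_bounded_by_h_range(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        expr = expr_frame([(g, "t", float(rng.uniform(0.1, 10))) for g in genes])
        h = {g: float(rng.uniform(100, 900)) for g in genes}
        val = tash(expr, h, "t")
        assert min(h.values()) <= val <= max(h.values())

    def test_exclusion_and_missing_h_dropped(self):
        expr = expr_frame([("g1", "t", 2.0), ("g2", "t", 1.0), ("g3", "t", 5.0)])
        h = {"g1": 300.0, "g2": 600.0}  # g3 has no value -> dropped
        assert tash(expr, h, "t") == pytest.approx(400.0)
        assert tash(expr, h, "t", exclude={"g2"}) == pytest.approx(300.0)

    def test_errors(self):
        expr = expr_frame([("g1", "t", 0.0)])
        with pytest.raises(ValueError):
            tash(expr, {"g1": 1.0}, "missing_tissue")
        with pytest.raises(ValueError):
            tash(expr, {"g1": 1.0}, "t")  # zero total expression

    def test_all_tissues_sorted_descending(self):
        expr = expr_frame(
            [("g1", "a", 1.0), ("g2", "a", 1.0), ("g1", "b", 1.0), ("g2", "b", 3.0)]
        )
        h = {"g1": 100.0, "g2": 500.0}
        out = tash_all_tissues(expr, h)
        assert list(out.index) == ["b", "a"]
        assert (out.diff().dropna() <= 0).all()


class TestRankForGsea:
    def test_explicit_center_and_scale(self):
        scores = rank_for_gsea({"a": 1.0, "b": 2.0, "c": 3.0}, center=2.0, scale=1.0)
        assert list(scores.index) == ["c", "b", "a"]
        assert list(scores) == [1.0, 0.0, -1.0]

    def test_ranking_invariant_under_affine_transform(self):
        values = {"a": 3.0, "b": 1.0, "c": 7.0, "d": 4.0}
        transformed = {g: 2.5 * v + 11.0 for g, v in values.items()}
        assert list(rank_for_gsea(values).index) == list(rank_for_gsea(transformed).index)

    def test_median_center_puts_half_at_or_below_zero(self):
        rng = np.random.default_rng(1)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.lognormal(8, 0.5, 101))}
        scores = rank_for_gsea(values)
        assert (scores <= 0).sum() >= len(scores) // 2

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            rank_for_gsea({"a": 1.0, "b": 1.0})

    def test_rnk_file_two_columns(self, tmp_path):
        scores = rank_for_gsea({"a": 1.0, "b": 2.0, "c": 3.0})
        path = tmp_path / "out.rnk"
        write_rnk(scores, path)
        lines = [l.split("\t") for l in path.read_text().strip().splitlines()]
        assert all(len(l) == 2 for l in lines)
        assert lines[0][0] == "c"
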