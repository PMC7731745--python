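"""DEG calling, co-different genes, category comparisons, ORA, ddCt."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import comb

import methylpair as mp
from methylpair.integration import deg_table


class TestCallDegs:
    def _table(self, fc, fdr):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(fc))],
                             "fc": fc, "fdr": fdr})

    @pytest.mark.parametrize("fc, fdr, direction", [
        (2.5, 0.01, "up"),
        (2.0, 0.001, None),   # strictly greater than 2 required
        (0.4, 0.04, "down"),
        (0.5, 0.01, None),    # strictly less than 0.5 required
        (3.0, 0.05, None),    # FDR strictly below 0.05
    ])
    def test_thresholds(self, fc, fdr, direction):
        degs = mp.call_degs(self._table([fc], [fdr]))
        if direction is None:
            assert degs.empty
        else:
            assert degs["direction"].iloc[0] == direction

    def test_missing_fdr_excluded(self):
        degs = mp.call_degs(self._table([3.0, 3.0], [0.01, np.nan]))
        assert list(degs["gene_id"]) == ["g0"]

    def test_replicates_recover_planted_degs(self):
        """Welch-on-log2 + BH recovers |log2FC| = 2 planted genes from 3 vs 3
        replicates at sd 0.25 with high sensitivity and controlled FDR."""
        sens, fdr = [], []
        for seed in range(20):
            cfg = mp.SimConfig(seed=seed)
            models = mp.generate_gene_models(cfg)
            expr, truth = mp.simulate_expression(models, cfg)
            degs = mp.call_degs(expr)
            planted = {g for g, _ in truth}
            called = set(degs["gene_id"])
            sens.append(len(called & planted) / len(planted))
            fdr.append(len(called - planted) / max(len(called), 1))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdr) <= 0.10

    def test_planted_direction_matches_sign(self):
        cfg = mp.SimConfig(seed=3)
        models = mp.generate_gene_models(cfg)
        expr, truth = mp.simulate_expression(models, cfg)
        degs = mp.call_degs(expr).set_index("gene_id")
        for gene, lfc in truth:
            if gene in degs.index:
                want = "up" if lfc > 0 else "down"
                assert degs.loc[gene, "direction"] == want


class TestCoDifferent:
    def _links(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g1", "g2", "g3", "g4", None, "g5", "g6"],
            "direction": ["hyper", "hypo", "hypo", "hyper", "hypo",
                          "hyper", "hyper", "hypo"],
            "delta": [0.10, -0.30, -0.2, 0.4, -0.1, 0.2, 0.5, -0.4],
            "category": ["first_exon", "other_intron", "promoter_p1",
                         "distal_intergenic", "utr5", "first_exon",
                         "other_exon", "first_intron"],
        })

    def _degs(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2", "g4", "g9"],
            "fc": [3.0, 0.3, 4.0, 5.0],
            "fdr": [0.01] * 4,
            "direction": ["up", "down", "up", "up"],
        })

    def test_manual_tally(self):
        res = mp.co_different(self._degs(), self._links())
        # co-different = DEG set intersected with DMR-linked genes
        assert set(res.genes["gene_id"]) == {"g1", "g2", "g4"}
        by = res.genes.set_index("gene_id")
        # g1 links hyper(0.10) and hypo(-0.30): larger |delta| wins
        assert by.loc["g1", "meth_direction"] == "hypo"
        assert by.loc["g1", "quadrant"] == "hypo-up"
        assert by.loc["g2", "quadrant"] == "hypo-down"
        assert res.quadrant_counts == {
            "hyper-up": 0, "hypo-up": 2, "hyper-down": 0, "hypo-down": 1}
        # DMR-level tally keeps every link
        assert res.dmr_quadrant_counts == {
            "hyper-up": 1, "hypo-up": 2, "hyper-down": 0, "hypo-down": 1}

    def test_deg_without_link_excluded(self):
        res = mp.co_different(self._degs(), self._links())
        assert "g9" not in set(res.genes["gene_id"])

    def test_quadrant_counts_sum_to_links(self):
        res = mp.co_different(self._degs(), self._links())
        links = self._links().dropna(subset=["gene_id"])
        deg_genes = set(self._degs()["gene_id"])
        n_overlap_links = int(links["gene_id"].isin(deg_genes).sum())
        assert sum(res.dmr_quadrant_counts.values()) == n_overlap_links
        assert sum(res.quadrant_counts.values()) == len(res.genes)


class TestFoldChangeByCategory:
    def _expr(self, gene_fc):
        return pd.DataFrame({
            "gene_id": list(gene_fc), "fc": [2.0 ** v for v in gene_fc.values()],
            "fdr": [0.01] * len(gene_fc),
        })

    def test_identical_arms_give_p_one(self):
        fcs = {"a": 1.0, "b": 2.0, "c": 1.5, "d": 1.0, "e": 2.0, "f": 1.5}
        links = pd.DataFrame({
            "gene_id": list(fcs),
            "direction": ["hyper"] * 3 + ["hypo"] * 3,
            "category": ["first_exon"] * 6,
            "delta": [0.1] * 3 + [-0.1] * 3,
        })
        out = mp.fold_change_by_category(links, self._expr(fcs))
        row = out.iloc[0]
        assert row["p_value"] == pytest.approx(1.0)
        assert row["median_log2fc_hyper"] == row["median_log2fc_hypo"]

    def test_exact_rank_sum_worked_example(self):
        # hyper log2FCs (-2, -1, -1.5) vs hypo (2, 1, 1.5): complete
        # separation of ranks, exact two-sided p = 2/C(6,3) = 0.1
        fcs = {"a": -2.0, "b": -1.0, "c": -1.5, "d": 2.0, "e": 1.0, "f": 1.5}
        links = pd.DataFrame({
            "gene_id": list(fcs),
            "direction": ["hyper"] * 3 + ["hypo"] * 3,
            "category": ["promoter_p1"] * 6,
            "delta": [0.1] * 3 + [-0.1] * 3,
        })
        out = mp.fold_change_by_category(links, self._expr(fcs))
        row = out.iloc[0]
        assert row["p_value"] == pytest.approx(0.1)
        assert row["median_log2fc_hypo"] > row["median_log2fc_hyper"]

    def test_underpowered_category_flagged(self):
        fcs = {"a": 1.0, "d": 2.0, "e": 1.0, "f": 1.5}
        links = pd.DataFrame({
            "gene_id": list(fcs),
            "direction": ["hyper"] + ["hypo"] * 3,
            "category": ["utr5"] * 4,
            "delta": [0.1, -0.1, -0.1, -0.1],
        })
        out = mp.fold_change_by_category(links, self._expr(fcs))
        assert not out.iloc[0]["testable"]
        assert np.isnan(out.iloc[0]["p_value"])


class TestTfSubset:
    def _expr(self):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)],
                             "fc": [1.0] * 10, "fdr": [0.5] * 10})

    def test_manual_intersection(self):
        degs = pd.DataFrame({"gene_id": ["g1", "g5"], "fc": [3.0, 0.2],
                             "fdr": [0.01, 0.01], "direction": ["up", "down"]})
        expressed, de_tfs = mp.tf_subset(self._expr(),
                                         ["g1", "g2", "g5", "nope"], degs)
        assert set(expressed["gene_id"]) == {"g1", "g2", "g5"}
        assert set(de_tfs["gene_id"]) == {"g1", "g5"}
        assert set(de_tfs["direction"]) == {"up", "down"}

    def test_disjoint_tf_list_empty(self):
        expressed, de_tfs = mp.tf_subset(self._expr(), ["x", "y"],
                                         self._expr().head(0))
        assert expressed.empty and de_tfs.empty

    def test_all_genes_are_tfs(self):
        expr = self._expr()
        expressed, _ = mp.tf_subset(expr, list(expr["gene_id"]), expr.head(0))
        assert expressed.equals(expr)


def hypergeom_upper_tail(n_universe, n_query, n_set, overlap):
    """Exact enumeration oracle: P(X >= overlap)."""
    total = comb(n_universe, n_query, exact=True)
    acc = 0
    for k in range(overlap, min(n_set, n_query) + 1):
        acc += comb(n_set, k, exact=True) * \
            comb(n_universe - n_set, n_query - k, exact=True)
    return acc / total


class TestOra:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(20)}
        pathway = {"g0", "g1", "g2", "g3"}
        query = {"g0", "g1", "g2", "g10", "g11"}
        out = mp.ora_enrichment(query, {"pw": pathway}, universe)
        assert out["overlap"].iloc[0] == 3
        # exact enumeration: [C(4,3)C(16,2) + C(4,4)C(16,1)] / C(20,5)
        expected = hypergeom_upper_tail(20, 5, 4, 3)
        assert expected == pytest.approx(496 / 15504, rel=1e-12)
        assert out["p_value"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        out = mp.ora_enrichment({"g0"}, {"pw": {"g5", "g6"}}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_pathway_outside_universe_skipped(self):
        out = mp.ora_enrichment({"g0"}, {"pw": {"zz"}}, {"g0", "g1"})
        assert out.empty

    def test_query_not_subset_raises(self):
        with pytest.raises(ValueError, match="stranger"):
            mp.ora_enrichment({"stranger"}, {"pw": {"g1"}}, {"g1"})

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = int(rng.integers(5, 26))
            universe = [f"g{i}" for i in range(m)]
            query = set(rng.choice(universe, int(rng.integers(1, m)), replace=False))
            pw = set(rng.choice(universe, int(rng.integers(1, m)), replace=False))
            out = mp.ora_enrichment(query, {"pw": pw}, set(universe))
            expected = hypergeom_upper_tail(m, len(query), len(pw),
                                            out["overlap"].iloc[0])
            assert out["p_value"].iloc[0] == pytest.approx(expected, rel=1e-9)


class TestDdct:
    @pytest.mark.parametrize("args, expected", [
        ((25, 20, 24, 20), 0.5),   # ddCt = +1 halves expression
        ((24, 20, 24, 20), 1.0),   # ddCt = 0
        ((23, 20, 24, 20), 2.0),   # ddCt = -1 doubles
    ])
    def test_worked_examples(self, args, expected):
        assert mp.ddct(*args) == pytest.approx(expected)

    @given(st.floats(1, 40), st.floats(1, 40))
    def test_identity_property(self, x, y):
        assert mp.ddct(x, x, y, y) == pytest.approx(1.0)


def test_deg_table_from_replicates_matches_group_mean_ratio():
    expr = pd.DataFrame({
        "gene_id": ["g1"],
        "adipogenic_rep1": [10.0], "adipogenic_rep2": [12.0],
        "adipogenic_rep3": [11.0],
        "myogenic_rep1": [40.0], "myogenic_rep2": [44.0],
        "myogenic_rep3": [48.0],
    })
    table = deg_table(expr)
    assert table["fc"].iloc[0] == pytest.approx(44 / 11)
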