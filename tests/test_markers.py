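import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import nescore as ns
from nescore.markers import _adjust_p, wilcoxon_de

from .oracles import exact_wilcoxon_oracle


def counts_matrix(data, genes, cells):
    return ns.ExpressionMatrix(
        pd.DataFrame(data, index=genes, columns=cells, dtype=float), "counts"
    )


@pytest.fixture
def qc_fixture():
    """5 cells, 2 planted violators: c4 low-genes+low-counts, c5 high-mito.

    300 genes; good cells express every gene at 2+ counts (600 transcripts,
    300 detected genes, mito ~0.7%).
    """
    genes = ["MT-1", "MT-2"] + [f"g{i}" for i in range(298)]
    good = np.full(300, 2.0)
    low = np.zeros(300)
    low[2:102] = 1.0  # 100 genes detected, 100 transcripts
    mito = good.copy()
    mito[:2] = 200.0  # 400 mito of ~996 transcripts
    data = np.column_stack([good, good, good, low, mito])
    return counts_matrix(data, genes, ["c1", "c2", "c3", "c4", "c5"])


class TestQCFilter:
    def test_planted_violators_removed_exactly(self, qc_fixture):
        kept, report = ns.qc_filter_cells(qc_fixture)
        assert kept.columns == ["c1", "c2", "c3"]
        assert report.removed_ids == ["c4", "c5"]
        assert report.n_removed == 2
        # c4 fails both the gene and the transcript criteria, counted in each
        assert report.removed_low_genes == 1
        assert report.removed_low_counts == 1
        assert report.removed_high_mito == 1

    def test_boundary_cell_is_retained(self):
        # exactly 250 genes, 500 transcripts, 20.0% mito: all retained
        genes = ["MT-1"] + [f"g{i}" for i in range(249)]
        # 250 genes, exactly 500 transcripts, exactly 20.0% mito
        col = np.concatenate([[100.0], np.full(248, 1.0), [152.0]])
        m = counts_matrix(col[:, None], genes, ["c1"])
        kept, report = ns.qc_filter_cells(m)
        assert kept.columns == ["c1"] and report.n_removed == 0

    def test_249_genes_removed(self):
        genes = [f"g{i}" for i in range(300)]
        col = np.zeros(300)
        col[:249] = 10.0  # 249 genes, plenty of counts
        m = counts_matrix(np.column_stack([col, np.full(300, 10.0)]), genes, ["bad", "ok"])
        kept, _ = ns.qc_filter_cells(m)
        assert kept.columns == ["ok"]

    def test_idempotent(self, qc_fixture):
        once, _ = ns.qc_filter_cells(qc_fixture)
        twice, report = ns.qc_filter_cells(once)
        assert twice.columns == once.columns and report.n_removed == 0

    def test_all_removed_errors(self):
        m = counts_matrix(np.ones((10, 2)), [f"g{i}" for i in range(10)], ["a", "b"])
        with pytest.raises(ns.ValidationError, match="no cell"):
            ns.qc_filter_cells(m)

    def test_simulated_planted_violators(self, atlas):
        counts, ann, _ = atlas
        kept, report = ns.qc_filter_cells(counts)
        planted = set(ann.table.index[ann.table["qc_fail"] != ""])
        assert set(report.removed_ids) == planted


class TestFilterGenes:
    def test_excluded_gene_absent(self):
        m = counts_matrix(np.ones((3, 4)), ["a", "b", "c"], list("wxyz"))
        out = ns.filter_genes(m, exclude_lists=[["b"]], min_cells_fraction=0)
        assert out.genes == ["a", "c"]

    def test_undetected_gene_removed(self):
        data = np.ones((3, 4))
        data[1] = 0.0
        m = counts_matrix(data, ["a", "b", "c"], list("wxyz"))
        out = ns.filter_genes(m, min_cells_fraction=0.001)
        assert out.genes == ["a", "c"]

    def test_no_op_configuration_is_identity(self):
        m = counts_matrix(np.zeros((2, 3)), ["a", "b"], list("xyz"))
        out = ns.filter_genes(m, exclude_lists=[], min_cells_fraction=0)
        assert out.genes == ["a", "b"]


class TestPseudobulk:
    def _ann(self, mapping):
        return ns.Annotation(pd.DataFrame({"sample_id": mapping}))

    def test_two_cells_sum(self):
        m = counts_matrix([[1.0, 2.0]], ["g"], ["c1", "c2"])
        pb = ns.pseudobulk_aggregate(m, self._ann({"c1": "s", "c2": "s"}))
        assert pb.values.loc["g", "s"] == 3.0

    def test_singleton_groups_identity(self):
        m = counts_matrix([[1.0, 2.0], [3.0, 4.0]], ["g1", "g2"], ["c1", "c2"])
        pb = ns.pseudobulk_aggregate(m, self._ann({"c1": "a", "c2": "b"}))
        np.testing.assert_array_equal(pb.values.to_numpy(), m.values.to_numpy())

    def test_matches_group_sum_oracle_and_conserves_totals(self, rng):
        cells = [f"c{i}" for i in range(100)]
        groups = {c: f"s{rng.integers(4)}" for c in cells}
        data = rng.poisson(3, (20, 100)).astype(float)
        m = counts_matrix(data, [f"g{i}" for i in range(20)], cells)
        pb = ns.pseudobulk_aggregate(m, self._ann(groups))
        for s in pb.columns:  # brute-force per-group summation
            members = [i for i, c in enumerate(cells) if groups[c] == s]
            np.testing.assert_array_equal(
                pb.values[s].to_numpy(), data[:, members].sum(axis=1)
            )
        assert pb.values.to_numpy().sum() == data.sum()

    def test_first_appearance_column_order(self):
        m = counts_matrix(np.ones((1, 3)), ["g"], ["c1", "c2", "c3"])
        pb = ns.pseudobulk_aggregate(m, self._ann({"c1": "b", "c2": "a", "c3": "b"}))
        assert pb.columns == ["b", "a"]

    def test_unannotated_cell_errors(self):
        m = counts_matrix(np.ones((1, 2)), ["g"], ["c1", "c2"])
        ann = ns.Annotation(pd.DataFrame({"sample_id": {"c1": "s"}}))
        with pytest.raises(ns.ValidationError, match="c2"):
            ns.pseudobulk_aggregate(m, ann)


def de_input(xa, xb):
    """Build a 1-gene log matrix + 2-group annotation."""
    na, nb = len(xa), len(xb)
    cols = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    expr = ns.ExpressionMatrix(
        pd.DataFrame([list(xa) + list(xb)], index=["g"], columns=cols), "log"
    )
    ann = ns.Annotation(pd.DataFrame({"grp": ["A"] * na + ["B"] * nb}, index=cols))
    return expr, ann


class TestWilcoxonDE:
    def test_identical_groups_null(self):
        expr, ann = de_input([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = wilcoxon_de(expr, ann, "grp", "A", "B")
        assert res.loc["g", "p_val"] == 1.0
        assert res.loc["g", "avg_log2FC"] == 0.0

    def test_fully_separated_4v4_exact_p(self):
        expr, ann = de_input([5.0, 6.0, 7.0, 8.0], [1.0, 2.0, 3.0, 4.0])
        res = wilcoxon_de(expr, ann, "grp", "A", "B")
        assert res.loc["g", "p_val"] == pytest.approx(2 / 70)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            na, nb = rng.integers(2, 7, size=2)
            xa = np.round(rng.normal(size=na), 1)
            xb = np.round(rng.normal(size=nb), 1)
            expr, ann = de_input(xa, xb)
            res = wilcoxon_de(expr, ann, "grp", "A", "B")
            assert res.loc["g", "p_val"] == pytest.approx(
                exact_wilcoxon_oracle(xa, xb), abs=1e-12
            )

    def test_normal_approx_close_to_scipy(self, rng):
        xa = rng.normal(0.5, 1, 30)
        xb = rng.normal(0.0, 1, 30)
        expr, ann = de_input(xa, xb)
        res = wilcoxon_de(expr, ann, "grp", "A", "B")
        ref = mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic").pvalue
        assert res.loc["g", "p_val"] == pytest.approx(ref, rel=1e-6)

    def test_fold_change_expm1_convention(self):
        # A has constant 2^3-1=7 on the linear scale, B constant 2^1-1=1
        expr, ann = de_input([3.0, 3.0, 3.0], [1.0, 1.0, 1.0])
        res = wilcoxon_de(expr, ann, "grp", "A", "B")
        assert res.loc["g", "avg_log2FC"] == pytest.approx(np.log2(8) - np.log2(2))
        assert res.loc["g", "direction"] == "up"

    def test_pct_detection_fractions(self):
        expr, ann = de_input([0.0, 1.0, 1.0, 1.0], [0.0, 0.0, 1.0, 0.0])
        res = wilcoxon_de(expr, ann, "grp", "A", "B")
        assert res.loc["g", "pct_in"] == 0.75
        assert res.loc["g", "pct_out"] == 0.25

    def test_bonferroni_multiplies_and_caps(self):
        p = np.array([0.001, 0.5, 0.9])
        np.testing.assert_allclose(_adjust_p(p, "bonferroni"), [0.003, 1.0, 1.0])

    def test_bh_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(_adjust_p(p, "bh"), [0.04, 0.04, 0.04, 0.04])

    def test_small_group_errors(self):
        expr, ann = de_input([1.0], [2.0, 3.0])
        with pytest.raises(ns.ValidationError, match=">=2"):
            wilcoxon_de(expr, ann, "grp", "A", "B")

    def test_counts_are_auto_logged(self, rng):
        cols = [f"c{i}" for i in range(8)]
        raw = ns.ExpressionMatrix(
            pd.DataFrame([rng.poisson(20, 8).astype(float)], index=["g"], columns=cols),
            "counts",
        )
        ann = ns.Annotation(pd.DataFrame({"grp": ["A"] * 4 + ["B"] * 4}, index=cols))
        res = wilcoxon_de(raw, ann, "grp", "A", "B")
        logged = wilcoxon_de(raw.to_log(), ann, "grp", "A", "B")
        pd.testing.assert_frame_equal(res, logged)


def marker_row(lfc, p_adj, pct_in=0.5, pct_out=0.05):
    return {
        "avg_log2FC": lfc, "p_val": p_adj / 10, "p_val_adj": p_adj,
        "pct_in": pct_in, "pct_out": pct_out,
        "direction": "up" if lfc >= 0 else "down",
    }


class TestDeriveNeFg:
    def _evidence(self, rows, meta=(), modules=()):
        degs = pd.DataFrame.from_dict(rows, orient="index")
        return ns.EvidenceSet(
            pseudobulk_degs=degs, meta_markers=set(meta), module_genes=set(modules)
        )

    def test_supported_up_gene_included(self):
        ev = self._evidence({"G1": marker_row(1.0, 1e-5)}, meta=["G1"])
        sig = ns.derive_ne_fg(ev)
        assert sig.up == ["G1"]
        assert sig.metadata["provenance"]["G1"] == ["pseudobulk", "meta_markers"]

    def test_unsupported_gene_excluded(self):
        ev = self._evidence(
            {"G1": marker_row(1.0, 1e-5), "G2": marker_row(2.0, 1e-9)}, meta=["G1"]
        )
        sig = ns.derive_ne_fg(ev)
        assert "G2" not in sig.up

    def test_down_gene_routed_by_sign(self):
        ev = self._evidence(
            {"U": marker_row(1.0, 1e-5), "D": marker_row(-1.0, 1e-5)},
            meta=["U", "D"],
        )
        sig = ns.derive_ne_fg(ev)
        assert sig.up == ["U"] and sig.down == ["D"]

    def test_thresholds_enforced(self):
        ev = self._evidence(
            {"weak": marker_row(0.4, 1e-5), "insig": marker_row(2.0, 0.02),
             "ok": marker_row(0.5, 1e-5)},
            meta=["weak", "insig", "ok"],
        )
        sig = ns.derive_ne_fg(ev)
        assert sig.up == ["ok"]

    def test_support_min_two_requires_both_streams(self):
        ev = self._evidence(
            {"one": marker_row(1.0, 1e-5), "both": marker_row(1.0, 1e-5)},
            meta=["one", "both"], modules=["both"],
        )
        sig = ns.derive_ne_fg(ev, support_min=2)
        assert sig.up == ["both"]

    def test_relaxing_thresholds_never_shrinks(self, rng):
        rows = {
            f"G{i}": marker_row(float(rng.uniform(-2, 2)), float(rng.uniform(0, 0.05)))
            for i in range(50)
        }
        ev = self._evidence(rows, meta=list(rows))
        strict = ns.derive_ne_fg(ev, lfc_threshold=0.8, p_adj_threshold=0.005)
        relaxed = ns.derive_ne_fg(ev, lfc_threshold=0.4, p_adj_threshold=0.02)
        assert set(strict.up) <= set(relaxed.up)
        assert set(strict.down) <= set(relaxed.down)

    def test_empty_result_errors(self):
        ev = self._evidence({"G1": marker_row(0.1, 0.9)}, meta=["G1"])
        with pytest.raises(ns.ValidationError, match="relax"):
            ns.derive_ne_fg(ev)


class TestThinSignature:
    def _markers(self, rows):
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_all_thresholds_met_retained(self):
        fg = ns.GeneSignature("fg", up=["G1"], down=[])
        cm = self._markers({"G1": marker_row(0.6, 1e-5, pct_in=0.35)})
        thin = ns.thin_signature(fg, cm)
        assert thin.up == ["G1"]

    def test_low_detection_excluded(self):
        fg = ns.GeneSignature("fg", up=["G1", "G2"])
        cm = self._markers({
            "G1": marker_row(0.6, 1e-5, pct_in=0.15),  # fails the >20% rule
            "G2": marker_row(0.6, 1e-5, pct_in=0.35),
        })
        assert ns.thin_signature(fg, cm).up == ["G2"]

    def test_down_needs_no_detection_floor(self):
        fg = ns.GeneSignature("fg", up=["U"], down=["D"])
        cm = self._markers({
            "U": marker_row(0.6, 1e-5, pct_in=0.5),
            "D": marker_row(-0.8, 1e-5, pct_in=0.01),
        })
        thin = ns.thin_signature(fg, cm)
        assert thin.down == ["D"]

    def test_empty_up_errors(self):
        fg = ns.GeneSignature("fg", up=["U"])
        cm = self._markers({"U": marker_row(0.1, 0.5)})
        with pytest.raises(ns.ValidationError, match="empty"):
            ns.thin_signature(fg, cm)

    def test_relaxing_min_pct_never_shrinks(self):
        fg = ns.GeneSignature("fg", up=["A", "B"])
        cm = self._markers({
            "A": marker_row(0.6, 1e-5, pct_in=0.25),
            "B": marker_row(0.6, 1e-5, pct_in=0.45),
        })
        strict = ns.thin_signature(fg, cm, min_pct=0.4)
        relaxed = ns.thin_signature(fg, cm, min_pct=0.2)
        assert set(strict.up) <= set(relaxed.up)


class TestPlantedRecovery:
    def test_full_derivation_recovers_planted_markers(self, atlas, derived):
        _, _, truth = atlas
        sig = derived["signature"]
        up_truth = set(truth.up)
        tp = len(set(sig.up) & up_truth)
        recall = tp / len(up_truth)
        fdr = 1 - tp / len(sig.up)
        assert recall >= 0.9
        assert fdr <= 0.1

    def test_ne_fg_supersets_thinned_signature(self, derived):
        assert set(derived["signature"].up) <= set(derived["ne_fg"].up)
        assert set(derived["signature"].down) <= set(derived["ne_fg"].down)
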