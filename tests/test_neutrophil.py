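"""Single-cell QC, normalisation, marker scoring and role assignment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gcresponse as g
from gcresponse.io import ExpressionMatrix
from gcresponse.neutrophil import (CellMatrix, annotate_by_cosine,
                                   classify_tumor_role, cluster_centroids,
                                   lineage_exclusion_filter, log_normalize,
                                   qc_filter, score_markers,
                                   sqrt_product_signature)
from gcresponse.synthetic import SingleCellConfig


def make_cells(counts, genes=None, cells=None, obs=None):
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{j}" for j in range(counts.shape[1])]
    return CellMatrix(counts=counts, gene_ids=genes, cell_ids=cells,
                      obs=obs if obs is not None else pd.DataFrame(index=cells))


class TestQc:
    def test_cell_with_99_genes_removed_100_retained(self):
        rng = np.random.default_rng(0)
        n_genes = 120
        counts = np.zeros((n_genes, 2), dtype=int)
        counts[:99, 0] = 1   # 99 expressed genes -> removed
        counts[:100, 1] = 1  # exactly 100 -> retained
        # make every gene pass the 3-cell gene filter
        pad = np.ones((n_genes, 3), dtype=int)
        cm = make_cells(np.hstack([counts, pad]))
        out = qc_filter(cm)
        assert "c0" not in out.cell_ids
        assert "c1" in out.cell_ids

    def test_gene_in_exactly_three_cells_retained(self):
        counts = np.zeros((2, 3), dtype=int)
        counts[0] = [1, 1, 1]   # 3 cells -> retained
        counts[1] = [1, 1, 0]   # 2 cells -> removed
        cm = make_cells(counts)
        out = qc_filter(cm, min_genes_per_cell=1)
        assert out.gene_ids == ["G0"]

    def test_high_mito_cells_removed(self):
        cfg = SingleCellConfig(mito_high_fraction=0.1, cells_per_cluster=100,
                               contamination_fraction=0.0)
        cm, _ = g.simulate_single_cells(cfg, seed=5)
        high = cm.obs["mito_fraction"] > 0.5
        out = qc_filter(cm, min_genes_per_cell=5)
        kept = set(out.cell_ids)
        assert not any(c in kept for c in cm.obs.index[high])
        # the vast majority of low-mito cells survive
        low = cm.obs.index[~high]
        assert np.mean([c in kept for c in low]) > 0.95

    def test_idempotent(self, cells_default):
        cm, _ = cells_default
        once = qc_filter(cm, min_genes_per_cell=5)
        twice = qc_filter(once, min_genes_per_cell=5)
        assert twice.cell_ids == once.cell_ids
        assert twice.gene_ids == once.gene_ids

    def test_all_cells_removed_is_error_with_summary(self):
        cm = make_cells(np.ones((5, 4), dtype=int))
        with pytest.raises(ValueError, match="QC"):
            qc_filter(cm)  # nobody has 100 genes


class TestLogNormalize:
    def test_closed_form(self):
        cm = make_cells(np.array([[10], [0]]))
        out = log_normalize(cm, scale=10_000)
        assert out.values[0, 0] == pytest.approx(math.log1p(10_000))
        assert out.values[1, 0] == 0.0

    def test_depth_invariance(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 20, size=12)
        cm = make_cells(np.column_stack([col, 2 * col]))
        out = log_normalize(cm)
        assert np.allclose(out.values[:, 0], out.values[:, 1])

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(6, 5))
        counts[0] += 1  # no zero-total cells
        cm = make_cells(counts)
        out = log_normalize(cm, scale=5000)
        totals = counts.sum(axis=0)
        for i in range(6):
            for j in range(5):
                assert out.values[i, j] == pytest.approx(
                    math.log1p(counts[i, j] * 5000 / totals[j]), rel=1e-12)

    def test_zero_total_cell_rejected(self):
        cm = make_cells(np.array([[1, 0], [1, 0]]))
        with pytest.raises(ValueError, match="zero-total"):
            log_normalize(cm)


class TestScoreMarkers:
    def test_single_present_gene_mean(self):
        genes = ["CXCL8", "OTHER"]
        cm = make_cells(np.array([[4], [0]]), genes=genes)
        norm = log_normalize(cm)
        cells, _ = score_markers(norm, {"TAN1": ("CXCL8", "CXCL1", "CXCL2",
                                                 "ICAM1", "CD44")})
        # only CXCL8 present: score is the mean over present members
        assert cells.loc["c0", "TAN1"] == pytest.approx(norm.values[0, 0])

    def test_all_zero_cell_scores_zero(self):
        cm = make_cells(np.array([[3, 0], [1, 0]]), genes=["PROK2", "MME"])
        cm2 = CellMatrix(counts=np.array([[3, 1], [1, 1]]),
                         gene_ids=["PROK2", "MME"], cell_ids=["a", "b"])
        norm = log_normalize(cm2)
        cells, _ = score_markers(norm, {"NETosis": ("PROK2", "MME")})
        assert (cells["NETosis"] >= 0).all()

    def test_absent_set_is_missing_not_zero(self):
        cm = make_cells(np.array([[1], [2]]), genes=["A", "B"])
        norm = log_normalize(cm)
        cells, _ = score_markers(norm, {"GHOST": ("X", "Y")})
        assert cells["GHOST"].isna().all()

    def test_planted_archetypes_score_highest_on_own_set(self, cells_default):
        cm, truth = cells_default
        keep = truth != "contaminant"
        cm = cm.subset(cell_mask=keep.to_numpy())
        norm = log_normalize(cm)
        _, clusters = score_markers(norm)
        for cl in clusters.index:
            own = cl.replace("-like", "")
            assert clusters.loc[cl].idxmax() == own


class TestAnnotation:
    def test_self_match_similarity_one(self):
        rng = np.random.default_rng(3)
        ref = pd.DataFrame(rng.uniform(0, 5, (25, 3)),
                           index=[f"G{i}" for i in range(25)],
                           columns=["A", "B", "C"])
        out = annotate_by_cosine(ref[["A"]].rename(columns={"A": "cl0"}), ref)
        assert out.loc["cl0", "label"] == "A"
        assert out.loc["cl0", "similarity"] == pytest.approx(1.0)

    def test_orthogonal_centroid_unassigned(self):
        genes = [f"G{i}" for i in range(24)]
        ref = pd.DataFrame(0.0, index=genes, columns=["A"])
        ref.iloc[:12, 0] = 1.0
        cent = pd.DataFrame(0.0, index=genes, columns=["cl"])
        cent.iloc[12:, 0] = 1.0
        out = annotate_by_cosine(cent, ref)
        assert out.loc["cl", "label"] == "Unassigned"

    def test_matches_all_pairs_oracle(self):
        from gcresponse._utils import cosine

        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(30)]
        ref = pd.DataFrame(rng.uniform(0, 1, (30, 4)), index=genes,
                           columns=list("ABCD"))
        cent = pd.DataFrame(rng.uniform(0, 1, (30, 5)), index=genes,
                            columns=[f"cl{i}" for i in range(5)])
        out = annotate_by_cosine(cent, ref, threshold=0.0)
        for cl in cent.columns:
            sims = {r: cosine(cent[cl].to_numpy(), ref[r].to_numpy())
                    for r in ref.columns}
            assert out.loc[cl, "label"] == max(sims, key=sims.get)

    def test_planted_archetypes_fully_recovered(self):
        cfg = SingleCellConfig(dropout=0.0, contamination_fraction=0.0,
                               mito_high_fraction=0.0, cells_per_cluster=40)
        cm, truth = g.simulate_single_cells(cfg, seed=6)
        norm = log_normalize(cm)
        cent = cluster_centroids(norm)
        ref_cm, _ = g.simulate_single_cells(cfg, seed=7)
        ref = cluster_centroids(log_normalize(ref_cm))
        out = annotate_by_cosine(cent, ref)
        assert (out["label"] == out.index).all()

    def test_too_few_shared_genes_rejected(self):
        small = pd.DataFrame(np.ones((5, 1)), index=list("abcde"),
                             columns=["cl"])
        with pytest.raises(ValueError, match="shared"):
            annotate_by_cosine(small, small.rename(columns={"cl": "A"}))


class TestLineageExclusion:
    def test_single_cd3e_count_removes_cell(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[0, 0] = 1  # CD3E in cell 0
        counts[1] = [5, 5]
        cm = make_cells(counts, genes=["CD3E", "HK"])
        out = lineage_exclusion_filter(cm)
        assert out.cell_ids == ["c1"]

    def test_clean_matrix_unchanged(self):
        cm = make_cells(np.ones((3, 4), dtype=int),
                        genes=["HK1", "HK2", "HK3"])
        out = lineage_exclusion_filter(cm)
        assert out.cell_ids == cm.cell_ids

    def test_planted_contaminants_confusion_counts(self):
        cfg = SingleCellConfig(contamination_fraction=0.05,
                               cells_per_cluster=200)
        cm, truth = g.simulate_single_cells(cfg, seed=8)
        out = lineage_exclusion_filter(cm)
        removed = set(cm.cell_ids) - set(out.cell_ids)
        contams = set(truth[truth == "contaminant"].index)
        assert len(contams & removed) >= 0.99 * len(contams)
        false_removed = removed - contams
        assert len(false_removed) <= 0.01 * (cm.n_cells - len(contams))

    def test_ig_high_cluster_removed(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 3, size=(3, 40))
        counts[0, 20:] += 10  # IGHA1-high second cluster
        obs = pd.DataFrame({"cluster": ["a"] * 20 + ["b"] * 20},
                           index=[f"c{j}" for j in range(40)])
        cm = make_cells(counts, genes=["IGHA1", "HK1", "HK2"], obs=obs)
        out = lineage_exclusion_filter(cm)
        assert set(out.obs["cluster"]) == {"a"}


class TestSqrtProductSignature:
    def expr(self, vals, genes, samples):
        return ExpressionMatrix(values=pd.DataFrame(vals, index=genes,
                                                    columns=samples))

    def test_unit_fixed_point(self):
        genes = [f"G{i}" for i in range(10)]
        m = self.expr(np.ones((10, 1)), genes, ["S1"])
        for expo in (2.0, 10.0):
            s = sqrt_product_signature(m, genes, epsilon=1e-12, exponent=expo)
            assert s["S1"] == pytest.approx(1.0, rel=1e-6)

    def test_zero_gene_decreases_score(self):
        genes = ["A", "B"]
        m1 = self.expr([[1.0], [1.0]], genes, ["S1"])
        m0 = self.expr([[0.0], [1.0]], genes, ["S1"])
        s1 = sqrt_product_signature(m1, genes)["S1"]
        s0 = sqrt_product_signature(m0, genes)["S1"]
        assert s0 < s1

    def test_matches_direct_product_oracle(self, rng):
        genes = [f"G{i}" for i in range(10)]
        vals = rng.uniform(0.1, 3.0, size=(10, 4))
        m = self.expr(vals, genes, list("abcd"))
        s = sqrt_product_signature(m, genes, epsilon=0.01, exponent=2)
        for j, sample in enumerate("abcd"):
            direct = math.sqrt(np.prod(vals[:, j] + 0.01))
            assert s[sample] == pytest.approx(direct, rel=1e-9)

    @given(st.floats(0.01, 10.0), st.floats(0.02, 5.0))
    def test_strictly_increasing_in_each_gene(self, x, bump):
        genes = ["A", "B", "C"]
        lo = self.expr([[x], [1.0], [2.0]], genes, ["S"])
        hi = self.expr([[x + bump], [1.0], [2.0]], genes, ["S"])
        assert (sqrt_product_signature(hi, genes)["S"]
                > sqrt_product_signature(lo, genes)["S"])

    def test_all_absent_errors(self):
        m = self.expr([[1.0]], ["A"], ["S"])
        with pytest.raises(ValueError):
            sqrt_product_signature(m, ["X", "Y"])


class TestTumorRole:
    def test_single_anti_cluster_fraction_one(self):
        labels = pd.Series(["TAN2-like"] * 8, index=[f"c{j}" for j in range(8)])
        out = classify_tumor_role(labels)
        assert out.loc["all", "anti-tumor"] == 1.0

    def test_even_pro_anti_split(self):
        labels = pd.Series(["TAN1-like"] * 5 + ["TAN2-like"] * 5,
                           index=[f"c{j}" for j in range(10)])
        out = classify_tumor_role(labels)
        assert out.loc["all"].tolist() == pytest.approx([0.5, 0.5, 0.0])

    def test_planted_mixture_recovered_exactly(self):
        labels = pd.Series(["TAN1-like"] * 60 + ["TAN2-like"] * 30 +
                           ["TAN3-like"] * 10,
                           index=[f"c{j}" for j in range(100)])
        samples = pd.Series(["P1"] * 100, index=labels.index)
        with pytest.warns(UserWarning, match="TAN3"):
            out = classify_tumor_role(labels, sample_key=samples)
        assert out.loc["P1"].tolist() == pytest.approx([0.6, 0.3, 0.1])

    def test_fractions_sum_to_one(self, cells_default):
        cm, truth = cells_default
        out = classify_tumor_role(cm.obs["cluster"],
                                  sample_key=cm.obs["sample"])
        assert np.allclose(out.sum(axis=1), 1.0)
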