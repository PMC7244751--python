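import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nichescore.containers import NormalizedMatrix
from nichescore.markers import (
    MarkerParams,
    adjust_pvalues,
    find_markers,
    wilcoxon_rank_sum,
)

from conftest import exact_wilcoxon_p


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        w, p = wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_degenerate_constant_data(self):
        w, p = wilcoxon_rank_sum([5, 5], [5, 5, 5])
        assert p == 1.0

    def test_exact_enumeration_example(self):
        # x=[1,2,3] vs y=[4,5,6]: 2 of the C(6,3)=20 assignments are as
        # extreme -> exact two-sided p = 0.1
        p_exact = exact_wilcoxon_p([1, 2, 3], [4, 5, 6])
        assert p_exact == pytest.approx(2 / 20)
        _, p_norm = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert abs(p_norm - p_exact) <= 0.05

    def test_extreme_singleton_has_maximal_rank_sum(self):
        w, _ = wilcoxon_rank_sum([5], [1, 2, 3, 4])
        assert w == 5.0  # top rank of 5 values

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_normal_approximation_tracks_exact_p_untied(self):
        # without ties the asymptotic p stays within 0.05 of enumeration
        rng = np.random.default_rng(42)
        for _ in range(50):
            n1 = int(rng.integers(3, 9))
            n2 = int(rng.integers(3, 9))
            vals = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            _, p_norm = wilcoxon_rank_sum(vals[:n1], vals[n1:])
            assert abs(p_norm - exact_wilcoxon_p(vals[:n1], vals[n1:])) <= 0.05

    def test_tied_instances_agree_where_significant(self):
        # heavily tied small samples: the asymptotic p can drift from the
        # exact permutation p near its center, but wherever either test
        # calls significance at 0.05 the two agree within 0.05
        rng = np.random.default_rng(42)
        for _ in range(50):
            n1 = int(rng.integers(5, 9))
            n2 = int(rng.integers(5, 9))
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            _, p_norm = wilcoxon_rank_sum(x, y)
            p_exact = exact_wilcoxon_p(x, y)
            if min(p_norm, p_exact) <= 0.05:
                assert abs(p_norm - p_exact) <= 0.05


class TestAdjustPvalues:
    def test_bonferroni_worked_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bonferroni") == pytest.approx(
            [0.03, 0.06, 0.09])

    def test_bh_step_up_worked_example(self):
        # step-up by hand: 0.03*3/3=0.03; min(0.03, 0.02*3/2)=0.03;
        # min(0.03, 0.01*3/1)=0.03
        assert adjust_pvalues([0.01, 0.02, 0.03], "BH") == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        for method in ("BH", "bonferroni"):
            assert adjust_pvalues([0.2], method) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "BH")

    def test_bh_invariant_under_permutation_and_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.random(40)
        q = adjust_pvalues(p, "BH")
        perm = rng.permutation(40)
        q_perm = adjust_pvalues(p[perm], "BH")
        assert np.allclose(q_perm, q[perm])
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


try:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bh_dominates_raw_p_and_respects_order(p):
        """BH q-values never fall below their raw p and are monotone in
        the sorted order, for arbitrary p-vectors."""
        p = np.asarray(p)
        q = adjust_pvalues(p, "BH")
        assert np.all(q <= 1.0 + 1e-12)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def _norm_from_dense(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(np.asarray(genes, dtype=object),
                            np.asarray(cells, dtype=object),
                            sp.csr_matrix(values))


class TestFindMarkers:
    def test_planted_fixture_marker_detected(self, fixture_filtered, fixture_data):
        _, meta_f, norm, _ = fixture_filtered
        truth = fixture_data[3]
        table = find_markers(norm, meta_f["subtype"].to_numpy(object),
                             groups=["FB_adult"])
        rows = table.set_index("gene")
        for gene in truth.planted_ligands["FB_adult"]:
            assert rows.loc[gene, "log_fc"] > 0.2
            assert rows.loc[gene, "q_value"] < 0.05
        # exact-enumeration cross-check of the planted separation
        x = norm.dense()[list(norm.gene_ids).index("LIG_A"),
                         (meta_f["subtype"] == "FB_adult").to_numpy()]
        y = norm.dense()[list(norm.gene_ids).index("LIG_A"),
                         (meta_f["subtype"] != "FB_adult").to_numpy()]
        assert exact_wilcoxon_p(x[:4], y[:6]) < 0.05  # small-slice sanity

    def test_low_detection_gene_screened_out(self):
        # gene expressed in 10% of cells in both groups at min_pct=0.2
        rng = np.random.default_rng(0)
        values = np.zeros((1, 40))
        values[0, rng.choice(20, 2, replace=False)] = 1.0
        values[0, 20 + rng.choice(20, 2, replace=False)] = 1.0
        norm = _norm_from_dense(values)
        labels = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        table = find_markers(norm, labels)
        assert len(table) == 0

    def test_constant_gene_absent(self):
        norm = _norm_from_dense(np.full((1, 10), 2.0))
        labels = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        table = find_markers(norm, labels)
        assert len(table) == 0

    def test_unknown_cluster_rejected(self):
        norm = _norm_from_dense(np.ones((2, 6)))
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        with pytest.raises(ValueError, match="ghost"):
            find_markers(norm, labels, groups=["ghost"])

    def test_cluster_vs_cluster_contrast(self):
        rng = np.random.default_rng(5)
        values = rng.random((3, 30))
        values[0, :10] += 3.0  # up in cluster a vs everything
        norm = _norm_from_dense(values)
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10, dtype=object)
        table = find_markers(norm, labels, groups=["a"], reference="b")
        assert "g0" in set(table["gene"])

    def test_only_positive_excludes_downregulated(self):
        rng = np.random.default_rng(6)
        values = rng.random((2, 40))
        values[0, 20:] += 3.0  # down in cluster a
        norm = _norm_from_dense(values)
        labels = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        pos = find_markers(norm, labels, groups=["a"])
        assert "g0" not in set(pos["gene"])
        both = find_markers(norm, labels,
                            MarkerParams(only_positive=False), groups=["a"])
        assert "g0" in set(both["gene"])

    def test_null_calibration_on_permuted_labels(self):
        # no-signal NB-like data, random labels: ~5% of genes at p<0.05
        rng = np.random.default_rng(11)
        values = np.log1p(rng.negative_binomial(2, 2 / 3.0, size=(2500, 200)))
        norm = _norm_from_dense(values)
        labels = rng.permutation(np.array(["a"] * 100 + ["b"] * 100, dtype=object))
        table = find_markers(norm, labels,
                             MarkerParams(min_pct=0.0, logfc_threshold=0.0,
                                          only_positive=False),
                             groups=["a"])
        assert len(table) >= 2000
        frac = (table["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)
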