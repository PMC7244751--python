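import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nichescore.containers import GeneSetCollection, InteractionLibrary, NormalizedMatrix
from nichescore.composition import changed_subtypes, subtype_proportions
from nichescore.interactome import (
    build_ligand_pathway_network,
    contribution_report,
    contribution_zsum,
    overlap_analyses,
    pair_ligand_receptor,
    select_receptors,
    select_secreted_ligands,
)
from nichescore.markers import find_markers

from conftest import brute_force_pairs


@pytest.fixture(scope="module")
def fixture_analysis(fixture_filtered, fixture_data):
    """Marker table, changes and assignment computed once on the fixture."""
    counts_f, meta_f, norm, _ = fixture_filtered
    _, _, bundle, truth = fixture_data
    labels = meta_f["subtype"].to_numpy(object)
    comp = subtype_proportions(meta_f)
    changes = changed_subtypes(comp, "P1", "P56")
    markers = find_markers(norm, labels, groups=["FB_adult", "FB_neo"])
    assignment = select_secreted_ligands(markers, bundle.annotations.secreted,
                                         changes)
    return meta_f, norm, labels, changes, markers, assignment, bundle, truth


class TestSelectSecretedLigands:
    def test_planted_ligands_assigned_to_changed_subtype(self, fixture_analysis):
        *_, assignment, bundle, truth = fixture_analysis
        assert list(assignment["FB_adult"]["gene"]) == ["LIG_A", "LIG_B"]

    def test_non_secreted_significant_genes_excluded(self, fixture_analysis):
        meta_f, norm, labels, changes, markers, *_ = fixture_analysis
        # empty secretome -> nothing can be a ligand
        empty = select_secreted_ligands(markers, set(), changes)
        assert all(len(t) == 0 for t in empty.values())

    def test_unchanged_subtype_gets_no_entry(self, fixture_analysis):
        *_, assignment, bundle, truth = fixture_analysis
        assert "CM_1" not in assignment

    def test_q_threshold_applied(self, fixture_analysis):
        meta_f, norm, labels, changes, markers, *_ = fixture_analysis
        bundle = fixture_analysis[6]
        strict = select_secreted_ligands(markers, bundle.annotations.secreted,
                                         changes, q_max=1e-12)
        assert all(len(t) == 0 for t in strict.values())


class TestLigandPathwayNetwork:
    def test_membership_edges_only_for_maturation_sets(self, fixture_analysis):
        *_, assignment, bundle, truth = fixture_analysis
        net = build_ligand_pathway_network(assignment, bundle.gene_sets,
                                           truth.maturation_set_ids)
        assert set(map(tuple, net[["ligand", "pathway"]].itertuples(index=False))) \
            == {("LIG_A", "M_SIG"), ("LIG_B", "M_SIG")}
        # LIG_C sits only in the decoy pathway -> dropped from the matched set
        assert "LIG_C" not in set(net["ligand"])

    def test_ligand_in_two_pathways_yields_two_edges(self):
        gs = GeneSetCollection({"P1": ("d", ["L"]), "P2": ("d", ["L", "x"])})
        assignment = {"s": pd.DataFrame({"gene": ["L"], "q_value": [1e-5],
                                         "log_fc": [1.0]})}
        net = build_ligand_pathway_network(assignment, gs, ["P1", "P2"])
        assert len(net) == 2

    def test_empty_maturation_list_gives_empty_network(self, fixture_analysis,
                                                       caplog):
        *_, assignment, bundle, truth = fixture_analysis
        with caplog.at_level("WARNING"):
            net = build_ligand_pathway_network(assignment, bundle.gene_sets, [])
        assert len(net) == 0


def _norm(values, genes, cells):
    return NormalizedMatrix(np.asarray(genes, dtype=object),
                            np.asarray(cells, dtype=object),
                            sp.csr_matrix(np.asarray(values, dtype=float)))


class TestContributionZsum:
    def test_two_cluster_arithmetic(self):
        # one ligand, cluster means 1 and 3 -> z = -+0.7071 with sample SD
        norm = _norm([[1.0, 1.0, 3.0, 3.0]], ["L"], list("abcd"))
        labels = np.array(["s1", "s1", "s2", "s2"], dtype=object)
        out = contribution_zsum(norm, labels, {"s1": ["L"], "s2": ["L"]})
        z = out.set_index("subtype")["z_sum"]
        assert z["s2"] == pytest.approx(np.sqrt(0.5))
        assert z["s1"] == pytest.approx(-np.sqrt(0.5))
        assert out.iloc[0]["subtype"] == "s2"

    def test_constant_ligand_contributes_zero(self):
        norm = _norm([[2.0, 2.0, 2.0, 2.0]], ["L"], list("abcd"))
        labels = np.array(["s1", "s1", "s2", "s2"], dtype=object)
        out = contribution_zsum(norm, labels, {"s1": ["L"], "s2": ["L"]})
        assert (out["z_sum"] == 0).all()

    def test_subtype_without_ligands_scores_zero(self):
        norm = _norm([[1.0, 3.0]], ["L"], list("ab"))
        labels = np.array(["s1", "s2"], dtype=object)
        out = contribution_zsum(norm, labels, {"s1": ["L"], "s2": []})
        assert out.set_index("subtype").loc["s2", "z_sum"] == 0.0

    def test_single_subtype_rejected(self):
        norm = _norm([[1.0, 2.0]], ["L"], list("ab"))
        with pytest.raises(ValueError, match="one cluster"):
            contribution_zsum(norm, np.array(["s1", "s1"], dtype=object),
                              {"s1": ["L"]})

    def test_invariant_to_cell_relabeling_and_gene_order(self):
        rng = np.random.default_rng(8)
        values = rng.random((4, 30))
        genes = ["g0", "g1", "g2", "g3"]
        cells = [f"c{i}" for i in range(30)]
        labels = np.array(["s1"] * 10 + ["s2"] * 10 + ["s3"] * 10, dtype=object)
        matched = {"s1": ["g0", "g2"], "s2": ["g1"], "s3": []}
        base = contribution_zsum(_norm(values, genes, cells), labels, matched)
        perm = rng.permutation(30)
        shuffled = contribution_zsum(_norm(values[:, perm], genes,
                                           [cells[i] for i in perm]),
                                     labels[perm], matched)
        pd.testing.assert_frame_equal(base, shuffled)
        gperm = [2, 0, 3, 1]
        reordered = contribution_zsum(_norm(values[gperm], [genes[i] for i in gperm],
                                            cells), labels, matched)
        pd.testing.assert_frame_equal(base, reordered)


class TestSelectReceptors:
    def test_fixture_planted_receptors_selected(self, fixture_filtered,
                                                fixture_data):
        _, meta_f, norm, _ = fixture_filtered
        _, _, bundle, truth = fixture_data
        table = find_markers(norm, meta_f["cell_type"].to_numpy(object),
                             groups=["CM"])
        receptors = select_receptors(table, bundle.annotations.membrane,
                                     target="CM", contrast="pooled")
        assert set(receptors.genes) == set(truth.planted_receptors)

    def test_specific_gene_not_in_membrane_list_excluded(self):
        table = pd.DataFrame({"gene": ["A", "B"], "cluster": "CM",
                              "log_fc": 1.0, "pct_in": 1.0, "pct_out": 0.0,
                              "p_value": [1e-6, 1e-6], "q_value": [1e-6, 1e-6],
                              "significant": True})
        receptors = select_receptors(table, {"B"})
        assert receptors.genes == ("B",)

    def test_membrane_gene_not_specific_excluded(self):
        table = pd.DataFrame({"gene": ["A"], "cluster": "CM", "log_fc": 0.1,
                              "pct_in": 0.5, "pct_out": 0.5,
                              "p_value": [0.9], "q_value": [0.9],
                              "significant": False})
        receptors = select_receptors(table, {"A"})
        assert receptors.genes == ()

    def test_empty_membrane_list_rejected(self):
        with pytest.raises(ValueError, match="membrane"):
            select_receptors(pd.DataFrame(columns=["gene", "q_value"]), set())


class TestPairLigandReceptor:
    def _receptors(self, genes):
        from nichescore.interactome import ReceptorSet
        return ReceptorSet(target="CM", genes=tuple(genes))

    def test_cross_join_filtered_by_library(self):
        assignment = {"s": pd.DataFrame({"gene": ["L1", "L2"],
                                         "q_value": [1e-5, 1e-5],
                                         "log_fc": [1, 1]})}
        lib = InteractionLibrary([("L1", "R1", 5.0)])
        pairs, counts = pair_ligand_receptor(assignment, self._receptors(["R1"]),
                                             lib)
        assert list(pairs.itertuples(index=False, name=None)) == [("s", "L1", "R1")]
        assert counts["s"] == 1

    def test_symmetric_storage_still_matches(self):
        assignment = {"s": pd.DataFrame({"gene": ["L1"], "q_value": [1e-5],
                                         "log_fc": [1]})}
        lib = InteractionLibrary([("R1", "L1", 2.0)])  # stored reversed
        pairs, counts = pair_ligand_receptor(assignment, self._receptors(["R1"]),
                                             lib)
        assert counts["s"] == 1

    def test_fixture_counts_match_ground_truth(self, fixture_analysis):
        meta_f, norm, labels, changes, markers, assignment, bundle, truth = \
            fixture_analysis
        table = find_markers(norm, meta_f["cell_type"].to_numpy(object),
                             groups=["CM"])
        receptors = select_receptors(table, bundle.annotations.membrane,
                                     target="CM", contrast="pooled")
        pairs, counts = pair_ligand_receptor(assignment, receptors,
                                             bundle.interactions)
        assert set(map(tuple, pairs[["ligand", "receptor"]]
                       .itertuples(index=False))) == truth.ligand_receptor_pairs
        assert counts["FB_adult"] == len(truth.ligand_receptor_pairs)
        assert counts["FB_neo"] == 0

    def test_equals_brute_force_triple_loop(self, fixture_analysis):
        meta_f, norm, labels, changes, markers, assignment, bundle, truth = \
            fixture_analysis
        receptors = self._receptors(truth.planted_receptors)
        pairs, _ = pair_ligand_receptor(assignment, receptors, bundle.interactions)
        oracle = brute_force_pairs(assignment, receptors.genes, bundle.interactions)
        assert sorted(pairs.itertuples(index=False, name=None)) == sorted(oracle)


class TestOverlapAnalyses:
    def _report(self, network_rows):
        from nichescore.interactome import ContributionReport
        net = pd.DataFrame(network_rows, columns=["ligand", "pathway", "subtype"])
        return ContributionReport(ligands={}, network=net,
                                  zsum=pd.DataFrame(), receptors=None,
                                  pairs=pd.DataFrame(),
                                  pair_counts=pd.Series(dtype=int))

    def test_disjoint_reports(self):
        a = self._report([("L1", "P1", "s")])
        b = self._report([("L2", "P2", "s")])
        out = overlap_analyses(a, b)
        assert out["n_shared_pathways"] == 0 and out["n_shared_ligands"] == 0

    def test_identical_reports_full_overlap(self):
        rows = [("L1", "P1", "s"), ("L2", "P2", "s")]
        out = overlap_analyses(self._report(rows), self._report(rows))
        assert out["shared_pathways"] == ["P1", "P2"]
        assert out["n_shared_ligands"] == out["n_ligands_union"] == 2

    def test_single_shared_ligand(self):
        a = self._report([("Cxcl12", "P1", "s"), ("L9", "P3", "s")])
        b = self._report([("Cxcl12", "P2", "t")])
        out = overlap_analyses(a, b)
        assert out["shared_ligands"] == ["Cxcl12"]
        assert out["n_shared_ligands"] == 1


def test_report_referential_integrity(fixture_analysis):
    """Every reported pair's ligand/receptor appears in the network and
    receptor tables of the assembled report."""
    meta_f, norm, labels, changes, markers, assignment, bundle, truth = \
        fixture_analysis
    table = find_markers(norm, meta_f["cell_type"].to_numpy(object), groups=["CM"])
    receptors = select_receptors(table, bundle.annotations.membrane,
                                 target="CM", contrast="pooled")
    report = contribution_report(norm, labels, markers, changes,
                                 bundle.gene_sets, truth.maturation_set_ids,
                                 bundle.annotations.secreted, receptors,
                                 bundle.interactions)
    assert set(report.pairs["ligand"]) <= report.ligand_ids()
    assert set(report.pairs["receptor"]) <= set(report.receptors.genes)
    assert list(report.zsum["rank"]) == list(range(1, len(report.zsum) + 1))
    for s, n in report.pair_counts.items():
        assert n == (report.pairs["subtype"] == s).sum()
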