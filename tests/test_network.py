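"""Four-branch intersection, gene refinement and the cooperation network."""

import pytest

from tfcoop.enrichment import (
    ALL_BRANCHES,
    BRANCH_AME_CHIP,
    BRANCH_TFT_CHIP,
    BRANCH_TFT_TX,
    BRANCH_URA_TX,
    DERecord,
    EnrichmentRecord,
    Regulon,
)
from tfcoop.families import FamilyEntry, FamilyResult, TFClassTable
from tfcoop.network import (
    build_network,
    connectivity_stats,
    intersect_families,
    network_share_report,
    refine_to_genes,
)


def _fam(barcode, branch, p):
    return FamilyResult(barcode, f"fam{barcode}", branch, p, 1, int(p < 0.05), p < 0.05)


def _branches(mapping):
    """mapping: branch -> {barcode: best_adj_p}."""
    return {
        b: [_fam(bc, b, p) for bc, p in d.items()] for b, d in mapping.items()
    }


class TestIntersectFamilies:
    def test_identical_singletons(self):
        res = _branches({b: {"1.2.6": 0.01} for b in ALL_BRANCHES})
        assert intersect_families(res) == {"1.2.6"}

    def test_disjoint_sets_empty(self):
        res = _branches({
            BRANCH_AME_CHIP: {"1.1.1": 0.01},
            BRANCH_TFT_CHIP: {"2.2.2": 0.01},
            BRANCH_URA_TX: {"3.3.3": 0.01},
            BRANCH_TFT_TX: {"4.4.4": 0.01},
        })
        assert intersect_families(res) == set()

    def test_missing_branch_rejected(self):
        res = _branches({BRANCH_AME_CHIP: {"1.1.1": 0.01}})
        with pytest.raises(ValueError, match="missing branch"):
            intersect_families(res)

    def test_decoys_with_partial_support_excluded(self):
        planted = {"1.1.1": 0.001, "2.2.2": 0.001, "3.3.3": 0.001}
        per_branch = {}
        for i, b in enumerate(ALL_BRANCHES):
            d = dict(planted)
            # each decoy family is significant in all but one branch
            for j, decoy in enumerate(["5.5.5", "6.6.6", "7.7.7", "8.8.8"]):
                d[decoy] = 0.9 if i == j else 0.001
            per_branch[b] = d
        result = intersect_families(_branches(per_branch))
        # brute-force oracle: intersect the significant sets directly
        oracle = set.intersection(
            *({bc for bc, p in d.items() if p < 0.05} for d in per_branch.values())
        )
        assert result == oracle == set(planted)

    def test_idempotent_and_commutative(self):
        d = {"1.1.1": 0.01, "2.2.2": 0.2}
        res = _branches({b: d for b in ALL_BRANCHES})
        assert intersect_families(res) == {"1.1.1"}


@pytest.fixture
def refine_setup():
    table = TFClassTable([
        FamilyEntry("1.2.6", "bHLH-ZIP", frozenset({"GOOD", "SIBLING"})),
        FamilyEntry("3.5.2", "Ets", frozenset({"OTHER"})),
    ])

    def rec(unit, branch, adj_p, z=None):
        return EnrichmentRecord(unit, branch, adj_p / 2, adj_pvalue=adj_p, z=z)

    gene_level = {
        BRANCH_TFT_TX: [rec("GOOD", BRANCH_TFT_TX, 0.001),
                        rec("SIBLING", BRANCH_TFT_TX, 0.8),
                        rec("OTHER", BRANCH_TFT_TX, 0.001)],
        BRANCH_URA_TX: [rec("GOOD", BRANCH_URA_TX, 0.001, z=4.5),
                        rec("SIBLING", BRANCH_URA_TX, 0.9, z=0.1),
                        rec("OTHER", BRANCH_URA_TX, 0.2, z=3.0)],
    }
    return table, gene_level


class TestRefineToGenes:
    def test_sibling_sharing_logo_fails_gene_filters(self, refine_setup):
        table, gene_level = refine_setup
        kept = refine_to_genes({"1.2.6", "3.5.2"}, gene_level, table)
        assert kept == ["GOOD"]  # SIBLING shares the family, not the evidence

    def test_three_of_four_branch_support_excluded(self, refine_setup):
        # OTHER is significant in TFT_tx but not URA_tx
        table, gene_level = refine_setup
        assert "OTHER" not in refine_to_genes({"1.2.6", "3.5.2"}, gene_level, table)

    def test_empty_family_set_empty_output(self, refine_setup):
        table, gene_level = refine_setup
        assert refine_to_genes(set(), gene_level, table) == []

    def test_direction_gate_optional(self, refine_setup):
        table, gene_level = refine_setup
        # without the direction gate, OTHER still fails on URA p; GOOD stays
        kept = refine_to_genes({"1.2.6", "3.5.2"}, gene_level, table,
                               require_direction=False)
        assert kept == ["GOOD"]

    def test_negative_z_fails_direction(self, refine_setup):
        table, gene_level = refine_setup
        gene_level[BRANCH_URA_TX][0] = EnrichmentRecord(
            "GOOD", BRANCH_URA_TX, 0.0005, adj_pvalue=0.001, z=-4.5
        )
        assert refine_to_genes({"1.2.6"}, gene_level, table) == []

    def test_output_subset_of_family_members(self, refine_setup):
        table, gene_level = refine_setup
        kept = refine_to_genes({"1.2.6"}, gene_level, table)
        assert set(kept) <= set(table.members("1.2.6"))


def _de(gene, sig=True):
    return DERecord(gene, -1.0, 0.001 if sig else 0.9, 0.01 if sig else 0.9, -1)


class TestBuildNetwork:
    def test_edges_require_de_and_peak_evidence(self):
        regs = {"TF1": Regulon("TF1", {"A": 1, "B": -1, "C": 1})}
        de = [_de("A"), _de("B"), _de("X", sig=False)]
        net = build_network(["TF1"], regs, de, epigenomic_target_genes={"A", "C"})
        assert [(e.tf, e.target) for e in net.edges] == [("TF1", "A")]
        assert net.edges[0].de_target and net.edges[0].peak_promoter

    def test_zero_overlap_all_isolated(self):
        regs = {"TF1": Regulon("TF1", {"A": 1})}
        net = build_network(["TF1"], regs, [_de("B")], epigenomic_target_genes=set())
        assert net.edges == [] and net.isolated_tfs == ["TF1"]

    def test_motif_evidence_flag(self):
        regs = {"TF1": Regulon("TF1", {"A": 1, "B": 1})}
        de = [_de("A"), _de("B")]
        net = build_network(["TF1"], regs, de, {"A", "B"}, motif_hits={"TF1": {"A"}})
        flags = {e.target: e.motif_hit for e in net.edges}
        assert flags == {"A": True, "B": False}

    def test_full_fixture_edges_superset_of_design(self, small_study):
        from tfcoop.pipeline import run_study_object

        res = run_study_object(small_study)
        truth = small_study.truth
        edge_set = {(e.tf, e.target) for e in res.network.edges}
        for tf in res.recovered_tfs:
            expected = {
                (tf, g)
                for g in truth.regulons[tf]
                if g in truth.de_true and g in res.epigenomic_target_genes
                and g in {r.gene for r in res.de_records if r.adj_pvalue < 0.05}
            }
            assert expected <= edge_set


class TestConnectivity:
    def test_star_network_no_hyperconnected(self):
        regs = {"TF1": Regulon("TF1", {f"G{i}": 1 for i in range(5)})}
        de = [_de(f"G{i}") for i in range(5)]
        net = build_network(["TF1"], regs, de, {f"G{i}" for i in range(5)})
        stats = connectivity_stats(net, k=3)
        assert stats.n_hyperconnected == 0
        assert set(stats.target_degree["n_tfs"]) == {1}

    def test_shared_target_hyperconnected(self):
        regs = {f"TF{i}": Regulon(f"TF{i}", {"HUB": 1}) for i in range(4)}
        net = build_network(sorted(regs), regs, [_de("HUB")], {"HUB"})
        stats = connectivity_stats(net, k=3)
        assert stats.n_hyperconnected == 1
        assert stats.target_degree.set_index("target").loc["HUB", "n_tfs"] == 4

    def test_out_degree_consistent_with_edges(self):
        regs = {"TF1": Regulon("TF1", {"A": 1, "B": 1})}
        net = build_network(["TF1"], regs, [_de("A"), _de("B")], {"A", "B"})
        stats = connectivity_stats(net)
        assert stats.tf_out_degree.set_index("tf").loc["TF1", "n_targets"] == 2


class TestShareReport:
    def test_eleven_of_1539_below_bound(self):
        rep = network_share_report(11, 1539)
        assert rep.pct == pytest.approx(100 * 11 / 1539)
        assert rep.text == "0.71%"
        assert rep.below_threshold  # < 0.8%

    def test_zero_selected(self):
        rep = network_share_report(0, 1539)
        assert rep.pct == 0.0 and rep.below_threshold

    def test_everything_selected(self):
        rep = network_share_report(1539, 1539)
        assert rep.pct == 100.0 and not rep.below_threshold

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            network_share_report(1, 0)
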