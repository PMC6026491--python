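"""DE testing, exact enrichment statistics and the URA activation score."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfcoop.enrichment import (
    BRANCH_TFT_CHIP,
    BRANCH_URA_TX,
    DERecord,
    Regulon,
    adjust_records,
    bh_adjust,
    classify_regulation,
    differential_expression,
    fisher_one_sided,
    motif_enrichment,
    tft_enrichment,
    upstream_regulator,
)
from tfcoop.motif import consensus_to_pssm
from tfcoop.simulate import SimConfig, generate_study

from conftest import random_pssm, random_sequence


def hypergeom_tail_oracle(a, b, c, d):
    """Exact upper tail by direct enumeration with integer binomials."""
    M, K, n = a + b + c + d, a + b, a + c
    denom = math.comb(M, n)
    kmax = min(K, n)
    total = sum(
        math.comb(K, k) * math.comb(M - K, n - k) for k in range(a, kmax + 1)
    )
    return total / denom if denom else 1.0


class TestFisher:
    def test_enriched_table_matches_enumeration(self):
        p = fisher_one_sided(10, 10, 0, 20)
        assert p == pytest.approx(hypergeom_tail_oracle(10, 10, 0, 20), rel=1e-10)

    def test_depleted_table_has_p_one(self):
        assert fisher_one_sided(0, 20, 10, 10) == pytest.approx(1.0)

    def test_all_zero_table(self):
        assert fisher_one_sided(0, 0, 0, 0) == 1.0

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_one_sided(1.5, 0, 0, 0)

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_enumeration_property(self, table):
        a, b, c, d = table
        assert fisher_one_sided(a, b, c, d) == pytest.approx(
            hypergeom_tail_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )


class TestBH:
    def test_three_increasing_pvalues(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 60)))
            order = np.argsort(p)
            n = len(p)
            stepped = p[order] * n / np.arange(1, n + 1)
            monot = np.minimum.accumulate(stepped[::-1])[::-1]
            expected = np.empty(n)
            expected[order] = np.minimum(monot, 1.0)
            assert np.allclose(bh_adjust(p), expected)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_capped(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_constant_vectors_are_fixed_points(self):
        # re-adjusting changes most vectors, but constants are fixed points
        for c in (0.0, 0.05, 0.3, 1.0):
            assert np.allclose(bh_adjust([c] * 5), [c] * 5)


class TestDifferentialExpression:
    def test_identical_matrices_no_de(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(8, 1, (50, 3)), index=[f"G{i}" for i in range(50)])
        recs = differential_expression(x, x.copy())
        assert all(r.adj_pvalue == 1.0 and r.log_fc == 0.0 for r in recs)

    def test_zero_noise_recovers_truth_exactly(self):
        study = generate_study(SimConfig(seed=5, lfc_noise_sd=0.0))
        recs = differential_expression(study.expr_control, study.expr_knockdown)
        called = {r.gene for r in recs if r.adj_pvalue < 0.05}
        assert called == study.truth.de_true
        by_gene = {r.gene: r for r in recs}
        for g in study.truth.de_true:
            assert abs(by_gene[g].log_fc) == pytest.approx(2.0)

    def test_requires_two_replicates(self):
        x = pd.DataFrame({"r1": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="replicates"):
            differential_expression(x, x)

    def test_requires_matching_genes(self):
        a = pd.DataFrame(np.ones((2, 2)), index=["A", "B"])
        b = pd.DataFrame(np.ones((2, 2)), index=["A", "C"])
        with pytest.raises(ValueError, match="gene"):
            differential_expression(a, b)

    def test_empirical_fdr_controlled(self):
        """BH at 0.05 keeps the realised false discovery fraction near alpha."""
        fdps = []
        for seed in range(20):
            study = generate_study(
                SimConfig(seed=900 + seed, n_genes=300, regulon_size=30)
            )
            recs = differential_expression(study.expr_control, study.expr_knockdown)
            called = {r.gene for r in recs if r.adj_pvalue < 0.05}
            fp = len(called - study.truth.de_true)
            fdps.append(fp / max(len(called), 1))
        assert np.mean(fdps) <= 0.07


class TestClassifyRegulation:
    def _records(self, n_down, n_up):
        mk = lambda g, d: DERecord(g, float(d), 0.001, 0.01, d)
        return [mk(f"D{i}", -1) for i in range(n_down)] + [
            mk(f"U{i}", 1) for i in range(n_up)
        ]

    def test_knockdown_study_fractions(self):
        # 2460 genes down and 1866 up after knocking down the factor
        summary = classify_regulation(self._records(2460, 1866))
        assert summary.fraction_positive_pct == 56.9
        assert summary.fraction_negative_pct == 43.1
        assert len(summary.positively_regulated) == 2460

    def test_all_down(self):
        s = classify_regulation(self._records(10, 0))
        assert (s.fraction_positive_pct, s.fraction_negative_pct) == (100.0, 0.0)

    def test_even_split(self):
        s = classify_regulation(self._records(1, 1))
        assert (s.fraction_positive_pct, s.fraction_negative_pct) == (50.0, 50.0)

    def test_empty_flagged_undefined(self):
        s = classify_regulation([])
        assert not s.defined and s.fraction_positive_pct is None


class TestTFTEnrichment:
    def test_perfect_overlap_exact_p(self):
        universe = {f"G{i}" for i in range(20)}
        reg = Regulon("TF", {f"G{i}": 1 for i in range(5)})
        rec = tft_enrichment({f"G{i}" for i in range(5)}, reg, universe)
        assert rec.pvalue == pytest.approx(1 / math.comb(20, 5), rel=1e-9)
        assert rec.n_support == 5

    def test_zero_overlap_p_one(self):
        universe = {f"G{i}" for i in range(20)}
        reg = Regulon("TF", {"G0": 1, "G1": -1})
        rec = tft_enrichment({"G10", "G11"}, reg, universe)
        assert rec.pvalue == pytest.approx(1.0)

    def test_query_equals_universe_p_one(self):
        universe = {f"G{i}" for i in range(10)}
        reg = Regulon("TF", {"G0": 1, "G1": 1})
        assert tft_enrichment(universe, reg, universe).pvalue == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            tft_enrichment(set(), Regulon("TF", {"G0": 1}), set())

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            tft_enrichment({"X"}, Regulon("TF", {"G0": 1}), {"G0"})


def _de(gene, direction, sig=True):
    return DERecord(gene, 2.0 * direction, 0.001 if sig else 0.9,
                    0.01 if sig else 0.95, direction)


class TestUpstreamRegulator:
    def test_four_consistent_activating_edges_z_two(self):
        # all activating targets go down upon knockdown -> factor-supported
        records = [_de(f"G{i}", -1) for i in range(4)]
        records += [_de(f"N{i}", 1, sig=False) for i in range(20)]
        reg = Regulon("TF", {f"G{i}": 1 for i in range(4)})
        rec = upstream_regulator(records, reg)
        assert rec.z == pytest.approx(2.0)
        assert rec.branch == BRANCH_URA_TX

    def test_balanced_consistency_z_zero(self):
        records = [_de("G0", -1), _de("G1", -1), _de("G2", 1), _de("G3", 1)]
        records += [_de(f"N{i}", 1, sig=False) for i in range(10)]
        reg = Regulon("TF", {g: 1 for g in ("G0", "G1", "G2", "G3")})
        assert upstream_regulator(records, reg).z == pytest.approx(0.0)

    def test_overlap_below_min_gives_no_z_but_p(self):
        records = [_de("G0", -1)] + [_de(f"N{i}", 1, sig=False) for i in range(10)]
        reg = Regulon("TF", {"G0": 1, "X1": 1, "X2": 1, "X3": 1})
        rec = upstream_regulator(records, reg, min_overlap=4)
        assert rec.z is None and 0 < rec.pvalue <= 1

    def test_sign_flip_negates_z_exactly(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(30)]
        records = [_de(g, int(rng.choice([-1, 1]))) for g in genes]
        flipped = [
            DERecord(r.gene, -r.log_fc, r.pvalue, r.adj_pvalue, -r.direction)
            for r in records
        ]
        reg = Regulon("TF", {g: int(rng.choice([-1, 1])) for g in genes[:12]})
        z = upstream_regulator(records, reg).z
        z_flipped = upstream_regulator(flipped, reg).z
        assert z_flipped == pytest.approx(-z)

    def test_planted_regulator_sign_recovered(self):
        hits = 0
        for seed in range(20):
            study = generate_study(SimConfig(seed=200 + seed, n_genes=200,
                                             regulon_size=25))
            recs = differential_expression(study.expr_control, study.expr_knockdown)
            tf = sorted(study.truth.cooperating_tfs)[0]
            rec = upstream_regulator(recs, study.regulons[tf])
            hits += rec.z is not None and rec.z > 0
        assert hits >= 19


class TestMotifEnrichment:
    def test_same_sequences_no_enrichment(self):
        rng = np.random.default_rng(3)
        pssm = random_pssm(rng, 8)
        seqs = [random_sequence(rng, 120) for _ in range(30)]
        rec = motif_enrichment(seqs, list(seqs), pssm)
        assert rec.pvalue > 0.4

    def test_absent_motif_p_one(self):
        pssm = consensus_to_pssm("M", "ACGTACGTAC", pseudocount=0.001)
        fg = ["TTTTTTTTTTTTTTTT"] * 5
        bg = ["TTTTTTTTTTTTTTTT"] * 5
        assert motif_enrichment(fg, bg, pssm).pvalue == pytest.approx(1.0)

    def test_empty_foreground_rejected(self):
        pssm = consensus_to_pssm("M", "ACGT")
        with pytest.raises(ValueError, match="foreground"):
            motif_enrichment([], ["ACGTACGT"], pssm)

    def test_sequence_shorter_than_motif_rejected(self):
        pssm = consensus_to_pssm("M", "ACGTACGT")
        with pytest.raises(ValueError, match="width"):
            motif_enrichment(["ACG"], ["ACGTACGTAA"], pssm)

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(4)
        pssm = random_pssm(rng, 10)
        cons = pssm.consensus
        fg = [cons.join([random_sequence(rng, 50), random_sequence(rng, 50)])
              for _ in range(40)]
        bg = [random_sequence(rng, 110) for _ in range(40)]
        assert motif_enrichment(fg, bg, pssm).pvalue < 1e-6


class TestAdjustRecords:
    def test_adjusts_within_branch_only(self):
        from tfcoop.enrichment import EnrichmentRecord

        recs = [
            EnrichmentRecord("A", BRANCH_TFT_CHIP, 0.01),
            EnrichmentRecord("B", BRANCH_TFT_CHIP, 0.04),
            EnrichmentRecord("A", BRANCH_URA_TX, 0.01),
        ]
        adj = adjust_records(recs)
        assert adj[0].adj_pvalue == pytest.approx(0.02)
        assert adj[1].adj_pvalue == pytest.approx(0.04)
        assert adj[2].adj_pvalue == pytest.approx(0.01)  # alone in its branch
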