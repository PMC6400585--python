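"""Clumping, proxy search, allele harmonisation and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prs_atlas.prs import (
    ScoreDefinition,
    combine_scores,
    compute_score,
    find_proxy,
    harmonize_alleles,
    ld_clump,
    reconcile_alleles,
    standardize_score,
)
from prs_atlas.simulate import SimulationConfig, simulate_genotypes, simulate_two_sample_gwas

from conftest import make_panel, make_stats


class TestLdClump:
    def test_greedy_rule_hand_trace(self, clump_panel):
        # rs1 best by p; rs2 in LD with it is removed; independent rs3 kept
        stats = make_stats([
            {"snp": "rs1", "pval": 1e-10},
            {"snp": "rs2", "pval": 1e-6},
            {"snp": "rs3", "pval": 1e-7},
        ])
        d = ld_clump(stats, clump_panel)
        assert d.snp == ["rs1", "rs3"]

    def test_independent_snps_all_retained(self, orthogonal_panel):
        stats = make_stats([
            {"snp": "rs1", "pval": 1e-6},
            {"snp": "rs2", "pval": 1e-7},
            {"snp": "rs3", "pval": 4e-5},
        ])
        d = ld_clump(stats, orthogonal_panel)
        assert sorted(d.snp) == ["rs1", "rs2", "rs3"]

    def test_subthreshold_snp_excluded(self, orthogonal_panel):
        stats = make_stats([
            {"snp": "rs1", "pval": 1e-6},
            {"snp": "rs2", "pval": 6e-5},
        ])
        assert ld_clump(stats, orthogonal_panel).snp == ["rs1"]

    def test_duplicate_column_keeps_one(self):
        col = [0, 0, 1, 1, 2, 2]
        panel = make_panel({"rs1": col, "rs2": col})
        stats = make_stats([
            {"snp": "rs1", "pval": 1e-8},
            {"snp": "rs2", "pval": 1e-6},
        ])
        d = ld_clump(stats, panel)
        assert d.snp == ["rs1"]

    def test_no_snp_passes_gives_empty_definition(self, orthogonal_panel):
        stats = make_stats([{"snp": "rs1", "pval": 0.5}])
        d = ld_clump(stats, orthogonal_panel)
        assert len(d) == 0 and d.provenance

    def test_order_independence(self, clump_panel):
        rows = [
            {"snp": "rs1", "pval": 1e-10},
            {"snp": "rs2", "pval": 1e-6},
            {"snp": "rs3", "pval": 1e-7},
        ]
        d1 = ld_clump(make_stats(rows), clump_panel)
        d2 = ld_clump(make_stats(rows[::-1]), clump_panel)
        assert d1.snp == d2.snp

    def test_window_limits_ld_pruning(self):
        # same LD but 20 Mb apart: outside the 10 Mb window, both kept
        s1 = [0, 0, 1, 1, 2, 2]
        s2 = [0, 0, 2, 2, 1, 1]
        panel = make_panel({"rs1": s1, "rs2": s2}, pos=[1, 20_000_001])
        stats = make_stats([
            {"snp": "rs1", "pval": 1e-10},
            {"snp": "rs2", "pval": 1e-6},
        ])
        assert ld_clump(stats, panel).snp == ["rs1", "rs2"]

    def test_retained_pairs_below_r2_threshold(self, rng):
        # exhaustive pairwise check on a random panel with real LD blocks
        panel = simulate_genotypes(
            400, 12, seed=31, ld_blocks=[((0, 1, 2), 0.9), ((5, 6), 0.8)]
        )
        stats = make_stats(
            [{"snp": s, "pval": 1e-6} for s in panel.snp_ids]
        )
        d = ld_clump(stats, panel, r2_threshold=0.05)
        for i, a in enumerate(d.snp):
            for b in d.snp[i + 1:]:
                assert panel.r2(a, b) < 0.05


class TestFindProxy:
    def test_exact_duplicate_is_best_proxy(self):
        col = [0, 1, 2, 1, 0, 2]
        panel = make_panel({"rs1": col, "rs2": col, "rs3": [0, 2, 0, 2, 0, 2]})
        hit = find_proxy("rs1", panel)
        assert hit["proxy"] == "rs2" and hit["r2"] == pytest.approx(1.0)
        assert not hit["sign_flip"]

    def test_weak_ld_returns_none(self, clump_panel):
        assert find_proxy("rs3", clump_panel) is None  # best available r2 = 0

    def test_negatively_correlated_proxy_flips_sign(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        panel = make_panel({"rs1": col, "rs2": 2 - col})
        hit = find_proxy("rs1", panel)
        assert hit["proxy"] == "rs2" and hit["sign_flip"]


class TestHarmonizeAlleles:
    def _definition(self, **kw):
        base = dict(
            snp=["rs1"], effect_allele=["A"], other_allele=["G"],
            weight=np.array([0.5]), eaf=[0.3],
        )
        base.update(kw)
        return ScoreDefinition(**base)

    def test_allele_swap_negates_weight(self):
        d = harmonize_alleles(
            self._definition(),
            {"rs1": {"effect": "G", "other": "A"}},
        )
        assert d.weight[0] == pytest.approx(-0.5)
        assert d.effect_allele == ["G"]

    def test_strand_flip_resolved_by_complement(self):
        d = harmonize_alleles(
            self._definition(),  # GWAS A/G == cohort T/C on the other strand
            {"rs1": {"effect": "T", "other": "C"}},
        )
        assert d.weight[0] == pytest.approx(0.5)

    def test_palindromic_ambiguous_frequency_dropped(self):
        d = harmonize_alleles(
            self._definition(effect_allele=["A"], other_allele=["T"], eaf=[0.50]),
            {"rs1": {"effect": "A", "other": "T", "freq": 0.50}},
        )
        assert len(d) == 0
        assert any("ambiguous" in line for line in d.provenance)

    def test_palindromic_low_frequency_retained(self):
        d = harmonize_alleles(
            self._definition(effect_allele=["C"], other_allele=["G"], eaf=[0.10]),
            {"rs1": {"effect": "C", "other": "G", "freq": 0.12}},
        )
        assert d.snp == ["rs1"] and d.weight[0] == pytest.approx(0.5)

    def test_palindromic_frequency_mismatch_flips(self):
        # cohort counts the same letter but its frequency mirrors 1 - EAF:
        # the counted allele is really the GWAS other allele
        d = harmonize_alleles(
            self._definition(effect_allele=["C"], other_allele=["G"], eaf=[0.10]),
            {"rs1": {"effect": "C", "other": "G", "freq": 0.88}},
        )
        assert d.weight[0] == pytest.approx(-0.5)

    def test_irreconcilable_alleles_dropped(self):
        d = harmonize_alleles(
            self._definition(),
            {"rs1": {"effect": "A", "other": "C"}},
        )
        assert len(d) == 0

    def test_reconcile_is_symmetric_for_plain_swap(self):
        assert reconcile_alleles("A", "G", "A", "G")[0] == "keep"
        assert reconcile_alleles("A", "G", "G", "A")[0] == "flip"
        assert reconcile_alleles("A", "G", "T", "C")[0] == "keep"
        assert reconcile_alleles("A", "G", "C", "T")[0] == "flip"


class TestScoring:
    def test_weighted_sum_arithmetic(self):
        panel = make_panel({"rs1": [0], "rs2": [1], "rs3": [2]})
        d = ScoreDefinition(
            snp=["rs1", "rs2", "rs3"], effect_allele=["A"] * 3,
            weight=np.array([0.1, -0.2, 0.3]),
        )
        assert compute_score(panel, d).raw[0] == pytest.approx(0.4)

    def test_zero_weights_zero_scores(self):
        panel = make_panel({"rs1": [0, 1, 2]})
        d = ScoreDefinition(snp=["rs1"], effect_allele=["A"], weight=np.array([0.0]))
        assert np.all(compute_score(panel, d).raw == 0)

    def test_unweighted_score_counts_trait_increasing_alleles(self):
        panel = make_panel({"rs1": [2], "rs2": [1]})
        d = ScoreDefinition(
            snp=["rs1", "rs2"], effect_allele=["A", "A"],
            weight=np.sign(np.array([-0.5, 0.2])), weighted=False,
        )
        assert compute_score(panel, d).raw[0] == pytest.approx(-1.0)

    def test_missing_snp_excluded_and_counted(self):
        panel = make_panel({"rs1": [0, 1]})
        d = ScoreDefinition(
            snp=["rs1", "rs9"], effect_allele=["A", "A"], weight=np.array([1.0, 5.0])
        )
        sv = compute_score(panel, d)
        assert sv.n_snps_used == 1
        assert np.allclose(sv.raw, [0.0, 1.0])

    def test_missing_dosage_mean_imputed(self):
        panel = make_panel({"rs1": [0, 2, np.nan, 2]})
        d = ScoreDefinition(snp=["rs1"], effect_allele=["A"], weight=np.array([1.0]))
        sv = compute_score(panel, d)
        assert sv.raw[2] == pytest.approx(np.nanmean([0, 2, 2]))

    def test_scoring_invariant_to_joint_allele_reflection(self):
        dos = np.array([0.0, 1, 2, 1, 0, 2, 2])
        p1 = make_panel({"rs1": dos})
        p2 = make_panel({"rs1": 2 - dos})
        d_pos = ScoreDefinition(snp=["rs1"], effect_allele=["A"], weight=np.array([0.7]))
        d_neg = ScoreDefinition(snp=["rs1"], effect_allele=["G"], weight=np.array([-0.7]))
        s1 = standardize_score(compute_score(p1, d_pos)).standardized
        s2 = standardize_score(compute_score(p2, d_neg)).standardized
        assert np.allclose(s1, s2)


class TestStandardize:
    def test_simple_case(self):
        sv = standardize_score(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(sv.standardized, [-1.0, 0.0, 1.0])

    def test_moments_are_exact(self, rng):
        sv = standardize_score(rng.normal(3.0, 7.0, size=500))
        assert abs(sv.standardized.mean()) < 1e-10
        assert abs(sv.standardized.std(ddof=1) - 1) < 1e-10

    def test_constant_scores_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_score(np.ones(10))


class TestCombine:
    def test_self_combination_is_identity(self, rng):
        sv = standardize_score(rng.normal(size=200))
        combined = combine_scores([sv, sv])
        assert np.allclose(combined.standardized, sv.standardized)

    def test_opposite_scores_error(self, rng):
        sv = standardize_score(rng.normal(size=100))
        neg = standardize_score(-sv.raw)
        with pytest.raises(ValueError, match="zero variance"):
            combine_scores([sv, neg])

    def test_three_independent_scores_add_variance(self, rng):
        svs = [standardize_score(rng.normal(size=20_000)) for _ in range(3)]
        combined = combine_scores(svs)
        assert combined.raw.std(ddof=1) == pytest.approx(np.sqrt(3), abs=0.05)

    def test_mismatched_individuals_error(self, rng):
        a = standardize_score(rng.normal(size=100))
        b = standardize_score(rng.normal(size=90))
        with pytest.raises(ValueError, match="individual"):
            combine_scores([a, b])


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(-2, 2), min_size=3, max_size=8))
def test_standardization_affine_invariant(weights):
    """Standardised scores are unchanged by affine rescaling of the raw score."""
    raw = np.asarray(weights) * 3.0 + 5.0
    if np.std(raw, ddof=1) == 0:
        return
    a = standardize_score(np.asarray(weights, dtype=float) * 3 + 5)
    b = standardize_score(np.asarray(weights, dtype=float))
    assert np.allclose(a.standardized, b.standardized, atol=1e-9)


def test_relaxed_threshold_recovers_more_heritability():
    """With many sub-significant true effects, the score built at 5e-5 tracks
    the true genetic value at least as well as the one built at 5e-8."""
    rng = np.random.default_rng(77)
    corrs = {5e-08: [], 5e-05: []}
    for rep in range(5):
        cfg = SimulationConfig(
            n_individuals=2000, n_snps=60, n_causal_snps=60,
            heritability_exposure=0.2, seed=int(rng.integers(2**31 - 1)),
        )
        pair = simulate_two_sample_gwas(cfg)
        geno = pair.outcome_sample["genotypes"]
        b = np.array([pair.truth["snp_effects"][s] for s in geno.snp_ids])
        true_genetic = geno.dosages @ b
        for thresh in corrs:
            sel = pair.exposure_stats.significant(thresh)
            if sel.empty:
                corrs[thresh].append(0.0)
                continue
            cols = [geno.index_of(s) for s in sel["snp"]]
            raw = geno.dosages[:, cols] @ sel["beta"].to_numpy()
            if raw.std() == 0:
                corrs[thresh].append(0.0)
                continue
            corrs[thresh].append(np.corrcoef(raw, true_genetic)[0, 1])
    assert np.mean(corrs[5e-05]) >= np.mean(corrs[5e-08]) - 0.03
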