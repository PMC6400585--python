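"""MR estimators against closed forms, hand computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prs_atlas.mr import (
    MrError,
    harmonize_two_sample,
    ivw,
    leave_one_out,
    mr_egger,
    steiger_filter,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from prs_atlas.simulate import SimulationConfig, simulate_two_sample_gwas

from conftest import make_instruments, make_stats


def wls_through_origin(g, G, w):
    """Independent oracle: explicit weighted least squares via lstsq."""
    sw = np.sqrt(w)
    sol, *_ = np.linalg.lstsq((sw * g)[:, None], sw * G, rcond=None)
    return sol[0]


def weighted_median_scan_oracle(ratios, weights):
    """Brute-force oracle: explicit cumulative-weight scan with pure-Python
    loops, interpolating where the midpoint cumulative weight crosses 1/2."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    mids = []
    for _, w in pairs:
        mids.append((cum + w / 2) / total)
        cum += w
    if mids[0] >= 0.5:
        return pairs[0][0]
    if mids[-1] <= 0.5:
        return pairs[-1][0]
    for k in range(1, len(pairs)):
        if mids[k] >= 0.5:
            b_lo, b_hi = pairs[k - 1][0], pairs[k][0]
            frac = (0.5 - mids[k - 1]) / (mids[k] - mids[k - 1])
            return b_lo + frac * (b_hi - b_lo)
    raise AssertionError("unreachable")




class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.4, 0.05, 0.2, 0.05)
        assert est.estimate == pytest.approx(0.5)
        assert est.se == pytest.approx(0.125)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.4, 0.05, 0.0, 0.05).estimate == 0.0

    def test_orientation_invariance(self):
        a = wald_ratio(0.4, 0.05, 0.2, 0.05)
        b = wald_ratio(-0.4, 0.05, -0.2, 0.05)
        assert a.estimate == b.estimate and a.se == b.se

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(MrError):
            wald_ratio(0.0, 0.05, 0.2, 0.05)


class TestIvw:
    def test_exact_proportional_case(self):
        instr = make_instruments([0.4, 0.2], [0.01, 0.01], [0.2, 0.1], [0.1, 0.1])
        est = ivw(instr)
        assert est.estimate == pytest.approx(0.5)
        assert est.se == pytest.approx(np.sqrt(1 / 20))  # Q = 0, no inflation
        assert est.q == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_q(self):
        # ratios 0.5 and 0.3 with ratio weights 16 and 4:
        # estimate 0.46, Q = 16 (0.04)^2 + 4 (0.16)^2 = 0.128
        instr = make_instruments(
            [0.4, 0.2], [0.01, 0.01], [0.2, 0.06], [0.1, 0.1]
        )
        est = ivw(instr)
        assert instr.ratio_weights == pytest.approx([16.0, 4.0])
        assert est.estimate == pytest.approx(0.46)
        assert est.q == pytest.approx(0.128)

    def test_duplicated_pair_reduces_to_wald_ratio(self):
        instr = make_instruments([0.3] * 5, [0.01] * 5, [0.12] * 5, [0.05] * 5)
        est = ivw(instr)
        assert est.estimate == pytest.approx(0.4)
        assert est.q == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_equals_wls_oracle(self, rng):
        for _ in range(50):
            J = rng.integers(2, 20)
            g = rng.normal(0.2, 0.1, J)
            G = rng.normal(0.05, 0.1, J)
            seG = rng.uniform(0.01, 0.2, J)
            instr = make_instruments(g, np.full(J, 0.01), G, seG)
            assert ivw(instr).estimate == pytest.approx(
                wls_through_origin(g, G, 1 / seG**2), abs=1e-10
            )

    def test_single_snp_directs_to_wald(self):
        instr = make_instruments([0.4], [0.01], [0.2], [0.1])
        with pytest.raises(MrError, match="wald"):
            ivw(instr)

    def test_type_one_error_calibrated(self):
        # beta = 0, no pleiotropy: fixed-effect IVW rejects at ~5%.  (The
        # random-effects variant only ever inflates the SE, so its rate is
        # bounded by this one; the full-scale band is asserted in the
        # acceptance suite at the study's n and m.)
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            pair = simulate_two_sample_gwas(
                SimulationConfig(n_individuals=2500, seed=int(rng.integers(2**31 - 1)))
            )
            instr = harmonize_two_sample(pair.exposure_stats, pair.outcome_stats)
            if len(instr) < 2:
                continue
            rejections += ivw(instr, model="fixed").p < 0.05
        assert 0.025 <= rejections / reps <= 0.075


class TestEgger:
    def test_exact_linear_case(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        G = 0.1 + 0.5 * g
        instr = make_instruments(g, [0.01] * 4, G, [0.05] * 4)
        est = mr_egger(instr)
        assert est.intercept == pytest.approx(0.1, abs=1e-12)
        assert est.estimate == pytest.approx(0.5, abs=1e-12)

    def test_needs_three_snps(self):
        with pytest.raises(MrError):
            mr_egger(make_instruments([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.05] * 2))

    def test_intercept_recovers_directional_pleiotropy(self):
        # all SNPs pleiotropic with mean direct effect 0.05, no causal effect:
        # the Egger intercept estimates that mean
        rng = np.random.default_rng(42)
        intercepts = []
        for _ in range(80):
            pair = simulate_two_sample_gwas(
                SimulationConfig(
                    n_individuals=10_000, seed=int(rng.integers(2**31 - 1)),
                    pleiotropy_fraction=1.0, pleiotropy_mean=0.05, pleiotropy_sd=0.01,
                )
            )
            instr = harmonize_two_sample(pair.exposure_stats, pair.outcome_stats)
            if len(instr) >= 3:
                intercepts.append(mr_egger(instr).intercept)
        intercepts = np.array(intercepts)
        mc_se = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(intercepts.mean() - 0.05) < 3 * mc_se

    def test_no_pleiotropy_intercept_near_zero(self):
        rng = np.random.default_rng(43)
        intercepts = []
        for _ in range(80):
            pair = simulate_two_sample_gwas(
                SimulationConfig(n_individuals=5000, seed=int(rng.integers(2**31 - 1)),
                                 causal_effect=0.3)
            )
            instr = harmonize_two_sample(pair.exposure_stats, pair.outcome_stats)
            if len(instr) >= 3:
                intercepts.append(mr_egger(instr).intercept)
        intercepts = np.array(intercepts)
        mc_se = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(intercepts.mean()) < 3 * mc_se


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        instr = make_instruments(
            [1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3
        )
        est = weighted_median(instr, n_boot=200, seed=1)
        assert est.estimate == pytest.approx(0.2)

    def test_identical_ratios(self):
        instr = make_instruments([0.2] * 4, [0.01] * 4, [0.1] * 4, [0.05] * 4)
        est = weighted_median(instr, n_boot=200, seed=1)
        assert est.estimate == pytest.approx(0.5)
        assert est.se < 0.3

    def test_majority_valid_instruments_dominate(self):
        # 10 valid instruments at ratio 0.5 with large weights, 4 invalid at
        # 2.0 with small weights
        g = np.r_[np.full(10, 0.5), np.full(4, 0.1)]
        G = np.r_[np.full(10, 0.25), np.full(4, 0.2)]
        seG = np.full(14, 0.05)
        instr = make_instruments(g, np.full(14, 0.01), G, seG)
        est = weighted_median(instr, n_boot=200, seed=1)
        oracle = weighted_median_scan_oracle(instr.ratios, instr.ratio_weights)
        assert est.estimate == pytest.approx(0.5, abs=0.01)
        assert est.estimate == pytest.approx(oracle, abs=1e-12)

    def test_matches_scan_oracle_on_random_instances(self, rng):
        for _ in range(200):
            J = int(rng.integers(3, 12))
            instr = make_instruments(
                rng.uniform(0.1, 0.5, J), np.full(J, 0.01),
                rng.normal(0.1, 0.2, J), rng.uniform(0.02, 0.2, J),
            )
            est = weighted_median(instr, n_boot=2, seed=0)
            oracle = weighted_median_scan_oracle(instr.ratios, instr.ratio_weights)
            assert est.estimate == pytest.approx(oracle, abs=1e-12)
            assert instr.ratios.min() <= est.estimate <= instr.ratios.max()


class TestWeightedMode:
    def test_identical_ratios_zero_bandwidth(self):
        instr = make_instruments([0.2] * 3, [0.01] * 3, [0.08] * 3, [0.05] * 3)
        est = weighted_mode(instr, n_boot=10, seed=0)
        assert est.estimate == pytest.approx(0.4)
        assert est.se == 0.0

    def test_majority_cluster_wins(self):
        g = np.r_[np.full(8, 0.5), np.full(3, 0.1)]
        G = np.r_[np.full(8, 0.25) + np.linspace(-0.002, 0.002, 8), np.full(3, 0.2)]
        instr = make_instruments(g, np.full(11, 0.01), G, np.full(11, 0.05))
        est = weighted_mode(instr, n_boot=50, seed=0)
        assert est.estimate == pytest.approx(0.5, abs=0.05)

    def test_permutation_invariance(self, rng):
        J = 9
        g = rng.uniform(0.2, 0.5, J)
        G = rng.normal(0.15, 0.05, J)
        seG = rng.uniform(0.02, 0.1, J)
        instr = make_instruments(g, np.full(J, 0.01), G, seG)
        perm = rng.permutation(J)
        instr_p = make_instruments(g[perm], np.full(J, 0.01), G[perm], seG[perm])
        a = weighted_mode(instr, n_boot=2, seed=0).estimate
        b = weighted_mode(instr_p, n_boot=2, seed=0).estimate
        assert a == pytest.approx(b, abs=1e-12)


class TestJointSignFlip:
    def test_all_estimators_invariant(self, rng):
        J = 8
        g = rng.uniform(0.1, 0.5, J)
        G = 0.4 * g + rng.normal(0, 0.02, J)
        seG = rng.uniform(0.02, 0.1, J)
        flip = np.where(rng.random(J) < 0.5, -1.0, 1.0)
        a = make_instruments(g, np.full(J, 0.01), G, seG)
        b = make_instruments(g * flip, np.full(J, 0.01), G * flip, seG)
        assert ivw(a).estimate == pytest.approx(ivw(b).estimate, abs=1e-12)
        assert mr_egger(a).estimate == pytest.approx(mr_egger(b).estimate, abs=1e-12)
        assert weighted_median(a, n_boot=2, seed=0).estimate == pytest.approx(
            weighted_median(b, n_boot=2, seed=0).estimate, abs=1e-12
        )
        assert weighted_mode(a, n_boot=2, seed=0).estimate == pytest.approx(
            weighted_mode(b, n_boot=2, seed=0).estimate, abs=1e-12
        )


class TestSingleSnpReduction:
    def test_median_and_mode_fall_back_to_wald(self):
        instr = make_instruments([0.4], [0.01], [0.2], [0.1])
        wald = wald_ratio(0.4, 0.01, 0.2, 0.1)
        med = weighted_median(instr, strict=False)
        mode = weighted_mode(instr, strict=False)
        assert med.estimate == wald.estimate == mode.estimate


class TestSteiger:
    def test_directional_verdicts(self):
        # SNP 1 explains more variance in the exposure, SNP 2 in the outcome
        instr = make_instruments(
            [0.30, 0.02], [0.01, 0.01], [0.02, 0.30], [0.01, 0.01],
            n_exposure=10_000, n_outcome=10_000,
        )
        filtered, verdicts = steiger_filter(instr)
        assert list(verdicts["retained"]) == [True, False]
        assert list(filtered.snp) == ["rs1"]

    def test_missing_sample_size_rejected(self):
        instr = make_instruments([0.3], [0.01], [0.1], [0.01],
                                 n_exposure=None, n_outcome=None)
        with pytest.raises(MrError, match="sample sizes"):
            steiger_filter(instr)

    def test_true_direction_retains_most_instruments(self):
        pair = simulate_two_sample_gwas(
            SimulationConfig(n_individuals=50_000, causal_effect=0.3, seed=44)
        )
        instr = harmonize_two_sample(pair.exposure_stats, pair.outcome_stats)
        filtered, verdicts = steiger_filter(instr)
        assert verdicts["retained"].mean() >= 0.9


class TestLeaveOneOut:
    def test_identical_ratios_all_equal(self):
        instr = make_instruments([0.3] * 5, [0.01] * 5, [0.15] * 5, [0.05] * 5)
        table = leave_one_out(instr)
        assert len(table) == 5
        assert np.allclose(table["estimate"], 0.5)
        assert not table["sign_change"].any()

    def test_dominant_outlier_flagged(self):
        # four tight null instruments plus one extreme precise outlier that
        # single-handedly drives the IVW p below 0.05
        g = np.array([0.2, 0.2, 0.2, 0.2, 0.4])
        G = np.array([0.001, -0.001, 0.002, -0.002, 0.4])
        seG = np.array([0.05, 0.05, 0.05, 0.05, 0.01])
        instr = make_instruments(g, np.full(5, 0.01), G, seG)
        table = leave_one_out(instr)
        assert table.loc[table["snp"] == "rs5", "p_crosses_alpha"].item()


class TestHarmonizeTwoSample:
    def test_swapped_outcome_alleles_flip_sign(self):
        expo = make_stats([{"snp": "rs1", "beta": 0.3, "pval": 1e-10},
                           {"snp": "rs2", "beta": 0.2, "pval": 1e-9}])
        outc = make_stats([
            {"snp": "rs1", "beta": 0.15, "pval": 1e-4,
             "effect_allele": "G", "other_allele": "A", "eaf": 0.7},
            {"snp": "rs2", "beta": 0.1, "pval": 1e-4},
        ], trait="outcome")
        instr = harmonize_two_sample(expo, outc)
        by = dict(zip(instr.snp, instr.beta_outcome))
        assert by["rs1"] == pytest.approx(-0.15)
        assert by["rs2"] == pytest.approx(0.1)

    def test_subthreshold_exposure_snp_excluded(self):
        expo = make_stats([{"snp": "rs1", "pval": 1e-10}, {"snp": "rs2", "pval": 1e-6}])
        outc = make_stats([{"snp": "rs1"}, {"snp": "rs2"}], trait="outcome")
        instr = harmonize_two_sample(expo, outc)
        assert list(instr.snp) == ["rs1"]

    def test_missing_outcome_snps_logged(self):
        expo = make_stats([{"snp": f"rs{i}", "pval": 1e-10} for i in range(1, 11)])
        outc = make_stats([{"snp": f"rs{i}"} for i in range(1, 9)], trait="outcome")
        instr = harmonize_two_sample(expo, outc)
        assert len(instr) == 8
        assert len(instr.dropped) == 2

    def test_no_instruments_is_an_error(self):
        expo = make_stats([{"snp": "rs1", "pval": 0.5}])
        outc = make_stats([{"snp": "rs1"}], trait="outcome")
        with pytest.raises(MrError, match="no instruments"):
            harmonize_two_sample(expo, outc)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(2, 15), st.integers(0, 10_000))
def test_ivw_matches_wls_property(J, seed):
    """IVW closed form equals an explicit weighted least-squares solve."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.05, 0.5, J) * np.where(rng.random(J) < 0.5, -1, 1)
    G = rng.normal(0.0, 0.2, J)
    seG = rng.uniform(0.01, 0.3, J)
    instr = make_instruments(g, np.full(J, 0.01), G, seG)
    assert ivw(instr).estimate == pytest.approx(
        wls_through_origin(g, G, 1 / seG**2), abs=1e-10
    )
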