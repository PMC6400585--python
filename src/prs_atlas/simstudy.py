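"""Power and false-positive comparison of the PRS test against IVW MR.

Replicated two-sample simulations under a causal model (the exposure affects
the outcome) and a null model (no causal effect), across a grid of
horizontal-pleiotropy levels.  The PRS arm builds a score from the discovery
(exposure) GWAS at a lenient threshold (5e-5) and tests the outcome on the
score in the disjoint outcome sample; the MR arm runs IVW on instruments at
the genome-wide threshold (5e-8).  The MR-Egger intercept test can be
tracked alongside as the pleiotropy detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mr import MrError, harmonize_two_sample, ivw, mr_egger, wald_ratio
from .prs import ld_clump, standardize_score
from .simulate import SimulationConfig, TwoSampleGwasPair, simulate_two_sample_gwas

__all__ = ["PrsTestResult", "prs_causal_test", "ivw_causal_test", "run_comparison"]


@dataclass
class PrsTestResult:
    p: float
    estimate: float
    se: float
    n_snps: int
    flagged: bool = False  # True when no SNP passed the threshold (p forced to 1)


def prs_causal_test(
    pair: TwoSampleGwasPair,
    p_threshold: float = 5e-05,
    panel=None,
) -> PrsTestResult:
    """Score-based causal test in the two-sample design.

    Weights come from the discovery (exposure) GWAS at ``p_threshold``
    (clumped against ``panel`` when given; the simulated SNPs are
    LD-independent so the default skips clumping); the outcome is regressed
    on the standardised score in the disjoint outcome sample.
    """
    if pair.outcome_sample is None:
        raise ValueError("pair carries no individual-level outcome sample")
    genotypes = pair.outcome_sample["genotypes"]
    y = np.asarray(pair.outcome_sample["outcome"], dtype=float)
    if panel is not None:
        definition = ld_clump(pair.exposure_stats, panel, p_threshold=p_threshold)
        sel = definition.to_frame()[["snp", "weight"]]
        snps, weights = sel["snp"].to_numpy(), sel["weight"].to_numpy()
    else:
        sel = pair.exposure_stats.significant(p_threshold)
        snps, weights = sel["snp"].to_numpy(), sel["beta"].to_numpy()
    if len(snps) == 0:
        return PrsTestResult(p=1.0, estimate=np.nan, se=np.nan, n_snps=0, flagged=True)
    cols = [genotypes.index_of(s) for s in snps]
    raw = genotypes.dosages[:, cols] @ weights
    if raw.std(ddof=1) == 0:
        return PrsTestResult(p=1.0, estimate=np.nan, se=np.nan, n_snps=len(snps), flagged=True)
    score = standardize_score(raw).standardized
    # closed-form simple regression of outcome on the standardised score
    n = len(y)
    sc = score - score.mean()
    yc = y - y.mean()
    sxx = float(sc @ sc)
    beta = float(sc @ yc) / sxx
    rss = float(yc @ yc) - beta * float(sc @ yc)
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta / se
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return PrsTestResult(p=p, estimate=beta, se=float(se), n_snps=len(snps))


def ivw_causal_test(
    pair: TwoSampleGwasPair, instrument_p: float = 5e-08, panel=None,
    model: str = "fixed",
) -> dict:
    """IVW (falling back to the Wald ratio for a single instrument) on the pair.

    The comparison uses the plain fixed-effect IVW — the estimator whose
    power the score-based test is measured against — by default.  Returns a
    dict with ``p``, ``estimate``, ``n_snps`` and, when at least three
    instruments are available, the Egger intercept p-value.
    """
    try:
        instr = harmonize_two_sample(
            pair.exposure_stats, pair.outcome_stats,
            panel=panel, instrument_p=instrument_p,
        )
    except MrError:
        return {"p": 1.0, "estimate": np.nan, "n_snps": 0,
                "egger_intercept_p": np.nan, "flagged": True}
    if len(instr) == 1:
        est = wald_ratio(
            instr.beta_exposure[0], instr.se_exposure[0],
            instr.beta_outcome[0], instr.se_outcome[0],
        )
        egger_p = np.nan
    else:
        est = ivw(instr, model=model)
        egger_p = mr_egger(instr).intercept_p if len(instr) >= 3 else np.nan
    return {"p": est.p, "estimate": est.estimate, "n_snps": len(instr),
            "egger_intercept_p": egger_p, "flagged": False}


def run_comparison(
    pleiotropy_levels=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    models=("causal", "null"),
    reps: int = 1000,
    n: int = 10_000,
    m: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    causal_effect: float = 0.3,
    directional: bool = True,
    pleiotropy_mean: float = 0.05,
    pleiotropy_sd: float = 0.05,
    heritability_exposure: float = 0.3,
    p_threshold_prs: float = 5e-05,
    instrument_p: float = 5e-08,
    include_egger: bool = True,
) -> pd.DataFrame:
    """Rejection rates per model x pleiotropy level x method.

    Each cell replicates ``reps`` two-sample simulations of ``n`` individuals
    per sample and ``m`` SNPs.  Directional pleiotropy draws the direct SNP
    effects Normal(``pleiotropy_mean``, ``pleiotropy_sd``); balanced
    pleiotropy sets the mean to zero.  Rates come with the binomial
    Monte-Carlo standard error sqrt(r (1 - r) / reps); replicate failures are
    recorded and the rate uses completed replicates only.
    """
    if not pleiotropy_levels:
        raise ValueError("pleiotropy grid is empty")
    rng = np.random.default_rng(seed)
    mean = pleiotropy_mean if directional else 0.0
    rows = []
    for model in models:
        beta = causal_effect if model == "causal" else 0.0
        for frac in pleiotropy_levels:
            rejected = {"PRS": 0, "IVW": 0, "EGGER_INTERCEPT": 0}
            completed = {"PRS": 0, "IVW": 0, "EGGER_INTERCEPT": 0}
            failures = 0
            for _ in range(reps):
                cfg = SimulationConfig(
                    n_individuals=n, n_snps=m, causal_effect=beta,
                    n_causal_snps=m, pleiotropy_fraction=frac,
                    pleiotropy_mean=mean, pleiotropy_sd=pleiotropy_sd,
                    heritability_exposure=heritability_exposure,
                    seed=int(rng.integers(2**31 - 1)),
                )
                try:
                    pair = simulate_two_sample_gwas(cfg)
                    prs_res = prs_causal_test(pair, p_threshold=p_threshold_prs)
                    ivw_res = ivw_causal_test(pair, instrument_p=instrument_p)
                except Exception:  # noqa: BLE001 - replicate failure is data
                    failures += 1
                    continue
                completed["PRS"] += 1
                completed["IVW"] += 1
                rejected["PRS"] += prs_res.p < alpha
                rejected["IVW"] += ivw_res["p"] < alpha
                if include_egger and np.isfinite(ivw_res["egger_intercept_p"]):
                    completed["EGGER_INTERCEPT"] += 1
                    rejected["EGGER_INTERCEPT"] += ivw_res["egger_intercept_p"] < alpha
            methods = ["PRS", "IVW"] + (["EGGER_INTERCEPT"] if include_egger else [])
            for method in methods:
                c = completed[method]
                rate = rejected[method] / c if c else np.nan
                rows.append(
                    {
                        "model": model,
                        "pleiotropy_fraction": frac,
                        "directional": directional,
                        "method": method,
                        "rate": rate,
                        "n_reps": c,
                        "mc_se": np.sqrt(rate * (1 - rate) / c) if c else np.nan,
                        "failures": failures,
                    }
                )
    return pd.DataFrame(rows)
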