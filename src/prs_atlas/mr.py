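"""Two-sample summary-data Mendelian randomization estimators.

Instruments are genome-wide-significant exposure SNPs (p < 5e-8 by default)
harmonised so that exposure effect gamma_j and outcome effect Gamma_j refer
to the same allele.  The estimators operate on the per-SNP Wald ratios
Gamma_j / gamma_j:

* IVW — weighted regression of Gamma on gamma through the origin, weights
  1/se_Gamma^2; multiplicative random effects by default.
* Cochran's Q — heterogeneity of the ratios about the IVW estimate.
* MR-Egger — same regression with a free intercept (directional-pleiotropy
  term), SNPs oriented so gamma_j >= 0.
* Weighted median / weighted mode — pleiotropy-robust estimators with
  parametric-bootstrap standard errors.
* Steiger directionality filtering and leave-one-out sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GwasSummaryStats
from .prs import ld_clump, reconcile_alleles

logger = logging.getLogger(__name__)


class MrError(ValueError):
    """Raised when an MR analysis cannot run (e.g. no instruments)."""


@dataclass
class InstrumentSet:
    """Harmonised exposure/outcome effect pairs for a set of instruments."""

    snp: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    p_exposure: np.ndarray | None = None
    n_exposure: int | None = None
    n_outcome: int | None = None
    effect_allele: np.ndarray | None = None
    dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if len(self.snp) == 0:
            raise MrError("no instruments")
        if (self.se_exposure <= 0).any() or (self.se_outcome <= 0).any():
            raise ValueError("instrument standard errors must be positive")

    def __len__(self) -> int:
        return len(self.snp)

    def subset(self, mask) -> "InstrumentSet":
        mask = np.asarray(mask)
        return InstrumentSet(
            self.snp[mask],
            self.beta_exposure[mask],
            self.se_exposure[mask],
            self.beta_outcome[mask],
            self.se_outcome[mask],
            None if self.p_exposure is None else self.p_exposure[mask],
            self.n_exposure,
            self.n_outcome,
            None if self.effect_allele is None else self.effect_allele[mask],
            list(self.dropped),
        )

    @property
    def ratios(self) -> np.ndarray:
        return self.beta_outcome / self.beta_exposure

    @property
    def ratio_weights(self) -> np.ndarray:
        """First-order inverse-variance weights of the Wald ratios."""
        return self.beta_exposure**2 / self.se_outcome**2


@dataclass
class MrEstimate:
    method: str
    estimate: float
    se: float
    p: float
    n_snps: int
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


def harmonize_two_sample(
    exposure: GwasSummaryStats,
    outcome: GwasSummaryStats,
    panel=None,
    instrument_p: float = 5e-08,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> InstrumentSet:
    """Select, clump and harmonise instruments across the two studies.

    The exposure is clumped at ``instrument_p`` against ``panel``; with
    ``panel=None`` SNPs are assumed LD-independent and only the p-value
    filter applies.  Outcome effects are aligned to the exposure's effect
    allele (sign flips for swaps, complementing for strand flips, palindromic
    SNPs with ambiguous frequency dropped); SNPs missing from the outcome are
    dropped and logged.
    """
    if panel is not None:
        definition = ld_clump(
            exposure, panel, p_threshold=instrument_p,
            r2_threshold=r2_threshold, window_kb=window_kb,
        )
        exp_rows = exposure.table[exposure.table["snp"].isin(definition.snp)]
    else:
        exp_rows = exposure.significant(instrument_p)
    if exp_rows.empty:
        raise MrError("no instruments")
    out = outcome.table.set_index("snp")

    keep, dropped = [], []
    for _, row in exp_rows.iterrows():
        s = row["snp"]
        if s not in out.index:
            dropped.append(f"{s}: absent from outcome study")
            continue
        o = out.loc[s]
        action, reason = reconcile_alleles(
            row["effect_allele"], row["other_allele"],
            o["effect_allele"], o["other_allele"],
            eaf_a=row["eaf"], eaf_b=o["eaf"],
        )
        if action == "drop":
            dropped.append(f"{s}: {reason}")
            continue
        sign = -1.0 if action == "flip" else 1.0
        keep.append(
            (s, row["beta"], row["se"], sign * o["beta"], o["se"],
             row["pval"], row["effect_allele"])
        )
    for msg in dropped:
        logger.info("harmonisation dropped %s", msg)
    if not keep:
        raise MrError("no instruments")
    snp, be, see, bo, seo, pe, ea = map(np.array, zip(*keep))
    return InstrumentSet(
        snp=snp,
        beta_exposure=be.astype(float),
        se_exposure=see.astype(float),
        beta_outcome=bo.astype(float),
        se_outcome=seo.astype(float),
        p_exposure=pe.astype(float),
        n_exposure=int(exposure.table["n"].median()),
        n_outcome=int(outcome.table["n"].median()),
        effect_allele=ea,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
) -> MrEstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order SE."""
    if beta_exposure == 0:
        raise MrError("Wald ratio undefined for zero exposure effect")
    est = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    z = est / se
    return MrEstimate(
        method="wald_ratio", estimate=float(est), se=float(se),
        p=float(2 * sps.norm.sf(abs(z))), n_snps=1,
    )


def ivw(instr: InstrumentSet, model: str = "random") -> MrEstimate:
    """Inverse-variance-weighted estimate with Cochran's Q.

    Estimate = sum(gamma Gamma / se_Gamma^2) / sum(gamma^2 / se_Gamma^2);
    fixed-effect SE = sqrt(1 / sum(gamma^2 / se_Gamma^2)); the default
    multiplicative random-effects SE inflates it by max(1, sqrt(Q/(J-1))).
    """
    if model not in {"fixed", "random"}:
        raise ValueError("model must be 'fixed' or 'random'")
    J = len(instr)
    if J < 2:
        raise MrError("IVW needs >= 2 SNPs; use wald_ratio for a single instrument")
    g, G, seG = instr.beta_exposure, instr.beta_outcome, instr.se_outcome
    sum_w_g2 = float(np.sum(g**2 / seG**2))
    est = float(np.sum(g * G / seG**2)) / sum_w_g2
    se_fixed = np.sqrt(1.0 / sum_w_g2)
    w = instr.ratio_weights
    q = float(np.sum(w * (instr.ratios - est) ** 2))
    q_df = J - 1
    q_p = float(sps.chi2.sf(q, q_df))
    se = se_fixed * max(1.0, np.sqrt(q / q_df)) if model == "random" else se_fixed
    z = est / se
    return MrEstimate(
        method=f"ivw_{model}", estimate=est, se=float(se),
        p=float(2 * sps.norm.sf(abs(z))), n_snps=J,
        q=q, q_df=q_df, q_p=q_p,
    )


def mr_egger(instr: InstrumentSet) -> MrEstimate:
    """MR-Egger regression: slope is the causal estimate, the intercept the
    average directional pleiotropic effect.

    SNPs are oriented so every gamma_j >= 0 (negating gamma and Gamma
    jointly), then Gamma is regressed on gamma with an intercept, weights
    1/se_Gamma^2.  Standard errors carry a multiplicative residual inflation
    of max(1, residual scale); p-values use a t distribution with J-2 df.
    """
    J = len(instr)
    if J < 3:
        raise MrError("MR-Egger needs >= 3 SNPs")
    flip = np.sign(instr.beta_exposure)
    flip[flip == 0] = 1.0
    g = instr.beta_exposure * flip
    G = instr.beta_outcome * flip
    w = 1.0 / instr.se_outcome**2
    X = np.column_stack([np.ones(J), g])
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ G)
    resid = G - X @ coef
    sigma = np.sqrt(float(resid @ (w * resid)) / (J - 2))
    inflation = max(1.0, sigma)
    ses = np.sqrt(np.diag(xtwx_inv)) * inflation
    t_int, t_slope = coef[0] / ses[0], coef[1] / ses[1]
    df = J - 2
    return MrEstimate(
        method="mr_egger", estimate=float(coef[1]), se=float(ses[1]),
        p=float(2 * sps.t.sf(abs(t_slope), df)), n_snps=J,
        intercept=float(coef[0]), intercept_se=float(ses[0]),
        intercept_p=float(2 * sps.t.sf(abs(t_int), df)),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: the point where the normalised cumulative
    weight (evaluated at segment midpoints) crosses one half."""
    order = np.argsort(ratios, kind="mergesort")
    b = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(b[0])
    if s[-1] <= 0.5:
        return float(b[-1])
    hi = int(np.searchsorted(s, 0.5))
    lo = hi - 1
    frac = (0.5 - s[lo]) / (s[hi] - s[lo])
    return float(b[lo] + frac * (b[hi] - b[lo]))


def _bootstrap_se(instr: InstrumentSet, point_fn, n_boot: int, seed) -> float:
    rng = np.random.default_rng(seed)
    J = len(instr)
    ests = np.empty(n_boot)
    for i in range(n_boot):
        g = rng.normal(instr.beta_exposure, instr.se_exposure)
        G = rng.normal(instr.beta_outcome, instr.se_outcome)
        ok = g != 0
        ests[i] = point_fn(G[ok] / g[ok], g[ok] ** 2 / instr.se_outcome[ok] ** 2)
    return float(ests.std(ddof=1))


def weighted_median(
    instr: InstrumentSet, n_boot: int = 1000, seed: int = 0, strict: bool = True
) -> MrEstimate:
    """Weighted median of the Wald ratios with parametric-bootstrap SE.

    Consistent when instruments carrying at least half the weight are valid.
    With ``strict=False`` a single instrument falls back to the Wald ratio.
    """
    J = len(instr)
    if J < 3:
        if not strict and J >= 1:
            return _few_snp_fallback(instr, "weighted_median")
        raise MrError("weighted median needs >= 3 SNPs")
    est = _weighted_median(instr.ratios, instr.ratio_weights)
    se = _bootstrap_se(instr, _weighted_median, n_boot, seed)
    se = max(se, 1e-12)
    z = est / se
    return MrEstimate(
        method="weighted_median", estimate=est, se=se,
        p=float(2 * sps.norm.sf(abs(z))), n_snps=J,
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = ratios.std(ddof=1) if len(ratios) > 1 else 0.0
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0) -> float:
    h = _mode_bandwidth(ratios, phi)
    if h == 0:
        return float(ratios[0])  # all ratios identical
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    instr: InstrumentSet,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    strict: bool = True,
) -> MrEstimate:
    """Weighted modal estimate: argmax of a weighted Gaussian kernel density
    over the Wald ratios, bandwidth 0.9 min(sd, IQR/1.349) J^(-1/5) scaled by
    ``phi``, evaluated on a 512-point grid spanning the ratios +/- 3h.
    """
    J = len(instr)
    if J < 3:
        if not strict and J >= 1:
            return _few_snp_fallback(instr, "weighted_mode")
        raise MrError("weighted mode needs >= 3 SNPs")
    est = _weighted_mode(instr.ratios, instr.ratio_weights, phi)
    if _mode_bandwidth(instr.ratios, phi) == 0:
        return MrEstimate("weighted_mode", est, 0.0, 0.0 if est != 0 else 1.0, J)
    se = _bootstrap_se(
        instr, lambda r, w: _weighted_mode(r, w, phi), n_boot, seed
    )
    se = max(se, 1e-12)
    z = est / se
    return MrEstimate(
        method="weighted_mode", estimate=est, se=se,
        p=float(2 * sps.norm.sf(abs(z))), n_snps=J,
    )


def _few_snp_fallback(instr: InstrumentSet, method: str) -> MrEstimate:
    """With one or two SNPs, median and mode reduce to the (weighted) ratio."""
    if len(instr) == 1:
        est = wald_ratio(
            instr.beta_exposure[0], instr.se_exposure[0],
            instr.beta_outcome[0], instr.se_outcome[0],
        )
    else:
        est = ivw(instr)
    est.method = f"{method}_fallback_{est.method}"
    return est


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------


def steiger_filter(
    instr: InstrumentSet,
    n_exposure: int | None = None,
    n_outcome: int | None = None,
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Drop instruments explaining more variance in the outcome than the exposure.

    Per SNP the variance explained is recovered from the t statistic,
    r^2 = t^2 / (t^2 + n - 2); the SNP is retained iff r^2 on the exposure
    exceeds r^2 on the outcome.  Returns the filtered set and per-SNP
    verdicts.
    """
    n_exp = n_exposure if n_exposure is not None else instr.n_exposure
    n_out = n_outcome if n_outcome is not None else instr.n_outcome
    if not n_exp or not n_out:
        raise MrError(f"sample sizes required for Steiger filtering of {list(instr.snp)}")
    t_exp = instr.beta_exposure / instr.se_exposure
    t_out = instr.beta_outcome / instr.se_outcome
    r2_exp = t_exp**2 / (t_exp**2 + n_exp - 2)
    r2_out = t_out**2 / (t_out**2 + n_out - 2)
    keep = r2_exp > r2_out
    verdicts = pd.DataFrame(
        {"snp": instr.snp, "r2_exposure": r2_exp, "r2_outcome": r2_out, "retained": keep}
    )
    if not keep.any():
        raise MrError("Steiger filtering removed every instrument")
    return instr.subset(keep), verdicts


def leave_one_out(instr: InstrumentSet, alpha: float = 0.05) -> pd.DataFrame:
    """Re-estimate IVW leaving each SNP out in turn.

    Flags SNPs whose removal changes the estimate's sign or moves the IVW p
    across ``alpha``.
    """
    J = len(instr)
    if J < 3:
        raise MrError("leave-one-out needs >= 3 SNPs")
    full = ivw(instr)
    rows = []
    for j in range(J):
        mask = np.arange(J) != j
        est = ivw(instr.subset(mask))
        rows.append(
            {
                "snp": instr.snp[j],
                "estimate": est.estimate,
                "se": est.se,
                "p": est.p,
                "sign_change": np.sign(est.estimate) != np.sign(full.estimate),
                "p_crosses_alpha": (est.p < alpha) != (full.p < alpha),
            }
        )
    return pd.DataFrame(rows)


def run_all_estimators(
    instr: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """IVW, Egger, weighted median and mode on one instrument set."""
    ests = []
    if len(instr) == 1:
        ests.append(
            wald_ratio(
                instr.beta_exposure[0], instr.se_exposure[0],
                instr.beta_outcome[0], instr.se_outcome[0],
            )
        )
    else:
        ests.append(ivw(instr))
        if len(instr) >= 3:
            ests.append(mr_egger(instr))
            ests.append(weighted_median(instr, n_boot=n_boot, seed=seed))
            ests.append(weighted_mode(instr, n_boot=n_boot, seed=seed))
    return pd.DataFrame(
        [
            {
                "method": e.method, "estimate": e.estimate, "se": e.se, "p": e.p,
                "n_snps": e.n_snps, "q": e.q, "q_p": e.q_p,
                "intercept": e.intercept, "intercept_p": e.intercept_p,
            }
            for e in ests
        ]
    )
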