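"""Phenome-wide association scan of standardised scores against cohort traits.

Each score is regressed on each trait with the family-appropriate model —
linear for continuous traits, logistic for case/control, proportional-odds
for ordered categories, multinomial for unordered ones — adjusted for the
standard covariate set (age, sex, ten principal components, genotyping
chip).  Effects are reported per SD of the score.  Variance explained is
recomputed unadjusted: plain R^2 for continuous traits, McFadden's pseudo-R^2
(1 - lnL_model / lnL_null) otherwise.

Supporting summaries mirror the atlas outputs: Bonferroni flags, signed
-log10 p-values for phenome plots, extreme-decile odds ratios and ROC/AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .prs import ScoreVector

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "sex", *[f"pc{i}" for i in range(1, 11)], "chip"]
MIN_COMPLETE_CASES = 50


@dataclass
class TraitSpec:
    """Analysis-side description of one scanned trait."""

    name: str
    family: str = "continuous"  # continuous | binary | ordinal | categorical
    levels: list | None = None  # order (ordinal) or full set (categorical)
    reference: object | None = None  # categorical reference level
    female_only: bool = False

    def __post_init__(self) -> None:
        if self.family not in {"continuous", "binary", "ordinal", "categorical"}:
            raise ValueError(f"unknown trait family {self.family!r}")
        if self.family == "ordinal":
            if not self.levels or len(self.levels) < 2:
                raise ValueError("ordinal traits need ordered levels")
            if len(self.levels) == 2:
                # degenerate ordinal == logistic; accepted so the two code
                # paths can be cross-checked, but 3+ levels is the intended use
                logger.info("ordinal trait %s has only 2 levels", self.name)
        if self.family == "categorical":
            if not self.levels:
                raise ValueError("categorical traits must declare their levels")
            if self.reference is None:
                self.reference = self.levels[0]
            if self.reference not in self.levels:
                raise ValueError("categorical reference level not among levels")


@dataclass
class AssociationResult:
    """One score-on-trait regression."""

    score: str
    trait: str
    family: str
    estimate: float = np.nan  # per SD of score; log-odds for odds families
    se: float = np.nan
    p: float = np.nan
    n: int = 0
    r2: float = np.nan
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    covariates: list = field(default_factory=list)
    converged: bool = True
    skipped_reason: str | None = None
    per_level: pd.DataFrame | None = None  # categorical: per-level effects


@dataclass
class ScanResult:
    """All score x trait associations plus multiplicity bookkeeping."""

    table: pd.DataFrame
    bonferroni_threshold: float
    n_tests: int


def mcfadden_r2(loglik_model: float, loglik_null: float) -> float:
    """McFadden's pseudo-R^2, 1 - lnL_model / lnL_null (both logs negative)."""
    if loglik_null == 0:
        raise ValueError("degenerate null model: log-likelihood is zero")
    if loglik_null > 0:
        raise ValueError("null log-likelihood must be negative")
    return 1.0 - loglik_model / loglik_null


def bonferroni_threshold(n_tests: int) -> float:
    """Family-wise 0.05 threshold: 0.05 / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 0.05 / n_tests


def expected_n_tests(n_scores: int, n_traits: int, n_excluded_pairs: int = 0) -> int:
    """Row count of a full cross-product scan minus excluded pairs."""
    return n_scores * n_traits - n_excluded_pairs


def _design(score: np.ndarray, covariates: pd.DataFrame | None, cov_names) -> pd.DataFrame:
    X = pd.DataFrame({"score": score})
    if covariates is not None and cov_names:
        X = pd.concat(
            [X.reset_index(drop=True),
             covariates[list(cov_names)].reset_index(drop=True)],
            axis=1,
        )
    return X


def fit_association(
    score: ScoreVector | np.ndarray,
    trait: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None,
    spec: TraitSpec,
    score_name: str = "score",
    sex: np.ndarray | None = None,
) -> AssociationResult:
    """Fit the family-appropriate regression of one trait on one score.

    Sex-restricted traits keep only females (coding: ``sex == 0`` is female,
    matching the cohort simulator) and drop the sex covariate.  Fewer than 50
    complete cases skips the pair; separation or non-convergence flags the
    row rather than dropping it.
    """
    if isinstance(score, ScoreVector):
        if score_name == "score":
            score_name = score.name
        score = score.standardized
    score = np.asarray(score, dtype=float)
    trait = pd.Series(np.asarray(trait, dtype=object), name=spec.name)
    cov_names = list(covariates.columns) if covariates is not None else []

    keep = ~np.isnan(score)
    if spec.female_only:
        if sex is None and covariates is not None and "sex" in covariates:
            sex = covariates["sex"].to_numpy()
        if sex is None:
            raise ValueError(f"trait {spec.name!r} is sex-restricted but no sex given")
        keep &= np.asarray(sex, dtype=float) == 0.0
        cov_names = [c for c in cov_names if c != "sex"]

    numeric = spec.family in {"continuous", "binary"}
    tvals = pd.to_numeric(trait, errors="coerce") if numeric else trait
    keep &= ~pd.isna(tvals).to_numpy()
    if covariates is not None and cov_names:
        keep &= ~covariates[cov_names].isna().any(axis=1).to_numpy()

    res = AssociationResult(
        score=score_name, trait=spec.name, family=spec.family,
        covariates=cov_names, n=int(keep.sum()),
    )
    if keep.sum() < MIN_COMPLETE_CASES:
        res.skipped_reason = f"only {int(keep.sum())} complete cases (< {MIN_COMPLETE_CASES})"
        res.converged = False
        return res

    y = tvals[keep]
    X = _design(score[keep], covariates.loc[keep] if covariates is not None else None, cov_names)
    X = sm.add_constant(X, has_constant="add")
    score_only = sm.add_constant(pd.DataFrame({"score": X["score"].to_numpy()}))
    null_X = score_only[["const"]]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            if spec.family == "continuous":
                yv = y.to_numpy(dtype=float)
                fit = sm.OLS(yv, X).fit()
                res.estimate = fit.params["score"]
                res.se = fit.bse["score"]
                res.p = fit.pvalues["score"]
                res.r2 = sm.OLS(yv, score_only).fit().rsquared
            elif spec.family == "binary":
                yv = y.to_numpy(dtype=float)
                fit = sm.Logit(yv, X).fit(disp=0, maxiter=200)
                res.converged = bool(fit.mle_retvals.get("converged", True))
                res.estimate = fit.params["score"]
                res.se = fit.bse["score"]
                res.p = fit.pvalues["score"]
                m = sm.Logit(yv, score_only).fit(disp=0, maxiter=200)
                m0 = sm.Logit(yv, null_X).fit(disp=0, maxiter=200)
                res.r2 = mcfadden_r2(m.llf, m0.llf)
            elif spec.family == "ordinal":
                yv = pd.Categorical(y, categories=spec.levels, ordered=True)
                Xo = X.drop(columns=["const"])  # OrderedModel absorbs intercepts
                fit = OrderedModel(yv, Xo, distr="logit").fit(
                    disp=0, method="bfgs", gtol=1e-08, maxiter=1000
                )
                res.converged = bool(fit.mle_retvals.get("converged", True))
                res.estimate = fit.params["score"]
                res.se = fit.bse["score"]
                res.p = fit.pvalues["score"]
                m = OrderedModel(
                    yv, score_only.drop(columns=["const"]), distr="logit"
                ).fit(disp=0, method="bfgs", gtol=1e-08, maxiter=1000)
                m0_ll = _ordinal_null_loglik(yv)
                res.r2 = mcfadden_r2(m.llf, m0_ll)
            else:  # categorical
                levels = [spec.reference] + [l for l in spec.levels if l != spec.reference]
                yv = pd.Categorical(y, categories=levels).codes
                fit = sm.MNLogit(yv, X).fit(disp=0, maxiter=200)
                res.converged = bool(fit.mle_retvals.get("converged", True))
                reduced = sm.MNLogit(yv, X.drop(columns=["score"])).fit(disp=0, maxiter=200)
                lr = 2.0 * (fit.llf - reduced.llf)
                df = len(levels) - 1
                res.p = float(sps.chi2.sf(max(lr, 0.0), df))
                per = []
                for j, lev in enumerate(levels[1:]):
                    b = fit.params.loc["score"].iloc[j]
                    se = fit.bse.loc["score"].iloc[j]
                    per.append({"level": lev, "estimate": b, "se": se,
                                "z": b / se if se > 0 else np.nan})
                res.per_level = pd.DataFrame(per)
                head = res.per_level.loc[res.per_level["z"].abs().idxmax()]
                res.estimate = head["estimate"]
                res.se = head["se"]
                m = sm.MNLogit(yv, score_only).fit(disp=0, maxiter=200)
                m0 = sm.MNLogit(yv, null_X).fit(disp=0, maxiter=200)
                res.r2 = mcfadden_r2(m.llf, m0.llf)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("fit failed for %s ~ %s: %s", spec.name, score_name, exc)
        res.converged = False
        res.skipped_reason = f"fit failed: {exc}"
        return res

    if spec.family in {"binary", "ordinal", "categorical"} and np.isfinite(res.estimate):
        res.odds_ratio = float(np.exp(res.estimate))
        res.ci_low = float(np.exp(res.estimate - 1.96 * res.se))
        res.ci_high = float(np.exp(res.estimate + 1.96 * res.se))
    return res


def _ordinal_null_loglik(y: pd.Categorical) -> float:
    """Intercept-only log-likelihood of an ordinal model: category frequencies."""
    counts = pd.Series(y).value_counts()
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum())


# ---------------------------------------------------------------------------
# Decile contrast, ROC
# ---------------------------------------------------------------------------


@dataclass
class DecileContrast:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    cases_top: int
    n_top: int
    cases_bottom: int
    n_bottom: int
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell


def decile_contrast(
    score: np.ndarray,
    trait: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> DecileContrast:
    """Odds of disease in the top versus bottom score decile.

    Deciles use type-7 empirical quantiles with boundary ties assigned to the
    lower decile.  Without covariates this is the 2x2 contingency odds ratio
    (with the Haldane-Anscombe 0.5 correction on a zero cell); with
    covariates a logistic model on the top-vs-bottom indicator is fitted
    within the two extreme deciles.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(trait, dtype=float)
    edges = np.quantile(score, np.linspace(0.1, 0.9, 9))  # type-7 default
    decile = np.searchsorted(edges, score, side="left")  # ties to lower decile
    top, bottom = decile == 9, decile == 0
    cases_top, n_top = int(y[top].sum()), int(top.sum())
    cases_bot, n_bot = int(y[bottom].sum()), int(bottom.sum())
    if cases_top + cases_bot < 20:
        raise ValueError(
            f"only {cases_top + cases_bot} cases across the extreme deciles (< 20)"
        )
    a, b = cases_top, n_top - cases_top
    c, d = cases_bot, n_bot - cases_bot
    corrected = 0 in (a, b, c, d)
    if covariates is None or corrected:
        if corrected:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log_or = np.log((a / b) / (c / d))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    else:
        mask = top | bottom
        X = sm.add_constant(
            pd.concat(
                [pd.Series(top[mask].astype(float), name="top").reset_index(drop=True),
                 covariates.loc[mask].reset_index(drop=True)],
                axis=1,
            )
        )
        fit = sm.Logit(y[mask], X).fit(disp=0, maxiter=200)
        log_or, se = fit.params["top"], fit.bse["top"]
    z = log_or / se
    return DecileContrast(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - 1.96 * se)),
        ci_high=float(np.exp(log_or + 1.96 * se)),
        p=float(2 * sps.norm.sf(abs(z))),
        cases_top=cases_top, n_top=n_top,
        cases_bottom=cases_bot, n_bottom=n_bot,
        corrected=corrected,
    )


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(predictor: np.ndarray, trait: np.ndarray) -> RocResult:
    """ROC curve and rank-statistic AUC.

    AUC is the probability that a random case outranks a random control,
    with ties counting one half (the Mann-Whitney statistic).  Curve points
    are computed at every distinct predictor value, threshold descending.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(trait, dtype=float)
    n_case, n_ctrl = int(y.sum()), int((1 - y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("ROC needs both cases and controls")
    ranks = sps.rankdata(x)
    auc = (ranks[y == 1].sum() - n_case * (n_case + 1) / 2) / (n_case * n_ctrl)
    order = np.argsort(-x, kind="mergesort")
    xs, ys = x[order], y[order]
    distinct = np.r_[np.diff(xs) != 0, True]
    tp = np.cumsum(ys)[distinct]
    fp = np.cumsum(1 - ys)[distinct]
    return RocResult(
        auc=float(auc),
        fpr=np.r_[0.0, fp / n_ctrl],
        tpr=np.r_[0.0, tp / n_case],
        thresholds=np.r_[np.inf, xs[distinct]],
    )


# ---------------------------------------------------------------------------
# Full scan
# ---------------------------------------------------------------------------


def run_scan(
    scores: dict,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    specs: list,
) -> ScanResult:
    """Fit every score x trait pair and assemble the atlas table.

    Individual fit failures are recorded (flagged rows) and the scan
    continues.  Rows are sorted by p within score; the Bonferroni threshold
    uses the number of executed tests.
    """
    rows = []
    for name, sv in scores.items():
        for spec in specs:
            r = fit_association(
                sv, phenotypes[spec.name], covariates, spec, score_name=name
            )
            rows.append(r)
    n_tests = len(rows)
    thresh = bonferroni_threshold(n_tests)
    table = pd.DataFrame(
        {
            "score": [r.score for r in rows],
            "trait": [r.trait for r in rows],
            "family": [r.family for r in rows],
            "estimate": [r.estimate for r in rows],
            "se": [r.se for r in rows],
            "p": [r.p for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "r2": [r.r2 for r in rows],
            "n": [r.n for r in rows],
            "converged": [r.converged for r in rows],
            "note": [r.skipped_reason or "" for r in rows],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["signed_log10p"] = -np.log10(np.clip(table["p"], 1e-300, 1.0)) * np.sign(
            table["estimate"]
        )
    table["bonferroni_pass"] = table["p"] < thresh
    table = (
        table.sort_values(["score", "p"], kind="mergesort").reset_index(drop=True)
    )
    return ScanResult(table=table, bonferroni_threshold=thresh, n_tests=n_tests)
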