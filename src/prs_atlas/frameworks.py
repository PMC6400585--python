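"""Decision procedures built on the two-sample MR estimators.

``triage`` encodes the three-step screen applied to phenome-scan hits:

1. IVW with Cochran's Q — weak IVW evidence means a causal effect is
   unlikely (NOT_SUPPORTED);
2. in the presence of heterogeneity, the weighted median and weighted mode
   must concur — if neither supports the effect the association is
   NOT_ROBUST;
3. steps 1-2 are re-run on Steiger-filtered instruments and the MR-Egger
   intercept is tested — a nonzero intercept or a reversed conclusion flags
   the association (SENSITIVITY_FLAGGED); otherwise it is a
   CAUSAL_CANDIDATE.

``bidirectional`` runs the triage in both orientations; ``mediation``
estimates a product-of-IVW-paths indirect effect and the proportion of the
total effect it accounts for; ``multivariable_mr`` estimates conditional
exposure effects from the union of instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mr import (
    InstrumentSet,
    MrError,
    MrEstimate,
    harmonize_two_sample,
    ivw,
    ld_clump,
    mr_egger,
    reconcile_alleles,
    steiger_filter,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

logger = logging.getLogger(__name__)


class Verdict(str, Enum):
    NOT_SUPPORTED = "NOT_SUPPORTED"
    NOT_ROBUST = "NOT_ROBUST"
    SENSITIVITY_FLAGGED = "SENSITIVITY_FLAGGED"
    CAUSAL_CANDIDATE = "CAUSAL_CANDIDATE"


@dataclass
class TriageVerdict:
    verdict: Verdict
    alpha: float
    step1: dict
    step2: dict | None = None
    step3: dict | None = None

    def to_dict(self) -> dict:
        def enc(step):
            if step is None:
                return None
            return {
                k: (v.__dict__ if isinstance(v, MrEstimate) else v)
                for k, v in step.items()
            }

        return {
            "verdict": self.verdict.value,
            "alpha": self.alpha,
            "step1": enc(self.step1),
            "step2": enc(self.step2),
            "step3": enc(self.step3),
        }


def _ivw_or_wald(instr: InstrumentSet, model: str = "random") -> MrEstimate:
    if len(instr) == 1:
        return wald_ratio(
            instr.beta_exposure[0], instr.se_exposure[0],
            instr.beta_outcome[0], instr.se_outcome[0],
        )
    return ivw(instr, model=model)


def triage(
    exposure,
    outcome,
    panel=None,
    alpha: float = 0.05,
    instrument_p: float = 5e-08,
    step2_always_binding: bool = False,
    n_boot: int = 500,
    seed: int = 0,
) -> TriageVerdict:
    """Three-step causal triage of one exposure -> outcome association.

    Step 1 uses the plain (fixed-effect) IVW together with Cochran's Q:
    heterogeneity is surfaced by Q and handled by the later steps rather than
    folded into the step-1 standard error.  Step 2 (median + mode) is binding
    when Q signals heterogeneity (Q_p < alpha), or always when
    ``step2_always_binding``; it still runs advisorily otherwise.  Step 3
    re-runs the estimate on Steiger-filtered instruments and tests the Egger
    intercept on the full set.
    """
    instr = harmonize_two_sample(
        exposure, outcome, panel=panel, instrument_p=instrument_p
    )
    est1 = _ivw_or_wald(instr, model="fixed")
    step1 = {"ivw": est1, "n_snps": len(instr)}
    if est1.p >= alpha:
        return TriageVerdict(Verdict.NOT_SUPPORTED, alpha, step1)

    step2 = None
    heterogeneous = est1.q_p is not None and est1.q_p < alpha
    if len(instr) >= 3:
        med = weighted_median(instr, n_boot=n_boot, seed=seed)
        mode = weighted_mode(instr, n_boot=n_boot, seed=seed + 1)
        binding = heterogeneous or step2_always_binding
        step2 = {"median": med, "mode": mode, "binding": binding}
        if binding and med.p >= alpha and mode.p >= alpha:
            return TriageVerdict(Verdict.NOT_ROBUST, alpha, step1, step2)

    step3: dict = {}
    flagged = False
    # the intercept is tested on the full set: directionality filtering tends
    # to remove exactly the pleiotropic SNPs the intercept would detect
    if len(instr) >= 3:
        egger = mr_egger(instr)
        step3["egger"] = egger
        if egger.intercept_p < alpha:
            flagged = True
            step3["pleiotropy"] = "Egger intercept indicates directional pleiotropy"
    try:
        filtered, verdicts = steiger_filter(instr)
        step3["steiger_removed"] = int((~verdicts["retained"]).sum())
        est_f = _ivw_or_wald(filtered, model="fixed")
        step3["ivw_filtered"] = est_f
        if est_f.p >= alpha:
            flagged = True
            step3["reversal"] = "IVW evidence lost after directionality filtering"
    except MrError as exc:
        flagged = True
        step3["error"] = str(exc)
    verdict = Verdict.SENSITIVITY_FLAGGED if flagged else Verdict.CAUSAL_CANDIDATE
    return TriageVerdict(verdict, alpha, step1, step2, step3)


@dataclass
class BidirectionalResult:
    forward: TriageVerdict | None
    reverse: TriageVerdict | None
    forward_error: str | None
    reverse_error: str | None
    label: str  # both | forward_only | reverse_only | neither


def bidirectional(
    trait_a, trait_b, panel=None, alpha: float = 0.05,
    instrument_p: float = 5e-08, **kwargs,
) -> BidirectionalResult:
    """Run the triage A -> B and B -> A with independently selected instruments."""
    fwd = rev = None
    fwd_err = rev_err = None
    try:
        fwd = triage(trait_a, trait_b, panel, alpha, instrument_p, **kwargs)
    except MrError as exc:
        fwd_err = str(exc)
    try:
        rev = triage(trait_b, trait_a, panel, alpha, instrument_p, **kwargs)
    except MrError as exc:
        rev_err = str(exc)
    if fwd is None and rev is None:
        raise MrError("neither direction is instrumentable")
    f_ok = fwd is not None and fwd.verdict == Verdict.CAUSAL_CANDIDATE
    r_ok = rev is not None and rev.verdict == Verdict.CAUSAL_CANDIDATE
    label = {
        (True, True): "both",
        (True, False): "forward_only",
        (False, True): "reverse_only",
        (False, False): "neither",
    }[(f_ok, r_ok)]
    return BidirectionalResult(fwd, rev, fwd_err, rev_err, label)


# ---------------------------------------------------------------------------
# Mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    traits: list
    edge_estimates: list  # MrEstimate per edge along the chain
    total: MrEstimate  # first trait -> outcome
    indirect: float
    indirect_se: float
    proportion_mediated: float
    proportion_formula: str
    flags: list = field(default_factory=list)


def mediation(
    chain: list,
    outcome,
    panel=None,
    instrument_p: float = 5e-08,
    formula: str = "indirect_over_total",
) -> MediationResult:
    """Product-of-paths mediation through an ordered chain of exposures.

    Edge effects (T1 -> T2, ..., Tk -> outcome) and the total effect
    (T1 -> outcome) are IVW estimates; the indirect effect is the product of
    the edge estimates, with a delta-method SE.  The default proportion
    mediated is indirect / total; ``formula="difference_over_total"`` gives
    (total - indirect) / total instead.
    """
    if len(chain) < 2:
        raise MrError("mediation needs a chain of at least two exposures")
    if formula not in {"indirect_over_total", "difference_over_total"}:
        raise ValueError(f"unknown proportion formula {formula!r}")
    studies = list(chain) + [outcome]
    names = [s.trait for s in studies]
    edges = []
    for a, b in zip(studies[:-1], studies[1:]):
        instr = harmonize_two_sample(a, b, panel=panel, instrument_p=instrument_p)
        edges.append(_ivw_or_wald(instr))
    instr_total = harmonize_two_sample(
        studies[0], outcome, panel=panel, instrument_p=instrument_p
    )
    total = _ivw_or_wald(instr_total)

    ests = np.array([e.estimate for e in edges])
    ses = np.array([e.se for e in edges])
    indirect = float(np.prod(ests))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(ests != 0, ses / ests, np.inf)
    indirect_se = float(abs(indirect) * np.sqrt(np.sum(rel**2))) if indirect != 0 else float("nan")

    flags = []
    if np.isclose(total.estimate, 0.0):
        flags.append("total effect near zero: proportion mediated undefined")
        proportion = float("nan")
    else:
        if formula == "indirect_over_total":
            proportion = indirect / total.estimate
        else:
            proportion = (total.estimate - indirect) / total.estimate
        if np.sign(indirect) != np.sign(total.estimate) and indirect != 0:
            flags.append("inconsistent mediation: indirect and total effects have opposite signs")
    return MediationResult(
        traits=names, edge_estimates=edges, total=total,
        indirect=indirect, indirect_se=indirect_se,
        proportion_mediated=proportion, proportion_formula=formula,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Multivariable MR
# ---------------------------------------------------------------------------


@dataclass
class MvmrResult:
    exposures: list
    table: pd.DataFrame  # conditional + univariable estimates per exposure
    n_instruments: int
    dropped: list = field(default_factory=list)


def multivariable_mr(
    exposures: list,
    outcome,
    panel=None,
    instrument_p: float = 5e-08,
    r2_threshold: float = 0.001,
) -> MvmrResult:
    """Conditional exposure effects from the union of clumped instruments.

    Instruments are the union over exposures of each one's genome-wide-
    significant clumped SNPs; SNPs missing from any study are dropped and
    logged.  Outcome effects are regressed on the matrix of exposure effects
    with no intercept and weights 1/se_Gamma^2; SEs carry the usual
    max(1, residual scale) inflation, p-values use t with J-k df.
    Univariable IVW estimates and the conditional/univariable attenuation
    ratio are reported alongside.
    """
    if not exposures:
        raise MrError("at least one exposure required")
    names = [e.trait for e in exposures]
    if len(set(names)) != len(names):
        raise ValueError("exposure traits must have distinct names")

    union: list[str] = []
    for expo in exposures:
        if panel is not None:
            definition = ld_clump(
                expo, panel, p_threshold=instrument_p, r2_threshold=r2_threshold
            )
            snps = list(definition.snp)
        else:
            snps = expo.significant(instrument_p)["snp"].tolist()
        union.extend(s for s in snps if s not in union)
    if not union:
        raise MrError("no instruments")

    ref = exposures[0].table.set_index("snp")
    tables = [e.table.set_index("snp") for e in exposures]
    out = outcome.table.set_index("snp")
    rows, dropped = [], []
    for s in union:
        if any(s not in t.index for t in tables) or s not in out.index:
            dropped.append(f"{s}: missing from at least one study")
            continue
        r = ref.loc[s]
        betas = []
        ok = True
        for t in tables:
            o = t.loc[s]
            action, reason = reconcile_alleles(
                r["effect_allele"], r["other_allele"],
                o["effect_allele"], o["other_allele"],
                eaf_a=r["eaf"], eaf_b=o["eaf"],
            )
            if action == "drop":
                dropped.append(f"{s}: {reason}")
                ok = False
                break
            betas.append((-1.0 if action == "flip" else 1.0) * o["beta"])
        if not ok:
            continue
        o = out.loc[s]
        action, reason = reconcile_alleles(
            r["effect_allele"], r["other_allele"],
            o["effect_allele"], o["other_allele"],
            eaf_a=r["eaf"], eaf_b=o["eaf"],
        )
        if action == "drop":
            dropped.append(f"{s}: {reason}")
            continue
        rows.append(
            (s, betas, (-1.0 if action == "flip" else 1.0) * o["beta"], o["se"])
        )
    for msg in dropped:
        logger.info("MVMR dropped %s", msg)
    if not rows:
        raise MrError("no instruments present in every study")

    J, k = len(rows), len(exposures)
    X = np.array([r[1] for r in rows])
    G = np.array([r[2] for r in rows])
    seG = np.array([r[3] for r in rows])
    w = 1.0 / seG**2
    XtW = X.T * w
    xtwx = XtW @ X
    if np.linalg.matrix_rank(xtwx) < k:
        corr = np.corrcoef(X.T)
        pairs = [
            f"{names[i]}~{names[j]}"
            for i in range(k) for j in range(i + 1, k)
            if abs(corr[i, j]) > 0.999
        ]
        raise MrError(
            "collinear exposure effects: " + (", ".join(pairs) or "rank deficient")
        )
    xtwx_inv = np.linalg.inv(xtwx)
    coef = xtwx_inv @ (XtW @ G)
    resid = G - X @ coef
    df = max(J - k, 1)
    sigma = np.sqrt(float(resid @ (w * resid)) / df)
    ses = np.sqrt(np.diag(xtwx_inv)) * max(1.0, sigma)

    uni = []
    for expo in exposures:
        try:
            instr = harmonize_two_sample(
                expo, outcome, panel=panel, instrument_p=instrument_p,
                r2_threshold=r2_threshold,
            )
            uni.append(_ivw_or_wald(instr).estimate)
        except MrError:
            uni.append(np.nan)

    table = pd.DataFrame(
        {
            "exposure": names,
            "conditional_estimate": coef,
            "se": ses,
            "p": 2 * sps.t.sf(np.abs(coef / ses), df),
            "univariable_estimate": uni,
            "attenuation": coef / np.asarray(uni),
        }
    )
    return MvmrResult(exposures=names, table=table, n_instruments=J, dropped=dropped)
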