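"""Polygenic risk score construction from GWAS summary statistics.

The pipeline is: select candidate SNPs below a p-value threshold, greedily
clump them to approximate LD independence against a reference panel
(r^2 < 0.001 by default), substitute proxies (r^2 >= 0.8) for SNPs absent
from the target genotypes, harmonise alleles between the GWAS and the target
coding, then score each individual as the weighted sum of effect-allele
dosages and standardise to zero mean / unit SD.

Scores may be unweighted (weights collapse to the sign of the reported beta,
i.e. the score counts trait-increasing alleles), the convention used when the
weight source overlaps the target cohort and overfitting is a concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    COMPLEMENT,
    GenotypeMatrix,
    GwasSummaryStats,
    ReferencePanel,
    is_palindromic,
)

logger = logging.getLogger(__name__)

#: Effect-allele-frequency band within which a palindromic SNP cannot be
#: aligned by frequency and is dropped.
PALINDROMIC_AMBIGUITY_BAND = (0.42, 0.58)


@dataclass
class ScoreDefinition:
    """The clumped, harmonised SNP/weight list defining one score."""

    snp: list
    effect_allele: list
    weight: np.ndarray
    weighted: bool = True
    p_threshold: float | None = None
    r2_threshold: float | None = None
    other_allele: list = field(default_factory=list)
    eaf: list = field(default_factory=list)  # GWAS effect-allele frequencies
    source: list = field(default_factory=list)  # "direct" or "proxy:<id>"
    provenance: list = field(default_factory=list)  # human-readable log lines

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        if len(set(self.snp)) != len(self.snp):
            raise ValueError("duplicate SNP ids in score definition")
        if not self.source:
            self.source = ["direct"] * len(self.snp)
        if not self.other_allele:
            self.other_allele = [None] * len(self.snp)
        if not self.eaf:
            self.eaf = [None] * len(self.snp)
        if not self.weighted and len(self.weight):
            if not np.isin(self.weight, (-1.0, 1.0)).all():
                raise ValueError("unweighted score weights must be +/-1")

    def __len__(self) -> int:
        return len(self.snp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp,
                "effect_allele": self.effect_allele,
                "weight": self.weight,
                "source": self.source,
            }
        )


@dataclass
class ScoreVector:
    """Per-individual raw and standardised score values."""

    iids: np.ndarray
    raw: np.ndarray
    standardized: np.ndarray
    n_snps_used: int
    name: str = "score"

    @property
    def n_individuals(self) -> int:
        return len(self.raw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iid": self.iids, "raw": self.raw, "standardized": self.standardized}
        )


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------


def ld_clump(
    stats: GwasSummaryStats,
    panel: ReferencePanel,
    p_threshold: float = 5e-05,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    unweighted: bool = False,
) -> ScoreDefinition:
    """Greedy p-value-ranked LD clumping against a reference panel.

    Candidates (p <= ``p_threshold``, present in the panel) are ranked by
    ascending p with ties broken by (chromosome, position, id); the best is
    accepted and every remaining candidate within ``window_kb`` of an accepted
    SNP with panel r^2 >= ``r2_threshold`` is discarded.  Accepted SNPs carry
    their GWAS betas as weights (their signs if ``unweighted``).
    """
    cand = stats.significant(p_threshold)
    provenance = []
    in_panel = cand["snp"].map(lambda s: s in panel)
    for s in cand.loc[~in_panel, "snp"]:
        provenance.append(f"dropped {s}: absent from reference panel")
    cand = cand[in_panel].copy()
    if cand.empty:
        logger.warning(
            "no SNP passes p<=%.3g for trait %r; empty score definition",
            p_threshold, stats.trait,
        )
        return ScoreDefinition(
            [], [], np.array([]), weighted=not unweighted,
            p_threshold=p_threshold, r2_threshold=r2_threshold,
            provenance=provenance + ["no SNP passed the p-value threshold"],
        )
    idx = cand["snp"].map(panel.index_of)
    cand["chrom"] = np.asarray(panel.chrom)[idx]
    cand["pos"] = np.asarray(panel.pos)[idx]
    cand = cand.sort_values(
        ["pval", "chrom", "pos", "snp"], kind="mergesort"
    ).reset_index(drop=True)

    accepted: list[int] = []
    alive = np.ones(len(cand), dtype=bool)
    window_bp = window_kb * 1000
    for i in range(len(cand)):
        if not alive[i]:
            continue
        accepted.append(i)
        row = cand.iloc[i]
        for j in range(i + 1, len(cand)):
            if not alive[j]:
                continue
            other = cand.iloc[j]
            if other["chrom"] != row["chrom"]:
                continue
            if abs(other["pos"] - row["pos"]) > window_bp:
                continue
            if panel.r2(row["snp"], other["snp"]) >= r2_threshold:
                alive[j] = False
                provenance.append(
                    f"dropped {other['snp']}: r2 with {row['snp']} >= {r2_threshold}"
                )
    kept = cand.iloc[accepted]
    weights = kept["beta"].to_numpy()
    if unweighted:
        weights = np.sign(weights)
    return ScoreDefinition(
        snp=kept["snp"].tolist(),
        effect_allele=kept["effect_allele"].tolist(),
        weight=weights,
        weighted=not unweighted,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        other_allele=kept["other_allele"].tolist(),
        eaf=kept["eaf"].tolist(),
        provenance=provenance,
    )


def find_proxy(
    snp: str,
    panel: ReferencePanel,
    r2_min: float = 0.8,
    exclude=(),
) -> dict | None:
    """Best-LD substitute for a SNP unavailable in the target genotypes.

    Returns ``{"proxy": id, "r2": float, "sign_flip": bool}`` for the panel
    SNP with maximal r^2 >= ``r2_min``, or None.  ``sign_flip`` is True when
    the proxy's effect allele is negatively correlated with the target's, in
    which case the inherited weight must change sign.
    """
    if snp not in panel:
        raise KeyError(f"target SNP {snp!r} not in panel")
    best = None
    for other in panel.snp_ids:
        if other == snp or other in exclude:
            continue
        r = panel.corr(snp, other)
        if best is None or r * r > best[1]:
            best = (other, r * r, r)
    if best is None or best[1] < r2_min:
        logger.info("no proxy at r2>=%.2f for %s", r2_min, snp)
        return None
    return {"proxy": best[0], "r2": best[1], "sign_flip": best[2] < 0}


# ---------------------------------------------------------------------------
# Allele harmonisation
# ---------------------------------------------------------------------------


def reconcile_alleles(
    a_eff: str,
    a_oth: str,
    b_eff: str,
    b_oth: str,
    eaf_a: float | None = None,
    eaf_b: float | None = None,
    ambiguity_band: tuple[float, float] = PALINDROMIC_AMBIGUITY_BAND,
) -> tuple[str, str]:
    """Reconcile study B's allele orientation with study A's.

    Returns ``(action, reason)`` where action is ``keep`` (same orientation),
    ``flip`` (B's effect refers to A's other allele; negate B's effect and
    reflect its frequency) or ``drop``.  Strand flips are resolved by
    complementing; palindromic pairs (A/T, C/G) are aligned by allele
    frequency unless either frequency falls in the ambiguity band, in which
    case the SNP is dropped.
    """
    if is_palindromic(a_eff, a_oth):
        if {b_eff, b_oth} != {a_eff, a_oth}:
            return "drop", "irreconcilable alleles"
        lo, hi = ambiguity_band
        if eaf_a is None or eaf_b is None:
            return "drop", "palindromic SNP without frequencies"
        if lo <= eaf_a <= hi or lo <= eaf_b <= hi:
            return "drop", "palindromic SNP with ambiguous frequency"
        eaf_b_oriented = eaf_b if b_eff == a_eff else 1.0 - eaf_b
        if (eaf_a < 0.5) == (eaf_b_oriented < 0.5):
            return ("keep" if b_eff == a_eff else "flip"), "palindromic, frequency-aligned"
        # frequencies disagree: B is on the opposite strand orientation
        return ("flip" if b_eff == a_eff else "keep"), "palindromic, frequency-aligned"
    if (b_eff, b_oth) == (a_eff, a_oth):
        return "keep", "same orientation"
    if (b_eff, b_oth) == (a_oth, a_eff):
        return "flip", "allele swap"
    c_eff, c_oth = COMPLEMENT.get(b_eff), COMPLEMENT.get(b_oth)
    if (c_eff, c_oth) == (a_eff, a_oth):
        return "keep", "strand flip"
    if (c_eff, c_oth) == (a_oth, a_eff):
        return "flip", "strand flip + allele swap"
    return "drop", "irreconcilable alleles"


def harmonize_alleles(
    definition: ScoreDefinition,
    cohort_alleles: dict,
) -> ScoreDefinition:
    """Align a score definition to the target cohort's allele coding.

    ``cohort_alleles`` maps SNP id -> ``{"effect": counted allele,
    "other": allele, "freq": counted-allele frequency}`` (``freq`` optional,
    needed only for palindromic SNPs).  Weights are negated where the cohort
    counts the GWAS other allele; palindromic SNPs with ambiguous frequency
    and irreconcilable allele sets are dropped and logged.
    """
    snps, alleles, others, eafs, weights, source = [], [], [], [], [], []
    prov = list(definition.provenance)
    for i, s in enumerate(definition.snp):
        if s not in cohort_alleles:
            prov.append(f"dropped {s}: no allele information in cohort")
            continue
        info = cohort_alleles[s]
        action, reason = reconcile_alleles(
            info["effect"], info["other"],
            definition.effect_allele[i], definition.other_allele[i],
            eaf_a=info.get("freq"), eaf_b=definition.eaf[i],
        )
        if action == "drop":
            prov.append(f"dropped {s}: {reason}")
            continue
        w = definition.weight[i]
        if action == "flip":
            w = -w
            prov.append(f"flipped {s}: {reason}")
        snps.append(s)
        alleles.append(info["effect"])
        others.append(info["other"])
        eafs.append(definition.eaf[i])
        weights.append(w)
        source.append(definition.source[i])
    return ScoreDefinition(
        snp=snps,
        effect_allele=alleles,
        weight=np.asarray(weights),
        weighted=definition.weighted,
        p_threshold=definition.p_threshold,
        r2_threshold=definition.r2_threshold,
        other_allele=others,
        eaf=eafs,
        source=source,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def compute_score(
    genotypes: GenotypeMatrix,
    definition: ScoreDefinition,
    name: str = "score",
    mean_impute: bool = True,
) -> ScoreVector:
    """Raw score: sum over SNPs of weight x effect-allele dosage.

    For an unweighted definition the weight is the sign of the reported beta
    (already stored as +/-1), so the score counts trait-increasing alleles.
    A missing dosage contributes the cohort-mean dosage at that SNP times the
    weight (mean imputation); with ``mean_impute=False`` individuals with any
    missing call get a NaN raw score.  SNPs absent from the genotypes are
    excluded and counted.
    """
    cols, weights, missing = [], [], 0
    for i, s in enumerate(definition.snp):
        if s not in genotypes:
            missing += 1
            logger.info("score %s: SNP %s absent from genotypes, excluded", name, s)
            continue
        cols.append(genotypes.index_of(s))
        weights.append(definition.weight[i])
    if missing:
        logger.warning("score %s: %d SNP(s) excluded as absent", name, missing)
    if not cols:
        raw = np.zeros(genotypes.n_individuals)
        return ScoreVector(genotypes.iids, raw, raw.copy(), 0, name)
    G = genotypes.dosages[:, cols]
    if mean_impute:
        col_means = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_means, G)
    raw = G @ np.asarray(weights)
    sv = ScoreVector(genotypes.iids, raw, np.full_like(raw, np.nan), len(cols), name)
    return sv


def standardize_score(score: ScoreVector | np.ndarray, name: str = "score") -> ScoreVector:
    """Centre and scale raw scores to mean 0, SD 1 (n - 1 denominator)."""
    if isinstance(score, ScoreVector):
        raw = score.raw
        iids = score.iids
        n_snps = score.n_snps_used
        name = score.name
    else:
        raw = np.asarray(score, dtype=float)
        iids = np.array([f"id_{i}" for i in range(len(raw))])
        n_snps = 0
    ok = ~np.isnan(raw)
    if ok.sum() < 2:
        raise ValueError(f"score {name!r}: need >= 2 non-missing individuals")
    sd = raw[ok].std(ddof=1)
    if sd == 0:
        raise ValueError(f"score {name!r} has zero variance; cannot standardise")
    std = (raw - raw[ok].mean()) / sd
    return ScoreVector(iids, raw, std, n_snps, name)


def combine_scores(scores: list, name: str = "combined") -> ScoreVector:
    """Sum standardised scores over the same individuals and re-standardise."""
    if not scores:
        raise ValueError("no scores to combine")
    base = scores[0]
    for s in scores[1:]:
        if len(s.iids) != len(base.iids) or not np.array_equal(s.iids, base.iids):
            raise ValueError("scores cover different individual sets")
    total = np.sum([s.standardized for s in scores], axis=0)
    combined = ScoreVector(
        base.iids, total, np.full_like(total, np.nan),
        sum(s.n_snps_used for s in scores), name,
    )
    return standardize_score(combined)
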