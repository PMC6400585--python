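"""Synthetic genotypes, cohorts, two-sample GWAS pairs and mediation chains.

Everything downstream — score construction, the phenome scan, the MR
estimators and the power study — is exercised against data from this module,
whose generative models carry explicit ground truth:

* genotypes are Binomial(2, p) hard calls with optional block LD;
* the exposure is an additive polygenic trait scaled to a target SNP
  heritability;
* the outcome adds a causal effect of the exposure plus, for a configurable
  fraction of SNPs, a direct ("horizontally pleiotropic") effect drawn
  Normal(mean, sd) — directional when mean != 0, balanced when mean == 0;
* the two summary-statistic sets of a two-sample design come from disjoint
  simulated samples;
* the mediation chain wires four traits X -> M1 -> M2 -> Y with private
  instruments per trait, a configurable direct X -> Y path, and a recorded
  true proportion mediated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .containers import GWAS_COLUMNS, GenotypeMatrix, GwasSummaryStats

__all__ = [
    "SimulationConfig",
    "TwoSampleGwasPair",
    "CohortTraitSpec",
    "SyntheticCohort",
    "MediationChain",
    "simulate_genotypes",
    "marginal_gwas",
    "simulate_two_sample_gwas",
    "simulate_cohort",
    "simulate_mediation_chain",
]


@dataclass
class SimulationConfig:
    """Parameters of the two-sample GWAS generator.

    Defaults mirror the study conditions of the power comparison: samples of
    10,000 individuals and 50 SNPs, all causal for the exposure, which has a
    SNP heritability of 0.3.  ``causal_effect`` is the effect of the exposure
    on the outcome per unit of exposure; ``pleiotropy_*`` control the direct
    SNP-on-outcome effects alpha_j.
    """

    n_individuals: int = 10_000
    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_effect: float = 0.0
    n_causal_snps: int = 50
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    heritability_exposure: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 1, got {self.maf_range}")
        if not 0.0 <= self.pleiotropy_fraction <= 1.0:
            raise ValueError("pleiotropy_fraction must lie in [0, 1]")
        if not 0.0 < self.heritability_exposure < 1.0:
            raise ValueError("heritability_exposure must lie in (0, 1)")
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps cannot exceed n_snps")
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be positive")


@dataclass
class TwoSampleGwasPair:
    """Exposure and outcome summary statistics from disjoint samples.

    ``truth`` records the generating parameters: the causal effect ``beta``,
    per-SNP exposure effects ``snp_effects`` and pleiotropic outcome effects
    ``alpha`` (zero for non-pleiotropic SNPs).  ``outcome_sample`` retains the
    outcome sample's individual-level genotypes and phenotypes so the PRS arm
    of the power study can score and test in a sample disjoint from the
    discovery GWAS.
    """

    exposure_stats: GwasSummaryStats
    outcome_stats: GwasSummaryStats
    truth: dict
    outcome_sample: dict | None = None


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_blocks: Sequence[tuple[Sequence[int], float]] | None = None,
    seed=None,
    spacing_bp: int = 100_000,
    chrom: int = 1,
) -> GenotypeMatrix:
    """Draw an n x m matrix of Binomial(2, p_j) dosages, p_j ~ Uniform(maf_range).

    ``ld_blocks`` is a sequence of ``(snp_indices, r2)`` pairs.  Within a
    block all members share the first member's allele frequency and are built
    from a shared latent haplotype pair: the first member *is* the latent
    haplotype, and each further member copies a latent allele with probability
    sqrt(r2), so its squared dosage correlation with the first member is r2
    (exact duplication at r2 = 1).  Positions are evenly spaced ``spacing_bp``
    apart on one chromosome.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"degenerate maf_range {maf_range}: need 0 < lo <= hi < 1")
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    if ld_blocks:
        for members, r2 in ld_blocks:
            members = list(members)
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"block r2 must lie in [0, 1], got {r2}")
            pb = p[members[0]]
            p[members] = pb
            theta = np.sqrt(r2)
            # latent haplotype pair shared by the block
            h = rng.random((n, 2)) < pb
            dosages[:, members[0]] = h.sum(axis=1)
            for j in members[1:]:
                copy = rng.random((n, 2)) < theta
                fresh = rng.random((n, 2)) < pb
                dosages[:, j] = np.where(copy, h, fresh).sum(axis=1)
    snp_ids = np.array([f"rs{j + 1}" for j in range(m)])
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        effect_allele=np.repeat("A", m),
        other_allele=np.repeat("G", m),
        chrom=np.repeat(chrom, m),
        pos=1 + spacing_bp * np.arange(m),
    )


def marginal_gwas(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    trait: str = "trait",
    trait_type: str = "continuous",
) -> GwasSummaryStats:
    """Per-SNP simple linear regressions of ``y`` on each dosage column.

    Vectorised across SNPs; two-sided p-values from the t distribution with
    n - 2 degrees of freedom.  Monomorphic SNPs get beta 0, infinite SE and
    p = 1.
    """
    y = np.asarray(y, dtype=float)
    G = genotypes.dosages
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = np.where(mono, 0.0, sxy / sxx_safe)
    rss = np.maximum(syy - beta * sxy, 0.0)
    dof = max(n - 2, 1)
    se = np.sqrt(rss / dof / sxx_safe)
    se = np.where(mono | (se == 0), np.inf, se)
    tval = np.where(np.isfinite(se), beta / se, 0.0)
    pval = np.clip(2 * sps.t.sf(np.abs(tval), dof), np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "snp": genotypes.snp_ids,
            "effect_allele": genotypes.effect_allele,
            "other_allele": genotypes.other_allele,
            "eaf": genotypes.freqs,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        },
        columns=GWAS_COLUMNS,
    )
    return GwasSummaryStats(table, trait=trait, trait_type=trait_type)


def _scaled_effects(
    rng: np.random.Generator, p: np.ndarray, n_causal: int, h2: float
) -> np.ndarray:
    """Per-SNP additive effects with total genetic variance h2.

    Raw effects are half-normal on a causal subset chosen at random — the
    effect allele is coded as the exposure-increasing allele, the convention
    under which "directional" pleiotropy (a nonzero mean of the direct
    outcome effects) is meaningful — and the vector is rescaled so that
    sum_j b_j^2 2 p_j (1 - p_j) = h2.
    """
    m = len(p)
    b = np.zeros(m)
    if n_causal == 0:
        if h2 > 0:
            raise ValueError(
                "heritability target unreachable: no causal SNPs carry effects"
            )
        return b
    causal = rng.choice(m, size=n_causal, replace=False)
    b[causal] = np.abs(rng.normal(0.0, 1.0, size=n_causal))
    var_g = float(np.sum(b**2 * 2 * p * (1 - p)))
    if var_g <= 0:
        raise ValueError(
            "heritability target unreachable: zero genetic variance from drawn effects"
        )
    return b * np.sqrt(h2 / var_g)


def simulate_two_sample_gwas(config: SimulationConfig) -> TwoSampleGwasPair:
    """Simulate a two-sample exposure/outcome GWAS pair with known truth.

    Exposure: x = sum_j b_j g_j + e, scaled so the SNPs explain
    ``heritability_exposure`` of unit total variance.  Outcome:
    y = beta x + sum_j alpha_j g_j + e' with Var(e') = 1.  Marginal
    regressions are run separately in two disjoint samples of
    ``n_individuals`` each.
    """
    cfg = config
    rng = _rng(cfg.seed)
    m = cfg.n_snps
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    b = _scaled_effects(rng, p, cfg.n_causal_snps, cfg.heritability_exposure)

    alpha = np.zeros(m)
    k = int(round(cfg.pleiotropy_fraction * m))
    if k > 0:
        pleio = rng.choice(m, size=k, replace=False)
        alpha[pleio] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=k)

    sd_e = np.sqrt(1.0 - cfg.heritability_exposure)
    snp_ids = np.array([f"rs{j + 1}" for j in range(m)])

    def draw_sample():
        G = rng.binomial(2, p, size=(cfg.n_individuals, m)).astype(float)
        x = G @ b + rng.normal(0.0, sd_e, size=cfg.n_individuals)
        return G, x

    G1, x1 = draw_sample()
    G2, x2 = draw_sample()
    y2 = cfg.causal_effect * x2 + G2 @ alpha + rng.normal(0.0, 1.0, size=cfg.n_individuals)

    def as_matrix(G):
        return GenotypeMatrix(
            dosages=G,
            snp_ids=snp_ids,
            effect_allele=np.repeat("A", m),
            other_allele=np.repeat("G", m),
            chrom=np.repeat(1, m),
            pos=1 + 100_000 * np.arange(m),
        )

    gm1, gm2 = as_matrix(G1), as_matrix(G2)
    exposure_stats = marginal_gwas(gm1, x1, trait="exposure")
    outcome_stats = marginal_gwas(gm2, y2, trait="outcome")
    truth = {
        "beta": cfg.causal_effect,
        "snp_effects": dict(zip(snp_ids, b)),
        "alpha": dict(zip(snp_ids, alpha)),
        "maf": dict(zip(snp_ids, p)),
    }
    outcome_sample = {"genotypes": gm2, "exposure": x2, "outcome": y2}
    return TwoSampleGwasPair(exposure_stats, outcome_stats, truth, outcome_sample)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

COVARIATE_NAMES = ["age", "sex", *[f"pc{i}" for i in range(1, 11)], "chip"]


@dataclass
class CohortTraitSpec:
    """Generative description of one cohort trait.

    ``snp_effects`` maps SNP ids to per-allele effects on the linear
    predictor; ``covariate_effects`` does the same for covariate columns.
    Families: ``continuous`` adds Gaussian noise of ``noise_sd``; ``binary``
    passes the predictor through a logistic link; ``ordinal`` thresholds a
    logistic latent variable at ``cutpoints`` (len(levels) - 1, ascending);
    ``categorical`` uses multinomial logits where each non-reference level's
    predictor is ``level_intercepts[level] + level_scales[level] * lp``.
    """

    name: str
    family: str = "continuous"
    snp_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    intercept: float = 0.0
    noise_sd: float = 1.0
    levels: list | None = None
    cutpoints: list | None = None
    level_intercepts: dict = field(default_factory=dict)
    level_scales: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in {"continuous", "binary", "ordinal", "categorical"}:
            raise ValueError(f"unknown trait family {self.family!r}")
        if self.family == "ordinal":
            if not self.levels or len(self.levels) < 3:
                raise ValueError("ordinal traits need >= 3 ordered levels")
            if self.cutpoints is None or len(self.cutpoints) != len(self.levels) - 1:
                raise ValueError("ordinal traits need len(levels) - 1 cutpoints")
            if list(self.cutpoints) != sorted(self.cutpoints):
                raise ValueError("ordinal cutpoints must be ascending")
        if self.family == "categorical" and (not self.levels or len(self.levels) < 2):
            raise ValueError("categorical traits need >= 2 levels")


@dataclass
class SyntheticCohort:
    """Genotypes, phenotypes, covariates and the generating truth."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict


def simulate_cohort(
    config: SimulationConfig,
    trait_specs: Sequence[CohortTraitSpec],
    ld_blocks=None,
) -> SyntheticCohort:
    """Simulate a biobank-style cohort with declared trait models.

    Covariates emulate the standard adjustment set: age (N(57, 8)), sex
    (Bernoulli 0.5), ten principal-component surrogates (standard normal) and
    a genotyping-chip indicator (Bernoulli 0.5).  Confounding is introduced
    only through ``covariate_effects`` in the trait specs.
    """
    rng = _rng(config.seed)
    genotypes = simulate_genotypes(
        config.n_individuals, config.n_snps, config.maf_range,
        ld_blocks=ld_blocks, seed=rng,
    )
    n = config.n_individuals
    cov = pd.DataFrame(
        {
            "age": rng.normal(57.0, 8.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            **{f"pc{i}": rng.normal(0.0, 1.0, size=n) for i in range(1, 11)},
            "chip": rng.integers(0, 2, size=n).astype(float),
        },
        index=pd.Index(genotypes.iids, name="iid"),
    )

    phenos = {}
    truth = {}
    for spec in trait_specs:
        lp = np.full(n, spec.intercept, dtype=float)
        for snp, eff in spec.snp_effects.items():
            if snp not in genotypes:
                raise ValueError(f"trait {spec.name!r} references unknown SNP {snp!r}")
            lp += eff * genotypes.column(snp)
        for name, eff in spec.covariate_effects.items():
            if name not in cov.columns:
                raise ValueError(
                    f"trait {spec.name!r} references unknown covariate {name!r}"
                )
            lp += eff * cov[name].to_numpy()
        if spec.family == "continuous":
            y = lp + rng.normal(0.0, spec.noise_sd, size=n)
        elif spec.family == "binary":
            y = (rng.random(n) < expit(lp)).astype(float)
        elif spec.family == "ordinal":
            latent = lp + rng.logistic(0.0, 1.0, size=n)
            idx = np.searchsorted(np.asarray(spec.cutpoints, dtype=float), latent)
            y = np.asarray(spec.levels, dtype=object)[idx]
        else:  # categorical
            levels = list(spec.levels)
            logits = np.zeros((n, len(levels)))
            for j, lev in enumerate(levels[1:], start=1):
                logits[:, j] = spec.level_intercepts.get(lev, 0.0) + (
                    spec.level_scales.get(lev, 1.0) * (lp - spec.intercept)
                )
            prob = np.exp(logits - logits.max(axis=1, keepdims=True))
            prob /= prob.sum(axis=1, keepdims=True)
            draw = (prob.cumsum(axis=1) < rng.random((n, 1))).sum(axis=1)
            y = np.asarray(levels, dtype=object)[draw]
        phenos[spec.name] = y
        truth[spec.name] = {
            "family": spec.family,
            "snp_effects": dict(spec.snp_effects),
            "covariate_effects": dict(spec.covariate_effects),
            "intercept": spec.intercept,
        }
    phenotypes = pd.DataFrame(phenos, index=cov.index)
    return SyntheticCohort(genotypes, phenotypes, cov, truth)


# ---------------------------------------------------------------------------
# Mediation chain
# ---------------------------------------------------------------------------


@dataclass
class MediationChain:
    """Four single-trait GWAS (X, M1, M2, Y) from disjoint samples, plus truth."""

    gwas: list  # list[GwasSummaryStats], ordered X, M1, M2, Y
    truth: dict


def simulate_mediation_chain(
    path_effects: tuple[float, float, float],
    direct: float,
    config: SimulationConfig,
    n_instruments: int = 10,
    h2_private: float = 0.1,
) -> MediationChain:
    """Simulate the four-trait causal chain X -> M1 -> M2 -> Y.

    Each trait owns ``n_instruments`` private SNPs contributing ``h2_private``
    of variance to that trait; X additionally affects Y directly with effect
    ``direct``.  Four disjoint samples of ``config.n_individuals`` are drawn
    and each trait's GWAS (over the union of all SNPs) is computed in its own
    sample, so every adjacent exposure/outcome pair is a genuine two-sample
    design.  The recorded true proportion mediated is
    (b1 b2 b3) / (b1 b2 b3 + direct).
    """
    b1, b2, b3 = path_effects
    indirect = b1 * b2 * b3
    total = indirect + direct
    truth = {
        "path_effects": (b1, b2, b3),
        "direct": direct,
        "indirect": indirect,
        "total": total,
    }
    if total == 0 and indirect != 0:
        truth["proportion_mediated"] = np.nan
        truth["undefined_proportion"] = True
    else:
        truth["proportion_mediated"] = indirect / total if total != 0 else 0.0
        truth["undefined_proportion"] = False

    rng = _rng(config.seed)
    names = ["X", "M1", "M2", "Y"]
    m_total = 4 * n_instruments
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m_total)
    snp_ids = np.array([f"rs{j + 1}" for j in range(m_total)])
    # private effect vectors, each non-zero on its own block of SNPs
    effects = []
    for t in range(4):
        block = np.zeros(m_total)
        sl = slice(t * n_instruments, (t + 1) * n_instruments)
        raw = rng.normal(0.0, 1.0, size=n_instruments)
        var_g = float(np.sum(raw**2 * 2 * p[sl] * (1 - p[sl])))
        block[sl] = raw * np.sqrt(h2_private / var_g)
        effects.append(block)
    truth["instruments"] = {
        name: list(snp_ids[t * n_instruments:(t + 1) * n_instruments])
        for t, name in enumerate(names)
    }

    gwas = []
    noise_sd = np.sqrt(1.0 - h2_private)
    for t, name in enumerate(names):
        G = rng.binomial(2, p, size=(config.n_individuals, m_total)).astype(float)
        e = rng.normal(0.0, noise_sd, size=(config.n_individuals, 4))
        x = G @ effects[0] + e[:, 0]
        m1 = b1 * x + G @ effects[1] + e[:, 1]
        m2 = b2 * m1 + G @ effects[2] + e[:, 2]
        y = b3 * m2 + direct * x + G @ effects[3] + e[:, 3]
        trait_values = {"X": x, "M1": m1, "M2": m2, "Y": y}
        gm = GenotypeMatrix(
            dosages=G,
            snp_ids=snp_ids,
            effect_allele=np.repeat("A", m_total),
            other_allele=np.repeat("G", m_total),
            chrom=np.repeat(1, m_total),
            pos=1 + 100_000 * np.arange(m_total),
        )
        gwas.append(marginal_gwas(gm, trait_values[name], trait=name))
    return MediationChain(gwas=gwas, truth=truth)
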