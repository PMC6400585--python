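"""End-to-end pipeline: (optionally simulated) inputs -> scores -> scan ->
triage of flagged hits -> atlas exports.

The configuration is a flat structured file (YAML); every source of
randomness flows from its single seed, so rerunning an identical
configuration reproduces byte-identical outputs.  Structured logs record
every dropped SNP and skipped pair with a reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as atlas_io
from .frameworks import triage
from .mr import MrError
from .prs import compute_score, ld_clump, standardize_score
from .scan import DEFAULT_COVARIATES, TraitSpec, run_scan
from .simulate import (
    CohortTraitSpec,
    SimulationConfig,
    marginal_gwas,
    simulate_cohort,
    simulate_genotypes,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    output_dir: str
    seed: int = 0
    gwas_files: dict = field(default_factory=dict)  # score name -> TSV path
    panel_prefix: str | None = None  # dosage-matrix prefix for the LD panel
    cohort_prefix: str | None = None  # dosage-matrix prefix for cohort genotypes
    phenotypes: str | None = None
    covariates_file: str | None = None
    simulate: dict | None = None  # synthetic-inputs block, see _simulate_inputs
    p_threshold: float = 5e-05
    instrument_p: float = 5e-08
    clump_r2: float = 0.001
    proxy_r2: float = 0.8
    alpha: float = 0.05
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    unweighted_scores: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for name, value in (
            ("p_threshold", self.p_threshold),
            ("instrument_p", self.instrument_p),
            ("clump_r2", self.clump_r2),
            ("proxy_r2", self.proxy_r2),
            ("alpha", self.alpha),
        ):
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        for label, p in (
            ("panel_prefix", self.panel_prefix),
            ("cohort_prefix", self.cohort_prefix),
            ("phenotypes", self.phenotypes),
            ("covariates_file", self.covariates_file),
        ):
            if p is not None and not Path(p).with_suffix(
                ".dosage.tsv" if label.endswith("prefix") else Path(p).suffix
            ).exists():
                raise ValueError(f"{label} path not resolvable: {p}")
        for name, p in self.gwas_files.items():
            if not Path(p).exists():
                raise ValueError(f"GWAS file for score {name!r} not resolvable: {p}")
        if self.simulate is None and not self.gwas_files:
            raise ValueError("either a simulate block or gwas_files is required")


def _simulate_inputs(cfg: PipelineConfig):
    """Build a small synthetic scenario: a cohort, a panel (the cohort's own
    genotypes) and one discovery GWAS per score from a disjoint sample."""
    sim = dict(cfg.simulate or {})
    n = int(sim.get("n_individuals", 2000))
    m = int(sim.get("n_snps", 40))
    n_scores = int(sim.get("n_scores", 2))
    trait_block = sim.get("traits")
    rng = np.random.default_rng(cfg.seed)

    snp_ids = [f"rs{j + 1}" for j in range(m)]
    specs = []
    if trait_block:
        for t in trait_block:
            specs.append(CohortTraitSpec(**t))
    else:
        specs = [
            CohortTraitSpec(
                name="trait_cont", family="continuous",
                snp_effects={snp_ids[0]: 0.3, snp_ids[1]: 0.2},
            ),
            CohortTraitSpec(
                name="trait_bin", family="binary", intercept=-1.5,
                snp_effects={snp_ids[0]: 0.25},
            ),
            CohortTraitSpec(
                name="trait_ord", family="ordinal",
                levels=[0, 1, 2], cutpoints=[-0.5, 0.8],
                snp_effects={snp_ids[2]: 0.2},
            ),
        ]
    cohort = simulate_cohort(
        SimulationConfig(
            n_individuals=n, n_snps=m, n_causal_snps=min(5, m),
            seed=int(rng.integers(2**31 - 1)),
        ),
        specs,
    )
    # discovery GWAS per score from disjoint simulated samples
    gwas = {}
    for s in range(n_scores):
        disc = simulate_genotypes(n, m, seed=int(rng.integers(2**31 - 1)))
        effects = np.zeros(m)
        causal = rng.choice(m, size=max(2, m // 10), replace=False)
        effects[causal] = rng.normal(0.0, 0.5, size=len(causal))
        x = disc.dosages @ effects + rng.normal(0.0, 1.0, size=n)
        gwas[f"score_{s + 1}"] = marginal_gwas(disc, x, trait=f"score_{s + 1}")
    return cohort, cohort.genotypes, gwas, specs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a manifest of produced artifacts.

    Aborts at validation before writing anything if the configuration is
    inconsistent or a referenced path is unreadable.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "dropped": []}

    if config.simulate is not None:
        cohort, panel, gwas, cohort_specs = _simulate_inputs(config)
        phenotypes, covariates = cohort.phenotypes, cohort.covariates
        scan_specs = [
            TraitSpec(name=s.name, family=s.family, levels=s.levels)
            for s in cohort_specs
        ]
    else:
        panel = atlas_io.read_dosage_matrix(config.panel_prefix)
        cohort_genotypes = (
            atlas_io.read_dosage_matrix(config.cohort_prefix)
            if config.cohort_prefix else panel
        )
        import pandas as pd

        phenotypes = pd.read_csv(config.phenotypes, sep="\t", index_col="iid")
        covariates = pd.read_csv(config.covariates_file, sep="\t", index_col="iid")
        gwas = {
            name: atlas_io.read_gwas(p, trait=name)
            for name, p in config.gwas_files.items()
        }
        scan_specs = [TraitSpec(name=c, family="continuous") for c in phenotypes.columns]

        class _C:  # minimal cohort shim for the file-based path
            pass

        cohort = _C()
        cohort.genotypes = cohort_genotypes

    scores = {}
    for name, stats in gwas.items():
        definition = ld_clump(
            stats, panel, p_threshold=config.p_threshold,
            r2_threshold=config.clump_r2,
            unweighted=name in config.unweighted_scores,
        )
        manifest["dropped"].extend(f"{name}: {line}" for line in definition.provenance)
        if len(definition) == 0:
            logger.warning("score %s has no SNPs at p<=%g; skipped", name, config.p_threshold)
            manifest["dropped"].append(f"{name}: skipped (empty definition)")
            continue
        sv = standardize_score(compute_score(cohort.genotypes, definition, name=name))
        scores[name] = sv
        dpath = out / f"{name}.definition.tsv"
        vpath = out / f"{name}.scores.tsv"
        atlas_io.write_score_definition(definition, dpath)
        atlas_io.write_score_vector(sv, vpath)
        manifest["outputs"][f"definition_{name}"] = str(dpath)
        manifest["outputs"][f"scores_{name}"] = str(vpath)

    cov = covariates[[c for c in config.covariates if c in covariates.columns]]
    result = run_scan(scores, phenotypes, cov, scan_specs)
    tsv, js = export_paths = atlas_io.export_atlas(
        result, out / "atlas",
        metadata={
            "seed": config.seed,
            "p_threshold": config.p_threshold,
            "clump_r2": config.clump_r2,
        },
    )
    manifest["outputs"]["atlas_tsv"] = str(tsv)
    manifest["outputs"]["atlas_json"] = str(js)

    # triage Bonferroni-passing hits where an outcome GWAS can be formed
    verdicts = {}
    hits = result.table[result.table["bonferroni_pass"] & result.table["converged"]]
    for _, row in hits.iterrows():
        family = row["family"]
        if family not in {"continuous", "binary"}:
            continue  # no summary-level outcome model for multi-level traits
        y = phenotypes[row["trait"]].to_numpy(dtype=float)
        outcome_stats = marginal_gwas(cohort.genotypes, y, trait=row["trait"])
        try:
            v = triage(
                gwas[row["score"]], outcome_stats, panel=panel,
                alpha=config.alpha, instrument_p=config.instrument_p,
            )
            verdicts[f"{row['score']}->{row['trait']}"] = v.to_dict()
        except MrError as exc:
            verdicts[f"{row['score']}->{row['trait']}"] = {"error": str(exc)}
    vpath = out / "triage.json"
    vpath.write_text(json.dumps(verdicts, indent=1, default=float))
    manifest["outputs"]["triage"] = str(vpath)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return manifest
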