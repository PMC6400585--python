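"""Reading and writing the pipeline's text formats.

GWAS summary statistics travel as tab-separated text with the canonical
header ``snp effect_allele other_allele eaf beta se pval n``; common header
dialects (b/beta, p/pval, a1/effect_allele, ...) are mapped automatically.
Genotypes are written either as a plain additive-dosage matrix with a SNP
metadata sidecar or as a minimal uncompressed VCF; phenotypes, covariates,
score definitions and score vectors are TSVs keyed by individual id.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GWAS_COLUMNS, VALID_ALLELES, GenotypeMatrix, GwasSummaryStats
from .prs import ScoreDefinition, ScoreVector
from .scan import ScanResult

logger = logging.getLogger(__name__)

#: Accepted aliases for each mandatory summary-statistics column.
COLUMN_ALIASES = {
    "snp": ["snp", "rsid", "markername", "variant_id", "id"],
    "effect_allele": ["effect_allele", "a1", "allele1", "ea"],
    "other_allele": ["other_allele", "a2", "allele2", "oa", "non_effect_allele"],
    "eaf": ["eaf", "effect_allele_frequency", "freq", "af"],
    "beta": ["beta", "b", "effect", "log_odds"],
    "se": ["se", "standard_error", "stderr"],
    "pval": ["pval", "p", "pvalue", "p_value"],
    "n": ["n", "samplesize", "sample_size", "n_total"],
}


def _map_columns(columns, column_map: dict | None) -> dict:
    mapping = {}
    lower = {c.lower(): c for c in columns}
    for canon, aliases in COLUMN_ALIASES.items():
        if column_map and canon in column_map:
            if column_map[canon] not in columns:
                raise ValueError(f"mapped column {column_map[canon]!r} not in file")
            mapping[canon] = column_map[canon]
            continue
        for alias in aliases:
            if alias in lower:
                mapping[canon] = lower[alias]
                break
        else:
            raise ValueError(f"missing mandatory column {canon!r} (aliases: {aliases})")
    return mapping


def read_gwas(
    path,
    column_map: dict | None = None,
    trait: str | None = None,
    trait_type: str = "continuous",
    sample_overlap: bool = False,
    sep: str = "\t",
) -> GwasSummaryStats:
    """Read and validate a summary-statistics file.

    Rows violating the invariants — non-positive or non-finite SE, p outside
    (0, 1], non-ACGT single-base alleles, duplicate SNP ids — are rejected
    with a line-numbered log message; a missing mandatory column is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    mapping = _map_columns(df.columns, column_map)
    df = df.rename(columns={v: k for k, v in mapping.items()})[GWAS_COLUMNS]
    # line numbers: header is line 1
    lines = np.arange(2, len(df) + 2)

    def reject(mask, reason):
        for ln in lines[mask.to_numpy()]:
            logger.warning("%s line %d rejected: %s", path.name, ln, reason)
        return ~mask

    ok = pd.Series(True, index=df.index)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    ok &= reject(~df["effect_allele"].isin(VALID_ALLELES)
                 | ~df["other_allele"].isin(VALID_ALLELES), "non-ACGT single-base allele")
    se = pd.to_numeric(df["se"], errors="coerce")
    ok &= reject(~(se > 0) | ~np.isfinite(se), "standard error not positive and finite")
    p = pd.to_numeric(df["pval"], errors="coerce")
    ok &= reject(~((p > 0) & (p <= 1)), "p-value outside (0, 1]")
    ok &= reject(df["snp"].duplicated(), "duplicate SNP id (first occurrence kept)")
    kept = df[ok].copy()
    for col in ("eaf", "beta", "se", "pval", "n"):
        kept[col] = pd.to_numeric(kept[col])
    logger.info("%s: %d rows read, %d kept", path.name, len(df), len(kept))
    return GwasSummaryStats(
        kept.reset_index(drop=True),
        trait=trait or path.stem,
        trait_type=trait_type,
        sample_overlap=sample_overlap,
    )


def write_gwas(stats: GwasSummaryStats, path) -> None:
    stats.to_tsv(path)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def write_dosage_matrix(genotypes: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write dosages as ``<prefix>.dosage.tsv`` plus ``<prefix>.snps.tsv`` sidecar."""
    prefix = Path(prefix)
    dosage_path = prefix.with_suffix(".dosage.tsv")
    sidecar_path = prefix.with_suffix(".snps.tsv")
    pd.DataFrame(
        genotypes.dosages, index=pd.Index(genotypes.iids, name="iid"),
        columns=genotypes.snp_ids,
    ).to_csv(dosage_path, sep="\t", float_format="%.10g")
    pd.DataFrame(
        {
            "snp": genotypes.snp_ids,
            "chrom": genotypes.chrom,
            "pos": genotypes.pos,
            "effect_allele": genotypes.effect_allele,
            "other_allele": genotypes.other_allele,
        }
    ).to_csv(sidecar_path, sep="\t", index=False)
    return dosage_path, sidecar_path


def read_dosage_matrix(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    dosages = pd.read_csv(prefix.with_suffix(".dosage.tsv"), sep="\t", index_col="iid")
    side = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
    if list(dosages.columns) != side["snp"].tolist():
        raise ValueError("dosage matrix and SNP sidecar disagree on SNP order")
    return GenotypeMatrix(
        dosages=dosages.to_numpy(dtype=float),
        snp_ids=side["snp"].to_numpy(),
        effect_allele=side["effect_allele"].to_numpy(),
        other_allele=side["other_allele"].to_numpy(),
        chrom=side["chrom"].to_numpy(),
        pos=side["pos"].to_numpy(),
        iids=dosages.index.to_numpy(),
    )


def write_vcf(genotypes: GenotypeMatrix, path) -> Path:
    """Minimal unphased VCF 4.2 with GT calls; reference = other allele."""
    path = Path(path)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.iids)) + "\n"
        )
        for j in range(genotypes.n_snps):
            calls = "\t".join(
                gt_map.get(d, "./.") for d in genotypes.dosages[:, j]
            )
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.pos[j]}\t{genotypes.snp_ids[j]}\t"
                f"{genotypes.other_allele[j]}\t{genotypes.effect_allele[j]}\t.\t.\t.\tGT\t"
                + calls + "\n"
            )
    return path


def read_vcf(path) -> GenotypeMatrix:
    """Read an uncompressed VCF of hard GT calls (ALT allele counted)."""
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    iids = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                iids = fields[9:]
                continue
            chroms.append(fields[0])
            poss.append(int(fields[1]))
            snp_ids.append(fields[2])
            refs.append(fields[3])
            alts.append(fields[4])
            gt_idx = fields[8].split(":").index("GT")
            row = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_idx].replace("|", "/")
                row.append(
                    np.nan if "." in gt else float(sum(int(a) for a in gt.split("/")))
                )
            rows.append(row)
    if iids is None:
        raise ValueError(f"{path}: no #CHROM header line")
    return GenotypeMatrix(
        dosages=np.array(rows, dtype=float).T,
        snp_ids=np.array(snp_ids),
        effect_allele=np.array(alts),
        other_allele=np.array(refs),
        chrom=np.array(chroms),
        pos=np.array(poss),
        iids=np.array(iids),
    )


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def write_score_definition(definition: ScoreDefinition, path) -> None:
    definition.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_score_definition(path, weighted: bool = True) -> ScoreDefinition:
    df = pd.read_csv(path, sep="\t")
    return ScoreDefinition(
        snp=df["snp"].tolist(),
        effect_allele=df["effect_allele"].tolist(),
        weight=df["weight"].to_numpy(),
        weighted=weighted,
        source=df["source"].tolist() if "source" in df else [],
    )


def write_score_vector(score: ScoreVector, path) -> None:
    score.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_score_vector(path, name: str = "score") -> ScoreVector:
    df = pd.read_csv(path, sep="\t")
    return ScoreVector(
        iids=df["iid"].to_numpy(),
        raw=df["raw"].to_numpy(),
        standardized=df["standardized"].to_numpy(),
        n_snps_used=0,
        name=name,
    )


# ---------------------------------------------------------------------------
# Atlas export
# ---------------------------------------------------------------------------

ATLAS_COLUMNS = [
    "score", "trait", "family", "estimate", "se", "p", "odds_ratio",
    "ci_low", "ci_high", "r2", "n", "signed_log10p", "bonferroni_pass",
    "converged", "note",
]


def export_atlas(result: ScanResult, out_prefix, metadata: dict | None = None):
    """Write the scan as ``<prefix>.tsv`` and ``<prefix>.json``.

    Column order is deterministic; floats are written with 17 significant
    digits so a round-trip read reproduces values to 1e-12.  The JSON carries
    run metadata (thresholds, seed, version) alongside the rows.
    """
    from . import __version__

    out_prefix = Path(out_prefix)
    tsv = out_prefix.with_suffix(".tsv")
    js = out_prefix.with_suffix(".json")
    table = result.table[ATLAS_COLUMNS]
    table.to_csv(tsv, sep="\t", index=False, float_format="%.17g")
    payload = {
        "metadata": {
            "version": __version__,
            "n_tests": result.n_tests,
            "bonferroni_threshold": result.bonferroni_threshold,
            **(metadata or {}),
        },
        "results": json.loads(table.to_json(orient="records")),
    }
    js.write_text(json.dumps(payload, indent=1))
    return tsv, js


def read_atlas(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t")
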