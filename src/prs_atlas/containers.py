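"""Core in-memory containers shared across the pipeline.

Two containers travel through every stage: :class:`GwasSummaryStats`, the
per-SNP association records of a single trait (used both as score weights and
as instrument effects), and :class:`GenotypeMatrix`, additive-coded hard-call
dosages for a set of individuals (used both as the LD reference panel and as
the cohort genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column order of a summary-statistics table.
GWAS_COLUMNS = [
    "snp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be resolved by alleles."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class GwasSummaryStats:
    """Summary statistics of one GWAS: one row per biallelic SNP.

    ``table`` must carry the columns in :data:`GWAS_COLUMNS`.  ``beta`` is the
    per-effect-allele effect (log odds ratio for binary traits), ``eaf`` the
    effect-allele frequency and ``n`` the per-SNP sample size.
    """

    table: pd.DataFrame
    trait: str = "trait"
    trait_type: str = "continuous"  # "continuous" or "binary"
    sample_overlap: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if self.table["snp"].duplicated().any():
            dups = self.table.loc[self.table["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate SNP ids in summary statistics: {dups[:5]}")
        self.table = self.table[GWAS_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def significant(self, p_threshold: float) -> pd.DataFrame:
        """Rows whose association p-value passes ``p_threshold``."""
        return self.table[self.table["pval"] <= p_threshold].copy()

    def subset(self, snps) -> "GwasSummaryStats":
        keep = self.table[self.table["snp"].isin(np.asarray(snps))]
        return GwasSummaryStats(
            keep.copy(), self.trait, self.trait_type, self.sample_overlap
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class GenotypeMatrix:
    """Additive hard-call dosages, individuals x SNPs.

    Entries are 0/1/2 counts of the effect allele; ``nan`` marks a missing
    call.  Positions are 1-based, matching the VCF convention.  Doubles as the
    LD reference panel, in which case positions must be strictly increasing
    within a chromosome.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    iids: np.ndarray | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        for name in ("snp_ids", "effect_allele", "other_allele", "chrom", "pos"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n, m = self.dosages.shape
        if not (
            len(self.snp_ids) == len(self.effect_allele) == len(self.other_allele)
            == len(self.chrom) == len(self.pos) == m
        ):
            raise ValueError("SNP metadata length does not match dosage columns")
        if self.iids is None:
            self.iids = np.array([f"id_{i}" for i in range(n)])
        if len(np.unique(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids in genotype matrix")
        lo, hi = np.nanmin(self.dosages, initial=0), np.nanmax(self.dosages, initial=2)
        if lo < 0 or hi > 2:
            raise ValueError("dosages outside [0, 2]")
        self._index = {s: j for j, s in enumerate(self.snp_ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """Empirical effect-allele frequencies, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def index_of(self, snp: str) -> int:
        try:
            return self._index[snp]
        except KeyError:
            raise KeyError(f"SNP {snp!r} not in genotype matrix") from None

    def column(self, snp: str) -> np.ndarray:
        return self.dosages[:, self.index_of(snp)]

    def validate_hard_calls(self) -> None:
        """Assert every non-missing entry is an integer dosage in {0, 1, 2}."""
        d = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(d, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-hard-call dosage present")

    # -- LD ----------------------------------------------------------------
    def corr(self, snp_a: str, snp_b: str) -> float:
        """Pearson correlation of dosages between two SNPs (signed r)."""
        a = self.column(snp_a)
        b = self.column(snp_b)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    def r2(self, snp_a: str, snp_b: str) -> float:
        return self.corr(snp_a, snp_b) ** 2

    def subset(self, snps) -> "GenotypeMatrix":
        idx = [self.index_of(s) for s in snps]
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.snp_ids[idx],
            self.effect_allele[idx],
            self.other_allele[idx],
            self.chrom[idx],
            self.pos[idx],
            self.iids,
        )


#: The LD reference panel is a genotype matrix whose positions matter.
ReferencePanel = GenotypeMatrix
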