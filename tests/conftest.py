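"""Shared fixtures: hand-built genotype panels and instrument sets."""

import numpy as np
import pandas as pd
import pytest

from prs_atlas.containers import GWAS_COLUMNS, GenotypeMatrix, GwasSummaryStats
from prs_atlas.mr import InstrumentSet


def make_panel(columns: dict, chrom=None, pos=None, effect=None, other=None):
    """GenotypeMatrix from a dict of snp -> dosage list."""
    snps = list(columns)
    dos = np.column_stack([np.asarray(columns[s], dtype=float) for s in snps])
    m = len(snps)
    return GenotypeMatrix(
        dosages=dos,
        snp_ids=np.array(snps),
        effect_allele=np.array(effect or ["A"] * m),
        other_allele=np.array(other or ["G"] * m),
        chrom=np.array(chrom or [1] * m),
        pos=np.array(pos if pos is not None else 1 + 100_000 * np.arange(m)),
    )


def make_stats(rows, trait="exposure", **kwargs):
    """GwasSummaryStats from a list of dicts with defaults filled in."""
    defaults = {
        "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
        "beta": 0.1, "se": 0.02, "pval": 1e-10, "n": 10_000,
    }
    table = pd.DataFrame([{**defaults, **r} for r in rows], columns=GWAS_COLUMNS)
    return GwasSummaryStats(table, trait=trait, **kwargs)


def make_instruments(beta_exp, se_exp, beta_out, se_out, **kwargs):
    J = len(beta_exp)
    return InstrumentSet(
        snp=np.array([f"rs{j + 1}" for j in range(J)]),
        beta_exposure=np.asarray(beta_exp, dtype=float),
        se_exposure=np.asarray(se_exp, dtype=float),
        beta_outcome=np.asarray(beta_out, dtype=float),
        se_outcome=np.asarray(se_out, dtype=float),
        n_exposure=kwargs.pop("n_exposure", 50_000),
        n_outcome=kwargs.pop("n_outcome", 50_000),
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def orthogonal_panel():
    """Three mutually uncorrelated SNPs (balanced design, exact zero r)."""
    a = [0] * 4 + [1] * 4 + [2] * 4
    b = [0, 2, 0, 2] * 3
    c = [0, 0, 2, 2] * 3
    return make_panel({"rs1": a, "rs2": b, "rs3": c})


@pytest.fixture
def clump_panel():
    """rs1 and rs2 correlated (r^2 = 0.25); rs3 exactly independent of both."""
    s1 = [0, 0, 1, 1, 2, 2]
    s2 = [0, 0, 2, 2, 1, 1]
    s3 = [0, 2, 0, 2, 0, 2]
    return make_panel({"rs1": s1, "rs2": s2, "rs3": s3})
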