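"""Shared fixtures: small synthetic studies and hand-built instrument fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cismr.instruments import GeneAnnotation, InstrumentSet
from cismr.simulate import LDMatrix, SimulationConfig, generate_paired_study


def make_sumstats(
    snp_ids,
    beta,
    se,
    pos=None,
    chrom="1",
    eaf=0.3,
    n=10_000,
    effect_allele="A",
    other_allele="G",
) -> pd.DataFrame:
    """Build a consistent summary-statistics table for tests."""
    L = len(snp_ids)
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": chrom,
            "pos": list(pos) if pos is not None else 3_000_000 + 10_000 * np.arange(L),
            "effect_allele": effect_allele if isinstance(effect_allele, list)
            else [effect_allele] * L,
            "other_allele": other_allele if isinstance(other_allele, list)
            else [other_allele] * L,
            "eaf": eaf if np.ndim(eaf) else [eaf] * L,
            "beta": beta,
            "se": se,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "n": n,
        }
    )


def ar1_ld(snp_ids, rho) -> LDMatrix:
    idx = np.arange(len(snp_ids))
    return LDMatrix(tuple(snp_ids), rho ** np.abs(idx[:, None] - idx[None, :]))


def make_instrument_set(
    protein_id="PROT1",
    n_snps=6,
    rho=0.3,
    b_zx=None,
    se_zx=0.03,
    p_thresh=1e-6,
    r2_thresh=0.6,
) -> InstrumentSet:
    """Instrument set with exposure-side effects, ready for run_grid."""
    snp_ids = [f"{protein_id}_snp{i}" for i in range(n_snps)]
    if b_zx is None:
        b_zx = np.linspace(0.5, 0.3, n_snps)
    b_zx = np.asarray(b_zx, dtype=float)
    se = np.full(n_snps, se_zx)
    p_zx = np.clip(2.0 * stats.norm.sf(np.abs(b_zx / se)),
                   np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": 3_000_000 + 10_000 * np.arange(n_snps),
            "effect_allele": "A",
            "other_allele": "G",
            "eaf_zx": 0.3,
            "b_zx": b_zx,
            "se_zx": se,
            "p_zx": p_zx,
            "n_zx": 872,
            "eaf_zy": 0.3,
            "b_zy": 0.0,
            "se_zy": 0.02,
            "p_zy": 1.0,
            "n_zy": 20_000,
        }
    )
    return InstrumentSet(
        protein_id=protein_id,
        table=table,
        ld_outcome=ar1_ld(snp_ids, rho),
        p_thresh=p_thresh,
        r2_thresh=r2_thresh,
        window_bp=2_000_000,
        heidi_capable=n_snps >= 5,
    )


@pytest.fixture(scope="session")
def small_study():
    """One modest paired study reused by read-only tests."""
    cfg = SimulationConfig(seed=42, n_outcome=4_000, n_cases=400)
    return generate_paired_study(cfg)


@pytest.fixture(scope="session")
def gene_fixture():
    return GeneAnnotation("GENE1", "1", 3_000_000, 3_100_000)
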