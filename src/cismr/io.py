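"""Plain-text readers and writers for the pipeline's tables.

All tables are tab-separated with a header row. Positions are 1-based;
BED gene input (0-based half-open) is converted on read. The summary-stats
writer emits a COJO-compatible column subset (SNP, A1, A2, freq, b, se, p, N)
plus CHR/POS.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gwas import SUMSTATS_COLUMNS, validate_sumstats
from .instruments import GeneAnnotation, InstrumentSet
from .simulate import GenotypePanel, LDMatrix, SimulationTruth

__all__ = [
    "write_dosages", "read_dosages",
    "write_phenotypes", "read_phenotypes",
    "write_variants", "read_variants",
    "write_ld_matrix", "read_ld_matrix",
    "write_truth", "read_truth",
    "write_sumstats", "read_sumstats",
    "write_instrument_set", "read_instrument_set",
    "read_genes",
]

_COJO_MAP = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "POS",
    "effect_allele": "A1", "other_allele": "A2",
    "eaf": "freq", "beta": "b", "se": "se", "p": "p", "n": "N",
}


def write_dosages(panel: GenotypePanel, path) -> None:
    # samples x SNPs, header row of SNP ids, first column sample_id
    df = pd.DataFrame(panel.dosages, columns=list(panel.snp_ids))
    df.insert(0, "sample_id", list(panel.sample_ids))
    df.to_csv(path, sep="\t", index=False)


def read_dosages(path, variants: pd.DataFrame | None = None) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    sample_ids = tuple(df["sample_id"].astype(str))
    snp_ids = tuple(df.columns[1:])
    dos = df.iloc[:, 1:].to_numpy(dtype=float)
    if variants is None:
        variants = pd.DataFrame(
            {"snp_id": snp_ids, "chrom": "NA", "pos": 0,
             "effect_allele": "NA", "other_allele": "NA",
             "eaf": dos.mean(axis=0) / 2.0}
        )
    return GenotypePanel(sample_ids, snp_ids, dos, variants)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variants(variants: pd.DataFrame, path) -> None:
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]
    variants[cols].to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int)
    return df


def write_ld_matrix(ld: LDMatrix, path) -> None:
    ld.to_dataframe().to_csv(path, sep="\t", index=True, index_label="snp_id")


def read_ld_matrix(path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return LDMatrix.from_dataframe(df)


def write_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "true_b": float(truth.true_b),
        "causal_snp_ids": list(truth.causal_snp_ids),
        "pleiotropic_snp_ids": list(truth.pleiotropic_snp_ids),
        "per_snp_effects": {k: float(v) for k, v in truth.per_snp_effects.items()},
        "realized_h2": float(truth.realized_h2),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return SimulationTruth(
        true_b=d["true_b"],
        causal_snp_ids=tuple(d["causal_snp_ids"]),
        pleiotropic_snp_ids=tuple(d["pleiotropic_snp_ids"]),
        per_snp_effects=d["per_snp_effects"],
        realized_h2=d["realized_h2"],
    )


def write_sumstats(df: pd.DataFrame, path) -> None:
    out = df[SUMSTATS_COLUMNS].rename(columns=_COJO_MAP)
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path, validate: bool = True) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    inv = {v: k for k, v in _COJO_MAP.items()}
    df = raw.rename(columns=inv)
    if validate:
        validate_sumstats(df)
    return df


def write_instrument_set(iset: InstrumentSet, table_path, sidecar_path) -> None:
    iset.table.to_csv(table_path, sep="\t", index=False)
    meta = {
        "protein_id": iset.protein_id,
        "p_thresh": float(iset.p_thresh),
        "r2_thresh": float(iset.r2_thresh),
        "window_bp": int(iset.window_bp),
        "heidi_capable": bool(iset.heidi_capable),
        "ld_outcome": {
            "snp_ids": list(iset.ld_outcome.snp_ids),
            "values": np.asarray(iset.ld_outcome.values).tolist(),
        },
    }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh)


def read_instrument_set(table_path, sidecar_path) -> InstrumentSet:
    table = pd.read_csv(table_path, sep="\t", dtype={"chrom": str})
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    ld = LDMatrix(tuple(meta["ld_outcome"]["snp_ids"]),
                  np.array(meta["ld_outcome"]["values"], dtype=float))
    return InstrumentSet(
        protein_id=meta["protein_id"],
        table=table,
        ld_outcome=ld,
        p_thresh=meta["p_thresh"],
        r2_thresh=meta["r2_thresh"],
        window_bp=meta["window_bp"],
        heidi_capable=meta["heidi_capable"],
    )


def read_genes(path) -> list[GeneAnnotation]:
    """Gene annotations from TSV (1-based, with header) or BED (0-based)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene_id"],
                         dtype={"chrom": str})
        return [
            GeneAnnotation.from_bed_row(r.gene_id, r.chrom, int(r.start), int(r.end))
            for r in df.itertuples()
        ]
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneAnnotation(r.gene_id, r.chrom, int(r.start), int(r.end))
        for r in df.itertuples()
    ]
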