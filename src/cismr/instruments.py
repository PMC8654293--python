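"""Instrument selection: cis windows, harmonization and dual-cohort pruning.

A protein's instruments are cis SNPs: variants inside the coding gene's
end points plus a flanking window (default 2 Mb each side) that pass the
exposure-association threshold in the exposure cohort. Candidate SNPs present
in both cohorts are harmonized to a common effect allele, then thinned by a
greedy loop that repeatedly takes the SNP with the smallest exposure p-value
and discards everything in strong LD with it (r-squared above the threshold)
in *either* cohort's LD estimate. Proteins retaining fewer than ``min_iv``
instruments are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .simulate import LDMatrix

__all__ = [
    "GeneAnnotation",
    "InstrumentSet",
    "InstrumentRejection",
    "PALINDROMIC_PAIRS",
    "cis_window",
    "intersect_and_harmonize",
    "greedy_prune",
    "select_instruments",
]

#: strand-ambiguous allele pairs excluded at harmonization by default
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene's location; start/end are 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start must not exceed end")

    @classmethod
    def from_bed_row(cls, gene_id: str, chrom: str, bed_start: int, bed_end: int):
        """Convert a 0-based half-open BED interval to 1-based inclusive."""
        return cls(gene_id, chrom, bed_start + 1, bed_end)


@dataclass(frozen=True)
class InstrumentSet:
    """Harmonized instruments for one protein, ready for MR estimation.

    ``table`` has one row per selected SNP (in selection order) with both
    cohorts' effects on the common effect allele; ``ld_outcome`` is the
    signed outcome-cohort correlation matrix in the same order — the matrix
    used for covariance modelling during estimation.
    """

    protein_id: str
    table: pd.DataFrame
    ld_outcome: LDMatrix
    p_thresh: float
    r2_thresh: float
    window_bp: int
    heidi_capable: bool = field(default=True)

    def __post_init__(self) -> None:
        if len(self.table) < 1:
            raise ValueError("an instrument set needs at least one SNP")
        if list(self.table["snp_id"]) != list(self.ld_outcome.snp_ids):
            raise ValueError("LD matrix order must match the SNP table")
        if (self.table["p_zx"] >= self.p_thresh).any():
            raise ValueError("all instruments must pass the exposure p threshold")

    @property
    def n_instruments(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class InstrumentRejection:
    """Record of a protein excluded from analysis, with the reason."""

    protein_id: str
    reason: str
    n_selected: int


def cis_window(gene: GeneAnnotation, window_bp: int = 2_000_000) -> tuple[str, int, int]:
    """Cis-regulatory interval: gene end points padded by ``window_bp`` each side.

    Returns ``(chrom, start, end)``, 1-based inclusive at both ends, clamped
    at position 1.
    """
    return gene.chrom, max(1, gene.start - window_bp), gene.end + window_bp


def intersect_and_harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exclude_palindromic: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join exposure and outcome summary stats on shared SNPs, aligning alleles.

    SNPs present in only one table are dropped silently (they are not
    candidates). Where the outcome's effect/other alleles are swapped
    relative to the exposure, the outcome beta changes sign and its EAF
    becomes 1 - EAF. Irreconcilable allele sets and (by default)
    strand-ambiguous palindromic SNPs are excluded with a logged reason.

    Returns ``(joined, exclusions)``; ``joined`` carries exposure columns
    suffixed ``_zx`` and outcome columns suffixed ``_zy`` on a common
    effect allele.
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r} in {name} table")
    merged = exposure.merge(
        outcome, on="snp_id", suffixes=("_x", "_y"), how="inner"
    )
    rows, excluded = [], []
    for rec in merged.itertuples(index=False):
        a1x, a2x = str(rec.effect_allele_x), str(rec.other_allele_x)
        a1y, a2y = str(rec.effect_allele_y), str(rec.other_allele_y)
        if exclude_palindromic and (a1x, a2x) in PALINDROMIC_PAIRS:
            excluded.append((rec.snp_id, "palindromic"))
            continue
        if (a1y, a2y) == (a1x, a2x):
            flip = 1.0
            eaf_y = rec.eaf_y
        elif (a1y, a2y) == (a2x, a1x):
            flip = -1.0
            eaf_y = 1.0 - rec.eaf_y
        else:
            excluded.append((rec.snp_id, "allele mismatch"))
            continue
        rows.append(
            {
                "snp_id": rec.snp_id,
                "chrom": rec.chrom_x,
                "pos": rec.pos_x,
                "effect_allele": a1x,
                "other_allele": a2x,
                "eaf_zx": rec.eaf_x,
                "b_zx": rec.beta_x,
                "se_zx": rec.se_x,
                "p_zx": rec.p_x,
                "n_zx": rec.n_x,
                "eaf_zy": eaf_y,
                "b_zy": flip * rec.beta_y,
                "se_zy": rec.se_y,
                "p_zy": rec.p_y,
                "n_zy": rec.n_y,
            }
        )
    joined = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf_zx", "b_zx", "se_zx", "p_zx", "n_zx",
            "eaf_zy", "b_zy", "se_zy", "p_zy", "n_zy",
        ],
    )
    exclusions = pd.DataFrame(excluded, columns=["snp_id", "reason"])
    return joined, exclusions


def greedy_prune(
    candidates: pd.DataFrame,
    ld_exposure: LDMatrix,
    ld_outcome: LDMatrix,
    p_thresh: float = 1e-6,
    r2_thresh: float = 0.6,
) -> list[str]:
    """Greedy dual-cohort LD thinning of exposure-associated candidates.

    Loop: (i) select the remaining SNP with the smallest exposure p-value;
    (ii) remove every SNP whose squared correlation with it exceeds
    ``r2_thresh`` in either cohort's LD estimate; (iii) repeat until no
    candidate remains. Ties on p break by smaller position, then
    lexicographic snp_id. The returned list (in selection order) is pairwise
    below the r-squared threshold in both cohorts.
    """
    if candidates.empty:
        return []
    for ld, name in ((ld_exposure, "exposure"), (ld_outcome, "outcome")):
        missing = set(candidates["snp_id"]) - set(ld.snp_ids)
        if missing:
            raise KeyError(
                f"SNP(s) missing from the {name} LD matrix: {sorted(missing)[:5]}"
            )
    pool = candidates.loc[candidates["p_zx"] < p_thresh,
                          ["snp_id", "pos", "p_zx"]].copy()
    pool = pool.sort_values(["p_zx", "pos", "snp_id"]).reset_index(drop=True)
    r2x = pd.DataFrame(ld_exposure.r2, index=list(ld_exposure.snp_ids),
                       columns=list(ld_exposure.snp_ids))
    r2y = pd.DataFrame(ld_outcome.r2, index=list(ld_outcome.snp_ids),
                       columns=list(ld_outcome.snp_ids))
    selected: list[str] = []
    remaining = list(pool["snp_id"])
    while remaining:
        top = remaining[0]
        selected.append(top)
        keep = []
        for s in remaining[1:]:
            if r2x.at[top, s] > r2_thresh or r2y.at[top, s] > r2_thresh:
                continue
            keep.append(s)
        remaining = keep
    return selected


def select_instruments(
    protein_id: str,
    gene: GeneAnnotation,
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld_exposure: LDMatrix,
    ld_outcome: LDMatrix,
    p_thresh: float = 1e-6,
    r2_thresh: float = 0.6,
    min_iv: int = 4,
    window_bp: int = 2_000_000,
    exclude_palindromic: bool = True,
) -> InstrumentSet | InstrumentRejection:
    """Full instrument-selection pipeline for one protein.

    Applies, in order: cis-window restriction of the exposure scan,
    cross-cohort intersection and allele harmonization, the exposure
    p-value threshold, and greedy dual-cohort LD pruning. Returns an
    :class:`InstrumentSet` (with the outcome-cohort signed LD matrix
    attached and ``heidi_capable`` false when fewer than five instruments
    survive) or an :class:`InstrumentRejection` when fewer than ``min_iv``
    remain.
    """
    chrom, lo, hi = cis_window(gene, window_bp)
    in_cis = (
        (exposure["chrom"].astype(str) == str(chrom))
        & (exposure["pos"] >= lo)
        & (exposure["pos"] <= hi)
    )
    joined, _ = intersect_and_harmonize(
        exposure.loc[in_cis], outcome, exclude_palindromic=exclude_palindromic
    )
    joined = joined.loc[joined["p_zx"] < p_thresh].reset_index(drop=True)
    chosen = greedy_prune(joined, ld_exposure, ld_outcome,
                          p_thresh=p_thresh, r2_thresh=r2_thresh)
    if len(chosen) < min_iv:
        return InstrumentRejection(
            protein_id=protein_id,
            reason=f"n_selected < min_iv ({len(chosen)} < {min_iv})",
            n_selected=len(chosen),
        )
    table = (
        joined.set_index("snp_id").loc[chosen].reset_index()
    )
    return InstrumentSet(
        protein_id=protein_id,
        table=table,
        ld_outcome=ld_outcome.submatrix(chosen),
        p_thresh=p_thresh,
        r2_thresh=r2_thresh,
        window_bp=window_bp,
        heidi_capable=len(chosen) >= 5,
    )
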