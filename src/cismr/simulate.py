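"""Synthetic paired-cohort generator for two-sample Mendelian randomization.

The generator produces the data structures the rest of the pipeline consumes,
with the statistical features the analysis assumes:

* an exposure cohort (default n = 872) in which a circulating protein level is
  driven by a handful of cis SNPs plus covariates and Gaussian noise, with a
  controllable fraction of protein variance explained;
* a much larger, disjoint case-control outcome cohort in which disease status
  follows a logistic model whose linear predictor carries the protein's
  genetic value (scaled to protein-SD units, so the configured ``true_b`` is
  the log-odds effect per SD of protein that every MR estimator targets),
  optional direct SNP effects (horizontal pleiotropy), and covariates;
* block-structured linkage disequilibrium shared by both cohorts, realised
  through a Gaussian-copula genotype model with two latent draws per
  individual (Hardy-Weinberg by construction).

Because the causal path from SNP to disease runs through the SNP->protein
genetic value, every instrument is valid by construction unless it is given a
planted direct effect, making recovery of ``true_b`` a well-posed test of the
downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "GenotypePanel",
    "LDMatrix",
    "PairedStudy",
    "simulate_ld_matrix",
    "simulate_genotypes",
    "generate_paired_study",
    "simulate_summary_mr",
    "dosage_correlation",
]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class LDMatrix:
    """Signed SNP correlation matrix r over an ordered SNP list."""

    snp_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("LD matrix must be square")
        if len(self.snp_ids) != v.shape[0]:
            raise ValueError("snp_ids length must match matrix dimension")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))

    @property
    def r2(self) -> np.ndarray:
        return self.values**2

    def submatrix(self, snp_ids) -> "LDMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return LDMatrix(tuple(snp_ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.snp_ids),
                            columns=list(self.snp_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LDMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("LD table row and column SNP ids must match")
        return cls(tuple(df.index), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class GenotypePanel:
    """Individual-level dosages plus per-SNP annotation for one cohort.

    ``dosages`` is an (n_samples, n_snps) array with entries in [0, 2];
    ``variants`` carries snp_id, chrom, pos (1-based), effect_allele,
    other_allele and eaf.
    """

    sample_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        if d.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match ids")
        if d.min() < 0 or d.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        object.__setattr__(self, "dosages", d)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one paired exposure/outcome study.

    Defaults mirror the study conditions the pipeline is designed around: an
    exposure cohort of 872 individuals with a protein whose cis architecture
    explains ~30% of variance through ten SNPs in two weakly correlated LD
    blocks, and an outcome cohort of 20,000 with 2,000 expected cases and a
    protective causal effect of OR 0.84 per protein SD.
    """

    seed: int = 0
    n_exposure: int = 872
    n_outcome: int = 20_000
    n_cases: int = 2_000
    n_snps_per_block: tuple[int, ...] = (5, 5)
    block_rho: float | tuple[float, ...] = 0.3
    eaf_range: tuple[float, float] = (0.1, 0.5)
    n_causal: int = 10
    h2_target: float = 0.3
    true_b: float = float(np.log(0.84))
    pleio_fraction: float = 0.0
    pleio_effect_sd: float = 0.05
    pleio_mean: float = 0.0
    n_pcs: int = 2

    def __post_init__(self) -> None:
        if self.n_cases >= self.n_outcome:
            raise InvalidConfigError("n_cases must be smaller than n_outcome")
        if not 0.0 < self.h2_target < 1.0:
            raise InvalidConfigError("h2_target must lie in (0, 1)")
        if not 0.0 <= self.pleio_fraction <= 1.0:
            raise InvalidConfigError("pleio_fraction must lie in [0, 1]")
        rhos = self.block_rhos
        if len(rhos) != len(self.n_snps_per_block):
            raise InvalidConfigError("one block_rho per block required")
        if any(not 0.0 <= r < 1.0 for r in rhos):
            raise InvalidConfigError("block_rho must lie in [0, 1)")
        if any(m < 1 for m in self.n_snps_per_block):
            raise InvalidConfigError("block sizes must be >= 1")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise InvalidConfigError("eaf_range must lie inside (0, 1)")
        if self.n_causal > self.n_snps:
            raise InvalidConfigError("n_causal exceeds the number of SNPs")

    @property
    def n_snps(self) -> int:
        return int(sum(self.n_snps_per_block))

    @property
    def block_rhos(self) -> tuple[float, ...]:
        if np.isscalar(self.block_rho):
            return (float(self.block_rho),) * len(self.n_snps_per_block)
        return tuple(float(r) for r in self.block_rho)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth kept alongside a synthetic study for recovery tests."""

    true_b: float
    causal_snp_ids: tuple[str, ...]
    pleiotropic_snp_ids: tuple[str, ...]
    per_snp_effects: dict[str, float]
    realized_h2: float


@dataclass(frozen=True)
class PairedStudy:
    """One synthetic two-sample study: disjoint cohorts sharing LD structure."""

    exposure: GenotypePanel
    protein: np.ndarray
    exposure_covariates: pd.DataFrame
    outcome: GenotypePanel
    case_status: np.ndarray
    outcome_covariates: pd.DataFrame
    ld: LDMatrix
    truth: SimulationTruth
    gene: "pd.Series | None" = None


def simulate_ld_matrix(config: SimulationConfig) -> LDMatrix:
    """Block-diagonal AR(1) signed LD matrix: within a block r_ij = rho^|i-j|.

    Cross-block correlations are exactly zero; the result is symmetric with
    unit diagonal and positive definite for any rho in [0, 1).
    """
    blocks = []
    for size, rho in zip(config.n_snps_per_block, config.block_rhos):
        idx = np.arange(size)
        blocks.append(rho ** np.abs(idx[:, None] - idx[None, :]))
    r = linalg.block_diag(*blocks)
    snp_ids = tuple(f"snp_{i:04d}" for i in range(r.shape[0]))
    return LDMatrix(snp_ids, r)


def dosage_correlation(r_latent: float, eaf_i: float, eaf_j: float) -> float:
    """Population dosage correlation implied by the Gaussian copula.

    Each haplotype carries the effect allele when its latent Gaussian falls
    below Phi^-1(eaf); the allele-level correlation is the tetrachoric-style
    quantity (Phi2(t_i, t_j; r) - p_i p_j) / sqrt(p_i q_i p_j q_j), and the
    dosage (sum of two independent haplotypes) inherits it unchanged.
    """
    ti, tj = stats.norm.ppf(eaf_i), stats.norm.ppf(eaf_j)
    p_both = stats.multivariate_normal.cdf(
        [ti, tj], mean=[0.0, 0.0], cov=[[1.0, r_latent], [r_latent, 1.0]]
    )
    num = p_both - eaf_i * eaf_j
    den = np.sqrt(eaf_i * (1 - eaf_i) * eaf_j * (1 - eaf_j))
    return float(num / den)


def simulate_genotypes(
    ld: LDMatrix,
    eafs: np.ndarray,
    n: int,
    seed: "int | np.random.Generator",
    variants: pd.DataFrame | None = None,
    sample_prefix: str = "S",
) -> GenotypePanel:
    """Draw genotype dosages with the target LD via a Gaussian copula.

    Two independent latent MVN(0, R) vectors per individual are thresholded
    at Phi^-1(eaf) and summed, giving Hardy-Weinberg dosages whose pairwise
    correlation approximates the signed latent r.
    """
    eafs = np.asarray(eafs, dtype=float)
    m = ld.values.shape[0]
    if eafs.shape != (m,):
        raise ValueError("eafs length must match the LD matrix dimension")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = np.linalg.cholesky(ld.values)
    thresholds = stats.norm.ppf(eafs)
    hap1 = rng.standard_normal((n, m)) @ chol.T < thresholds
    hap2 = rng.standard_normal((n, m)) @ chol.T < thresholds
    dosages = (hap1.astype(float) + hap2.astype(float))
    if variants is None:
        variants = pd.DataFrame(
            {
                "snp_id": list(ld.snp_ids),
                "chrom": "1",
                "pos": 1 + 10_000 * np.arange(m),
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": eafs,
            }
        )
    sample_ids = tuple(f"{sample_prefix}{i:06d}" for i in range(n))
    return GenotypePanel(sample_ids, ld.snp_ids, dosages, variants.reset_index(drop=True))


def _covariate_table(rng: np.random.Generator, n: int, n_pcs: int,
                     prefix: str) -> pd.DataFrame:
    cov = {
        "sex": rng.integers(0, 2, size=n).astype(float),
        "age": rng.normal(55.0, 8.0, size=n),
    }
    for k in range(n_pcs):
        cov[f"pc{k + 1}"] = rng.standard_normal(n)
    df = pd.DataFrame(cov)
    df.insert(0, "sample_id", [f"{prefix}{i:06d}" for i in range(n)])
    return df


def _covariate_effect(df: pd.DataFrame, betas: dict[str, float]) -> np.ndarray:
    """Linear covariate contribution with age used on a standardized scale."""
    age_std = (df["age"].to_numpy() - df["age"].mean()) / df["age"].std()
    out = betas["sex"] * df["sex"].to_numpy() + betas["age"] * age_std
    for col in df.columns:
        if col.startswith("pc"):
            out = out + betas["pc"] * df[col].to_numpy()
    return out


def generate_paired_study(config: SimulationConfig) -> PairedStudy:
    """Generate one full two-sample study with known ground truth.

    The exposure cohort's protein is ``genetic value + covariates + noise``
    with the noise variance set so that the genetic fraction of total protein
    variance equals ``h2_target``. The outcome cohort (disjoint individuals,
    same SNPs and LD) gets disease labels from a logistic model whose linear
    predictor is ``alpha + true_b * (genetic value / protein SD) + direct
    pleiotropic SNP effects + covariates``, with alpha tuned by root-finding
    so the expected case count equals ``n_cases``. Scaling the genetic value
    by the protein SD makes ``true_b`` the log-odds effect per protein SD --
    exactly the per-SNP Wald-ratio estimand.
    """
    rng = np.random.default_rng(config.seed)
    ld = simulate_ld_matrix(config)
    m = config.n_snps
    eafs = rng.uniform(*config.eaf_range, size=m)

    # shared variant annotation: one chromosome, SNPs inside a synthetic
    # gene's cis window so instrument selection can run end to end
    gene = pd.Series({"gene_id": "GENE1", "chrom": "1",
                      "start": 3_000_000, "end": 3_100_000})
    positions = 3_050_000 - 5_000 * (m // 2) + 10_000 * np.arange(m)
    variants = pd.DataFrame(
        {
            "snp_id": list(ld.snp_ids),
            "chrom": "1",
            "pos": positions,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eafs,
        }
    )

    exposure = simulate_genotypes(ld, eafs, config.n_exposure, rng,
                                  variants=variants, sample_prefix="EXP")
    outcome = simulate_genotypes(ld, eafs, config.n_outcome, rng,
                                 variants=variants, sample_prefix="OUT")

    causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    # per-SNP effect sizes: cis architecture with a dominant lead pQTL.
    # The lead SNP carries 40% of the genetic variance (~12% of protein
    # variance at the default h2), the secondary signals split the rest
    # (~2% each) — mirroring cis proteins whose single-SNP variance
    # explained runs from a few percent up to tens of percent
    beta = np.zeros(m)
    if config.n_causal == 1:
        shares = np.array([1.0])
    else:
        shares = rng.uniform(1.0, 2.0, size=config.n_causal)
        shares[1:] = 0.6 * shares[1:] / shares[1:].sum()
        shares[0] = 0.4
        rng.shuffle(shares)
    pq2 = 2.0 * eafs[causal_idx] * (1.0 - eafs[causal_idx])
    beta[causal_idx] = (rng.choice([-1.0, 1.0], size=config.n_causal)
                        * np.sqrt(shares / pq2))

    g_exp = exposure.dosages @ beta
    v_g = float(np.var(g_exp))
    exp_cov = _covariate_table(rng, config.n_exposure, config.n_pcs, "EXP")
    cov_betas = {"sex": 0.10, "age": 0.10, "pc": 0.05}
    c_exp = _covariate_effect(exp_cov, cov_betas)
    v_y = v_g / config.h2_target  # total protein variance implied by h2
    v_noise = v_y - v_g - float(np.var(c_exp))
    if v_noise <= 0:
        raise InvalidConfigError(
            "h2_target plus covariate effects exceed total protein variance"
        )
    protein = g_exp + c_exp + rng.normal(0.0, np.sqrt(v_noise), config.n_exposure)

    # planted horizontal pleiotropy: direct SNP -> disease effects on a
    # subset of the causal (instrument) SNPs
    n_pleio = int(round(config.pleio_fraction * config.n_causal))
    pleio_idx = np.sort(rng.choice(causal_idx, size=n_pleio, replace=False))
    delta = np.zeros(m)
    if n_pleio:
        delta[pleio_idx] = rng.normal(config.pleio_mean, config.pleio_effect_sd,
                                      size=n_pleio)

    out_cov = _covariate_table(rng, config.n_outcome, config.n_pcs, "OUT")
    sigma_y = np.sqrt(v_y)
    g_out = outcome.dosages @ beta
    eta = (
        config.true_b * (g_out - g_exp.mean()) / sigma_y
        + (outcome.dosages - outcome.dosages.mean(axis=0)) @ delta
        + _covariate_effect(out_cov, {"sex": 0.10, "age": 0.05, "pc": 0.02})
    )
    target = config.n_cases / config.n_outcome

    def _expected_fraction(alpha: float) -> float:
        return float(np.mean(special.expit(alpha + eta))) - target

    alpha = optimize.brentq(_expected_fraction, -40.0, 40.0)
    case_status = (rng.random(config.n_outcome)
                   < special.expit(alpha + eta)).astype(int)

    # realized h2 = in-sample R^2 of protein on the causal dosages
    x = np.column_stack([np.ones(config.n_exposure),
                         exposure.dosages[:, causal_idx]])
    resid = protein - x @ np.linalg.lstsq(x, protein, rcond=None)[0]
    realized_h2 = float(1.0 - np.var(resid) / np.var(protein))

    truth = SimulationTruth(
        true_b=config.true_b,
        causal_snp_ids=tuple(ld.snp_ids[i] for i in causal_idx),
        pleiotropic_snp_ids=tuple(ld.snp_ids[i] for i in pleio_idx),
        per_snp_effects={ld.snp_ids[i]: float(beta[i]) for i in causal_idx},
        realized_h2=realized_h2,
    )
    return PairedStudy(
        exposure=exposure,
        protein=protein,
        exposure_covariates=exp_cov,
        outcome=outcome,
        case_status=case_status,
        outcome_covariates=out_cov,
        ld=ld,
        truth=truth,
        gene=gene,
    )


def simulate_summary_mr(
    n_snps: int,
    true_b: float,
    seed: "int | np.random.Generator",
    *,
    ld: LDMatrix | None = None,
    b_zx_range: tuple[float, float] = (0.15, 0.65),
    se_zx: float = 0.03,
    se_zy: float = 0.02,
    n_pleio: int = 0,
    pleio_mean: float = 0.0,
    pleio_sd: float = 0.0,
):
    """Draw summary statistics for one MR study directly at the summary level.

    True exposure effect magnitudes are uniform over ``b_zx_range`` (per SD
    of protein; the spread mirrors strong cis-pQTLs whose single-SNP
    variance explained runs from a few percent to tens of percent) with
    random signs. Outcome effects are ``true_b * b_zx`` plus direct
    (pleiotropic) effects on the ``n_pleio`` weakest instruments — the
    strongest cis signal is taken to act through the protein, so the top
    (reference) instrument stays valid. Direct effects are directional on
    the oriented scale: each is ``sign(b_zx) * N(pleio_mean, pleio_sd)``,
    so a nonzero ``pleio_mean`` shifts every Wald ratio the same way.
    Estimation errors carry the LD correlation structure on both sides,
    mirroring how correlated instruments behave in real summary data.
    Returns ``(MRInput, pleiotropic_snp_ids)``; useful for fast power and
    calibration studies of the estimators without individual-level
    simulation.
    """
    from .estimators import MRInput

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ld is None:
        ld = LDMatrix(tuple(f"snp_{i:04d}" for i in range(n_snps)),
                      np.eye(n_snps))
    if len(ld.snp_ids) != n_snps:
        raise ValueError("ld dimension must equal n_snps")
    chol = np.linalg.cholesky(ld.values)
    magnitude = rng.uniform(*b_zx_range, size=n_snps)
    signs = rng.choice([-1.0, 1.0], size=n_snps)
    b_zx_true = signs * magnitude
    delta = np.zeros(n_snps)
    pleio_idx = np.argsort(magnitude)[:n_pleio] if n_pleio else np.array([], int)
    if n_pleio:
        delta[pleio_idx] = signs[pleio_idx] * rng.normal(
            pleio_mean, max(pleio_sd, 1e-12), n_pleio
        )
    b_zx = b_zx_true + se_zx * (chol @ rng.standard_normal(n_snps))
    b_zy = true_b * b_zx_true + delta + se_zy * (chol @ rng.standard_normal(n_snps))
    p_zx = 2.0 * stats.norm.sf(np.abs(b_zx) / se_zx)
    inp = MRInput(
        snp_ids=ld.snp_ids,
        b_zx=b_zx,
        se_zx=np.full(n_snps, se_zx),
        b_zy=b_zy,
        se_zy=np.full(n_snps, se_zy),
        ld=ld.values,
        p_zx=p_zx,
    )
    pleio_ids = tuple(np.array(ld.snp_ids)[np.sort(pleio_idx)]) if n_pleio else ()
    return inp, pleio_ids
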