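"""Per-SNP association scans, phenotype transformation and variant QC.

The exposure cohort is scanned with ordinary least squares on the
rank-inverse-normal (INT) protein level; the outcome cohort with per-SNP
maximum-likelihood logistic regression on disease status. Both adjust for
covariates. Results are returned as summary-statistics tables (one row per
SNP: alleles, EAF, beta, SE, p, N) ready for instrument selection and MR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import GenotypePanel

__all__ = [
    "QCThresholds",
    "SUMSTATS_COLUMNS",
    "rank_inverse_normal",
    "qc_filter_variants",
    "hwe_test",
    "linear_scan",
    "logistic_scan",
    "variance_explained",
    "validate_sumstats",
]

#: canonical column order of a summary-statistics table
SUMSTATS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]


@dataclass(frozen=True)
class QCThresholds:
    """Variant QC cutoffs: MAF, Hardy-Weinberg p, missingness, imputation info."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-20
    missing_max: float = 0.05
    info_min: float = 0.8

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "missing_max", "info_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def rank_inverse_normal(values, groups=None) -> np.ndarray:
    """Rank-based inverse normal transformation, optionally within groups.

    Within each group the i-th order statistic maps to
    ``Phi^-1((rank_i - 0.5) / n)`` with average ranks for ties, yielding an
    approximately standard-normal variable. Missing values (NaN) are left
    missing and do not consume ranks. The output is invariant to any strictly
    increasing transformation of the input.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    if groups is None:
        groups = np.zeros(x.shape[0], dtype=int)
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        in_group = groups == g
        obs = in_group & ~np.isnan(x)
        n = int(obs.sum())
        if n < 2:
            raise ValueError(
                f"group {g!r} has {n} non-missing value(s); at least 2 required"
            )
        ranks = stats.rankdata(x[obs], method="average")
        out[obs] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square test of Hardy-Weinberg equilibrium from genotype counts.

    Expected counts come from the sample allele frequency; returns 1.0 when
    any expected count is zero (monomorphic sample).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    if (expected == 0).any():
        return 1.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter_variants(
    stats_table: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove variants failing any QC threshold; log one reason per removal.

    Rules are evaluated in fixed order MAF -> HWE -> missingness -> info and
    the first failing rule is logged. The ``hwe_p``, ``missing_rate`` and
    ``info`` columns are each optional; absent columns are not tested.
    The operation is idempotent.
    """
    df = stats_table.reset_index(drop=True)
    maf = np.minimum(df["eaf"].to_numpy(float), 1.0 - df["eaf"].to_numpy(float))
    reasons = np.array([""] * len(df), dtype=object)
    fail = maf < thresholds.maf_min
    reasons[fail & (reasons == "")] = "MAF"
    if "hwe_p" in df.columns:
        fail = df["hwe_p"].to_numpy(float) < thresholds.hwe_p_min
        reasons[fail & (reasons == "")] = "HWE"
    if "missing_rate" in df.columns:
        fail = df["missing_rate"].to_numpy(float) > thresholds.missing_max
        reasons[fail & (reasons == "")] = "missingness"
    if "info" in df.columns:
        fail = df["info"].to_numpy(float) < thresholds.info_min
        reasons[fail & (reasons == "")] = "info"
    removed = reasons != ""
    log = pd.DataFrame(
        {"snp_id": df.loc[removed, "snp_id"].to_numpy(),
         "reason": reasons[removed]}
    )
    return df.loc[~removed].reset_index(drop=True), log


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        cov = covariates.drop(columns=["sample_id"], errors="ignore")
        cov = cov.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    return np.column_stack([np.ones(n), cov])


def linear_scan(
    panel: GenotypePanel,
    phenotype,
    covariates: pd.DataFrame | np.ndarray | None = None,
    apply_int: bool = False,
    int_groups=None,
) -> pd.DataFrame:
    """OLS association scan of a quantitative phenotype on each SNP dosage.

    Covariates (plus an intercept) are projected out of both phenotype and
    dosages (Frisch-Waugh-Lovell), so the per-SNP slope, SE and t-based
    p-value are exactly those of the full joint OLS fit. A constant dosage
    column is reported with ``se = inf`` and ``p = 1`` rather than dropped.
    With ``apply_int=True`` the phenotype is INT-transformed first.
    """
    y = np.asarray(phenotype, dtype=float)
    n, m = panel.dosages.shape
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match the panel")
    if apply_int:
        y = rank_inverse_normal(y, groups=int_groups)
    c = _design(covariates, n)
    k = c.shape[1]
    # residualize y and all dosage columns against the covariate design
    coef_y, *_ = np.linalg.lstsq(c, y, rcond=None)
    y_r = y - c @ coef_y
    coef_x, *_ = np.linalg.lstsq(c, panel.dosages, rcond=None)
    x_r = panel.dosages - c @ coef_x

    sxx = np.einsum("ij,ij->j", x_r, x_r)
    sxy = x_r.T @ y_r
    df_resid = n - k - 1
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    p = np.ones(m)
    ok = sxx > 1e-12 * n
    beta[ok] = sxy[ok] / sxx[ok]
    if ok.any():
        rss = y_r @ y_r - beta[ok] ** 2 * sxx[ok]
        sigma2 = np.maximum(rss, 0.0) / df_resid
        se[ok] = np.sqrt(sigma2 / sxx[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta[ok] / se[ok]
        p[ok] = 2.0 * stats.t.sf(np.abs(tstat), df=df_resid)
    out = panel.variants.copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["n"] = n
    return out[SUMSTATS_COLUMNS]


def logistic_scan(
    panel: GenotypePanel,
    labels,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP ML logistic regression of case status on dosage + covariates.

    Beta is the log-odds per dosage unit with Wald SE and p. SNPs whose fit
    fails to converge (e.g. quasi-complete separation) are flagged with
    ``se = inf`` and ``p = 1`` instead of being dropped.
    """
    y = np.asarray(labels, dtype=float)
    n, m = panel.dosages.shape
    if y.shape[0] != n:
        raise ValueError("labels length does not match the panel")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both case and control labels must be present")
    c = _design(covariates, n)
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    p = np.ones(m)
    for j in range(m):
        x = np.column_stack([c, panel.dosages[:, j]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", False):
                continue
            b, s = fit.params[-1], fit.bse[-1]
            if not np.isfinite(s) or s > 1e3:
                continue
            beta[j], se[j] = b, s
            p[j] = 2.0 * stats.norm.sf(abs(b / s))
        except Exception:
            continue
    out = panel.variants.copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["n"] = n
    return out[SUMSTATS_COLUMNS]


def variance_explained(
    panel: GenotypePanel,
    phenotype,
    covariates: pd.DataFrame | np.ndarray | None = None,
    snp_subset=None,
) -> tuple[pd.Series, float]:
    """Per-SNP and joint incremental R-squared of a SNP subset.

    Per-SNP R2 is the gain in R2 from adding that SNP alone to the
    covariate-only model; joint R2 is the gain from adding all subset SNPs
    together. Aliased (linearly dependent) SNPs are dropped from the joint
    fit with a warning.
    """
    if snp_subset is None:
        snp_subset = list(panel.snp_ids)
    snp_subset = list(snp_subset)
    if not snp_subset:
        raise ValueError("snp_subset must be non-empty")
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    c = _design(covariates, n)

    def rss(design: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ coef
        return float(r @ r)

    tss = float(((y - y.mean()) ** 2).sum())
    rss0 = rss(c)
    idx = {s: i for i, s in enumerate(panel.snp_ids)}
    per_snp = {}
    for s in snp_subset:
        d = np.column_stack([c, panel.dosages[:, idx[s]]])
        per_snp[s] = max(0.0, (rss0 - rss(d)) / tss)
    joint_design = np.column_stack([c] + [panel.dosages[:, idx[s]] for s in snp_subset])
    if np.linalg.matrix_rank(joint_design) < joint_design.shape[1]:
        warnings.warn("rank-deficient joint design; aliased SNPs dropped",
                      stacklevel=2)
    joint = max(0.0, (rss0 - rss(joint_design)) / tss)
    return pd.Series(per_snp, name="r2"), float(min(joint, 1.0))


def validate_sumstats(df: pd.DataFrame, rel_tol: float = 0.10) -> pd.DataFrame:
    """Consistency checks on a summary-statistics table (on read).

    Requires unique SNP ids, strictly positive SEs, p in (0, 1], and that p
    agrees with the two-sided normal tail of beta/se within ``rel_tol``
    relative tolerance (skipped for sentinel rows with infinite SE, and in
    the deep tail where the stored p may come from a t reference).
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing summary-statistics columns: {missing}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id {dup!r}")
    se = df["se"].to_numpy(float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be strictly positive")
    p = df["p"].to_numpy(float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    finite = np.isfinite(se)
    z = np.abs(df["beta"].to_numpy(float) / np.where(finite, se, np.inf))
    expected = 2.0 * stats.norm.sf(z)
    # below p ~ 1e-3 a t-based stored p legitimately diverges from the
    # normal tail by more than 10% at cohort sizes in the hundreds, so the
    # check covers only the bulk of the distribution
    check = finite & (expected > 1e-3) & (p > 1e-3)
    with np.errstate(invalid="ignore"):
        rel = np.abs(p - expected) / np.where(check, expected, 1.0)
    bad = check & (rel > rel_tol)
    if bad.any():
        snp = df.loc[np.flatnonzero(bad)[0], "snp_id"]
        raise ValueError(
            f"p-value of {snp!r} inconsistent with beta/se beyond "
            f"{rel_tol:.0%} relative tolerance"
        )
    return df
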