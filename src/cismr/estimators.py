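"""Causal-effect estimators for correlated genetic instruments.

The main estimator combines per-SNP Wald ratios by generalized least squares
(GLS), modelling the covariance between ratios induced by linkage
disequilibrium, and tests the combined effect with a 1-df chi-square
statistic — the GSMR approach. Before estimation, instruments whose ratio
deviates from the top instrument's beyond a heterogeneity threshold can be
removed as pleiotropic outliers (HEIDI-outlier). Three sensitivity
estimators with different robustness profiles are provided: correlated-
instrument inverse-variance weighting and MR-Egger (both with a random-
effect SE floor at 1), and the weighted median with bootstrap SE.

All causal effects are log-odds of disease per one SD of the (INT)
protein level; helpers convert to odds ratios with 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = [
    "MRInput",
    "MREstimate",
    "wald_ratio",
    "gls_causal_estimate",
    "heidi_outlier",
    "gsmr",
    "ivw_correlated",
    "egger_correlated",
    "weighted_median",
    "to_odds_ratio",
]

_Z975 = 1.959964  # Phi^-1(0.975)
_COND_LIMIT = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Covariance matrix numerically singular; instruments too correlated."""


@dataclass(frozen=True)
class MRInput:
    """Harmonized summary inputs for one protein-disease pair.

    ``b_zx``/``se_zx`` are SNP effects on the exposure (per SD of protein),
    ``b_zy``/``se_zy`` on the outcome (log-odds), all on a common effect
    allele; ``ld`` is the signed SNP correlation matrix in SNP order;
    ``p_zx`` identifies the top (reference) instrument.
    """

    snp_ids: tuple[str, ...]
    b_zx: np.ndarray
    se_zx: np.ndarray
    b_zy: np.ndarray
    se_zy: np.ndarray
    ld: np.ndarray
    p_zx: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("b_zx", "se_zx", "b_zy", "se_zy", "p_zx"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
        ld = np.asarray(self.ld, dtype=float)
        L = len(self.snp_ids)
        if L < 1:
            raise ValueError("at least one instrument required")
        for name, a in arrays.items():
            if a.shape != (L,):
                raise ValueError(f"{name} must have length {L}")
        if ld.shape != (L, L):
            raise ValueError("LD matrix shape must match the instrument count")
        if not np.allclose(ld, ld.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(ld), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if (arrays["se_zx"] <= 0).any() or (arrays["se_zy"] <= 0).any():
            raise ValueError("standard errors must be strictly positive")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)
        object.__setattr__(self, "ld", ld)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))

    @property
    def n_instruments(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: np.ndarray) -> "MRInput":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MRInput(
            snp_ids=tuple(np.array(self.snp_ids)[keep]),
            b_zx=self.b_zx[keep],
            se_zx=self.se_zx[keep],
            b_zy=self.b_zy[keep],
            se_zy=self.se_zy[keep],
            ld=self.ld[np.ix_(keep, keep)],
            p_zx=self.p_zx[keep],
        )

    @classmethod
    def from_instrument_set(cls, iset) -> "MRInput":
        t = iset.table
        return cls(
            snp_ids=tuple(t["snp_id"]),
            b_zx=t["b_zx"].to_numpy(float),
            se_zx=t["se_zx"].to_numpy(float),
            b_zy=t["b_zy"].to_numpy(float),
            se_zy=t["se_zy"].to_numpy(float),
            ld=iset.ld_outcome.values,
            p_zx=t["p_zx"].to_numpy(float),
        )


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate: log-odds per protein SD, with OR scale."""

    method: str
    b: float
    se: float
    p: float
    or_: float
    ci_low: float
    ci_high: float
    n_iv_initial: int
    n_iv_used: int
    removed_snp_ids: tuple[str, ...] = ()
    heidi_applied: bool = False
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    phi: float | None = None
    bootstrap_seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("confidence interval must bracket the OR")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if self.n_iv_used > self.n_iv_initial:
            raise ValueError("n_iv_used cannot exceed n_iv_initial")


def to_odds_ratio(b: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect to (OR, 95% CI low, 95% CI high)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return (
        float(np.exp(b)),
        float(np.exp(b - _Z975 * se)),
        float(np.exp(b + _Z975 * se)),
    )


def _estimate(method: str, b: float, se: float, p: float, L0: int, L: int,
              **kw) -> MREstimate:
    or_, lo, hi = to_odds_ratio(b, se)
    return MREstimate(method=method, b=float(b), se=float(se),
                      p=float(min(max(p, np.finfo(float).tiny), 1.0)),
                      or_=or_, ci_low=lo, ci_high=hi,
                      n_iv_initial=L0, n_iv_used=L, **kw)


def wald_ratio(b_zx, se_zx, b_zy, se_zy):
    """Per-SNP causal ratio and its first-order delta-method variance.

    ``beta = b_zy / b_zx`` with
    ``var = (se_zy^2 + beta^2 * se_zx^2) / b_zx^2``. Vectorized.
    """
    b_zx = np.asarray(b_zx, dtype=float)
    if np.any(b_zx == 0):
        raise ZeroDivisionError("Wald ratio undefined for b_zx = 0")
    b_zy = np.asarray(b_zy, dtype=float)
    se_zx = np.asarray(se_zx, dtype=float)
    se_zy = np.asarray(se_zy, dtype=float)
    beta = b_zy / b_zx
    var = (se_zy**2 + beta**2 * se_zx**2) / b_zx**2
    return beta, var


def _orient_ld(inp: MRInput) -> np.ndarray:
    """LD with signs re-expressed for the orientation where all b_zx >= 0."""
    signs = np.where(inp.b_zx < 0, -1.0, 1.0)
    return inp.ld * np.outer(signs, signs)


def _corr_solve(corr: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve corr @ x = rhs, rejecting numerically singular LD.

    All covariance matrices here factor as D @ corr @ D with diagonal D, so
    solves are done in the scaled (correlation) system: the scale of D then
    cannot masquerade as singularity, and the condition guard applies to
    the LD structure itself.
    """
    if np.linalg.cond(corr) > _COND_LIMIT:
        raise SingularCovarianceError(
            "instrument covariance matrix is numerically singular; "
            "use a stricter r2 threshold"
        )
    c, low = linalg.cho_factor(corr)
    return linalg.cho_solve((c, low), rhs)


def gls_causal_estimate(inp: MRInput, heidi_applied: bool = False,
                        removed: tuple[str, ...] = (),
                        n_iv_initial: int | None = None) -> MREstimate:
    """GSMR-style GLS combination of Wald ratios over correlated instruments.

    With per-SNP ratios beta_i, delta-method variances v_i and covariance
    ``V_ij = r_ij sqrt(v_i v_j)``:
    ``b = (1' V^-1 beta) / (1' V^-1 1)`` with ``se = (1' V^-1 1)^(-1/2)``
    (fixed-effect convention) and p from the upper tail of chi-square(1) at
    ``(b/se)^2``. With one instrument this collapses to the Wald ratio with
    a normal-based p.
    """
    beta, var = wald_ratio(inp.b_zx, inp.se_zx, inp.b_zy, inp.se_zy)
    sd = np.sqrt(var)
    # the covariance model r_ij sqrt(v_i v_j) applies in the canonical
    # orientation b_zx >= 0 (sqrt discards the sign of b_zx_i b_zx_j, so
    # orienting first is what makes the estimate allele-flip invariant)
    ld = _orient_ld(inp)
    # V^-1 = D^-1 R^-1 D^-1 with D = diag(sd); work in the scaled system
    w = _corr_solve(ld, np.column_stack([beta / sd, 1.0 / sd]))
    denom = (1.0 / sd) @ w[:, 1]
    b = float((1.0 / sd) @ w[:, 0] / denom)
    se = float(denom**-0.5)
    p = float(stats.chi2.sf((b / se) ** 2, df=1))
    return _estimate("gsmr", b, se, p, n_iv_initial or inp.n_instruments,
                     inp.n_instruments, heidi_applied=heidi_applied,
                     removed_snp_ids=tuple(removed))


def heidi_outlier(inp: MRInput, alpha: float = 0.01,
                  min_instruments: int = 5) -> tuple[MRInput, tuple[str, ...], bool]:
    """Single-pass pleiotropy outlier removal against the top instrument.

    The reference ratio is the Wald ratio of the SNP with the smallest
    exposure p-value. Each other SNP's deviation ``d_i = beta_i - beta_ref``
    has variance ``v_i + v_ref - 2 r_{i,ref} sqrt(v_i v_ref)``; SNPs with a
    chi-square(1) p below ``alpha`` are removed in one pass. With fewer than
    ``min_instruments`` SNPs the procedure is disabled and the input is
    returned unchanged.

    Returns ``(filtered input, removed snp_ids, applied flag)``.
    """
    L = inp.n_instruments
    if L < min_instruments:
        return inp, (), False
    beta, var = wald_ratio(inp.b_zx, inp.se_zx, inp.b_zy, inp.se_zy)
    ref = int(np.argmin(inp.p_zx))
    d = beta - beta[ref]
    # same canonical-orientation convention as the GLS covariance
    cov_ref = _orient_ld(inp)[:, ref] * np.sqrt(var * var[ref])
    var_d = var + var[ref] - 2.0 * cov_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var_d > 0, d**2 / var_d, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p[ref] = 1.0
    keep = p >= alpha
    removed = tuple(np.array(inp.snp_ids)[~keep])
    return inp.subset(keep), removed, True


def gsmr(inp: MRInput, heidi: bool = True, heidi_alpha: float = 0.01,
         heidi_min_instruments: int = 5) -> MREstimate:
    """HEIDI-outlier filtering (when enabled and feasible) followed by GLS."""
    L0 = inp.n_instruments
    removed: tuple[str, ...] = ()
    applied = False
    if heidi:
        inp, removed, applied = heidi_outlier(
            inp, alpha=heidi_alpha, min_instruments=heidi_min_instruments
        )
    return gls_causal_estimate(inp, heidi_applied=applied, removed=removed,
                               n_iv_initial=L0)


def ivw_correlated(inp: MRInput, random_effects: bool = True,
                   _allow_single: bool = False) -> MREstimate:
    """Correlated-instrument IVW: GLS of b_zy on b_zx through the origin.

    The error covariance is ``Omega_ij = r_ij se_zy_i se_zy_j`` (outcome
    side only). The SE uses a multiplicative random-effect inflation
    ``phi = max(1, sqrt(RSS_gls / (L - 1)))``; with ``random_effects=False``
    (or L = 1 in test-only mode) phi is fixed at 1. With identity LD this
    reduces to the classic inverse-variance weighted estimator.
    """
    L = inp.n_instruments
    if L < 2 and not _allow_single:
        raise ValueError("IVW requires at least 2 instruments")
    # Omega^-1 = D^-1 R^-1 D^-1 with D = diag(se_zy)
    xs, ys = inp.b_zx / inp.se_zy, inp.b_zy / inp.se_zy
    w = _corr_solve(inp.ld, np.column_stack([xs, ys]))
    xtx = float(xs @ w[:, 0])
    b = float(xs @ w[:, 1]) / xtx
    if random_effects and L > 1:
        resid_s = ys - b * xs
        rss = float(resid_s @ _corr_solve(inp.ld, resid_s))
        phi = max(1.0, np.sqrt(rss / (L - 1)))
    else:
        phi = 1.0
    se = phi / np.sqrt(xtx)
    p = 2.0 * stats.norm.sf(abs(b / se))
    return _estimate("ivw", b, se, p, L, L, phi=float(phi))


def egger_correlated(inp: MRInput, random_effects: bool = True) -> MREstimate:
    """Correlated-instrument MR-Egger: GLS of b_zy on [1, b_zx].

    Instruments are first oriented so every exposure effect is non-negative
    (negating both betas and the corresponding LD signs), making the
    intercept interpretable as the average directional pleiotropic effect;
    its p-value is the pleiotropy test. The slope is the causal estimate.
    SE inflation phi is floored at 1 with L - 2 residual df.
    """
    L = inp.n_instruments
    if L < 3:
        raise ValueError("MR-Egger requires >=3 instruments")
    signs = np.where(inp.b_zx < 0, -1.0, 1.0)
    x = signs * inp.b_zx
    y = signs * inp.b_zy
    ld = inp.ld * np.outer(signs, signs)
    design = np.column_stack([np.ones(L), x])
    # Omega = D ld D with D = diag(se_zy); solve in the scaled system
    ds = design / inp.se_zy[:, None]
    ys = y / inp.se_zy
    w = _corr_solve(ld, np.column_stack([ds, ys[:, None]]))
    xtx = ds.T @ w[:, :2]
    xty = ds.T @ w[:, 2]
    coef = np.linalg.solve(xtx, xty)
    if random_effects:
        resid_s = ys - ds @ coef
        rss = float(resid_s @ _corr_solve(ld, resid_s))
        phi = max(1.0, np.sqrt(rss / (L - 2)))
    else:
        phi = 1.0
    cov = phi**2 * np.linalg.inv(xtx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_slope = 2.0 * stats.norm.sf(abs(slope / se_slope))
    p_int = 2.0 * stats.norm.sf(abs(intercept / se_int))
    return _estimate("egger", slope, se_slope, p_slope, L, L,
                     egger_intercept=intercept,
                     egger_intercept_p=float(min(max(p_int, np.finfo(float).tiny), 1.0)),
                     phi=float(phi))


def weighted_median(inp: MRInput, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    Ratios are weighted by inverse variance; with cumulative weights
    ``S_i = sum_{j<=i} w_j - w_i / 2`` (weights normalized, ratios sorted
    ascending) the estimate interpolates linearly between the two ratios
    bracketing S = 1/2. It is consistent when valid instruments carry at
    least half the weight. The SE is the SD of the estimate over ``n_boot``
    parametric resamples of the per-SNP effects, drawn independently (LD is
    ignored in the bootstrap).
    """
    if inp.n_instruments < 3:
        raise ValueError("weighted median requires >=3 instruments")
    if n_boot < 2:
        raise ValueError("bootstrap needs n_boot >= 2")

    def _wm(b_zx: np.ndarray, b_zy: np.ndarray) -> float:
        beta, var = wald_ratio(b_zx, inp.se_zx, b_zy, inp.se_zy)
        w = 1.0 / var
        w = w / w.sum()
        order = np.argsort(beta)
        beta, w = beta[order], w[order]
        s = np.cumsum(w) - 0.5 * w
        return float(np.interp(0.5, s, beta))

    b = _wm(inp.b_zx, inp.b_zy)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        bx = rng.normal(inp.b_zx, inp.se_zx)
        by = rng.normal(inp.b_zy, inp.se_zy)
        draws[i] = _wm(bx, by)
    se = float(draws.std(ddof=1))
    p = 2.0 * stats.norm.sf(abs(b / se)) if se > 0 else 1.0
    L = inp.n_instruments
    return _estimate("wmedian", b, se, p, L, L, bootstrap_seed=seed)
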