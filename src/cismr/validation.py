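"""Calibration experiments: recovery of known effects from synthetic studies.

These drivers wire the whole pipeline together over many replicated
synthetic studies and summarize how well the estimators recover the
generating parameters — mean estimate, CI coverage, type-I error, outlier
detection power. They are what the validation suite and the reproduction
script run; each takes a seed and returns plain dictionaries/DataFrames.

In the recovery experiments the instrument set is the known causal SNP set
(valid instruments by construction), isolating estimator calibration from
instrument-selection effects; the LD matrix is re-estimated from the outcome
cohort's genotypes in every replicate, as the pipeline does on real data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import (
    MRInput,
    egger_correlated,
    gls_causal_estimate,
    gsmr,
    heidi_outlier,
    ivw_correlated,
    weighted_median,
)
from .gwas import linear_scan, logistic_scan
from .simulate import SimulationConfig, generate_paired_study, simulate_summary_mr

__all__ = [
    "single_study_estimate",
    "recovery_experiment",
    "heidi_power_experiment",
    "egger_power_experiment",
    "median_vs_ivw_experiment",
]

_Z975 = 1.959964


def single_study_estimate(config: SimulationConfig, heidi: bool = True):
    """Generate one study, run both scans and GSMR on the causal SNP set.

    Returns ``(MREstimate, SimulationTruth)``.
    """
    study = generate_paired_study(config)
    exp_stats = linear_scan(
        study.exposure, study.protein,
        covariates=study.exposure_covariates, apply_int=True,
    ).set_index("snp_id")
    out_stats = logistic_scan(
        study.outcome, study.case_status,
        covariates=study.outcome_covariates,
    ).set_index("snp_id")

    ivs = list(study.truth.causal_snp_ids)
    idx = [study.outcome.snp_ids.index(s) for s in ivs]
    ld_hat = np.corrcoef(study.outcome.dosages[:, idx], rowvar=False)
    np.fill_diagonal(ld_hat, 1.0)
    inp = MRInput(
        snp_ids=tuple(ivs),
        b_zx=exp_stats.loc[ivs, "beta"].to_numpy(float),
        se_zx=exp_stats.loc[ivs, "se"].to_numpy(float),
        b_zy=out_stats.loc[ivs, "beta"].to_numpy(float),
        se_zy=out_stats.loc[ivs, "se"].to_numpy(float),
        ld=ld_hat,
        p_zx=exp_stats.loc[ivs, "p"].to_numpy(float),
    )
    return gsmr(inp, heidi=heidi), study.truth


def recovery_experiment(
    n_reps: int,
    seed: int,
    true_b: float,
    base_config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Replicate full-pipeline GSMR estimation over independent studies.

    Returns one row per replicate with the estimate, SE, p, whether the 95%
    CI covered ``true_b``, and whether the null was rejected at 0.05.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(n_reps) % (2**31)]
    rows = []
    for rep_seed in seeds:
        cfg_kw = dict(seed=rep_seed, true_b=true_b)
        if base_config is not None:
            cfg_kw = {
                **{f: getattr(base_config, f)
                   for f in SimulationConfig.__dataclass_fields__},
                **cfg_kw,
            }
        est, truth = single_study_estimate(SimulationConfig(**cfg_kw))
        covered = (est.b - _Z975 * est.se <= true_b <= est.b + _Z975 * est.se)
        rows.append(
            {"b": est.b, "se": est.se, "p": est.p,
             "covered": bool(covered), "rejected": est.p < 0.05,
             "n_iv_used": est.n_iv_used, "realized_h2": truth.realized_h2}
        )
    return pd.DataFrame(rows)


def heidi_power_experiment(
    n_reps: int,
    seed: int,
    n_snps: int = 10,
    n_pleio: int = 3,
    true_b: float = float(np.log(0.84)),
    pleio_mean: float = 0.15,
    pleio_sd: float = 0.03,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Outlier detection and bias reduction with planted directional pleiotropy.

    Summary-level replicates with ``n_pleio`` of ``n_snps`` instruments
    given direct outcome effects of mean ``pleio_mean``. Per replicate:
    the fraction of planted SNPs flagged by the outlier test, and the GLS
    bias before vs after removal.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep_seed in (int(s) for s in ss.generate_state(n_reps) % (2**31)):
        inp, pleio_ids = simulate_summary_mr(
            n_snps, true_b, rep_seed,
            n_pleio=n_pleio, pleio_mean=pleio_mean, pleio_sd=pleio_sd,
        )
        before = gls_causal_estimate(inp)
        filtered, removed, applied = heidi_outlier(inp, alpha=alpha)
        after = gls_causal_estimate(filtered)
        flagged = set(removed) & set(pleio_ids)
        rows.append(
            {
                "frac_planted_flagged": len(flagged) / n_pleio,
                "n_false_flags": len(set(removed) - set(pleio_ids)),
                "bias_before": before.b - true_b,
                "bias_after": after.b - true_b,
                "heidi_applied": applied,
            }
        )
    return pd.DataFrame(rows)


def egger_power_experiment(
    n_reps: int,
    seed: int,
    n_snps: int = 20,
    pleio_mean: float = 0.05,
    pleio_sd: float = 0.01,
    se_zy: float = 0.015,
    true_b: float = float(np.log(0.84)),
) -> pd.DataFrame:
    """Power of the Egger intercept test under directional pleiotropy.

    Every instrument receives a direct effect with nonzero mean, the
    textbook scenario the intercept is designed to detect. ``se_zy``
    reflects a biobank-scale outcome scan, where per-SNP log-odds SEs for
    common variants sit around 0.01-0.02.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep_seed in (int(s) for s in ss.generate_state(n_reps) % (2**31)):
        inp, _ = simulate_summary_mr(
            n_snps, true_b, rep_seed,
            n_pleio=n_snps, pleio_mean=pleio_mean, pleio_sd=pleio_sd,
            se_zy=se_zy,
        )
        est = egger_correlated(inp)
        rows.append({"intercept": est.egger_intercept,
                     "intercept_p": est.egger_intercept_p,
                     "detected": est.egger_intercept_p < 0.05})
    return pd.DataFrame(rows)


def median_vs_ivw_experiment(
    n_reps: int,
    seed: int,
    n_snps: int = 30,
    invalid_fraction: float = 0.3,
    pleio_sd: float = 0.1,
    true_b: float = float(np.log(0.84)),
    n_boot: int = 200,
) -> pd.DataFrame:
    """Weighted-median robustness vs IVW under balanced contamination.

    A minority of instruments get zero-mean direct effects (balanced
    pleiotropy); the weighted median should stay near the truth while IVW
    absorbs the contamination into its estimate and inflated SE.
    """
    ss = np.random.SeedSequence(seed)
    n_invalid = int(round(invalid_fraction * n_snps))
    rows = []
    for rep_seed in (int(s) for s in ss.generate_state(n_reps) % (2**31)):
        inp, _ = simulate_summary_mr(
            n_snps, true_b, rep_seed,
            n_pleio=n_invalid, pleio_mean=0.0, pleio_sd=pleio_sd,
        )
        wm = weighted_median(inp, n_boot=n_boot, seed=rep_seed)
        ivw = ivw_correlated(inp)
        rows.append({"wm_bias": wm.b - true_b, "ivw_bias": ivw.b - true_b})
    return pd.DataFrame(rows)
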