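"""MR estimators: Wald ratios, GLS/GSMR, HEIDI, IVW, Egger, weighted median."""

import numpy as np
import pytest
from scipy import stats

from cismr.estimators import (
    MRInput,
    SingularCovarianceError,
    egger_correlated,
    gls_causal_estimate,
    gsmr,
    heidi_outlier,
    ivw_correlated,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from cismr.reporting import format_or_ci
from cismr.simulate import simulate_summary_mr

from .conftest import ar1_ld


def make_input(b_zx, b_zy, se_zx=0.03, se_zy=0.02, ld=None, p_zx=None):
    L = len(b_zx)
    b_zx = np.asarray(b_zx, dtype=float)
    se_zx = np.broadcast_to(np.asarray(se_zx, dtype=float), (L,))
    se_zy = np.broadcast_to(np.asarray(se_zy, dtype=float), (L,))
    if p_zx is None:
        p_zx = 2.0 * stats.norm.sf(np.abs(b_zx) / se_zx)
    return MRInput(
        snp_ids=tuple(f"s{i}" for i in range(L)),
        b_zx=b_zx,
        se_zx=np.array(se_zx),
        b_zy=np.asarray(b_zy, dtype=float),
        se_zy=np.array(se_zy),
        ld=np.eye(L) if ld is None else np.asarray(ld, dtype=float),
        p_zx=np.asarray(p_zx, dtype=float),
    )


class TestWaldRatio:
    def test_exact_arithmetic(self):
        beta, var = wald_ratio(0.5, 0.0, -0.1, 0.05)
        assert beta == pytest.approx(-0.2)
        assert var == pytest.approx(0.01)

    def test_unit_denominator(self):
        beta, _ = wald_ratio(1.0, 0.1, 0.37, 0.05)
        assert beta == pytest.approx(0.37)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.1, 0.1, 0.1)

    def test_delta_variance_matches_sampling_oracle(self):
        # brute-force oracle: 1e6 sampled ratios at se/|b| <= 0.1
        rng = np.random.default_rng(123)
        b_zx, se_zx, b_zy, se_zy = 0.5, 0.05, -0.2, 0.02
        ratios = rng.normal(b_zy, se_zy, 10**6) / rng.normal(b_zx, se_zx, 10**6)
        _, var = wald_ratio(b_zx, se_zx, b_zy, se_zy)
        assert var == pytest.approx(ratios.var(), rel=0.10)


class TestGLSCausalEstimate:
    def test_single_instrument_collapses_to_wald_ratio(self):
        inp = make_input([0.5], [-0.1], se_zx=1e-9, se_zy=0.05)
        est = gls_causal_estimate(inp)
        beta, var = wald_ratio(0.5, 1e-9, -0.1, 0.05)
        assert est.b == pytest.approx(beta, abs=1e-12)
        assert est.se == pytest.approx(np.sqrt(var), rel=1e-12)
        z = beta / np.sqrt(var)
        assert est.p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-10)

    def test_equal_weight_mean_of_two_independent_ratios(self):
        # equal variances: b = (0.1 + 0.3) / 2
        inp = make_input([1.0, 1.0], [0.1, 0.3], se_zx=1e-12, se_zy=0.05)
        assert gls_causal_estimate(inp).b == pytest.approx(0.2, abs=1e-10)

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            L = 5
            ld = ar1_ld([f"s{i}" for i in range(L)], 0.6).values
            inp = make_input(rng.uniform(0.2, 0.6, L) * rng.choice([-1, 1], L),
                             rng.normal(0, 0.1, L), se_zx=0.03, se_zy=0.02,
                             ld=ld)
            est = gls_causal_estimate(inp)
            beta, var = wald_ratio(inp.b_zx, inp.se_zx, inp.b_zy, inp.se_zy)
            s = np.sign(inp.b_zx)  # covariance convention: b_zx >= 0
            v = ld * np.outer(s, s) * np.outer(np.sqrt(var), np.sqrt(var))
            vinv = np.linalg.inv(v)
            ones = np.ones(L)
            b_oracle = ones @ vinv @ beta / (ones @ vinv @ ones)
            se_oracle = (ones @ vinv @ ones) ** -0.5
            assert est.b == pytest.approx(b_oracle, rel=1e-10)
            assert est.se == pytest.approx(se_oracle, rel=1e-10)

    def test_identity_ld_equals_scalar_ivw_of_ratios(self):
        rng = np.random.default_rng(6)
        inp = make_input(rng.uniform(0.3, 0.6, 8), rng.normal(0, 0.1, 8))
        est = gls_causal_estimate(inp)
        beta, var = wald_ratio(inp.b_zx, inp.se_zx, inp.b_zy, inp.se_zy)
        w = 1.0 / var
        assert est.b == pytest.approx((w * beta).sum() / w.sum(), rel=1e-10)
        assert est.se == pytest.approx(w.sum() ** -0.5, rel=1e-10)

    def test_perfectly_correlated_instruments_rejected(self):
        ld = np.array([[1.0, 1.0], [1.0, 1.0]])
        inp = make_input([0.5, 0.5], [0.1, 0.1], ld=ld)
        with pytest.raises(SingularCovarianceError):
            gls_causal_estimate(inp)


class TestHeidiOutlier:
    def test_identical_ratios_remove_nothing(self):
        inp = make_input([0.5, 0.4, 0.45, 0.55, 0.6],
                         np.array([0.5, 0.4, 0.45, 0.55, 0.6]) * 0.2)
        _, removed, applied = heidi_outlier(inp)
        assert removed == () and applied

    def test_fewer_than_five_instruments_disable_the_procedure(self):
        inp = make_input([0.5, 0.4, 0.45, 0.55], [0.1, 0.08, 0.09, 0.4])
        out, removed, applied = heidi_outlier(inp)
        assert out is inp and removed == () and not applied

    def test_displaced_instrument_detected_with_high_power(self):
        # plant one ratio displaced by 8 * sqrt(v_i + v_ref)
        rng = np.random.default_rng(7)
        detected = 0
        reps = 200
        for _ in range(reps):
            L = 8
            b_zx = rng.uniform(0.3, 0.6, L)
            se_zx, se_zy = 0.03, 0.02
            true = -0.17
            b_zy = true * b_zx + rng.normal(0, se_zy, L)
            b_zx_hat = b_zx + rng.normal(0, se_zx, L)
            inp0 = make_input(b_zx_hat, b_zy, se_zx=se_zx, se_zy=se_zy)
            _, var = wald_ratio(inp0.b_zx, inp0.se_zx, inp0.b_zy, inp0.se_zy)
            ref = int(np.argmin(inp0.p_zx))
            j = (ref + 1) % L
            b_zy = b_zy.copy()
            b_zy[j] += 8 * np.sqrt(var[j] + var[ref]) * inp0.b_zx[j]
            inp = make_input(b_zx_hat, b_zy, se_zx=se_zx, se_zy=se_zy)
            _, removed, _ = heidi_outlier(inp, alpha=0.01)
            detected += inp.snp_ids[j] in removed
        assert detected / reps >= 0.95

    def test_gsmr_wrapper_records_removals(self):
        inp, pleio = simulate_summary_mr(10, -0.17, seed=9, n_pleio=2,
                                         pleio_mean=0.4, pleio_sd=0.01)
        est = gsmr(inp)
        assert est.heidi_applied
        assert est.n_iv_initial == 10
        assert est.n_iv_used == 10 - len(est.removed_snp_ids)
        assert set(pleio) <= set(est.removed_snp_ids)


class TestIVW:
    def test_collinear_input_is_exact_with_unit_phi(self):
        inp = make_input([0.5, 0.4], [0.1, 0.08], se_zy=0.05)
        est = ivw_correlated(inp)
        assert est.b == pytest.approx(0.2, abs=1e-12)
        assert est.phi == 1.0

    def test_identity_ld_reduces_to_classic_formula(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.2, 0.6, 6)
        y = rng.normal(0, 0.1, 6)
        se = rng.uniform(0.01, 0.05, 6)
        inp = make_input(x, y, se_zy=se)
        est = ivw_correlated(inp, random_effects=False)
        b_classic = (x * y / se**2).sum() / (x**2 / se**2).sum()
        assert est.b == pytest.approx(b_classic, rel=1e-12)

    def test_random_effect_se_floored_at_one(self):
        # heterogeneous ratios inflate phi; collinear ones leave phi = 1
        inp = make_input([0.5, 0.4, 0.3], [0.1, -0.2, 0.3], se_zy=0.01)
        assert ivw_correlated(inp).phi > 1.0

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(9)
        L = 5
        ld = ar1_ld([f"s{i}" for i in range(L)], 0.4).values
        x, y = rng.uniform(0.2, 0.6, L), rng.normal(0, 0.1, L)
        inp = make_input(x, y, ld=ld)
        flip = np.array([1, -1, 1, -1, 1.0])
        inp_f = make_input(x * flip, y * flip, ld=ld * np.outer(flip, flip))
        for f in (ivw_correlated, gls_causal_estimate):
            a, b = f(inp), f(inp_f)
            assert a.b == pytest.approx(b.b, abs=1e-12)
            assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError):
            ivw_correlated(make_input([0.5], [0.1]))

    def test_single_instrument_test_mode_matches_wald(self):
        inp = make_input([0.5], [0.1], se_zx=1e-12, se_zy=0.05)
        est = ivw_correlated(inp, random_effects=False, _allow_single=True)
        assert est.b == pytest.approx(0.2, abs=1e-12)


class TestEgger:
    def test_exact_line_recovers_intercept_and_slope(self):
        x = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
        y = 0.05 + 0.2 * x
        inp = make_input(x, y, se_zy=1e-4)
        est = egger_correlated(inp)
        assert est.b == pytest.approx(0.2, abs=1e-8)
        assert est.egger_intercept == pytest.approx(0.05, abs=1e-8)

    def test_orientation_canonicalization(self):
        x = np.array([0.2, 0.3, 0.4, 0.5])
        y = 0.05 + 0.2 * x + np.array([1e-3, -2e-3, 0.0, 1e-3])
        inp = make_input(x, y)
        est_pre = egger_correlated(inp)
        est_neg = egger_correlated(make_input(-x, -y))
        assert est_pre.b == pytest.approx(est_neg.b, abs=1e-12)
        assert est_pre.egger_intercept == pytest.approx(est_neg.egger_intercept,
                                                        abs=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match="3 instruments"):
            egger_correlated(make_input([0.5, 0.4], [0.1, 0.08]))


class TestWeightedMedian:
    def test_middle_ratio_with_equal_weights(self):
        inp = make_input([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], se_zx=1e-12,
                         se_zy=0.1)
        assert weighted_median(inp, n_boot=10, seed=0).b == pytest.approx(2.0)

    def test_seeded_bootstrap_is_deterministic(self):
        inp = make_input([0.5, 0.4, 0.3], [0.1, 0.08, 0.05])
        a = weighted_median(inp, n_boot=200, seed=42)
        b = weighted_median(inp, n_boot=200, seed=42)
        assert a.se == b.se and a.bootstrap_seed == 42

    def test_breakdown_resistance_under_minority_contamination(self):
        # <=50% of weight displaced by +1 leaves the estimate near truth
        rng = np.random.default_rng(10)
        L, true = 30, -0.17
        x = rng.uniform(0.3, 0.6, L)
        y = true * x
        y[:12] += 1.0 * x[:12]  # 40% invalid
        inp = make_input(x, y, se_zx=1e-6, se_zy=1e-3)
        est = weighted_median(inp, n_boot=50, seed=1)
        assert est.b == pytest.approx(true, abs=0.05)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            weighted_median(make_input([0.5, 0.4], [0.1, 0.08]))


class TestOddsRatioScale:
    def test_null_effect_interval(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert (round(or_, 2), round(lo, 2), round(hi, 2)) == (1.0, 0.82, 1.22)

    def test_published_style_rounding(self):
        # an OR of 0.84 with CI (0.80, 0.88) implies se = ln(0.88/0.80)/(2z)
        b = np.log(0.84)
        se = np.log(0.88 / 0.80) / (2 * 1.959964)
        assert format_or_ci(*to_odds_ratio(b, se)) == "0.84 (0.80–0.88)"

    def test_degenerate_interval(self):
        or_, lo, hi = to_odds_ratio(0.3, 0.0)
        assert or_ == lo == hi == pytest.approx(np.exp(0.3))


class TestStructuralInvariances:
    def test_permutation_invariance_of_all_estimators(self):
        rng = np.random.default_rng(11)
        L = 6
        ld = ar1_ld([f"s{i}" for i in range(L)], 0.5).values
        inp = make_input(rng.uniform(0.2, 0.6, L), rng.normal(0, 0.1, L),
                         ld=ld)
        perm = rng.permutation(L)
        inp_p = MRInput(
            snp_ids=tuple(np.array(inp.snp_ids)[perm]),
            b_zx=inp.b_zx[perm], se_zx=inp.se_zx[perm],
            b_zy=inp.b_zy[perm], se_zy=inp.se_zy[perm],
            ld=inp.ld[np.ix_(perm, perm)], p_zx=inp.p_zx[perm],
        )
        for f in (gls_causal_estimate, ivw_correlated, egger_correlated):
            a, b = f(inp), f(inp_p)
            assert a.b == pytest.approx(b.b, abs=1e-12)
            assert a.se == pytest.approx(b.se, abs=1e-12)
        wm_a = weighted_median(inp, n_boot=20, seed=0)
        wm_b = weighted_median(inp_p, n_boot=20, seed=0)
        assert wm_a.b == pytest.approx(wm_b.b, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            make_input([0.5, 0.4], [0.1, 0.08], ld=np.array([[1, 0.3],
                                                             [0.4, 1.0]]))
        with pytest.raises(ValueError):
            make_input([0.5], [0.1], se_zy=-0.1)
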