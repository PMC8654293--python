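"""Instrument selection: cis windows, harmonization, greedy dual-cohort pruning."""

import numpy as np
import pandas as pd
import pytest

from cismr.instruments import (
    GeneAnnotation,
    InstrumentRejection,
    InstrumentSet,
    cis_window,
    greedy_prune,
    intersect_and_harmonize,
    select_instruments,
)
from cismr.simulate import LDMatrix

from .conftest import ar1_ld, make_sumstats


class TestCisWindow:
    def test_two_megabase_padding(self):
        gene = GeneAnnotation("G", "7", 3_000_000, 3_100_000)
        assert cis_window(gene) == ("7", 1_000_000, 5_100_000)

    def test_clamped_at_chromosome_start(self):
        gene = GeneAnnotation("G", "7", 500_000, 600_000)
        assert cis_window(gene)[1] == 1

    def test_boundary_position_is_inside(self):
        gene = GeneAnnotation("G", "7", 3_000_000, 3_100_000)
        _, lo, hi = cis_window(gene)
        assert lo <= 5_100_000 <= hi

    def test_inverted_gene_rejected(self):
        with pytest.raises(ValueError):
            GeneAnnotation("G", "7", 10, 5)

    def test_bed_conversion(self):
        g = GeneAnnotation.from_bed_row("G", "7", 99, 200)
        assert (g.start, g.end) == (100, 200)


class TestHarmonization:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        expo = make_sumstats(["rs1"], [0.3], [0.03])
        outc = make_sumstats(["rs1"], [0.1], [0.02], effect_allele=["G"],
                             other_allele=["A"], eaf=0.7)
        joined, excl = intersect_and_harmonize(expo, outc)
        assert excl.empty
        assert joined["b_zy"].iloc[0] == pytest.approx(-0.1)
        assert joined["eaf_zy"].iloc[0] == pytest.approx(0.3)

    def test_irreconcilable_alleles_excluded(self):
        expo = make_sumstats(["rs1"], [0.3], [0.03])
        outc = make_sumstats(["rs1"], [0.1], [0.02], other_allele=["C"])
        joined, excl = intersect_and_harmonize(expo, outc)
        assert joined.empty
        assert list(excl["reason"]) == ["allele mismatch"]

    def test_palindromic_excluded_by_default_but_configurable(self):
        expo = make_sumstats(["rs1", "rs2"], [0.3, 0.2], [0.03, 0.03],
                             effect_allele=["A", "A"], other_allele=["T", "G"])
        outc = make_sumstats(["rs1", "rs2"], [0.1, 0.1], [0.02, 0.02],
                             effect_allele=["A", "A"], other_allele=["T", "G"])
        joined, excl = intersect_and_harmonize(expo, outc)
        assert list(joined["snp_id"]) == ["rs2"]
        assert list(excl["reason"]) == ["palindromic"]
        joined2, excl2 = intersect_and_harmonize(expo, outc,
                                                 exclude_palindromic=False)
        assert len(joined2) == 2 and excl2.empty

    def test_self_harmonization_is_sign_identical(self):
        t = make_sumstats(["rs1", "rs2", "rs3"], [0.3, -0.2, 0.15],
                          [0.03, 0.03, 0.03])
        joined, _ = intersect_and_harmonize(t, t)
        np.testing.assert_allclose(joined["b_zx"], joined["b_zy"])

    def test_duplicate_snp_rejected(self):
        t = make_sumstats(["rs1", "rs1"], [0.3, 0.3], [0.03, 0.03])
        with pytest.raises(ValueError, match="duplicate"):
            intersect_and_harmonize(t, t.drop_duplicates("snp_id"))


def _candidates(snp_ids, pvals, pos=None):
    df = make_sumstats(snp_ids, [0.5] * len(snp_ids), [0.03] * len(snp_ids),
                       pos=pos)
    df = df.rename(columns={"p": "p_zx"})
    return df[["snp_id", "pos", "p_zx"]].assign(p_zx=pvals)


def _pair_ld(snp_ids, pairs):
    """LD with r for the named pairs, identity elsewhere."""
    L = len(snp_ids)
    m = np.eye(L)
    idx = {s: i for i, s in enumerate(snp_ids)}
    for (a, b), r in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
    return LDMatrix(tuple(snp_ids), m)


class TestGreedyPrune:
    ids = ["A", "B", "C"]

    def test_removal_via_exposure_ld(self):
        cand = _candidates(self.ids, [1e-9, 1e-8, 1e-7])
        ldx = _pair_ld(self.ids, {("A", "B"): np.sqrt(0.7)})
        ldy = _pair_ld(self.ids, {})
        assert greedy_prune(cand, ldx, ldy, r2_thresh=0.6) == ["A", "C"]

    def test_removal_via_outcome_ld_alone(self):
        cand = _candidates(self.ids, [1e-9, 1e-8, 1e-7])
        ldx = _pair_ld(self.ids, {})
        ldy = _pair_ld(self.ids, {("A", "B"): np.sqrt(0.7)})
        assert greedy_prune(cand, ldx, ldy, r2_thresh=0.6) == ["A", "C"]

    def test_empty_candidates(self):
        cand = _candidates([], [])
        ld = _pair_ld([], {})
        assert greedy_prune(cand, ld, ld) == []

    def test_missing_snp_in_ld_errors(self):
        cand = _candidates(self.ids, [1e-9, 1e-8, 1e-7])
        ld2 = _pair_ld(["A", "B"], {})
        with pytest.raises(KeyError, match="outcome"):
            greedy_prune(cand, _pair_ld(self.ids, {}), ld2)

    def test_tie_break_by_position_then_id(self):
        cand = _candidates(["Z", "Y"], [1e-8, 1e-8], pos=[200, 100])
        ld = _pair_ld(["Z", "Y"], {("Z", "Y"): 0.9})
        assert greedy_prune(cand, ld, ld, r2_thresh=0.6) == ["Y"]

    def test_matches_bruteforce_reimplementation(self):
        # independent re-implementation of the select/remove loop,
        # written with sets and explicit pairwise scans
        def brute_force(cand, r2x, r2y, p_thresh, r2_thresh):
            alive = {
                row.snp_id: (row.p_zx, row.pos)
                for row in cand.itertuples()
                if row.p_zx < p_thresh
            }
            out = []
            while alive:
                top = min(alive, key=lambda s: (alive[s][0], alive[s][1], s))
                out.append(top)
                dead = {
                    s for s in alive
                    if r2x.loc[top, s] > r2_thresh or r2y.loc[top, s] > r2_thresh
                }
                for s in dead | {top}:
                    alive.pop(s, None)
            return out

        rng = np.random.default_rng(77)
        for _ in range(200):
            L = int(rng.integers(2, 13))
            ids = [f"v{i}" for i in range(L)]
            pvals = 10.0 ** rng.uniform(-12, -6.5, L)
            pos = rng.choice(10**6, size=L, replace=False)
            cand = _candidates(ids, pvals, pos=pos)

            def random_ld():
                w = rng.normal(size=(L, L + 2))
                c = w @ w.T
                d = np.sqrt(np.diag(c))
                return LDMatrix(tuple(ids), c / np.outer(d, d))

            ldx, ldy = random_ld(), random_ld()
            got = greedy_prune(cand, ldx, ldy, p_thresh=1e-6, r2_thresh=0.3)
            r2x = pd.DataFrame(ldx.r2, index=ids, columns=ids)
            r2y = pd.DataFrame(ldy.r2, index=ids, columns=ids)
            assert got == brute_force(cand, r2x, r2y, 1e-6, 0.3)


def _selection_fixture(n_snps, pvals=None):
    """AR(1) rho=0.8 block of cis SNPs with p increasing along position."""
    ids = [f"rs{i}" for i in range(n_snps)]
    if pvals is None:
        # ascending along the block, all below the 1e-6 instrument threshold
        pvals = [1e-16 * 10**i for i in range(n_snps)]
    betas = [0.5 - 0.01 * i for i in range(n_snps)]
    expo = make_sumstats(ids, betas, [0.03] * n_snps)
    expo["p"] = pvals
    outc = make_sumstats(ids, [0.05] * n_snps, [0.02] * n_snps, n=20_000)
    ld = ar1_ld(ids, 0.8)
    gene = GeneAnnotation("GENE1", "1", 3_000_000, 3_100_000)
    return gene, expo, outc, ld


class TestSelectInstruments:
    # with rho=0.8 and p ordered along the block, the greedy loop removes a
    # radius-1 neighbourhood at r2=0.6 (0.8^2 > 0.6) and a radius-3
    # neighbourhood at r2=0.2, so selections are every 2nd / every 4th SNP
    def test_default_selection_pattern(self):
        gene, expo, outc, ld = _selection_fixture(9)
        res = select_instruments("P", gene, expo, outc, ld, ld)
        assert isinstance(res, InstrumentSet)
        assert list(res.table["snp_id"]) == ["rs0", "rs2", "rs4", "rs6", "rs8"]
        assert res.heidi_capable
        assert list(res.ld_outcome.snp_ids) == list(res.table["snp_id"])

    def test_stricter_settings_select_strict_subsets(self):
        pvals = [1e-12, 1e-11, 1e-10, 1e-9, 2e-7, 3e-7, 4e-7, 5e-7, 6e-7]
        gene, expo, outc, ld = _selection_fixture(9, pvals)

        def sel(p_thresh, r2_thresh):
            r = select_instruments("P", gene, expo, outc, ld, ld,
                                   p_thresh=p_thresh, r2_thresh=r2_thresh,
                                   min_iv=1)
            return set(r.table["snp_id"])

        default = sel(1e-6, 0.6)
        for strict in (sel(1e-6, 0.2), sel(5e-8, 0.6), sel(5e-8, 0.2)):
            assert strict < default

    def test_selection_parameters_recorded(self):
        gene, expo, outc, ld = _selection_fixture(9)
        res = select_instruments("P", gene, expo, outc, ld, ld,
                                 p_thresh=5e-8, r2_thresh=0.2, min_iv=1)
        assert (res.p_thresh, res.r2_thresh) == (5e-8, 0.2)

    def test_too_few_instruments_rejected(self):
        gene, expo, outc, ld = _selection_fixture(5)  # selects rs0, rs2, rs4
        res = select_instruments("P", gene, expo, outc, ld, ld)
        assert isinstance(res, InstrumentRejection)
        assert res.n_selected == 3
        assert "min_iv" in res.reason

    def test_four_instruments_disable_heidi(self):
        gene, expo, outc, ld = _selection_fixture(7)  # rs0, rs2, rs4, rs6
        res = select_instruments("P", gene, expo, outc, ld, ld)
        assert isinstance(res, InstrumentSet)
        assert res.n_instruments == 4 and not res.heidi_capable

    def test_cis_window_restricts_candidates(self):
        gene, expo, outc, ld = _selection_fixture(9)
        expo.loc[0, "pos"] = 50_000_000  # best SNP moved out of cis range
        res = select_instruments("P", gene, expo, outc, ld, ld, min_iv=1)
        assert "rs0" not in set(res.table["snp_id"])

    def test_deterministic_given_inputs(self):
        gene, expo, outc, ld = _selection_fixture(9)
        a = select_instruments("P", gene, expo, outc, ld, ld)
        b = select_instruments("P", gene, expo, outc, ld, ld)
        pd.testing.assert_frame_equal(a.table, b.table)
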