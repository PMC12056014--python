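"""EHH decay, iHH integration, iHS/xpEHH values and their standardization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.ehh import (
    EhhCurve,
    EhhParams,
    ehh_decay_curve,
    ehh_step,
    ihs_unstandardized,
    integrate_ihh,
    standardize,
    xpehh_unstandardized,
)

from conftest import ehh_pair_oracle, make_matrix, random_panel


class TestEhhStep:
    def test_core_only_interval_is_one(self):
        hm = make_matrix([[1, 1, 1, 0], [0, 1, 0, 1]])
        carriers = [0, 1, 2]  # carriers of the derived core allele at site 0
        assert ehh_step(hm, carriers, (0, 0)) == 1.0

    def test_single_extension_split(self):
        # 4 carriers, extension alleles {0,0,0,1}: (C(3,2)+C(1,2))/C(4,2) = 0.5
        hm = make_matrix([[1, 1, 1, 1], [0, 0, 0, 1]])
        assert ehh_step(hm, [0, 1, 2, 3], (0, 1)) == pytest.approx(0.5)

    def test_two_site_extension(self):
        # strings {00,00,01,11}: one identical pair of 6 -> 1/6
        hm = make_matrix([[1, 1, 1, 1], [0, 0, 0, 1], [0, 0, 1, 1]])
        assert ehh_step(hm, [0, 1, 2, 3], (0, 2)) == pytest.approx(1 / 6)

    def test_fewer_than_two_carriers_errors(self):
        hm = make_matrix([[1, 0]])
        with pytest.raises(ValueError):
            ehh_step(hm, [0], (0, 0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(2, 11))
        n_hap = int(rng.integers(3, 9))
        hm = random_panel(rng, n_sites, n_hap)
        carriers = np.arange(n_hap)
        for lo in range(n_sites):
            for hi in range(lo, n_sites):
                assert ehh_step(hm, carriers, (lo, hi)) == pytest.approx(
                    ehh_pair_oracle(hm, carriers, lo, hi)
                )

    def test_non_increasing_in_extension(self, rng):
        hm = random_panel(rng, 12, 8)
        carriers = np.arange(8)
        vals = [ehh_step(hm, carriers, (0, hi)) for hi in range(12)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestIntegrateIhh:
    def test_constant_trapezoid(self):
        c = EhhCurve(0, "pooled", [(0, 1.0), (10000, 1.0)])
        assert integrate_ihh(c, 0.05) == pytest.approx(10000)

    def test_stops_after_first_below_cutoff_point(self):
        c = EhhCurve(0, "pooled", [(0, 1.0), (1000, 0.5), (2000, 0.04), (3000, 0.04)])
        # 750 into the second point, plus 270 into the below-cutoff point
        assert integrate_ihh(c, 0.05) == pytest.approx(1020)

    def test_single_point_is_zero(self):
        assert integrate_ihh(EhhCurve(0, "pooled", [(0, 1.0)]), 0.05) == 0.0

    def test_matches_independent_summation(self, rng):
        dists = np.cumsum(rng.integers(100, 2000, size=12)).astype(float)
        ehhs = np.sort(rng.random(12))[::-1]
        pts = [(0.0, 1.0)] + list(zip(dists, ehhs))
        cutoff = 0.3
        # independent: explicit loop with early stop
        area = 0.0
        for (d0, e0), (d1, e1) in zip(pts, pts[1:]):
            area += (e0 + e1) * (d1 - d0) / 2
            if e1 < cutoff:
                break
        assert integrate_ihh(EhhCurve(0, "x", pts), cutoff) == pytest.approx(area)


def unique_end_panel(mid_rows, pops=None):
    """Panel whose haplotypes carry unique id bits at both chromosome ends.

    Guarantees every pairwise EHH curve decays to exactly 0 before the ends,
    so a tiny positive cutoff integrates the full decay without truncation.
    """
    mid = np.asarray(mid_rows, dtype=np.int8)
    n_hap = mid.shape[1]
    assert n_hap <= 16
    ids = np.array([[(h >> b) & 1 for h in range(n_hap)] for b in range(4)], dtype=np.int8)
    alleles = np.concatenate([ids, mid, ids[::-1]], axis=0)
    return make_matrix(alleles, pops=pops)


TINY = EhhParams(cutoff=1e-9)


class TestIhs:
    def test_symmetric_panel_scores_zero(self):
        # derived and ancestral carriers have mirror-image haplotype structure
        mid = [[0, 0, 1, 1], [0, 1, 0, 1], [0, 0, 1, 1],
               [1, 1, 0, 0],
               [0, 1, 0, 1], [0, 0, 1, 1], [0, 1, 0, 1]]
        hm = unique_end_panel(mid)
        val, reason = ihs_unstandardized(hm, "POP1", 7, TINY)
        assert reason is None
        assert val == pytest.approx(0.0)

    def test_long_derived_haplotypes_give_negative_score(self):
        # derived carriers identical over the span; ancestral diverse
        mid = np.zeros((9, 8), dtype=np.int8)
        mid[4, :4] = 1  # core: haps 0-3 derived
        mid[0, 4:] = [0, 1, 0, 1]  # ancestral carriers split early on both sides
        mid[8, 4:] = [0, 0, 1, 1]
        hm = unique_end_panel(mid)
        val, reason = ihs_unstandardized(hm, "POP1", 8, TINY)
        assert reason is None
        assert val < 0

    def test_matches_hand_enumeration_on_toy_panel(self, rng):
        hm = unique_end_panel(rng.integers(0, 2, size=(5, 8)))
        core = 6
        n_sites = hm.n_sites
        params = TINY
        carriers = {1: np.flatnonzero(hm.alleles[core] == 1),
                    0: np.flatnonzero(hm.alleles[core] == 0)}
        assert min(c.size for c in carriers.values()) >= 2
        ihh = {}
        for al, cset in carriers.items():
            total = 0.0
            for direction in (-1, 1):
                idxs = range(core - 1, -1, -1) if direction < 0 else range(core + 1, n_sites)
                pts = [(0.0, 1.0)]
                for j in idxs:
                    lo, hi = min(j, core), max(j, core)
                    pts.append(
                        (abs(float(hm.positions[j] - hm.positions[core])),
                         ehh_pair_oracle(hm, cset, lo, hi))
                    )
                for (d0, e0), (d1, e1) in zip(pts, pts[1:]):
                    total += (e0 + e1) * (d1 - d0) / 2
            ihh[al] = total
        expected = math.log(ihh[0] / ihh[1])
        val, reason = ihs_unstandardized(hm, "POP1", core, params)
        assert reason is None
        assert val == pytest.approx(expected)

    def test_antisymmetric_under_polarity_swap(self, rng):
        hm = unique_end_panel(rng.integers(0, 2, size=(5, 8)))
        core = 6
        v1, r1 = ihs_unstandardized(hm, "POP1", core, TINY)
        hm.alleles[core] = 1 - hm.alleles[core]
        v2, r2 = ihs_unstandardized(hm, "POP1", core, TINY)
        assert r1 is None and r2 is None
        assert v1 == pytest.approx(-v2)

    def test_few_carriers_is_na(self):
        hm = make_matrix([[0, 0], [1, 0], [0, 0]])
        val, reason = ihs_unstandardized(hm, "POP1", 1)
        assert math.isnan(val) and reason == "few_carriers"

    def test_truncation_by_gap_is_na(self):
        alleles = np.array([[0, 1, 0, 1]] * 5, dtype=np.int8)
        alleles[2] = [1, 1, 0, 0]
        hm = make_matrix(alleles, positions=[1000, 2000, 3000, 300_000, 301_000])
        val, reason = ihs_unstandardized(hm, "POP1", 2, EhhParams(max_gap_bp=200_000))
        assert math.isnan(val) and reason in ("gap", "chrom_end")


class TestXpehh:
    def test_identical_panels_score_zero(self, rng):
        # each haplotype has an identical twin in the other population, so the
        # pooled EHH floors at the twin-pair fraction; stop just above it
        block = unique_end_panel(rng.integers(0, 2, size=(5, 6))).alleles
        alleles = np.concatenate([block, block], axis=1)
        hm = make_matrix(alleles, pops=["A"] * 6 + ["B"] * 6)
        val, reason = xpehh_unstandardized(hm, "A", "B", 6, EhhParams(cutoff=0.1))
        assert reason is None
        assert val == pytest.approx(0.0)

    def test_homogeneous_population_scores_positive(self, rng):
        mid = np.concatenate(
            [np.zeros((9, 6), dtype=np.int8), rng.integers(0, 2, size=(9, 6), dtype=np.int8)],
            axis=1,
        )
        hm = unique_end_panel(mid, pops=["A"] * 6 + ["B"] * 6)
        val, reason = xpehh_unstandardized(hm, "A", "B", 8, TINY)
        assert reason is None
        assert val > 0

    def test_exact_antisymmetry(self, rng):
        hm = unique_end_panel(rng.integers(0, 2, size=(5, 12)), pops=["A"] * 6 + ["B"] * 6)
        v_ab, r1 = xpehh_unstandardized(hm, "A", "B", 6, TINY)
        v_ba, r2 = xpehh_unstandardized(hm, "B", "A", 6, TINY)
        assert r1 is None and r2 is None
        assert v_ab == -v_ba

    def test_matches_pair_oracle_with_pooled_boundary(self, rng):
        hm = unique_end_panel(rng.integers(0, 2, size=(5, 10)), pops=["A"] * 6 + ["B"] * 4)
        core = 6
        n_sites = hm.n_sites
        params = TINY
        cols = {"A": np.arange(6), "B": np.arange(6, 10)}
        ihh = {}
        for pop, cset in cols.items():
            total = 0.0
            for direction in (-1, 1):
                idxs = range(core - 1, -1, -1) if direction < 0 else range(core + 1, n_sites)
                pts = [(0.0, 1.0)]
                for j in idxs:
                    lo, hi = min(j, core), max(j, core)
                    pts.append(
                        (abs(float(hm.positions[j] - hm.positions[core])),
                         ehh_pair_oracle(hm, cset, lo, hi))
                    )
                for (d0, e0), (d1, e1) in zip(pts, pts[1:]):
                    total += (e0 + e1) * (d1 - d0) / 2
            ihh[pop] = total
        val, reason = xpehh_unstandardized(hm, "A", "B", core, params)
        assert reason is None
        assert val == pytest.approx(math.log(ihh["A"] / ihh["B"]))


class TestStandardize:
    def test_single_bin_z_scores(self):
        std, _ = standardize(np.array([1.0, 2.0, 3.0]), np.array([0.5, 0.5, 0.5]),
                             mode="global", min_bin_size=1)
        assert std == pytest.approx([-1.0, 0.0, 1.0])  # sample SD

    def test_bins_have_zero_mean_unit_sd(self, rng):
        x = rng.normal(size=500)
        f = rng.random(500)
        std, bins = standardize(x, f, n_bins=10, min_bin_size=20)
        for b in np.unique(bins[bins >= 0]):
            sel = bins == b
            assert abs(std[sel].mean()) < 1e-9
            assert abs(std[sel].std(ddof=1) - 1) < 1e-9

    def test_rank_preserved_within_bins(self, rng):
        x = rng.normal(size=300)
        f = rng.random(300)
        std, bins = standardize(x, f, n_bins=5, min_bin_size=20)
        for b in np.unique(bins[bins >= 0]):
            sel = bins == b
            assert (np.argsort(x[sel]) == np.argsort(std[sel])).all()

    def test_nan_propagates(self):
        x = np.array([1.0, np.nan, 2.0, 3.0])
        std, bins = standardize(x, np.full(4, 0.5), mode="global", min_bin_size=1)
        assert np.isnan(std[1]) and bins[1] == -1

    def test_all_na_errors(self):
        with pytest.raises(ValueError):
            standardize(np.array([np.nan, np.nan]), np.array([0.1, 0.2]))


def test_ehh_decay_curve_monotone_and_truncation_flag(rng):
    hm = random_panel(rng, 30, 10)
    curve = ehh_decay_curve(hm, np.arange(10), 15, +1, EhhParams())
    ehhs = [e for _, e in curve.points]
    assert ehhs[0] == 1.0
    assert all(a >= b for a, b in zip(ehhs, ehhs[1:]))
    # cutoff 0 can never be reached -> walk runs to the chromosome end
    curve = ehh_decay_curve(hm, np.arange(10), 15, +1, EhhParams(cutoff=0.0))
    assert curve.truncated == "chrom_end"
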