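"""Composite candidate calling: windows, top-1% cut, FST gate, exon mapping."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.calls import (
    call_candidates,
    eqtl_flag,
    map_and_classify,
    merge_eqtl,
    region_proportions,
    top_window_cut,
    window_extreme_counts,
)
from sweepscan.ehh import ScoreTrack
from sweepscan.hapio import GeneAnnotation, RegionClass


def track_from_scores(scores, chrom="chr1", statistic="iHS", pops=("P1",), positions=None):
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    pos = np.asarray(positions) if positions is not None else np.arange(1, n + 1) * 100
    return ScoreTrack(
        statistic=statistic,
        pops=tuple(pops),
        chrom=np.full(n, chrom),
        pos=pos,
        freq=np.full(n, 0.5),
        unstd=scores,
        std=scores,
        na_reason=np.full(n, "", dtype=object),
    )


class TestWindowCounts:
    def test_three_window_example(self):
        tr = track_from_scores([2.5, 1.0, 2.1, 0.0, 3.0])
        ws = window_extreme_counts(tr, window_size=3, score_cut=2.0)
        # ends excluded; centered counts
        assert ws["n_extreme"].tolist() == [2, 1, 2]
        assert ws["pos"].tolist() == [200, 300, 400]

    def test_all_na_counts_zero(self):
        tr = track_from_scores([np.nan] * 7)
        ws = window_extreme_counts(tr, window_size=3, score_cut=2.0)
        assert (ws["n_extreme"] == 0).all()

    def test_all_extreme_counts_full_window(self):
        tr = track_from_scores([3.0] * 9)
        ws = window_extreme_counts(tr, window_size=5, score_cut=2.0)
        assert (ws["n_extreme"] == 5).all()

    def test_short_chromosome_warns_and_yields_nothing(self):
        tr = track_from_scores([2.5, 2.5, 2.5])
        with pytest.warns(UserWarning, match="window"):
            with pytest.raises(ValueError):
                window_extreme_counts(tr, window_size=5, score_cut=2.0)

    def test_matches_brute_force_recount(self, rng):
        scores = rng.normal(size=200) * 1.5
        scores[rng.choice(200, 10, replace=False)] = np.nan
        tr = track_from_scores(scores)
        ws = window_extreme_counts(tr, window_size=11, score_cut=2.0)
        for _, row in ws.iterrows():
            c = int(np.flatnonzero(tr.pos == row["pos"])[0])
            window = scores[c - 5 : c + 6]
            expected = int(np.nansum(np.abs(np.nan_to_num(window)) > 2.0))
            assert row["n_extreme"] == expected


class TestTopWindowCut:
    def test_sparse_extremes_select_exact_windows(self):
        counts = np.zeros(1000, dtype=int)
        counts[:10] = 40
        ws = pd.DataFrame({"chrom": "c", "pos": np.arange(1000), "n_extreme": counts})
        thr = top_window_cut(ws, top_frac=0.01)
        assert thr == 40
        assert (ws["n_extreme"] >= thr).sum() == 10

    def test_uniform_counts_nearest_rank(self, rng):
        counts = rng.integers(0, 51, size=997)
        ws = pd.DataFrame({"chrom": "c", "pos": np.arange(997), "n_extreme": counts})
        thr = top_window_cut(ws, top_frac=0.01)
        k = int(np.ceil(0.01 * 997))
        assert thr == np.sort(counts)[len(counts) - k]

    def test_all_equal_counts_all_qualify(self):
        ws = pd.DataFrame({"chrom": "c", "pos": np.arange(50), "n_extreme": 7})
        thr = top_window_cut(ws, top_frac=0.01)
        assert thr == 7
        assert (ws["n_extreme"] >= thr).all()

    def test_single_window_errors(self):
        ws = pd.DataFrame({"chrom": "c", "pos": [1], "n_extreme": [3]})
        with pytest.raises(ValueError):
            top_window_cut(ws)


def _fst_pass_frame(track, passes):
    return pd.DataFrame({"chrom": track.chrom, "pos": track.pos,
                         "passes_threshold": passes})


class TestCallCandidates:
    def setup_method(self):
        scores = np.zeros(9)
        scores[4] = 2.5
        scores[3] = 2.2
        self.track = track_from_scores(scores)
        self.ws = window_extreme_counts(self.track, window_size=3, score_cut=2.0)

    def test_conjunction_emits(self):
        fst = _fst_pass_frame(self.track, np.ones(9, dtype=bool))
        out = call_candidates(self.track, self.ws, 1, fst, 2.0)
        assert 500 in out["pos"].tolist()

    def test_fst_failure_blocks(self):
        fst = _fst_pass_frame(self.track, np.zeros(9, dtype=bool))
        out = call_candidates(self.track, self.ws, 1, fst, 2.0)
        assert len(out) == 0

    def test_subthreshold_score_in_qualifying_window_blocked(self):
        # site 5 (score 0) sits in a qualifying window but fails the site cut
        fst = _fst_pass_frame(self.track, np.ones(9, dtype=bool))
        out = call_candidates(self.track, self.ws, 1, fst, 2.0)
        assert 600 not in out["pos"].tolist()

    def test_coordinate_mismatch_errors(self):
        fst = _fst_pass_frame(self.track, np.ones(9, dtype=bool)).iloc[:5]
        with pytest.raises(ValueError, match="missing"):
            call_candidates(self.track, self.ws, 1, fst, 2.0)

    def test_monotone_in_score_cut(self, rng):
        scores = rng.normal(size=300) * 2
        track = track_from_scores(scores)
        ws = window_extreme_counts(track, 11, 2.0)
        fst = _fst_pass_frame(track, rng.random(300) < 0.5)
        lo = call_candidates(track, ws, 1, fst, 2.0)
        hi = call_candidates(track, ws, 1, fst, 2.5)
        assert set(hi["pos"]) <= set(lo["pos"])

    def test_xpehh_target_follows_sign(self):
        scores = np.zeros(9)
        scores[4] = 2.5
        scores[3] = -2.2
        track = track_from_scores(scores, statistic="xpEHH", pops=("A", "B"))
        ws = window_extreme_counts(track, 3, 2.0)
        fst = _fst_pass_frame(track, np.ones(9, dtype=bool))
        out = call_candidates(track, ws, 1, fst, 2.0)
        by_pos = out.set_index("pos")["target_pop"]
        assert by_pos[500] == "A" and by_pos[400] == "B"


def _genes():
    g1 = GeneAnnotation("G1", "G1", "chr1", "+")
    g1.add_interval(100, 200, RegionClass.CDS)
    g1.add_interval(150, 260, RegionClass.THREE_UTR)  # overlapping transcript
    g2 = GeneAnnotation("G2", "G2", "chr1", "-")
    g2.add_interval(400, 500, RegionClass.NONCODING_EXON)
    return {"G1": g1, "G2": g2}


def _cand(pos):
    return pd.DataFrame(
        {"chrom": ["chr1"], "pos": [pos], "statistic": ["iHS"], "target_pop": ["P1"],
         "pops": ["P1"], "score": [2.5], "fst_pass": [True]}
    )


class TestMapAndClassify:
    def test_cds_precedence_over_utr(self):
        out = map_and_classify(_cand(180), _genes())
        assert out.iloc[0]["gene_id"] == "G1"
        assert out.iloc[0]["region_class"] == "CDS"

    def test_utr_only_region(self):
        out = map_and_classify(_cand(230), _genes())
        assert out.iloc[0]["region_class"] == "THREE_UTR"

    def test_intergenic_dropped(self):
        assert len(map_and_classify(_cand(350), _genes())) == 0

    def test_noncoding_exon(self):
        out = map_and_classify(_cand(450), _genes())
        assert out.iloc[0]["region_class"] == "NONCODING_EXON"


class TestEqtl:
    def test_strict_threshold(self):
        assert eqtl_flag(0.95) is True
        assert eqtl_flag(0.9) is False
        assert eqtl_flag(0.0) is False

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            eqtl_flag(1.2)

    def test_merge_annotates_tissues(self):
        cand = _cand(180)
        m = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [180, 180],
                          "tissue": ["Brain", "Liver"], "m_value": [0.95, 0.5]})
        out = merge_eqtl(cand, m)
        assert out.iloc[0]["eqtl_tissues"] == "Brain"


class TestRegionProportions:
    def test_mixed_classes(self):
        df = pd.DataFrame({
            "chrom": "chr1", "pos": [1, 2, 3, 4], "statistic": "iHS",
            "target_pop": "P1",
            "region_class": ["CDS", "CDS", "THREE_UTR", "NONCODING_EXON"],
        })
        props = region_proportions(df)
        assert props == {"CDS": 0.5, "THREE_UTR": 0.25, "NONCODING_EXON": 0.25,
                         "FIVE_UTR": 0.0}

    def test_single_class(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [1], "statistic": "iHS",
                           "target_pop": "P1", "region_class": ["CDS"]})
        assert region_proportions(df)["CDS"] == 1.0

    def test_sums_to_one_on_random_mix(self, rng):
        classes = rng.choice(["CDS", "FIVE_UTR", "THREE_UTR", "NONCODING_EXON"], 97)
        df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(97), "statistic": "iHS",
                           "target_pop": "P1", "region_class": classes})
        props = region_proportions(df)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)
        # brute-force tally
        for cls in set(classes):
            assert props[cls] == pytest.approx((classes == cls).mean())

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            region_proportions(pd.DataFrame(columns=["chrom", "pos", "region_class"]))
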