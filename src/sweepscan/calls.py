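"""Composite positively-selected-variant calling.

A site is called a candidate when three conditions hold jointly:

1. its own standardized |iHS| or |xpEHH| exceeds ``score_cut`` (default 2);
2. the 51-SNP window centered on it ranks in the genome-wide top 1% by the
   number of extreme-score SNPs it contains (extreme scores cluster around
   true sweeps, isolated outliers do not);
3. its FST passes the allele-frequency-binned top-tail threshold for the
   relevant population pair.

Candidates are then intersected with exon annotations (a variant must fall in
at least one exon), classified into 5'UTR / 3'UTR / CDS / non-coding-exon with
CDS taking precedence when transcripts disagree, and optionally flagged with
eQTL effects (m-value > 0.9, strict).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .ehh import ScoreTrack
from .fst import nearest_rank_upper
from .hapio import REGION_PRECEDENCE, GeneAnnotation, RegionClass

__all__ = [
    "window_extreme_counts",
    "top_window_cut",
    "call_candidates",
    "map_and_classify",
    "eqtl_flag",
    "merge_eqtl",
    "region_proportions",
]


def window_extreme_counts(
    track: ScoreTrack, window_size: int = 51, score_cut: float = 2.0
) -> pd.DataFrame:
    """Count extreme-score SNPs in a sliding window centered on each site.

    Windows slide by one SNP; a window exists only where the center has
    (window_size-1)/2 scored sites on both sides within its chromosome
    (chromosome-end windows are excluded so every count shares one
    denominator).  NA scores count as non-extreme.  Chromosomes with fewer
    than ``window_size`` sites contribute no windows (a warning is issued).

    Returns a DataFrame with chrom, pos, n_extreme.
    """
    if window_size % 2 != 1:
        raise ValueError("window_size must be odd")
    half = window_size // 2
    out = []
    for chrom in pd.unique(track.chrom):
        sel = track.chrom == chrom
        pos = track.pos[sel]
        std = track.std[sel]
        if pos.size < window_size:
            warnings.warn(
                f"chromosome {chrom}: {pos.size} scored sites < window size "
                f"{window_size}; no windows"
            )
            continue
        extreme = (np.abs(np.nan_to_num(std, nan=0.0)) > score_cut).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(extreme)])
        centers = np.arange(half, pos.size - half)
        counts = csum[centers + half + 1] - csum[centers - half]
        out.append(pd.DataFrame({"chrom": chrom, "pos": pos[centers], "n_extreme": counts}))
    if not out:
        raise ValueError("no chromosome had enough scored sites for a window")
    return pd.concat(out, ignore_index=True)


def top_window_cut(window_stats: pd.DataFrame, top_frac: float = 0.01) -> int:
    """Genome-wide extreme-count threshold selecting the top ``top_frac`` windows.

    Nearest-rank rule: with n windows, the threshold is the k-th largest
    n_extreme, k = ceil(top_frac * n); a window qualifies iff
    n_extreme >= threshold (ties may push the qualifying fraction above
    ``top_frac``).  When every window has the same count, all qualify.
    """
    counts = window_stats["n_extreme"].to_numpy()
    if counts.size < 2:
        raise ValueError("need at least 2 windows to define a top fraction")
    return int(nearest_rank_upper(counts.astype(float), top_frac))


def call_candidates(
    track: ScoreTrack,
    window_stats: pd.DataFrame,
    window_threshold: int,
    fst_pass: pd.DataFrame,
    score_cut: float = 2.0,
) -> pd.DataFrame:
    """Emit candidate variants: extreme site in a qualifying window with high FST.

    ``fst_pass`` must carry chrom, pos, passes_threshold covering every scored
    site of the track (coordinate mismatch is an error).  For an iHS track the
    caller supplies the union-over-pairs pass flag; for xpEHH the pair's own.

    Returns chrom, pos, statistic, pops, score, fst_pass columns; for xpEHH
    the target population is the first label when the score is positive and
    the second when negative.
    """
    sites = pd.DataFrame({"chrom": track.chrom, "pos": track.pos, "score": track.std})
    fmap = fst_pass.set_index(["chrom", "pos"])["passes_threshold"]
    idx = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    if not idx.isin(fmap.index).all():
        missing = sites[~idx.isin(fmap.index)].iloc[0]
        raise ValueError(
            f"FST records missing for scored site {missing['chrom']}:{missing['pos']}"
        )
    sites["fst_pass"] = fmap.loc[idx].to_numpy()
    wmap = window_stats.set_index(["chrom", "pos"])["n_extreme"]
    in_window = idx.isin(wmap.index)
    n_ext = np.full(len(sites), -1, dtype=np.int64)
    n_ext[in_window] = wmap.loc[idx[in_window]].to_numpy()
    qualifies = n_ext >= window_threshold
    extreme = np.abs(np.nan_to_num(sites["score"].to_numpy(), nan=0.0)) > score_cut
    keep = extreme & qualifies & sites["fst_pass"].to_numpy()
    cand = sites.loc[keep, ["chrom", "pos", "score", "fst_pass"]].copy()
    cand.insert(2, "statistic", track.statistic)
    if track.statistic == "xpEHH":
        target = np.where(cand["score"].to_numpy() > 0, track.pops[0], track.pops[1])
        cand.insert(3, "target_pop", target)
        cand.insert(4, "pops", "/".join(track.pops))
    else:
        cand.insert(3, "target_pop", track.pops[0])
        cand.insert(4, "pops", track.pops[0])
    return cand.reset_index(drop=True)


def _annotation_trees(
    annotations: dict[str, GeneAnnotation]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in annotations.values():
        tree = trees.setdefault(g.chrom, IntervalTree())
        for start, end, region in g.intervals:
            tree.addi(start, end + 1, (g.gene_id, region))  # half-open internally
    return trees


def map_and_classify(
    candidates: pd.DataFrame, annotations: dict[str, GeneAnnotation]
) -> pd.DataFrame:
    """Keep exonic candidates; attach gene_id and region_class.

    A candidate inside exons of several genes yields one row per gene.  When
    transcripts of a gene disagree on the class of the position, precedence is
    CDS > 5'UTR > 3'UTR > non-coding exon.  Intergenic/intronic candidates are
    dropped.
    """
    trees = _annotation_trees(annotations)
    rows = []
    for _, row in candidates.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        hits: dict[str, list[RegionClass]] = {}
        for iv in tree.at(int(row["pos"])):
            gid, region = iv.data
            hits.setdefault(gid, []).append(region)
        for gid, regions in sorted(hits.items()):
            best = min(regions, key=REGION_PRECEDENCE.index)
            out = row.to_dict()
            out["gene_id"] = gid
            out["region_class"] = best.value
            rows.append(out)
    cols = list(candidates.columns) + ["gene_id", "region_class"]
    return pd.DataFrame(rows, columns=cols)


def eqtl_flag(m: float) -> bool:
    """True iff the eQTL posterior m-value exceeds 0.9 (strict inequality)."""
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"m-value {m} outside [0, 1]")
    return m > 0.9


def merge_eqtl(candidates: pd.DataFrame, m_table: pd.DataFrame) -> pd.DataFrame:
    """Attach per-tissue eQTL flags from an m-value table keyed by (chrom, pos, tissue)."""
    m = m_table.copy()
    m["has_effect"] = [eqtl_flag(v) for v in m["m_value"]]
    eff = (
        m[m["has_effect"]]
        .groupby(["chrom", "pos"])["tissue"]
        .apply(lambda t: ",".join(sorted(t)))
        .rename("eqtl_tissues")
    )
    out = candidates.merge(eff, on=["chrom", "pos"], how="left")
    out["eqtl_tissues"] = out["eqtl_tissues"].fillna("")
    return out


def region_proportions(candidates: pd.DataFrame) -> dict[str, float]:
    """Fraction of distinct candidate variants per exonic region class.

    A variant mapped to several genes counts once, under its highest-precedence
    class.  Proportions sum to 1.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates to summarize")
    best = (
        candidates.assign(
            _rank=candidates["region_class"].map(
                {rc.value: i for i, rc in enumerate(REGION_PRECEDENCE)}
            )
        )
        .sort_values("_rank")
        .drop_duplicates(subset=["chrom", "pos", "statistic", "target_pop"], keep="first")
    )
    total = len(best)
    out = {rc.value: 0.0 for rc in RegionClass}
    for cls, cnt in best["region_class"].value_counts().items():
        out[cls] = cnt / total
    return out
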