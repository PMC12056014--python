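"""Per-site two-population Weir–Cockerham FST and frequency-binned thresholds.

The estimator is the 1984 variance-component form FST = a / (a + b + c) with
a the among-population, b the among-individual-within-population and c the
within-individual component, computed from diploid genotype counts.  Because
the attainable FST of a site depends strongly on its allele frequency, sites
are binned by pooled derived-allele frequency and the empirical top tail of
each bin defines that bin's threshold (nearest-rank upper quantile, flag
inclusive at the threshold).  Negative estimates are kept as-is; they simply
never reach a top tail.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .hapio import HaplotypeMatrix

__all__ = [
    "wc_fst_site",
    "genotype_counts",
    "fst_records",
    "binned_fst_thresholds",
    "nearest_rank_upper",
]


def wc_fst_site(
    counts1: tuple[int, int, int], counts2: tuple[int, int, int]
) -> float:
    """Weir–Cockerham FST from (n_hom_ref, n_het, n_hom_alt) of two populations.

    Computed in exact rational arithmetic (genotype counts are integers), so
    fixed differences return exactly 1.0 regardless of sample sizes.  Returns
    NaN when the total variance a+b+c is zero (site monomorphic across both
    populations).  The estimate may be negative.
    """
    for c in (*counts1, *counts2):
        if c < 0:
            raise ValueError("negative genotype count")
    r = 2
    n = [Fraction(sum(counts1)), Fraction(sum(counts2))]
    if min(n) < 1:
        raise ValueError("each population needs at least one diploid individual")
    # alt-allele frequency and observed heterozygosity per population
    p = [
        Fraction(counts1[1] + 2 * counts1[2], 2 * sum(counts1)),
        Fraction(counts2[1] + 2 * counts2[2], 2 * sum(counts2)),
    ]
    h = [Fraction(counts1[1], sum(counts1)), Fraction(counts2[1], sum(counts2))]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - Fraction(r - 1, r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - Fraction(r - 1, r) * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return math.nan
    return float(a / denom)


def genotype_counts(hm: HaplotypeMatrix, pop: str, site: int) -> tuple[int, int, int]:
    """(n_hom_ancestral, n_het, n_hom_derived) for one site and population.

    Haplotype columns 2i and 2i+1 are the two chromosomes of diploid i.
    """
    cols = hm.pop_indices(pop)
    alle = hm.alleles[site, cols]
    pair_sum = alle[0::2] + alle[1::2]
    return (
        int((pair_sum == 0).sum()),
        int((pair_sum == 1).sum()),
        int((pair_sum == 2).sum()),
    )


def fst_records(
    hms: Sequence[HaplotypeMatrix], pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Per-site FST records for one population pair across chromosomes.

    Columns: chrom, pos, fst, pooled_freq (derived, over both populations).
    """
    frames = []
    for hm in hms:
        cols_a, cols_b = hm.pop_indices(pop_a), hm.pop_indices(pop_b)
        pooled = hm.alleles[:, np.concatenate([cols_a, cols_b])].mean(axis=1)
        fst = _wc_fst_sites(hm.alleles[:, cols_a], hm.alleles[:, cols_b])
        frames.append(
            pd.DataFrame(
                {"chrom": hm.chrom, "pos": hm.positions, "fst": fst, "pooled_freq": pooled}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _wc_fst_sites(hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
    """Vectorized W&C FST over all sites; same estimator as `wc_fst_site`."""
    r = 2
    n = np.array([hap_a.shape[1] // 2, hap_b.shape[1] // 2], dtype=float)
    p = np.stack([hap_a.mean(axis=1), hap_b.mean(axis=1)])
    het = np.stack(
        [
            (hap_a[:, 0::2] != hap_a[:, 1::2]).mean(axis=1),
            (hap_b[:, 0::2] != hap_b[:, 1::2]).mean(axis=1),
        ]
    )
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * het).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    with np.errstate(invalid="ignore"):
        out = np.where(denom == 0.0, np.nan, a / denom)
    return out


def nearest_rank_upper(values: np.ndarray, quantile: float) -> float:
    """Nearest-rank upper quantile: the k-th largest value, k = ceil(quantile*n)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n == 0:
        raise ValueError("empty value set")
    k = max(1, math.ceil(quantile * n))
    return float(values[n - k])


def binned_fst_thresholds(
    records: pd.DataFrame,
    bin_width: float = 0.05,
    quantile: float = 0.05,
    min_bin_size: int = 20,
) -> tuple[dict[int, float], pd.DataFrame]:
    """Flag the top-tail FST records within pooled-allele-frequency bins.

    Bins are [0, w), [w, 2w), ... on ``pooled_freq``; bins with fewer than
    ``min_bin_size`` non-NA records are merged with the frequency-adjacent
    bin holding fewer records.  Within each (merged) bin the threshold is the
    nearest-rank upper ``quantile`` of fst and a record passes iff
    fst >= threshold.  NA fst never passes.

    Returns (bin id -> threshold, records with bin_id / bin_threshold /
    passes_threshold columns added).
    """
    if len(records) == 0:
        raise ValueError("no FST records")
    rec = records.copy()
    n_bins = int(math.ceil(1.0 / bin_width))
    raw_bin = np.clip(
        (rec["pooled_freq"].to_numpy() / bin_width).astype(np.int64), 0, n_bins - 1
    )
    valid = ~rec["fst"].isna().to_numpy()
    if not valid.any():
        raise ValueError("all FST values are NA")
    from .ehh import _merge_small_bins

    present = np.unique(raw_bin[valid])
    merged_valid = _merge_small_bins(raw_bin[valid], present, min_bin_size)
    bin_id = np.full(len(rec), -1, dtype=np.int64)
    bin_id[valid] = merged_valid
    thresholds: dict[int, float] = {}
    thr_col = np.full(len(rec), np.nan)
    passes = np.zeros(len(rec), dtype=bool)
    fst = rec["fst"].to_numpy()
    for b in np.unique(merged_valid):
        sel = bin_id == b
        thr = nearest_rank_upper(fst[sel], quantile)
        thresholds[int(b)] = thr
        thr_col[sel] = thr
        passes[sel] = fst[sel] >= thr
    rec["bin_id"] = bin_id
    rec["bin_threshold"] = thr_col
    rec["passes_threshold"] = passes
    return thresholds, rec
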