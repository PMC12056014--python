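"""Extended haplotype homozygosity statistics: EHH, iHH, iHS and xpEHH.

EHH at distance d from a core SNP is the probability that two randomly chosen
haplotypes carrying the core allele are identical over the whole interval from
the core out to d.  iHH integrates the EHH decay curve (trapezoidal, physical
bp) until it first drops below a cutoff.  The unstandardized iHS of a site is
ln(iHH_ancestral / iHH_derived): unusually long haplotypes around the derived
allele (an incomplete sweep) give large negative values.  xpEHH compares the
pooled iHH of two populations, ln(iHH_A / iHH_B), both integrals sharing the
boundary where the EHH of the two populations pooled together first falls
below the cutoff; sweeps at/near fixation in A give large positive values.

Scores are standardized genome-wide: iHS within equal-width derived-allele
frequency bins (extreme haplotype lengths are frequency dependent), xpEHH in
one global bin.  Defaults (cutoff 0.05, max extension 1 Mb, max gap 200 kb,
100 frequency bins) follow common scan practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hapio import HaplotypeMatrix

__all__ = [
    "EhhParams",
    "EhhCurve",
    "ScoreTrack",
    "ehh_step",
    "ehh_decay_curve",
    "integrate_ihh",
    "ihs_unstandardized",
    "xpehh_unstandardized",
    "standardize",
    "ihs_track",
    "xpehh_track",
]


@dataclass(frozen=True)
class EhhParams:
    """Tuning knobs of the EHH integration, with scan-practice defaults."""

    cutoff: float = 0.05
    max_extension_bp: int = 1_000_000
    max_gap_bp: int = 200_000
    n_bins: int = 100
    min_bin_size: int = 20


@dataclass
class EhhCurve:
    """EHH decay away from a core site, in one direction."""

    core_site: int
    core_allele: str  # 'ancestral' | 'derived' | 'pooled'
    points: list[tuple[float, float]]  # (distance_bp, ehh), first is (0, 1.0)
    truncated: str | None = None  # None, or 'chrom_end' | 'max_extension' | 'gap'


@dataclass
class ScoreTrack:
    """Per-site standardized scores for one statistic over one genome."""

    statistic: str  # 'iHS' | 'xpEHH'
    pops: tuple[str, ...]
    chrom: np.ndarray
    pos: np.ndarray
    freq: np.ndarray  # derived-allele frequency (target pop for iHS, pooled for xpEHH)
    unstd: np.ndarray
    std: np.ndarray
    na_reason: np.ndarray = field(default=None)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)


def _ehh_from_groups(group_ids: np.ndarray) -> float:
    """Sum_g C(k_g,2) / C(n,2) from current group labels."""
    n = group_ids.size
    counts = np.bincount(group_ids)
    num = (counts * (counts - 1)).sum()
    return float(num) / (n * (n - 1))


def ehh_step(hm: HaplotypeMatrix, carriers: np.ndarray, interval: tuple[int, int]) -> float:
    """EHH of ``carriers`` over the inclusive site-index ``interval``.

    Probability that two distinct carriers are identical over the interval:
    sum over distinct haplotype strings g of C(k_g, 2), divided by C(n, 2).
    """
    carriers = np.asarray(carriers)
    if carriers.size < 2:
        raise ValueError("EHH needs at least 2 carrier haplotypes")
    lo, hi = interval
    block = hm.alleles[lo : hi + 1, carriers]
    _, inv = np.unique(block, axis=1, return_inverse=True)
    return _ehh_from_groups(inv)


def _walk(
    hm: HaplotypeMatrix,
    carrier_sets: Sequence[np.ndarray],
    core: int,
    direction: int,
    params: EhhParams,
    stop_on: int = 0,
) -> tuple[list[list[tuple[float, float]]], str | None]:
    """Extend from the core in one direction, tracking EHH of several carrier sets.

    Stops (inclusively) at the first site where the EHH of
    ``carrier_sets[stop_on]`` falls below ``params.cutoff``; returns the decay
    points of every set plus a truncation reason when the cutoff was never
    reached before a boundary (chromosome end, max extension, oversized gap).
    """
    positions = hm.positions
    n_sites = hm.n_sites
    # identity strings run from the core site outward: seed the groups with the
    # core alleles (a no-op for single-core-allele carrier sets as in iHS)
    core_row = hm.alleles[core]
    groups = [core_row[c].astype(np.int64) for c in carrier_sets]
    points: list[list[tuple[float, float]]] = [[(0.0, 1.0)] for _ in carrier_sets]
    core_pos = positions[core]
    prev_pos = core_pos
    j = core
    while True:
        j += direction
        if j < 0 or j >= n_sites:
            return points, "chrom_end"
        pos = positions[j]
        dist = abs(int(pos) - int(core_pos))
        if dist > params.max_extension_bp:
            return points, "max_extension"
        if abs(int(pos) - int(prev_pos)) > params.max_gap_bp:
            return points, "gap"
        prev_pos = pos
        row = hm.alleles[j]
        stop_val = None
        for s, (cset, g) in enumerate(zip(carrier_sets, groups)):
            n = cset.size
            key = g * 2 + row[cset]
            counts = np.bincount(key)
            nz = counts > 0
            groups[s] = (np.cumsum(nz) - 1)[key]  # compressed group ids
            e = float((counts * (counts - 1)).sum()) / (n * (n - 1))
            points[s].append((float(dist), e))
            if s == stop_on:
                stop_val = e
        if stop_val < params.cutoff:
            return points, None


def ehh_decay_curve(
    hm: HaplotypeMatrix,
    carriers: np.ndarray,
    core: int,
    direction: int,
    params: EhhParams = EhhParams(),
    core_allele: str = "pooled",
) -> EhhCurve:
    """EHH decay curve for one carrier set in one direction (+1 right, -1 left)."""
    carriers = np.asarray(carriers)
    if carriers.size < 2:
        raise ValueError("EHH needs at least 2 carrier haplotypes")
    pts, trunc = _walk(hm, [carriers], core, direction, params)
    return EhhCurve(core_site=core, core_allele=core_allele, points=pts[0], truncated=trunc)


def integrate_ihh(curve: EhhCurve, cutoff: float = 0.05) -> float:
    """Trapezoidal area (bp·EHH) under one decay curve.

    Accumulates outward from distance 0 and stops at the first point whose EHH
    is below ``cutoff``, including the final trapezoid into that point.  EHH is
    integrated above zero (no baseline subtraction).
    """
    pts = curve.points
    area = 0.0
    for (d0, e0), (d1, e1) in zip(pts, pts[1:]):
        area += 0.5 * (e0 + e1) * (d1 - d0)
        if e1 < cutoff:
            break
    return area


def _ihh_two_sided(
    hm: HaplotypeMatrix,
    carriers: np.ndarray,
    core: int,
    params: EhhParams,
    allele: str,
) -> tuple[float, str | None]:
    total = 0.0
    for direction in (-1, +1):
        pts, trunc = _walk(hm, [carriers], core, direction, params)
        if trunc is not None:
            return math.nan, trunc
        curve = EhhCurve(core, allele, pts[0])
        total += integrate_ihh(curve, params.cutoff)
    return total, None


def ihs_unstandardized(
    hm: HaplotypeMatrix,
    pop: str,
    site: int,
    params: EhhParams = EhhParams(),
) -> tuple[float, str | None]:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at one site.

    Returns ``(value, None)`` or ``(nan, reason)`` where reason is one of
    ``few_carriers``, ``chrom_end``, ``max_extension``, ``gap``, ``zero_ihh``.
    """
    cols = hm.pop_indices(pop)
    row = hm.alleles[site, cols]
    derived = cols[row == 1]
    ancestral = cols[row == 0]
    if derived.size < 2 or ancestral.size < 2:
        return math.nan, "few_carriers"
    ihh_a, trunc = _ihh_two_sided(hm, ancestral, site, params, "ancestral")
    if trunc:
        return math.nan, trunc
    ihh_d, trunc = _ihh_two_sided(hm, derived, site, params, "derived")
    if trunc:
        return math.nan, trunc
    if ihh_a == 0.0 or ihh_d == 0.0:
        return math.nan, "zero_ihh"
    # difference of logs keeps the polarity-swap antisymmetry exact
    return math.log(ihh_a) - math.log(ihh_d), None


def xpehh_unstandardized(
    hm: HaplotypeMatrix,
    pop_a: str,
    pop_b: str,
    site: int,
    params: EhhParams = EhhParams(),
) -> tuple[float, str | None]:
    """Unstandardized xpEHH = ln(iHH_A / iHH_B) at one site.

    Each population's iHH pools both core alleles over all of its haplotypes;
    both integrals stop at the shared boundary where the EHH of the two
    populations pooled together first drops below the cutoff.
    """
    cols_a = hm.pop_indices(pop_a)
    cols_b = hm.pop_indices(pop_b)
    if cols_a.size < 2 or cols_b.size < 2:
        return math.nan, "few_carriers"
    pooled = np.concatenate([cols_a, cols_b])
    ihh = [0.0, 0.0]
    for direction in (-1, +1):
        pts, trunc = _walk(hm, [pooled, cols_a, cols_b], site, direction, params, stop_on=0)
        if trunc is not None:
            return math.nan, trunc
        # integrate A and B over the sites included by the pooled stop rule
        for k in (1, 2):
            curve = EhhCurve(site, "pooled", pts[k])
            ihh[k - 1] += _integrate_all(curve)
    if ihh[0] == 0.0 or ihh[1] == 0.0:
        return math.nan, "zero_ihh"
    # difference of logs keeps xpEHH(A,B) == -xpEHH(B,A) exact
    return math.log(ihh[0]) - math.log(ihh[1]), None


def _integrate_all(curve: EhhCurve) -> float:
    """Trapezoidal area over every recorded point (boundary set by the caller)."""
    pts = curve.points
    area = 0.0
    for (d0, e0), (d1, e1) in zip(pts, pts[1:]):
        area += 0.5 * (e0 + e1) * (d1 - d0)
    return area


# ---------------------------------------------------------------------------
# standardization


def _merge_small_bins(bin_of: np.ndarray, order: np.ndarray, min_size: int) -> np.ndarray:
    """Merge frequency-adjacent bins until each has >= min_size members.

    ``bin_of`` assigns each element to a bin id; ``order`` lists bin ids in
    frequency order.  An undersized bin is merged with the adjacent bin that
    currently holds fewer members (ties toward the lower-frequency side).
    Returns a relabeled assignment.
    """
    groups: list[list[int]] = [[b] for b in order]
    counts = {b: int((bin_of == b).sum()) for b in order}

    def gcount(g: list[int]) -> int:
        return sum(counts[b] for b in g)

    changed = True
    while changed and len(groups) > 1:
        changed = False
        for gi, g in enumerate(groups):
            if gcount(g) < min_size:
                if gi == 0:
                    tgt = 1
                elif gi == len(groups) - 1:
                    tgt = gi - 1
                else:
                    tgt = gi - 1 if gcount(groups[gi - 1]) <= gcount(groups[gi + 1]) else gi + 1
                groups[min(gi, tgt)] = groups[min(gi, tgt)] + groups[max(gi, tgt)]
                del groups[max(gi, tgt)]
                changed = True
                break
    merged = np.empty_like(bin_of)
    for new_id, g in enumerate(groups):
        merged[np.isin(bin_of, g)] = new_id
    return merged


def standardize(
    unstd: np.ndarray,
    freq: np.ndarray,
    n_bins: int = 100,
    mode: str = "freq_bins",
    min_bin_size: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize raw scores to z-scores, per derived-frequency bin or globally.

    ``freq_bins`` (iHS): sites binned by derived-allele frequency into
    ``n_bins`` equal-width bins on [0, 1]; undersized bins (< ``min_bin_size``
    non-NA scores) are merged with their frequency-nearest neighbour; each
    score becomes (x - bin mean) / bin sample SD.  ``global`` (xpEHH): one bin.
    NaN scores propagate.  Returns (std, merged-bin id per site; -1 for NaN).
    """
    unstd = np.asarray(unstd, dtype=float)
    freq = np.asarray(freq, dtype=float)
    valid = ~np.isnan(unstd)
    if not valid.any():
        raise ValueError("all scores are NA; nothing to standardize")
    std = np.full_like(unstd, np.nan)
    bin_id = np.full(unstd.shape, -1, dtype=np.int64)
    if mode == "global":
        raw_bin = np.zeros(unstd.shape, dtype=np.int64)
    elif mode == "freq_bins":
        raw_bin = np.clip((freq * n_bins).astype(np.int64), 0, n_bins - 1)
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    present = np.unique(raw_bin[valid])
    merged_valid = _merge_small_bins(raw_bin[valid], present, min_bin_size)
    mv_full = np.full(unstd.shape, -1, dtype=np.int64)
    mv_full[valid] = merged_valid
    for b in np.unique(merged_valid):
        sel = mv_full == b
        x = unstd[sel]
        if x.size < 2:
            continue  # leave as NaN: cannot estimate a spread
        sd = x.std(ddof=1)
        if sd == 0.0:
            continue
        std[sel] = (x - x.mean()) / sd
        bin_id[sel] = b
    return std, bin_id


# ---------------------------------------------------------------------------
# track builders (genome-wide across chromosomes)


def ihs_track(
    hms: Sequence[HaplotypeMatrix],
    pop: str,
    params: EhhParams = EhhParams(),
) -> ScoreTrack:
    """Compute and standardize iHS for every site of every chromosome, one population."""
    chroms, poss, freqs, raws, reasons = [], [], [], [], []
    for hm in hms:
        f = hm.derived_freq(pop)
        for s in range(hm.n_sites):
            val, reason = ihs_unstandardized(hm, pop, s, params)
            chroms.append(hm.chrom)
            poss.append(hm.positions[s])
            freqs.append(f[s])
            raws.append(val)
            reasons.append(reason or "")
    raw = np.array(raws)
    freq = np.array(freqs)
    std, _ = standardize(raw, freq, n_bins=params.n_bins, mode="freq_bins",
                         min_bin_size=params.min_bin_size)
    return ScoreTrack(
        statistic="iHS",
        pops=(pop,),
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        freq=freq,
        unstd=raw,
        std=std,
        na_reason=np.array(reasons, dtype=object),
    )


def xpehh_track(
    hms: Sequence[HaplotypeMatrix],
    pop_a: str,
    pop_b: str,
    params: EhhParams = EhhParams(),
) -> ScoreTrack:
    """Compute and standardize xpEHH(A, B) for every site; one global bin."""
    chroms, poss, freqs, raws, reasons = [], [], [], [], []
    for hm in hms:
        cols = np.concatenate([hm.pop_indices(pop_a), hm.pop_indices(pop_b)])
        pooled_freq = hm.alleles[:, cols].mean(axis=1)
        for s in range(hm.n_sites):
            val, reason = xpehh_unstandardized(hm, pop_a, pop_b, s, params)
            chroms.append(hm.chrom)
            poss.append(hm.positions[s])
            freqs.append(pooled_freq[s])
            raws.append(val)
            reasons.append(reason or "")
    raw = np.array(raws)
    freq = np.array(freqs)
    std, _ = standardize(raw, freq, mode="global", min_bin_size=params.min_bin_size)
    return ScoreTrack(
        statistic="xpEHH",
        pops=(pop_a, pop_b),
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        freq=freq,
        unstd=raw,
        std=std,
        na_reason=np.array(reasons, dtype=object),
    )
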