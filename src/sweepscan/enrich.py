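"""Gene-set enrichment by random resampling, and Fisher 2x2 lineage comparisons.

The null model: draw the same number of genes as the focal set, uniformly
without replacement from the gene universe, and record how many carry the
positively-selected flag; repeat (100,000 times at full scale) to build the
null distribution of the count.  The observed count is judged against the 5%
tails with add-one empirical p-values, p = (1 + exceedances) / (R + 1), which
never return zero.  Replicates use seed-sequence substreams indexed by
replicate, so chunked or partial runs reproduce bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "EnrichmentResult",
    "resample_null",
    "empirical_tail_p",
    "enrichment_test",
    "fisher_2x2",
]


@dataclass
class EnrichmentResult:
    """Outcome of the resampling enrichment test for one focal gene set."""

    observed: int
    reps: int
    seed: int
    p_upper: float
    p_lower: float
    significant_high: bool
    significant_low: bool
    alpha: float
    null_counts: np.ndarray = field(repr=False, default=None)

    def to_json(self, path: str | Path | None = None) -> str:
        hist = np.bincount(self.null_counts) if self.null_counts is not None else []
        payload = {
            "observed": self.observed,
            "reps": self.reps,
            "seed": self.seed,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "significant_high": self.significant_high,
            "significant_low": self.significant_low,
            "alpha": self.alpha,
            "null_histogram": [int(c) for c in hist],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def resample_null(
    psg_flags: np.ndarray, k: int, reps: int, seed: int
) -> np.ndarray:
    """Null counts: per replicate, draw k genes without replacement, count flagged.

    ``psg_flags`` is a boolean array over the gene universe.  Each replicate r
    draws from its own substream (SeedSequence(seed).spawn), so results do not
    depend on chunking and are reproducible bit-for-bit under one seed.
    """
    flags = np.asarray(psg_flags, dtype=bool)
    n = flags.size
    if k > n:
        raise ValueError(f"draw size {k} exceeds universe size {n}")
    if reps < 1:
        raise ValueError("need at least one replicate")
    children = np.random.SeedSequence(seed).spawn(reps)
    counts = np.empty(reps, dtype=np.int64)
    for r, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        idx = rng.choice(n, size=k, replace=False)
        counts[r] = int(flags[idx].sum())
    return counts


def empirical_tail_p(
    null_counts: np.ndarray, observed: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Add-one empirical tail probabilities of the observed count.

    p_upper = (1 + #{null >= observed}) / (R + 1), p_lower with <=.  Each tail
    is an independent one-sided test at ``alpha`` (callers may Bonferroni the
    two tails to alpha/2 if a single two-sided decision is wanted).
    """
    null_counts = np.asarray(null_counts)
    r = null_counts.size
    if r < 1:
        raise ValueError("need at least one replicate")
    p_upper = (1 + int((null_counts >= observed).sum())) / (r + 1)
    p_lower = (1 + int((null_counts <= observed).sum())) / (r + 1)
    return p_upper, p_lower


def enrichment_test(
    universe: pd.DataFrame,
    focal_ids,
    reps: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Full resampling test of a focal gene set against a flagged gene universe.

    ``universe`` has columns gene_id and psg_flag; ``focal_ids`` is an iterable
    of gene ids, all of which must be present in the universe.
    """
    ids = universe["gene_id"].to_numpy()
    flags = universe["psg_flag"].to_numpy(dtype=bool)
    focal = set(focal_ids)
    missing = focal - set(ids)
    if missing:
        raise ValueError(f"focal genes not in universe: {sorted(missing)[:5]}")
    observed = int(flags[np.isin(ids, list(focal))].sum())
    null = resample_null(flags, k=len(focal), reps=reps, seed=seed)
    p_upper, p_lower = empirical_tail_p(null, observed, alpha)
    return EnrichmentResult(
        observed=observed,
        reps=reps,
        seed=seed,
        p_upper=p_upper,
        p_lower=p_lower,
        significant_high=p_upper <= alpha,
        significant_low=p_lower <= alpha,
        alpha=alpha,
        null_counts=null,
    )


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Exact conditional test: sums hypergeometric probabilities of tables (with
    the observed margins) no more probable than the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)
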