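"""Branch-site likelihood-ratio test post-processing.

Consumes per-gene log-likelihood pairs from branch-site codon-model fits (the
modified Model A with free foreground omega vs the null with foreground omega
fixed at 1) and produces the LRT statistic 2(lnL_alt - lnL_null), its p-value
under the boundary mixture convention p = 0.5 * Pr(chi2_1 >= LRT), and a
Bonferroni-adjusted p.  Running the codon-model optimizer itself is out of
scope; a convenience reader extracts lnL values from codeml main output.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import chi2

__all__ = [
    "LrtRecord",
    "lrt_statistic",
    "halved_chi2_p",
    "bonferroni",
    "lrt_table",
    "read_lnl_table",
    "parse_codeml_lnl",
]


@dataclass
class LrtRecord:
    """One gene's branch-site test on one lineage."""

    gene: str
    branch: str
    lnl_alt: float
    lnl_null: float
    lrt: float
    p_half: float
    p_bonf: float


def lrt_statistic(lnl_alt: float, lnl_null: float) -> float:
    """2(lnL_alt - lnL_null), clamped at 0 (with a warning) for optimizer noise."""
    if not (math.isfinite(lnl_alt) and math.isfinite(lnl_null)):
        raise ValueError("log-likelihoods must be finite")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < 0.0:
        warnings.warn(
            f"negative LRT statistic {stat:.4g} clamped to 0 "
            "(alternative should nest the null)"
        )
        stat = 0.0
    return stat


def halved_chi2_p(lrt: float) -> float:
    """p = 0.5 * Pr(chi2_1 >= lrt): the ½χ²₀ + ½χ²₁ mixture for boundary tests."""
    if lrt < 0:
        raise ValueError("LRT statistic must be non-negative")
    return 0.5 * float(chi2.sf(lrt, df=1))


def bonferroni(p: float, m: int) -> float:
    """min(1, m*p) for a family of m tests."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p)


def lrt_table(records: pd.DataFrame, family_size: int | None = None) -> pd.DataFrame:
    """Compute lrt, p_half, p_bonf for a table of (gene, branch, lnl_alt, lnl_null).

    ``family_size`` defaults to the number of rows (genes successfully tested
    on the branch); pass the true family size explicitly when rows are a
    subset of the tested genes.
    """
    m = family_size if family_size is not None else len(records)
    out = records.copy()
    out["lrt"] = [lrt_statistic(a, b) for a, b in zip(out["lnl_alt"], out["lnl_null"])]
    out["p_half"] = [halved_chi2_p(x) for x in out["lrt"]]
    out["p_bonf"] = [bonferroni(p, m) for p in out["p_half"]]
    return out


def read_lnl_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns gene, branch, lnl_alt, lnl_null (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "branch", "lnl_alt", "lnl_null"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


_LNL_RE = re.compile(r"lnL\(ntime:.*?\):?\s*(-?\d+\.?\d*)")


def parse_codeml_lnl(path: str | Path) -> float:
    """Extract the lnL value from a codeml main-output ('mlc') file.

    Anchored to the 'lnL(ntime:' line; raises when no such line is found, in
    which case values should be supplied via the manual TSV instead.
    """
    text = Path(path).read_text()
    m = _LNL_RE.search(text)
    if not m:
        raise ValueError(f"{path}: no 'lnL(ntime:' line found")
    return float(m.group(1))
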