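"""End-to-end orchestration: haplotypes → scores → FST → calls → enrichment.

`run_scan` composes the stages with one config and seed: per-population iHS
tracks, xpEHH for every population pair, pairwise binned-FST thresholds, the
composite candidate rule, exon mapping, per-statistic and union gene calls,
and the focal-set resampling enrichment test.  A run manifest records the
config, seed, inputs and versions so identical inputs reproduce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calls import (
    call_candidates,
    map_and_classify,
    region_proportions,
    top_window_cut,
    window_extreme_counts,
)
from .ehh import EhhParams, ScoreTrack, ihs_track, xpehh_track
from .enrich import EnrichmentResult, enrichment_test
from .fst import binned_fst_thresholds, fst_records
from .hapio import FocalGeneSet, GeneAnnotation, HaplotypeMatrix

__all__ = ["ScanConfig", "ScanResult", "run_scan"]


@dataclass
class ScanConfig:
    """All thresholds of the composite scan (defaults are the published rule)."""

    score_cut: float = 2.0
    window_size: int = 51
    top_frac: float = 0.01
    fst_quantile: float = 0.05
    fst_bin_width: float = 0.05
    maf_min: float = 0.05
    alpha: float = 0.05
    reps: int = 100_000
    seed: int = 0
    ehh: EhhParams = field(default_factory=EhhParams)


@dataclass
class ScanResult:
    tracks: list  # ScoreTrack per statistic/population(-pair)
    fst: dict  # (popA, popB) -> flagged record DataFrame
    window_thresholds: dict  # track key -> top-1% integer cut
    raw_candidates: pd.DataFrame  # composite-rule candidates before exon mapping
    candidates: pd.DataFrame  # exon-mapped candidate variants
    gene_calls: pd.DataFrame  # gene_id, called_ihs, called_xpehh, called_any, focal
    region_props: dict | None
    enrichment: EnrichmentResult | None
    manifest: dict


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _maf_filter(panels, pops, maf_min):
    out = []
    for hm in panels:
        maf_ok = np.ones(hm.n_sites, dtype=bool)
        for p in pops:
            f = hm.derived_freq(p)
            maf_ok &= np.minimum(f, 1 - f) >= maf_min
        out.append(hm.subset_sites(maf_ok))
    return out


def _track_key(track: ScoreTrack) -> str:
    return f"{track.statistic}:{'/'.join(track.pops)}"


def run_scan(
    panels: list[HaplotypeMatrix],
    annotations: dict[str, GeneAnnotation],
    focal: FocalGeneSet | None,
    config: ScanConfig = ScanConfig(),
    outdir: str | Path | None = None,
    do_enrichment: bool = True,
) -> ScanResult:
    """Run the whole composite scan on an in-memory panel.

    A site participates only if its MAF passes ``maf_min`` in every analyzed
    population (the conjunctive scope, recorded in the manifest).  The FST
    gate for an iHS candidate is passing the binned threshold in at least one
    pair involving the target population; xpEHH uses its own pair.
    """
    t0 = time.time()
    pops = panels[0].populations
    panels = _maf_filter(panels, pops, config.maf_min)
    if any(hm.n_sites == 0 for hm in panels):
        raise ValueError("a chromosome lost all sites to the MAF filter")
    _log(f"[scan] {len(panels)} chromosome(s), populations {pops}, "
         f"{sum(h.n_sites for h in panels)} sites after MAF filter")

    tracks: list[ScoreTrack] = []
    for p in pops:
        tracks.append(ihs_track(panels, p, config.ehh))
        _log(f"[scan] iHS({p}) done ({time.time() - t0:.1f}s)")
    pairs = list(combinations(pops, 2))
    for a, b in pairs:
        tracks.append(xpehh_track(panels, a, b, config.ehh))
        _log(f"[scan] xpEHH({a},{b}) done ({time.time() - t0:.1f}s)")

    fst_flagged: dict[tuple, pd.DataFrame] = {}
    for a, b in pairs:
        rec = fst_records(panels, a, b)
        _, flagged = binned_fst_thresholds(
            rec, bin_width=config.fst_bin_width, quantile=config.fst_quantile
        )
        fst_flagged[(a, b)] = flagged
    _log(f"[scan] FST thresholds done ({time.time() - t0:.1f}s)")

    window_thresholds: dict[str, int] = {}
    all_cands = []
    for track in tracks:
        wstats = window_extreme_counts(track, config.window_size, config.score_cut)
        wthr = top_window_cut(wstats, config.top_frac)
        window_thresholds[_track_key(track)] = wthr
        if track.statistic == "iHS":
            p = track.pops[0]
            rel = [df for pair, df in fst_flagged.items() if p in pair]
            merged = rel[0][["chrom", "pos"]].copy()
            passes = np.zeros(len(merged), dtype=bool)
            for df in rel:
                passes |= df["passes_threshold"].to_numpy()
            merged["passes_threshold"] = passes
        else:
            merged = fst_flagged[(track.pops[0], track.pops[1])]
        cands = call_candidates(track, wstats, wthr, merged, config.score_cut)
        all_cands.append(cands)
    raw_candidates = (
        pd.concat(all_cands, ignore_index=True)
        if all_cands
        else pd.DataFrame(columns=["chrom", "pos", "statistic", "target_pop", "pops", "score", "fst_pass"])
    )
    mapped = map_and_classify(raw_candidates, annotations)
    _log(f"[scan] {len(raw_candidates)} raw candidates, {len(mapped)} exon-mapped rows "
         f"({time.time() - t0:.1f}s)")

    gene_ids = sorted(annotations)
    by_stat = {
        s: set(mapped.loc[mapped["statistic"] == s, "gene_id"]) for s in ("iHS", "xpEHH")
    }
    union = by_stat["iHS"] | by_stat["xpEHH"]
    gene_calls = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "called_ihs": [g in by_stat["iHS"] for g in gene_ids],
            "called_xpehh": [g in by_stat["xpEHH"] for g in gene_ids],
            "called_any": [g in union for g in gene_ids],
            "focal": [focal is not None and g in focal.gene_ids for g in gene_ids],
        }
    )

    region_props = region_proportions(mapped) if len(mapped) else None

    enr = None
    if do_enrichment and focal is not None and focal.size > 0:
        universe = pd.DataFrame(
            {"gene_id": gene_calls["gene_id"], "psg_flag": gene_calls["called_any"]}
        )
        enr = enrichment_test(
            universe, focal.gene_ids, reps=config.reps, seed=config.seed, alpha=config.alpha
        )
        _log(f"[scan] enrichment: observed={enr.observed} p_upper={enr.p_upper:.4g}")
    elif do_enrichment:
        _log("[scan] enrichment stage skipped: empty focal gene set")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "populations": pops,
        "maf_scope": "conjunctive: site kept iff MAF passes in every analyzed population",
        "ihs_fst_gate": "pass in >= 1 pair involving the target population",
        "n_sites": {hm.chrom: hm.n_sites for hm in panels},
        "window_thresholds": window_thresholds,
        "n_candidates": int(len(raw_candidates)),
        "n_genes_called": int(len(union)),
    }

    result = ScanResult(
        tracks=tracks,
        fst=fst_flagged,
        window_thresholds=window_thresholds,
        raw_candidates=raw_candidates,
        candidates=mapped,
        gene_calls=gene_calls,
        region_props=region_props,
        enrichment=enr,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _config_dict(config: ScanConfig) -> dict:
    d = asdict(config)
    return d


def _write_outputs(result: ScanResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    result.gene_calls.to_csv(outdir / "gene_calls.tsv", sep="\t", index=False)
    for track in result.tracks:
        name = _track_key(track).replace(":", "_").replace("/", "_")
        pd.DataFrame(
            {
                "chrom": track.chrom,
                "pos": track.pos,
                "freq": track.freq,
                "unstd": track.unstd,
                "std": track.std,
                "na_reason": track.na_reason,
            }
        ).to_csv(outdir / f"scores_{name}.tsv", sep="\t", index=False)
    for (a, b), df in result.fst.items():
        df.to_csv(outdir / f"fst_{a}_{b}.tsv", sep="\t", index=False)
    if result.enrichment is not None:
        result.enrichment.to_json(outdir / "enrichment.json")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))


def input_digest(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
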