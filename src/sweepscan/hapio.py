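"""Phased-haplotype data model and I/O for the selection-scan pipeline.

The central container is :class:`HaplotypeMatrix`: a (sites x haplotypes)
binary matrix of ancestral/derived alleles for one chromosome, carrying
per-haplotype population labels and per-site metadata.  Alleles are polarized
on read: 0 means ancestral, 1 means derived.  The ancestral state is taken
from the VCF ``AA`` INFO tag when present; otherwise the reference allele is
assumed ancestral and the site is flagged (``ancestral_source = 'ref_fallback'``).

Coordinates are 1-based inclusive everywhere inside the package; BED input
(0-based half-open) is converted on read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "RegionClass",
    "HaplotypeMatrix",
    "GeneAnnotation",
    "FocalGeneSet",
    "read_pop_map",
    "read_phased_vcf",
    "read_gene_annotation",
    "read_focal_gene_set",
    "site_allele_freq",
    "write_site_metadata",
]


class RegionClass(str, Enum):
    """Exonic region classes used to classify candidate variants."""

    FIVE_UTR = "FIVE_UTR"
    THREE_UTR = "THREE_UTR"
    CDS = "CDS"
    NONCODING_EXON = "NONCODING_EXON"


#: Precedence when transcripts disagree about the class of a position.
REGION_PRECEDENCE = (
    RegionClass.CDS,
    RegionClass.FIVE_UTR,
    RegionClass.THREE_UTR,
    RegionClass.NONCODING_EXON,
)


@dataclass
class HaplotypeMatrix:
    """Phased biallelic alleles for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    positions : ndarray of int64, shape (n_sites,)
        1-based physical coordinates, strictly increasing.
    alleles : ndarray of int8, shape (n_sites, n_haplotypes)
        0 = ancestral, 1 = derived.
    hap_pop : ndarray of str, shape (n_haplotypes,)
        Population label of each haplotype (two consecutive haplotypes per
        diploid sample).
    site_meta : DataFrame, optional
        Per-site ``ref``, ``alt`` and ``ancestral_source`` columns.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    hap_pop: np.ndarray
    site_meta: pd.DataFrame | None = None
    sample_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.hap_pop = np.asarray(self.hap_pop)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != self.positions.size:
            raise ValueError("alleles must be (n_sites, n_haplotypes)")
        if self.hap_pop.size != self.alleles.shape[1]:
            raise ValueError("hap_pop length must equal haplotype count")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError(f"positions not strictly increasing on {self.chrom}")
        bad = ~np.isin(self.alleles, (0, 1))
        if bad.any():
            raise ValueError("alleles must be 0 (ancestral) or 1 (derived)")

    # -- basic queries -----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_haplotypes(self) -> int:
        return int(self.alleles.shape[1])

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.hap_pop:
            seen.setdefault(str(p), None)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        """Column indices of the haplotypes belonging to ``pop``."""
        idx = np.flatnonzero(self.hap_pop == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population {pop!r}")
        return idx

    def derived_freq(self, pop: str | None = None) -> np.ndarray:
        """Derived-allele frequency per site, in one population or overall."""
        cols = self.pop_indices(pop) if pop is not None else slice(None)
        sub = self.alleles[:, cols]
        return sub.mean(axis=1)

    def subset_sites(self, mask: np.ndarray) -> "HaplotypeMatrix":
        meta = self.site_meta.loc[np.asarray(mask)].reset_index(drop=True) if self.site_meta is not None else None
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[mask],
            alleles=self.alleles[mask],
            hap_pop=self.hap_pop,
            site_meta=meta,
            sample_names=self.sample_names,
        )


@dataclass
class GeneAnnotation:
    """Exon structure of one gene, as 1-based inclusive intervals."""

    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int, RegionClass]] = field(default_factory=list)

    def add_interval(self, start: int, end: int, region: RegionClass) -> None:
        if end < start:
            raise ValueError(f"interval end < start for gene {self.gene_id}: ({start}, {end})")
        item = (int(start), int(end), region)
        if item not in self.intervals:
            self.intervals.append(item)


@dataclass(frozen=True)
class FocalGeneSet:
    """The focal gene set tested for enrichment (e.g. GWAS hits for a trait)."""

    gene_ids: frozenset

    @property
    def size(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# readers


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→population TSV (no header)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            out[parts[0]] = parts[1]
    return out


_SNP_ALLELES = frozenset("ACGT")


def read_phased_vcf(
    path: str | Path,
    pop_map: Mapping[str, str] | str | Path,
    maf_min: float = 0.05,
    pops: Sequence[str] | None = None,
) -> list[HaplotypeMatrix]:
    """Read phased diploid VCF into one :class:`HaplotypeMatrix` per chromosome.

    Only biallelic SNPs are kept (indels and multiallelic records dropped).
    A site is retained when its minor allele frequency is >= ``maf_min``
    (inclusive) in *every* population named in ``pops`` (default: all
    populations in the map) — the conjunctive filter scope.  Sites with any
    missing allele in a participating population are dropped.

    Alleles are polarized to ancestral/derived via the ``AA`` INFO tag when it
    matches REF or ALT; otherwise REF is treated as ancestral and the site is
    flagged ``ref_fallback`` in ``site_meta``.
    """
    if not isinstance(pop_map, Mapping):
        pop_map = read_pop_map(pop_map)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pop_map]
    if missing:
        raise ValueError(f"samples absent from population map: {missing[:5]}")
    sample_pop = np.array([pop_map[s] for s in samples])
    hap_pop = np.repeat(sample_pop, 2)
    participating = list(pops) if pops is not None else sorted(set(sample_pop))
    part_cols = {p: np.flatnonzero(hap_pop == p) for p in participating}
    for p, cols in part_cols.items():
        if cols.size == 0:
            raise ValueError(f"population {p!r} has no samples in the VCF")

    per_chrom: dict[str, dict[str, list]] = {}
    for v in vcf:
        ref, alts = v.REF, v.ALT
        if len(alts) != 1:
            continue
        alt = alts[0]
        if ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
            continue  # indel or symbolic allele
        gts = v.genotypes  # [[a0, a1, phased], ...]
        hap = np.empty(2 * len(gts), dtype=np.int16)
        for i, g in enumerate(gts):
            if len(g) == 2:  # haploid call
                raise ValueError(f"haploid genotype at {v.CHROM}:{v.POS} sample {samples[i]}")
            if not g[-1] and g[0] != -1:
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS} sample {samples[i]}")
            hap[2 * i] = g[0]
            hap[2 * i + 1] = g[1]
        # sites with missing alleles are dropped (phase-3-like panels are
        # essentially complete; keeps the matrix strictly 0/1)
        if (hap < 0).any():
            continue
        aa = v.INFO.get("AA")
        source = "ref_fallback"
        ancestral = ref
        if aa is not None:
            aa_clean = str(aa).split("|")[0].strip().upper()
            if aa_clean == ref:
                ancestral, source = ref, "AA"
            elif aa_clean == alt:
                ancestral, source = alt, "AA"
        derived = (hap == 1) if ancestral == ref else (hap == 0)
        derived = derived.astype(np.int8)
        keep = True
        for cols in part_cols.values():
            f = derived[cols].mean()
            if min(f, 1.0 - f) < maf_min:
                keep = False
                break
        if not keep:
            continue
        store = per_chrom.setdefault(
            v.CHROM, {"pos": [], "alle": [], "ref": [], "alt": [], "src": []}
        )
        store["pos"].append(v.POS)
        store["alle"].append(derived)
        store["ref"].append(ref)
        store["alt"].append(alt)
        store["src"].append(source)

    if not per_chrom:
        raise ValueError(f"no sites left after biallelic/MAF filtering of {path}")

    out = []
    for chrom, store in per_chrom.items():
        meta = pd.DataFrame(
            {"ref": store["ref"], "alt": store["alt"], "ancestral_source": store["src"]}
        )
        out.append(
            HaplotypeMatrix(
                chrom=chrom,
                positions=np.array(store["pos"], dtype=np.int64),
                alleles=np.array(store["alle"], dtype=np.int8),
                hap_pop=hap_pop,
                site_meta=meta,
                sample_names=samples,
            )
        )
    return out


_GFF_TYPE_MAP = {
    "five_prime_UTR": RegionClass.FIVE_UTR,
    "three_prime_UTR": RegionClass.THREE_UTR,
    "CDS": RegionClass.CDS,
}

_BED_SUFFIXES = {
    "CDS": RegionClass.CDS,
    "FIVE_UTR": RegionClass.FIVE_UTR,
    "5UTR": RegionClass.FIVE_UTR,
    "THREE_UTR": RegionClass.THREE_UTR,
    "3UTR": RegionClass.THREE_UTR,
    "NONCODING_EXON": RegionClass.NONCODING_EXON,
    "NC": RegionClass.NONCODING_EXON,
}


def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for chunk in raw.strip().rstrip(";").split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed GFF3 attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gene_annotation(path: str | Path, format: str = "gff3") -> dict[str, GeneAnnotation]:
    """Read exon annotations from GFF3 or BED into per-gene interval sets.

    GFF3: ``five_prime_UTR``/``three_prime_UTR``/``CDS`` features map directly;
    ``exon`` features are kept as NONCODING_EXON only for genes that carry no
    coding feature (non-coding genes).  Genes are identified by the
    ``gene_id`` attribute, falling back to ``Parent``/``ID``.

    BED: 0-based half-open rows named ``<gene>_<CLASS>`` are converted to
    1-based inclusive; CLASS is one of CDS, FIVE_UTR/5UTR, THREE_UTR/3UTR,
    NONCODING_EXON/NC.
    """
    fmt = format.lower()
    if fmt not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    genes: dict[str, GeneAnnotation] = {}
    pending_exons: list[tuple[str, int, int]] = []

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "bed":
                if len(fields) < 4:
                    raise ValueError(f"{path}:{ln}: BED line needs >= 4 fields")
                chrom, start_s, end_s, name = fields[:4]
                try:
                    start0, end0 = int(start_s), int(end_s)
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
                if end0 < start0:
                    raise ValueError(f"{path}:{ln}: end < start")
                region = None
                gene_id = name
                for suffix, rc in _BED_SUFFIXES.items():
                    if name.upper().endswith("_" + suffix):
                        region = rc
                        gene_id = name[: -(len(suffix) + 1)]
                        break
                if region is None:
                    raise ValueError(f"{path}:{ln}: BED name {name!r} lacks a region-class suffix")
                g = genes.setdefault(gene_id, GeneAnnotation(gene_id, gene_id, chrom, "+"))
                g.add_interval(start0 + 1, end0, region)
                continue
            # GFF3
            if len(fields) != 9:
                raise ValueError(f"{path}:{ln}: GFF3 line needs 9 fields, got {len(fields)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{ln}: end < start")
            try:
                attrs = _gff_attributes(attrs_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
            gene_id = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"{path}:{ln}: feature without gene_id/Parent/ID")
            symbol = attrs.get("gene_name", gene_id)
            if ftype == "gene":
                genes.setdefault(gene_id, GeneAnnotation(gene_id, symbol, chrom, strand))
                continue
            if ftype in _GFF_TYPE_MAP:
                g = genes.setdefault(gene_id, GeneAnnotation(gene_id, symbol, chrom, strand))
                g.add_interval(start, end, _GFF_TYPE_MAP[ftype])
            elif ftype == "exon":
                genes.setdefault(gene_id, GeneAnnotation(gene_id, symbol, chrom, strand))
                pending_exons.append((gene_id, start, end))

    # exons of genes without coding features are non-coding exons
    for gene_id, start, end in pending_exons:
        g = genes[gene_id]
        if not g.intervals:
            g.add_interval(start, end, RegionClass.NONCODING_EXON)
    # drop genes that ended up with no exon intervals at all
    return {gid: g for gid, g in genes.items() if g.intervals}


def read_focal_gene_set(
    path: str | Path, universe: Iterable[str] | None = None
) -> FocalGeneSet:
    """Read a one-column gene-id TSV (header optional, lines starting '#' skipped)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower() in ("gene_id", "gene"):
                continue
            ids.append(line.split("\t")[0])
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate gene ids in focal set {path}")
    if universe is not None:
        missing = set(ids) - set(universe)
        if missing:
            raise ValueError(f"focal genes absent from the gene universe: {sorted(missing)[:5]}")
    return FocalGeneSet(frozenset(ids))


def site_allele_freq(hm: HaplotypeMatrix, pop: str, site: int) -> float:
    """Derived-allele frequency at one site within one population."""
    cols = hm.pop_indices(pop)
    if not 0 <= site < hm.n_sites:
        raise IndexError(f"site index {site} out of range")
    return float(hm.alleles[site, cols].mean())


def write_site_metadata(hms: Sequence[HaplotypeMatrix], path: str | Path) -> None:
    """Write per-site metadata TSV: chrom, pos, ref, alt, ancestral_source, per-pop freq."""
    pops = hms[0].populations
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "pos", "ref", "alt", "ancestral_source"] + [f"freq_{p}" for p in pops])
        for hm in hms:
            meta = hm.site_meta
            freqs = {p: hm.derived_freq(p) for p in pops}
            for i in range(hm.n_sites):
                ref = meta.iloc[i]["ref"] if meta is not None else "."
                alt = meta.iloc[i]["alt"] if meta is not None else "."
                src = meta.iloc[i]["ancestral_source"] if meta is not None else "."
                w.writerow(
                    [hm.chrom, hm.positions[i], ref, alt, src]
                    + [f"{freqs[p][i]:.6g}" for p in pops]
                )
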