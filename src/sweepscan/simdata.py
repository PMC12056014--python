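"""Seeded synthetic phased-haplotype panels with planted selective sweeps.

The generator emulates the statistical structure the scans assume, without a
full coalescent simulation:

* ancestral allele frequencies from a neutral-like spectrum (density ∝ 1/x,
  truncated), so the MAF spectrum straddles the 0.05 filter;
* per-population frequencies from the Balding–Nichols drift model with
  divergence parameter F (mean-preserving around the ancestral frequency);
* haplotypes as recombinant mosaics of K population founders — crossovers are
  Poisson in physical distance, so linkage (and hence EHH) decays with
  distance — plus private mutations;
* hard sweeps: carriers of the derived core allele are rewritten as copies of
  one template haplotype over an exponentially-distributed surrounding
  segment, producing the long shared haplotypes and clustered extreme scores
  the composite caller targets;
* gene annotations with 5'UTR/CDS/3'UTR structure plus non-coding-exon genes,
  a focal gene set, and a truth table tying sweeps to genes.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hapio import GeneAnnotation, FocalGeneSet, HaplotypeMatrix, RegionClass

__all__ = [
    "SweepSpec",
    "SimConfig",
    "TruthTable",
    "SimResult",
    "balding_nichols_freqs",
    "simulate_neutral_panel",
    "impose_sweep",
    "simulate",
    "write_outputs",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SweepSpec:
    """One planted hard sweep.

    ``core_pos`` may be left None, in which case the simulator places the core
    inside an exon (of a focal gene with probability ``focal_enrichment``).
    ``strength`` in (0, 1] scales the mean shared-segment length per side as a
    fraction of chromosome length; 1.0 means whole-chromosome sharing.
    """

    population: str
    target_freq: float = 0.85
    strength: float = 0.05
    chrom: int = 0
    core_pos: int | None = None


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset (seed determines everything)."""

    seed: int = 0
    populations: dict = field(default_factory=lambda: {"POP1": 50, "POP2": 50})
    n_chroms: int = 2
    n_sites: int = 1000  # per chromosome
    chrom_length_bp: int = 1_000_000
    freq_min: float = 0.05  # ancestral-spectrum truncation
    freq_max: float = 0.95
    divergence_F: float = 0.05
    n_founders: int = 100
    recomb_rate: float = 5e-5  # founder-mosaic crossovers per bp per haplotype
    mut_rate: float = 2e-6  # private-mutation flips per bp per haplotype
    sweeps: list = field(default_factory=list)
    n_genes: int = 40  # per chromosome
    noncoding_gene_frac: float = 0.1
    focal_set_size: int = 20
    focal_enrichment: float = 0.0
    # auto-placed sweeps on one chromosome keep this distance so template
    # copying of one sweep cannot overwrite another's carriers
    min_sweep_spacing_bp: int = 300_000

    def validate(self) -> None:
        if self.n_sites > self.chrom_length_bp:
            raise ValueError("n_sites exceeds chromosome length")
        if not 0 < self.freq_min < self.freq_max < 1:
            raise ValueError("bad ancestral-frequency truncation bounds")
        for sw in self.sweeps:
            if not 0.05 <= sw.target_freq <= 0.99:
                raise ValueError(f"sweep target frequency {sw.target_freq} outside [0.05, 0.99]")
            if not 0 < sw.strength <= 1:
                raise ValueError("sweep strength must be in (0, 1]")
            if sw.population not in self.populations:
                raise ValueError(f"sweep population {sw.population!r} not configured")
            if sw.core_pos is not None and not 1 <= sw.core_pos <= self.chrom_length_bp:
                raise ValueError("sweep core position outside chromosome")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["sweeps"] = [SweepSpec(**s) if isinstance(s, dict) else s for s in d.get("sweeps", [])]
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """What was planted: sweep sites and per-gene focal / sweep flags."""

    sweeps: pd.DataFrame  # chrom, pos, population, target_freq, strength, gene_id, in_focal
    genes: pd.DataFrame  # gene_id, chrom, focal, has_sweep


@dataclass
class SimResult:
    panels: list  # one HaplotypeMatrix per chromosome (all populations)
    annotations: dict  # gene_id -> GeneAnnotation
    focal: FocalGeneSet
    truth: TruthTable
    config: SimConfig


def _ancestral_freqs(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Draw from density ∝ 1/x on [lo, hi] by inverse CDF."""
    u = rng.random(n)
    return lo * (hi / lo) ** u


def balding_nichols_freqs(
    p0: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-population frequencies around ancestral p0 under drift parameter F.

    Beta(p0 (1-F)/F, (1-p0)(1-F)/F): mean p0, variance F p0 (1-p0).
    F = 0 returns p0 unchanged.
    """
    p0 = np.asarray(p0, dtype=float)
    if F == 0.0:
        return p0.copy()
    c = (1.0 - F) / F
    return rng.beta(p0 * c, (1.0 - p0) * c)


def _mosaic_haplotypes(
    founders: np.ndarray,
    positions: np.ndarray,
    n_hap: int,
    length_bp: int,
    recomb_rate: float,
    mut_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Build n_hap recombinant mosaics of the founder haplotypes."""
    n_sites, k = founders.shape
    out = np.empty((n_sites, n_hap), dtype=np.int8)
    for h in range(n_hap):
        n_x = rng.poisson(recomb_rate * length_bp)
        breaks = np.sort(rng.integers(1, length_bp + 1, size=n_x))
        source = rng.integers(0, k, size=n_x + 1)
        seg_of_site = np.searchsorted(breaks, positions, side="right")
        hap = founders[np.arange(n_sites), source[seg_of_site]]
        n_mut = rng.poisson(mut_rate * length_bp)
        if n_mut:
            flip = rng.integers(0, n_sites, size=min(n_mut, n_sites))
            hap = hap.copy()
            hap[flip] = 1 - hap[flip]
        out[:, h] = hap
    return out


def simulate_neutral_panel(cfg: SimConfig) -> tuple[list[HaplotypeMatrix], np.random.Generator]:
    """Generate the neutral multi-population panel, one matrix per chromosome.

    Returns the panel list and the generator (so callers continue the stream
    for annotations and sweeps, keeping the whole dataset seed-determined).
    """
    cfg.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed)))
    pops = list(cfg.populations)
    hap_pop = np.concatenate([[p] * (2 * cfg.populations[p]) for p in pops])
    panels = []
    for ci in range(cfg.n_chroms):
        positions = np.sort(rng.choice(cfg.chrom_length_bp, size=cfg.n_sites, replace=False)) + 1
        p0 = _ancestral_freqs(rng, cfg.n_sites, cfg.freq_min, cfg.freq_max)
        blocks = []
        for p in pops:
            p_pop = balding_nichols_freqs(p0, cfg.divergence_F, rng)
            founders = (rng.random((cfg.n_sites, cfg.n_founders)) < p_pop[:, None]).astype(np.int8)
            blocks.append(
                _mosaic_haplotypes(
                    founders,
                    positions,
                    2 * cfg.populations[p],
                    cfg.chrom_length_bp,
                    cfg.recomb_rate,
                    cfg.mut_rate,
                    rng,
                )
            )
        alleles = np.concatenate(blocks, axis=1)
        ref = _BASES[rng.integers(0, 4, cfg.n_sites)]
        shift = rng.integers(1, 4, cfg.n_sites)
        alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
        anc_is_ref = rng.random(cfg.n_sites) < 0.5
        meta = pd.DataFrame(
            {
                "ref": ref,
                "alt": alt,
                "ancestral": np.where(anc_is_ref, ref, alt),
                "ancestral_source": "AA",
            }
        )
        panels.append(
            HaplotypeMatrix(
                chrom=f"chr{ci + 1}",
                positions=positions,
                alleles=alleles,
                hap_pop=hap_pop,
                site_meta=meta,
            )
        )
    return panels, rng


def impose_sweep(
    hm: HaplotypeMatrix,
    pop: str,
    core_site: int,
    target_freq: float,
    strength: float,
    chrom_length_bp: int,
    mut_rate: float,
    rng: np.random.Generator,
) -> None:
    """Rewrite derived-core carriers as template copies around the core (in place).

    Carrier count is round(target_freq * n_haplotypes) of the population; each
    carrier copies one template haplotype over a segment whose per-side length
    is exponential with mean strength * chrom_length (whole chromosome when
    strength == 1), then receives fresh private mutations inside the segment.
    Non-carriers get the ancestral core allele, so the core's derived frequency
    is exactly the target.
    """
    cols = hm.pop_indices(pop)
    n_car = int(round(target_freq * cols.size))
    if n_car < 2:
        raise ValueError("sweep target frequency yields fewer than 2 carrier haplotypes")
    carriers = rng.choice(cols, size=n_car, replace=False)
    template = hm.alleles[:, carriers[0]].copy()
    template[core_site] = 1
    core_pos = int(hm.positions[core_site])
    hm.alleles[core_site, cols] = 0
    for col in carriers:
        if strength >= 1.0:
            lo, hi = 0, hm.n_sites - 1
        else:
            left = rng.exponential(strength * chrom_length_bp)
            right = rng.exponential(strength * chrom_length_bp)
            lo = int(np.searchsorted(hm.positions, core_pos - left, side="left"))
            hi = int(np.searchsorted(hm.positions, core_pos + right, side="right")) - 1
        hm.alleles[lo : hi + 1, col] = template[lo : hi + 1]
        seg_bp = int(hm.positions[hi]) - int(hm.positions[lo]) + 1
        n_mut = rng.poisson(mut_rate * seg_bp)
        if n_mut:
            flip = rng.integers(lo, hi + 1, size=n_mut)
            flip = flip[flip != core_site]
            hm.alleles[flip, col] = 1 - hm.alleles[flip, col]
    hm.alleles[core_site, carriers] = 1


def _make_annotations(
    cfg: SimConfig, rng: np.random.Generator
) -> dict[str, GeneAnnotation]:
    genes: dict[str, GeneAnnotation] = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        spacing = cfg.chrom_length_bp // (cfg.n_genes + 1)
        for gi in range(cfg.n_genes):
            gid = f"G{ci + 1:02d}{gi + 1:04d}"
            start = spacing * (gi + 1) + int(rng.integers(-spacing // 4, spacing // 4 + 1))
            start = max(1, start)
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneAnnotation(gid, gid, chrom, strand)
            cursor = start
            if rng.random() < cfg.noncoding_gene_frac:
                for _ in range(int(rng.integers(1, 3))):
                    length = int(rng.integers(300, 1500))
                    g.add_interval(cursor, cursor + length - 1, RegionClass.NONCODING_EXON)
                    cursor += length + int(rng.integers(500, 2000))
            else:
                utr_a = int(rng.integers(200, 500))
                utr_b = int(rng.integers(400, 900))
                first = RegionClass.FIVE_UTR if strand == "+" else RegionClass.THREE_UTR
                last = RegionClass.THREE_UTR if strand == "+" else RegionClass.FIVE_UTR
                g.add_interval(cursor, cursor + utr_a - 1, first)
                cursor += utr_a + int(rng.integers(500, 2000))
                for _ in range(int(rng.integers(2, 4))):
                    length = int(rng.integers(300, 1200))
                    g.add_interval(cursor, cursor + length - 1, RegionClass.CDS)
                    cursor += length + int(rng.integers(500, 2000))
                g.add_interval(cursor, cursor + utr_b - 1, last)
            genes[gid] = g
    return genes


def _exon_sites(g: GeneAnnotation, hm: HaplotypeMatrix) -> np.ndarray:
    hits = np.zeros(hm.n_sites, dtype=bool)
    for start, end, _ in g.intervals:
        lo = np.searchsorted(hm.positions, start, side="left")
        hi = np.searchsorted(hm.positions, end, side="right")
        hits[lo:hi] = True
    return np.flatnonzero(hits)


def simulate(cfg: SimConfig) -> SimResult:
    """Full synthetic dataset: panel + annotations + focal set + truth table."""
    panels, rng = simulate_neutral_panel(cfg)
    annotations = _make_annotations(cfg, rng)
    gene_ids = list(annotations)
    focal_ids = list(rng.choice(gene_ids, size=min(cfg.focal_set_size, len(gene_ids)), replace=False))
    focal = FocalGeneSet(frozenset(focal_ids))
    pops = list(cfg.populations)

    sweep_rows = []
    used_genes: set[str] = set()
    placed: dict[str, list[int]] = {}
    for sw in cfg.sweeps:
        hm = panels[sw.chrom]
        if sw.core_pos is not None:
            core = int(np.argmin(np.abs(hm.positions - sw.core_pos)))
            gene_id, in_focal = "", False
        else:
            core, gene_id, in_focal = _place_core(
                cfg, hm, annotations, focal_ids, used_genes, sw, pops, rng,
                placed.get(hm.chrom, []),
            )
            used_genes.add(gene_id)
        placed.setdefault(hm.chrom, []).append(int(hm.positions[core]))
        impose_sweep(
            hm, sw.population, core, sw.target_freq, sw.strength,
            cfg.chrom_length_bp, cfg.mut_rate, rng,
        )
        sweep_rows.append(
            (hm.chrom, int(hm.positions[core]), sw.population, sw.target_freq,
             sw.strength, gene_id, in_focal)
        )
    sweeps_df = pd.DataFrame(
        sweep_rows,
        columns=["chrom", "pos", "population", "target_freq", "strength", "gene_id", "in_focal"],
    )
    genes_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [annotations[g].chrom for g in gene_ids],
            "focal": [g in focal.gene_ids for g in gene_ids],
            "has_sweep": [g in set(sweeps_df["gene_id"]) for g in gene_ids],
        }
    )
    return SimResult(panels, annotations, focal, TruthTable(sweeps_df, genes_df), cfg)


def _place_core(cfg, hm, annotations, focal_ids, used, sw, pops, rng, placed_bp=()):
    """Pick an exonic, MAF-eligible, centrally located core site for a sweep."""
    want_focal = bool(rng.random() < cfg.focal_enrichment)
    lo_bp, hi_bp = 0.2 * cfg.chrom_length_bp, 0.8 * cfg.chrom_length_bp
    other_freqs = [hm.derived_freq(p) for p in pops if p != sw.population]

    def pool_of(focal_only: bool) -> list[str]:
        # focal_only=False draws uniformly over ALL genes (focal included), so
        # focal_enrichment=0 leaves focal genes hit at the background rate
        pool = [g for g in (focal_ids if focal_only else annotations)
                if g not in used and annotations[g].chrom == hm.chrom]
        pool.sort()
        rng.shuffle(pool)
        return pool

    # preferred pool first; fall back to the other so a sparse focal set on
    # this chromosome cannot abort the run
    for focal_only in (want_focal, not want_focal):
        for gid in pool_of(focal_only):
            sites = _exon_sites(annotations[gid], hm)
            if sites.size == 0:
                continue
            ok = (hm.positions[sites] >= lo_bp) & (hm.positions[sites] <= hi_bp)
            for f in other_freqs:
                ok &= (f[sites] >= 0.08) & (f[sites] <= 0.90)
            for bp in placed_bp:
                ok &= np.abs(hm.positions[sites] - bp) >= cfg.min_sweep_spacing_bp
            eligible = sites[ok]
            if eligible.size:
                return int(rng.choice(eligible)), gid, gid in set(focal_ids)
    raise ValueError("no eligible exonic core site found for sweep; relax the config")


def demo_sweep_config(seed: int) -> SimConfig:
    """The standard seeded scan-evaluation dataset: three strong sweeps on a
    five-chromosome genome (two chromosomes left fully neutral), two
    populations of 50 diploids, focal set enriched for swept genes."""
    return SimConfig(
        seed=seed,
        populations={"POP1": 50, "POP2": 50},
        n_chroms=5,
        n_sites=800,
        sweeps=[
            SweepSpec("POP1", chrom=0),
            SweepSpec("POP2", chrom=1),
            SweepSpec("POP1", chrom=2),
        ],
        focal_enrichment=0.7,
        focal_set_size=20,
    )


#: chromosomes of demo_sweep_config carrying no sweep
DEMO_NEUTRAL_CHROMS = ("chr4", "chr5")


# ---------------------------------------------------------------------------
# writers


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCF (AA INFO tag, phased GT), GFF3, focal list, pop map and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    pops = list(cfg.populations)
    samples = [f"{p}_{i:03d}" for p in pops for i in range(cfg.populations[p])]
    paths = {
        "vcf": outdir / "panel.vcf",
        "gff3": outdir / "genes.gff3",
        "focal": outdir / "focal_genes.tsv",
        "pop_map": outdir / "pop_map.tsv",
        "truth_sweeps": outdir / "truth_sweeps.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
    }
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for hm in result.panels:
            fh.write(f"##contig=<ID={hm.chrom},length={cfg.chrom_length_bp}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for hm in result.panels:
            meta = hm.site_meta
            for s in range(hm.n_sites):
                ref, alt = meta.iloc[s]["ref"], meta.iloc[s]["alt"]
                anc = meta.iloc[s]["ancestral"]
                row = hm.alleles[s]
                coded = row if anc == ref else 1 - row
                gts = "\t".join(
                    f"{coded[2 * i]}|{coded[2 * i + 1]}" for i in range(len(samples))
                )
                fh.write(
                    f"{hm.chrom}\t{hm.positions[s]}\t.\t{ref}\t{alt}\t.\tPASS\tAA={anc}\tGT\t{gts}\n"
                )
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in result.annotations.values():
            start = min(s for s, _, _ in g.intervals)
            end = max(e for _, e, _ in g.intervals)
            fh.write(
                f"{g.chrom}\tsim\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_id={g.gene_id};gene_name={g.gene_symbol}\n"
            )
            has_cds = any(r == RegionClass.CDS for _, _, r in g.intervals)
            type_of = {
                RegionClass.FIVE_UTR: "five_prime_UTR",
                RegionClass.THREE_UTR: "three_prime_UTR",
                RegionClass.CDS: "CDS",
                RegionClass.NONCODING_EXON: "exon",
            }
            for s, e, r in sorted(g.intervals):
                ft = type_of[r]
                if not has_cds:
                    ft = "exon"
                fh.write(
                    f"{g.chrom}\tsim\t{ft}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id};gene_id={g.gene_id}\n"
                )
    with open(paths["focal"], "w") as fh:
        fh.write("gene_id\n")
        for gid in sorted(result.focal.gene_ids):
            fh.write(gid + "\n")
    with open(paths["pop_map"], "w") as fh:
        for p in pops:
            for i in range(cfg.populations[p]):
                fh.write(f"{p}_{i:03d}\t{p}\n")
    result.truth.sweeps.to_csv(paths["truth_sweeps"], sep="\t", index=False)
    result.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return paths
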