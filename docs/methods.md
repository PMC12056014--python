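# Methods

## Scope and model

`sweepscan` implements a two-level positive-selection analysis:

1. **Population level** — haplotype-based scans (iHS, xpEHH) on phased
   biallelic SNPs, combined with per-site Weir–Cockerham F<sub>ST</sub>
   thresholds binned by allele frequency and a clustered-outlier window
   rule, yielding per-variant and per-gene calls, region classification and
   an optional eQTL flag (m-value > 0.9, strict).
2. **Phylogeny level** — post-processing of branch-site codon-model fits:
   LRT statistic 2Δℓ from (lnL_alt, lnL_null) pairs, p = ½·Pr(χ²₁ ≥ 2Δℓ)
   under the ½χ²₀+½χ²₁ boundary mixture, Bonferroni adjustment over the
   family of genes tested per branch.  Fitting the codon models themselves
   (e.g. with codeml) is out of scope; a convenience parser extracts lnL
   from codeml main output, anchored to the `lnL(ntime:` line.

Enrichment of a focal gene set is tested by uniform resampling without
replacement from the gene universe (100,000 replicates at full scale) with
add-one empirical tail probabilities; pairwise lineage comparisons use
Fisher's exact test (two-sided, via scipy).

## Definitions and conventions

* **EHH.** For a carrier set C and distance d, EHH(d) = Σ_g C(k_g,2)/C(|C|,2)
  over distinct haplotype strings g spanning core→d.  Identity strings start
  *at the core site* and extend outward; for single-allele carrier sets
  (iHS) this is the textbook definition, for pooled sets (xpEHH) it means
  haplotypes differing at the core are never identical.  The recorded curve
  starts at (0, 1.0) by convention.
* **iHH.** Trapezoidal integration over physical distance (bp), both
  directions summed, stopping inclusively at the first point with
  EHH < cutoff (default 0.05).  No genetic map is used (a constant-rate hook
  exists in config).  If the cutoff is not reached before the chromosome
  end, the 1 Mb maximum extension, or a > 200 kb inter-SNP gap, the site is
  NA with the reason recorded.  These defaults are the standard scan-tool
  defaults and are exposed in `EhhParams`.
* **iHS sign.** ln(iHH_ancestral) − ln(iHH_derived): long derived haplotypes
  give negative scores.  Only |score| enters the calling rule, so the sign
  convention is internal; the log-difference form makes the
  polarity-swap antisymmetry (and xpEHH(A,B) = −xpEHH(B,A)) exact in
  floating point.
* **Standardization.** iHS: 100 equal-width derived-frequency bins on [0,1];
  bins with < 20 non-NA scores are merged with the frequency-adjacent bin
  currently holding fewer sites (ties toward lower frequency); z-scores use
  the sample SD (n−1).  xpEHH: one global bin.  NA propagates.
* **F<sub>ST</sub>.** Weir & Cockerham (1984) a/(a+b+c) per site from diploid
  genotype counts.  The scalar API computes in exact rational arithmetic
  (counts are integers), so fixed differences give exactly 1.0; the
  vectorized genome path uses floating point.  Negative estimates are kept
  (not clipped) so bin quantiles are undistorted; monomorphic sites are NA.
* **Binned thresholds.** Pooled derived-allele frequency (unfolded), bins of
  width 0.05, same merge rule as standardization; threshold = nearest-rank
  upper 5% (k-th largest, k = ⌈q·n⌉), pass is inclusive (≥).  The same
  nearest-rank rule defines the top-1% window cut, where it also yields the
  documented tie behaviour: if every window has the same count, all qualify.
* **Windows.** 51 SNPs, sliding by one SNP, centered; a window exists only
  with 25 scored flanking sites on both sides of the center within the
  chromosome (chromosome-end windows are excluded so all counts share one
  denominator).  NA scores count as non-extreme.
* **Composite call.** |score| > 2 AND centered window qualifies AND
  F<sub>ST</sub> pass.  For iHS (a one-population statistic) the
  F<sub>ST</sub> gate is satisfied by any pair involving the target
  population; xpEHH uses its own pair.  An xpEHH candidate's target
  population is the first of the pair for positive scores and the second
  for negative ones, which together with computing every unordered pair once
  covers all ordered comparisons.
* **MAF scope.** A site participates in a given scan only if its minor
  allele frequency is ≥ 0.05 in *every* analyzed population (conjunctive;
  recorded in the run manifest).  Sites with missing alleles are dropped.
  Ancestral alleles come from the VCF `AA` tag when it matches REF or ALT;
  otherwise REF is assumed ancestral and the site is flagged
  `ref_fallback`.
* **Region classes.** Internal coordinates are 1-based inclusive (BED is
  converted on read).  When transcripts disagree, precedence is
  CDS > 5'UTR > 3'UTR > non-coding exon.  GFF3 `exon` features count as
  non-coding exons only for genes without coding features.
* **Enrichment.** p_upper = (1 + #{null ≥ obs})/(R+1), p_lower analogous;
  each tail is a one-sided test at α = 0.05 (both are reported, so users may
  Bonferroni the pair).  Replicates draw from per-replicate
  `SeedSequence(seed).spawn` substreams, so results are independent of
  chunking and bit-reproducible.  The gene universe is the full annotation
  set of the analysis (all genes eligible for calling).
* **LRT.** Negative 2Δℓ (optimizer noise in the inputs) is clamped to 0 with
  a warning.  The Bonferroni family size is supplied explicitly and defaults
  to the number of rows processed.

## The synthetic-data generator

`simdata` emulates the statistical structure the scans assume, not human
demography:

* **Ancestral spectrum**: density ∝ 1/x truncated to [0.05, 0.95], so the
  MAF filter boundary is exercised from both sides.
* **Population divergence**: Balding–Nichols, per-population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.05 by default — the scale of
  human continental differentiation; mean-preserving by construction.
* **Haplotypes**: recombinant mosaics of K = 100 population founders with
  crossovers Poisson(5×10⁻⁵ per bp) — mean copy-segment 20 kb, so background
  EHH decays over tens of kb — plus private mutations Poisson(2×10⁻⁶ per
  bp).  These rates were chosen so that neutral haplotype sharing is modest
  relative to planted sweeps while linkage still decays smoothly with
  distance; a coalescent backend would be a drop-in alternative but is not
  required for exercising the statistics.
* **Sweeps**: carriers of the derived core allele (frequency set exactly to
  the target) are rewritten as copies of one template haplotype over a
  segment whose per-side length is exponential with mean
  `strength × chrom_length` (strength = 1 is special-cased to the whole
  chromosome, making the stated all-carriers-identical limit exact), then
  re-mutated.  Auto-placed cores are confined to exons, to the central 60%
  of the chromosome (so EHH integration does not run off the ends), to
  sites whose frequency in the unswept populations is in [0.08, 0.90] (so
  planted cores survive the MAF filter of pair analyses), and to ≥ 300 kb
  from other cores on the chromosome (so one sweep's template copying
  cannot overwrite another's carriers).  With probability
  `focal_enrichment` the host gene is drawn from the focal set, otherwise
  uniformly from all genes — so at enrichment 0 focal genes are hit at the
  background rate.
* **Annotations**: ~40 genes per chromosome with 5'UTR/CDS×(2–3)/3'UTR
  structure on either strand, ~10% non-coding genes with plain exons.

What it does **not** emulate: growth, migration, admixture, background
selection, genotype error, realistic gene density or recombination maps.
Passing the power checks therefore demonstrates that the statistics respond
to the haplotype structure they are defined on, not that the pipeline's
power on real human data equals the measured rates.

## Problem sizes and evaluation conditions

The standard evaluation dataset (`demo_sweep_config`) is two populations of
50 diploids, five 1 Mb chromosomes of 800 SNPs each, three strong sweeps
(target frequency 0.85, strength 0.05 → mean shared segment 50 kb per side)
on chromosomes 1–3, chromosomes 4–5 fully neutral, and a 20-gene focal set
with enrichment 0.7.  At this scale a sweep's footprint is a far larger
genome fraction than in a real genome, so the genome-wide top-1% window cut
and the binned F<sub>ST</sub> tails are partly set by the sweeps themselves;
"recovery" is therefore assessed as a composite candidate in the swept
population within 100 kb of the planted core (the scan's regional
resolution), measured over 50 seeds, alongside the per-site false-call rate
on the neutral chromosomes.  Enrichment calibration uses a 2,000-gene
universe with 400 flagged genes, draws of 320, and 2,000 replicates per
test — granular enough that the discrete add-one test's exact null firing
rate (0.0425, computed from the hypergeometric/binomial null) sits near the
nominal 5%.  Full-scale behaviour (100,000 replicates on a 20,000-gene
universe) is exercised for determinism and runtime.

## Known limitations

* Only two-population F<sub>ST</sub> (the pipeline runs all pairs); no
  Hudson estimator, no windowed F<sub>ST</sub>.
* No nSL/iHH12, no genetic-map integration, single-threaded.
* The branch-site layer consumes externally computed likelihoods; it cannot
  detect a mis-specified model fit, only post-process it.
* The VCF reader requires fully phased diploid records and drops any site
  with missing alleles; no imputation or multiallelic decomposition.
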