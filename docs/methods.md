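# Methods

This note documents the models, conventions and numerical choices
behind `apespectra`, and what the synthetic validation does and does
not demonstrate.

## Mutation classes and strand collapse

A single-nucleotide change is identified by its ancestral k-mer context
(k = 3 or 7) and derived central base. Because a mutation observed on
one strand is its reverse complement on the other, classes are
collapsed so the central ancestral base is A or C: 32 collapsed triplet
contexts × 3 derived bases = 96 classes, and 8,192 collapsed 7-mer
contexts × 3 = 24,576 classes, exactly 256 per parent triplet class.
All vectors in the package share one canonical lexicographic order
(`AAA>C` first, `TCT>T` last), and collapsing is applied iff the
central ancestral base is G or T. Content counting obeys the same
convention, so recomputing spectra or contents from a
reverse-complemented reference is an exact no-op (tested).

## Polarization and the filter cascade

Ancestral alleles are assigned by cross-genus parsimony: a biallelic
site segregating in exactly one genus takes as ancestral the allele
fixed in every other genus with data. Violations are excluded with a
single reason code each, in a fixed order chosen so reasons are
unambiguous:

1. parsimony exclusions (monomorphic; >2 alleles in a genus;
   segregating in ≥2 genera; conflicting fixed alleles among the
   outgroup genera);
2. missingness in the focal genus above a threshold (default 0 for
   complete-call ape-style panels; 0.2 is the conventional choice for
   large human/mouse-style panels);
3. N in the flanking context — ±1 bp for triplet analyses, ±3 bp for
   7-mer analyses;
4. recurrent mutation, operationalized as the derived allele also being
   observed in another genus after polarization (with genotype-level
   data and the parsimony exclusions applied first this is a
   conservative backstop; it mainly matters for pre-polarized input);
5. singletons (k = 1; higher sequencing-error risk), or k ≠ 2 in
   doubleton-only replicate mode;
6. derived allele frequency ≥ 0.5 (inclusive), guarding against
   ancestral-state misassignment;
7. excess heterozygosity, one-sided exact Hardy–Weinberg test at
   α = 0.05.

With only two genera in a panel, a fixed-derived outgroup simply flips
the polarization (parsimony cannot distinguish it); the
multiple-fixed-alleles exclusion therefore requires at least three
genera, which the three-genus tests exercise. In a single-genus panel
there is no outgroup and the reference allele is taken as ancestral.

The Hardy–Weinberg test is the exact conditional test: given n diploids
and n_a derived alleles, P(h heterozygotes) ∝ n! 2^h / (n_AA! h! n_aa!),
summed one-sided over h ≥ observed. Monomorphic sites return p = 1.
The implementation (log-gamma) is verified against an independent
oracle that enumerates all 2^(2N) haplotype assignments with bit
arithmetic for every table with 2N ≤ 20 (agreement < 1e-12).

## Spectrum construction

*Species spectra* count each segregating site once regardless of
frequency. *Individual spectra* weight homozygous derived sites 2 and
heterozygous sites 1, i.e. the average of the two haplotype spectra.
*Randomized spectra* credit each site to exactly one carrier haplotype
chosen uniformly among the k derived copies, so a heterozygous carrier
is selected with probability 1/k and a homozygous one with 2/k. This
makes per-class totals over samples exactly equal to the site counts
(conservation is exact, not in expectation) and removes the covariance
between individuals that shared ancestral variants otherwise induce —
the property that lets between-individual distances and PCA reflect
mutation-process differences rather than shared drift, and that damps
the imprint of GC-biased gene conversion, which concentrates in
high-frequency alleles.

## Content normalization

Compartments differ in composition, so raw class counts mislead. Three
corrections, all driven by sliding-window (1 bp step) k-mer counts that
use only windows lying wholly inside a segment and containing no N:

- **Rate rescaling**: multiply each class count by
  (reference content / own content) of its ancestral context, then
  normalize to sum 1. The reference is a neutral baseline compartment;
  the result is scale-invariant in the reference content, and classes
  sharing a context share one factor.
- **Count downscaling** for two-compartment count-based tests: the
  compartment with more of a class's context has its count multiplied
  by the (≤1) content ratio; the other is untouched. Counts are kept
  real-valued by default (the magnitude is what chi-square-style tests
  need); optional integer rounding is provided since a rounding policy
  is inherently a convention.
- **7-mer correction**: each 7-mer-resolved count is reweighted by its
  own 7-mer content ratio before collapsing to the parent triplet
  class. When every within-class ratio is equal this reduces exactly to
  triplet rescaling (tested); when compartments differ in extended
  context composition it removes apparent triplet-rate differences that
  are composition artifacts, which the acceptance suite demonstrates on
  a triplet-only process over compartments with heterogeneous 7-mer
  content (corrected mean log-odds ≈ 0).

Classes with zero content in both compartments are dropped from
comparisons rather than imputed. Zero content with a nonzero count is a
hard error naming the context, since it indicates inconsistent inputs.

## Statistical layer

- **PCA** on centered/scaled matrices. Constant columns are dropped
  before scaling (detected on the centered matrix with a relative
  1e-12 threshold, since a non-representable constant can leave a
  ~1e-17 standard deviation); each loading is oriented so its
  largest-magnitude entry is positive, making signs deterministic.
- **NMF**: Frobenius objective, coordinate-descent solver, random
  non-negative initialization, default 20 restarts with the best fit
  kept; signature rows are normalized to sum 1 with the mass moved to
  exposures. Tolerance 1e-8 / 5,000 iterations recovers exact low-rank
  inputs to <1e-6 relative error. Signatures from independent runs are
  pooled and clustered with cosine distance and average linkage.
- **Log-odds heatmaps**: natural-log ratio of rescaled rates per class.
  Classes with a zero rate in either compartment are masked rather than
  pseudocounted (no pseudocount convention is assumed); masked classes
  are dropped pairwise in the Pearson correlation between heatmaps.
- **Spectrum-fit likelihood**: P_s = Σ_i count_i · log p_i,s with the
  multinomial coefficient omitted (it cancels in comparisons); effect
  size is the fold range exp(max−min) across candidate species, with
  20× playing the role of a 0.05 cutoff. A zero model probability on an
  observed class yields −∞ and an infinite fold range, reported as such.
- **Placement bootstrap**: each target segment is re-placed uniformly
  among all positions on its chromosome where it fits wholly inside a
  background segment and contains no N (resampling on N, budget 1,000
  per segment); overlaps between placed segments are allowed, as is
  appropriate when the target is a small fraction of the background.
  100 replicates by default. The enrichment statistic is a single
  class's log odds between downscale-normalized counts; the observed
  value gets a 95% percentile CI from 1,000 multinomial resamples of
  the target's variants, and is flagged when it lies outside the
  empirical min–max of the replicate null.
- **Replication-timing quartiles**: non-overlapping 20 kb windows,
  windows without measurements dropped, quartile cuts at the 25th/75th
  percentiles of window means; ties beyond a quarter of the windows are
  trimmed in (chromosome, start) order for determinism. Measurements
  are assigned to the window containing their midpoint.

## The synthetic generator

The generator emulates the data-generating assumptions the pipeline is
meant to detect, not a full population-genetic history:

- iid uniform reference bases (optional CpG-enrichment knob for
  realistic CpG-class availability); no N by default;
- compartments built from shuffled segments with per-compartment length
  ranges, scheduled so no two consecutive segments share a compartment
  (BED merging therefore cannot fuse a compartment into oversized
  segments, keeping the placement bootstrap's precondition satisfiable
  by construction);
- per-lineage class distributions ∝ signature mixture × compartment cis
  multiplier × context availability; positions drawn uniformly without
  replacement within (compartment, context) pools;
- derived counts from a truncated neutral 1/k spectrum — the real
  frequency distribution of a species' variants is not modeled, so this
  is a neutral stand-in — with an optional exponential tilt
  exp(±γ·k/2N) on weak→strong / strong→weak classes mimicking
  GC-biased gene conversion;
- genotypes by uniform assignment of the k derived haplotypes
  (Hardy–Weinberg conditional on frequency). Optional contamination
  makes a fraction of sites pseudo-heterozygous across the whole focal
  genus (each sample het with probability 0.85), the footprint of a
  collapsed segmental duplication, which the excess-het filter then
  removes;
- optional shared ancestral variants planted in two genera — fixed
  derived in one and segregating in the other with probability ½,
  segregating in both otherwise — to exercise the parsimony exclusions;
- one counter-based Philox stream seeded by the single config seed
  drives every draw, so outputs are byte-identical across runs and
  platforms.

The **reference study** (`standard_config`) is 2 genera × 2 species ×
9 diploids, 2 Mb of genome over 2 chromosomes, three fixed Dirichlet
signatures with species-distinct dosages, 25,000 variants per lineage
(100,000 total), a neutral baseline compartment covering half the
genome in 8–16 kb segments, and a cis compartment (20%, 1–3 kb
segments) with a 2× multiplier on one class. The perturbed class
(`AAG>G`) was chosen as one carrying substantial mass in every
lineage's mixture so its baseline rate is well measured; the sizes keep
a full validation run around a minute on one CPU while leaving
Monte-Carlo error comfortably inside the recovery tolerances (the
planted ln 2 ≈ 0.693 log-odds is recovered within ±0.15, typically
±0.05).

What passing these tests shows: the pipeline's bookkeeping (polarization,
filtering, conservation, normalization identities) is exact, and its
statistics recover planted trans- and cis-acting structure at realistic
panel sizes. What it does not show: robustness to features real panels
have and the generator omits — linkage and demography, sequencing and
mapping error, reference bias between species, recurrent mutation at
hypermutable sites, and non-equilibrium frequency spectra.

## Known limitations

- Parsimony polarization is biased wherever mutation rates are high
  enough for parallel mutations (e.g. CpG transitions); the DAF < 0.5
  filter mitigates but does not remove this.
- The recurrent-mutation operationalization is genotype-level and
  conservative; with the parsimony exclusions applied first it rarely
  fires on well-formed panels.
- Species-level 2N uses the panel's sample count and assumes complete
  genotypes within the focal genus when the missingness threshold is 0.
- The Euclidean distance analysis defaults to frequency vectors (counts
  are offered as an option) because total variant numbers differ
  between samples; the log base for heatmaps is the natural log,
  recorded in output metadata.
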