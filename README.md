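# apespectra

Compartmentalized mutation-spectrum analysis for multi-species
polymorphism panels.

## The problem

Germline mutation rates are not uniform: different three-base-pair
motifs mutate at different rates, those rates evolve between lineages
(*trans*-acting modifiers), and they also vary between regions of the
genome such as late-replicating DNA or ancient repeats (*cis*-acting
modifiers). Separating these two axes requires ascertaining **mutation
spectra** — histograms of segregating variants over the 96
strand-collapsed triplet mutation classes (`AAA>C` … `TCT>T`) — per
individual, per species, and per *genomic compartment* (a named set of
intervals sharing an annotation, e.g. a replication-timing quartile),
and then comparing them with careful normalization for each
compartment's nucleotide content.

`apespectra` implements that pipeline for anyone working with a
multi-genus variant panel (VCF + reference FASTA + BED compartments +
a sample table), and ships a synthetic-panel generator with known
signature structure so every stage can be validated end to end without
any external data.

## What it computes

- **Polarization by parsimony.** A biallelic site segregating in exactly
  one genus is polarized to the allele fixed in all other genera; sites
  segregating in several genera, with multiple fixed alleles, or with
  more than two alleles in a genus are excluded. Further filters drop
  singletons, sites with derived allele frequency ≥ 0.5, sites with N
  in the flanking context, recurrent mutations, and sites failing a
  one-sided exact Hardy–Weinberg test for heterozygote excess
  (*P* < 0.05), a signature of collapsed duplications.
- **Spectra.** Species spectra count every segregating site once.
  Individual spectra weight homozygous derived alleles twice. A
  *randomized* mode credits each site, with frequency *k*/2*N*, to
  exactly one uniformly chosen carrier haplotype (a heterozygote with
  probability 1/*k*, a homozygote 2/*k*), removing the spurious
  between-individual covariance created by shared drift.
- **Content normalization.** Rescaled rates
  `R(m_i, C) = #m_i,C · (#t_NCNR / #t_C)` with `r = R/ΣR`, where `t` is
  the class's collapsed triplet and the reference is a neutral baseline
  compartment; a count-preserving variant that only ever scales the
  content-richer compartment *down*; and a 7-mer-resolved correction
  that reweights each of the 256 7-mer members of a triplet class by
  its own content ratio before collapsing.
- **Comparison.** PCA of centered/scaled spectrum matrices, NMF
  signature extraction (best of random restarts) with agglomerative
  signature clustering across runs, within/between-group Euclidean
  distance distributions, per-class log-odds heatmaps between
  compartments with cross-species Pearson correlation, a multinomial
  log-likelihood fit of de novo mutation spectra against candidate
  species (`P_s = Σ_i #m_i · log p_i,s`, effect size
  `exp(max P − min P)` with a 20× significance convention), and a
  length-preserving placement bootstrap that re-scatters a compartment's
  segments inside a background compartment to build an empirical null
  for single-class enrichments.

## Worked example

```python
import numpy as np
import apespectra as ap

# reference study: 2 genera x 2 species x 9 diploids, 3 known signatures,
# one compartment with a 2x cis multiplier on class AAG>G
cfg = ap.standard_config(seed=1, n_snvs_per_lineage=5_000)
sim = ap.simulate_panel(cfg, "demo")
kept, disp, tally = ap.polarize_and_filter(sim.vcf, sim.panel, sim.sequences)
print(f"kept {len(kept)} of {len(disp)} sites; exclusions: {tally}")

rng = np.random.default_rng(1)
spectra = ap.randomized_spectrum(kept, sim.panel, rng)
pca = ap.run_pca(ap.build_spectrum_matrix([s.frequencies() for s in spectra.values()]))
print("PC1/PC2 variance:", np.round(pca.variance_fractions[:2], 3))

nmf = ap.run_nmf(ap.build_spectrum_matrix(list(spectra.values())), 3,
                 restarts=10, rng=rng)
print("signature cosines:",
      [round(c, 3) for _, _, c in ap.match_signatures(nmf.signatures,
                                                      cfg.true_signatures)])
```

prints

```
kept 14196 of 20000 sites; exclusions: {'singleton': 5804}
PC1/PC2 variance: [0.195 0.08 ]
signature cosines: [0.969, 0.961, 0.933]
```

The filter removes the 29% of simulated variants that are singletons
(the expected mass of *k* = 1 under the neutral 1/*k* frequency
spectrum at 2*N* = 18). PC1 of the randomized individual spectra
separates the two genera, PC2 the species within them, and NMF recovers
all three planted signatures at cosine similarity ≥ 0.93. Comparing
content-rescaled rates between the cis-perturbed compartment and the
baseline recovers the planted 2× effect:

```
AAG>G log-odds cis vs baseline: 0.676 (truth ln 2 = 0.693)
```

A command-line interface mirrors the library
(`apespectra run-all --config run.json --seed 1`), with one subcommand
per stage (`simulate`, `filter`, `spectra`, `normalize`, `pca`, `nmf`,
`distances`, `heatmap`, `bootstrap-erv`, `dnmfit`) and a manifest of
checksummed artifacts for reproducible re-runs.

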