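"""Polarization by cross-genus parsimony and the site-filter cascade.

Sites from a multi-genus polymorphism panel are polarized by parsimony:
a biallelic site segregating within exactly one genus is assigned the
allele fixed in all other genera as ancestral.  Sites violating the
single-mutation assumption (segregating in several genera, carrying
multiple fixed alleles, or showing more than two alleles in one genus)
are excluded, as are singletons, sites at derived allele frequency
>= 0.5, sites with N in the flanking context, sites whose derived
allele recurs in another genus, and sites failing a one-sided exact
Hardy-Weinberg test for heterozygote excess (a signature of collapsed
segmental duplications).

Every input site receives exactly one disposition; excluded sites carry
a single reason code so that filter tallies partition the input.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.special import gammaln

# exclusion reason codes, in cascade order
REASONS = (
    "monomorphic",
    ">2-alleles-in-genus",
    "multi-genus-segregating",
    "multiple-fixed-alleles",
    "missingness",
    "N-context",
    "recurrent",
    "singleton",
    "not-doubleton",
    "DAF>=0.5",
    "HWE-excess-het",
)


@dataclasses.dataclass
class PanelMetadata:
    """Sample -> (subspecies, species, genus) map for a variant panel."""

    samples: list[str]
    subspecies_of: dict[str, str]
    species_of: dict[str, str]
    genus_of: dict[str, str]

    def __post_init__(self) -> None:
        for s in self.samples:
            if s not in self.genus_of:
                raise ValueError(f"sample {s!r} missing from panel metadata")

    @property
    def genera(self) -> list[str]:
        return sorted(set(self.genus_of.values()))

    @property
    def species(self) -> list[str]:
        return sorted(set(self.species_of.values()))

    def samples_of_species(self, species: str) -> list[str]:
        return [s for s in self.samples if self.species_of[s] == species]

    def samples_of_genus(self, genus: str) -> list[str]:
        return [s for s in self.samples if self.genus_of[s] == genus]

    def haplotypes_of_species(self, species: str) -> int:
        return 2 * len(self.samples_of_species(species))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanelMetadata":
        samples, sub, spp, gen = [], {}, {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("sample\t"):
                    continue
                name, subspecies, species, genus = line.split("\t")[:4]
                samples.append(name)
                sub[name], spp[name], gen[name] = subspecies, species, genus
        return cls(samples, sub, spp, gen)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tsubspecies\tspecies\tgenus\n")
            for s in self.samples:
                fh.write(f"{s}\t{self.subspecies_of[s]}\t{self.species_of[s]}\t{self.genus_of[s]}\n")

    def subset(self, keep: list[str]) -> "PanelMetadata":
        keep_set = set(keep)
        return PanelMetadata(
            [s for s in self.samples if s in keep_set],
            {s: v for s, v in self.subspecies_of.items() if s in keep_set},
            {s: v for s, v in self.species_of.items() if s in keep_set},
            {s: v for s, v in self.genus_of.items() if s in keep_set},
        )


@dataclasses.dataclass
class PolarizedSNV:
    """A biallelic site with parsimony-assigned ancestral/derived alleles.

    ``k`` counts derived haplotypes among the ``n_hap`` (2N) non-missing
    haplotypes of the focal genus.  ``sample_copies`` maps each derived
    carrier in the focal genus to its copy number (1 het, 2 hom);
    ``genotype_counts`` are (ancestral hom, het, derived hom) in the focal
    genus, feeding the Hardy-Weinberg test.  Contexts are ancestral-state
    strings centered on the site (N-padded at chromosome edges).
    """

    chrom: str
    pos: int  # 1-based
    ancestral: str
    derived: str
    genus: str
    species: str | None
    k: int
    n_hap: int
    context3: str
    context7: str
    sample_copies: dict[str, int]
    genotype_counts: tuple[int, int, int]
    derived_elsewhere: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.n_hap - 1):
            raise ValueError(f"k={self.k} out of range for 2N={self.n_hap}")
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived alleles are identical")
        for ctx, mid in ((self.context3, 1), (self.context7, 3)):
            if ctx[mid] != self.ancestral:
                raise ValueError(f"context {ctx} not centered on ancestral allele")

    @property
    def daf(self) -> float:
        return self.k / self.n_hap

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclasses.dataclass
class SiteDisposition:
    site: str
    verdict: str  # "kept" | "excluded"
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.verdict == "excluded" and self.reason not in REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")
        if self.verdict == "kept" and self.reason is not None:
            raise ValueError("kept sites carry no reason")


# --------------------------------------------------------------------------
# polarization
# --------------------------------------------------------------------------


def polarize_by_parsimony(
    chrom: str,
    pos: int,
    alleles: list[str],
    genotypes: np.ndarray,
    panel: PanelMetadata,
    reference,
    missingness_threshold: float = 0.0,
):
    """Polarize one site; returns a :class:`PolarizedSNV` or a disposition.

    ``genotypes`` is an (n_samples, 2) array of allele indices into
    ``alleles`` (-1 for missing), rows ordered as ``panel.samples``.
    A site is kept for polarization when exactly one genus segregates and
    every other genus with data is fixed for one shared allele, which
    becomes ancestral.  With a single-genus panel (no outgroup genera)
    the reference allele is taken as ancestral.
    """
    site = f"{chrom}:{pos}"
    genotypes = np.asarray(genotypes)
    if len(alleles) > 2:
        return SiteDisposition(site, "excluded", ">2-alleles-in-genus")

    by_genus: dict[str, np.ndarray] = {}
    for g in panel.genera:
        idx = [i for i, s in enumerate(panel.samples) if panel.genus_of[s] == g]
        by_genus[g] = genotypes[idx]

    seg, fixed = [], {}
    for g, gt in by_genus.items():
        observed = np.unique(gt[gt >= 0])
        if len(observed) > 2:
            return SiteDisposition(site, "excluded", ">2-alleles-in-genus")
        if len(observed) == 2:
            seg.append(g)
        elif len(observed) == 1:
            fixed[g] = int(observed[0])

    if len(seg) == 0:
        return SiteDisposition(site, "excluded", "monomorphic")
    if len(seg) > 1:
        return SiteDisposition(site, "excluded", "multi-genus-segregating")
    focal = seg[0]

    outgroup_alleles = {a for g, a in fixed.items() if g != focal}
    if len(outgroup_alleles) > 1:
        return SiteDisposition(site, "excluded", "multiple-fixed-alleles")
    anc_idx = outgroup_alleles.pop() if outgroup_alleles else 0  # ref ancestral if no outgroup
    der_idx = 1 - anc_idx

    gt = by_genus[focal]
    focal_samples = panel.samples_of_genus(focal)
    missing = gt < 0
    n_hap_total = gt.size
    miss_frac = missing.sum() / n_hap_total
    if miss_frac > missingness_threshold:
        return SiteDisposition(site, "excluded", "missingness")

    present = ~missing
    n_hap = int(present.sum())
    k = int((gt[present] == der_idx).sum())
    if k == 0 or k == n_hap:
        return SiteDisposition(site, "excluded", "monomorphic")

    copies = {}
    n_anc_hom = n_het = n_der_hom = 0
    for sample, row in zip(focal_samples, gt):
        c = int((row[row >= 0] == der_idx).sum())
        if np.all(row >= 0):
            if c == 0:
                n_anc_hom += 1
            elif c == 1:
                n_het += 1
            else:
                n_der_hom += 1
        if c:
            copies[sample] = c

    species = {panel.species_of[s] for s in copies}
    focal_species = species.pop() if len(species) == 1 else None

    derived_elsewhere = any(a == der_idx for g, a in fixed.items() if g != focal)
    ancestral, derived = alleles[anc_idx], alleles[der_idx]
    ctx7 = _context(reference, chrom, pos, ancestral)
    return PolarizedSNV(
        chrom=chrom,
        pos=pos,
        ancestral=ancestral,
        derived=derived,
        genus=focal,
        species=focal_species,
        k=k,
        n_hap=n_hap,
        context3=ctx7[2:5],
        context7=ctx7,
        sample_copies=copies,
        genotype_counts=(n_anc_hom, n_het, n_der_hom),
        derived_elsewhere=derived_elsewhere,
    )


def _context(reference, chrom: str, pos: int, ancestral: str) -> str:
    """Ancestral 7-mer around a 1-based position, N-padded at edges."""
    seq = reference[chrom]
    p0 = pos - 1
    lo, hi = p0 - 3, p0 + 4
    chunk = str(seq[max(lo, 0) : min(hi, len(seq))]).upper()
    chunk = "N" * max(0, -lo) + chunk + "N" * max(0, hi - len(seq))
    return chunk[:3] + ancestral.upper() + chunk[4:]


# --------------------------------------------------------------------------
# Hardy-Weinberg exact test (one-sided, heterozygote excess)
# --------------------------------------------------------------------------


def hwe_excess_het_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact one-sided P(het count >= observed | allele counts).

    Conditional on the observed allele counts, the probability of a
    genotype configuration with h heterozygotes among n diploids is
    proportional to ``n! 2^h / (n_AA! h! n_aa!)``; the p-value sums this
    over all configurations with at least the observed number of
    heterozygotes.  Monomorphic sites return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("genotype counts must be non-negative with positive total")
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa  # minor-allele-agnostic: conditioning symmetric
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    h_values = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    log_w = (
        h_values * np.log(2.0)
        - gammaln((n_a - h_values) / 2 + 1)
        - gammaln(h_values + 1)
        - gammaln(n - (n_a + h_values) / 2 + 1)
    )
    w = np.exp(log_w - log_w.max())
    p = w[h_values >= n_Aa].sum() / w.sum()
    return float(min(p, 1.0))


# --------------------------------------------------------------------------
# filter cascade
# --------------------------------------------------------------------------


def apply_site_filters(
    snv: PolarizedSNV,
    use_doubletons_only: bool = False,
    context_order: int = 3,
    min_derived_count: int = 2,
    hwe_alpha: float = 0.05,
) -> SiteDisposition:
    """Apply the post-polarization filter cascade to one site.

    Order: N context (±1 bp at triplet resolution, ±3 bp at 7-mer) ->
    recurrent derived allele -> singleton (k < ``min_derived_count``;
    doubleton-only mode demands k == 2) -> derived allele frequency
    (excluded at >= 0.5, inclusive) -> Hardy-Weinberg heterozygote excess
    at ``hwe_alpha``.
    """
    ctx = snv.context3 if context_order == 3 else snv.context7
    if "N" in ctx:
        return SiteDisposition(snv.key, "excluded", "N-context")
    if snv.derived_elsewhere:
        return SiteDisposition(snv.key, "excluded", "recurrent")
    if snv.k < min_derived_count:
        return SiteDisposition(snv.key, "excluded", "singleton")
    if use_doubletons_only and snv.k != 2:
        return SiteDisposition(snv.key, "excluded", "not-doubleton")
    if snv.daf >= 0.5:
        return SiteDisposition(snv.key, "excluded", "DAF>=0.5")
    if hwe_excess_het_test(*snv.genotype_counts) < hwe_alpha:
        return SiteDisposition(snv.key, "excluded", "HWE-excess-het")
    return SiteDisposition(snv.key, "kept")


def polarize_and_filter(
    vcf_path: str | Path,
    panel: PanelMetadata,
    reference,
    use_doubletons_only: bool = False,
    context_order: int = 3,
    missingness_threshold: float = 0.0,
    hwe_alpha: float = 0.05,
):
    """Run polarization and the filter cascade over a VCF.

    Returns (kept PolarizedSNVs, all dispositions, tally of exclusion
    reasons).  The VCF sample columns must match the panel exactly.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    if list(vcf.samples) != panel.samples:
        raise ValueError("VCF sample columns do not match the panel table")
    kept, dispositions = [], []
    tally: dict[str, int] = {}
    for variant in vcf:
        alleles = [variant.REF] + list(variant.ALT)
        gts = np.array(variant.genotypes, dtype=np.int64)[:, :2]
        res = polarize_by_parsimony(
            variant.CHROM, variant.POS, alleles, gts, panel, reference,
            missingness_threshold=missingness_threshold,
        )
        if isinstance(res, SiteDisposition):
            disp = res
            snv = None
        else:
            snv = res
            disp = apply_site_filters(
                res,
                use_doubletons_only=use_doubletons_only,
                context_order=context_order,
                hwe_alpha=hwe_alpha,
            )
        dispositions.append(disp)
        if disp.verdict == "kept":
            kept.append(snv)
        else:
            tally[disp.reason] = tally.get(disp.reason, 0) + 1
    return kept, dispositions, tally


def write_dispositions(dispositions: list[SiteDisposition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tverdict\treason\n")
        for d in dispositions:
            fh.write(f"{d.site}\t{d.verdict}\t{d.reason or '.'}\n")


# --------------------------------------------------------------------------
# frequency stratification
# --------------------------------------------------------------------------


def frequency_stratified_subset(
    sites: list[PolarizedSNV],
    edges: list[float],
    on: str = "daf",
) -> dict[str, list[PolarizedSNV]]:
    """Partition sites into derived-frequency (or derived-count) bins.

    ``edges`` define half-open bins [e0, e1), ..., [e_{n-1}, e_n], the last
    bin closed so the bins cover the full range.  Every site must fall in
    some bin; the union of the returned lists equals the input.
    """
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if on not in ("daf", "k"):
        raise ValueError("stratify on 'daf' or 'k'")
    edges = sorted(edges)
    labels = [f"[{edges[i]},{edges[i + 1]})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]},{edges[-1]}]")
    out: dict[str, list[PolarizedSNV]] = {lbl: [] for lbl in labels}
    for snv in sites:
        x = snv.daf if on == "daf" else snv.k
        if x < edges[0] or x > edges[-1]:
            raise ValueError(f"site {snv.key} value {x} outside bin edges")
        i = min(int(np.searchsorted(edges, x, side="right")) - 1, len(labels) - 1)
        out[labels[i]].append(snv)
    return out
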