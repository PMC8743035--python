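"""Synthetic multi-species variant panels with known mutational signatures.

The generator emulates the data-generating assumptions probed by the
downstream pipeline: each lineage (species) draws its variants from a
mixture of shared trans-acting 96-class signatures with lineage-specific
dosages; genomic compartments may multiply class probabilities by a
cis-acting factor; derived-allele counts follow a neutral 1/k site
frequency spectrum (optionally tilted toward strong alleles to mimic
GC-biased gene conversion); genotypes are drawn exchangeably given the
derived count (Hardy-Weinberg conditional on frequency), with an
optional excess-heterozygosity contamination; and a configurable
fraction of "shared ancestral" variants segregate or are fixed in more
than one genus, exercising the parsimony exclusions.

Outputs are plain-text standard formats (FASTA reference = ancestral
genome, per-compartment BED, VCF v4.2 with GT, tab-separated panel
table) plus a JSON ground-truth record, all deterministic given the
seed (one counter-based Philox stream drives every draw).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import catalog
from .compartments import GenomicCompartment
from .filtering import PanelMetadata

_BASES = np.array(list("ACGT"))
BACKGROUND = "background"


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclasses.dataclass
class SpeciesSpec:
    species: str
    n_diploids: int
    subspecies: str | None = None


@dataclasses.dataclass
class GenusSpec:
    genus: str
    species: list[SpeciesSpec]


@dataclasses.dataclass
class CompartmentSpec:
    """A named compartment covering ``fraction`` of the genome.

    ``cis_multiplier`` (96-vector) multiplies class probabilities for
    variants arising inside the compartment; ``segment_length`` bounds
    the lengths of the segments the compartment is split into.
    """

    name: str
    fraction: float
    cis_multiplier: np.ndarray | None = None
    segment_length: tuple[int, int] = (1_000, 4_000)


@dataclasses.dataclass
class SimulationConfig:
    seed: int
    genera: list[GenusSpec]
    lineage_dosages: dict[str, np.ndarray]  # species -> K_true weights
    true_signatures: np.ndarray  # K_true x 96, rows sum to 1
    compartments: list[CompartmentSpec]
    sequence_length: int = 1_000_000  # total over all chromosomes
    n_chromosomes: int = 2
    n_snvs_per_lineage: int = 10_000
    shared_ancestral_fraction: float = 0.0
    sfs_model: str = "neutral-1/k"
    excess_het_fraction: float = 0.0
    gbgc_shift: float = 0.0
    cpg_enrichment: float = 0.0
    background_segment_length: tuple[int, int] = (2_000, 8_000)

    def validate(self) -> None:
        sig = np.asarray(self.true_signatures, dtype=float)
        if np.any(sig < 0):
            raise ValueError("signature entries must be non-negative")
        if np.any(np.abs(sig.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every signature row must sum to 1")
        if sig.shape[1] != len(catalog.classes(3)):
            raise ValueError("signatures must have 96 columns")
        if self.sequence_length < 10_000:
            raise ValueError("sequence_length must be at least 10 kb")
        frac = sum(c.fraction for c in self.compartments)
        if frac > 1.0 + 1e-9:
            raise ValueError(f"compartment fractions sum to {frac} > 1")
        if not (0 <= self.shared_ancestral_fraction < 1):
            raise ValueError("shared_ancestral_fraction must be in [0, 1)")
        for spec in self.species_specs():
            if spec.species not in self.lineage_dosages:
                raise ValueError(f"no dosages for lineage {spec.species!r}")
            d = np.asarray(self.lineage_dosages[spec.species], dtype=float)
            if d.shape != (sig.shape[0],) or np.any(d < 0) or d.sum() == 0:
                raise ValueError(f"invalid dosage vector for {spec.species!r}")
        for comp in self.compartments:
            if comp.cis_multiplier is not None:
                m = np.asarray(comp.cis_multiplier, dtype=float)
                if m.shape != (sig.shape[1],) or np.any(m < 0):
                    raise ValueError(f"invalid cis multiplier for {comp.name!r}")

    def species_specs(self) -> list[SpeciesSpec]:
        return [s for g in self.genera for s in g.species]

    def genus_of_species(self) -> dict[str, str]:
        return {s.species: g.genus for g in self.genera for s in g.species}

    def panel(self) -> PanelMetadata:
        samples, sub, spp, gen = [], {}, {}, {}
        for g in self.genera:
            for s in g.species:
                for i in range(s.n_diploids):
                    name = f"{s.species}_{i}"
                    samples.append(name)
                    sub[name] = s.subspecies or s.species
                    spp[name] = s.species
                    gen[name] = g.genus
        return PanelMetadata(samples, sub, spp, gen)


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth for one simulated panel.

    ``records`` holds one entry per emitted variant (position, class,
    lineage, compartment, derived count, haplotype total, shared flag);
    ``expected_spectra`` are the realized per-lineage class
    distributions (signature mixture x cis x context availability,
    marginalized over compartments); ``cis_multipliers`` the realized
    per-compartment 96-vectors.
    """

    records: list[dict]
    expected_spectra: dict[str, list[float]]
    mixtures: dict[str, list[float]]
    cis_multipliers: dict[str, list[float]]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=None))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclasses.dataclass
class SimulationResult:
    fasta: Path
    beds: dict[str, Path]
    vcf: Path
    panel_table: Path
    truth_json: Path
    truth: SimulationTruth
    panel: PanelMetadata
    compartments: dict[str, GenomicCompartment]
    sequences: dict[str, str]


# --------------------------------------------------------------------------
# site frequency spectrum
# --------------------------------------------------------------------------


def sfs_sample(
    n_haplotypes: int,
    model: str = "neutral-1/k",
    rng: np.random.Generator | None = None,
    tilt: float = 0.0,
) -> int:
    """Draw a derived-haplotype count k in [1, n-1].

    Under ``neutral-1/k`` the probability of k is proportional to 1/k
    (the standard neutral site frequency spectrum), truncated to
    segregating counts.  ``tilt`` applies an exponential frequency bias
    exp(tilt * k/n), the device used to mimic GC-biased gene conversion
    (positive for weak-to-strong mutations, negative for
    strong-to-weak).
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if model != "neutral-1/k":
        raise ValueError(f"unknown SFS model {model!r}")
    rng = rng if rng is not None else np.random.default_rng()
    k = np.arange(1, n_haplotypes)
    w = np.exp(tilt * k / n_haplotypes) / k
    return int(rng.choice(k, p=w / w.sum()))


def _sfs_probs(n_haplotypes: int, tilt: float) -> np.ndarray:
    k = np.arange(1, n_haplotypes)
    w = np.exp(tilt * k / n_haplotypes) / k
    return w / w.sum()


# --------------------------------------------------------------------------
# genome and compartment layout
# --------------------------------------------------------------------------


def _simulate_reference(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-chromosome base codes, iid uniform with an optional CpG boost."""
    n_chrom = config.n_chromosomes
    L = config.sequence_length // n_chrom
    seqs = {}
    for c in range(n_chrom):
        codes = rng.integers(0, 4, size=L, dtype=np.int8)
        if config.cpg_enrichment > 0:
            n_cpg = int(config.cpg_enrichment * L / 2)
            pos = rng.choice(L - 1, size=n_cpg, replace=False)
            codes[pos] = 1  # C
            codes[pos + 1] = 2  # G
        seqs[f"chr{c + 1}"] = codes
    return seqs


def _layout_compartments(
    config: SimulationConfig,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
) -> tuple[dict[str, GenomicCompartment], dict[str, np.ndarray]]:
    """Segment the genome into the configured compartments plus background.

    Each compartment's genome share is cut into segments with lengths
    drawn from its configured range; segments are shuffled, de-adjacented
    (no two consecutive segments share a compartment, so BED merging
    cannot create oversized segments) and laid out end to end across the
    chromosomes.  Returns the compartments and a per-chromosome array of
    compartment ids per base (-1 = background).
    """
    total = sum(chrom_lengths.values())
    pieces: list[tuple[int, int]] = []  # (comp_id, length)
    for ci, comp in enumerate(config.compartments):
        target = int(round(comp.fraction * total))
        lo, hi = comp.segment_length
        acc = 0
        while acc < target:
            ln = int(rng.integers(lo, hi + 1))
            ln = min(ln, target - acc)
            pieces.append((ci, ln))
            acc += ln
    acc_named = sum(ln for _, ln in pieces)
    lo, hi = config.background_segment_length
    acc = 0
    while acc < total - acc_named:
        ln = int(min(rng.integers(lo, hi + 1), total - acc_named - acc))
        pieces.append((-1, ln))
        acc += ln
    pieces = _interleave(pieces, rng)

    comp_of_pos = {c: np.full(L, -1, dtype=np.int8) for c, L in chrom_lengths.items()}
    intervals: dict[int, dict[str, list[list[int]]]] = {}
    chroms = sorted(chrom_lengths)
    chrom_i, cursor = 0, 0
    for comp_id, ln in pieces:
        while ln > 0 and chrom_i < len(chroms):
            chrom = chroms[chrom_i]
            L = chrom_lengths[chrom]
            take = min(ln, L - cursor)
            if comp_id >= 0 and take > 0:
                intervals.setdefault(comp_id, {}).setdefault(chrom, []).append(
                    [cursor, cursor + take]
                )
                comp_of_pos[chrom][cursor : cursor + take] = comp_id
            cursor += take
            ln -= take
            if cursor >= L:
                chrom_i, cursor = chrom_i + 1, 0
    comps = {}
    for ci, comp in enumerate(config.compartments):
        ivals = {c: np.array(v) for c, v in intervals.get(ci, {}).items()}
        comps[comp.name] = GenomicCompartment(comp.name, ivals)
    return comps, comp_of_pos


def _interleave(
    pieces: list[tuple[int, int]], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Randomized ordering that avoids consecutive same-compartment pieces.

    Greedy scheduling: repeatedly place a piece from the compartment with
    the most remaining pieces among those differing from the previous
    placement (random tie-break).  This keeps BED merging from fusing a
    compartment's segments into oversized runs; when only one compartment
    remains, an occasional adjacency (a single pairwise fusion) is
    tolerated.
    """
    buckets: dict[int, list[tuple[int, int]]] = {}
    for piece in pieces:
        buckets.setdefault(piece[0], []).append(piece)
    for b in buckets.values():
        order = rng.permutation(len(b))
        b[:] = [b[i] for i in order]
    out: list[tuple[int, int]] = []
    prev = None
    while any(buckets.values()):
        candidates = [cid for cid, b in buckets.items() if b and cid != prev]
        if not candidates:
            candidates = [cid for cid, b in buckets.items() if b]
        sizes = np.array([len(buckets[c]) for c in candidates])
        best = sizes.max()
        top = [c for c, s in zip(candidates, sizes) if s == best]
        cid = top[int(rng.integers(len(top)))]
        out.append(buckets[cid].pop())
        prev = cid
    return out


class _PositionPool:
    """Shuffled eligible positions grouped by (compartment, triplet context).

    Positions are consumed sequentially per group, which makes draws
    uniform without replacement across the whole simulation.
    """

    def __init__(self, seqs, comp_of_pos, n_comp, rng):
        chroms = sorted(seqs)
        chrom_ids, positions, keys = [], [], []
        table3 = catalog.collapse_table(3)
        for ci, chrom in enumerate(chroms):
            codes = seqs[chrom].astype(np.int64)
            L = len(codes)
            centers = np.arange(3, L - 3)
            trip = table3[codes[centers - 1] * 16 + codes[centers] * 4 + codes[centers + 1]]
            comp = comp_of_pos[chrom][centers].astype(np.int64)
            chrom_ids.append(np.full(len(centers), ci, dtype=np.int64))
            positions.append(centers)
            keys.append((comp + 1) * 32 + trip)  # background (-1) -> bucket 0
        chrom_ids = np.concatenate(chrom_ids)
        positions = np.concatenate(positions)
        keys = np.concatenate(keys)
        perm = rng.permutation(len(keys))
        order = perm[np.argsort(keys[perm], kind="stable")]
        self.chroms = chroms
        self.chrom_ids = chrom_ids[order]
        self.positions = positions[order]
        sorted_keys = keys[order]
        self.starts = np.searchsorted(sorted_keys, np.arange((n_comp + 1) * 32))
        self.ends = np.searchsorted(sorted_keys, np.arange((n_comp + 1) * 32), side="right")
        self.cursors = self.starts.copy()

    def available(self, n_comp: int) -> np.ndarray:
        """(n_comp + 1, 32) context availability; row 0 is background."""
        return (self.ends - self.starts).reshape(n_comp + 1, 32)

    def take(self, comp_id: int, trip: int, n: int):
        """Next n shuffled (chrom, 0-based position) pairs of a group."""
        key = (comp_id + 1) * 32 + trip
        c = self.cursors[key]
        if c + n > self.ends[key]:
            raise RuntimeError(
                "exhausted eligible positions for context "
                f"{catalog.contexts(3)[trip]!r} in compartment bucket {comp_id}"
            )
        self.cursors[key] = c + n
        sl = slice(c, c + n)
        return [(self.chroms[ci], int(p)) for ci, p in
                zip(self.chrom_ids[sl], self.positions[sl])]


# --------------------------------------------------------------------------
# genotype assembly
# --------------------------------------------------------------------------


def _hwe_genotypes(n_diploids: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Derived-copy counts per sample from k uniformly placed haplotypes."""
    slots = rng.choice(2 * n_diploids, size=k, replace=False)
    counts = np.zeros(n_diploids, dtype=np.int64)
    np.add.at(counts, slots // 2, 1)
    return counts


def _excess_het_genotypes(
    n_diploids: int, rng: np.random.Generator, p_het: float = 0.85
) -> np.ndarray:
    """Pseudo-heterozygous genotypes mimicking a collapsed duplication.

    A cryptic segmental duplication carrying a fixed paralogous variant
    makes most individuals look heterozygous regardless of population
    frequency; each sample is het with probability ``p_het``, clamped so
    the site stays segregating below 0.5 derived frequency.
    """
    het = rng.random(n_diploids) < p_het
    if het.all():
        het[int(rng.integers(n_diploids))] = False
    if not het.any():
        het[int(rng.integers(n_diploids))] = True
    return het.astype(np.int64)


# --------------------------------------------------------------------------
# the generator
# --------------------------------------------------------------------------


def simulate_panel(config: SimulationConfig, outdir: str | Path) -> SimulationResult:
    """Generate reference, compartments, VCF, panel table and ground truth."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.Generator(np.random.Philox(config.seed))

    seqs = _simulate_reference(config, rng)
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    comps, comp_of_pos = _layout_compartments(config, chrom_lengths, rng)
    pool = _PositionPool(seqs, comp_of_pos, len(config.compartments), rng)
    n_comp = len(config.compartments)
    avail = pool.available(n_comp).astype(float)  # row 0 = background

    sig = np.asarray(config.true_signatures, dtype=float)
    ctx_of_class = catalog.class_context_of(3)
    cis = np.ones((n_comp + 1, sig.shape[1]))
    for ci, comp in enumerate(config.compartments):
        if comp.cis_multiplier is not None:
            cis[ci + 1] = np.asarray(comp.cis_multiplier, dtype=float)

    panel = config.panel()
    genus_of = config.genus_of_species()
    species_specs = {s.species: s for s in config.species_specs()}
    samples_by_species = {
        sp: panel.samples_of_species(sp) for sp in species_specs
    }
    sample_index = {s: i for i, s in enumerate(panel.samples)}
    n_samples = len(panel.samples)
    genus_rows = {
        g.genus: np.array([sample_index[s] for s in panel.samples_of_genus(g.genus)])
        for g in config.genera
    }

    mixtures = {}
    expected = {}
    records: list[dict] = []
    variants: list[tuple[str, int, str, str, np.ndarray]] = []  # chrom,p0,ref,alt,copies
    used_mass_warning: list[str] = []

    comp_names = [BACKGROUND] + [c.name for c in config.compartments]

    def class_weight_matrix(mix: np.ndarray) -> np.ndarray:
        W = mix[None, :] * cis * avail[:, ctx_of_class]
        if W.sum() == 0:
            raise RuntimeError("no class has available context anywhere in the genome")
        zero = (W.sum(axis=0) == 0) & (mix > 0)
        if np.any(zero):
            used_mass_warning.append(
                f"classes with mixture mass but zero context availability: "
                f"{[catalog.classes(3)[i] for i in np.flatnonzero(zero)]}"
            )
        return W / W.sum()

    def emit(chrom, p0, class_idx, copies_by_sample, lineage, comp_name, k, n_hap, shared):
        lbl = catalog.classes(3)[class_idx]
        canon_ctx, canon_derived = lbl.split(">")
        ref_code = int(seqs[chrom][p0])
        ancestral = str(_BASES[ref_code])
        if ancestral in "GT":  # reference strand carries the collapsed complement
            derived = catalog.COMPLEMENT[canon_derived]
        else:
            derived = canon_derived
        variants.append((chrom, p0, ancestral, derived, copies_by_sample))
        records.append(
            {
                "chrom": chrom,
                "pos": p0 + 1,
                "class": lbl,
                "class_index": int(class_idx),
                "lineage": lineage,
                "compartment": comp_name,
                "k": int(k),
                "n_hap": int(n_hap),
                "shared": shared,
            }
        )
        return ancestral, derived

    # lineage-specific variants
    for sp_name, spec in species_specs.items():
        mix = np.asarray(config.lineage_dosages[sp_name], dtype=float) @ sig
        mix = mix / mix.sum()
        mixtures[sp_name] = mix
        W = class_weight_matrix(mix)
        expected[sp_name] = W.sum(axis=0) / W.sum()
        counts = rng.multinomial(config.n_snvs_per_lineage, W.ravel()).reshape(W.shape)
        n_dip = spec.n_diploids
        sp_samples = samples_by_species[sp_name]
        sp_rows = np.array([sample_index[s] for s in sp_samples])
        for comp_row in range(n_comp + 1):
            for class_idx in np.flatnonzero(counts[comp_row]):
                n_draw = int(counts[comp_row, class_idx])
                trip = int(ctx_of_class[class_idx])
                places = pool.take(comp_row - 1, trip, n_draw)
                for chrom, p0 in places:
                    # derived count under the (optionally gBGC-tilted) SFS
                    lbl = catalog.classes(3)[int(class_idx)]
                    canon_ctx, canon_d = lbl.split(">")
                    anc = canon_ctx[1]
                    tilt = _gbgc_tilt(anc, canon_d, config.gbgc_shift)
                    k = int(
                        rng.choice(
                            np.arange(1, 2 * n_dip), p=_sfs_probs(2 * n_dip, tilt)
                        )
                    )
                    copies = np.zeros(n_samples, dtype=np.int8)
                    if config.excess_het_fraction > 0 and rng.random() < config.excess_het_fraction:
                        # contamination spans the whole genus, as a collapsed
                        # duplication in the shared reference would
                        g_rows = genus_rows[genus_of[sp_name]]
                        gcounts = _excess_het_genotypes(len(g_rows), rng)
                        copies[g_rows] = gcounts
                        k_site, n_hap_site = int(gcounts.sum()), 2 * len(g_rows)
                    else:
                        copies[sp_rows] = _hwe_genotypes(n_dip, k, rng)
                        k_site, n_hap_site = k, 2 * n_dip
                    emit(
                        chrom, p0, int(class_idx), copies, sp_name,
                        comp_names[comp_row], k_site, n_hap_site, False,
                    )

    # shared ancestral variants: fixed-derived in one genus and segregating
    # in another (probability 1/2), or segregating in both (probability 1/2)
    n_lineage_total = config.n_snvs_per_lineage * len(species_specs)
    f = config.shared_ancestral_fraction
    n_shared = int(round(f / (1 - f) * n_lineage_total)) if f > 0 else 0
    genera = [g.genus for g in config.genera]
    if n_shared > 0 and len(genera) < 2:
        raise ValueError("shared ancestral variants require at least two genera")
    for _ in range(n_shared):
        ga, gb = rng.choice(len(genera), size=2, replace=False)
        ga, gb = genera[ga], genera[gb]
        first_species = next(s for g in config.genera if g.genus == ga for s in g.species)
        mix = mixtures[first_species.species]
        W = class_weight_matrix(mix)
        flat = rng.choice(W.size, p=W.ravel())
        comp_row, class_idx = divmod(int(flat), W.shape[1])
        trip = int(ctx_of_class[class_idx])
        chrom, p0 = pool.take(comp_row - 1, trip, 1)[0]
        copies = np.zeros(n_samples, dtype=np.int8)
        ks = {}
        for genus, mode in ((ga, "first"), (gb, "segregating")):
            g_samples = panel.samples_of_genus(genus)
            g_rows = np.array([sample_index[s] for s in g_samples])
            n_dip_g = len(g_samples)
            if mode == "first" and rng.random() < 0.5:
                copies[g_rows] = 2  # fixed derived
                ks[genus] = 2 * n_dip_g
            else:
                kg = int(rng.choice(np.arange(1, 2 * n_dip_g), p=_sfs_probs(2 * n_dip_g, 0.0)))
                copies[g_rows] = _hwe_genotypes(n_dip_g, kg, rng)
                ks[genus] = kg
        emit(
            chrom, p0, int(class_idx), copies, f"shared:{ga}+{gb}",
            comp_names[comp_row], max(ks.values()), sum(ks.values()), True,
        )

    # ---- write outputs ----------------------------------------------------
    seq_strings = {c: "".join(_BASES[s]) for c, s in seqs.items()}
    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(seq_strings):
            fh.write(f">{chrom}\n")
            s = seq_strings[chrom]
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")

    beds = {}
    for name, comp in comps.items():
        p = outdir / f"compartment_{name}.bed"
        comp.to_bed(p)
        beds[name] = p

    vcf_path = outdir / "panel.vcf"
    _write_vcf(vcf_path, variants, chrom_lengths, panel.samples)

    panel_path = outdir / "panel.tsv"
    panel.to_tsv(panel_path)

    truth = SimulationTruth(
        records=records,
        expected_spectra={k: list(map(float, v)) for k, v in expected.items()},
        mixtures={k: list(map(float, v)) for k, v in mixtures.items()},
        cis_multipliers={
            comp.name: list(map(float, cis[i + 1]))
            for i, comp in enumerate(config.compartments)
        },
        seed=config.seed,
    )
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    if used_mass_warning:
        (outdir / "simulation_warnings.txt").write_text("\n".join(used_mass_warning))

    return SimulationResult(
        fasta=fasta,
        beds=beds,
        vcf=vcf_path,
        panel_table=panel_path,
        truth_json=truth_path,
        truth=truth,
        panel=panel,
        compartments=comps,
        sequences=seq_strings,
    )


def _gbgc_tilt(ancestral: str, derived: str, shift: float) -> float:
    if shift == 0:
        return 0.0
    weak = "AT"
    if ancestral in weak and derived not in weak:
        return shift
    if ancestral not in weak and derived in weak:
        return -shift
    return 0.0


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(path, variants, chrom_lengths, samples) -> None:
    variants = sorted(variants, key=lambda v: (v[0], v[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for chrom, p0, ref, alt, copies in variants:
            gts = "\t".join(_GT[int(c)] for c in copies)
            fh.write(f"{chrom}\t{p0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# --------------------------------------------------------------------------
# ready-made study configuration
# --------------------------------------------------------------------------


def default_signatures(k: int = 3) -> np.ndarray:
    """K fixed, well-separated 96-class signatures (Dirichlet draws).

    Generated once from a fixed internal stream so that the study
    conditions do not move with the simulation seed.
    """
    rng = np.random.default_rng(90210)
    sig = rng.dirichlet(np.full(len(catalog.classes(3)), 0.5), size=k)
    return sig


def standard_config(
    seed: int,
    n_snvs_per_lineage: int = 25_000,
    cis_class: str = "AAG>G",
    cis_factor: float = 2.0,
    **overrides,
) -> SimulationConfig:
    """The package's reference study: 2 genera x 2 species, 9 diploids each.

    Three trans-acting signatures with species-distinct dosages, a
    neutral baseline compartment (half the genome, long segments so it
    can host length-matched bootstrap placements) and a cis-perturbed
    compartment in which one class's rate is multiplied by
    ``cis_factor``.  The default perturbed class carries substantial
    mass in every lineage's mixture, so its baseline rate is well
    measured.
    """
    sig = default_signatures(3)
    cis = np.ones(len(catalog.classes(3)))
    cis[catalog.class_index(3)[cis_class]] = cis_factor
    genera = [
        GenusSpec("GenusA", [SpeciesSpec("speciesA1", 9), SpeciesSpec("speciesA2", 9)]),
        GenusSpec("GenusB", [SpeciesSpec("speciesB1", 9), SpeciesSpec("speciesB2", 9)]),
    ]
    dosages = {
        "speciesA1": np.array([0.60, 0.25, 0.15]),
        "speciesA2": np.array([0.45, 0.40, 0.15]),
        "speciesB1": np.array([0.15, 0.25, 0.60]),
        "speciesB2": np.array([0.15, 0.45, 0.40]),
    }
    compartments = [
        CompartmentSpec("baseline", 0.50, None, segment_length=(8_000, 16_000)),
        CompartmentSpec("ciscomp", 0.20, cis, segment_length=(1_000, 3_000)),
    ]
    kwargs = dict(
        seed=seed,
        genera=genera,
        lineage_dosages=dosages,
        true_signatures=sig,
        compartments=compartments,
        sequence_length=2_000_000,
        n_chromosomes=2,
        n_snvs_per_lineage=n_snvs_per_lineage,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
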