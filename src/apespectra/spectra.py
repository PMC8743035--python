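"""Mutation spectra of individuals and species.

A spectrum is a vector of counts (or frequencies) over the 96
strand-collapsed triplet mutation classes (24,576 at 7-mer
resolution).  Three constructions are provided:

* species spectra: every site segregating within the species counts
  once, regardless of frequency;
* individual spectra: each derived allele carried by the individual
  counts once per haplotype (homozygous derived = 2, heterozygous = 1),
  so the spectrum is the average over the two phased haplotypes;
* randomized spectra: each site is credited to exactly one uniformly
  chosen carrier haplotype, which removes the covariance between
  individuals induced by shared (identical-by-descent) derived alleles
  while preserving the covariance from independent mutations of the
  same class.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog
from .compartments import GenomicCompartment
from .filtering import PanelMetadata, PolarizedSNV


@dataclasses.dataclass
class SpectrumVector:
    """Counts or frequencies over the canonical mutation-class order."""

    values: np.ndarray
    order: int = 3
    unit: str = "count"  # "count" | "frequency"
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(catalog.classes(self.order))
        if self.values.shape != (n,):
            raise ValueError(f"expected {n} classes for order {self.order}")
        if np.any(self.values < 0):
            raise ValueError("spectrum values must be non-negative")
        if self.unit == "frequency" and self.values.sum() > 0:
            if abs(self.values.sum() - 1.0) > 1e-9:
                raise ValueError("frequency spectrum does not sum to 1")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def frequencies(self) -> "SpectrumVector":
        """Normalized copy; empty spectra are undefined and raise."""
        if self.total == 0:
            raise ValueError("frequency spectrum undefined for an empty spectrum")
        return SpectrumVector(
            self.values / self.total, self.order, "frequency", dict(self.provenance)
        )

    def labels(self) -> tuple[str, ...]:
        return catalog.classes(self.order)


def site_class(snv: PolarizedSNV, order: int = 3) -> int:
    ctx = snv.context3 if order == 3 else snv.context7
    return catalog.class_of(ctx, snv.derived)


def sites_in_compartment(
    sites: list[PolarizedSNV], compartment: GenomicCompartment
) -> list[PolarizedSNV]:
    """Subset of sites whose (0-based) position lies inside the compartment."""
    by_chrom: dict[str, list[PolarizedSNV]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    out = []
    for chrom, group in by_chrom.items():
        pos = np.array([s.pos - 1 for s in group])
        mask = compartment.membership(chrom, pos)
        out.extend(s for s, m in zip(group, mask) if m)
    return out


def _species_k(snv: PolarizedSNV, panel: PanelMetadata, species: str) -> tuple[int, int]:
    """Derived haplotype count and 2N restricted to one species."""
    k = sum(c for s, c in snv.sample_copies.items() if panel.species_of[s] == species)
    return k, panel.haplotypes_of_species(species)


def species_spectrum(
    sites: list[PolarizedSNV],
    panel: PanelMetadata,
    species: str,
    order: int = 3,
    compartment_name: str = "",
) -> SpectrumVector:
    """Aggregate spectrum: one count per site segregating within the species."""
    values = np.zeros(len(catalog.classes(order)))
    for snv in sites:
        k, n_hap = _species_k(snv, panel, species)
        if 1 <= k <= n_hap - 1:  # segregating within this species
            values[site_class(snv, order)] += 1
    return SpectrumVector(
        values, order, "count",
        {"id": species, "level": "species", "compartment": compartment_name, "mode": "aggregate"},
    )


def individual_spectrum(
    sites: list[PolarizedSNV],
    sample: str,
    panel: PanelMetadata,
    order: int = 3,
    compartment_name: str = "",
) -> SpectrumVector:
    """Per-individual spectrum; hom-derived sites carry twice the het weight."""
    if sample not in panel.samples:
        raise KeyError(f"sample {sample!r} not in panel")
    values = np.zeros(len(catalog.classes(order)))
    for snv in sites:
        copies = snv.sample_copies.get(sample, 0)
        if copies:
            values[site_class(snv, order)] += copies
    return SpectrumVector(
        values, order, "count",
        {"id": sample, "level": "individual", "compartment": compartment_name, "mode": "full"},
    )


def randomized_spectrum(
    sites: list[PolarizedSNV],
    panel: PanelMetadata,
    rng: np.random.Generator,
    order: int = 3,
    compartment_name: str = "",
) -> dict[str, SpectrumVector]:
    """Credit each site to one uniformly chosen carrier haplotype.

    A heterozygous carrier owns 1 of the k derived haplotypes and is
    selected with probability 1/k; a homozygous carrier owns 2 and is
    selected with probability 2/k.  Summing the returned vectors over
    samples reproduces the per-site count vector exactly.
    """
    n_classes = len(catalog.classes(order))
    out = {s: np.zeros(n_classes) for s in panel.samples}
    for snv in sites:
        carriers = [s for s in panel.samples if s in snv.sample_copies]
        if not carriers:
            raise ValueError(f"site {snv.key} has no carriers in the panel")
        weights = np.array([snv.sample_copies[s] for s in carriers], dtype=float)
        chosen = carriers[_weighted_pick(weights, rng)]
        out[chosen][site_class(snv, order)] += 1
    return {
        s: SpectrumVector(
            v, order, "count",
            {"id": s, "level": "individual", "compartment": compartment_name,
             "mode": "randomized"},
        )
        for s, v in out.items()
    }


def _weighted_pick(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Pick an index with probability proportional to integer weights."""
    cum = np.cumsum(weights)
    u = rng.integers(int(cum[-1]))
    return int(np.searchsorted(cum, u, side="right"))


def subsample_individuals(
    panel: PanelMetadata, n_per_species: int, rng: np.random.Generator
) -> PanelMetadata:
    """Uniform without-replacement subsample of individuals per species."""
    keep = []
    for species in panel.species:
        samples = panel.samples_of_species(species)
        if n_per_species > len(samples):
            raise ValueError(
                f"requested {n_per_species} individuals from species {species!r} "
                f"with only {len(samples)}"
            )
        idx = rng.choice(len(samples), size=n_per_species, replace=False)
        keep.extend(samples[i] for i in sorted(idx))
    return panel.subset(keep)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def spectra_to_frame(spectra: list[SpectrumVector]) -> pd.DataFrame:
    """Classes (canonical order) as rows, one column per spectrum."""
    if not spectra:
        raise ValueError("no spectra to serialize")
    order = spectra[0].order
    if any(s.order != order for s in spectra):
        raise ValueError("mixed context orders")
    cols = {}
    for i, s in enumerate(spectra):
        name = s.provenance.get("id", f"spectrum{i}")
        comp = s.provenance.get("compartment", "")
        cols[f"{name}|{comp}" if comp else name] = s.values
    return pd.DataFrame(cols, index=list(catalog.classes(order)))


def write_spectra(
    spectra: list[SpectrumVector], path: str | Path, seed: int | None = None
) -> None:
    """TSV (classes x spectra) plus a JSON provenance sidecar."""
    path = Path(path)
    spectra_to_frame(spectra).to_csv(path, sep="\t", index_label="class")
    sidecar = {
        "seed": seed,
        "unit": spectra[0].unit,
        "order": spectra[0].order,
        "spectra": [s.provenance for s in spectra],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_spectra(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="class")
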