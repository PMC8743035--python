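import numpy as np
import pytest

import apespectra as ap


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Small simulated panel for fast structural tests."""
    cfg = ap.standard_config(11, n_snvs_per_lineage=2_000)
    return ap.simulate_panel(cfg, tmp_path_factory.mktemp("small_sim"))


@pytest.fixture(scope="session")
def small_kept(small_sim):
    kept, dispositions, tally = ap.polarize_and_filter(
        small_sim.vcf, small_sim.panel, small_sim.sequences
    )
    return kept, dispositions, tally


@pytest.fixture(scope="session")
def standard_sim(tmp_path_factory):
    """The reference study: 2 genera x 2 species, 9 diploids, 1e5 variants."""
    cfg = ap.standard_config(101, n_snvs_per_lineage=25_000)
    return ap.simulate_panel(cfg, tmp_path_factory.mktemp("standard_sim"))


@pytest.fixture(scope="session")
def standard_kept(standard_sim):
    kept, _, tally = ap.polarize_and_filter(
        standard_sim.vcf, standard_sim.panel, standard_sim.sequences
    )
    return kept, tally


def make_snv(
    chrom="chr1",
    pos=100,
    ancestral="A",
    derived="G",
    genus="GenusA",
    species="speciesA1",
    k=2,
    n_hap=18,
    context7="AAAAAAA",
    sample_copies=None,
    genotype_counts=None,
    derived_elsewhere=False,
):
    """Hand-built polarized site for unit tests."""
    context7 = context7[:3] + ancestral + context7[4:]
    if sample_copies is None:
        sample_copies = {f"{species}_{i}": 1 for i in range(k)}
    if genotype_counts is None:
        n_het = sum(1 for c in sample_copies.values() if c == 1)
        n_hom = sum(1 for c in sample_copies.values() if c == 2)
        genotype_counts = (n_hap // 2 - n_het - n_hom, n_het, n_hom)
    return ap.PolarizedSNV(
        chrom=chrom,
        pos=pos,
        ancestral=ancestral,
        derived=derived,
        genus=genus,
        species=species,
        k=k,
        n_hap=n_hap,
        context3=context7[2:5],
        context7=context7,
        sample_copies=sample_copies,
        genotype_counts=genotype_counts,
        derived_elsewhere=derived_elsewhere,
    )


def tiny_panel(n=4, species="speciesA1", genus="GenusA"):
    samples = [f"{species}_{i}" for i in range(n)]
    return ap.PanelMetadata(
        samples,
        {s: species for s in samples},
        {s: species for s in samples},
        {s: genus for s in samples},
    )
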