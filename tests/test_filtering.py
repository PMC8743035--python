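"""Parsimony polarization, HWE exact test, and the filter cascade."""

import numpy as np
import pytest

import apespectra as ap
from apespectra.filtering import (
    SiteDisposition,
    apply_site_filters,
    frequency_stratified_subset,
    hwe_excess_het_test,
    polarize_by_parsimony,
)

from conftest import make_snv


def four_genus_panel(n_per=2):
    samples, sub, spp, gen = [], {}, {}, {}
    for g in ("Homo", "Pan", "Gorilla", "Pongo"):
        for i in range(n_per):
            s = f"{g.lower()}_{i}"
            samples.append(s)
            sub[s] = spp[s] = g.lower()
            gen[s] = g
    return ap.PanelMetadata(samples, sub, spp, gen)


REF = {"chr1": "ACGTACGTACGTACGTACGT"}


def gts(*pairs):
    return np.array(pairs)


def test_polarized_to_allele_fixed_in_other_genera():
    panel = four_genus_panel()
    # rows follow panel.samples order (Homo x2, Pan x2, Gorilla x2, Pongo x2):
    # Homo segregates A/G, everyone else fixed A
    g = gts([0, 1], [0, 1], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0])
    snv = polarize_by_parsimony("chr1", 10, ["A", "G"], g, panel, REF)
    assert snv.ancestral == "A" and snv.derived == "G"
    assert snv.genus == "Homo" and snv.k == 2 and snv.n_hap == 4
    assert snv.context3[1] == "A"


def test_excluded_when_segregating_in_two_genera():
    panel = four_genus_panel()
    g = gts([0, 1], [0, 0], [0, 1], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0])
    disp = polarize_by_parsimony("chr1", 10, ["A", "G"], g, panel, REF)
    assert isinstance(disp, SiteDisposition)
    assert disp.reason == "multi-genus-segregating"


def test_excluded_on_multiple_fixed_alleles():
    panel = four_genus_panel()
    # Homo segregates; Pan fixed ALT, Gorilla/Pongo fixed REF
    g = gts([0, 1], [0, 0], [1, 1], [1, 1], [0, 0], [0, 0], [0, 0], [0, 0])
    disp = polarize_by_parsimony("chr1", 10, ["A", "G"], g, panel, REF)
    assert disp.reason == "multiple-fixed-alleles"


def test_polarization_flips_when_outgroups_fix_the_alt():
    panel = four_genus_panel()
    # all outgroups fixed for the ALT allele: ALT becomes ancestral
    g = gts([0, 0], [0, 1], [1, 1], [1, 1], [1, 1], [1, 1], [1, 1], [1, 1])
    snv = polarize_by_parsimony("chr1", 10, ["A", "G"], g, panel, REF)
    assert snv.ancestral == "G" and snv.derived == "A"
    assert snv.k == 3  # three A haplotypes are now the derived ones
    assert snv.context3[1] == "G"


def test_multiallelic_and_missingness_and_monomorphic():
    panel = four_genus_panel()
    g0 = gts([0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0])
    assert polarize_by_parsimony("chr1", 10, ["A", "G"], g0, panel, REF).reason == "monomorphic"
    g3 = gts([0, 1], [0, 2], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0])
    assert (
        polarize_by_parsimony("chr1", 10, ["A", "G", "T"], g3, panel, REF).reason
        == ">2-alleles-in-genus"
    )
    gm = gts([0, 1], [-1, -1], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0])
    assert polarize_by_parsimony("chr1", 10, ["A", "G"], gm, panel, REF).reason == "missingness"
    # with a permissive threshold the same site is polarized
    snv = polarize_by_parsimony(
        "chr1", 10, ["A", "G"], gm, panel, REF, missingness_threshold=0.5
    )
    assert snv.k == 1 and snv.n_hap == 2


# ---------------------------------------------------------------- HWE


def _hwe_oracle_tables(n_diploids):
    """Exhaustive enumeration of haplotype->genotype configurations.

    All 2^(2n) derived/ancestral haplotype assignments are enumerated with
    bit arithmetic; conditioning on the derived-allele count makes each
    assignment equally likely, giving the exact conditional distribution of
    the heterozygote count fully independently of the analytic formula.
    """
    m = 2 * n_diploids
    x = np.arange(1 << m, dtype=np.uint64)
    n_derived = np.bitwise_count(x)
    pair_mask = np.uint64(sum(1 << (2 * i) for i in range(n_diploids)))
    hets = np.bitwise_count((x ^ (x >> np.uint64(1))) & pair_mask)
    table = {}
    for na in range(m + 1):
        sel = hets[n_derived == na]
        h_vals, h_counts = np.unique(sel, return_counts=True)
        table[na] = dict(zip(h_vals.astype(int), h_counts.astype(int)))
    return table


@pytest.mark.parametrize("n_diploids", [1, 2, 3, 5])
def test_hwe_matches_bitwise_enumeration(n_diploids):
    oracle = _hwe_oracle_tables(n_diploids)
    for n_aa in range(n_diploids + 1):
        for n_het in range(n_diploids - n_aa + 1):
            n_AA = n_diploids - n_aa - n_het
            na = n_het + 2 * n_aa
            dist = oracle[na]
            total = sum(dist.values())
            p_oracle = sum(c for h, c in dist.items() if h >= n_het) / total
            p = hwe_excess_het_test(n_AA, n_het, n_aa)
            assert abs(p - p_oracle) < 1e-12


def test_hwe_trivial_cases():
    assert hwe_excess_het_test(0, 0, 5) == 1.0
    assert hwe_excess_het_test(5, 0, 0) == 1.0
    # 2 diploids, 2 derived alleles: h in {0, 2} with weights 2 and 4
    assert hwe_excess_het_test(0, 2, 0) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        hwe_excess_het_test(0, 0, 0)


# ---------------------------------------------------------------- cascade


def test_cascade_stated_rules():
    assert apply_site_filters(make_snv(k=1, sample_copies={"s": 1})).reason == "singleton"
    snv = make_snv(k=9, n_hap=18, sample_copies={f"s{i}": 1 for i in range(9)})
    assert apply_site_filters(snv).reason == "DAF>=0.5"  # 0.5 exactly is excluded
    assert apply_site_filters(make_snv(k=3), use_doubletons_only=True).reason == "not-doubleton"
    assert apply_site_filters(make_snv(k=2), use_doubletons_only=True).verdict == "kept"
    assert apply_site_filters(make_snv(derived_elsewhere=True)).reason == "recurrent"


def test_cascade_N_context_depends_on_order():
    snv = make_snv(context7="NNAAANN")
    assert apply_site_filters(snv, context_order=3).verdict == "kept"
    assert apply_site_filters(snv, context_order=7).reason == "N-context"


def test_cascade_hwe_exclusion():
    # 10 of 12 diploids heterozygous (DAF < 0.5): excess heterozygosity
    snv = make_snv(
        k=10, n_hap=24,
        sample_copies={f"s{i}": 1 for i in range(10)},
        genotype_counts=(2, 10, 0),
    )
    assert hwe_excess_het_test(*snv.genotype_counts) < 0.05
    assert apply_site_filters(snv).reason == "HWE-excess-het"


def test_cascade_partition_and_idempotence(small_sim, small_kept):
    kept, dispositions, tally = small_kept
    assert len(dispositions) == len(small_sim.truth.records)
    n_excluded = sum(1 for d in dispositions if d.verdict == "excluded")
    assert sum(tally.values()) == n_excluded
    assert n_excluded + len(kept) == len(dispositions)
    # re-filtering kept sites changes nothing
    assert all(apply_site_filters(s).verdict == "kept" for s in kept)


# ----------------------------------------------------- stratification


def test_stratification_partitions():
    sites = [make_snv(k=k, sample_copies={f"s{i}": 1 for i in range(k)}) for k in (2, 3, 5, 8)]
    bins = frequency_stratified_subset(sites, [0, 0.5], on="daf")
    assert sum(len(v) for v in bins.values()) == len(sites)
    kbins = frequency_stratified_subset(sites, [2, 3, 17], on="k")
    assert len(kbins["[2,3)"]) == 1 and len(kbins["[3,17]"]) == 3
    with pytest.raises(ValueError):
        frequency_stratified_subset(sites, [2], on="k")


def test_gbgc_shift_raises_high_frequency_weak_to_strong(tmp_path):
    """Strong-favoring transmission bias shows up in the frequency strata."""
    cfg = ap.standard_config(17, n_snvs_per_lineage=4_000, gbgc_shift=3.0)
    res = ap.simulate_panel(cfg, tmp_path / "gbgc")
    kept, _, _ = ap.polarize_and_filter(res.vcf, res.panel, res.sequences)

    def ws_fraction(sites):
        ws = sum(1 for s in sites if s.ancestral in "AT" and s.derived in "GC")
        sw = sum(1 for s in sites if s.ancestral in "GC" and s.derived in "AT")
        return ws / max(ws + sw, 1)

    low = [s for s in kept if s.k <= 3]
    high = [s for s in kept if s.k > 6]
    assert ws_fraction(high) > ws_fraction(low)
    # mean derived count is higher for weak->strong than strong->weak
    mean_k = lambda pred: np.mean([s.k for s in kept if pred(s)])  # noqa: E731
    assert mean_k(lambda s: s.ancestral in "AT" and s.derived in "GC") > mean_k(
        lambda s: s.ancestral in "GC" and s.derived in "AT"
    )
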