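"""Interval algebra, k-mer content counting, bootstrap and timing quartiles."""

import numpy as np
import pytest
from scipy.stats import chisquare

from apespectra import catalog
from apespectra.compartments import (
    ContextContent,
    GenomicCompartment,
    bootstrap_ervlike,
    combine_compartments,
    compartment_content,
    count_context_in_segment,
    merge_intervals,
    replication_timing_quartiles,
)


def comp(name, **ivals):
    return GenomicCompartment(name, {c: np.array(v) for c, v in ivals.items()})


# ---------------------------------------------------------------- content


def test_content_hand_enumeration():
    """'AACGT' slides windows AAC, ACG, CGT; CGT collapses onto ACG."""
    counts = count_context_in_segment("AACGT", 3)
    content = {c: int(n) for c, n in zip(catalog.contexts(3), counts) if n}
    assert content == {"AAC": 1, "ACG": 2}


def test_content_short_segment_and_N():
    assert count_context_in_segment("AC", 3).sum() == 0
    # windows touching the N contribute nothing
    assert count_context_in_segment("ANAAA", 3).sum() == 1  # only AAA


def test_content_conservation_and_bounds():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=500))
    ref = {"chr1": seq}
    c = comp("x", chr1=[[10, 60], [100, 101], [200, 300]])
    content = compartment_content(ref, c, 3)
    n_windows_max = sum(max(e - s - 2, 0) for s, e in c.intervals["chr1"])
    assert content.n_windows <= n_windows_max
    # manual window count excluding N
    manual = 0
    for s, e in c.intervals["chr1"]:
        for i in range(s, e - 2):
            if "N" not in seq[i : i + 3]:
                manual += 1
    assert content.n_windows == manual


def test_content_reverse_complement_invariant():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    rc = catalog.revcomp(seq)
    c_fwd = compartment_content({"chr1": seq}, comp("f", chr1=[[0, 400]]), 3)
    c_rev = compartment_content({"chr1": rc}, comp("r", chr1=[[0, 400]]), 3)
    assert np.array_equal(c_fwd.counts, c_rev.counts)
    c7f = compartment_content({"chr1": seq}, comp("f", chr1=[[0, 400]]), 7)
    c7r = compartment_content({"chr1": rc}, comp("r", chr1=[[0, 400]]), 7)
    assert np.array_equal(c7f.counts, c7r.counts)


def test_content_rejects_out_of_bounds():
    with pytest.raises(ValueError):
        compartment_content({"chr1": "ACGT"}, comp("x", chr1=[[0, 10]]), 3)


# ---------------------------------------------------------------- algebra


def test_algebra_trivial_identities():
    a = comp("a", chr1=[[0, 10]])
    b = comp("b", chr1=[[5, 15]])
    assert combine_compartments(a, a, "subtract").total_length == 0
    inter = combine_compartments(a, b, "intersect")
    assert inter.intervals["chr1"].tolist() == [[5, 10]]


def test_algebra_matches_per_base_oracle():
    """100 random small interval sets vs a per-base membership oracle."""
    rng = np.random.default_rng(42)
    L = 60
    for _ in range(100):
        def rand_comp(name):
            n = rng.integers(1, 5)
            starts = rng.integers(0, L - 1, size=n)
            ends = starts + rng.integers(1, 12, size=n)
            return comp(name, chr1=np.column_stack([starts, np.minimum(ends, L)]))

        a, b = rand_comp("a"), rand_comp("b")
        mask_a = np.zeros(L, dtype=bool)
        mask_b = np.zeros(L, dtype=bool)
        for s, e in a.intervals["chr1"]:
            mask_a[s:e] = True
        for s, e in b.intervals["chr1"]:
            mask_b[s:e] = True
        for mode, oracle in (
            ("union", mask_a | mask_b),
            ("intersect", mask_a & mask_b),
            ("subtract", mask_a & ~mask_b),
        ):
            got = combine_compartments(a, b, mode)
            got_mask = np.zeros(L, dtype=bool)
            for s, e in got.intervals.get("chr1", []):
                got_mask[s:e] = True
            assert np.array_equal(got_mask, oracle), mode
            # merged and sorted
            iv = got.intervals.get("chr1", np.zeros((0, 2), int))
            assert np.all(np.diff(iv[:, 0]) > 0) if len(iv) > 1 else True
            assert all(iv[i, 1] < iv[i + 1, 0] for i in range(len(iv) - 1))


def test_merge_intervals_drops_empty_and_merges_adjacent():
    out = merge_intervals(np.array([[5, 5], [0, 3], [3, 6], [10, 12]]))
    assert out.tolist() == [[0, 6], [10, 12]]


# ---------------------------------------------------------------- bootstrap


def _lengths(c):
    return sorted(
        (chrom, int(e - s)) for chrom, s, e in c.segments()
    )


def _raw_lengths(c):
    out = []
    for chrom, arr in c.intervals.items():
        out += [(chrom, int(e - s)) for s, e in arr]
    return sorted(out)


def test_bootstrap_preserves_length_multiset_and_background():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    ref = {"chr1": seq}
    background = comp("bg", chr1=[[0, 900], [1000, 2000]])
    target = comp("t", chr1=[[10, 20], [30, 80], [100, 103]])
    reps = bootstrap_ervlike(target, background, ref, n_reps=20, rng=rng)
    assert len(reps) == 20
    for rep in reps:
        assert _raw_lengths(rep) == _raw_lengths(target)
        for chrom, s, e in rep.segments():
            assert background.membership(chrom, np.arange(s, e)).all()


def test_bootstrap_background_equals_target_stays_inside():
    rng = np.random.default_rng(6)
    ref = {"chr1": "ACGT" * 100}
    target = comp("t", chr1=[[40, 60]])
    reps = bootstrap_ervlike(target, target, ref, n_reps=5, rng=rng)
    for rep in reps:
        (s, e), = rep.intervals["chr1"]
        assert 40 <= s and e <= 60 and e - s == 20


def test_bootstrap_avoids_N_and_fails_when_impossible():
    rng = np.random.default_rng(7)
    ref = {"chr1": "A" * 50 + "N" * 10 + "A" * 40}
    background = comp("bg", chr1=[[0, 100]])
    target = comp("t", chr1=[[0, 8]])
    reps = bootstrap_ervlike(target, background, ref, n_reps=30, rng=rng)
    for rep in reps:
        (s, e), = rep.intervals["chr1"]
        assert "N" not in ref["chr1"][s:e]
    all_n = {"chr1": "N" * 100}
    with pytest.raises(RuntimeError):
        bootstrap_ervlike(target, background, all_n, n_reps=1, rng=rng)


def test_bootstrap_placement_uniform_over_eligible_starts():
    """Placed starts are uniform over the eligible-start enumeration."""
    rng = np.random.default_rng(8)
    ref = {"chr1": "A" * 100}
    background = comp("bg", chr1=[[0, 40], [60, 90]])
    target = comp("t", chr1=[[0, 10]])
    # eligible starts: 0..30 within [0,40), 60..80 within [60,90) -> 52 slots
    eligible = list(range(0, 31)) + list(range(60, 81))
    counts = {s: 0 for s in eligible}
    reps = bootstrap_ervlike(target, background, ref, n_reps=10_000, rng=rng)
    for rep in reps:
        (s, _), = rep.intervals["chr1"]
        counts[s] += 1
    stat, p = chisquare(list(counts.values()))
    assert p > 0.01


# ------------------------------------------------------- timing quartiles


def test_timing_quartiles_forced_and_percentile():
    lengths = {"chr1": 80_000}
    timing = [("chr1", i * 20_000 + 500, i * 20_000 + 600, v)
              for i, v in enumerate([1.0, 2.0, 3.0, 4.0])]
    early, late = replication_timing_quartiles(timing, lengths)
    assert early.intervals["chr1"].tolist() == [[0, 20_000]]
    assert late.intervals["chr1"].tolist() == [[60_000, 80_000]]


def test_timing_quartiles_fraction_with_random_means():
    rng = np.random.default_rng(9)
    n = 1000
    lengths = {"chr1": n * 20_000}
    timing = [("chr1", i * 20_000 + 1, i * 20_000 + 2, float(rng.random()))
              for i in range(n)]
    early, late = replication_timing_quartiles(timing, lengths)
    # adjacent chosen windows merge, so compare covered length (window count)
    assert abs(early.total_length / 20_000 - n / 4) <= 1
    assert abs(late.total_length / 20_000 - n / 4) <= 1


def test_timing_quartiles_tie_rule_and_empty():
    lengths = {"chr1": 80_000}
    timing = [("chr1", i * 20_000, i * 20_000 + 5, 1.0) for i in range(4)]
    early, late = replication_timing_quartiles(timing, lengths)
    # all means equal: first ceil(n/4) windows in start order on both sides
    assert early.intervals["chr1"].tolist() == [[0, 20_000]]
    assert late.intervals["chr1"].tolist() == [[0, 20_000]]
    with pytest.raises(ValueError):
        replication_timing_quartiles([], lengths)


def test_context_content_key_bounds():
    c = ContextContent(order=3, counts=np.zeros(32, dtype=int))
    assert len(c.as_dict()) == 0
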