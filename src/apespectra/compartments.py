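"""Genomic compartments: interval algebra, k-mer content, and interval bootstraps.

A compartment is a named set of genomic intervals (BED dialect: 0-based,
half-open) sharing an annotation, e.g. the latest-replicating quartile of
the genome or a repeat class.  This module provides the interval
arithmetic needed to build compartments from annotations, the sliding
window k-mer content counts used for mutation-rate normalization, a
length-preserving placement bootstrap that builds matched null
compartments inside a background compartment, and replication-timing
quartile construction from windowed timing measurements.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from pathlib import Path

import numpy as np

from . import catalog

# --------------------------------------------------------------------------
# compartments and interval algebra
# --------------------------------------------------------------------------


@dataclasses.dataclass
class GenomicCompartment:
    """Named set of 0-based half-open intervals, per chromosome.

    Intervals are normalized on construction: sorted by start and merged
    where overlapping or adjacent, so downstream window counting never
    double-counts.
    """

    name: str
    intervals: dict[str, np.ndarray]  # chrom -> (n, 2) int array

    def __post_init__(self) -> None:
        norm = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if np.any(arr[:, 1] < arr[:, 0]) or np.any(arr < 0):
                raise ValueError(f"invalid interval in compartment {self.name!r} on {chrom}")
            norm[chrom] = merge_intervals(arr)
        self.intervals = norm

    @property
    def total_length(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values()))

    def segments(self):
        """Yield (chrom, start, end) over all merged segments."""
        for chrom in sorted(self.intervals):
            for start, end in self.intervals[chrom]:
                yield chrom, int(start), int(end)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a single 0-based position."""
        arr = self.intervals.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        i = np.searchsorted(arr[:, 0], pos, side="right") - 1
        return i >= 0 and pos < arr[i, 1]

    def membership(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership of 0-based positions on one chromosome."""
        positions = np.asarray(positions)
        arr = self.intervals.get(chrom)
        if arr is None or len(arr) == 0:
            return np.zeros(len(positions), dtype=bool)
        i = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < arr[i[ok], 1]
        return out

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "GenomicCompartment":
        path = Path(path)
        ivals: dict[str, list[list[int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                ivals.setdefault(chrom, []).append([int(start), int(end)])
        arrays = {c: np.array(v, dtype=np.int64) for c, v in ivals.items()}
        return cls(name or path.stem, arrays)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.segments():
                fh.write(f"{chrom}\t{start}\t{end}\n")


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent half-open intervals."""
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    arr = arr[arr[:, 1] > arr[:, 0]]
    if len(arr) == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return np.array(out, dtype=np.int64)


def _intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append([lo, hi])
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < end:
            if b[k, 0] > cur:
                out.append([cur, b[k, 0]])
            cur = max(cur, b[k, 1])
            k += 1
        if cur < end:
            out.append([cur, end])
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def combine_compartments(
    a: GenomicCompartment,
    b: GenomicCompartment,
    mode: str,
    name: str | None = None,
) -> GenomicCompartment:
    """Half-open interval algebra: ``intersect``, ``subtract`` or ``union``."""
    if mode not in ("intersect", "subtract", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    chroms = set(a.intervals) | set(b.intervals)
    empty = np.zeros((0, 2), dtype=np.int64)
    out = {}
    for chrom in chroms:
        ia = a.intervals.get(chrom, empty)
        ib = b.intervals.get(chrom, empty)
        if mode == "union":
            out[chrom] = merge_intervals(np.vstack([ia, ib]))
        elif mode == "intersect":
            out[chrom] = _intersect(ia, ib)
        else:
            out[chrom] = _subtract(ia, ib)
    return GenomicCompartment(name or f"{a.name}_{mode}_{b.name}", out)


# --------------------------------------------------------------------------
# k-mer content
# --------------------------------------------------------------------------


@dataclasses.dataclass
class ContextContent:
    """Strand-collapsed k-mer context counts for one compartment.

    ``counts`` is aligned to :func:`apespectra.catalog.contexts` (32 keys at
    order 3, 8,192 at order 7).  ``n_windows`` is the number of counted
    windows, i.e. windows lying wholly inside a segment and free of N.
    """

    order: int
    counts: np.ndarray
    compartment: str = ""

    @property
    def n_windows(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(catalog.contexts(self.order), self.counts) if n}


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Sequence slice [start, end) from a pyfaidx Fasta or a plain mapping."""
    if isinstance(reference, Mapping):
        return str(reference[chrom][start:end])
    return str(reference[chrom][start:end])  # pyfaidx Fasta shares the slice API


def _chrom_length(reference, chrom: str) -> int:
    return len(reference[chrom])


def count_context_in_segment(seq: str, order: int) -> np.ndarray:
    """Collapsed context counts of all full windows inside one segment."""
    codes = catalog.encode_sequence(seq).astype(np.int64)
    n = len(codes) - order + 1
    counts = np.zeros(len(catalog.contexts(order)), dtype=np.int64)
    if n <= 0:
        return counts
    # base-4 rolling code over windows; windows touching an N are dropped
    kmer = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(order):
        col = codes[j : j + n]
        bad |= col == 4
        kmer = kmer * 4 + np.where(col == 4, 0, col)
    kmer = kmer[~bad]
    idx = catalog.collapse_table(order)[kmer]
    np.add.at(counts, idx, 1)
    return counts


def compartment_content(reference, compartment: GenomicCompartment, order: int) -> ContextContent:
    """Sliding-window (1 bp step) collapsed k-mer content of a compartment.

    Only windows lying wholly inside a single segment count; windows
    containing N are excluded.
    """
    counts = np.zeros(len(catalog.contexts(order)), dtype=np.int64)
    for chrom, start, end in compartment.segments():
        if end > _chrom_length(reference, chrom):
            raise ValueError(
                f"interval {chrom}:{start}-{end} exceeds chromosome length "
                f"{_chrom_length(reference, chrom)}"
            )
        counts += count_context_in_segment(_fetch(reference, chrom, start, end), order)
    return ContextContent(order=order, counts=counts, compartment=compartment.name)


# --------------------------------------------------------------------------
# length-preserving placement bootstrap ("ERV-like" null compartments)
# --------------------------------------------------------------------------


def bootstrap_ervlike(
    target: GenomicCompartment,
    background: GenomicCompartment,
    reference,
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
    retry_budget: int = 1000,
) -> list[GenomicCompartment]:
    """Build ``n_reps`` null compartments with the target's segment lengths.

    Each target segment is re-placed uniformly at random among all starts
    on its own chromosome at which the segment fits wholly inside a
    background segment; placements containing an N are resampled (up to
    ``retry_budget`` attempts per segment).  Placed segments may overlap
    each other, mirroring a shuffle that does not police collisions.
    """
    rng = rng if rng is not None else np.random.default_rng()
    reps = []
    # pre-extract background sequences once per (chrom, segment)
    bg_segs = {chrom: background.intervals.get(chrom, np.zeros((0, 2), dtype=np.int64))
               for chrom in background.intervals}
    for r in range(n_reps):
        placed: dict[str, list[list[int]]] = {}
        for chrom, start, end in target.segments():
            seg_len = end - start
            segs = bg_segs.get(chrom)
            if segs is None or len(segs) == 0:
                raise ValueError(f"no background segments on {chrom} to place a target segment")
            slots = np.maximum(segs[:, 1] - segs[:, 0] - seg_len + 1, 0)
            if slots.sum() == 0:
                raise ValueError(
                    f"no background segment on {chrom} can hold a {seg_len} bp target segment"
                )
            p = slots / slots.sum()
            for _ in range(retry_budget):
                i = rng.choice(len(segs), p=p)
                s = int(segs[i, 0] + rng.integers(slots[i]))
                if "N" not in _fetch(reference, chrom, s, s + seg_len).upper():
                    placed.setdefault(chrom, []).append([s, s + seg_len])
                    break
            else:
                raise RuntimeError(
                    f"could not place a {seg_len} bp segment on {chrom} without N "
                    f"after {retry_budget} attempts"
                )
        reps.append(
            _raw_compartment(f"{target.name}_boot{r}", placed)
        )
    return reps


def _raw_compartment(name: str, placed: dict[str, list[list[int]]]) -> GenomicCompartment:
    """Compartment that preserves the placed segment multiset (no merging).

    Overlapping placements are deliberately kept distinct so that the
    per-chromosome length multiset of every replicate matches the target
    exactly; the object bypasses the merging constructor.
    """
    comp = GenomicCompartment.__new__(GenomicCompartment)
    comp.name = name
    comp.intervals = {
        c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2) for c, v in placed.items()
    }
    return comp


# --------------------------------------------------------------------------
# replication-timing quartiles
# --------------------------------------------------------------------------


def replication_timing_quartiles(
    timing: "np.ndarray | list[tuple[str, int, int, float]]",
    chrom_lengths: dict[str, int],
    window: int = 20_000,
) -> tuple[GenomicCompartment, GenomicCompartment]:
    """Earliest- and latest-replicating quartile compartments.

    ``timing`` is BedGraph-style rows (chrom, start, end, value).  Each
    chromosome is tiled with non-overlapping windows of ``window`` bp; a
    measurement is assigned to the window containing its midpoint, and
    windows with at least one measurement get the mean of their values.
    The earliest quartile collects windows with mean value at or below the
    25th percentile of window means, the latest those at or above the 75th;
    if ties push a quartile past a quarter of the measured windows, excess
    windows are trimmed in (chrom, start) order.
    """
    sums: dict[tuple[str, int], float] = {}
    ns: dict[tuple[str, int], int] = {}
    for chrom, start, end, value in timing:
        mid = (int(start) + int(end)) // 2
        key = (chrom, (mid // window) * window)
        sums[key] = sums.get(key, 0.0) + float(value)
        ns[key] = ns.get(key, 0) + 1
    if not sums:
        raise ValueError("no replication-timing measurements supplied")
    keys = sorted(sums)
    means = np.array([sums[k] / ns[k] for k in keys])
    q25, q75 = np.percentile(means, [25, 75])
    n_q = int(np.ceil(len(keys) / 4))

    def pick(mask: np.ndarray, name: str) -> GenomicCompartment:
        chosen = [k for k, m in zip(keys, mask) if m][:n_q]
        ivals: dict[str, list[list[int]]] = {}
        for chrom, start in chosen:
            end = min(start + window, chrom_lengths.get(chrom, start + window))
            ivals.setdefault(chrom, []).append([start, end])
        return GenomicCompartment(name, {c: np.array(v) for c, v in ivals.items()})

    early = pick(means <= q25, "replication_earliest_quartile")
    late = pick(means >= q75, "replication_latest_quartile")
    return early, late
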