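"""Strand-collapsed mutation-class catalog.

A single-nucleotide change is classified by its ancestral k-mer context
(k = 3 or 7) and the derived central base.  Because a mutation on one
strand is the reverse-complement mutation on the other, each raw
(context, derived) pair is collapsed onto a canonical representative
whose central ancestral base is A or C.  At triplet resolution this
yields 32 collapsed contexts and 96 mutation classes; at 7-mer
resolution, 8,192 contexts and 24,576 classes, 256 per parent triplet
class.

Classes are kept in a fixed lexicographic order (``AAA>C`` first,
``TCT>T`` last for k = 3) so that every spectrum vector in the package
shares the same indexing.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# integer codes used by the vectorized k-mer counters (N = 4 marks
# windows that must be discarded)
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@lru_cache(maxsize=None)
def contexts(order: int) -> tuple[str, ...]:
    """All strand-collapsed k-mer contexts (central base A or C), sorted."""
    _check_order(order)
    mid = order // 2
    out = []

    def build(prefix: str) -> None:
        if len(prefix) == order:
            out.append(prefix)
            return
        choices = "AC" if len(prefix) == mid else BASES
        for b in choices:
            build(prefix + b)

    build("")
    return tuple(sorted(out))


@lru_cache(maxsize=None)
def classes(order: int) -> tuple[str, ...]:
    """All strand-collapsed mutation classes as ``CONTEXT>DERIVED`` labels."""
    out = []
    for ctx in contexts(order):
        center = ctx[order // 2]
        for d in BASES:
            if d != center:
                out.append(f"{ctx}>{d}")
    return tuple(out)


@lru_cache(maxsize=None)
def context_index(order: int) -> dict[str, int]:
    return {c: i for i, c in enumerate(contexts(order))}


@lru_cache(maxsize=None)
def class_index(order: int) -> dict[str, int]:
    return {c: i for i, c in enumerate(classes(order))}


@lru_cache(maxsize=None)
def class_context_of(order: int) -> np.ndarray:
    """Index array mapping class index -> index of its ancestral context."""
    cidx = context_index(order)
    return np.array([cidx[lbl.split(">")[0]] for lbl in classes(order)], dtype=np.int64)


@lru_cache(maxsize=None)
def class7_parent3() -> np.ndarray:
    """Index array mapping each 7-mer class to its parent triplet class.

    The central triplet of a collapsed 7-mer is itself collapsed (central
    base A or C), so the parent is read off directly.
    """
    idx3 = class_index(3)
    out = np.empty(len(classes(7)), dtype=np.int64)
    for i, lbl in enumerate(classes(7)):
        ctx, d = lbl.split(">")
        out[i] = idx3[f"{ctx[2:5]}>{d}"]
    return out


def classify_mutation(context: str, derived: str) -> str:
    """Map an ancestral context and derived central base to its class label.

    The context must have odd length 3 or 7 with no N; collapsing (reverse
    complement of both context and derived base) is applied iff the
    central ancestral base is G or T.
    """
    order = len(context)
    _check_order(order)
    context = context.upper()
    derived = derived.upper()
    if "N" in context or derived == "N":
        raise ValueError(f"context/derived may not contain N: {context}>{derived}")
    center = context[order // 2]
    if derived == center:
        raise ValueError(f"derived base equals ancestral central base: {context}>{derived}")
    if center in "GT":
        context = revcomp(context)
        derived = COMPLEMENT[derived]
    return f"{context}>{derived}"


def class_of(context: str, derived: str) -> int:
    """Index of :func:`classify_mutation`'s class in the canonical order."""
    lbl = classify_mutation(context, derived)
    return class_index(len(context))[lbl]


@lru_cache(maxsize=None)
def collapse_table(order: int) -> np.ndarray:
    """Lookup table mapping raw k-mer codes to collapsed context indices.

    Raw k-mers are encoded base-4 most-significant-first.  Used by the
    vectorized content counters.
    """
    _check_order(order)
    cidx = context_index(order)
    n = 4**order
    table = np.empty(n, dtype=np.int64)
    for code in range(n):
        s = _decode(code, order)
        if s[order // 2] in "GT":
            s = revcomp(s)
        table[code] = cidx[s]
    return table


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, N/other=4)."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.int8)
    for b, c in BASE_CODE.items():
        table[ord(b)] = c
    return table[raw]


def _decode(code: int, order: int) -> str:
    out = []
    for _ in range(order):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _check_order(order: int) -> None:
    if order not in (3, 7):
        raise ValueError(f"context order must be 3 or 7, got {order}")
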