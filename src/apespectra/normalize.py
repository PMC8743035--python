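"""Context-content normalization of compartment mutation spectra.

Compartments differ in k-mer composition, so raw class counts are not
comparable: a compartment rich in AAA triplets offers more opportunity
for AAA>ACA mutations.  Three corrections are implemented:

* :func:`rescale_rates` — reference-content rate rescaling: each class
  count is multiplied by the ratio (reference content / own content) of
  its ancestral context, then the vector is normalized to rates summing
  to 1.  The reference is conventionally a neutral baseline compartment
  (nonconserved, nonrepetitive).
* :func:`downscale_counts` — for two-compartment count-based tests, the
  count of each class is scaled *down* (never up) in whichever
  compartment has the larger content of its context, preserving
  count-like magnitudes.
* :func:`sevenmer_correct` — re-weights 7-mer-resolved counts by 7-mer
  content ratios before collapsing to the 96 triplet classes, removing
  apparent triplet-rate differences that are purely extended-context
  composition effects.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import catalog
from .compartments import ContextContent
from .spectra import SpectrumVector


@dataclasses.dataclass
class RescaledRates:
    """Content-rescaled mutation rates for one compartment.

    ``weights`` are the intermediate per-class rescaled counts R; ``rates``
    is their normalization to sum 1.
    """

    reference: str
    compartment: str
    weights: np.ndarray
    rates: np.ndarray
    order: int = 3

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if self.rates.sum() > 0 and abs(self.rates.sum() - 1.0) > 1e-9:
            raise ValueError("rates must sum to 1")


def _check_content(counts: np.ndarray, content: np.ndarray, ctx_of: np.ndarray,
                   order: int, what: str) -> None:
    bad = (counts > 0) & (content[ctx_of] == 0)
    if np.any(bad):
        ctx = catalog.contexts(order)[ctx_of[int(np.flatnonzero(bad)[0])]]
        raise ValueError(f"nonzero count on context {ctx!r} with zero {what} content")


def rescale_rates(
    counts: SpectrumVector,
    content: ContextContent,
    content_ref: ContextContent,
) -> RescaledRates:
    """Rescale class counts by reference/own context content, normalize to 1.

    Classes sharing an ancestral context share the same scaling factor;
    zero counts stay zero.  Scale-invariant in the reference content.
    """
    order = counts.order
    if content.order != order or content_ref.order != order:
        raise ValueError("content order does not match spectrum order")
    ctx_of = catalog.class_context_of(order)
    _check_content(counts.values, content.counts, ctx_of, order, "compartment")
    ratio = np.zeros(len(content.counts))
    own = content.counts.astype(float)
    ref = content_ref.counts.astype(float)
    nz = own > 0
    ratio[nz] = ref[nz] / own[nz]
    weights = counts.values * ratio[ctx_of]
    total = weights.sum()
    rates = weights / total if total > 0 else weights.copy()
    return RescaledRates(
        reference=content_ref.compartment,
        compartment=content.compartment,
        weights=weights,
        rates=rates,
        order=order,
    )


def downscale_counts(
    counts_1: SpectrumVector,
    content_1: ContextContent,
    counts_2: SpectrumVector,
    content_2: ContextContent,
    round_to_int: bool = False,
) -> tuple[SpectrumVector, SpectrumVector]:
    """Scale each class's count down in the content-richer compartment.

    For a class on context t: if compartment 1 has at least as much t
    content as compartment 2, its count is multiplied by the (<= 1)
    content ratio and compartment 2's is untouched, and symmetrically
    otherwise.  Adjusted counts never exceed the raw counts.  Real-valued
    by default; ``round_to_int`` rounds to the nearest integer for
    count-based tests.
    """
    order = counts_1.order
    if counts_2.order != order or content_1.order != order or content_2.order != order:
        raise ValueError("mismatched context orders")
    ctx_of = catalog.class_context_of(order)
    _check_content(counts_1.values, content_1.counts, ctx_of, order, "compartment-1")
    _check_content(counts_2.values, content_2.counts, ctx_of, order, "compartment-2")
    t1 = content_1.counts[ctx_of].astype(float)
    t2 = content_2.counts[ctx_of].astype(float)
    adj1 = counts_1.values.copy()
    adj2 = counts_2.values.copy()
    bigger1 = t1 >= t2
    with np.errstate(divide="ignore", invalid="ignore"):
        adj1[bigger1] = np.where(
            t1[bigger1] > 0, counts_1.values[bigger1] * t2[bigger1] / t1[bigger1], 0.0
        )
        adj2[~bigger1] = counts_2.values[~bigger1] * t1[~bigger1] / t2[~bigger1]
    if round_to_int:
        adj1, adj2 = np.rint(adj1), np.rint(adj2)
    mk = lambda v, src: SpectrumVector(  # noqa: E731
        v, order, "count", {**src.provenance, "normalization": "downscaled"}
    )
    return mk(adj1, counts_1), mk(adj2, counts_2)


def sevenmer_correct(
    counts7: SpectrumVector,
    content7: ContextContent,
    content7_target: ContextContent,
) -> RescaledRates:
    """Correct 3-mer rates for 7-mer composition differences.

    Each 7-mer-resolved count is reweighted by the target/own content
    ratio of its own 7-mer context; the reweighted counts are then summed
    within their parent triplet class and normalized.  When every 7-mer
    ratio within a class is equal this reduces to triplet-level
    :func:`rescale_rates`.
    """
    if counts7.order != 7 or content7.order != 7 or content7_target.order != 7:
        raise ValueError("7-mer correction needs order-7 inputs")
    ctx_of = catalog.class_context_of(7)
    _check_content(counts7.values, content7.counts, ctx_of, 7, "compartment")
    ratio = np.zeros(len(content7.counts))
    own = content7.counts.astype(float)
    tgt = content7_target.counts.astype(float)
    nz = own > 0
    ratio[nz] = tgt[nz] / own[nz]
    weighted7 = counts7.values * ratio[ctx_of]
    weights3 = np.zeros(len(catalog.classes(3)))
    np.add.at(weights3, catalog.class7_parent3(), weighted7)
    total = weights3.sum()
    rates = weights3 / total if total > 0 else weights3.copy()
    return RescaledRates(
        reference=content7_target.compartment,
        compartment=content7.compartment,
        weights=weights3,
        rates=rates,
        order=3,
    )
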