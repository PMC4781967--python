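"""Cross-compendium CpG-set overlap with hypergeometric significance.

Given two CpG probe-id sets drawn from a common array universe (e.g. this
pipeline's age-selected set against an externally published compendium),
report the shared probes, the expected overlap under random draws
(|A|·|B|/universe) and the hypergeometric upper-tail probability of seeing
at least the observed intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

from .stats import hypergeom_upper_tail

__all__ = ["OverlapReport", "overlap_compendia", "gene_set_overlap"]


@dataclass(frozen=True)
class OverlapReport:
    """Overlap of two probe sets over a finite universe."""

    n_a: int
    n_b: int
    universe: int
    shared_ids: tuple[str, ...]
    overlap: int
    expected: float
    tail_p: float


def overlap_compendia(set_a, set_b, universe: int) -> OverlapReport:
    """Intersect two CpG compendia and score the overlap.

    ``universe`` is the number of probes both sets were drawn from (the
    post-filter array probe count); it must be at least |A ∪ B|.
    """
    a, b = set(set_a), set(set_b)
    if universe < len(a | b):
        raise ValueError(
            f"universe {universe} smaller than |A ∪ B| = {len(a | b)}"
        )
    shared = tuple(sorted(a & b))
    return OverlapReport(
        n_a=len(a),
        n_b=len(b),
        universe=universe,
        shared_ids=shared,
        overlap=len(shared),
        expected=len(a) * len(b) / universe,
        tail_p=hypergeom_upper_tail(len(shared), len(a), len(b), universe),
    )


def gene_set_overlap(genes_a, genes_b) -> dict:
    """Plain set-intersection report for gene lists (no universe assumed).

    Used to compare DMR-associated genes against a user-supplied literature
    list; returns shared symbols and the share of A found in B.
    """
    a, b = set(genes_a), set(genes_b)
    shared = sorted(a & b)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "shared": shared,
        "overlap": len(shared),
        "fraction_of_a": len(shared) / len(a) if a else 0.0,
    }
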