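"""DMR calling by 15-kb single-linkage chaining of selected CpGs.

A differentially methylated region (DMR) is a maximal chain of >= 2
age-selected CpGs, all in one direction on one chromosome, where every
consecutive pair of CpG positions is separated by at most ``max_gap`` bp
(default 15,000, boundary inclusive: a gap of exactly 15,000 chains).
Chaining is single-linkage on the position-sorted CpGs, so the result is
independent of input order and idempotent: re-calling on a DMR's members
returns the same DMR.

Decreasing and increasing CpG lists are chained separately and never mixed.

:func:`cluster_chance_probability` quantifies how often such chains arise by
chance: it draws uniformly random same-size probe subsets from the manifest
and measures the probability of at least one chain, plus the expected chain
count, against the manifest's actual position geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import comb
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .io import ProbeManifest
from .screen import CpGScreenRecord

__all__ = ["Dmr", "call_dmrs", "annotate_genes", "cluster_chance_probability",
           "ClusterChanceResult"]

DEFAULT_MAX_GAP = 15_000


@dataclass(frozen=True)
class Dmr:
    """A called region: member probes sorted by position, 1-based inclusive span."""

    dmr_id: str
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    direction: str
    mean_rho: float
    genes: frozenset = frozenset()

    @property
    def n_cpgs(self) -> int:
        return len(self.probe_ids)


def call_dmrs(
    selected: Sequence[CpGScreenRecord],
    manifest: ProbeManifest,
    max_gap: int = DEFAULT_MAX_GAP,
    min_cpgs: int = 2,
) -> list[Dmr]:
    """Chain selected same-direction CpGs into DMRs.

    All records must share one direction (call once per direction list).
    Returns DMRs sorted by (chromosome order in the manifest vocabulary,
    start).  ``dmr_id`` is deterministic: ``<dir>-chr<chrom>-<start>``.

    Raises
    ------
    ValidationError
        If a record's probe is absent from the manifest, or directions mix.
    """
    if not selected:
        return []
    directions = {r.direction for r in selected}
    if len(directions) != 1:
        raise ValidationError(f"mixed directions in one call: {sorted(map(str, directions))}")
    direction = selected[0].direction

    by_chrom: dict[str, list[tuple[int, CpGScreenRecord]]] = {}
    for rec in selected:
        if rec.probe_id not in manifest:
            raise ValidationError(f"probe {rec.probe_id!r} not in manifest")
        chrom, pos = manifest.position_of(rec.probe_id)
        by_chrom.setdefault(chrom, []).append((pos, rec))

    tag = "dec" if direction == "decreasing" else "inc"
    dmrs: list[Dmr] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        members = sorted(by_chrom[chrom], key=lambda t: (t[0], t[1].probe_id))
        chain: list[tuple[int, CpGScreenRecord]] = [members[0]]
        for item in members[1:]:
            if item[0] - chain[-1][0] <= max_gap:
                chain.append(item)
            else:
                _emit(chain, chrom, tag, direction, min_cpgs, dmrs)
                chain = [item]
        _emit(chain, chrom, tag, direction, min_cpgs, dmrs)
    return dmrs


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def _emit(chain, chrom, tag, direction, min_cpgs, out: list) -> None:
    if len(chain) < min_cpgs:
        return
    start = chain[0][0]
    end = chain[-1][0]
    out.append(
        Dmr(
            dmr_id=f"{tag}-chr{chrom}-{start}",
            chrom=chrom,
            start=start,
            end=end,
            probe_ids=tuple(r.probe_id for _, r in chain),
            direction=direction,
            mean_rho=float(np.mean([r.rho for _, r in chain])),
        )
    )


def annotate_genes(
    dmrs: Iterable[Dmr], manifest: ProbeManifest
) -> tuple[list[Dmr], float]:
    """Fill each DMR's gene set (union over member probes).

    Returns the annotated DMRs and the gene-associated fraction: the share of
    DMRs with a non-empty gene set (0.0 for an empty input).
    """
    out: list[Dmr] = []
    n_assoc = 0
    for d in dmrs:
        genes = frozenset().union(*(manifest.genes_of(p) for p in d.probe_ids))
        n_assoc += bool(genes)
        out.append(replace(d, genes=genes))
    frac = n_assoc / len(out) if out else 0.0
    return out, frac


@dataclass(frozen=True)
class ClusterChanceResult:
    """Monte-Carlo estimate of chance clustering under random CpG selection."""

    p_any_chain: float
    p_any_chain_se: float
    expected_chains: float
    n_reps: int
    exact: bool = False  # True when the n_selected = 2 enumeration was used


def cluster_chance_probability(
    n_selected: int,
    manifest: ProbeManifest,
    max_gap: int = DEFAULT_MAX_GAP,
    n_reps: int = 10_000,
    seed: int = 0,
    exact_pairs: bool = True,
) -> ClusterChanceResult:
    """Probability that a random n-subset of manifest probes contains a chain.

    The null model draws ``n_selected`` probes uniformly without replacement
    from the manifest and asks whether any two consecutive (position-sorted,
    same-chromosome) probes lie within ``max_gap``.  For ``n_selected = 2``
    an exact enumeration over all probe pairs is used (the Monte-Carlo path
    can be forced with ``exact_pairs=False``); otherwise a seeded Monte-Carlo
    estimate with ``n_reps`` replicates is returned together with the
    expected number of distinct chains per draw.
    """
    n_probes = len(manifest)
    if n_selected > n_probes:
        raise ValidationError(
            f"cannot select {n_selected} of {n_probes} manifest probes"
        )
    if n_reps < 100:
        raise ValidationError("n_reps must be >= 100")

    _, order = np.unique(manifest.df["chrom"].to_numpy(), return_inverse=True)
    pos = manifest.df["pos"].to_numpy(dtype=np.int64)
    # encode (chrom, pos) as one sortable integer axis per chromosome block
    span = pos.max() + max_gap + 2
    coded = order.astype(np.int64) * span + pos

    if n_selected < 2:
        return ClusterChanceResult(0.0, 0.0, 0.0, n_reps=0, exact=True)

    if n_selected == 2 and exact_pairs:
        coded_sorted = np.sort(coded)
        # count pairs within max_gap on the coded axis (same chromosome block)
        right = np.searchsorted(coded_sorted, coded_sorted + max_gap, side="right")
        n_close = int((right - np.arange(n_probes) - 1).sum())
        p = n_close / comb(n_probes, 2)
        return ClusterChanceResult(p, 0.0, p, n_reps=0, exact=True)

    rng = np.random.default_rng(seed)
    hits = 0
    chain_counts = np.empty(n_reps)
    for r in range(n_reps):
        pick = rng.choice(n_probes, size=n_selected, replace=False)
        c = np.sort(coded[pick])
        close = np.diff(c) <= max_gap
        hits += bool(close.any())
        # chains = runs of consecutive close pairs
        chain_counts[r] = (close & ~np.concatenate(([False], close[:-1]))).sum()
    p = hits / n_reps
    se = float(np.sqrt(p * (1.0 - p) / n_reps))
    return ClusterChanceResult(
        p_any_chain=p,
        p_any_chain_se=se,
        expected_chains=float(chain_counts.mean()),
        n_reps=n_reps,
    )
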