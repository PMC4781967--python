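"""Genus-age trends and DMR-genus linkage.

The microbiome arm works on the subjects shared between the beta matrix and
the genus relative-abundance table (the study design profiles a subset of
the methylation cohort).  Two operations:

* :func:`genus_age_trends` - Pearson correlation of each genus's abundance
  with age among shared control subjects; a relaxed p < 0.1 cutoff selects
  trend genera (small-n trend screening, deliberately uncorrected).
* :func:`link_dmrs_to_genera` - for each (DMR, selected genus) pair, Pearson
  correlation of every member CpG's beta with the genus abundance; the pair
  is *linked* when at least ``min_cpgs`` (default 2) member CpGs correlate
  at p < 0.1.  The correlation of the DMR-average beta with the abundance is
  reported alongside.

Abundances enter the correlations as given (relative abundances); an
optional log10(x + pseudocount) transform is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dmr import Dmr
from .errors import ConfigurationError, DegenerateInputError
from .io import AbundanceTable, BetaMatrix, SampleSheet
from .stats import pearson

log = logging.getLogger("agedmr")

__all__ = ["GenusTrend", "genus_age_trends", "DmrGenusLink", "link_dmrs_to_genera"]


@dataclass(frozen=True)
class GenusTrend:
    """Pearson age trend of one genus's relative abundance."""

    genus: str
    r: float
    p_value: float
    n_used: int
    direction: str  # 'increasing' | 'decreasing'
    selected: bool


@dataclass(frozen=True)
class DmrGenusLink:
    """Linkage evidence between one DMR and one genus."""

    dmr_id: str
    genus: str
    n_cpgs_passing: int
    per_cpg: tuple[tuple[str, float, float], ...]  # (probe_id, r, p)
    avg_meth_r: float
    avg_meth_p: float
    linked: bool
    reason: str | None = None  # set when linkage was impossible


def _shared_controls(
    samples: SampleSheet, *column_sources
) -> list[str]:
    shared = [
        s
        for s in samples.subjects_in("control")
        if all(s in src for src in column_sources)
    ]
    return shared


def _maybe_log(values: np.ndarray, log_transform: bool, pseudocount: float) -> np.ndarray:
    if not log_transform:
        return values
    return np.log10(values + pseudocount)


def genus_age_trends(
    abundance: AbundanceTable,
    samples: SampleSheet,
    p_threshold: float = 0.1,
    log_transform: bool = False,
    pseudocount: float = 1e-4,
) -> list[GenusTrend]:
    """Pearson abundance-vs-age trend for every genus with non-zero variance.

    Constant genera are excluded with a logged warning.  Requires >= 3
    control subjects shared with the abundance table.
    """
    shared = _shared_controls(samples, list(abundance.subject_ids))
    if len(shared) < 3:
        raise ConfigurationError(
            f"need >= 3 shared control subjects, have {len(shared)}"
        )
    ages = samples.ages_of(shared)
    trends: list[GenusTrend] = []
    for genus in abundance.genus_ids:
        vals = _maybe_log(
            abundance.df.loc[genus, shared].to_numpy(dtype=float),
            log_transform, pseudocount,
        )
        try:
            res = pearson(ages, vals)
        except DegenerateInputError:
            log.warning("genus %s: constant abundance, excluded", genus)
            continue
        except ValueError:
            log.warning("genus %s: < 3 complete pairs, excluded", genus)
            continue
        trends.append(
            GenusTrend(
                genus=str(genus),
                r=res.estimate,
                p_value=res.p_value,
                n_used=res.n_used,
                direction="increasing" if res.estimate >= 0 else "decreasing",
                selected=bool(res.p_value < p_threshold),
            )
        )
    return trends


def link_dmrs_to_genera(
    beta: BetaMatrix,
    abundance: AbundanceTable,
    samples: SampleSheet,
    dmrs: list[Dmr],
    trends: list[GenusTrend],
    p_threshold: float = 0.1,
    min_cpgs: int = 2,
    all_genera: bool = False,
    log_transform: bool = False,
    pseudocount: float = 1e-4,
) -> list[DmrGenusLink]:
    """Correlate member-CpG methylation with genus abundance per DMR.

    Only age-selected genera are tested unless ``all_genera`` is set.  A
    (DMR, genus) pair is linked when >= ``min_cpgs`` member CpGs correlate
    with the abundance at p < ``p_threshold``.  DMRs with fewer than
    ``min_cpgs`` analysable probes among the shared subjects are reported
    unlinked with a reason rather than dropped silently.
    """
    shared = _shared_controls(
        samples, list(abundance.subject_ids), list(beta.subject_ids)
    )
    if len(shared) < 3:
        raise ConfigurationError(
            f"need >= 3 subjects shared between beta and abundance, have {len(shared)}"
        )
    genera = [t.genus for t in trends if all_genera or t.selected]
    links: list[DmrGenusLink] = []
    for d in dmrs:
        sub = beta.df.loc[list(d.probe_ids), shared].to_numpy(dtype=float)
        for genus in genera:
            vals = _maybe_log(
                abundance.df.loc[genus, shared].to_numpy(dtype=float),
                log_transform, pseudocount,
            )
            per_cpg = []
            n_pass = 0
            n_usable = 0
            for k, probe in enumerate(d.probe_ids):
                try:
                    res = pearson(sub[k], vals)
                except (DegenerateInputError, ValueError):
                    per_cpg.append((probe, float("nan"), float("nan")))
                    continue
                n_usable += 1
                n_pass += res.p_value < p_threshold
                per_cpg.append((probe, res.estimate, res.p_value))
            reason = None
            if n_usable < min_cpgs:
                reason = f"only {n_usable} analysable CpG(s) in shared subjects"
            avg = np.nanmean(sub, axis=0)
            try:
                avg_res = pearson(avg, vals)
                avg_r, avg_p = avg_res.estimate, avg_res.p_value
            except (DegenerateInputError, ValueError):
                avg_r, avg_p = float("nan"), float("nan")
            links.append(
                DmrGenusLink(
                    dmr_id=d.dmr_id,
                    genus=genus,
                    n_cpgs_passing=n_pass,
                    per_cpg=tuple(per_cpg),
                    avg_meth_r=avg_r,
                    avg_meth_p=avg_p,
                    linked=bool(reason is None and n_pass >= min_cpgs),
                    reason=reason,
                )
            )
    return links
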