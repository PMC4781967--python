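"""End-to-end orchestration: screen -> DMRs -> disease -> microbiome -> overlap.

:func:`run_pipeline` executes every stage on validated in-memory inputs and
returns a :class:`RunSummary` whose ``summary`` dict is schema-stable JSON:
headline counts, fractions (one-decimal percentages), the two Fisher
enrichment p-values, optional compendium-overlap blocks, and provenance
(thresholds, config hash, package version).  Every count in the summary is
recomputable from the intermediate tables, which are written as TSV when an
output directory is given.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .disease import dmr_disease_test, enrichment_tests
from .dmr import Dmr, annotate_genes, call_dmrs
from .io import (
    AbundanceTable,
    BetaMatrix,
    ProbeManifest,
    SampleSheet,
    write_dmr_bed,
)
from .microbiome import genus_age_trends, link_dmrs_to_genera
from .overlap import overlap_compendia
from .screen import ScreenResult, screen_age_cpgs

log = logging.getLogger("agedmr")

__all__ = ["Thresholds", "RunSummary", "percent", "run_pipeline"]


@dataclass(frozen=True)
class Thresholds:
    """All stage thresholds in one block (defaults are the study's cutoffs)."""

    p_age: float = 0.05
    delta: float = 0.10
    max_gap: int = 15_000
    min_cpgs: int = 2
    p_disease: float = 0.05
    p_microbiome: float = 0.1
    min_link_cpgs: int = 2


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-away-from-zero to one decimal (82.608.. -> 82.6)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    q = (Decimal(numerator) * 100) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RunSummary:
    """Everything a run computed, plus the tables it computed it from."""

    summary: dict
    screen: ScreenResult
    dmrs_decreasing: list[Dmr]
    dmrs_increasing: list[Dmr]
    disease_results: dict  # disease -> list[DmrDiseaseResult]
    genus_trends: list = field(default_factory=list)
    dmr_genus_links: list = field(default_factory=list)


def _screen_frame(screen: ScreenResult, manifest: ProbeManifest) -> pd.DataFrame:
    rows = []
    for r in screen.records:
        chrom, pos = manifest.position_of(r.probe_id) if r.probe_id in manifest else ("", 0)
        rows.append(
            (r.probe_id, chrom, pos, r.rho, r.p_value, r.delta, r.n_used,
             r.direction or "", int(r.selected), int(r.sign_conflict),
             int(r.delta_imputed))
        )
    return pd.DataFrame(
        rows,
        columns=["probe_id", "chrom", "pos", "rho", "p", "delta", "n_used",
                 "direction", "selected", "sign_conflict", "delta_imputed"],
    ).set_index("probe_id")


def _dmr_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (d.dmr_id, d.chrom, d.start, d.end, d.n_cpgs, d.direction,
             ";".join(sorted(d.genes)), d.mean_rho, ";".join(d.probe_ids))
            for d in dmrs
        ],
        columns=["dmr_id", "chrom", "start", "end", "n_cpgs", "direction",
                 "genes", "mean_rho", "probe_ids"],
    ).set_index("dmr_id")


def _disease_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.dmr_id, r.disease, r.p_avg, int(r.significant),
             r.n_probes_used, ";".join(f"{p:.6g}" for p in r.per_cpg_p))
            for r in results
        ],
        columns=["dmr_id", "disease", "p_avg", "significant", "n_probes_used",
                 "per_cpg_p"],
    ).set_index("dmr_id")


def _link_frame(links: list) -> pd.DataFrame:
    rows = []
    for l in links:
        for probe, r, p in l.per_cpg:
            rows.append(
                (l.dmr_id, l.genus, probe, r, p,
                 int(not pd.isna(p) and p < 0.1), int(l.linked))
            )
    return pd.DataFrame(
        rows,
        columns=["dmr_id", "genus", "probe_id", "r", "p", "passing", "dmr_linked"],
    )


def run_pipeline(
    manifest: ProbeManifest,
    beta: BetaMatrix,
    samples: SampleSheet,
    abundance: AbundanceTable | None = None,
    external_sets: dict[str, set] | None = None,
    thresholds: Thresholds = Thresholds(),
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> RunSummary:
    """Run every stage in order and assemble the run summary.

    ``abundance`` enables the microbiome stage; ``external_sets`` maps a
    label to an external CpG compendium for overlap scoring against this
    run's selected sets (universe = manifest probe count).  ``outdir``
    triggers TSV/BED/JSON output.  ``seed`` is recorded in provenance only -
    the pipeline stages themselves are deterministic.
    """
    th = thresholds
    log.info("screen: %d probes x %d subjects", len(beta.probe_ids), len(beta.subject_ids))
    screen = screen_age_cpgs(beta, samples, p_threshold=th.p_age, delta_threshold=th.delta)

    dec, frac_dec = annotate_genes(
        call_dmrs(screen.decreasing, manifest, max_gap=th.max_gap, min_cpgs=th.min_cpgs),
        manifest,
    )
    inc, frac_inc = annotate_genes(
        call_dmrs(screen.increasing, manifest, max_gap=th.max_gap, min_cpgs=th.min_cpgs),
        manifest,
    )
    all_dmrs = dec + inc
    log.info("dmrs: %d decreasing, %d increasing", len(dec), len(inc))

    groups_present = set(samples.df["group"])
    disease_results: dict[str, list] = {}
    overlap_counts: dict[str, dict[str, int]] = {}
    for disease in ("UC", "CD"):
        if disease not in groups_present:
            continue
        res = dmr_disease_test(beta, samples, all_dmrs, disease, p_threshold=th.p_disease)
        disease_results[disease] = res
        sig_ids = {r.dmr_id for r in res if r.significant}
        overlap_counts[disease] = {
            "decreasing": sum(d.dmr_id in sig_ids for d in dec),
            "increasing": sum(d.dmr_id in sig_ids for d in inc),
        }

    enrichment = None
    if {"UC", "CD"} <= set(overlap_counts) and all_dmrs:
        e = enrichment_tests(
            len(dec), len(inc),
            overlap_counts["UC"]["decreasing"], overlap_counts["UC"]["increasing"],
            overlap_counts["CD"]["decreasing"], overlap_counts["CD"]["increasing"],
        )
        enrichment = {
            "p_uc_vs_cd": e.p_uc_vs_cd,
            "p_dec_vs_inc_uc": e.p_dec_vs_inc_uc,
            "note": "UC and CD arms count the same DMR set (paired, not independent)",
        }

    trends: list = []
    links: list = []
    if abundance is not None:
        trends = genus_age_trends(abundance, samples, p_threshold=th.p_microbiome)
        links = link_dmrs_to_genera(
            beta, abundance, samples, all_dmrs, trends,
            p_threshold=th.p_microbiome, min_cpgs=th.min_link_cpgs,
        )

    overlaps = {}
    for label, ext in (external_sets or {}).items():
        own = {r.probe_id for r in screen.selected}
        rep = overlap_compendia(own, ext, universe=len(manifest))
        overlaps[label] = {
            "n_a": rep.n_a, "n_b": rep.n_b, "universe": rep.universe,
            "overlap": rep.overlap, "expected": rep.expected, "tail_p": rep.tail_p,
            "shared_ids": list(rep.shared_ids),
        }

    counts = {
        "probes_screened": len(screen.records),
        "selected_cpgs_decreasing": len(screen.decreasing),
        "selected_cpgs_increasing": len(screen.increasing),
        "dmrs_decreasing": len(dec),
        "dmrs_increasing": len(inc),
        "gene_associated_dmrs_decreasing": sum(bool(d.genes) for d in dec),
        "gene_associated_dmrs_increasing": sum(bool(d.genes) for d in inc),
        "disease_overlap": overlap_counts,
        "linked_dmr_genus_pairs": sum(l.linked for l in links),
    }
    fractions = {}
    if dec:
        fractions["gene_associated_pct_decreasing"] = percent(
            counts["gene_associated_dmrs_decreasing"], len(dec)
        )
    if inc:
        fractions["gene_associated_pct_increasing"] = percent(
            counts["gene_associated_dmrs_increasing"], len(inc)
        )
    for disease, oc in overlap_counts.items():
        if dec:
            fractions[f"{disease}_overlap_pct_decreasing"] = percent(oc["decreasing"], len(dec))
        if inc:
            fractions[f"{disease}_overlap_pct_increasing"] = percent(oc["increasing"], len(inc))

    th_dict = asdict(th)
    provenance = {
        "tool_version": __version__,
        "thresholds": th_dict,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(th_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "diagnostics": {
            "n_degenerate_probes": screen.n_degenerate,
            "n_sign_conflicts": screen.n_sign_conflicts,
        },
    }
    summary = {
        "counts": counts,
        "fractions": fractions,
        "enrichment": enrichment,
        "overlap": overlaps,
        "provenance": provenance,
    }

    result = RunSummary(
        summary=summary,
        screen=screen,
        dmrs_decreasing=dec,
        dmrs_increasing=inc,
        disease_results=disease_results,
        genus_trends=trends,
        dmr_genus_links=links,
    )
    if outdir is not None:
        _write_outputs(result, manifest, Path(outdir))
    return result


def _write_outputs(res: RunSummary, manifest: ProbeManifest, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _screen_frame(res.screen, manifest).to_csv(outdir / "screen.tsv", sep="\t")
    all_dmrs = res.dmrs_decreasing + res.dmrs_increasing
    _dmr_frame(all_dmrs).to_csv(outdir / "dmrs.tsv", sep="\t")
    if all_dmrs:
        write_dmr_bed(all_dmrs, outdir / "dmrs.bed")
    for disease, results in res.disease_results.items():
        _disease_frame(results).to_csv(outdir / f"disease_{disease}.tsv", sep="\t")
    if res.genus_trends:
        pd.DataFrame(
            [(t.genus, t.r, t.p_value, t.n_used, t.direction, int(t.selected))
             for t in res.genus_trends],
            columns=["genus", "r", "p", "n_used", "direction", "selected"],
        ).set_index("genus").to_csv(outdir / "genus_trends.tsv", sep="\t")
    if res.dmr_genus_links:
        _link_frame(res.dmr_genus_links).to_csv(
            outdir / "dmr_genus_links.tsv", sep="\t", index=False
        )
    (outdir / "run_summary.json").write_text(
        json.dumps(res.summary, indent=2, default=float) + "\n", encoding="utf-8"
    )
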