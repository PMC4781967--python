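"""Recovery and calibration experiments on synthetic cohorts.

These routines measure how well the pipeline recovers the generator's
planted structure, and how its false-positive behaviour compares with the
analytic/simulation null expectations.  They are shared by the analysis
drivers, the test suite and the reproduction script so every reported
number comes from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dmr import Dmr, call_dmrs, cluster_chance_probability
from .microbiome import genus_age_trends, link_dmrs_to_genera
from .screen import null_selection_rate, screen_age_cpgs
from .simulate import Cohort, simulate_cohort

__all__ = [
    "RegionRecovery",
    "region_recovery",
    "NullCalibration",
    "null_calibration",
    "linkage_replicates",
    "truth_dmrs",
]


@dataclass(frozen=True)
class RegionRecovery:
    """Planted-region recovery of one cohort run."""

    n_regions: int
    n_recovered: int
    n_false_dmrs: int
    recovery_pct: float


def region_recovery(cohort: Cohort, dmrs: list[Dmr] | None = None) -> RegionRecovery:
    """Score called DMRs against the cohort's planted regions.

    A planted region counts as recovered when one called DMR of the same
    direction contains at least two of the region's planted probes.  A
    called DMR containing no planted probe is a false call.

    ``dmrs`` may be passed to score an existing call; otherwise the screen
    and caller run here with default thresholds.
    """
    if dmrs is None:
        res = screen_age_cpgs(cohort.beta, cohort.samples)
        dmrs = call_dmrs(res.decreasing, cohort.manifest) + call_dmrs(
            res.increasing, cohort.manifest
        )
    truth = cohort.truth
    probe_region = truth.probes["region_id"]
    recovered = set()
    n_false = 0
    for d in dmrs:
        regions_hit: dict[str, int] = {}
        any_planted = False
        for p in d.probe_ids:
            rid = probe_region.get(p, "")
            if rid:
                any_planted = True
                regions_hit[rid] = regions_hit.get(rid, 0) + 1
        if not any_planted:
            n_false += 1
            continue
        for rid, n in regions_hit.items():
            if n >= 2 and truth.regions.loc[rid, "direction"] == d.direction:
                recovered.add(rid)
    n_regions = len(truth.regions)
    return RegionRecovery(
        n_regions=n_regions,
        n_recovered=len(recovered),
        n_false_dmrs=n_false,
        recovery_pct=100.0 * len(recovered) / n_regions if n_regions else 0.0,
    )


@dataclass(frozen=True)
class NullCalibration:
    """Observed vs predicted false-positive behaviour with nothing planted."""

    selection_rate: float
    selection_rate_se: float
    oracle_rate: float
    oracle_rate_se: float
    false_dmr_rate: float  # chance-called DMRs per replicate cohort
    predicted_false_dmr_rate: float
    n_probes_total: int
    n_replicates: int


def null_calibration(
    n_replicates: int = 100,
    n_probes: int = 2000,
    n_controls: int = 22,
    noise_sd: float = 0.03,
    seed: int = 0,
    oracle_reps: int = 10_000,
) -> NullCalibration:
    """Replicate cohorts with no planted effects; measure false positives.

    The per-probe selection rate is compared against the joint-null
    simulation oracle (:func:`agedmr.screen.null_selection_rate`); the
    chance-DMR rate against :func:`cluster_chance_probability` evaluated at
    the mean selected count on the replicate manifest geometry.
    """
    rng = np.random.default_rng(seed)
    n_selected_total = 0
    n_dmrs_total = 0
    selected_counts = []
    last_cohort = None
    for _ in range(n_replicates):
        cohort = simulate_cohort(
            n_probes=n_probes, n_controls=n_controls, n_uc=0, n_cd=0,
            n_dmrs_down=0, n_dmrs_up=0, n_genera=0, n_trend_genera=0,
            noise_sd=noise_sd, seed=int(rng.integers(2**31 - 1)),
        )
        res = screen_age_cpgs(cohort.beta, cohort.samples)
        n_sel = len(res.selected)
        n_selected_total += n_sel
        selected_counts.append(n_sel)
        n_dmrs_total += len(call_dmrs(res.decreasing, cohort.manifest))
        n_dmrs_total += len(call_dmrs(res.increasing, cohort.manifest))
        last_cohort = cohort

    total_probes = n_replicates * n_probes
    rate = n_selected_total / total_probes
    rate_se = float(np.sqrt(rate * (1 - rate) / total_probes))
    ages = last_cohort.samples.ages_of(last_cohort.samples.subjects_in("control"))
    oracle_rate, oracle_se = null_selection_rate(
        ages, noise_sd, n_reps=oracle_reps, seed=seed + 1
    )
    mean_selected = max(2, round(np.mean(selected_counts)))
    chance = cluster_chance_probability(
        mean_selected, last_cohort.manifest, n_reps=2000, seed=seed + 2
    )
    return NullCalibration(
        selection_rate=rate,
        selection_rate_se=rate_se,
        oracle_rate=oracle_rate,
        oracle_rate_se=oracle_se,
        false_dmr_rate=n_dmrs_total / n_replicates,
        predicted_false_dmr_rate=chance.expected_chains,
        n_probes_total=total_probes,
        n_replicates=n_replicates,
    )


def truth_dmrs(cohort: Cohort) -> list[Dmr]:
    """Build the DMRs a perfect caller would emit from the truth table."""
    out = []
    for rid, row in cohort.truth.regions.iterrows():
        members = tuple(
            cohort.truth.probes.index[cohort.truth.probes["region_id"] == rid]
        )
        tag = "dec" if row["direction"] == "decreasing" else "inc"
        out.append(
            Dmr(
                dmr_id=f"{tag}-chr{row['chrom']}-{row['start']}",
                chrom=str(row["chrom"]), start=int(row["start"]),
                end=int(row["end"]), probe_ids=members,
                direction=row["direction"],
                mean_rho=-0.9 if row["direction"] == "decreasing" else 0.9,
            )
        )
    return out


def linkage_replicates(
    coupling: float,
    n_replicates: int = 100,
    n_subjects: int = 10,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the coupled (DMR, genus) pair links.

    Each replicate simulates a minimal cohort (one planted decreasing
    region, one coupled genus among several null genera, ``n_subjects``
    controls all profiled for abundance), builds the region's DMR from
    truth, and applies the >= 2 CpG p < 0.1 linkage rule with the coupled
    genus always evaluated (``all_genera=True`` so a failed age-trend screen
    cannot hide the pair).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        cohort = simulate_cohort(
            n_controls=n_subjects, n_uc=0, n_cd=0, n_probes=40,
            n_dmrs_down=1, n_dmrs_up=0, n_genera=8, n_trend_genera=1,
            coupling=coupling, abundance_subjects=None,
            seed=int(rng.integers(2**31 - 1)),
        )
        (dmr,) = truth_dmrs(cohort)
        genus = cohort.truth.regions.iloc[0]["coupled_genus"] or \
            cohort.truth.genera.index[0]
        trends = genus_age_trends(cohort.abundance, cohort.samples)
        links = link_dmrs_to_genera(
            cohort.beta, cohort.abundance, cohort.samples, [dmr], trends,
            all_genera=True,
        )
        hits += any(
            l.linked for l in links if l.dmr_id == dmr.dmr_id and l.genus == genus
        )
    return hits / n_replicates
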