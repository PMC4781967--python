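"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline assumes in a
pediatric colonic-mucosa study:

* a control cohort (default 22 subjects) aged 3.5-17.5 years, with the age
  extremes guaranteed present;
* *planted* CpG probes whose beta drifts linearly with age, reaching a
  target span effect (default 0.25, i.e. 25 percentage points between the
  age extremes) in either direction, grouped into regions whose total span
  never exceeds ``dmr_span_bp`` (<= 15 kb, so every fully recovered region
  is callable as a single DMR);
* *null* probes with age-independent beta, spaced > 15 kb from any
  neighbour so chance chains cannot form among them;
* UC/CD disease groups whose betas carry a constant offset (default +0.15)
  at a subset of planted regions, independent of age;
* genus relative abundances where selected genera are coupled to a planted
  region's methylation through a shared latent factor.

Coupling semantics: for coupling strength ``c`` in [0, 1], a coupled
genus's latent signal is the convex combination
``c * z_region + (1 - c) * eps`` of the standardized DMR-average beta
(sign-alternated across genera) and independent standard-normal noise.  The
signal enters an exponential link (scale 0.5) and is normalised per subject
so abundances sum to one.  ``c = 1`` makes the genus a deterministic
monotone function of region methylation; ``c = 0`` decouples it entirely.

Noise on betas is Gaussian with clipping to [0.02, 0.98] by default (simple
effect-size arithmetic); a moment-matched Beta-distributed mode is available
via ``beta_noise=True``.

All randomness flows from one ``numpy`` Generator seeded by
``config.seed``: identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AbundanceTable,
    BetaMatrix,
    ProbeManifest,
    SampleSheet,
    write_abundance,
    write_beta,
    write_manifest,
    write_samples,
)

__all__ = ["SimulationConfig", "TruthTable", "Cohort", "simulate_cohort", "write_cohort"]

BETA_CLIP = (0.02, 0.98)
_ABUNDANCE_LINK_SCALE = 0.5  # exponent scale of the abundance link function
_N_AUTOSOMES = 22


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_controls: int = 22
    n_uc: int = 10
    n_cd: int = 10
    age_min: float = 3.5
    age_max: float = 17.5
    n_probes: int = 5000
    n_dmrs_down: int = 20
    n_dmrs_up: int = 20
    cpgs_per_dmr: tuple[int, int] = (3, 6)
    dmr_span_bp: int = 12_000
    age_span_effect: float = 0.25
    disease_shift: float = 0.15
    disease_linked_frac: float = 0.5
    noise_sd: float = 0.03
    beta_noise: bool = False
    n_genera: int = 25
    n_trend_genera: int = 5
    coupling: float = 0.7
    abundance_subjects: int | None = 10
    n_snp_probes: int = 0
    n_xy_probes: int = 0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        if not 0 < self.age_span_effect < 1:
            raise ValueError("age_span_effect must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.dmr_span_bp > 15_000:
            raise ValueError("dmr_span_bp must be <= 15,000 so regions stay callable")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")
        for name in ("n_controls", "n_uc", "n_cd", "n_probes", "n_dmrs_down",
                     "n_dmrs_up", "n_genera", "n_trend_genera",
                     "n_snp_probes", "n_xy_probes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_trend_genera > self.n_genera:
            raise ValueError("n_trend_genera cannot exceed n_genera")


@dataclass(frozen=True)
class TruthTable:
    """Machine-readable ground truth for recovery tests.

    ``probes``: indexed by probe_id - planted flag, direction, span effect,
    region_id.  ``regions``: indexed by region_id - chrom, start, end,
    n_cpgs, direction, disease ('' | 'UC' | 'CD'), coupled_genus.
    ``genera``: indexed by genus - coupled_region, coupling, trend_sign.
    """

    probes: pd.DataFrame
    regions: pd.DataFrame
    genera: pd.DataFrame

    @property
    def planted_probe_ids(self) -> list[str]:
        return list(self.probes.index[self.probes["planted"]])


@dataclass(frozen=True)
class Cohort:
    """One simulated dataset plus its generating config and truth."""

    manifest: ProbeManifest
    beta: BetaMatrix
    samples: SampleSheet
    abundance: AbundanceTable
    truth: TruthTable
    config: SimulationConfig


def _region_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Interleave decreasing/increasing regions across autosomes.

    Returns a list of dicts with region id, chrom, direction and member
    positions.  Region starts are spaced 300 kb apart within a chromosome,
    far below any null-probe coordinate, so planted regions can never chain
    with each other or with null probes.
    """
    directions = []
    nd, ni = cfg.n_dmrs_down, cfg.n_dmrs_up
    while nd or ni:
        if nd:
            directions.append("decreasing")
            nd -= 1
        if ni:
            directions.append("increasing")
            ni -= 1
    regions = []
    per_chrom_count: dict[str, int] = {}
    lo, hi = cfg.cpgs_per_dmr
    for r, direction in enumerate(directions):
        chrom = str((r % _N_AUTOSOMES) + 1)
        k = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = k + 1
        start = 1_000_000 + k * 300_000
        n_cpgs = int(rng.integers(lo, hi + 1))
        max_gap = max(100, cfg.dmr_span_bp // max(1, n_cpgs - 1))
        gaps = rng.integers(100, max_gap + 1, size=n_cpgs - 1)
        positions = start + np.concatenate(([0], np.cumsum(gaps)))
        regions.append(
            {
                "region_id": f"R{r:03d}",
                "chrom": chrom,
                "direction": direction,
                "positions": positions.astype(np.int64),
            }
        )
    return regions


def _beta_noise(rng, mu: np.ndarray, sd: float, use_beta: bool) -> np.ndarray:
    """Additive Gaussian noise, or moment-matched Beta sampling around mu."""
    if not use_beta:
        return mu + rng.normal(0.0, sd, size=mu.shape)
    m = np.clip(mu, 0.03, 0.97)
    k = m * (1 - m) / sd**2 - 1
    k = np.maximum(k, 0.5)
    return rng.beta(m * k, (1 - m) * k)


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> Cohort:
    """Generate one full synthetic cohort.

    Accepts either a ready :class:`SimulationConfig` or keyword overrides of
    its defaults.  Raises ``ValueError`` when the planted probes demanded by
    the region settings exceed ``n_probes``.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- subjects -----------------------------------------------------------
    ages_ctrl = rng.uniform(cfg.age_min, cfg.age_max, size=cfg.n_controls)
    if cfg.n_controls >= 2:
        ages_ctrl[0], ages_ctrl[1] = cfg.age_min, cfg.age_max
    subjects = [f"C{i + 1:02d}" for i in range(cfg.n_controls)]
    groups = ["control"] * cfg.n_controls
    ages = list(ages_ctrl)
    for prefix, group, n in (("U", "UC", cfg.n_uc), ("D", "CD", cfg.n_cd)):
        ages.extend(rng.uniform(cfg.age_min, cfg.age_max, size=n))
        subjects.extend(f"{prefix}{i + 1:02d}" for i in range(n))
        groups.extend([group] * n)
    ages = np.asarray(ages)
    samples = SampleSheet(
        df=pd.DataFrame(
            {"age_years": ages, "group": groups}, index=pd.Index(subjects, name="subject_id")
        )
    )

    # --- probe layout -------------------------------------------------------
    regions = _region_layout(cfg, rng)
    n_planted = int(sum(len(r["positions"]) for r in regions))
    n_special = n_planted + cfg.n_snp_probes + cfg.n_xy_probes
    if n_special > cfg.n_probes:
        raise ValueError(
            f"config demands {n_special} planted/flagged probes but only "
            f"{cfg.n_probes} probes total"
        )
    n_null = cfg.n_probes - n_special

    chroms: list[str] = []
    positions: list[int] = []
    planted_flag: list[bool] = []
    direction_col: list[str] = []
    region_col: list[str] = []
    snp_flag: list[bool] = []
    for r in regions:
        for pos in r["positions"]:
            chroms.append(r["chrom"])
            positions.append(int(pos))
            planted_flag.append(True)
            direction_col.append(r["direction"])
            region_col.append(r["region_id"])
            snp_flag.append(False)
    for j in range(n_null):  # >15 kb spacing: no chance chains among nulls
        chroms.append(str((j % _N_AUTOSOMES) + 1))
        positions.append(50_000_000 + (j // _N_AUTOSOMES) * 20_000)
        planted_flag.append(False)
        direction_col.append("")
        region_col.append("")
        snp_flag.append(False)
    for j in range(cfg.n_snp_probes):
        chroms.append(str((j % _N_AUTOSOMES) + 1))
        positions.append(150_000_000 + (j // _N_AUTOSOMES) * 20_000)
        planted_flag.append(False)
        direction_col.append("")
        region_col.append("")
        snp_flag.append(True)
    for j in range(cfg.n_xy_probes):
        chroms.append("X")
        positions.append(1_000_000 + j * 20_000)
        planted_flag.append(False)
        direction_col.append("")
        region_col.append("")
        snp_flag.append(False)

    probe_ids = [f"cg{i + 1:08d}" for i in range(cfg.n_probes)]
    # 80% of regions carry a gene symbol; half of the null probes do
    region_has_gene = {
        r["region_id"]: (i % 5 != 4) for i, r in enumerate(regions)
    }
    genes = []
    for i in range(cfg.n_probes):
        if planted_flag[i] and region_has_gene[region_col[i]]:
            genes.append(frozenset({f"GENE{region_col[i][1:]}"}))
        elif not planted_flag[i] and i % 2 == 0:
            genes.append(frozenset({f"NULG{i:05d}"}))
        else:
            genes.append(frozenset())
    manifest = ProbeManifest(
        df=pd.DataFrame(
            {"chrom": chroms, "pos": positions, "genes": genes, "snp_flag": snp_flag},
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    # --- disease links ------------------------------------------------------
    n_linked = round(cfg.disease_linked_frac * len(regions))
    disease_of_region = {r["region_id"]: "" for r in regions}
    # period-4 pattern UC,CD,CD,UC so disease is not confounded with the
    # period-2 decreasing/increasing interleave of the region list
    for i in range(n_linked):
        disease_of_region[regions[i]["region_id"]] = (
            "UC" if i % 4 in (0, 3) else "CD"
        )

    # --- beta matrix --------------------------------------------------------
    n_subj = len(subjects)
    age_mid = (cfg.age_min + cfg.age_max) / 2
    slope_unit = cfg.age_span_effect / (cfg.age_max - cfg.age_min)
    mu = np.empty((cfg.n_probes, n_subj))
    base_null = rng.uniform(0.1, 0.9, size=cfg.n_probes)
    center_planted = rng.uniform(0.25, 0.65, size=cfg.n_probes)
    group_arr = np.asarray(groups)
    for i in range(cfg.n_probes):
        if planted_flag[i]:
            s = slope_unit if direction_col[i] == "increasing" else -slope_unit
            mu[i] = center_planted[i] + s * (ages - age_mid)
            dz = disease_of_region[region_col[i]]
            if dz:
                mu[i] = mu[i] + cfg.disease_shift * (group_arr == dz)
        else:
            mu[i] = base_null[i]
    values = np.clip(
        _beta_noise(rng, mu, cfg.noise_sd, cfg.beta_noise), *BETA_CLIP
    )
    beta = BetaMatrix(
        df=pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=subjects)
    )

    # --- genus abundances ---------------------------------------------------
    controls = subjects[: cfg.n_controls]
    if cfg.abundance_subjects is None or cfg.abundance_subjects >= cfg.n_controls:
        abund_subjects = list(controls)
    else:
        pick = rng.choice(cfg.n_controls, size=cfg.abundance_subjects, replace=False)
        abund_subjects = [controls[i] for i in sorted(pick)]
    n_as = len(abund_subjects)
    genus_names = [f"Genus{g + 1:02d}" for g in range(cfg.n_genera)]
    raw = np.empty((cfg.n_genera, n_as))
    coupled_region = [""] * cfg.n_genera
    trend_sign = np.zeros(cfg.n_genera, dtype=int)
    beta_abund = beta.df[abund_subjects]
    for g in range(cfg.n_genera):
        eps = rng.normal(0.0, 1.0, size=n_as)
        if g < cfg.n_trend_genera and regions and cfg.coupling > 0:
            region = regions[g % len(regions)]
            member_ids = [probe_ids[i] for i in range(cfg.n_probes)
                          if region_col[i] == region["region_id"]]
            avg = beta_abund.loc[member_ids].mean(axis=0).to_numpy()
            z = (avg - avg.mean()) / avg.std()
            # period-4 alternation: the region list interleaves directions
            # with period 2, so a period-2 sign would make every coupled
            # genus trend the same way with age
            sign = 1 if (g // 2) % 2 == 0 else -1
            raw[g] = cfg.coupling * sign * z + (1 - cfg.coupling) * eps
            coupled_region[g] = region["region_id"]
            trend_sign[g] = sign
        else:
            if g < cfg.n_trend_genera and regions:
                coupled_region[g] = regions[g % len(regions)]["region_id"]
            raw[g] = eps
    base_g = rng.normal(0.0, 1.0, size=(cfg.n_genera, 1))
    u = np.exp(base_g + _ABUNDANCE_LINK_SCALE * raw)
    abundance = AbundanceTable(
        df=pd.DataFrame(
            u / u.sum(axis=0, keepdims=True),
            index=pd.Index(genus_names, name="genus"),
            columns=abund_subjects,
        )
    )

    # --- truth tables -------------------------------------------------------
    probes_truth = pd.DataFrame(
        {
            "planted": planted_flag,
            "direction": direction_col,
            "span_effect": [cfg.age_span_effect if p else 0.0 for p in planted_flag],
            "region_id": region_col,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    genus_of_region = {r: "" for r in disease_of_region}
    for g, rid in enumerate(coupled_region):
        if rid and not genus_of_region[rid]:
            genus_of_region[rid] = genus_names[g]
    regions_truth = pd.DataFrame(
        {
            "chrom": [r["chrom"] for r in regions],
            "start": [int(r["positions"][0]) for r in regions],
            "end": [int(r["positions"][-1]) for r in regions],
            "n_cpgs": [len(r["positions"]) for r in regions],
            "direction": [r["direction"] for r in regions],
            "disease": [disease_of_region[r["region_id"]] for r in regions],
            "coupled_genus": [genus_of_region[r["region_id"]] for r in regions],
        },
        index=pd.Index([r["region_id"] for r in regions], name="region_id"),
    )
    genera_truth = pd.DataFrame(
        {
            "coupled_region": coupled_region,
            "coupling": [cfg.coupling if coupled_region[g] and trend_sign[g] else 0.0
                         for g in range(cfg.n_genera)],
            "trend_sign": trend_sign,
        },
        index=pd.Index(genus_names, name="genus"),
    )
    truth = TruthTable(probes=probes_truth, regions=regions_truth, genera=genera_truth)
    return Cohort(
        manifest=manifest, beta=beta, samples=samples,
        abundance=abundance, truth=truth, config=cfg,
    )


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write the five tables plus truth tables and config under ``outdir``.

    Returns a name -> path mapping of everything written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": out / "manifest.tsv",
        "beta": out / "beta.tsv",
        "samples": out / "samples.tsv",
        "abundance": out / "abundance.tsv",
        "truth_probes": out / "truth_probes.tsv",
        "truth_regions": out / "truth_regions.tsv",
        "truth_genera": out / "truth_genera.tsv",
        "config": out / "sim_config.json",
    }
    write_manifest(cohort.manifest, paths["manifest"])
    write_beta(cohort.beta, paths["beta"])
    write_samples(cohort.samples, paths["samples"])
    write_abundance(cohort.abundance, paths["abundance"])
    cohort.truth.probes.to_csv(paths["truth_probes"], sep="\t")
    cohort.truth.regions.to_csv(paths["truth_regions"], sep="\t")
    cohort.truth.genera.to_csv(paths["truth_genera"], sep="\t")
    cfg = asdict(cohort.config)
    cfg["cpgs_per_dmr"] = list(cfg["cpgs_per_dmr"])
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n", encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
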