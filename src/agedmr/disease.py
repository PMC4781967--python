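"""Disease (UC/CD) overlap testing at age-DMRs, and the enrichment contrasts.

For each DMR the per-subject average beta over member CpGs is compared
between controls and the disease group by the pooled two-sample Student t;
per-CpG t-tests are retained for the detailed table.  A DMR is
disease-overlapping when the DMR-average p is below 0.05.

The two enrichment contrasts summarise the overlap counts across all DMRs
with a two-tailed Fisher exact test:

* contrast 1 (UC vs CD): of all DMRs (both directions pooled), how many
  overlap UC vs how many overlap CD;
* contrast 2 (decreasing vs increasing, within UC): how many decreasing
  DMRs overlap UC vs how many increasing DMRs do.

Contrast 1 places the same DMR set in both columns (each DMR is tested once
per disease); the run summary flags that the two arms are paired, so the
Fisher p there is a descriptive contrast rather than a test on independent
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dmr import Dmr
from .errors import ConfigurationError
from .io import BetaMatrix, SampleSheet
from .stats import TwoByTwo, fisher_exact_two_tailed, student_t_test

log = logging.getLogger("agedmr")

__all__ = ["DmrDiseaseResult", "dmr_disease_test", "EnrichmentResult", "enrichment_tests"]


@dataclass(frozen=True)
class DmrDiseaseResult:
    """Control-vs-disease methylation test for one DMR."""

    dmr_id: str
    disease: str
    p_avg: float
    per_cpg_p: tuple[float, ...]
    significant: bool
    n_probes_used: int
    n_probes_dropped: int = 0


def dmr_disease_test(
    beta: BetaMatrix,
    samples: SampleSheet,
    dmrs: list[Dmr],
    disease: str,
    p_threshold: float = 0.05,
) -> list[DmrDiseaseResult]:
    """Test each DMR's average methylation between controls and one disease.

    A member probe with no data in either group is dropped from the average
    (logged); its per-CpG p is NaN.  Requires >= 2 subjects per group.
    """
    if disease not in ("UC", "CD"):
        raise ConfigurationError(f"disease must be 'UC' or 'CD', got {disease!r}")
    ctrl = [s for s in samples.subjects_in("control") if s in beta.subject_ids]
    dis = [s for s in samples.subjects_in(disease) if s in beta.subject_ids]
    if len(ctrl) < 2 or len(dis) < 2:
        raise ConfigurationError(
            f"need >= 2 subjects per group, have {len(ctrl)} control / "
            f"{len(dis)} {disease}"
        )
    results: list[DmrDiseaseResult] = []
    for d in dmrs:
        sub_c = beta.df.loc[list(d.probe_ids), ctrl].to_numpy(dtype=float)
        sub_d = beta.df.loc[list(d.probe_ids), dis].to_numpy(dtype=float)
        usable = ~(
            np.isnan(sub_c).all(axis=1) | np.isnan(sub_d).all(axis=1)
        )
        n_dropped = int((~usable).sum())
        if n_dropped:
            log.warning(
                "%s: dropped %d member probe(s) with no data in a group",
                d.dmr_id, n_dropped,
            )
        per_cpg = []
        for k in range(len(d.probe_ids)):
            if not usable[k]:
                per_cpg.append(float("nan"))
                continue
            per_cpg.append(student_t_test(sub_c[k], sub_d[k]))
        avg_c = np.nanmean(sub_c[usable], axis=0)
        avg_d = np.nanmean(sub_d[usable], axis=0)
        p_avg = student_t_test(avg_c, avg_d)
        results.append(
            DmrDiseaseResult(
                dmr_id=d.dmr_id,
                disease=disease,
                p_avg=p_avg,
                per_cpg_p=tuple(per_cpg),
                significant=bool(p_avg < p_threshold),
                n_probes_used=int(usable.sum()),
                n_probes_dropped=n_dropped,
            )
        )
    return results


@dataclass(frozen=True)
class EnrichmentResult:
    """The two Fisher contrasts over DMR-disease overlap counts."""

    p_uc_vs_cd: float
    p_dec_vs_inc_uc: float
    table_uc_vs_cd: TwoByTwo
    table_dec_vs_inc_uc: TwoByTwo


def enrichment_tests(
    n_dec: int,
    n_inc: int,
    uc_dec: int,
    uc_inc: int,
    cd_dec: int,
    cd_inc: int,
) -> EnrichmentResult:
    """Fisher exact enrichment contrasts from DMR overlap counts.

    Parameters are the decreasing/increasing DMR totals and, per disease,
    the number of DMRs in each direction that overlap it.
    """
    n_all = n_dec + n_inc
    uc = uc_dec + uc_inc
    cd = cd_dec + cd_inc
    for name, num, den in (
        ("UC/dec", uc_dec, n_dec), ("UC/inc", uc_inc, n_inc),
        ("CD/dec", cd_dec, n_dec), ("CD/inc", cd_inc, n_inc),
    ):
        if num > den:
            raise ValueError(f"overlap {name} = {num} exceeds its arm total {den}")
    t1 = TwoByTwo(uc, n_all - uc, cd, n_all - cd)
    t2 = TwoByTwo(uc_dec, n_dec - uc_dec, uc_inc, n_inc - uc_inc)
    return EnrichmentResult(
        p_uc_vs_cd=fisher_exact_two_tailed(t1),
        p_dec_vs_inc_uc=fisher_exact_two_tailed(t2),
        table_uc_vs_cd=t1,
        table_dec_vs_inc_uc=t2,
    )
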