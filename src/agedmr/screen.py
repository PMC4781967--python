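"""Per-CpG screening for age-dependent methylation.

A probe is *selected* when both filters pass on the control subjects:

1. Spearman correlation of beta with age is significant (two-sided
   p < ``p_threshold``, default 0.05);
2. the methylation difference between the oldest and the youngest subject,
   ``delta = beta(oldest) - beta(youngest)``, is at least ``delta_threshold``
   in absolute value (default 0.10, i.e. a 10-percentage-point drift over
   the observed age span).

Direction (increasing/decreasing) is assigned by the sign of rho, never by
delta: the selected lists are correlation-defined, and the rare probes where
noise flips the sign of delta relative to rho are admitted but counted in
the diagnostics.

Missing-value rules: a probe needs >= 3 complete (beta, age) pairs to be
screened at all; if the extreme-aged subject's beta is missing, delta falls
back to the nearest-aged subject with data and the record is flagged.
Subjects sharing the extreme age contribute the mean of their betas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import ConfigurationError, DegenerateInputError
from .io import BetaMatrix, SampleSheet
from .stats import EXACT_SPEARMAN_N, spearman

log = logging.getLogger("agedmr")

INCREASING = "increasing"
DECREASING = "decreasing"


@dataclass(frozen=True)
class CpGScreenRecord:
    """Age-screening statistics for one probe."""

    probe_id: str
    rho: float
    p_value: float
    delta: float
    n_used: int
    direction: str | None  # None for degenerate probes
    selected: bool
    sign_conflict: bool = False  # sign(rho) != sign(delta)
    delta_imputed: bool = False  # extreme-age beta missing, neighbour used


@dataclass
class ScreenResult:
    """All per-probe records plus the partitioned selected lists."""

    records: list[CpGScreenRecord]
    p_threshold: float
    delta_threshold: float
    n_degenerate: int = 0
    n_sign_conflicts: int = 0

    @property
    def selected(self) -> list[CpGScreenRecord]:
        return [r for r in self.records if r.selected]

    @property
    def increasing(self) -> list[CpGScreenRecord]:
        return [r for r in self.records if r.selected and r.direction == INCREASING]

    @property
    def decreasing(self) -> list[CpGScreenRecord]:
        return [r for r in self.records if r.selected and r.direction == DECREASING]


def _extreme_value(row: np.ndarray, order: np.ndarray, ages: np.ndarray) -> tuple[float, bool]:
    """Beta at the extreme age, walking inward past missing values.

    ``order`` sorts subjects so the wanted extreme comes first; subjects tied
    at the first age with data are averaged.  The second return value flags
    that the value is imputed (true extreme missing, or a tied subject
    missing).
    """
    extreme_age = ages[order[0]]
    for idx in order:
        if not np.isnan(row[idx]):
            at_age = np.flatnonzero(ages == ages[idx])
            have = at_age[~np.isnan(row[at_age])]
            imputed = (ages[idx] != extreme_age) or (have.size != at_age.size)
            return float(row[have].mean()), bool(imputed)
    return np.nan, True


def screen_age_cpgs(
    beta: BetaMatrix,
    samples: SampleSheet,
    p_threshold: float = 0.05,
    delta_threshold: float = 0.10,
) -> ScreenResult:
    """Screen every probe for age-dependent methylation in the controls.

    Returns one :class:`CpGScreenRecord` per probe with >= 3 complete values;
    degenerate (constant) probes get a record with ``direction=None`` and are
    excluded from both direction lists without aborting the run.

    Raises
    ------
    ConfigurationError
        If fewer than 3 control subjects with distinct ages are available.
    """
    controls = samples.subjects_in("control")
    controls = [s for s in controls if s in beta.subject_ids]
    if len(controls) < 3:
        raise ConfigurationError(
            f"need >= 3 control subjects with beta values, have {len(controls)}"
        )
    ages = samples.ages_of(controls)
    if np.unique(ages).size < 2:
        raise ConfigurationError("controls must span >= 2 distinct ages")

    B = beta.df[controls].to_numpy(dtype=float)
    n_probes, n_subj = B.shape
    probe_ids = list(beta.probe_ids)

    young_order = np.argsort(ages, kind="stable")
    old_order = young_order[::-1]

    complete = ~np.isnan(B).any(axis=1)
    rho = np.full(n_probes, np.nan)
    pval = np.full(n_probes, np.nan)
    n_used = np.full(n_probes, 0, dtype=int)
    degenerate = np.zeros(n_probes, dtype=bool)

    # Fast path: complete rows, vectorised rank correlation.  Only valid in
    # the t-approximation regime; small cohorts take the per-probe path so
    # the exact small-n p-value applies.
    fast = complete if n_subj > EXACT_SPEARMAN_N else np.zeros(n_probes, dtype=bool)
    if fast.any():
        rows = B[fast]
        const = np.ptp(rows, axis=1) == 0
        ranks = _sps.rankdata(rows, axis=1)
        age_rank = _sps.rankdata(ages)
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        ac = age_rank - age_rank.mean()
        denom = np.sqrt((rc**2).sum(axis=1) * (ac @ ac))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip((rc @ ac) / denom, -1.0, 1.0)
            t = r * np.sqrt((n_subj - 2) / (1.0 - r**2))
        p = 2.0 * _sps.t.sf(np.abs(t), df=n_subj - 2)
        p[np.abs(r) >= 1.0] = 0.0
        r[const] = np.nan
        p[const] = np.nan
        idx = np.flatnonzero(fast)
        rho[idx], pval[idx] = r, p
        n_used[idx] = n_subj
        degenerate[idx] = const

    for i in np.flatnonzero(~fast):
        row = B[i]
        try:
            res = spearman(ages, row)
        except DegenerateInputError:
            degenerate[i] = True
            n_used[i] = int((~np.isnan(row)).sum())
            continue
        except ValueError:
            degenerate[i] = True  # < 3 complete pairs: unanalysable
            n_used[i] = int((~np.isnan(row)).sum())
            continue
        rho[i], pval[i], n_used[i] = res.estimate, res.p_value, res.n_used

    # delta: oldest minus youngest, vectorised for complete rows; rows with
    # missing extremes (all-NaN slices included) are recomputed below
    young_ids = np.flatnonzero(ages == ages.min())
    old_ids = np.flatnonzero(ages == ages.max())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        delta = np.nanmean(B[:, old_ids], axis=1) - np.nanmean(B[:, young_ids], axis=1)
    imputed = np.zeros(n_probes, dtype=bool)
    extreme_missing = np.isnan(B[:, young_ids]).any(axis=1) | np.isnan(
        B[:, old_ids]
    ).any(axis=1)
    for i in np.flatnonzero(extreme_missing):
        y, imp_y = _extreme_value(B[i], young_order, ages)
        o, imp_o = _extreme_value(B[i], old_order, ages)
        delta[i] = o - y
        imputed[i] = imp_y or imp_o

    records: list[CpGScreenRecord] = []
    n_conflict = 0
    n_degen = 0
    for i in range(n_probes):
        if degenerate[i] or n_used[i] < 3:
            n_degen += 1
            records.append(
                CpGScreenRecord(
                    probe_id=probe_ids[i], rho=np.nan, p_value=np.nan,
                    delta=float(delta[i]), n_used=int(n_used[i]),
                    direction=None, selected=False,
                )
            )
            continue
        direction = INCREASING if rho[i] > 0 else DECREASING if rho[i] < 0 else None
        sel = (
            direction is not None
            and pval[i] < p_threshold
            and abs(delta[i]) >= delta_threshold
        )
        conflict = bool(
            sel and delta[i] != 0 and np.sign(rho[i]) != np.sign(delta[i])
        )
        n_conflict += conflict
        records.append(
            CpGScreenRecord(
                probe_id=probe_ids[i], rho=float(rho[i]), p_value=float(pval[i]),
                delta=float(delta[i]), n_used=int(n_used[i]),
                direction=direction, selected=bool(sel),
                sign_conflict=conflict, delta_imputed=bool(imputed[i]),
            )
        )
    if n_degen:
        log.info("screen: %d degenerate/unanalysable probe(s) excluded", n_degen)
    return ScreenResult(
        records=records,
        p_threshold=p_threshold,
        delta_threshold=delta_threshold,
        n_degenerate=n_degen,
        n_sign_conflicts=n_conflict,
    )


def null_selection_rate(
    ages: np.ndarray,
    noise_sd: float,
    n_reps: int = 10_000,
    p_threshold: float = 0.05,
    delta_threshold: float = 0.10,
    seed: int = 0,
) -> tuple[float, float]:
    """Joint null pass rate of the two screening filters, by direct simulation.

    Simulates ``n_reps`` independent null probes (constant true beta plus
    Gaussian noise of ``noise_sd``) over the given age vector, applies both
    filters, and returns (rate, Monte-Carlo standard error).  This is the
    calibration oracle for the screen's false-selection rate: the two filters
    are correlated, so the joint rate is below the product of the marginals
    and has no convenient closed form.
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    base = rng.uniform(0.1, 0.9, size=(n_reps, 1))
    B = np.clip(base + rng.normal(0.0, noise_sd, size=(n_reps, n)), 0.02, 0.98)
    ranks = _sps.rankdata(B, axis=1)
    age_rank = _sps.rankdata(ages)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    ac = age_rank - age_rank.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (ac @ ac))
    r = np.clip((rc @ ac) / denom, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * _sps.t.sf(np.abs(t), df=n - 2)
    young = np.flatnonzero(ages == ages.min())
    old = np.flatnonzero(ages == ages.max())
    delta = B[:, old].mean(axis=1) - B[:, young].mean(axis=1)
    passed = (p < p_threshold) & (np.abs(delta) >= delta_threshold)
    rate = float(passed.mean())
    se = float(np.sqrt(rate * (1.0 - rate) / n_reps))
    return rate, se
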