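import numpy as np
import pandas as pd
import pytest

from agedmr.io import BetaMatrix, ProbeManifest, SampleSheet
from agedmr.simulate import simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study: 22 controls, 5,000 probes, 20+20 regions."""
    return simulate_cohort(seed=42)


@pytest.fixture(scope="session")
def even_ages():
    """22 evenly spaced ages spanning 3.5-17.5 years (extremes included)."""
    return np.linspace(3.5, 17.5, 22)


def make_manifest(rows):
    """rows: (probe_id, chrom, pos[, genes set][, snp_flag])."""
    ids, chroms, pos, genes, snp = [], [], [], [], []
    for r in rows:
        ids.append(r[0])
        chroms.append(str(r[1]))
        pos.append(int(r[2]))
        genes.append(frozenset(r[3]) if len(r) > 3 else frozenset())
        snp.append(bool(r[4]) if len(r) > 4 else False)
    return ProbeManifest(
        df=pd.DataFrame(
            {"chrom": chroms, "pos": pos, "genes": genes, "snp_flag": snp},
            index=pd.Index(ids, name="probe_id"),
        )
    )


def make_samples(ages, groups=None, prefix="S"):
    ages = np.asarray(ages, dtype=float)
    groups = list(groups) if groups is not None else ["control"] * len(ages)
    ids = [f"{prefix}{i:02d}" for i in range(len(ages))]
    return SampleSheet(
        df=pd.DataFrame(
            {"age_years": ages, "group": groups},
            index=pd.Index(ids, name="subject_id"),
        )
    )


def make_beta(values, probe_ids, subject_ids):
    return BetaMatrix(
        df=pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index(list(probe_ids), name="probe_id"),
            columns=list(subject_ids),
        )
    )
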