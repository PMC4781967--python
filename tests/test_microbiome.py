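"""Genus-age trends and DMR-genus linkage rules."""

import numpy as np
import pytest

from agedmr.dmr import Dmr
from agedmr.errors import ConfigurationError
from agedmr.io import AbundanceTable
from agedmr.microbiome import genus_age_trends, link_dmrs_to_genera

from conftest import make_beta, make_samples


def abundance_of(rows, genus_ids, subject_ids):
    import pandas as pd
    return AbundanceTable(
        df=pd.DataFrame(np.asarray(rows, dtype=float),
                        index=pd.Index(genus_ids, name="genus"),
                        columns=list(subject_ids))
    )


@pytest.fixture
def ten_subjects():
    ages = np.linspace(4.0, 16.0, 10)
    return ages, make_samples(ages)


class TestGenusTrends:
    def test_exact_age_proportional_genus(self, ten_subjects):
        ages, samples = ten_subjects
        ab = abundance_of([0.01 * ages], ["Roseburia"], samples.subject_ids)
        (t,) = genus_age_trends(ab, samples)
        assert t.r == pytest.approx(1.0)
        assert t.selected and t.direction == "increasing"

    def test_constant_genus_excluded(self, ten_subjects):
        ages, samples = ten_subjects
        ab = abundance_of([[0.05] * 10, 0.01 * ages], ["Flat", "Up"],
                          samples.subject_ids)
        trends = genus_age_trends(ab, samples)
        assert [t.genus for t in trends] == ["Up"]

    def test_no_shared_subjects_is_configuration_error(self, ten_subjects):
        _, samples = ten_subjects
        ab = abundance_of([[0.1, 0.2, 0.3]], ["G"], ["X1", "X2", "X3"])
        with pytest.raises(ConfigurationError):
            genus_age_trends(ab, samples)

    def test_planted_trends_recovered_and_null_rate_calibrated(self):
        """Planted |r|=0.6 genera at n=10 against a simulation oracle."""
        rng = np.random.default_rng(3)
        n, r_true = 10, 0.6
        ages = np.linspace(4.0, 16.0, n)
        samples = make_samples(ages)
        z = (ages - ages.mean()) / ages.std()

        def draw(n_genera, coupled):
            rows = np.empty((n_genera, n))
            for g in range(n_genera):
                eps = rng.normal(size=n)
                s = r_true * z + np.sqrt(1 - r_true**2) * eps if coupled else eps
                rows[g] = 0.01 * np.exp(0.5 * s)
            return rows

        planted = draw(5, True)
        nulls = draw(20, False)
        ab = abundance_of(
            np.vstack([planted, nulls]),
            [f"P{g}" for g in range(5)] + [f"N{g}" for g in range(20)],
            samples.subject_ids,
        )
        trends = {t.genus: t for t in genus_age_trends(ab, samples)}
        planted_hits = sum(trends[f"P{g}"].selected for g in range(5))
        null_hits = sum(trends[f"N{g}"].selected for g in range(20))
        # oracle: same generative law, 5000 reps each
        o_planted = np.mean([
            genus_age_trends(
                abundance_of(draw(1, True), ["G"], samples.subject_ids), samples
            )[0].selected
            for _ in range(700)
        ])
        # null pass rate is the nominal level by construction; use it directly
        assert abs(planted_hits / 5 - o_planted) <= 3 * np.sqrt(
            o_planted * (1 - o_planted) * (1 / 5 + 1 / 700)
        )
        assert abs(null_hits / 20 - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / 20)


def linked_case(coupling, seed, n=10, k=3):
    """A k-CpG DMR and a genus sharing (or not) its latent signal."""
    rng = np.random.default_rng(seed)
    ages = np.linspace(4.0, 16.0, n)
    samples = make_samples(ages)
    cpgs = np.clip(0.6 - 0.018 * ages + rng.normal(0, 0.03, (k, n)), 0, 1)
    avg = cpgs.mean(axis=0)
    z = (avg - avg.mean()) / avg.std()
    raw = coupling * z + (1 - coupling) * rng.normal(size=n)
    ab = abundance_of([0.05 * np.exp(0.5 * raw)], ["G"], samples.subject_ids)
    probe_ids = [f"cg{i}" for i in range(k)]
    beta = make_beta(cpgs, probe_ids, samples.subject_ids)
    dmr = Dmr(dmr_id="dec-chr1-100", chrom="1", start=100, end=100 + k,
              probe_ids=tuple(probe_ids), direction="decreasing", mean_rho=-0.9)
    trends = genus_age_trends(ab, samples)
    return beta, ab, samples, dmr, trends


class TestLinkage:
    def test_affine_coupling_links_all_cpgs(self, ten_subjects):
        ages, samples = ten_subjects
        genus = 0.002 * ages
        cpgs = np.vstack([0.1 + 10 * genus, 0.2 + 5 * genus, 0.9 - 20 * genus])
        beta = make_beta(cpgs, ["cg0", "cg1", "cg2"], samples.subject_ids)
        ab = abundance_of([genus], ["G"], samples.subject_ids)
        dmr = Dmr(dmr_id="d", chrom="1", start=1, end=3,
                  probe_ids=("cg0", "cg1", "cg2"), direction="increasing",
                  mean_rho=0.9)
        trends = genus_age_trends(ab, samples)
        (link,) = link_dmrs_to_genera(beta, ab, samples, [dmr], trends)
        assert link.n_cpgs_passing == 3 and link.linked
        assert abs(link.avg_meth_r) > 0.99

    def test_single_passing_cpg_is_not_linked(self, ten_subjects):
        ages, samples = ten_subjects
        rng = np.random.default_rng(8)
        genus = 0.002 * ages

        def orthogonal_to(v, seed):
            # residual of a random vector after projecting out v and the mean
            r = np.random.default_rng(seed).normal(size=v.size)
            vc = v - v.mean()
            r = r - r.mean() - (r @ vc) / (vc @ vc) * vc
            return 0.4 + 0.05 * r / np.abs(r).max()

        cpgs = np.vstack([0.1 + 20 * genus,
                          orthogonal_to(genus, 1), orthogonal_to(genus, 2)])
        beta = make_beta(cpgs, ["cg0", "cg1", "cg2"], samples.subject_ids)
        ab = abundance_of([genus], ["G"], samples.subject_ids)
        dmr = Dmr(dmr_id="d", chrom="1", start=1, end=3,
                  probe_ids=("cg0", "cg1", "cg2"), direction="increasing",
                  mean_rho=0.9)
        (link,) = link_dmrs_to_genera(beta, ab, samples, [dmr],
                                      genus_age_trends(ab, samples))
        assert link.n_cpgs_passing == 1 and not link.linked

    def test_linked_monotone_in_thresholds(self):
        beta, ab, samples, dmr, trends = linked_case(0.5, seed=21)
        def n_pass(p_th):
            (l,) = link_dmrs_to_genera(beta, ab, samples, [dmr], trends,
                                       p_threshold=p_th, all_genera=True)
            return l.n_cpgs_passing
        assert n_pass(0.01) <= n_pass(0.1) <= n_pass(0.5)
        (strict,) = link_dmrs_to_genera(beta, ab, samples, [dmr], trends,
                                        min_cpgs=4, all_genera=True)
        (loose,) = link_dmrs_to_genera(beta, ab, samples, [dmr], trends,
                                       min_cpgs=1, all_genera=True)
        assert loose.linked >= strict.linked

    def test_coupled_pairs_detected_uncoupled_rare(self):
        hits = {0.7: 0, 0.0: 0}
        n_reps = 30
        for c in hits:
            for s in range(n_reps):
                beta, ab, samples, dmr, trends = linked_case(c, seed=1000 + s)
                (l,) = link_dmrs_to_genera(beta, ab, samples, [dmr], trends,
                                           all_genera=True)
                hits[c] += l.linked
        assert hits[0.7] >= 0.9 * n_reps
        assert hits[0.0] <= 0.3 * n_reps

    def test_row_and_column_order_irrelevant(self):
        beta, ab, samples, dmr, trends = linked_case(0.7, seed=4)
        (base,) = link_dmrs_to_genera(beta, ab, samples, [dmr], trends,
                                      all_genera=True)
        perm = np.random.default_rng(0).permutation(ab.df.shape[1])
        import pandas as pd
        ab2 = AbundanceTable(df=ab.df.iloc[:, perm])
        beta2 = make_beta(beta.df.to_numpy()[:, perm], beta.df.index,
                          np.asarray(beta.df.columns)[perm])
        (other,) = link_dmrs_to_genera(beta2, ab2, samples, [dmr], trends,
                                       all_genera=True)
        assert base.linked == other.linked
        assert base.n_cpgs_passing == other.n_cpgs_passing
        for (p1, r1, q1), (p2, r2, q2) in zip(base.per_cpg, other.per_cpg):
            assert p1 == p2 and r1 == pytest.approx(r2, abs=1e-12)

    def test_too_few_shared_subjects_is_configuration_error(self):
        beta, ab, samples, dmr, trends = linked_case(0.7, seed=4)
        import pandas as pd
        ab_small = AbundanceTable(df=ab.df.iloc[:, :2])
        with pytest.raises(ConfigurationError):
            link_dmrs_to_genera(beta, ab_small, samples, [dmr], trends)

    def test_undersized_dmr_reported_with_reason(self):
        beta, ab, samples, dmr, trends = linked_case(0.7, seed=4, k=3)
        import pandas as pd
        from agedmr.io import BetaMatrix
        df = beta.df.copy()
        df.loc[["cg1", "cg2"]] = np.nan  # only one analysable CpG remains
        (l,) = link_dmrs_to_genera(BetaMatrix(df=df), ab, samples, [dmr],
                                   trends, all_genera=True)
        assert not l.linked and l.reason is not None
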