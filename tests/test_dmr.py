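"""DMR chaining rules, idempotence and the chance-clustering null."""

import math

import numpy as np
import pytest

from agedmr.dmr import annotate_genes, call_dmrs, cluster_chance_probability
from agedmr.errors import ValidationError
from agedmr.screen import CpGScreenRecord

from conftest import make_manifest


def rec(probe_id, direction="decreasing", rho=-0.8):
    return CpGScreenRecord(probe_id=probe_id, rho=rho, p_value=0.01, delta=-0.2,
                           n_used=22, direction=direction, selected=True)


def manifest_at(positions, chrom="1"):
    return make_manifest([(f"cg{i}", chrom, p) for i, p in enumerate(positions)])


def records_for(manifest, direction="decreasing"):
    rho = -0.8 if direction == "decreasing" else 0.8
    return [rec(p, direction, rho) for p in manifest.probe_ids]


class TestChaining:
    def test_gap_rule_drops_distant_singleton(self):
        m = manifest_at([1000, 10000, 30000])
        dmrs = call_dmrs(records_for(m), m)
        assert len(dmrs) == 1
        assert dmrs[0].probe_ids == ("cg0", "cg1")
        assert (dmrs[0].start, dmrs[0].end) == (1000, 10000)

    def test_boundary_gap_chains(self):
        positions = [1000 + 14999 * i for i in range(5)]
        m = manifest_at(positions)
        dmrs = call_dmrs(records_for(m), m)
        assert len(dmrs) == 1 and dmrs[0].n_cpgs == 5
        assert dmrs[0].end - dmrs[0].start == 59_996

    def test_gap_of_exactly_15000_chains(self):
        m = manifest_at([1000, 16000])
        assert len(call_dmrs(records_for(m), m)) == 1

    def test_all_gaps_too_large_yields_nothing(self):
        m = manifest_at([1000, 20000, 40000])
        assert call_dmrs(records_for(m), m) == []

    def test_chromosomes_never_chain_together(self):
        m = make_manifest([("cg0", "1", 1000), ("cg1", "2", 1500)])
        assert call_dmrs(records_for(m), m) == []

    def test_mixed_directions_rejected(self):
        m = manifest_at([1000, 2000])
        with pytest.raises(ValidationError, match="direction"):
            call_dmrs([rec("cg0", "decreasing"), rec("cg1", "increasing", 0.8)], m)

    def test_probe_absent_from_manifest_names_probe(self):
        m = manifest_at([1000])
        with pytest.raises(ValidationError, match="cgZZ"):
            call_dmrs([rec("cgZZ")], m)

    def test_mean_rho_is_member_average(self):
        m = manifest_at([1000, 2000])
        records = [rec("cg0", rho=-0.6), rec("cg1", rho=-1.0)]
        assert call_dmrs(records, m)[0].mean_rho == pytest.approx(-0.8)


class TestInvariances:
    def _random_case(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.unique(rng.integers(1, 500_000, size=30))
        return manifest_at(pos)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_input_order_irrelevant_and_partition_complete(self, seed):
        m = self._random_case(seed)
        records = records_for(m)
        rng = np.random.default_rng(seed + 100)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = call_dmrs(records, m)
        b = call_dmrs(shuffled, m)
        assert a == b
        member = {p for d in a for p in d.probe_ids}
        singles = {r.probe_id for r in records} - member
        assert member | singles == {r.probe_id for r in records}

    @pytest.mark.parametrize("seed", [3, 4])
    def test_idempotence_on_called_members(self, seed):
        m = self._random_case(seed)
        records = records_for(m)
        dmrs = call_dmrs(records, m)
        members = {p for d in dmrs for p in d.probe_ids}
        again = call_dmrs([r for r in records if r.probe_id in members], m)
        assert again == dmrs

    def test_wider_gap_never_drops_more_singletons(self):
        m = self._random_case(7)
        records = records_for(m)
        n = len(records)
        dropped = []
        for gap in (2000, 15000, 50000):
            dmrs = call_dmrs(records, m, max_gap=gap)
            dropped.append(n - sum(d.n_cpgs for d in dmrs))
        assert dropped == sorted(dropped, reverse=True)


class TestAnnotation:
    def test_gene_union_and_fraction(self):
        m = make_manifest([
            ("cg0", "1", 1000, {"A"}), ("cg1", "1", 2000, {"A", "B"}),
            ("cg2", "1", 40000, set()), ("cg3", "1", 41000, set()),
        ])
        dmrs = call_dmrs(records_for(m), m)
        assert len(dmrs) == 2
        annotated, frac = annotate_genes(dmrs, m)
        assert annotated[0].genes == frozenset({"A", "B"})
        assert annotated[1].genes == frozenset()
        assert frac == pytest.approx(0.5)

    def test_paper_style_fraction(self):
        # 23 regions, 19 gene-associated: fraction 19/23
        rows = []
        for i in range(23):
            genes = {f"G{i}"} if i < 19 else set()
            rows.append((f"cgA{i}", "1", 1_000_000 * (i + 1), genes))
            rows.append((f"cgB{i}", "1", 1_000_000 * (i + 1) + 500, genes))
        m = make_manifest(rows)
        dmrs, frac = annotate_genes(call_dmrs(records_for(m), m), m)
        assert len(dmrs) == 23
        assert frac == pytest.approx(19 / 23)


class TestClusterChance:
    def test_zero_gap_with_distinct_positions(self):
        m = manifest_at(list(range(1000, 1000 + 50 * 100, 100)))
        res = cluster_chance_probability(2, m, max_gap=0, n_reps=200, seed=1)
        assert res.p_any_chain == 0.0

    def test_certain_chain_when_all_probes_close(self):
        m = manifest_at([1000, 2000, 3000])
        res = cluster_chance_probability(3, m, n_reps=200, seed=1)
        assert res.p_any_chain == 1.0

    def test_exact_pair_probability_matches_enumeration(self):
        # 100 probes spaced 100 kb apart plus one adjacent: 1 chainable pair
        positions = [1 + 100_000 * i for i in range(100)] + [1 + 100_000 * 99 + 500]
        m = manifest_at(positions)
        exact = cluster_chance_probability(2, m, n_reps=200, seed=0)
        assert exact.exact
        assert exact.p_any_chain == pytest.approx(1 / math.comb(101, 2))
        mc = cluster_chance_probability(2, m, n_reps=10_000, seed=11,
                                        exact_pairs=False)
        se = max(mc.p_any_chain_se, math.sqrt(exact.p_any_chain
                                              * (1 - exact.p_any_chain) / 10_000))
        assert abs(mc.p_any_chain - exact.p_any_chain) <= 3 * se

    def test_oversized_selection_rejected(self):
        m = manifest_at([1000, 2000])
        with pytest.raises(ValidationError):
            cluster_chance_probability(5, m, n_reps=200)
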