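"""Per-probe Welch statistics and windowed DMR calling."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from promdmr import (
    DMR,
    DMRSet,
    ProbeSignalMatrix,
    ProbeStat,
    call_dmrs,
    dmr_genes,
    probe_stats,
    welch_t,
)


class TestWelch:
    def test_closed_form_fixture(self):
        # SZ=[1,2,3], CT=[4,5,6]: t = -3/sqrt(2/3), df = 4 exactly
        t, df, diff = welch_t(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert t == pytest.approx(-3.0 * math.sqrt(1.5), rel=1e-12)
        assert df == pytest.approx(4.0, rel=1e-12)
        assert diff == -3.0

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        case = rng.normal(0.3, 1.2, size=(50, 20))
        ctrl = rng.normal(0.0, 0.8, size=(50, 25))
        t, df, _ = welch_t(case, ctrl, axis=1)
        ref = sps.ttest_ind(case, ctrl, axis=1, equal_var=False)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(df, ref.df, rtol=1e-10)

    def test_zero_variance_uses_floor_not_nan(self):
        t, df, _ = welch_t(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0, 2.0]))
        assert t == 0.0 and np.isfinite(df)

    def test_group_smaller_than_two_rejected(self):
        with pytest.raises(ValueError):
            welch_t(np.array([1.0]), np.array([1.0, 2.0]))


class TestProbeStats:
    def test_identical_groups_give_zero_t(self, tiny_universe, small_sheet):
        probe_ids = [p.probe_id for p in tiny_universe.probes]
        values = np.full((len(probe_ids), 6), 3.0)
        m = ProbeSignalMatrix(values, probe_ids, small_sheet.sample_ids, small_sheet)
        stats = probe_stats(m)
        assert all(s.t_value == 0.0 and s.mean_diff == 0.0 for s in stats)

    def test_fixture_statistic_and_direction(self, small_matrix):
        stats = probe_stats(small_matrix)
        for s in stats:
            assert s.t_value == pytest.approx(-3.0 * math.sqrt(1.5), rel=1e-10)
            assert s.mean_diff == -3.0 and s.df == pytest.approx(4.0)

    def test_invariant_under_sample_shuffling(self, small_matrix):
        rng = np.random.default_rng(1)
        small_matrix.values += rng.normal(0, 0.3, size=small_matrix.values.shape)
        base = probe_stats(small_matrix)
        perm = rng.permutation(len(small_matrix.sample_ids))
        shuffled = ProbeSignalMatrix(
            small_matrix.values[:, perm],
            small_matrix.probe_ids,
            [small_matrix.sample_ids[i] for i in perm],
            small_matrix.sheet,
        )
        for a, b in zip(base, probe_stats(shuffled)):
            assert a.t_value == pytest.approx(b.t_value, rel=1e-12)


def stats_for(universe, t_by_probe, diff_sign=1.0):
    return [
        ProbeStat(p.probe_id, t_by_probe.get(p.probe_id, 0.0),
                  diff_sign * t_by_probe.get(p.probe_id, 0.0), 20.0)
        for p in universe.probes
    ]


class TestCallDmrs:
    def test_all_zero_stats_yield_empty_set(self, tiny_universe):
        out = call_dmrs(stats_for(tiny_universe, {}), tiny_universe, threshold_p=1e-5)
        assert len(out) == 0

    def test_single_window_closed_form(self, tiny_universe):
        # one promoter, 4 probes each t=3: S = 4*3/sqrt(4) = 6, p = erfc(6/sqrt 2)
        t_map = {f"prom1_P{j+1}": 3.0 for j in range(4)}
        out = call_dmrs(stats_for(tiny_universe, t_map), tiny_universe,
                        threshold_p=1e-5, cell_type="neuron")
        assert len(out) == 1
        d = out.dmrs[0]
        assert d.score == pytest.approx(6.0)
        assert d.p_value == pytest.approx(2.0 * sps.norm.sf(6.0), rel=1e-9)
        assert d.p_value == pytest.approx(1.973e-9, rel=1e-3)
        assert d.direction == "hyper" and d.promoter_id == "prom1"
        assert d.n_probes == 4

    def test_hypomethylated_direction_from_negative_diffs(self, tiny_universe):
        t_map = {f"prom2_P{j+1}": -4.0 for j in range(4)}
        out = call_dmrs(stats_for(tiny_universe, t_map), tiny_universe, threshold_p=1e-3)
        assert out.dmrs[0].direction == "hypo"

    def test_threshold_monotonicity(self, planted_dataset):
        _, universe, matrices, _ = planted_dataset
        stats = probe_stats(matrices["neuron"])
        sets = {
            thr: {(d.promoter_id, d.start, d.end)
                  for d in call_dmrs(stats, universe, threshold_p=thr).dmrs}
            for thr in (1e-8, 1e-5, 1e-3)
        }
        assert sets[1e-8] <= sets[1e-5] <= sets[1e-3]

    def test_merging_collapses_overlapping_windows(self, tiny_universe):
        # extend prom1 with more probes so two overlapping windows both pass
        from promdmr import Probe, PromoterUniverse

        extra = [
            Probe(f"prom1_X{j}", "prom1", "chr1", 1000 + 480 + j * 60, 1000 + 500 + j * 60)
            for j in range(2)
        ]
        u = PromoterUniverse(list(tiny_universe.promoters), tiny_universe.probes + extra)
        t_map = {p.probe_id: 4.0 for p in u.probes if p.promoter_id == "prom1"}
        out = call_dmrs(stats_for(u, t_map), u, threshold_p=1e-4)
        from_prom1 = [d for d in out.dmrs if d.promoter_id == "prom1"]
        assert len(from_prom1) == 1  # three overlapping windows, merged
        assert from_prom1[0].n_probes == 6

    def test_permutation_requires_matrix_and_enough_perms(self, tiny_universe, small_matrix):
        stats = probe_stats(small_matrix)
        with pytest.raises(ValueError):
            call_dmrs(stats, tiny_universe, null="permutation")
        with pytest.raises(ValueError):
            call_dmrs(stats, tiny_universe, null="permutation",
                      matrix=small_matrix, n_perm=50)

    def test_permutation_deterministic_under_seed(self, planted_dataset):
        _, universe, matrices, _ = planted_dataset
        m = matrices["neuron"]
        stats = probe_stats(m)
        kw = dict(threshold_p=1e-2, null="permutation", n_perm=300, seed=9, matrix=m)
        a = call_dmrs(stats, universe, **kw)
        b = call_dmrs(stats, universe, **kw)
        assert [(d.promoter_id, d.p_value, d.score) for d in a.dmrs] == [
            (d.promoter_id, d.p_value, d.score) for d in b.dmrs
        ]

    def test_analytic_and_permutation_p_agree_without_correlation(self):
        # single-window promoters (4 probes), independent noise: the two nulls
        # estimate the same tail, so log10 p should agree within 0.3
        from promdmr import SimConfig, generate_methylation_dataset, generate_universe

        cfg = SimConfig(n_promoters=150, probes_per_promoter=4, n_case=35, n_control=35,
                        dmr_fraction=0.0, probe_correlation=0.0, noise_sd=0.5, seed=21)
        u = generate_universe(cfg)
        m = generate_methylation_dataset(u, cfg)[0]["neuron"]
        stats = probe_stats(m)
        ana = call_dmrs(stats, u, threshold_p=1.0 - 1e-12, null="analytic")
        per = call_dmrs(stats, u, threshold_p=1.0 - 1e-12, null="permutation",
                        n_perm=4000, seed=3, matrix=m)
        p_ana = {d.promoter_id: d.p_value for d in ana.dmrs}
        p_per = {d.promoter_id: d.p_value for d in per.dmrs}
        deltas = [
            abs(math.log10(pa) - math.log10(p_per[pid]))
            for pid, pa in p_ana.items()
            if 0.02 <= pa <= 0.5  # range resolvable by 4000 permutations
        ]
        assert len(deltas) >= 20
        # the permutation null conditions on realized between-probe sample
        # correlation, so individual promoters fluctuate; agreement is
        # distributional: typical discrepancy well under 0.3 dex
        assert float(np.median(deltas)) < 0.15
        assert np.mean(np.array(deltas) < 0.3) >= 0.9

    def test_short_promoters_are_skipped(self, tiny_universe):
        out = call_dmrs(stats_for(tiny_universe, {}), tiny_universe,
                        min_probes=6, threshold_p=0.5)
        assert len(out) == 0


class TestDmrGenes:
    def mk(self, i, promoter, gene):
        return DMR(f"neuron_dmr_{i:05d}", "chr1", 100 * i, 100 * i + 50, promoter, gene,
                   4, 6.0, 1e-9, "hyper", "neuron")

    def test_multiple_dmrs_in_one_promoter_collapse(self, tiny_universe):
        dmrs = DMRSet([self.mk(1, "prom1", "GENE_A"), self.mk(2, "prom1", "GENE_A")],
                      1e-5, "relaxed", "neuron")
        assert dmr_genes(dmrs, tiny_universe) == ["GENE_A"]

    def test_empty_set_gives_empty_list(self, tiny_universe):
        empty = DMRSet([], 1e-5, "relaxed", "neuron")
        assert dmr_genes(empty, tiny_universe) == []

    def test_multiplicity_structure_91_dmrs_69_genes(self):
        # 22 promoters with two DMRs + 47 with one = 91 DMRs over 69 genes
        from promdmr import Probe, Promoter, PromoterUniverse

        promoters, probes, dmrs = [], [], []
        i = 0
        for g in range(69):
            pid, gene = f"prom{g}", f"GENE{g}"
            start = 1000 + g * 2000
            promoters.append(Promoter(pid, "chr1", start, start + 1000, "+", gene))
            probes.append(Probe(f"{pid}_P1", pid, "chr1", start + 10, start + 60))
            for _ in range(2 if g < 22 else 1):
                i += 1
                dmrs.append(self.mk(i, pid, gene))
        u = PromoterUniverse(promoters, probes)
        dmr_set = DMRSet(dmrs, 1e-5, "relaxed", "neuron")
        assert len(dmr_set) == 91
        assert len(dmr_genes(dmr_set, u)) == 69
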