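"""Drift-null simulator: standing variation, drift, region clustering."""

import math

import numpy as np
import pytest
from scipy import stats

from poolsweep._wf import Chromosome, SimPopulation
from poolsweep.driftsim import (
    DriftSimConfig,
    differentiated_regions,
    evolve_neutral,
    init_standing_variation,
    merged_line_counts,
    run_drift_null,
    window_fst_from_counts,
    _drift_generations,
)

SMALL = dict(locus_length=200_000, n_replicates=2, seed=0)


class TestStandingVariation:
    def test_zero_mutation_rate_no_sites(self):
        cfg = DriftSimConfig(mu=0.0, **SMALL)
        pop = init_standing_variation(cfg, np.random.default_rng(1))
        assert pop.n_sites == 0

    def test_watterson_segregating_sites(self):
        cfg = DriftSimConfig(**SMALL)
        rng = np.random.default_rng(2)
        n_hap = 4 * cfg.n_line  # 2 lines x n_line diploids
        theta_l = 4 * cfg.ne_ancestral * cfg.mu * cfg.locus_length
        expected = theta_l * sum(1 / i for i in range(1, n_hap))
        counts = [init_standing_variation(cfg, rng).n_sites for _ in range(10)]
        assert np.mean(counts) == pytest.approx(expected, rel=0.15)

    def test_site_frequency_spectrum_shape(self):
        # expected unfolded SFS: E[# sites at derived count i] = theta*L/i.
        # Counts within a replicate are genealogically correlated (far from
        # independent Poisson), so the check is a per-bin ratio band over
        # aggregated replicates rather than a chi-square test.
        cfg = DriftSimConfig(**SMALL)
        rng = np.random.default_rng(3)
        n_hap = 4 * cfg.n_line
        theta_l = 4 * cfg.ne_ancestral * cfg.mu * cfg.locus_length
        reps = 20
        observed = np.zeros(n_hap - 1)
        for _ in range(reps):
            pop = init_standing_variation(cfg, rng)
            for c in pop.allele_counts():
                if 0 < c < n_hap:
                    observed[c - 1] += 1
        expected = reps * theta_l / np.arange(1, n_hap)
        for i in (0, 1, 2):
            assert observed[i] == pytest.approx(expected[i], rel=0.4)
        assert observed[9:].sum() == pytest.approx(expected[9:].sum(), rel=0.4)
        # strictly decreasing on aggregate: singletons dominate
        assert observed[0] > observed[1] > observed[4]

    def test_positions_within_locus_and_sorted(self):
        cfg = DriftSimConfig(**SMALL)
        pop = init_standing_variation(cfg, np.random.default_rng(4))
        assert pop.positions.min() >= 1
        assert pop.positions.max() <= cfg.locus_length
        assert np.all(np.diff(pop.positions) >= 0)


class TestEvolveNeutral:
    def test_zero_generations_identity(self):
        cfg = DriftSimConfig(generations=0, **SMALL)
        rng = np.random.default_rng(5)
        pop = init_standing_variation(cfg, rng)
        line1, line2 = evolve_neutral(pop, cfg, rng)
        half = cfg.n_line
        f1 = pop.subset_individuals(np.arange(half)).allele_frequencies()
        assert np.array_equal(line1.allele_frequencies(), f1)

    @staticmethod
    def _het_founders():
        # every individual heterozygous: p = 0.5 in both sexes
        H = np.zeros((50, 1), dtype=np.uint8)
        H[0::2, 0] = 1
        return H

    def _drift_variance(self, cfg, seed, reps=1500):
        genome = (Chromosome("locus", 1000, 0.0),)
        rng = np.random.default_rng(seed)
        H = self._het_founders()
        finals = []
        for _ in range(reps):
            pop = SimPopulation(
                haplotypes=H.copy(),
                positions=np.array([500.0]),
                chrom_ids=np.array([0], dtype=np.int32),
                genome=genome,
            )
            finals.append(_drift_generations(pop, cfg, rng).allele_frequencies()[0])
        return float(np.var(finals))

    def test_multi_generation_drift_variance_sex_structured(self):
        # Ne = 4*20*5/25 = 16 from the breeding sex ratio; over t generations
        # Var(p_t) = pq (1 - (1 - 1/2Ne)^t).  (A single generation from a
        # fixed parent pool gives pq/2N instead; the sex-ratio Ne is the
        # long-run rate.)
        cfg = DriftSimConfig(
            locus_length=1000, mu=0.0, generations=10, sex_structured=True, seed=0
        )
        var = self._drift_variance(cfg, seed=6)
        expected = 0.25 * (1 - (1 - 1 / 32) ** 10)
        assert var == pytest.approx(expected, rel=0.2)

    def test_multi_generation_drift_variance_unstructured(self):
        cfg = DriftSimConfig(locus_length=1000, mu=0.0, generations=10, seed=0)
        var = self._drift_variance(cfg, seed=7)
        expected = 0.25 * (1 - (1 - 1 / 50) ** 10)
        assert var == pytest.approx(expected, rel=0.2)


class TestDifferentiatedRegions:
    def test_no_fixed_opposite_sites_empty(self):
        pos = np.array([100.0, 200.0])
        assert differentiated_regions(pos, np.array([1.0, 0.5]), np.array([1.0, 0.5])) == []

    def test_two_sites_form_one_region(self):
        pos = np.array([10_000.0, 20_000.0])
        regions = differentiated_regions(
            pos, np.array([1.0, 0.0]), np.array([0.0, 1.0]), cluster_gap=50_000
        )
        assert len(regions) == 1
        assert regions[0].length == pytest.approx(10_000)
        assert regions[0].n_sites == 2

    def test_gap_at_cluster_gap_splits(self):
        pos = np.array([0.0, 50_000.0])
        regions = differentiated_regions(
            pos, np.array([1.0, 1.0]), np.array([0.0, 0.0]), cluster_gap=50_000
        )
        assert len(regions) == 2

    def test_fst_threshold_mode(self):
        pos = np.array([100.0, 200.0, 300.0])
        f1 = np.array([0.95, 0.5, 1.0])
        f2 = np.array([0.05, 0.5, 0.0])
        strict = differentiated_regions(pos, f1, f2, cluster_gap=1000)
        assert sum(r.n_sites for r in strict) == 1
        loose = differentiated_regions(pos, f1, f2, cluster_gap=1000, fst_threshold=0.8)
        assert sum(r.n_sites for r in loose) == 2

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            pos = np.sort(rng.choice(np.arange(1, 500_000, dtype=float), n, replace=False))
            f1 = rng.choice([0.0, 0.5, 1.0], size=n)
            f2 = rng.choice([0.0, 0.5, 1.0], size=n)
            gap = int(rng.integers(1_000, 100_000))
            got = differentiated_regions(pos, f1, f2, cluster_gap=gap)
            diff = sorted(
                p
                for p, a, b in zip(pos, f1, f2)
                if (a == 1.0 and b == 0.0) or (a == 0.0 and b == 1.0)
            )
            expected = []
            cluster = []
            for p in diff:
                if cluster and p - cluster[-1] < gap:
                    cluster.append(p)
                else:
                    if cluster:
                        expected.append((cluster[0], cluster[-1], len(cluster)))
                    cluster = [p]
            if cluster:
                expected.append((cluster[0], cluster[-1], len(cluster)))
            assert [(r.start, r.end, r.n_sites) for r in got] == expected


class TestRunDriftNull:
    def test_deterministic_under_seed(self):
        cfg = DriftSimConfig(locus_length=200_000, generations=5, n_replicates=2, seed=42)
        a = run_drift_null(cfg).to_dict()
        b = run_drift_null(cfg).to_dict()
        assert a == b

    def test_zero_generations_no_regions(self):
        cfg = DriftSimConfig(locus_length=200_000, generations=0, n_replicates=1, seed=9)
        s = run_drift_null(cfg)
        assert s.frac_replicates_with_region == 0.0
        assert s.pct_sequence_differentiated == 0.0

    def test_higher_recombination_shorter_regions(self):
        lengths = {}
        for rec in (2.8, 6.4):
            cfg = DriftSimConfig(
                locus_length=2_000_000, rec_rate=rec, n_replicates=8, seed=7
            )
            s = run_drift_null(cfg, compute_window_fst=False)
            flat = [x for rep in s.region_lengths for x in rep]
            lengths[rec] = np.mean(flat)
        assert lengths[2.8] > lengths[6.4]

    def test_large_lines_drift_vanishes(self):
        cfg = DriftSimConfig(
            locus_length=200_000, n_line=200, generations=5, n_replicates=2, seed=11
        )
        s = run_drift_null(cfg, compute_window_fst=False)
        assert s.frac_replicates_with_region == 0.0


class TestCrossModuleConsistency:
    def test_window_fst_matches_popstats_on_exhaustive_reads(self):
        from poolsweep.pooldata import PooledSiteCounts
        from poolsweep import popstats

        cfg = DriftSimConfig(locus_length=100_000, generations=10, n_replicates=1, seed=13)
        rng = np.random.default_rng(cfg.seed)
        founders = init_standing_variation(cfg, rng)
        line1, line2 = evolve_neutral(founders, cfg, rng)
        pos, c1, c2 = merged_line_counts(line1, line2)
        n = 2 * cfg.n_line
        # keep integer founder positions so sync coordinates are exact
        keep = pos == np.floor(pos)
        pos, c1, c2 = pos[keep], c1[keep], c2[keep]
        direct = window_fst_from_counts(
            pos, c1, n, c2, n, cfg.locus_length, window=1000, step=500
        )
        sites = [
            PooledSiteCounts(
                "locus",
                int(p),
                "A",
                np.array(
                    [[int(a), 0, 0, n - int(a), 0, 0], [int(b), 0, 0, n - int(b), 0, 0]]
                ),
            )
            for p, a, b in zip(pos, c1, c2)
        ]
        wins = popstats.window_fst(
            sites,
            min_count=1,
            min_covered_fraction=0.0,
            chrom_sizes={"locus": cfg.locus_length},
        )
        via_popstats = np.array([w.fst for w in wins if not math.isnan(w.fst)])
        assert len(via_popstats) == len(direct)
        np.testing.assert_allclose(via_popstats, direct, rtol=1e-9, atol=1e-12)
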