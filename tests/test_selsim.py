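"""Selection-experiment generator: response, pooling, F2 panel."""

import numpy as np
import pytest

from poolsweep._wf import Chromosome, SimPopulation
from poolsweep.selsim import (
    ExperimentResult,
    SelectionSimConfig,
    TraitModel,
    sample_pools,
    simulate_experiment,
    simulate_f2,
)

TINY = dict(
    genome=(Chromosome("chr1", 2_000_000, 2.8),),
    generations=8,
    relax_at=4,
    relax_generations=3,
    founder_ne=300,
    founder_mu=2e-8,
)


@pytest.fixture(scope="module")
def tiny_experiment():
    cfg = SelectionSimConfig(seed=101, **TINY)
    return cfg, simulate_experiment(cfg, np.random.default_rng(cfg.seed))


class TestSimulateExperiment:
    def test_reproducible_under_seed(self):
        cfg = SelectionSimConfig(seed=55, **TINY)
        a = simulate_experiment(cfg, np.random.default_rng(cfg.seed))
        b = simulate_experiment(cfg, np.random.default_rng(cfg.seed))
        assert a.trait_means.equals(b.trait_means)
        assert np.array_equal(
            a.populations["HighSel"].haplotypes, b.populations["HighSel"].haplotypes
        )

    def test_null_architecture_diverges_only_by_drift(self):
        cfg = SelectionSimConfig(
            n_qtl=1, qtl_effects=(0.0,), seed=77, phenotype_floor=None, **TINY
        )
        exp = simulate_experiment(cfg, np.random.default_rng(cfg.seed))
        tm = exp.trait_means
        last = tm[tm.generation == tm.generation.max()]
        hi = last[last.line == "HighSel"].mean_phenotype.mean()
        lo = last[last.line == "LowSel"].mean_phenotype.mean()
        # zero genetic variance: difference is sampling noise of the means
        assert abs(hi - lo) < 2.0

    def test_selected_lines_diverge(self, tiny_experiment):
        _, exp = tiny_experiment
        tm = exp.trait_means
        for line, sign in (("HighSel", +1), ("LowSel", -1)):
            sub = tm[(tm.line == line) & (tm.sex == "F")].sort_values("generation")
            response = sign * (sub.mean_phenotype.iloc[-1] - sub.mean_phenotype.iloc[0])
            assert response > 1.0

    def test_relaxed_lines_flat_after_branching(self):
        cfg = SelectionSimConfig(
            seed=33,
            genome=(Chromosome("chr1", 2_000_000, 2.8),),
            generations=16,
            relax_at=6,
            relax_generations=10,
            founder_ne=300,
            founder_mu=2e-8,
        )
        exp = simulate_experiment(cfg, np.random.default_rng(cfg.seed))
        tm = exp.trait_means
        for line in ("HighRelax", "LowRelax"):
            sub = tm[(tm.line == line) & (tm.sex == "F")].sort_values("generation")
            drift = abs(sub.mean_phenotype.iloc[-1] - sub.mean_phenotype.iloc[0])
            assert drift < 2.5  # no sustained directional response

    def test_single_large_qtl_fixes_opposite_alleles(self):
        cfg = SelectionSimConfig(
            n_qtl=1, qtl_effects=(3.0,), simulate_relaxed=False, seed=13,
            genome=(Chromosome("chr1", 2_000_000, 2.8),),
            generations=20, relax_at=10, founder_ne=300, founder_mu=2e-8,
        )
        exp = simulate_experiment(cfg, np.random.default_rng(cfg.seed))
        cols = exp.trait_model.qtl_columns(exp.populations["HighSel"])
        p_hi = exp.populations["HighSel"].allele_frequencies()[cols][0]
        p_lo = exp.populations["LowSel"].allele_frequencies()[cols][0]
        assert abs(p_hi - p_lo) > 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SelectionSimConfig(parents_early=(40, 28))
        with pytest.raises(ValueError):
            SelectionSimConfig(h2=1.5)
        with pytest.raises(ValueError):
            SelectionSimConfig(relax_at=50)


def _uniform_half_population(n_ind, n_sites, length=100_000):
    """Population where every site has frequency exactly 0.5."""
    genome = (Chromosome("chr1", length, 0.0),)
    H = np.zeros((2 * n_ind, n_sites), dtype=np.uint8)
    H[0::2] = 1
    return SimPopulation(
        haplotypes=H,
        positions=np.linspace(1000, length - 1000, n_sites).round().astype(float),
        chrom_ids=np.zeros(n_sites, dtype=np.int32),
        genome=genome,
        sex=np.array([0] * (n_ind // 3) + [1] * (n_ind - n_ind // 3), dtype=np.int8),
    )


def _experiment_from_population(pop, config):
    n_sites = pop.n_sites
    trait = TraitModel(
        qtl_chrom_ids=np.zeros(0, dtype=np.int32),
        qtl_positions=np.zeros(0),
        effects=np.zeros(0),
        founder_dosage_means=np.zeros(0),
        sigma_e=1.0,
        sex_effect=0.0,
        trait_mean=8.0,
        floor=None,
    )
    import pandas as pd

    return ExperimentResult(
        populations={"HighSel": pop, "LowSel": pop, "HighRelax": pop, "LowRelax": pop},
        trait_model=trait,
        trait_means=pd.DataFrame(),
        ref_bases=np.array(["A"] * n_sites),
        alt_bases=np.array(["G"] * n_sites),
        config=config,
    )


class TestSamplePools:
    def test_read_frequency_sampling_variance(self, rng):
        # at true frequency 0.5 and depth ~35: Var(p_hat) ~ pq/depth
        pop = _uniform_half_population(40, 400)
        cfg = SelectionSimConfig(mean_depth=(35.0,) * 4, **TINY)
        exp = _experiment_from_population(pop, cfg)
        sites = sample_pools(exp, rng)
        freqs, depths = [], []
        for s in sites:
            cov = s.counts[0].sum()
            if cov > 0:
                freqs.append(s.counts[0, 3] / cov)
                depths.append(cov)
        # pool of 30 from the 40: pooled freq stays exactly 0.5 (all hets)
        mean_d = np.mean(depths)
        expected_var = 0.25 / mean_d
        assert np.var(freqs) == pytest.approx(expected_var, rel=0.35)
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.02)

    def test_high_depth_converges_to_pool_frequency(self, rng):
        pop = _uniform_half_population(40, 100)
        cfg = SelectionSimConfig(mean_depth=(5000.0,) * 4, **TINY)
        exp = _experiment_from_population(pop, cfg)
        sites = sample_pools(exp, rng)
        for s in sites[:50]:
            cov = s.counts[0].sum()
            assert s.counts[0, 3] / cov == pytest.approx(0.5, abs=0.05)

    def test_monomorphic_site_single_allele(self, tiny_experiment, rng):
        cfg, exp = tiny_experiment
        sites = sample_pools(exp, rng)
        hi = exp.populations["HighSel"]
        fixed = np.nonzero(hi.allele_frequencies() == 0.0)[0]
        if fixed.size:
            s = sites[int(fixed[0])]
            assert s.counts[0, 3] == 0  # no alternative reads in the high pool

    def test_pool_size_exceeding_population_raises(self, rng):
        pop = _uniform_half_population(10, 20)
        cfg = SelectionSimConfig(pool_sizes=(30, 30, 20, 16), **TINY)
        exp = _experiment_from_population(pop, cfg)
        with pytest.raises(ValueError, match="pool size"):
            sample_pools(exp, rng)

    def test_sync_round_trip(self, tiny_experiment, rng, tmp_path):
        from poolsweep.pooldata import read_sync, write_sync

        _, exp = tiny_experiment
        sites = sample_pools(exp, rng)
        write_sync(sites, tmp_path / "x.sync")
        back = read_sync(tmp_path / "x.sync")
        assert len(back) == len(sites)
        assert np.array_equal(back[0].counts, sites[0].counts)


@pytest.fixture(scope="module")
def f2_setup():
    cfg = SelectionSimConfig(
        n_qtl=1, qtl_effects=(2.0,), simulate_relaxed=False, seed=21,
        genome=(Chromosome("chr1", 5_000_000, 2.8),),
        generations=20, relax_at=10, founder_ne=300, founder_mu=2e-8,
        f2_panel_size=200,
    )
    rng = np.random.default_rng(cfg.seed)
    exp = simulate_experiment(cfg, rng)
    panel = simulate_f2(
        exp.populations["HighSel"], exp.populations["LowSel"],
        exp.trait_model, cfg, rng,
    )
    return cfg, exp, panel


class TestSimulateF2:
    def test_panel_shape_and_codes(self, f2_setup):
        cfg, _, panel = f2_setup
        assert len(panel.individuals) == cfg.f2_n_extremes
        assert panel.n_markers <= cfg.f2_panel_size
        assert set(np.unique(panel.genotypes)) <= {0.0, 1.0, 2.0}
        assert ((panel.markers.delta_p >= 0) & (panel.markers.delta_p <= 1)).all()

    def test_qtl_marker_in_panel(self, f2_setup):
        _, exp, panel = f2_setup
        qtl_pos = int(exp.trait_model.qtl_positions[0])
        assert qtl_pos in set(panel.markers.pos)

    def test_homozygote_class_difference_near_twice_effect(self, f2_setup):
        _, exp, panel = f2_setup
        qtl_pos = int(exp.trait_model.qtl_positions[0])
        j = int(np.nonzero(panel.markers.pos.to_numpy() == qtl_pos)[0][0])
        g = panel.genotypes[:, j]
        y = panel.individuals.phenotype.to_numpy()
        diff = y[g == 2].mean() - y[g == 0].mean()
        # extremes design inflates the contrast; it must at least reach 2a
        assert diff >= 2 * 2.0 - 1.0

    def test_extremes_are_tail_heavy(self, f2_setup):
        cfg, exp, panel = f2_setup
        rng = np.random.default_rng(99)
        cfg_full = SelectionSimConfig(
            **{**cfg.__dict__, "f2_n_extremes": cfg.f2_total, "seed": 99}
        )
        full = simulate_f2(
            exp.populations["HighSel"], exp.populations["LowSel"],
            exp.trait_model, cfg_full, rng,
        )
        assert panel.individuals.phenotype.var() > full.individuals.phenotype.var()

    def test_mismatched_site_lists_raise(self, f2_setup):
        _, exp, _ = f2_setup
        hi = exp.populations["HighSel"]
        import dataclasses

        other = dataclasses.replace(
            exp.populations["LowSel"],
            positions=exp.populations["LowSel"].positions + 1,
        )
        with pytest.raises(ValueError, match="share"):
            simulate_f2(hi, other, exp.trait_model, exp.config, np.random.default_rng(0))
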