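"""Synthetic-data generator emulating the bidirectional selection experiment.

Two lines descend from a common randombred base population and undergo 39
generations of divergent truncation selection on a polygenic log2 antibody
titer: each generation, 30 male and 60 female candidates are produced, of
which the top (high line) or bottom (low line) 7♂/28♀ (generations 1-10)
or 8♂/32♀ (11 onwards) become parents, with a per-dam family cap that
approximates restricted truncation selection.  Relaxed sublines branch at
generation 24 and random-mate for 16 generations.  The four terminal
populations are pool-sequenced in silico (Poisson depth, binomial allele
sampling), and an F2 intercross of the selected lines yields a marker
panel of phenotypic extremes for association analysis.

The trait is additive: ``y = mean + Σ a_j (dosage_j - 2 p0_j) + sex_effect
* female + N(0, σ_e)``, with QTL effects drawn from an exponential
distribution and rescaled so that the founder genetic variance matches the
configured narrow-sense heritability; titers are floored at zero, which
lets the low line plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._wf import Chromosome, SimPopulation, founders_from_msprime, next_generation
from .assoc import MarkerPanel
from .pooldata import BASES, PooledSiteCounts

DEFAULT_GENOME = (
    Chromosome("chr1", 15_000_000, 2.8),
    Chromosome("chr2", 15_000_000, 2.8),
    Chromosome("chr3", 10_000_000, 6.4),
    Chromosome("chr4", 10_000_000, 6.4),
)

POOL_NAMES = ("HighSel", "LowSel", "HighRelax", "LowRelax")


@dataclass(frozen=True)
class SelectionSimConfig:
    """Study conditions of the emulated experiment (defaults throughout)."""

    genome: tuple[Chromosome, ...] = DEFAULT_GENOME
    n_qtl: int = 50
    qtl_effects: tuple[float, ...] | None = None  # explicit effects override
    h2: float = 0.3
    sigma_p: float = 3.0  # founder phenotypic SD, log2-titer units
    trait_mean: float = 8.0  # founder mean log2 titer
    sex_effect: float = 1.0  # added to females, log2-titer units
    phenotype_floor: float | None = 0.0
    candidates_per_sex: tuple[int, int] = (30, 60)  # (males, females)
    parents_early: tuple[int, int] = (7, 28)  # gens 1-10
    parents_late: tuple[int, int] = (8, 32)  # gens 11+
    parents_switch_gen: int = 11
    generations: int = 39
    relax_at: int = 24
    relax_generations: int = 16
    simulate_relaxed: bool = True
    family_cap: int = 2  # max selected offspring per dam family
    pool_sizes: tuple[int, ...] = (30, 30, 20, 16)
    mean_depth: tuple[float, ...] = (32.3, 36.7, 35.4, 34.8)
    f2_n_f1: int = 64
    f2_total: int = 256
    f2_n_extremes: int = 128
    f2_panel_size: int = 1024
    include_qtl_in_panel: bool = True
    founder_ne: int = 1000
    founder_mu: float = 1e-8
    forward_mu: float = 0.0  # standing variation only by default
    qtl_min_maf: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        for par, cand in zip(self.parents_early, self.candidates_per_sex):
            if par > cand:
                raise ValueError("parents cannot exceed candidates per sex")
        for par, cand in zip(self.parents_late, self.candidates_per_sex):
            if par > cand:
                raise ValueError("parents cannot exceed candidates per sex")
        if self.simulate_relaxed and not self.relax_at < self.generations:
            raise ValueError("relax_at must be < generations")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")


@dataclass
class TraitModel:
    """Additive genetic architecture on the log2-titer scale."""

    qtl_chrom_ids: np.ndarray
    qtl_positions: np.ndarray
    effects: np.ndarray  # per copy of the derived (1) allele
    founder_dosage_means: np.ndarray  # 2 * founder frequency per QTL
    sigma_e: float
    sex_effect: float
    trait_mean: float
    floor: float | None

    def qtl_columns(self, pop: SimPopulation) -> np.ndarray:
        """Locate the QTL columns in a population's (sorted) site list."""
        key_pop = pop.chrom_ids.astype(np.int64) * (2**33) + np.round(
            pop.positions * 4
        ).astype(np.int64)
        key_q = self.qtl_chrom_ids.astype(np.int64) * (2**33) + np.round(
            self.qtl_positions * 4
        ).astype(np.int64)
        idx = np.searchsorted(key_pop, key_q)
        if np.any(idx >= len(key_pop)) or np.any(key_pop[idx] != key_q):
            raise ValueError("QTL site missing from population site list")
        return idx

    def genetic_values(self, pop: SimPopulation) -> np.ndarray:
        cols = self.qtl_columns(pop)
        dosage = pop.haplotypes[0::2, cols] + pop.haplotypes[1::2, cols]
        return (dosage - self.founder_dosage_means) @ self.effects

    def phenotypes(self, pop: SimPopulation, rng: np.random.Generator) -> np.ndarray:
        if pop.sex is None:
            raise ValueError("population lacks sex labels")
        y = (
            self.trait_mean
            + self.genetic_values(pop)
            + self.sex_effect * (pop.sex == 1)
            + rng.normal(0.0, self.sigma_e, pop.n_individuals)
        )
        if self.floor is not None:
            y = np.maximum(y, self.floor)
        return y


@dataclass
class ExperimentResult:
    """Terminal populations, trait model and per-generation trait means."""

    populations: dict[str, SimPopulation]
    trait_model: TraitModel
    trait_means: pd.DataFrame  # line, generation, sex, mean_phenotype
    ref_bases: np.ndarray  # per founder site
    alt_bases: np.ndarray
    config: SelectionSimConfig

    def truth(self) -> dict:
        """QTL positions/effects for parameter-recovery checks."""
        genome = self.config.genome
        return {
            "qtl": [
                {
                    "chrom": genome[int(c)].name,
                    "pos": int(p),
                    "effect": float(a),
                }
                for c, p, a in zip(
                    self.trait_model.qtl_chrom_ids,
                    self.trait_model.qtl_positions,
                    self.trait_model.effects,
                )
            ],
            "sigma_e": self.trait_model.sigma_e,
            "sex_effect": self.trait_model.sex_effect,
        }


def _make_sexes(config: SelectionSimConfig) -> np.ndarray:
    n_m, n_f = config.candidates_per_sex
    return np.concatenate([np.zeros(n_m, dtype=np.int8), np.ones(n_f, dtype=np.int8)])


def _build_trait_model(
    founders: SimPopulation, config: SelectionSimConfig, rng: np.random.Generator
) -> TraitModel:
    freqs = founders.allele_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    eligible = np.nonzero(maf >= config.qtl_min_maf)[0]
    if len(eligible) < config.n_qtl:
        raise ValueError("not enough intermediate-frequency sites for the QTL")
    cols = np.sort(rng.choice(eligible, size=config.n_qtl, replace=False))
    if config.qtl_effects is not None:
        if len(config.qtl_effects) != config.n_qtl:
            raise ValueError("qtl_effects length must equal n_qtl")
        effects = np.asarray(config.qtl_effects, dtype=float)
    else:
        effects = rng.exponential(1.0, size=config.n_qtl)
    p = freqs[cols]
    vg_raw = float(np.sum(2.0 * p * (1 - p) * effects**2))
    vg_target = config.h2 * config.sigma_p**2
    if config.qtl_effects is None and vg_raw > 0:
        effects = effects * np.sqrt(vg_target / vg_raw)
        vg = vg_target
    else:
        vg = vg_raw
    sigma_e = float(np.sqrt(max(config.sigma_p**2 - vg, 1e-12)))
    return TraitModel(
        qtl_chrom_ids=founders.chrom_ids[cols].copy(),
        qtl_positions=founders.positions[cols].copy(),
        effects=effects,
        founder_dosage_means=2.0 * p,
        sigma_e=sigma_e,
        sex_effect=config.sex_effect,
        trait_mean=config.trait_mean,
        floor=config.phenotype_floor,
    )


def _select_parents(
    phen: np.ndarray,
    sex: np.ndarray,
    dams_of: np.ndarray | None,
    n_males: int,
    n_females: int,
    direction: int,
    family_cap: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-sex truncation selection with a per-dam family cap.

    ``direction`` +1 selects the highest phenotypes, -1 the lowest.
    ``dams_of[i]`` is the dam family of candidate *i* (-1 = founder, no
    cap).  Returns (sire indices, dam indices).
    """
    score = direction * phen
    fam_count: dict[int, int] = {}
    chosen: dict[int, list[int]] = {0: [], 1: []}
    want = {0: n_males, 1: n_females}
    for s in (0, 1):
        cand = np.nonzero(sex == s)[0]
        for i in cand[np.argsort(-score[cand], kind="stable")]:
            fam = int(dams_of[i]) if dams_of is not None else -1
            if family_cap is not None and fam >= 0:
                if fam_count.get(fam, 0) >= family_cap:
                    continue
                fam_count[fam] = fam_count.get(fam, 0) + 1
            chosen[s].append(int(i))
            if len(chosen[s]) == want[s]:
                break
        if len(chosen[s]) < want[s]:
            # cap too restrictive for this candidate pool: fill ignoring it
            for i in cand[np.argsort(-score[cand], kind="stable")]:
                if int(i) not in chosen[s]:
                    chosen[s].append(int(i))
                    if len(chosen[s]) == want[s]:
                        break
    return np.array(chosen[0]), np.array(chosen[1])


def _breed(
    pop: SimPopulation,
    sires: np.ndarray,
    dams: np.ndarray,
    config: SelectionSimConfig,
    rng: np.random.Generator,
) -> tuple[SimPopulation, np.ndarray]:
    """Produce the next candidate generation; returns (population, dams_of)."""
    n = sum(config.candidates_per_sex)
    mothers = rng.choice(dams, size=n)
    fathers = rng.choice(sires, size=n)
    child = next_generation(
        pop, mothers, fathers, rng, mu=config.forward_mu, sex=_make_sexes(config)
    )
    return child, mothers


def _parents_for_gen(config: SelectionSimConfig, gen: int) -> tuple[int, int]:
    return (
        config.parents_early if gen < config.parents_switch_gen else config.parents_late
    )


def simulate_experiment(
    config: SelectionSimConfig, rng: np.random.Generator | None = None
) -> ExperimentResult:
    """Run the full bidirectional selection experiment.

    Returns the four terminal populations (HighSel, LowSel and, when
    enabled, HighRelax/LowRelax after their 16 random-mating generations),
    the realized trait model and the per-generation phenotype means.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_cand = sum(config.candidates_per_sex)
    founders = founders_from_msprime(
        config.genome, 2 * n_cand, config.founder_ne, config.founder_mu, rng
    )
    trait = _build_trait_model(founders, config, rng)
    n_sites = founders.n_sites
    # random ref/alt base assignment for sync export
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref_bases = np.array([BASES[i] for i in ref_idx])
    alt_bases = np.array([BASES[i] for i in alt_idx])

    lines: dict[str, SimPopulation] = {}
    dams_of: dict[str, np.ndarray | None] = {}
    for k, name in enumerate(("HighSel", "LowSel")):
        pop = founders.subset_individuals(np.arange(k * n_cand, (k + 1) * n_cand))
        pop.sex = _make_sexes(config)
        lines[name] = pop
        dams_of[name] = None

    records: list[dict] = []
    relaxed: dict[str, SimPopulation] = {}

    def record(line: str, gen: int, phen: np.ndarray, sex: np.ndarray) -> None:
        for s, label in ((0, "M"), (1, "F")):
            m = phen[sex == s]
            if m.size:
                records.append(
                    {
                        "line": line,
                        "generation": gen,
                        "sex": label,
                        "mean_phenotype": float(m.mean()),
                    }
                )

    for gen in range(1, config.generations + 1):
        for name, direction in (("HighSel", +1), ("LowSel", -1)):
            pop = lines[name]
            phen = trait.phenotypes(pop, rng)
            record(name, gen - 1, phen, pop.sex)
            n_m, n_f = _parents_for_gen(config, gen)
            sires, dams = _select_parents(
                phen, pop.sex, dams_of[name], n_m, n_f, direction, config.family_cap
            )
            lines[name], dams_of[name] = _breed(pop, sires, dams, config, rng)
        if config.simulate_relaxed and gen == config.relax_at:
            relaxed["HighRelax"] = lines["HighSel"]
            relaxed["LowRelax"] = lines["LowSel"]

    # relaxed sublines: random parent choice, no selection
    for name in list(relaxed):
        pop = relaxed[name]
        for rgen in range(1, config.relax_generations + 1):
            phen = trait.phenotypes(pop, rng)
            record(name, config.relax_at + rgen - 1, phen, pop.sex)
            n_m, n_f = _parents_for_gen(config, config.relax_at + rgen)
            males = np.nonzero(pop.sex == 0)[0]
            females = np.nonzero(pop.sex == 1)[0]
            sires = rng.choice(males, size=n_m, replace=False)
            dams = rng.choice(females, size=n_f, replace=False)
            pop, _ = _breed(pop, sires, dams, config, rng)
        relaxed[name] = pop

    # terminal phenotype record for the selected lines
    for name in ("HighSel", "LowSel"):
        phen = trait.phenotypes(lines[name], rng)
        record(name, config.generations, phen, lines[name].sex)

    populations = {"HighSel": lines["HighSel"], "LowSel": lines["LowSel"]}
    populations.update(relaxed)
    return ExperimentResult(
        populations=populations,
        trait_model=trait,
        trait_means=pd.DataFrame(records),
        ref_bases=ref_bases,
        alt_bases=alt_bases,
        config=config,
    )


def sample_pools(
    experiment: ExperimentResult,
    rng: np.random.Generator,
    pool_order: Sequence[str] = POOL_NAMES,
) -> list[PooledSiteCounts]:
    """In-silico pooled sequencing of the four terminal populations.

    Per pool: ``pool_size`` individuals are drawn without replacement, and
    at every site the read depth is Poisson(mean_depth) with derived-allele
    reads Binomial(depth, pooled allele frequency).  Rows come out in sync
    order (chrom, pos) on the founder site list.
    """
    config = experiment.config
    pops = [experiment.populations[name] for name in pool_order if name in experiment.populations]
    names = [name for name in pool_order if name in experiment.populations]
    n_pools = len(pops)
    base_pop = pops[0]
    n_sites = base_pop.n_sites
    alt_reads = np.empty((n_pools, n_sites), dtype=np.int64)
    depth = np.empty((n_pools, n_sites), dtype=np.int64)
    for k, (pop, name) in enumerate(zip(pops, names)):
        size = config.pool_sizes[k]
        if size > pop.n_individuals:
            raise ValueError(f"pool size {size} exceeds population size for {name}")
        if pop.n_sites != n_sites or not np.array_equal(pop.positions, base_pop.positions):
            raise ValueError("populations must share one site list for pooling")
        chosen = rng.choice(pop.n_individuals, size=size, replace=False)
        sub = pop.subset_individuals(chosen)
        q = sub.allele_counts() / (2.0 * size)
        depth[k] = rng.poisson(config.mean_depth[k], size=n_sites)
        alt_reads[k] = rng.binomial(depth[k], q)
    ref_reads = depth - alt_reads

    base_index = {b: i for i, b in enumerate(BASES)}
    sites: list[PooledSiteCounts] = []
    for s in range(n_sites):
        counts = np.zeros((n_pools, 6), dtype=np.int64)
        ri = base_index[experiment.ref_bases[s]]
        ai = base_index[experiment.alt_bases[s]]
        counts[:, ri] = ref_reads[:, s]
        counts[:, ai] += alt_reads[:, s]
        chrom = config.genome[int(base_pop.chrom_ids[s])].name
        sites.append(
            PooledSiteCounts(
                chrom=chrom,
                pos=int(base_pop.positions[s]),
                ref=str(experiment.ref_bases[s]),
                counts=counts,
            )
        )
    return sites


def simulate_f2(
    high: SimPopulation,
    low: SimPopulation,
    trait_model: TraitModel,
    config: SelectionSimConfig,
    rng: np.random.Generator,
) -> MarkerPanel:
    """F2 intercross of the selected lines, keeping the phenotypic extremes.

    Reciprocal line crosses produce ``f2_n_f1`` F1s; F1 intermating
    produces ``f2_total`` F2s; within each sex the highest and lowest
    quarters of ``f2_n_extremes`` are retained.  The marker panel holds
    sites segregating among the F1 parents, down-sampled to
    ``f2_panel_size`` (QTL sites kept when requested), with genotypes
    coded as dosage of the high-line allele.
    """
    if not np.array_equal(high.positions, low.positions):
        raise ValueError("lines must share one site list")
    combined = SimPopulation(
        haplotypes=np.concatenate([high.haplotypes, low.haplotypes], axis=0),
        positions=high.positions,
        chrom_ids=high.chrom_ids,
        genome=high.genome,
        generation=high.generation,
    )
    nh = high.n_individuals
    high_m = np.nonzero(high.sex == 0)[0]
    high_f = np.nonzero(high.sex == 1)[0]
    low_m = nh + np.nonzero(low.sex == 0)[0]
    low_f = nh + np.nonzero(low.sex == 1)[0]

    n_f1 = config.f2_n_f1
    half = n_f1 // 2
    fathers = np.concatenate(
        [rng.choice(high_m, size=half), rng.choice(low_m, size=n_f1 - half)]
    )
    mothers = np.concatenate(
        [rng.choice(low_f, size=half), rng.choice(high_f, size=n_f1 - half)]
    )
    f1_sex = rng.integers(0, 2, size=n_f1).astype(np.int8)
    f1 = next_generation(combined, mothers, fathers, rng, mu=config.forward_mu, sex=f1_sex)

    f1_m = np.nonzero(f1.sex == 0)[0]
    f1_f = np.nonzero(f1.sex == 1)[0]
    if f1_m.size == 0 or f1_f.size == 0:
        raise ValueError("F1 generation lacks one sex")
    n_f2 = config.f2_total
    f2_sex = rng.integers(0, 2, size=n_f2).astype(np.int8)
    f2 = next_generation(
        f1,
        rng.choice(f1_f, size=n_f2),
        rng.choice(f1_m, size=n_f2),
        rng,
        mu=config.forward_mu,
        sex=f2_sex,
    )
    phen = trait_model.phenotypes(f2, rng)

    # phenotypic extremes, balanced within sex (keep everyone when the
    # genotyped sample is the whole cross)
    if config.f2_n_extremes >= n_f2:
        keep = list(range(n_f2))
    else:
        keep = []
        counts = [int((f2.sex == s).sum()) for s in (0, 1)]
        quotas = [round(config.f2_n_extremes * c / n_f2) for c in counts]
        quotas[1] = config.f2_n_extremes - quotas[0]
        for s in (0, 1):
            idx = np.nonzero(f2.sex == s)[0]
            quota = quotas[s]
            if len(idx) < quota:
                raise ValueError("not enough F2 individuals of one sex for the extremes")
            order = idx[np.argsort(phen[idx])]
            keep.extend(order[: quota // 2])
            keep.extend(order[-(quota - quota // 2):])
        keep = sorted(keep)
    extremes = f2.subset_individuals(keep)
    phen_keep = phen[keep]

    # marker panel: sites segregating among the F1 parents
    f1_freq = f1.allele_frequencies()
    poly = np.nonzero((f1_freq > 0) & (f1_freq < 1))[0]
    if poly.size == 0:
        raise ValueError("no polymorphic markers for the F2 panel")
    qtl_cols = trait_model.qtl_columns(f2)
    panel_size = min(config.f2_panel_size, poly.size)
    if config.include_qtl_in_panel:
        qtl_poly = np.intersect1d(qtl_cols, poly)
        rest = np.setdiff1d(poly, qtl_poly)
        n_extra = max(panel_size - qtl_poly.size, 0)
        extra = rng.choice(rest, size=min(n_extra, rest.size), replace=False)
        cols = np.sort(np.concatenate([qtl_poly, extra]))
    else:
        cols = np.sort(rng.choice(poly, size=panel_size, replace=False))

    p_high_derived = high.allele_frequencies()[cols]
    p_low_derived = low.allele_frequencies()[cols]
    # high-line allele: the allele more frequent in the high line (tie: derived)
    high_is_derived = p_high_derived >= p_low_derived
    p_high = np.where(high_is_derived, p_high_derived, 1 - p_high_derived)
    p_low = np.where(high_is_derived, p_low_derived, 1 - p_low_derived)
    delta_p = p_high - p_low

    dosage_derived = (
        extremes.haplotypes[0::2, cols] + extremes.haplotypes[1::2, cols]
    ).astype(float)
    genotypes = np.where(high_is_derived, dosage_derived, 2.0 - dosage_derived)

    genome = config.genome
    markers = pd.DataFrame(
        {
            "id": [
                f"m_{genome[int(c)].name}_{int(p)}"
                for c, p in zip(f2.chrom_ids[cols], f2.positions[cols])
            ],
            "chrom": [genome[int(c)].name for c in f2.chrom_ids[cols]],
            "pos": [int(p) for p in f2.positions[cols]],
            "p_high": p_high,
            "p_low": p_low,
            "delta_p": delta_p,
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [f"F2_{i:04d}" for i in range(len(keep))],
            "sex": extremes.sex.astype(int),
            "phenotype": phen_keep,
        }
    )
    return MarkerPanel(markers=markers, genotypes=genotypes, individuals=individuals)
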