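"""Neutral drift null for the two-line breeding design.

Simulates the expected genomic differentiation between two lines that
descend from a common base population and drift — without selection —
through the experiment's breeding scheme: ancestral effective size 500,
then two independent lines of 25 diploids (80% females) for 39
generations.  A high mutation rate (the chicken mitochondrial rate,
3.13e-7 per site per generation) is used to endow the base population with
abundant standing variation; recombination is 2.8 cM/Mb for
macrochromosome-like loci and 6.4 cM/Mb for microchromosome-like loci.

Sites at which the two terminal lines are fixed for alternative alleles
are "differentiated"; differentiated sites less than 50 kb apart are
clustered into regions of differentiation.  The summary reports the
region-length distribution, the fraction of replicate fragments with at
least one region, the percentage of fragment DNA inside regions, and the
median 1 kb / 50%-overlap window F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._wf import Chromosome, SimPopulation, founders_from_msprime, next_generation

__all__ = [
    "DriftSimConfig",
    "DriftSummary",
    "DiffRegion",
    "SimPopulation",
    "init_standing_variation",
    "evolve_neutral",
    "differentiated_regions",
    "window_fst_from_counts",
    "run_drift_null",
]


@dataclass(frozen=True)
class DriftSimConfig:
    """Parameters of the drift-null experiment (defaults = study conditions)."""

    locus_length: int = 5_000_000
    mu: float = 3.13e-7
    rec_rate: float = 2.8  # cM/Mb; 2.8 macro-, 6.4 micro-chromosomes
    ne_ancestral: int = 500
    n_line: int = 25
    prop_female: float = 0.8
    generations: int = 39
    n_replicates: int = 200
    cluster_gap: int = 50_000
    min_region_sites: int = 2  # a "stretch" needs >=2 differentiated sites
    fst_threshold: float | None = None  # None -> fixed-difference rule
    sex_structured: bool = False  # True -> parents drawn per sex, Ne = 4NfNm/N
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mu < 0 or self.rec_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_line < 2:
            raise ValueError("n_line must be >= 2")
        if not 0 < self.prop_female < 1:
            raise ValueError("prop_female must be in (0, 1)")

    @property
    def n_females(self) -> int:
        return int(round(self.prop_female * self.n_line))

    @property
    def n_males(self) -> int:
        return self.n_line - self.n_females


@dataclass(frozen=True)
class DiffRegion:
    """A cluster of differentiated sites; span = last site - first site."""

    start: float
    end: float
    n_sites: int

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class DriftSummary:
    """Aggregate of differentiated-region statistics across replicates."""

    region_lengths: list[list[float]]  # per replicate
    median_length: float
    mean_length: float
    max_length: float
    median_window_fst: float
    frac_replicates_with_region: float
    pct_sequence_differentiated: float
    n_replicates: int
    config: DriftSimConfig

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "median_length": self.median_length,
            "mean_length": self.mean_length,
            "max_length": self.max_length,
            "median_window_fst": self.median_window_fst,
            "frac_replicates_with_region": self.frac_replicates_with_region,
            "pct_sequence_differentiated": self.pct_sequence_differentiated,
            "n_regions_total": int(sum(len(r) for r in self.region_lengths)),
            "rec_rate_cm_mb": self.config.rec_rate,
            "generations": self.config.generations,
        }


def _locus(config: DriftSimConfig) -> Chromosome:
    return Chromosome("locus", config.locus_length, config.rec_rate)


def init_standing_variation(
    config: DriftSimConfig, rng: np.random.Generator
) -> SimPopulation:
    """Founders of the two lines: an equilibrium coalescent sample of
    ``2 * n_line`` diploids from a population of size ``ne_ancestral``."""
    return founders_from_msprime(
        genome=[_locus(config)],
        n_individuals=2 * config.n_line,
        ne=config.ne_ancestral,
        mu=config.mu,
        rng=rng,
    )


def _drift_generations(
    pop: SimPopulation, config: DriftSimConfig, rng: np.random.Generator
) -> SimPopulation:
    """Random mating within a line for ``generations`` rounds.

    Default mode: an unstructured Wright-Fisher population of ``n_line``
    diploids (every offspring draws both parents uniformly with
    replacement; Ne = n_line).  This realized drift level reproduces the
    published window-differentiation of the breeding experiment's own
    neutral reference simulations; see the methods documentation.

    ``sex_structured=True`` instead draws dams from the ``n_females``
    females and sires from the remaining males, realizing the smaller
    Ne = 4*Nf*Nm/(Nf+Nm) of an unequal breeding sex ratio.
    """
    n = config.n_line
    nf = config.n_females
    for _ in range(config.generations):
        if config.sex_structured:
            mothers = rng.integers(0, nf, size=n)
            fathers = nf + rng.integers(0, n - nf, size=n)
        else:
            mothers = rng.integers(0, n, size=n)
            fathers = rng.integers(0, n, size=n)
        pop = next_generation(pop, mothers, fathers, rng, mu=config.mu)
    return pop


def evolve_neutral(
    pop: SimPopulation, config: DriftSimConfig, rng: np.random.Generator
) -> tuple[SimPopulation, SimPopulation]:
    """Split the founders into two lines of ``n_line`` diploids and drift
    each independently for ``generations`` generations."""
    if pop.n_individuals < 2 * config.n_line:
        raise ValueError("founder population too small for two lines")
    line1 = pop.subset_individuals(np.arange(config.n_line))
    line2 = pop.subset_individuals(np.arange(config.n_line, 2 * config.n_line))
    return _drift_generations(line1, config, rng), _drift_generations(line2, config, rng)


def merged_line_counts(
    line1: SimPopulation, line2: SimPopulation
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union site list of two lines: (positions, counts1, counts2).

    Sites private to one line (post-split mutations) get count 0 in the
    other.  Positions are unique within each line by construction.
    """
    p1, p2 = line1.positions, line2.positions
    union = np.union1d(p1, p2)
    c1 = np.zeros(len(union), dtype=np.int64)
    c2 = np.zeros(len(union), dtype=np.int64)
    c1[np.searchsorted(union, p1)] = line1.allele_counts()
    c2[np.searchsorted(union, p2)] = line2.allele_counts()
    return union, c1, c2


def differentiated_regions(
    positions: np.ndarray,
    freq1: np.ndarray,
    freq2: np.ndarray,
    cluster_gap: int = 50_000,
    fst_threshold: float | None = None,
    min_sites: int = 1,
) -> list[DiffRegion]:
    """Cluster differentiated sites into regions.

    By default a site is differentiated when the lines are fixed for
    alternative alleles (freq 1 vs 0); with ``fst_threshold`` set, a
    per-site Nei F_ST = (H_T - H_S)/H_T >= threshold is used instead.
    Consecutive differentiated sites < ``cluster_gap`` apart (strict) merge
    transitively; clusters with fewer than ``min_sites`` sites are dropped.
    """
    positions = np.asarray(positions, dtype=float)
    freq1 = np.asarray(freq1, dtype=float)
    freq2 = np.asarray(freq2, dtype=float)
    if fst_threshold is None:
        mask = ((freq1 == 1.0) & (freq2 == 0.0)) | ((freq1 == 0.0) & (freq2 == 1.0))
    else:
        pbar = 0.5 * (freq1 + freq2)
        ht = 2.0 * pbar * (1.0 - pbar)
        hs = freq1 * (1.0 - freq1) + freq2 * (1.0 - freq2)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
        mask = fst >= fst_threshold
    pos = np.sort(positions[mask])
    if pos.size == 0:
        return []
    breaks = np.nonzero(np.diff(pos) >= cluster_gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(pos) - 1]])
    regions = [
        DiffRegion(start=float(pos[i]), end=float(pos[j]), n_sites=int(j - i + 1))
        for i, j in zip(starts, ends)
    ]
    return [r for r in regions if r.n_sites >= min_sites]


def window_fst_from_counts(
    positions: np.ndarray,
    c1: np.ndarray,
    n1: int,
    c2: np.ndarray,
    n2: int,
    locus_length: int,
    window: int = 1000,
    step: int = 500,
) -> np.ndarray:
    """Karlsson ratio-of-sums window F_ST from exhaustive allele counts.

    Treats the full haplotype sets as "reads": coverage = 2N per line,
    counts = derived/ancestral allele counts.  Returns the F_ST of every
    defined window (windows with denominator 0 are omitted).
    """
    a1 = c1.astype(float)
    b1 = n1 - a1
    a2 = c2.astype(float)
    b2 = n2 - a2
    hw = 0.5 * (
        2.0 * a1 * b1 / (n1 * (n1 - 1.0)) + 2.0 * a2 * b2 / (n2 * (n2 - 1.0))
    )
    hb = (a1 * b2 + a2 * b1) / (float(n1) * n2)
    # skip sites monomorphic across both lines (denominator 0)
    keep = hb > 0
    pos = positions[keep]
    num = hb[keep] - hw[keep]
    den = hb[keep]
    order = np.argsort(pos)
    pos, num, den = pos[order], num[order], den[order]
    cs_num = np.concatenate([[0.0], np.cumsum(num)])
    cs_den = np.concatenate([[0.0], np.cumsum(den)])
    starts = np.arange(0, locus_length - window + 1, step)
    lo = np.searchsorted(pos, starts, side="right")
    hi = np.searchsorted(pos, starts + window, side="right")
    wnum = cs_num[hi] - cs_num[lo]
    wden = cs_den[hi] - cs_den[lo]
    defined = wden > 0
    return wnum[defined] / wden[defined]


def run_drift_null(config: DriftSimConfig, compute_window_fst: bool = True) -> DriftSummary:
    """Run the replicated drift-null experiment; reproducible given seed."""
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(config.seed)
    lengths_per_rep: list[list[float]] = []
    window_fsts: list[np.ndarray] = []
    pct_per_rep: list[float] = []
    n_with_region = 0
    n_hap = 2 * config.n_line
    for _ in range(config.n_replicates):
        founders = init_standing_variation(config, rng)
        line1, line2 = evolve_neutral(founders, config, rng)
        pos, c1, c2 = merged_line_counts(line1, line2)
        regions = differentiated_regions(
            pos,
            c1 / n_hap,
            c2 / n_hap,
            cluster_gap=config.cluster_gap,
            fst_threshold=config.fst_threshold,
            min_sites=config.min_region_sites,
        )
        lengths = [r.length for r in regions]
        lengths_per_rep.append(lengths)
        if regions:
            n_with_region += 1
        pct_per_rep.append(100.0 * sum(lengths) / config.locus_length)
        if compute_window_fst:
            window_fsts.append(
                window_fst_from_counts(
                    pos, c1, n_hap, c2, n_hap, config.locus_length
                )
            )
    flat = np.array([x for rep in lengths_per_rep for x in rep], dtype=float)
    all_fst = np.concatenate(window_fsts) if window_fsts else np.array([])
    median_fst = float(np.median(all_fst)) if all_fst.size else float("nan")
    return DriftSummary(
        region_lengths=lengths_per_rep,
        median_length=float(np.median(flat)) if flat.size else 0.0,
        mean_length=float(flat.mean()) if flat.size else 0.0,
        max_length=float(flat.max()) if flat.size else 0.0,
        median_window_fst=median_fst,
        frac_replicates_with_region=n_with_region / config.n_replicates,
        pct_sequence_differentiated=float(np.mean(pct_per_rep)),
        n_replicates=config.n_replicates,
        config=config,
    )
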