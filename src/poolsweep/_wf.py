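"""Forward Wright–Fisher machinery shared by the drift-null simulator and
the selection-experiment generator.

Populations are diploid; haplotypes ``2i`` and ``2i+1`` belong to individual
``i``.  Genotypes are stored as a dense ``(2N, S)`` uint8 matrix over
segregating-site columns sorted by (chromosome, position).  Meioses draw a
Poisson number of crossovers per chromosome from its genetic length and
assort chromosomes independently; new mutations arise at a per-site
per-gamete rate and create fresh columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class Chromosome:
    """A chromosome with physical length (bp) and recombination rate (cM/Mb)."""

    name: str
    length: int
    rec_cm_mb: float

    @property
    def morgans(self) -> float:
        """Genetic length in Morgans (expected crossovers per meiosis)."""
        return self.rec_cm_mb * (self.length / 1e6) / 100.0


@dataclass
class SimPopulation:
    """Diploid population state: haplotype matrix over segregating sites.

    ``positions`` are 1-based bp coordinates; columns are sorted by
    (chrom_id, position).  Founder sites have integer positions; mutations
    that arise during forward simulation are placed at continuous uniform
    positions so that independently evolving lines never alias distinct
    mutations to the same coordinate.  ``sex`` (0 = male, 1 = female) is
    optional and used only by the selection generator.
    """

    haplotypes: np.ndarray  # (2N, S) uint8
    positions: np.ndarray  # (S,) float64; founder sites sit on integers
    chrom_ids: np.ndarray  # (S,) int32, index into genome
    genome: tuple[Chromosome, ...]
    generation: int = 0
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be even (diploids)")
        key = self.chrom_ids.astype(np.int64) * (max(c.length for c in self.genome) + 1) + self.positions
        if np.any(np.diff(key) < 0):
            raise ValueError("site columns must be sorted by (chrom, position)")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def allele_counts(self) -> np.ndarray:
        """Derived-allele count per site over all haplotypes."""
        return self.haplotypes.sum(axis=0, dtype=np.int64)

    def allele_frequencies(self) -> np.ndarray:
        return self.allele_counts() / self.haplotypes.shape[0]

    def subset_individuals(self, idx: Sequence[int]) -> "SimPopulation":
        idx = np.asarray(idx)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return replace(
            self,
            haplotypes=self.haplotypes[rows].copy(),
            sex=None if self.sex is None else self.sex[idx].copy(),
        )

    def chrom_slices(self) -> list[tuple[int, int]]:
        """Half-open column ranges [lo, hi) for each chromosome in the genome."""
        out = []
        for cid in range(len(self.genome)):
            lo = int(np.searchsorted(self.chrom_ids, cid))
            hi = int(np.searchsorted(self.chrom_ids, cid, side="right"))
            out.append((lo, hi))
        return out


def make_gametes(
    pop: SimPopulation, parents: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per entry of ``parents`` (diploid indices), shape (G, S).

    Crossover counts are Poisson(genetic length) per chromosome; crossover
    breakpoints are uniform on the chromosome; chromosomes assort
    independently (fresh random phase per chromosome).
    """
    H = pop.haplotypes
    parents = np.asarray(parents)
    G = len(parents)
    out = np.empty((G, pop.n_sites), dtype=H.dtype)
    for (lo, hi), chrom in zip(pop.chrom_slices(), pop.genome):
        phase = rng.integers(0, 2, size=G)
        out[:, lo:hi] = H[2 * parents + phase, lo:hi]
        lam = chrom.morgans
        if lam <= 0 or hi == lo:
            continue
        n_x = rng.poisson(lam, size=G)
        pos_block = pop.positions[lo:hi]
        for g in np.nonzero(n_x)[0]:
            cuts = np.sort(rng.integers(1, chrom.length, size=n_x[g]))
            parity = np.searchsorted(cuts, pos_block, side="right") % 2
            h0 = H[2 * parents[g] + phase[g], lo:hi]
            h1 = H[2 * parents[g] + 1 - phase[g], lo:hi]
            out[g, lo:hi] = np.where(parity == 0, h0, h1)
    return out


def _inject_mutations(
    H: np.ndarray,
    positions: np.ndarray,
    chrom_ids: np.ndarray,
    genome: tuple[Chromosome, ...],
    mu: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add Poisson(n_hap * mu * genome_length) new single-copy mutation columns."""
    if mu <= 0:
        return H, positions, chrom_ids
    n_hap = H.shape[0]
    lengths = np.array([c.length for c in genome], dtype=float)
    total = lengths.sum()
    n_mut = rng.poisson(n_hap * mu * total)
    if n_mut == 0:
        return H, positions, chrom_ids
    cids = rng.choice(len(genome), size=n_mut, p=lengths / total).astype(chrom_ids.dtype)
    pos_new = np.array(
        [rng.uniform(1.0, genome[c].length + 1.0) for c in cids], dtype=np.float64
    )
    rows = rng.integers(0, n_hap, size=n_mut)
    cols = np.zeros((n_hap, n_mut), dtype=H.dtype)
    cols[rows, np.arange(n_mut)] = 1
    positions = np.concatenate([positions, pos_new])
    chrom_ids = np.concatenate([chrom_ids, cids])
    H = np.concatenate([H, cols], axis=1)
    order = np.lexsort((positions, chrom_ids))
    return H[:, order], positions[order], chrom_ids[order]


def next_generation(
    pop: SimPopulation,
    mothers: np.ndarray,
    fathers: np.ndarray,
    rng: np.random.Generator,
    mu: float = 0.0,
    sex: np.ndarray | None = None,
) -> SimPopulation:
    """Produce offspring; entry *i* has mother ``mothers[i]``, father ``fathers[i]``."""
    if len(mothers) != len(fathers):
        raise ValueError("mothers and fathers must have equal length")
    gam_m = make_gametes(pop, np.asarray(mothers), rng)
    gam_f = make_gametes(pop, np.asarray(fathers), rng)
    n = len(mothers)
    H = np.empty((2 * n, pop.n_sites), dtype=pop.haplotypes.dtype)
    H[0::2] = gam_m
    H[1::2] = gam_f
    H, positions, chrom_ids = _inject_mutations(
        H, pop.positions, pop.chrom_ids, pop.genome, mu, rng
    )
    return SimPopulation(
        haplotypes=H,
        positions=positions,
        chrom_ids=chrom_ids,
        genome=pop.genome,
        generation=pop.generation + 1,
        sex=sex,
    )


def founders_from_msprime(
    genome: Sequence[Chromosome],
    n_individuals: int,
    ne: float,
    mu: float,
    rng: np.random.Generator,
) -> SimPopulation:
    """Equilibrium standing variation: a coalescent sample of ``n_individuals``
    diploids from a population of effective size ``ne``, one independent
    msprime replicate per chromosome, with binary (0/1) mutations at rate
    ``mu`` per site per generation."""
    import msprime

    hap_blocks: list[np.ndarray] = []
    pos_blocks: list[np.ndarray] = []
    cid_blocks: list[np.ndarray] = []
    for cid, chrom in enumerate(genome):
        seeds = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=n_individuals,
            population_size=ne,
            sequence_length=chrom.length,
            recombination_rate=chrom.rec_cm_mb * 1e-8,  # cM/Mb -> Morgans/bp
            random_seed=int(seeds[0]),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=mu,
            model=msprime.BinaryMutationModel(),
            random_seed=int(seeds[1]),
        )
        gm = ts.genotype_matrix()  # (S, 2N)
        hap_blocks.append(gm.T.astype(np.uint8))
        pos = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.float64)
        pos_blocks.append(pos)
        cid_blocks.append(np.full(len(pos), cid, dtype=np.int32))
    H = (
        np.concatenate(hap_blocks, axis=1)
        if hap_blocks
        else np.zeros((2 * n_individuals, 0), dtype=np.uint8)
    )
    return SimPopulation(
        haplotypes=H,
        positions=np.concatenate(pos_blocks) if pos_blocks else np.zeros(0, dtype=np.float64),
        chrom_ids=np.concatenate(cid_blocks) if cid_blocks else np.zeros(0, dtype=np.int32),
        genome=tuple(genome),
        generation=0,
    )
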