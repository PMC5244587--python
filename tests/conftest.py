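"""Shared fixtures and synthetic-data helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from poolsweep.pooldata import PooledSiteCounts


def make_haplotype_region(
    rng: np.random.Generator,
    pool_alt_freqs: dict[str, tuple[float, ...]],
    site_members: list[tuple[int, ...]],
    depth: float = 35.0,
    chrom: str = "chr2",
    start: int = 1000,
    spacing: int = 100,
) -> tuple[list[PooledSiteCounts], list[str]]:
    """Synthesize pooled reads for a region built from known haplotypes.

    ``pool_alt_freqs[name]`` gives the frequencies of the alternative
    haplotypes (Haplo2, Haplo3, ...) in that pool; the reference haplotype
    takes the complement.  ``site_members[i]`` lists the 1-based
    alternative haplotypes carrying the non-reference allele at site *i*.
    Reads: depth ~ Poisson(depth), alt reads ~ Binomial(depth, summed
    frequency of the member haplotypes).
    """
    names = list(pool_alt_freqs)
    sites = []
    pos = start
    for mem in site_members:
        counts = np.zeros((len(names), 6), dtype=int)
        for k, nm in enumerate(names):
            freqs = pool_alt_freqs[nm]
            alt_freq = sum(freqs[h - 1] for h in mem)
            d = rng.poisson(depth)
            a = rng.binomial(d, min(alt_freq, 1.0))
            counts[k, 0] = d - a  # reference allele: A
            counts[k, 3] = a  # alternative allele: G
        sites.append(PooledSiteCounts(chrom, pos, "A", counts))
        pos += spacing
    return sites, names


def random_sync_sites(
    rng: np.random.Generator,
    n_sites: int = 50,
    n_pools: int = 2,
    chrom: str = "chr1",
    max_pos: int = 100_000,
    depth: int = 40,
) -> list[PooledSiteCounts]:
    """Random biallelic pooled sites sorted by position."""
    positions = np.sort(rng.choice(np.arange(1, max_pos + 1), size=n_sites, replace=False))
    sites = []
    for pos in positions:
        a_idx, b_idx = rng.choice(4, size=2, replace=False)
        counts = np.zeros((n_pools, 6), dtype=int)
        for k in range(n_pools):
            d = rng.poisson(depth)
            p = rng.uniform()
            a = rng.binomial(d, p)
            counts[k, a_idx] = a
            counts[k, b_idx] = d - a
        sites.append(PooledSiteCounts(chrom, int(pos), "ATCG"[a_idx], counts))
    return sites


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
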