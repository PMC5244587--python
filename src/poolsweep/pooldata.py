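"""Data model and I/O for pooled allele counts (PoPoolation2 ``sync`` format).

A sync file stores, per genomic site, the read counts of the six pileup
classes A, T, C, G, N and deletion for every sequenced pool::

    chr1   100   A   10:0:0:0:0:0   0:0:0:12:0:0

Positions are 1-based (sync convention).  All internal window/region
arithmetic elsewhere in the package is 0-based half-open and converts at
I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: order of count fields within one pool column
BASES = ("A", "T", "C", "G", "N", "del")
#: indices of true nucleotide counts (N and deletions never feed frequencies)
NUCLEOTIDES = slice(0, 4)


class SyncParseError(ValueError):
    """Raised for malformed sync rows; carries the 1-based line number."""


@dataclass(frozen=True)
class PooledSiteCounts:
    """Read counts of the six pileup classes for every pool at one site.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name.
    pos : int
        1-based position.
    ref : str
        Reference base.
    counts : numpy.ndarray
        Integer array of shape ``(n_pools, 6)`` ordered A,T,C,G,N,del.
    """

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[1] != 6:
            raise ValueError("counts must have shape (n_pools, 6)")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Per-pool coverage: the sum of all six count classes."""
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class SiteFilterParams:
    """Site-level coverage and allele-count filters.

    ``min_cov``/``max_cov`` are *exclusive* bounds (coverage must satisfy
    ``min_cov < cov < max_cov`` in every pool).  ``min_count`` is the
    minimum summed read count for an allele to be considered present.
    """

    min_cov: int = 10
    max_cov: int = 100
    min_count: int = 3

    def __post_init__(self) -> None:
        if not self.min_cov < self.max_cov:
            raise ValueError("min_cov must be < max_cov")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def read_sync(path: str | Path) -> list[PooledSiteCounts]:
    """Parse a sync file into a list of :class:`PooledSiteCounts` in file order."""
    sites: list[PooledSiteCounts] = []
    n_pools: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise SyncParseError(
                    f"line {lineno}: expected >=4 whitespace-separated fields, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            pools = fields[3:]
            if n_pools is None:
                n_pools = len(pools)
            elif len(pools) != n_pools:
                raise SyncParseError(
                    f"line {lineno}: expected {n_pools} pool columns, got {len(pools)}"
                )
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(f"line {lineno}: non-integer position {pos_s!r}") from None
            counts = np.empty((len(pools), 6), dtype=np.int64)
            for i, col in enumerate(pools):
                parts = col.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"line {lineno}: pool column {i + 1} has {len(parts)} fields, expected 6"
                    )
                try:
                    counts[i] = [int(x) for x in parts]
                except ValueError:
                    raise SyncParseError(
                        f"line {lineno}: non-integer count in pool column {i + 1}: {col!r}"
                    ) from None
            sites.append(PooledSiteCounts(chrom, pos, ref, counts))
    return sites


def write_sync(sites: Iterable[PooledSiteCounts], path: str | Path) -> None:
    """Write sites to ``path`` in sync format (round-trips with :func:`read_sync`)."""
    with open(path, "w") as fh:
        n_pools = None
        for site in sites:
            if n_pools is None:
                n_pools = site.n_pools
            elif site.n_pools != n_pools:
                raise ValueError("all sites must share the same pool count")
            cols = "\t".join(":".join(str(int(c)) for c in pool) for pool in site.counts)
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{cols}\n")


def filter_sites(
    sites: Sequence[PooledSiteCounts], params: SiteFilterParams
) -> list[PooledSiteCounts]:
    """Keep sites whose coverage lies strictly inside the bounds in *every* pool.

    Order-preserving and idempotent.  ``min_count`` does not remove sites
    here; it governs allele presence in :func:`major_alleles`/``is_snp``.
    """
    out = []
    for site in sites:
        cov = site.coverage
        if (cov > params.min_cov).all() and (cov < params.max_cov).all():
            out.append(site)
    return out


def major_alleles(site: PooledSiteCounts, min_count: int = 1) -> tuple[int, int] | None:
    """Indices (into A,T,C,G) of the two highest-count alleles across pools.

    Counts are summed across pools; alleles below ``min_count`` are treated
    as absent.  Ties are broken by the fixed base order A<T<C<G.  Returns
    ``None`` when no allele reaches ``min_count``; for a monomorphic site
    the second index is the lowest-ordered remaining base (with count 0).
    """
    totals = site.counts[:, NUCLEOTIDES].sum(axis=0).astype(np.int64)
    present = totals >= min_count
    if not present.any():
        return None
    masked = np.where(present, totals, -1)
    # stable argsort on negated counts -> ties resolved by base order A<T<C<G
    order = np.argsort(-masked, kind="stable")
    first = int(order[0])
    second = int(order[1])
    return first, second


def is_snp(site: PooledSiteCounts, min_count: int = 3) -> bool:
    """True when at least two alleles reach ``min_count`` (summed across pools)."""
    totals = site.counts[:, NUCLEOTIDES].sum(axis=0)
    return int((totals >= min_count).sum()) >= 2
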