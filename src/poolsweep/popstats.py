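"""Population statistics from pooled read counts.

Implements allele frequencies, expected heterozygosity, the Karlsson et al.
heterozygosity-based F_ST estimator per SNP, its ratio-of-sums aggregation
over sliding windows, pairwise window-F_ST matrices, and the unequal
sex-ratio effective population size.

The per-SNP F_ST components for pools with biallelic counts (a_i, b_i) and
informative coverage n_i = a_i + b_i are

    h_within  = mean_i [ 2 a_i b_i / (n_i (n_i - 1)) ]
    h_between = (a_1 b_2 + a_2 b_1) / (n_1 n_2)
    F_ST      = (h_between - h_within) / h_between

and a window's F_ST is the ratio of the summed numerators to the summed
denominators over its SNPs (ratio of sums, not mean of ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pooldata import NUCLEOTIDES, PooledSiteCounts, SiteFilterParams, major_alleles


@dataclass(frozen=True)
class FstComponents:
    """Per-SNP numerator/denominator of the Karlsson ratio-of-sums estimator."""

    h_within: float
    h_between: float

    @property
    def numerator(self) -> float:
        return self.h_between - self.h_within

    @property
    def denominator(self) -> float:
        return self.h_between

    @property
    def fst(self) -> float:
        if self.h_between == 0:
            return math.nan
        return self.numerator / self.h_between


@dataclass(frozen=True)
class FstWindow:
    """A fixed-width window on one chromosome (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    fst: float  # raw ratio of sums; NaN when undefined
    n_snps: int
    covered_fraction: float

    @property
    def fst_clamped(self) -> float:
        """Raw ratio floored at 0 (for summaries; the raw value stays visible)."""
        return max(self.fst, 0.0) if not math.isnan(self.fst) else math.nan


@dataclass(frozen=True)
class BreedingScheme:
    """Numbers of breeding females and males per generation."""

    n_females: int
    n_males: int

    def __post_init__(self) -> None:
        if self.n_females < 1 or self.n_males < 1:
            raise ValueError("parent counts must be >= 1")


def effective_population_size(scheme: BreedingScheme) -> float:
    """Variance effective size under unequal sex ratio: 4*Nf*Nm / (Nf + Nm)."""
    nf, nm = scheme.n_females, scheme.n_males
    return 4.0 * nf * nm / (nf + nm)


def expected_heterozygosity(p: float) -> float:
    """Expected heterozygosity 2p(1-p) of a biallelic site."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return 2.0 * p * (1.0 - p)


def allele_frequencies(
    site: PooledSiteCounts, min_count: int = 1
) -> tuple[tuple[int, int], np.ndarray] | None:
    """Per-pool frequency of the dataset-level major allele.

    Returns ``(allele_pair, freqs)`` where ``allele_pair`` holds the indices
    of the two retained alleles (summed across pools, ties A<T<C<G) and
    ``freqs[i]`` is the frequency of the first allele in pool *i* computed
    from reads of the two retained alleles only.  Pools with zero
    informative reads get NaN.  Returns ``None`` for all-N/del sites.
    """
    pair = major_alleles(site, min_count=min_count)
    if pair is None:
        return None
    a = site.counts[:, pair[0]].astype(float)
    b = site.counts[:, pair[1]].astype(float)
    n = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(n > 0, a / np.where(n > 0, n, 1), np.nan)
    return pair, freqs


def karlsson_snp_components(
    counts_pool1: tuple[float, float], counts_pool2: tuple[float, float]
) -> FstComponents | None:
    """Karlsson per-SNP components from biallelic counts of two pools.

    ``counts_pool*`` are (a, b): reads of the two retained alleles in that
    pool.  Returns ``None`` (site skipped) when either pool has informative
    coverage < 2 or when both pools are monomorphic for the same allele
    (denominator 0).  The numerator is returned unclamped and may be
    slightly negative.
    """
    a1, b1 = counts_pool1
    a2, b2 = counts_pool2
    n1 = a1 + b1
    n2 = a2 + b2
    if n1 < 2 or n2 < 2:
        return None
    h1 = 2.0 * a1 * b1 / (n1 * (n1 - 1.0))
    h2 = 2.0 * a2 * b2 / (n2 * (n2 - 1.0))
    h_within = 0.5 * (h1 + h2)
    h_between = (a1 * b2 + a2 * b1) / (n1 * n2)
    if h_between == 0.0:
        return None
    return FstComponents(h_within=h_within, h_between=h_between)


def site_components(
    site: PooledSiteCounts,
    pool_i: int,
    pool_j: int,
    min_count: int = 3,
) -> FstComponents | None:
    """Karlsson components for one site and one pool pair, or None if skipped.

    The site must be a SNP after biallelic reduction (two alleles with
    summed count >= ``min_count``); otherwise it is skipped.
    """
    totals = site.counts[:, NUCLEOTIDES].sum(axis=0)
    if int((totals >= min_count).sum()) < 2:
        return None
    pair = major_alleles(site, min_count=min_count)
    if pair is None:
        return None
    i0, i1 = pair
    c1 = (float(site.counts[pool_i, i0]), float(site.counts[pool_i, i1]))
    c2 = (float(site.counts[pool_j, i0]), float(site.counts[pool_j, i1]))
    return karlsson_snp_components(c1, c2)


def _check_sorted(sites: Sequence[PooledSiteCounts]) -> None:
    prev_chrom = None
    prev_pos = -1
    seen: set[str] = set()
    for s in sites:
        if s.chrom != prev_chrom:
            if s.chrom in seen:
                raise ValueError("sites are not sorted by (chrom, pos)")
            seen.add(s.chrom)
            prev_chrom = s.chrom
            prev_pos = -1
        if s.pos < prev_pos:
            raise ValueError("sites are not sorted by (chrom, pos)")
        prev_pos = s.pos


def window_fst(
    sites: Sequence[PooledSiteCounts],
    pool_i: int = 0,
    pool_j: int = 1,
    window: int = 1000,
    step: int = 500,
    min_covered_fraction: float = 1.0,
    min_count: int = 3,
    chrom_sizes: dict[str, int] | None = None,
) -> list[FstWindow]:
    """Sliding-window Karlsson F_ST between two pools.

    Windows of ``window`` bp at ``step`` bp offsets tile each chromosome
    starting at position 1; a final partial window is dropped.  Sites must
    be sorted by (chrom, pos) and already coverage-filtered.
    ``covered_fraction`` is (rows present in the window) / window — with
    all-position pileup-derived input this is true coverage fraction; with
    variant-only input set ``min_covered_fraction=0``.  Windows failing the
    fraction or containing no defined SNP carry ``fst = NaN``.
    """
    _check_sorted(sites)
    by_chrom: dict[str, list[PooledSiteCounts]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    out: list[FstWindow] = []
    for chrom, chrom_sites in by_chrom.items():
        pos = np.array([s.pos for s in chrom_sites], dtype=np.int64)
        num = np.full(len(chrom_sites), np.nan)
        den = np.full(len(chrom_sites), np.nan)
        for k, s in enumerate(chrom_sites):
            comp = site_components(s, pool_i, pool_j, min_count=min_count)
            if comp is not None:
                num[k] = comp.numerator
                den[k] = comp.denominator
        length = chrom_sizes.get(chrom) if chrom_sizes else None
        if length is None:
            length = int(pos[-1])
        # 0-based half-open windows anchored at chromosome position 1
        for start in range(0, length - window + 1, step):
            end = start + window
            lo = int(np.searchsorted(pos, start + 1))  # pos is 1-based
            hi = int(np.searchsorted(pos, end, side="right"))
            n_rows = hi - lo
            covered = n_rows / window
            defined = ~np.isnan(den[lo:hi])
            n_snps = int(defined.sum())
            if covered < min_covered_fraction or n_snps == 0:
                fst = math.nan
            else:
                d = float(den[lo:hi][defined].sum())
                fst = float(num[lo:hi][defined].sum()) / d if d > 0 else math.nan
            out.append(FstWindow(chrom, start, end, fst, n_snps, covered))
    return out


def windows_to_frame(windows: Sequence[FstWindow]) -> pd.DataFrame:
    """Tabulate windows (chrom, start, end, n_snps, covered_fraction, fst)."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "covered_fraction": [w.covered_fraction for w in windows],
            "fst": [w.fst for w in windows],
        }
    )


def pairwise_fst_matrix(
    sites: Sequence[PooledSiteCounts],
    n_pools: int | None = None,
    region: tuple[str, int, int] | None = None,
    pool_names: Sequence[str] | None = None,
    **window_kwargs,
) -> pd.DataFrame:
    """Symmetric matrix of mean window F_ST for all pool pairs.

    ``region`` is (chrom, start, end) in 0-based half-open coordinates;
    when given, only sites inside it contribute.  Entries are the mean of
    defined windows (negative window ratios floored at 0); NaN when no
    window is defined for a pair.
    """
    sites = list(sites)
    if region is not None:
        chrom, start, end = region
        sites = [s for s in sites if s.chrom == chrom and start < s.pos <= end]
    if not sites:
        raise ValueError("no sites in region")
    if n_pools is None:
        n_pools = sites[0].n_pools
    if n_pools < 2:
        raise ValueError("need at least 2 pools")
    names = list(pool_names) if pool_names is not None else [f"pool{i}" for i in range(n_pools)]
    mat = np.zeros((n_pools, n_pools))
    for i in range(n_pools):
        for j in range(i + 1, n_pools):
            wins = window_fst(sites, pool_i=i, pool_j=j, **window_kwargs)
            vals = [w.fst_clamped for w in wins if not math.isnan(w.fst)]
            mat[i, j] = mat[j, i] = float(np.mean(vals)) if vals else math.nan
    return pd.DataFrame(mat, index=names, columns=names)
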