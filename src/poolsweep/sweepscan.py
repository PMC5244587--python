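"""Candidate selective-sweep region detection from window F_ST tracks.

A scan takes a windowed F_ST track, derives a percentile cutoff from the
empirical distribution of defined windows, clusters above-cutoff windows
that lie within a maximum gap of one another on the same chromosome, and
removes clusters that consist of a single window or contain fewer than two
SNPs.  Region coordinates are 0-based half-open, spanning from the first
retained window's start to the last retained window's end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .pooldata import PooledSiteCounts
from .popstats import FstWindow, allele_frequencies, expected_heterozygosity


@dataclass(frozen=True)
class ScanParams:
    """Cutoff percentile, clustering gap, and region-retention minima."""

    percentile: float = 95.0
    max_gap: int = 500_000
    min_windows: int = 2
    min_snps: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


@dataclass(frozen=True)
class SweepRegion:
    """A clustered run of extreme-F_ST windows (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    n_snps: int
    max_fst: float
    mean_fst: float

    @property
    def length(self) -> int:
        return self.end - self.start


def fst_cutoff(windows: Sequence[FstWindow], percentile: float = 95.0) -> float:
    """Percentile cutoff of the defined window-F_ST distribution.

    Uses linear interpolation between order statistics (numpy default).
    """
    vals = np.array([w.fst for w in windows if not math.isnan(w.fst)])
    if vals.size == 0:
        raise ValueError("no defined windows")
    return float(np.percentile(vals, percentile))


def cluster_windows(
    windows: Sequence[FstWindow],
    cutoff: float,
    max_gap: int = 500_000,
    snp_positions: Mapping[str, Sequence[int]] | None = None,
) -> list[SweepRegion]:
    """Group above-cutoff windows into candidate regions (pre-filter).

    Windows with ``fst > cutoff`` (strict) are clustered transitively when
    the gap between the end of one retained window and the start of the
    next is ``< max_gap`` (strict); clusters never span chromosomes.

    Degenerate case: when the cutoff equals the maximum defined window
    F_ST (e.g. a saturated track where >5% of windows sit at the
    estimator's ceiling of 1), strict comparison would retain nothing, so
    windows *equal* to the cutoff are retained instead — "the top tail"
    then means the windows at the ceiling.

    ``n_snps`` sums the SNP counts of the retained member windows unless
    ``snp_positions`` (per-chromosome sorted 1-based SNP positions) is
    given, in which case distinct SNPs inside the retained windows are
    counted exactly (adjacent retained windows overlap by half a window,
    so the plain sum can double-count).
    """
    defined = [w for w in windows if not math.isnan(w.fst)]
    max_fst = max((w.fst for w in defined), default=math.nan)
    inclusive = not math.isnan(max_fst) and cutoff >= max_fst
    retained = [w for w in defined if (w.fst >= cutoff if inclusive else w.fst > cutoff)]
    retained.sort(key=lambda w: (w.chrom, w.start))
    regions: list[SweepRegion] = []
    cluster: list[FstWindow] = []

    def flush() -> None:
        if not cluster:
            return
        chrom = cluster[0].chrom
        start = cluster[0].start
        end = max(w.end for w in cluster)
        if snp_positions is not None and chrom in snp_positions:
            pos = np.asarray(snp_positions[chrom])
            mask = np.zeros(len(pos), dtype=bool)
            for w in cluster:
                mask |= (pos > w.start) & (pos <= w.end)
            n_snps = int(mask.sum())
        else:
            n_snps = sum(w.n_snps for w in cluster)
        fsts = [w.fst for w in cluster]
        regions.append(
            SweepRegion(
                chrom=chrom,
                start=start,
                end=end,
                n_windows=len(cluster),
                n_snps=n_snps,
                max_fst=max(fsts),
                mean_fst=float(np.mean(fsts)),
            )
        )

    for w in retained:
        if cluster and w.chrom == cluster[-1].chrom and (w.start - max(c.end for c in cluster)) < max_gap:
            cluster.append(w)
        else:
            flush()
            cluster = [w]
    flush()
    return regions


def filter_regions(
    regions: Sequence[SweepRegion], min_windows: int = 2, min_snps: int = 2
) -> list[SweepRegion]:
    """Remove single-window clusters and clusters with too few SNPs."""
    return [r for r in regions if r.n_windows >= min_windows and r.n_snps >= min_snps]


def region_summary(regions: Sequence[SweepRegion], genome_size: int) -> dict:
    """Genome-level summary: count, span, % of genome, length statistics."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    lengths = np.array([r.length for r in regions], dtype=float)
    if lengths.size == 0:
        return {
            "n_regions": 0,
            "total_span": 0,
            "pct_genome": 0.0,
            "mean_length": 0.0,
            "median_length": 0.0,
            "min_length": 0.0,
            "max_length": 0.0,
        }
    total = float(lengths.sum())
    return {
        "n_regions": int(lengths.size),
        "total_span": int(total),
        "pct_genome": 100.0 * total / genome_size,
        "mean_length": float(lengths.mean()),
        "median_length": float(np.median(lengths)),
        "min_length": float(lengths.min()),
        "max_length": float(lengths.max()),
    }


def sweep_het_ratio(
    sites: Sequence[PooledSiteCounts],
    regions: Sequence[SweepRegion],
    min_count: int = 3,
) -> dict[int, dict[str, float]]:
    """Per-pool mean expected heterozygosity inside regions vs genome-wide.

    Heterozygosity is averaged over SNP sites only (sites with two alleles
    reaching ``min_count`` summed across pools).  Returns, per pool index,
    ``{"sweep_het", "genome_het", "ratio"}``; values are NaN when no SNP
    falls inside the regions.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))

    het_all: list[np.ndarray] = []
    het_in: list[np.ndarray] = []
    for site in sites:
        af = allele_frequencies(site, min_count=min_count)
        if af is None:
            continue
        pair, freqs = af
        # SNP test: both retained alleles reach min_count summed across pools
        a_tot = int(site.counts[:, pair[0]].sum())
        b_tot = int(site.counts[:, pair[1]].sum())
        if a_tot < min_count or b_tot < min_count:
            continue
        h = np.array(
            [expected_heterozygosity(p) if not math.isnan(p) else math.nan for p in freqs]
        )
        het_all.append(h)
        spans = by_chrom.get(site.chrom, ())
        if any(start < site.pos <= end for start, end in spans):
            het_in.append(h)

    n_pools = sites[0].n_pools if sites else 0
    out: dict[int, dict[str, float]] = {}
    all_mat = np.array(het_all) if het_all else np.empty((0, n_pools))
    in_mat = np.array(het_in) if het_in else np.empty((0, n_pools))
    for p in range(n_pools):
        genome = float(np.nanmean(all_mat[:, p])) if all_mat.size else math.nan
        sweep = float(np.nanmean(in_mat[:, p])) if in_mat.size else math.nan
        ratio = sweep / genome if genome and not math.isnan(sweep) and genome > 0 else math.nan
        out[p] = {"sweep_het": sweep, "genome_het": genome, "ratio": ratio}
    return out


def point_region_distance(pos: int, start: int, end: int) -> int:
    """Distance in bp from a 1-based point to a region given in the same
    1-based coordinates; 0 when the point lies inside the region."""
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def regions_to_bed(regions: Sequence[SweepRegion]) -> str:
    """Render regions as BED (0-based half-open) text."""
    lines = [f"{r.chrom}\t{r.start}\t{r.end}\tsweep\t{r.max_fst:.4f}" for r in regions]
    return "\n".join(lines) + ("\n" if lines else "")


def intersect_regions(
    regions: Sequence[SweepRegion], intervals: Sequence[tuple[str, int, int]]
) -> list[tuple[SweepRegion, tuple[str, int, int]]]:
    """Generic overlap of sweep regions with user intervals (0-based half-open)."""
    out = []
    for r in regions:
        for iv in intervals:
            if iv[0] == r.chrom and iv[1] < r.end and r.start < iv[2]:
                out.append((r, iv))
    return out
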