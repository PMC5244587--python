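"""Haplotype-frequency inference within a sweep region from pooled data.

Inside a strong candidate sweep one line is typically fixed for a single
haplotype while others keep segregating.  Taking the fixed pool as the
reference haplotype, every site's allele frequencies are re-expressed as
the frequency of the non-reference allele ("polarization").  Sites then
fall into frequency bands within each pool: a band's center equals the
summed frequency of the alternative haplotypes that carry the
non-reference allele at its sites.  Clustering sites into bands by their
cross-pool frequency profiles and solving a small non-negative
least-squares system recovers the per-pool haplotype frequencies; the
reference haplotype takes the complement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans

from .pooldata import PooledSiteCounts
from .popstats import allele_frequencies, pairwise_fst_matrix


class NoReferencePoolError(RuntimeError):
    """No pool is fixed across enough of the region to polarize against."""


@dataclass
class PolarizedRegion:
    """Per-site, per-pool frequencies of the non-reference-haplotype allele."""

    chrom: str
    start: int
    end: int
    positions: np.ndarray  # (n_sites,)
    freqs: np.ndarray  # (n_sites, n_pools), NaN where a pool had no reads
    reference_pool: int


@dataclass
class HaplotypeModel:
    """Inferred haplotypes and their per-pool frequencies.

    ``frequencies`` is pools x haplotypes; column 0 is the reference
    haplotype (complement of the alternatives).  ``site_classes`` maps each
    polarized site to a class; ``class_members`` gives, per class, the
    subset of alternative haplotypes (1-based among alternatives) whose
    frequencies sum to the class's band center.
    """

    frequencies: pd.DataFrame
    site_classes: np.ndarray
    class_members: list[tuple[int, ...]]
    residual: float
    ambiguous: bool


def _pool_major_freqs(
    sites: Sequence[PooledSiteCounts], min_count: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """(n_sites, n_pools) frequency of the dataset-major allele + positions."""
    rows = []
    pos = []
    for s in sites:
        af = allele_frequencies(s, min_count=min_count)
        if af is None:
            continue
        rows.append(af[1])
        pos.append(s.pos)
    if not rows:
        raise ValueError("region contains no usable sites")
    return np.array(rows), np.array(pos)


def find_reference_pool(
    region_sites: Sequence[PooledSiteCounts],
    fix_tol: float = 0.95,
    min_sites: int = 10,
    min_fixed_fraction: float = 0.9,
) -> int:
    """Pool fixed (major-allele frequency >= fix_tol) at most region sites.

    Raises :class:`NoReferencePoolError` when no pool is fixed at at least
    ``min_fixed_fraction`` of the sites.
    """
    freqs, _ = _pool_major_freqs(region_sites)
    if freqs.shape[0] < min_sites:
        raise ValueError(
            f"region has {freqs.shape[0]} usable sites; need >= {min_sites}"
        )
    maj = np.maximum(freqs, 1 - freqs)
    with np.errstate(invalid="ignore"):
        frac_fixed = np.nanmean(maj >= fix_tol, axis=0)
    best = int(np.nanargmax(frac_fixed))
    if frac_fixed[best] < min_fixed_fraction:
        raise NoReferencePoolError(
            f"no pool fixed at >= {min_fixed_fraction:.0%} of sites "
            f"(best: pool {best} at {frac_fixed[best]:.0%})"
        )
    return best


def polarize(
    region_sites: Sequence[PooledSiteCounts],
    reference_pool: int,
    fix_tol: float = 0.95,
) -> PolarizedRegion:
    """Re-express all pools' frequencies relative to the reference haplotype.

    At each site the reference pool's major allele defines the 0-allele;
    other pools' frequencies become frequencies of the alternative allele.
    Sites where the reference pool is not fixed (within ``fix_tol``) or has
    no reads are dropped (the sequential position filter).
    """
    freqs, pos = _pool_major_freqs(region_sites)
    ref = freqs[:, reference_pool]
    keep = ~np.isnan(ref) & (np.maximum(ref, 1 - ref) >= fix_tol)
    freqs, pos = freqs[keep], pos[keep]
    ref = freqs[:, reference_pool]
    # frequency of the allele NOT carried by the reference haplotype
    ref_major_is_first = ref >= 0.5
    polarized = np.where(ref_major_is_first[:, None], 1 - freqs, freqs)
    chrom = region_sites[0].chrom
    return PolarizedRegion(
        chrom=chrom,
        start=int(pos.min()),
        end=int(pos.max()),
        positions=pos,
        freqs=polarized,
        reference_pool=reference_pool,
    )


def _choose_n_classes(
    profiles: np.ndarray, max_classes: int, freq_tol: float, min_sites: int
) -> tuple[np.ndarray, np.ndarray]:
    """1-D-per-pool band clustering via KMeans over cross-pool profiles.

    Picks the smallest k whose maximum within-class per-pool spread is
    below ``freq_tol``; merges classes smaller than ``min_sites`` into the
    nearest class.  Returns (labels, class centers).
    """
    n = profiles.shape[0]
    best = None
    for k in range(1, max_classes + 1):
        if k > n:
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(profiles)
        labels = km.labels_
        spread = 0.0
        for c in range(k):
            members = profiles[labels == c]
            if len(members):
                spread = max(spread, float(np.ptp(members, axis=0).max()))
        best = (labels, km.cluster_centers_)
        if spread <= 2 * freq_tol:
            break
    labels, centers = best
    # merge undersized classes into the nearest surviving center
    while True:
        sizes = np.bincount(labels, minlength=len(centers))
        small = [c for c in np.nonzero(sizes)[0] if 0 < sizes[c] < min_sites]
        if not small or (sizes > 0).sum() <= 1:
            break
        c = small[0]
        others = [o for o in np.nonzero(sizes)[0] if o != c]
        dists = [np.linalg.norm(centers[o] - centers[c]) for o in others]
        labels[labels == c] = others[int(np.argmin(dists))]
        centers[c] = np.inf
    # compact labels and recompute centers from members
    kept = np.unique(labels)
    remap = {c: i for i, c in enumerate(kept)}
    labels = np.array([remap[c] for c in labels])
    centers = np.array([profiles[labels == i].mean(axis=0) for i in range(len(kept))])
    return labels, centers


def infer_haplotypes(
    polarized: PolarizedRegion,
    k_max: int = 3,
    freq_tol: float = 0.15,
    min_sites_per_class: int = 5,
    pool_names: Sequence[str] | None = None,
) -> HaplotypeModel:
    """Recover up to ``k_max`` haplotypes (reference included) per pool.

    Sites are clustered into classes by their cross-pool polarized
    frequency profiles; each class is assigned a subset of the alternative
    haplotypes, shared across pools, and per-pool haplotype frequencies are
    solved by non-negative least squares from the class band centers.  The
    model is flagged ambiguous when no assignment reproduces the band
    centers within ``freq_tol``.
    """
    n_pools = polarized.freqs.shape[1]
    others = [p for p in range(n_pools) if p != polarized.reference_pool]
    profiles = np.nan_to_num(polarized.freqs[:, others], nan=0.0)
    m_max = k_max - 1  # alternative haplotypes
    max_classes = 2**m_max - 1
    labels, centers = _choose_n_classes(
        profiles, max_classes, freq_tol, min_sites_per_class
    )
    n_classes = centers.shape[0]

    best_err = math.inf
    best: tuple[np.ndarray, list[tuple[int, ...]]] | None = None
    for m in range(1, m_max + 1):
        subsets = [
            tuple(np.nonzero(bits)[0] + 1)
            for bits in itertools.product((0, 1), repeat=m)
            if any(bits)
        ]
        if n_classes > len(subsets):
            continue
        for assign in itertools.permutations(subsets, n_classes):
            X = np.zeros((n_classes, m))
            for c, subset in enumerate(assign):
                for h in subset:
                    X[c, h - 1] = 1.0
            Q = np.zeros((len(others), m))
            err = 0.0
            for col, _pool in enumerate(others):
                q, res = nnls(X, centers[:, col])
                Q[col] = q
                err += res**2
            err = math.sqrt(err / (n_classes * len(others)))
            # parsimony: prefer fewer haplotypes at comparable fit
            if err < best_err - 1e-9:
                best_err = err
                best = (Q, list(assign), m)
        if best is not None and best_err <= freq_tol / 2:
            break

    if best is None:
        raise ValueError("no haplotype assignment possible for the region")
    Q, assignment, m = best
    ambiguous = best_err > freq_tol

    freq = np.zeros((n_pools, m + 1))
    for row, pool in enumerate(others):
        q = np.clip(Q[row], 0.0, 1.0)
        total = q.sum()
        if total > 1.0:
            q = q / total
        freq[pool, 1:] = q
        freq[pool, 0] = max(0.0, 1.0 - q.sum())
    freq[polarized.reference_pool, 0] = 1.0

    names = (
        list(pool_names)
        if pool_names is not None
        else [f"pool{p}" for p in range(n_pools)]
    )
    cols = ["Haplo1"] + [f"Haplo{h + 1}" for h in range(1, m + 1)]
    return HaplotypeModel(
        frequencies=pd.DataFrame(freq, index=names, columns=cols),
        site_classes=labels,
        class_members=assignment,
        residual=best_err,
        ambiguous=ambiguous,
    )


def region_fst_table(
    region_sites: Sequence[PooledSiteCounts],
    pool_names: Sequence[str] | None = None,
    **window_kwargs,
) -> pd.DataFrame:
    """Pairwise mean window F_ST between all pools across the region."""
    window_kwargs.setdefault("min_covered_fraction", 0.0)
    return pairwise_fst_matrix(region_sites, pool_names=pool_names, **window_kwargs)
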