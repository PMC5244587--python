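"""Multi-locus association of highly differentiated markers with log2 titers.

The procedure mirrors a two-stage, backward-elimination model selection:

1. restrict the marker panel to SNPs whose pooled allele-frequency
   difference between the selected lines exceeds 0.7;
2. cluster neighboring markers (< 5 Mb gaps) and pick one representative
   per cluster by within-cluster backward elimination;
3. fit all representatives jointly (fixed sex effect + additive marker
   dosages, ordinary least squares on log2 day-5 titers) and eliminate
   backwards under an adaptive FDR criterion, reporting a loose (20%) and
   a strict (5%) tier.

The FDR stopping rule applies a Benjamini-Hochberg step-down in which the
multiplicity denominator stays fixed at the number of markers that entered
the elimination (markers already eliminated count as accepted nulls); this
keeps the probability of retaining any marker under a global null at
roughly the nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class MarkerPanel:
    """SNP markers with pooled line frequencies plus F2 genotypes/phenotypes.

    ``markers``: DataFrame with columns id, chrom, pos, p_high, p_low,
    delta_p (frequency of the high-line allele in each line and their
    absolute difference).  ``genotypes``: (n_individuals, n_markers) float
    array of high-line-allele dosages 0/1/2 with NaN for missing.
    ``individuals``: DataFrame with columns id, sex (0 male / 1 female),
    phenotype (log2 titer).
    """

    markers: pd.DataFrame
    genotypes: np.ndarray
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("genotype matrix shape mismatch")
        g = self.genotypes
        ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0/1/2 or missing")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def to_csv(self, path: str | Path) -> None:
        """One-file layout: marker rows; two leading pseudo-rows carry the
        per-individual sex and phenotype."""
        ind_cols = list(self.individuals["id"].astype(str))
        meta_cols = ["id", "chrom", "pos", "p_high", "p_low", "delta_p"]
        header = meta_cols + ind_cols
        rows = []
        rows.append(
            ["_sex", "", "", "", "", ""] + [str(int(s)) for s in self.individuals["sex"]]
        )
        rows.append(
            ["_phenotype", "", "", "", "", ""]
            + [repr(float(p)) for p in self.individuals["phenotype"]]
        )
        for j, m in self.markers.reset_index(drop=True).iterrows():
            geno = [
                "" if math.isnan(x) else str(int(x)) for x in self.genotypes[:, j]
            ]
            rows.append(
                [
                    str(m["id"]),
                    str(m["chrom"]),
                    str(int(m["pos"])),
                    repr(float(m["p_high"])),
                    repr(float(m["p_low"])),
                    repr(float(m["delta_p"])),
                ]
                + geno
            )
        with open(path, "w") as fh:
            fh.write(",".join(header) + "\n")
            for r in rows:
                fh.write(",".join(r) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path, dtype={"id": str}, keep_default_na=True)
        sex_row = df[df["id"] == "_sex"].iloc[0]
        phen_row = df[df["id"] == "_phenotype"].iloc[0]
        mk = df[~df["id"].isin(["_sex", "_phenotype"])].reset_index(drop=True)
        ind_cols = list(df.columns[6:])
        individuals = pd.DataFrame(
            {
                "id": ind_cols,
                "sex": [int(sex_row[c]) for c in ind_cols],
                "phenotype": [float(phen_row[c]) for c in ind_cols],
            }
        )
        genotypes = mk[ind_cols].to_numpy(dtype=float).T
        markers = mk[["id", "chrom", "pos", "p_high", "p_low", "delta_p"]].copy()
        markers["pos"] = markers["pos"].astype(int)
        return cls(markers=markers, genotypes=genotypes, individuals=individuals)


@dataclass
class EliminationResult:
    """Outcome of one backward-elimination pass."""

    retained: list[int]  # column indices into the input genotype matrix
    estimates: np.ndarray  # per retained marker, final joint model
    se: np.ndarray
    pvalues: np.ndarray
    adjusted_p: np.ndarray
    drop_order: list[int]  # eliminated columns, first-dropped first
    excluded: list[int]  # dropped before fitting (missingness/aliasing)
    sex_effect: tuple[float, float] | None  # (estimate, se)


@dataclass
class AssocResult:
    """Two-stage scan output: Table-3-style marker effects with FDR tiers."""

    table: pd.DataFrame  # id, chrom, pos, delta_p, estimate, se, pvalue, tier
    n_candidates: int
    n_clusters: int
    representatives: list[int]  # marker indices into the panel
    fdr_tiers: tuple[float, float]
    status: str = "ok"


def differentiated_marker_subset(panel: MarkerPanel, delta: float = 0.7) -> np.ndarray:
    """Indices of markers with pooled line frequency difference > delta (strict)."""
    return np.nonzero(panel.markers["delta_p"].to_numpy() > delta)[0]


def cluster_markers(
    markers: pd.DataFrame, gap: int = 5_000_000, subset: Sequence[int] | None = None
) -> list[list[int]]:
    """Single-linkage clusters of markers along each chromosome.

    Markers < ``gap`` bp apart (strict) join the same cluster; clusters
    never span chromosomes.  Returns lists of marker indices (into the
    full table) ordered by genome position.
    """
    idx = np.arange(len(markers)) if subset is None else np.asarray(subset)
    sub = markers.iloc[idx]
    order = np.lexsort((sub["pos"].to_numpy(), sub["chrom"].to_numpy(dtype=object)))
    idx = idx[order]
    clusters: list[list[int]] = []
    for i in idx:
        row = markers.iloc[i]
        if clusters:
            last = markers.iloc[clusters[-1][-1]]
            if row["chrom"] == last["chrom"] and row["pos"] - last["pos"] < gap:
                clusters[-1].append(int(i))
                continue
        clusters.append([int(i)])
    return clusters


def bh_adjust(p: np.ndarray, n_total: int) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values with a fixed total test count.

    Equivalent to BH over ``n_total`` tests in which the absent ones have
    p = 1 (they were already eliminated and accepted as null).
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * n_total / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _prepare_design(
    genotypes: np.ndarray,
    covariates: np.ndarray | None,
    max_missing: float,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Impute, drop high-missingness and aliased marker columns.

    Returns (imputed genotypes, usable column indices, excluded indices).
    Aliasing is detected by incremental Gram-Schmidt against the intercept,
    the covariates, and previously accepted markers.
    """
    n, m = genotypes.shape
    X = genotypes.copy()
    excluded: list[int] = []
    usable: list[int] = []
    base = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        base.extend(cov.T)
    Q: list[np.ndarray] = []
    for b in base:
        v = b.astype(float)
        for q in Q:
            v = v - q * (q @ v)
        nv = np.linalg.norm(v)
        if nv > 1e-10:
            Q.append(v / nv)
    for j in range(m):
        col = X[:, j]
        miss = np.isnan(col)
        if miss.mean() > max_missing:
            excluded.append(j)
            continue
        if miss.any():
            col = np.where(miss, np.nanmean(col), col)
            X[:, j] = col
        v = col.astype(float)
        norm0 = np.linalg.norm(v)
        for q in Q:
            v = v - q * (q @ v)
        nv = np.linalg.norm(v)
        if norm0 == 0 or nv < 1e-8 * norm0:
            excluded.append(j)  # constant or aliased with current design
            continue
        Q.append(v / nv)
        usable.append(j)
    return X, np.array(usable, dtype=int), excluded


def backward_eliminate(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    fdr: float = 0.05,
    m_total: int | None = None,
    positions: Sequence[int] | None = None,
    max_missing: float = 0.2,
) -> EliminationResult:
    """OLS backward elimination of additive marker terms under an FDR stop.

    At each step the current model (intercept + covariates + markers) is
    fit; marker p-values are BH-adjusted with the fixed denominator
    ``m_total`` (default: the number of marker columns supplied).  While
    any adjusted p exceeds ``fdr``, the marker with the largest raw p is
    dropped (ties broken toward the later genome position) and the model
    refit.  Covariates (e.g. sex) are never eliminated; effects are
    re-estimated in the final joint model.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    if genotypes.ndim == 1:
        genotypes = genotypes[:, None]
    phenotype = np.asarray(phenotype, dtype=float)
    n, m = genotypes.shape
    if m_total is None:
        m_total = m
    X, usable, excluded = _prepare_design(genotypes, covariates, max_missing)
    if excluded:
        import warnings

        warnings.warn(
            f"dropped {len(excluded)} marker(s) (missingness or aliasing)",
            stacklevel=2,
        )
    pos = (
        np.asarray(positions, dtype=float)
        if positions is not None
        else np.arange(m, dtype=float)
    )

    def fit(cols: list[int]):
        parts = [np.ones((n, 1))]
        n_cov = 0
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != n:
                cov = cov.T
            parts.append(cov)
            n_cov = cov.shape[1]
        if cols:
            parts.append(X[:, cols])
        design = np.hstack(parts)
        res = sm.OLS(phenotype, design).fit()
        k0 = 1 + n_cov
        return res, k0

    current = list(usable)
    drop_order: list[int] = []
    while current:
        res, k0 = fit(current)
        pvals = res.pvalues[k0:]
        adj = bh_adjust(pvals, m_total)
        if (adj <= fdr).all():
            break
        worst_p = pvals.max()
        cand = [i for i, p in enumerate(pvals) if p == worst_p]
        # tie-break: drop the marker later in genome order
        drop_local = max(cand, key=lambda i: pos[current[i]])
        drop_order.append(current.pop(drop_local))

    res, k0 = fit(current)
    if current:
        pvals = res.pvalues[k0:]
        adj = bh_adjust(pvals, m_total)
        est = res.params[k0:]
        se = res.bse[k0:]
    else:
        pvals = np.array([])
        adj = np.array([])
        est = np.array([])
        se = np.array([])
    sex_eff = None
    if covariates is not None:
        sex_eff = (float(res.params[1]), float(res.bse[1]))
    return EliminationResult(
        retained=current,
        estimates=np.asarray(est),
        se=np.asarray(se),
        pvalues=np.asarray(pvals),
        adjusted_p=adj,
        drop_order=drop_order,
        excluded=excluded,
        sex_effect=sex_eff,
    )


def two_stage_scan(
    panel: MarkerPanel,
    delta: float = 0.7,
    gap: int = 5_000_000,
    fdr_tiers: tuple[float, float] = (0.05, 0.20),
) -> AssocResult:
    """Cluster-representative selection followed by genome-wide elimination.

    Stage 1 picks one representative marker per cluster (single-marker
    clusters pass through; multi-marker clusters are reduced by
    within-cluster backward elimination at the loose tier, keeping the
    survivor with the smallest joint-model p, or the last marker dropped
    when none survive).  Stage 2 eliminates the representatives jointly at
    the loose tier and flags the subset that also survives continued
    elimination at the strict tier; the 5% set is nested in the 20% set by
    construction.
    """
    strict, loose = min(fdr_tiers), max(fdr_tiers)
    y = panel.individuals["phenotype"].to_numpy(dtype=float)
    sex = panel.individuals["sex"].to_numpy(dtype=float)
    cand = differentiated_marker_subset(panel, delta)
    if cand.size == 0:
        return AssocResult(
            table=pd.DataFrame(
                columns=["id", "chrom", "pos", "delta_p", "estimate", "se", "pvalue", "tier"]
            ),
            n_candidates=0,
            n_clusters=0,
            representatives=[],
            fdr_tiers=(strict, loose),
            status="no markers pass the frequency-difference filter",
        )
    clusters = cluster_markers(panel.markers, gap=gap, subset=cand)
    reps: list[int] = []
    for cl in clusters:
        if len(cl) == 1:
            reps.append(cl[0])
            continue
        sub = panel.genotypes[:, cl]
        pos = panel.markers["pos"].to_numpy()[cl]
        elim = backward_eliminate(
            sub, y, covariates=sex, fdr=loose, m_total=len(cl), positions=pos
        )
        if elim.retained:
            best = elim.retained[int(np.argmin(elim.pvalues))]
        elif elim.drop_order:
            best = elim.drop_order[-1]
        else:
            best = 0
        reps.append(cl[best])

    pos_reps = panel.markers["pos"].to_numpy()[reps]
    G = panel.genotypes[:, reps]
    elim20 = backward_eliminate(
        G, y, covariates=sex, fdr=loose, m_total=len(reps), positions=pos_reps
    )
    if elim20.retained:
        elim05 = backward_eliminate(
            G[:, elim20.retained],
            y,
            covariates=sex,
            fdr=strict,
            m_total=len(reps),
            positions=pos_reps[elim20.retained],
        )
        strict_set = {elim20.retained[i] for i in elim05.retained}
    else:
        strict_set = set()

    rows = []
    for k, local in enumerate(elim20.retained):
        gi = reps[local]
        m = panel.markers.iloc[gi]
        rows.append(
            {
                "id": m["id"],
                "chrom": m["chrom"],
                "pos": int(m["pos"]),
                "delta_p": float(m["delta_p"]),
                "estimate": float(elim20.estimates[k]),
                "se": float(elim20.se[k]),
                "pvalue": float(elim20.pvalues[k]),
                "tier": f"{strict:.0%}" if local in strict_set else f"{loose:.0%}",
            }
        )
    table = pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "delta_p", "estimate", "se", "pvalue", "tier"]
    )
    return AssocResult(
        table=table,
        n_candidates=int(cand.size),
        n_clusters=len(clusters),
        representatives=reps,
        fdr_tiers=(strict, loose),
    )
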