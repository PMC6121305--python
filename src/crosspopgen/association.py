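"""Genome scans (GLM and mixed-model), Bonferroni threshold and QTL calling.

The fixed-effects scan regresses the phenotype on each marker's dosage with
the structure covariates Q (one column dropped against the intercept); the
mixed-model scan first fits the polygenic null y = Xb + g + e once
(P3D: variance components are not re-estimated per marker), rotates
phenotype, covariates and markers into the kinship eigenbasis, whitens by
the fitted per-eigenvalue variances, and then applies the same
residualised least-squares test.  With an identity kinship the two scans
coincide exactly.

QTL regions are clusters of Bonferroni-significant markers: adjacent
significant markers on a chromosome closer than the merge distance join a
region whose bounds are the outermost member positions and whose peak is
the minimum-p member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .mixedmodel import reml_fit
from .structure import GRM

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    table: pd.DataFrame  # marker_id, chrom, pos_bp, effect, p_value, model
    model: str
    threshold: float | None = None

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        thr = threshold if threshold is not None else self.threshold
        if thr is None:
            raise ValueError("no significance threshold given")
        return self.table[self.table["p_value"] <= thr]

    def genomic_inflation(self) -> float:
        """Lambda_GC: median chi-square over its null median."""
        chi2 = stats.chi2.isf(self.table["p_value"].clip(upper=1.0 - 1e-15), df=1)
        return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def _covariate_matrix(n: int, q_matrix: np.ndarray | None) -> np.ndarray:
    c = np.ones((n, 1))
    if q_matrix is not None:
        q = np.atleast_2d(np.asarray(q_matrix, dtype=float))
        if q.shape[0] != n:
            q = q.T
        q = q[:, :-1]  # drop one membership column against the intercept
        if q.shape[1] > 0:
            c = np.column_stack([c, q])
    if np.linalg.matrix_rank(c) < c.shape[1]:
        raise ValueError("collinear covariates after column reduction")
    return c


def _scan_core(
    y: np.ndarray, x_markers: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residualised per-marker least squares; returns (beta, p)."""
    n, p = c.shape
    proj = c @ np.linalg.pinv(c)
    my = y - proj @ y
    mx = x_markers - proj @ x_markers
    sxx = (mx**2).sum(axis=0)
    df = n - p - 1
    beta = np.zeros(x_markers.shape[1])
    pval = np.ones(x_markers.shape[1])
    ok = sxx > 1e-12
    beta[ok] = (mx[:, ok] * my[:, None]).sum(axis=0) / sxx[ok]
    syy = float(my @ my)
    rss = syy - beta[ok] ** 2 * sxx[ok]
    rss = np.clip(rss, 1e-300, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = beta[ok] ** 2 * sxx[ok] / (rss / df)
    pval[ok] = stats.f.sf(f, 1, df)
    return beta, pval


def glm_scan(
    y: np.ndarray, geno: GenotypeMatrix, q_matrix: np.ndarray | None = None
) -> AssociationResult:
    """Fixed-effects dosage-trend scan: y = mu + Q a + x b + e per marker.

    Markers monomorphic in the analysed lines get p = 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.nan_to_num(geno.dosages(), nan=1.0)
    c = _covariate_matrix(y.size, q_matrix)
    beta, pval = _scan_core(y, x, c)
    table = pd.DataFrame(
        {
            "marker_id": geno.markers["marker_id"],
            "chrom": geno.markers["chrom"],
            "pos_bp": geno.markers["pos_bp"],
            "effect": beta,
            "p_value": pval,
            "model": "GLM",
        }
    )
    return AssociationResult(table=table, model="GLM")


def mlm_scan(
    y: np.ndarray,
    geno: GenotypeMatrix,
    q_matrix: np.ndarray | None,
    kinship: GRM,
) -> AssociationResult:
    """Mixed-model scan with P3D variance components and EMMA rotation.

    The polygenic null (kinship random effect, Q fixed) is fitted once by
    REML; every marker is then tested by generalised least squares in the
    whitened eigenbasis.  Falls back to the fixed-effects scan with a
    logged warning if the null fit does not converge.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.nan_to_num(geno.dosages(), nan=1.0)
    c = _covariate_matrix(y.size, q_matrix)
    vc = reml_fit(y, c, kinship.matrix)
    if not vc.converged:
        logger.warning("mixed-model null did not converge; falling back to GLM")
        res = glm_scan(y, geno, q_matrix)
        res.table["model"] = "MLM"
        res.model = "MLM"
        return res
    d, u = vc.eigvals, vc.eigvecs
    w = np.sqrt(vc.lam * d + 1.0)
    ty = (u.T @ y) / w
    tc = (u.T @ c) / w[:, None]
    tx = (u.T @ x) / w[:, None]
    beta, pval = _scan_core(ty, tx, tc)
    table = pd.DataFrame(
        {
            "marker_id": geno.markers["marker_id"],
            "chrom": geno.markers["chrom"],
            "pos_bp": geno.markers["pos_bp"],
            "effect": beta,
            "p_value": pval,
            "model": "MLM",
        }
    )
    return AssociationResult(table=table, model="MLM")


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_markers."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return alpha / n_markers


@dataclass
class QTLRegion:
    qtl_id: str
    trait: str
    chrom: str
    start_bp: int
    end_bp: int
    peak_marker: str
    peak_p: float
    member_markers: list[str]
    positive_allele: str | None = None  # "alt" if the alt allele raises the trait
    peak_effect: float = float("nan")


def call_qtl(
    assoc: AssociationResult,
    threshold: float,
    merge_distance_kb: float = 1000.0,
    trait: str = "trait",
) -> list[QTLRegion]:
    """Cluster significant markers into QTL regions.

    Adjacent significant markers on the same chromosome at most
    ``merge_distance_kb`` apart join one region; bounds are min/max member
    positions (single-marker regions have start = end); the peak is the
    minimum-p member.  Returns a sorted, disjoint list.
    """
    sig = assoc.table[assoc.table["p_value"] <= threshold].copy()
    regions: list[QTLRegion] = []
    if sig.empty:
        return regions
    merge_bp = merge_distance_kb * 1000.0
    counter = 1
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp")
        bp = grp["pos_bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(bp) > merge_bp)
        bounds = np.concatenate([[0], breaks + 1, [len(grp)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            cluster = grp.iloc[int(a) : int(b)]
            peak = cluster.loc[cluster["p_value"].idxmin()]
            effect = float(peak["effect"])
            regions.append(
                QTLRegion(
                    qtl_id=f"q{trait}.{chrom}.{counter}",
                    trait=trait,
                    chrom=str(chrom),
                    start_bp=int(cluster["pos_bp"].min()),
                    end_bp=int(cluster["pos_bp"].max()),
                    peak_marker=str(peak["marker_id"]),
                    peak_p=float(peak["p_value"]),
                    member_markers=list(cluster["marker_id"]),
                    positive_allele="alt" if effect > 0 else "ref",
                    peak_effect=effect,
                )
            )
            counter += 1
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def allele_effect(geno: GenotypeMatrix, y: np.ndarray, marker_id: str) -> float:
    """Difference of mean phenotypes between the two homozygote classes.

    mean(y | genotype = 2) - mean(y | genotype = 0); heterozygous and
    missing calls are excluded.  Raises if either homozygote class is
    absent.
    """
    y = np.asarray(y, dtype=float).ravel()
    j = geno.marker_index(marker_id)
    calls = geno.calls[:, j]
    hi = calls == 2
    lo = calls == 0
    if not hi.any() or not lo.any():
        raise ValueError(f"marker {marker_id!r} lacks one homozygote class")
    return float(y[hi].mean() - y[lo].mean())


def qtl_table(regions: list[QTLRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "qtl_id": [r.qtl_id for r in regions],
            "trait": [r.trait for r in regions],
            "chrom": [r.chrom for r in regions],
            "start_bp": [r.start_bp for r in regions],
            "end_bp": [r.end_bp for r in regions],
            "peak_marker": [r.peak_marker for r in regions],
            "peak_p": [r.peak_p for r in regions],
            "peak_effect": [r.peak_effect for r in regions],
            "n_markers": [len(r.member_markers) for r in regions],
            "positive_allele": [r.positive_allele for r in regions],
        }
    )
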