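"""QTL validation: haplotype contrasts, pyramiding regression, pleiotropy,
and per-trait summary statistics.

A QTL's "contrasting haplotypes" are operationalised as the two homozygote
classes at its peak SNP (residual heterozygotes excluded), compared with a
Welch t test and a Wilcoxon rank-sum test.  Pyramiding counts, per line,
how many positive-effect QTL alleles it carries (two per homozygous
positive class, one per heterozygote) and regresses the phenotype on the
count; a positive slope indicates additive accumulation of favourable
alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import QTLRegion, allele_effect
from .genotypes import GenotypeMatrix
from .simdata import PhenotypeTable


@dataclass
class HaplotypeContrast:
    qtl_id: str
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    median_high: float
    median_low: float
    t_p: float
    wilcoxon_p: float
    testable: bool
    note: str = ""


def contrast_haplotypes(
    y: np.ndarray,
    geno: GenotypeMatrix,
    qtl: QTLRegion,
    min_class_size: int = 3,
) -> HaplotypeContrast:
    """Welch t and Wilcoxon rank-sum tests between peak-SNP homozygote classes."""
    y = np.asarray(y, dtype=float).ravel()
    j = geno.marker_index(qtl.peak_marker)
    calls = geno.calls[:, j]
    hi = y[calls == 2]
    lo = y[calls == 0]
    if hi.size < min_class_size or lo.size < min_class_size:
        return HaplotypeContrast(
            qtl_id=qtl.qtl_id, n_high=hi.size, n_low=lo.size,
            mean_high=float("nan"), mean_low=float("nan"),
            median_high=float("nan"), median_low=float("nan"),
            t_p=1.0, wilcoxon_p=1.0, testable=False,
            note=f"class below minimum size {min_class_size}",
        )
    if np.array_equal(np.sort(hi), np.sort(lo)):
        t_p, w_p = 1.0, 1.0
    else:
        t_p = float(stats.ttest_ind(hi, lo, equal_var=False).pvalue)
        w_p = float(stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue)
    return HaplotypeContrast(
        qtl_id=qtl.qtl_id, n_high=hi.size, n_low=lo.size,
        mean_high=float(hi.mean()), mean_low=float(lo.mean()),
        median_high=float(np.median(hi)), median_low=float(np.median(lo)),
        t_p=t_p, wilcoxon_p=w_p, testable=True,
    )


@dataclass
class PyramidingResult:
    trait: str
    counts: np.ndarray  # positive-effect allele count per line
    slope: float
    intercept: float
    correlation: float
    p_value: float


def pyramiding_regression(
    y: np.ndarray, geno: GenotypeMatrix, qtls: list[QTLRegion]
) -> PyramidingResult:
    """OLS of phenotype on the per-line count of positive-effect QTL alleles.

    The positive allele of each QTL is the one whose homozygote class has
    the higher phenotype mean (sign of the peak-marker allele effect).
    """
    if len(qtls) < 2:
        raise ValueError("pyramiding needs at least 2 QTL")
    y = np.asarray(y, dtype=float).ravel()
    counts = np.zeros(y.size)
    for q in qtls:
        j = geno.marker_index(q.peak_marker)
        calls = geno.calls[:, j].astype(float)
        calls[geno.calls[:, j] < 0] = np.nan
        eff = allele_effect(geno, y, q.peak_marker)
        dose = calls if eff >= 0 else 2.0 - calls
        counts += np.nan_to_num(dose, nan=1.0)  # missing counted as one allele
    if np.unique(counts).size < 2:
        raise ValueError("all lines carry the same allele count; regression undefined")
    res = stats.linregress(counts, y)
    return PyramidingResult(
        trait=qtls[0].trait,
        counts=counts,
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
        p_value=float(res.pvalue),
    )


def pleiotropy_overlap(qtl_sets: dict[str, list[QTLRegion]]) -> list[list[QTLRegion]]:
    """Group QTL of different traits whose regions intersect (closed intervals).

    Returns connected components with at least two traits involved.
    """
    all_qtl = [q for qs in qtl_sets.values() for q in qs]
    n = len(all_qtl)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = all_qtl[i], all_qtl[j]
            if a.trait == b.trait or a.chrom != b.chrom:
                continue
            if a.start_bp <= b.end_bp and b.start_bp <= a.end_bp:
                union(i, j)
    groups: dict[int, list[QTLRegion]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(all_qtl[i])
    out = []
    for members in groups.values():
        traits = {q.trait for q in members}
        if len(traits) >= 2:
            out.append(sorted(members, key=lambda q: (q.chrom, q.start_bp)))
    out.sort(key=lambda g: (g[0].chrom, g[0].start_bp))
    return out


@dataclass
class TraitSummaries:
    shapiro_p: pd.Series  # per trait
    correlations: pd.DataFrame
    correlation_p: pd.DataFrame


def trait_summaries(blups: pd.DataFrame) -> TraitSummaries:
    """Shapiro-Wilk normality p per trait and pairwise Pearson correlations.

    ``blups``: line x trait values (one column per trait).  Constant traits
    yield missing correlation entries.
    """
    traits = list(blups.columns)
    sh = {}
    for t in traits:
        v = blups[t].dropna().to_numpy()
        if v.size < 3:
            raise ValueError(f"trait {t!r} has fewer than 3 observations")
        sh[t] = float(stats.shapiro(v).pvalue)
    k = len(traits)
    corr = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    corr_p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    for i in range(k):
        for j in range(i + 1, k):
            a = blups[traits[i]].to_numpy(dtype=float)
            b = blups[traits[j]].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if a[ok].std() == 0 or b[ok].std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(a[ok], b[ok])
            corr.iloc[i, j] = corr.iloc[j, i] = r
            corr_p.iloc[i, j] = corr_p.iloc[j, i] = p
    return TraitSummaries(shapiro_p=pd.Series(sh), correlations=corr, correlation_p=corr_p)
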