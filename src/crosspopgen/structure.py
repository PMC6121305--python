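"""Population structure: PCA, DAPC clustering with BIC-selected k, and GRMs.

DAPC follows the usual sequence: PCA of centred dosages, k-means on the
retained PCs for k = 1..k_max with the Bayesian information criterion
BIC(k) = n log(WSS/n) + log(n) * k * d selecting the cluster number, then a
linear discriminant model on the chosen clusters whose posterior
membership probabilities form the Q matrix used as fixed covariates in
association scans and heritability models.

The genomic relationship matrix uses the VanRaden centred-dosage
cross-product scaled by sum(2 p (1-p)); its diagonal averages about 1 and
it is invariant to marker order and to duplicating all markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import GenotypeMatrix


def pca(geno: GenotypeMatrix, standardize: bool = False):
    """PCA of column-centred dosages.

    Returns (scores, variance_explained); scores are orthogonal columns
    ordered by variance, variance_explained sums to 1 over all components.
    """
    if geno.n_lines < 2:
        raise ValueError("need at least 2 lines for PCA")
    x = geno.dosages()
    if np.isnan(x).any():
        raise ValueError("PCA expects imputed (complete) genotypes")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2
    total = var.sum()
    var_explained = var / total if total > 0 else var
    return scores, var_explained


@dataclass
class StructureResult:
    pc_scores: np.ndarray
    variance_explained: np.ndarray
    retained_pcs: int
    bic_curve: pd.DataFrame  # columns k, bic
    best_k: int
    cluster_labels: np.ndarray
    q_matrix: np.ndarray  # lines x best_k posterior memberships


def _kmeans_wss(scores: np.ndarray, k: int, seed: int) -> tuple[float, np.ndarray]:
    n = scores.shape[0]
    if k == 1:
        labels = np.zeros(n, dtype=int)
        wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(scores)
        wss = float(km.inertia_)
    return max(wss, 1e-12), labels


def _bic_curve(kept: np.ndarray, k_max: int, seed: int, n_null: int = 3):
    """Null-calibrated k-means BIC.

    In a high-dimensional PC space k-means lowers the within-cluster sum of
    squares substantially even on structureless data, so the textbook
    per-cluster penalty under-penalises and the per-parameter penalty
    over-penalises.  The penalty is therefore calibrated on permutation
    nulls (each PC column shuffled independently, preserving marginal
    variances while destroying cluster structure), plus a small log(n)*k
    term that breaks ties toward fewer clusters.
    """
    n = kept.shape[0]
    rng = np.random.default_rng(seed)
    data_term = np.empty(k_max)
    labels_by_k = {}
    for k in range(1, k_max + 1):
        wss, labels = _kmeans_wss(kept, k, seed)
        data_term[k - 1] = n * np.log(wss / n)
        labels_by_k[k] = labels
    null_drop = np.zeros(k_max)
    for _ in range(n_null):
        perm = np.column_stack([rng.permutation(col) for col in kept.T])
        base = None
        for k in range(1, k_max + 1):
            wss, _ = _kmeans_wss(perm, k, seed)
            term = n * np.log(wss / n)
            if k == 1:
                base = term
            null_drop[k - 1] += (base - term) / n_null
    ks = np.arange(1, k_max + 1)
    bic = data_term + null_drop + np.log(n) * ks
    return pd.DataFrame({"k": ks, "bic": bic}), labels_by_k


def dapc(
    geno: GenotypeMatrix, n_pcs: int = 100, k_max: int = 10, seed: int = 0
) -> StructureResult:
    """Discriminant analysis of principal components with BIC-selected k."""
    if k_max >= geno.n_lines:
        raise ValueError("k_max must be smaller than the number of lines")
    scores, var_explained = pca(geno)
    rank = int((var_explained > 1e-12).sum())
    n_keep = int(min(n_pcs, rank, geno.n_lines - 1))
    kept = scores[:, :n_keep]

    bic_curve, labels_by_k = _bic_curve(kept, k_max, seed)
    best_k = int(bic_curve.loc[bic_curve["bic"].idxmin(), "k"])
    labels = labels_by_k[best_k]

    if best_k == 1:
        q = np.ones((geno.n_lines, 1))
    else:
        # discriminant axes on a PC subspace small enough to stay stable
        n_da_pcs = int(min(n_keep, max(best_k, geno.n_lines // 3)))
        lda = LinearDiscriminantAnalysis()
        lda.fit(kept[:, :n_da_pcs], labels)
        labels = lda.predict(kept[:, :n_da_pcs])
        q = lda.predict_proba(kept[:, :n_da_pcs])
    return StructureResult(
        pc_scores=scores,
        variance_explained=var_explained,
        retained_pcs=n_keep,
        bic_curve=bic_curve,
        best_k=best_k,
        cluster_labels=labels,
        q_matrix=q,
    )


@dataclass
class GRM:
    matrix: np.ndarray
    method: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        self.matrix = (m + m.T) / 2.0


def grm(geno: GenotypeMatrix, method: str = "vanraden", ridge: float = 1e-8) -> GRM:
    """VanRaden genomic relationship matrix from imputed dosages.

    G = Z Z' / sum(2 p (1-p)) with Z the dosage matrix centred at 2p per
    marker (monomorphic markers contribute nothing), then rescaled so the
    mean self-relationship is 1: the raw VanRaden diagonal approaches
    1 + F and inbred lines (F ~ 1) would otherwise sit near 2, which
    distorts the h^2 = sigma_g^2/(sigma_g^2+sigma_e^2) scale.  A small
    ridge keeps G numerically PSD.
    """
    if method != "vanraden":
        raise ValueError(f"unknown GRM method {method!r}")
    x = geno.dosages()
    if np.isnan(x).any():
        raise ValueError("GRM expects imputed (complete) genotypes")
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers")
    z = x[:, poly] - 2.0 * p[poly]
    denom = float((2.0 * p[poly] * (1.0 - p[poly])).sum())
    g = z @ z.T / denom
    g /= np.mean(np.diag(g))
    if ridge > 0:
        g = g + ridge * np.eye(g.shape[0])
    return GRM(matrix=g, method=method)
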