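"""Single-random-effect REML in spectral form: GREML heritability and BLUP.

The model is

    y = X beta + g + eps,   g ~ N(0, A sigma_g^2),  eps ~ N(0, I sigma_e^2),

with A a symmetric PSD relationship matrix.  Because there is a single
relationship matrix, the restricted likelihood profiled over
(beta, sigma_e^2) is a univariate function of the variance ratio
lambda = sigma_g^2 / sigma_e^2.  After rotating by the eigenvectors of A
the covariance is diagonal, so each likelihood evaluation is O(n) plus one
small least-squares solve, and the maximisation is a 1-D search (coarse
grid + bounded Brent on log10 lambda).  Variance components are clamped at
the boundary, hence h^2 = sigma_g^2/(sigma_g^2+sigma_e^2) always lands in
[0, 1].

The same engine fits the GWAS mixed-model null (kinship as A), GREML SNP
heritability (GRM from all SNPs or a subset), and multi-environment BLUP
(A = Z Z' over the line-incidence matrix, environment as a fixed effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .simdata import PhenotypeTable

_LOG_LAMBDA_RANGE = (-8.0, 8.0)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    log_likelihood: float
    converged: bool
    lam: float
    # spectral context reused by downstream steps (P3D scans, BLUP back-solve)
    eigvals: np.ndarray | None = None
    eigvecs: np.ndarray | None = None

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else 0.0


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    n_snps_used: int
    sigma_g2: float
    sigma_e2: float


def _reml_loglik(log10_lam: float, d: np.ndarray, ty: np.ndarray, tx: np.ndarray) -> float:
    """Profiled restricted log-likelihood at variance ratio 10**log10_lam."""
    lam = 10.0**log10_lam
    n, p = tx.shape
    w = lam * d + 1.0
    sw = np.sqrt(w)
    yw = ty / sw
    xw = tx / sw[:, None]
    xtx = xw.T @ xw
    beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma_e2 = rss / df
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0 or sigma_e2 <= 0:
        return -np.inf
    ll = -0.5 * (
        df * (np.log(2.0 * np.pi * sigma_e2) + 1.0) + np.log(w).sum() + logdet_xtx
    )
    return float(ll)


def reml_fit(y: np.ndarray, x_fixed: np.ndarray, a: np.ndarray) -> VarianceComponents:
    """Maximise the restricted likelihood of (sigma_g^2, sigma_e^2).

    Parameters
    ----------
    y : phenotype vector (finite values only)
    x_fixed : fixed-effect design, full column rank, includes the intercept
    a : symmetric PSD relationship matrix aligned with y
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x_fixed, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    n = y.size
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype values")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    a = np.asarray(a, dtype=float)
    if a.shape != (n, n):
        raise ValueError("relationship matrix misaligned with phenotype")

    d, u = np.linalg.eigh((a + a.T) / 2.0)
    d = np.clip(d, 0.0, None)
    ty = u.T @ y
    tx = u.T @ x

    lo, hi = _LOG_LAMBDA_RANGE
    grid = np.linspace(lo, hi, 65)
    vals = np.array([_reml_loglik(g, d, ty, tx) for g in grid])
    k = int(np.argmax(vals))
    g_lo = grid[max(k - 1, 0)]
    g_hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, d, ty, tx),
        bounds=(g_lo, g_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best = res.x if -res.fun >= vals[k] else grid[k]
    ll = _reml_loglik(best, d, ty, tx)
    lam = 10.0**best

    w = lam * d + 1.0
    sw = np.sqrt(w)
    xw = tx / sw[:, None]
    beta, *_ = np.linalg.lstsq(xw, ty / sw, rcond=None)
    rss = float(((ty / sw - xw @ beta) ** 2).sum())
    sigma_e2 = rss / (n - x.shape[1])
    sigma_g2 = lam * sigma_e2
    # boundary clamping: treat ratios at the search edge as boundary solutions
    if best <= lo + 1e-9:
        sigma_e2 = sigma_g2 + sigma_e2
        sigma_g2 = 0.0
        lam = 0.0
    converged = bool(res.success)
    return VarianceComponents(
        sigma_g2=float(max(sigma_g2, 0.0)),
        sigma_e2=float(max(sigma_e2, 0.0)),
        log_likelihood=ll,
        converged=converged,
        lam=float(lam),
        eigvals=d,
        eigvecs=u,
    )


class VarianceComponentModel:
    """Model-object wrapper around :func:`reml_fit` with a summary table."""

    def __init__(self, y: np.ndarray, x_fixed: np.ndarray, a: np.ndarray):
        self.y = np.asarray(y, dtype=float).ravel()
        self.x = np.atleast_2d(np.asarray(x_fixed, dtype=float))
        if self.x.shape[0] != self.y.size:
            self.x = self.x.T
        self.a = np.asarray(a, dtype=float)

    def fit(self) -> "VarianceComponentResults":
        vc = reml_fit(self.y, self.x, self.a)
        return VarianceComponentResults(self, vc)


class VarianceComponentResults:
    def __init__(self, model: VarianceComponentModel, vc: VarianceComponents):
        self.model = model
        self.vc = vc

    @property
    def h2(self) -> float:
        return self.vc.h2

    def h2_se(self) -> float:
        return _h2_se(self.model.y, self.model.x, self.vc)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sigma_g2": [self.vc.sigma_g2],
                "sigma_e2": [self.vc.sigma_e2],
                "h2": [self.vc.h2],
                "h2_se": [self.h2_se()],
                "logLik": [self.vc.log_likelihood],
                "converged": [self.vc.converged],
            }
        )


def _h2_se(y: np.ndarray, x: np.ndarray, vc: VarianceComponents) -> float:
    """SE of h^2 from the observed information of the profiled likelihood.

    The profile restricted log-likelihood is re-expressed in h^2 through
    lambda = h^2/(1-h^2); the curvature at the optimum is estimated by a
    central second difference and inverted.
    """
    d, u = vc.eigvals, vc.eigvecs
    ty = u.T @ y
    tx = u.T @ x

    def ll_of_h2(h2: float) -> float:
        h2 = min(max(h2, 1e-9), 1.0 - 1e-9)
        return _reml_loglik(np.log10(h2 / (1.0 - h2)), d, ty, tx)

    h2 = min(max(vc.h2, 1e-6), 1.0 - 1e-6)
    eps = 1e-4
    if h2 < 2 * eps or h2 > 1 - 2 * eps:
        eps = h2 / 2 if h2 < 0.5 else (1 - h2) / 2
        if eps <= 0:
            return float("nan")
    curv = (ll_of_h2(h2 + eps) - 2.0 * ll_of_h2(h2) + ll_of_h2(h2 - eps)) / eps**2
    if curv >= 0:
        return float("nan")
    return float(np.sqrt(-1.0 / curv))


# ---------------------------------------------------------------------------
# GREML heritability
# ---------------------------------------------------------------------------


def estimate_h2(
    y: np.ndarray,
    q_matrix: np.ndarray | None,
    geno,
    snp_subset: np.ndarray | None = None,
) -> HeritabilityEstimate:
    """GREML h^2 from a GRM built on a SNP subset, with Q covariates fixed.

    ``snp_subset`` is an index array into the genotype's markers (default:
    all).  With the member SNPs of one QTL region this yields h2_QTL; with
    the union over all QTL of a trait, h2_GWAS.
    """
    from .structure import grm as build_grm

    y = np.asarray(y, dtype=float).ravel()
    sub = geno if snp_subset is None else geno.take_markers(np.asarray(snp_subset))
    if sub.n_markers == 0:
        raise ValueError("empty SNP subset")
    if (np.nan_to_num(sub.maf()) <= 0).all():
        raise ValueError("no polymorphic SNP in subset")
    g = build_grm(sub)
    n = y.size
    x = np.ones((n, 1))
    if q_matrix is not None and np.ndim(q_matrix) == 2 and np.shape(q_matrix)[1] > 0:
        q = np.asarray(q_matrix, dtype=float)
        x = np.column_stack([x, q[:, :-1]])  # drop one column vs the intercept
    vc = reml_fit(y, x, g.matrix)
    se = _h2_se(y, x, vc)
    return HeritabilityEstimate(
        h2=vc.h2, se=se, n_snps_used=sub.n_markers,
        sigma_g2=vc.sigma_g2, sigma_e2=vc.sigma_e2,
    )


# ---------------------------------------------------------------------------
# Multi-environment BLUP
# ---------------------------------------------------------------------------


@dataclass
class BlupTable:
    """Shrunken per-line genetic values and the line-model variance components."""

    blups: pd.DataFrame  # index line_id, one column per trait
    components: dict  # trait -> VarianceComponents

    def values_for(self, trait: str, line_ids) -> np.ndarray:
        return self.blups.loc[list(line_ids), trait].to_numpy()


def blup_line_effects(pheno: PhenotypeTable) -> BlupTable:
    """Fit y_ie = mu + env_e + line_i + eps by REML and return line BLUPs.

    Environment enters as a fixed effect, line as the random effect
    (A = Z Z' over the line-incidence matrix).  Unbalanced data are allowed;
    a line observed in no environment is an error.
    """
    data = pheno.data
    blup_cols = {}
    comps = {}
    all_lines = list(pd.unique(data["line_id"]))
    for trait in pheno.traits():
        sub = data[data["trait"] == trait].dropna(subset=["value"])
        lines = pd.unique(sub["line_id"])
        missing_lines = set(all_lines) - set(lines)
        if missing_lines:
            raise ValueError(
                f"lines with zero observations for {trait!r}: {sorted(missing_lines)[:5]}"
            )
        line_idx = {l: i for i, l in enumerate(lines)}
        envs = pd.unique(sub["environment"])
        env_idx = {e: i for i, e in enumerate(envs)}
        y = sub["value"].to_numpy(dtype=float)
        n_obs = y.size
        z = np.zeros((n_obs, len(lines)))
        z[np.arange(n_obs), [line_idx[l] for l in sub["line_id"]]] = 1.0
        x = np.ones((n_obs, 1))
        if len(envs) > 1:
            e_dummy = np.zeros((n_obs, len(envs) - 1))
            ei = np.array([env_idx[e] for e in sub["environment"]])
            for k in range(1, len(envs)):
                e_dummy[ei == k, k - 1] = 1.0
            x = np.column_stack([x, e_dummy])
        vc = reml_fit(y, x, z @ z.T)
        # BLUP of line effects: u = sigma_g^2 Z' V^{-1} (y - X beta)
        d, u_rot = vc.eigvals, vc.eigvecs
        lam = vc.lam
        w = lam * d + 1.0
        ty, tx = u_rot.T @ y, u_rot.T @ x
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(tx / sw[:, None], ty / sw, rcond=None)
        resid_rot = (ty - tx @ beta) / w  # V^{-1}(y - Xb) up to sigma_e^2
        vinv_resid = u_rot @ resid_rot
        u_blup = lam * (z.T @ vinv_resid)  # sigma_g^2/sigma_e^2 cancels the scale
        blup_cols[trait] = pd.Series(u_blup, index=lines)
        comps[trait] = vc
    blups = pd.DataFrame(blup_cols).loc[all_lines]
    return BlupTable(blups=blups, components=comps)
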