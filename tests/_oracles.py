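"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the code paths they verify: REML via explicit
matrix inversion instead of the eigendecomposition, diversity via pairwise
difference counting, LD via direct correlation on extracted columns.
"""

import numpy as np
from scipy import optimize


def brute_force_reml(y, x, a, log10_lam_range=(-8.0, 8.0)):
    """REML by direct matrix inversion, profiled over the variance ratio.

    Returns (sigma_g2, sigma_e2, max restricted log-likelihood).
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    n, p = x.shape

    def neg_ll(log10_lam):
        lam = 10.0**log10_lam
        v = lam * a + np.eye(n)
        vinv = np.linalg.inv(v)
        xtvx = x.T @ vinv @ x
        beta = np.linalg.solve(xtvx, x.T @ vinv @ y)
        r = y - x @ beta
        quad = float(r @ vinv @ r)
        sigma_e2 = quad / (n - p)
        _, ld_v = np.linalg.slogdet(v)
        _, ld_x = np.linalg.slogdet(xtvx)
        ll = -0.5 * (
            (n - p) * (np.log(2.0 * np.pi * sigma_e2) + 1.0) + ld_v + ld_x
        )
        return -ll

    grid = np.linspace(*log10_lam_range, 161)
    vals = [neg_ll(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    best = res.x if res.fun <= vals[k] else grid[k]
    lam = 10.0**best
    v = lam * a + np.eye(n)
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    beta = np.linalg.solve(xtvx, x.T @ vinv @ y)
    r = y - x @ beta
    sigma_e2 = float(r @ vinv @ r) / (n - p)
    return lam * sigma_e2, sigma_e2, -neg_ll(best)


def brute_force_reml_loglik(y, x, a, lam):
    """Restricted log-likelihood at a fixed variance ratio, by inversion."""
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    n, p = x.shape
    v = lam * a + np.eye(n)
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    beta = np.linalg.solve(xtvx, x.T @ vinv @ y)
    r = y - x @ beta
    sigma_e2 = float(r @ vinv @ r) / (n - p)
    _, ld_v = np.linalg.slogdet(v)
    _, ld_x = np.linalg.slogdet(xtvx)
    return -0.5 * ((n - p) * (np.log(2.0 * np.pi * sigma_e2) + 1.0) + ld_v + ld_x)


def mean_pairwise_differences(calls):
    """Average per-pair allele differences summed over sites (diploid coding).

    Each line contributes two allele copies per site; the mean number of
    pairwise differences between allele copies equals sum over sites of
    2 p (1-p) n/(n-1).
    """
    n_lines, m = calls.shape
    total = 0.0
    for j in range(m):
        col = calls[:, j]
        col = col[col >= 0]
        alleles = np.concatenate([(col >= 1).astype(int), (col >= 2).astype(int)])
        k = alleles.size
        diffs = 0
        for a in range(k):
            for b in range(a + 1, k):
                diffs += alleles[a] != alleles[b]
        total += diffs / (k * (k - 1) / 2) if k >= 2 else 0.0
    return total


def direct_r2(xa, xb):
    """Squared Pearson correlation of two dosage vectors (complete cases)."""
    ok = ~(np.isnan(xa) | np.isnan(xb))
    r = np.corrcoef(xa[ok], xb[ok])[0, 1]
    return r * r
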