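"""Diversity, differentiation, linkage disequilibrium and LD decay.

LD is the squared Pearson correlation of genotype dosages (0/1/2), the
composite estimate appropriate for unphased inbred lines.  The expected
decay of r^2 with distance follows the Hill & Weir drift-sampling
expectation

    E[r^2] = [(10+C)/((2+C)(11+C))] * [1 + ((3+C)(12+12C+C^2)) / (n(2+C)(11+C))]

with C = c*d (d the bp distance, c the decay coefficient to estimate) and n
the number of sampled gametes (twice the number of individuals).  The
half-decay distance is where the fitted curve reaches half its value at
d -> 0; note the n -> infinity zero-distance limit is 10/22.

Diversity is Watterson/Nei-style per-site pi with the n/(n-1) small-sample
correction; differentiation is the Hudson Fst estimator computed as a ratio
of averages across sites, which is robust for small numbers of demes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .genotypes import GenotypeMatrix

# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------


def pairwise_r2(geno: GenotypeMatrix, max_window_kb: float = 2000.0) -> pd.DataFrame:
    """All intra-chromosome dosage-r^2 pairs within a bp window.

    Returns a DataFrame (chrom, marker_i, marker_j, bp_i, bp_j, dist_bp, r2).
    Pairs involving a zero-variance marker are skipped.  Missing calls are
    handled by complete-case correlation per pair only when present; with
    imputed input the fast full-matrix path is used.
    """
    window_bp = max_window_kb * 1000.0
    x = geno.dosages()
    has_missing = np.isnan(x).any()
    frames = []
    mk = geno.markers
    for chrom, grp in mk.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            continue
        bp = grp["pos_bp"].to_numpy(dtype=float)
        sub = x[:, idx]
        if has_missing:
            r2m = _masked_corr_sq(sub)
        else:
            sd = sub.std(axis=0)
            ok = sd > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.corrcoef(sub, rowvar=False)
            r2m = c**2
            r2m[~ok, :] = np.nan
            r2m[:, ~ok] = np.nan
        ii, jj = np.triu_indices(idx.size, k=1)
        dist = bp[jj] - bp[ii]
        keep = (dist <= window_bp) & (dist > 0) & np.isfinite(r2m[ii, jj])
        if not keep.any():
            continue
        ids = grp["marker_id"].to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "marker_i": ids[ii[keep]],
                    "marker_j": ids[jj[keep]],
                    "bp_i": bp[ii[keep]].astype(np.int64),
                    "bp_j": bp[jj[keep]].astype(np.int64),
                    "dist_bp": dist[keep].astype(np.int64),
                    "r2": np.clip(r2m[ii[keep], jj[keep]], 0.0, 1.0),
                }
            )
        )
    if not frames:
        raise ValueError("no polymorphic intra-chromosome pairs within the window")
    return pd.concat(frames, ignore_index=True)


def _masked_corr_sq(sub: np.ndarray) -> np.ndarray:
    """Squared pairwise complete-case correlation with NaN entries allowed."""
    m = sub.shape[1]
    out = np.full((m, m), np.nan)
    obs = ~np.isnan(sub)
    z = np.nan_to_num(sub)
    n = obs.T.astype(float) @ obs
    s = z.T @ obs.astype(float)
    ss = (z**2).T @ obs.astype(float)
    cross = z.T @ z
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_i = s / n
        cov = cross / n - mean_i * mean_i.T
        var_i = ss / n - mean_i**2
        denom = var_i * var_i.T
        out = np.where(denom > 0, cov**2 / denom, np.nan)
    out[n < 2] = np.nan
    return out


def prune_ld(
    geno: GenotypeMatrix,
    window_kb: float = 2000.0,
    step_snps: int = 50,
    r2_max: float = 0.9,
) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning: drop any marker whose r^2 with an
    already-retained marker within ``window_kb`` exceeds ``r2_max``.

    The earlier marker of a high-LD pair is kept.  The scan is
    window-complete, so the output contains no retained intra-window pair
    with r^2 > r2_max regardless of ``step_snps`` (kept for interface
    compatibility with SNP-stepped pruners).
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must lie in (0, 1]")
    window_bp = window_kb * 1000.0
    x = geno.dosages()
    x = np.nan_to_num(x, nan=np.nanmean(x) if np.isnan(x).any() else 0.0)
    keep: list[int] = []
    for chrom, grp in geno.markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        bp = grp["pos_bp"].to_numpy(dtype=float)
        retained: list[int] = []  # positions within idx
        for j in range(idx.size):
            xj = x[:, idx[j]]
            if xj.std() == 0:
                retained.append(j)  # monomorphic: r2 undefined, keep
                continue
            drop = False
            for i in reversed(retained):
                if bp[j] - bp[i] > window_bp:
                    break
                xi = x[:, idx[i]]
                if xi.std() == 0:
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                if r * r > r2_max:
                    drop = True
                    break
            if not drop:
                retained.append(j)
        keep.extend(idx[retained])
    return geno.take_markers(np.sort(np.array(keep, dtype=int)))


# ---------------------------------------------------------------------------
# LD decay (Hill-Weir expectation)
# ---------------------------------------------------------------------------


def hill_weir_expected_r2(C: np.ndarray, n_gametes: int) -> np.ndarray:
    """Expected r^2 at scaled distance C = c*d for n sampled gametes."""
    C = np.asarray(C, dtype=float)
    n = float(n_gametes)
    a = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    b = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return a * b


@dataclass
class LDDecayResults:
    """Fitted LD-decay curve: decay coefficient, zero-distance r2, half-decay."""

    c: float
    n_gametes: int
    r2_at_zero: float
    half_decay_bp: float
    rss: float
    n_pairs: int

    def predict(self, dist_bp: np.ndarray) -> np.ndarray:
        return hill_weir_expected_r2(self.c * np.asarray(dist_bp, dtype=float), self.n_gametes)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c": [self.c],
                "n_gametes": [self.n_gametes],
                "r2_at_zero": [self.r2_at_zero],
                "half_decay_bp": [self.half_decay_bp],
                "half_decay_kb": [self.half_decay_bp / 1000.0],
                "rss": [self.rss],
                "n_pairs": [self.n_pairs],
            }
        )


class LDDecayModel:
    """Nonlinear least-squares fit of the Hill-Weir E[r^2] curve to LD pairs.

    Parameters
    ----------
    pairs : DataFrame with columns dist_bp and r2 (output of pairwise_r2)
    n_gametes : number of sampled gametes (2 x individuals)
    """

    def __init__(self, pairs: pd.DataFrame, n_gametes: int):
        d = pairs["dist_bp"].to_numpy(dtype=float)
        r2 = pairs["r2"].to_numpy(dtype=float)
        if d.size < 10:
            raise ValueError("need at least 10 LD pairs to fit the decay curve")
        if np.unique(d).size < 2:
            raise ValueError("all pair distances equal; decay is unidentifiable")
        self.dist = d
        self.r2 = r2
        self.n_gametes = int(n_gametes)

    def _rss(self, log10_c: float) -> float:
        pred = hill_weir_expected_r2(10.0**log10_c * self.dist, self.n_gametes)
        return float(((self.r2 - pred) ** 2).sum())

    def fit(self) -> LDDecayResults:
        # 1-D problem in log10(c): coarse grid then local refinement
        grid = np.linspace(-12.0, 0.0, 61)
        vals = [self._rss(g) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            self._rss, bounds=(g0 - 0.5, g0 + 0.5), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError("LD-decay fit did not converge")
        c = float(10.0**res.x)
        r2_zero = float(hill_weir_expected_r2(np.array(0.0), self.n_gametes))
        half = self._half_decay(c, r2_zero)
        return LDDecayResults(
            c=c,
            n_gametes=self.n_gametes,
            r2_at_zero=r2_zero,
            half_decay_bp=half,
            rss=float(res.fun),
            n_pairs=self.dist.size,
        )

    def _half_decay(self, c: float, r2_zero: float) -> float:
        target = r2_zero / 2.0

        def f(d):
            return hill_weir_expected_r2(np.array(c * d), self.n_gametes) - target

        hi = 1.0
        while f(hi) > 0:
            hi *= 10.0
            if hi > 1e15:
                raise RuntimeError("half-decay distance out of range")
        return float(optimize.brentq(f, 1e-12, hi, xtol=1e-9, rtol=1e-12))


def fit_ld_decay(pairs: pd.DataFrame, n_gametes: int) -> LDDecayResults:
    """Convenience wrapper: fit the Hill-Weir decay model and return results."""
    return LDDecayModel(pairs, n_gametes).fit()


# ---------------------------------------------------------------------------
# Diversity and differentiation
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    pi_per_site: float
    pi_total: float
    n_variant_sites: int


def nucleotide_diversity(geno: GenotypeMatrix) -> DiversityStats:
    """Per-site nucleotide diversity with small-sample correction.

    site pi = 2 p (1-p) * n/(n-1), n = non-missing allele count; averaged
    over all sites (pi_per_site) and summed over variant sites (pi_total).
    """
    if geno.n_lines < 2:
        raise ValueError("need at least 2 lines")
    obs = ~geno.missing_mask()
    n_alleles = 2.0 * obs.sum(axis=0)
    dose = np.where(obs, geno.calls, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dose.sum(axis=0) / n_alleles
        site_pi = 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0)
    site_pi = np.where(n_alleles >= 2, site_pi, np.nan)
    variant = (site_pi > 0) & np.isfinite(site_pi)
    return DiversityStats(
        pi_per_site=float(np.nanmean(site_pi)),
        pi_total=float(np.nansum(site_pi[variant])),
        n_variant_sites=int(variant.sum()),
    )


def fst(geno_a: GenotypeMatrix, geno_b: GenotypeMatrix) -> float:
    """Hudson Fst between two populations, ratio of averages across sites.

    Per site: N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
              D = p1(1-p2) + p2(1-p1);  Fst = sum(N)/sum(D).
    Sites are matched by (chrom, bp); sites monomorphic in both populations
    are excluded.  Slightly negative estimates are possible by construction.
    """
    ka = {(r.chrom, r.pos_bp): j for j, r in enumerate(geno_a.markers.itertuples(index=False))}
    kb = {(r.chrom, r.pos_bp): j for j, r in enumerate(geno_b.markers.itertuples(index=False))}
    shared = [k for k in ka if k in kb]
    if not shared:
        raise ValueError("no shared markers")
    ja = np.array([ka[k] for k in shared])
    jb = np.array([kb[k] for k in shared])

    def freq_and_n(g: GenotypeMatrix, jj: np.ndarray):
        obs = ~g.missing_mask()[:, jj]
        n = 2.0 * obs.sum(axis=0)
        dose = np.where(obs, g.calls[:, jj], 0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = dose.sum(axis=0) / n
        return p, n

    p1, n1 = freq_and_n(geno_a, ja)
    p2, n2 = freq_and_n(geno_b, jb)
    ok = (n1 >= 2) & (n2 >= 2)
    poly = ((p1 > 0) & (p1 < 1)) | ((p2 > 0) & (p2 < 1)) | (np.abs(p1 - p2) > 0)
    ok &= poly
    if not ok.any():
        raise ValueError("no shared polymorphic site")
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


# ---------------------------------------------------------------------------
# Haplotype blocks (D' confidence-interval method)
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeBlock:
    chrom: str
    start_bp: int
    end_bp: int
    marker_ids: list[str]


def _dprime_ci(
    c11: float, c12: float, c21: float, c22: float, grid: np.ndarray
) -> tuple[float, float]:
    """Likelihood-based CI for |D'| from two-locus haplotype counts.

    Marginal allele frequencies are held at their MLEs; the multinomial
    likelihood is profiled over |D'| in [0,1] along the sign of the observed
    D, and the 5th/95th points of the normalised likelihood give the CI.
    """
    total = c11 + c12 + c21 + c22
    if total == 0:
        return 0.0, 0.0
    pA = (c11 + c12) / total
    pB = (c11 + c21) / total
    d_obs = c11 / total - pA * pB
    if d_obs >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        sign = 1.0
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
        sign = -1.0
    if dmax <= 0:
        return 0.0, 0.0
    d = sign * grid * dmax
    f11 = np.clip(pA * pB + d, 1e-12, 1.0)
    f12 = np.clip(pA * (1 - pB) - d, 1e-12, 1.0)
    f21 = np.clip((1 - pA) * pB - d, 1e-12, 1.0)
    f22 = np.clip((1 - pA) * (1 - pB) + d, 1e-12, 1.0)
    ll = c11 * np.log(f11) + c12 * np.log(f12) + c21 * np.log(f21) + c22 * np.log(f22)
    like = np.exp(ll - ll.max())
    cdf = np.cumsum(like) / like.sum()
    lo = float(grid[int(np.searchsorted(cdf, 0.05))])
    hi = float(grid[min(int(np.searchsorted(cdf, 0.95)), grid.size - 1)])
    return lo, hi


def haplotype_blocks(
    geno: GenotypeMatrix,
    max_block_kb: float = 2000.0,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    min_strong_fraction: float = 0.95,
    max_block_markers: int = 30,
) -> list[HaplotypeBlock]:
    """Call haplotype blocks with the D' confidence-interval method.

    A pair is in "strong LD" when its |D'| CI is [>= strong_low, >= strong_high]
    and shows "strong recombination" when the CI upper bound < recomb_high.
    Blocks are maximal contiguous marker runs, capped at ``max_block_kb``,
    in which the strong-LD fraction among informative pairs is at least
    ``min_strong_fraction``.  Haplotypes are taken from homozygous calls
    (lines heterozygous or missing at either marker are excluded per pair),
    which is exact for inbred material.
    """
    grid = np.linspace(0.0, 1.0, 101)
    blocks: list[HaplotypeBlock] = []
    hom = geno.calls  # 0/2 informative, 1 or MISSING excluded pairwise
    for chrom, grp in geno.markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        bp = grp["pos_bp"].to_numpy()
        ids = grp["marker_id"].to_numpy()
        m = idx.size
        if m < 2:
            continue

        def pair_state(a: int, b: int) -> int:
            """1 strong LD, -1 strong recombination, 0 uninformative."""
            xa = hom[:, idx[a]]
            xb = hom[:, idx[b]]
            ok = ((xa == 0) | (xa == 2)) & ((xb == 0) | (xb == 2))
            ha = xa[ok] // 2
            hb = xb[ok] // 2
            if ha.size < 2 or ha.std() == 0 or hb.std() == 0:
                return 0
            c11 = int(((ha == 1) & (hb == 1)).sum())
            c12 = int(((ha == 1) & (hb == 0)).sum())
            c21 = int(((ha == 0) & (hb == 1)).sum())
            c22 = int(((ha == 0) & (hb == 0)).sum())
            lo, hi = _dprime_ci(c11, c12, c21, c22, grid)
            if lo >= strong_low and hi >= strong_high:
                return 1
            if hi < recomb_high:
                return -1
            return 0

        cache: dict[tuple[int, int], int] = {}

        def state(a: int, b: int) -> int:
            if (a, b) not in cache:
                cache[(a, b)] = pair_state(a, b)
            return cache[(a, b)]

        i = 0
        while i < m - 1:
            best_j = None
            n_strong = 0
            n_inf = 0
            j = i
            while (
                j + 1 < m
                and bp[j + 1] - bp[i] <= max_block_kb * 1000.0
                and j + 1 - i < max_block_markers
            ):
                j += 1
                for a in range(i, j):
                    st = state(a, j)
                    if st != 0:
                        n_inf += 1
                        if st == 1:
                            n_strong += 1
                if n_inf > 0 and n_strong / n_inf >= min_strong_fraction:
                    best_j = j
            if best_j is not None:
                blocks.append(
                    HaplotypeBlock(
                        chrom=str(chrom),
                        start_bp=int(bp[i]),
                        end_bp=int(bp[best_j]),
                        marker_ids=list(ids[i : best_j + 1]),
                    )
                )
                i = best_j + 1
            else:
                i += 1
    return blocks


def blocks_to_bed(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """Blocks as BED (0-based half-open, converted from 1-based closed)."""
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start": [b.start_bp - 1 for b in blocks],
            "end": [b.end_bp for b in blocks],
            "n_markers": [len(b.marker_ids) for b in blocks],
        }
    )
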