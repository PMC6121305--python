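"""Cross-population composite-likelihood sweep scan and signature calling.

The scan contrasts, at each grid point along a chromosome, two models for
the alternate-allele frequencies observed in an "objective" population
given the frequencies in a "reference" population:

* neutral drift — the objective frequency q of a SNP with reference
  frequency p is modelled as Normal(p, omega * p(1-p) + p(1-p)/n_obj),
  where omega is a genome-wide variance-inflation factor estimated from
  the data by the method of moments (it absorbs shared drift since the
  populations split) and the second term is binomial sampling noise;

* selective sweep at the grid point — a hitchhiking mixture: with escape
  probability c = 1 - exp(-d/w) (d the genetic distance of the SNP from
  the focal point, w a sweep-width parameter) the SNP recombined away and
  drifts neutrally; otherwise it was dragged to near-fixation of whichever
  allele rode the sweep, which was the alternate allele with probability p.

The per-SNP log-likelihood ratios are down-weighted for SNPs with many
high-LD neighbours in the window, summed over the window's SNPs (nearest
``max_snps_per_window`` within ``window_morgan``), maximised over a grid of
sweep widths and clipped at zero (the neutral model is nested at w -> 0).

Signature calling follows a segment/percentile recipe: per 10-kb segment
the maximum window score is recorded; runs of at least two adjacent
segments above the genome-wide 80th percentile form putative sweeps; sweeps
separated by at most one sub-threshold segment merge (taking the maximum
score); merged sweeps that become adjacent combine; and sweeps whose score
reaches the 90th percentile of all putative sweep scores are reported as
selection signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .association import QTLRegion


@dataclass
class XPCLRParams:
    window_morgan: float = 0.005
    max_snps_per_window: int = 100
    grid_size_bp: int = 100
    ld_cut: float = 0.7
    sweep_widths_morgan: tuple = (1e-4, 2e-4, 5e-4, 1e-3, 2e-3, 5e-3)
    min_omega: float = 1e-3
    fixation_extra_var: float = 1e-3


@dataclass
class SweepScoreTrack:
    scores: pd.DataFrame  # chrom, pos_bp, score, n_snps
    params: XPCLRParams

    def __post_init__(self) -> None:
        if (self.scores["score"] < 0).any() or not np.isfinite(
            self.scores["score"]
        ).all():
            raise ValueError("scores must be finite and non-negative")


@dataclass
class SegmentScores:
    segments: pd.DataFrame  # chrom, seg_index, start_bp, end_bp, x_max, defined
    segment_bp: int
    x80: float


@dataclass
class SelectionSignature:
    chrom: str
    start_bp: int
    end_bp: int
    score: float
    n_segments: int


def _shared_freqs(ref: GenotypeMatrix, obj: GenotypeMatrix) -> pd.DataFrame:
    """Alt-allele frequencies at markers shared by coordinate."""
    ka = {
        (r.chrom, r.pos_bp): j for j, r in enumerate(ref.markers.itertuples(index=False))
    }
    rows = []
    p_ref_all = ref.alt_freq()
    p_obj_all = obj.alt_freq()
    n_obj_obs = (~obj.missing_mask()).sum(axis=0) * 2
    for j, r in enumerate(obj.markers.itertuples(index=False)):
        key = (r.chrom, r.pos_bp)
        if key not in ka:
            continue
        i = ka[key]
        rows.append(
            (r.chrom, r.pos_bp, getattr(r, "pos_cm", np.nan), p_ref_all[i], p_obj_all[j], n_obj_obs[j], j)
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos_bp", "pos_cm", "p_ref", "p_obj", "n_obj", "obj_col"]
    )
    # need reference polymorphism for a defined drift variance
    df = df[(df["p_ref"] > 0) & (df["p_ref"] < 1) & (df["n_obj"] >= 2)]
    return df.reset_index(drop=True)


def _normal_logpdf(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


def xpclr_score(
    ref: GenotypeMatrix,
    obj: GenotypeMatrix,
    params: XPCLRParams | None = None,
) -> SweepScoreTrack:
    """Composite-likelihood sweep scores for the objective population.

    Genetic positions come from the markers' cM column; where absent a
    uniform 1 cM/Mb map is assumed.  Scores are >= 0 by construction.
    """
    params = params or XPCLRParams()
    snps = _shared_freqs(ref, obj)
    if len(snps) < 2:
        raise ValueError("fewer than 2 shared polymorphic SNPs")

    p = snps["p_ref"].to_numpy()
    q = snps["p_obj"].to_numpy()
    n_obj = snps["n_obj"].to_numpy(dtype=float)

    # genome-wide variance inflation (method of moments), sampling noise removed
    ratio = (q - p) ** 2 / (p * (1.0 - p))
    omega = float(max(np.mean(ratio) - np.mean(1.0 / n_obj), params.min_omega))

    var_neutral = omega * p * (1.0 - p) + p * (1.0 - p) / n_obj
    log_fn = _normal_logpdf(q, p, var_neutral)
    var_fix = p * (1.0 - p) / n_obj + params.fixation_extra_var
    f_fix = p * np.exp(_normal_logpdf(q, 1.0, var_fix)) + (1.0 - p) * np.exp(
        _normal_logpdf(q, 0.0, var_fix)
    )
    log_ff = np.log(np.clip(f_fix, 1e-300, None))
    log_r = log_ff - log_fn  # per-SNP fixation-vs-neutral log ratio

    widths = np.asarray(params.sweep_widths_morgan, dtype=float)
    half_window = params.window_morgan / 2.0

    frames = []
    obj_mk = obj.markers
    obj_dose = np.nan_to_num(obj.dosages(), nan=1.0)
    for chrom, grp in snps.groupby("chrom", sort=False):
        bp = grp["pos_bp"].to_numpy(dtype=float)
        cm = grp["pos_cm"].to_numpy(dtype=float)
        if np.isnan(cm).any():
            cm = bp / 1e6  # uniform 1 cM/Mb fallback
        morgan = cm / 100.0
        lr = log_r[grp.index.to_numpy()]

        # LD down-weighting: 1 / (1 + number of high-r2 partners in the window)
        cols = grp["obj_col"].to_numpy()
        sub = obj_dose[:, cols]
        sd = sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = np.corrcoef(sub, rowvar=False) ** 2
        cc = np.nan_to_num(np.atleast_2d(cc))
        near = np.abs(morgan[:, None] - morgan[None, :]) <= params.window_morgan
        high_ld = (cc > params.ld_cut) & near
        np.fill_diagonal(high_ld, False)
        weights = 1.0 / (1.0 + high_ld.sum(axis=1))
        weights[sd == 0] = 1.0

        chrom_end = int(obj_mk.loc[obj_mk["chrom"] == chrom, "pos_bp"].max())
        grid = np.arange(params.grid_size_bp, chrom_end + 1, params.grid_size_bp, dtype=float)
        grid_morgan = np.interp(grid, bp, morgan)

        scores = np.zeros(grid.size)
        n_used = np.zeros(grid.size, dtype=int)
        chunk = 512
        for a in range(0, grid.size, chunk):
            gm = grid_morgan[a : a + chunk]
            dmat = np.abs(gm[:, None] - morgan[None, :])
            in_win = dmat <= half_window
            # cap at the nearest max_snps_per_window SNPs
            counts = in_win.sum(axis=1)
            over = counts > params.max_snps_per_window
            if over.any():
                dmasked = np.where(in_win, dmat, np.inf)
                kth = np.partition(
                    dmasked[over], params.max_snps_per_window - 1, axis=1
                )[:, params.max_snps_per_window - 1]
                in_win[over] &= dmasked[over] <= kth[:, None]
            dmat = np.where(in_win, dmat, np.nan)
            best = np.full(gm.size, -np.inf)
            for w in widths:
                c = -np.expm1(-dmat / w)  # escape probability, in (0, 1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = np.logaddexp(
                        np.log(np.clip(c, 1e-300, None)),
                        np.log1p(-np.clip(c, None, 1.0 - 1e-15)) + lr[None, :],
                    )
                term = np.where(in_win, term * weights[None, :], 0.0)
                best = np.maximum(best, np.nansum(term, axis=1))
            scores[a : a + chunk] = np.clip(best, 0.0, None)
            n_used[a : a + chunk] = in_win.sum(axis=1)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos_bp": grid.astype(np.int64), "score": scores, "n_snps": n_used}
            )
        )
    track = pd.concat(frames, ignore_index=True)
    if (track["n_snps"] < 2).all():
        raise ValueError("fewer than 2 shared SNPs in every window")
    return SweepScoreTrack(scores=track, params=params)


def segment_scores(track: SweepScoreTrack, segment_bp: int = 10_000) -> SegmentScores:
    """Per-segment maxima of window scores and their genome-wide 80th percentile.

    A segment is "defined" when at least one grid point in it had a window
    containing >= 1 SNP; undefined segments are excluded from the
    percentile.
    """
    df = track.scores
    if df.empty:
        raise ValueError("empty score track")
    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        seg_idx = (grp["pos_bp"].to_numpy() - 1) // segment_bp
        n_seg = int(seg_idx.max()) + 1
        xmax = np.full(n_seg, np.nan)
        defined = np.zeros(n_seg, dtype=bool)
        valid = grp["n_snps"].to_numpy() >= 1
        for s in range(n_seg):
            in_seg = seg_idx == s
            ok = in_seg & valid
            if ok.any():
                defined[s] = True
                xmax[s] = grp["score"].to_numpy()[ok].max()
        for s in range(n_seg):
            rows.append(
                (chrom, s, s * segment_bp + 1, (s + 1) * segment_bp, xmax[s], defined[s])
            )
    segments = pd.DataFrame(
        rows, columns=["chrom", "seg_index", "start_bp", "end_bp", "x_max", "defined"]
    )
    vals = segments.loc[segments["defined"], "x_max"].to_numpy()
    if vals.size == 0:
        raise ValueError("no defined segments")
    x80 = float(np.percentile(vals, 80))
    return SegmentScores(segments=segments, segment_bp=segment_bp, x80=x80)


def call_signatures(segments: SegmentScores) -> list[SelectionSignature]:
    """Selection signatures from segment scores.

    Steps: (1) runs of >= 2 adjacent segments strictly above the 80th
    percentile form putative sweeps; (2) sweeps separated by at most one
    below-threshold segment merge, taking the maximum score; (3) merged
    sweeps that end up adjacent combine; (4) sweeps at or above the 90th
    percentile of all putative sweep scores are returned.
    """
    x80 = segments.x80
    sweeps: list[dict] = []
    for chrom, grp in segments.segments.groupby("chrom", sort=False):
        grp = grp.sort_values("seg_index")
        high = (grp["defined"] & (grp["x_max"] > x80)).to_numpy()
        idx = grp["seg_index"].to_numpy()
        xmax = grp["x_max"].to_numpy()
        # (1) runs of >= 2 high segments
        runs = []
        a = None
        for i, h in enumerate(high):
            if h and a is None:
                a = i
            elif not h and a is not None:
                if i - a >= 2:
                    runs.append((a, i - 1))
                a = None
        if a is not None and len(high) - a >= 2:
            runs.append((a, len(high) - 1))
        # (2) + (3): merge runs separated by <= 1 segment, repeatedly
        merged = []
        for run in runs:
            if merged and run[0] - merged[-1][1] - 1 <= 1:
                merged[-1] = (merged[-1][0], run[1])
            else:
                merged.append(list(run))
                merged[-1] = tuple(merged[-1])
        for a0, b0 in merged:
            span = xmax[a0 : b0 + 1]
            sweeps.append(
                {
                    "chrom": chrom,
                    "start_bp": int(idx[a0] * segments.segment_bp + 1),
                    "end_bp": int((idx[b0] + 1) * segments.segment_bp),
                    "score": float(np.nanmax(span)),
                    "n_segments": int(b0 - a0 + 1),
                }
            )
    if not sweeps:
        return []
    scores = np.array([s["score"] for s in sweeps])
    cut = float(np.percentile(scores, 90))
    sigs = [
        SelectionSignature(**s) for s in sweeps if s["score"] >= cut
    ]
    sigs.sort(key=lambda s: (s.chrom, s.start_bp))
    return sigs


def signatures_table(sigs: list[SelectionSignature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sigs],
            "start_bp": [s.start_bp for s in sigs],
            "end_bp": [s.end_bp for s in sigs],
            "score": [s.score for s in sigs],
            "n_segments": [s.n_segments for s in sigs],
        }
    )


def qtl_sweep_overlap(
    signatures: list[SelectionSignature],
    qtls: list[QTLRegion],
    flank_kb: float = 100.0,
) -> pd.DataFrame:
    """QTL-signature associations under closed-interval overlap with flanks.

    A QTL extended by ``flank_kb`` on both sides is associated with every
    signature whose interval it intersects (closed intervals; boundary
    touch counts).
    """
    flank = flank_kb * 1000.0
    rows = []
    for q in qtls:
        q_lo = q.start_bp - flank
        q_hi = q.end_bp + flank
        for k, s in enumerate(signatures):
            if s.chrom != q.chrom:
                continue
            if q_lo <= s.end_bp and s.start_bp <= q_hi:
                gap = max(s.start_bp - q.end_bp, q.start_bp - s.end_bp, 0)
                rows.append((q.qtl_id, q.trait, f"sig{k}", s.chrom, s.start_bp, s.end_bp, gap))
    return pd.DataFrame(
        rows,
        columns=["qtl_id", "trait", "signature_id", "chrom", "sig_start_bp", "sig_end_bp", "gap_bp"],
    )
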