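"""Genotype matrices: VCF I/O, marker filtering, imputation and population merging.

The central container is :class:`GenotypeMatrix`, lines x bi-allelic SNP
markers with calls coded as the count of the alternate allele (0/1/2) and
``-1`` for missing.  Marker metadata (chromosome, bp, optional cM, alleles)
lives in a pandas DataFrame aligned with the call columns.

Filtering follows the conventional thresholds for GBS-derived SNP sets in
inbred populations: markers with minor allele frequency below 0.05 or a
genotyping (call) rate below 60% are dropped; both boundaries are
inclusive-retain.  Missing calls are imputed with a deterministic
k-nearest-line modal rule, a stand-in appropriate for near-homozygous
bi-parental material where haplotype-phasing imputation adds little.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "pos_cm", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype calls with marker metadata.

    Parameters
    ----------
    line_ids : array of str
    population_labels : array of str, same length as line_ids
    markers : DataFrame with columns marker_id, chrom, pos_bp, pos_cm, ref, alt
    calls : int8 array, shape (n_lines, n_markers), values {0,1,2,-1}
    """

    line_ids: np.ndarray
    population_labels: np.ndarray
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.population_labels = np.asarray(self.population_labels, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.markers)} markers"
            )
        if len(self.population_labels) != len(self.line_ids):
            raise ValueError("population_labels length mismatch")
        ids = self.markers["marker_id"]
        if ids.duplicated().any():
            raise ValueError("duplicated marker ids")
        self.markers = self.markers.reset_index(drop=True)

    # -- derived per-marker statistics -------------------------------------

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def call_rate(self) -> np.ndarray:
        """Non-missing fraction per marker."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, missing calls excluded."""
        obs = ~self.missing_mask()
        dose = np.where(obs, self.calls, 0).astype(float)
        n_alleles = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = dose.sum(axis=0) / n_alleles
        return np.where(n_alleles > 0, p, np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def dosages(self) -> np.ndarray:
        """Float dosage matrix with missing as NaN."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        return x

    # -- subsetting --------------------------------------------------------

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.line_ids.copy(),
            self.population_labels.copy(),
            self.markers.iloc[idx].reset_index(drop=True),
            self.calls[:, idx].copy(),
        )

    def take_lines(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.line_ids[idx],
            self.population_labels[idx],
            self.markers.copy(),
            self.calls[idx].copy(),
        )

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.markers["marker_id"].to_numpy() == marker_id)
        if hits.size == 0:
            raise KeyError(f"marker {marker_id!r} not found")
        return int(hits[0])

    def marker_summary(self) -> pd.DataFrame:
        """Per-marker summary table (id, chrom, bp, maf, call_rate)."""
        return pd.DataFrame(
            {
                "marker_id": self.markers["marker_id"],
                "chrom": self.markers["chrom"],
                "pos_bp": self.markers["pos_bp"],
                "maf": self.maf(),
                "call_rate": self.call_rate(),
            }
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}
_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_BASES = {"A", "C", "G", "T"}


def read_vcf(path: str, population_labels=None) -> GenotypeMatrix:
    """Read bi-allelic SNP records from a VCF into a GenotypeMatrix.

    Multi-allelic and non-SNP records are skipped (counts logged).
    Coordinates are kept 1-based as in the VCF.  Missing genotypes ("./.")
    become the missing code.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    line_ids = np.array(vcf.samples, dtype=object)
    rows = []
    calls_cols = []
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        if var.REF not in _BASES or alts[0] not in _BASES:
            n_skipped += 1
            continue
        gt = var.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        calls_cols.append(gt)
        rows.append(
            (
                var.ID if var.ID else f"{var.CHROM}_{var.POS}",
                var.CHROM,
                int(var.POS),
                np.nan,
                var.REF,
                alts[0],
            )
        )
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    calls = (
        np.column_stack(calls_cols)
        if calls_cols
        else np.empty((len(line_ids), 0), dtype=np.int8)
    )
    if population_labels is None:
        population_labels = np.array(["pop0"] * len(line_ids), dtype=object)
    return GenotypeMatrix(line_ids, np.asarray(population_labels, dtype=object), markers, calls)


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write a minimal deterministic VCF 4.2 (GT only, './.' for missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in geno.line_ids)
            + "\n"
        )
        calls = geno.calls
        mk = geno.markers
        for j in range(geno.n_markers):
            gts = "\t".join(_GT_STR[int(c)] for c in calls[:, j])
            fh.write(
                f"{mk.at[j, 'chrom']}\t{mk.at[j, 'pos_bp']}\t{mk.at[j, 'marker_id']}\t"
                f"{mk.at[j, 'ref']}\t{mk.at[j, 'alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filtering / imputation / merging
# ---------------------------------------------------------------------------

def filter_markers(
    geno: GenotypeMatrix, maf_min: float = 0.05, call_rate_min: float = 0.60
) -> GenotypeMatrix:
    """Retain markers with MAF >= maf_min and call rate >= call_rate_min.

    Boundary convention is inclusive-retain: a marker at exactly the
    threshold survives (the removal rule is a strict "<").  Marker order is
    preserved.  Idempotent.
    """
    for name, thr in (("maf_min", maf_min), ("call_rate_min", call_rate_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    maf = geno.maf()
    cr = geno.call_rate()
    keep = np.flatnonzero((np.nan_to_num(maf) >= maf_min) & (cr >= call_rate_min))
    return geno.take_markers(keep)


def _pairwise_allele_sharing(calls: np.ndarray) -> np.ndarray:
    """Line x line allele-sharing similarity over jointly observed markers.

    s_ij = 1 - mean(|x_i - x_j|)/2 over markers non-missing in both lines.
    """
    obs = (calls != MISSING).astype(np.float64)
    x = np.where(calls == MISSING, 0, calls).astype(np.float64)
    # |xi - xj| decomposed over genotype classes via indicator matmuls
    ind = [(calls == c).astype(np.float64) for c in (0, 1, 2)]
    absdiff = np.zeros((calls.shape[0], calls.shape[0]))
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            absdiff += abs(a - b) * (ind[a] @ ind[b].T)
    shared = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - absdiff / (2.0 * shared)
    sim[shared == 0] = 0.0
    return sim


def impute_missing(geno: GenotypeMatrix, k_neighbors: int = 10) -> GenotypeMatrix:
    """Impute missing calls from the modal genotype of the k most similar lines.

    Similarity is allele sharing over jointly non-missing markers of the
    *same chromosome* as the missing call: in bi-parental material
    haplotype sharing is chromosome-scale (few crossovers per meiosis), so
    a line's nearest neighbours differ from chromosome to chromosome.
    Observed calls are never altered.  Ties in the modal vote break toward
    the genotype homozygous for the marker's major allele, then toward the
    lower genotype code, making the rule deterministic.
    """
    calls = geno.calls.copy()
    miss = calls == MISSING
    if not miss.any():
        return GenotypeMatrix(
            geno.line_ids.copy(), geno.population_labels.copy(), geno.markers.copy(), calls
        )
    if miss.all(axis=0).any():
        bad = np.flatnonzero(miss.all(axis=0))
        raise ValueError(f"{bad.size} markers missing in all lines (first index {bad[0]})")

    p = geno.alt_freq()
    major_hom = np.where(p > 0.5, 2, 0).astype(np.int8)  # p == 0.5 -> ref hom
    row_index = np.arange(geno.n_lines)[None, :].repeat(geno.n_lines, 0)

    for _, grp in geno.markers.groupby("chrom", sort=False):
        cols_chrom = grp.index.to_numpy()
        sub = calls[:, cols_chrom]
        sim = _pairwise_allele_sharing(sub)
        np.fill_diagonal(sim, -np.inf)
        # stable neighbour ranking: similarity desc, then line index asc
        order = np.lexsort((row_index, -sim), axis=1)
        for i in np.flatnonzero(miss[:, cols_chrom].any(axis=1)):
            neighbors = order[i]
            for j in cols_chrom[np.flatnonzero(miss[i, cols_chrom])]:
                votes = calls[neighbors, j]
                votes = votes[votes != MISSING][:k_neighbors]
                if votes.size == 0:
                    calls[i, j] = major_hom[j]
                    continue
                counts = np.bincount(votes, minlength=3)
                tied = np.flatnonzero(counts == counts.max())
                if tied.size == 1:
                    calls[i, j] = tied[0]
                elif major_hom[j] in tied:
                    calls[i, j] = major_hom[j]
                else:
                    calls[i, j] = tied[0]
    return GenotypeMatrix(
        geno.line_ids.copy(), geno.population_labels.copy(), geno.markers.copy(), calls
    )


def merge_populations(genos: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge populations on the union of markers (keyed by chrom, bp).

    Calls at markers absent from a population become missing.  Population
    labels are preserved; per-marker statistics are implicitly recomputed on
    the merged set.  Conflicting ref/alt alleles at the same coordinate are
    an error.
    """
    if not genos:
        raise ValueError("nothing to merge")
    key_info: dict[tuple, tuple] = {}
    for g in genos:
        for row in g.markers.itertuples(index=False):
            key = (row.chrom, row.pos_bp)
            info = (row.marker_id, row.ref, row.alt, row.pos_cm)
            if key in key_info:
                if (key_info[key][1], key_info[key][2]) != (row.ref, row.alt):
                    raise ValueError(f"conflicting ref/alt at {key}")
            else:
                key_info[key] = info
    keys = sorted(key_info, key=lambda k: (str(k[0]), k[1]))
    markers = pd.DataFrame(
        [
            (key_info[k][0], k[0], k[1], key_info[k][3], key_info[k][1], key_info[k][2])
            for k in keys
        ],
        columns=MARKER_COLUMNS,
    )
    col_of = {k: j for j, k in enumerate(keys)}
    # union of lines keyed by line_id (first occurrence wins on conflicts),
    # which makes the merge idempotent
    row_of: dict = {}
    line_ids: list = []
    labels: list = []
    for g in genos:
        for lid, lab in zip(g.line_ids, g.population_labels):
            if lid not in row_of:
                row_of[lid] = len(line_ids)
                line_ids.append(lid)
                labels.append(lab)
    calls = np.full((len(line_ids), len(keys)), MISSING, dtype=np.int8)
    for g in genos:
        cols = np.array(
            [col_of[(r.chrom, r.pos_bp)] for r in g.markers.itertuples(index=False)], dtype=int
        )
        rows = np.array([row_of[lid] for lid in g.line_ids], dtype=int)
        block = calls[np.ix_(rows, cols)]
        incoming = g.calls
        fill = block == MISSING
        block[fill] = incoming[fill]
        calls[np.ix_(rows, cols)] = block
    return GenotypeMatrix(
        np.array(line_ids, dtype=object), np.array(labels, dtype=object), markers, calls
    )
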