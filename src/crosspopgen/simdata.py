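"""Forward simulation of bi-parental populations, phenotypes and divergent pairs.

Everything downstream of this module (filtering, LD, structure, GWAS,
heritability, sweep scanning) is exercised on data produced here, so the
simulator reproduces the statistical structure those analyses assume:

* meiosis under the Haldane (no-interference) map function — crossovers form
  a Poisson process on the cM scale, so the recombination fraction between
  markers separated by ``d`` cM is ``(1 - exp(-2d/100)) / 2``;
* F6 recombinant inbred lines by single seed descent (five selfing
  generations after the F1, residual heterozygosity ~(1/2)^5) and
  F1-derived doubled haploids (one meiosis, fully homozygous);
* additive multi-environment phenotypes with planted QTL, an infinitesimal
  polygenic background carried by genome-wide marker effects, and a residual
  variance calibrated empirically to a target broad-sense heritability of
  line means;
* divergently selected population pairs in which one population is
  truncation-selected toward one allele at a chosen locus, dragging linked
  variation along with it — the raw material of a selective-sweep scan.

The default genome is 15 chromosomes of 20 Mb at 1 cM/Mb, a desk-scale echo
of the flax karyotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MARKER_COLUMNS, MISSING, GenotypeMatrix, write_vcf

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Ordered marker map: marker_id, chrom, pos_bp (1-based), pos_cm."""

    markers: pd.DataFrame  # columns marker_id, chrom, pos_bp, pos_cm

    def __post_init__(self) -> None:
        m = self.markers.reset_index(drop=True)
        if len(m) == 0:
            raise ValueError("empty genetic map")
        if m["marker_id"].duplicated().any():
            raise ValueError("duplicated marker ids in map")
        for _, grp in m.groupby("chrom", sort=False):
            bp = grp["pos_bp"].to_numpy()
            cm = grp["pos_cm"].to_numpy()
            if not (np.diff(bp) > 0).all():
                raise ValueError("bp positions must be strictly increasing per chromosome")
            if not (np.diff(cm) >= 0).all():
                raise ValueError("cM positions must be non-decreasing per chromosome")
            if (bp < 0).any() or (cm < 0).any():
                raise ValueError("positions must be non-negative")
        self.markers = m

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_slices(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            out.append((chrom, grp.index.to_numpy()))
        return out


@dataclass
class CrossDesign:
    """One bi-parental cross: population type, size, parental haplotypes."""

    population_type: str  # "RIL_F6" or "DH"
    n_lines: int
    parent_a: np.ndarray  # allele vector over the map, values {0,1}
    parent_b: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.population_type not in ("RIL_F6", "DH"):
            raise ValueError(f"unknown population_type {self.population_type!r}")
        if self.n_lines <= 0:
            raise ValueError("n_lines must be positive")
        self.parent_a = np.asarray(self.parent_a, dtype=np.int8)
        self.parent_b = np.asarray(self.parent_b, dtype=np.int8)
        if self.parent_a.shape != self.parent_b.shape:
            raise ValueError("parent haplotypes differ in length")


@dataclass
class TraitModel:
    """Additive genetic architecture of one simulated trait."""

    qtl: list[tuple[str, float]]  # (marker_id, additive effect in trait units)
    target_h2: float | None = None  # broad-sense h2 of line means; None = use residual_sd
    n_environments: int = 6
    env_effects: np.ndarray | None = None
    residual_sd: float = 1.0
    polygenic_sd: float = 0.0
    mean: float = 0.0
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.target_h2 is not None and not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must lie in [0, 1]")
        if self.n_environments < 1:
            raise ValueError("n_environments must be >= 1")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.target_h2 == 1.0:
            raise ValueError("target_h2 = 1 contradicts a positive residual_sd")
        if self.env_effects is None:
            self.env_effects = np.zeros(self.n_environments)
        self.env_effects = np.asarray(self.env_effects, dtype=float)
        if len(self.env_effects) != self.n_environments:
            raise ValueError("env_effects length must equal n_environments")


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: line_id, trait, environment, value."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"line_id", "trait", "environment", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")

    def traits(self) -> list[str]:
        return list(pd.unique(self.data["trait"]))

    def line_means(self, trait: str) -> pd.Series:
        sub = self.data[self.data["trait"] == trait]
        return sub.groupby("line_id", sort=False)["value"].mean()


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------


def uniform_map(
    n_chromosomes: int = 15,
    chrom_length_bp: int = 20_000_000,
    n_markers_per_chrom: int = 1000,
    cm_per_mb: float = 1.0,
    rng: np.random.Generator | None = None,
) -> GeneticMap:
    """Uniform-recombination map: markers at random (or even) bp positions.

    With ``rng`` given, marker positions are drawn uniformly per chromosome;
    otherwise they are evenly spaced.  cM positions follow bp linearly at
    ``cm_per_mb``.
    """
    rows = []
    for c in range(1, n_chromosomes + 1):
        if rng is None:
            bp = np.linspace(1, chrom_length_bp, n_markers_per_chrom).astype(np.int64)
        else:
            bp = np.sort(
                rng.choice(np.arange(1, chrom_length_bp + 1), size=n_markers_per_chrom, replace=False)
            )
        cm = bp / 1e6 * cm_per_mb
        for j, (b, m) in enumerate(zip(bp, cm)):
            rows.append((f"chr{c}_{b}", f"chr{c}", int(b), float(m)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "pos_cm"]))


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def _recomb_fractions(gmap: GeneticMap) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (marker indices, recombination fraction between neighbours)."""
    out = []
    for _, idx in gmap.chrom_slices():
        cm = gmap.markers["pos_cm"].to_numpy()[idx]
        d = np.diff(cm)
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))  # Haldane
        out.append((idx, r))
    return out


def _gametes(h0: np.ndarray, h1: np.ndarray, chrom_info, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from haplotype pair (h0, h1), vectorised.

    Crossovers between adjacent markers occur independently with the
    Haldane recombination fraction of the interval (no interference).
    """
    n, m = h0.shape
    out = np.empty((n, m), dtype=h0.dtype)
    for idx, r in chrom_info:
        start = rng.integers(0, 2, size=n)
        if len(idx) > 1:
            switches = rng.random((n, len(idx) - 1)) < r
            phase = (start[:, None] + np.concatenate(
                [np.zeros((n, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
            )) % 2
        else:
            phase = start[:, None]
        sub0 = h0[:, idx]
        sub1 = h1[:, idx]
        out[:, idx] = np.where(phase == 0, sub0, sub1)
    return out


def simulate_biparental_cross(gmap: GeneticMap, design: CrossDesign) -> GenotypeMatrix:
    """Simulate an F6 RIL or F1-derived DH population from two parents.

    RIL_F6: five generations of selfing (single seed descent) after the F1;
    residual heterozygosity is retained, not forced to zero.  DH: a single
    meiosis of the F1 followed by chromosome doubling, fully homozygous.
    Genotypes are coded as the count of the parent-B allele where the
    parents differ (via ref/alt assignment below: ref = parent A's allele,
    alt = parent B's allele at segregating markers).
    """
    if design.parent_a.shape[0] != gmap.n_markers:
        raise ValueError("parent haplotype length does not match map")
    if (design.parent_a == design.parent_b).all():
        # degenerate but legal: no polymorphism, all lines identical to parents
        pass
    rng = np.random.default_rng(design.seed)
    chrom_info = _recomb_fractions(gmap)
    n = design.n_lines
    pa = np.broadcast_to(design.parent_a, (n, gmap.n_markers)).copy()
    pb = np.broadcast_to(design.parent_b, (n, gmap.n_markers)).copy()

    if design.population_type == "DH":
        g = _gametes(pa, pb, chrom_info, rng)
        h0, h1 = g, g.copy()
    else:  # RIL_F6
        h0, h1 = pa, pb  # F1
        for _ in range(5):  # F1 -> F2 -> ... -> F6
            g0 = _gametes(h0, h1, chrom_info, rng)
            g1 = _gametes(h0, h1, chrom_info, rng)
            h0, h1 = g0, g1

    calls = (h0 + h1).astype(np.int8)  # counts the allele coded 1
    markers = gmap.markers.copy()
    # alleles: code-0 allele = A, code-1 allele = T (placeholder bases)
    markers["ref"] = "A"
    markers["alt"] = "T"
    markers = markers[["marker_id", "chrom", "pos_bp", "pos_cm", "ref", "alt"]]
    line_ids = np.array([f"L{design.seed}_{i:04d}" for i in range(n)], dtype=object)
    labels = np.array([f"pop{design.seed}"] * n, dtype=object)
    return GenotypeMatrix(line_ids, labels, markers, calls)


def sprinkle_missing(geno: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Mask a random fraction of calls as missing (emulates GBS dropouts)."""
    rng = np.random.default_rng(seed)
    calls = geno.calls.copy()
    mask = rng.random(calls.shape) < rate
    calls[mask] = MISSING
    return GenotypeMatrix(
        geno.line_ids.copy(), geno.population_labels.copy(), geno.markers.copy(), calls
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    geno: GenotypeMatrix, model: TraitModel, seed: int = 0
) -> PhenotypeTable:
    """Simulate multi-environment phenotypes with planted QTL.

    y_ie = mu + env_e + sum_q a_q (x_iq - 1) + polygenic_i + eps_ie.

    The polygenic term is built from genome-wide random marker effects
    (infinitesimal model) scaled to ``polygenic_sd``, so a SNP-derived
    relationship matrix can recover it.  When ``target_h2`` is set, the
    residual SD is rescaled so the broad-sense heritability of line means,
    var(G) / (var(G) + sigma_e^2 / n_env), hits the target empirically.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_lines
    x = geno.dosages()
    x = np.nan_to_num(x, nan=1.0)  # missing treated as heterozygote dosage

    g = np.zeros(n)
    for marker_id, effect in model.qtl:
        j = geno.marker_index(marker_id)
        g += effect * (x[:, j] - 1.0)
    if model.polygenic_sd > 0:
        centered = x - x.mean(axis=0)
        beta = rng.normal(size=geno.n_markers)
        poly = centered @ beta
        sd = poly.std()
        if sd > 0:
            poly *= model.polygenic_sd / sd
        g += poly

    sigma_e = model.residual_sd
    if model.target_h2 is not None:
        var_g = g.var()
        if model.target_h2 == 0.0:
            g = np.zeros(n)
        elif var_g == 0.0:
            raise ValueError("target_h2 > 0 but the genetic variance is zero")
        else:
            # var(G)/(var(G) + se^2/E) = h2  =>  se^2 = E var(G) (1-h2)/h2
            sigma_e = float(
                np.sqrt(model.n_environments * var_g * (1.0 - model.target_h2) / model.target_h2)
            )

    rows = []
    for e in range(model.n_environments):
        eps = rng.normal(0.0, sigma_e, size=n)
        y = model.mean + model.env_effects[e] + g + eps
        for lid, val in zip(geno.line_ids, y):
            rows.append((lid, model.trait, f"env{e + 1}", val))
    return PhenotypeTable(pd.DataFrame(rows, columns=["line_id", "trait", "environment", "value"]))


def true_genetic_values(geno: GenotypeMatrix, model: TraitModel) -> np.ndarray:
    """QTL-only genetic values (no polygenic or residual term); test helper."""
    x = np.nan_to_num(geno.dosages(), nan=1.0)
    g = np.zeros(geno.n_lines)
    for marker_id, effect in model.qtl:
        g += effect * (x[:, geno.marker_index(marker_id)] - 1.0)
    return g


# ---------------------------------------------------------------------------
# Divergent selection
# ---------------------------------------------------------------------------


def simulate_divergent_pair(
    gmap: GeneticMap,
    design_a: CrossDesign,
    design_b: CrossDesign,
    selected_locus: str,
    selection_intensity: float,
    n_generations: int = 10,
    n_selfing_after: int = 3,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Simulate a neutral population and a selected sister population.

    Population A follows its cross design unselected.  Population B starts
    from the F1 of its own parents and is bred as an intermating population
    under truncation-style selection: each generation every offspring draws
    two distinct parents with probability proportional to
    ``(1 - s) + s * dosage/2`` of the favoured (code-1) allele at
    ``selected_locus``.  Random intermating supplies the recombination that
    localises the hitchhiking footprint around the selected locus; a few
    final selfing generations (``n_selfing_after``) restore the
    near-homozygous structure of inbred material.  ``s = 0`` reduces to
    drift; ``s = 1`` drives the favoured allele to fixation given enough
    generations.
    """
    if not 0.0 <= selection_intensity <= 1.0:
        raise ValueError("selection_intensity must be in [0, 1]")
    ids = gmap.markers["marker_id"].to_numpy()
    hits = np.flatnonzero(ids == selected_locus)
    if hits.size == 0:
        raise ValueError(f"selected locus {selected_locus!r} not on map")
    locus = int(hits[0])

    pop_a = simulate_biparental_cross(gmap, design_a)

    rng = np.random.default_rng(design_b.seed)
    chrom_info = _recomb_fractions(gmap)
    n = design_b.n_lines
    h0 = np.broadcast_to(design_b.parent_a, (n, gmap.n_markers)).copy()
    h1 = np.broadcast_to(design_b.parent_b, (n, gmap.n_markers)).copy()
    s = selection_intensity
    for _ in range(n_generations):
        dosage = (h0[:, locus] + h1[:, locus]).astype(float)
        w = (1.0 - s) + s * dosage / 2.0
        total = w.sum()
        probs = np.full(n, 1.0 / n) if total <= 0 else w / total
        p1 = rng.choice(n, size=n, p=probs)
        p2 = rng.choice(n, size=n, p=probs)
        clash = p1 == p2
        while clash.any() and n > 1:
            p2[clash] = rng.choice(n, size=int(clash.sum()), p=probs)
            clash = p1 == p2
        g0 = _gametes(h0[p1], h1[p1], chrom_info, rng)
        g1 = _gametes(h0[p2], h1[p2], chrom_info, rng)
        h0, h1 = g0, g1
    for _ in range(n_selfing_after):
        g0 = _gametes(h0, h1, chrom_info, rng)
        g1 = _gametes(h0, h1, chrom_info, rng)
        h0, h1 = g0, g1

    calls = (h0 + h1).astype(np.int8)
    markers = gmap.markers.copy()
    markers["ref"] = "A"
    markers["alt"] = "T"
    markers = markers[["marker_id", "chrom", "pos_bp", "pos_cm", "ref", "alt"]]
    line_ids = np.array([f"S{design_b.seed}_{i:04d}" for i in range(n)], dtype=object)
    labels = np.array([f"sel{design_b.seed}"] * n, dtype=object)
    pop_b = GenotypeMatrix(line_ids, labels, markers, calls)
    return pop_a, pop_b


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------


def write_dataset(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable | None,
    gmap: GeneticMap,
    out_dir: str,
    manifest_extra: dict | None = None,
) -> dict:
    """Write VCF genotypes, TSV phenotypes/map and a JSON manifest.

    Output is deterministic byte-for-byte for identical inputs.  Returns the
    written file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(out / "genotypes.vcf"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "map": str(out / "map.tsv"),
        "populations": str(out / "populations.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    write_vcf(geno, paths["vcf"])
    if pheno is not None:
        pheno.data.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.10g")
    else:
        paths.pop("phenotypes")
    gmap.markers.to_csv(paths["map"], sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(
        {"line_id": geno.line_ids, "population": geno.population_labels}
    ).to_csv(paths["populations"], sep="\t", index=False)
    manifest = {
        "n_lines": int(geno.n_lines),
        "n_markers": int(geno.n_markers),
        "files": {k: Path(v).name for k, v in paths.items() if k != "manifest"},
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_map(path: str) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    return GeneticMap(df[["marker_id", "chrom", "pos_bp", "pos_cm"]])


def read_phenotypes(path: str) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))
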