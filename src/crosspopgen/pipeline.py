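"""End-to-end orchestration: simulate/read -> QC -> LD -> structure -> BLUP ->
GWAS -> heritability -> sweep scan -> validation, with per-stage outputs.

Every stage writes plain TSV/VCF/JSON artifacts under its own subdirectory
of ``out_dir``; the run manifest records the seed and a hash of the
configuration, making a run reproducible byte for byte.  Stages can be
resumed: earlier artifacts are reloaded from disk instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, genotypes, mixedmodel, popgen, structure, sweep, validation
from .simdata import (
    CrossDesign,
    GeneticMap,
    PhenotypeTable,
    TraitModel,
    read_map,
    read_phenotypes,
    simulate_biparental_cross,
    simulate_divergent_pair,
    simulate_phenotypes,
    sprinkle_missing,
    uniform_map,
    write_dataset,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "ld", "structure", "blup", "gwas", "herit", "sweep", "validate"]


@dataclass
class TraitConfig:
    name: str
    n_qtl: int
    h2: float
    qtl_effect: float = 1.0


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults give the desk-scale synthetic study."""

    # simulation block (used when no input paths are given)
    n_chromosomes: int = 15
    chrom_length_bp: int = 20_000_000
    markers_per_chrom: int = 1000
    cm_per_mb: float = 1.0
    population_sizes: tuple = (97, 91, 72)
    population_types: tuple = ("RIL_F6", "RIL_F6", "DH")
    missing_rate: float = 0.03
    selection_intensity: float = 0.8
    traits: tuple = (
        TraitConfig("oil", n_qtl=3, h2=0.7),
        TraitConfig("yield", n_qtl=1, h2=0.3),
        TraitConfig("height", n_qtl=2, h2=0.5),
    )
    n_environments: int = 6
    # optional real inputs (override simulation)
    vcf_path: str | None = None
    phenotype_path: str | None = None
    map_path: str | None = None
    populations_path: str | None = None
    # filtering
    maf_min: float = 0.05
    call_rate_min: float = 0.60
    impute_k: int = 10
    # LD
    ld_window_kb: float = 2000.0
    prune_window_kb: float = 2000.0
    prune_step_snps: int = 50
    prune_r2_max: float = 0.9
    block_max_kb: float = 2000.0
    # structure
    n_pcs: int = 100
    k_max: int = 10
    # GWAS
    alpha: float = 0.05
    merge_distance_kb: float = 1000.0
    models: tuple = ("GLM", "MLM")
    qtl_h2_flank_kb: float = 500.0
    # sweep
    sweep_window_morgan: float = 0.005
    sweep_max_snps: int = 100
    sweep_grid_bp: int = 5000
    sweep_ld_cut: float = 0.7
    segment_bp: int = 10_000
    overlap_flank_kb: float = 100.0

    def validate(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        for name in ("maf_min", "call_rate_min", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.prune_r2_max <= 1.0:
            raise ValueError("prune_r2_max must lie in (0, 1]")
        if self.sweep_grid_bp <= 0 or self.segment_bp <= 0:
            raise ValueError("grid/segment sizes must be positive")
        for p in (self.vcf_path, self.phenotype_path, self.map_path, self.populations_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        traits = raw.pop("traits", None)
        cfg = cls(**raw)
        if traits is not None:
            cfg = cls(**{**raw, "traits": tuple(TraitConfig(**t) for t in traits)})
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Stage: simulate (or load real inputs)
# ---------------------------------------------------------------------------


def _simulate_dataset(cfg: PipelineConfig, seed: int):
    rng = np.random.default_rng(seed)
    gmap = uniform_map(
        cfg.n_chromosomes, cfg.chrom_length_bp, cfg.markers_per_chrom, cfg.cm_per_mb, rng=rng
    )
    m = gmap.n_markers
    anc = rng.uniform(0.1, 0.9, size=m)  # ancestral allele frequencies

    def parents():
        return rng.random(m) < anc, rng.random(m) < anc

    pa1, pb1 = parents()
    pa2, pb2 = parents()
    pa3, pb3 = parents()
    d1 = CrossDesign(cfg.population_types[0], cfg.population_sizes[0], pa1, pb1,
                     seed=int(rng.integers(2**31)))
    d2 = CrossDesign(cfg.population_types[1], cfg.population_sizes[1], pa2, pb2,
                     seed=int(rng.integers(2**31)))
    d3 = CrossDesign(cfg.population_types[2], cfg.population_sizes[2], pa3, pb3,
                     seed=int(rng.integers(2**31)))

    # selected locus: mid-chromosome marker segregating in population 2
    seg2 = np.flatnonzero(pa2 != pb2)
    mid = gmap.markers.iloc[seg2]
    chrom1 = mid[mid["chrom"] == mid["chrom"].iloc[0]]
    locus = chrom1.iloc[len(chrom1) // 2]["marker_id"]
    pop1, pop2 = simulate_divergent_pair(
        gmap, d1, d2, selected_locus=locus, selection_intensity=cfg.selection_intensity
    )
    pop3 = simulate_biparental_cross(gmap, d3)
    # distinct population labels
    pop1.population_labels[:] = "popA"
    pop2.population_labels[:] = "popB"
    pop3.population_labels[:] = "popC"
    pop1.line_ids = np.array([f"A{i:04d}" for i in range(pop1.n_lines)], dtype=object)
    pop2.line_ids = np.array([f"B{i:04d}" for i in range(pop2.n_lines)], dtype=object)
    pop3.line_ids = np.array([f"C{i:04d}" for i in range(pop3.n_lines)], dtype=object)

    merged = genotypes.merge_populations([pop1, pop2, pop3])

    # phenotypes on complete merged genotypes; QTL drawn from markers that
    # segregate within every population so the signal is not purely
    # between-population (which the Q covariates would absorb)
    per_pop_maf = []
    for lab in pd.unique(merged.population_labels):
        sub = merged.take_lines(np.flatnonzero(merged.population_labels == lab))
        per_pop_maf.append(np.nan_to_num(sub.maf()))
    common = np.minimum.reduce(per_pop_maf)
    frames = []
    qtl_truth = {}
    for tc in cfg.traits:
        candidates = np.flatnonzero(common >= 0.15)
        if candidates.size < tc.n_qtl:
            candidates = np.flatnonzero(np.nan_to_num(merged.maf()) >= 0.2)
        chosen = rng.choice(candidates, size=tc.n_qtl, replace=False)
        qtl = [(merged.markers["marker_id"].iloc[int(j)], tc.qtl_effect) for j in chosen]
        model = TraitModel(
            qtl=qtl, target_h2=tc.h2, n_environments=cfg.n_environments,
            env_effects=rng.normal(0.0, 0.5, size=cfg.n_environments),
            polygenic_sd=0.5 * tc.qtl_effect, trait=tc.name,
        )
        frames.append(simulate_phenotypes(merged, model, seed=int(rng.integers(2**31))).data)
        qtl_truth[tc.name] = [mid for mid, _ in qtl]
    pheno = PhenotypeTable(pd.concat(frames, ignore_index=True))

    merged = sprinkle_missing(merged, cfg.missing_rate, seed=int(rng.integers(2**31)))
    return gmap, merged, pheno, {"selected_locus": str(locus), "qtl_truth": qtl_truth}


def _stage_simulate(cfg: PipelineConfig, seed: int, out: Path):
    if cfg.vcf_path:
        labels = None
        if cfg.populations_path:
            ptab = pd.read_csv(cfg.populations_path, sep="\t")
            labels = ptab["population"].to_numpy(dtype=object)
        geno = genotypes.read_vcf(cfg.vcf_path, population_labels=labels)
        gmap = read_map(cfg.map_path) if cfg.map_path else None
        pheno = read_phenotypes(cfg.phenotype_path) if cfg.phenotype_path else None
        truth = {}
        if gmap is not None:
            cm = dict(zip(gmap.markers["marker_id"], gmap.markers["pos_cm"]))
            geno.markers["pos_cm"] = [cm.get(m, np.nan) for m in geno.markers["marker_id"]]
    else:
        gmap, geno, pheno, truth = _simulate_dataset(cfg, seed)
    ddir = out / "genotypes"
    if gmap is not None:
        write_dataset(geno, pheno, gmap, str(ddir), manifest_extra={"seed": seed, **truth})
    return {"gmap": gmap, "geno_raw": geno, "pheno": pheno, "truth": truth}


def _load_simulate(cfg: PipelineConfig, out: Path):
    ddir = out / "genotypes"
    ptab = pd.read_csv(ddir / "populations.tsv", sep="\t")
    geno = genotypes.read_vcf(str(ddir / "genotypes.vcf"),
                              population_labels=ptab["population"].to_numpy(dtype=object))
    gmap = read_map(str(ddir / "map.tsv"))
    cm = dict(zip(gmap.markers["marker_id"], gmap.markers["pos_cm"]))
    geno.markers["pos_cm"] = [cm.get(m, np.nan) for m in geno.markers["marker_id"]]
    pheno_path = ddir / "phenotypes.tsv"
    pheno = read_phenotypes(str(pheno_path)) if pheno_path.exists() else None
    with open(ddir / "manifest.json") as fh:
        truth = json.load(fh)
    return {"gmap": gmap, "geno_raw": geno, "pheno": pheno, "truth": truth}


# ---------------------------------------------------------------------------
# Remaining stages
# ---------------------------------------------------------------------------


def _stage_filter(cfg: PipelineConfig, state: dict, out: Path):
    geno = genotypes.filter_markers(state["geno_raw"], cfg.maf_min, cfg.call_rate_min)
    geno = genotypes.impute_missing(geno, cfg.impute_k)
    genotypes.write_vcf(geno, str(out / "genotypes" / "filtered_imputed.vcf"))
    _tsv(geno.marker_summary(), out / "genotypes" / "marker_summary.tsv")
    state["geno"] = geno
    return state


def _load_filter(cfg: PipelineConfig, state: dict, out: Path):
    raw = state["geno_raw"]
    geno = genotypes.read_vcf(str(out / "genotypes" / "filtered_imputed.vcf"))
    # restore population labels and cM from the raw dataset
    lab = dict(zip(raw.line_ids, raw.population_labels))
    geno.population_labels = np.array([lab[l] for l in geno.line_ids], dtype=object)
    cm = dict(zip(raw.markers["marker_id"], raw.markers["pos_cm"]))
    geno.markers["pos_cm"] = [cm.get(m, np.nan) for m in geno.markers["marker_id"]]
    state["geno"] = geno
    return state


def _stage_ld(cfg: PipelineConfig, state: dict, out: Path):
    geno = state["geno"]
    pruned = popgen.prune_ld(geno, cfg.prune_window_kb, cfg.prune_step_snps, cfg.prune_r2_max)
    pairs = popgen.pairwise_r2(pruned, cfg.ld_window_kb)
    fit = popgen.fit_ld_decay(pairs, n_gametes=2 * geno.n_lines)
    blocks = popgen.haplotype_blocks(geno, cfg.block_max_kb)
    ldir = out / "ld"
    _tsv(pairs, ldir / "ld_pairs.tsv")
    _tsv(fit.summary(), ldir / "ld_decay.tsv")
    _tsv(popgen.blocks_to_bed(blocks), ldir / "haplotype_blocks.bed.tsv")
    _tsv(pruned.markers[["marker_id"]], ldir / "pruned_markers.tsv")
    # per-population diversity and pairwise Fst
    pops = list(pd.unique(geno.population_labels))
    rows = []
    for p in pops:
        sub = geno.take_lines(np.flatnonzero(geno.population_labels == p))
        d = popgen.nucleotide_diversity(sub)
        rows.append((p, d.pi_per_site, d.pi_total, d.n_variant_sites))
    _tsv(pd.DataFrame(rows, columns=["population", "pi_per_site", "pi_total", "n_variant_sites"]),
         ldir / "diversity.tsv")
    fst_rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a = geno.take_lines(np.flatnonzero(geno.population_labels == pops[i]))
            b = geno.take_lines(np.flatnonzero(geno.population_labels == pops[j]))
            fst_rows.append((pops[i], pops[j], popgen.fst(a, b)))
    _tsv(pd.DataFrame(fst_rows, columns=["pop_a", "pop_b", "fst"]), ldir / "fst.tsv")
    state["ld_fit"] = fit
    return state


def _stage_structure(cfg: PipelineConfig, state: dict, out: Path, seed: int):
    geno = state["geno"]
    res = structure.dapc(geno, n_pcs=cfg.n_pcs, k_max=cfg.k_max, seed=seed)
    g = structure.grm(geno)
    sdir = out / "structure"
    _tsv(pd.DataFrame(res.pc_scores[:, :10],
                      columns=[f"PC{i+1}" for i in range(min(10, res.pc_scores.shape[1]))])
         .assign(line_id=geno.line_ids), sdir / "pc_scores.tsv")
    _tsv(res.bic_curve, sdir / "bic_curve.tsv")
    q = pd.DataFrame(res.q_matrix, columns=[f"Q{i+1}" for i in range(res.q_matrix.shape[1])])
    q.insert(0, "line_id", geno.line_ids)
    _tsv(q, sdir / "q_matrix.tsv")
    _tsv(pd.DataFrame(g.matrix), sdir / "grm.tsv")
    state["structure"] = res
    state["grm"] = g
    return state


def _load_structure(cfg: PipelineConfig, state: dict, out: Path):
    sdir = out / "structure"
    q = pd.read_csv(sdir / "q_matrix.tsv", sep="\t")
    qm = q.drop(columns=["line_id"]).to_numpy(dtype=float)
    labels = qm.argmax(axis=1)
    bic = pd.read_csv(sdir / "bic_curve.tsv", sep="\t")
    state["structure"] = structure.StructureResult(
        pc_scores=np.zeros((qm.shape[0], 1)), variance_explained=np.array([1.0]),
        retained_pcs=1, bic_curve=bic, best_k=qm.shape[1], cluster_labels=labels, q_matrix=qm,
    )
    gmat = pd.read_csv(sdir / "grm.tsv", sep="\t").to_numpy(dtype=float)
    state["grm"] = structure.GRM(matrix=gmat, method="vanraden")
    return state


def _stage_blup(cfg: PipelineConfig, state: dict, out: Path):
    pheno = state["pheno"]
    if pheno is None:
        raise RuntimeError("no phenotypes available for the blup stage")
    table = mixedmodel.blup_line_effects(pheno)
    bdir = out / "herit"
    _tsv(table.blups.reset_index(names="line_id"), bdir / "blups.tsv")
    state["blups"] = table
    return state


def _load_blup(cfg: PipelineConfig, state: dict, out: Path):
    df = pd.read_csv(out / "herit" / "blups.tsv", sep="\t").set_index("line_id")
    state["blups"] = mixedmodel.BlupTable(blups=df, components={})
    return state


def _stage_gwas(cfg: PipelineConfig, state: dict, out: Path):
    geno = state["geno"]
    q = state["structure"].q_matrix
    kin = state["grm"]
    blups = state["blups"].blups
    thr = association.bonferroni_threshold(geno.n_markers, cfg.alpha)
    gdir = out / "gwas"
    all_qtl: dict[str, list] = {}
    for trait in blups.columns:
        y = blups.loc[list(geno.line_ids), trait].to_numpy(dtype=float)
        scans = {}
        if "GLM" in cfg.models:
            scans["GLM"] = association.glm_scan(y, geno, q)
        if "MLM" in cfg.models:
            scans["MLM"] = association.mlm_scan(y, geno, q, kin)
        regions = []
        for tag, res in scans.items():
            res.threshold = thr
            _tsv(res.table, gdir / f"assoc_{trait}_{tag.lower()}.tsv")
            regions.extend(association.call_qtl(res, thr, cfg.merge_distance_kb, trait=trait))
        # de-duplicate overlapping GLM/MLM regions per trait
        regions.sort(key=lambda r: (r.chrom, r.start_bp))
        uniq: list = []
        for r in regions:
            if uniq and r.chrom == uniq[-1].chrom and r.start_bp <= uniq[-1].end_bp:
                keep = r if r.peak_p < uniq[-1].peak_p else uniq[-1]
                keep.start_bp = min(r.start_bp, uniq[-1].start_bp)
                keep.end_bp = max(r.end_bp, uniq[-1].end_bp)
                keep.member_markers = sorted(set(uniq[-1].member_markers) | set(r.member_markers))
                uniq[-1] = keep
            else:
                uniq.append(r)
        all_qtl[trait] = uniq
        _tsv(association.qtl_table(uniq), gdir / f"qtl_{trait}.tsv")
    qtab = pd.concat(
        [association.qtl_table(v) for v in all_qtl.values()], ignore_index=True
    ) if all_qtl else pd.DataFrame()
    _tsv(qtab, gdir / "qtl_all.tsv")
    state["qtl"] = all_qtl
    state["threshold"] = thr
    return state


def _stage_herit(cfg: PipelineConfig, state: dict, out: Path):
    geno = state["geno"]
    q = state["structure"].q_matrix
    blups = state["blups"].blups
    rows = []
    flank = cfg.qtl_h2_flank_kb * 1000.0
    mk = geno.markers
    for trait in blups.columns:
        y = blups.loc[list(geno.line_ids), trait].to_numpy(dtype=float)
        est = mixedmodel.estimate_h2(y, q, geno)
        rows.append((trait, "all_snps", est.h2, est.se, est.n_snps_used))
        union_idx: set[int] = set()
        for r in state.get("qtl", {}).get(trait, []):
            in_region = np.flatnonzero(
                (mk["chrom"] == r.chrom)
                & (mk["pos_bp"] >= r.start_bp - flank)
                & (mk["pos_bp"] <= r.end_bp + flank)
            )
            union_idx.update(int(i) for i in in_region)
            if in_region.size >= 2:
                e = mixedmodel.estimate_h2(y, q, geno, snp_subset=in_region)
                rows.append((trait, r.qtl_id, e.h2, e.se, e.n_snps_used))
        if len(union_idx) >= 2:
            e = mixedmodel.estimate_h2(y, q, geno, snp_subset=np.array(sorted(union_idx)))
            rows.append((trait, "all_qtl", e.h2, e.se, e.n_snps_used))
    tab = pd.DataFrame(rows, columns=["trait", "subset", "h2", "se", "n_snps"])
    _tsv(tab, out / "herit" / "heritability.tsv")
    state["heritability"] = tab
    return state


def _stage_sweep(cfg: PipelineConfig, state: dict, out: Path):
    geno = state["geno"]
    pops = list(pd.unique(geno.population_labels))
    if len(pops) < 2:
        logger.warning("sweep stage skipped: fewer than 2 populations")
        return state
    ref = geno.take_lines(np.flatnonzero(geno.population_labels == pops[0]))
    obj = geno.take_lines(np.flatnonzero(geno.population_labels == pops[1]))
    params = sweep.XPCLRParams(
        window_morgan=cfg.sweep_window_morgan,
        max_snps_per_window=cfg.sweep_max_snps,
        grid_size_bp=cfg.sweep_grid_bp,
        ld_cut=cfg.sweep_ld_cut,
    )
    track = sweep.xpclr_score(ref, obj, params)
    segs = sweep.segment_scores(track, cfg.segment_bp)
    sigs = sweep.call_signatures(segs)
    sdir = out / "sweep"
    _tsv(track.scores, sdir / "score_track.tsv")
    _tsv(segs.segments, sdir / "segments.tsv")
    _tsv(sweep.signatures_table(sigs), sdir / "signatures.tsv")
    qtls = [r for v in state.get("qtl", {}).values() for r in v]
    overlap = sweep.qtl_sweep_overlap(sigs, qtls, cfg.overlap_flank_kb)
    _tsv(overlap, sdir / "qtl_sweep_overlap.tsv")
    genome_bp = geno.markers.groupby("chrom")["pos_bp"].max().sum()
    covered = sum(s.end_bp - s.start_bp + 1 for s in sigs)
    _tsv(
        pd.DataFrame(
            {
                "n_signatures": [len(sigs)],
                "mean_size_kb": [np.mean([s.end_bp - s.start_bp + 1 for s in sigs]) / 1000.0]
                if sigs
                else [0.0],
                "genome_fraction": [covered / genome_bp if genome_bp else 0.0],
                "x80": [segs.x80],
            }
        ),
        sdir / "sweep_summary.tsv",
    )
    state["signatures"] = sigs
    state["sweep_overlap"] = overlap
    return state


def _stage_validate(cfg: PipelineConfig, state: dict, out: Path):
    geno = state["geno"]
    blups = state["blups"].blups
    vdir = out / "validation"
    rows = []
    pyr_rows = []
    for trait, regions in state.get("qtl", {}).items():
        y = blups.loc[list(geno.line_ids), trait].to_numpy(dtype=float)
        for r in regions:
            c = validation.contrast_haplotypes(y, geno, r)
            rows.append(
                (trait, r.qtl_id, c.n_high, c.n_low, c.mean_high, c.mean_low,
                 c.t_p, c.wilcoxon_p, c.testable)
            )
        if len(regions) >= 2:
            try:
                pr = validation.pyramiding_regression(y, geno, regions)
                pyr_rows.append((trait, pr.slope, pr.correlation, pr.p_value))
            except ValueError as err:
                logger.warning("pyramiding undefined for %s: %s", trait, err)
    _tsv(
        pd.DataFrame(
            rows,
            columns=["trait", "qtl_id", "n_high", "n_low", "mean_high", "mean_low",
                     "t_p", "wilcoxon_p", "testable"],
        ),
        vdir / "haplotype_contrasts.tsv",
    )
    _tsv(pd.DataFrame(pyr_rows, columns=["trait", "slope", "correlation", "p_value"]),
         vdir / "pyramiding.tsv")
    groups = validation.pleiotropy_overlap(state.get("qtl", {}))
    _tsv(
        pd.DataFrame(
            [(k, q.qtl_id, q.trait, q.chrom, q.start_bp, q.end_bp)
             for k, g in enumerate(groups) for q in g],
            columns=["group", "qtl_id", "trait", "chrom", "start_bp", "end_bp"],
        ),
        vdir / "pleiotropy_groups.tsv",
    )
    summ = validation.trait_summaries(blups)
    _tsv(summ.shapiro_p.rename("shapiro_p").rename_axis("trait").reset_index(),
         vdir / "normality.tsv")
    _tsv(summ.correlations.rename_axis("trait").reset_index(), vdir / "trait_correlations.tsv")
    state["validation_groups"] = groups
    return state


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------


def run_pipeline(
    config: PipelineConfig,
    out_dir: str,
    seed: int = 0,
    resume_from: str | None = None,
) -> dict:
    """Run the full analysis; returns the in-memory stage state.

    ``resume_from`` names the first stage to recompute; earlier stages are
    reloaded from the artifacts a previous run left under ``out_dir``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if resume_from and resume_from not in STAGES:
        raise ValueError(f"unknown stage {resume_from!r}")
    if resume_from in ("herit", "sweep", "validate"):
        # QTL regions live only in memory; re-derive them from the scans
        resume_from = "gwas"
    start = STAGES.index(resume_from) if resume_from else 0

    state: dict = {}
    # (re)load everything before the start stage
    if start > 0:
        state.update(_load_simulate(config, out))
    if start > STAGES.index("filter"):
        state = _load_filter(config, state, out)
    if start > STAGES.index("structure"):
        state = _load_structure(config, state, out)
    if start > STAGES.index("blup"):
        state = _load_blup(config, state, out)

    for stage in STAGES[start:]:
        logger.info("stage: %s", stage)
        try:
            if stage == "simulate":
                state.update(_stage_simulate(config, seed, out))
            elif stage == "filter":
                state = _stage_filter(config, state, out)
            elif stage == "ld":
                state = _stage_ld(config, state, out)
            elif stage == "structure":
                state = _stage_structure(config, state, out, seed)
            elif stage == "blup":
                state = _stage_blup(config, state, out)
            elif stage == "gwas":
                state = _stage_gwas(config, state, out)
            elif stage == "herit":
                state = _stage_herit(config, state, out)
            elif stage == "sweep":
                state = _stage_sweep(config, state, out)
            elif stage == "validate":
                state = _stage_validate(config, state, out)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "stages": STAGES[start:],
        "n_lines": int(state["geno"].n_lines) if "geno" in state else None,
        "n_markers": int(state["geno"].n_markers) if "geno" in state else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return state
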