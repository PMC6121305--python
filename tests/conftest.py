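import numpy as np
import pandas as pd
import pytest

from crosspopgen.genotypes import merge_populations
from crosspopgen.simdata import (
    CrossDesign,
    GeneticMap,
    simulate_biparental_cross,
    uniform_map,
)


@pytest.fixture(scope="session")
def tiny_map() -> GeneticMap:
    """Two chromosomes, 20 evenly spaced markers each, 1 cM/Mb."""
    return uniform_map(n_chromosomes=2, chrom_length_bp=10_000_000, n_markers_per_chrom=20)


def make_cross(gmap, pop_type="RIL_F6", n=60, seed=0, pa=None, pb=None, label="pop"):
    m = gmap.n_markers
    if pa is None:
        pa = np.zeros(m, dtype=np.int8)
    if pb is None:
        pb = np.ones(m, dtype=np.int8)
    g = simulate_biparental_cross(gmap, CrossDesign(pop_type, n, pa, pb, seed=seed))
    g.line_ids = np.array([f"{label}{seed}_{i:04d}" for i in range(n)], dtype=object)
    g.population_labels = np.array([label] * n, dtype=object)
    return g


@pytest.fixture(scope="session")
def study_map() -> GeneticMap:
    """Desk-scale analogue of the study genome: 15 chromosomes, 100 markers each."""
    return uniform_map(n_chromosomes=15, chrom_length_bp=20_000_000, n_markers_per_chrom=100)


@pytest.fixture(scope="session")
def merged_260(study_map):
    """Three bi-parental populations (97 + 91 + 72 = 260 lines) merged.

    Parents drawn from shared ancestral allele frequencies so that markers
    segregate both within and between populations.
    """
    rng = np.random.default_rng(42)
    m = study_map.n_markers
    anc = rng.uniform(0.1, 0.9, m)
    pops = []
    for k, (typ, n) in enumerate([("RIL_F6", 97), ("RIL_F6", 91), ("DH", 72)]):
        pa = (rng.random(m) < anc).astype(np.int8)
        pb = (rng.random(m) < anc).astype(np.int8)
        pops.append(
            make_cross(study_map, typ, n, seed=100 + k, pa=pa, pb=pb, label=f"pop{k}")
        )
    return merge_populations(pops)


@pytest.fixture(scope="session")
def null_panel():
    """260 lines x 10,500 independent bi-allelic markers for calibration.

    Markers are drawn independently (no LD), as required for exact
    finite-sample uniformity checks of scan p values; map positions spread
    them over 15 chromosomes.
    """
    rng = np.random.default_rng(777)
    n, m = 260, 10_500
    p = rng.uniform(0.05, 0.95, size=m)
    hap1 = rng.random((n, m)) < p
    hap2 = rng.random((n, m)) < p
    calls = (hap1.astype(np.int8) + hap2.astype(np.int8))
    per_chrom = m // 15
    markers = pd.DataFrame(
        {
            "marker_id": [f"n{j}" for j in range(m)],
            "chrom": [f"chr{j // per_chrom + 1}" for j in range(m)],
            "pos_bp": [(j % per_chrom + 1) * 1000 for j in range(m)],
            "pos_cm": [(j % per_chrom + 1) * 0.001 for j in range(m)],
            "ref": "A",
            "alt": "T",
        }
    )
    from crosspopgen.genotypes import GenotypeMatrix

    line_ids = np.array([f"N{i}" for i in range(n)], dtype=object)
    labels = np.array(["panel"] * n, dtype=object)
    return GenotypeMatrix(line_ids, labels, markers, calls)


def five_subpopulations(study_map, seed):
    """Five well-separated subpopulations: two crosses split in two + one DH."""
    rng = np.random.default_rng(seed)
    m = study_map.n_markers
    anc = rng.uniform(0.1, 0.9, m)
    pops = []
    for k in range(5):
        pa = (rng.random(m) < anc).astype(np.int8)
        pb = (rng.random(m) < anc).astype(np.int8)
        typ = "DH" if k == 4 else "RIL_F6"
        pops.append(
            make_cross(study_map, typ, 50, seed=1000 * seed + k, pa=pa, pb=pb, label=f"P{k}")
        )
    return merge_populations(pops)
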