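# Methods

This note documents the models, numerical choices and known limitations of
`crosspopgen`.  It is written for a reader who wants to know exactly what
the package computes and what passing its tests does — and does not — show
about real data.

## Synthetic data: what the simulator emulates

The simulator produces the three ingredients the analyses assume.

**Bi-parental crosses.**  Meiosis follows the Haldane (no-interference)
map function: crossovers form a Poisson process on the cM scale, so the
recombination fraction over `d` cM is `(1 − e^(−2d/100))/2`.  This choice
matches the uniform-recombination assumption used throughout and has
closed-form checks (DH recombinant fraction, RIL map expansion
`2r/(1+2r)`).  F6 RILs are built by five generations of selfing after the
F1 (single seed descent); residual heterozygosity is *retained* at its
expected (1/2)⁵ ≈ 3.1 % so that filtering and imputation see realistic
inputs.  DH lines are one meiosis followed by doubling.  The default
genome is 15 chromosomes × 20 Mb at 1 cM/Mb — a desk-scale echo of the
flax karyotype (15 chromosomes, ~300 Mb).  Founder haplotypes are drawn
from shared ancestral allele frequencies so markers segregate both within
and between crosses; GBS-style missingness is added as i.i.d. dropouts
(default 3 %).

**Phenotypes.**  `y_ie = μ + env_e + Σ_q a_q (x_iq − 1) + polygenic_i +
ε_ie`.  The polygenic term is built from genome-wide random marker effects
(an infinitesimal model) rather than i.i.d. line noise, so a SNP-derived
relationship matrix can capture it — a prerequisite for GREML
parameter-recovery experiments.  When a target heritability is requested,
the residual SD is rescaled so the broad-sense heritability of line means,
`var(G)/(var(G)+σ²_e/E)`, hits the target empirically; this sidesteps
solving for the variance decomposition analytically in the presence of the
polygenic term.  Environment effects are free parameters (no G×E beyond
additive environment shifts; no epistasis).

**Divergent selection.**  The selected sister population is bred as an
intermating population: each generation, each offspring draws two distinct
parents with probability `(1−s) + s·dosage/2` of the favoured allele at
the selected locus, followed by a few selfing generations (default 3) to
restore inbred structure.  Random intermating matters: under pure selfing
with selection, whole chromosomes hitchhike (one meiosis per generation
between effectively two haplotypes) and the sweep footprint cannot be
localised.  Ten generations of intermating give a footprint of a few cM
around the locus while the rest of the genome only drifts.  `s = 0` is
drift; `s = 1` fixes the favoured allele given enough generations.

What the simulator does **not** emulate: sequencing-read error profiles,
GBS restriction-site bias (missingness is uniform rather than
marker-correlated), genotyping error, multi-allelic variation,
segregation distortion, and real recombination-rate heterogeneity.
Passing tests therefore demonstrate the *statistical machinery* is correct
and calibrated under the stated model, not that any particular real
dataset would yield the same numbers.

## Genotype QC

Filtering removes markers with MAF < 0.05 or call rate < 60 %; both
boundaries retain a marker exactly at the threshold (the removal rule is a
strict `<`).  Imputation replaces each missing call by the modal genotype
of the 10 most-similar lines, with similarity measured by allele sharing
over the *same chromosome* — in bi-parental material haplotype sharing is
chromosome-scale, and chromosome-local similarity raises masked-call
recovery from ~85 % to >90 % in our masking experiments.  Ties break
toward the major-allele homozygote, then the lower genotype code, making
the rule fully deterministic.  This is a stand-in for haplotype-phasing
imputation; for near-homozygous inbred lines the phasing step adds little.
Populations are merged on the union of (chromosome, bp) coordinates with
conflicting ref/alt alleles treated as an error; lines are keyed by id, so
merging is idempotent.

## LD statistics

r² is the squared Pearson correlation of 0/1/2 dosages — the composite
estimate appropriate for unphased inbreds.  Pruning is a single
left-to-right pass dropping any marker in high LD (r² > 0.9) with an
already-retained marker within the 2000-kb window; this guarantees the
audit property (no surviving in-window pair above the cutoff) for *every*
in-window pair, which a stepped scan does not.  Haplotype blocks use the
D′ confidence-interval method: per pair, a profile multinomial likelihood
over |D′| with marginals at their MLEs gives a 90 % CI; strong LD is
CI ∈ [≥0.70, ≥0.98], strong recombination CI_high < 0.90; blocks are
maximal contiguous runs (capped at 2000 kb and, for tractability, at 30
markers) with ≥95 % of informative pairs in strong LD.

The decay model is the Hill–Weir expectation of r² under drift with
sampling (`n` = 2 × lines).  The fit is 1-D least squares in log₁₀(c)
(coarse grid, then bounded Brent; tolerance 10⁻¹⁰), which cannot diverge
and recovers a noise-free `c` to <0.1 %.  "Maximum LD" for the half-decay
rule is the fitted value at `d → 0`, not the maximum observed r² (observed
maxima are noise-dominated); the half point is found by bisection.

## Structure and kinship

PCA operates on column-centred dosages via SVD.  DAPC retains up to 100
PCs (clipped to rank), runs k-means for k = 1..10 and selects k by a BIC
whose penalty is **null-calibrated**: the naive per-parameter penalty
(`log n · k · d`) overwhelms any real clustering signal once ~100 PCs are
retained, while a per-cluster penalty (`log n · k`) under-penalises
because k-means genuinely lowers the within-cluster sum of squares on
structureless high-dimensional scores.  We therefore subtract the WSS
drop measured on permutation nulls (each PC column shuffled independently;
3 draws, fixed seed) — a gap-statistic-style correction — plus `log n · k`
to break ties toward fewer clusters.  On five well-separated
subpopulations this selects k = 5 essentially always; on one homogeneous
cross it selects k = 1.  The Q matrix is the posterior membership from a
linear discriminant model on the retained PCs; one column is dropped when
Q enters a regression, to avoid collinearity with the intercept.

The GRM is VanRaden's centred cross-product over Σ2p(1−p), then rescaled
so the mean self-relationship is 1: the raw diagonal approaches `1+F` and
fully inbred lines would sit near 2, which silently halves the
`σ²_g/(σ²_g+σ²_e)` scale.  A 10⁻⁸ ridge keeps it numerically PSD.  The
same matrix serves as the MLM kinship and the GREML relationship matrix.

## REML engine

With a single relationship matrix the restricted likelihood profiled over
(β, σ²_e) is univariate in λ = σ²_g/σ²_e.  After rotating by the
eigenvectors of A the covariance is diagonal; each evaluation is O(n) plus
a small least-squares solve.  The search is a 65-point grid on
log₁₀λ ∈ [−8, 8] followed by bounded Brent — global and monotone-safe.
Solutions at the lower search edge are clamped to the σ²_g = 0 boundary,
so ĥ² ∈ [0, 1] by construction.  Standard errors come from a central
second difference of the profile likelihood in h².  A degenerate A = I
collapses to a flat profile and returns the boundary solution with total
variance equal to the residual sample variance.  The spectral path is
verified against an independent matrix-inversion implementation to 10⁻⁶.

BLUPs fit `y_ie = μ + env_e + line_i + ε` with environment fixed and line
random (A = ZZ′ over the line-incidence matrix); the alternative
(environment random) changes little for ≤8 environments and is not
implemented.  Line effects are recovered as `λ Z′(λZZ′+I)⁻¹(y − Xβ̂)`.

## Association scans

The GLM is per-marker least squares with the intercept and reduced Q as
covariates, computed by Frisch–Waugh residualisation (vectorised across
markers), F-tested with n − p − 1 denominator degrees of freedom; markers
monomorphic in the analysed lines get p = 1.  The MLM fits the polygenic
null once (P3D), then whitens phenotype, covariates and markers by
`(λd_i+1)^{-1/2}` in the kinship eigenbasis and applies the same test —
with identity kinship this reproduces the GLM exactly.  No compression is
applied by default (each line its own group): at n = 260 the exact
computation is cheap, and compression is a speed device rather than a
statistical requirement.  Known behaviour worth stating: with the tested
markers also in the kinship (proximal contamination), the MLM deflates
the genomic inflation factor below 1; it remains far closer to 1 than the
uncovariated GLM under strong polygenic confounding.

QTL regions cluster Bonferroni-significant markers per chromosome with a
1000-kb merge distance — between the shortest and the merged-population
half-decay scales of the LD analyses — and are exposed as a configuration
knob.  h²_QTL uses the SNPs within the region ±500 kb (single-marker
regions would otherwise yield no GRM); h²_GWAS uses the union over a
trait's regions.  Estimates for SNP subsets selected by significance in
the same sample are optimistically biased; the package reports them as
defined and documents, rather than corrects, the bias.

## Sweep scan

The composite-likelihood machinery is described in the README; the
numerical specifics are: ω is a method-of-moments estimate of
`E[(q−p)²/(p(1−p))]` minus mean sampling noise, floored at 10⁻³; the
near-fixation component has variance `p(1−p)/n + 10⁻³`; the sweep-width
grid is {1, 2, 5, 10, 20, 50}×10⁻⁴ Morgan; windows take the nearest 100
SNPs within 0.005 Morgan of the grid point; each SNP's contribution is
divided by one plus its number of window neighbours with r² > 0.7; scores
are clipped at zero (the neutral model is nested at w → 0).  SNPs
monomorphic in the reference population carry no drift information and
are excluded.  Scores are invariant to allele relabelling by symmetry of
both densities.

Signature calling follows the segment recipe exactly: 10-kb segments take
the maximum window score among windows with ≥1 SNP; runs of ≥2 segments
strictly above the genome-wide 80th percentile of defined segments form
putative sweeps; sweeps separated by at most one sub-threshold segment
merge (keeping the maximum score), which also covers the "same peak"
combination case as adjacency; signatures are the sweeps at or above the
90th percentile of putative-sweep scores.  Percentiles are genome-wide.
The default pipeline grid is 5 kb (the scan is grid-resolution-bounded by
the 10-kb segmentation anyway); the scorer accepts any grid size.

## Pipeline determinism and problem sizes

Every stage is a pure function of (inputs, configuration, seed); all
outputs are plain TSV/VCF/JSON written with fixed float formatting, so
identical seeds reproduce byte-identical trees, and the manifest (seed +
configuration hash) suffices to reproduce a run.  Default problem sizes —
260 lines, 15 000 markers, 15 chromosomes, 6 environments, three traits,
one selected locus — run the full pipeline in about a minute on one CPU.
Test experiments use 5–20 replicate seeds per recovery claim; these sizes
were chosen as the smallest at which the binomial noise of a recovery rate
is clearly separated from the asserted bounds.

## Known limitations

- The sweep scorer is a contract-level reimplementation of the
  cross-population composite-likelihood idea, not a bit-compatible clone
  of the published scanner; absolute score magnitudes are not comparable
  across implementations (percentile-based calling is).
- The D′-CI block finder uses fixed conventional thresholds; at very small
  sample sizes the profile-likelihood CI is coarse.
- GREML standard errors come from the profiled curvature and ignore
  uncertainty in the GRM itself.
- Imputation is local-similarity voting; it does not model LD decay within
  a chromosome and will underperform phasing-based methods at high
  missingness in outbred material.
- The BIC null calibration re-runs k-means on permuted scores; with very
  few lines (<30) the permutation null is noisy and k selection unstable.
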