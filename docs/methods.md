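# Methods

## Model and procedure

`trajlink` integrates two inputs that were produced upstream: a gene-level
GWAS association table (Z-score and p-value per gene, typically from a
SNP-to-gene aggregation tool, with technical covariates such as gene
length) and an scRNA-seq count matrix whose cells carry a pseudotime and,
for branched trajectories, a branch label. All statistics are ordinary
least squares with homoskedastic t-tests; the package deliberately uses
one regression engine everywhere so that every stage can be verified
against an independent textbook fit.

**Preprocessing.** Mouse data are mapped to human gene ids through a
user-supplied ortholog table; any source or target id occurring more than
once is excluded (strict one-to-one rule, applied symmetrically). Genes
detected (count > 0) in fewer than `min_cells` cells (default 10) are
removed, then counts are library-size normalized: each cell's counts are
scaled to a fixed total (default 10,000) and transformed with log1p, so
per cell Σ(exp(lognorm) − 1) recovers the scale factor exactly. The order
is mapping → filtering → normalization; detection counts are therefore
evaluated on the mapped gene universe. The dataset-average expression A is
the mean of the log-normalized layer over all cells, computed after
filtering.

**Cell–trait scores.** For each cell, Z is regressed on an intercept, the
cell's log-normalized expression C, the average expression A, and the
covariate block B from the trait table; the score is the t-statistic of
the C coefficient. Genes present in only one of the two inputs are dropped
to the intersection. Gene–gene correlation induced by linkage
disequilibrium is *not* modelled — that would require an external
reference panel — so the score is a homoskedastic approximation of the
generalized gene-property statistic of the same form; its consequences are
discussed under Limitations. All cells share the fixed design block, so
scoring is implemented by residualizing Z and each cell vector against
that block once (Frisch–Waugh–Lovell); the result is numerically identical
to per-cell OLS (verified to 1e−8 against statsmodels) but costs one matrix
product per chunk of cells. Cells with constant expression get an
undefined (NaN) score rather than zero, so they cannot bias the trajectory
test; more than 50% undefined cells aborts the run.

**Trajectory link.** `score ~ 1 + pseudotime`, one-sided upper-tail t-test
on the slope. The statistic is invariant to affine rescaling of
pseudotime, so pseudotime units are irrelevant. Traits are ranked by
−log10 p, ties broken by name.

**Branches.** Pre-branch progenitors are ranked by pseudotime (ties broken
by cell id), the rank-1 cell is copied into every branch, and remaining
ranks alternate across branches (rank parity for two branches, rank mod 3
for three). Branch dependency compares `score ~ pseudotime` with
`score ~ pseudotime + branch:pseudotime` on this duplicated-progenitor
table via a likelihood-ratio test using Gaussian profile log-likelihoods
of the OLS fits (σ² profiled out), referred to χ² with (branches − 1)
degrees of freedom; Benjamini–Hochberg FDR is applied across the traits of
one dataset. Per-branch direction uses `score ~ branch:pseudotime` (one
slope per branch, shared intercept) with one-sided tests per slope. The
whole-trajectory test uses the original (unduplicated) table; only
branch-aware models see duplicated progenitors. The duplicated rank-1 cell
contributes one row per branch, matching the assignment used for fitting.

**Spline alternative.** A natural cubic spline basis on pseudotime
(default df = 3: the linear column plus two curvature terms, boundary
knots at the data range, interior knots at quantiles) generalizes the
linear link; because the basis spans the linear trend, a nested F-test of
spline vs linear flags non-monotone score–pseudotime patterns such as a
mid-trajectory peak. df = 3 is the smallest basis that can represent a
single interior extremum.

**Gene kinetics.** Per gene, `lognorm ~ 1 + pseudotime + n_detected`
(Gaussian GLM; the detected-genes covariate absorbs per-cell depth
effects, and is dropped automatically if constant). n_detected is counted
from raw counts (count > 0), not from the normalized layer. Genes with
zero-variance expression score t = 0 — they stay mid-list instead of being
dropped, which keeps the gene universe identical across branches. Exact
linear fits (zero residual) score ±∞ by slope sign. Branch-restricted
kinetics replace the pseudotime term with branch:pseudotime interactions
on the duplicated-progenitor table. Genes are ranked ascending by effect
t; ties break by gene id.

**GSEA.** Classic weighted Kolmogorov–Smirnov running sum over the ranked
list: hits add |effect t|^w (default w = 1) normalized to the set's total,
misses subtract 1/(N − hits); the enrichment score is the signed maximum
deviation. Conventions are fixed explicitly: the list ascends, so a set
concentrated among *induced* genes drives the running sum negative —
trajectory-linked sets are those with FDR q < 0.05 **and** NES < 0. Set
sizes are counted within the ranked universe and filtered with strict
bounds 50 < size < 500. The null is gene-label permutation (random
same-size sets, default 1000 draws, seeded); NES divides ES by the mean
|ES| of same-sign permutations; the permutation p compares |ES| within the
sign class with the (1+k)/(1+m) correction; FDR is Benjamini–Hochberg over
the permutation p-values (simpler and deterministic compared with
NES-bucket FDR; the selection rule is threshold-based, so any monotone
variant selects the same sets — this difference is deliberate and
documented here). The leading edge is the member suffix from the
running-sum extremum for negative ES (prefix for positive ES). Permutation
ES values are evaluated only at the 2·|S| positions where extrema can
occur (immediately before/after hits), which is exact and makes the
permutation loop a vectorized batch; the production running sum itself is
verified against an exhaustive brute-force recomputation in the tests.

**Competitive set test and prioritization.** For each trajectory-linked
set, Z is regressed on [intercept, A, covariates, 1(gene ∈ leading edge)]
and the indicator coefficient gets a one-sided upper-tail test: are
leading-edge genes more trait-associated than background after covariate
adjustment? Sets with p < 0.05 are significant. Candidate genes are the
union of significant sets' leading edges filtered to gene-level trait
p < 0.05 (strict), sorted by trait p, each listing its contributing sets.
Both thresholds are defaults of the stated procedure and overridable.

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| `min_cells` | 10 | detection filter: keep genes with count>0 in ≥ this many cells |
| `scale` | 10,000 | library-size normalization target per cell |
| `gsea_min_size`/`gsea_max_size` | 50 / 500 | strict set-size bounds within the ranked universe |
| `n_perm` | 1,000 | permutation draws per set; the smallest attainable p is ≈ 1/(same-sign draws+1), so q has a floor of roughly n_sets/(n_perm/2) under BH |
| `gsea_q`, `set_alpha`, `gene_alpha` | 0.05 | selection thresholds for linked sets, trait-associated sets, candidate genes |
| spline `df` | 3 | natural-spline basis size (linear + 2 curvature columns) |
| p→Z clamp | [1e−300, 1−1e−16] | keeps the inverse-normal transform finite while preserving order |

## The synthetic-data generator

The generator emulates the statistical situation the pipeline targets, at
the package's standard study conditions: 2,000 genes × 500 cells, 100
trait genes with mean Z shift 2 (p from the upper-tail normal), 100
induced genes gaining 1 log-unit of relative expression per unit
pseudotime, 50 genes in the overlap carrying the planted link. Pseudotime
is uniform on (0,1); branched runs place the branch point at the 0.4
quantile (cells before it are progenitors, later cells commit uniformly at
random; the induced program is confined to the first branch). Counts are
gamma-Poisson (negative binomial, dispersion 0.5) around compositional
gene proportions times log-normal library factors (mean 450 counts, σ=0.3
on the log scale), chosen so each cell detects 10–20% of genes — the
dropout regime of droplet scRNA-seq; an optional extra Bernoulli dropout
sharpens this. Gene length is log-normal (median 20 kb) and can be
correlated with Z to exercise covariate adjustment. One planted gene set
draws half its 100 members from the planted signal pool (overlap first,
then induced-only genes) and the rest at random; decoy sets are uniform
draws with sizes in (50, 500). All generators are deterministic given the
config seed, and gene roles come from a shared derived stream so GWAS and
expression outputs stay mutually consistent.

What the generator does **not** emulate: transcriptome-wide co-expression
structure, LD-induced correlation between gene Z-scores, batch effects,
doublets, or non-uniform pseudotime densities. Passing tests therefore
establish the pipeline's internal correctness and its behavior under
idealized independence assumptions — not robustness to correlated noise in
real data.

## Validation studies and what they show

`trajlink.validation` (used by both the test suite and
`scripts/acceptance.py`) computes:

- **Oracle equivalence** — cell scoring, gene kinetics and the competitive
  test match statsmodels OLS to < 1e−8 on 100 random fixtures, and the
  4-point hand fixture (C=[0,1,2,3], Z=[0,1,2,2]) returns β=0.7,
  t=4.041452 from the closed-form formulas.
- **Type-I calibration** — the null generator is the planted scenario with
  the induction slope set to 0 (expression kinetics flat, hence scores
  independent of pseudotime); at 500 genes × 200 cells over 1000
  replicates the one-sided link test rejects at ≈ 0.05.
- **Power** — at the default planted scenario the planted trait ranks
  first among 5 decoys and reaches p < 0.05 in ~100% of 200 replicates.
- **Branch dependency** — with a slope-1-vs-0 program (300 cells/branch,
  noise sd 0.5) the LRT reaches p < 1e−6 in ~100% of replicates, and its
  null statistic passes a KS test against χ²(1) over 1000 replicates.
- **GSEA exactness** — the running sum and leading edge equal a
  brute-force recomputation on all fixtures up to 200 genes, and
  permutation p-values are uniform under null rankings.
- **End-to-end recovery** — over 50 full-pipeline replicates the planted
  set passes both the GSEA selection and the competitive test in 100% of
  runs; on average 84% of the candidacy-eligible planted overlap genes
  (those with gene-level trait p < 0.05) appear in the candidate table.
  The misses are low-expression induced genes whose kinetic t is
  attenuated by dropout and lands mid-list, ahead of the running-sum
  extremum — an inherent ceiling of leading-edge-based prioritization at
  these effect sizes, not a defect of the enrichment computation (which is
  brute-force-verified). Note also that with trait-gene Z drawn from
  Normal(2, 1), only ≈ 64% of planted genes can ever pass the gene-level
  p < 0.05 candidacy filter, which is why recovery is reported relative to
  the eligible genes (the unconditional fraction is reported alongside).

## Known limitations

- **No LD adjustment.** Both the cell score and the competitive test treat
  gene-level Z-scores as independent observations; with real GWAS input,
  correlated neighboring genes make both tests anti-conservative to a
  degree this package cannot estimate without a reference panel.
- **Cells are treated as independent observations in the trajectory
  test**, but all cells share one Z vector. When Z carries no trait signal
  yet genes are induced along the trajectory, the shared Z induces a
  replicate-level random slope in the scores and inflates the one-sided
  test (measured rejection ≈ 0.11 at α = 0.05 in simulation). Conversely,
  when trait genes are present but disjoint from the induced program,
  compositional normalization gives background genes a genuinely negative
  pseudotime trend and the one-sided test almost never rejects (≈ 0.01).
  Both behaviors are properties of the method's design, documented here so
  users interpret borderline links accordingly.
- **Positive links only.** The one-sided test targets risk-gene expression
  *increasing* along the trajectory; declining programs require flipping
  the ranking, and non-monotone ones the spline comparison.
- **The inverse-normal transform saturates** below p ≈ 1e−300 and, in the
  other tail, above z ≈ 6 in float64; extreme inputs are clamped with a
  warning and keep their order.
- **Permutation p-values are granular** at 1/(n_perm/2 + 1); with the
  default 1000 permutations and 20 sets, the smallest attainable BH q is
  ≈ 0.04 — raise `n_perm` when more resolution near the 0.05 threshold is
  needed.
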