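# Methods

## The mixture model

A bulk methylation profile is modelled as a proportion-weighted linear
combination of cell-type-specific profiles.  For a vector `B` of beta
values over a CpG panel and reference profiles `X_t` (the per-type
median over QC-filtered sorted samples),

    B = Σ_t p_t X_t + e,      p_t ≥ 0,  Σ_t p_t ≤ 1,  no intercept,

with `e` treated as homoscedastic noise.  Only the coefficient
estimates are used — no standard errors or tests — so mild violations
of the linear-model assumptions (correlated CpGs in the panel,
truncated noise near 0 and 1) are tolerable.  The inequality `Σ p ≤ 1`
rather than an equality leaves room for populations absent from the
reference; in practice the estimates of whole-blood samples sum close
to 1.

### The constrained solver

The fit is a convex quadratic program in at most nine variables.  It is
solved exactly in two steps: plain non-negative least squares
(`scipy.optimize.nnls`); if the solution violates `Σ p ≤ 1`, the
constraint must be active at the optimum (convexity), and the
equality-constrained problem is solved by enumerating the active set of
the non-negativity constraints — for each support, the KKT system with
a Lagrange multiplier for `Σ p = 1` is solved and the best
sign-feasible candidate kept.  For the optimal support this reproduces
the optimum, so enumeration (≤ 2^d systems, d ≤ 9) is exact, cheap, and
immune to the cycling/tolerance issues of iterative active-set codes.
Rank-deficient designs are solved by least squares inside the KKT
systems, preferring the minimum-norm optimum, with a warning.  A
first-order KKT check at tolerance 1e-6 guards the result.  Tests
verify the solver against a brute-force 0.001-step grid enumeration of
the feasible region.

Missing values in a query sample are dropped row-wise (complete-case
per sample); the reference basis itself is required to be complete.  At
least `d + 1` usable rows are required.

## Panel selection

Deconvolution uses a panel of CpGs that separate the reference types,
assembled from two sub-lists computed on the sorted reference samples:

* **ANOVA sub-list** — CpGs ranked by one-way ANOVA p-value across all
  types; the top *m* enter the panel.  Ranking runs on beta values
  directly (the model is linear in beta space), with complete-case
  exclusion of CpGs missing in any reference sample.
* **Pair-specific sub-list** — for every unordered pair of types, CpGs
  ranked by Welch's t-test; a pair's top-*n* CpGs enter only if they
  appear in no other pair's top-*n* (so each retained CpG separates one
  specific pair).  Welch's unequal-variance form is used because sorted
  data sets have very unequal sizes and variances.

Ties in either ranking break lexicographically by CpG ID, which makes
every downstream result deterministic.  Zero-variance CpGs are assigned
p = 1 when the group means agree (spread ≤ 1e-9, judged on the means
rather than the between-group sum of squares, which picks up float
round-off) and p = 0 when they differ — the natural limits of the
tests on noise-free data.

`(m, n)` are chosen by minimizing a calibration error on samples of
measured composition.  The search is deterministic alternating
coordinate descent over user grids (default m ∈ {50,…,500},
n ∈ {10,…,100}): scan m at fixed n, fix the best m, scan n, repeat
until stable (max 20 rounds).  Each scan includes the incumbent, so the
error is non-increasing across rounds; ties break toward smaller
panels (parsimony).  Coordinate descent cannot in general certify a
global optimum on a grid, but the error surface in (m, n) is
empirically well-behaved — tests verify recovery of the exhaustive-scan
optimum on small planted instances.  Two-type models (the CD4/CD8
refinement and two-subtype models) have a single pair ranking and no
ANOVA list, so a plain 1-D scan over n suffices.

### Calibration error

For estimated vs. true proportions across samples, per type t with
non-constant truth:

    err = mean_t [ (1 − r_t) + MSE_t / Var(truth_t) ],

where r is the Pearson correlation and Var uses the sample (ddof = 1)
variance.  Standardizing the MSE by the truth variance puts rare
subtypes (≈1% of blood) on the same footing as granulocytes (≈55%);
the (1 − r) term preserves the linear relationship needed when
estimates serve as regression covariates.  Perfect recovery scores 0.
Types with constant truth have no defined correlation and are excluded;
a varying truth met by a constant estimate scores r = 0 rather than
undefined, so degenerate estimators are penalized, not excused.

## Two-stage refinement and subtypes

Similar populations (CD4 vs. CD8) separate poorly in the full
six-type fit.  The second stage subtracts the fitted contributions of
all other types,

    B̂_CD4,CD8 = B − (p̂_CD14 X_CD14 + p̂_CD19 X_CD19 + p̂_Gran X_Gran + p̂_NK X_NK),

evaluates this partitioned profile on a pair-specific panel, refits the
two-type model, and rescales both coefficients by a common factor so
their sum equals the stage-1 pair sum.  Refinement therefore never
alters other types' estimates.  Partitioned values may fall slightly
outside [0, 1]; they are deliberately not clipped, because the refit is
plain least squares on the residual profile and clipping would bias the
coefficients toward the interior.

Subtype estimation is the same operation with a single parent kept:
partition to `B̂_parent`, refit over the parent's subtype profiles on a
subtype panel, rescale so the subtype estimates sum to the parent's
*refined* estimate (the refined rather than stage-1 value is used for
internal consistency; the partition likewise uses refined estimates).
If the refit is identically zero while the parent mass is positive, the
stage-1 estimates are retained (pair refinement) or the parent mass is
split uniformly (subtypes), with a warning.  Switched and unswitched
memory B cells are fitted as separate columns — their sorted references
are distinct populations — and summed into a single reported `Bmem`.

A monocyte/granulocyte pair refinement is supported by the same
machinery but not built by default: refitting that pair does not
improve on the stage-1 estimates.

## Quality control

Applied to each data set before basis construction, in this order:
detection-p masking (a cell is masked when p ≥ 0.01 — the boundary is
masked, the conservative reading of "not significantly detected"),
removal of CpGs with strictly more than 10% missing cells, removal of
samples with strictly more than 1% missing cells computed on the
surviving CpGs, kNN imputation, SNP-probe removal from a caller-supplied
exclusion list (MAF computation is upstream).  Imputation fills a
missing cell with the mean of that sample's values at the k nearest CpG
rows (default k = 10, the common default of kNN imputation tools);
distance is the root-mean-square difference over shared observed
samples, so rows observed on different sample subsets remain
comparable, and neighbours are drawn from rows observed at the target
sample.  Batch correction and Infinium I/II chemistry normalization are
out of scope: the toolkit consumes already-normalized beta values.

## Simulation

Whole-blood truth: per sample, each main type's proportion is drawn
from a normal, negatives clamped to 0, and the vector renormalized to
sum to 1.  Subtype truth: per parent, subtype normals are drawn, clamped
and rescaled so the block sums to the parent's value.  Default means/SDs
follow normal-blood reference ranges for healthy adults — Gran
0.55 (0.10), CD4 0.15 (0.05), CD8 0.10 (0.04), CD14 0.08 (0.03), NK
0.07 (0.03), CD19 0.05 (0.02), with subtype means splitting the parent
(e.g. Tnaive/Tmem 45% each and Treg 10% of CD4) and SDs scaled
accordingly.  These defaults are the package's own choices of plausible
values.  A mixture is the proportion-weighted sum of donor columns,
one donor drawn uniformly with replacement per population per sample;
subtype donors replace their parent wherever subtype truth exists.
Sorted-parent mode (`sorted:CD4` etc.) applies the same construction to
one parent's subtypes with proportions summing to 1.  100 samples per
simulated data set is the default.

The synthetic reference generator emulates sorted-cell array data:
a bimodal baseline (Beta(5,45)/Beta(45,5) mixture, modes near 0.1 and
0.9), `n_diff` private CpGs per main type shifted 0.8 toward the
opposite mode (top cell-type markers on arrays are near-fully
switched), subtype profiles inheriting the parent plus 0.4-shifts on
their own private CpGs (subtype differences are subtler), and truncated
Gaussian sample noise (default sd 0.02).  Private CpG blocks are
interleaved across types so that deterministic tie-breaking cannot
concentrate a panel on one type.  What this generator does *not*
emulate: probe-chemistry artifacts, batch effects, detection failures,
spatial correlation along the genome, biological donor-to-donor
covariance structure, or reference populations missing from the model
(e.g. eosinophil/neutrophil substructure).  Passing recovery tests on
this generator therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not performance on any
particular real cohort.

## Study scales and numerical choices

The default end-to-end study uses 50,000 CpGs, 500 planted differential
CpGs per type/subtype, 10 sorted samples per population, noise sd 0.02
and 100 mixtures; it completes in seconds on one core.  Test fixtures
use 1,000–5,000 CpGs.  Default panel sizes when no calibration data are
supplied: main m = 300, n = 50; pair and two-subtype panels n = 300;
three-subtype panels m = 300, n = 50.

Tolerances: solver feasibility p ≥ −1e-12, Σp ≤ 1 + 1e-9; KKT check
1e-6; proportion-table row sums ≤ 1 + 1e-8; conservation of pair and
subtype mass is exact up to float round-off (≤1e-12 asserted).
Noise-free mixtures composed from the basis medians themselves are
recovered to ≤1e-6 at every stage.

## Known limitations

* The reference must contain every abundant population of the mixture;
  mass from unmodelled populations leaks into the closest profiles.
* Subtype accuracy in whole blood is bounded by the accuracy of the
  parent estimate, since subtype estimates are rescaled to the parent
  mass.
* Panel-size calibration requires external samples of measured
  composition; the defaults are sensible but not cohort-optimal.
* The QC imputation is quadratic in the number of CpG rows carrying
  missing values and intended for reference-sized matrices, not
  epigenome-scale imputation.
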