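# Methods

This note records the models implemented by protimpute, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
benchmark does and does not demonstrate.

## Data model and spaces

A dataset is a samples × proteins grid of positive intensities with an
explicit missing mask. Three working spaces are used:

* **intensity** — the original scale; required by CAM because the archetype
  mixture model is linear in intensities and the log transform would break
  that linearity;
* **log2** — the scale on which most methods operate and on which accuracy
  is evaluated for the non-CAM methods; proteomic intensities are roughly
  log-normal, so errors on this scale are comparable across the dynamic
  range;
* **protein-standardized log2** — observed mean 0, observed *population*
  standard deviation 1 per protein.

The preprocessing map is: Min/2, Mean and swKNN run on the log2 matrix
(Min/2 computes its fill on the intensity scale, see below); pwKNN and all
factorization methods run on the standardized matrix and results are
de-standardized before evaluation, since these methods assume comparable
column scales and (for PCA-type fits) centered columns; CAM runs on
intensities and is evaluated on intensities. Mixed-space comparisons are
never ranked together: the benchmark records the evaluation space per row
and computes SOR only within one space.

Standardization uses the population (divide-by-N) standard deviation — the
same convention as the NRMSE denominator, which makes "impute every entry
with mean(X_Ω)" score NRMSE = 1 exactly and gives the metric a clean
baseline interpretation. Sample-wise normalization is median centering in
log space (robust to missingness); it is provided but not part of the
default pipeline, because the synthetic generator produces no sample-level
loading offsets.

Protein filtering removes proteins whose missing fraction strictly exceeds
0.8 (a protein missing exactly 80% of samples is kept).

## Imputers

**Min/2.** Per protein, missing entries become half the observed minimum
*intensity*. On a log2 matrix that is (observed min − 1). The function also
offers the literal halve-as-stored rule (`halve_in="stored"`), but note
that halving a log2 value is a square root on the intensity scale and is
not a sensible censoring fill; the benchmark harness always uses the
intensity rule.

**Mean.** Per protein, the observed arithmetic mean (in whatever space the
matrix is supplied).

**swKNN / pwKNN.** For a missing entry, candidate neighbours are the
samples (resp. proteins) that observe that entry's protein (resp. sample).
Distance is Euclidean over mutually observed positions, divided by the
square root of the overlap size so pairs with different overlaps are
comparable. The k nearest neighbours (ties broken toward the smaller
index) contribute a weighted average with weights 1/(d + 1e−9). An entry
with no candidates falls back to the protein mean (0 in standardized
space), logged. Correlation distance is selectable; Euclidean is the
default. Both imputers are verified against an exhaustive brute-force
oracle.

**PPCA.** The model x = W z + μ + ε with z ~ N(0, I_l), ε ~ N(0, σ²I),
fitted by EM on the observed entries. The E-step computes each sample's
latent posterior from its own observed coordinates; the M-step jointly
re-estimates (W, μ) by per-protein regression on [E z, 1] and σ² from
expected residuals, so the observed-data log-likelihood is non-decreasing
(the recorded trace is checked for this in the tests). σ² is floored at
1e−12; at that boundary — reached only on noiseless data — exact EM
monotonicity no longer applies. Initialization comes from an SVDImpute
fill; the seed controls a vanishing (1e−10) perturbation of the initial
loadings.

**NIPALS.** Components are extracted one at a time by alternating
regressions of scores on loadings and vice versa, each regression using
only observed cells, deflating after each component. One sequential pass
leaves a deflation bias when data are missing, so the extraction is cycled
(up to 5 backfitting sweeps, each component refitted against the residual
of the others) until the reconstruction stabilizes. No internal centering:
the caller supplies centered/standardized data.

**SVDImpute.** Missing entries start at protein means; iterate truncated
rank-l SVD of the filled matrix and refill the missing cells from the
reconstruction until the relative change of the imputed entries falls
below 1e−6.

**SVT.** Soft-threshold the singular values of Y by τ and feed the
observed-entry residual back: X̂ = shrink(Y, τ), Y ← Y + δ·P_Ω(X − X̂).
Defaults τ = 5√(mn), δ = 1.2/observed-fraction (the standard heuristics;
no rank parameter is needed). The run starts from the warm point
Y⁰ = k₀δ·P_Ω(X) with k₀ = ⌈τ/(δ‖P_Ω(X)‖₂)⌉, which yields the same iterate
sequence as Y⁰ = 0 minus the initial iterations where the shrinkage
returns zero. Stops at relative observed residual < 1e−4; aborts with a
diagnostic if the residual grows to 10× its initial value.

Rank selection for the rank-parameterized methods is left to the harness's
parameter sweep (`sweep_parameters`, grid 2…15 by default); standalone
calls require an explicit rank.

## RMF and FRMF

The objective is

E(A, S) = Σ_obs (X_ij − A_i S_j)² + λ_A‖A‖²_F + λ_S‖S‖²_F
          + α Σ_i Σ_{k∈F(i)} ‖A_i − A_k‖²_F.

The implementation differentiates this objective exactly — including both
directions of each neighbourhood edge — and the analytic gradients are
verified against central finite differences (relative error < 1e−5) in the
test suite. The pairwise penalty above is the default; an average-based
variant α Σ_i ‖A_i − mean_{k∈F(i)} A_k‖² is selectable
(`fused_mode="average"`), as the two forms appear interchangeably in the
literature and differ only in how strongly high-degree samples are pulled.

Neighbourhoods F(i) are the t most similar samples by cosine similarity
(t = 5 default), computed over mutually observed entries of the
standardized matrix for FRMF_self, or over external per-sample score
vectors for FRMF_cross. Samples with no valid pair get an empty
neighbourhood and participate only through the data term.

Optimization is full-batch gradient descent with a fixed step, default
0.25/(max(m, n) + 2α·max-degree) — a cheap curvature bound for O(1)
standardized entries. If the objective rises for 5 consecutive iterations
(or turns non-finite) the step is halved, at most 10 times. Factors are
initialized from the truncated SVD of a mean-filled matrix plus 1%
seed-controlled noise; with α = 0 the code path is exactly RMF, so the two
produce bitwise-identical traces under a shared seed. Suggested sweep
grids: l ∈ {2,…,15}, λ ∈ {0.01, 0.1, 1}, α ∈ {0.01, 0.1, 1, 10},
t ∈ {3, 5, 10}.

## CAM

Each protein's m-vector is normalized to unit sum, placing all proteins in
a scatter simplex whose vertices are the (scaled) columns of the mixing
matrix A. The fit: (1) k-means with `n_clusters` (default 50, capped at
the number of distinct points; empty clusters from duplicate points are
dropped) on the normalized points; (2) for each candidate k, choose the k
cluster centers minimizing the total residual of expressing *all* centers
as convex combinations of the chosen ones — greedy selection followed by
single-swap refinement, the convex fit solved by nonnegative least squares
with a soft sum-to-one row; (3) markers are the proteins in each vertex
cluster whose distance to the center is within the `margin_quantile`
(default 0.1) quantile, at least one per vertex; (4) A is the per-archetype
mean of marker intensity columns, rescaled column-wise (one nonnegative
scalar per column, by NNLS against the all-ones vector) so rows of A sum to
approximately 1 — the mixing-proportion convention, with S absorbing the
scale; (5) S is recovered per protein by NNLS.

**Order selection.** The published MDL-style score

MDL(k) = ½·log(Σ_j ‖x(j) − A s(j)‖²) + ((k−1)m/2)·log(n_MG) + (kn/2)·log(m)

is implemented verbatim as `compute_mdl` (n_MG is the total marker count;
the residual is floored at 1e−12). As a selection criterion, however, its
likelihood term is additively dominated by the parameter-count penalties at
every realistic problem size (the penalties grow like n·log m per unit of
k while ½·log RSS can swing only a few dozen nats), so its argmin always
lands on the smallest candidate k. `cam_fit` therefore defaults to a
corrected description length that replaces the first term with the
standard Gaussian code length (mn/2)·log(RSS/(mn)) and keeps the same two
penalties (`mdl_variant="corrected"`; `"printed"` is selectable). On
noiseless 3-archetype data the corrected score selects k = 3 in 10/10
seeded runs with per-column mixing recovery r > 0.999.

**Imputation.** CAM_complete fits on the fully observed proteins (at least
10·k required), then re-estimates every protein's s(j) by NNLS over its
observed samples and fills missing entries from A·s(j); proteins observed
in fewer than k samples fall back to a mean fill, logged. CAM_SVT and
CAM_NIPALS first complete the matrix with the named low-rank method on the
standardized log2 scale, map back to intensities, fit CAM on the completed
matrix, and overwrite only the originally missing entries with A·S.
Nonpositive fills (possible when an NNLS coefficient is zero) fall back to
half the protein's observed minimum, logged, so filled values are always
strictly positive.

## Simulation designs

**Generator.** Mixing rows are flat-Dirichlet on the k-simplex (k = 3
default); a fraction (default 0.1 per archetype) of proteins are exclusive
markers; profiles combine a log-normal base abundance (σ = 1.2 natural log,
a realistic multi-decade dynamic range) with per-archetype log-normal
variation (σ = 0.8); intensities are (A·S)·10⁶ with multiplicative
log-normal noise (σ = 0.3, i.e. ≈30% CV, typical of label-free
quantification). Defaults m = 50 samples × n = 300 proteins keep every
benchmark cell inside a desk-scale compute budget; the generator itself
scales freely. A clustered variant draws mixing rows from concentrated
Dirichlets (concentration 8 toward each sample's cluster archetype) to
create the two-cluster regime where similarity fusion should help.

**Artificial injection.** MCAR removes exactly round(α·mn) entries
uniformly, redrawing (≤100 times) if a protein would lose all observations.
MNAR is a hard global quantile cut-off: the lowest ⌊α·mn⌋ values of the
full matrix are removed, deterministically, ties broken by (row, column)
order — modeling a shared lower limit of detection rather than
probabilistic thinning. Mixed injection applies the MNAR cut-off first
(so the quantile refers to the full dataset), then MCAR among the
survivors; rates sweep 1–50% by default.

**Proportional masking.** On a matrix with authentic missing values, each
protein p loses round(c·r_p·obs_p) of its *observed* entries, where r_p is
its authentic missing rate; the single constant c is calibrated by
bisection so the total masked count matches the global target (within one
entry, counts being integers). Masks are drawn only from observed entries —
a mask landing on an already-missing cell would contribute no evaluable
ground truth — and at least one observation per protein is always kept.
Proteins with no authentic missingness receive no mask (no masking floor
is applied).

## Evaluation

RMSE and NRMSE as defined in the README; NRMSE uses the population
variance of the true values at Ω. Per-protein NRMSE excludes proteins with
fewer than two held-out entries or zero variance there; the exclusion
depends only on the ground truth, so the protein subset is identical for
all methods and the SOR rank-sum conservation P·M(M+1)/2 holds exactly.
SOR ranks ascending with average ranks on ties. SOR grows with the number
of missing-bearing proteins, so values are comparable only within one
(rate, trial) cell, never across rates; reports carry the cell identity on
every row.

The harness records every failure (a method that errors at one cell yields
a NaN row with the message) and aggregates mean ± sd over trials. All
randomness is derived from a single config seed.

## What the synthetic benchmark shows — and what it does not

The generator produces data that are genuinely low-rank plus multiplicative
noise, with missingness mechanisms that exactly match the injectors'
definitions. Passing recovery tests therefore demonstrates algorithmic
correctness (each method recovers the structure it models) and the
qualitative mechanism–method interactions: half-minimum wins under
censoring, low-rank methods win under MCAR, similarity fusion helps when
samples cluster. Real proteomics data differ in ways the generator does not
emulate: batch effects, peptide-to-protein roll-up artifacts, heteroscedastic
noise that shrinks with intensity, correlated (pathway-level) protein blocks
beyond the archetype structure, and authentic missingness whose mechanism is
unknown and unverifiable. Absolute NRMSE values from the benchmark should
not be read as estimates of accuracy on any real dataset, and method
rankings can shift when the low-rank-plus-censoring assumptions are badly
violated (e.g. NIPALS can diverge on heavily censored proteins, visible as
occasional large-NRMSE trials under MNAR at low rates).

## Known limitations

* FRMF uses fixed-step gradient descent; very large α values require many
  iterations (the step shrinks with the fused curvature bound).
* CAM requires a complete (or pre-completed) positive matrix and enough
  fully observed proteins; its geometry degrades when markers themselves
  are missing — the hybrid variants exist precisely to mitigate this.
* The Setting-2 masker needs authentic missingness to be present and
  leaves proteins with a single observation unmasked.
* No batch-effect modeling, quantile normalization, peptide-level
  missingness, or correlation-based performance measures.
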