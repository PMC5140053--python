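# Methods

## Dynamics model and design construction

Gene expression is modeled with linear dynamics: the rate of change of gene
*i*'s mRNA is a decay term plus a weighted sum of TF expression,
`dx_i/dt = −α x_i + Σ_j β_ij x_j` over TFs j ≠ i. The decay rate α is shared
by all genes; the default 0.1 min⁻¹ corresponds to an exponential time
constant of 10 minutes, a typical bacterial mRNA lifetime. (A per-gene α is
biologically plausible but not implemented; the `alpha` argument is the
configuration hook.)

`build_response_design` turns an `ExpressionDataset` into one regression row
per usable condition:

* steady state (derivative zero): response `α·x(t_k)`, predictors = TF values
  at t_k;
* time-series pair (t_k → t_{k+1}, Δt minutes): response
  `(x(t_{k+1}) − x(t_k))/Δt + α·x(t_k)`, predictors = TF values at the
  *earlier* timepoint. Chain-starting conditions contribute no row.

Steady-state and time-series rows are concatenated without reweighting.
Missing expression values are rejected at load — imputation is out of scope.
α = 0 is accepted only behind an explicit flag (`allow_zero_alpha`), the
convention of the synthetic-data generator.

Predictors are standardized per column: centered, and scaled to unit
*population* (ddof = 0) variance — so a two-row column (1, 3) becomes
(−1, 1). Constant columns are centered only and flagged, with sd recorded as
1 so mapping coefficients back to the raw scale is well defined
(`NetworkCoefficients.to_original_scale` divides each TF row by its sd).
Self-regulation is handled structurally: TF j is removed from gene j's
predictor set, and β_jj ≡ 0.

## Fused L2 objective and solvers

The joint objective over sources s is

    Σ_s ‖X_s β_s − Y_s‖² + λ_R ‖β_s‖² + λ_S Σ_c w_c (β[c.left] − β[c.right])²

Each constraint couples two coefficients identified by (source, TF, gene).
As with ridge regression, the combined penalty is a zero-mean Gaussian prior
on β; for a two-coefficient model with one fusion constraint the implied
prior has variance (λ_R+λ_S)/(λ_R²+2λ_Rλ_S) and covariance
λ_S/(λ_R²+2λ_Rλ_S) — the unit test inverts the 2×2 precision numerically and
checks both (λ_R = λ_S = 1 gives 2/3 and 1/3).

**Direct solver.** Responses sharing any chain of constraints must be solved
together; depth-first search on the response graph (networkx connected
components) yields the blocks. Each block is vectorized into one augmented
least-squares system: the sources' design blocks diagonally concatenated,
then ridge rows √(λ_R·κ)·I, then one row per internal constraint with
+√(λ_S w) and −√(λ_S w) in the fused columns (the square roots are required
for the quadratic expansion to reproduce λ_S(β_i − β_j)² exactly, though a
plain description of the construction often omits them). The system is
solved by an LAPACK least-squares factorization, not normal equations.
Unconstrained responses without relaxed-prior coefficients are batched per
predictor mask into multi-RHS solves. With λ_R = 0 a rank check raises
rather than silently returning a minimum-norm solution.

**Iterative solver.** For large many-to-many constraint blocks, and to
compute a λ_S path cheaply, a Jacobi-style scheme re-solves each response's
ridge problem with quadratic pulls toward the *previous* iterate's fused
partner values. The per-response normal matrices are Cholesky-factored once
per λ_S and reused across iterations. The fixed point satisfies the joint
stationarity conditions, so the iteration converges to the convex objective's
global minimizer; the contraction slows as λ_S grows (the pull term dominates
the curvature), which is why defaults are tol 1e-6 / max_iter 50 at the
typical operating range (λ_S ≈ 1 converges in well under 10 passes) while
path computation inside cross-validation runs looser (1e-4) but longer (300).
Non-convergence warns and flags the result, never silently. Grid values are
warm-started from the previous solution. Components above 5000 coefficients
are routed from the direct to the iterative solver automatically.

**Priors on individual edges.** Known interactions can be penalized less:
coefficients listed in `prior_edges` get ridge weight λ_R·κ with κ =
`prior_relax` (default 0.1; only "relax" is prescribed by the approach, the
factor is this package's choice).

## Constraint generation

* **Orthology:** one constraint per (orthologous TF pair) × (orthologous gene
  pair) spanning the same source pair; with >2 sources, all source pairs are
  enumerated. A pair acts on the regulator side only if both members are
  declared TFs, and on the target side only if both are response genes.
  Many-to-many orthology generates the full bipartite product. Constraints
  are stored with canonically ordered endpoints and deduplicated; constraints
  that would touch a structural zero (self-regulation) are skipped.
* **Operons:** within one source, for each TF t and each unordered pair of
  distinct genes in the same operon, (t→i) ≈ (t→j).

## Adaptive fusion

The saturating penalty is defined through its derivative:

    p′(θ) = λ·θ        0 ≤ θ ≤ a/2
          = λ·(a − θ)  a/2 < θ ≤ a
          = 0          θ > a

quadratic at the origin, tapering from a/2, constant (value λa²/4) beyond a.
This is the unique continuous piecewise-linear derivative with those three
regimes; it differs from SCAD/MCP in being L2-like rather than L1-like at
the origin — differences between fused coefficients are not expected to be
exactly zero, only small.

Optimization is iterated local quadratic approximation: starting from θ = 0
for every constraint, each round sets constraint weight w = p′(θ)/(2θ)
(limit λ/2 at θ = 0; exactly 0 for θ ≥ a) from the current networks and
re-solves the fused-L2 problem. Because p′(θ)/θ is non-increasing, the
quadratic surrogate majorizes p and the true objective is non-increasing
across rounds (asserted numerically in tests). Since the quadratic-region
weight is λ/2, the package sets λ = 2λ_S by default so that adaptive fusion
with small differences reproduces fused-L2 at the user's λ_S exactly.
Constraints with final weight 0 are reported as **unfused**; θ is measured on
the standardized-coefficient scale, where the solver operates.

The saturation point `a` is the q-th percentile (numpy linear interpolation;
default q = 60) of |β_left − β_right| over constraints from networks fitted
independently (λ_S = 0) — q expresses the prior belief about the fraction of
constraints that are genuine; roughly (100 − q)% start in the saturated zone.
Cross-validating `a` was considered and rejected as disproportionate to its
role as a working hypothesis.

## Hyperparameter selection and workflow

λ_R and λ_S are selected sequentially (a joint 2-D grid search is
deliberately out of scope): first λ_R by K-fold CV on held-out squared
prediction error with λ_S = 0, over a descending log-spaced grid from
λ_max = max|XᵀY| down to 10⁻³λ_max (20 points); then λ_S along the
warm-started iterative path over {0, 0.01, 0.1, 0.5, 1, 2, 5, 10}. CV units
are regression rows; ties in CV error break toward the heavier penalty.
Neither selection ever sees the gold standard.

The full workflow (`run_workflow`) mirrors the end-to-end procedure: load and
cross-validate inputs; split each source's gold standard into a prior half
(TFA estimation and relaxed-ridge priors) and an evaluation half, by a seeded
random half-split; build and standardize tasks; generate constraints; select
λ_R on the primary source; optionally set `a`; then per CV fold select λ_S on
the training rows (inner 2-fold split), fit fused and independent networks,
rank the primary source's edges, and evaluate precision–recall against the
held-out gold half (prior-half edges and self-edges are excluded from the
eligible universe). Curves are averaged across folds on a common recall grid;
a final fit on all rows, at the median per-fold λ_S, produces the reported
network. All randomness flows from the run seed, and two runs with the same
seed produce byte-identical outputs.

## TF activity, scoring, evaluation

**TFA.** Given a signed prior P (target genes × TFs, entries ±1), activities
solve P·A ≈ E_targets in the least-squares sense via the Moore–Penrose
pseudoinverse; TFs without prior targets keep their own expression, so an
identity prior reproduces the expression-based pipeline exactly. Magnitudes
are left to the pseudoinverse — the prior contributes connectivity and sign
only. Estimated activities replace TF expression on the predictor side only;
responses always come from measured expression.

**Confidence scores.** The default rescaling is
S_ij = σ²_j/(σ²_j + β²_ij·var(TF_i)), with σ²_j the mean squared residual of
gene j's full model: S ∈ (0, 1], S = 1 iff β = 0, strictly decreasing in
|β|. An exact leave-one-predictor-out refit variant (ratio of residual
variances) is provided for comparison but is not the default: refitting
against the data alone would discard exactly the information fusion added. A
zero-residual response with nonzero β gets a 1e-12 floor and a flag. Public
rankings report confidence = 1 − S so larger is better; raw S is retained.

**Rank combination.** Score matrices over a common edge set are converted to
ranks (average ranks on ties), averaged per edge, and re-ranked — the
standard baseline for combining independently fitted networks.

**PR/ROC.** Gold-standard signs are ignored (recovery, not sign, is
evaluated); self-edges are excluded; the universe can be restricted to the
constrained or non-constrained subnetwork. AUPR uses the step-interpolation
convention Σ_k (r_k − r_{k−1})·p_k, i.e. average precision — on the worked
4-edge example (gold = {e1, e3}, ranking e1 e2 e3 e4) this gives 5/6. A
random ranking's expected AUPR equals the positive rate (checked by Monte
Carlo). Implementation delegates to scikit-learn's
`average_precision_score`/`roc_curve`; the hand-computed values in the tests
are the independent check.

## Synthetic data generator

The generator emulates the full multi-species study design and is the
package's test bed:

1. **Orthology:** one-to-one random pairing of floor(frac·n) TFs and
   floor(frac·n) non-TF genes separately (TFs never pair with non-TFs);
   floor is this package's rounding convention.
2. **Networks:** coefficients are drawn per fused group (an entry plus
   everything reachable through fusion): zero with probability `sparsity`,
   else a shared v ~ N(0, 1) plus independent N(0, σ_f²) per member — nonzero
   entries are N(0, 1 + σ_f²) marginally and fused pairs differ by
   N(0, 2σ_f²). σ_f defaults to 0.1 (mild divergence); it is a free parameter
   of the study design.
3. **Expression:** two-timepoint pairs with decay treated as zero:
   Y_T1 ~ N(0, I), X_T1 its TF columns, Y_T2 = Y_T1 + X_T1·β + ε with
   ε ~ N(0, noise_sd²), noise_sd default 0.1 (also a free parameter — the
   study design fixes no value). Emitted with Δt = 1 so the design builder
   (α = 0) reproduces X_T1·β + ε exactly.
4. **Corruption:** false negatives remove floor(fn_rate·n) true pairs; false
   positives add round(fp_rate·n_true) random pairs per pool (rates in units
   of the true pair count, TF and gene pools corrupted separately, never
   duplicating a true pair). Truth labels propagate to constraints: a
   constraint is genuine only if both its TF pair and gene pair are.

All randomness flows from one seed through named substreams, so each stage is
independently reproducible. The generator supports exactly two sources —
every study design it emulates is pairwise.

What it does *not* emulate: realistic multi-timepoint kinetics, decay, batch
effects, platform-specific noise, or a TFA layer (simulated TF mRNA *is* the
activity). Passing tests on this generator therefore demonstrate the
estimator's statistical behavior under the stated model, not robustness to
real-data artifacts.

## Reference studies (`fusenet.experiments`) and their scales

Problem sizes were chosen so each study runs in seconds to a few minutes on
one core while preserving the qualitative regime (under-constrained fits,
partial orthology):

* **Data pooling:** 10 TFs × 50 genes, 75% orthology, 75% sparsity, 10
  samples in the source of interest vs 40 in the relative; λ_R then λ_S by
  CV. Outcome: coefficient MSE of the data-poor source, fused vs independent.
* **Subnetwork recovery:** 20 TFs × 100 genes, 50% sparsity, 15 samples
  (0.75·p — under-constrained); AUPR at λ_S = 1 vs 0 on the constrained
  subnetwork, and on the non-constrained one at 90% orthology.
* **Adaptive fusion under corruption:** 35 TFs × 100 genes, 30 samples, 60%
  true orthology plus fp_rate = 2/3 (≈40% of constraints false), a at the
  60th percentile, λ = 2λ_S with λ_S = 1. Outcomes: unfusing rate by
  constraint truth; MSE of the incorrectly fused subnetwork, adaptive vs
  fused-L2.
* **TFA:** 5 TFs × 150 genes × 30 steady-state conditions; latent activities
  drive targets, measured TF mRNA is activity + N(0, 1) noise; activities
  re-estimated from half of the true signed edges. The network is sparse
  (edge probability 0.2) and each TF retains ~15 prior targets — the
  identifiability conditions network component analysis needs; with dense
  regulator overlap or few targets the sign-only pseudoinverse mixes
  activities and the advantage degrades.

## Numerical choices, degenerate inputs, limitations

* Ties: CV-error ties resolve to the heavier penalty; ranking ties resolve
  lexicographically for deterministic, diffable output.
* Degenerate inputs rejected with messages: zero usable conditions,
  non-positive Δt, unknown predecessor, missing expression values, empty gold
  standard at evaluation, empty constraint set for a-selection, fewer rows
  than folds, single-fold CV, false-positive counts exceeding the unpaired
  pool.
* Constant predictor columns are centered, flagged, and left unscaled.
* A zero-residual response with nonzero β floors σ² at 1e-12 and flags the
  score matrix.
* λ_S selection with no constraints warns and returns the grid minimum.
* When fits are under-determined, CV can legitimately prefer λ_S > 0 even for
  entirely false constraints — fusing two coefficients whose true values are
  both zero is extra shrinkage. The all-false-constraint selection test
  therefore runs in a well-determined regime (20 rows vs 4 predictors); in
  the under-determined regime the preference for fusion is a property of the
  estimator, not a defect.
* The λ_S → ∞ limit with complete one-to-one fusion equals ridge on the
  pooled (stacked) data with penalty 2λ_R, since each source retains its own
  ridge term.
* Per-gene decay rates, L1/elastic-net variants, sign-aware evaluation,
  bootstrap bands on PR curves, and orthology computation from sequence are
  out of scope.
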