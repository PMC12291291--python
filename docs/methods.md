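# Methods

This note documents the models and procedures implemented in `cregulon`,
the numerical choices behind them, and what the built-in benchmark does and
does not establish.

## From counts to regulatory networks

The upstream stage (`cregulon.grn`) is optional: the core model consumes
per-cluster TF×TG strength matrices from any source. When raw counts are
supplied, cells of one cluster are merged into counts-per-million
pseudo-bulk profiles, PEᵢ for genes and POᵣ for ATAC peaks. Peaks with
PO ≥ 2 CPM (configurable `accessibility_threshold`) are the candidate
regulatory elements; the trans-regulatory score is

    R_ij = (Σ_r B_ir · PO_r · I_rj) · 2^|D_ij| · sqrt(PE_i · PE_j)

with the sum restricted to accessible REs (an `accessible_only=False`
switch removes the restriction; with it the openness of silent chromatin
would leak into every score, so the restricted form is the default). The
motif-binding prior B, RE–TG interaction prior I and TF–TG correlation
prior D are plain user-supplied tables; learning them is out of scope.
Genes with zero pseudo-bulk expression produce exactly zero rows/columns of
R (no pseudocount — the square-root factor annihilates them), which is the
behaviour the formula itself dictates.

## Combinatorial effect

Co-regulation of a TF pair is scored by the connection specificity index of
the Pearson correlations between TF rows of R:

    CSI_ij = #{l : PCC_il ≤ PCC_ij − ε and PCC_jl ≤ PCC_ij − ε} / M,  ε = 0.05.

The count runs over all M TFs including i and j; with unit diagonal those
self terms essentially never satisfy the margin, and this convention is
what the /M normalisation implies. TFs with constant regulatory profiles
have undefined correlations; these are set to 0 with a warning rather than
propagating NaNs. Cluster-specific activity is the expression specificity
index ESI = clamp₀¹(mean_in/mean_out − 0.5); a zero out-of-cluster mean is
floored at 10⁻⁶ of the global mean so a TF expressed only inside the
cluster clamps to 1 instead of dividing by zero. The combinatorial effect
is C = CSI ∘ (ESI ESIᵀ).

**The diagonal of C is kept.** C_ii = CSI_ii·ESI_i² is not a meaningful
"self-combination", but the decomposition below fits C ≈ X A Xᵀ whose
diagonal carries each TF's module scale. Zeroing the diagonal of C while
fitting it in the reconstruction provably biases the per-cluster
associations toward the extremes (a planted 0.9/0.1 cluster is recovered as
0.96/0.04 and 0.05/0.95 collapses to 0/1 on noiseless planted instances,
where the diagonal-kept fit recovers the planted weights to three
decimals). Self-pairs are excluded downstream where pairs are reported.

## Joint module decomposition

The K combinatorial-effect matrices are decomposed as Cᵏ ≈ X Aₖ Xᵀ with a
shared non-negative loading matrix X (M×L, column 2-norms ≤ 1, row sums
≤ 1) and per-cluster diagonal Aₖ ≥ 0 with Σₗ Aₖₗ = 1, minimising

    Σ_k ‖Cᵏ − X Aₖ Xᵀ‖²_F − μ ‖Cᵏ ∘ (X Aₖ Xᵀ)‖₁ .

The reward term concentrates the modules on TF pairs with large
combinatorial effect. Its weight μ is calibrated once so that both terms
balance at the initial factorisation:

    μ = Σ_k ‖Cᵏ − X⁰Aₖ⁰X⁰ᵀ‖²_F / Σ_k ⟨Cᵏ, X⁰Aₖ⁰X⁰ᵀ⟩ ,

with a μ = 0 fallback (and warning) when the denominator vanishes.

**Initialisation.** X⁰ comes from a damped multiplicative symmetric NMF of
the mean matrix C⁰ = (Σₖ Cᵏ)/K (rule X ← X ∘ (½ + ½ (C⁰X)/(XXᵀX)), 500
iterations from a seeded uniform start), capped onto the constraint set;
Aₖ⁰ is uniform (1/L). Because the objective is non-convex and the problem
at small M has competing local optima (a single dense column plus
singletons can reconstruct nearly as well as the true blocks), the fit
restarts from five seeded initialisations and keeps the solution with the
smallest objective; μ is shared across restarts so their objectives are
comparable. Everything is driven by one integer seed and is bitwise
reproducible.

**Iteration.** Multiplicative updates

    X  ← X ∘ [(4 + 2μ) Σ_k Cᵏ X Aₖ] / [Σ_k 4 X Aₖ Xᵀ X Aₖ]
    Aₖ ← Aₖ ∘ diag[(1 + μ) Xᵀ Cᵏ X] / diag[Xᵀ X Aₖ Xᵀ X]

with denominators floored at 10⁻¹⁰, stopping when the relative objective
change drops below 10⁻⁴ (default) or after 1000 iterations. The iterates
are deliberately **not** projected onto the constraint set inside the loop:
the X rule's fixed point overshoots the reconstruction scale by a factor
(1 + μ/2), so clamping the column norms every sweep converts that steady
inflation into a winner-take-all sharpening of each column (empirically the
association weights drift from correct values to degenerate 0/1 within ~40
sweeps). Instead a single projection is applied at convergence: column
norms are absorbed into the Aₖ (which leaves every reconstruction
unchanged), the A rows are renormalised to convex weights with a
compensating shared column scale (capped at 1) so the renormalisation is as
reconstruction-neutral as the constraints allow, and rows of X with sum
above 1 are scaled down. All constraints hold exactly (to 10⁻⁸) on the
returned factors. No per-iteration descent guarantee exists for these
updates (the reward term sees to that); the recorded loss trace lets users
check the behaviour, and the returned objective never exceeded the initial
one on any test instance.

**Choosing L.** `select_n_modules` fits each candidate L and applies an
elbow rule — the smallest L whose relative loss decrease to the next
candidate is at most 0.05 — to the final Frobenius reconstruction errors.
The reconstruction error, not the full objective, is compared because μ is
recalibrated for each L, which makes the full objectives incomparable (and
negative). At benchmark scale (M = 5) the elbow is not reliable — a third
module often reconstructs the 5×5 matrices slightly better — so the
benchmark and its acceptance checks fix L = 2 explicitly.

## Extracting discrete cRegulons

Pair effects CE_ij = X_il·X_jl of module l are tested against a Gamma null
fitted (maximum likelihood, location 0; method-of-moments fallback) to the
module's strictly positive upper-triangle CE values; pairs with upper-tail
p ≤ 0.05 form the module's TF pairs, and their union ordered by loading is
the module TF set. This calibration needs what real data provides: a large
bulk of near-zero pair effects against which the module pairs are extreme.
At M = 5 (10 pairs) no Gamma fit can flag three near-equal within-module
pairs, so the benchmark reports module membership by matching fitted
columns to planted modules (via each module's exclusive TFs) and taking the
top TFs by loading at the planted module size — the standard
benchmark-against-known-truth evaluation. Per cluster, TF–TG edges are
scored by the rank-1 projection S = Xₗ(XₗᵀRᵏ), restricted to module TFs and
the TGs they regulate (R_ij > 0); a Gaussian fitted to those scores keeps
edges with upper-tail p ≤ 0.01 (constant scores select nothing). REs are
joined per selected edge from the TF–RE–TG triplets; an RE used by two or
more module TFs on the same TG is flagged co-bound. Both nulls are fitted
per module and per cluster, not pooled.

## Annotation

Cluster annotation is the fitted A itself; thresholds 0.01 ("relevant") and
0.1 ("strong") are exposed on `AnnotationResult`. A cell with expression e
over a cluster's TGs scores e·Rᵀ·X; scores are normalised to sum 1 by
default since they are compared across modules (the flag is recorded). A
cell group with cluster proportions p scores p·A. Association-plot
geometry: U = A U′ when module coordinates are given, U′ = A⁺U (least
squares via pseudo-inverse, minimum-norm with a warning when A is
rank-deficient) when cell-type coordinates come from an external embedding.
Edges are drawn at score ≥ 0.02 by default (configurable; 0.1 is the
stricter published convention).

## Comparative statistics

The transition score between modules i and j averages module i's TFs'
loadings in column j (forward) and vice versa (backward), blended 0.5/0.5.
The differential degree of a module between two cell groups is
(max − min)·(max/min) of its two annotation scores, with the minimum
floored at 10⁻⁴ to keep the degree finite. Significance comes from
permutation backgrounds: N (default 50) random re-divisions of the pooled
cells into the observed group sizes give per-module means and SDs, a
Z-score, a two-sided normal p and Benjamini–Hochberg FDR. The time-point
change test re-divides the pooled cells into disjoint pseudo-groups of the
observed sizes (overlapping draws would correlate the pseudo-groups and
deflate the null, making the test anti-conservative) and reports the
fraction of n_perm = 10000 permuted changes strictly exceeding the observed
change. The normal approximation to a 20–50-sample background of a skewed
non-negative statistic is itself mildly anti-conservative per test; the
pooled rate of FDR < 0.05 calls under a homogeneous null stays at the
nominal level, which is what the calibration test asserts.

## Benchmark generator

`SimulationSpec` defaults encode the planted design: two modules over 5 TFs
and 10 TGs with TF3 shared; within-module strengths drawn U(0.8, 1) with
probability 0.8 and U(0, 0.2) otherwise, cross-module mirrored; three cell
types preserving module entries with probabilities (0.8, 0.2), (0.5, 0.5),
(0.2, 0.8) and redrawing the rest from U(0, 1); cross-module entries are
never perturbed (the perturbation loops only over within-module pairs).
Production rates are 0.6/0.4/0.5 for dominant/non-dominant/shared TFs (a
tied cell type gets 0.5 everywhere); 1000 cells per type.

Counts come from a built-in steady-state simulator: TF levels equal their
production rates (unit decay), TG levels are the R-weighted linear
activation of TF levels, each cell applies mean-preserving log-normal noise
(σ = 0.3) and Poisson sampling at library depth 50 (both configurable).
This emulates the mean structure and overdispersion that matter here — TF
specificity across cell types and TG levels that grow with regulatory
input — but not dropout, dynamic bursting kinetics, batch effects or
realistic library-size variation; passing benchmark tests therefore shows
pipeline correctness on data matching the model's assumptions, not
robustness to real single-cell noise. An external simulator can be plugged
in by passing its count matrix wherever `simulate_counts` output is used.

With per-entry sampling at the stated probabilities, roughly one seed in
ten draws a base network whose in-module profile for some TF is mostly
weak; recovery of that TF then rests on the residual loading ranking, which
the top-k matched membership captures.

## Known limitations

- The multiplicative updates have no descent proof; pathological inputs
  could in principle end above the initial objective (not observed).
- The Gamma pair test is uninformative below a few dozen TFs.
- The elbow rule for L is unreliable at very small M.
- Cell-level annotation uses the assigned cluster's network; for external
  cells the best-matching cluster (by correlation with pseudo-bulk) should
  be chosen by the caller.
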