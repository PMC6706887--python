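# Methods

`mrcps` implements a consensus stratification workflow for patient cohorts
with two transcriptomic platforms (a microarray-like and an RNA-seq-like
matrix over a shared gene-symbol set) and categorical clinical labels (INSS
stage, high/low risk) plus overall-survival endpoints.  This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Preprocessing

Both expression matrices are restricted to their shared gene symbols
(lexicographic order, for determinism) and standardized per gene across
samples (sample SD, `n−1` denominator).  Constant genes are removed rather
than divided by zero; gene rows with any missing value are dropped rather
than imputed; duplicate gene symbols keep the highest-variance row.  These
are common conventions, not statements about any particular dataset.

## Co-expression module mining (lmQCM)

Gene–gene edge weights are absolute Spearman correlations (average ranks at
ties).  An optional spectral-style normalization `W'_ij = W_ij /
sqrt(d_i d_j)` is provided (`normalize=True`); it is off by default.  On
small networks (hundreds of genes) the normalized weight scale varies
inversely with module size, so the relative seed gate described below
suppresses larger modules; on genome-scale networks, where background
degree dominates every gene's degree, the two settings behave similarly.

Mining parameters (defaults `gamma=0.80`, `lambda_=2`, `t_density=1`,
`beta=0.4`, `min_size=10`):

* **Seeding** — candidate seeds are edges whose weight reaches
  `gamma * w_max` and is a local maximum (no adjacent edge of either
  endpoint is strictly heavier), processed in descending weight order.
  `gamma` is the parameter that decides whether a module can be initiated.
* **Growth** — from a seed pair, the outside vertex `v` maximizing its
  total weight `w(v, C)` into the current cluster `C` is accepted while
  `w(v, C)/|C| ≥ α_d · d(C)` with the adaptive coefficient
  `α_d = 1 − 1/(2·lambda_·(|C| + t_density))` and `d(C)` the current mean
  pairwise weight.  The rule is scale-free: the threshold tracks the
  cluster's own density, while `α_d` tightens as the cluster grows.  Ties
  break toward the smallest gene index, making mining deterministic.
* **Filtering and merging** — modules below `min_size` are dropped; any
  two modules whose overlap ratio `|A∩B| / min(|A|,|B|)` exceeds `beta`
  are merged, iterating largest-first to a fixpoint so the final set has
  no residual overlap above `beta`.  Genes may belong to several modules.

## Eigengenes

Each module is summarized by the first principal component of its z-scored
submatrix (genes as variables, samples as observations), computed by SVD.
The component sign is arbitrary, so it is fixed by positive correlation
with the module's mean expression profile; the score vector is then
re-standardized to unit variance.  The explained-variance ratio of the
first component is recorded per module.

## Patient similarity

Both constructions start from a K-means clustering of patients in
eigengene space (`base_k` clusters, 20 restarts, fixed seed).

**Cluster-density affinity.**  Within each base cluster a Gaussian kernel
density is evaluated at every member,

    f(i) = 1/(N_i (2π h²)^{p/2}) · Σ_{j∈cluster(i)} exp(−‖x_i−x_j‖²/(2h²)),

and the affinity of two distinct same-cluster patients is `f(i)·f(j)`;
cross-cluster affinity is 0 and the diagonal is 1.  The kernel uses the
squared norm (the standard Gaussian form).  Bandwidth `h` defaults to
`"auto"`: Silverman's multivariate rule per cluster on the pooled
per-feature SD.  Because density products can be far from 1 depending on
`h` and the dimension `p`, off-diagonal values are rescaled by their
maximum into [0, 1] by default (`rescale=False` disables this) so that
geometric fusion and the consensus weighting operate on comparable scales.

**Scaled exponential kernel.**  `W(i,j) = exp(−d²(x_i,x_j)/(μ·ε_ij))` with
`ε_ij = [mean d(x_i, D(i)) + mean d(x_j, D(j)) + d(x_i,x_j)]/3`, where
`D(i)` is the cluster containing `i` and the mean excludes the self-point
(including it would only shrink the local scale).  `μ` defaults to 0.5,
the midpoint of the range commonly recommended for this kernel.

## Fusion

* **Geometric** — elementwise `sqrt(W1·W2)`; affinity survives only where
  both platforms place the pair in a shared cluster.
* **SNF** — both matrices are normalized (off-diagonal
  `W_ij/(2Σ_{k≠i}W_ik)`, diagonal 1/2, rows sum to 1) and cross-diffused
  through their K-nearest-neighbor local kernels
  (`S_ij = W_ij/(2Σ_{k∈N_i}W_ik)` on the K strongest neighbors, zero
  diagonal, rows sum to 1/2), re-normalizing and symmetrizing after each
  step; after `iters` steps the two matrices are averaged and symmetrized.
  Defaults `K = min(20, max(5, n/10))`, `iters = 20`, standard values in
  the fusion literature; re-normalization between steps is required for
  numerical stability of the recursion.  Ties at the K-th neighbor break
  by sample order.  Exactly two platforms are supported.

## Consensus stratification

Clinical partitions enter as 0/1 connectivity matrices `S^l`
(`S^l_ij = 1` iff same category).  Stage and risk are equally weighted
(`L = 2`).  The molecularly weighted consensus is
`S~L = (1/L) Σ_l S^l ∘ sqrt(W)` and a candidate partition `S` is scored by
`‖S~L − S ∘ sqrt(W)‖²_F`.  The optimizer:

1. spectral relaxation — top-`k` eigenvectors of `S~L`, rows normalized,
   K-means with 50 restarts and a fixed seed;
2. greedy single-sample reassignment on the exact objective, started from
   the spectral labels, from each clinical partition with ≤ k categories,
   and from seeded random restarts (20 when n ≤ 30, else 2);
3. for n ≤ 9, an exhaustive enumeration mode certifies the global optimum
   (used as an oracle in the tests).

**Plateau handling.**  The objective decomposes over connected components
of the affinity graph: pairs with `W_ij = 0` contribute nothing whichever
way they are grouped, so the placement of whole cluster fragments
(component × cluster intersections) across components is often exactly
objective-free, and would otherwise be an artifact of initialization that
the downstream model selection then overfits.  Free fragments are
therefore regrouped deterministically by the plain (unweighted) clinical
consensus `Σ_{i<j}(mean_l S^l_ij − S_ij)²`, under two guards: a move must
provably leave the weighted objective unchanged (|Δ| < 1e-12), and a
majority of fragment–destination pairs must be clinically co-grouped
(mean co-membership > 1/2).  The second guard stops a sliver of impure
pairs from merging two large molecular blocks about which the clinical
consensus is exactly indifferent (stage says split, risk says merge).

**Cluster number.**  For each `k` in `k_range` the optimized partition is
scored by `φ = Σ_u NMI(C_u, C_f)` over the base clusterings — the clinical
partitions plus one molecular base clustering (K-means on the concatenated
platform eigengenes, `k` chosen by silhouette).  NMI uses natural-log
entropies, `NMI = (H₁+H₂−H₁₂)/sqrt(H₁·H₂)`, defined as 0 when either
marginal entropy is 0.  The `k` maximizing `φ` wins; ties break toward
smaller `k`.

## Survival evaluation and the DE filter

Kaplan–Meier curves and the G-group log-rank test (χ² with G−1 degrees of
freedom) are computed with lifelines; tied event and censoring times follow
the standard convention (events first).  The differential-expression filter
takes a raw non-negative (FPKM-like) matrix, runs two-sided two-sample
t-tests on `log2(x+1)`, computes fold change on the raw scale with
pseudocount 1, adjusts p-values by Benjamini–Hochberg, and flags genes with
`FC ≥ 1.5` or `FC ≤ 1/1.5` and adjusted p < 0.001.  The magnitude rule is
two-sided by design; log base and pseudocount are documented defaults.

## Synthetic cohorts

The generator emulates the data structure the workflow assumes, so every
stage is testable without external data:

* planted modules `x_g = a_g·f_m + ε` with loadings `a_g ~ U[factor_loading, 1]`
  (positively co-expressed, matching the eigengene sign convention), factor
  `f_m = center(m, subgroup) + N(0,1)`, noise `ε ~ N(0, noise_sd²)`;
  background genes are pure `N(0,1)` noise.  Platform B reuses the shared
  genes' module structure with independently redrawn loadings and noise.
* subgroup centers form a regular simplex with pairwise distance
  `subgroup_separation` (default 5 within-subgroup factor SDs), randomly
  oriented in module space, so the nominal spacing — and hence subgroup
  separability in eigengene space — is guaranteed for every seed rather
  than realized on average.
* stage labels follow the subgroup (worst hazard → stage 4, then 3, 2, 1,
  4S) with mislabel probability `stage_confusion` (default 0.1); mislabels
  draw from the stage levels in use, so stage remains a noisy view of the
  subgroups rather than acquiring spurious categories.  Risk is high iff
  the subgroup hazard exceeds the median hazard.
* survival is Weibull with scale `1/hazard` (shape 1 = exponential,
  the default, chosen for tractability); censoring is independent
  `Uniform(0, M)` with `M` solved numerically so the expected censoring
  fraction matches `censor_rate`.

What the generator does **not** emulate: count noise (negative-binomial
RNA-seq), platform-specific probe effects, batch structure beyond what
z-scoring removes, overlapping planted modules, or covariate-dependent
censoring.  Passing tests therefore demonstrate correctness of the
algorithms under the stated latent-factor model, not performance on any
real cohort.

## Validation experiments and problem sizes

The experiments in `mrcps.validation` (run by the test suite and
`scripts/acceptance.py`) use sizes chosen to finish in minutes on one CPU:

* module recovery: 200 genes, 5 planted modules of 10–30 genes, 150
  patients, `factor_loading` 0.85, `noise_sd` 0.25, default miner;
* optimizer certification: 20 random 7-sample problems against exhaustive
  enumeration;
* cluster-number recovery: 10 cohorts of 120 patients, 150 genes, 4
  modules, 3 subgroups with hazards (0.08, 0.03, 0.01)/month, 20%
  censoring and `stage_confusion = 0` — the fully aligned regime this
  experiment is about (with 10% mislabels the method legitimately isolates
  the contradictory patients as extra small groups);
* log-rank calibration: 2000 equal-hazard replicates, 100 per group;
* DE filter: 4-fold shifts in 50 of 500 genes, 30 samples per group,
  5 seeds.

## Known limitations

* The Frobenius objective is blind to pairs with zero fused affinity; the
  canonicalization above makes the result deterministic but the grouping
  of molecularly disconnected blocks is decided by the clinical consensus
  and the NMI selection, not by the objective itself.
* The spectral optimizer is a relaxation; optimality is certified only for
  n ≤ 9 (exhaustive mode) and empirically on small random problems.
* The density affinity is exactly block-sparse on the base clustering, so
  its quality is bounded by the base K-means; the exponential kernel is
  dense and degrades more gracefully.
* `differential_expression` assumes approximate normality of log-values;
  it is a filter in the spirit of the workflow, not a replacement for
  count-based DE models.
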