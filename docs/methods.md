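# Methods

## Problem setting

Gut-microbiome case–control studies disagree with each other far more
than chance would allow: protocol, population and sequencing batch
effects dominate taxon abundances, so markers found by abundance
testing in one cohort routinely fail to replicate in the next.
Co-occurrence structure is more conserved than abundance. This package
therefore works at the level of taxon–taxon correlation networks: it
pools networks across studies in a way that is robust to study size
imbalance, and it identifies disease-associated taxa by how strongly
each taxon drives the re-organization of network *modules* between the
healthy and diseased states, rather than by abundance shifts.

## Network integration by inverse-variance weighting

Each study *i* contributes a correlation matrix estimated from its own
samples (Spearman by default; any externally estimated matrix can be
plugged in, since every downstream step consumes only a generic
correlation matrix). Studies are aligned on the union of taxa; a pair
absent from a study is filled with correlation 0 there.

For a given taxon pair with per-study correlations *r_i* from *n_i*
samples, the conditional deviation of *r_i* is the Hedges–Olkin
large-sample variance

    v_i = (1 − r_i²) / (n_i − 1),

and the pooled correlation is the inverse-variance weighted mean

    ρ = Σ w_i r_i / Σ w_i,   w_i = 1 / v_i.

Weights are computed per pair ("univariate" weighting): *r* varies
across pairs, so each co-abundance variable carries its own weights.
Large studies — whose correlations are individually weaker but better
estimated — dominate the pool, which is the intended correction for
size imbalance between cohorts. A study's *contribution* is its share
of the total off-diagonal weight mass; contributions sum to one and
grow monotonically with the study's sample size.

Numerical choices:

* at r = ±1 the raw deviation is 0 (infinite weight); it is floored at
  `EPS_V = 1e-12`, which keeps pooling finite while letting a perfect
  correlation dominate any finite-weight companion;
* a zero-filled pair still contributes its 0 with the weight of r = 0,
  i.e. n − 1, because the fill is part of the aligned co-abundance
  pattern (`skip_missing=True` excludes such pairs instead);
* per-study rather than per-pair weighting is not offered: the pooled
  estimate would then ignore that weak pairs are weak.

## Module-shift scoring

Given the pooled health matrix A = [c_ij] and disease matrix
A′ = [c′_ij] over the same taxa:

1. **Similarity.** s_ij = (1 + c_ij)/2 maps correlations to [0, 1].
2. **Soft threshold.** a_ij = s_ij^β suppresses weak similarities
   smoothly. β is chosen as in weighted gene co-expression analysis:
   the smallest candidate whose adjacency yields a scale-free topology
   fit R² ≥ 0.8 (log-frequency vs log-connectivity regression with a
   negative slope), with the best-fitting candidate as a warned
   fallback. One β, fit on the health matrix, is applied to both
   groups — fitting separately would confound module shift with
   threshold shift. On the simulator's dense, equal-connectivity
   matrices the scale-free criterion is degenerate (every node in a
   block has nearly the same connectivity, so the log–log regression
   is uninformative and the fallback is unstable); benchmark runs
   therefore fix β = 6, the standard convention for unsigned networks
   when the fit does not resolve.
3. **Topological overlap.** ω_ij = (l_ij + a_ij) / (min{k_i, k_j} + 1 −
   a_ij), with l_ij = Σ_u a_iu a_uj and k_i = Σ_u a_iu, measures shared
   neighborhoods; d_ij = 1 − ω_ij is the distance. A fully isolated
   pair (k_i = k_j = 0, a_ij = 0) gets ω = 0, the formula's limit.
4. **Modules.** Average-linkage hierarchical clustering of d, cut at
   0.99 of the maximum merge height. Clusters below `min_module_size`
   (default 5 — smaller modules are unstable under the TOM transform)
   are merged into their nearest cluster by mean inter-cluster
   distance, smallest first, ties to the lowest label; a dendrogram
   whose merge heights are all equal carries no structure and yields a
   single module. The procedure is fully deterministic.
5. **Intersection modules.** Crossing the health partition (n modules)
   with the disease partition (m modules) yields K ≤ nm nonempty cells
   — the units that remain identifiable across states. The N×K
   matrices D_mod and D′_mod hold each node's mean TOM distance to each
   cell in each state (excluding the node itself; a singleton own-cell
   contributes 0), and ΔD = D′_mod − D_mod.
6. **Score.** For node i, NeighborsA(i) are the cells inside i's
   health-network module and NeighborsB(i) the cells inside its
   disease-network module, each excluding i's own cell, and

       NMSS(i) = Σ_{j ∈ NeighborsA(i)} ΔD_ij − Σ_{l ∈ NeighborsB(i)} ΔD_il.

   A node that migrates moves away from its old neighborhood (ΔD > 0
   on the A side) and towards its new one (ΔD < 0 on the B side), so
   both terms push the score up; a stable node scores near zero.
   Reported scores are |NMSS| min–max normalized to [0, 1] per run.

Two symmetries worth knowing: swapping the two *distance matrices*
negates NMSS exactly (ΔD antisymmetry), while exchanging the *group
labels* of a whole run swaps the neighbor roles along with ΔD's sign
and leaves each node's score magnitude invariant — the driving force
of a transition is the same seen from either end. The neighbor
definition ("cells sharing the node's parent module") is one of two
defensible readings; the complementary one ("cells outside the parent
module") is available via `neighbor_mode="other_modules"` and flips
signs without changing magnitudes in the two-module case.

## The simulator

`simulate` builds ground-truthed benchmark pairs:

* **Blocks.** Module k is Σ_k = ρ_k(U_kᵀU_k) + (1 − ρ_k)I, where U_k
  holds g_k random unit vectors from R^{M_k}. Vectors are drawn from
  the positive orthant of the sphere, so within-module correlations
  are positive (cooperative), bounded by ρ_k, with spread controlled
  by M_k (M_k = 1 gives exactly ρ_k everywhere). Sign-mixed blocks —
  the sphere-uniform alternative — do not behave as modules under the
  TOM transform and are not what a cooperative guild looks like.
  Blocks sit on the diagonal of an N×N matrix, zeros outside,
  eigenvalue-clipped and rescaled to the nearest valid correlation
  matrix (PSD repair, floor 1e-8).
* **Perturbation.** Submodule rows of the source module receive noise
  rows ε_k·(uᵀu) with ε_k linear between `noise_min` and `noise_max`
  (graded disturbance: weakly and strongly hit submodules coexist, so
  some migrations sit near the detection limit). A migrating submodule
  applies its noise *directionally* — ties to the remaining source
  members weakened, ties to every target member strengthened — which
  is what plants the ground truth; a non-migrating submodule applies
  the same magnitudes with random signs, a disturbance that moves it
  nowhere. The result is clipped to [−1, 1] and PSD-repaired.
* **Defaults** mirror the benchmark scale: 120 taxa, modules of 80
  (target) and 40 (source, one taxon per submodule), ρ = 0.8, M = 5,
  30 of 40 submodules migrating (fraction 0.75), noise band 0.2–0.8
  with span m = 10. At the top of that band the per-tie shift
  (≈ 0.64·ε) is commensurate with the within-module tie strength
  (≈ 0.5), i.e. "moderate" noise: strong enough that migration is
  well defined, not so strong that ties saturate at the clip bound.
* **Abundance sampling.** `sample_abundances` draws logistic-normal
  compositions (multivariate normal with the target correlation,
  exponentiated, renormalized per sample) for end-to-end tests from
  abundance tables. Compositional closure induces a small negative
  bias of order −1/(N−1) in empirical correlations, which the tests
  account for by using enough taxa.

What the simulator does *not* emulate: read counts and sequencing
error, zero inflation, compositional estimation artifacts beyond the
closure of the sampler, taxon-abundance shifts (migration changes
correlation structure only), and between-study protocol heterogeneity
beyond sample-size imbalance. Passing benchmarks therefore demonstrate
that the scorer recovers coherent correlation-structure shifts at
realistic module scales — not that any particular real cohort is free
of confounding.

## Benchmarking

The sensitivity/specificity sweep takes every unique score as a
candidate threshold (prediction: score ≥ t) and picks the threshold
minimizing |sensitivity − specificity| — the intersection point of the
two curves — with ties resolved to the lower threshold. AUC is the
rank-based Mann–Whitney statistic with midrank ties. The Jaccard Edge
Index baseline compares each node's thresholded neighbor sets
(|corr| ≥ 0.3 by default) between the two networks; its change score
is 1 − JEI. Evaluation is restricted to the disturbed submodules —
positives are the migrated ones, negatives the disturbed-but-
stationary ones — matching how the planted design defines ground
truth.

The noise sweep scales the whole graded band (ε_1 = ε_r/4) and runs
replicate simulate–perturb–score cycles per level, with per-replicate
seeds derived from a master seed by a fixed counter scheme. The
default grid ε_r ∈ {0.4, 0.6, 0.8, 1.0, 1.5, 2.0} spans sub-signal
(0.4: shifts too small to flip membership) through the favorable
regime (0.6–1.5) to saturation (2.0). Beyond saturation the AUC may
stay flat rather than fall: the scorer keys on *coherent* module
shift, and incoherent saturation of stationary rows neither helps nor
outranks it — the property asserted is that more noise does not keep
improving detection.

`scripts/acceptance.py` recomputes the two headline numbers from
scratch at 120-taxon scale (seconds of runtime): the mean recall of
migrated submodules at the intersection threshold over 20 seeds of the
default benchmark, and the grand mean AUC over 10 replicates at each
favorable noise level.

## Known limitations

* Module detection uses a fixed-height dendrogram cut with small-
  cluster merging, not the full dynamic tree cut; very nested module
  structures may be split differently than WGCNA would split them.
* The scale-free β fit needs a broad connectivity distribution; on
  near-regular graphs it falls back (with a warning) and a manual β is
  preferable.
* Scores are min–max normalized per run, so they are comparable within
  a run but not across runs with different taxon sets.
* When migration is strong, the disease network's modules can merge
  into one; scoring still separates migrated from stationary
  submodules, but module labels themselves become uninformative in
  that state.
* The integration weights assume correlations are estimated
  independently per study and that n_i is the effective sample size;
  repeated measures within a study would overstate its weight.
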