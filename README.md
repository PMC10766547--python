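# netmoss

Batch-effect-robust integration of microbial co-occurrence networks and
**NetMoss** module-shift scoring of disease-associated taxa.

Abundance-based biomarker discovery in gut-microbiome case–control
studies replicates poorly: between-study batch effects (protocol,
population, sequencing) swamp the abundance signal. Co-occurrence
structure is more stable. This package

1. **integrates** per-study taxon–taxon correlation networks into one
   network per group (case/control) with inverse-variance
   ("univariate") weights — per taxon pair, study *i* contributes its
   correlation *r_i* with weight *w_i* = (n_i − 1)/(1 − r_i²), so
   large cohorts dominate and size imbalance stops biasing the pool:

   ρ = Σ w_i r_i / Σ w_i

2. **scores** each taxon's contribution to the health→disease shift of
   network modules. Correlations are mapped to similarities
   s = (1 + c)/2, soft-thresholded (a = s^β), turned into a
   topological-overlap distance d = 1 − ω with
   ω_ij = (l_ij + a_ij)/(min{k_i, k_j} + 1 − a_ij), and clustered into
   modules per state. Crossing the two partitions gives K intersection
   modules; with ΔD the per-node change in mean distance to each
   intersection module, the NetMoss score of node i is

   NMSS(i) = Σ_{j ∈ NeighborsA(i)} ΔD_ij − Σ_{l ∈ NeighborsB(i)} ΔD_il

   (A = health-side neighboring modules, B = disease-side). Taxa that
   migrate between modules — moving away from their old neighborhood
   and towards a new one — take the largest scores.

3. **benchmarks** scorers on a block-modular correlation simulator
   with planted submodule migrations and graded noise, reporting
   sensitivity/specificity curves, the intersection-point threshold,
   and rank-based AUC, with the Jaccard Edge Index as baseline.

For whom: microbiome researchers doing cross-study meta-analysis of
co-occurrence networks, and methods researchers who need a
ground-truthed simulator for network-shift detection.
See `docs/methods.md` for the full model description and assumptions.

## Worked example

Simulate the default two-module benchmark (120 taxa; 30 of the 40
source-module submodules migrate to the 80-taxon target module under
graded noise) and score the transition:

```python
import warnings
from netmoss import SimulationSpec, simulate_pair, run_netmoss_from_matrices
from netmoss.evaluate import benchmark_pair

pair = simulate_pair(SimulationSpec(seed=7))
result = run_netmoss_from_matrices(
    pair.control_network(), pair.case_network(), beta=6
)
print(result.to_frame().sort_values("score", ascending=False).head(5).round(3))

report = benchmark_pair(pair)
print(f"AUC over the 40 disturbed submodules: {report.auc:.3f}")
print(f"intersection threshold: {report.best_threshold:.3f}")
print(f"recall of migrated submodules at that threshold: {report.sensitivity_at_best:.3f}")
```

prints

```
           raw_score  score  module_health  module_disease
taxon
taxon_116      0.104  1.000              1               0
taxon_120      0.101  0.959              1               0
taxon_112      0.099  0.914              1               0
taxon_115      0.098  0.907              1               0
taxon_111      0.096  0.872              1               0

AUC over the 40 disturbed submodules: 0.923
intersection threshold: 0.211
recall of migrated submodules at that threshold: 0.833
```

The five top-scoring taxa sit in the source module in the health
partition (`module_health = 1`) and in the target module in the
disease partition (`module_disease = 0`) — they migrated, and all five
are in the planted migrated set. `score` is |NMSS| min–max normalized
to [0, 1]; the intersection threshold 0.211 is where the sensitivity
and specificity curves cross, and flagging scores above it recovers
83% of the truly migrated submodules in this single pair.

The same pipeline runs from the shell:

```sh
netmoss simulate control.tsv case.tsv truth.txt --seed 7
netmoss score --case case.tsv --control control.tsv --beta 6 -o scores.tsv
netmoss benchmark --reps 10 --seed 0 -o report.tsv
```

Real data enter through `read_abundance_table` / `netmoss filter`
(prevalence–abundance filtering at 0.1% in ≥10% of samples, the field's
usual rule), `netmoss build` (Spearman by default, or any plugin
estimator), and `netmoss integrate` with a study-size metadata table.

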