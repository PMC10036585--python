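# braindyn

Dynamic community structure of multilayer temporal brain networks.

Resting-state fMRI parcellated into N regions yields one signal per region.
A static correlation network averages away how the brain's community
structure reorganises over a scan. This package implements the multilayer
temporal-network alternative for two-group (patient vs control) studies:
sliding-window functional connectivity, multilayer modularity maximisation,
module-allegiance metrics of dynamic reconfiguration, a flexibility-ranked
core–periphery division, and the group-statistics layer — plus a
synthetic-cohort generator with planted, time-varying modular structure so
the whole pipeline can be validated against a known ground truth.

## The model

Each sliding window (length *w*, step *s*) gives one layer: the pairwise
Pearson correlation matrix A<sup>l</sup> of the windowed signals (diagonal
zeroed, negative weights zeroed by default). Layers are coupled ordinally —
node *j* in layer *l* is linked to itself in layers *l* ± 1 with weight ω.
A community assignment g assigns every node-layer (i, l) a label; its
quality is the multilayer modularity

Q = (1/2μ) Σ<sub>ijlr</sub> [ (A<sub>ijl</sub> − γ k<sub>il</sub>k<sub>jl</sub>/(2m<sub>l</sub>)) δ<sub>lr</sub> + δ<sub>ij</sub> ω<sub>jlr</sub> ] δ(g<sub>il</sub>, g<sub>jr</sub>)

with the Newman–Girvan null model within each layer (k = intralayer
strength, m<sub>l</sub> = layer weight), structural resolution γ, and
μ = ½ Σ k<sub>jr</sub> the total node-layer strength. Q is maximised by a
seeded generalized Louvain heuristic (greedy node-layer moves, community
aggregation, repeat); because the landscape is degenerate, an ensemble of
independently seeded runs (default 50) is kept and metrics are averaged
over runs.

From the ensemble:

- **module allegiance** P<sub>ij</sub> — fraction of (run, layer) pairs in
  which i and j share a community;
- **recruitment** — mean allegiance of a node to its own functional
  system; **integration** — mean allegiance to nodes outside its system;
- **flexibility** — fraction of adjacent-layer transitions at which a
  node changes community; **promiscuity** — fraction of all communities
  (beyond its first) a node ever joins;
- **core–periphery** — the k least / most flexible nodes per group.

Group differences use pooled-variance t tests with Benjamini–Hochberg FDR
per analysis family; symptom correlations are Pearson within the case
group; study power comes from the noncentral t distribution.

## Worked example

The `analysis/` scripts run a complete desk-scale study on a synthetic
cohort (10 subjects per group, 20 regions in 4 systems, 120 samples; the
case group's planted partitions switch at 6 per 100 samples vs 2 for
controls; run them in order from `analysis/`):

```
$ python 01_simulate.py
wrote 20 subjects to .../scratch/study/cohort
mean planted switches: case 7.1, control 2.9 (rates 6.0 vs 2.0 per 100 samples)

$ python 02_detect_communities.py
20 subjects, 26 layers each, 10-run ensembles
         mean_Q  mean_quantity
group
case     0.4677           3.86
control  0.4676           4.21

$ python 03_compute_metrics.py   # node/system metric tables

$ python 04_group_stats.py
community quality: t(18) = 0.002, P(FDR) = 0.9982
0 significant metric comparisons after FDR (none)
core overlap between groups: 2/3; periphery overlap: 3/3
symptom correlation at ROI_011 (flexibility): r = 0.5644, P = 0.0892, n = 10
```

Reading the numbers: both groups decompose into about four communities
with modularity Q ≈ 0.47; case-group integration and flexibility run
higher (see `results/study/system_metrics_group_means.tsv`), in the
direction of the planted faster switching, but with 10 subjects per group
no single comparison survives FDR — the directional effect is established
by the seeded replicate test in the suite, not by one small cohort. The
symptom score was generated from planted flexibility at ROI_011, and the
pipeline recovers a positive correlation there. All tables land in
`results/study/`.

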