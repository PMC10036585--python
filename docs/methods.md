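# Methods

## Model and procedure

The pipeline treats a subject's parcellated resting-state recording as a
temporal multilayer network. Overlapping sliding windows (default 50
samples, step 1; at a 2 s sampling interval that is a 100 s window, and a
190-sample series yields 141 layers) each produce one intralayer network:
the pairwise Pearson correlation of the windowed regional signals with
zeroed diagonal. The same node in adjacent layers is coupled with a
uniform weight ω (ordinal coupling), giving a supra-adjacency matrix with
the correlation matrices on the diagonal blocks and ω·I on the first
off-diagonal blocks.

Community structure is scored by multilayer modularity with the
Newman–Girvan null model per layer and resolution parameters γ (structural)
and ω (temporal), both defaulting to 1. The normalisation μ is half the
total node-layer strength, counting both intralayer strength and interlayer
coupling strength; self-pairs i = j are included in the null term. The
interlayer indicator is read as δ_ij — the coupling term rewards the *same
node* keeping its community across adjacent layers — which is the standard
multilayer form and the only reading consistent with a per-node interlayer
strength.

Maximisation is a generalized Louvain heuristic over node-layer tuples:
greedy single-node moves (a move's gain is the sum of supra-modularity
weights into the target community; a fresh singleton community is always a
candidate, which matters when every attachment is negative), then
aggregation of communities into super-nodes preserving the weight
structure, repeated until no move improves Q. The attained Q is recomputed
from the final labels through the independent evaluator, so the reported
value never drifts from the labels.

The modularity landscape is highly degenerate, so each subject is run as
an ensemble (default 50 runs) with consecutive seeds. Sweep order and
tie-breaks among equal-gain moves are drawn from the run's own RNG: runs
are bit-reproducible given their seed, and the ensemble explores distinct
optima. Metrics — not partitions — are averaged over runs: allegiance is
accumulated jointly over runs and layers; flexibility and promiscuity are
computed per run and averaged (mean of ratios; the alternative,
ratio of means, is numerically close but less standard as a per-run
statistic). Per-subject Q is likewise the ensemble mean.

Integration is implemented as the mean allegiance to nodes *outside* the
node's system, normalised by N − n_S. A variant that sums within the
system under the same normaliser exists behind `as_printed=True` for
audit, but it contradicts the metric's meaning (between-system alliance)
and is not used anywhere in the pipeline. Allegiance's diagonal is fixed
at 1 (a node is always with itself), which contributes the self-term to
recruitment. Promiscuity of a single-community assignment is defined as 0
(the limit of "participates in only one community"). Flexibility divides
the per-node change count by L − 1, the number of adjacent-layer
transitions.

Statistics: continuous metrics are screened with a one-sample
Kolmogorov–Smirnov test against a normal with estimated mean/SD (the
estimated-parameter caveat applies: asymptotic p-values are
anti-conservative; the test is used as a screen, not an inferential
endpoint). Group comparisons use the pooled-variance Student t
(df = n1 + n2 − 2, matching the conventional df reporting for two groups
of 34 and 35), categorical contrasts a Pearson chi-square without
continuity correction, and multiple comparisons are corrected by
Benjamini–Hochberg *within each analysis family*: the community-level
pair, each metric's system-level set, and each metric's node-level set.
Symptom correlations are Pearson within the case group only (the severity
score exists only for patients). Power for the two-tailed two-sample t is
computed from the noncentral t distribution; at d = 0.6, n = 34/35,
α = 0.05 it is 0.690.

## Synthetic cohorts

The generator emulates a two-group resting-state study as a
piecewise-stationary Gaussian process. A small set of planted partitions
is drawn once per cohort: state 0 equals the emitted region→system blocks;
each further state reassigns a fraction of regions (default 0.3, always
including the symptom-linked region) to other communities. Each subject's
hidden state sequence starts in state 0 and switches per sample with
probability rate/100 (memoryless Bernoulli switching; rates default to 2
per 100 samples for controls and 6 for cases) to a uniformly drawn other
state. Within a segment, samples are drawn with a block-constant
correlation matrix — 0.8 within planted communities, 0.1 across, unit
variances — and independent N(0, 0.25) noise (noise_sd 0.5) is added.
That correlation family is positive semidefinite whenever
0 ≤ between ≤ within ≤ 1; an eigenvalue-clipping repair (tolerance 1e-8)
covers the singular boundary. Per-subject seeds are spec.seed + subject
index, controls first.

Case-group symptom scores are 1 + 150·(planted flexibility at the linked
region) + N(0, symptom_noise_sd²), clipped to the 1–23 range of a clinical
severity scale; the slope puts typical scores mid-scale (≈ 8.5 at a
planted flexibility of 0.05). Controls carry no score.

What the generator does *not* emulate: hemodynamics, scanner and motion
artefacts, spatial autocorrelation between neighbouring parcels, and
heavy-tailed or nonstationary noise. Passing tests therefore demonstrate
that the pipeline recovers planted covariance-defined community dynamics,
not that it is robust to fMRI preprocessing choices.

A structural caveat found while validating: planted per-node flexibility
is defined by partition-id changes, and detected flexibility by label
continuity, which the ω coupling anchors to each community's persisting
core. When a perturbation reassigns close to half of a community, the
core is no longer a majority, community identity across a switch becomes
ambiguous, and the two notions decouple (the across-node correlation
between planted and detected flexibility can even invert). Recovery
checks therefore use modest reassignment fractions (≤ 0.3), and the
switching timescale is kept longer than the window so that most layers
are stationary.

## Numerical choices

- Negative correlations are zeroed by default (the Newman–Girvan null
  presumes nonnegative weights); `abs` and `keep` are available and the
  choice is recorded in the run manifest.
- No Fisher z-transform is applied before community detection.
- Louvain move tolerance 1e-10; ties among gains within 1e-12 broken
  uniformly at random from the run's RNG; at most 100 aggregation rounds
  (safety valve, warned).
- Zero-weight layers contribute no intralayer term and raise a warning;
  a network with μ = 0 is rejected.
- Core–periphery ties at the cut are broken by region index with a
  warning.
- Degenerate group comparisons (zero pooled variance) are reported as
  t = 0, p = 1 when the constant groups coincide rather than erroring the
  whole pipeline.
- Windows are half-open, 0-based sample ranges internally; exports number
  windows and layers from 1.

## Problem sizes

The bundled study (analysis/) and the validation suite run at desk scale,
chosen so planted effects are detectable with comfortable margins: 10
subjects per group, 20 regions in 4 systems, 120–240 samples, 20-sample
windows stepped by 4, 3–10-run ensembles. The full-scale operating point
(90 regions, 190 samples, 141 layers, 50 runs) is the default of
`PipelineConfig` and `CohortSpec` and runs the same code paths; nothing in
the implementation depends on the reduced sizes. Exhaustive-enumeration
optimality checks cap the community count at 4 (the cap can only lower
the enumerated optimum, so optimality bounds proven against it are
conservative).

## Known limitations

- Ensemble averaging of metrics does not produce a consensus partition;
  questions about *which* communities exist are answered per run.
- Flexibility depends on label continuity and hence on ω; with ω = 0
  layer labels are independent and flexibility is not meaningful.
- The KS screen is not a gate: the pipeline always applies t tests, as
  the reference analysis did, rather than branching to nonparametrics.
- Group-level core–periphery sets are descriptive; no inferential test is
  attached to their overlap.
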