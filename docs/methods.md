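# Methods

## Pipeline

Per subject, each run (frames × ROI matrix) is globally z-scored using the
pooled mean and sample SD of *all* its entries (for the default geometry,
146 × 62 = 9052 values), not per column: global normalization preserves
between-region amplitude differences within a run while equating runs. The
frames of one task condition (default the self-initiated movement
condition, "SI") are then extracted; within each contiguous same-condition
block the first `ceil(trim/TR)` frames are dropped to let the hemodynamic
response settle (default 10 s at TR 3.5 s → 3 frames), and the survivors are
concatenated across blocks and runs. A block shorter than the trim
contributes nothing and is logged, not raised.

From the concatenated matrix, Pearson correlations between all node pairs
form a symmetric matrix with unit diagonal. Thresholding at wiring cost *c*
retains the `K = round(c·N(N−1)/2)` pairs with the largest **signed**
correlation (half-away-from-zero rounding; ties at the cutoff broken by
lexicographic node-pair order). Signed rather than absolute ranking means
anticorrelations never become edges — consistent with the positive minimal
correlation ratios such networks report. The weakest retained correlation is
kept as metadata. Group networks retain edges present in strictly more than
half of a group's subjects (support ≥ ⌊n/2⌋+1).

## Graph metrics and null models

Distances are unweighted shortest paths, computed by parallel breadth-first
search over boolean matrix products; unreachable pairs are NaN in the
distance table and contribute 0 to global efficiency (Latora–Marchiori
convention), which keeps low-cost fragmented graphs well-defined. Local
efficiency is the mean over nodes of the global efficiency of each node's
neighbour subgraph; nodes with fewer than two neighbours contribute 0.

Null models per cost: (a) degree-preserving randomization by double edge
swaps, targeting 10 successful swaps per edge within a bounded attempt
budget — when no valid swap exists (a star graph) the best-effort graph is
returned with the shortfall recorded rather than raising; (b) a
deterministic ring lattice filled in increasing neighbour-offset order until
the edge budget is met. Defaults: 20 random realizations per cost and a cost
grid of 0.01–0.50 in steps of 0.005; both are parameters and the acceptance
script uses a coarser grid (0.05–0.49, step 0.02) with 4 realizations to fit
its runtime envelope — grid resolution, not grid coverage, is what changes.

The small-world range is the maximal contiguous grid interval where
E_glob(random) > E_glob(observed) > E_glob(lattice) and
E_loc(observed) > E_loc(random); an empty range is signalled as `None`, never
silently as a degenerate interval. The cost-efficiency peak is found by
shape-preserving piecewise-cubic Hermite (PCHIP) interpolation of the
group-averaged CE curve on a 0.001-step grid — PCHIP neither overshoots nor
invents extrema, which is the property needed when "smoothing" a concave
efficiency profile; argmax ties resolve to the smallest cost.

## Group statistics

Edge-wise comparisons use Fisher-transformed correlations (z = atanh r). The
default two-sample test is the pooled-variance Student t (a config switch
enables Welch's form); significance is judged at α = 0.05 uncorrected, as is
conventional for exploratory edge screens at this scale. Edge–activity and
edge–RT relations are Pearson correlations; RT pairs whose cortical node is
in the a-priori DLPFC list are tested uncorrected, all others are
Benjamini–Hochberg adjusted. The candidate cortical set for the RT analysis
defaults to the cortical nodes of significant group-difference edges plus
the a-priori DLPFC/VLPFC lists. Path lengths from the two primary motor
nodes are compared with the two-sided Wilcoxon rank-sum test: exact
enumeration of the rank-sum null (midranks for ties) when the combined
sample is ≤ 20, tie-corrected normal approximation without continuity
correction otherwise; subjects for whom a target is unreachable are excluded
from that pair and counted, not imputed — imputation would bias the means.
Degenerate inputs (zero-variance groups, constant regressors) flag the row
rather than aborting the table.

## Synthetic cohort generator

The generator defines the study conditions the tests assume: two groups of
14 and 12 subjects, 4 runs × 146 frames at TR 3.5 s, and the packaged 62-ROI
registry partitioned into four communities (dorsal motor, prefrontal,
ventral visual, subcortical) by name prefix. Each ROI series is a
unit-variance Gaussian factor model

    x_i(t) = √b · f_c(i)(t) + Σ_e √κ_se · h_e(t) + σ_i · ε_i(t)

with community factors f_c (base coupling b = 0.25), one latent factor per
designated edge with per-subject coupling κ_se, and σ_i² = 1 − b − Σκ so the
population correlation of a pair is exactly b·[same community] + κ — the
closed form the tests check against. Configurations whose coupling budget
could exceed unit variance at any node are rejected up front with the
offending nodes named. Frames are i.i.d.; hemodynamic convolution, drift,
autocorrelation, motion and physiological noise are deliberately out of
scope, so passing tests certify the statistics pipeline, not robustness to
fMRI artefacts.

Planted structure, fixed as the package's defaults:

- **Attenuated edges** (5, spanning within- and cross-community pairs):
  coupling 0.45 in group 1, multiplied by 0.5 in group 2. Subjects share a
  latent factor κ_s ~ N(0, 0.10) on these edges plus N(0, 0.02) edge noise;
  couplings are clipped to [0.02, 0.70].
- **Subcortical activity**: during SI frames each subcortical ROI's raw
  signal is shifted by ±3.0·κ_s (+ for striatal ROIs, − for thalamic) plus
  N(0, 0.05) noise, so edge strength correlates positively with striatal and
  negatively with thalamic activity indices. Surrogate task-contrast
  t-values are 4.0 + 3.0·κ_s + N(0, 0.3).
- **Response time**: two designated cortico-striatal edges carry independent
  couplings 0.30 + N(0, 0.20); a subject's mean inter-press interval is
  800 − 1200·(κ_DLPFC − 0.3) + 1200·(κ_VLPFC − 0.3) + N(0, 40) ms. Button
  presses are i.i.d. intervals (SD 30 ms) within condition blocks; the ET
  and CTL conditions add fixed offsets (+255, +36 ms). Per-condition press
  counts (20 per run) and block tiling (2 rest frames + repeating 24-frame
  SI/ET/CTL blocks) are configurable since block granularity is a free
  design choice.

Per-subject generators are spawned from the master seed via
`numpy.random.SeedSequence`, giving bit-identical cohorts for a fixed seed
without seed collisions.

## Verification strategy and problem sizes

- Graph metrics are checked against independent oracles (Floyd–Warshall,
  neighbour-subgraph enumeration, networkx) on 500 random graphs of ≤ 25
  nodes.
- Type-I error of the t-test, correlation test and rank-sum test is measured
  on 2000 zero-effect cohorts (14 vs 12 subjects, 8 ROIs, 50 frames — small
  cohorts keep the replicate count high); all three land near the nominal
  5%.
- Planted-effect recovery runs 100 full-size replicate cohorts; a replicate
  counts as recovered when every attenuated edge is detected (p < 0.05,
  group 1 > group 2), the activity-correlation rows of the *planted* edges
  show the striatal-positive/thalamic-negative sign pattern with at least
  one significant row per side, and both designated RT correlations have
  their planted signs. Judging activity signs on planted edges only is
  deliberate: chance-significant edges carry no planted activity coupling,
  so their correlations are noise and say nothing about recovery.
- The acceptance script uses one default cohort for the curve-based
  quantities, 40 replicates for recovery rates, and 400 for calibration.

## Known limitations

- The factor model yields homogeneous within-community correlations; real
  connectivity is heterogeneous, so empirical quantities like total group
  connectivity (~27% here at cost 0.28) need not match values observed in
  vivo (~11–13%).
- Temporal autocorrelation is absent, so the effective sample size of a
  correlation equals the retained frame count; with real BOLD data the
  Fisher-z sampling variance would be larger than the tests assume.
- The exact Wilcoxon enumeration is O(C(n1+n2, n1)) and is therefore capped
  at combined n = 20.
- The double-edge-swap null is approximate for graphs with very constrained
  degree sequences (e.g. stars); the shortfall counter makes this visible in
  results rather than hiding it.
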