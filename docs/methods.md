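# Methods

## Data model

Input is a replicate-resolved abundance table over a short, unevenly spaced
time grid that starts at the time-zero control (default design: 0, 0.5, 1,
2, 4, 6, 12, 24, 48 h with duplicate measurements). Entities belong to one
of five classes — `TF`, `TR` (the regulator side), `metabolic_gene`,
`protein`, `metabolite` (the target side) — and non-regulators carry labels
from a closed vocabulary of ten biological processes. Missing replicate
values are recorded as absent, never as zeros; downstream statistics
average over the replicates that exist. The grid is data-driven: 48 h (or
any later point) is carried through I/O but excluded from the analysis
window by default.

## Preprocessing

Fold change is the replicate-mean abundance at time t divided by the
replicate-mean at time 0; entities with a zero or absent baseline go to an
exclusion report rather than being dropped silently. All downstream
analysis operates on log2 fold changes, which makes up- and down-responses
symmetric and linear scaling of a profile an exact linear operation.

An entity is **differential** when |log2 fc| ≥ log2(2) at any analysis-window
time point; the **onset** is the first such crossing, the **direction** the
sign of that first crossing. Onsets in (0, 4] h are early (BTS, before
TAG-synthesis onset), onsets in [6, 24] h late (ATS). Down-regulation uses
the symmetric cutoff fc ≤ 1/2. Raising the threshold can only move entities
toward "unchanged" (monotonicity, property-tested).

Normality diagnostics per time point (across entities) record Shapiro–Wilk
W and p, bias-corrected sample skewness and excess kurtosis, their exact
small-sample standard errors

    SE_skew = sqrt(6n(n−1) / ((n−2)(n+1)(n+3)))
    SE_kurt = 2·SE_skew·sqrt((n²−1) / ((n−3)(n+5)))

and the z ratios statistic/SE. The report is a recorded diagnostic, not a
gate: the pipeline proceeds regardless, and optional histogram/Q-Q/box
plots are emitted behind a flag. The report accepts either raw replicate
means or fold changes, since which of the two the diagnostics should be
computed on is a user decision; the pipeline applies it to windowed log2
fold changes, separately for transcripts and metabolites.

## Time-lagged correlation

For series x (regulator) and y (target) sharing the analysis grid and lag ℓ
in sample steps, the paired points are (x_i, y_{i+ℓ}); positive ℓ means the
regulator leads. Lags act in **index space**, not hours, because the grid
is uneven — on the default 7-point window one step spans 0.5 h early and
12 h late. The default lag set {0, +1} is the minimal regulator-leads
choice for a 7-point series; {−1, 0, +1} is available in the config for
users who want to admit target-leads associations. The reported result is
the lag maximizing |r| (ties break toward smaller |lag|, then the positive
lag), with n − |ℓ| paired points; `min_overlap` (default 5) refuses
correlations on fewer pairs, which guards the t approximation at lag 1.

Two-sided p-values use the exact t transform t = r·√((n−2)/(1−r²)) with
n − 2 degrees of freedom, p = 0 at |r| = 1. A seeded permutation
alternative (default 10,000 shuffles) is available since the small-n t
approximation is a modelling choice. Edges are retained at |r| ≥ 0.9 and
p ≤ 0.05 on **raw** p-values — deliberately no multiple-testing correction,
as the retention rule is part of the method being implemented; a
Benjamini–Hochberg column is emitted in the audit table for reference only.
Comparisons are strictly bipartite (regulator vs gene/protein, regulator vs
metabolite); TF–TF and gene–gene correlations are never computed, and only
differential entities enter.

## Network, motifs, degree diagnostics

Edges are undirected (correlation is symmetric) signed links carrying
(r, lag, n, p, sign); the TF endpoint is written first on export. Building
the network validates annotations and the bipartite constraint, and
deduplicates repeated node pairs keeping the larger |r|. A process
subnetwork is the induced graph on all regulator nodes plus the non-TF
nodes carrying that process label. A **single-input motif** is a regulator
together with ≥ 2 targets whose only regulator neighbor it is (the standard
SIM definition; the minimum of 2 makes "single target" trivially excluded);
motifs are disjoint in targets by construction and are merged into one SIM
subnetwork. Exports are SIF (the minimal Cytoscape-ingestible text format,
interaction labels `pos`/`neg`), GraphML (lossless round-trip), and
node/edge attribute CSVs with the class→shape map TF/TR→circle,
gene/protein→square, metabolite→triangle.

Degree diagnostics histogram TF and all-node degrees and fit a power law by
least squares on log-log **logarithmically binned** count densities
(doubling bins, which reduces the bias of fitting raw histograms). The fit
is a qualitative diagnostic, not an inferential claim: `scale_free_like` is
true when the exponent lies in [1, 4] and R² ≥ 0.8, undetermined when fewer
than 4 non-empty bins exist. On 2,000-node configuration-model graphs with
a planted exponent of 2.5 the estimate lands within ±0.4; Erdős–Rényi
graphs are correctly not flagged.

## Hub calling and typing

A **hub** is a regulator in the top 5% of regulator degrees in both the
whole network and at least one process subnetwork ("any"; an "all
subnetworks where present" variant is a config switch). The ranking takes
k = ceil(fraction × U) with all ties at the k-th degree value included —
deterministic and invariant under node relabeling — where U is the size of
the regulator universe of the dataset (all annotated TF/TR entities, the
set over which the co-response screen was exhaustive). When no universe is
supplied the ranking falls back to the regulators with degree ≥ 1 in the
network at hand. Only degree ≥ 1 regulators are callable either way.

Edge **phase** comes from response onsets rather than from re-running
correlations inside 4-point windows (statistically meaningless at this
length). Two modes:

* `target` (default): the phase is the window of the *target's* onset —
  BTS, ATS, or none when either endpoint is unaltered. Rationale: a
  regulator has exactly one onset time, so demanding that both endpoints
  share a window would make it impossible for any regulator to have
  clear-phase partners in both windows — yet a permanent hub is precisely a
  regulator whose partners respond in both phases. Typing the edge by the
  regulated partner's response timing preserves that class.
* `strict`: both onsets must fall in the same window; split onsets are
  `mixed`. Provided for users who want the conservative reading; under it
  the permanent class is unreachable by construction.

Hub **types** use clear-phase edges only (mixed and none excluded): BTS
only → BTS-specific, ATS only → ATS-specific, both → permanent, neither →
unclassified. A condition-specific hub must additionally drive a SIM whose
targets span ≥ 2 biological processes (the "several target genes in
different biological processes" predicate, operationalized and
configurable); specific candidates failing it stay unclassified. The
participation matrix reports, per hub (columns grouped
BTS-specific/ATS-specific/permanent), which of the ten processes its
partners touch, with the whole-network degree as the final row.

## Synthetic data

The generator emulates the study design — three entity classes (default 60
TF/TR, 80 genes, 40 metabolites), the 9-point grid, duplicates, fold-change
responses crossing 2-fold early or late, regulator→target co-response with
optional one-step lag — while remaining seed-deterministic: identical
(config, seed) reproduce byte-identical tables, and different seeds share
the truth topology.

Planted regulators get piecewise-linear log2 fc archetypes: an early
impulse (onset ≤ 1 h, peak 2 h, decay), a late transient (rise from 6 h,
peak 12 h, partial relaxation), and a two-phase riser whose full-strength
copies (coefficient 0.9–1.0) cross 2-fold early while attenuated copies
(0.48–0.60) cross only late — the mechanism that realizes a both-phase
(permanent) hub from pure scaled copies. Each planted target is its
regulator's profile shifted by the planted lag and scaled by a signed
coefficient, plus per-replicate multiplicative log-normal noise
exp(N(0, σ²)) on the abundance scale (σ = 0.15 by default), so fold-change
noise is symmetric in log space and at σ = 0 every planted pair correlates
at exactly ±1 at its planted lag.

The default configuration plants an early-only, a late-only, and a
both-phase hub (6, 6, and 8 targets — four per phase block, so a few noisy
onset flips cannot erase either side of the both-phase evidence) plus 8
single-target regulators that reproduce the many-weak-regulators/few-hubs
degree structure; 20% of the remaining non-TF entities are background
responders, and everything else fluctuates within ±0.3 log2 fc. Process
labels are assigned round-robin (hub targets over a per-hub process triple,
so every hub's SIM spans ≥ 2 processes; everything else over the full
vocabulary, so every process subnetwork is nonempty).

Two construction rules make the generator a usable oracle. First,
**packing**: every regulator profile is rejection-sampled so that no
non-planted regulator×target pair can reach the retention cutoff — pairwise
|r| ≤ 0.80 across all relative shifts the lag search can apply (archetypes,
fixed by design, are allowed their measured ≤ 0.83). This pins the σ = 0
network to the planted truth exactly (the soundness anchor) and leaves a
0.07+ margin that replicate noise essentially cannot bridge. Second,
**shape variance**: with noise of s ≈ 0.15 per windowed log2 fc point, a
planted pair's expected correlation is roughly
1/√((1+s²/V_x)(1+s²/V_y)); the archetypes and the free shape family (three
levels, two sharp transitions) therefore keep temporal variance high, and
free-shape amplitudes stay in [2.0, 2.5] (effect cap 2.5). Greedy packing
can rarely wedge; the generator restarts the phase deterministically off
the continuing random stream (up to 6 attempts) before declaring a config
infeasible.

What the generator does **not** emulate: mechanistic (e.g. ODE) dynamics of
metabolism, realistic mass-spectrometry noise (heteroscedasticity, missing
not at random, batch effects), correlated replicates, or regulators whose
targets deviate from shifted-scaled copies. Passing recovery tests
therefore demonstrates that the pipeline's rules are implemented soundly
and are detectable under the stated noise model — not that the thresholds
are optimal for any particular real dataset.

Recovery scoring is standard set precision/recall (and Jaccard) over
called vs planted edge pairs and hub ids, plus type accuracy over recovered
planted hubs; precision is reported as undefined (absent) on empty calls.
Under the default noisy configuration, measured over 20 seeds by
`scripts/acceptance.py`: hub precision/recall 1.0, type accuracy ≈ 0.95,
edge Jaccard ≈ 0.92. The occasional typing miss is an ATS hub promoted to
permanent by a single spurious early-phase edge — honest behavior of the
≥ 1-clear-edge typing rule under noise.

## Numerical choices and degenerate inputs

* Correlations clip to [−1, 1] against rounding; |r| = 1 returns p = 0.
* Constant series raise "zero variance"; too-short overlaps raise "overlap
  below minimum"; both are recorded per pair in the audit table rather than
  aborting the screen.
* Lag ties (equal |r|) resolve to the smaller |lag|, then the positive lag.
* The time-zero baseline must be positive; the analysis window, windows for
  BTS/ATS, and the lag set are all configurable, with validation that the
  two phase windows are disjoint.
* Onsets falling in the gap between the phase windows (impossible on the
  default grid) count as early if they precede the late window's start.
* Exit codes of the CLI: 0 ok, 1 stage failure, 2 usage error.

## Problem sizes

Defaults throughout are sized for interactive use: 180-entity synthetic
datasets (≈ 500–600 bipartite pairs per screen), 100-network oracle sweeps,
and 20-seed recovery estimates — each stage runs in seconds on one CPU, the
full acceptance sweep in a few minutes.

## Known limitations

* The 7-point analysis window makes |r| ≥ 0.9 a very coarse detector:
  attenuated couplings (coefficient ≲ 0.5 at σ = 0.15) sit near the
  detection boundary, which is visible in the recovery scores.
* Raw p-values with |r| ≥ 0.9 mirror the published criteria; users wanting
  error control should filter on the emitted Benjamini–Hochberg column
  instead.
* The power-law diagnostic is least-squares on binned counts, adequate for
  a qualitative flag but not a substitute for likelihood-based power-law
  inference.
* Phase typing depends on onset calls, which are threshold crossings of
  noisy curves; near-threshold profiles can flip phase between seeds.
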