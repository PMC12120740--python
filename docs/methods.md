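# Methods

This note records the models and procedures implemented in `spatialephys`,
the parameter defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical decisions a
maintainer would want to know.

## Coordinate conventions

All spatial quantities are Cartesian micrometres with the origin at the
lower-left corner of the electrode array or slide, x rightward, y upward;
angles are counter-clockwise radians. Electrode ids run row-major from the
lower-left corner, so electrode `r·cols + c` sits at `(c·pitch, r·pitch)`.
Visium-style position tables carry full-resolution pixel coordinates with
rows growing downward; on read they are scaled by
(55 µm / spot-diameter-in-pixels) and the row axis is flipped. Time is in
seconds, amplitude in microvolts.

## LFP event detection and features

Traces are band-limited with a fourth-order Butterworth band-pass, 1–100 Hz
by default — the slow-oscillation band of interest for hippocampal slice
LFP; the acquisition hardware band (0.1–5 kHz) sits well outside both
edges. The filter is applied forward–backward (zero phase) so detected
event times are not skewed by group delay; the price is a squared
single-pass magnitude response, which only sharpens the already steep
roll-off.

Events are local extrema of |x| exceeding `threshold_sigma` robust standard
deviations, with σ estimated as MAD/0.6745 so that the estimate is
insensitive to the events themselves. The threshold multiplier (default 5),
the merge window for nearby extrema (default 20 ms, larger of the two
kept), and the ±100 ms window over which amplitude, positive/negative peak
counts and energy (sum of squared samples) are measured are all
configurable: the appropriate values depend on the oscillation class being
targeted. On a trace whose MAD is zero (sparse signal on a silent
baseline), σ falls back to the standard deviation so that planted-template
constructions remain detectable.

Spurious electrodes are removed by quantile thresholding of per-electrode
event counts (defaults: outside the [1st, 99th] percentile band). The
defaults are deliberately permissive; tighten them for recordings with
known artefact channels.

Network events — needed both for the per-electrode event-delay feature and
for center-of-activity trajectories — are defined as maximal runs of
10 ms windows in which the pooled population event rate exceeds its mean
plus 3 SD. An electrode's event delay is the mean latency from network
onset to its first event inside the epoch; electrodes silent during an
epoch contribute nothing to that epoch's mean.

Waveform classification projects equal-length event snippets onto the
leading 3 principal components and partitions them with k-means (fixed
seed, 10 restarts). The silhouette score is reported because it is
invariant to label permutation; identical snippets make it undefined and
the result is flagged degenerate rather than erroring.

## Spatial alignment

The two modalities are related by a similarity transform only — resize plus
rotation, no shear. Two homologous landmark pairs define it: {i, j} in the
spot frame (dentate-gyrus crest midpoint and supra-blade edge) and {k, l}
in the electrode frame. After converting each frame to micrometres with its
physical anchor, the scale is the landmark-separation ratio ‖l−k‖/‖j−i‖
(for coordinate tables this is the exact analogue of resizing one image
onto the other using the known spot/electrode sizes), the rotation is
θ = atan2(y′, x′) − atan2(y, x) of the landmark offsets from the horizontal
line through the fused point m = k, wrapped to (−π, π], and the
translation fuses i with k. With exact landmarks T(j) = l and the reported
residual ‖T(j) − l‖/‖l − k‖ is zero; with noisy landmarks it is a quality
metric, never absorbed into a shear term. Recovery of a planted rotation
and scale from exact landmarks is accurate to machine precision, and the
angular error under landmark jitter σ_L grows linearly at rate ∝ σ_L/‖j−i‖.

Fractional matching assigns an electrode to every spot whose centre lies
within `r_assign` (default spot radius + half pitch, so a footprint that
touches the spot disc counts; a strictly-inside-disc rule is available by
passing `r_assign = spot_diameter/2`). Weights are uniform over a spot's
electrodes — area-overlap weighting was considered and rejected as false
precision given landmark placement error of order the electrode pitch.
Spot-level features are weight-averaged; missing electrode values are
dropped from that spot's mean with the remaining weights renormalised, so
a spot's delay is never biased toward zero by silent electrodes.

## Quality control and normalisation

Spots expressing fewer than 1000 unique genes are removed (configurable;
synthetic fixtures with few genes use a lower bound), mitochondrial and
ribosomal genes are dropped by symbol prefix {mt-, Rps, Rpl, Mrps, Mrpl},
and every remaining spot is scaled to the median pre-normalisation total
count. Scaling preserves within-spot proportions exactly.

## Gene–feature correlation

Each gene is tested against one spot-level feature with Spearman's ρ
(average ranks for ties), computed as Pearson correlation of ranks, with
two-sided p-values from the t-approximation for n ≥ 10 spots and exact
permutation enumeration below that. Benjamini–Hochberg step-up adjustment
is applied over the set of genes actually tested (constant genes are
reported with missing ρ and excluded from the family). The implementation
is checked against a brute-force step-up enumeration and a
rank-then-Pearson oracle in the test suite.

## Joint factorisation

The joint matrix V has one row per spot and one column per significant gene
(normalised expression) plus a final column holding the electrophysiological
feature min-max scaled to the gene columns' global maximum, keeping all
columns non-negative and on one scale — the anchor choice is this package's
own and is configurable in effect through the feature passed in.

V ≈ WH is fitted by multiplicative updates for the Tikhonov-regularised
objective ‖V − WH‖²_F + α‖W‖²_F + β Σ_j ‖H[:,j]‖² (the column-norm penalty
on H equals ‖H‖²_F; it is written per column to make the sparsity role
explicit). Defaults α = β = 0.1; both zero recovers plain NMF. Updates stop
at relative objective change < 1e-6 or 1000 iterations (both arguments);
the objective is recorded every iteration and is non-increasing, which the
tests assert, up to round-off once the objective reaches machine precision.
The best of 10 random restarts (by final objective) is returned, and
scikit-learn's NMF serves as an independent cross-check in the tests, never
as the implementation.

Rank selection computes the reconstruction error over a rank range, each
fit warm-started from the previous rank's solution padded with one small
random factor (making the error curve non-increasing by nesting), and
returns the breakpoint of the best two-segment piecewise-linear fit — the
"two linear regimes" reading of an error-curve elbow. The planted rank of
a noisy synthetic low-rank matrix is recovered reliably (10/10 seeds in the
acceptance run).

## Network topology

Spot–spot similarity is normalized mutual information (arithmetic-mean
normalisation) between expression profiles discretized into 8
equal-frequency bins over a gene family; 1 − NMI is the corresponding
distance. NMI carries a small positive bias of order (bins−1)²/(2·n_genes)
under independence — with 200 genes and 8 bins, ≈0.06 — so absolute
thresholds should be read against that floor. Spots with constant profiles
have undefined entropy partners and are reported missing. Electrode–
electrode connectivity is the Pearson correlation of event counts on a
common 100 ms grid; zero-variance electrodes are excluded.

Graphs are thresholded by one of three rules — absolute cutoff (inclusive,
default 0.8 for spot graphs), top edge fraction (default 2% for electrode
graphs; ties at the cut broken by larger weight then lexicographic node
pair), or mean + c·SD — and the applied rule is stamped into the graph's
provenance. Isolated nodes are retained.

Node metrics: degree and clustering coefficient on the binarized graph,
strength on weights, and nodal efficiency as the mean of inverse
shortest-path lengths (0 toward unreachable nodes), computed with a
compiled all-pairs BFS. Nodal (not global) efficiency is used so that the
hub criterion is a per-node quantity. A node is a hub when it lies in the
top 20% for at least two of {strength, clustering, efficiency}; ties at the
80th percentile are included (with a small numeric tolerance so equal
values perturbed in the last float digit still tie), and the all-tied case
is flagged degenerate. Rich-club nodes are hubs with degree above the
network mean; φ(k) = 2E_{>k}/(n_{>k}(n_{>k}−1)) is computed for every k
below the maximum degree over the subgraph of nodes with degree strictly
greater than k, and is missing (not zero) where fewer than two such nodes
exist.

Degree distributions are fitted two ways: lognormal (μ, σ) by maximum
likelihood on positive degrees, scored by R² between empirical and fitted
complementary CDFs on log-log axes; and a Pareto tail exponent by the
conditional MLE (Hill estimator) above x_min (default: median degree),
scored by R² between the linearly binned tail histogram and the
bin-averaged fitted density — bin-averaged because a heavy-tailed pdf
varies steeply within wide linear bins and pointwise evaluation would
misstate the fit. Each model is also compared to the data with a
two-sample KS test against a same-size sample drawn from the fitted model
under a fixed seed.

## Multiscale dynamics

The diffusion map uses a Gaussian kernel with adaptive per-point bandwidth
(distance to the 15th neighbour by default), symmetrised and row-normalised
into a Markov operator; eigenpairs come from the symmetric conjugate, the
trivial stationary component is dropped, and each eigenvector's sign is
fixed by making its largest-magnitude entry positive so the embedding is
deterministic. Duplicate points simply share kernel rows. Pseudotime is the
Euclidean distance from a root in the embedding with components rescaled by
λ/(1−λ); the root defaults to the extremum of the first diffusion
component, a rule chosen for determinism — domain knowledge should override
it when a biological origin is known. Per-region mean pseudotime is
reported for regional comparisons; the comparison itself is left to the
user. The module accepts externally computed embeddings, so a
potential-distance embedding can be slotted in unchanged.

The center of activity of a time window is the activity-weighted electrode
centroid (weights: event counts by default, summed |amplitude| optionally).
A trajectory over a network event evaluates the CA in consecutive windows
(10 ms default); duration is offset − onset, path length the sum of
consecutive CA distances, displacement rate their ratio. Events with fewer
than two non-empty windows are flagged degenerate. Because the path is
measured between the first and last non-empty window centres, the rate
carries a bias factor of roughly (1 − window/duration); recovery within 10%
of a planted plane-wave speed therefore needs events lasting at least ~10
windows, which the acceptance run satisfies with a 16 × 32 electrode patch
and speeds of 4–12 mm/s.

## Prediction

Gradient-boosted regression trees (300 trees, learning rate 0.05, depth 3
by default — unexceptional settings for a few hundred samples; all exposed)
predict a spot-level feature from gene-family expression over repeated
70/30 train/test splits (default 100 iterations), reporting the per-split
Pearson r and explained-variance accuracy. Regression is the primary mode
because the targets are continuous and the scores used are continuous; a
classification reading over target bins can be obtained by binning the
target upstream. Chance level is a permutation null: the target is shuffled
and refitted per permutation (default 100), and the threshold is null mean
+ 3 null SD. Condition contrasts compare per-iteration r values with
two-sample t tests, BH-adjusted across families. Balancing subsamples the
larger of two datasets to a stated fraction (default 0.5) before
comparison.

## Synthetic data generator

`simulate_multimodal_slice` emulates one slice session: a rectangular
electrode array (default 64 × 64, 42 µm pitch) whose per-electrode event
rates are constant within horizontal region bands (defaults: DG 0.8,
CA3 1.0, CA1 0.6, EC 0.3 events/s — slow-oscillation rates of the order
seen in pharmacologically activated slices), homogeneous Poisson event
times over 600 s, lognormal amplitudes around 50 µV; a spot lattice
(55 µm spots on 100 µm centres, subsampled to 300 spots by default) whose
negative-binomial gene counts (dispersion 0.5, variance μ + 0.5μ²) have
log-mean = baseline + coupling · z(local rate), the local rate being the
mean planted rate of electrodes under the spot footprint; and a planted
similarity transform (default 30°, 1.7×) between the frames with one exact
landmark pair in each.

Two generator choices matter for interpretation. First, coupled genes
(default 10% of genes, coupling 0.8) have their baselines shifted down by
1.5 log units: they behave like immediate-early genes — strongly induced
but a small fraction of total transcript mass. Without this, the coupled
mass share is large enough that total-count normalisation imprints a
compositional anti-correlation on every uncoupled gene, and no procedure
could hold the false-discovery rate while the generator's own "uncoupled
means null" premise is violated. Second, per-spot library sizes vary
lognormally (sd 0.3), so total-count normalisation does real work.

What the generator does **not** emulate: hippocampal anatomy (regions are
abstract bands used only to exercise region-conditioned statistics),
spatial autocorrelation of expression beyond what activity coupling
induces, cell-type mixtures, transcriptome-wide gene counts (500 genes by
default), bursting/refractory event-time structure, or electrode-level
noise correlations. Tests passing on these fixtures therefore demonstrate
the correctness of the algorithms under their stated assumptions, not
performance on real tissue.

All randomness flows from one integer seed; sub-stages derive their
generators by fixed offsets, so a slice is bitwise reproducible.

## Problem sizes in tests and the acceptance script

The test and acceptance runs use desk-scale versions of each experiment:
alignment over a 24-angle × 3-scale grid; 100 random graphs of ≤ 50 nodes
against brute-force oracles; coupled-gene recovery on 20 slices of
400 spots × 200 genes; degree fits at n = 2000; factorisation-rank
selection over 10 seeds on 100 × 30 matrices; prediction calibration and
contrast over 20 seed replicates of 200 spots with 60-tree fits and 15
split iterations. The end-to-end check runs the command-line pipeline at
the full acquisition geometry (64 × 64 electrodes, 600 s, 500 genes,
300 spots). These sizes are the package's chosen defaults for routine
verification; every size is an argument and scales up unchanged.

## Known limitations

- The alignment model is strictly similarity (no affine/shear term); tissue
  deformation between recording and sectioning shows up as landmark
  residual, not as a corrected fit.
- NMI between discretized profiles has a positive bias under independence
  that scales with bins²/genes; compare graphs built with the same family
  size, or use the mean+SD threshold rule which adapts to the empirical
  distribution.
- The permutation chance threshold refits one split per permutation; with
  very small spot counts the null SD is itself noisy and the 3-SD rule is
  conservative.
- Diffusion pseudotime assumes a single connected progression; branching
  trajectories are out of scope.
- Multiplicative NMF updates converge slowly near exact factorisations;
  for machine-precision recovery, pass a tighter tolerance and larger
  iteration cap (as the tests do) rather than relying on defaults.
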