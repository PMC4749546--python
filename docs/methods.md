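# Methods

This note documents the models behind `dendromito`, the defaults and why
they were chosen, the estimator designs where the choice was genuinely open,
and the known limits of what the synthetic validation shows.

## Coordinate system: the skeleton

All spatial statistics are referenced to an `ArborSkeleton`: a rooted
geometric tree whose links are at most ~1 µm long, with positions in µm.
Points on the skeleton are `(segment id, arc offset)` pairs; distances
between them are geodesic along the tree by default (a Euclidean mode exists
for sensitivity analysis). Geodesic queries use a multi-source Dijkstra
pass from the target set to every node, after which evaluating the distance
of any query point costs O(1) plus a same-segment correction — this is what
makes 10⁴-iteration Monte Carlo nulls cheap. Equidistant projections
tie-break toward the lowest segment id, deterministically. Anisotropic
voxels are supported throughout; geometry is always computed in µm, never in
voxel units.

## Synthetic generators

Every generator is a pure function of its parameter dataclass, including the
seed; one seeded `numpy` generator drives each call.

**Arbor** (`generate_arbor`): a stochastic binary-branching tree grown in a
thin 3-D slab, emulating planar stratified dendrites. Each branch event
converts one degree-2 node into a degree-3 node, so branch-point counts are
exact. Branch polylines are ~25 µm with ±40% jitter and a mild per-step
direction wiggle; paths bounce off the field walls. Requested trees whose
planned length exceeds 0.05 µm of dendrite per µm³ of field are rejected
with an error naming the bound. Calibration experiments in the tests use
`n_branch_events=80` in a 300 × 300 × 12 µm field (~2 mm total dendrite),
the scale of a mature RGC arbor.

**Placement** (`place_organelles`): synapses are a Poisson process along arc
length at `synapse_density` (default 0.5 µm⁻¹). Mitochondria are a
three-part mixture: a `synapse_affinity` fraction anchored within
`capture_radius` (geodesic, via a random walk along the tree) of a random
synapse, a `branch_affinity` fraction anchored near a random branch point,
the remainder uniform. The mitochondrion count derives from
`mito_volume_fraction` (default 0.1) as `fraction × total_length /
mito_length_um`: organelles of ~1 µm length filling the dendrite
cross-section make the linear packing fraction equal the volumetric one.

**Transport** (`simulate_tracks`): each organelle is long-lived stationary
with probability `1 − motile_prob`, else motile. Motile organelles
alternate exponentially distributed runs (mean 5 s) and pauses (mean 3 s);
each run draws a speed from a positive-truncated Gaussian (0.5 ± 0.15 µm/s)
and reverses direction with probability 0.5 per run; positions reflect at
the path ends and are sampled at 0.9 fps. These defaults are the study
conditions the estimators are validated under; exponential bouts and
two-state kinetics are the simplest model consistent with organelles that
are either motile or stationary. The ground truth records the
continuous-time bout durations actually drawn (final truncated bout
excluded) — the correct reference for calibration, since frame-sampled
state labels alias sub-frame pauses.

**Ca²⁺ events** (`simulate_calcium`): global and local events arrive as
independent Poisson processes (defaults 0.0141 and 0.0102 events/s, the
physiological regime of spontaneous dendritic transients); local events
cover `local_extent` (10 µm) around a random arc position. The waveform is
a step rise of `amplitude_dff` with exponential decay (`decay_tau`, 2 s) on
a baseline of 1, plus Gaussian noise. Amplitude, decay and event duration
(5 s) are placeholders for indicator kinetics, not measured values. With
`motility_coupling > 0`, each motile organelle arrests with that probability
for the event duration: its positions are clamped at the onset value and the
motion it would have made is subtracted from later frames, which keeps the
trajectory continuous and preserves post-event run structure.

**Spike trains** (`simulate_spike_trains`): population bursts arrive as a
Poisson process; each cell joins a burst with `participation_prob` and fires
Poisson spikes at `within_burst_rate` while it lasts, over an independent
Poisson baseline. Cell-body positions support the <200 µm neighbor
criterion.

**Renderer** (`render_volume`, `render_movie`): the cytosol channel is a
tube (exact Euclidean distance transform around the skeleton), organelles
and puncta are multilinearly splatted impulses; everything is blurred with a
Gaussian PSF, normalized so an isolated impulse peaks near 1, and corrupted
with Poisson shot noise plus Gaussian read noise. Defaults: 0.4/0.2/0.2 µm
voxels (z/y/x), PSF σ 0.6/0.25/0.25 µm, 200 expected counts at unit
brightness, background 5 counts, read noise 2 counts. A warning is logged
when voxels are coarser than 2× the PSF σ. Conservation and sub-voxel
centroid accuracy are tested against the splat positions.

## Segmentation

Dendrite masks come from global Otsu, an intensity quantile, or a
fraction-of-maximum threshold (the latter suited to clean renders), followed
by small-object removal (1 µm³) and morphological closing. Skeletonization
reduces the medial-axis voxel graph to a tree by minimum spanning tree
(junction loops in raw skeletons would violate the tree invariants), prunes
side spurs shorter than 2 µm, and resamples junction-to-junction paths into
links of at most 1 µm (±10% tolerance).

Synapse puncta use iterative thresholding within the mask: the threshold
steps down from the 99.9th to the 90th intensity percentile in 20 steps; at
each step, connected components with volume in [0.05, 3] µm³ that do not
touch an already accepted punctum are accepted and frozen. The freeze
prevents nearby puncta from merging as the threshold drops; centroids are
intensity-weighted (sub-voxel). Mitochondrial voxels use local
thresholding: intensity above the local mean + 2 local SD in a 3 µm window,
restricted to the mask (an epsilon guards against filter round-off in
signal-free regions). The published protocols for both steps are
parameter-free citations; these defaults are declared substitutes chosen for
reproducibility, with every parameter exposed.

Two detection limits are inherent and worth stating: puncta closer than
about 2 PSF σ along the dendrite merge optically and cannot be split by any
threshold schedule, so count recovery is only near-exact at densities where
such pairs are rare; the same applies to permanently overlapping organelles
in movies.

## Spatial statistics

`monte_carlo_null` redraws the synapse set uniformly along arc length
(mitochondria fixed), recomputes the mean geodesic NND per iteration
(default 1000), and reports the observed mean, the null mean, a z-score and
the empirical p (fraction of null means at or below the observed). The
geodesic default follows from the randomization being along the dendrites;
NND direction is synapse→mitochondrion, with the reverse available. Under
uniform placement the empirical p is itself uniform (tested by KS over 200
synthetic cells); with 80% of mitochondria anchored within 1 µm of synapses
on a 2 mm arbor, p < 0.01 in ≥95% of cells.

`branch_distance_profile` accumulates dendrite length and mitochondrial
amount per geodesic-distance-to-branch bin (default 1 µm bins to 10 µm).
Bin lengths are exact: on each segment the distance to the nearest branch
point is piecewise linear with slope ±1, so bin overlaps are closed-form
interval lengths. The normalization reference is the arbor-wide mean
density (total amount / total length) — the profile of a uniform placement
is 1 in every bin. With 1 µm bins the enrichment ceiling equals
total length / length-within-1 µm-of-a-branch (~9 on the calibration
arbor); resolving a ≥15-fold regime requires tighter anchoring and sub-µm
bins (0.45 µm capture, 0.5 µm bins in the tests). Mitochondrial "amount"
defaults to per-point weights (projected voxel counts when projecting an
organelle mask); centroid counting is the unweighted case.

## Motility estimation

Kymographs take the maximum intensity across a configurable line width
perpendicular to the path, per arc bin (one voxel) per frame. The linker
detects 1-D peaks per time column (prominence 3 robust SDs, 0.6 µm minimum
separation, parabolic sub-bin refinement) and links them greedily in order
of increasing displacement with a 2 µm/frame gate and gap closing up to 4
frames. On the benchmark conditions (≤10 organelles per 50 µm, default
noise) frame-level recall — true (organelle, frame) positions matched within
0.5 µm — is ≥0.9; identity fragmentation across crossings is counted
honestly rather than hidden.

The motile fraction counts organelles whose frame-pair displacement exceeds
`move_threshold` at least once within the observation window (default 60 s);
the instantaneous fraction is per frame pair. The movement criterion is not
standardized anywhere; 0.4 µm per frame pair (~2 spatial bins at typical
sampling) is this package's default and is reported with every output.

`segment_runs_pauses` classifies frame-pair speeds against `speed_threshold`
(0.1 µm/s, min bout 2 frames) and then applies a model-based refinement
(`split_fraction=0.8`): within a run, any pair slower than 80% of the run's
peak pair speed betrays a sub-frame pause (pairs are also tested jointly
with their neighbor, since a pause straddling a frame boundary spreads its
deficit over two pairs), and durations are measured by inverting
displacement — moving time in any pair is |Δx|/v. The resulting accounting
is an exact partition: run + pause durations sum to the track duration.
At 0.9 fps with exponential 5 s/3 s kinetics this recovers run and pause
means within one frame interval and the duration-weighted run speed within
5%; pauses shorter than ~0.25 s remain invisible, leaving a residual upward
bias of ~0.9 s on the run mean under these kinetics. The refinement assumes
approximately constant within-run speed; for noisy linker output it can be
disabled (`split_fraction=None`).

`displacement_fraction` labels connected pixel regions at baseline and calls
a region displaced when the fraction of its pixels overlapping any organelle
pixel in the later image is strictly below 0.20 — retaining at least 20% of
pixels means *not* displaced, an inclusive survival rule.

## Activity analysis

ΔF/F uses F₀ = mean of the lowest intensity quartile by default (robust to
sparse transients on a flat baseline); explicit and mean-based baselines are
available. Events are maximal runs of frames above mean + 2 SD of the whole
recording; the onset is the first supra-threshold frame, consistent with the
time-above-threshold bookkeeping, and detection is invariant to affine
intensity rescaling. An event is *global* when ≥80% of local windows go
supra-threshold during its frame run, else *local*.

Peri-event alignment bins the instantaneous motile fraction in lag windows
around event onsets (bin = one frame ≈ 1.11 s) and averages across events
with SEM. The first post-onset bin contains the frame pair that straddles
the onset, whose displacement is pre-onset motion — arrest is only visible
from one frame after the onset, a sampling limit at 0.9 fps. Δspeed
compares mean speeds in 5 s windows before/after each onset for organelles
moving in the pre window (mean pre speed > 0.1 µm/s), with a two-sided
Wilcoxon signed-rank test.

Cross-correlations bin spikes at 100 ms (traces at one frame), subtract a
boxcar-smoothed rate (jitter window, default 2 s) from each train, and
Pearson-normalize the residual correlation per lag. This is a declared
functional substitute for rate-drift-corrected correlation methods whose
exact normalization is not reproducible from the available description; it
has the property that motivates the correction — rate-matched but
independent trains with a shared slow envelope give ≈0 at all lags, while
genuinely co-bursting trains keep a dominant zero-lag peak. Without
correction the statistic is the plain Pearson correlation per lag
(identical inputs peak at exactly 1).

## Pipeline and reproducibility

`run_pipeline` executes simulate → render → segment → track → classify plus
spatial and activity stages from a single nested config; every stochastic
stage receives a seed derived from the global seed by a stable hash, and
reports are serialized with sorted keys and rounded floats, so identical
configs produce bit-identical `report.json` files. Missing stage inputs
raise errors naming the producer stage. The demo "developmental contrast"
config simulates two conditions (motile probability 0.3 vs 0.0) through the
full imaging loop; a 40 µm path with 8 organelles and a 90 s movie keeps the
round trip under a few seconds.

## What the synthetic validation does and does not show

The generator matches the statistical structure the estimators assume —
which is exactly why parameter recovery is a meaningful test of estimator
correctness, and why it says nothing about model misspecification on real
data. Real recordings add photobleaching, stage drift, focus loss,
non-exponential bout mixtures, organelle fission/fusion, and indicator
nonlinearity, none of which are modeled (deliberately: they would make the
oracle ambiguous). Thresholds (movement criterion, speed threshold, local
contrast k) are declared package defaults, not reconstructions of the
unpublished originals, and all outputs carry the values used.
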