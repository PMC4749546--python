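# dendromito

Quantification of mitochondrial distribution, transport, and activity
coupling in neuronal dendrites — with a synthetic-data generator that
provides ground truth for every estimator.

## The problem

In developing retinal ganglion cells (RGCs), mitochondria are positioned
near synapses and dendritic branch points, move along dendrites in
alternating runs and pauses, and may (or may not) respond to Ca²⁺ activity
such as retinal waves. Testing claims about these behaviors requires a set
of spatial and temporal statistics that are easy to state but fiddly to get
right:

- **Is a mitochondrion closer to synapses than chance?** Compare the mean
  nearest-neighbor distance (NND) from synapses to mitochondria against a
  Monte Carlo null in which synapse positions are re-drawn uniformly along
  the dendritic skeleton. Distances are geodesic (along the tree), not
  straight-line.
- **Are mitochondria enriched at branch points?** Bin the arbor by geodesic
  distance to the nearest branch point and compare mitochondrial density per
  bin against the arbor-wide mean density (normalized density; the bin at
  distance 0 gives the fold enrichment).
- **How motile are organelles?** From kymographs or tracks: the *motile
  fraction* (moved at least once within a 1-minute window), the
  *instantaneous* motile fraction (moved between consecutive frames at
  0.9 fps), run/pause durations and run speeds from a two-state transport
  model, and a long-interval displacement measure (a baseline organelle is
  *displaced* when fewer than 20% of its pixels overlap any organelle in the
  later image).
- **Does activity gate transport?** ΔF/F transient detection at a
  mean + 2 SD threshold, peri-event alignment of the instantaneous motile
  fraction, pre/post speed changes, and cross-correlations between
  neighboring cells corrected for slow nonstationary rate drift.

The imaging data behind such studies is rarely deposited, so the package
includes a first-class synthetic module (`dendromito.synthetic`): branching
arbors in a thin slab, organelle placements with tunable synapse/branch
affinity, two-state run-and-pause transport at 0.9 fps, step-rise /
exponential-decay Ca²⁺ events with optional motility coupling, correlated
burst firing across cells, and a renderer that turns all of it into noisy
multi-channel TIFFs. Every generator is a pure function of its parameter
object (seed included), and every estimator is validated against the
generator's hidden truth.

## Worked example

```python
import numpy as np
from dendromito.synthetic import (ArborParams, PlacementParams, MotilityParams,
                                  generate_arbor, place_organelles, simulate_tracks)
from dendromito.spatial import (monte_carlo_null, branch_distance_profile,
                                enrichment_at_branch)
from dendromito.motility import classify_motility

sk = generate_arbor(ArborParams(n_branch_events=80,
                                field_extent=(300.0, 300.0, 12.0), seed=1))
print(f"arbor: {sk.total_length:.0f} um of dendrite, "
      f"{len(sk.branch_points)} branch points")

cell = place_organelles(sk, PlacementParams(synapse_affinity=0.8,
                                            capture_radius=1.0, seed=2))
res = monte_carlo_null(cell.synapses, cell.mitochondria, sk,
                       n_iterations=1000, seed=3)
print(f"NND observed {res.nnd_observed:.2f} um vs random {res.nnd_random:.2f} um "
      f"(z = {res.z_score:.1f}, p = {res.p_empirical:.3f})")

anchored = place_organelles(sk, PlacementParams(branch_affinity=1.0,
                                                capture_radius=0.45,
                                                mito_volume_fraction=0.5, seed=4))
prof = branch_distance_profile(anchored.mitochondria, sk, bin_width=0.5)
print(f"branch-point enrichment: {enrichment_at_branch(prof):.1f}-fold")

tracks, truth = simulate_tracks(300.0, MotilityParams(motile_prob=0.3,
                                                      duration=90.0, seed=5),
                                n_organelles=1000)
stats = classify_motility(tracks, window=60.0)
print(f"motile fraction {stats.motile_fraction:.3f} (generator 0.300), "
      f"mean instantaneous {stats.mean_instantaneous:.3f}")
```

prints

```
arbor: 2027 um of dendrite, 80 branch points
NND observed 4.41 um vs random 5.09 um (z = -4.3, p = 0.000)
branch-point enrichment: 16.9-fold
motile fraction 0.309 (generator 0.300), mean instantaneous 0.142
```

Reading the output: with 80% of mitochondria anchored within 1 µm of a
synapse, the observed synapse→mitochondrion NND (4.41 µm) falls well below
the Monte Carlo null (5.09 µm, z = −4.3) — the co-localization is detected.
Tightly branch-anchored organelles are ~17-fold enriched in the first
half-micron bin. A population with a 30% motile probability is recovered at
30.9% by the per-minute metric, with the instantaneous fraction much lower,
as it must be.

## Command line

```sh
dendromito run --seed 7 --out out/          # demo two-condition pipeline
dendromito demo --seed 0 --out fixtures/    # small TIFF/SWC/CSV bundle
dendromito motility --tracks tracks.csv --window 60 --move-threshold 0.4
dendromito displacement --t0 a.tif --t1 b.tif --overlap 0.2
dendromito spatial --skeleton cell.swc --synapses syn.csv --mitochondria mito.csv --out out/
dendromito activity --traces traces.csv
```

`dendromito run` executes simulate → render → segment → track → classify
from a YAML config (default: a two-condition "developmental contrast" with
motile probabilities 0.3 vs 0.0) and writes a `report.json` that is
bit-identical across runs with the same seed.

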