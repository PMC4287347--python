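# Methods

This note records the statistical model behind `hypercoev`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing
results.

## Pipeline model

The object of analysis is the windowed edge-weight matrix: for N regions
and W non-overlapping windows, an E × W matrix (E = N(N−1)/2) whose entry
(e, w) is the Pearson correlation of the two regions of edge e over
window w.  Co-evolution is defined at the level of this matrix: two edges
co-evolve when their weight rows are correlated across windows.  The
E × E correlation matrix **X** is tested entry-wise (two-sided t
transform with W − 2 degrees of freedom), corrected by Benjamini–Hochberg
FDR over the E(E−1)/2 upper-triangular entries, binarized, and decomposed
into connected components.  Components of size ≥ 2 are hyperedges;
singletons are excluded from all downstream statistics.

Assumptions worth keeping in mind:

* the t-transform p-value treats the W windows as independent draws; it
  is exact for i.i.d. Gaussian rows and approximate otherwise;
* the two-sided test links strongly anti-correlated edge pairs as well
  (a `greater` one-sided option exists);
* FDR is applied once per subject, so hypergraphs are per-individual
  objects; group statements are made through the co-evolution network P
  and pooled size/degree distributions.

## Defaults and parameters

| parameter | default | unit | notes |
|---|---|---|---|
| band edges | 0.06 – 0.125 | Hz | task-relevant low-frequency BOLD band |
| Butterworth order | 4 | – | order per direction; applied forward–backward (zero phase), so the effective magnitude response is squared |
| motion threshold | 0.25 | mm mean FD | runs at or above are excluded |
| window length | 60 | s | 30 samples at TR 2 s, 24 at TR 2.5 s; point-count windowing available for TR-mixed designs |
| FDR level q | 0.05 | – | mandatory config entry, echoed in outputs |
| permutations | 1000 | – | task tests and spatial metrics; add-one p, floor 1/(n+1) |
| alpha | 0.05 | – | Bonferroni family = all (hyperedge, task) tests of one subject |

The filter order and zero-phase application are package choices: zero
phase avoids introducing inter-region lags that would bias windowed
correlations.  Filtering precedes windowing; windows never straddle run
boundaries; trailing partial windows are discarded because a short window
biases the Pearson estimate.

Permutation nulls: the task-specificity null draws window sets without
replacement from the other tasks' windows at window granularity (the
statistic lives on the windowed series, so a "time point" is one
window).  The between-task spatial comparison swaps the two networks'
strengths connection-wise with probability 1/2, preserving each
connection's geometry while exchanging task identity.

## Synthetic generator

The generator plants groups of edges that share one latent window
trajectory.  The trajectory is a mean-reverting (AR(1), coefficient 0.6)
Gaussian walk, standardized and squashed through `tanh(1.5·z)` into
[−1, 1].  Mean reversion matters: a pure random walk over a few dozen
windows is so smooth that two *independent* trajectories frequently show
large spurious correlation (the classic spurious-regression effect),
which merges planted groups that should be separable.  The squash gain
1.5 spreads trajectories over the unit interval (sd ≈ 0.8) so planted
co-evolution has realistic dynamic range.

* **Edge level** — member rows are
  `tanh(level_task + amplitude·latent + noise_sd·ε)`; non-member rows and
  inactive windows are independent noise through the same squash, so all
  weights stay in (−1, 1).  Optional per-task levels create between-task
  contrasts that survive within-task shuffling — the mechanism by which
  hyperedges persist under the within-task null.
* **Region level** — the two nodes of a member edge share a band-limited
  carrier (random sinusoids in 0.065–0.12 Hz) with mixing weight
  `amplitude·(1 + latent)/2` on top of independent baseline noise, so the
  windowed Pearson weight rises and falls with the trajectory and equals
  1 exactly when `noise_sd = 0`.  Carriers and baselines are drawn
  independently per window: the generator plants *window-level* edge
  dynamics, and carrying narrowband signals across window boundaries
  would smear temporal autocorrelation into every edge-weight series,
  producing spurious edge–edge correlation unrelated to the planted
  structure.

What the generator does **not** emulate: hemodynamic response functions,
scanner artifacts, spatial structure (no volumes are produced), and the
cross-window autocorrelation of real BOLD.  One realistic effect does
appear at region level: with ~7 effective samples per 60-s narrowband
window, weight estimates of edges sharing a node are dependent, so
region-level instances grow small spurious components (mostly
node-sharing edge pairs) on top of the planted ones.  Tests on the region
route therefore assert that planted groups are recovered as distinct
hyperedges, not that nothing else appears; passing them shows the
pipeline recovers planted structure under estimation noise, not that
real-data hypergraphs are free of estimation-driven components.

## Benchmark study conditions

The planted benchmarks mimic the four-task design they are meant to
exercise: rest and attention at TR 2 s, two memory tasks at TR 2.5 s,
eight 60-s windows each (W = 32), N = 30 nodes, three groups of three
disjoint edges, amplitude 0.9, noise sd 0.2.  The task-labelling
benchmark uses 16 windows per task (W = 64): a task-confined signal
occupies a quarter of the windows, and that dilution demands the larger
sample for the edge–edge correlation to resolve membership; the planted
amplitude and noise are unchanged.  The within-task-null benchmark adds
three level-shift groups with mutually orthogonal per-task mean patterns
(±0.8), so the three group kinds separate cleanly: level shifts survive
the within-task null, transients do not, and nothing survives the overall
null.  Problem sizes (30 nodes, 50 seeds, 1000 permutations) are the
package's desk-scale defaults; every routine streams the E × E matrix in
row blocks and has been exercised at N = 194 (E = 18 721) scale.

## Numerical conventions and edge cases

* Edge indexing is 0-based lexicographic over pairs (i < j) everywhere;
  hypergraphs are comparable across subjects because of this single
  convention.
* A constant region row in a window yields undefined correlations; they
  are set to 0 with a warning naming the node and window (batch jobs
  should not abort on a degenerate window).  A constant edge row gets
  r = 0, p = 1 against every other edge.
* |r| = 1 maps to p = 0 through the t transform (infinite t); the BH pass
  handles zeros correctly.
* Permutation p-values use the add-one rule and can never be 0; with
  Bonferroni over many tests the resolution floor 1/(n_permutations + 1)
  can exceed the corrected threshold — the permutation count must grow
  with the test family, and `classify` records both in its output.
* Spatial metrics on degenerate inputs (constant strengths or geometry,
  fewer than three connections) return an undefined-result marker rather
  than a number.
* All randomness flows from explicit seeds through `SeedSequence` spawns
  (one stream per edge row for nulls, one per (hyperedge, task) test for
  classification), so results are independent of evaluation order and
  bit-reproducible.

## Atlas refinement

Regions are flagged when mean size falls below the 25th percentile of the
starting scale's mean sizes (frozen at start, so the flag set shrinks and
the iteration terminates) or when the cross-subject coefficient of
variation (sample sd / mean) exceeds 30%.  A flagged region is tentatively
merged with its siblings under the same coarser-scale parent — the only
machine-checkable reading of "anatomically sensible groupings" — and the
merge is kept only if it strictly improves the flagged measure without
increasing the merged region's CV beyond its worst member or the
within-subject spread of region sizes.  Unmergeable high-CV regions are
excluded as `high-cv`, failed merges as `rejected-merge`, and regions
with any zero-size subject as `no-data`.  Guarantees: every accepted
region ends below the CV threshold; a merged region is never more
variable than its worst member; and total voxel counts are conserved per
subject across accepted plus excluded regions.

## Known limitations

* The t-transform p-values are anti-conservative when edge-weight series
  are autocorrelated; with real BOLD data the FDR level q is then nominal
  rather than exact.  A permutation-based edge–edge p-value would be the
  conservative alternative and is deliberately out of scope here.
* "Probability" in the co-evolution network weights every hypergraph
  equally; large hyperedges are not down-weighted.
* No overlapping/tapered windows, no pair-specific (two-task) hyperedge
  classification, and no path-based network efficiency measures.
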