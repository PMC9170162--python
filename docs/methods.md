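# Methods

This document describes the models and numerical choices implemented in
`endonet`, the defaults and their rationale, what the synthetic generator
does and does not emulate, and known limitations.

## 1. Tissue geometry

`build_hex_lattice(n_rows, n_cols, cell_diameter=30, jitter=0)` tiles
pointy-top hexagons of 30 µm nominal diameter (typical endothelial cell
scale). Vertex jitter is applied to *shared* vertices (one displacement per
lattice vertex), so neighbouring cells deform together and adjacency is
invariant under jitter; jitter must stay below a quarter of the cell pitch
to preserve polygon validity.

- **Adjacency** (`neighbors_from_rois`): two cells are structural
  neighbours when their polygons are within `contact_tol` (default 1 nm,
  i.e. effectively zero separation). An STRtree makes this O(n log n).
  Interior cells of the perfect lattice have exactly 6 neighbours.
- **Boundary exclusion** (`flag_boundary_cells`): cells with a vertex on or
  outside the concave hull (shapely `concave_hull`, ratio 0.2) of all
  centroids are flagged and excluded from every statistic, because their
  neighbourhoods are truncated. On a rectangular lattice this is the
  perimeter ring.
- **Label images**: geometry can round-trip through a label TIFF
  (`write_label_image` / `read_label_image`); pixel 4-adjacency recovers
  polygon adjacency up to rasterization loss at corner contacts.

## 2. Sensitivity assignment

`assign_sensitivity(tissue, fraction, mode, mean_cluster_size)` marks
`round(fraction x n_cells)` non-boundary cells as agonist-sensitive.

- `random`: uniform draw — the calibration control.
- `clustered`: connected clusters grown by seeded breadth-first accretion;
  per-cluster sizes are Poisson around `mean_cluster_size` (min 1).
  By default clusters may touch and merge into larger patches, as real
  sensory clusters can. With `min_separation=1` clusters are grown with a
  one-cell buffer so distinct planted clusters are never adjacent; the
  reference network experiment uses this to plant well-separated
  communities (the buffer is relaxed only on overcrowded lattices).
- Each cluster's seed cell is its **pacemaker** (initiator).

Defaults `fraction=0.25`, `mean_cluster_size=5` reflect the responding
fraction and cluster scale at a low (EC₂₅-like) agonist dose.

## 3. Signal generator

`simulate_recording(tissue, sens, params)` produces F/F₀ traces at
`fs=10` Hz with baseline 1 and multiplicative Gaussian noise
(`noise_sd=0.02`).

Event dynamics (defaults in `SimulationParams`):

- Each pacemaker fires Poisson events after `onset=60` s at
  `event_rate=0.015` Hz x cluster size (the cluster's event budget is
  carried by its initiator). The low rate keeps inter-event intervals
  (~13 s per cluster) well above the refractory period, so trains stay
  aperiodic — important because periodic trains would contaminate the
  circular-scramble null (Section 5).
- Events cascade neighbour-to-neighbour with probability
  `propagation_prob=0.8` and delay `propagation_delay=0.5` s per hop,
  implemented as an event-queue simulation with a per-cell
  `refractory_s=5` s.
- **Only sensitive cells relay.** Insensitive neighbours are terminal
  recipients: their activation is delayed by an additional exponential
  latency (`terminal_latency_s=1.5`, mean) and their transient amplitude is
  scaled by `terminal_amplitude_scale=0.25`, which puts it below the 5×SD
  detection threshold. This models passive, IP₃-nonregenerative spread and
  reproduces the key observation that only about the sensitive fraction of
  cells is *detected* as active at low dose.
- Transients are difference-of-exponentials kernels
  (`transient_rise=0.1` s, `transient_decay=2` s), peak-normalized to
  `event_amplitude=0.5` — 25× the baseline noise SD.

`simulate_uncaging(tissue, site, wave_speed, shortcut_cells,
shortcut_advance)` generates a radial wave: activation time =
distance/speed + Gaussian jitter (`activation_jitter_sd=0.2` s); designated
short-circuit cells activate `shortcut_advance` seconds early.

**What the generator does not emulate:** real Ca²⁺ oscillation frequency
modulation with dose, photobleaching and drift, optical crosstalk between
neighbouring ROIs, heterogeneous cell sizes beyond vertex jitter, and true
biophysical IP₃/Ca²⁺ kinetics. It is a statistical surrogate for testing
the pipeline, not a biophysical model.

## 4. Trace processing

- `baseline_correct`: divide by the per-cell mean over the baseline window
  (≥ 1 s; positive baseline required).
- `binarize`: events are samples where the first difference strictly
  exceeds `threshold_sd_mult=5` times the SD of the *derivative* in the
  baseline window (the threshold is applied to the same signal the SD is
  measured on). Event columns are stamped at the later sample, (i+1)/fs.
- `detect_activation`: first supra-threshold event at/after onset; cells
  without one are non-responders.
- `select_first_responders`: the earliest-activating quota of
  `ceil(fraction x n_cells)` cells (deterministic mergesort tie-break on
  activation time, then cell id). Restricting analysis to first responders
  focuses on directly stimulated cells rather than passive followers.
- `exclude_initial_window`: optionally zeroes events in [onset,
  onset+skip) to drop the synchronized onset burst (default skip 0 in the
  simulation pipeline, where no burst artifact is generated; 300 s when
  mimicking burst-contaminated recordings).

## 5. Functional coupling and the scramble null

`pairwise_coupling` computes, for each cell pair, the mean over
`n_windows=2` non-overlapping 60-s windows of the lag-maximized Pearson
correlation of the binary event trains, lags −2.5…+2.5 s in 0.1 s steps
(overlap-restricted; positive lag means the second cell follows the first).
Count-based Pearson over sparse binary trains is computed with sparse
matrix products and cumulative sums, so all pairs and lags cost roughly one
sparse matmul per lag. A window where either train has zero variance
contributes 0.

The significance cutoff is the 99.9th percentile of a null ensemble built
by circularly rotating every train by independent uniform offsets,
`null_n_iter=100` times (`aggregation="pooled"` over all iterations and
pairs; `"mean_of_iterations"` averages per-iteration percentiles). Edges
are pairs with coupling strictly above the cutoff. Circular rotation
preserves each train's event count and autocorrelation while destroying
alignment; its known blind spot is near-periodic trains, which re-align
under rotation — the generator's low event rate avoids this regime.

## 6. Graph metrics and random references

For the observed network (isolated nodes kept): L = mean shortest path over
connected pairs; C_raw = transitivity (3 x triangles / connected triples);
degree histogram; γ = OLS slope of log10 count vs log10 degree (unbinned,
degrees with nonzero count).

`random_reference` re-draws, `n_iter` times, a node set of the same size
uniformly from the non-boundary pool and rebuilds the correlation network
at the *observed* cutoff; L_R and C_R are grand means over iterations
(iterations with no edges contribute NaN to L and 0 to C). This reference
asks: "would an arbitrary set of cells of this size show the same
organization?" — most random draws hit undetected (insensitive) cells, so
C_R is small and σ = (C_raw/C_R)/(L/L_R) greatly exceeds 1 for genuinely
clustered activity. With a random *node selection* (the label-randomized
control) the observed network is itself a draw from the reference ensemble
and σ sits within its null spread of 1. `sigma_null_sd` reports the SD of
σ recomputed per reference iteration.

Default `reference_n_iter=100` (the pipeline's reference experiment uses 20
for speed; the estimator is a mean, so fewer iterations only widen its
variance).

## 7. Sensory-cluster statistics

On the structural lattice restricted to active non-boundary cells:
components (including singletons), clusters (components ≥ 2, also per 100
cells), mean cells per cluster, and active degree (mean number of active
neighbours of an active cell). `permutation_null` redraws equal-sized
active sets uniformly among non-boundary cells `n_perm=1000` times and
reports per-statistic null mean, SD and the add-one two-sided empirical
p-value, p = min(1, 2 x min(tail counts + 1)/(n_perm + 1)).
`agonist_overlap` reports the percentage of cells recruited by each of two
agonists and the conditional overlaps.

## 8. Wave propagation

`wave_fit` regresses distance on activation time (OLS, ≥ 3 cells,
residual SD with ddof=2); the slope is the front speed. `detect_shortcuts`
flags cells whose residual exceeds `k_sd=3` x residual SD (mode
`"residual"`), or whose distance within a time bin exceeds the bin mean by
the same criterion (mode `"time_binned"`); `distance_threshold` is the
smallest flagged distance. Flagged cells activate too far ahead of the
front for contact-mediated spread, implicating long-range projections.

## 9. Numerical and reproducibility choices

- All stochastic stages take explicit seeds; child seeds are derived with
  `numpy.random.SeedSequence` and kept below 2³¹.
- The lag grid requires `fs x lag_step` to be integral so lags are whole
  sample shifts (0.1 s at 10 Hz = 1 sample).
- Strict inequalities are used at both detection thresholds (derivative >
  5×SD; coupling > cutoff), so ties never create events or edges.
- Configuration is a frozen `RunConfig` dataclass with a stable SHA-256
  hash recorded in outputs.

## 10. Limitations

- The random reference redraws node sets rather than rewiring edges;
  degree sequences are not preserved. This matches the "arbitrary cells of
  the same count" question but differs from degree-preserving rewiring
  nulls, and σ values are not comparable between the two conventions.
- γ is an OLS slope on unbinned log counts; for the ~80-node networks
  analyzed here the degree range is one decade, so γ is indicative, not a
  rigorous power-law fit (no logarithmic binning or maximum-likelihood
  estimation).
- The scramble null is anti-conservative for periodic trains (Section 5).
- Transitivity of small graphs is coarse: with tens of nodes, C_raw and
  C_R take few distinct values, and σ has substantial replicate-to-
  replicate spread (the reference experiment's σ ranges roughly 1.0-2.4
  over seeds with median ≈ 1.5).
- Pixel-based adjacency from label images can miss corner contacts that
  polygon adjacency finds; the polygon route is authoritative.
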