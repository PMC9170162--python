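# endonet

Functional-network analysis of multicellular Ca²⁺ imaging in intact
endothelium, with a synthetic tissue and signal generator that stands in for
raw imaging data.

## Scientific problem

The endothelium lining blood vessels is a communicating sheet of cells.
Agonists such as acetylcholine evoke Ca²⁺ transients in a spatially
clustered subpopulation of sensitive cells, and activity propagates to
neighbours with short lags, occasionally jumping over long distances through
membrane projections ("short circuits"). From per-cell fluorescence traces
and cell-outline geometry, this package reconstructs the *functional*
network — which cells fire together, at what lag — and quantifies its
organization:

- **Small-world structure.** The functional network is compared against
  degree-matched random reference networks: path-length ratio λ = L/L_R,
  clustering ratio C = C_raw/C_R, and the small-world coefficient
  σ = C/λ. σ > 1 indicates locally clustered yet globally short-path
  ("small-world") organization.
- **Scale-free tendency.** The degree distribution is summarized by the
  log–log slope γ.
- **Sensory clusters.** Spatial clustering of responding cells on the
  structural (contact) lattice is tested against a 1,000-fold permutation
  null.
- **Wave propagation.** Radial activation waves from a focal stimulus are
  fit as distance vs. time; cells activating far ahead of the front
  (≥ 3× the residual SD) are flagged as short-circuit recipients.

## The model

Because raw imaging data are not machine-readable here, `endonet.simulate`
generates surrogate recordings on a jittered hexagonal lattice (~6 contact
neighbours per interior cell):

- 25% of cells are agonist-sensitive, planted in connected clusters of mean
  size 5; each cluster has a pacemaker cell that initiates Poisson-timed
  events after stimulus onset.
- Events propagate neighbour-to-neighbour with probability 0.8 and a 0.5 s
  hop delay; only sensitive cells regenerate and relay the signal.
  Insensitive neighbours receive delayed, strongly attenuated transients
  that stay below the 5×SD detection threshold — as in tissue, where only a
  quarter of cells respond at low agonist dose.
- Transients are fast-rise/slow-decay kernels (amplitude ≥ 20× the baseline
  noise SD) on multiplicative baseline noise at 10 Hz.

The analysis pipeline is generator-agnostic: it consumes a trace matrix
(CSV with a JSON metadata header), cell geometry (GeoJSON polygons or a
label TIFF) and a YAML run configuration.

## Worked example

The one-call reference experiment simulates a 20×20 tissue (400 cells,
360 s at 10 Hz, onset at 60 s) and runs the full pipeline:

```python
>>> from endonet.pipeline import clustered_smallworld_experiment
>>> res, tissue, sens, rec = clustered_smallworld_experiment(1, reference_n_iter=20)
>>> m = res.metrics
>>> m.n_nodes, m.n_edges
(81, 70)
>>> round(m.L, 3), round(m.C_raw, 3)
(1.459, 0.769)
>>> round(m.lam, 3), round(m.sigma, 3)
(1.375, 1.584)
```

The 81 analyzed nodes are the first-responding quota (25% of 324 interior
cells, rounded up); σ = 1.58 > 1 detects small-world organization. The same
pipeline on a random node selection (label-randomized control) gives
σ ≈ 1.24 with C_raw often 0 — statistically indistinguishable from its own
reference ensemble.

Command-line equivalent:

```bash
endonet simulate --rows 20 --cols 20 --seed 1 --out results/simulation
endonet network --traces results/simulation/traces.csv \
    --geometry results/simulation/tissue.geojson --out results/network
```

## Reproduction

The numbered scripts in `analysis/` regenerate every table in `results/`:

```bash
python analysis/01_simulate_tissue.py     # traces, geometry, event log
python analysis/02_functional_network.py  # edges, metrics.json
python analysis/03_graph_metrics.py       # small_world.csv, 10 replicates
python analysis/04_sensory_clusters.py    # cluster_stats.csv, overlap
python analysis/05_wave_propagation.py    # wave_table.csv, wave_fit.json
```

Representative outputs (seeds as committed in the scripts):

- `02`: 81 nodes, 76 edges, null cutoff 0.719, σ = 1.33, γ = −1.18.
- `03`: median σ = 1.51 and median λ = 1.35 over 10 study replicates;
  median σ = 1.24 for the random-selection control.
- `04`: clustered sensitivity gives 12.3 cells/cluster vs. a permutation
  null of 4.96 (p < 0.05 in 20/20 seeds); random sensitivity gives 5.05
  vs. 4.96 (0/20 rejections).
- `05`: fitted front speed 20.12 µm/s for a simulated 20 µm/s wave; all 5
  planted short-circuit cells flagged, no false flags.

The headline target is reproduced by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
# seed 1 -> {"t2": {"value": 1.684, "n": 400}}  (median sigma over 10 runs)
```

Every stage is seeded; identical seeds and configuration give bit-identical
outputs.
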