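# mesoconn

Mesoscale functional-connectivity analysis for whole-brain single-cell
calcium imaging, exercised end to end on a synthetic generator with planted
structure.

Whole-brain light-sheet imaging of larval zebrafish yields fluorescence
traces for tens of thousands of neurons per animal. To ask
network-neuroscience questions of such data — are functional connections
shaped by geometry? is the network hierarchically modular? which nodes are
hubs, and which reconfigure under stimulation? — cells must first be
aggregated into a common set of nodes, and the resulting signed correlation
networks analyzed with methods that respect their signed, fully weighted
character. `mesoconn` implements that pipeline as a reusable library:

- **Parcellation**: multistage clustering (spatial k-means on pooled
  left-hemisphere coordinates → mirrored centroids → global-signal
  regression → correlation-distance k-means → spatial subdivision) that
  produces spatially contiguous, functionally homogeneous, hemispherically
  symmetric parcels shared across subjects.
- **Networks**: parcel-averaged traces, Fisher-z Pearson correlation
  matrices A = {A_ij}, group averages, and Fourier phase-randomized
  surrogate nulls that preserve every trace's amplitude spectrum.
- **Modules**: signed modularity maximization with a uniform null,
  Q(γ) = Σ_{i≠j} (A_ij − γ) δ(g_i, g_j), optimized by a generalized
  Louvain heuristic; resolutions γ sampled from the network's own weight
  distribution; a statistically gated consensus hierarchy; significance of
  Q against the surrogate ensemble.
- **Multilayer**: condition networks coupled by an interlayer weight ω
  (sampled log-uniformly on [0.001, 10]), multilayer modularity, and node
  flexibility f_i = 1 − 2/(T(T−1)) Σ_{r<s} δ(g_ir, g_is).
- **Metrics**: participation coefficient p_i⁺ = 1 − Σ_c (κ_ic⁺/k_i⁺)²,
  absolute strength s_i = Σ_j |A_ij|, z-Rand partition similarity, distance
  profiles, hemispheric symmetry, Mantel tests, and subject/condition
  similarity reports.
- **Synthetic data**: a generator planting hemispheric symmetry, distance
  decay, a two-level module hierarchy, condition-dependent flexible cells,
  a global signal, and per-subject individuality — so every stage is
  testable against known ground truth without any download.

The brute-force enumeration oracles used to validate the optimizers live in
`mesoconn.exhaustive`. See `docs/methods.md` for the models and numerical
choices.

## Worked example

```python
from mesoconn import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1), out_dir="results/run")
for k in ("n_parcels", "hemisphere_similarity_r", "n_hierarchy_levels",
          "flexibility_participation_r", "self_similarity_r",
          "intersubject_similarity_r"):
    print(k, report.headline[k])
```

prints (seed 1):

```
n_parcels 48
hemisphere_similarity_r 0.9739784835030579
n_hierarchy_levels 5
flexibility_participation_r 0.7000926201035291
self_similarity_r 0.9628292959359296
intersubject_similarity_r 0.8514334246317439
```

Reading: the 800 planted cells aggregate into 48 mirror-paired parcels;
left and right within-hemisphere connectivity are nearly identical (the
plant is hemispherically symmetric); the consensus hierarchy finds 5 nested
levels whose modularity beats phase-randomized surrogates; the nodes that
switch modules across stimulus conditions are the same nodes that straddle
module boundaries at rest (positive flexibility–participation correlation);
and each synthetic subject is more similar to itself across conditions than
to other subjects — the fingerprinting signature.

The same analyses can be run step by step as numbered scripts:

```bash
python analysis/01_simulate.py
python analysis/02_parcellate.py
python analysis/03_networks_geometry.py
python analysis/04_hierarchy_hubs.py
python analysis/05_multilayer_flexibility.py
python analysis/06_similarity_fingerprint.py
```

each of which prints what it found and writes tables under `results/`.
A `mesoconn` CLI wraps the same stages (`mesoconn simulate`, `parcellate`,
`build-fc`, `modules`, `multilayer`, `metrics`, `run`, `report`).

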