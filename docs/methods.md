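# Methods

`mesoconn` reimplements, as a tested pipeline over synthetic data, a
mesoscale functional-connectivity analysis of whole-brain single-cell
calcium imaging in larval zebrafish: cells are aggregated into
hemispherically symmetric parcels, parcel activity yields signed Fisher-z
correlation networks, and those networks are analyzed with uniform-null
signed modularity maximization (hierarchical and multilayer), hub metrics,
and similarity statistics. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic experiments do
and do not establish.

## Synthetic study generator

The generator produces the statistical structure the analyses assume of
real data; it is not a biophysical simulator.

**Geometry.** Cells are rejection-sampled uniformly inside the left half of
an ellipsoid (default semi-axes 150 × 400 × 100 px, midline along axis 0 —
roughly the proportions of a registered larval zebrafish volume in pixel
units) and mirrored exactly, so every left cell has a bit-identical right
partner. Mirror symmetry is therefore exact to machine precision, which the
parcellation stage relies on.

**Correlation plant.** Each cell carries a fine-module label; fine modules
nest in coarse modules. The structured correlation target is

    R = T + (1 − T) ∘ exp(−λ D),

where `T` holds the planted tree targets (within-fine 0.6 > within-coarse
0.3 > between 0.05 by default, 1 on the diagonal), `D` is the pairwise
distance matrix and λ (`decay_rate`, default 0.01 /px, i.e. a 100 px decay
length) is the spatial kernel rate; λ = 0 disables the kernel. Because fine
modules are defined on the left hemisphere and mirrored, homotopic cell
pairs share modules, which produces the planted minority of strong
long-range mirror-symmetric connections on top of the distance decay. `R`
is projected to the nearest positive-semidefinite matrix (eigenvalue
clipping) and factored once per condition; traces are Gaussian:

    x_i(t) = [structured component]_i(t) + a_g · g(t) + a_s/√m · Σ_k u_k(i) z_k(t) + σ ε_i(t)

with a shared global signal `g` (weight `global_amp`, default 0.5),
independent noise (`noise_sd`, default 1.0), and per-subject modes
described below. With no modules and λ = 0 the structured component is
absent and the expected off-diagonal correlation is the closed form
`global_amp² / (global_amp² + noise_sd²)`, which the tests verify.

**Conditions and flexibility.** Five conditions (spontaneous, phototaxis,
optomotor, looming, dark flash) share the plant except that a designated
flexible cell subset is reassigned to other fine modules per stimulus
condition via `condition_remap`; the spontaneous condition always uses the
base assignment. This is the ground truth that multilayer flexibility
should recover.

**Subject individuality.** Each subject receives `n_subject_modes = 80`
latent signals with spatially smooth loading maps (Gaussian bumps at random
anchor cells, lengthscale 40 px, centered and RMS-normalized, amplitude
`subject_amp = 2.5`), drawn once per subject and shared across that
subject's conditions. Smoothness is essential: per-cell-pair iid
correlation jitter averages away under parcel aggregation and produces no
subject-level individuality. With these defaults the parcel-level
intersubject FC similarity is ≈ 0.85 and the within-subject
(across-condition) similarity ≈ 0.96 — strictly between 0 and 1 with self
above other, which is the property the fingerprinting analysis needs.

**What the generator does not emulate.** Calcium indicator kinetics,
spiking, motion artifacts, non-Gaussian fluorescence marginals, real
neuroanatomy, per-subject cell clouds (all subjects share one exactly
aligned cloud), and realistic levels of biological variability. Because the
planted block structure is far cleaner than biology, intersubject
similarity stays higher than in real recordings; tests passing here show
that the machinery recovers planted structure under the stated noise, not
that it would recover structure at real-data noise levels.

## Parcellation

Stages, with the defaults used by the desk-scale analysis in parentheses
(full-scale values would be k_spatial = 2500, k_functional = 100):

1. **Spatial k-means** (k_spatial = 60 per hemisphere, best of 10
   replicates) on left-hemisphere coordinates pooled over subjects.
2. **Mirroring**: right centroids are exact reflections; right cells join
   the nearest mirrored centroid. The homotopic cluster pairing is a
   bijection by construction.
3. **Global-signal regression** of each cell's concatenated
   (spontaneous + stimulus) trace on [intercept, mean-over-cells trace];
   residuals are exactly orthogonal to the global signal.
4. **Functional k-means** (k_functional = 12) with correlation distance on
   the spatial-cluster correlation matrix averaged over subjects and
   hemispheres (a cluster's block averaged with its homotopic partner's).
   Correlation distance is realized by row centering + unit-norm scaling
   before Euclidean k-means, so labels are invariant to positive affine
   transforms of rows.
5. **Spatial subdivision**: within each functional cluster, single-linkage
   agglomeration of spatial-cluster centroids cut at `min_gap` (60 px)
   separates spatially disconnected chunks; any chunk whose centroid
   diameter (max pairwise distance) reaches `max_diameter` (200 px) is
   split by recursive bisecting 2-means. Left-hemisphere groups, mirrored,
   are the parcels, so the homotopic parcel pairing is a fixed-point-free
   involution.

The two spatial constraints are not jointly satisfiable in the worst case:
a compact cloud wider than `max_diameter` must be split, and the resulting
siblings are closer than `min_gap`. The implementation guarantees the
diameter bound always and the gap bound between linkage-separated groups;
diameter-driven splits are the only way the gap can be violated. Under the
default generator geometry spatial-cluster centroids are sparse enough that
such splits do not occur, and the pipeline asserts both constraints on its
output.

Cells exactly on the midline would be labeled left by convention (the
sampler produces none). Empty spatial clusters for a subject are excluded
from that subject's correlation average.

## Networks and surrogate nulls

Parcel traces are means of member-cell residual traces (global signal
regressed over the concatenated recording, then restricted to each
condition's frames). Edges are Fisher-transformed Pearson correlations,
`A_ij = atanh(r_ij)`, diagonal zero; correlations numerically at ±1 are
clipped to ±(1 − 1e−12). Group networks are element-wise means across
subjects.

Surrogates rotate the phases of every non-DC (and non-Nyquist, for even
length) Fourier bin of each parcel trace by independent uniform offsets and
invert the real FFT, preserving each amplitude spectrum (hence mean and
variance) exactly while destroying cross-correlations. Surrogate group
networks repeat the subject-FC + group-average computation on surrogate
traces. Source-vs-surrogate FC similarity uses Spearman correlation of
upper triangles; on planted data its mean over an ensemble is ≈ 0.

## Modularity maximization

Quality function (single layer):

    Q(γ, {g_i}) = Σ_{i≠j} (A_ij − γ) δ(g_i, g_j),

a uniform null `P_ij = 1` scaled by the resolution γ — appropriate for
correlation matrices and free of the resolution limit of degree-preserving
nulls. The sum runs over ordered pairs with the diagonal excluded, so
all-singletons scores exactly 0 and Q is invariant to shifting all weights
and γ by the same constant.

**Optimizer.** A generalized Louvain heuristic on the dense modularity
matrix: greedy single-node moves (with an always-available empty community,
so nodes can split off) until no move improves Q, then aggregation,
repeated to a fixed point. Node visitation order is randomized from the
seed. `louvain_optimize` takes the best of 20 restarts (first from
singletons, then from random coarse initializations) and never returns less
than both trivial partitions. On 2,000 random signed 8-node instances it
matched the exhaustively enumerated optimum (Bell(8) = 4,140 partitions) on
every instance; the package ships the enumeration oracle in
`mesoconn.exhaustive` and the test suite re-runs this comparison.

**Resolution sampling.** γ_max is the maximum off-diagonal weight (above
it singletons are optimal); γ_min is the smallest γ producing ≥ 2 modules,
located by bisection with repeated Louvain runs. γ values are drawn with
replacement from the connection weights inside [γ_min, γ_max], so the
sampling density follows the network's own weight distribution
(desk default 300 samples; one Louvain run per sample).

**Consensus hierarchy.** The ensemble is summarized by a coassignment
matrix (fraction of partitions joining each pair). Recursively, within the
current node set: the observed maximum off-diagonal coassignment is
compared against a permutation null (each partition's labels shuffled
within the node set, 100 permutations); if p < α = 0.05 the set is split by
Louvain on the null-centered coassignment submatrix and recursion
continues. Levels are tree cuts at increasing depth, so each level refines
its parent by construction. The permutation statistic and the
Louvain-on-centered-coassignment split are this package's concrete
realization of statistically gated recursive consensus clustering.

**Significance vs surrogates.** For each hierarchy level, the empirical
statistic is the maximum Q among ensemble partitions with that level's
module count (at their own γ); each surrogate network is optimized once at
the median of those γ values, and p = (1 + #{Q_surr ≥ Q_emp}) / (1 + n),
Bonferroni-multiplied by the number of levels. The desk default of 200
surrogates keeps the corrected floor below 0.05 for hierarchies of ≤ 9
levels.

## Multilayer modules and flexibility

Condition networks are layers; node i in layer s couples to itself in every
other layer with weight ω (categorical all-to-all coupling):

    Q = Σ_s Σ_{i≠j} (A_s,ij − γ) δ(g_is, g_js) + Σ_i Σ_{s≠r} ω δ(g_is, g_ir),

optimized by the same Louvain engine on the supra-modularity matrix (N·T
supra-nodes; 30 restarts including a start with each node merged across
layers). ω = 0 decomposes exactly into independent single-layer problems;
large ω locks every node's label across layers. ω is sampled as 10^u with
u uniform on [−3, 1] (so ω spans 0.001–10); γ and ω samples are drawn
independently and paired, one optimization per pair (desk default 100
pairs).

Flexibility is the fraction of layer pairs on which a node's assignment
differs, `f_i = 1 − 2/(T(T−1)) Σ_{r<s} δ(g_ir, g_is)`; per-node flexibility
is averaged over runs whose mean per-layer module count lies in [2, 25],
with runs weighted equally, and a rank-transformed average is also reported
(rank transformation removes the baseline shift that ω induces without
changing the spatial pattern).

## Network metrics

- **Participation** (positive weights only):
  `p_i⁺ = 1 − Σ_c (κ_ic⁺ / k_i⁺)²`; nodes with zero positive strength get 0
  by convention. Computed at every hierarchy level, averaged, and
  rank-transformed; bounded by 1 − 1/C for C modules.
- **Absolute strength** `s_i = Σ_j |A_ij|`.
- **z-Rand**: the count of co-assigned pairs `w_XY` standardized by its
  mean `W_X W_Y / W` and the closed-form permutation-model variance (exact
  integer pair counts; the variance formula follows the standard z-Rand
  reference). One-sided normal p-values; Monte-Carlo tests confirm mean ≈ 0
  under independent random partitions.
- **Geometry profile**: distance-binned mean weight (within- and
  between-hemisphere separately) and connection-class proportions with
  thresholds t_neutral = 0.1, t_strong = 0.5 in Fisher-z units
  (anticorrelation < −t_neutral; neutral |w| ≤ t_neutral; weak positive ≤
  t_strong; strong positive above). The thresholds and equal-width bins are
  configurable; empty bins report NaN, not 0.
- **Hemispheric similarity**: Pearson r between left within-hemisphere
  edge weights and the homotopically reordered right ones (Fisher-z units).
- **Mantel test**: Pearson r of upper triangles; one-sided permutation p
  with simultaneous row/column permutation (desk default 999 permutations;
  calibration verified under independence).
- **Similarity report**: pairwise upper-triangle Pearson r; with subject ×
  condition labels, mean self-similarity (same subject, different
  conditions) vs mean intersubject similarity (different subjects,
  different conditions).

## Orchestration, sizes and determinism

`run_pipeline` executes simulate → parcellate → networks (+ surrogates) →
geometry → hierarchy (+ significance) → hubs → multilayer flexibility →
similarity, logging each stage's seed and wall time. Per-stage seeds are
spawned from the master seed by a counter-based scheme
(`SeedSequence([master, stage])`), so stages can be rerun in isolation;
every output file carries a hash of the config and loaders can reject
mismatched reuse.

The desk-scale defaults (800 cells, 3 subjects, 5 conditions, 600 frames,
60 spatial clusters/hemisphere, 12 functional clusters, 300 γ samples, 100
multilayer pairs, 200 surrogates) were chosen so the full pipeline and its
planted-recovery experiments complete in minutes on one core while every
stage still has enough signal for its statistical test to resolve; the
generator's scientific parameters (correlation targets, decay rate, noise,
flexibility plant) are the study conditions and are independent of these
sizes.

## Known limitations

- Zero-lag Pearson correlation only; no lagged, partial or directed
  connectivity, no deconvolution.
- The consensus split criterion and the level-wise surrogate comparison
  are concrete realizations of methods whose published descriptions leave
  the statistic underdetermined; alternatives (e.g. different split
  statistics) would give slightly different hierarchies.
- Full-scale results on real recordings (256 parcels from 80,000 cells per
  subject, 10,000 resolution samples) are outside the desk scale exercised
  here; the pipeline's parameters accept those values unchanged.
- The gap/diameter tension in the parcel subdivision (above) means the gap
  guarantee is conditional on geometry; the pipeline asserts it on its own
  outputs rather than assuming it.
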