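# Methods

## Data model and conventions

An FC input is a symmetric `N×N` matrix of edgewise test statistics
(diagonal ignored, symmetry enforced at 1e-12). The complete FC graph has
`N(N−1)/2` edges; edge adjacency is node-sharing (two edges are neighbors
iff they share an ROI), so edge clusters are exactly the connected
subgraphs of the thresholded ROI graph and cluster size is the component's
**edge count**. Voxel clusters, by contrast, count **voxels**.

All engines work on the positive tail only: a statistic ≤ 0 receives
TFCE = 0. Negative-tail and two-sided analyses run the machinery a second
time on the negated input (CLI `--negate`, inference `tails="neg"/"both"`
with Bonferroni doubling of the smaller tail; off by default since
one-tailed is the common convention and doubling is the conservative
explicit choice).

Threshold discretization:

- thresholds are `h_k = k·dh` for `k = 1..nth`, `nth = ⌈tmax/dh⌉` — the
  ceiling guarantees the map's maximum statistic is covered by the topmost
  threshold;
- membership is **non-strict** (`stat ≥ h_k`), so `bin(stat) = ⌊stat/dh⌋`
  with exact float-floor semantics and no tolerance: values exactly on a
  bin boundary behave deterministically and documentably. The h = 0 term
  contributes nothing for `H > 0`, so the sum effectively starts at `dh`
  (right-endpoint heights). This makes the single-edge discretized sum
  converge to `t^{H+1}/(H+1)` from above as `dh → 0`.
- the reference engine evaluates level-k membership as `bin(stat) ≥ k`
  rather than `stat ≥ k·dh` — algebraically identical, but immune to the
  float rounding of `k·dh`, so the oracle and the incremental engine can
  never disagree about membership at a boundary.
- `tmax` (hence `nth`) is recomputed per statistic map, including
  separately for every permutation: the grid is a property of the map, not
  of the analysis.

Default exponents are the field's standard choices: `E = 0.4, H = 3.0` for
FC data and `E = 0.5, H = 2.0` for voxel data; `dh = 0.1` by default, with
`dh = 0.25` acceptable for large-scale screening (the power analysis below
shows dh has no measurable power cost in these conditions).

## The incremental engine

Bins are processed from `nth` down to 1. Each edge either joins an
existing cluster in O(1) (both endpoints already co-clustered, or one
endpoint fresh) or merges two clusters; merging relabels every node of the
smaller cluster (union-by-size), bounding total relabeling by
O(N log N). Full relabeling — not path-compressed union-find — is
deliberate: the per-threshold size snapshot requires every node's current
cluster to be readable by direct indexing at the end of each bin. The
merge counter (every event that reduces the cluster count by one, starting
from N conceptual singletons) can never exceed N−1.

After bin k the snapshot `S[k][v]` records node v's cluster edge count (0
for untouched nodes, with `0^E := 0` for `E > 0`). Then
`F[k][v] = F[k−1][v] + S[k][v]^E (k·dh)^H dh` accumulates ascending, and
edge `(u,v)` reads `TFCE = F[bin][u]`, which equals `F[bin][v]` bitwise
because both endpoints share a cluster at every level up to the edge's bin.

Memory: `S` and `F` are dense `(nth+1)×N` arrays. When `(nth+1)·N` exceeds
a configurable budget (default 2²⁴ entries) the engine does not
materialize `F`: it streams one `F` row at a time, resolving the edges of
bin k as soon as row k is complete. `S` stays dense (every row of `F`
depends on all earlier rows of `S`), so the fallback saves the float64 `F`
matrix (~⅔ of the peak); results are bit-identical and tested as such.
Within a bin, edges are processed in (u,v)-lexicographic order — cluster
results are order-invariant, so this fixes internal state for
reproducibility only.

## The exact engine

Sorting the distinct positive statistics `0 = hs(0) < hs(1) < … < hs(nv)`
makes `c(x,h)` piecewise constant, so

    TFCE(x) = Σ_{i: hs(i) ≤ stat(x)} c(x, hs(i))^E · (hs(i)^{H+1} − hs(i−1)^{H+1})/(H+1).

The sweep runs descending. Each cluster stores a running score and its
last flushed height; touching a cluster first flushes the pending interval
in O(1) (`flush_cluster`). A merge flushes both constituents to the merge
height, freezes them, and creates a new cluster object holding the
combined size; parent pointers from both constituents let any edge recover
its total as (sum of scores along the parent chain from its entry cluster)
minus its recorded entry score. Integration runs from 0 (every surviving
cluster is flushed to height 0 at the end), matching the `hs(0) = 0`
convention. Tied statistics collapse into one height: all edges at the tie
enter before anything below is flushed, and the zero-length interval
between ties contributes nothing — this preserves the piecewise formula
exactly under ties. `H = −1` is rejected (the power integral has no such
closed form); the exact engine takes no `dh` and the CLI refuses `--dh`
with `--method exact`.

## The voxel graph transform

One node per in-mask voxel (activating at its own statistic), one edge per
adjacent in-mask pair under 6/18/26-connectivity, with weight
`min(stat_u, stat_v)`. Because an edge never outlives either endpoint,
thresholding the graph at h reproduces the components of the thresholded
volume exactly — singleton supra-threshold voxels included, which the
edge-only FC representation would miss. Within a threshold bin, node
activations are processed before edge activations so singletons exist
before edges join them. Out-of-mask voxels are absent from the graph, not
zero-valued nodes. 18-connectivity is included as a standard option
alongside 6 and 26. The per-voxel TFCE contribution is added directly
after each bin (cluster sizes are node counts, readable from the merge
state), so no `S`/`F` accumulator is needed.

Coordinates are 0-based array indices; adjacency offsets are generated
programmatically; any NIfTI affine is carried through I/O untouched and
never interpreted.

## Permutation inference

Observed edgewise t statistics (pooled-variance two-sample, or one-sample
against zero; zero-variance edges get t = 0 with a logged warning) are
TFCE-transformed by the chosen engine; the null distribution collects the
global maximum TFCE from `n_perm` relabelings (two-sample: group-label
shuffles; one-sample: sign flips). p-values use
`(1 + #{perm: max ≥ observed})/(n_perm + 1)`, never zero and exact-level.
The permutation sequence depends only on the seed and design, so engine
choice cannot alter the inference beyond TFCE numerics. Requesting more
permutations than distinct relabelings warns and keeps sampling with
replacement.

Power estimation draws `n_reps` independent datasets with a planted
effect; per-edge power is the rejection frequency at level α. When several
parameter sets are compared (e.g. dh values), each repetition reuses the
identical subject draw and permutation sequence across parameter sets, so
power differences isolate the parameters. A user-supplied node→network
labeling yields per-network power (mean rejection frequency over edges
with both endpoints inside the network; "top" networks are ranked by that
mean, descending). At 100 repetitions the binomial standard error of any
power estimate is at most √(0.25/100) = 5%.

## Synthetic data

`synth_stat_matrix` emulates a smoothed edgewise t-statistic map: an
`N×N` standard-normal field, zero-padded 2D Gaussian filter with
`σ = 0.01·N` by default (σ proportional to N keeps the correlation
structure a constant fraction of the matrix across parcellation sizes; the
ratio is exposed because no canonical value exists), then symmetrization
by averaging with the transpose. The filtered field is rescaled to unit
marginal SD before symmetrizing (`standardize=True`): smoothing alone
shrinks the marginal SD by ~`1/(2σ√π)`, which would leave `tmax` below
common `dh` values and make every TFCE map trivially empty; the rescale
keeps the output on a t-statistic scale (`tmax ≈ 3–4`) where the engines
do real work. Averaging with the transpose shrinks the scale by a further
~√2 on the (mostly independent) off-diagonal pairs.

`synth_group_dataset` draws independent upper-triangle Gaussian noise per
subject (null edges are then exactly Student-t distributed under the
two-sample t, which the tests verify by KS) and adds
`effect_size · noise_sd` at the effect edges for group B. Defaults — 20
subjects per group, 30 ROIs, a 5-node effect block, effect 0.5 SD — are a
small two-group FC study. What this generator does **not** emulate:
subject-level correlation structure between edges, heavy-tailed or
autocorrelated fMRI noise, site/motion confounds, or realistic effect
topographies. Passing calibration and power tests therefore demonstrates
the correctness of the inference machinery under exchangeability, not
performance on real fMRI data.

`synth_voxel_image` places Gaussian blobs of a given peak on a zero
background with optional additive noise — enough structure to exercise
cluster formation, not a model of SPM-style random fields.

## Validation suites and problem sizes

The test battery (all of it runs in the default `pytest` invocation; the
full suite takes about a minute on one CPU) includes:

- incremental vs reference: 108 smoothed matrices spanning
  N ∈ {10, 30, 80} × dh ∈ {0.01, 0.1, 0.25} × (E,H) ∈ {(0.4,3), (0.5,2),
  (1,1)} × 4 seeds, max relative difference ≤ 1e-9; plus the N = 200,
  dh = 0.1 absolute bound < 0.001;
- exact vs explicit interval enumeration (networkx components per
  interval) on random 12–15-node graphs; λ-scaling `λ^{H+1}`; discrete →
  exact convergence;
- voxel graph clusters vs `scipy.ndimage.label` on random masked volumes
  (≤ 12³, all three connectivities, 20 random thresholds each);
  incremental voxel TFCE vs threshold-label-sum brute force;
- structural bounds: merge counter ≤ N−1 (= N−1 when connected),
  S non-increasing in k, exact endpoint symmetry of F;
- inference calibration: familywise error over 200 null simulations
  (N = 30, 20 subjects/group, 200 permutations) within [0.02, 0.09] at
  α = 0.05; power monotone over effect sizes {0.3, 0.8, 1.5} at 100
  repetitions; dh ∈ {0.01, 0.25} power difference within 2 binomial SE on
  shared draws at 50 repetitions. These sizes keep each suite seconds-to-
  minutes while leaving the binomial error bars informative.

## Known limitations

- The FC engines are quadratic in N by construction; the pure-Python merge
  loop is comfortable to N ≈ 1000 but is not a compiled implementation.
- Sparse statistic matrices, directed graphs, and anatomical-proximity
  (SPC-style) edge adjacency are out of scope; adjacency is node-sharing
  for FC and geometric for voxels.
- GLM contrasts beyond one/two-sample t, FDR procedures, and cluster-size
  (non-TFCE) inference are not provided.
- Surface/CIFTI data and anisotropic-voxel adjacency weighting are not
  supported; voxel adjacency is purely index-based.
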