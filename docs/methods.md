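# Methods

## Problem setting

Multichannel EEG coherence networks couple an electrode layout (a 2D
top-view head projection) with a matrix of magnitude-squared coherences
`c(v, v') ∈ [0, 1]` between electrode signals in a frequency band.
`eegfu` partitions such networks into *functional units* (FUs):
spatially connected groups of electrodes whose pairwise coherences are
all significant, i.e. spatially connected cliques of the thresholded
("significant") coherence graph. Three detection methods are
implemented — CCB, MCB and IWB — together with the coherence estimator
that produces the networks, the analytic significance threshold, and
FU-map rendering.

Spatial structure is the Voronoi diagram of the electrode positions:
two electrodes are *Voronoi neighbors* when their cells share a boundary
segment of positive length, and a set is *Voronoi connected* when it
induces a connected subgraph of that relation. Zero-length ridges are
excluded deliberately; on a square grid this makes the neighbor relation
exactly 4-connectivity (diagonal cells touch only at a point). A
collinear layout degenerates to the chain of consecutive sites, which is
handled as a special case rather than an error.

## Coherence estimation and the significance threshold

Recordings are event-related: each channel is observed in `L` equal
segments (one per stimulus repetition, default 1 s at 256 Hz). Each
segment is mean-detrended, Hann-tapered and Fourier transformed; auto-
and cross-spectra are averaged over the `L` segments and the coherence
is `|f_xy|² / (f_xx f_yy)` per frequency bin `k·fs/T` (one-sided). No
overlap is used — the segments are experimentally defined epochs, and
the analytic null threshold

    θ = 1 − p^(1/(L−1))

is the (1−p) quantile of estimated coherence under independence only
when exactly `L` independent segments are averaged. This coupling is
the estimator's acceptance surface: the test suite verifies that for
independent white noise the fraction of bin coherences above
`θ(0.01, 13)` ≈ 0.319 lies in [0.005, 0.02] (binomial band around
p = 0.01, 200 replicates). The estimator is also cross-checked
numerically against an independent Welch implementation configured to
the same conventions.

Band networks average bin *coherences* (not spectra) over
`λ_lo ≤ λ ≤ λ_hi`. Averaging spectra first would also have been
defensible; bin-coherence averaging is simpler and keeps each band value
inside [0, 1] by construction. Thresholding uses the closed inequality
`c ≥ θ` throughout.

## Local average coherence

The per-electrode *local average coherence* is the mean of `c(v, u)`
over **all** Voronoi neighbors `u`, including sub-threshold values.
This is a property of the raw coherence field, not of the significant
graph; restricting to significant neighbors would reorder vertices (on
the built-in 12-node fixture it would rank `b` above `f`) and break the
reference ordering `h,a,f,e,b,l,d,g,i,j,c,k` that the CCB processing
order reproduces. Ties are broken by ascending label order everywhere a
ranking or iteration order matters — determinism is a design requirement
so that identical inputs always give identical partitions.

## CCB: community clique detection

CCB is a single-phase, spatially constrained variant of Louvain-style
greedy modularity optimization. Modularity uses the ordered-pair
convention including diagonal null terms (`c(v,v) = 0`):

    Q = (1/2m) Σ_{v,v'} [c(v,v') − K_v K_{v'} / 2m] δ(L(v), L(v'))

with `m` half the total weight and `K_v` the weighted degree. Starting
from singletons, vertices are visited in descending local average
coherence; vertex `v` may move into community `C_i` only when it is
connected (in the significant graph) to *every* member of `C_i` and has
at least one Voronoi neighbor in it, and the move is skipped entirely
when removing `v` would spatially disconnect its source community.
Among admissible targets the first community (ascending index) with the
strictly positive maximum gain wins. Passes repeat until a sweep makes
no move. There is no aggregation phase: communities must remain cliques
of original electrodes, so every output community with ≥ 2 members is a
spatially connected clique.

The closed-form gain of moving `v` into `C_i` is

    ΔQ = (1/m) [ Σ_{l∈C_i} c(v,l) − Σ_{l∈C_{L(v)}\{v}} c(v,l)
                 − K_v (K_{C_i} − K_{C_{L(v)}} + K_v) / 2m ].

Under the ordered-pair convention above, the `1/m` prefactor makes this
*exactly* the modularity difference of the move; the test suite holds
the identity to 1e−10 over hundreds of random states and moves. (A
`1/2m` prefactor — sometimes seen with other summation conventions —
would be a positive rescaling and leave every greedy decision, and hence
every partition, unchanged.)

The candidate bookkeeping (`H_i`: vertices connected to all members of
`C_i`; `R_i`: vertices with a Voronoi neighbor in `C_i`) is maintained
incrementally — intersection with the mover's graph neighborhood, union
with its Voronoi neighborhood — with the source community's sets
recomputed from its survivors. A `full_recompute` mode recomputes both
sides from scratch; tests assert both modes give identical partitions,
and a `debug` mode validates the clique/connectivity invariants and the
monotonicity of Q after every accepted move.

## MCB: Voronoi-constrained maximal cliques

MCB enumerates the cliques of the significant graph that are maximal
*within the family of Voronoi-connected cliques* — a returned set may be
a strict subset of a larger, spatially disconnected clique. The
recursion is Bron–Kerbosch-like with a spatial frontier: candidates
connected to the whole growing clique are split into `currentcand`
(Voronoi-adjacent to at least one member, addable now) and `complcand`
(only reachable after the frontier grows toward them); adding vertex `v`
promotes its Voronoi neighbors from `complcand`. The next vertex is the
candidate with the most graph connections to the remaining candidates
(ties: lowest label by default, or seeded random — the clique *set* is
identical either way, only traversal order changes).

The used-vertex (`not`) set is split the same way as the candidate set:
a previously processed vertex suppresses a report only while it is
Voronoi-adjacent to the growing clique, because only then could it
extend the clique within the Voronoi-connected family. Treating `not`
as a single set would wrongly suppress, for example, the second of two
singleton cliques joined by a significant but spatially non-adjacent
edge. Correctness is checked against an exhaustive subset-scan oracle
on fifty random 12-vertex grid graphs.

A vertex belonging to several enumerated cliques is kept only in the
clique of largest *total strength* (sum of within-clique significant
edge weights); ties go to the clique whose sorted member tuple is
lexicographically first. The residual of a clique that loses vertices
is kept as an FU even though it is no longer maximal; if a removal
spatially disconnects a residual (not observed on any built-in fixture,
and impossible on the worked example), a warning is emitted and the set
is still reported — the behavior in this corner is genuinely
underdetermined. Enumeration is exponential in the worst case and is
intended for layouts up to ~128 electrodes.

## IWB: improved graph watershed

Markers are electrodes whose local average coherence is a weak maximum
over their *significantly connected* Voronoi neighbors (at least one
such neighbor required). The flood can only travel along significant
spatial edges, so electrodes with none cannot seed a basin — on the
12-node fixture this yields exactly the three reference markers; the
two isolated electrodes end as singletons regardless. Comparing against
all Voronoi neighbors instead would leave a community markerless (and
therefore unfloodable) whenever a stronger neighboring community drags
the boundary averages up, which contradicts the recovery behavior the
planted-partition benchmark requires. Equal-value plateaus of mutually
Voronoi-adjacent candidates contribute one marker: the smallest label.

Each marker seeds a basin; the queue is initialized with significant
edges from markers to their unlabeled Voronoi neighbors and popped in
descending coherence (ties: insertion order, then lexicographic edge).
A popped edge `(v, v')` labels `v'` into `v`'s basin only if `v'` is
significantly connected to every current member — basins stay cliques —
and then enqueues significant edges from `v'` to its unlabeled Voronoi
neighbors. Edges failing the clique test are discarded, not re-queued.
If `v'` already carries another label, the two basins merge iff their
union is a clique; no spatial re-check is needed because both basins
grew Voronoi-connected and the popped edge's endpoints bridge them.
Unlabeled vertices become singletons. The implementation can replay its
dequeue log, and the test suite pins the full event sequence on the
worked example, including one failed and one successful merge.

## FU maps

For an FU `C`, the average coherence `ĉ(C)` is the mean over ordered
member pairs, and for disjoint FUs the inter-FU coherence
`c'(C1, C2) = Σ c(v_i, v_j) / (|C1||C2|)`; both include sub-threshold
coherences so that sizes normalize comparably. `ĉ` is undefined for
singletons and rendered as an uncolored circle.

The map shows each electrode's Voronoi cell clipped (for rendering only)
to a padded convex hull, or to a circular head outline for montage
layouts. FUs with at least `display_min_size` members (default 5, a
configurable convention; 4 is also seen in practice) receive gray levels
by greedy coloring over a deterministic palette such that Voronoi-
adjacent displayed FUs never share a level; smaller FUs' cells are
white. A circle at each displayed FU's barycenter (arithmetic mean of
member positions — it may fall outside the FU's own cells) is colored by
`ĉ`; lines join displayed FU pairs whose `c'` reaches the line threshold
(default: the significance threshold θ; closed comparison, with a strict
mode available). Circle and line colors come from one fixed sequential
colormap with domain [0, 1], so colors are comparable across maps. SVG
output is hand-written with fixed formatting and is byte-stable for
fixed inputs; PNG uses matplotlib.

## Synthetic data

The generator suite defines the study conditions used by the tests:

* **Worked example fixture** — the exact 12×12 coherence matrix on a
  3×4 unit grid (rows a–d / e–h / i–l, position (col, −row)), θ = 0.2.
  All three methods, the vertex ordering, the clique enumeration and
  the watershed dequeue order are pinned to their published traces.
* **Planted-partition networks** — contiguous communities grown by
  seeded multi-source BFS on a grid (contiguity is guaranteed by
  construction, matching the spatial assumption of all three methods);
  coherence `within ± jitter·U(−1,1)` inside, `between ± jitter·U(−1,1)`
  across, clamped to [0, 1]. Defaults: 3×4 grid, 2 communities, within
  0.7, between 0.1, jitter 0.05, θ = 0.3 — a regime where each
  community is an isolated spatial clique, so exact recovery by all
  three methods is the correctness bar (20 seeds in the tests).
* **Simulated recordings** — each community shares a latent sinusoid
  (default 10 Hz) whose phase is redrawn per segment; channels see
  `snr·source + unit noise` (default snr 1, L = 13 segments of 256
  samples at 256 Hz, mirroring the event-related design). Different
  communities get independent sources, so cross-community coherence
  follows the independence null.

What the generators do *not* emulate: volume conduction and reference-
electrode leakage (which inflate short-range coherence in real EEG),
1/f background spectra, artifacts, or any realistic forward model.
Passing the recovery tests therefore shows the algorithmic chain is
correct under its own assumptions, not that FUs on real recordings are
neurophysiologically meaningful. Real-data results (larger montages,
oddball ERP recordings) are out of scope: no such data ships with the
package, and the synthetic pipeline test stands in for them.

## Numerical conventions and edge cases

* Matrix validation: symmetry within 1e−12 (file reader: 1e−9, then
  symmetrization by averaging), exactly zero diagonal, values in [0, 1].
* Estimated coherences are clipped to [0, 1] only against rounding-level
  excursions; the estimator is analytically bounded.
* Zero-variance channels are an error naming the channel; an isolated
  zero-power bin with nonzero total variance yields coherence 0 rather
  than NaN.
* Degenerate Voronoi input: duplicate positions are an error naming the
  colliding labels; collinear layouts fall back to the sorted chain.
* All randomness (generators, optional random tie-breaks) flows through
  `numpy.random.Generator` objects seeded explicitly; identical seeds
  give byte-identical outputs.
* Problem sizes in the test suite and acceptance script — 12-vertex
  graphs, 20 generator seeds, 200 calibration replicates, 50 oracle
  graphs — were chosen so the exhaustive oracles (subset scans over
  2^12 sets) stay exact while the whole suite runs in well under a
  minute.

## Known limitations

* CCB is greedy: it maximizes modularity only over the move sequence
  its constraints admit, with no restarts or aggregation; different
  processing orders could yield different (valid) partitions.
* The watershed discards edges that fail the clique test at pop time;
  a vertex rejected early is only reachable again through a different
  queued edge.
* MCB enumeration cost grows exponentially with clique structure;
  beyond ~128 electrodes it is not the tool of choice.
* The display-size and line-threshold defaults are conventions, not
  estimates; they are parameters precisely because the literature
  varies.
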