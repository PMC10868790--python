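# Methods

This note documents the models implemented in `connscale`, the parameters
that matter, what the synthetic cohort generator does and does not emulate,
and the numerical and design choices made where more than one reasonable
option existed.

## Modularity and the multiresolution consensus

Modularity is scored as

    Q(γ) = (1/2m) Σ_ij [ W_ij − γ P_ij ] δ(σ_i, σ_j),   P_ij = k_i k_j / 2m,

with strengths k, total weight 2m, and the diagonal terms of the
configuration null included. Q is reported normalized by 2m; normalization
does not change the argmax at fixed γ and makes values comparable across
networks. Optimization is Louvain (igraph's `community_multilevel` with the
resolution parameter), seeded per call for reproducibility; the one-module
and all-singleton baselines are always evaluated so the returned partition
never scores below either.

The multiresolution sweep is two-step: `n_gamma` log-spaced resolutions
over [0.01, 10] (one Louvain run each), then `n_gamma` more over
[γ_L, γ_H], where γ_L is the smallest resolution yielding ≥ 2 modules and
γ_H the largest yielding ≤ N/2. Fine-sweep partitions violating the
[2, N/2] window are dropped — the operationalization of "informative
partitions only"; with well-behaved networks only a handful fall out. One
run per γ is used in the sweep (across hundreds of resolutions the ensemble
is already diverse); restarts are reserved for the consensus step
(default 100 restarts of Louvain at γ = 1 on the CC matrix, diagonal
zeroed so the graph has no self-loops). γ_L/γ_H are determined per animal;
a joint window across animals can be imposed by passing a fixed
`coarse_range` to each call.

Module features: IMD is the mean, over modules with ≥ 2 nodes, of
within-module edge count / (n_m choose 2); singleton modules are excluded
(density undefined) and an all-singleton partition is an error. The
long-distance feature ranks existing edges by Euclidean distance (ties
broken by ascending node pair), takes the top ceil(0.05·E), counts those
with endpoints in different modules, and normalizes by the module count —
values above 1 are therefore possible by construction. The interhemispheric
index is mean between-hemisphere CC over mean within-hemisphere CC with the
diagonal excluded.

## Communication measures

Edge weights are converted to lengths L = 1/W. SPE inverts the shortest
path-length matrix elementwise; unreachable pairs get SPE = 0 and are
excluded from couplings via the validity mask. Search information follows
the unique shortest path, made deterministic by a lexicographic tie-break
(smallest next node index among ties — relevant only for exactly tied
lengths, e.g. integer-weight toys); transition probabilities are
p_uv = W_uv / s_u. NSI is the symmetric form −(SI_ij + SI_ji)/2; the /2
averaging is a convention and is immaterial to all rank-based statistics
downstream. Communicability normalizes by S^(−1/2) W S^(−1/2) before the
matrix exponential; a `literal_strength_product` switch provides the
W_ij/(s_i s_j) variant. Isolated nodes are NaN-masked; a fully empty graph
returns the identity (no walks).

The morphospace standardizes the mean off-diagonal SPE and CMY against
ensembles (default 10 realizations) of 1-D ring lattices and uniform random
graphs with the same node count, edge count, and weight multiset (weights
assigned by random permutation of the empirical multiset — the reference
families inherit the weight distribution, so the scaling is invariant to
uniform weight rescaling). `(X − ⟨X_latt⟩)/(⟨X_rand⟩ − ⟨X_latt⟩)` maps the
lattice reference to 0 and the random reference to 1; single-realization
permutation noise is roughly ±0.02 at N = 100 and 400 edges.

## Portraits and representative selection

A portrait B[l,k] counts nodes with k others at binned shortest-path
distance l. Continuous distances are discretized into 25 quantile bins;
when networks are compared, bin edges come from the pooled distances of
the comparison set, so portraits share a common discretization. One
overflow bin beyond the last edge absorbs unreachable pairs, keeping
disconnected graphs comparable. The divergence converts each portrait to a
joint distribution P(l,k) ∝ k·B[l,k] (each cell weighted by the node pairs
it represents) and takes the base-2 Jensen–Shannon divergence, which is
symmetric, zero on identical portraits, and bounded by 1.

Representative ("centroid") selection computes pairwise divergences over
repeated instantiations, discards instances whose mean distance exceeds
the median by more than 3 scaled MADs (consistency constant 1.4826), and
returns the survivor with minimal mean distance recomputed over survivors
(ties to the lowest index). Cohort outlier flagging adds a within-order
rule: items whose total distance to same-order members has z > 3 inside
their own order; singleton orders are exempt (z undefined) and reported.

## Null models

- Mantel-style: rows and columns of a node-pair matrix permuted jointly;
  value multiset, symmetry, and unit diagonal conserved exactly.
- Module allegiance: node→module labels shuffled; module-size multiset
  conserved exactly.
- Distance-binned rewiring: existing edges sorted by Euclidean distance
  into `n_bins` equal-count bins (default 10; the bin count trades
  geometric fidelity against randomization headroom), then degree-preserving
  double-edge swaps within bins only (default 10× attempts per bin edge
  count; swaps creating self-loops or duplicates are rejected). Weights
  travel with their edge, so weight–geometry coupling is broken only at
  bin resolution. Degree sequence and per-bin counts are conserved exactly.

## Cross-animal statistics

Node-pair couplings are Spearman correlations over masked upper-triangle
entries; non-edges contribute weight 0 and cost 0, distance is always
defined, and communication masks propagate. Per-animal coefficients are
Fisher z-transformed (atanh, clipped at |ρ| = 1 − 1e-12) before the
volume correlation — a monotone transform, so rank-based trend statistics
are unchanged by it (asserted in tests); it is kept for scale reporting.

The allometric fit subsamples 90% of animals without replacement (the
scheme is subsampling, not resampling), fits OLS in log10 space, and
reports the mean ± sd over iterations. Note the subsample sd understates
the slope's sampling error by the delete-d factor sqrt(k/(n−k)) ≈ 3 at
frac = 0.9; recovery tests use the corrected scale. With zero noise the
sd collapses to 0 and the configured law is recovered exactly.

Partial rank correlation rank-transforms all variables, residualizes on
the covariate ranks by least squares, and correlates residuals (t-test
with n − 2 − q df). Taxonomic orders enter as one-hot covariates with the
first level dropped. p-values are reported raw; a Benjamini–Hochberg
option is deliberately not applied by default, mirroring single-panel
reporting practice.

## Synthetic cohort generator

The generator defines the study conditions for every test. Defaults:
200 animals, N = 200 nodes (100 per hemisphere; tests and the acceptance
script use 40 animals and N = 100 for speed — problem sizes chosen so the
full suite completes in minutes), brain volumes log-uniform over
[0.0842, 1597.3] cm³, GM from BV via slope 0.98 / intercept 0.013 and WM
from GM via slope 1.16 / intercept −1.45 in log10-mm³ space, each with
0.05 log10 noise. Pseudo-taxonomic order labels are volume-ordered bins,
reproducing the order–volume collinearity seen in real cohorts.

Geometry: two unit-ball hemisphere clouds mirrored across x = 0, scaled by
volume^(1/3). Each hemisphere holds 4 module centers; nodes choose a
module with probability ∝ exp(−distance-to-center / λ(V)). Edges appear
with probability ∝ exp(−d_ij/λ(V)) · (1 + 4·[same module]), rescaled by
bisection so the realized density hits the 0.15 target even where
short-range probabilities saturate; weights are exp(−d_ij/λ(V)) with
lognormal jitter (ln-sd 1.0, the dispersion scale of streamline counts).
The decay length λ(V) starts at 1.0 hemisphere radii and shrinks
geometrically by 10^0.2 per volume decade (~7× across the range). This
single knob plants the studied trends: larger "brains" have spatially
tighter and denser modules, stronger CC–weight/cost coupling, more
negative CC–distance and distance–efficiency couplings, and lower
standardized routing efficiency. Fiber lengths are 1.2× the Euclidean
distance on existing edges (tracts never shorter than straight lines;
factor configurable). Per-animal random streams derive from (cohort seed,
animal index), so cohorts are reproducible and order-independent.

What the generator does **not** emulate: tractography biases, hemispheric
asymmetries, heavy-tailed degree distributions, true parcellation
variability (the jittered-replicate helper multiplies weights by lognormal
noise with a free sigma — the within-animal variability of repeated
parcellations is uncharacterized, so the magnitude used in centroid tests
is a stated choice, 0.05–0.3), interhemispheric module formation (planted
modules never span hemispheres), or a positive volume trend in
between-module long-distance edges and diffusion preference. Passing tests
therefore demonstrate that the pipeline recovers planted effects of
realistic size and sign — not that real connectomes behave this way.

## Pipeline

Per-animal stages are independent; failures are isolated, logged, and the
run aborts only when the failed fraction exceeds a configured tolerance
(default 0: any failure raises). Runs are fully determined by the
(cohort, config) pair; no on-disk caching layer is used — at these problem
sizes a per-animal run costs seconds, and a content-addressed cache would
add staleness failure modes for no measurable gain. Optional density
thresholding (MST backbone plus descending-weight fill to d ∈ {0.05, 0.10,
0.15}, ceil rounding, ascending-pair tie-break) is applied before all
per-animal analyses when configured.

## Known limitations

- Louvain is greedy; at a single resolution it can return suboptimal
  partitions. The consensus over hundreds of resolutions plus restarts is
  the mitigation, and the trivial-baseline guard bounds the worst case.
- Search information costs O(N² · path length) via explicit path
  reconstruction; adequate at N ≤ a few hundred, not tuned beyond that.
- The morphospace's random reference can be disconnected at low density;
  unreachable pairs enter the mean SPE as zeros, consistent with the
  empirical treatment.
- The partial-correlation covariate control is generic (ranked one-hot
  regression); it is not a phylogenetic regression and does not model
  trait covariance structure.
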