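# Methods

This note documents the model, the numerical choices and the limits of what
the synthetic experiments show.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The reconstruction model

A network state is a binary directed graph on n nodes with exactly K links
and no self-loops, embedded at fixed coordinates.  The objective is

    E(alpha) = alpha * W/W0 + (1 - alpha) * L/L0,       alpha in [0, 1]

with W the summed Euclidean link lengths, L the summed directed shortest-path
step counts over ordered pairs, and W0/L0 single-constraint benchmarks.  L is
finite only on strongly connected graphs, so strong connectivity is a hard
feasibility constraint throughout: the initial random network is strongly
connected, and every proposed move that would break strong connectivity is
rejected and resampled.  Strong connectivity is the weakest condition making
L well defined, which is why it is the package's reading of "the network must
not become disconnected".

With this normalization E >= alpha + (1-alpha) at the joint optimum, i.e.
E >= 1 rather than E in (0, 1].  Any strictly increasing rescaling of E
leaves the optimizer's decisions unchanged at fixed alpha, so the simple
min-normalized form is used and no attempt is made to force E into (0, 1].

### Moves

One existing link is chosen uniformly and deleted; one absent ordered
non-self pair is chosen uniformly and added (four endpoint roles, K
conserved).  A degree-preserving double-edge swap would be wrong here: the
phenomena of interest (hub emergence) require the degree sequence to change,
and only edge relocation at fixed K allows that.  Re-adding the just-deleted
pair is excluded (it would be a null move).  Connectivity-violating
proposals are resampled with a retry budget of 10n per step; an exhausted
budget is a no-op step.

### Annealing schedule

* `steps_per_T = 1000` rewiring attempts per temperature stage;
* geometric cooling `T <- 0.9 T`;
* termination at `T_stop = 1e-6 * T0`;
* `T0` calibrated per run: 200 probe moves are evaluated from the initial
  state and `T0 = mean(dE+) / (-ln 0.8)`, so the initial acceptance ratio of
  worsening moves is about 0.8.  Calibration makes the schedule invariant to
  the layout's length unit and to the normalization of E.
* Metropolis acceptance `P = min(1, exp(-dE/T))`; the best-seen
  configuration (not the final one) is returned — standard practice, and it
  makes the result a monotone function of search quality.

All randomness flows through `numpy.random.default_rng(seed)`; identical
(layout, K, alpha, schedule, seed) gives bit-identical results.  Seeds for
sweeps derive from a master seed via `numpy.random.SeedSequence` with the
(alpha index, realization index) pair, so realizations are reproducible and
independent without coordination.

### Benchmarks

`W0` is the best W over several wiring-only (alpha=1) runs; `L0` the best L
over several efficiency-only (alpha=0) runs; both runs enforce strong
connectivity, and one benchmark pair is shared by all realizations on a
layout.  On a uniform ring with K = 5n the wiring optimum is provably the
+-1/+-2(/+-3) nearest-neighbor chord lattice, which the annealer attains
exactly (asserted in the tests); on sparse layouts the efficiency optimum is
analytic, `L0 = 2 n(n-1) - K`, attained by any diameter-2 configuration.

### Per-move evaluation

L is recomputed after every evaluated move by a level-synchronous BFS from
all sources simultaneously (boolean frontier-matrix products); the loop runs
for as many iterations as the graph's diameter, which is small (2–6) in all
regimes where L matters.  The same computation detects disconnection (an
unreached pair).  At alpha = 1 the objective never consults L, so only
strong connectivity is verified, by two single-source sweeps.  W is updated
incrementally (subtract the deleted chord, add the new one); the tests
assert that the incrementally maintained W, L and E agree with from-scratch
recomputation to 1e-9 relative.

### A note on the alpha = 0 optimum

At sparse densities the efficiency-only optimum is exactly degenerate: every
diameter-2 configuration attains the same L = 2n(n-1) - K.  A configuration
with a full global hub (degree 2(n-1)) is one member of that optimum class;
configurations whose largest node misses one or two links are others, and
the objective cannot prefer among them.  Annealed runs therefore always
reach the exact optimum L with a single z-score hub, but the hub's degree is
2(n-1) only in a fraction of seeds.  As soon as the wiring term has any
weight (the single-hub regime, e.g. alpha = 0.15 on the scaled ring) the tie
is broken and the full 2(n-1) hub appears in every run.

## Modularity and partitions

Directed modularity Q = (1/m) sum_ij [A_ij - k_i^out k_j^in / m] d(c_i,c_j)
is maximized by Leicht–Newman spectral bisection on the symmetrized
modularity matrix with Kernighan–Lin fine-tuning, applied recursively with
the generalized (subgraph) modularity matrix; a candidate split is kept only
if directly evaluated Q increases.  Because the landscape is degenerate the
maximizer runs 50 restarts by default: restart 0 is the plain spectral
split, later restarts randomly perturb the spectral sign vector (flip
probability 0.08) before fine-tuning.  Degeneracy is reported as the mean
pairwise co-assignment disagreement across restarts.  On n <= 7 instances
the maximizer matches exhaustive enumeration over all set partitions
(asserted in the tests).

Spatial clustering exposes the seven hierarchical linkage criteria
(`centroid, ward, single, complete, average, weighted, median`) plus
k-means, cut to exactly k clusters.  "Inner squared distance" is Ward's
criterion and "weighted center of mass" is median linkage — their standard
names.  Ward is the default for module/cluster comparisons, being the most
conservative (largest stable mismatch set) choice.

Partition matching assigns each group of partition B to the A-group covering
most of its nodes (several B-groups may share one A-group; ties go to the
lowest A index and are recorded); nodes outside their group's assigned
A-group are mismatched.  The chance level is the mean mismatch rate over
full label permutations of B with group sizes preserved.

## Metric conventions

* **Hubs** — z-score of the chosen degree variant (total by default; in/out
  variants exposed) with threshold 2.0; a zero-variance degree sequence has
  no hubs.  sigma is the population standard deviation.
* **Locality F** — per node, W_i_min / W_i with inputs and outputs minimized
  independently against the sorted distances to all other nodes;
  zero-degree nodes are excluded from the network mean; a node whose links
  all have zero length (coincident coordinates) gets F_i = 1.
* **Geographical centrality** — ascending rank of summed distances, globally
  or within a subset; sums are quantized to 9 significant digits before
  ranking so exact symmetries tie.
* **Neighborhood density** — counts of other nodes within r = r_norm * d_max
  divided by the disc area (2-D) or sphere volume (3-D).
* **Recovery rate** — R = (R1 + R0)/2 with R1/R0 the agreement rates on the
  reference's off-diagonal 1- and 0-entries; restrictions (node-subset
  pairs, distance bins) select the entry set first; a restriction with no
  1-entries or no 0-entries leaves R undefined and flagged.  Distance bins
  default to four equal-width bins of normalized distance.
* **Degree-preserving nulls** — directed double-edge swaps, 10K accepted
  swaps per benchmark, attempt-capped so swap-rigid graphs terminate.
* **Correlation significance** — Pearson correlation with a 2-sigma band
  from 100 order-shuffled surrogates (~95% level; the tests measure a 4–8%
  false-positive rate under independence).
* **Hub removal** — ratio of per-pair mean shortest paths after/before
  removing the largest-total-degree node (per-pair means because the pair
  counts differ); disconnection is reported as an infinite ratio with the
  unreachable-pair count.

## Power-law testing

Discrete power law p(x) = x^-gamma / zeta(gamma, x_min).  gamma is fitted by
bounded MLE, x_min by KS minimization over candidate cutoffs leaving at
least 10 tail points; the plausibility p is the fraction of semi-parametric
surrogates (empirical body below x_min, exact inverse-CDF model draws above)
whose own refitted KS distance reaches the data's.  The exponent search is
bounded to (1, 6]: empirical degree exponents sit well inside that range,
and beyond it a discrete power law over the narrow support of a real tail
becomes indistinguishable from exponential decay, which would let the model
mimic arbitrary fast-decaying alternatives and void the test's power.  The
surrogate ensemble defaults to 1000 (callers choose smaller ensembles where
only coarse p resolution is needed).

## Synthetic data

The generators produce the three geometries the analysis assumes, not
anatomically faithful models:

* `ring1d` — n nodes equally spaced on a unit circle; chord distances.
* `two_cluster_3d` — two 3-D Gaussian clouds (default separation 10, spread
  2) with per-node log-normal jitter scales (sigma 0.6) for heterogeneous
  local density.  Preset `macaque_like`: n=103, K=2518, matching the printed
  cortical scale and its 0.237 connection density.
* `head_cord_tail_2d` — a dense isotropic head cluster holding most nodes
  (preset: 166 of 276), a sparse quasi-1-D cord along the middle stretch of
  the axis, and a compact tail cluster at the far end (default axis length
  30, head diameter 1).  The cord occupies the 5·head_scale … 0.65·length
  stretch so that the three planted groups are exactly recoverable by Ward
  clustering — the property the partition-matching validation depends on.
  Preset `elegans_like`: n=276, K=2902.

Reference networks draw K directed links without replacement with weight
exp(-d/lambda) (Gumbel top-K), optionally boosting links incident to planted
hubs (nodes chosen by regional geographical-centrality rank).  The
exponential decay form is a modeling choice; the real systems' decay form is
unknown, so the presets are qualitative stand-ins, not calibrated fits.  If
a draw is not strongly connected it is repaired by adding the shortest
absent links from condensation sinks to sources and then dropping the
lowest-weight surplus links whose removal preserves strong connectivity
(exact K restored; repairs counted and returned).

What passing on these generators does *not* show: agreement with real
anatomy (in/out degree asymmetry, true decay shapes, the real systems'
module counts), robustness to measurement noise in coordinates, or behavior
on weakly connected empirical networks — loaders report but do not enforce
strong connectivity for user-supplied references.

## Problem sizes

The study conditions used by the tests and the acceptance script are
scaled-down versions of the full protocol, chosen as the smallest sizes
where each phenomenon is unambiguous: the 1-D model runs at n=50, K=250
(same 0.102 density as 200/2000) with 5 realizations per alpha and regime
representatives alpha = 0, 0.15, 0.6, 1; dense-regime modularity and
planted-structure recovery run at the printed Macaque scale n=103, K=2518
(5 realizations; reduced cooling for the recovery comparison); brute-force
oracle comparisons run at n <= 8.  The full-scale protocol (alpha grid with
50 realizations per point) is available through `connectopt.pipeline` /
`reconstruct sweep`.

## Known limitations

* The annealer recomputes L in full after each evaluated move; this is the
  right trade-off at n ~ 100–300 but would need incremental shortest-path
  maintenance well beyond n ~ 10^3.
* The modularity maximizer is spectral bisection + KL; it matches exhaustive
  enumeration at tiny n and the expected random-graph Q at n ~ 100, but like
  all modularity maximizers it has a resolution limit and degenerate optima
  (quantified, not eliminated, by the restart protocol).
* Partition matching is asymmetric by construction (B onto A); the shuffled
  null uses full label permutations, which is the large-ensemble limit of
  pairwise element swaps.
* `AnnealSchedule.T0 = None` calibrates per run from probe moves, so runs
  with different seeds use slightly different T0; fix T0 explicitly if exact
  schedule identity across seeds matters.
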