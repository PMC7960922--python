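# Methods

## Model

A network is a weighted undirected graph on `n` nodes with symmetric
nonnegative adjacency matrix `A`, zero diagonal, strengths
`s_i = Σ_j A_ij` and degrees `d_i = |{j : A_ij > 0}|`. Activity on the
network is modelled as heat diffusion generated by the normalized graph
Laplacian `𝓛 = D^{−1/2}(D − A)D^{−1/2}` (D = diag(s)); the heat kernel
`h(τ) = exp(−τ𝓛)` gives the pairwise heat transferred after diffusion
time τ. The normalized Laplacian is preferred over the combinatorial one
because its stationary mode `v_i ∝ √s_i` absorbs degree/strength
irregularity; its spectrum lies in [0, 2], so all heat-kernel
eigenvalues lie in `[e^{−2τ}, 1]`.

**Isolated nodes.** We use the matrix-product convention
`D_ii^{−1/2} = 0` when `s_i = 0`: an isolated node contributes a zero
row and column to 𝓛 (not a unit diagonal), so it neither sends nor
receives heat and `h(τ)` acts as the identity on it. The alternative —
a unit diagonal entry — would make isolated nodes "leak" heat that goes
nowhere; under edge-conserving rewiring the zero-row convention is the
one for which total heat is conserved componentwise.

**Adaptive rewiring.** Each step:

1. pick a pivot `k` uniformly among nodes with `0 < d_k < n − 1`;
2. with probability `p_random` pick the new partner `j1` uniformly among
   non-neighbors of k and the pruned partner `j2` uniformly among
   neighbors; otherwise compute `h(τ)` of the **current** adjacency
   matrix and take `j1 = argmax_{(k,j)∉E} h_kj(τ)`,
   `j2 = argmin_{(k,j)∈E} h_kj(τ)`;
3. delete edge (k, j2), create edge (k, j1) carrying the deleted edge's
   weight.

Edge count, total weight, and the multiset of edge weights are exact
invariants of the dynamics; the pivot's degree and strength are
unchanged by a step. Nodes isolated when they lose their last edge stay
in the graph and can only be reconnected by being some pivot's `j1`.
Exact ties in the argmax/argmin (which occur in symmetric early-stage
configurations) are broken uniformly at random to avoid index-order
bias. Note that the rule is applied unconditionally: it does *not*
require `h_kj1 ≥ h_kj2`, and the best non-neighbor can receive less heat
than the worst neighbor — the move is made regardless.

If no eligible pivot exists (complete or empty graph) the run stops and
returns the partial trajectory with a flag; the standard parameter
regime never reaches such a state.

## Initial networks

Initial topologies are uniform connected `G(n, m)` graphs with
`m = round(2 ln(n)(n − 1))` edges — twice the `ln n / n` connectivity
threshold, giving `m = 912` and mean degree `2m/n = 18.24` at the
standard `n = 100`. Connectivity is enforced by rejection sampling
(rejections are vanishingly rare at this density). Weights are i.i.d.
from one of two families, then rescaled so their sum equals `m`:

* **normal**: N(μ = 1, σ = 0.25), redrawing nonpositive samples. The
  redraw (rather than clamping to zero) preserves the edge count; at
  these parameters a nonpositive draw has probability ≈ 3 × 10⁻⁵, so
  the truncation is statistically invisible.
* **lognormal**: LogN(μ = 0, σ = 1) — right-skewed, median e^μ = 1,
  many small weights and a heavy tail.

## Metrics and classification

* **Modularity** is Newman's weighted `Q = 1/(2m) Σ_ij [A_ij −
  s_i s_j / 2m] δ(c_i, c_j)` with `m` the *total weight* (which equals
  the edge count after weight normalization and is conserved by
  rewiring). Communities come from igraph's multilevel (Louvain)
  heuristic; Q is then re-evaluated exactly for the returned assignment.
  Louvain's node-order randomness is controlled by seeding (and
  restoring) Python's global `random` state around the igraph call;
  resolution is the default 1.
* **Degree outliers**: fraction of nodes with degree strictly outside
  `⟨k⟩ ± 3√⟨k⟩`, the 3-σ band of the Poisson degree distribution of a
  comparable random graph, with `⟨k⟩ = 2m/n` the network's own
  (conserved) mean degree. Centralized networks have many outliers;
  modular and near-random ones almost none.
* **Classification**: `Q < 0.45` centralized, `Q > 0.50` modular,
  between them a gray zone (the zone is bracketed by the mean
  transition-interval modularity of the two weight families).

## Experiments

* **τ sweep**: for each τ on a grid, generate fresh random networks and
  rewire 4,000 steps at `p_random = 0.2`; record final Q and outlier
  proportion. Q(τ) rises to a plateau and then falls; the outlier
  proportion follows an ascending sigmoid.
* **Transition location**: τ\* is the grid point with the largest
  absolute central finite-difference derivative of the outlier curve
  (restricted to the descending segment when applied to Q curves); ties
  resolve to the smallest τ. No sub-grid interpolation is done, so the
  grid step (0.25 by default) bounds the precision.
* **Initial-vs-final correlation**: Pearson ρ between the modularity of
  the initial random network and of the same network after 4,000
  rewirings.
* **Two-stage experiment**: fresh network → 4,000 rewirings at τ\*
  (records `Q_4000`) → 4,000 more at `τ_test` (records `Q_8000`);
  OLS fit `Q_8000 = α Q_4000 + β` and squared Pearson R². β ≫ α
  indicates specificity, α ≈ 1 robustness/lock-in, low R² flexibility.
* **Bootstrap R²**: fix a pool of pairs (default 200), resample 100
  pairs with replacement 1,000 times, and report the mean and SD of R².

Replicates are seeded through `SeedSequence((master_seed, round(τ·1000),
replicate_index))`, so every (τ, replicate) cell is an independent
stream that can be reproduced in isolation, and every experiment is a
deterministic function of its configuration.

## Numerical choices

* The full heat kernel is computed by spectral decomposition of the
  symmetric 𝓛 (`V diag(e^{−τλ}) V^T`), stable for all τ since every
  exponent is nonpositive; it agrees with a 50-term Taylor series to
  better than 1e−8 on random graphs.
* The simulator needs only **row k** of `h(τ)` per step. It uses the
  splitting `exp(−τ𝓛) = e^{−τ} exp(τP)` with `P = D^{−1/2} A D^{−1/2}`
  (spectral radius ≤ 1) and sums the Taylor series of `exp(τP) e_k` by
  dense matrix-vector products. Terms are carried until the
  `τ^j / j!` bound falls below 1e−14 (≈ 30 terms at τ ≈ 4), giving
  agreement with the spectral route to ~1e−10 while costing ~30 gemvs
  instead of an eigendecomposition — a 4,000-step run at n = 100 takes
  well under a second.
* Strengths are maintained incrementally during a run; when a node's
  degree reaches zero its strength is reset to exactly 0 so that the
  `s^{−1/2}` scaling never amplifies cancellation residue.
* Symmetry of input adjacency matrices is checked to 1e−10 absolute;
  argmax/argmin ties use a 1e−12 relative tolerance.
* Weight normalization is exact to 1e−9 relative; edge-list files store
  weights with 17 significant digits so write→read round-trips are
  bit-exact.

## Problem sizes and what the tests show

The published statistics are Monte-Carlo estimates over 100–1,000
replicates. The package's test suite and `scripts/acceptance.py` rerun
the same protocols at desk scale — 10–15 replicates per grid point for
the τ sweeps, 40–80 replicates for the correlation and two-stage
experiments — sizes at which the transition intervals are resolved to
one grid step (±0.25) and the fitted slopes/intercepts to roughly ±0.1.
Bootstrap pools are correspondingly reduced (pool = sample = the
replicate count) where the full 200-pair pool is not simulated.

The synthetic networks are exactly the model's study conditions, not a
stand-in for empirical data: uniform connected G(n, m) topologies with
i.i.d. normalized weights. Real anatomical networks have spatial
embedding, degree correlations, and directed, input-driven dynamics that
the model deliberately omits, so passing tests validate the simulator
and statistics, not any claim about biological tissue.

## Known limitations

* Only the two weight families above are built in (parameters are
  configurable; families are not extensible without code).
* `find_transition` returns a grid point; refine the grid around a
  coarse estimate for more resolution.
* Louvain is a heuristic: the returned Q can sit below the true optimum
  (the tests bound the gap on small graphs by exhaustive enumeration).
* Directed graphs, self-loops, and negative weights are rejected by
  design; small-world/rich-club statistics are out of scope.
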