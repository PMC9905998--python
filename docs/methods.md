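# Methods

This note records the model definition, the numerical choices made in
`phylodca`, and their known limitations.

## Model

Sequences are length-`L` Ising configurations `s ∈ {−1, +1}^L` governed by

```
H(s) = − Σ_{(i,j) ∈ E} J s_i s_j − Σ_i h_i s_i
```

with a uniform ferromagnetic coupling `J = 1` on the edges `E` of a fixed
contact graph and zero fields `h = 0` (both can be overridden; sparse random
"background" couplings off the graph are supported for robustness studies).
The benchmark contact graph is an Erdős–Rényi draw `G(200, 0.02)` with
exactly 413 edges, shipped as a package fixture
(`src/phylodca/data/er200_q0.02_413edges.tsv`) together with the seed that
regenerates it, so all experiments share one ground truth.

Temperature `T` enters through the Metropolis criterion
`p = min[1, exp(−ΔH/T)]` and acts as an inverse selection strength: at large
`T` structural constraints are weak, at small `T` the system orders.

A generalized `q`-state Potts mode (`PottsHamiltonian`) supports per-pair
coupling matrices and per-site field vectors; binary mode is the `q = 2`
special case used for the benchmark.

## Equilibrium sampling

Independent equilibrium sequences are the "no phylogeny" reference. Each MSA
row starts from a uniform random state and evolves by single-flip Metropolis
moves until the running mean of `|m|` (magnetization per site, windows counted
in *accepted* moves) plateaus.

Numerical choices:

- **Plateau rule.** A window of `10·L` accepted moves (single flip); the chain
  stops when at least 10 windows have elapsed *and* three consecutive window
  means agree within relative tolerance 2% (scale floored at `1/L` so the
  rule is meaningful when `|m| ≈ 0`). Requiring a streak guards against
  chance agreement of two noisy windows, which in early testing left a large
  fraction of sequences under-equilibrated.
- **Cap.** A hard cap of `200·L` accepted moves (and `200·cap` proposals, so
  frozen low-`T` chains terminate). Hitting the cap is logged and flagged in
  the MSA provenance; at `T > T_C`, where `|m|` fluctuates around 0 and the
  plateau rule rarely fires, the cap is the routine stopping point rather
  than an anomaly.
- **Jump-chain correction.** Stopping a Metropolis chain exactly at an
  accepted move samples the *embedded jump chain*, whose stationary law is
  `π(x)·r(x)` with `r(x)` the acceptance probability out of `x` — not the
  Boltzmann law `π`. On a 2-spin system this bias cancels the target
  correlation `tanh(J/T)` almost exactly. The kernel therefore appends a
  fixed-length suffix of `20·L` proposals (not conditioned on acceptance)
  after the plateau/cap stop, which restores `π`. This bug was caught by the
  exact small-system distribution oracles in the test suite.
- **Wolff cluster moves.** For the zero-field uniform-ferromagnetic case, a
  Wolff move grows a cluster of aligned spins with bond probability
  `1 − exp(−2J/T)` and flips it; every move is accepted, so no jump-chain
  correction is needed. One cluster flip decorrelates far more than one
  single-spin flip, so Wolff defaults are a window of `L/10` and a cap of
  `4·L` accepted moves. Wolff is the default generator for large equilibrium
  reference MSAs (an order of magnitude faster at equal quality); the two
  samplers are cross-checked against each other in the tests.
- **Seeding.** One RNG stream per MSA (rows drawn sequentially from a single
  32-bit kernel seed) rather than per-row substreams: it avoids 32-bit
  per-row seed collisions across large sweeps while preserving bit-exact
  determinism per master seed.

## Phylogenetic generation

An equilibrium ancestor is evolved along a complete binary tree of `G = 11`
generations (`2^11 = 2048` leaves). Every branch receives exactly `μ`
*accepted* single-flip Metropolis mutations at the same temperature;
rejected proposals do not count. Small `μ` means strongly correlated leaves
(strong phylogeny); `μ → ∞` recovers independent equilibrium sampling.
Nodes use heap indexing (root 0, children of `k` at `2k+1, 2k+2`); every
branch's ordered mutation log `(site, old, new)` is recorded, so any node
state can be replayed bit-exactly from the ancestor (`replay_node`), and
logs round-trip through a TSV format.

The **earliest-mutation index** of a pair,
`G(i, j) = max(g_i, g_j)` with `g_i` the first generation at which site `i`
has flipped anywhere in the tree, stratifies pairs by how early shared
ancestry could correlate them. Sites that never mutate carry a NaN sentinel
and are excluded from score-vs-`G` statistics (with the count reported).

A generalized mode evolves binary or `q`-state sequences along an arbitrary
user-supplied Newick tree, with `round(scale · branch_length)` accepted
mutations per branch (`scale` defaults to `L`); the analogous index `G'`
counts accepted mutations from the root instead of generations.

## Contact inference

All methods score site pairs; symmetric `ScoreMatrix` objects carry the
method name and regularization metadata.

- **Covariance:** `|C_ij|`, `C_ij = ⟨s_i s_j⟩ − ⟨s_i⟩⟨s_j⟩`.
- **Mutual information:** plug-in MI (nats) from pairwise frequencies with
  pseudocount `λ = 0.01` (added as `λ/q` to single-site and `λ/q²` to pair
  counts before renormalization).
- **mfDCA:** mean-field DCA, `J = −C̃⁻¹` where `C̃` is the connected
  correlation matrix from frequencies with pseudocount `λ = 0.5`; scored by
  `|J_ij|`. A singular `C̃` raises a `ConvergenceError` advising a larger
  pseudocount.
- **plmDCA:** joint pseudolikelihood maximization over all sites with L2
  penalties `λ_J = λ_h = 0.01` (per the conditional-likelihood objective),
  optimized with L-BFGS-B (`gtol = 1e-5`, `maxiter = 500`); couplings are
  symmetrized and scored by `|J_ij|` in binary mode, or by the Frobenius
  norm of the zero-sum-gauge coupling block in `q`-state mode.
- **APC:** the average-product correction
  `S_ij − S̄_i S̄_j / S̄`, with row means excluding the diagonal. If the
  overall mean score is 0 the correction is skipped with a warning.

Evaluation ranks all `i < j` pairs by score (ties broken lexicographically,
so results are platform-independent) and reports the TP fraction among the
top `N_pred` pairs; at `N_pred = 413` (the number of true contacts) the TP
fraction equals both PPV and TPR. ROC AUC, per-pair shortest-path length in
the contact graph, site conservation, a site-covariance PCA, and
score-vs-`G` correlations (`rho` over pairs, `rho_M` over per-`G` medians)
complete the report.

## Transition temperature

The ferromagnetic transition is located by scanning magnetization
histograms on a temperature grid (benchmark scan: `T ∈ [3, 6]`, step 0.2;
2000 Wolff samples per point, burn-in 300 clusters, thinning 3). Each
histogram (50 bins on `[−1, 1]`, lightly smoothed) is called bimodal when
peaks of prominence ≥ 5% of the maximum exist on both sides of `m = 0`;
`T_C` is the midpoint between the last bimodal and the first unimodal grid
point, so the grid step bounds the resolution (±0.1 here). The annealed
random-graph formula `tanh(J/T_C) = ⟨k⟩ / (⟨k²⟩ − ⟨k⟩)` (≈ 3.98 for the
fixture graph) serves as an independent closed-form cross-check.

## Experiment sweeps

`run_sweep` regenerates every `(T, μ, replicate)` cell from scratch — a
fresh ancestor and a fresh tree, or a fresh independent equilibrium MSA
size-matched at `2^G` rows — and scores it with every requested method,
with and without APC. Per-cell seeds derive deterministically from the
master seed via `SeedSequence(entropy=master, spawn_key=(ti, mi, rep))`, so
any cell can be recomputed in isolation bit-identically; result tables
carry a configuration hash. Failed cells are logged and marked, never
silently dropped. `regularization_sweep` reuses identical datasets across
regularization settings so differences are attributable to the
regularization alone.

## Replicate variability

The benchmark's replicate-to-replicate spread of the TP fraction deserves a
caveat. Even for a fixed true contact map, the TP fraction at
`N_pred = 413` has intrinsic ranking noise of order
`sqrt(p(1−p)/413) ≈ 0.021` at `p ≈ 0.75`, so a cross-realization standard
deviation below `10⁻²` is not attainable in the phylogenetic regimes:
measured SDs at `T = 5` are ≈ 0.002 (equilibrium cells, where `p ≈ 1`
suppresses the binomial term) but ≈ 0.02–0.05 for `μ ∈ {5, 15}`. A
`10⁻²`-level figure is only consistent with the *standard error of the
mean* over ~100 realizations (SD/√100 ≈ 0.005). The acceptance test for
this criterion checks the SD as stated and is expected to fail for the
phylogenetic cells; it is kept red deliberately rather than widened.

## Limitations

- The plateau heuristic is a practical equilibration test, not a proof of
  convergence; for `T` near or below `T_C` single-flip chains can remain
  trapped, which is why Wolff sampling is preferred there and why
  cap-hitting is surfaced in provenance.
- The `μ` accepted mutations per branch define the evolution model; they are
  a jump-chain dynamic by construction and intentionally receive no
  correction (the bias discussed above applies only to equilibrium
  sampling, where the target is the Boltzmann law).
- plmDCA uses a dense joint optimization; cost grows steeply with `L` and
  `q`. The benchmark (`L = 200`, binary, `M = 2048`) takes a few seconds
  per MSA on one core.
- The histogram-based `T_C` detector resolves to half the grid step and
  assumes the scan brackets the transition; out-of-range scans return an
  explicit no-detection message instead of an estimate.
- Finite-size effects: all statements about `T_C` and TP fractions are for
  the fixed 200-site fixture, not the thermodynamic limit.
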