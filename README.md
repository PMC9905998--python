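# phylodca

**How phylogenetic correlations degrade structural-contact inference — a
controlled Ising benchmark.**

Coevolution-based contact prediction (DCA and friends) assumes that the
sequences in an alignment are independent samples from the same selective
landscape. Real protein families violate this: sequences are leaves of a
phylogeny, and shared ancestry creates inter-site correlations that have
nothing to do with structure. `phylodca` isolates this effect in the
cleanest setting possible:

- **Ground truth is exact.** Sequences are spin configurations of an Ising
  model whose couplings live on a known contact graph — an Erdős–Rényi
  `G(200, 0.02)` draw with 413 edges, shipped as a fixture so every
  experiment shares one truth.
- **Phylogeny is a dial.** Data are generated either as independent
  equilibrium (Boltzmann) samples, or as the 2048 leaves of a complete
  binary tree with exactly `μ` accepted Metropolis mutations per branch.
  Small `μ` = strong phylogeny; `μ → ∞` recovers equilibrium.
- **Inference is head-to-head.** Four scores — covariance, mutual
  information, mean-field DCA, and pseudolikelihood DCA — each with and
  without the average-product correction (APC), are benchmarked by the
  fraction of true contacts among the top 413 predictions (where TP
  fraction = PPV = TPR).

The headline result: phylogeny hurts every method, local methods
(covariance, MI) collapse first, plmDCA degrades most gracefully, and APC
buys back part of the loss. A per-pair "earliest-mutation" index `G`
explains *why*: pairs that mutate early in the tree split the leaves into
large coherent blocks and look strongly coupled regardless of structure.

## Worked example

Equilibrium data are the best case — with 2048 independent sequences every
method essentially solves the problem
(`python examples/01_equilibrium_inference.py`):

```
benchmark graph: 200 sites, 413 contacts
equilibrium MSA: 2048 x 200 (mean accepted moves/seq: 800)

method       TP fraction       AUC
covariance        0.9976    1.0000
mi                0.9976    1.0000
mfdca             1.0000    1.0000
plmdca            1.0000    1.0000
```

Turning on the phylogeny changes the picture entirely
(`python examples/02_phylogeny_degrades_inference.py`, mean TP fraction
over 3 replicates at T = 5):

```
regime          covariance    +APC          mi    +APC       mfdca    +APC      plmdca    +APC
equilibrium          0.995   0.997       0.995   0.997       0.999   0.999       0.997   0.997
mu = 15              0.546   0.640       0.613   0.667       0.799   0.793       0.769   0.773
mu = 5               0.035   0.062       0.055   0.078       0.104   0.122       0.187   0.190
```

The mechanism is visible in the earliest-mutation index: the median
covariance score falls monotonically with the generation `G` by which both
sites of a pair have first mutated
(`python examples/04_mutation_depth.py`, one μ = 5 replicate):

```
   G  median score  n pairs
   1        0.1936       36
   2        0.1513      264
   3        0.0749     1185
   ...
  10        0.0029      199

pair-level Pearson rho(G, score)   = -0.527
median-level Pearson rho_M         = -0.867
```

Early-mutating pairs dominate the score scale by an order of magnitude —
they, not the contacts, top the ranking under strong phylogeny.

All experiments run in the paramagnetic phase: the model's
ferromagnetic transition sits at T_C ≈ 4.1 (magnetization-histogram scan,
`python examples/03_transition_temperature.py`; annealed closed-form
cross-check gives 3.98), safely below the working temperature T = 5.

More examples: `examples/05_newick_qstate.py` (q-state Potts sequences on
an arbitrary Newick tree, FASTA export) and `examples/06_config_sweep.py`
(YAML-config-driven sweeps with per-cell deterministic seeds).

## Package layout

| module | contents |
|---|---|
| `phylodca.graph` | contact graphs, ER sampling, the 413-edge fixture |
| `phylodca.hamiltonian` | Ising / Potts energies, background couplings |
| `phylodca.sampling` | Metropolis + Wolff equilibrium samplers, T_C scan |
| `phylodca.phylogeny` | binary-tree and Newick evolution, mutation logs, G index |
| `phylodca.inference` | covariance, MI, mfDCA, plmDCA, APC |
| `phylodca.evaluation` | TP fraction, AUC, score-vs-G statistics, reports |
| `phylodca.experiments` | config-driven sweeps with deterministic per-cell seeds |

Model definitions, numerical choices (plateau rule, jump-chain correction,
Wolff defaults, T_C detector) and limitations are documented in
[docs/methods.md](docs/methods.md).
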