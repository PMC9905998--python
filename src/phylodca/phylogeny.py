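"""Sequence evolution along phylogenies under structural constraints.

Starting from an equilibrium ancestor, sequences are duplicated and
mutated along a tree; every proposed mutation (a single spin flip, or a
state change in q-state mode) is accepted by the same Metropolis
criterion used for equilibrium sampling, so every sequence in the tree
remains an equilibrium sequence.  The leaves form an MSA whose columns
carry both structural and phylogenetic correlations.

Two modes are supported:

- a complete binary tree with exactly ``mu`` accepted mutations per
  branch (the minimal model; ``n_generations`` duplications give
  ``2**n_generations`` leaves), and
- an arbitrary user-supplied Newick tree, where each branch receives
  ``round(scale * branch_length)`` accepted mutations.

Every accepted mutation is logged per branch, which makes it possible to
replay any node sequence and to compute, for a pair of sites, the
earliest generation (or earliest cumulative mutation count) at which
both sites have mutated away from their ancestral state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import _kernels
from .hamiltonian import HamiltonianSpec, PottsHamiltonian
from .msa import SpinMSA
from .sampling import SamplerParams, _kernel_seed, _weighted_neighbors

__all__ = [
    "PhylogenyRecord",
    "evolve_on_binary_tree",
    "evolve_on_newick",
    "earliest_mutation_generation",
    "earliest_mutation_count",
    "first_flip_generations",
    "first_flip_counts",
    "pair_mutation_depth",
    "binary_tree_newick",
    "write_mutation_log",
    "read_mutation_log",
]


@dataclass
class PhylogenyRecord:
    """Rooted tree + ancestor + complete per-branch mutation logs.

    ``branch_logs[b]`` is the ordered list of accepted mutations
    ``(site, old_state, new_state)`` on branch ``b``.  In binary-tree
    mode nodes use heap indexing (root 0, children of k at 2k+1, 2k+2)
    and branch ``b`` is the edge into node ``b + 1``; node depth is its
    generation (root = generation 0).  In Newick mode branches are
    numbered in preorder and ``newick_tree`` holds the dendropy tree
    whose edges carry a ``branch_id`` annotation.
    """

    kind: str                          # "binary_tree" | "newick"
    ancestor: np.ndarray
    n_states: int
    branch_logs: list[list[tuple[int, int, int]]]
    mu: int | None = None
    n_generations: int | None = None
    node_states: np.ndarray | None = None   # binary mode: (n_nodes, L)
    newick_tree: dendropy.Tree | None = None
    branch_children: list[int] | None = None  # newick: parent node idx per branch
    provenance: dict = field(default_factory=dict)
    _g_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_sites(self) -> int:
        return len(self.ancestor)

    @property
    def n_branches(self) -> int:
        return len(self.branch_logs)

    # ---- binary-tree helpers -------------------------------------------
    @property
    def n_nodes(self) -> int:
        if self.kind != "binary_tree":
            raise ValueError("node indexing applies to binary-tree records")
        return 2 ** (self.n_generations + 1) - 1

    @staticmethod
    def node_depth(node: int) -> int:
        """Generation index of a heap node (root = 0)."""
        return int(math.floor(math.log2(node + 1)))

    def replay_node(self, node: int) -> np.ndarray:
        """Recompute a node's sequence from the ancestor and branch logs."""
        if self.kind != "binary_tree":
            raise ValueError("replay_node applies to binary-tree records")
        path = []
        k = node
        while k > 0:
            path.append(k)
            k = (k - 1) // 2
        seq = self.ancestor.copy()
        for child in reversed(path):
            for site, old, new in self.branch_logs[child - 1]:
                if seq[site] != old:
                    raise RuntimeError(
                        f"inconsistent log on branch into node {child}")
                seq[site] = new
        return seq

    def leaf_indices(self) -> np.ndarray:
        g = self.n_generations
        return np.arange(2 ** g - 1, 2 ** (g + 1) - 1)

    def leaves(self) -> np.ndarray:
        """Leaf sequences in fixed left-to-right order."""
        if self.kind == "binary_tree":
            if self.node_states is not None:
                return self.node_states[self.leaf_indices()]
            return np.array([self.replay_node(k) for k in self.leaf_indices()])
        raise ValueError("use the SpinMSA returned by evolve_on_newick")


def evolve_on_binary_tree(
    spec: HamiltonianSpec,
    params: SamplerParams,
    ancestor: np.ndarray,
    mu: int,
    n_generations: int,
    rng_seed: int | None = None,
) -> tuple[PhylogenyRecord, SpinMSA]:
    """Evolve ``ancestor`` along a complete binary tree.

    On every branch, single-site spin flips are proposed (site uniform)
    and Metropolis-accepted at ``params.temperature`` until exactly
    ``mu`` are accepted.  The ancestor should itself be an equilibrium
    sequence at the same temperature (caller's responsibility; recorded
    in provenance).

    Returns the full record (with every node's sequence) and the leaf
    MSA of ``2**n_generations`` sequences.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    ancestor = np.asarray(ancestor, dtype=np.int8)
    if ancestor.shape != (spec.n_sites,):
        raise ValueError("ancestor length must match the graph")
    if not np.all(np.isin(ancestor, (-1, 1))):
        raise ValueError("ancestor must be a +-1 sequence")
    seed_master = params.rng_seed if rng_seed is None else rng_seed
    seed = _kernel_seed(np.random.SeedSequence(seed_master))
    idx, wt, indptr = _weighted_neighbors(spec)
    node_states, log_site, log_old, log_new = _kernels.binary_tree_evolve(
        ancestor, idx, wt, indptr, spec.field_array(), params.temperature,
        mu, n_generations, seed)
    branch_logs = [
        [(int(log_site[b, k]), int(log_old[b, k]), int(log_new[b, k]))
         for k in range(mu)]
        for b in range(node_states.shape[0] - 1)
    ]
    provenance = {
        "kind": "phylogeny",
        "tree": "binary",
        "temperature": params.temperature,
        "mu": mu,
        "n_generations": n_generations,
        "rng_seed": seed_master,
        "ancestor_equilibrium": "assumed (caller-supplied)",
    }
    record = PhylogenyRecord(
        kind="binary_tree", ancestor=ancestor, n_states=2,
        branch_logs=branch_logs, mu=mu, n_generations=n_generations,
        node_states=node_states, provenance=provenance)
    msa = SpinMSA(matrix=record.leaves(), n_states=2, provenance=provenance)
    return record, msa


def _as_potts(model) -> tuple[PottsHamiltonian, bool]:
    if isinstance(model, HamiltonianSpec):
        return PottsHamiltonian.from_ising(model), True
    if isinstance(model, PottsHamiltonian):
        return model, False
    raise TypeError("model must be a HamiltonianSpec or PottsHamiltonian")


def evolve_on_newick(
    model,
    params: SamplerParams,
    tree: dendropy.Tree | str,
    root_seq: np.ndarray,
    scale: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[PhylogenyRecord, SpinMSA]:
    """Evolve a sequence along an arbitrary Newick tree.

    Branch ``b`` receives ``round(scale * length(b))`` accepted
    mutations; proposals pick a uniform site and a uniform new state
    different from the current one, accepted by the Metropolis criterion
    under ``model``.  ``scale`` defaults to the sequence length
    (interpreting branch lengths as expected substitutions per site).

    ``model`` may be a binary :class:`HamiltonianSpec` (sequences are
    +-1 spins) or a general :class:`PottsHamiltonian` (states 0..q-1).
    """
    potts, ising_input = _as_potts(model)
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    gen = np.random.default_rng(rng)
    root_seq = np.asarray(root_seq)
    if root_seq.shape != (potts.n_sites,):
        raise ValueError("root_seq length must match the model")
    if ising_input:
        work = ((root_seq + 1) // 2).astype(np.int64)  # -1/+1 -> 0/1
    else:
        work = root_seq.astype(np.int64)
        if work.min() < 0 or work.max() >= potts.n_states:
            raise ValueError("root_seq states out of range")
    if scale is None:
        scale = float(potts.n_sites)

    def decode(arr):
        return 2 * np.asarray(arr) - 1 if ising_input else np.asarray(arr)

    def decode_state(s: int) -> int:
        return 2 * s - 1 if ising_input else s

    # Assign preorder branch ids and check lengths up front.
    branches = []
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        length = edge.length if edge.length is not None else 0.0
        if length < 0:
            raise ValueError("negative branch length in tree")
        edge.branch_id = len(branches)
        branches.append(edge)

    n_states = potts.n_states
    node_seq: dict[int, np.ndarray] = {id(tree.seed_node): work.copy()}
    branch_logs: list[list[tuple[int, int, int]]] = [[] for _ in branches]
    for edge in branches:
        parent_seq = node_seq[id(edge.tail_node)]
        seq = parent_seq.copy()
        target = int(round(scale * (edge.length or 0.0)))
        log = branch_logs[edge.branch_id]
        accepted = 0
        while accepted < target:
            site = int(gen.integers(potts.n_sites))
            old = int(seq[site])
            new = int(gen.integers(n_states - 1))
            if new >= old:
                new += 1
            dh = potts.delta_energy(seq, site, new)
            if dh <= 0 or gen.random() < np.exp(-dh / params.temperature):
                log.append((site, decode_state(old), decode_state(new)))
                seq[site] = new
                accepted += 1
        node_seq[id(edge.head_node)] = seq

    leaves = []
    names = []
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaves.append(decode(node_seq[id(leaf)]))
        if leaf.taxon is not None and leaf.taxon.label:
            names.append(leaf.taxon.label)
        elif leaf.label:
            names.append(leaf.label)
        else:
            names.append(f"leaf{i}")
    provenance = {
        "kind": "phylogeny",
        "tree": "newick",
        "temperature": params.temperature,
        "scale": scale,
        "n_states": 2 if ising_input else n_states,
    }
    record = PhylogenyRecord(
        kind="newick", ancestor=decode(work), n_states=2 if ising_input else n_states,
        branch_logs=branch_logs, newick_tree=tree, provenance=provenance)
    msa = SpinMSA(matrix=np.array(leaves), n_states=2 if ising_input else n_states,
                  provenance=provenance, names=names)
    return record, msa


# ---------------------------------------------------------------------------
# Earliest-mutation statistics
# ---------------------------------------------------------------------------

def first_flip_generations(record: PhylogenyRecord) -> np.ndarray:
    """Per-site earliest generation g_i at which some node carries a state
    differing from the ancestor's (binary-tree mode); NaN if never.
    """
    if record.kind != "binary_tree":
        raise ValueError("generation indices apply to binary-tree records")
    if record._g_cache is not None:
        return record._g_cache
    states = (record.node_states if record.node_states is not None
              else np.array([record.replay_node(k)
                             for k in range(record.n_nodes)]))
    g = np.full(record.n_sites, np.nan)
    for node in range(1, record.n_nodes):
        depth = PhylogenyRecord.node_depth(node)
        diff = states[node] != record.ancestor
        newly = diff & (np.isnan(g) | (g > depth))
        g[newly] = depth
    record._g_cache = g
    return g


def earliest_mutation_generation(record: PhylogenyRecord, i: int,
                                 j: int) -> int | None:
    """G = max(g_i, g_j): first generation at which *both* sites of the
    pair have mutated (in some sequence) relative to the ancestor.

    Returns ``None`` (sentinel) if either site never differs anywhere.
    """
    for s in (i, j):
        if not (0 <= s < record.n_sites):
            raise IndexError(f"site {s} out of range")
    g = first_flip_generations(record)
    val = max(g[i], g[j])
    return None if np.isnan(val) else int(val)


def pair_mutation_depth(record: PhylogenyRecord) -> np.ndarray:
    """Symmetric matrix of G = max(g_i, g_j); NaN marks sentinel pairs."""
    g = first_flip_generations(record)
    return np.maximum.outer(g, g)


def first_flip_counts(record: PhylogenyRecord) -> np.ndarray:
    """Per-site G_i for Newick records: minimum, over root-to-node paths,
    of the cumulative accepted-mutation count up to (and including) the
    first mutation that moves site i away from its root state.  NaN if
    the site never leaves the root state.
    """
    if record.kind != "newick" or record.newick_tree is None:
        raise ValueError("mutation counts apply to Newick records")
    n = record.n_sites
    root_state = record.ancestor
    best = np.full(n, np.nan)
    tree = record.newick_tree

    def visit(node, seq, count, found):
        for edge in node.child_edge_iter():
            log = record.branch_logs[edge.branch_id]
            child_seq = seq.copy()
            child_found = found.copy()
            c = count
            for site, old, new in log:
                c += 1
                child_seq[site] = new
                if not child_found[site] and new != root_state[site]:
                    child_found[site] = True
                    if np.isnan(best[site]) or c < best[site]:
                        best[site] = c
            visit(edge.head_node, child_seq, c, child_found)

    visit(tree.seed_node, root_state.copy(), 0, np.zeros(n, dtype=bool))
    return best


def earliest_mutation_count(record: PhylogenyRecord, i: int,
                            j: int) -> int | None:
    """G' = max(G_i, G_j) with mutation-count resolution (Newick mode).

    Returns ``None`` if either site never mutates away from its root
    state anywhere in the tree.
    """
    for s in (i, j):
        if not (0 <= s < record.n_sites):
            raise IndexError(f"site {s} out of range")
    best = first_flip_counts(record)
    val = max(best[i], best[j])
    return None if np.isnan(val) else int(val)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def binary_tree_newick(record: PhylogenyRecord) -> str:
    """Export a binary-tree record as Newick with unit branch lengths;
    leaves are named leaf0000.. in left-to-right order."""
    if record.kind != "binary_tree":
        raise ValueError("record is not a binary tree")

    def build(node: int) -> str:
        if node >= 2 ** record.n_generations - 1:
            rank = node - (2 ** record.n_generations - 1)
            return f"leaf{rank:04d}:1"
        return f"({build(2 * node + 1)},{build(2 * node + 2)}):1"

    left = build(1)
    right = build(2)
    return f"({left},{right});"


def write_mutation_log(record: PhylogenyRecord, path: str | Path) -> None:
    """TSV log: branch_id, order, site, old_state, new_state."""
    rows = [
        {"branch_id": b, "order": k, "site": site, "old_state": old,
         "new_state": new}
        for b, log in enumerate(record.branch_logs)
        for k, (site, old, new) in enumerate(log)
    ]
    pd.DataFrame(rows, columns=["branch_id", "order", "site", "old_state",
                                "new_state"]).to_csv(path, sep="\t", index=False)


def read_mutation_log(path: str | Path) -> list[list[tuple[int, int, int]]]:
    df = pd.read_csv(path, sep="\t")
    n_branches = int(df["branch_id"].max()) + 1 if len(df) else 0
    logs: list[list[tuple[int, int, int]]] = [[] for _ in range(n_branches)]
    for b, grp in df.sort_values(["branch_id", "order"]).groupby("branch_id"):
        logs[int(b)] = [(int(r.site), int(r.old_state), int(r.new_state))
                        for r in grp.itertuples()]
    return logs
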