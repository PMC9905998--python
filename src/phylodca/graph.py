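"""Contact graphs: the ground-truth structure behind the synthetic sequences.

A :class:`ContactGraph` is a fixed undirected graph on ``n_sites`` sites.
Its edges play the role of structural contacts in a protein: each edge
carries a ferromagnetic coupling in the sequence-generation Hamiltonian,
and contact inference is evaluated against the edge set.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ContactGraph",
    "sample_er_graph",
    "read_edge_list",
    "write_edge_list",
    "benchmark_graph",
]

#: Name of the packaged 200-site, 413-edge benchmark realization.
_BENCHMARK_RESOURCE = "er200_q0.02_413edges.tsv"


@dataclass(frozen=True)
class ContactGraph:
    """Undirected graph whose edges are the true structural contacts.

    Parameters
    ----------
    n_sites:
        Number of sites (graph nodes), 0-based indices.
    edges:
        Edge set stored canonically as sorted tuples ``(i, j)`` with
        ``i < j``.
    edge_prob:
        The Erdos-Renyi edge probability used to draw the graph
        (metadata; ``None`` for hand-built graphs).
    """

    n_sites: int
    edges: frozenset[tuple[int, int]]
    edge_prob: float | None = None
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("a contact graph needs at least 2 sites")
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at site {i}")
            if not (0 <= i < self.n_sites and 0 <= j < self.n_sites):
                raise ValueError(f"edge ({i}, {j}) out of range [0, {self.n_sites})")
            canon.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_pairs(self) -> int:
        """Total number of unordered site pairs."""
        return self.n_sites * (self.n_sites - 1) // 2

    def edge_array(self) -> np.ndarray:
        """Edges as an ``(n_edges, 2)`` int array, sorted lexicographically."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        a = np.zeros((self.n_sites, self.n_sites), dtype=np.int8)
        e = self.edge_array()
        if len(e):
            a[e[:, 0], e[:, 1]] = 1
            a[e[:, 1], e[:, 0]] = 1
        return a

    def degrees(self) -> np.ndarray:
        """Number of contacts of each site."""
        return self.adjacency_matrix().sum(axis=1).astype(np.int64)

    def neighbor_lists(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style neighbour structure ``(indices, indptr)``.

        Site ``i``'s neighbours are ``indices[indptr[i]:indptr[i + 1]]``.
        """
        adj: list[list[int]] = [[] for _ in range(self.n_sites)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        indptr = np.zeros(self.n_sites + 1, dtype=np.int64)
        for i, nb in enumerate(adj):
            indptr[i + 1] = indptr[i] + len(nb)
        indices = np.empty(indptr[-1], dtype=np.int64)
        for i, nb in enumerate(adj):
            indices[indptr[i]:indptr[i + 1]] = sorted(nb)
        return indices, indptr

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges


def sample_er_graph(
    n_sites: int, edge_prob: float, rng: np.random.Generator | int | None = None
) -> ContactGraph:
    """Draw an Erdos-Renyi graph G(n, p): each pair is an edge with prob. p.

    Parameters
    ----------
    n_sites:
        Number of sites (>= 2).
    edge_prob:
        Independent probability of each of the ``n(n-1)/2`` edges.
    rng:
        :class:`numpy.random.Generator`, an integer seed, or ``None``.
    """
    if not (0.0 <= edge_prob <= 1.0):
        raise ValueError(f"edge_prob must be in [0, 1], got {edge_prob}")
    if n_sites < 2:
        raise ValueError(f"n_sites must be >= 2, got {n_sites}")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)
    iu = np.triu_indices(n_sites, k=1)
    mask = gen.random(len(iu[0])) < edge_prob
    edges = frozenset(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    return ContactGraph(n_sites=n_sites, edges=edges, edge_prob=edge_prob,
                        seed=int(seed) if seed is not None else None)


def write_edge_list(graph: ContactGraph, path: str | Path) -> None:
    """Write a TSV edge list: header line then one ``i<TAB>j`` per edge."""
    path = Path(path)
    parts = [f"n_sites={graph.n_sites}"]
    if graph.edge_prob is not None:
        parts.append(f"edge_prob={graph.edge_prob}")
    if graph.seed is not None:
        parts.append(f"seed={graph.seed}")
    lines = ["# " + " ".join(parts)]
    lines += [f"{i}\t{j}" for i, j in sorted(graph.edges)]
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> ContactGraph:
    """Read a TSV edge list written by :func:`write_edge_list`."""
    n_sites = None
    edge_prob = None
    seed = None
    edges = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line.lstrip("# ").split():
                key, _, val = tok.partition("=")
                if key == "n_sites":
                    n_sites = int(val)
                elif key == "edge_prob":
                    edge_prob = float(val)
                elif key == "seed":
                    seed = int(val)
            continue
        i, j = line.split("\t")
        edges.add((int(i), int(j)))
    if n_sites is None:
        raise ValueError(f"{path}: missing '# n_sites=...' header")
    return ContactGraph(n_sites=n_sites, edges=frozenset(edges),
                        edge_prob=edge_prob, seed=seed)


def benchmark_graph() -> ContactGraph:
    """The canonical 200-site, 413-edge ER(200, 0.02) benchmark graph.

    A single fixed realization is shipped with the package so that all
    benchmark runs use the same contact map.  It was drawn with a fixed,
    recorded seed (see the file header), chosen as the first seed whose
    ER(200, 0.02) draw has exactly 413 edges.
    """
    ref = importlib.resources.files("phylodca") / "data" / _BENCHMARK_RESOURCE
    with importlib.resources.as_file(ref) as path:
        return read_edge_list(path)
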