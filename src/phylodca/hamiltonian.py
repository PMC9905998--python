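"""Ising / Potts Hamiltonians encoding structural constraints.

The minimal model places an Ising spin on every site of a contact graph
and couples contacting sites ferromagnetically:

    H(sigma) = - sum_i h_i sigma_i - sum_{i<j} J_ij sigma_i sigma_j

with J_ij = J on edges (default J = 1, h = 0), so the default energy is
minus the number of satisfied edges plus the number of violated ones.
An optional "background" adds small couplings on non-edge pairs.

A general q-state Potts Hamiltonian is provided for evolving sequences
with richer alphabets (e.g. 21 amino acid states) along arbitrary trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import ContactGraph

__all__ = [
    "HamiltonianSpec",
    "PottsHamiltonian",
    "energy",
    "delta_energy",
    "sample_background_couplings",
]


@dataclass(frozen=True)
class HamiltonianSpec:
    """Binary (Ising) Hamiltonian on a contact graph.

    Parameters
    ----------
    graph:
        Contact graph; couplings of ``coupling_value`` sit on its edges.
    coupling_value:
        Uniform ferromagnetic coupling J on every edge (default 1).
    fields:
        Per-site field ``h_i``; scalar broadcast or length-``n_sites``
        array.  Default 0.
    background_couplings:
        Optional mapping ``(i, j) -> J_ij`` on *non-edge* pairs, modelling
        a weak background of spurious couplings.
    """

    graph: ContactGraph
    coupling_value: float = 1.0
    fields: float | np.ndarray = 0.0
    background_couplings: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j) in self.background_couplings:
            if self.graph.has_edge(i, j):
                raise ValueError(
                    f"background coupling on ({i}, {j}) overlaps a graph edge"
                )
            if i == j or not (0 <= i < self.n_sites and 0 <= j < self.n_sites):
                raise ValueError(f"invalid background pair ({i}, {j})")

    @property
    def n_sites(self) -> int:
        return self.graph.n_sites

    def field_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.fields, dtype=np.float64),
                               (self.n_sites,)).copy()

    def coupling_matrix(self) -> np.ndarray:
        """Dense symmetric J matrix (edges + background)."""
        jmat = self.graph.adjacency_matrix().astype(np.float64) * self.coupling_value
        for (i, j), v in self.background_couplings.items():
            jmat[i, j] += v
            jmat[j, i] += v
        return jmat

    @property
    def is_uniform_ferromagnetic(self) -> bool:
        """True when the Wolff cluster algorithm applies (h = 0, uniform J > 0)."""
        h = self.field_array()
        return (
            self.coupling_value > 0
            and not self.background_couplings
            and bool(np.all(h == 0.0))
        )


def sample_background_couplings(
    graph: ContactGraph, sd: float, rng: np.random.Generator | int | None = None
) -> dict[tuple[int, int], float]:
    """Draw N(0, sd^2) background couplings on every non-edge pair."""
    gen = np.random.default_rng(rng)
    out: dict[tuple[int, int], float] = {}
    for i in range(graph.n_sites):
        for j in range(i + 1, graph.n_sites):
            if not graph.has_edge(i, j):
                out[(i, j)] = float(gen.normal(0.0, sd))
    return out


def _check_binary(seq: np.ndarray, n_sites: int) -> np.ndarray:
    seq = np.asarray(seq)
    if seq.shape != (n_sites,):
        raise ValueError(f"sequence length {seq.shape} != n_sites {n_sites}")
    return seq


def energy(spec: HamiltonianSpec, seq: np.ndarray) -> float:
    """Total energy H(sigma) of a +-1 sequence under *spec*."""
    seq = _check_binary(seq, spec.n_sites).astype(np.float64)
    h = spec.field_array()
    e = -float(h @ seq)
    edge = spec.graph.edge_array()
    if len(edge):
        e -= spec.coupling_value * float(np.sum(seq[edge[:, 0]] * seq[edge[:, 1]]))
    for (i, j), v in spec.background_couplings.items():
        e -= v * seq[i] * seq[j]
    return e


def delta_energy(spec: HamiltonianSpec, seq: np.ndarray, site: int) -> float:
    """Energy change from flipping ``seq[site]``, computed locally.

    Equals ``2 * sigma_i * (h_i + sum_{j in N(i)} J_ij sigma_j)``: only the
    flipped site's neighbourhood is visited.
    """
    seq = _check_binary(seq, spec.n_sites)
    if not (0 <= site < spec.n_sites):
        raise IndexError(f"site {site} out of range [0, {spec.n_sites})")
    h = spec.field_array()
    local = float(h[site])
    for (i, j) in spec.graph.edges:
        if i == site:
            local += spec.coupling_value * seq[j]
        elif j == site:
            local += spec.coupling_value * seq[i]
    for (i, j), v in spec.background_couplings.items():
        if i == site:
            local += v * seq[j]
        elif j == site:
            local += v * seq[i]
    return 2.0 * float(seq[site]) * local


@dataclass(frozen=True)
class PottsHamiltonian:
    """General q-state Potts Hamiltonian.

    States are 0-based integers in ``[0, n_states)``.  The energy is

        H(s) = - sum_i h_i(s_i) - sum_{i<j} J_ij(s_i, s_j).

    Couplings are a mapping ``(i, j) -> (q, q)`` array with ``i < j``;
    absent pairs have zero coupling.
    """

    n_sites: int
    n_states: int
    fields: np.ndarray  # (n_sites, n_states)
    couplings: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.fields, dtype=np.float64)
        if f.shape != (self.n_sites, self.n_states):
            raise ValueError("fields must have shape (n_sites, n_states)")
        object.__setattr__(self, "fields", f)
        for (i, j), jij in self.couplings.items():
            if not (0 <= i < j < self.n_sites):
                raise ValueError(f"coupling pair ({i}, {j}) must satisfy 0 <= i < j")
            if np.asarray(jij).shape != (self.n_states, self.n_states):
                raise ValueError(f"coupling block ({i}, {j}) has wrong shape")

    @classmethod
    def from_ising(cls, spec: HamiltonianSpec) -> "PottsHamiltonian":
        """Embed a binary Ising spec as a 2-state Potts model.

        State 0 maps to spin -1 and state 1 to spin +1.
        """
        spins = np.array([-1.0, 1.0])
        h = spec.field_array()[:, None] * spins[None, :]
        block = np.outer(spins, spins)
        couplings: dict[tuple[int, int], np.ndarray] = {
            (i, j): spec.coupling_value * block for (i, j) in sorted(spec.graph.edges)
        }
        for (i, j), v in spec.background_couplings.items():
            key = (min(i, j), max(i, j))
            couplings[key] = couplings.get(key, 0.0) + v * block
        return cls(n_sites=spec.n_sites, n_states=2, fields=h, couplings=couplings)

    def _neighbors(self) -> dict[int, list[tuple[int, np.ndarray, bool]]]:
        nb: dict[int, list[tuple[int, np.ndarray, bool]]] = {
            i: [] for i in range(self.n_sites)
        }
        for (i, j), jij in self.couplings.items():
            nb[i].append((j, jij, True))    # J(s_i, s_j)
            nb[j].append((i, jij, False))   # J(s_other, s_j) transposed access
        return nb

    def energy(self, seq: np.ndarray) -> float:
        seq = np.asarray(seq)
        if seq.shape != (self.n_sites,):
            raise ValueError("sequence length mismatch")
        e = -float(np.sum(self.fields[np.arange(self.n_sites), seq]))
        for (i, j), jij in self.couplings.items():
            e -= float(jij[seq[i], seq[j]])
        return e

    def delta_energy(self, seq: np.ndarray, site: int, new_state: int) -> float:
        """Energy change from setting ``seq[site] = new_state`` (local)."""
        if not (0 <= site < self.n_sites):
            raise IndexError("site out of range")
        if not (0 <= new_state < self.n_states):
            raise ValueError("new_state out of range")
        old = int(seq[site])
        d = -(self.fields[site, new_state] - self.fields[site, old])
        for (i, j), jij in self.couplings.items():
            if i == site:
                d -= jij[new_state, seq[j]] - jij[old, seq[j]]
            elif j == site:
                d -= jij[seq[i], new_state] - jij[seq[i], old]
        return float(d)
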