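"""Equilibrium sequence generation and the ferromagnetic transition.

Independent equilibrium sequences are the "no phylogeny" regime: each
row of the MSA is initialized at random and evolved by Metropolis (or
Wolff cluster) moves under the structural Hamiltonian until the absolute
magnetization |m| plateaus, so all inter-column correlations come from
the contact graph alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import _kernels
from .graph import ContactGraph
from .hamiltonian import HamiltonianSpec
from .msa import SpinMSA

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerParams",
    "metropolis_accept",
    "sample_equilibrium",
    "wolff_step",
    "estimate_transition_temperature",
    "TransitionScan",
    "annealed_transition_temperature",
]


@dataclass(frozen=True)
class SamplerParams:
    """Monte Carlo settings shared by the equilibrium and phylogeny regimes.

    Parameters
    ----------
    temperature:
        Sampling temperature T > 0; acts as an inverse selection strength.
    proposal_kind:
        ``"single_flip"`` or ``"wolff_cluster"``.
    window:
        Plateau-detection window, in accepted moves (default ``10 * L``).
    tol:
        Relative tolerance between consecutive window means of |m|.
    cap:
        Hard cap on accepted moves per sequence (default ``200 * L``).
    rng_seed:
        Master seed for the generation.
    """

    temperature: float
    proposal_kind: str = "single_flip"
    window: int | None = None
    tol: float = 0.02
    cap: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.proposal_kind not in ("single_flip", "wolff_cluster"):
            raise ValueError(f"unknown proposal_kind {self.proposal_kind!r}")
        if self.window is not None and self.window < 1:
            raise ValueError("window must be >= 1")
        if (self.window is not None and self.cap is not None
                and self.cap < self.window):
            raise ValueError("cap must be >= window")

    def resolved(self, n_sites: int) -> "SamplerParams":
        """Fill in size-dependent defaults for a given sequence length.

        Single-flip moves default to windows of ``10 * L`` accepted moves
        with a cap of ``200 * L``; Wolff cluster moves decorrelate far
        faster per accepted move, so their defaults are ``L / 10`` and
        ``4 * L``.
        """
        if self.proposal_kind == "wolff_cluster":
            window = self.window if self.window is not None else max(1, n_sites // 10)
            cap = self.cap if self.cap is not None else 4 * n_sites
        else:
            window = self.window if self.window is not None else 10 * n_sites
            cap = self.cap if self.cap is not None else 200 * n_sites
        return replace(self, window=window, cap=cap)


def metropolis_accept(delta_h: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min[1, exp(-dH/T)]."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_h <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_h / temperature))


def _weighted_neighbors(spec: HamiltonianSpec):
    """CSR neighbour lists with coupling weights (edges + background)."""
    n = spec.n_sites
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j in spec.graph.edges:
        adj[i].append((j, spec.coupling_value))
        adj[j].append((i, spec.coupling_value))
    for (i, j), v in spec.background_couplings.items():
        adj[i].append((j, v))
        adj[j].append((i, v))
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i, nb in enumerate(adj):
        indptr[i + 1] = indptr[i] + len(nb)
    idx = np.empty(indptr[-1], dtype=np.int64)
    wt = np.empty(indptr[-1], dtype=np.float64)
    for i, nb in enumerate(adj):
        for k, (j, v) in enumerate(sorted(nb)):
            idx[indptr[i] + k] = j
            wt[indptr[i] + k] = v
    return idx, wt, indptr


def _kernel_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0])


def sample_equilibrium(spec: HamiltonianSpec, params: SamplerParams,
                       n_sequences: int) -> SpinMSA:
    """Generate ``n_sequences`` mutually independent equilibrium sequences.

    Each row starts from a uniform random state and is evolved until the
    plateau criterion on |m| is met (or the accepted-move cap is hit, in
    which case a warning is emitted and the row is flagged).
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    p = params.resolved(spec.n_sites)
    seed = _kernel_seed(np.random.SeedSequence(p.rng_seed))
    idx, wt, indptr = _weighted_neighbors(spec)
    if p.proposal_kind == "wolff_cluster":
        if not spec.is_uniform_ferromagnetic:
            raise ValueError(
                "Wolff cluster sampling requires zero fields and a uniform "
                "ferromagnetic coupling"
            )
        matrix, n_acc, conv = _kernels.equilibrium_msa_wolff(
            n_sequences, spec.n_sites, idx, indptr, spec.coupling_value,
            p.temperature, p.window, p.tol, p.cap, seed)
    else:
        matrix, n_acc, conv = _kernels.equilibrium_msa_metropolis(
            n_sequences, spec.n_sites, idx, wt, indptr, spec.field_array(),
            p.temperature, p.window, p.tol, p.cap, seed)
    n_flagged = int(np.sum(~conv))
    if n_flagged:
        logger.warning(
            "%d/%d sequences hit the accepted-move cap (%d) before the |m| "
            "plateau; they are returned but flagged in provenance",
            n_flagged, n_sequences, p.cap)
    provenance = {
        "kind": "equilibrium",
        "temperature": p.temperature,
        "proposal_kind": p.proposal_kind,
        "rng_seed": p.rng_seed,
        "n_accepted_mean": float(np.mean(n_acc)),
        "n_not_converged": n_flagged,
    }
    return SpinMSA(matrix=matrix, n_states=2, provenance=provenance)


def wolff_step(spec: HamiltonianSpec, seq: np.ndarray, temperature: float,
               rng: np.random.Generator) -> np.ndarray:
    """One Wolff cluster move: grow a cluster of aligned spins with bond
    probability 1 - exp(-2J/T) and flip it.  Returns a new array.

    Only valid for zero fields and a uniform ferromagnetic coupling.
    """
    if not spec.is_uniform_ferromagnetic:
        raise ValueError("Wolff moves require h = 0 and uniform J > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    seq = np.asarray(seq, dtype=np.int8).copy()
    idx, indptr = spec.graph.neighbor_lists()
    p_add = 1.0 - np.exp(-2.0 * spec.coupling_value / temperature)
    seed_site = int(rng.integers(spec.n_sites))
    in_cluster = np.zeros(spec.n_sites, dtype=bool)
    in_cluster[seed_site] = True
    stack = [seed_site]
    seed_spin = seq[seed_site]
    while stack:
        site = stack.pop()
        for j in idx[indptr[site]:indptr[site + 1]]:
            if not in_cluster[j] and seq[j] == seed_spin:
                if rng.random() < p_add:
                    in_cluster[j] = True
                    stack.append(int(j))
    seq[in_cluster] = -seq[in_cluster]
    return seq


@dataclass
class TransitionScan:
    """Result of a magnetization-histogram temperature scan."""

    t_c: float | None
    histograms: pd.DataFrame            # columns: temperature, bin_center, count
    peak_table: pd.DataFrame            # columns: temperature, n_peaks, bimodal
    message: str = ""
    samples: dict[float, np.ndarray] = field(default_factory=dict)


def _is_bimodal(m_samples: np.ndarray, n_bins: int = 50) -> tuple[bool, int, np.ndarray, np.ndarray]:
    """Detect a two-peak (+-|m*|) structure in the magnetization histogram.

    The histogram (50 bins on [-1, 1]) is lightly smoothed; peaks are
    local maxima with prominence >= 5% of the maximum count.  The
    distribution is called bimodal when peaks exist on both sides of
    m = 0 (|center| > 0.05).
    """
    counts, edges = np.histogram(m_samples, bins=n_bins, range=(-1.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    peaks, _ = find_peaks(smooth, prominence=0.05 * smooth.max())
    pk_centers = centers[peaks]
    bimodal = bool(np.any(pk_centers < -0.05) and np.any(pk_centers > 0.05))
    return bimodal, len(peaks), centers, counts


def estimate_transition_temperature(
    spec: HamiltonianSpec,
    t_grid,
    params: SamplerParams,
    n_samples: int = 2000,
    n_burn: int = 300,
    thin: int = 3,
) -> TransitionScan:
    """Locate the ferromagnetic-paramagnetic transition by scanning
    magnetization histograms over a temperature grid.

    At each T a Wolff (or single-flip) chain collects ``n_samples``
    magnetization values; the transition estimate is the midpoint
    between the last bimodal and the first unimodal grid temperature.
    """
    t_grid = sorted(float(t) for t in np.atleast_1d(np.asarray(t_grid, dtype=float)))
    if len(t_grid) < 3:
        raise ValueError("t_grid needs at least 3 temperatures")
    idx, wt, indptr = _weighted_neighbors(spec)
    use_wolff = (params.proposal_kind == "wolff_cluster"
                 and spec.is_uniform_ferromagnetic)
    seed_seq = np.random.SeedSequence(params.rng_seed)
    rows_h, rows_p, samples = [], [], {}
    for t, child in zip(t_grid, seed_seq.spawn(len(t_grid))):
        seed = _kernel_seed(child)
        if use_wolff:
            m = _kernels.wolff_magnetization_chain(
                spec.n_sites, idx, indptr, spec.coupling_value, t,
                n_burn, n_samples, thin, seed)
        else:
            # Single-flip fallback: one fresh equilibrium sequence per sample.
            p = replace(params, temperature=t, rng_seed=seed)
            m = sample_equilibrium(spec, p, n_samples).matrix.mean(axis=1)
        samples[t] = m
        bimodal, n_peaks, centers, counts = _is_bimodal(m)
        rows_p.append({"temperature": t, "n_peaks": n_peaks, "bimodal": bimodal})
        for c, n in zip(centers, counts):
            rows_h.append({"temperature": t, "bin_center": c, "count": int(n)})
    peak_table = pd.DataFrame(rows_p)
    histograms = pd.DataFrame(rows_h)
    flags = peak_table["bimodal"].to_numpy()
    if not flags.any():
        return TransitionScan(None, histograms, peak_table,
                              "no transition detected (no bimodal histogram)",
                              samples)
    last_bimodal = int(np.max(np.nonzero(flags)[0]))
    if last_bimodal == len(t_grid) - 1:
        return TransitionScan(None, histograms, peak_table,
                              "no transition detected inside the grid "
                              "(still bimodal at the highest temperature)",
                              samples)
    t_c = 0.5 * (t_grid[last_bimodal] + t_grid[last_bimodal + 1])
    return TransitionScan(float(t_c), histograms, peak_table, "", samples)


def annealed_transition_temperature(graph: ContactGraph,
                                    coupling: float = 1.0) -> float:
    """Annealed random-graph estimate: tanh(J/T_c) = <k> / (<k^2> - <k>).

    An independent closed-form cross-check for the histogram scan, exact
    only in the annealed approximation.
    """
    k = graph.degrees().astype(float)
    denom = np.mean(k ** 2) - k.mean()
    if denom <= 0 or not (0 < k.mean() / denom < 1):
        raise ValueError("graph too sparse for a ferromagnetic transition")
    ratio = k.mean() / denom
    return coupling / np.arctanh(ratio)
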