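"""Numba kernels for Metropolis and Wolff sampling of the Ising model.

All kernels operate on int8 spin states (+1/-1) and a CSR-style weighted
neighbour structure ``(nbr_idx, nbr_wt, nbr_ptr)`` so that background
couplings are handled uniformly with edge couplings.  Each kernel seeds
numba's module-level RNG once and draws sequentially, so a single 32-bit
seed determines the whole output.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "equilibrium_msa_metropolis",
    "equilibrium_msa_wolff",
    "binary_tree_evolve",
    "wolff_magnetization_chain",
]


@njit(cache=True, inline="always")
def _local_field(state, site, nbr_idx, nbr_wt, nbr_ptr, h):
    acc = h[site]
    for k in range(nbr_ptr[site], nbr_ptr[site + 1]):
        acc += nbr_wt[k] * state[nbr_idx[k]]
    return acc


@njit(cache=True)
def _metropolis_until_plateau(state, nbr_idx, nbr_wt, nbr_ptr, h, temperature,
                              window, tol, cap):
    """Single-flip Metropolis until the running mean of |m| plateaus.

    Returns (n_accepted, converged).  Windows are counted in accepted
    moves; the chain stops once at least 10 windows have elapsed and 3
    consecutive window means of |m| agree within relative ``tol`` (this
    guards against chance agreement of two noisy windows), or at ``cap``
    accepted moves.
    """
    n = state.shape[0]
    spin_sum = 0
    for i in range(n):
        spin_sum += state[i]
    accepted = 0
    proposals = 0
    max_proposals = 200 * cap if cap > 0 else 0
    win_acc = 0.0
    win_count = 0
    n_windows = 0
    streak = 0
    prev_mean = -1.0
    converged = False
    while accepted < cap:
        site = np.random.randint(0, n)
        proposals += 1
        dh = 2.0 * state[site] * _local_field(state, site, nbr_idx, nbr_wt,
                                              nbr_ptr, h)
        if dh <= 0.0 or np.random.random() < np.exp(-dh / temperature):
            spin_sum -= 2 * state[site]
            state[site] = -state[site]
            accepted += 1
            win_acc += abs(spin_sum) / n
            win_count += 1
            if win_count == window:
                cur_mean = win_acc / window
                n_windows += 1
                if prev_mean >= 0.0:
                    scale = max(prev_mean, 1.0 / n)
                    if abs(cur_mean - prev_mean) < tol * scale:
                        streak += 1
                    else:
                        streak = 0
                    if n_windows >= 10 and streak >= 3:
                        converged = True
                        break
                prev_mean = cur_mean
                win_acc = 0.0
                win_count = 0
        if proposals >= max_proposals:
            break
    # Fixed-length proposal suffix.  Stopping exactly at an accepted move
    # samples the embedded jump chain, whose stationary law overweights
    # states with high acceptance probability; a fixed number of further
    # proposals (not conditioned on acceptance) restores the target
    # Boltzmann distribution.
    for _ in range(20 * n):
        site = np.random.randint(0, n)
        dh = 2.0 * state[site] * _local_field(state, site, nbr_idx, nbr_wt,
                                              nbr_ptr, h)
        if dh <= 0.0 or np.random.random() < np.exp(-dh / temperature):
            state[site] = -state[site]
    return accepted, converged


@njit(cache=True)
def equilibrium_msa_metropolis(n_rows, n_sites, nbr_idx, nbr_wt, nbr_ptr, h,
                               temperature, window, tol, cap, seed):
    """Generate ``n_rows`` independent equilibrium sequences (single-flip).

    Each row is initialized uniformly at random and run to the |m|
    plateau.  Returns (msa, n_accepted, converged).
    """
    np.random.seed(seed)
    msa = np.empty((n_rows, n_sites), dtype=np.int8)
    n_accepted = np.empty(n_rows, dtype=np.int64)
    converged = np.empty(n_rows, dtype=np.bool_)
    state = np.empty(n_sites, dtype=np.int8)
    for r in range(n_rows):
        for i in range(n_sites):
            state[i] = 1 if np.random.random() < 0.5 else -1
        acc, conv = _metropolis_until_plateau(state, nbr_idx, nbr_wt, nbr_ptr,
                                             h, temperature, window, tol, cap)
        msa[r, :] = state
        n_accepted[r] = acc
        converged[r] = conv
    return msa, n_accepted, converged


@njit(cache=True)
def _wolff_flip(state, nbr_idx, nbr_ptr, p_add, stack, in_cluster):
    """One Wolff cluster flip; returns the cluster size."""
    n = state.shape[0]
    seed_site = np.random.randint(0, n)
    in_cluster[:] = False
    in_cluster[seed_site] = True
    stack[0] = seed_site
    top = 1
    size = 0
    seed_spin = state[seed_site]
    while top > 0:
        top -= 1
        site = stack[top]
        size += 1
        for k in range(nbr_ptr[site], nbr_ptr[site + 1]):
            j = nbr_idx[k]
            if not in_cluster[j] and state[j] == seed_spin:
                if np.random.random() < p_add:
                    in_cluster[j] = True
                    stack[top] = j
                    top += 1
    for i in range(n):
        if in_cluster[i]:
            state[i] = -state[i]
    return size


@njit(cache=True)
def equilibrium_msa_wolff(n_rows, n_sites, nbr_idx, nbr_ptr, coupling,
                          temperature, window, tol, cap, seed):
    """Generate independent equilibrium sequences with Wolff cluster moves.

    Valid only for zero fields and uniform ferromagnetic couplings.
    The plateau rule matches the single-flip kernel, with one accepted
    move per cluster flip.
    """
    np.random.seed(seed)
    p_add = 1.0 - np.exp(-2.0 * coupling / temperature)
    msa = np.empty((n_rows, n_sites), dtype=np.int8)
    n_accepted = np.empty(n_rows, dtype=np.int64)
    converged = np.empty(n_rows, dtype=np.bool_)
    state = np.empty(n_sites, dtype=np.int8)
    stack = np.empty(n_sites, dtype=np.int64)
    in_cluster = np.empty(n_sites, dtype=np.bool_)
    for r in range(n_rows):
        for i in range(n_sites):
            state[i] = 1 if np.random.random() < 0.5 else -1
        accepted = 0
        win_acc = 0.0
        win_count = 0
        n_windows = 0
        streak = 0
        prev_mean = -1.0
        conv = False
        while accepted < cap:
            _wolff_flip(state, nbr_idx, nbr_ptr, p_add, stack, in_cluster)
            accepted += 1
            spin_sum = 0
            for i in range(n_sites):
                spin_sum += state[i]
            win_acc += abs(spin_sum) / n_sites
            win_count += 1
            if win_count == window:
                cur_mean = win_acc / window
                n_windows += 1
                if prev_mean >= 0.0:
                    scale = max(prev_mean, 1.0 / n_sites)
                    if abs(cur_mean - prev_mean) < tol * scale:
                        streak += 1
                    else:
                        streak = 0
                    if n_windows >= 10 and streak >= 3:
                        conv = True
                        break
                prev_mean = cur_mean
                win_acc = 0.0
                win_count = 0
        msa[r, :] = state
        n_accepted[r] = accepted
        converged[r] = conv
    return msa, n_accepted, converged


@njit(cache=True)
def binary_tree_evolve(ancestor, nbr_idx, nbr_wt, nbr_ptr, h, temperature, mu,
                       n_generations, seed):
    """Evolve an ancestor along a complete binary tree, mu accepted
    mutations (single-flip Metropolis) on every branch.

    Nodes use heap indexing: node 0 is the root, node k's children are
    2k+1 and 2k+2; branches are identified by their child node.  Returns

    - node_states: (2^(G+1) - 1, n_sites) spins of every node,
    - log_site, log_old, log_new: (n_branches, mu) per-branch ordered
      accepted-mutation logs, where branch b is the edge into node b + 1.
    """
    np.random.seed(seed)
    n_sites = ancestor.shape[0]
    n_nodes = 2 ** (n_generations + 1) - 1
    n_branches = n_nodes - 1
    node_states = np.empty((n_nodes, n_sites), dtype=np.int8)
    node_states[0, :] = ancestor
    log_site = np.empty((n_branches, mu), dtype=np.int64)
    log_old = np.empty((n_branches, mu), dtype=np.int8)
    log_new = np.empty((n_branches, mu), dtype=np.int8)
    state = np.empty(n_sites, dtype=np.int8)
    for child in range(1, n_nodes):
        parent = (child - 1) // 2
        state[:] = node_states[parent, :]
        b = child - 1
        accepted = 0
        while accepted < mu:
            site = np.random.randint(0, n_sites)
            dh = 2.0 * state[site] * _local_field(state, site, nbr_idx, nbr_wt,
                                                  nbr_ptr, h)
            if dh <= 0.0 or np.random.random() < np.exp(-dh / temperature):
                log_site[b, accepted] = site
                log_old[b, accepted] = state[site]
                state[site] = -state[site]
                log_new[b, accepted] = state[site]
                accepted += 1
        node_states[child, :] = state
    return node_states, log_site, log_old, log_new


@njit(cache=True)
def wolff_magnetization_chain(n_sites, nbr_idx, nbr_ptr, coupling, temperature,
                              n_burn, n_samples, thin, seed):
    """One Wolff chain; returns magnetization m = mean spin at each sample."""
    np.random.seed(seed)
    p_add = 1.0 - np.exp(-2.0 * coupling / temperature)
    state = np.empty(n_sites, dtype=np.int8)
    for i in range(n_sites):
        state[i] = 1 if np.random.random() < 0.5 else -1
    stack = np.empty(n_sites, dtype=np.int64)
    in_cluster = np.empty(n_sites, dtype=np.bool_)
    for _ in range(n_burn):
        _wolff_flip(state, nbr_idx, nbr_ptr, p_add, stack, in_cluster)
    out = np.empty(n_samples, dtype=np.float64)
    for s in range(n_samples):
        for _ in range(thin):
            _wolff_flip(state, nbr_idx, nbr_ptr, p_add, stack, in_cluster)
        spin_sum = 0
        for i in range(n_sites):
            spin_sum += state[i]
        out[s] = spin_sum / n_sites
    return out
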