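"""Benchmarking inferred scores against the true contact graph.

The headline statistic is the true-positive (TP) fraction: the fraction
of actual contacts among the top-scoring pairs.  Evaluated at a number
of predictions equal to the number of true contacts, it coincides with
both the positive predictive value and the true positive rate.  The
module also computes the ROC AUC, graph descriptors (shortest-path
length L, neighbour counts N), site conservation, a sequence-variance
PCA, and the score-versus-earliest-mutation statistics that diagnose
phylogenetic false positives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path
from sklearn.metrics import roc_auc_score

from .graph import ContactGraph
from .inference import ScoreMatrix
from .msa import SpinMSA

__all__ = [
    "ranked_pairs",
    "tp_fraction",
    "auc",
    "shortest_path_lengths",
    "score_vs_depth_stats",
    "site_conservation",
    "site_pca",
    "EvalReport",
    "evaluate_scores",
]


def _upper(scores: np.ndarray):
    ell = scores.shape[0]
    iu = np.triu_indices(ell, k=1)
    return iu, scores[iu]


def ranked_pairs(score: ScoreMatrix) -> np.ndarray:
    """All i<j pairs ranked by score descending; ties broken by ascending
    (i, j) lexicographic order (deterministic across platforms).

    Returns an (n_pairs, 2) array of site indices.
    """
    iu, vals = _upper(score.scores)
    order = np.lexsort((iu[1], iu[0], -vals))
    return np.column_stack((iu[0][order], iu[1][order]))


def tp_fraction(score: ScoreMatrix, truth: ContactGraph,
                n_pred: int | None = None) -> float:
    """Fraction of true contacts among the ``n_pred`` top-scoring pairs.

    ``n_pred`` defaults to the number of edges, at which the TP fraction
    equals both PPV and TPR.
    """
    if score.n_sites != truth.n_sites:
        raise ValueError("score matrix and graph sizes differ")
    n_pred = truth.n_edges if n_pred is None else int(n_pred)
    if n_pred < 1:
        raise ValueError("n_pred must be >= 1")
    if n_pred > truth.n_pairs:
        raise ValueError(f"n_pred {n_pred} exceeds the {truth.n_pairs} pairs")
    top = ranked_pairs(score)[:n_pred]
    hits = sum(truth.has_edge(int(i), int(j)) for i, j in top)
    return hits / n_pred


def auc(score: ScoreMatrix, truth: ContactGraph) -> float:
    """Rank-based ROC AUC: probability that a random true edge outscores a
    random non-edge, counting ties 1/2."""
    if score.n_sites != truth.n_sites:
        raise ValueError("score matrix and graph sizes differ")
    iu, vals = _upper(score.scores)
    labels = np.array([truth.has_edge(int(i), int(j))
                       for i, j in zip(iu[0], iu[1])])
    if labels.all() or not labels.any():
        raise ValueError("need at least one edge and one non-edge")
    return float(roc_auc_score(labels, vals))


def shortest_path_lengths(truth: ContactGraph) -> np.ndarray:
    """All-pairs unweighted shortest-path length matrix (BFS distances).

    L = 1 marks contacting sites; disconnected pairs get ``inf``.
    """
    adj = csr_matrix(truth.adjacency_matrix())
    return _csgraph_shortest_path(adj, method="D", unweighted=True)


def score_vs_depth_stats(table: pd.DataFrame) -> dict:
    """Score-versus-earliest-mutation statistics.

    ``table`` must have columns ``G`` and ``score``; rows with sentinel
    (NaN) G must be excluded by the caller.  Returns a dict with

    - ``medians``: median score per G value (Series indexed by G),
    - ``rho``: Pearson correlation of (G, score) over all pairs (no
      binning), 0 with ``zero_variance=True`` if scores are constant,
    - ``rho_m``: Pearson correlation over (G, median score at G); None
      when fewer than 2 distinct G values exist.
    """
    if table["G"].isna().any():
        raise ValueError("sentinel (NaN) G values must be excluded first")
    g = table["G"].to_numpy(dtype=float)
    s = table["score"].to_numpy(dtype=float)
    medians = table.groupby("G")["score"].median()
    zero_var = s.std() == 0 or g.std() == 0
    rho = 0.0 if zero_var else float(np.corrcoef(g, s)[0, 1])
    if medians.size < 2:
        rho_m = None
    else:
        mg = medians.index.to_numpy(dtype=float)
        mv = medians.to_numpy(dtype=float)
        rho_m = (0.0 if mv.std() == 0 else float(np.corrcoef(mg, mv)[0, 1]))
    return {"medians": medians, "rho": rho, "rho_m": rho_m,
            "zero_variance": bool(zero_var)}


def site_conservation(msa: SpinMSA) -> np.ndarray:
    """Majority-state frequency of every site (no pseudocount), in [1/q, 1]."""
    x = msa.matrix
    states = np.array([-1, 1]) if msa.is_binary else np.arange(msa.n_states)
    counts = (x[None, :, :] == states[:, None, None]).sum(axis=1)
    return counts.max(axis=0) / x.shape[0]


def site_pca(msa: SpinMSA, truth: ContactGraph | None = None):
    """Leading principal component of the site-site covariance matrix.

    Returns ``(pc1, degrees)``: each site's coordinate on the top
    eigenvector (sign fixed so the largest-magnitude entry is positive)
    and its number of neighbours in ``truth`` (None if no graph given).
    Sites in tightly coupled clusters co-vary and load strongly on PC1.
    """
    if msa.n_sequences < 2:
        raise ValueError("PCA needs at least 2 sequences")
    x = msa.matrix.astype(np.float64)
    cov = np.cov(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc1 = eigvecs[:, -1]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    degrees = truth.degrees() if truth is not None else None
    return pc1, degrees


@dataclass
class EvalReport:
    """Per-pair table plus summary statistics for one score matrix."""

    table: pd.DataFrame          # i, j, score, is_contact, L, [G]
    summary: dict

    def write(self, table_path: str | Path, summary_path: str | Path) -> None:
        self.table.to_csv(table_path, sep="\t", index=False)
        Path(summary_path).write_text(json.dumps(self.summary, indent=2,
                                                 default=float) + "\n")


def evaluate_scores(
    score: ScoreMatrix,
    truth: ContactGraph,
    n_pred: int | None = None,
    pair_depth: np.ndarray | None = None,
    msa: SpinMSA | None = None,
    extra_summary: dict | None = None,
) -> EvalReport:
    """Full evaluation of one score matrix against the ground truth.

    ``pair_depth`` is an optional L x L matrix of earliest-mutation
    indices G (NaN sentinel); when given, per-pair G and the score-vs-G
    correlations are included.  When ``msa`` is given, pair conservation
    (mean of the two sites' conservations) is added.
    """
    iu, vals = _upper(score.scores)
    spl = shortest_path_lengths(truth)
    table = pd.DataFrame({
        "i": iu[0], "j": iu[1], "score": vals,
        "is_contact": [truth.has_edge(int(a), int(b))
                       for a, b in zip(iu[0], iu[1])],
        "L": spl[iu],
    })
    summary = {
        "method": score.method,
        "apc": score.apc_applied,
        "n_pred": truth.n_edges if n_pred is None else int(n_pred),
        "tp_fraction": tp_fraction(score, truth, n_pred),
        "auc": auc(score, truth),
    }
    if pair_depth is not None:
        table["G"] = pair_depth[iu]
        valid = table.dropna(subset=["G"])
        stats = score_vs_depth_stats(valid[["G", "score"]])
        summary["rho"] = stats["rho"]
        summary["rho_m"] = stats["rho_m"]
        summary["n_sentinel_pairs"] = int(table["G"].isna().sum())
    if msa is not None:
        cons = site_conservation(msa)
        table["conservation"] = 0.5 * (cons[iu[0]] + cons[iu[1]])
    if extra_summary:
        summary.update(extra_summary)
    return EvalReport(table=table, summary=summary)
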