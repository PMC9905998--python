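"""Pair coevolution scores: covariance, mutual information, mfDCA, plmDCA.

Local methods (covariance, MI) compare two-column statistics directly.
Global methods fit a Potts model P(sigma) ~ exp(-H(sigma)) to the MSA's
one- and two-body frequencies — mfDCA by inverting the pseudocount-
regularized covariance matrix, plmDCA by maximizing an L2-regularized
pseudolikelihood — and score a pair by the magnitude of its inferred
coupling.  All four can be post-processed with the average product
correction (APC).

Default regularization follows standard contact-prediction practice:
pseudocount 0.01 for MI, 0.5 for mfDCA, and L2 strengths
lambda_J = lambda_h = 0.01 for plmDCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .msa import SpinMSA

__all__ = [
    "FrequencyModel",
    "ScoreMatrix",
    "PottsModel",
    "ConvergenceError",
    "compute_frequencies",
    "covariance_scores",
    "mi_scores",
    "mfdca_scores",
    "plmdca_scores",
    "apply_apc",
    "frobenius_scores",
    "write_scores",
]

DEFAULT_LAMBDA_MI = 0.01
DEFAULT_LAMBDA_MFDCA = 0.5
DEFAULT_LAMBDA_PLM = 0.01


class ConvergenceError(RuntimeError):
    """Raised when the pseudolikelihood optimizer terminates abnormally."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyModel:
    """Pseudocount-corrected one- and two-site frequencies.

    Binary mode mixes with weights lambda/2 (one-site) and lambda/4
    (two-site); q-state mode generalizes these to lambda/q and
    lambda/q^2.  Diagonal blocks follow the convention
    f_ii(a, b) = delta_ab * f_i(a).
    """

    lam: float
    f1: np.ndarray          # (L, q)
    f2: np.ndarray          # (L, L, q, q)
    n_states: int


@dataclass
class ScoreMatrix:
    """Symmetric L x L matrix of pair coevolution scores (diagonal ignored)."""

    scores: np.ndarray
    method: str
    apc_applied: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("scores must be a square matrix")
        if not np.allclose(s, s.T, equal_nan=True):
            raise ValueError("scores must be symmetric")
        off = s[~np.eye(len(s), dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal scores must be finite")
        self.scores = s

    @property
    def n_sites(self) -> int:
        return self.scores.shape[0]


@dataclass
class PottsModel:
    """Inferred fields and couplings.

    Binary mode: ``couplings`` is (L, L) with scalar J_ij (the Ising
    parametrization, which is already the zero-sum gauge) and ``fields``
    is (L,).  q-state mode: ``couplings`` is (L, L, q, q) and ``fields``
    (L, q); the zero-sum gauge can be applied with
    :meth:`to_zero_sum_gauge`.
    """

    fields: np.ndarray | None
    couplings: np.ndarray
    n_states: int
    gauge: str | None = None

    @property
    def is_binary(self) -> bool:
        return self.couplings.ndim == 2

    def to_zero_sum_gauge(self) -> "PottsModel":
        """Shift every coupling block so its rows and columns sum to zero,
        moving the absorbed parts into the fields."""
        if self.is_binary:
            return PottsModel(self.fields, self.couplings, self.n_states,
                              gauge="zero_sum")
        j = self.couplings.copy()
        row = j.mean(axis=3, keepdims=True)        # mean over b
        col = j.mean(axis=2, keepdims=True)        # mean over a
        tot = j.mean(axis=(2, 3), keepdims=True)
        j_zs = j - row - col + tot
        h = None
        if self.fields is not None:
            # h'_i(a) = h_i(a) + sum_j [ mean_b J_ij(a, b) - mean_ab J_ij ]
            h = self.fields + (row - tot)[:, :, :, 0].sum(axis=1)
        return PottsModel(h, j_zs, self.n_states, gauge="zero_sum")


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def _one_hot(msa: SpinMSA) -> np.ndarray:
    """(M, L, q) indicator array; binary states are ordered (-1, +1)."""
    x = msa.matrix
    if msa.is_binary:
        states = np.array([-1, 1])
    else:
        states = np.arange(msa.n_states)
    return (x[:, :, None] == states[None, None, :]).astype(np.float64)


def compute_frequencies(msa: SpinMSA, lam: float) -> FrequencyModel:
    """Pseudocount-corrected frequencies at strength ``lam`` in [0, 1]."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("pseudocount must be in [0, 1]")
    if msa.n_sequences < 1:
        raise ValueError("empty MSA")
    q = 2 if msa.is_binary else msa.n_states
    m, ell = msa.matrix.shape
    onehot = _one_hot(msa)
    f1 = onehot.mean(axis=0)
    f2 = np.empty((ell, ell, q, q))
    for a in range(q):
        for b in range(q):
            f2[:, :, a, b] = onehot[:, :, a].T @ onehot[:, :, b] / m
    f1t = lam / q + (1.0 - lam) * f1
    f2t = lam / q ** 2 + (1.0 - lam) * f2
    # Diagonal convention: f_ii(a, b) = delta_ab f_i(a).
    diag = np.zeros((ell, q, q))
    diag[:, np.arange(q), np.arange(q)] = f1t
    f2t[np.arange(ell), np.arange(ell)] = diag
    return FrequencyModel(lam=lam, f1=f1t, f2=f2t, n_states=q)


# ---------------------------------------------------------------------------
# Local scores
# ---------------------------------------------------------------------------

def covariance_scores(msa: SpinMSA) -> ScoreMatrix:
    """|C_ij| with C_ij = <s_i s_j> - <s_i><s_j> (no pseudocount).

    Defined for the binary +-1 model only; equals
    4 [f_ij(1,1) - f_i(1) f_j(1)] in frequency form.
    """
    if not msa.is_binary:
        raise ValueError("covariance scores are defined for binary MSAs only")
    x = msa.matrix.astype(np.float64)
    m1 = x.mean(axis=0)
    cov = x.T @ x / x.shape[0] - np.outer(m1, m1)
    np.fill_diagonal(cov, 0.0)
    return ScoreMatrix(scores=np.abs(cov), method="covariance")


def mi_scores(msa: SpinMSA, lam: float = DEFAULT_LAMBDA_MI) -> ScoreMatrix:
    """Mutual information of pseudocount-corrected pair frequencies (nats).

    No finite-size correction is applied: all datasets compared share
    the same size, hence the same finite-size bias.
    """
    fm = compute_frequencies(msa, lam)
    outer = fm.f1[:, None, :, None] * fm.f1[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(fm.f2 > 0, fm.f2 * np.log(fm.f2 / outer), 0.0)
    mi = terms.sum(axis=(2, 3))
    np.fill_diagonal(mi, 0.0)
    return ScoreMatrix(scores=0.5 * (mi + mi.T), method="mi")


# ---------------------------------------------------------------------------
# Global scores
# ---------------------------------------------------------------------------

def mfdca_scores(msa: SpinMSA,
                 lam: float = DEFAULT_LAMBDA_MFDCA) -> tuple[ScoreMatrix, PottsModel]:
    """Mean-field DCA: J = -(C~^-1) with the pseudocount-regularized
    covariance matrix

        C~_ij = (1-lam)<s_i s_j> - (1-lam)^2 <s_i><s_j>      (i != j)
        C~_ii = (1-lam)^2 (1 - <s_i>^2) + lam (2-lam),

    scored by |J_ij|.  Binary MSAs only.
    """
    if not msa.is_binary:
        raise ValueError("mfDCA is implemented for the binary model only")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("pseudocount must be in [0, 1]")
    x = msa.matrix.astype(np.float64)
    m = x.shape[0]
    m1 = x.mean(axis=0)
    m2 = x.T @ x / m
    c = (1.0 - lam) * m2 - (1.0 - lam) ** 2 * np.outer(m1, m1)
    np.fill_diagonal(c, (1.0 - lam) ** 2 * (1.0 - m1 ** 2) + lam * (2.0 - lam))
    try:
        j = -np.linalg.inv(c)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"regularized covariance matrix is singular ({err}); "
            "raise the pseudocount lam to regularize it") from err
    np.fill_diagonal(j, 0.0)
    j = 0.5 * (j + j.T)
    model = PottsModel(fields=None, couplings=j, n_states=2, gauge="zero_sum")
    return ScoreMatrix(scores=np.abs(j), method="mfdca"), model


def _plm_binary(x: np.ndarray, lambda_j: float, lambda_h: float,
                gtol: float, maxiter: int) -> tuple[np.ndarray, np.ndarray]:
    """Joint L-BFGS over all per-site logistic regressions.

    Site r's conditional is P(s_r | rest) = sigmoid(2 s_r (h_r + sum_j
    W_rj s_j)); the objective is the summed mean negative log conditional
    likelihood plus lambda_h h^2 + lambda_J sum_j W_rj^2 per site.
    """
    m, ell = x.shape
    n_w = ell * ell

    def unpack(theta):
        w = theta[:n_w].reshape(ell, ell).copy()
        np.fill_diagonal(w, 0.0)
        return w, theta[n_w:]

    def objective(theta):
        w, h = unpack(theta)
        a = h[None, :] + x @ w.T
        z = 2.0 * x * a
        loss = float(np.sum(np.logaddexp(0.0, -z)) / m)
        loss += lambda_j * float(np.sum(w ** 2)) + lambda_h * float(np.sum(h ** 2))
        q = (-2.0 * x) * expit(-z) / m
        gw = q.T @ x + 2.0 * lambda_j * w
        np.fill_diagonal(gw, 0.0)
        gh = q.sum(axis=0) + 2.0 * lambda_h * h
        return loss, np.concatenate([gw.ravel(), gh])

    theta0 = np.zeros(n_w + ell)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol,
                            "maxfun": 10 * maxiter})
    if res.status == 2:
        raise ConvergenceError(
            f"pseudolikelihood optimizer failed: {res.message} "
            f"(nit={res.nit}, nfev={res.nfev}, |g|_max="
            f"{np.max(np.abs(res.jac)):.3g})")
    w, h = unpack(res.x)
    return w, h


def _plm_qstate(onehot: np.ndarray, x: np.ndarray, q: int, lambda_j: float,
                lambda_h: float, gtol: float,
                maxiter: int) -> tuple[np.ndarray, np.ndarray]:
    """Joint L-BFGS over all per-site multinomial regressions (q states)."""
    m, ell = x.shape
    n_w = ell * ell * q * q
    site_idx = np.arange(ell)
    diag_mask = np.zeros((ell, ell, q, q), dtype=bool)
    diag_mask[site_idx, site_idx] = True

    def unpack(theta):
        w = theta[:n_w].reshape(ell, ell, q, q).copy()
        w[diag_mask] = 0.0
        h = theta[n_w:].reshape(ell, q)
        return w, h

    def objective(theta):
        w, h = unpack(theta)
        # a[m, r, s] = h_r(s) + sum_j W[r, j, s, x_mj]
        a = h[None] + np.einsum("rjst,mjt->mrs", w, onehot, optimize=True)
        lse = logsumexp(a, axis=2)
        picked = np.take_along_axis(a, x[:, :, None], axis=2)[:, :, 0]
        loss = float(np.sum(lse - picked) / m)
        loss += lambda_j * float(np.sum(w ** 2)) + lambda_h * float(np.sum(h ** 2))
        p = np.exp(a - lse[:, :, None])
        g = p.copy()
        np.put_along_axis(g, x[:, :, None], np.take_along_axis(g, x[:, :, None], 2) - 1.0, 2)
        g /= m
        gw = np.einsum("mrs,mjt->rjst", g, onehot, optimize=True)
        gw += 2.0 * lambda_j * w
        gw[diag_mask] = 0.0
        gh = g.sum(axis=0) + 2.0 * lambda_h * h
        return loss, np.concatenate([gw.ravel(), gh.ravel()])

    theta0 = np.zeros(n_w + ell * q)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol,
                            "maxfun": 10 * maxiter})
    if res.status == 2:
        raise ConvergenceError(
            f"pseudolikelihood optimizer failed: {res.message} "
            f"(nit={res.nit}, nfev={res.nfev})")
    return unpack(res.x)


def plmdca_scores(
    msa: SpinMSA,
    lambda_j: float = DEFAULT_LAMBDA_PLM,
    lambda_h: float = DEFAULT_LAMBDA_PLM,
    gtol: float = 1e-5,
    maxiter: int = 500,
) -> tuple[ScoreMatrix, PottsModel]:
    """Pseudolikelihood-maximization DCA.

    Each site's conditional distribution given all others is fit with an
    L2 penalty (strength ``lambda_j`` on couplings, ``lambda_h`` on
    fields); the asymmetric estimates are combined by averaging,
    J_ij = (J_ij^(i) + J_ji^(j)) / 2.  Binary MSAs are scored by |J_ij|;
    q-state MSAs are moved to the zero-sum gauge and scored by the
    Frobenius norm of each q x q block.
    """
    if msa.is_binary:
        x = msa.matrix.astype(np.float64)
        w, h = _plm_binary(x, lambda_j, lambda_h, gtol, maxiter)
        j = 0.5 * (w + w.T)
        np.fill_diagonal(j, 0.0)
        model = PottsModel(fields=h, couplings=j, n_states=2, gauge="zero_sum")
        return ScoreMatrix(scores=np.abs(j), method="plmdca"), model
    x = msa.matrix.astype(np.int64)
    q = msa.n_states
    onehot = _one_hot(msa)
    w, h = _plm_qstate(onehot, x, q, lambda_j, lambda_h, gtol, maxiter)
    # Average the two asymmetric estimates of each block.
    j = 0.5 * (w + np.transpose(w, (1, 0, 3, 2)))
    model = PottsModel(fields=h, couplings=j, n_states=q).to_zero_sum_gauge()
    return frobenius_scores(model, method="plmdca"), model


def frobenius_scores(model: PottsModel, method: str = "frobenius") -> ScoreMatrix:
    """Frobenius norm of each q x q coupling block (q-state models).

    Requires the zero-sum gauge, in which the norm is gauge-independent
    and comparable across pairs.
    """
    if model.is_binary:
        raise ValueError("Frobenius scoring applies to q-state models; "
                         "binary couplings are scored by |J_ij| directly")
    if model.gauge != "zero_sum":
        raise ValueError("apply the zero-sum gauge before Frobenius scoring")
    s = np.sqrt(np.sum(model.couplings ** 2, axis=(2, 3)))
    np.fill_diagonal(s, 0.0)
    return ScoreMatrix(scores=0.5 * (s + s.T), method=method)


# ---------------------------------------------------------------------------
# APC
# ---------------------------------------------------------------------------

def apply_apc(score: ScoreMatrix) -> ScoreMatrix:
    """Average product correction: S_ij - S_i. * S_.j / S_bar.

    Row means S_i. run over j != i and S_bar is the overall off-diagonal
    mean.  Returns the input unchanged (with a warning) if S_bar == 0.
    """
    s = score.scores.copy()
    ell = s.shape[0]
    off = ~np.eye(ell, dtype=bool)
    np.fill_diagonal(s, 0.0)
    row_mean = s.sum(axis=1) / (ell - 1)          # row mean over j != i
    total_mean = s[off].mean()
    if total_mean == 0:
        warnings.warn("APC skipped: mean score is zero", stacklevel=2)
        return ScoreMatrix(scores=score.scores.copy(), method=score.method,
                           apc_applied=False)
    corrected = s - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corrected, 0.0)
    return ScoreMatrix(scores=corrected, method=score.method, apc_applied=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_scores(score: ScoreMatrix, path: str | Path,
                 apc: ScoreMatrix | None = None,
                 reg: float | None = None) -> None:
    """TSV of per-pair scores sorted by raw score descending (ties broken
    by ascending (i, j)); columns i, j, raw_score, apc_score, method, lambda."""
    ell = score.n_sites
    iu = np.triu_indices(ell, k=1)
    df = pd.DataFrame({
        "i": iu[0], "j": iu[1],
        "raw_score": score.scores[iu],
        "apc_score": apc.scores[iu] if apc is not None else np.nan,
        "method": score.method,
        "lambda": reg if reg is not None else np.nan,
    })
    order = np.lexsort((df["j"], df["i"], -df["raw_score"]))
    df.iloc[order].to_csv(path, sep="\t", index=False)
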