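"""Config-driven sweeps over phylogeny strength and temperature.

A sweep holds the contact graph fixed and, for every (temperature, mu,
replicate) cell, regenerates the data from scratch — a fresh equilibrium
ancestor evolved along a fresh tree (or a fresh independent equilibrium
MSA for the reference cells, size-matched at 2**n_generations rows) —
then scores it with every requested method, with and without APC.
Per-cell seeds are derived deterministically from the master seed, so
any single cell can be recomputed in isolation, bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference
from .evaluation import auc as eval_auc, tp_fraction
from .graph import ContactGraph, benchmark_graph, read_edge_list, sample_er_graph
from .hamiltonian import HamiltonianSpec
from .msa import SpinMSA
from .phylogeny import evolve_on_binary_tree
from .sampling import SamplerParams, sample_equilibrium

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "run_sweep",
    "regularization_sweep",
    "summarize",
    "load_config",
    "save_config",
    "score_msa",
    "generate_dataset",
    "EQUILIBRIUM",
]

SUPPORTED_METHODS = ("covariance", "mi", "mfdca", "plmdca")

#: Sentinel mu value marking the independent-equilibrium reference cells.
EQUILIBRIUM = None


@dataclass
class ExperimentConfig:
    """Declarative description of one sweep.

    ``mus`` may contain ``None`` (or ``inf``), denoting the equilibrium
    reference regime; the equilibrium MSA is size-matched with
    ``2**n_generations`` sequences.
    """

    graph: str | ContactGraph = "benchmark"
    temperatures: tuple = (5.0,)
    mus: tuple = (EQUILIBRIUM, 15, 5)
    n_generations: int = 11
    n_replicates: int = 10
    methods: tuple = SUPPORTED_METHODS
    apc: tuple = (False, True)
    lambda_mi: float = inference.DEFAULT_LAMBDA_MI
    lambda_mfdca: float = inference.DEFAULT_LAMBDA_MFDCA
    lambda_plm_j: float = inference.DEFAULT_LAMBDA_PLM
    lambda_plm_h: float = inference.DEFAULT_LAMBDA_PLM
    equilibrium_proposal: str = "single_flip"
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.temperatures or not self.mus:
            raise ValueError("temperature and mu grids must be non-empty")
        for m in self.methods:
            if m not in SUPPORTED_METHODS:
                raise ValueError(f"unknown method {m!r}")
        mus = tuple(None if (m is None or (isinstance(m, float) and np.isinf(m)))
                    else int(m) for m in self.mus)
        self.mus = mus

    def resolve_graph(self) -> ContactGraph:
        if isinstance(self.graph, ContactGraph):
            return self.graph
        if self.graph == "benchmark":
            return benchmark_graph()
        return read_edge_list(self.graph)

    def config_hash(self) -> str:
        d = asdict(self)
        if isinstance(self.graph, ContactGraph):
            d["graph"] = sorted(self.graph.edges)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    d = asdict(config)
    if isinstance(config.graph, ContactGraph):
        raise ValueError("save_config requires a graph path or 'benchmark'")
    Path(path).write_text(yaml.safe_dump(d))


def load_config(path: str | Path) -> ExperimentConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("temperatures", "mus", "methods", "apc"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return ExperimentConfig(**d)


def generate_dataset(
    spec: HamiltonianSpec,
    temperature: float,
    mu: int | None,
    n_generations: int,
    seed_seq: np.random.SeedSequence,
    equilibrium_proposal: str = "single_flip",
):
    """One replicate's data: (msa, record-or-None).

    ``mu is None`` produces the equilibrium reference (independent rows);
    otherwise an equilibrium ancestor is evolved along the binary tree.
    ``equilibrium_proposal`` selects the move kind for the independent
    equilibrium rows ("single_flip" or "wolff_cluster"); branch dynamics
    on the tree are always single-flip, as mutations are single changes.
    """
    ss_anc, ss_tree = seed_seq.spawn(2)
    n_rows = 2 ** n_generations
    if mu is None:
        params = SamplerParams(temperature=temperature,
                               proposal_kind=equilibrium_proposal,
                               rng_seed=int(ss_anc.generate_state(1)[0] >> 1))
        return sample_equilibrium(spec, params, n_rows), None
    params = SamplerParams(temperature=temperature,
                           rng_seed=int(ss_anc.generate_state(1)[0] >> 1))
    ancestor = sample_equilibrium(spec, params, 1).matrix[0]
    record, msa = evolve_on_binary_tree(
        spec, params, ancestor, mu, n_generations,
        rng_seed=int(ss_tree.generate_state(1)[0] >> 1))
    return msa, record


def score_msa(msa: SpinMSA, methods=SUPPORTED_METHODS,
              lambda_mi: float = inference.DEFAULT_LAMBDA_MI,
              lambda_mfdca: float = inference.DEFAULT_LAMBDA_MFDCA,
              lambda_plm_j: float = inference.DEFAULT_LAMBDA_PLM,
              lambda_plm_h: float = inference.DEFAULT_LAMBDA_PLM,
              apc: tuple = (False, True)) -> dict:
    """Score one MSA with every requested method; returns a dict keyed by
    (method, apc_flag) -> ScoreMatrix."""
    out = {}
    for method in methods:
        if method == "covariance":
            raw = inference.covariance_scores(msa)
        elif method == "mi":
            raw = inference.mi_scores(msa, lam=lambda_mi)
        elif method == "mfdca":
            raw, _ = inference.mfdca_scores(msa, lam=lambda_mfdca)
        elif method == "plmdca":
            raw, _ = inference.plmdca_scores(msa, lambda_j=lambda_plm_j,
                                             lambda_h=lambda_plm_h)
        else:  # pragma: no cover - guarded by config validation
            raise ValueError(method)
        if False in apc:
            out[(method, False)] = raw
        if True in apc:
            out[(method, True)] = inference.apply_apc(raw)
    return out


def _cell_seed_seq(master_seed: int, ti: int, mi: int, rep: int
                   ) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(ti, mi, rep))


def run_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full (T, mu, replicate) x method x APC sweep.

    Returns one row per (cell, method, APC flag) with TP fraction and
    AUC; failed cells are logged and marked with NaN results.  The table
    carries the config hash in ``df.attrs``.
    """
    graph = config.resolve_graph()
    spec = HamiltonianSpec(graph=graph)
    rows = []
    for ti, temperature in enumerate(config.temperatures):
        for mi_idx, mu in enumerate(config.mus):
            for rep in range(config.n_replicates):
                ss = _cell_seed_seq(config.master_seed, ti, mi_idx, rep)
                cell_seed = int(ss.generate_state(1)[0])
                try:
                    msa, _ = generate_dataset(spec, temperature, mu,
                                              config.n_generations, ss,
                                              config.equilibrium_proposal)
                    scored = score_msa(
                        msa, config.methods, config.lambda_mi,
                        config.lambda_mfdca, config.lambda_plm_j,
                        config.lambda_plm_h, config.apc)
                    for (method, apc_flag), sm in scored.items():
                        rows.append({
                            "T": temperature, "mu": mu, "method": method,
                            "apc": apc_flag, "replicate": rep,
                            "tp_fraction": tp_fraction(sm, graph),
                            "auc": eval_auc(sm, graph),
                            "seed": cell_seed, "failed": False,
                        })
                except Exception:
                    logger.exception("cell (T=%s, mu=%s, rep=%d) failed",
                                     temperature, mu, rep)
                    for method in config.methods:
                        for apc_flag in config.apc:
                            rows.append({
                                "T": temperature, "mu": mu, "method": method,
                                "apc": apc_flag, "replicate": rep,
                                "tp_fraction": np.nan, "auc": np.nan,
                                "seed": cell_seed, "failed": True,
                            })
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = config.config_hash()
    df.attrs["master_seed"] = config.master_seed
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sweep_results.tsv", sep="\t", index=False)
        summarize(df).to_csv(out / "sweep_summary.tsv", sep="\t", index=False)
    return df


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of TP fraction and AUC per (T, mu, method, APC) cell."""
    grouped = (df[~df["failed"]]
               .groupby(["T", "mu", "method", "apc"], dropna=False)
               .agg(tp_mean=("tp_fraction", "mean"),
                    tp_sd=("tp_fraction", "std"),
                    auc_mean=("auc", "mean"),
                    auc_sd=("auc", "std"),
                    n=("tp_fraction", "size"))
               .reset_index())
    grouped.attrs = dict(df.attrs)
    return grouped


def regularization_sweep(config: ExperimentConfig, grids: dict) -> pd.DataFrame:
    """TP fraction per regularization setting on fixed datasets.

    ``grids`` maps method name to a list of settings: a pseudocount for
    "mi"/"mfdca", or a (lambda_j, lambda_h) pair for "plmdca".  The same
    datasets (identical seeds) are reused across all settings, so
    differences are attributable to regularization alone.
    """
    graph = config.resolve_graph()
    spec = HamiltonianSpec(graph=graph)
    rows = []
    for ti, temperature in enumerate(config.temperatures):
        for mi_idx, mu in enumerate(config.mus):
            for rep in range(config.n_replicates):
                ss = _cell_seed_seq(config.master_seed, ti, mi_idx, rep)
                cell_seed = int(ss.generate_state(1)[0])
                msa, _ = generate_dataset(spec, temperature, mu,
                                          config.n_generations, ss,
                                          config.equilibrium_proposal)
                for method, settings in grids.items():
                    for setting in settings:
                        if method == "mi":
                            raw = inference.mi_scores(msa, lam=setting)
                            reg = {"lambda": setting}
                        elif method == "mfdca":
                            raw, _ = inference.mfdca_scores(msa, lam=setting)
                            reg = {"lambda": setting}
                        elif method == "plmdca":
                            lj, lh = setting
                            raw, _ = inference.plmdca_scores(
                                msa, lambda_j=lj, lambda_h=lh)
                            reg = {"lambda": lj, "lambda_h": lh}
                        else:
                            raise ValueError(f"unsupported method {method!r}")
                        for apc_flag in config.apc:
                            sm = (inference.apply_apc(raw) if apc_flag else raw)
                            rows.append({
                                "T": temperature, "mu": mu, "method": method,
                                "apc": apc_flag, "replicate": rep,
                                **reg,
                                "tp_fraction": tp_fraction(sm, graph),
                                "auc": eval_auc(sm, graph),
                                "seed": cell_seed,
                            })
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = config.config_hash()
    return df
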