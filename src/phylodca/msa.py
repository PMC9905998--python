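"""Spin multiple sequence alignments (MSAs) and their on-disk formats.

A :class:`SpinMSA` is an M x L matrix: one row per sequence, one column
per site.  The minimal model uses Ising spins (+1/-1); the generalized
q-state mode uses integer states 0..q-1 (mapped to amino acid letters on
FASTA export).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["SpinMSA", "write_msa", "read_msa", "write_fasta", "read_fasta"]

#: FASTA alphabet for q-state MSAs: the 20 amino acids plus the gap.
QSTATE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
#: FASTA alphabet for the binary model: +1 -> 'A', -1 -> 'B'.
BINARY_ALPHABET = {1: "A", -1: "B"}


@dataclass
class SpinMSA:
    """M x L alignment of spin (or Potts-state) sequences.

    Parameters
    ----------
    matrix:
        Integer matrix, one sequence per row.  Binary mode: values in
        {-1, +1}.  q-state mode: values in [0, n_states).
    n_states:
        Alphabet size; 2 denotes the binary +-1 model.
    provenance:
        Free-form generation metadata (regime, temperature, seeds, ...).
    names:
        Optional per-row sequence names (e.g. tree tip labels).
    """

    matrix: np.ndarray
    n_states: int = 2
    provenance: dict = field(default_factory=dict)
    names: list[str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] < 1:
            raise ValueError("MSA matrix must be 2-D with at least one row")
        if self.n_states == 2:
            if not np.all(np.isin(m, (-1, 1))):
                raise ValueError("binary MSA values must be +1 or -1")
            m = m.astype(np.int8)
        else:
            if m.min() < 0 or m.max() >= self.n_states:
                raise ValueError(f"states must lie in [0, {self.n_states})")
            m = m.astype(np.int16)
        self.matrix = m
        if self.names is not None and len(self.names) != m.shape[0]:
            raise ValueError("names length must match number of rows")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def is_binary(self) -> bool:
        return self.n_states == 2


def write_msa(msa: SpinMSA, path: str | Path) -> None:
    """Plain-text matrix, one row per sequence, '#'-prefixed header."""
    path = Path(path)
    header = {"n_states": msa.n_states, **msa.provenance}
    lines = ["# " + json.dumps(header, default=str)]
    if msa.names is not None:
        lines.append("# names=" + json.dumps(msa.names))
    for row in msa.matrix:
        lines.append(" ".join(format(int(v), "+d" if msa.is_binary else "d")
                              for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_msa(path: str | Path) -> SpinMSA:
    header: dict = {}
    names = None
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if body.startswith("names="):
                names = json.loads(body[len("names="):])
            elif body.startswith("{"):
                header = json.loads(body)
            continue
        rows.append([int(tok) for tok in line.split()])
    n_states = int(header.pop("n_states", 2))
    return SpinMSA(matrix=np.array(rows), n_states=n_states,
                   provenance=header, names=names)


def write_fasta(msa: SpinMSA, path: str | Path) -> None:
    """FASTA export: binary spins map +1->'A', -1->'B'; q-state maps
    state k to the k-th letter of the 21-symbol amino acid alphabet."""
    if not msa.is_binary and msa.n_states > len(QSTATE_ALPHABET):
        raise ValueError("alphabet too large for FASTA export")
    records = []
    for r, row in enumerate(msa.matrix):
        if msa.is_binary:
            s = "".join(BINARY_ALPHABET[int(v)] for v in row)
        else:
            s = "".join(QSTATE_ALPHABET[int(v)] for v in row)
        name = msa.names[r] if msa.names is not None else f"seq{r}"
        records.append(SeqRecord(Seq(s), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, n_states: int = 2) -> SpinMSA:
    records = list(SeqIO.parse(str(path), "fasta"))
    names = [rec.id for rec in records]
    if n_states == 2:
        rev = {"A": 1, "B": -1}
        matrix = np.array([[rev[c] for c in str(rec.seq)] for rec in records])
    else:
        rev_q = {c: k for k, c in enumerate(QSTATE_ALPHABET)}
        matrix = np.array([[rev_q[c] for c in str(rec.seq)] for rec in records])
    return SpinMSA(matrix=matrix, n_states=n_states, names=names)
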