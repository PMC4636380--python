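"""File formats: energy matrices (TSV/JSON), sequences (FASTA), kernels and
result tables (TSV/CSV), run manifests (JSON).

Conventions: energies in k_B T, rates in units of u, times in 1/u; window
coordinates in exported tables are 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import ALPHABET

__all__ = [
    "read_energy_matrix",
    "write_energy_matrix",
    "read_fasta",
    "write_fasta",
    "write_manifest",
]

_ROWS = list(ALPHABET)


def write_energy_matrix(xi: np.ndarray, path) -> None:
    """Write a 4 x n energy matrix; ``.json`` suffix selects JSON, anything
    else TSV with A/C/G/T row labels."""
    xi = np.asarray(xi, dtype=float)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps({"alphabet": ALPHABET, "matrix": xi.tolist()}, indent=1))
    else:
        pd.DataFrame(xi, index=_ROWS).to_csv(path, sep="\t", header=False)


def read_energy_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        if data.get("alphabet", ALPHABET) != ALPHABET:
            raise ValueError(f"unsupported alphabet {data.get('alphabet')!r}")
        xi = np.asarray(data["matrix"], dtype=float)
    else:
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        if list(df.index) != _ROWS:
            raise ValueError(f"energy matrix rows must be labeled {_ROWS}, got {list(df.index)}")
        xi = df.to_numpy(dtype=float)
    if xi.shape[0] != 4:
        raise ValueError("energy matrix must have 4 rows")
    return xi


def read_fasta(path) -> dict:
    """Read sequences as a name -> uppercase-ACGT-string mapping."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) - set(ALPHABET):
            raise ValueError(f"record {rec.id!r} contains non-ACGT characters")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_manifest(path, **params) -> None:
    """JSON manifest of run parameters (seeds included by the caller)."""

    def _clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        return v

    Path(path).write_text(json.dumps({k: _clean(v) for k, v in params.items()}, indent=1, sort_keys=True))
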