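"""File I/O: tabular data, FASTA sequences, parameter files, result records.

All tabular formats are TSV with a header row; every artifact written by the
package starts with comment lines recording the package version, a hash of
the generating configuration and the RNG seed, so each output is reproducible
from its own header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .fits import DepolymerisationCurve, ITCCurve
from .hamiltonian import load_model_params
from .lattice import Sequence

__all__ = [
    "config_hash",
    "artifact_header",
    "write_table",
    "read_table",
    "read_itc_curve",
    "write_itc_curve",
    "read_depoly_curve",
    "write_depoly_curve",
    "read_fasta",
    "read_params",
    "write_json_record",
]


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping/dataclass."""
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def artifact_header(config=None, seed: Optional[int] = None) -> str:
    from . import __version__

    lines = [f"# amylattice {__version__}"]
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    if seed is not None:
        lines.append(f"# rng_seed: {seed}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path, config=None, seed=None) -> None:
    """TSV with header row, prefixed by provenance comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(artifact_header(config, seed))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, required=None) -> pd.DataFrame:
    """Read a TSV table (``#`` comment lines ignored), checking that the
    required columns are present."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_itc_curve(path: str | Path) -> ITCCurve:
    """TSV with columns temperature_K, delta_H_kJ_per_mol and optional sigma."""
    df = read_table(path, required=["temperature_K", "delta_H_kJ_per_mol"])
    return ITCCurve(
        temperatures=df["temperature_K"].to_numpy(float),
        delta_h=df["delta_H_kJ_per_mol"].to_numpy(float),
        sigma=df["sigma"].to_numpy(float) if "sigma" in df.columns else None,
    )


def write_itc_curve(curve: ITCCurve, path: str | Path, config=None, seed=None) -> None:
    df = pd.DataFrame(
        {"temperature_K": curve.temperatures, "delta_H_kJ_per_mol": curve.delta_h}
    )
    if curve.sigma is not None:
        df["sigma"] = curve.sigma
    write_table(df, path, config=config, seed=seed)


def read_depoly_curve(
    path: str | Path, total_conc: float, temperature: float = 298.15
) -> DepolymerisationCurve:
    """TSV with columns denaturant_M, fraction_monomer."""
    df = read_table(path, required=["denaturant_M", "fraction_monomer"])
    return DepolymerisationCurve(
        denaturant=df["denaturant_M"].to_numpy(float),
        fraction_monomer=df["fraction_monomer"].to_numpy(float),
        total_conc=total_conc,
        temperature=temperature,
    )


def write_depoly_curve(
    curve: DepolymerisationCurve, path: str | Path, config=None, seed=None
) -> None:
    df = pd.DataFrame(
        {
            "denaturant_M": curve.denaturant,
            "fraction_monomer": curve.fraction_monomer,
        }
    )
    write_table(df, path, config=config, seed=seed)


def read_fasta(path: str | Path) -> dict:
    """Sequences from a FASTA file as {record id: Sequence}; lowercase
    residues are normalised to uppercase."""
    out = {}
    for record in SeqIO.parse(str(path), "fasta"):
        out[record.id] = Sequence(str(record.seq).upper())
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


#: Flat key = value parameter files (shared dialect with the model files).
read_params = load_model_params


def write_json_record(record, path: str | Path, config=None, seed=None) -> None:
    """Fit results and similar records as JSON with provenance fields."""
    if is_dataclass(record) and not isinstance(record, type):
        record = asdict(record)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    payload = {"record": record}
    if config is not None:
        payload["config_hash"] = config_hash(config)
    if seed is not None:
        payload["rng_seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
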