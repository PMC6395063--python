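"""Tab-separated table round-tripping, manifests and config files."""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_table",
    "read_table",
    "write_manifest",
    "read_manifest",
    "load_config",
    "file_sha256",
]

#: Required columns (and dtypes on read) for the table kinds the pipeline passes around.
SCHEMAS = {
    "trials": {"run": int, "t": int, "chosen": int, "outcome": int,
               "true_high": int, "payout_high": float},
    "beliefs": {"run": int, "t": int, "chosen": int, "chosen_h": int, "outcome": int,
                "entropy": float, "relative_uncertainty": float, "ev_chosen": float,
                "pH1": float, "pH2": float, "pH3": float, "pH4": float},
    "pupil_trace": {"time_ms": float, "value": float, "is_missing": bool, "run": int},
    "baselines": {"trial": int, "baseline": float, "lost": bool, "run": int, "t": int},
}

FLOAT_FORMAT = "%.12g"  # floats round-trip at 12 significant digits


def _check_schema(table: pd.DataFrame, kind: str | None) -> None:
    if kind is None:
        return
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    missing = [c for c in SCHEMAS[kind] if c not in table.columns]
    if missing:
        raise ValueError(f"{kind} table missing required columns: {missing}")


def write_table(table: pd.DataFrame, path: str, kind: str | None = None) -> str:
    _check_schema(table, kind)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path: str, kind: str | None = None) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    _check_schema(table, kind)
    if kind is not None:
        for col, dtype in SCHEMAS[kind].items():
            table[col] = table[col].astype(dtype)
    return table


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str, hash_files: bool = True) -> str:
    """Write a run manifest; file hashes are computed relative to the
    manifest's directory for the entries under ``files``."""
    base = os.path.dirname(os.path.abspath(path))
    out = dict(manifest)
    if hash_files and "files" in out:
        files = {}
        for name, rel in out["files"].items():
            full = os.path.join(base, rel)
            if not os.path.exists(full):
                raise FileNotFoundError(f"manifest references missing file {rel}")
            files[name] = {"path": rel, "sha256": file_sha256(full)}
        out["files"] = files
    with open(path, "w") as f:
        json.dump(out, f, indent=1, sort_keys=True)
    return path


def read_manifest(path: str, verify: bool = True) -> dict:
    with open(path) as f:
        manifest = json.load(f)
    if verify and "files" in manifest:
        base = os.path.dirname(os.path.abspath(path))
        for name, entry in manifest["files"].items():
            full = os.path.join(base, entry["path"])
            if not os.path.exists(full):
                raise FileNotFoundError(f"manifest references missing file {entry['path']}")
            if "sha256" in entry and file_sha256(full) != entry["sha256"]:
                raise ValueError(f"hash mismatch for {name} ({entry['path']})")
    return manifest


def load_config(path: str) -> dict:
    with open(path) as f:
        if path.endswith((".yaml", ".yml")):
            return yaml.safe_load(f) or {}
        return json.load(f)


def save_array_store(path: str, arrays: dict[str, np.ndarray]) -> str:
    """HDF5 array store (one dataset per key)."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=arr)
    return path


def load_array_store(path: str) -> dict[str, np.ndarray]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            out[name] = f[name][...]
    return out
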