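"""Tabular I/O: TSV with a '#'-prefixed metadata block.

Every pipeline table is plain TSV with a one-line header, optionally
preceded by '# key: value' metadata lines (tool version, seed, config
hash) so runs are diff-able and spreadsheet-safe.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping/dataclass."""
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict

        obj = asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_metadata(path: str | Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta
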