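"""TSV matrix and configuration I/O plus run provenance records.

Expression matrices follow the omics convention: tab-separated, first column
gene identifiers, header row of measurement times in hours, empty cells for
missing values.
"""

from __future__ import annotations

import json
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "load_run_config",
    "write_provenance",
]


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a gene x time TSV matrix; empty cells become NaN (missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id(s) in {path}: {', '.join(map(str, set(dup)))}")
    try:
        times = np.asarray([float(c) for c in df.columns])
    except ValueError as e:
        raise ValueError(f"non-numeric time header in {path}: {e}") from None
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"header times must be strictly increasing in {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            raise ValueError(
                f"unparseable value(s) in {path} column {col}: {bad.iloc[0]!r}")
    df.columns = times
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df.astype(float)


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    """Write a gene x time matrix as TSV; NaN becomes an empty cell."""
    out = df.copy()
    out.columns = [format(float(c), "g") for c in out.columns]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="")


def load_run_config(path) -> dict:
    """Load a YAML or JSON run configuration file into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_provenance(path, config, seed) -> None:
    """Record the exact configuration and library versions of a run.

    Deliberately excludes timestamps so that identical runs produce
    byte-identical artifacts.
    """
    import scipy

    from . import __version__

    record = {
        "config": _jsonable(config),
        "seed": seed,
        "versions": {
            "protdyn": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
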