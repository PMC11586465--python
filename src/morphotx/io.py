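"""Plain-text serialization: TSV tables, GMT gene sets, JSON summaries.

All tabular output uses a fixed column order and 6-significant-digit
floating formatting so that repeated runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_tsv", "read_tsv", "write_gmt", "read_gmt", "write_json"]

FLOAT_FMT = "%.6g"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_gmt(gene_sets, path: str | Path) -> None:
    """Write gene sets as GMT: one line per set — name, description, members."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in gene_sets:
            desc = getattr(gs, "description", "") or getattr(gs, "direction", "none")
            fh.write("\t".join([gs.name, str(desc), *gs.genes]) + "\n")


def read_gmt(path: str | Path):
    """Read a GMT file into (name, description, genes) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (needs name, description, >=1 gene): {line[:80]}")
            out.append((parts[0], parts[1], parts[2:]))
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_coerce)
        fh.write("\n")


def _coerce(x):
    try:
        import numpy as np

        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(x)}")
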