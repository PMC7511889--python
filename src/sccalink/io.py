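"""Shared tabular I/O helpers.

All pipeline tables are CSV or TSV with a header row, UTF-8, '.' decimal.
Floats are written with 12 significant digits, which round-trips the
pipeline's quantities bit-exactly for practical purposes.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.12g"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV table, sniffing the delimiter from the header line."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:  # pragma: no cover - message plumbing
        raise ValueError(f"unparseable table {path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)
    return path


def dkt_region_names() -> list[str]:
    """The 62 cortical region labels of the Desikan-Killiany-Tourville atlas
    (31 per hemisphere, ``lh_``/``rh_`` prefixed)."""
    text = resources.files("sccalink.data").joinpath("dkt62.txt").read_text()
    names = [line.strip() for line in text.splitlines() if line.strip()]
    assert len(names) == 62
    return names


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
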