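"""CSV/JSON output with provenance headers.

CSV dialect: UTF-8, period decimal separator, units embedded in column
names, and '#'-prefixed header comment lines carrying run metadata
(config hash, tool version, strategy, seed). No timestamps are written,
so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__

__all__ = ["write_csv", "read_csv", "write_json"]


def _header_lines(metadata: Mapping[str, object]) -> str:
    lines = [f"# cyclopk {__version__}"]
    for key, value in metadata.items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_csv(path: str | Path, frame: pd.DataFrame, metadata: Mapping[str, object]) -> Path:
    """Write a DataFrame with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_lines(metadata))
        frame.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")


def write_json(path: str | Path, payload: object) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
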