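"""Dataset and report I/O.

Datasets are delimited text with a header and columns ``a``, ``b``
(factor levels coded C/T, 0/1 or -1/1) and ``y`` (numeric outcome).
Reports are written as TSV (rates rounded to 3 decimals, like the
printed tables) mirrored by JSON at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .anova import _normalize_levels
from .simulate import SampleData

__all__ = ["DatasetFormatError", "read_dataset", "write_dataset", "write_report"]


class DatasetFormatError(ValueError):
    """A dataset file does not conform to the a/b/y contract."""


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
        return "," if dialect == "csv" else "\t"
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_dataset(path: str | Path, dialect: str | None = None) -> SampleData:
    """Read a 2x2 dataset; infers the design from the observed cell counts.

    Every cell must contain at least two rows so that each cell carries
    variance.  Raises :class:`DatasetFormatError` on a missing column,
    a non-numeric outcome, unrecognized level codes or an underfilled
    cell.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, dialect), float_precision="round_trip")
    cols = {c.strip().lower(): c for c in frame.columns}
    for required in ("a", "b", "y"):
        if required not in cols:
            raise DatasetFormatError(f"{path.name}: missing required column {required!r}")
    try:
        a = _normalize_levels(frame[cols["a"]].to_numpy(), "a")
        b = _normalize_levels(frame[cols["b"]].to_numpy(), "b")
    except ValueError as exc:
        raise DatasetFormatError(f"{path.name}: {exc}") from exc
    y = pd.to_numeric(frame[cols["y"]], errors="coerce").to_numpy(float)
    if np.isnan(y).any():
        bad = int(np.isnan(y).sum())
        raise DatasetFormatError(f"{path.name}: {bad} non-numeric value(s) in column 'y'")
    counts = np.bincount(a * 2 + b, minlength=4)
    if (counts < 2).any():
        raise DatasetFormatError(
            f"{path.name}: every cell needs >= 2 rows, observed counts {tuple(counts)}"
        )
    return SampleData.from_arrays(a, b, y)


def write_dataset(sample: SampleData, path: str | Path, dialect: str | None = None) -> Path:
    """Write a sample as delimited text with header a,b,y and C/T levels."""
    path = Path(path)
    sample.to_frame().to_csv(path, sep=_sep_for(path, dialect), index=False)
    return path


def _tsv_formatted(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    return out


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    formats: tuple[str, ...] = ("tsv", "json"),
) -> list[Path]:
    """Write named tables under ``out_dir``; returns the paths written.

    TSV keeps the frame's column order and prints floats with three
    decimals; JSON (records orientation) keeps full precision.  An empty
    table yields a header-only TSV and an empty JSON list.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - {"tsv", "json"}
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    written = []
    for name, table in tables.items():
        if "tsv" in formats:
            path = out_dir / f"{name}.tsv"
            _tsv_formatted(table).to_csv(path, sep="\t", index=False)
            written.append(path)
        if "json" in formats:
            path = out_dir / f"{name}.json"
            records = json.loads(table.to_json(orient="records", double_precision=15))
            path.write_text(json.dumps(records, indent=1, allow_nan=True) + "\n")
            written.append(path)
    return written
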