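"""Readers and writers for the formats the package touches.

Series tables are comma-delimited UTF-8 text with a required header row,
one optional timestamp column and one column per variable (the layout of
typical sensor-logger exports: date-time, temperature, humidity, soil
moisture).  Timestamps are parsed leniently and carried as labels only.
Symbol sequences are read from standard FASTA via Biopython.  Results are
written as JSON (full diagnostics) or TSV (one matched pair per row).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .core import (
    LcssResult,
    MatchTrace,
    MultivariateSeries,
    SwlcssError,
    SymbolSequence,
)

__all__ = [
    "FormatError",
    "read_series_csv",
    "write_series_csv",
    "read_fasta",
    "write_result",
    "read_result_json",
]


class FormatError(SwlcssError, ValueError):
    pass


def read_series_csv(
    path,
    timestamp_column: str | None = None,
    variable_columns: Sequence[str] | None = None,
    identifier: str | None = None,
) -> MultivariateSeries:
    """Read a multivariate series from a delimited text table.

    Columns are matched by name, so file column order does not matter.  With
    ``variable_columns=None`` every column except the timestamp column is
    taken as a variable, in file order.

    Raises
    ------
    FormatError
        If a declared column is missing or a variable cell is not numeric
        (the row and column are named).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    if timestamp_column is not None and timestamp_column not in df.columns:
        raise FormatError(f"declared timestamp column {timestamp_column!r} not in {path}")
    if variable_columns is None:
        variable_columns = [c for c in df.columns if c != timestamp_column]
    missing = [c for c in variable_columns if c not in df.columns]
    if missing:
        raise FormatError(f"declared columns missing from {path}: {missing}")

    columns = []
    for name in variable_columns:
        vals = []
        for row_idx, cell in enumerate(df[name]):
            try:
                f = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell {cell!r} at row {row_idx}, column {name!r} in {path}"
                ) from None
            vals.append(int(f) if f.is_integer() else f)
        columns.append(SymbolSequence(f"{path.stem}:{name}", vals))

    timestamps = None
    if timestamp_column is not None:
        timestamps = tuple(str(v).strip() for v in df[timestamp_column])

    return MultivariateSeries(
        identifier or path.stem,
        tuple(variable_columns),
        tuple(columns),
        timestamps,
    )


def write_series_csv(series: MultivariateSeries, path, timestamp_column: str = "timestamp") -> None:
    data = {}
    if series.timestamps is not None:
        data[timestamp_column] = list(series.timestamps)
    for name in series.variable_names:
        data[name] = list(series.column(name).values)
    pd.DataFrame(data).to_csv(path, index=False)


def read_fasta(path) -> list[SymbolSequence]:
    """Read symbol sequences from a FASTA file.

    Residues are folded to upper case; the identifier is the first
    whitespace-delimited token of the header.  An empty file yields an empty
    list; sequence data before any header is an error.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FormatError(f"sequence data before any FASTA header in {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SymbolSequence(rec.id, str(rec.seq).upper()))
    return records


def _trace_payload(trace: MatchTrace, S=None, T=None) -> list[dict]:
    out = []
    for p in trace:
        entry: dict = {"i": p.i, "j": p.j}
        if S is not None and S.timestamps is not None:
            entry["timestamp_s"] = S.timestamps[p.i]
        if T is not None and T.timestamps is not None:
            entry["timestamp_t"] = T.timestamps[p.j]
        out.append(entry)
    return out


def write_result(
    result: LcssResult,
    path,
    format: str = "json",
    S: MultivariateSeries | None = None,
    T: MultivariateSeries | None = None,
) -> None:
    """Write an LCSS result to *path* as JSON or TSV.

    JSON carries the run parameters, per-pass and per-stage lengths, the
    comparison count and the matched pairs (with timestamps when the series
    are given).  TSV has one matched pair per row with the matched values per
    variable when the series are given.
    """
    path = Path(path)
    if format == "json":
        payload = {
            "length": result.length,
            "best_start": result.best_start,
            "pass_lengths": list(result.pass_lengths),
            "stage_lengths": list(result.stage_lengths),
            "comparisons": result.comparisons,
            "parameters": {
                k: (list(v) if isinstance(v, (tuple, list)) else v)
                for k, v in result.parameters.items()
            },
            "pairs": _trace_payload(result.best_trace, S, T),
        }
        try:
            path.write_text(json.dumps(payload, indent=2) + "\n")
        except OSError as exc:
            raise FormatError(f"cannot write result to {path}: {exc}") from exc
        return
    if format == "tsv":
        rows = []
        for p in result.best_trace:
            row: dict = {"i": p.i, "j": p.j}
            if S is not None and T is not None:
                for name in S.variable_names:
                    row[f"S.{name}"] = S.column(name)[p.i]
                    row[f"T.{name}"] = T.column(name)[p.j]
            rows.append(row)
        cols = ["i", "j"] if not rows else list(rows[0].keys())
        try:
            pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        except OSError as exc:
            raise FormatError(f"cannot write result to {path}: {exc}") from exc
        return
    raise FormatError(f"unknown result format {format!r} (use 'json' or 'tsv')")


def read_result_json(path) -> LcssResult:
    """Read back a JSON result written by :func:`write_result`."""
    payload = json.loads(Path(path).read_text())
    trace = MatchTrace(
        [(e["i"], e["j"]) for e in payload["pairs"]],
        sigma=None,
        start_offset=payload.get("best_start", 0),
    )
    return LcssResult(
        best_trace=trace,
        length=payload["length"],
        best_start=payload["best_start"],
        pass_lengths=list(payload["pass_lengths"]),
        stage_lengths=list(payload["stage_lengths"]),
        comparisons=payload["comparisons"],
        parameters=dict(payload["parameters"]),
    )
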