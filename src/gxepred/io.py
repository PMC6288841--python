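"""Readers and writers for the pipeline's plain-CSV file formats.

All tabular I/O is RFC-4180 CSV with a header row, UTF-8.  Readers validate
strictly and reject malformed input with the offending row in the message;
nothing is silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: one (line, environment, value) per cell.

    ``lines`` and ``envs`` preserve order of first appearance, which fixes
    the column layout of every design matrix downstream.
    """

    lines: list[str]
    envs: list[str]
    records: pd.DataFrame  # columns: line, env, value

    def __post_init__(self) -> None:
        dup = self.records.duplicated(subset=["line", "env"])
        if dup.any():
            row = self.records[dup].iloc[0]
            raise ValueError(f"duplicate (line, env) pair: ({row['line']}, {row['env']})")
        vals = self.records["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite phenotype values present")

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "PhenotypeTable":
        lines = list(dict.fromkeys(records["line"]))
        envs = list(dict.fromkeys(records["env"]))
        return cls(lines=lines, envs=envs, records=records.reset_index(drop=True))

    @property
    def n_records(self) -> int:
        return len(self.records)

    def cells(self) -> list[tuple[str, str]]:
        return list(zip(self.records["line"], self.records["env"]))

    def values(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)

    def subset(self, cells: list[tuple[str, str]]) -> "PhenotypeTable":
        """Rows for the given cells, in the given order."""
        idx = {(l, e): i for i, (l, e) in enumerate(self.cells())}
        rows = [idx[c] for c in cells]
        sub = self.records.iloc[rows].reset_index(drop=True)
        return PhenotypeTable(lines=self.lines, envs=self.envs, records=sub)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a long-format phenotype CSV with header ``line,env,value``."""
    df = pd.read_csv(path, dtype={0: str, 1: str})
    required = ["line", "env", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must contain line,env,value")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: non-numeric value {df['value'].iloc[row]!r} at data row {row + 1}")
    df = df[required].copy()
    df["value"] = vals
    dup = df.duplicated(subset=["line", "env"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"{path}: duplicate (line, env) pair ({df['line'].iloc[row]}, {df['env'].iloc[row]}) at data row {row + 1}"
        )
    return PhenotypeTable.from_records(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)


def read_markers(path: str | Path):
    """Read a marker CSV: first column line IDs, remaining columns numeric codes."""
    from gxepred.kinship import MarkerMatrix

    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a line-ID column plus at least one marker column")
    line_col = df.columns[0]
    line_ids = df[line_col].tolist()
    if len(set(line_ids)) != len(line_ids):
        seen: set[str] = set()
        for lid in line_ids:
            if lid in seen:
                raise ValueError(f"{path}: duplicate line ID {lid!r}")
            seen.add(lid)
    marker_ids = list(df.columns[1:])
    vals = df[marker_ids].apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        rows, cols = np.nonzero(vals.isna().to_numpy())
        r, c = int(rows[0]), int(cols[0])
        raise ValueError(
            f"{path}: non-numeric marker value {df[marker_ids[c]].iloc[r]!r} at data row {r + 1}, column {marker_ids[c]!r}"
        )
    return MarkerMatrix(values=vals.to_numpy(dtype=float), line_ids=line_ids, marker_ids=marker_ids)


def write_markers(markers, path: str | Path) -> None:
    df = pd.DataFrame(markers.values, columns=markers.marker_ids)
    df.insert(0, "line", markers.line_ids)
    df.to_csv(path, index=False)


def read_grm(path: str | Path):
    """Read a square labelled GRM CSV (first column and header are line IDs)."""
    from gxepred.kinship import GenomicRelationship

    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: GRM must be square, got {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: GRM row and column labels disagree")
    return GenomicRelationship(values=df.to_numpy(dtype=float), line_ids=list(df.index.astype(str)))


def write_grm(grm, path: str | Path) -> None:
    df = pd.DataFrame(grm.values, index=grm.line_ids, columns=grm.line_ids)
    df.to_csv(path)


def read_h2(path: str | Path) -> dict[str, float]:
    """Per-environment heritabilities: CSV with header ``env,h2``."""
    df = pd.read_csv(path, dtype={0: str})
    if "env" not in df.columns or "h2" not in df.columns:
        raise ValueError(f"{path}: header must contain env,h2")
    h2 = {}
    for i, row in df.iterrows():
        val = float(row["h2"])
        if not (0 < val <= 1):
            raise ValueError(f"{path}: h2={val} for env {row['env']!r} outside (0, 1]")
        h2[str(row["env"])] = val
    return h2


def write_results(table, path: str | Path) -> None:
    """Write an accuracy table, sorted by (model, env) for stable diffs."""
    df = table.to_frame().sort_values(["model", "env"]).reset_index(drop=True)
    df.to_csv(path, index=False)


def read_results(path: str | Path):
    from gxepred.metrics import AccuracyTable

    df = pd.read_csv(path, dtype={"model": str, "env": str})
    required = ["model", "env", "apc", "se", "n_replicates"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return AccuracyTable(rows=df[df.columns.tolist()])
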