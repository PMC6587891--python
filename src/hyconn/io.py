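"""Readers and writers for the plain-text exchange formats.

Time series and connectivity matrices travel as TSV (regions × time points
and regions × regions respectively); cohort manifests as a three-column TSV
(subject_id, label, path). Connectivity files carry their construction
parameters in a ``# key=value`` header block so a network can be rebuilt
into the same typed object it was written from. All readers reject
non-finite values; all writers use 17 significant digits so round-trips are
exact to 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .networks import ConnectivityMatrix

__all__ = [
    "ROITimeSeriesMatrix",
    "CohortManifest",
    "RegionTable",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "read_network",
    "write_network",
    "read_region_table",
]

VALID_LABELS = ("patient", "control")
_FMT = "%.17g"


@dataclass
class ROITimeSeriesMatrix:
    """One subject's region-by-time signal matrix (n regions × m time points)."""

    values: np.ndarray
    region_labels: list | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time-series matrix must be 2-D (regions × time points)")
        n, m = self.values.shape
        if n < 3:
            raise ValueError(f"need at least 3 regions for triplet analysis, got {n}")
        if m < 2:
            raise ValueError(f"need at least 2 time points, got {m}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-series matrix contains non-finite values")
        if self.region_labels is None:
            self.region_labels = [f"R{i + 1}" for i in range(n)]
        elif len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} region labels for {n} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class CohortManifest:
    """(subject_id, label, path) records; ids unique, labels patient/control."""

    records: list

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s) in manifest: {dup}")
        for sid, label, _ in self.records:
            if label not in VALID_LABELS:
                raise ValueError(
                    f"subject {sid!r}: unknown label {label!r} (expected one of {VALID_LABELS})"
                )

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


@dataclass
class RegionTable:
    """Ordered, unique region names (e.g., the 90 AAL region names)."""

    names: list

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("region names must be unique")

    def __len__(self):
        return len(self.names)


def _sniff_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None  # any whitespace


def read_timeseries(path, region_table: RegionTable | None = None,
                    transpose: bool = False) -> ROITimeSeriesMatrix:
    """Read a rectangular numeric TSV/CSV into a time-series matrix.

    Delimiter is sniffed from the first line. Errors name the offending
    1-based row and column. ``transpose`` accommodates files stored as
    time points × regions.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows = []
    width = None
    for r, line in enumerate(lines, start=1):
        cells = line.split(delim) if delim else line.split()
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged table — row {r} has {len(cells)} cells, expected {width}"
            )
        row = []
        for c, cell in enumerate(cells, start=1):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(f"{path}: non-finite value at row {r}, column {c}")
            row.append(v)
        rows.append(row)
    values = np.array(rows, dtype=float)
    if transpose:
        values = values.T
    labels = list(region_table.names) if region_table is not None else None
    return ROITimeSeriesMatrix(values, region_labels=labels, subject_id=path.stem)


def write_timeseries(ts: ROITimeSeriesMatrix, path) -> None:
    np.savetxt(path, ts.values, delimiter="\t", fmt=_FMT)


def read_manifest(path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["subject_id", "label", "path"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: manifest columns must be {expected}, got {list(df.columns)}")
    return CohortManifest([tuple(r) for r in df.itertuples(index=False)])


def write_manifest(manifest: CohortManifest, path) -> None:
    pd.DataFrame(manifest.records, columns=["subject_id", "label", "path"]).to_csv(
        path, sep="\t", index=False
    )


def write_network(C: ConnectivityMatrix, path) -> None:
    """Write a connectivity matrix with its kind/parameters as '# key=value' headers."""
    with open(path, "w") as fh:
        fh.write(f"# kind={C.kind}\n")
        for key, val in C.params.items():
            fh.write(f"# {key}={val}\n")
        np.savetxt(fh, C.values, delimiter="\t", fmt=_FMT)


def read_network(path) -> ConnectivityMatrix:
    path = Path(path)
    headers = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                headers[key.strip()] = val.strip()
            elif line.strip():
                data_lines.append(line)
    values = np.loadtxt(data_lines, delimiter="\t", ndmin=2)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite values in network matrix")
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T, atol=1e-12):
        raise ValueError(f"{path}: connectivity matrix must be symmetric")
    kind = headers.pop("kind", "first_order")
    params = {}
    for key, val in headers.items():
        if key == "k":
            params[key] = int(val)
        else:
            try:
                params[key] = float(val)
            except ValueError:
                params[key] = val
    return ConnectivityMatrix(values, kind=kind, params=params)


def read_region_table(path) -> RegionTable:
    with open(path) as fh:
        names = [ln.strip() for ln in fh if ln.strip()]
    return RegionTable(names)
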