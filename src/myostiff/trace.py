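"""Force-trace container and its plain-text file format.

Traces are comma-separated text with ``#``-prefixed metadata header lines
and named columns ``time_s, strain, force_rel``.  Columns are matched by
name, so column order in a file is irrelevant.  Strain is stored as a
dimensionless fraction; force in relative units.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ForceTrace", "TraceFormatError", "read_trace", "write_trace"]

COLUMNS = ("time_s", "strain", "force_rel")


class TraceFormatError(ValueError):
    """Raised for malformed trace files or inconsistent trace arrays."""


@dataclass
class ForceTrace:
    """Sampled (time, strain, force) series from one stretch-hold recording."""

    time_s: np.ndarray
    strain: np.ndarray
    force: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time_s.size
        if n < 2 or self.strain.size != n or self.force.size != n:
            raise TraceFormatError("trace arrays must have equal length >= 2")
        dt = np.diff(self.time_s)
        if np.any(dt < 0):
            raise TraceFormatError("time_s must be monotone non-decreasing")
        med = np.median(dt)
        if med > 0 and np.max(np.abs(dt - med)) > 0.1 * med:
            raise TraceFormatError("sampling jitter exceeds 10% of median interval")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def __len__(self):
        return self.time_s.size


def write_trace(trace: ForceTrace, path) -> None:
    """Write a trace as CSV with ``#`` metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# myostiff trace v1\n")
        for key, value in trace.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(",".join(COLUMNS) + "\n")
        data = np.column_stack([trace.time_s, trace.strain, trace.force])
        np.savetxt(fh, data, fmt="%.17g", delimiter=",")  # lossless float round-trip


def read_trace(path) -> ForceTrace:
    """Read a trace file, matching columns by name and parsing metadata.

    Raises ``TraceFormatError`` citing the offending line for ragged rows,
    non-numeric cells, missing columns or non-monotone time.
    """
    path = Path(path)
    meta: dict = {}
    header = None
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                missing = set(COLUMNS) - set(header)
                if missing:
                    raise TraceFormatError(
                        f"{path}:{lineno}: missing column(s) {sorted(missing)}"
                    )
                continue
            cells = line.split(",")
            if len(cells) != len(header):
                raise TraceFormatError(
                    f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise TraceFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if header is None or not rows:
        raise TraceFormatError(f"{path}: no data rows found")
    data = np.asarray(rows, dtype=float)
    cols = {name: data[:, header.index(name)] for name in COLUMNS}
    try:
        return ForceTrace(cols["time_s"], cols["strain"], cols["force_rel"], meta=meta)
    except TraceFormatError as exc:
        raise TraceFormatError(f"{path}: {exc}") from None
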