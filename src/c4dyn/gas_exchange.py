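"""Gas-exchange time-series container and the LI-6800-style CSV dialect.

The on-disk format is plain CSV with a ``#``-prefixed ``key: value``
metadata header block (species, protocol, chamber settings), UTF-8, '.'
decimal separator, and the fixed column names ``time_s, A, gs, Ci, Ca,
PAR, Tleaf, RH``.  Columns are matched by name, so column order is
irrelevant; time must be strictly increasing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("time_s", "A", "gs", "Ci", "Ca", "PAR", "Tleaf", "RH")


@dataclass
class GasExchangeSeries:
    """A logged gas-exchange record with a metadata header."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"gas-exchange series missing column(s): {missing}")
        t = self.data["time_s"].to_numpy(dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(
                f"time_s must be strictly increasing (violated at row {bad})"
            )

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.data[col].to_numpy(dtype=float)

    @property
    def time_s(self) -> np.ndarray:
        return self["time_s"]


def write_gas_exchange(series: GasExchangeSeries, path: str | Path) -> None:
    """Write the series with its '#'-prefixed metadata header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in series.meta.items():
            fh.write(f"# {key}: {val}\n")
        series.data.to_csv(fh, index=False, float_format="%.17g")


def read_gas_exchange(path: str | Path) -> GasExchangeSeries:
    """Read a gas-exchange CSV, validating columns, rows and time ordering.

    Malformed data rows are reported with their 1-based line numbers.
    """
    path = Path(path)
    meta: dict = {}
    body_lines: list[str] = []
    line_numbers: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                entry = stripped.lstrip("#").strip()
                if ":" in entry:
                    key, _, val = entry.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            body_lines.append(line)
            line_numbers.append(lineno)
    if not body_lines:
        raise ValueError(f"{path}: no data rows")

    header = [c.strip() for c in body_lines[0].split(",")]
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {missing}")

    n_cols = len(header)
    bad_rows = []
    for line, lineno in zip(body_lines[1:], line_numbers[1:]):
        fields = line.rstrip("\n").split(",")
        if len(fields) != n_cols:
            bad_rows.append((lineno, "wrong field count"))
            continue
        for f in fields:
            f = f.strip()
            if f:
                try:
                    float(f)
                except ValueError:
                    bad_rows.append((lineno, f"non-numeric field {f!r}"))
                    break
    if bad_rows:
        detail = "; ".join(f"line {n}: {why}" for n, why in bad_rows[:5])
        raise ValueError(f"{path}: {len(bad_rows)} malformed row(s): {detail}")

    frame = pd.read_csv(io.StringIO("".join(body_lines)))
    return GasExchangeSeries(data=frame, meta=meta)


def series_from_simulation(result, meta: dict | None = None,
                           every_s: float | None = None) -> GasExchangeSeries:
    """Build a gas-exchange series from a SimulationResult."""
    t = result.time
    cond = [result.forcing.at(min(ti, t[-1] - 1e-9)) for ti in t]
    frame = pd.DataFrame({
        "time_s": t,
        "A": result.a_net,
        "gs": result.gs,
        "Ci": result.ci,
        "Ca": [c.ca for c in cond],
        "PAR": [c.par for c in cond],
        "Tleaf": result.t_leaf,
        "RH": [c.rh for c in cond],
    })
    if every_s is not None:
        grid = np.arange(t[0], t[-1] + 1e-9, every_s)
        keep = np.searchsorted(t, grid)
        keep = np.unique(np.clip(keep, 0, len(t) - 1))
        frame = frame.iloc[keep].reset_index(drop=True)
    return GasExchangeSeries(data=frame, meta=meta or {})
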