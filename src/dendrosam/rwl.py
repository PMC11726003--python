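"""Reading and writing Tucson (RWL) decadal ring-width files.

The Tucson layout stores one series per sample id as decade rows: an id
field, the calendar year of the first value on the row, then up to ten
width values.  Widths are integers in units of 0.01 mm (stop marker 999)
or 0.001 mm (stop marker -9999); the stop marker terminates the series and
identifies the dialect.  A long-form CSV alternative (tree_id, year,
width_mm) is provided for pipelines that do not start from Tucson files.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bai import RingWidthSeries

__all__ = ["read_rwl", "write_rwl", "read_width_table", "write_width_table", "RwlParseError"]

_STOP_MARKERS = {999: 0.01, -9999: 0.001}


class RwlParseError(ValueError):
    """Malformed Tucson file; message carries the offending line number."""


def read_rwl(path: str | Path) -> list[RingWidthSeries]:
    """Parse a Tucson decadal file into one :class:`RingWidthSeries` per id.

    Both 0.01 mm (999-terminated) and 0.001 mm (-9999-terminated) dialects
    are handled, per series.  Raises :class:`RwlParseError` with a line
    number on malformed decade rows, duplicate ids, or an empty file.
    """
    text = Path(path).read_text()
    raw: dict[str, list[tuple[int, int]]] = {}  # id -> [(year, int value)]
    closed: set[str] = set()
    scale: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        # three optional header lines per series id are tolerated (ITRDB style)
        parts = line.split()
        if len(parts) < 2:
            raise RwlParseError(f"line {lineno}: expected id and decade year")
        sid = parts[0]
        try:
            year = int(parts[1])
        except ValueError:
            # header/comment line (non-numeric second field): skip
            continue
        if sid in closed:
            raise RwlParseError(f"line {lineno}: duplicate series id {sid!r}")
        vals = []
        for tok in parts[2:]:
            try:
                vals.append(int(tok))
            except ValueError as exc:
                raise RwlParseError(f"line {lineno}: bad width field {tok!r}") from exc
        if len(vals) > 10:
            raise RwlParseError(f"line {lineno}: more than 10 width fields")
        store = raw.setdefault(sid, [])
        if store and year != store[-1][0] + 1:
            raise RwlParseError(
                f"line {lineno}: decade row for {sid!r} starts at {year}, "
                f"expected {store[-1][0] + 1}"
            )
        for v in vals:
            if v in _STOP_MARKERS:
                closed.add(sid)
                scale[sid] = _STOP_MARKERS[v]
                break
            store.append((year, v))
            year += 1
    if not raw:
        raise RwlParseError("no series found in file")
    out = []
    for sid, pairs in raw.items():
        unit = scale.get(sid, 0.01)  # unterminated series default to 0.01 mm
        years = np.array([y for y, _ in pairs], dtype=int)
        widths = np.array([v for _, v in pairs], dtype=float) * unit
        out.append(RingWidthSeries(sid, years, widths))
    return out


def write_rwl(series: Iterable[RingWidthSeries], path: str | Path, units: str = "0.01mm") -> None:
    """Write series in Tucson decadal layout.

    ``units`` selects the dialect: ``"0.01mm"`` (999 stop marker) or
    ``"0.001mm"`` (-9999 stop marker).
    """
    if units == "0.01mm":
        factor, stop = 100.0, 999
    elif units == "0.001mm":
        factor, stop = 1000.0, -9999
    else:
        raise ValueError(f"unknown units {units!r}")
    buf = io.StringIO()
    for s in series:
        vals = [int(round(w * factor)) for w in s.widths_mm] + [stop]
        years = list(range(s.first_year, s.first_year + len(vals)))
        i = 0
        while i < len(vals):
            year = years[i]
            row_end = (year // 10 + 1) * 10  # decade rows break at multiples of 10
            chunk = []
            while i < len(vals) and years[i] < row_end:
                chunk.append(vals[i])
                i += 1
            buf.write(f"{s.tree_id:<8}{year:>4}" + "".join(f"{v:>6}" for v in chunk) + "\n")
    Path(path).write_text(buf.getvalue())


def read_width_table(path: str | Path) -> list[RingWidthSeries]:
    """Read a long-form CSV (tree_id, year, width_mm) into series."""
    df = pd.read_csv(path)
    need = {"tree_id", "year", "width_mm"}
    if not need.issubset(df.columns):
        raise ValueError(f"width table must have columns {sorted(need)}")
    out = []
    for tid, g in df.groupby("tree_id", sort=True):
        g = g.sort_values("year")
        out.append(RingWidthSeries(str(tid), g["year"].to_numpy(), g["width_mm"].to_numpy()))
    return out


def write_width_table(series: Sequence[RingWidthSeries], path: str | Path) -> None:
    rows = [
        {"tree_id": s.tree_id, "year": int(y), "width_mm": float(w)}
        for s in series
        for y, w in zip(s.years, s.widths_mm)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
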