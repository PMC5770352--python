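"""Append-only experiment log and its CSV serialization.

Every measurement, actuator command, maneuver and protocol event of one
run lands in a single :class:`TimeSeriesLog`, ordered by time.  The CSV
form is the archival format: header ``time_min,stream,variable,value,
units,event``, UTF-8, numeric values printed with 9 significant digits.
Serialization is idempotent — writing a log that has been read back
reproduces the file byte for byte — which is the reproducibility contract
the tests pin down.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd

__all__ = ["LogRow", "TimeSeriesLog", "STREAMS"]

STREAMS = ("measurements", "commands", "maneuvers", "positions", "events")

_HEADER = ["time_min", "stream", "variable", "value", "units", "event"]


class LogRow(NamedTuple):
    time_min: float
    stream: str
    variable: str
    value: float
    units: str
    event: str


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


@dataclass
class TimeSeriesLog:
    """Ordered record of everything that happened in one experiment."""

    rows: list[LogRow] = field(default_factory=list)

    def append(
        self,
        time_min: float,
        stream: str,
        variable: str,
        value: float,
        units: str = "",
        event: str = "",
    ) -> None:
        if stream not in STREAMS:
            raise ValueError(f"unknown stream {stream!r}")
        if self.rows and time_min < self.rows[-1].time_min:
            raise ValueError(
                f"log times must be non-decreasing: {time_min} after {self.rows[-1].time_min}"
            )
        if not math.isfinite(value):
            raise ValueError(f"non-finite log value for {variable!r} at t={time_min}")
        self.rows.append(LogRow(time_min, stream, variable, float(value), units, event))

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeSeriesLog):
            return NotImplemented
        return self.rows == other.rows

    def select(self, stream: str, variable: str | None = None) -> list[LogRow]:
        """Rows of one stream, optionally restricted to one variable."""
        return [
            r
            for r in self.rows
            if r.stream == stream and (variable is None or r.variable == variable)
        ]

    def to_frame(self) -> pd.DataFrame:
        """The log as a pandas DataFrame (one row per entry)."""
        return pd.DataFrame(self.rows, columns=_HEADER)

    # -- CSV serialization ------------------------------------------------

    def to_csv_text(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(_HEADER)
        for r in self.rows:
            writer.writerow([_fmt(r.time_min), r.stream, r.variable, _fmt(r.value), r.units, r.event])
        return buf.getvalue()

    def write_csv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_csv_text(), encoding="utf-8")

    @classmethod
    def from_csv_text(cls, text: str) -> "TimeSeriesLog":
        reader = csv.reader(io.StringIO(text))
        header = next(reader)
        if header != _HEADER:
            raise ValueError(f"unexpected log header: {header}")
        log = cls()
        for t, stream, variable, value, units, event in reader:
            log.append(float(t), stream, variable, float(value), units, event)
        return log

    @classmethod
    def read_csv(cls, path: str | Path) -> "TimeSeriesLog":
        return cls.from_csv_text(Path(path).read_text(encoding="utf-8"))
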