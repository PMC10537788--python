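"""Trace file I/O and descriptive statistics.

Trace files are plain CSV with the header ``time_s,velocity_mps``, '.'
decimal separator, UTF-8. Unit suffixes are kept in every header the
package writes to prevent silent unit drift (the surrounding literature
mixes km/h and m/s).
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputError, ParseError
from .models import CodaResult, SummaryStats, VelocityTrace

TRACE_HEADER = ("time_s", "velocity_mps")


def read_trace(path, sampling_hz: float | None = None) -> VelocityTrace:
    """Read a velocity trace CSV; malformed rows are reported with their
    line number. The nominal rate defaults to the median sample spacing."""
    path = Path(path)
    times: list[float] = []
    speeds: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != TRACE_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(TRACE_HEADER)!r}, got "
                f"{','.join(header)!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise ParseError(f"{path}: expected 2 columns, got {len(row)}",
                                 line=lineno)
            try:
                t, v = float(row[0]), float(row[1])
            except ValueError:
                raise ParseError(f"{path}: non-numeric value in {row!r}",
                                 line=lineno) from None
            if times and t <= times[-1]:
                raise ParseError(f"{path}: time stamps not strictly "
                                 f"increasing at t={t!r}", line=lineno)
            times.append(t)
            speeds.append(v)
    if not times:
        raise ParseError(f"{path}: no data rows")
    ts = np.asarray(times)
    if sampling_hz is None:
        sampling_hz = 1.0 / float(np.median(np.diff(ts)))
    try:
        return VelocityTrace(ts, np.asarray(speeds), sampling_hz)
    except InputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_trace(trace: VelocityTrace, path) -> None:
    """Write a trace CSV; float values use shortest round-trip repr, so a
    write/read cycle preserves them exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(",".join(TRACE_HEADER) + "\n")
        for t, v in zip(trace.times, trace.speeds):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def best_of(attempts: Sequence):
    """Best (minimum-time) attempt; ties resolve to the earliest attempt.

    Accepts :class:`CodaResult` objects, any objects with a ``time``
    attribute, or plain numbers.
    """
    if len(attempts) == 0:
        raise InputError("best_of needs at least one attempt")
    key = (lambda a: a.time) if hasattr(attempts[0], "time") else float
    best = attempts[0]
    for a in attempts[1:]:
        if key(a) < key(best):
            best = a
    return best


def descriptive_summary(values) -> SummaryStats:
    """Mean, SD (n-1 denominator), range and linear-interpolation quartiles.

    A singleton has no sample SD; it is reported as 0 with
    ``sd_defined=False``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise InputError("descriptive_summary needs a non-empty vector")
    if not np.all(np.isfinite(x)):
        raise InputError("values must be finite")
    n = len(x)
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 interpolation
    return SummaryStats(
        n=n,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if n >= 2 else 0.0,
        minimum=float(x.min()),
        maximum=float(x.max()),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        sd_defined=n >= 2,
    )
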