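"""Readers and writers for the plain-text formats used by the pipeline.

Time courses travel as tab-delimited matrices (``chrom``, ``position``,
then one numeric column per sampling time, labelled in minutes).  Origin
sets and calls are BED6+ (0-based half-open single-bp intervals, score =
efficiency x 1000, extra columns for the firing window and, for calls,
the derived replication-timing statistics).  Tracks are bedGraph.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fit import OriginCall
from .model import Origin, ReplicationModel, replication_times
from .profiles import TimeCourse, TimingProfile

__all__ = [
    "TimeCourseParseError",
    "read_timecourse",
    "write_timecourse",
    "read_origins_bed",
    "write_origins_bed",
    "write_calls_bed",
    "write_bedgraph",
    "write_timing_table",
]


class TimeCourseParseError(ValueError):
    """Malformed time-course file (offending detail in the message)."""


def _format_number(x: float) -> str:
    return format(x, "g")


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    """Write a time course as a tab-delimited matrix (lossless round trip)."""
    df = pd.DataFrame(tc.values, columns=[_format_number(t) for t in tc.times])
    df.insert(0, "position", tc.positions.astype(np.int64))
    df.insert(0, "chrom", tc.chrom)
    df.to_csv(path, sep="\t", index=False)


def read_timecourse(path: str | Path, normalized: bool = False) -> TimeCourse:
    """Read a tab-delimited time-course matrix.

    The header must start with ``chrom`` and ``position`` followed by
    ascending numeric time labels.  Rows are sorted by position on read
    (with a warning if the file was shuffled); ragged or non-numeric rows
    raise :class:`TimeCourseParseError` naming the offense and line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise TimeCourseParseError(f"{path}: ragged or malformed row: {exc}") from exc
    if df.shape[1] < 3 or list(df.columns[:2]) != ["chrom", "position"]:
        raise TimeCourseParseError(
            f"{path}: header must be 'chrom<TAB>position<TAB><time>...', "
            f"got {list(df.columns[:3])}"
        )
    try:
        times = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise TimeCourseParseError(f"{path}: non-numeric time label: {exc}") from exc
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise TimeCourseParseError(f"{path}: time labels must be strictly ascending")

    values = df.iloc[:, 2:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(np.isnan(values).any(axis=1))[0]
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based numbering.
        raise TimeCourseParseError(
            f"{path}: non-numeric or missing value at line {bad[0] + 2}"
        )
    positions = pd.to_numeric(df["position"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(positions).any():
        raise TimeCourseParseError(
            f"{path}: non-numeric position at line "
            f"{int(np.nonzero(np.isnan(positions))[0][0]) + 2}"
        )
    if np.any(np.diff(positions) < 0):
        warnings.warn(f"{path}: positions out of order; sorting", stacklevel=2)
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        values = values[order]
    if np.any(np.diff(positions) == 0):
        raise TimeCourseParseError(f"{path}: duplicate positions")
    chroms = df["chrom"].unique()
    if chroms.size != 1:
        raise TimeCourseParseError(f"{path}: expected a single chrom, got {list(chroms)}")
    return TimeCourse(
        chrom=str(chroms[0]), positions=positions, times=times,
        values=values, normalized=normalized,
    )


_ORIGIN_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "t_s", "t_e"]


def write_origins_bed(
    origins: Sequence[Origin],
    path: str | Path,
    chrom: str = "chr1",
    efficiencies: Sequence[float] | None = None,
) -> None:
    """Write an origin set as BED6+ with firing-window columns."""
    eff = list(efficiencies) if efficiencies is not None else [0.0] * len(origins)
    rows = []
    for i, (o, e) in enumerate(zip(origins, eff), start=1):
        rows.append(
            {
                "chrom": chrom,
                "start": int(o.location),
                "end": int(o.location) + 1,
                "name": f"ORI_{i}",
                "score": int(round(e * 1000)),
                "strand": ".",
                "t_s": _format_number(o.t_fire_start),
                "t_e": _format_number(o.t_fire_end),
            }
        )
    pd.DataFrame(rows, columns=_ORIGIN_BED_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_origins_bed(path: str | Path) -> tuple[str, list[Origin]]:
    """Read a BED6+ origin set (needs the t_s/t_e extra columns)."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 8:
        raise TimeCourseParseError(
            f"{path}: origin BED needs 8 columns (BED6 + t_s, t_e), got {df.shape[1]}"
        )
    df.columns = _ORIGIN_BED_COLUMNS + [f"extra_{i}" for i in range(df.shape[1] - 8)]
    origins = [
        Origin(float(r.start), float(r.t_s), float(r.t_e)) for r in df.itertuples()
    ]
    chroms = df["chrom"].unique()
    if chroms.size != 1:
        raise TimeCourseParseError(f"{path}: expected a single chrom, got {list(chroms)}")
    return str(chroms[0]), origins


def write_calls_bed(
    calls: Sequence[OriginCall],
    path: str | Path,
    chrom: str,
    velocity: float,
    chrom_length: float | None = None,
) -> None:
    """Write origin calls with the full per-origin timing table.

    Columns: BED6 plus T_s, T_e, T_0, T_100, T_50, DT.  The replication
    times at each call come from evaluating the consolidated call set as
    a model at the supplied fork velocity.
    """
    rows = []
    if calls:
        length = chrom_length or max(c.location for c in calls) + 1
        model = ReplicationModel(
            origins=[Origin(c.location, c.t_fire_start, c.t_fire_end) for c in calls],
            fork_velocity=velocity,
            chrom_length=length,
        )
        for i, c in enumerate(calls, start=1):
            t0, t100 = replication_times(model, c.location)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(c.location),
                    "end": int(c.location) + 1,
                    "name": f"ORI_{i}",
                    "score": int(round(c.efficiency * 1000)),
                    "strand": ".",
                    "t_s": _format_number(c.t_fire_start),
                    "t_e": _format_number(c.t_fire_end),
                    "t_0": _format_number(t0),
                    "t_100": _format_number(t100),
                    "t_50": _format_number((t0 + t100) / 2.0),
                    "dt": _format_number(t100 - t0),
                }
            )
    columns = _ORIGIN_BED_COLUMNS + ["t_0", "t_100", "t_50", "dt"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False, header=False)


def write_bedgraph(
    positions: np.ndarray,
    values: np.ndarray,
    path: str | Path,
    chrom: str,
    span: float | None = None,
) -> None:
    """Write a track as bedGraph, tiling each probe over its spacing."""
    positions = np.asarray(positions, dtype=float)
    if span is None:
        span = float(np.median(np.diff(positions))) if positions.size > 1 else 1.0
    with open(path, "w") as fh:
        for x, v in zip(positions, values):
            if np.isnan(v) or x < 0:
                continue
            start = int(x)
            fh.write(f"{chrom}\t{start}\t{start + int(span)}\t{_format_number(v)}\n")


def write_timing_table(profile: TimingProfile, path: str | Path, chrom: str) -> None:
    """Combined per-locus T0/T100/T50/DT table (tab-delimited, with header)."""
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "position": profile.positions.astype(np.int64),
            "t_0": profile.t0,
            "t_100": profile.t100,
            "t_50": profile.t50,
            "dt": profile.dt,
            "valid": profile.valid.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
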