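"""Core records and tab-separated table I/O.

The pipeline works on two kinds of text tables, both tab-separated with a
header row and naive local timestamps (UTC+1, no timezone arithmetic):

* a *screening metadata* table — one row per screening: film title, age
  class (FSK 0/6/12/16), room, start/end time, viewer count, optional
  under-12 count, optional exclusion flag;
* a *compound table* — first column timestamps on a uniform ~30 s grid,
  one further column per measured compound (mixing ratios in ppb; CO2 in
  ppm).

Column names and separators are configured through :class:`TableDialect`
rather than hard-coded; the defaults match the tables this package's
synthetic generator writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, GapError, RowError, WindowError

AGE_CLASSES = (0, 6, 12, 16)

__all__ = [
    "AGE_CLASSES",
    "ScreeningRecord",
    "CompoundSeries",
    "StudyTable",
    "TableDialect",
    "DEFAULT_DIALECT",
    "read_screenings",
    "write_screenings",
    "read_compound_table",
    "write_compound_table",
    "slice_screening",
    "build_study",
]


@dataclass(frozen=True)
class TableDialect:
    """Names and conventions of the on-disk tables."""

    sep: str = "\t"
    # screening metadata columns
    film_col: str = "film_title"
    class_col: str = "age_class"
    room_col: str = "room_id"
    start_col: str = "start_time"
    end_col: str = "end_time"
    viewers_col: str = "viewer_count"
    under12_col: str = "under12_count"
    excluded_col: str = "excluded"
    id_col: str = "screening_id"
    # compound table conventions
    time_col: str = "time"
    co2_id: str = "CO2"
    # grid handling
    step_tolerance_s: float = 1.0
    max_gap_steps: int = 3

    @property
    def mandatory_columns(self) -> tuple[str, ...]:
        return (self.film_col, self.class_col, self.start_col,
                self.end_col, self.viewers_col)


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class ScreeningRecord:
    """One showing of one film to one audience."""

    screening_id: str
    film_title: str
    age_class: int
    room_id: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    viewer_count: int
    under12_count: int | None = None
    excluded: bool = False

    def __post_init__(self):
        if self.age_class not in AGE_CLASSES:
            raise ValueError(
                f"age_class must be one of {AGE_CLASSES}, got {self.age_class!r}")
        if not self.end_time > self.start_time:
            raise ValueError(
                f"end_time must be after start_time for {self.screening_id!r}")
        if self.viewer_count < 1:
            raise ValueError(
                f"viewer_count must be positive for {self.screening_id!r}")
        if self.under12_count is not None:
            if not (0 <= self.under12_count <= self.viewer_count):
                raise ValueError(
                    f"under12_count out of range for {self.screening_id!r}")

    @property
    def length_minutes(self) -> float:
        return (self.end_time - self.start_time).total_seconds() / 60.0


@dataclass(frozen=True)
class CompoundSeries:
    """A uniformly sampled mixing-ratio trace for one compound.

    ``values`` may contain NaN for missing samples only when
    ``allow_missing=True`` (raw table reads); sliced, analysis-ready
    series are gap-free.
    """

    compound_id: str
    timestamps: np.ndarray  # datetime64[s], strictly increasing, uniform
    values: np.ndarray      # float64, same length
    unit: str = "ppb"
    per_person: bool = False
    allow_missing: bool = field(default=False, compare=False)

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype="datetime64[s]")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if ts.shape != vals.shape or ts.ndim != 1:
            raise ValueError("timestamps and values must be equal-length 1-d arrays")
        if len(ts) < 2:
            raise ValueError("series must have length >= 2")
        steps = np.diff(ts).astype("timedelta64[s]").astype(float)
        if np.any(steps <= 0):
            bad = ts[1:][steps <= 0][0]
            raise FormatError(f"timestamps not strictly increasing at {bad}")
        if np.ptp(steps) > DEFAULT_DIALECT.step_tolerance_s:
            raise FormatError(
                f"non-uniform sampling grid for {self.compound_id!r}: "
                f"steps range {steps.min()}..{steps.max()} s")
        if np.any(np.isinf(vals)):
            raise ValueError("values must be finite")
        if not self.allow_missing and np.any(np.isnan(vals)):
            raise ValueError("missing values not allowed in an analysis-ready series")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def step_seconds(self) -> float:
        return float(np.diff(self.timestamps[:2]).astype("timedelta64[s]")[0]
                     / np.timedelta64(1, "s"))

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.timestamps[0])

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.timestamps[-1])

    def hours_from_start(self) -> np.ndarray:
        """Elapsed time of each sample in hours from the first sample."""
        dt = (self.timestamps - self.timestamps[0]).astype("timedelta64[s]")
        return dt.astype(float) / 3600.0


@dataclass
class StudyTable:
    """All screenings of a study plus their per-screening compound traces."""

    screenings: list[ScreeningRecord]
    series: dict[tuple[str, str], CompoundSeries]  # (screening_id, compound_id)

    def __post_init__(self):
        ids = {r.screening_id for r in self.screenings}
        units: dict[str, str] = {}
        for (sid, cid), s in self.series.items():
            if sid not in ids:
                raise ValueError(f"series references unknown screening {sid!r}")
            if units.setdefault(cid, s.unit) != s.unit:
                raise ValueError(f"inconsistent units for compound {cid!r}")

    @property
    def compounds(self) -> list[str]:
        return sorted({cid for _, cid in self.series})

    def active_screenings(self) -> list[ScreeningRecord]:
        return [r for r in self.screenings if not r.excluded]


# ---------------------------------------------------------------------------
# screening metadata

def _parse_timestamp(raw, line: int, col: str) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(str(raw))
    except (ValueError, TypeError) as exc:
        raise RowError(line, f"unparsable timestamp in column {col!r}: {raw!r}") from exc
    if pd.isna(ts):
        raise RowError(line, f"missing timestamp in column {col!r}")
    return ts


def _parse_int(raw, line: int, col: str) -> int:
    try:
        value = int(str(raw).strip())
    except (ValueError, TypeError) as exc:
        raise RowError(line, f"non-integer value in column {col!r}: {raw!r}") from exc
    return value


def read_screenings(path, dialect: TableDialect = DEFAULT_DIALECT,
                    exclude_ids: Iterable[str] = ()) -> list[ScreeningRecord]:
    """Read a screening-metadata table.

    ``exclude_ids`` lets QC-discarded screenings be flagged from an external
    exclusion list; they are returned with ``excluded=True``, never dropped.
    """
    frame = pd.read_csv(path, sep=dialect.sep, dtype=str)
    for col in dialect.mandatory_columns:
        if col not in frame.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    exclude_ids = set(exclude_ids)
    records = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        sid = (str(row[dialect.id_col]) if dialect.id_col in frame.columns
               else f"S{i:04d}")
        under12 = None
        if dialect.under12_col in frame.columns:
            raw = row[dialect.under12_col]
            if not (pd.isna(raw) or str(raw).strip() in ("", "NA")):
                under12 = _parse_int(raw, line, dialect.under12_col)
        excluded = sid in exclude_ids
        if dialect.excluded_col in frame.columns:
            raw = str(row[dialect.excluded_col]).strip().lower()
            excluded = excluded or raw in ("1", "true", "yes")
        try:
            rec = ScreeningRecord(
                screening_id=sid,
                film_title=str(row[dialect.film_col]),
                age_class=_parse_int(row[dialect.class_col], line, dialect.class_col),
                room_id=(str(row[dialect.room_col])
                         if dialect.room_col in frame.columns else "room1"),
                start_time=_parse_timestamp(row[dialect.start_col], line, dialect.start_col),
                end_time=_parse_timestamp(row[dialect.end_col], line, dialect.end_col),
                viewer_count=_parse_int(row[dialect.viewers_col], line, dialect.viewers_col),
                under12_count=under12,
                excluded=excluded,
            )
        except ValueError as exc:
            raise RowError(line, str(exc)) from exc
        records.append(rec)
    return records


def write_screenings(path, records: Iterable[ScreeningRecord],
                     dialect: TableDialect = DEFAULT_DIALECT) -> None:
    d = dialect
    rows = []
    for r in records:
        rows.append({
            d.id_col: r.screening_id,
            d.film_col: r.film_title,
            d.class_col: r.age_class,
            d.room_col: r.room_id,
            d.start_col: r.start_time.strftime("%Y-%m-%d %H:%M:%S"),
            d.end_col: r.end_time.strftime("%Y-%m-%d %H:%M:%S"),
            d.viewers_col: r.viewer_count,
            d.under12_col: "" if r.under12_count is None else r.under12_count,
            d.excluded_col: int(r.excluded),
        })
    pd.DataFrame(rows).to_csv(path, sep=d.sep, index=False)


# ---------------------------------------------------------------------------
# compound tables

def read_compound_table(path, dialect: TableDialect = DEFAULT_DIALECT
                        ) -> dict[str, CompoundSeries]:
    """Read a compound table: timestamp column + one column per compound."""
    frame = pd.read_csv(path, sep=dialect.sep)
    if frame.shape[1] < 2 or frame.empty:
        raise FormatError(f"compound table {path} is empty or has no compound columns")
    time_col = frame.columns[0]
    ts = pd.to_datetime(frame[time_col], errors="coerce")
    if ts.isna().any():
        bad = frame[time_col][ts.isna()].iloc[0]
        raise FormatError(f"unparsable timestamp {bad!r} in column {time_col!r}")
    ts64 = ts.to_numpy().astype("datetime64[s]")
    diffs = np.diff(ts64).astype(float)
    if np.any(diffs <= 0):
        dup = pd.Timestamp(ts64[1:][diffs <= 0][0])
        raise FormatError(f"timestamps not strictly increasing (at {dup})")
    out: dict[str, CompoundSeries] = {}
    for col in frame.columns[1:]:
        unit = "ppm" if col == dialect.co2_id else "ppb"
        out[col] = CompoundSeries(
            compound_id=col,
            timestamps=ts64,
            values=frame[col].to_numpy(dtype=float),
            unit=unit,
            allow_missing=True,
        )
    return out


def write_compound_table(path, series_map: Mapping[str, CompoundSeries],
                         dialect: TableDialect = DEFAULT_DIALECT) -> None:
    """Write compound traces sharing one grid to a single table."""
    ids = sorted(series_map)
    first = series_map[ids[0]]
    data = {dialect.time_col: [pd.Timestamp(t).strftime("%Y-%m-%d %H:%M:%S")
                               for t in first.timestamps]}
    for cid in ids:
        s = series_map[cid]
        if not np.array_equal(s.timestamps, first.timestamps):
            raise ValueError("all series in one table must share a grid")
        data[cid] = s.values
    pd.DataFrame(data).to_csv(path, sep=dialect.sep, index=False,
                              float_format="%.6g")


# ---------------------------------------------------------------------------
# windowing

def _fill_small_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap."""
    vals = values.copy()
    isnan = np.isnan(vals)
    if not isnan.any():
        return vals
    if isnan[0] or isnan[-1]:
        raise GapError("missing samples at a window boundary")
    idx = np.arange(len(vals))
    # find NaN runs
    run_start = None
    for i in range(len(vals)):
        if isnan[i] and run_start is None:
            run_start = i
        elif not isnan[i] and run_start is not None:
            if i - run_start > max_gap:
                raise GapError(
                    f"gap of {i - run_start} samples exceeds {max_gap}")
            run_start = None
    vals[isnan] = np.interp(idx[isnan], idx[~isnan], vals[~isnan])
    return vals


def slice_screening(series: CompoundSeries, record: ScreeningRecord,
                    max_gap_steps: int | None = None) -> CompoundSeries:
    """Extract the closed window [start_time, end_time] from a trace.

    Boundary samples are inclusive; interior gaps of at most
    ``max_gap_steps`` samples are linearly interpolated, longer gaps raise
    :class:`GapError` so the caller can flag the screening excluded.
    """
    if max_gap_steps is None:
        max_gap_steps = DEFAULT_DIALECT.max_gap_steps
    t0 = np.datetime64(record.start_time.to_datetime64(), "s")
    t1 = np.datetime64(record.end_time.to_datetime64(), "s")
    mask = (series.timestamps >= t0) & (series.timestamps <= t1)
    if not mask.any() or mask.sum() < 2:
        raise WindowError(
            f"window {record.start_time}..{record.end_time} does not overlap "
            f"series span {series.start}..{series.end}")
    values = _fill_small_gaps(series.values[mask], max_gap_steps)
    return replace(series, timestamps=series.timestamps[mask],
                   values=values, allow_missing=False)


def build_study(screenings: Iterable[ScreeningRecord],
                tables: Mapping[str, CompoundSeries],
                max_gap_steps: int | None = None) -> StudyTable:
    """Assemble a :class:`StudyTable` by windowing full-span compound traces.

    Screenings whose window is missing or has an uninterpolatable gap are
    kept with ``excluded=True`` and get no series.
    """
    out_recs: list[ScreeningRecord] = []
    out_series: dict[tuple[str, str], CompoundSeries] = {}
    for rec in screenings:
        if rec.excluded:
            out_recs.append(rec)
            continue
        sliced: dict[str, CompoundSeries] = {}
        ok = True
        for cid, full in tables.items():
            try:
                sliced[cid] = slice_screening(full, rec, max_gap_steps)
            except (WindowError, GapError):
                ok = False
                break
        if ok:
            out_recs.append(rec)
            for cid, s in sliced.items():
                out_series[(rec.screening_id, cid)] = s
        else:
            out_recs.append(replace(rec, excluded=True))
    return StudyTable(out_recs, out_series)
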