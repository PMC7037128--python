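"""Reading and writing Langmuir-trough logs and analysis reports.

A trough log is delimited text (comma or tab, auto-detected) with a header
row naming at least a time, a trough-area and a surface-pressure column.
Units are fixed at this boundary: seconds, cm² and mN/m respectively —
there is no unit inference anywhere downstream. Experiment metadata may be
embedded as ``# key: value`` comment lines or supplied programmatically;
explicit overrides take precedence over file comments, which take
precedence over defaults.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, TraceParseError

__all__ = [
    "IsothermRecord",
    "ExperimentMeta",
    "IsothermTrace",
    "read_trace",
    "write_trace",
    "write_report",
    "read_report",
]

#: Accepted case-insensitive header synonyms for the three required columns.
COLUMN_SYNONYMS: dict[str, frozenset[str]] = {
    "time": frozenset({"t", "time", "time_s"}),
    "area": frozenset({"a", "area", "area_cm2", "trough_area", "trough_area_cm2"}),
    "pressure": frozenset(
        {"pi", "p", "pressure", "surface_pressure", "surface_pressure_mn_m"}
    ),
}

_META_FIELDS = (
    "sample_id",
    "lipid_mixture",
    "ecn_wt_percent",
    "replicate",
    "temperature",
    "trough_area_max",
    "trough_area_min",
)


@dataclass(frozen=True)
class IsothermRecord:
    """One sample of a trough log: time [s], trough area [cm²], Π [mN/m].

    Surface pressure may be slightly negative (sensor noise on a clean
    interface); the trough area must be positive and time non-negative.
    """

    time: float
    trough_area: float
    surface_pressure: float

    def __post_init__(self) -> None:
        if not self.trough_area > 0:
            raise TraceParseError(
                f"trough_area must be positive, got {self.trough_area!r}"
            )
        if self.time < 0:
            raise TraceParseError(f"time must be non-negative, got {self.time!r}")


@dataclass(frozen=True)
class ExperimentMeta:
    """Per-sample experiment metadata carried through the pipeline."""

    sample_id: str = "sample"
    lipid_mixture: str = ""
    ecn_wt_percent: float = 0.0
    replicate: int = 1
    temperature: float = 298.15  # kelvin; room-temperature default
    trough_area_max: float = 166.0
    trough_area_min: float = 46.0

    def __post_init__(self) -> None:
        if self.ecn_wt_percent < 0:
            raise TraceParseError("ecn_wt_percent must be >= 0")
        if self.replicate < 1:
            raise TraceParseError("replicate must be a positive integer")
        if not self.temperature > 0:
            raise TraceParseError("temperature must be positive (kelvin)")
        if not self.trough_area_min < self.trough_area_max:
            raise TraceParseError("trough_area_min must be < trough_area_max")


@dataclass(frozen=True)
class IsothermTrace:
    """A validated, time-ordered Π–A trace plus its experiment metadata."""

    meta: ExperimentMeta
    records: tuple[IsothermRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 4:
            raise InsufficientDataError(
                f"a trace needs at least 4 records, got {len(self.records)}"
            )
        times = np.array([r.time for r in self.records])
        if not np.all(np.diff(times) > 0):
            raise TraceParseError("records must be strictly increasing in time")

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def areas(self) -> np.ndarray:
        return np.array([r.trough_area for r in self.records])

    @property
    def pressures(self) -> np.ndarray:
        return np.array([r.surface_pressure for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


def trace_from_arrays(
    times: Iterable[float],
    areas: Iterable[float],
    pressures: Iterable[float],
    meta: ExperimentMeta | None = None,
) -> IsothermTrace:
    """Build a trace from parallel arrays (convenience constructor)."""
    records = tuple(
        IsothermRecord(float(t), float(a), float(p))
        for t, a, p in zip(times, areas, pressures, strict=True)
    )
    return IsothermTrace(meta=meta or ExperimentMeta(), records=records)


def _canonical_header(name: str) -> str | None:
    key = re.sub(r"[^a-z0-9_]", "", str(name).strip().lower().replace(" ", "_"))
    for canon, synonyms in COLUMN_SYNONYMS.items():
        if key in synonyms:
            return canon
    return None


def _parse_comment_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped.startswith("#"):
                continue
            body = stripped.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip().lower().replace(" ", "_")
                if key in _META_FIELDS:
                    meta[key] = value.strip()
    return meta


_META_TYPES: dict[str, type] = {
    "sample_id": str,
    "lipid_mixture": str,
    "ecn_wt_percent": float,
    "replicate": int,
    "temperature": float,
    "trough_area_max": float,
    "trough_area_min": float,
}


def read_trace(
    path: str | Path, meta_overrides: Mapping[str, Any] | None = None
) -> IsothermTrace:
    """Read a delimited trough log into a validated :class:`IsothermTrace`.

    The delimiter (comma or tab) and the column order are auto-detected;
    header matching is case-insensitive over the synonyms in
    :data:`COLUMN_SYNONYMS`. Rows are sorted by time and duplicate
    timestamps collapsed keeping the first occurrence.

    Parameters
    ----------
    path
        Trough log file.
    meta_overrides
        Metadata values taking precedence over ``# key: value`` comment
        lines in the file, which in turn take precedence over defaults.

    Raises
    ------
    FormatError
        A required column is missing.
    TraceParseError
        A cell is non-numeric or violates a record invariant; the message
        cites the offending (1-based) data row.
    InsufficientDataError
        Fewer than 4 valid rows remain.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep=None, engine="python", comment="#", skip_blank_lines=True
        )
    except pd.errors.EmptyDataError as exc:
        raise InsufficientDataError(f"{path}: no data rows") from exc

    colmap: dict[str, str] = {}
    for col in frame.columns:
        canon = _canonical_header(col)
        if canon is not None and canon not in colmap:
            colmap[canon] = col
    for required in ("time", "area", "pressure"):
        if required not in colmap:
            raise FormatError(
                f"{path}: missing required column '{required}' "
                f"(accepted headers: {sorted(COLUMN_SYNONYMS[required])})"
            )

    data = frame[[colmap["time"], colmap["area"], colmap["pressure"]]].copy()
    data.columns = ["time", "area", "pressure"]
    for col in data.columns:
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TraceParseError(
                f"{path}: non-numeric {col!r} value in data row {row}: "
                f"{data[col].iloc[row - 1]!r}"
            )
        data[col] = coerced

    bad_area = ~(data["area"] > 0)
    if bad_area.any():
        row = int(np.flatnonzero(bad_area.to_numpy())[0]) + 1
        raise TraceParseError(
            f"{path}: trough area must be positive; data row {row} has "
            f"{data['area'].iloc[row - 1]!r}"
        )
    bad_time = data["time"] < 0
    if bad_time.any():
        row = int(np.flatnonzero(bad_time.to_numpy())[0]) + 1
        raise TraceParseError(f"{path}: negative time in data row {row}")

    data = data.sort_values("time", kind="stable")
    data = data.drop_duplicates(subset="time", keep="first")
    if len(data) < 4:
        raise InsufficientDataError(
            f"{path}: need at least 4 valid rows, got {len(data)}"
        )

    meta_kwargs: dict[str, Any] = {
        "sample_id": path.stem,
        "trough_area_max": float(data["area"].max()),
        "trough_area_min": float(data["area"].min()),
    }
    comments = _parse_comment_meta(path)
    for key, raw in comments.items():
        meta_kwargs[key] = _META_TYPES[key](raw)
    for key, value in (meta_overrides or {}).items():
        if key not in _META_FIELDS:
            raise FormatError(f"unknown metadata field {key!r}")
        meta_kwargs[key] = _META_TYPES[key](value)
    # The file's own area range may exceed a stale comment range; never let
    # the meta invariant reject otherwise valid data unless explicitly set.
    if meta_kwargs["trough_area_min"] >= meta_kwargs["trough_area_max"]:
        meta_kwargs["trough_area_min"] = float(data["area"].min())
        meta_kwargs["trough_area_max"] = float(data["area"].max()) or 1.0

    records = tuple(
        IsothermRecord(float(t), float(a), float(p))
        for t, a, p in zip(data["time"], data["area"], data["pressure"])
    )
    return IsothermTrace(meta=ExperimentMeta(**meta_kwargs), records=records)


def _fmt(x: float) -> str:
    return f"{float(x):.17g}"


def write_trace(trace: IsothermTrace, path: str | Path, delimiter: str = ",") -> None:
    """Write a trace as a trough log with metadata comment lines.

    Numbers are serialized at full double precision so that
    ``read_trace(write_trace(x)) == x`` to better than 1e-12 relative.
    """
    path = Path(path)
    meta = trace.meta
    with open(path, "w", encoding="utf-8") as fh:
        for key in _META_FIELDS:
            value = getattr(meta, key)
            if isinstance(value, float):
                value = _fmt(value)
            fh.write(f"# {key}: {value}\n")
        fh.write(delimiter.join(["time_s", "area_cm2", "surface_pressure"]) + "\n")
        for rec in trace.records:
            fh.write(
                delimiter.join(
                    [_fmt(rec.time), _fmt(rec.trough_area), _fmt(rec.surface_pressure)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Analysis reports


def _normalise_by_sample(items: Any) -> dict[str, list]:
    """Accept either ``{sample_id: [objs]}`` or a flat list of objs."""
    if items is None:
        return {}
    if isinstance(items, Mapping):
        return {str(k): list(v) for k, v in items.items()}
    return {"sample": list(items)}


def _row(obj: Any, sample_id: str | None = None) -> dict[str, Any]:
    d = dataclasses.asdict(obj)
    # Flatten nested dataclasses (VolmerFit.params, fit_window tuples).
    flat: dict[str, Any] = {}
    if sample_id is not None:
        flat["sample_id"] = sample_id
    for key, value in d.items():
        if isinstance(value, dict):
            for k2, v2 in value.items():
                flat[f"{key}_{k2}"] = v2
        elif isinstance(value, (tuple, list)):
            for i, v2 in enumerate(value):
                flat[f"{key}_{i}"] = v2
        else:
            flat[key] = value
    return flat


def write_report(
    metrics: Any,
    fits: Any,
    comparisons: Sequence[Any] | None,
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write per-cycle metrics, Volmer fits and group comparisons.

    ``metrics`` and ``fits`` may be flat lists (single sample) or mappings
    ``{sample_id: [..]}``. CSV output contains three ``# section:``
    delimited blocks (cycles, volmer_fits, comparisons) with one row per
    cycle per sample and a stable column order; JSON output is a single
    document with ``cycles``, ``volmer_fits`` and ``comparisons`` arrays.
    Both serialize at full precision and round-trip via
    :func:`read_report` to 1e-12 relative.
    """
    path = Path(path)
    metrics_by = _normalise_by_sample(metrics)
    fits_by = _normalise_by_sample(fits)
    comparisons = list(comparisons or [])

    cycle_rows = [
        _row(m, sid) for sid, ms in metrics_by.items() for m in ms
    ]
    fit_rows = [_row(f, sid) for sid, fs in fits_by.items() for f in fs]
    comp_rows = [_row(c) for c in comparisons]

    if format == "json":
        doc = {
            "cycles": cycle_rows,
            "volmer_fits": fit_rows,
            "comparisons": comp_rows,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, allow_nan=True)
            fh.write("\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8") as fh:
            for section, rows in (
                ("cycles", cycle_rows),
                ("volmer_fits", fit_rows),
                ("comparisons", comp_rows),
            ):
                fh.write(f"# section: {section}\n")
                if rows:
                    frame = pd.DataFrame(rows)
                    buf = io.StringIO()
                    frame.to_csv(buf, index=False, float_format="%.17g")
                    fh.write(buf.getvalue())
    else:
        raise FormatError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str | None = None) -> dict[str, list[dict]]:
    """Read back a report written by :func:`write_report`.

    Returns a dict with ``cycles``, ``volmer_fits`` and ``comparisons``
    lists of plain row dicts (numbers as floats/ints, missing as None).
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return {
            "cycles": doc.get("cycles", []),
            "volmer_fits": doc.get("volmer_fits", []),
            "comparisons": doc.get("comparisons", []),
        }
    sections: dict[str, list[dict]] = {
        "cycles": [],
        "volmer_fits": [],
        "comparisons": [],
    }
    current: str | None = None
    buffer: list[str] = []

    def _flush() -> None:
        nonlocal buffer
        if current is not None and buffer:
            frame = pd.read_csv(io.StringIO("".join(buffer)))
            frame = frame.astype(object).where(pd.notna(frame), None)
            sections[current] = frame.to_dict(orient="records")
        buffer = []

    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            match = re.match(r"#\s*section:\s*(\w+)", line)
            if match:
                _flush()
                current = match.group(1)
            elif current is not None and line.strip():
                buffer.append(line)
    _flush()
    return sections
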