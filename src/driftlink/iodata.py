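"""Data model and readers/writers for all-ions frame tables and reports.

The native interchange dialect is a flat CSV of 4-D centroided peaks with
columns ``rt_min, dt_ms, mz, intensity`` — one record per (retention time,
drift time, m/z) spot.  Retention time is in minutes and drift time in
milliseconds throughout.  The final metabolite report mirrors the standard
screening-table layout: name, formula, RT, observed m/z, ppm error, mean CCS
and its RSD, detection count, and a per-sample presence matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FRAME_COLUMNS",
    "FrameTable",
    "Feature",
    "ReportRow",
    "FrameFormatError",
    "ReportError",
    "read_frames",
    "write_frames",
    "write_report",
    "format_report_text",
    "write_hits",
    "read_hits",
]

FRAME_COLUMNS = ("rt_min", "dt_ms", "mz", "intensity")


class FrameFormatError(ValueError):
    """A frame table violating the documented dialect (named row/column)."""


class ReportError(ValueError):
    """Invalid report content (e.g. an empty row list)."""


@dataclass
class FrameTable:
    """All-ions 4-D peak list plus acquisition metadata.

    ``df`` holds one row per centroided (rt, dt, m/z, intensity) record,
    sorted by (rt, dt, mz).  ``metadata`` carries passive acquisition
    annotations such as the collision energy (V), drift gas and polarity.
    """

    df: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FRAME_COLUMNS if c not in self.df.columns]
        if missing:
            raise FrameFormatError(f"missing column(s): {', '.join(missing)}")
        df = self.df.loc[:, list(FRAME_COLUMNS)].astype(float)
        values = df.to_numpy()
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            row = int(np.argwhere(bad.any(axis=1))[0][0])
            raise FrameFormatError(
                f"row {row}: non-finite or negative value in frame record"
            )
        self.df = df.sort_values(list(FRAME_COLUMNS), kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_intensity(self) -> float:
        return float(self.df["intensity"].sum())

    @classmethod
    def from_records(
        cls, records: Iterable[Sequence[float]], metadata: Optional[dict] = None
    ) -> "FrameTable":
        df = pd.DataFrame(list(records), columns=list(FRAME_COLUMNS))
        return cls(df, metadata or {})


def read_frames(path, metadata: Optional[dict] = None) -> FrameTable:
    """Read a frame table from the native CSV dialect.

    Validates the header and every record; malformed rows raise
    :class:`FrameFormatError` naming the first offending row number
    (0-based, excluding the header).
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface as dialect error
        raise FrameFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise FrameFormatError(
            f"{path}: missing column(s): {', '.join(missing)}"
        )
    for column in FRAME_COLUMNS:
        coerced = pd.to_numeric(df[column], errors="coerce")
        bad = coerced.isna() | ~np.isfinite(coerced) | (coerced < 0)
        if bad.any():
            row = int(bad.idxmax())
            raise FrameFormatError(
                f"{path}: row {row}: invalid value {df[column].iloc[row]!r} "
                f"in column {column!r}"
            )
        df[column] = coerced
    return FrameTable(df, metadata or {})


def write_frames(frames: FrameTable, path) -> None:
    """Write a frame table in the native CSV dialect (UTF-8, '.' decimal)."""
    frames.df.to_csv(path, index=False, float_format="%.6f")


@dataclass
class Feature:
    """One ion species located at (RT apex, DT apex, m/z) with intensity."""

    rt_apex: float
    dt_apex: float
    mz: float
    intensity: float
    charge: int = 1
    ccs: Optional[float] = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("feature charge must be >= 1")
        if self.intensity < 0:
            raise ValueError("feature intensity must be >= 0")


@dataclass
class ReportRow:
    """One aggregated metabolite row of the final screening report."""

    name: str
    formula: str
    rt: float
    mz_observed: float
    delta_ppm: float
    ccs_mean: Optional[float]
    ccs_rsd: Optional[float]
    n_detections: int
    presence: Dict[str, bool] = field(default_factory=dict)


def _row_record(row: ReportRow, samples: Sequence[str]) -> Dict[str, object]:
    record: Dict[str, object] = {
        "name": row.name,
        "formula": row.formula,
        "rt_min": f"{row.rt:.2f}",
        "mz_observed": f"{row.mz_observed:.4f}",
        "delta_ppm": f"{row.delta_ppm:.1f}",
        "ccs_A2": "" if row.ccs_mean is None else f"{row.ccs_mean:.1f}",
        "ccs_rsd_pct": "" if row.ccs_rsd is None else f"{row.ccs_rsd:.1f}",
        "n": row.n_detections,
    }
    for sample in samples:
        record[sample] = "yes" if row.presence.get(sample, False) else "no"
    return record


def _collect_samples(rows: Sequence[ReportRow]) -> List[str]:
    samples: List[str] = []
    for row in rows:
        for sample in row.presence:
            if sample not in samples:
                samples.append(sample)
    return samples


def write_report(
    rows: Sequence[ReportRow], path, samples: Optional[Sequence[str]] = None
) -> None:
    """Write the metabolite report as CSV in screening-table column order.

    m/z is printed to 4 decimals, ppm / CCS / CCS-RSD to 1 decimal.  An empty
    row list raises :class:`ReportError`.
    """
    if not rows:
        raise ReportError("report has no rows")
    if samples is None:
        samples = _collect_samples(rows)
    records = [_row_record(row, samples) for row in rows]
    pd.DataFrame(records).to_csv(path, index=False)


def format_report_text(
    rows: Sequence[ReportRow], samples: Optional[Sequence[str]] = None
) -> str:
    """Render the report as an aligned plain-text table."""
    if not rows:
        raise ReportError("report has no rows")
    if samples is None:
        samples = _collect_samples(rows)
    records = [_row_record(row, samples) for row in rows]
    headers = list(records[0].keys())
    widths = {
        h: max(len(h), *(len(str(r[h])) for r in records)) for h in headers
    }
    lines = ["  ".join(h.ljust(widths[h]) for h in headers)]
    for record in records:
        lines.append("  ".join(str(record[h]).ljust(widths[h]) for h in headers))
    return "\n".join(lines) + "\n"


def write_hits(hits: Sequence[object], path) -> None:
    """Write metabolite hits as a JSON-lines stream (one hit per line)."""
    with open(path, "w", encoding="utf-8") as handle:
        for hit in hits:
            payload = asdict(hit) if hasattr(hit, "__dataclass_fields__") else dict(hit)
            handle.write(json.dumps(payload, sort_keys=True) + "\n")


def read_hits(path) -> List[dict]:
    """Read a JSON-lines hit stream back into plain dictionaries."""
    hits = []
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line:
                hits.append(json.loads(line))
    return hits
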