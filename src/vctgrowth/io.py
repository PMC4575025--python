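"""Reading and writing longitudinal nodule-volume measurement tables.

The on-disk format is delimited text (comma or tab) with one row per scan
and a header naming five fields::

    patient_id,nodule_id,scan_date,volume_mm3,calcified

``scan_date`` is an ISO-8601 calendar date; elapsed time between scans is
the whole-day difference of calendar dates.  Rows are grouped by nodule and
sorted by date on read; validation problems are reported with their row
numbers, all at once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["COLUMNS", "NoduleSeries", "read_measurements", "write_measurements"]

COLUMNS = ("patient_id", "nodule_id", "scan_date", "volume_mm3", "calcified")


@dataclass
class NoduleSeries:
    """One nodule's dated volume measurements, sorted by scan date.

    ``days`` gives each scan's offset in whole days from the first scan.
    """

    nodule_id: str
    patient_id: str
    dates: list[date]
    volumes: np.ndarray
    calcified: bool = False
    true_volumes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.dates) != len(self.volumes):
            raise ValidationError(
                f"nodule {self.nodule_id}: {len(self.dates)} dates but "
                f"{len(self.volumes)} volumes"
            )
        if np.any(self.volumes <= 0):
            raise ValidationError(
                f"nodule {self.nodule_id}: volumes must be positive"
            )
        order = np.argsort([d.toordinal() for d in self.dates], kind="stable")
        self.dates = [self.dates[i] for i in order]
        self.volumes = self.volumes[order]
        if self.true_volumes is not None:
            self.true_volumes = np.asarray(self.true_volumes, dtype=float)[order]

    @property
    def n_scans(self) -> int:
        return len(self.volumes)

    @property
    def days(self) -> np.ndarray:
        d0 = self.dates[0]
        return np.array([(d - d0).days for d in self.dates], dtype=float)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"not a boolean flag: {value!r}")


def read_measurements(path: str | Path) -> list[NoduleSeries]:
    """Read a delimited measurement table into per-nodule series.

    Accepts comma- or tab-separated text.  All validation failures —
    missing columns, unparseable dates, non-positive volumes, duplicate
    (nodule, date) pairs — are collected and raised together with the
    offending row numbers (header = row 1).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")

    problems: list[str] = []
    parsed = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header occupies row 1
        try:
            scan_date = date.fromisoformat(str(row["scan_date"]).strip())
        except ValueError:
            problems.append(f"row {rowno}: unparseable scan_date {row['scan_date']!r}")
            continue
        try:
            volume = float(row["volume_mm3"])
        except (TypeError, ValueError):
            problems.append(f"row {rowno}: non-numeric volume {row['volume_mm3']!r}")
            continue
        if not volume > 0:
            problems.append(f"row {rowno}: non-positive volume {volume}")
            continue
        try:
            calcified = _parse_bool(row["calcified"])
        except ValueError:
            problems.append(f"row {rowno}: bad calcified flag {row['calcified']!r}")
            continue
        parsed.append(
            (str(row["patient_id"]), str(row["nodule_id"]), scan_date, volume, calcified, rowno)
        )

    seen: dict[tuple[str, date], int] = {}
    for patient, nodule, scan_date, _, _, rowno in parsed:
        key = (nodule, scan_date)
        if key in seen:
            problems.append(
                f"row {rowno}: duplicate scan of nodule {nodule} on {scan_date} "
                f"(first at row {seen[key]})"
            )
        else:
            seen[key] = rowno
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))

    groups: dict[str, list] = {}
    for rec in parsed:
        groups.setdefault(rec[1], []).append(rec)
    series = []
    for nodule_id, recs in groups.items():
        recs.sort(key=lambda r: r[2])
        series.append(
            NoduleSeries(
                nodule_id=nodule_id,
                patient_id=recs[0][0],
                dates=[r[2] for r in recs],
                volumes=np.array([r[3] for r in recs]),
                calcified=recs[0][4],
            )
        )
    return series


def write_measurements(
    cohort: Iterable[NoduleSeries], path: str | Path, sep: str = ","
) -> None:
    """Write series to delimited text; round-trips through read_measurements."""
    rows = []
    for s in cohort:
        for d, v in zip(s.dates, s.volumes):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "nodule_id": s.nodule_id,
                    "scan_date": d.isoformat(),
                    "volume_mm3": repr(float(v)),
                    "calcified": s.calcified,
                }
            )
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, sep=sep, index=False)
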