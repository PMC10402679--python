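"""Domain types for machine QC/service logs and dose-metric tables, with CSV I/O.

The package consumes three delimited-text inputs:

``qc_log``
    ``date,item_id,measured_deviation`` — one row per QC measurement of one
    item, with the signed deviation in the item's tolerance unit.
``service_log``
    ``item_id,onset_date,found_date,repaired_date,found_by_qc`` — one row per
    machine failure: when it is judged to have begun (or the last QC test that
    missed it), when it was discovered, and when function was restored.
``dose_metrics``
    ``patient_id,item_id,interval_days,delta_ptv_pct,delta_cord_cgy`` — per
    patient and per tested interval, the magnitude of the dose perturbation a
    tolerance-level error would cause: change in the percentage of the PTV
    covered by the prescription dose (percentage points) and change in the
    maximum spinal-cord dose (cGy). These come from a treatment planning
    system; this package only consumes them.

All dates are ISO-8601 calendar dates and all durations are whole-day date
differences, so the estimators are independent of any site's duty calendar.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "QCItem",
    "IntervalGrid",
    "QCMeasurement",
    "ServiceEvent",
    "DoseMetricRecord",
    "DEFAULT_CATALOG",
    "DEFAULT_GRID",
    "catalog_by_id",
    "read_qc_log",
    "qc_log_from_frame",
    "service_log_from_frame",
    "dose_metrics_from_frame",
    "write_qc_log",
    "read_service_log",
    "write_service_log",
    "read_dose_metrics",
    "write_dose_metrics",
    "load_config",
]

TOLERANCE_UNITS = ("degrees", "mm")


class ValidationError(ValueError):
    """An input file or record violates the documented schema or an invariant."""


@dataclasses.dataclass(frozen=True)
class QCItem:
    """A monitored machine parameter with its tolerance.

    ``item_id`` is the small integer index m in the failure-mode notation
    FM(QC_m, D_n). ``modeled_error`` describes the tolerance-level
    perturbation used for severity assessment.
    """

    item_id: int
    name: str
    tolerance_value: float
    tolerance_unit: str
    modeled_error: str = ""

    def __post_init__(self) -> None:
        if self.tolerance_value <= 0:
            raise ValidationError(
                f"QC item {self.item_id}: tolerance must be positive, "
                f"got {self.tolerance_value}"
            )
        if self.tolerance_unit not in TOLERANCE_UNITS:
            raise ValidationError(
                f"QC item {self.item_id}: tolerance_unit must be one of "
                f"{TOLERANCE_UNITS}, got {self.tolerance_unit!r}"
            )

    def within_tolerance(self, deviation: float) -> bool:
        """True when |deviation| <= tolerance (the boundary counts as within)."""
        return abs(deviation) <= self.tolerance_value


@dataclasses.dataclass(frozen=True)
class IntervalGrid:
    """The ordered grid of tested QC intervals, in days."""

    intervals: tuple[int, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ivs = tuple(int(i) for i in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise ValidationError("interval grid is empty")
        if any(i < 1 for i in ivs):
            raise ValidationError(f"intervals must be >= 1 day, got {ivs}")
        if any(b <= a for a, b in zip(ivs, ivs[1:])):
            raise ValidationError(f"intervals must be strictly increasing, got {ivs}")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(f"D{i}" for i in ivs))
        elif len(self.labels) != len(ivs):
            raise ValidationError("labels must parallel intervals")

    def __contains__(self, interval: int) -> bool:
        return interval in self.intervals

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def label(self, interval: int) -> str:
        return self.labels[self.intervals.index(interval)]


@dataclasses.dataclass(frozen=True)
class QCMeasurement:
    """One dated QC measurement of one item.

    ``within_tolerance`` is always recomputed from the catalog tolerance when
    reading from disk; a stored flag never survives a round trip.
    """

    date: dt.date
    item_id: int
    measured_deviation: float
    within_tolerance: bool


@dataclasses.dataclass(frozen=True)
class ServiceEvent:
    """A machine failure episode from the service log."""

    item_id: int
    onset_date: dt.date
    found_date: dt.date
    repaired_date: dt.date
    found_by_qc: bool

    def __post_init__(self) -> None:
        if not (self.onset_date <= self.found_date <= self.repaired_date):
            raise ValidationError(
                f"service event for item {self.item_id}: dates must satisfy "
                f"onset <= found <= repaired, got {self.onset_date} / "
                f"{self.found_date} / {self.repaired_date}"
            )


@dataclasses.dataclass(frozen=True)
class DoseMetricRecord:
    """Dose perturbation magnitudes for one patient, item, and interval."""

    patient_id: str
    item_id: int
    interval_days: int
    delta_ptv_pct: float
    delta_cord_cgy: float

    def __post_init__(self) -> None:
        if self.delta_ptv_pct < 0 or self.delta_cord_cgy < 0:
            raise ValidationError(
                f"dose metrics for patient {self.patient_id}, item "
                f"{self.item_id}: deltas are absolute magnitudes and must be "
                f">= 0"
            )


#: The six monthly mechanical QC items of an Elekta Unity MR-linac with the
#: institutional tolerances this method was developed on. Serves as the
#: default catalog; any catalog can be supplied via config.
DEFAULT_CATALOG: tuple[QCItem, ...] = (
    QCItem(1, "gantry angle indicator", 0.2, "degrees", "0.2 deg change in gantry angle"),
    QCItem(2, "collimator-couch coincidence", 0.2, "degrees", "0.2 deg change in gantry angle"),
    QCItem(3, "jaw position indicator", 1.0, "mm", "1.0 mm shift in jaws"),
    QCItem(4, "couch position indicator", 1.0, "mm", "1.0 mm shift in AP direction"),
    QCItem(5, "radiation isocenter size", 0.5, "mm", "0.5 mm translational shift in three axes"),
    QCItem(6, "MR-to-MV fit", 1.0, "mm", "1.0 mm translational shift in three axes"),
)

#: Daily, weekly, biweekly, triweekly, monthly, bimonthly.
DEFAULT_GRID = IntervalGrid((1, 7, 14, 21, 30, 60))


def catalog_by_id(catalog: Iterable[QCItem]) -> dict[int, QCItem]:
    out: dict[int, QCItem] = {}
    for item in catalog:
        if item.item_id in out:
            raise ValidationError(f"duplicate item_id {item.item_id} in catalog")
        out[item.item_id] = item
    return out


def _parse_date(value, path: Path, row: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValidationError(f"{path}, row {row}: bad {column} {value!r}: {exc}") from None


def _parse_bool(value, path: Path, row: int, column: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValidationError(f"{path}, row {row}: bad {column} {value!r}")


def _require_columns(frame: pd.DataFrame, expected: Sequence[str], path: Path) -> None:
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}; header must contain {list(expected)}")


def _lookup_item(item_id, items: Mapping[int, QCItem], path: Path, row: int) -> QCItem:
    try:
        key = int(item_id)
    except (TypeError, ValueError):
        raise ValidationError(f"{path}, row {row}: bad item_id {item_id!r}") from None
    if key not in items:
        raise ValidationError(f"{path}, row {row}: unknown item_id {key} (not in catalog)")
    return items[key]


def qc_log_from_frame(
    frame: pd.DataFrame, catalog: Iterable[QCItem], source: str | Path = "<dataframe>"
) -> list[QCMeasurement]:
    """Build QC measurements from a dataframe with the qc_log schema."""
    path = Path(source)
    items = catalog_by_id(catalog)
    frame = frame.astype(str)
    _require_columns(frame, ("date", "item_id", "measured_deviation"), path)
    records = []
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        item = _lookup_item(rec.item_id, items, path, row)
        date = _parse_date(rec.date, path, row, "date")
        try:
            deviation = float(rec.measured_deviation)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}, row {row}: bad measured_deviation {rec.measured_deviation!r}"
            ) from None
        records.append(
            QCMeasurement(date, item.item_id, deviation, item.within_tolerance(deviation))
        )
    return records


def read_qc_log(path: str | Path, catalog: Iterable[QCItem]) -> list[QCMeasurement]:
    """Read a QC measurement log, recomputing within_tolerance from the catalog."""
    return qc_log_from_frame(pd.read_csv(path, dtype=str), catalog, path)


def write_qc_log(records: Iterable[QCMeasurement], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.date.isoformat(), r.item_id, repr(r.measured_deviation)) for r in records],
        columns=["date", "item_id", "measured_deviation"],
    )
    frame.to_csv(path, index=False)


def service_log_from_frame(
    frame: pd.DataFrame, catalog: Iterable[QCItem], source: str | Path = "<dataframe>"
) -> list[ServiceEvent]:
    """Build service events from a dataframe; returned sorted by found_date."""
    path = Path(source)
    items = catalog_by_id(catalog)
    frame = frame.astype(str)
    _require_columns(
        frame, ("item_id", "onset_date", "found_date", "repaired_date", "found_by_qc"), path
    )
    events = []
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        item = _lookup_item(rec.item_id, items, path, row)
        try:
            events.append(
                ServiceEvent(
                    item.item_id,
                    _parse_date(rec.onset_date, path, row, "onset_date"),
                    _parse_date(rec.found_date, path, row, "found_date"),
                    _parse_date(rec.repaired_date, path, row, "repaired_date"),
                    _parse_bool(rec.found_by_qc, path, row, "found_by_qc"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {row}: {exc}") from None
    events.sort(key=lambda e: (e.found_date, e.item_id, e.onset_date))
    return events


def read_service_log(path: str | Path, catalog: Iterable[QCItem]) -> list[ServiceEvent]:
    """Read a service/failure log; events are returned sorted by found_date."""
    return service_log_from_frame(pd.read_csv(path, dtype=str), catalog, path)


def write_service_log(events: Iterable[ServiceEvent], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (
                e.item_id,
                e.onset_date.isoformat(),
                e.found_date.isoformat(),
                e.repaired_date.isoformat(),
                e.found_by_qc,
            )
            for e in events
        ],
        columns=["item_id", "onset_date", "found_date", "repaired_date", "found_by_qc"],
    )
    frame.to_csv(path, index=False)


def dose_metrics_from_frame(
    frame: pd.DataFrame,
    catalog: Iterable[QCItem],
    grid: IntervalGrid,
    source: str | Path = "<dataframe>",
) -> list[DoseMetricRecord]:
    """Build dose-metric records from a dataframe, validated against catalog and grid."""
    path = Path(source)
    items = catalog_by_id(catalog)
    frame = frame.astype(str)
    _require_columns(
        frame, ("patient_id", "item_id", "interval_days", "delta_ptv_pct", "delta_cord_cgy"), path
    )
    records = []
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        item = _lookup_item(rec.item_id, items, path, row)
        try:
            interval = int(rec.interval_days)
        except (TypeError, ValueError):
            raise ValidationError(f"{path}, row {row}: bad interval_days {rec.interval_days!r}") from None
        if interval not in grid:
            raise ValidationError(
                f"{path}, row {row}: interval_days {interval} is not in the "
                f"tested grid {grid.intervals}"
            )
        try:
            ptv = float(rec.delta_ptv_pct)
            cord = float(rec.delta_cord_cgy)
        except (TypeError, ValueError):
            raise ValidationError(f"{path}, row {row}: bad dose delta") from None
        try:
            records.append(DoseMetricRecord(str(rec.patient_id), item.item_id, interval, ptv, cord))
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {row}: {exc}") from None
    return records


def read_dose_metrics(
    path: str | Path, catalog: Iterable[QCItem], grid: IntervalGrid
) -> list[DoseMetricRecord]:
    """Read a per-patient dose-perturbation table, validated against catalog and grid."""
    return dose_metrics_from_frame(pd.read_csv(path, dtype=str), catalog, grid, path)


def write_dose_metrics(records: Iterable[DoseMetricRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (r.patient_id, r.item_id, r.interval_days, repr(r.delta_ptv_pct), repr(r.delta_cord_cgy))
            for r in records
        ],
        columns=["patient_id", "item_id", "interval_days", "delta_ptv_pct", "delta_cord_cgy"],
    )
    frame.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML analysis/scenario config.

    Recognised keys: ``items`` (list of QCItem field mappings), ``grid`` (list
    of interval days), and any further scalar options, passed through
    untouched. Returns a dict with ``catalog`` (tuple of QCItem) and ``grid``
    (IntervalGrid) materialised, falling back to the built-in defaults.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: config must be a mapping")
    config = dict(raw)
    items = config.pop("items", None)
    if items is not None:
        config["catalog"] = tuple(QCItem(**entry) for entry in items)
    else:
        config["catalog"] = DEFAULT_CATALOG
    grid = config.pop("grid", None)
    if grid is not None:
        config["grid"] = IntervalGrid(tuple(int(i) for i in grid))
    else:
        config["grid"] = DEFAULT_GRID
    return config
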