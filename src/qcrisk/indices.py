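"""Severity, occurrence, and detection indices for failure modes.

A failure mode FM(QC_m, D_n) is a QC item m tested every n days with its
assigned tolerance. Three quantities of failure are estimated from the
records and mapped onto the TG-100 1-10 ranking scales:

* **Severity (S)** — the dose perturbation a tolerance-level error would
  cause, scored per patient against two criteria (change in % PTV covered by
  the prescription dose; change in maximum spinal-cord dose) and pooled over
  the patient cohort.
* **Occurrence (O)** — the fraction of observed operating time the parameter
  spent out of tolerance. An item that never failed during the observation
  period is ranked 2, never 1: absence of failures over a finite record does
  not support the <=0.01% rate that rank 1 asserts.
* **Detection (D)** — the fraction of the observation period failures
  persisted undetected. A failure missed by a QC test and discovered later is
  credited half the gap between that test and the discovery, the expected
  undetected duration when the true onset is equally likely anywhere in the
  gap.

Each quantity is expressed in percent and ranked by a table of nine upper
bounds (ranks 1-9); anything above the last bound is rank 10, and an exact
boundary maps to the lower rank.
"""

from __future__ import annotations

import bisect
import dataclasses
import datetime as dt
import logging
import math
from collections.abc import Iterable, Sequence
from decimal import ROUND_HALF_UP, Decimal

from .records import QCItem, QCMeasurement, ServiceEvent, DoseMetricRecord, ValidationError

__all__ = [
    "RankTable",
    "TG100_TABLES",
    "SeverityResult",
    "OccurrenceResult",
    "DetectionResult",
    "RankProfile",
    "rank_from_table",
    "occurrence_index",
    "detection_index",
    "severity_index",
    "rank_profile",
    "round_rank",
]

logger = logging.getLogger(__name__)

CRITERIA = ("severity_ptv", "severity_cord", "occurrence", "detection")
AGGREGATIONS = ("max_of_criteria", "ptv_only", "cord_only")
POOLINGS = ("mean_of_ranks", "rank_of_means")
ROUNDINGS = ("nearest", "floor", "ceiling")


@dataclasses.dataclass(frozen=True)
class RankTable:
    """Nine ordered upper bounds mapping a quantity to ranks 1-9 (10 above)."""

    criterion: str
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValidationError(f"unknown ranking criterion {self.criterion!r}")
        if len(self.thresholds) != 9:
            raise ValidationError(
                f"rank table {self.criterion}: exactly 9 upper bounds required, "
                f"got {len(self.thresholds)}"
            )
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValidationError(
                f"rank table {self.criterion}: thresholds must be strictly increasing"
            )


#: TG-100-style ranking scales: upper bounds for ranks 1-9.
#: severity_ptv in percentage points of PTV coverage change, severity_cord in
#: cGy of maximum-cord-dose change, occurrence and detection in percent of the
#: observation period.
TG100_TABLES: dict[str, RankTable] = {
    "severity_ptv": RankTable("severity_ptv", (1, 2, 3, 4, 5, 10, 15, 20, 50)),
    "severity_cord": RankTable("severity_cord", (45, 90, 135, 180, 225, 450, 675, 900, 2250)),
    "occurrence": RankTable("occurrence", (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1, 2, 5)),
    "detection": RankTable("detection", (0.01, 0.2, 0.5, 1, 2, 5, 10, 15, 20)),
}

#: Rank given to an item whose records show no failure at all.
NEVER_FAILED_OCCURRENCE_RANK = 2


@dataclasses.dataclass(frozen=True)
class OccurrenceResult:
    item_id: int
    quantity: float  # percent of observed time out of tolerance
    ever_failed: bool
    rank: int


@dataclasses.dataclass(frozen=True)
class DetectionResult:
    item_id: int
    quantity: float  # percent of the period failures persisted undetected
    rank: int
    interval_days: int | None = None


@dataclasses.dataclass(frozen=True)
class SeverityResult:
    item_id: int
    interval_days: int
    per_patient_ranks: tuple[int, ...]
    mean_rank: float
    mean_delta_ptv_pct: float
    mean_delta_cord_cgy: float


@dataclasses.dataclass(frozen=True)
class RankProfile:
    """Integer S, O, D ranks of one failure mode FM(QC_m, D_n)."""

    item_id: int
    interval_days: int
    S: int
    O: int
    D: int

    def __post_init__(self) -> None:
        for name, rank in (("S", self.S), ("O", self.O), ("D", self.D)):
            if not (isinstance(rank, int) and 1 <= rank <= 10):
                raise ValidationError(
                    f"FM(QC{self.item_id}, D{self.interval_days}): {name} rank "
                    f"must be an integer in 1-10, got {rank!r}"
                )


def rank_from_table(quantity: float, table: RankTable) -> int:
    """Map a non-negative quantity to its rank: smallest r with bound >= quantity.

    An exact boundary maps to the lower rank (bounds are inclusive upper
    limits); quantities above the ninth bound are rank 10.
    """
    if quantity < 0 or not math.isfinite(quantity):
        raise ValidationError(f"quantity must be finite and >= 0, got {quantity}")
    return bisect.bisect_left(table.thresholds, quantity) + 1


def _out_of_tolerance_days(
    log: Sequence[QCMeasurement],
    item: QCItem,
    service: Sequence[ServiceEvent] | None,
    window_start: dt.date,
    window_end: dt.date,
) -> int:
    """Count calendar days the item is observed out of tolerance.

    A failing measurement holds the "failed" state from its date until the
    next passing measurement of the item or the repair that covers it,
    whichever is earlier; each calendar day counts once.
    """
    records = sorted((r for r in log if r.item_id == item.item_id), key=lambda r: r.date)
    pass_dates = [r.date for r in records if r.within_tolerance]
    repairs = sorted(
        (e for e in (service or ()) if e.item_id == item.item_id),
        key=lambda e: e.repaired_date,
    )
    failed: set[dt.date] = set()
    for rec in records:
        if rec.within_tolerance:
            continue
        end = window_end
        nxt = bisect.bisect_right(pass_dates, rec.date)
        if nxt < len(pass_dates):
            end = min(end, pass_dates[nxt])
        for event in repairs:
            if event.onset_date <= rec.date < event.repaired_date:
                end = min(end, event.repaired_date)
                break
        day = max(rec.date, window_start)
        while day < end:
            failed.add(day)
            day += dt.timedelta(days=1)
    return len(failed)


def occurrence_index(
    log: Sequence[QCMeasurement],
    item: QCItem,
    period_days: int,
    service: Sequence[ServiceEvent] | None = None,
    tables: dict[str, RankTable] = TG100_TABLES,
) -> OccurrenceResult:
    """Occurrence index: percent of the observation period out of tolerance.

    ``period_days`` is the length of the observation period, which must cover
    all log dates for the item. When the log shows no out-of-tolerance record
    the item is ranked 2 (never 1), per the never-detected convention.
    """
    if period_days <= 0:
        raise ValidationError(f"period_days must be positive, got {period_days}")
    records = [r for r in log if r.item_id == item.item_id]
    if not records:
        return OccurrenceResult(item.item_id, 0.0, False, NEVER_FAILED_OCCURRENCE_RANK)
    start = min(r.date for r in records)
    end = start + dt.timedelta(days=period_days)
    if any(r.date >= end for r in records):
        raise ValidationError(
            f"item {item.item_id}: log dates extend past the {period_days}-day "
            f"observation period starting {start}"
        )
    failed_days = _out_of_tolerance_days(log, item, service, start, end)
    quantity = 100.0 * failed_days / period_days
    ever_failed = any(not r.within_tolerance for r in records)
    if not ever_failed:
        rank = NEVER_FAILED_OCCURRENCE_RANK
    else:
        rank = rank_from_table(quantity, tables["occurrence"])
    return OccurrenceResult(item.item_id, quantity, ever_failed, rank)


def detection_index(
    service: Sequence[ServiceEvent],
    item: QCItem,
    period_days: int,
    interval_days: int | None = None,
    tables: dict[str, RankTable] = TG100_TABLES,
) -> DetectionResult:
    """Detection index: percent of the period failures persisted undetected.

    Every failure the QC test missed (``found_by_qc`` false) contributes half
    the days between its onset (the missing QC test) and its discovery;
    failures caught by the QC test itself contribute nothing.
    """
    if period_days <= 0:
        raise ValidationError(f"period_days must be positive, got {period_days}")
    undetected = sum(
        (e.found_date - e.onset_date).days / 2.0
        for e in service
        if e.item_id == item.item_id and not e.found_by_qc
    )
    quantity = 100.0 * undetected / period_days
    rank = rank_from_table(quantity, tables["detection"])
    return DetectionResult(item.item_id, quantity, rank, interval_days)


def severity_index(
    metrics: Iterable[DoseMetricRecord],
    item: QCItem,
    interval_days: int,
    aggregation: str = "max_of_criteria",
    pooling: str = "mean_of_ranks",
    tables: dict[str, RankTable] = TG100_TABLES,
) -> SeverityResult:
    """Severity index for FM(item, interval) pooled over the patient cohort.

    Each patient's PTV-coverage and cord-dose deltas are ranked separately and
    combined per ``aggregation`` (default: the worse of the two). With the
    default ``mean_of_ranks`` pooling the cohort index is the arithmetic mean
    of the per-patient combined ranks, which is why it is generally not an
    integer; ``rank_of_means`` instead ranks the cohort-mean quantities.
    """
    if aggregation not in AGGREGATIONS:
        raise ValidationError(f"aggregation must be one of {AGGREGATIONS}, got {aggregation!r}")
    if pooling not in POOLINGS:
        raise ValidationError(f"pooling must be one of {POOLINGS}, got {pooling!r}")
    rows = [
        r for r in metrics if r.item_id == item.item_id and r.interval_days == interval_days
    ]
    if not rows:
        raise ValidationError(
            f"no dose metrics for item {item.item_id} at interval {interval_days} d"
        )

    def combine(ptv_rank: int, cord_rank: int) -> int:
        if aggregation == "ptv_only":
            return ptv_rank
        if aggregation == "cord_only":
            return cord_rank
        return max(ptv_rank, cord_rank)

    per_patient = tuple(
        combine(
            rank_from_table(r.delta_ptv_pct, tables["severity_ptv"]),
            rank_from_table(r.delta_cord_cgy, tables["severity_cord"]),
        )
        for r in rows
    )
    mean_ptv = sum(r.delta_ptv_pct for r in rows) / len(rows)
    mean_cord = sum(r.delta_cord_cgy for r in rows) / len(rows)
    if pooling == "mean_of_ranks":
        mean_rank = sum(per_patient) / len(per_patient)
    else:
        mean_rank = float(
            combine(
                rank_from_table(mean_ptv, tables["severity_ptv"]),
                rank_from_table(mean_cord, tables["severity_cord"]),
            )
        )
    return SeverityResult(item.item_id, interval_days, per_patient, mean_rank, mean_ptv, mean_cord)


def round_rank(mean_rank: float, rounding: str = "nearest") -> int:
    """Round a fractional severity index to an integer rank.

    ``nearest`` rounds half away from zero (2.5 -> 3), the convention of
    everyday hand-rounding rather than banker's rounding.
    """
    if rounding == "nearest":
        return int(Decimal(repr(mean_rank)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    if rounding == "floor":
        return math.floor(mean_rank)
    if rounding == "ceiling":
        return math.ceil(mean_rank)
    raise ValidationError(f"rounding must be one of {ROUNDINGS}, got {rounding!r}")


def rank_profile(
    item: QCItem,
    interval_days: int,
    S: SeverityResult,
    O: OccurrenceResult,
    D: DetectionResult,
    rounding: str = "nearest",
) -> RankProfile:
    """Assemble the integer (S, O, D) profile of FM(item, interval)."""
    for result in (S, O, D):
        if result.item_id != item.item_id:
            raise ValidationError(
                f"rank_profile: result for item {result.item_id} does not match "
                f"item {item.item_id}"
            )
    s_rank = round_rank(S.mean_rank, rounding)
    if not 1 <= s_rank <= 10:
        logger.warning(
            "FM(QC%d, D%d): rounded S rank %d outside 1-10; clamping",
            item.item_id, interval_days, s_rank,
        )
        s_rank = min(10, max(1, s_rank))
    return RankProfile(item.item_id, interval_days, s_rank, O.rank, D.rank)
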