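"""Model/Results interface over the full QC-frequency risk analysis.

``QCFrequencyModel`` holds the three inputs (QC measurement log, service log,
per-patient dose-metric table) together with the QC catalog, the tested
interval grid, and the numeric conventions; ``fit()`` estimates the S, O, D
indices for every failure mode FM(QC_m, D_n), classifies each (S, O) pair on
the 10x10 risk matrix, and returns a ``QCFrequencyResults`` carrying the rank
table, the per-item frequency recommendations, and reporting/plotting
helpers.

    >>> model = QCFrequencyModel.from_csv("qc_log.csv", "service_log.csv",
    ...                                   "dose_metrics.csv")
    >>> results = model.fit()
    >>> print(results.summary())
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import pandas as pd

from . import records
from .records import (
    DEFAULT_CATALOG,
    DEFAULT_GRID,
    DoseMetricRecord,
    IntervalGrid,
    QCItem,
    QCMeasurement,
    ServiceEvent,
    ValidationError,
)
from .indices import (
    DetectionResult,
    OccurrenceResult,
    RankProfile,
    SeverityResult,
    detection_index,
    occurrence_index,
    rank_profile,
    severity_index,
)
from .matrix import (
    FrequencyRecommendation,
    RiskMatrix,
    build_risk_matrix,
    plot_rm_map,
    recommend_frequency,
    render_rm_map,
)
from .evaluation import ScheduleComparison, ScheduleEvaluation, compare_schedules

__all__ = ["QCFrequencyModel", "QCFrequencyResults"]


class QCFrequencyModel:
    """Risk-matrix QC-frequency analysis of one machine's records.

    Parameters
    ----------
    measurements, events, dose_metrics
        The validated record lists (see :mod:`qcrisk.records`).
    catalog, grid
        The QC-item catalog and the tested interval grid.
    period_days
        Observation period in days. Defaults to the span of the QC log
        (first to last measurement date, inclusive).
    aggregation
        How a patient's PTV and cord severity ranks combine:
        ``max_of_criteria`` (default, worst case), ``ptv_only``, ``cord_only``.
    pooling
        Cohort pooling of severity: ``mean_of_ranks`` (default) or
        ``rank_of_means``.
    rounding
        How fractional severity indices become integer ranks: ``nearest``
        (default, half away from zero), ``floor``, or ``ceiling``.
    """

    def __init__(
        self,
        measurements: Sequence[QCMeasurement],
        events: Sequence[ServiceEvent],
        dose_metrics: Sequence[DoseMetricRecord],
        catalog: Sequence[QCItem] = DEFAULT_CATALOG,
        grid: IntervalGrid = DEFAULT_GRID,
        period_days: int | None = None,
        aggregation: str = "max_of_criteria",
        pooling: str = "mean_of_ranks",
        rounding: str = "nearest",
    ) -> None:
        self.measurements = list(measurements)
        self.events = list(events)
        self.dose_metrics = list(dose_metrics)
        self.catalog = tuple(catalog)
        records.catalog_by_id(self.catalog)  # uniqueness check
        self.grid = grid
        if period_days is None:
            if not self.measurements:
                raise ValidationError(
                    "period_days must be given when the QC log is empty"
                )
            dates = [m.date for m in self.measurements]
            period_days = (max(dates) - min(dates)).days + 1
        if period_days <= 0:
            raise ValidationError(f"period_days must be positive, got {period_days}")
        self.period_days = int(period_days)
        self.aggregation = aggregation
        self.pooling = pooling
        self.rounding = rounding

    @classmethod
    def from_csv(
        cls,
        qc_log: str | Path,
        service_log: str | Path,
        dose_metrics: str | Path,
        catalog: Sequence[QCItem] = DEFAULT_CATALOG,
        grid: IntervalGrid = DEFAULT_GRID,
        **kwargs,
    ) -> "QCFrequencyModel":
        return cls(
            records.read_qc_log(qc_log, catalog),
            records.read_service_log(service_log, catalog),
            records.read_dose_metrics(dose_metrics, catalog, grid),
            catalog=catalog,
            grid=grid,
            **kwargs,
        )

    @classmethod
    def from_dataframes(
        cls,
        qc_log: pd.DataFrame,
        service_log: pd.DataFrame,
        dose_metrics: pd.DataFrame,
        catalog: Sequence[QCItem] = DEFAULT_CATALOG,
        grid: IntervalGrid = DEFAULT_GRID,
        **kwargs,
    ) -> "QCFrequencyModel":
        return cls(
            records.qc_log_from_frame(qc_log, catalog),
            records.service_log_from_frame(service_log, catalog),
            records.dose_metrics_from_frame(dose_metrics, catalog, grid),
            catalog=catalog,
            grid=grid,
            **kwargs,
        )

    def fit(self) -> "QCFrequencyResults":
        """Estimate all indices, classify every failure mode, and recommend intervals."""
        matrix = build_risk_matrix()
        occurrence: dict[int, OccurrenceResult] = {}
        detection: dict[int, DetectionResult] = {}
        severity: dict[tuple[int, int], SeverityResult] = {}
        profiles: list[RankProfile] = []
        recommendations: dict[int, FrequencyRecommendation] = {}
        for item in self.catalog:
            occ = occurrence_index(
                self.measurements, item, self.period_days, service=self.events
            )
            det = detection_index(self.events, item, self.period_days)
            occurrence[item.item_id] = occ
            detection[item.item_id] = det
            item_profiles = []
            for interval in self.grid:
                sev = severity_index(
                    self.dose_metrics,
                    item,
                    interval,
                    aggregation=self.aggregation,
                    pooling=self.pooling,
                )
                severity[(item.item_id, interval)] = sev
                item_profiles.append(
                    rank_profile(item, interval, sev, occ, det, rounding=self.rounding)
                )
            profiles.extend(item_profiles)
            recommendations[item.item_id] = recommend_frequency(
                item, item_profiles, matrix, self.grid
            )
        return QCFrequencyResults(
            model=self,
            matrix=matrix,
            occurrence=occurrence,
            detection=detection,
            severity=severity,
            profiles=tuple(profiles),
            recommendations=recommendations,
        )


@dataclasses.dataclass(frozen=True)
class QCFrequencyResults:
    """Fitted indices, risk classifications, and frequency recommendations."""

    model: QCFrequencyModel
    matrix: RiskMatrix
    occurrence: dict[int, OccurrenceResult]
    detection: dict[int, DetectionResult]
    severity: dict[tuple[int, int], SeverityResult]
    profiles: tuple[RankProfile, ...]
    recommendations: dict[int, FrequencyRecommendation]

    def rank_table(self) -> pd.DataFrame:
        """Mean severity index per item and interval, with O and D ranks."""
        grid = self.model.grid
        rows = []
        for item in self.model.catalog:
            row: dict[str, object] = {"item_id": item.item_id, "name": item.name}
            for interval in grid:
                row[f"S_{grid.label(interval)}"] = round(
                    self.severity[(item.item_id, interval)].mean_rank, 3
                )
            row["O"] = self.occurrence[item.item_id].rank
            row["D"] = self.detection[item.item_id].rank
            rows.append(row)
        return pd.DataFrame(rows).set_index("item_id")

    def recommendations_table(self) -> pd.DataFrame:
        grid = self.model.grid
        rows = []
        for item in self.model.catalog:
            rec = self.recommendations[item.item_id]
            rows.append(
                {
                    "item_id": item.item_id,
                    "name": item.name,
                    "recommended_interval_days": rec.recommended_interval_days,
                    "recommended_label": grid.label(rec.recommended_interval_days),
                    "rule": rec.rule_applied,
                    "candidates": " ".join(grid.label(i) for i in rec.candidates),
                }
            )
        return pd.DataFrame(rows).set_index("item_id")

    def risk_trace(self) -> pd.DataFrame:
        """One row per failure mode: item, interval, S, O, D, level, recommended."""
        by_key = {(p.item_id, p.interval_days): p for p in self.profiles}
        rows = []
        for item in self.model.catalog:
            rec = self.recommendations[item.item_id]
            for interval, level in rec.per_interval_levels:
                p = by_key[(item.item_id, interval)]
                rows.append(
                    {
                        "item_id": item.item_id,
                        "interval_days": interval,
                        "S": p.S,
                        "O": p.O,
                        "D": p.D,
                        "level": level.label,
                        "recommended": interval == rec.recommended_interval_days,
                    }
                )
        return pd.DataFrame(rows)

    def schedule_evaluations(
        self, label: str, schedule: Mapping[int, int] | None = None
    ) -> list[ScheduleEvaluation]:
        """Per-item (O, D, E) evaluations under the fitted ranks.

        ``schedule`` (item_id -> interval days) defaults to the recommended
        intervals; it only annotates which schedule is being evaluated — O
        and D ranks always come from the fitted records of that schedule's
        observation window.
        """
        return [
            ScheduleEvaluation(
                item.item_id,
                label,
                self.occurrence[item.item_id].rank,
                self.detection[item.item_id].rank,
            )
            for item in self.model.catalog
        ]

    def compare_to(self, old: "QCFrequencyResults") -> ScheduleComparison:
        """E-metric comparison of this (new) analysis against an old one."""
        return compare_schedules(
            self.schedule_evaluations("new"), old.schedule_evaluations("old")
        )

    def render_risk_maps(self) -> str:
        return render_rm_map([self.recommendations[i.item_id] for i in self.model.catalog])

    def plot_risk_maps(self, path: str | Path) -> None:
        plot_rm_map([self.recommendations[i.item_id] for i in self.model.catalog], path)

    def summary(self) -> str:
        """Human-readable report: rank table, recommendations, matrix tally."""
        model = self.model
        counts = self.matrix.level_counts()
        lines = [
            "QC-frequency risk-matrix analysis",
            "=" * 70,
            f"items: {len(model.catalog)}   intervals tested: "
            + " ".join(model.grid.labels)
            + f"   period: {model.period_days} d",
            f"severity aggregation: {model.aggregation}   pooling: {model.pooling}"
            f"   rounding: {model.rounding}",
            "",
            "Mean severity index per interval, with O and D ranks",
            "-" * 70,
            self.rank_table().to_string(),
            "",
            "Recommended QC intervals",
            "-" * 70,
            self.recommendations_table().to_string(),
            "",
            f"risk matrix cells: {counts['low']} low / {counts['medium']} medium / "
            f"{counts['high']} high",
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write the report bundle (CSV tables + text map) to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rank_table": outdir / "rank_table.csv",
            "recommendations": outdir / "recommendations.csv",
            "risk_trace": outdir / "risk_trace.csv",
            "rm_map": outdir / "rm_map.txt",
        }
        self.rank_table().to_csv(paths["rank_table"])
        self.recommendations_table().to_csv(paths["recommendations"])
        self.risk_trace().to_csv(paths["risk_trace"], index=False)
        paths["rm_map"].write_text(self.render_risk_maps() + "\n")
        return paths
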