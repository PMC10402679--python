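"""Synthetic machine logs, service events, and dose-metric tables.

The generator emulates the data-generating reality behind a machine's QC and
service records so that every pipeline stage is testable without clinical
data, with exhaustive day-by-day ground truth alongside:

* failures arrive as a memoryless (exponential inter-arrival) process;
* once an item has failed, its deviation exceeds tolerance until repaired;
* QC tests at the configured interval flag a true exceedance with the
  configured sensitivity; a missed failure is discovered by service staff
  after a configured delay (or by a later QC test, whichever comes first);
* a discovered failure is repaired after a short fixed delay.

Days are consecutive operating days (day i maps to ``start_date + i``), so
calendar-date differences equal operating-day counts and the occurrence and
detection denominators are unambiguous. Failure rates are quoted per
operating year of 240 days (20 working days x 12 months), matching the
1.5 yr = 360 d bookkeeping of monthly machine QA programmes.

The dose-effect model behind the severity inputs is an explicit stand-in:
per-patient dose deviations grow with the QC interval as a configurable
power law with lognormal patient-to-patient variability. Real severity
tables come from a treatment planning system; the generator only reproduces
their qualitative shape (monotone growth with interval).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np

from .records import (
    DEFAULT_CATALOG,
    DEFAULT_GRID,
    DoseMetricRecord,
    IntervalGrid,
    QCItem,
    QCMeasurement,
    ServiceEvent,
    ValidationError,
    write_dose_metrics,
    write_qc_log,
    write_service_log,
)
from .indices import (
    TG100_TABLES,
    NEVER_FAILED_OCCURRENCE_RANK,
    RankProfile,
    rank_from_table,
    round_rank,
)

__all__ = [
    "WORKING_DAYS_PER_YEAR",
    "ScriptedFailure",
    "SimulationConfig",
    "DoseEffectModel",
    "DEFAULT_DOSE_MODELS",
    "simulate_machine_log",
    "simulate_dose_metrics",
    "observed_out_of_tolerance_days",
    "half_interval_quantity",
    "FixtureBundle",
    "end_to_end_fixture",
]

#: Operating days per year: 20 working days per month, 12 months.
WORKING_DAYS_PER_YEAR = 240


@dataclasses.dataclass(frozen=True)
class ScriptedFailure:
    """A deterministic failure episode overriding stochastic arrivals.

    ``onset_day`` is the operating-day index recorded as the failure onset
    (for a failure the QC test missed: the day of that last clean test);
    the failure is discovered on ``found_day`` and repaired on
    ``repaired_day`` (default: the day after discovery).
    """

    item_id: int
    onset_day: int
    found_day: int
    repaired_day: int | None = None
    found_by_qc: bool = False

    def __post_init__(self) -> None:
        repaired = self.repaired_day if self.repaired_day is not None else self.found_day + 1
        if not (0 <= self.onset_day <= self.found_day <= repaired):
            raise ValidationError(
                f"scripted failure for item {self.item_id}: need "
                f"0 <= onset <= found <= repaired"
            )


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters for the machine-log simulator.

    ``failure_rate`` is expected failures per 240-operating-day year, either a
    scalar applied to every item or a mapping item_id -> rate (absent items
    never fail). The default rate makes the first catalog item fail about
    once per 360 operating days — roughly one out-of-tolerance day per 1.5
    years under daily QC — while the remaining items never fail, the regime
    observed on a well-maintained machine where only the most exercised
    parameter (the gantry angle) ever drifts out of tolerance.
    """

    seed: int = 0
    period_days: int = 360
    items: tuple[QCItem, ...] = DEFAULT_CATALOG
    failure_rate: float | Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {1: 2.0 / 3.0}
    )
    drift_sd: float | Mapping[int, float] | None = None  # default: tolerance / 4
    repair_delay_days: int = 1
    service_delay_days: int = 6
    qc_interval_days: int = 1
    detection_sensitivity: float = 1.0
    start_date: dt.date = dt.date(2020, 6, 1)
    scripted_failures: tuple[ScriptedFailure, ...] = ()

    def __post_init__(self) -> None:
        if self.period_days < 1:
            raise ValidationError("period_days must be >= 1")
        if self.qc_interval_days < 1 or self.qc_interval_days > self.period_days:
            raise ValidationError("need 1 <= qc_interval_days <= period_days")
        if not 0.0 <= self.detection_sensitivity <= 1.0:
            raise ValidationError("detection_sensitivity must be in [0, 1]")
        rates = self._rates().values()
        if any(r < 0 for r in rates):
            raise ValidationError("failure rates must be >= 0")
        if self.repair_delay_days < 1 or self.service_delay_days < 0:
            raise ValidationError("delays must be non-negative (repair >= 1 day)")

    def _rates(self) -> dict[int, float]:
        if isinstance(self.failure_rate, Mapping):
            return {i.item_id: float(self.failure_rate.get(i.item_id, 0.0)) for i in self.items}
        return {i.item_id: float(self.failure_rate) for i in self.items}

    def _drift(self, item: QCItem) -> float:
        if self.drift_sd is None:
            return item.tolerance_value / 4.0
        if isinstance(self.drift_sd, Mapping):
            return float(self.drift_sd.get(item.item_id, item.tolerance_value / 4.0))
        return float(self.drift_sd)


def _date(config: SimulationConfig, day: int) -> dt.date:
    return config.start_date + dt.timedelta(days=day)


def _in_tolerance_draw(rng: np.random.Generator, tol: float, sd: float) -> float:
    return float(np.clip(rng.normal(0.0, sd), -tol, tol))


def _exceedance_draw(rng: np.random.Generator, tol: float) -> float:
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return float(sign * tol * (1.2 + abs(rng.normal(0.0, 0.3))))


def simulate_machine_log(
    config: SimulationConfig,
) -> tuple[list[QCMeasurement], list[ServiceEvent], dict[int, dict[str, float]]]:
    """Simulate QC measurements and service events for every catalog item.

    Returns the measurement log, the service log, and per-item ground truth
    from exhaustive day-by-day bookkeeping of the latent machine state:
    ``out_of_tolerance_fraction`` (percent of the period the item was truly
    failed) and ``undetected_fraction`` (percent of the period a failure
    existed but had not yet been discovered), plus ``n_failures`` and
    ``ever_failed``.

    An item with scripted failures follows the script exactly (no stochastic
    arrivals for that item); QC tests during a scripted missed failure record
    clean-looking values, reproducing a detection miss.
    """
    rng = np.random.default_rng(config.seed)
    rates = config._rates()
    period = config.period_days
    interval = config.qc_interval_days
    # Run past the period so failures arising near its end are still resolved
    # (their events carry dates beyond the period; truth is tallied inside it).
    horizon = period + config.service_delay_days + config.repair_delay_days + interval + 1

    measurements: list[QCMeasurement] = []
    events: list[ServiceEvent] = []
    truth: dict[int, dict[str, float]] = {}

    for item in config.items:
        tol = item.tolerance_value
        sd = config._drift(item)
        p_day = rates[item.item_id] / WORKING_DAYS_PER_YEAR
        scripted = sorted(
            (f for f in config.scripted_failures if f.item_id == item.item_id),
            key=lambda f: f.onset_day,
        )
        scripted_mode = bool(scripted)
        script_iter = iter(scripted)
        next_script = next(script_iter, None)

        failed_since: int | None = None
        found_day: int | None = None
        repaired_day: int | None = None
        service_due: int | None = None
        missed_qc: int | None = None
        current: ScriptedFailure | None = None
        failed_days = 0
        undetected_days = 0
        n_failures = 0

        for t in range(horizon):
            # 1. repair completes at the start of the day
            if repaired_day is not None and t >= repaired_day:
                failed_since = found_day = repaired_day = None
                service_due = missed_qc = None
                current = None
            # 2. failure onset
            if failed_since is None and t < period:
                if scripted_mode:
                    if next_script is not None and t == next_script.onset_day:
                        current = next_script
                        next_script = next(script_iter, None)
                        failed_since = t
                        n_failures += 1
                elif p_day > 0 and rng.random() < p_day:
                    failed_since = t
                    service_due = t + config.service_delay_days
                    n_failures += 1
            # 3. QC test
            if t % interval == 0 and t < period:
                if failed_since is not None and found_day is None:
                    if current is not None:
                        detected = current.found_by_qc and t == current.found_day
                    else:
                        detected = rng.random() < config.detection_sensitivity
                    if detected:
                        found_day = t
                        repaired_day = (
                            current.repaired_day
                            if current is not None and current.repaired_day is not None
                            else t + config.repair_delay_days
                        )
                        value = _exceedance_draw(rng, tol)
                        events.append(
                            ServiceEvent(
                                item.item_id,
                                _date(config, failed_since),
                                _date(config, t),
                                _date(config, repaired_day),
                                True,
                            )
                        )
                    else:
                        value = _in_tolerance_draw(rng, tol, sd)
                        missed_qc = t
                elif failed_since is not None:
                    value = _exceedance_draw(rng, tol)  # known broken, awaiting repair
                else:
                    value = _in_tolerance_draw(rng, tol, sd)
                measurements.append(
                    QCMeasurement(_date(config, t), item.item_id, value, abs(value) <= tol)
                )
            # 4. discovery outside QC (service staff / scripted discovery)
            if failed_since is not None and found_day is None:
                due = current.found_day if current is not None else service_due
                if due is not None and t >= due:
                    found_day = t
                    repaired_day = (
                        current.repaired_day
                        if current is not None and current.repaired_day is not None
                        else t + config.repair_delay_days
                    )
                    onset_day = missed_qc if missed_qc is not None else failed_since
                    if current is not None:
                        onset_day = current.onset_day
                    events.append(
                        ServiceEvent(
                            item.item_id,
                            _date(config, onset_day),
                            _date(config, t),
                            _date(config, repaired_day),
                            current.found_by_qc if current is not None else False,
                        )
                    )
            # 5. ground-truth tallies inside the observation period
            if t < period and failed_since is not None:
                failed_days += 1
                if found_day is None:
                    undetected_days += 1

        truth[item.item_id] = {
            "out_of_tolerance_fraction": 100.0 * failed_days / period,
            "undetected_fraction": 100.0 * undetected_days / period,
            "n_failures": float(n_failures),
            "ever_failed": float(n_failures > 0),
        }

    events.sort(key=lambda e: (e.found_date, e.item_id, e.onset_date))
    return measurements, events, truth


@dataclasses.dataclass(frozen=True)
class DoseEffectModel:
    """Power-law interval scaling of dose perturbations with patient noise.

    ``base_ptv_effect`` (% PTV coverage change) and ``base_cord_effect``
    (cGy of maximum-cord-dose change) are the expected deltas at the shortest
    tested interval; expected deltas grow as
    ``base * (interval / shortest) ** interval_scaling_exponent`` and each
    patient draw is multiplied by a mean-one lognormal factor with
    coefficient of variation ``patient_variability_cv``.
    """

    base_ptv_effect: float = 1.0
    base_cord_effect: float = 45.0
    interval_scaling_exponent: float = 0.7
    patient_variability_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.base_ptv_effect < 0 or self.base_cord_effect < 0:
            raise ValidationError("dose effects must be >= 0")
        if self.patient_variability_cv < 0:
            raise ValidationError("patient_variability_cv must be >= 0")


#: Default per-item dose-effect models: cohort-mean rank traces climb from
#: ~1 at daily testing to ~8 at bimonthly, the shape seen in machine QA data.
DEFAULT_DOSE_MODELS: dict[int, DoseEffectModel] = {
    item.item_id: DoseEffectModel() for item in DEFAULT_CATALOG
}


def simulate_dose_metrics(
    models: Mapping[int, DoseEffectModel],
    grid: IntervalGrid,
    n_patients: int,
    seed: int,
) -> list[DoseMetricRecord]:
    """Draw per-patient dose-perturbation magnitudes for every item and interval."""
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    shortest = grid.intervals[0]
    records: list[DoseMetricRecord] = []
    for item_id in sorted(models):
        model = models[item_id]
        cv = model.patient_variability_cv
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        mu = -0.5 * sigma * sigma
        for p in range(1, n_patients + 1):
            for interval in grid:
                scale = (interval / shortest) ** model.interval_scaling_exponent
                ptv = model.base_ptv_effect * scale * math.exp(rng.normal(mu, sigma))
                cord = model.base_cord_effect * scale * math.exp(rng.normal(mu, sigma))
                records.append(
                    DoseMetricRecord(f"P{p:02d}", item_id, interval, ptv, cord)
                )
    return records


def observed_out_of_tolerance_days(
    measurements: Sequence[QCMeasurement],
    events: Sequence[ServiceEvent],
    item_id: int,
    start: dt.date,
    period_days: int,
) -> int:
    """Brute-force day-by-day count of observed out-of-tolerance days.

    Walks every calendar day of the window, switching state on each recorded
    measurement (failing record -> failed, passing record -> clear) and on
    repair dates. Serves as the independent oracle for the occurrence
    estimator's span arithmetic.
    """
    by_date = {m.date: m for m in measurements if m.item_id == item_id}
    repair_dates = {e.repaired_date for e in events if e.item_id == item_id}
    bad = False
    count = 0
    day = start
    for _ in range(period_days):
        if day in by_date:
            bad = not by_date[day].within_tolerance
        elif bad and day in repair_dates:
            bad = False
        if bad:
            count += 1
        day += dt.timedelta(days=1)
    return count


def half_interval_quantity(
    events: Sequence[ServiceEvent], item_id: int, period_days: int
) -> float:
    """Hand-summed undetected-duration percentage over missed failures."""
    total = sum(
        (e.found_date - e.onset_date).days / 2.0
        for e in events
        if e.item_id == item_id and not e.found_by_qc
    )
    return 100.0 * total / period_days


@dataclasses.dataclass(frozen=True)
class FixtureBundle:
    """A self-consistent synthetic dataset with its expected analysis results."""

    config: SimulationConfig
    measurements: tuple[QCMeasurement, ...]
    events: tuple[ServiceEvent, ...]
    dose_metrics: tuple[DoseMetricRecord, ...]
    ground_truth: dict[int, dict[str, float]]
    expected_occurrence: dict[int, tuple[float, int]]  # item -> (quantity %, rank)
    expected_detection: dict[int, tuple[float, int]]
    expected_profiles: tuple[RankProfile, ...]
    paths: dict[str, Path] = dataclasses.field(default_factory=dict)


def end_to_end_fixture(
    seed: int,
    outdir: str | Path | None = None,
    n_patients: int = 10,
    config: SimulationConfig | None = None,
    dose_models: Mapping[int, DoseEffectModel] = DEFAULT_DOSE_MODELS,
) -> FixtureBundle:
    """Generate the three input files plus their expected rank profiles.

    Expected occurrence/detection quantities come from the brute-force
    observed-record oracles above (day-by-day walk and hand half-interval
    summation), not from the estimators; expected severity means are the
    cohort means of per-patient worst-criterion ranks. Identical seeds give
    byte-identical files.
    """
    config = config if config is not None else SimulationConfig(seed=seed)
    measurements, events, truth = simulate_machine_log(config)
    dose = simulate_dose_metrics(dose_models, DEFAULT_GRID, n_patients, seed + 1)

    start = config.start_date
    period = config.period_days
    expected_occurrence: dict[int, tuple[float, int]] = {}
    expected_detection: dict[int, tuple[float, int]] = {}
    profiles: list[RankProfile] = []
    for item in config.items:
        bad_days = observed_out_of_tolerance_days(
            measurements, events, item.item_id, start, period
        )
        o_quantity = 100.0 * bad_days / period
        ever = any(
            not m.within_tolerance for m in measurements if m.item_id == item.item_id
        )
        o_rank = (
            rank_from_table(o_quantity, TG100_TABLES["occurrence"])
            if ever
            else NEVER_FAILED_OCCURRENCE_RANK
        )
        expected_occurrence[item.item_id] = (o_quantity, o_rank)
        d_quantity = half_interval_quantity(events, item.item_id, period)
        d_rank = rank_from_table(d_quantity, TG100_TABLES["detection"])
        expected_detection[item.item_id] = (d_quantity, d_rank)
        for interval in DEFAULT_GRID:
            per_patient = [
                max(
                    rank_from_table(r.delta_ptv_pct, TG100_TABLES["severity_ptv"]),
                    rank_from_table(r.delta_cord_cgy, TG100_TABLES["severity_cord"]),
                )
                for r in dose
                if r.item_id == item.item_id and r.interval_days == interval
            ]
            mean_rank = sum(per_patient) / len(per_patient)
            profiles.append(
                RankProfile(item.item_id, interval, round_rank(mean_rank), o_rank, d_rank)
            )

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths["qc_log"] = outdir / "qc_log.csv"
        paths["service_log"] = outdir / "service_log.csv"
        paths["dose_metrics"] = outdir / "dose_metrics.csv"
        paths["ground_truth"] = outdir / "ground_truth.json"
        write_qc_log(measurements, paths["qc_log"])
        write_service_log(events, paths["service_log"])
        write_dose_metrics(dose, paths["dose_metrics"])
        payload = {
            "seed": config.seed,
            "period_days": period,
            "start_date": start.isoformat(),
            "items": {str(k): v for k, v in sorted(truth.items())},
        }
        paths["ground_truth"].write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    return FixtureBundle(
        config,
        tuple(measurements),
        tuple(events),
        tuple(dose),
        truth,
        expected_occurrence,
        expected_detection,
        tuple(profiles),
        paths,
    )
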