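import pytest
from hypothesis import given
from hypothesis import strategies as st

from qcrisk.indices import (
    TG100_TABLES,
    RankTable,
    rank_from_table,
    occurrence_index,
    detection_index,
    severity_index,
    rank_profile,
    round_rank,
    SeverityResult,
    OccurrenceResult,
    DetectionResult,
)
from qcrisk.records import DoseMetricRecord, ServiceEvent, ValidationError
from qcrisk.simulate import observed_out_of_tolerance_days

from conftest import DAY0, day, measurement


class TestRankFromTable:
    @pytest.mark.parametrize(
        "quantity, criterion, expected",
        [
            (12.0, "severity_ptv", 7),       # exceeds 10, within 15
            (500.0, "severity_cord", 7),     # within the 675 cGy bound
            (0.01, "occurrence", 1),         # exact first boundary -> lower rank
            (6.0, "occurrence", 10),         # above the last bound
            (0.278, "occurrence", 6),
            (0.833, "detection", 4),
            (15.0, "severity_ptv", 7),       # boundary inclusive
            (15.001, "severity_ptv", 8),
            (0.0, "detection", 1),
        ],
    )
    def test_threshold_mapping(self, quantity, criterion, expected):
        assert rank_from_table(quantity, TG100_TABLES[criterion]) == expected

    def test_negative_quantity_rejected(self):
        with pytest.raises(ValidationError):
            rank_from_table(-0.1, TG100_TABLES["occurrence"])

    def test_malformed_table_rejected(self):
        with pytest.raises(ValidationError):
            RankTable("occurrence", (1, 2, 3))
        with pytest.raises(ValidationError):
            RankTable("occurrence", (1, 2, 2, 3, 4, 5, 6, 7, 8))

    @pytest.mark.parametrize("criterion", sorted(TG100_TABLES))
    @given(a=st.floats(0, 60), b=st.floats(0, 60))
    def test_monotone_in_quantity(self, criterion, a, b):
        table = TG100_TABLES[criterion]
        lo, hi = sorted((a, b))
        assert rank_from_table(lo, table) <= rank_from_table(hi, table)


class TestOccurrenceIndex:
    def test_single_bad_day_in_360(self, gantry):
        """One out-of-tolerance day over 360 gives 0.278% and rank 6."""
        log = [
            measurement(0, gantry, 0.05),
            measurement(100, gantry, 0.30),
            measurement(101, gantry, 0.02),
            measurement(359, gantry, 0.01),
        ]
        result = occurrence_index(log, gantry, 360)
        assert result.quantity == pytest.approx(100.0 / 360, abs=5e-4)
        assert result.ever_failed
        assert result.rank == 6

    def test_never_failed_gets_rank_two(self, gantry):
        log = [measurement(i, gantry, 0.0) for i in range(0, 360, 30)]
        result = occurrence_index(log, gantry, 360)
        assert result == OccurrenceResult(gantry.item_id, 0.0, False, 2)

    def test_empty_log_gets_rank_two(self, gantry):
        assert occurrence_index([], gantry, 360).rank == 2

    def test_half_period_out_of_tolerance(self, gantry):
        log = [
            measurement(0, gantry, 0.5),
            measurement(180, gantry, 0.0),
            measurement(359, gantry, 0.0),
        ]
        result = occurrence_index(log, gantry, 360)
        assert result.quantity == pytest.approx(50.0)
        assert result.rank == 10

    def test_repair_ends_failed_state_before_next_measurement(self, gantry):
        # bad at day 10; repaired day 13; next (clean) measurement day 20
        log = [
            measurement(0, gantry, 0.0),
            measurement(10, gantry, 0.4),
            measurement(20, gantry, 0.0),
            measurement(29, gantry, 0.0),
        ]
        events = [ServiceEvent(1, day(10), day(12), day(13), True)]
        result = occurrence_index(log, gantry, 30, service=events)
        assert result.quantity == pytest.approx(100.0 * 3 / 30)

    def test_log_beyond_period_rejected(self, gantry):
        log = [measurement(0, gantry, 0.0), measurement(400, gantry, 0.0)]
        with pytest.raises(ValidationError, match="period"):
            occurrence_index(log, gantry, 360)

    @given(flags=st.lists(st.booleans(), min_size=1, max_size=40))
    def test_matches_day_by_day_oracle(self, gantry, flags):
        """Span arithmetic equals a brute-force daily walk on random logs."""
        tol = gantry.tolerance_value
        log = [
            measurement(i, gantry, 0.0 if ok else 2 * tol) for i, ok in enumerate(flags)
        ]
        period = len(flags)
        result = occurrence_index(log, gantry, period)
        oracle_days = observed_out_of_tolerance_days(log, [], gantry.item_id, DAY0, period)
        assert result.quantity == pytest.approx(100.0 * oracle_days / period)


class TestDetectionIndex:
    def test_missed_failure_half_interval(self, gantry):
        """Clean QC day 100, discovery day 106: 3 undetected days, 0.833%, rank 4."""
        events = [ServiceEvent(1, day(100), day(106), day(107), False)]
        result = detection_index(events, gantry, 360)
        assert result.quantity == pytest.approx(100.0 * 3 / 360)
        assert result.rank == 4

    def test_no_events_is_rank_one(self, gantry):
        assert detection_index([], gantry, 360) == DetectionResult(1, 0.0, 1, None)

    def test_failure_found_by_qc_contributes_nothing(self, gantry):
        events = [ServiceEvent(1, day(100), day(106), day(107), True)]
        assert detection_index(events, gantry, 360).quantity == 0.0

    def test_contributions_sum_over_missed_failures(self, gantry):
        # hand enumeration: (6 + 10)/2 = 8 undetected days over 360
        events = [
            ServiceEvent(1, day(50), day(56), day(57), False),
            ServiceEvent(1, day(200), day(210), day(211), False),
            ServiceEvent(1, day(300), day(302), day(303), True),
            ServiceEvent(2, day(40), day(48), day(49), False),  # other item
        ]
        result = detection_index(events, gantry, 360)
        assert result.quantity == pytest.approx(100.0 * 8 / 360)
        assert result.rank == 6  # 2.22% is within the 5% bound


def dose(item_id, interval, ptv, cord, patient="P01"):
    return DoseMetricRecord(patient, item_id, interval, ptv, cord)


class TestSeverityIndex:
    def test_mean_of_ranks_is_arithmetic_mean(self, gantry):
        # per-patient combined ranks 1, 1, 1, 2
        rows = [
            dose(1, 7, 0.5, 10.0, "P01"),
            dose(1, 7, 0.9, 20.0, "P02"),
            dose(1, 7, 0.2, 5.0, "P03"),
            dose(1, 7, 1.5, 30.0, "P04"),
        ]
        result = severity_index(rows, gantry, 7)
        assert result.per_patient_ranks == (1, 1, 1, 2)
        assert result.mean_rank == pytest.approx(1.25)

    def test_single_patient_below_first_bounds(self, gantry):
        result = severity_index([dose(1, 1, 0.5, 30.0)], gantry, 1)
        assert result.per_patient_ranks == (1,)
        assert result.mean_rank == 1.0

    def test_cohort_mean_fractional_rank(self, gantry):
        """One rank-2 and nineteen rank-3 patients pool to 2.95, matching the
        magnitude of published fractional severity indices."""
        rows = [dose(1, 7, 1.5, 10.0, "P01")]  # rank 2
        rows += [dose(1, 7, 2.5, 10.0, f"P{i:02d}") for i in range(2, 21)]  # rank 3
        result = severity_index(rows, gantry, 7)
        assert result.mean_rank == pytest.approx(2.95)

    def test_worst_criterion_aggregation_default(self, gantry):
        # PTV rank 1, cord rank 7 -> combined 7
        result = severity_index([dose(1, 1, 0.5, 500.0)], gantry, 1)
        assert result.per_patient_ranks == (7,)
        assert severity_index([dose(1, 1, 0.5, 500.0)], gantry, 1,
                              aggregation="ptv_only").per_patient_ranks == (1,)
        assert severity_index([dose(1, 1, 0.5, 500.0)], gantry, 1,
                              aggregation="cord_only").per_patient_ranks == (7,)

    def test_rank_of_means_pooling(self, gantry):
        # quantities 0.5 and 3.5 -> ranks 1 and 4, mean-of-ranks 2.5;
        # mean quantity 2.0 -> rank 2 under rank_of_means
        rows = [dose(1, 1, 0.5, 0.0, "P01"), dose(1, 1, 3.5, 0.0, "P02")]
        assert severity_index(rows, gantry, 1).mean_rank == pytest.approx(2.5)
        assert severity_index(rows, gantry, 1, pooling="rank_of_means").mean_rank == 2.0

    def test_missing_records_error_names_pair(self, gantry):
        with pytest.raises(ValidationError, match="item 1.*interval 30"):
            severity_index([dose(1, 7, 1.0, 10.0)], gantry, 30)

    @given(
        ranks_quantities=st.lists(
            st.sampled_from([(0.5, 1), (1.5, 2), (2.5, 3), (4.5, 5), (12.0, 7), (60.0, 10)]),
            min_size=1,
            max_size=12,
        )
    )
    def test_pooled_mean_bounded_by_patient_ranks(self, gantry, ranks_quantities):
        rows = [
            dose(1, 1, q, 0.0, f"P{i:02d}") for i, (q, _) in enumerate(ranks_quantities)
        ]
        expected = [r for _, r in ranks_quantities]
        result = severity_index(rows, gantry, 1)
        assert list(result.per_patient_ranks) == expected
        assert min(expected) <= result.mean_rank <= max(expected)


class TestRankProfile:
    @pytest.mark.parametrize(
        "mean, rounding, expected",
        [
            (2.950, "nearest", 3),
            (6.556, "floor", 6),
            (6.556, "nearest", 7),
            (2.5, "nearest", 3),  # half away from zero
            (1.0, "nearest", 1),
            (1.0, "floor", 1),
            (1.0, "ceiling", 1),
            (4.01, "ceiling", 5),
        ],
    )
    def test_rounding_modes(self, mean, rounding, expected):
        assert round_rank(mean, rounding) == expected

    def test_assembles_profile(self, gantry):
        S = SeverityResult(1, 7, (3, 3), 2.950, 3.0, 100.0)
        O = OccurrenceResult(1, 0.278, True, 6)
        D = DetectionResult(1, 0.833, 4)
        profile = rank_profile(gantry, 7, S, O, D)
        assert (profile.S, profile.O, profile.D) == (3, 6, 4)

    def test_item_mismatch_rejected(self, gantry):
        S = SeverityResult(2, 7, (1,), 1.0, 0.5, 10.0)
        O = OccurrenceResult(1, 0.0, False, 2)
        D = DetectionResult(1, 0.0, 1)
        with pytest.raises(ValidationError):
            rank_profile(gantry, 7, S, O, D)
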