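"""Schedule evaluation with the efficiency metric E = O/D.

E compares the occurrence rank of an item against its detection rank under a
given QC schedule: the higher E, the better the schedule detects the failures
that actually occur. Comparing E between an old and a proposed schedule says
whether the change improved failure detection (E up), left it unchanged, or
degraded it.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .records import ValidationError

__all__ = [
    "ScheduleEvaluation",
    "ScheduleComparison",
    "efficiency",
    "round_reported",
    "compare_schedules",
]


def _check_rank(name: str, rank: int) -> None:
    if not (isinstance(rank, int) and 1 <= rank <= 10):
        raise ValidationError(f"{name} rank must be an integer in 1-10, got {rank!r}")


def efficiency(O_rank: int, D_rank: int) -> float:
    """E = O/D from the integer occurrence and detection ranks."""
    _check_rank("O", O_rank)
    _check_rank("D", D_rank)
    return O_rank / D_rank


def round_reported(value: float, places: int = 2) -> float:
    """Round half away from zero for reporting (2/7 -> 0.29, 2/6 -> 0.33)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class ScheduleEvaluation:
    """O, D ranks and E for one item under one schedule ('new' or 'old')."""

    item_id: int
    label: str
    O_rank: int
    D_rank: int

    def __post_init__(self) -> None:
        _check_rank("O", self.O_rank)
        _check_rank("D", self.D_rank)

    @property
    def E(self) -> float:
        return efficiency(self.O_rank, self.D_rank)

    @property
    def E_reported(self) -> float:
        return round_reported(self.E)


@dataclasses.dataclass(frozen=True)
class ScheduleComparison:
    pairs: tuple[tuple[ScheduleEvaluation, ScheduleEvaluation], ...]  # (new, old)
    verdicts: dict[int, str]  # item_id -> improved | unchanged | worse

    @property
    def counts(self) -> dict[str, int]:
        out = {"improved": 0, "unchanged": 0, "worse": 0}
        for verdict in self.verdicts.values():
            out[verdict] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for new, old in self.pairs:
            rows.append(
                {
                    "item_id": new.item_id,
                    "O_new": new.O_rank,
                    "D_new": new.D_rank,
                    "E_new": new.E_reported,
                    "O_old": old.O_rank,
                    "D_old": old.D_rank,
                    "E_old": old.E_reported,
                    "verdict": self.verdicts[new.item_id],
                }
            )
        return pd.DataFrame(rows)


def compare_schedules(
    new: Sequence[ScheduleEvaluation], old: Sequence[ScheduleEvaluation]
) -> ScheduleComparison:
    """Per-item E comparison between a proposed and an existing schedule.

    Verdicts are decided exactly on the rank ratios by cross-multiplication,
    so 2/6 vs 2/7 compares as improved without float-equality judgement.
    """
    new_by_item = {e.item_id: e for e in new}
    old_by_item = {e.item_id: e for e in old}
    if len(new_by_item) != len(new) or len(old_by_item) != len(old):
        raise ValidationError("duplicate item in a schedule evaluation list")
    if set(new_by_item) != set(old_by_item):
        only = set(new_by_item) ^ set(old_by_item)
        raise ValidationError(f"items present on one side only: {sorted(only)}")
    pairs = []
    verdicts = {}
    for item_id in sorted(new_by_item):
        n, o = new_by_item[item_id], old_by_item[item_id]
        lhs = n.O_rank * o.D_rank  # E_new vs E_old without division
        rhs = o.O_rank * n.D_rank
        verdicts[item_id] = "improved" if lhs > rhs else ("unchanged" if lhs == rhs else "worse")
        pairs.append((n, o))
    return ScheduleComparison(tuple(pairs), verdicts)
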