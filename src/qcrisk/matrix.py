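"""The 10x10 severity-occurrence risk matrix and QC-frequency recommendation.

The matrix follows the AIAG/VDA FMEA handbook reference layout, extended to
the 10-point TG-100 severity and occurrence scales and amended so that
never-failing but potentially catastrophic items (O = 1 with S of 9 or 10)
are still flagged medium rather than low. The band rules, in order of
precedence:

1. S = 1 -> low (a harmless failure is low risk no matter how often).
2. O = 1 -> medium if S is 9 or 10, otherwise low.
3. S in 2-5: O+S in 9-10 -> medium, O+S in 11-15 -> high, otherwise low.
4. S in 6-10: O+S in 9-11 -> medium, O+S in 12-20 -> high, otherwise low.

A QC item tested over a grid of intervals yields one (S, O) cell per
interval; scanning from the shortest interval upward, the first interval
classified medium risk is the recommended test frequency — the longest
interval whose residual risk is still conditionally acceptable, balancing
risk against physicist effort.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

from .records import IntervalGrid, QCItem, ValidationError
from .indices import RankProfile

__all__ = [
    "RiskLevel",
    "RiskMatrix",
    "RankProfile",
    "FrequencyRecommendation",
    "classify_risk",
    "build_risk_matrix",
    "recommend_frequency",
    "format_matrix",
    "render_rm_map",
    "plot_rm_map",
]

logger = logging.getLogger(__name__)


class RiskLevel(enum.IntEnum):
    """Totally ordered risk level: low (green) < medium (yellow) < high (red)."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def color(self) -> str:
        return {"low": "green", "medium": "yellow", "high": "red"}[self.label]


def classify_risk(S: int, O: int) -> RiskLevel:
    """Classify one (S, O) cell by the band rules documented in the module."""
    for name, rank in (("S", S), ("O", O)):
        if not (isinstance(rank, int) and 1 <= rank <= 10):
            raise ValidationError(f"{name} rank must be an integer in 1-10, got {rank!r}")
    if S == 1:
        return RiskLevel.LOW
    if O == 1:
        return RiskLevel.MEDIUM if S >= 9 else RiskLevel.LOW
    total = O + S
    if 2 <= S <= 5:
        if 9 <= total <= 10:
            return RiskLevel.MEDIUM
        if 11 <= total <= 15:
            return RiskLevel.HIGH
        return RiskLevel.LOW
    if 9 <= total <= 11:
        return RiskLevel.MEDIUM
    if 12 <= total <= 20:
        return RiskLevel.HIGH
    return RiskLevel.LOW


@dataclasses.dataclass(frozen=True)
class RiskMatrix:
    """The full (S, O) -> level lookup over all 100 rank combinations."""

    cells: dict[tuple[int, int], RiskLevel]

    def __post_init__(self) -> None:
        expected = {(s, o) for s in range(1, 11) for o in range(1, 11)}
        if set(self.cells) != expected:
            raise ValidationError("risk matrix must assign exactly the 100 (S, O) cells")

    def __getitem__(self, key: tuple[int, int]) -> RiskLevel:
        return self.cells[key]

    def level_counts(self) -> dict[str, int]:
        counts = {level.label: 0 for level in RiskLevel}
        for level in self.cells.values():
            counts[level.label] += 1
        return counts


def build_risk_matrix() -> RiskMatrix:
    """Apply classify_risk to every (S, O) pair."""
    return RiskMatrix(
        {(s, o): classify_risk(s, o) for s in range(1, 11) for o in range(1, 11)}
    )


def format_matrix(matrix: RiskMatrix) -> str:
    """Render the matrix as text, O decreasing down the page, with a level tally."""
    letters = {RiskLevel.LOW: "L", RiskLevel.MEDIUM: "M", RiskLevel.HIGH: "H"}
    lines = ["O\\S  " + " ".join(f"{s:2d}" for s in range(1, 11))]
    for o in range(10, 0, -1):
        row = " ".join(f" {letters[matrix[(s, o)]]}" for s in range(1, 11))
        lines.append(f"{o:3d}  {row}")
    counts = matrix.level_counts()
    lines.append(
        f"low (L/green): {counts['low']}   medium (M/yellow): {counts['medium']}   "
        f"high (H/red): {counts['high']}"
    )
    return "\n".join(lines)


@dataclasses.dataclass(frozen=True)
class FrequencyRecommendation:
    """Recommended QC interval for one item, with its per-interval risk trace."""

    item_id: int
    per_interval_levels: tuple[tuple[int, RiskLevel], ...]
    recommended_interval_days: int
    candidates: tuple[int, ...]  # every tested interval not classified high
    rule_applied: str  # first_medium | longest_all_low | last_before_high
    profiles: tuple[RankProfile, ...] = ()


def recommend_frequency(
    item: QCItem,
    profiles: Sequence[RankProfile],
    matrix: RiskMatrix,
    grid: IntervalGrid | None = None,
) -> FrequencyRecommendation:
    """Pick the QC interval for one item from its per-interval rank profiles.

    Intervals are scanned from shortest to longest. The first interval
    classified medium is recommended (``first_medium``). If every interval is
    low, the longest tested interval is recommended (``longest_all_low``); if
    a high-risk interval appears before any medium one, the longest interval
    preceding it is recommended (``last_before_high``). An item already at
    high risk at the shortest tested interval needs escalation beyond the
    grid and raises an error.
    """
    profiles = sorted(
        (p for p in profiles if p.item_id == item.item_id), key=lambda p: p.interval_days
    )
    intervals = [p.interval_days for p in profiles]
    if len(set(intervals)) != len(intervals):
        raise ValidationError(f"item {item.item_id}: duplicate interval in profiles")
    if grid is not None and intervals != list(grid.intervals):
        raise ValidationError(
            f"item {item.item_id}: profiles cover intervals {intervals}, "
            f"expected the tested grid {list(grid.intervals)}"
        )
    if not profiles:
        raise ValidationError(f"item {item.item_id}: no rank profiles")
    if len({p.O for p in profiles}) > 1:
        raise ValidationError(
            f"item {item.item_id}: all failure modes of one item share one O rank"
        )

    levels = [(p.interval_days, matrix[(p.S, p.O)]) for p in profiles]
    values = [level for _, level in levels]
    if any(b < a for a, b in zip(values, values[1:])):
        logger.warning(
            "item %d: risk level is not monotone across intervals %s; "
            "recommendation follows scan order", item.item_id, intervals,
        )

    first_medium = next((i for i, lv in enumerate(values) if lv is RiskLevel.MEDIUM), None)
    first_high = next((i for i, lv in enumerate(values) if lv is RiskLevel.HIGH), None)
    if first_medium is not None and (first_high is None or first_medium < first_high):
        recommended, rule = intervals[first_medium], "first_medium"
    elif first_high is not None:
        if first_high == 0:
            raise ValidationError(
                f"item {item.item_id}: already high risk at the shortest tested "
                f"interval ({intervals[0]} d); escalation beyond the grid is needed"
            )
        recommended, rule = intervals[first_high - 1], "last_before_high"
    else:
        recommended, rule = intervals[-1], "longest_all_low"

    candidates = tuple(iv for iv, lv in levels if lv is not RiskLevel.HIGH)
    return FrequencyRecommendation(
        item.item_id, tuple(levels), recommended, candidates, rule, tuple(profiles)
    )


def render_rm_map(recommendations: Sequence[FrequencyRecommendation]) -> str:
    """Text rendering of the per-item risk-matrix maps (interval x S rank).

    One grid per item: rows are tested intervals (shortest at the top),
    columns are S ranks 1-10; each failure mode's cell is marked with its
    level letter and the recommended interval row is flagged with ``<-``.
    """
    if not recommendations:
        raise ValidationError("render_rm_map: no recommendations to render")
    letters = {RiskLevel.LOW: "L", RiskLevel.MEDIUM: "M", RiskLevel.HIGH: "H"}
    blocks = []
    for rec in recommendations:
        s_by_interval = {p.interval_days: p.S for p in rec.profiles}
        lines = [f"QC{rec.item_id}  (S rank 1-10 across; recommended {rec.recommended_interval_days} d,"
                 f" rule {rec.rule_applied})"]
        lines.append("  interval  " + " ".join(f"{s:2d}" for s in range(1, 11)))
        for interval, level in rec.per_interval_levels:
            cells = ["· "] * 10
            s = s_by_interval.get(interval)
            if s is not None:
                cells[s - 1] = f"{letters[level]} "
            marker = " <-" if interval == rec.recommended_interval_days else ""
            lines.append(f"  D{interval:<7d} " + " ".join(c.strip().ljust(2) for c in cells).rstrip() + marker)
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks)


def plot_rm_map(
    recommendations: Sequence[FrequencyRecommendation], path: str | Path
) -> None:
    """Write a PNG of the per-item risk maps, one panel per item."""
    if not recommendations:
        raise ValidationError("plot_rm_map: no recommendations to render")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    n = len(recommendations)
    ncols = min(3, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows), squeeze=False)
    for ax in axes.flat[n:]:
        ax.set_axis_off()
    for ax, rec in zip(axes.flat, recommendations):
        intervals = [iv for iv, _ in rec.per_interval_levels]
        s_by_interval = {p.interval_days: p.S for p in rec.profiles}
        for row, (interval, level) in enumerate(rec.per_interval_levels):
            s = s_by_interval[interval]
            ax.add_patch(
                Rectangle((s - 0.5, row - 0.5), 1, 1, facecolor=level.color,
                          edgecolor="black", alpha=0.8)
            )
        ax.set_xlim(0.5, 10.5)
        ax.set_ylim(len(intervals) - 0.5, -0.5)
        ax.set_xticks(range(1, 11))
        ax.set_yticks(range(len(intervals)))
        ax.set_yticklabels([f"D{iv}" for iv in intervals])
        ax.set_xlabel("S rank")
        ax.set_title(f"QC{rec.item_id} (recommended D{rec.recommended_interval_days})")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
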