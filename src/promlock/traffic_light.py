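"""Rule-based GREEN/YELLOW/RED classification of locked follow-up windows.

The classification combines three ingredients, in strict precedence order:

1. *Absolute state* — RED if any present metric is below its RED threshold
   (index < 0.75 or VAS < 50 by default); GREEN only if both metrics are
   present and both meet their GREEN thresholds (index >= 0.85 and
   VAS >= 70); otherwise YELLOW.  A single-metric window can therefore be
   RED or YELLOW but never GREEN.
2. *Meaningful change vs baseline* — per metric, where both the baseline and
   follow-up values exist: improvement is a change >= +MID in either metric,
   deterioration a change <= -MID in either metric (MID 0.03 index, 5 VAS).
   The two flags are not mutually exclusive.
3. *High baseline* — baseline index >= 0.90 and/or VAS >= 80, used both as a
   reporting stratifier for ceiling effects and in the downgrade rule.

Final color: absolute RED dominates; absolute GREEN is downgraded to YELLOW
when the episode meaningfully deteriorated from a high baseline; absolute
YELLOW escalates to RED on meaningful deterioration (configurable).
Episodes without a computable baseline pair keep their absolute state.

All threshold comparisons are exact at the instrument's native precision:
index values are compared as integer hundredths, VAS as integers, so no
floating-point tolerance enters the rule table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .window_engine import Timepoint

__all__ = [
    "Color",
    "Thresholds",
    "ChangeFlags",
    "TrafficLightResult",
    "absolute_state",
    "change_flags",
    "is_high_baseline",
    "final_traffic_light",
    "classify_followups",
]


class Color(str, Enum):
    RED = "RED"
    YELLOW = "YELLOW"
    GREEN = "GREEN"


#: RED < YELLOW < GREEN; used for monotonicity and trajectory comparisons.
COLOR_ORDER = {Color.RED: 0, Color.YELLOW: 1, Color.GREEN: 2}


@dataclass(frozen=True)
class Thresholds:
    index_red: float = 0.75
    index_green: float = 0.85
    vas_red: int = 50
    vas_green: int = 70
    mid_index: float = 0.03
    mid_vas: int = 5
    ceiling_index: float = 0.90
    ceiling_vas: int = 80

    def __post_init__(self) -> None:
        if not self.index_red < self.index_green:
            raise ValueError("index_red must be below index_green")
        if not self.vas_red < self.vas_green:
            raise ValueError("vas_red must be below vas_green")
        if self.mid_index <= 0 or self.mid_vas <= 0:
            raise ValueError("MID thresholds must be positive")


@dataclass(frozen=True)
class ChangeFlags:
    improved: bool
    deteriorated: bool
    computable: bool


@dataclass(frozen=True)
class TrafficLightResult:
    timepoint: Timepoint
    absolute: Color
    flags: ChangeFlags
    high_baseline: bool
    final: Color


def _cents(value: float | None) -> int | None:
    """Index utility as integer hundredths (the instrument's precision)."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return None
    return int(round(float(value) * 100))


def _vas_int(value: object) -> int | None:
    if value is None or value is pd.NA or (isinstance(value, float) and np.isnan(value)):
        return None
    return int(round(float(value)))


def absolute_state(index: float | None, vas: int | None, thr: Thresholds) -> Color:
    """Absolute health state from the metrics present in the window.

    Raises ValueError when both metrics are absent: the caller must restrict
    to evaluable windows.
    """
    ic, vc = _cents(index), _vas_int(vas)
    if ic is None and vc is None:
        raise ValueError("absolute_state requires at least one metric (evaluable window)")
    if (ic is not None and ic < _cents(thr.index_red)) or (vc is not None and vc < thr.vas_red):
        return Color.RED
    if ic is not None and vc is not None and ic >= _cents(thr.index_green) and vc >= thr.vas_green:
        return Color.GREEN
    return Color.YELLOW


def change_flags(
    base: tuple[float | None, int | None],
    follow: tuple[float | None, int | None],
    thr: Thresholds,
) -> ChangeFlags:
    """MID-based change flags over the metrics paired at both timepoints."""
    deltas: list[tuple[int, int]] = []  # (delta, mid) in scaled integer units
    b_ic, f_ic = _cents(base[0]), _cents(follow[0])
    if b_ic is not None and f_ic is not None:
        deltas.append((f_ic - b_ic, _cents(thr.mid_index)))
    b_v, f_v = _vas_int(base[1]), _vas_int(follow[1])
    if b_v is not None and f_v is not None:
        deltas.append((f_v - b_v, thr.mid_vas))
    if not deltas:
        return ChangeFlags(improved=False, deteriorated=False, computable=False)
    return ChangeFlags(
        improved=any(d >= mid for d, mid in deltas),
        deteriorated=any(d <= -mid for d, mid in deltas),
        computable=True,
    )


def is_high_baseline(base: tuple[float | None, int | None], thr: Thresholds) -> bool:
    """Ceiling stratifier: any present baseline metric at/above its ceiling."""
    ic, vc = _cents(base[0]), _vas_int(base[1])
    if ic is not None and ic >= _cents(thr.ceiling_index):
        return True
    if vc is not None and vc >= thr.ceiling_vas:
        return True
    return False


def final_traffic_light(
    absolute: Color,
    flags: ChangeFlags,
    high_baseline: bool,
    *,
    escalate_on_deterioration: bool = True,
) -> Color:
    """Combine absolute state, change flags and ceiling handling.

    ``escalate_on_deterioration`` controls the YELLOW -> RED escalation on
    meaningful deterioration; it is exposed because "transition toward an
    unacceptable state" admits stricter operationalizations.
    """
    if absolute is Color.RED:
        return Color.RED
    deteriorated = flags.computable and flags.deteriorated
    if absolute is Color.GREEN:
        return Color.YELLOW if (deteriorated and high_baseline) else Color.GREEN
    return Color.RED if (escalate_on_deterioration and deteriorated) else Color.YELLOW


TRAFFIC_COLUMNS = [
    "episode_id",
    "institution",
    "timepoint",
    "absolute",
    "improved",
    "deteriorated",
    "computable",
    "high_baseline",
    "final",
]


def classify_followups(
    assignments: pd.DataFrame,
    thr: Thresholds | None = None,
    *,
    escalate_on_deterioration: bool = True,
) -> pd.DataFrame:
    """Traffic-light results for every evaluable 12 m / 24 m window.

    ``assignments`` is the window-assignment table; baseline values are joined
    per episode to derive change flags and the high-baseline stratifier.
    """
    thr = thr or Thresholds()
    base_rows = assignments[
        (assignments["timepoint"] == Timepoint.BASELINE.value) & assignments["evaluable"]
    ]
    baselines: dict[object, tuple[float | None, int | None]] = {
        r.episode_id: (r.eq5d_index, r.eq_vas) for r in base_rows.itertuples(index=False)
    }

    rows: list[dict[str, object]] = []
    follow = assignments[
        assignments["timepoint"].isin([Timepoint.M12.value, Timepoint.M24.value])
        & assignments["evaluable"]
    ]
    for r in follow.itertuples(index=False):
        base = baselines.get(r.episode_id, (None, None))
        current = (r.eq5d_index, r.eq_vas)
        absolute = absolute_state(*current, thr)
        flags = change_flags(base, current, thr)
        high = is_high_baseline(base, thr)
        final = final_traffic_light(
            absolute, flags, high, escalate_on_deterioration=escalate_on_deterioration
        )
        rows.append(
            {
                "episode_id": r.episode_id,
                "institution": r.institution,
                "timepoint": r.timepoint,
                "absolute": absolute.value,
                "improved": flags.improved,
                "deteriorated": flags.deteriorated,
                "computable": flags.computable,
                "high_baseline": high,
                "final": final.value,
            }
        )
    return pd.DataFrame(rows, columns=TRAFFIC_COLUMNS)
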