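"""12 -> 24 month trajectory (stability) classes.

Episodes evaluable at both follow-up windows receive one of five classes.
The rules are evaluated in order and the first match wins:

1. PERSISTENT_LOW   — final RED at both timepoints;
2. STABLE_HIGH      — final GREEN at both and no meaningful deterioration
                      between 12 m and 24 m;
3. LATE_DECLINE     — meaningful deterioration without improvement, or a
                      worsening traffic-light color without improvement;
4. LATE_IMPROVEMENT — the mirror image of rule 3;
5. MIXED            — everything else (conflicting change flags, stable
                      non-extreme patterns).

Change flags between the two follow-ups use the same MID thresholds as the
change-from-baseline analysis.  Color ordering is RED < YELLOW < GREEN.
The rule order is load-bearing (e.g. a RED->RED episode that also improved
on a metric is still PERSISTENT_LOW) and is isolated behind
:func:`stability_class` so alternative rule sets can be swapped in.
"""

from __future__ import annotations

from enum import Enum

import pandas as pd

from .traffic_light import COLOR_ORDER, ChangeFlags, Color, Thresholds, change_flags
from .window_engine import Timepoint

__all__ = ["StabilityClass", "stability_class", "assign_stability"]


class StabilityClass(str, Enum):
    STABLE_HIGH = "STABLE_HIGH"
    LATE_DECLINE = "LATE_DECLINE"
    LATE_IMPROVEMENT = "LATE_IMPROVEMENT"
    PERSISTENT_LOW = "PERSISTENT_LOW"
    MIXED = "MIXED"


def stability_class(
    color12: Color,
    color24: Color,
    flags_12_24: ChangeFlags,
) -> StabilityClass:
    """Assign the trajectory class from the two final colors and the 12->24 m flags.

    When no metric is paired across the two follow-ups (``computable`` False,
    possible when the windows hold disjoint single metrics) both change flags
    are treated as False and the colors alone drive the class.
    """
    computable = flags_12_24.computable
    imp = computable and flags_12_24.improved
    det = computable and flags_12_24.deteriorated
    worsened = COLOR_ORDER[color24] < COLOR_ORDER[color12]
    improved_color = COLOR_ORDER[color24] > COLOR_ORDER[color12]

    if color12 is Color.RED and color24 is Color.RED:
        return StabilityClass.PERSISTENT_LOW
    if color12 is Color.GREEN and color24 is Color.GREEN and not det:
        return StabilityClass.STABLE_HIGH
    if (det and not imp) or (worsened and not imp):
        return StabilityClass.LATE_DECLINE
    if (imp and not det) or (improved_color and not det):
        return StabilityClass.LATE_IMPROVEMENT
    return StabilityClass.MIXED


STABILITY_COLUMNS = [
    "episode_id",
    "institution",
    "stability_class",
    "color12",
    "color24",
    "improved_12_24",
    "deteriorated_12_24",
]


def assign_stability(
    traffic: pd.DataFrame,
    assignments: pd.DataFrame,
    thr: Thresholds | None = None,
) -> pd.DataFrame:
    """Stability classes for all episodes with both 12 m and 24 m results.

    ``traffic`` is the traffic-light table and ``assignments`` the window
    table (used for the raw 12 m / 24 m values behind the change flags).
    """
    thr = thr or Thresholds()
    finals: dict[tuple[object, str], str] = {
        (r.episode_id, r.timepoint): r.final for r in traffic.itertuples(index=False)
    }
    values: dict[tuple[object, str], tuple[float | None, int | None]] = {
        (r.episode_id, r.timepoint): (r.eq5d_index, r.eq_vas)
        for r in assignments.itertuples(index=False)
        if r.evaluable
    }
    inst: dict[object, object] = dict(zip(traffic["episode_id"], traffic["institution"]))

    rows = []
    episode_order = list(dict.fromkeys(traffic["episode_id"]))
    for eid in episode_order:
        k12, k24 = (eid, Timepoint.M12.value), (eid, Timepoint.M24.value)
        if k12 not in finals or k24 not in finals:
            continue
        flags = change_flags(values[k12], values[k24], thr)
        cls = stability_class(Color(finals[k12]), Color(finals[k24]), flags)
        rows.append(
            {
                "episode_id": eid,
                "institution": inst[eid],
                "stability_class": cls.value,
                "color12": finals[k12],
                "color24": finals[k24],
                "improved_12_24": flags.improved,
                "deteriorated_12_24": flags.deteriorated,
            }
        )
    return pd.DataFrame(rows, columns=STABILITY_COLUMNS)
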