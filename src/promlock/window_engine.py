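"""Locked-window selection of PROM observations around the treatment anchor.

Each eligible episode contributes at most one observation per timepoint:

* baseline: day -90..+14 around T0 (preferring pre-treatment days <= 0),
  with a fallback window of +15..+90 flagged ``early_post_baseline``;
* 12 months: days 180..365, closest to the 270-day target;
* 24 months: days 660..820, closest to the 730-day target.

All bounds are inclusive.  An observation is selectable only if it carries at
least one of the two metrics (index and/or VAS); a window with such an
observation is *evaluable*.  Offsets are whole days (observation date minus
T0); day 0 counts as pre-treatment.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputValidationError

logger = logging.getLogger(__name__)


class Timepoint(str, Enum):
    BASELINE = "BASELINE"
    M12 = "M12"
    M24 = "M24"


@dataclass(frozen=True)
class WindowSpec:
    """Inclusive day-offset window with a selection target.

    ``fallback`` (baseline only) is a second inclusive window tried when the
    primary window holds no selectable observation.
    """

    name: Timepoint
    lower: int
    upper: int
    target: int
    fallback: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (self.lower <= self.target <= self.upper):
            raise ValueError(f"window {self.name}: lower <= target <= upper violated")


DEFAULT_WINDOWS: dict[Timepoint, WindowSpec] = {
    Timepoint.BASELINE: WindowSpec(Timepoint.BASELINE, -90, 14, 0, fallback=(15, 90)),
    Timepoint.M12: WindowSpec(Timepoint.M12, 180, 365, 270),
    Timepoint.M24: WindowSpec(Timepoint.M24, 660, 820, 730),
}


def select_in_window(
    candidates: Sequence[tuple[Any, int]],
    lower: int,
    upper: int,
    target: int,
) -> tuple[Any, int] | None:
    """Pick the observation closest to ``target`` within [lower, upper].

    ``candidates`` are ``(payload, day)`` pairs.  Ties in distance break to
    the smaller day.  Returns None when the window is empty.
    """
    in_window = [(obs, day) for obs, day in candidates if lower <= day <= upper]
    if not in_window:
        return None
    return min(in_window, key=lambda item: (abs(item[1] - target), item[1]))


def select_baseline(
    candidates: Sequence[tuple[Any, int]],
    spec: WindowSpec,
) -> tuple[tuple[Any, int] | None, bool]:
    """Two-step baseline selection.

    Step 1, within the preferred window: if any pre-treatment observation
    (day <= 0) exists, take the one closest to T0 (largest day <= 0);
    otherwise take the post-treatment observation closest to T0 (smallest
    day >= 1).  Step 2, only if step 1 found nothing: take the earliest
    observation in the fallback window and flag it early-post.
    """
    preferred = [(obs, day) for obs, day in candidates if spec.lower <= day <= spec.upper]
    pre = [(obs, day) for obs, day in preferred if day <= 0]
    if pre:
        return max(pre, key=lambda item: item[1]), False
    if preferred:
        return min(preferred, key=lambda item: item[1]), False
    if spec.fallback is not None:
        lo, hi = spec.fallback
        late = [(obs, day) for obs, day in candidates if lo <= day <= hi]
        if late:
            return min(late, key=lambda item: item[1]), True
    return None, False


def _is_missing(value: object) -> bool:
    return value is None or value is pd.NA or (isinstance(value, float) and np.isnan(value))


def _parse_obs_date(value: object, row_id: object, bad: list[str]) -> dt.date | None:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = "" if _is_missing(value) else str(value).strip()
    if not text:
        bad.append(f"row for episode {row_id!r} has empty obs_date")
        return None
    try:
        return dt.date.fromisoformat(text)
    except ValueError:
        bad.append(f"episode {row_id!r}: unparseable obs_date {value!r}")
        return None


def _metric(value: object) -> float | None:
    if _is_missing(value):
        return None
    text = str(value).strip()
    if not text:
        return None
    return float(text)


ASSIGNMENT_COLUMNS = [
    "episode_id",
    "institution",
    "timepoint",
    "obs_date",
    "offset_days",
    "eq5d_index",
    "eq_vas",
    "early_post_baseline",
    "evaluable",
]


def assign_windows(
    cohort: pd.DataFrame,
    observations: pd.DataFrame,
    specs: Mapping[Timepoint, WindowSpec] | None = None,
) -> pd.DataFrame:
    """One row per eligible episode x timepoint with the selected observation.

    Observations referencing unknown episodes are logged and ignored.
    Observations with both metrics missing are never selectable.  When several
    selectable observations share a day, the one with more non-missing metrics
    wins, then the first by input order (logged).
    """
    specs = dict(specs or DEFAULT_WINDOWS)
    for col in ("episode_id", "obs_date"):
        if col not in observations.columns:
            raise InputValidationError(f"observations table is missing column {col!r}")

    t0_by_episode: dict[object, dt.date] = dict(zip(cohort["episode_id"], cohort["t0"]))
    inst_by_episode: dict[object, object] = dict(zip(cohort["episode_id"], cohort["institution"]))

    # (day -> record) per episode, after validity filtering and same-day dedup
    per_episode: dict[object, dict[int, dict[str, object]]] = {eid: {} for eid in t0_by_episode}
    bad_dates: list[str] = []
    n_unknown = 0
    for order, row in enumerate(observations.itertuples(index=False)):
        eid = row.episode_id
        if eid not in per_episode:
            n_unknown += 1
            continue
        date = _parse_obs_date(row.obs_date, eid, bad_dates)
        if date is None:
            continue
        index = _metric(getattr(row, "eq5d_index", None))
        vas = _metric(getattr(row, "eq_vas", None))
        if index is None and vas is None:
            continue  # not a valid observation; never selectable
        day = (date - t0_by_episode[eid]).days
        record = {
            "obs_date": date,
            "eq5d_index": index,
            "eq_vas": int(round(vas)) if vas is not None else None,
            "n_metrics": (index is not None) + (vas is not None),
            "order": order,
        }
        held = per_episode[eid].get(day)
        if held is None:
            per_episode[eid][day] = record
        else:
            keep_new = (record["n_metrics"], -record["order"]) > (held["n_metrics"], -held["order"])
            logger.info(
                "episode %r: duplicate observations on day %d; keeping %s by (metrics, input order)",
                eid,
                day,
                "newer" if keep_new else "earlier",
            )
            if keep_new:
                per_episode[eid][day] = record
    if bad_dates:
        raise InputValidationError("invalid observation dates: " + "; ".join(bad_dates))
    if n_unknown:
        logger.warning("ignored %d observations referencing unknown episode ids", n_unknown)

    rows: list[dict[str, object]] = []
    for eid, days in per_episode.items():
        candidates = [(rec, day) for day, rec in sorted(days.items())]
        for tp, spec in specs.items():
            if tp is Timepoint.BASELINE:
                chosen, early = select_baseline(candidates, spec)
            else:
                chosen, early = select_in_window(candidates, spec.lower, spec.upper, spec.target), False
            row: dict[str, object] = {
                "episode_id": eid,
                "institution": inst_by_episode[eid],
                "timepoint": tp.value,
                "obs_date": None,
                "offset_days": pd.NA,
                "eq5d_index": np.nan,
                "eq_vas": pd.NA,
                "early_post_baseline": early,
                "evaluable": chosen is not None,
            }
            if chosen is not None:
                rec, day = chosen
                row.update(
                    obs_date=rec["obs_date"],
                    offset_days=day,
                    eq5d_index=rec["eq5d_index"] if rec["eq5d_index"] is not None else np.nan,
                    eq_vas=rec["eq_vas"] if rec["eq_vas"] is not None else pd.NA,
                )
            rows.append(row)

    out = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    out["offset_days"] = out["offset_days"].astype("Int64")
    out["eq_vas"] = out["eq_vas"].astype("Int64")
    out["eq5d_index"] = out["eq5d_index"].astype(float)
    out["early_post_baseline"] = out["early_post_baseline"].astype(bool)
    out["evaluable"] = out["evaluable"].astype(bool)
    return out


OVERALL = "OVERALL"


def evaluability_table(assignments: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Evaluable counts/percentages and offset summaries by institution x timepoint.

    Denominators are always the full eligible cohort of the institution; the
    early-post-baseline rate shares that denominator (baseline rows only).
    Percentages are rounded to 2 decimals.
    """
    institutions = list(pd.unique(cohort["institution"]))
    groups: list[tuple[str, pd.Series]] = [
        (inst, cohort["institution"] == inst) for inst in institutions
    ]
    groups.append((OVERALL, pd.Series(True, index=cohort.index)))

    rows = []
    for inst, mask in groups:
        n_eligible = int(mask.sum())
        eligible_ids = set(cohort.loc[mask, "episode_id"])
        sub = assignments[assignments["episode_id"].isin(eligible_ids)]
        for tp in (Timepoint.BASELINE, Timepoint.M12, Timepoint.M24):
            tp_rows = sub[sub["timepoint"] == tp.value]
            ev = tp_rows[tp_rows["evaluable"]]
            offsets = ev["offset_days"].dropna().astype(int).to_numpy()
            row: dict[str, object] = {
                "institution": inst,
                "timepoint": tp.value,
                "n_eligible": n_eligible,
                "n_evaluable": int(len(ev)),
                "pct_evaluable": round(100.0 * len(ev) / n_eligible, 2) if n_eligible else np.nan,
                "offset_median": float(np.median(offsets)) if offsets.size else np.nan,
                "offset_q1": float(np.quantile(offsets, 0.25)) if offsets.size else np.nan,
                "offset_q3": float(np.quantile(offsets, 0.75)) if offsets.size else np.nan,
            }
            if tp is Timepoint.BASELINE:
                n_early = int(ev["early_post_baseline"].sum())
                row["n_early_post"] = n_early
                row["pct_early_post"] = (
                    round(100.0 * n_early / n_eligible, 2) if n_eligible else np.nan
                )
            else:
                row["n_early_post"] = pd.NA
                row["pct_early_post"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
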