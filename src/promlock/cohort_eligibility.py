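"""Cohort assembly: tumor-behavior mapping and hierarchical treatment anchors.

Episodes enter the analysis cohort when (i) their histology label maps to the
Malignant or Intermediate behavior tier and (ii) a time anchor T0 can be
derived.  T0 is the start of definitive treatment, taken hierarchically:
the index surgery date when available, otherwise the radiotherapy start
date, otherwise the systemic-therapy start date.  The hierarchy is purely
availability-based — a present surgery date wins even if a radiotherapy
start date precedes it chronologically.

Every excluded episode is logged with exactly one primary reason; behavior
tier is screened before anchor availability, so an unanchored benign episode
is recorded as BENIGN, not NO_ANCHOR.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import InputValidationError

logger = logging.getLogger(__name__)

#: Dates before this are treated as recording artefacts, not real treatment starts.
MIN_PLAUSIBLE_DATE = dt.date(1990, 1, 1)

DATE_COLUMNS = ("surgery_date", "rt_start_date", "systemic_start_date")
REQUIRED_EPISODE_COLUMNS = ("episode_id", "institution", "histology_label") + DATE_COLUMNS


class BehaviorTier(str, Enum):
    MALIGNANT = "MALIGNANT"
    INTERMEDIATE = "INTERMEDIATE"
    BENIGN = "BENIGN"
    UNCLEAR = "UNCLEAR"


#: Tiers that enter the analysis cohort.
ELIGIBLE_TIERS = frozenset({BehaviorTier.MALIGNANT, BehaviorTier.INTERMEDIATE})


class AnchorSource(str, Enum):
    SURGERY = "SURGERY"
    RADIOTHERAPY = "RADIOTHERAPY"
    SYSTEMIC = "SYSTEMIC"


class ExclusionReason(str, Enum):
    BENIGN = "BENIGN"
    UNCLEAR = "UNCLEAR"
    NO_ANCHOR = "NO_ANCHOR"


@dataclass(frozen=True)
class TreatmentDates:
    surgery_date: dt.date | None = None
    rt_start_date: dt.date | None = None
    systemic_start_date: dt.date | None = None


@dataclass(frozen=True)
class AnchorResult:
    t0: dt.date
    source: AnchorSource


def normalize_label(label: str) -> str:
    """Case- and whitespace-insensitive canonical form of a histology label."""
    return " ".join(str(label).split()).casefold()


@dataclass(frozen=True)
class MappingEntry:
    tier: BehaviorTier
    confidence: str = ""
    rationale: str = ""


@dataclass
class BehaviorMapping:
    """Normalized histology label -> (behavior tier, confidence, rationale)."""

    entries: Mapping[str, MappingEntry] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BehaviorMapping":
        for col in ("histology_label", "tier"):
            if col not in frame.columns:
                raise InputValidationError(f"behavior mapping is missing column {col!r}")
        entries: dict[str, MappingEntry] = {}
        for row in frame.itertuples(index=False):
            key = normalize_label(row.histology_label)
            if key in entries:
                raise InputValidationError(
                    f"behavior mapping has duplicate label after normalization: {key!r}"
                )
            tier_raw = str(row.tier).strip().upper()
            try:
                tier = BehaviorTier(tier_raw)
            except ValueError as exc:
                raise InputValidationError(
                    f"behavior mapping: unknown tier {row.tier!r} for label {row.histology_label!r}"
                ) from exc
            entries[key] = MappingEntry(
                tier=tier,
                confidence=str(getattr(row, "confidence", "") or ""),
                rationale=str(getattr(row, "rationale", "") or ""),
            )
        return cls(entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BehaviorMapping":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))


def map_behavior(label: object, mapping: BehaviorMapping) -> BehaviorTier:
    """Map a free-text histology label to its behavior tier.

    Labels that are empty, missing from the mapping, or explicitly mapped as
    ambiguous resolve to UNCLEAR; mapping failure is never an exception.
    """
    if label is None or (isinstance(label, float) and pd.isna(label)) or not str(label).strip():
        logger.warning("empty histology label; classified as UNCLEAR")
        return BehaviorTier.UNCLEAR
    entry = mapping.entries.get(normalize_label(str(label)))
    if entry is None:
        return BehaviorTier.UNCLEAR
    return entry.tier


def derive_t0(dates: TreatmentDates, *, today: dt.date | None = None) -> AnchorResult | None:
    """Hierarchical time anchor: surgery > radiotherapy start > systemic start.

    A date is usable when it falls within [1990-01-01, today]; implausible
    dates are treated as missing.  Returns None when no usable anchor exists.
    """
    today = today or dt.date.today()

    def usable(d: dt.date | None) -> bool:
        return d is not None and MIN_PLAUSIBLE_DATE <= d <= today

    for value, source in (
        (dates.surgery_date, AnchorSource.SURGERY),
        (dates.rt_start_date, AnchorSource.RADIOTHERAPY),
        (dates.systemic_start_date, AnchorSource.SYSTEMIC),
    ):
        if usable(value):
            return AnchorResult(t0=value, source=source)
    return None


def _parse_date(value: object) -> dt.date | None:
    """Parse an ISO date cell; '' / NaN -> None; garbage -> ValueError."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = str(value).strip()
    if not text or text.lower() in {"nan", "nat", "none"}:
        return None
    return dt.date.fromisoformat(text)


def parse_treatment_dates(episodes: pd.DataFrame) -> list[TreatmentDates]:
    """Parse the three treatment-date columns, reporting bad cells by episode."""
    bad: list[str] = []
    parsed: list[TreatmentDates] = []
    for row in episodes.itertuples(index=False):
        values: dict[str, dt.date | None] = {}
        for col in DATE_COLUMNS:
            try:
                values[col] = _parse_date(getattr(row, col))
            except ValueError:
                bad.append(f"{row.episode_id}:{col}={getattr(row, col)!r}")
                values[col] = None
        parsed.append(TreatmentDates(**values))
    if bad:
        raise InputValidationError("unparseable treatment dates for episodes: " + "; ".join(bad))
    return parsed


def build_analysis_cohort(
    episodes: pd.DataFrame,
    mapping: BehaviorMapping,
    *,
    today: dt.date | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen episodes into the analysis cohort.

    Returns ``(cohort, exclusions)``.  The cohort frame carries the input
    columns plus ``behavior_tier``, ``t0`` (date) and ``anchor_source``; the
    exclusion log has one row per excluded episode with its single primary
    reason (BENIGN / UNCLEAR before NO_ANCHOR).
    """
    missing = [c for c in REQUIRED_EPISODE_COLUMNS if c not in episodes.columns]
    if missing:
        raise InputValidationError(f"episodes table is missing columns: {missing}")
    dup = episodes["episode_id"][episodes["episode_id"].duplicated()]
    if not dup.empty:
        raise InputValidationError(f"duplicate episode_id values: {sorted(set(dup))}")

    dates = parse_treatment_dates(episodes)
    tiers: list[BehaviorTier] = []
    anchors: list[AnchorResult | None] = []
    for row, d in zip(episodes.itertuples(index=False), dates):
        tiers.append(map_behavior(row.histology_label, mapping))
        anchors.append(derive_t0(d, today=today))

    keep_mask: list[bool] = []
    exclusion_rows: list[dict[str, object]] = []
    for row, tier, anchor in zip(episodes.itertuples(index=False), tiers, anchors):
        if tier not in ELIGIBLE_TIERS:
            reason = ExclusionReason.BENIGN if tier is BehaviorTier.BENIGN else ExclusionReason.UNCLEAR
        elif anchor is None:
            reason = ExclusionReason.NO_ANCHOR
        else:
            keep_mask.append(True)
            continue
        keep_mask.append(False)
        exclusion_rows.append(
            {
                "episode_id": row.episode_id,
                "institution": row.institution,
                "histology_label": row.histology_label,
                "behavior_tier": tier.value,
                "reason": reason.value,
            }
        )

    cohort = episodes.loc[keep_mask].copy().reset_index(drop=True)
    kept = [i for i, k in enumerate(keep_mask) if k]
    cohort["behavior_tier"] = [tiers[i].value for i in kept]
    cohort["t0"] = [anchors[i].t0 for i in kept]
    cohort["anchor_source"] = [anchors[i].source.value for i in kept]
    exclusions = pd.DataFrame(
        exclusion_rows,
        columns=["episode_id", "institution", "histology_label", "behavior_tier", "reason"],
    )
    logger.info(
        "cohort assembled: %d retained, %d excluded (%s)",
        len(cohort),
        len(exclusions),
        exclusions["reason"].value_counts().to_dict() if len(exclusions) else {},
    )
    return cohort, exclusions
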