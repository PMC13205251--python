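"""Institution-level benchmarking tables and the end-to-end pipeline.

Aggregates the upstream stages into two tidy tables mirroring the usual
reporting layout of a two-institution PROM feasibility study:

* a cohort/evaluability table (behavior tiers, anchor sources, locked-window
  evaluability with full-cohort denominators, offset timing), and
* an outcome table (index/VAS distributions, MID-based change, traffic-light
  distributions, stability classes).

Every percentage is stored next to its numerator and denominator, and the
denominator follows the stage that produced the row: evaluability rows use
the full eligible cohort, change rows the episodes with a computable
baseline pair, traffic-light rows the evaluable episodes at the timepoint,
and stability rows the episodes evaluable at both follow-ups.

Between-institution comparisons use the Pearson chi-square statistic without
continuity correction for categorical rows (all table sizes, including 2x2)
and the Mann-Whitney U test for continuous rows.  For small samples
(n_x + n_y <= 12) the Mann-Whitney p-value comes from exact enumeration of
rank assignments (midranks under ties); larger samples use the normal
approximation with tie-corrected variance and continuity correction.
p-values are two-sided and reported to 3 decimals, percentages to 2.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_eligibility import BehaviorMapping, build_analysis_cohort
from .errors import AnalysisError
from .stability import STABILITY_COLUMNS, StabilityClass, assign_stability
from .traffic_light import TRAFFIC_COLUMNS, Color, Thresholds, classify_followups
from .window_engine import (
    ASSIGNMENT_COLUMNS,
    DEFAULT_WINDOWS,
    OVERALL,
    Timepoint,
    WindowSpec,
    assign_windows,
    evaluability_table,
)

logger = logging.getLogger(__name__)

#: Exact Mann-Whitney enumeration is used up to this pooled sample size.
EXACT_MWU_MAX_N = 12


# ---------------------------------------------------------------------------
# statistical primitives
# ---------------------------------------------------------------------------

def pearson_chi_square(table: object) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    ``table`` is a 2-D count array (rows = groups, columns = categories).
    All-zero columns are dropped first; a degenerate table (fewer than two
    rows/columns, or a zero margin) raises :class:`AnalysisError`.
    Returns ``(X2, df, p)``.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise AnalysisError("contingency table must be two-dimensional")
    counts = counts[:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise AnalysisError("contingency table needs >=2 rows and >=2 non-zero columns")
    if (counts.sum(axis=1) == 0).any():
        raise AnalysisError("contingency table has a zero row margin")
    if (counts < 0).any():
        raise AnalysisError("contingency table counts must be non-negative")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _mwu_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating rank assignments.

    Midranks handle ties; the p-value is the fraction of assignments whose U
    is at least as far from the null mean n_x n_y / 2 as the observed U.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = nx * ny / 2.0
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    d_obs = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(nx + ny), nx):
        u = ranks[list(comb)].sum() - nx * (nx + 1) / 2.0
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    *,
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(min(U_x, U_y), p)``.

    ``method='auto'`` enumerates the exact permutation distribution when
    n_x + n_y <= 12 and otherwise uses the normal approximation with
    tie-corrected variance and continuity correction.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise AnalysisError("mann_whitney_u requires two non-empty samples")
    if method not in {"auto", "exact", "asymptotic"}:
        raise AnalysisError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and xa.size + ya.size <= EXACT_MWU_MAX_N)
    if use_exact:
        u1, p = _mwu_exact(xa, ya)
    else:
        res = stats.mannwhitneyu(
            xa, ya, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u1, p = float(res.statistic), float(res.pvalue)
    u_min = min(u1, xa.size * ya.size - u1)
    return u_min, float(min(p, 1.0))


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles with linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise AnalysisError("median_iqr requires a non-empty sample")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

TIDY_COLUMNS = [
    "section",
    "variable",
    "category",
    "group",
    "n",
    "denominator",
    "pct",
    "median",
    "q1",
    "q3",
    "p",
]


@dataclass
class BenchmarkReport:
    """Tidy benchmarking tables plus the flat test register."""

    institutions: list[str]
    table1: pd.DataFrame
    table2: pd.DataFrame
    tests: pd.DataFrame

    def to_dict(self) -> dict:
        def records(frame: pd.DataFrame) -> list[dict]:
            out = []
            for rec in frame.to_dict(orient="records"):
                out.append(
                    {
                        k: (None if isinstance(v, float) and math.isnan(v) else _plain(v))
                        for k, v in rec.items()
                    }
                )
            return out

        return {
            "institutions": list(self.institutions),
            "table1": records(self.table1),
            "table2": records(self.table2),
            "tests": records(self.tests),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(out / "table1_like.csv", index=False)
        self.table2.to_csv(out / "table2_like.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _plain(v: object) -> object:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if v is pd.NA:
        return None
    return v


class _ReportBuilder:
    def __init__(self, institutions: list[str]) -> None:
        self.institutions = institutions
        self.rows1: list[dict] = []
        self.rows2: list[dict] = []
        self.tests: list[dict] = []
        self.testable = len(institutions) == 2

    def _row(self, **kw: object) -> dict:
        base = {c: np.nan for c in TIDY_COLUMNS}
        base.update(kw)
        return base

    def _register(self, name: str, statistic: float, df: object, p: float) -> float:
        self.tests.append({"test": name, "statistic": statistic, "df": df, "p": p})
        return p

    def categorical(
        self,
        dest: list[dict],
        section: str,
        variable: str,
        counts_by_group: Mapping[str, Mapping[str, int]],
        denominators: Mapping[str, int],
        categories: Sequence[str],
        *,
        drop_for_test: Iterable[str] = (),
    ) -> None:
        """Add count/percentage rows per category and group, plus one chi-square."""
        p = np.nan
        if self.testable:
            drop = set(drop_for_test)
            table = [
                [counts_by_group[g].get(c, 0) for c in categories if c not in drop]
                for g in self.institutions
            ]
            try:
                x2, dof, p = pearson_chi_square(table)
                self._register(f"{section}:{variable}", x2, dof, p)
            except AnalysisError as exc:
                logger.info("test skipped for %s:%s (%s)", section, variable, exc)
        groups = list(self.institutions) + [OVERALL]
        for cat in categories:
            for g in groups:
                if g == OVERALL:
                    n = sum(counts_by_group[h].get(cat, 0) for h in self.institutions)
                    denom = sum(denominators[h] for h in self.institutions)
                else:
                    n, denom = counts_by_group[g].get(cat, 0), denominators[g]
                dest.append(
                    self._row(
                        section=section,
                        variable=variable,
                        category=cat,
                        group=g,
                        n=int(n),
                        denominator=int(denom),
                        pct=round(100.0 * n / denom, 2) if denom else np.nan,
                        p=round(p, 3) if not np.isnan(p) else np.nan,
                    )
                )

    def continuous(
        self,
        dest: list[dict],
        section: str,
        variable: str,
        values_by_group: Mapping[str, Sequence[float]],
    ) -> None:
        """Add median [IQR] rows per group, plus one Mann-Whitney comparison."""
        p = np.nan
        if self.testable:
            a, b = (np.asarray(list(values_by_group.get(g, ())), float) for g in self.institutions)
            if a.size and b.size:
                u, p = mann_whitney_u(a, b)
                self._register(f"{section}:{variable}", u, None, p)
        groups = list(self.institutions) + [OVERALL]
        for g in groups:
            if g == OVERALL:
                vals: list[float] = []
                for h in self.institutions:
                    vals.extend(values_by_group.get(h, ()))
            else:
                vals = list(values_by_group.get(g, ()))
            if vals:
                med, q1, q3 = median_iqr(vals)
            else:
                med = q1 = q3 = np.nan
            dest.append(
                self._row(
                    section=section,
                    variable=variable,
                    group=g,
                    n=len(vals),
                    median=med,
                    q1=q1,
                    q3=q3,
                    p=round(p, 3) if not np.isnan(p) else np.nan,
                )
            )


def build_benchmark_report(
    cohort: pd.DataFrame,
    assignments: pd.DataFrame,
    traffic: pd.DataFrame,
    stability: pd.DataFrame,
    *,
    covariates: Sequence[str] = (),
    exclude_unknown_from_tests: bool = True,
) -> BenchmarkReport:
    """Assemble the two benchmarking tables with statistical comparisons.

    ``covariates`` names categorical columns of the cohort to summarize;
    their "Unknown" level is shown descriptively but excluded from the test
    table unless ``exclude_unknown_from_tests`` is False.  An empty cohort
    yields an empty report with headers; with other than two institutions the
    descriptive rows are produced and every p is not-applicable (NaN).
    """
    institutions = sorted(pd.unique(cohort["institution"])) if len(cohort) else []
    b = _ReportBuilder(institutions)
    denom_eligible = {g: int((cohort["institution"] == g).sum()) for g in institutions}

    if institutions:
        # --- table 1: cohort composition, anchors, evaluability, timing ----
        tier_counts = {
            g: cohort.loc[cohort["institution"] == g, "behavior_tier"].value_counts().to_dict()
            for g in institutions
        }
        b.categorical(
            b.rows1, "cohort", "behavior_tier", tier_counts, denom_eligible,
            ["MALIGNANT", "INTERMEDIATE"],
        )
        anchor_counts = {
            g: cohort.loc[cohort["institution"] == g, "anchor_source"].value_counts().to_dict()
            for g in institutions
        }
        b.categorical(
            b.rows1, "cohort", "t0_source", anchor_counts, denom_eligible,
            ["SURGERY", "RADIOTHERAPY", "SYSTEMIC"],
        )

        ev = assignments.merge(cohort[["episode_id"]], on="episode_id")
        for tp in (Timepoint.BASELINE, Timepoint.M12, Timepoint.M24):
            tp_rows = ev[ev["timepoint"] == tp.value]
            counts = {
                g: {
                    "evaluable": int(
                        (tp_rows["evaluable"] & (tp_rows["institution"] == g)).sum()
                    ),
                    "not_evaluable": int(
                        (~tp_rows["evaluable"] & (tp_rows["institution"] == g)).sum()
                    ),
                }
                for g in institutions
            }
            b.categorical(
                b.rows1, "evaluability", f"evaluable_{tp.value}", counts, denom_eligible,
                ["evaluable", "not_evaluable"],
            )
            offs = {
                g: tp_rows.loc[
                    tp_rows["evaluable"] & (tp_rows["institution"] == g), "offset_days"
                ].dropna().astype(int).tolist()
                for g in institutions
            }
            b.continuous(b.rows1, "timing", f"offset_{tp.value}", offs)

        base = ev[ev["timepoint"] == Timepoint.BASELINE.value]
        early_counts = {
            g: {
                "early_post": int(
                    (base["early_post_baseline"] & (base["institution"] == g)).sum()
                ),
                "other": denom_eligible[g]
                - int((base["early_post_baseline"] & (base["institution"] == g)).sum()),
            }
            for g in institutions
        }
        b.categorical(
            b.rows1, "evaluability", "early_post_baseline", early_counts, denom_eligible,
            ["early_post", "other"],
        )

        for cov in covariates:
            if cov not in cohort.columns:
                logger.warning("covariate %r not in cohort; skipped", cov)
                continue
            levels = sorted(cohort[cov].astype(str).unique())
            counts = {
                g: cohort.loc[cohort["institution"] == g, cov].astype(str).value_counts().to_dict()
                for g in institutions
            }
            b.categorical(
                b.rows1, "covariates", cov, counts, denom_eligible, levels,
                drop_for_test={"Unknown"} if exclude_unknown_from_tests else (),
            )

        # --- table 2: status, change, traffic lights, stability ------------
        wide = _values_wide(assignments)
        for tp in (Timepoint.BASELINE, Timepoint.M12, Timepoint.M24):
            for metric in ("eq5d_index", "eq_vas"):
                vals = {
                    g: wide.loc[
                        (wide["institution"] == g), f"{metric}_{tp.value}"
                    ].dropna().tolist()
                    for g in institutions
                }
                b.continuous(b.rows2, "status", f"{metric}_{tp.value}", vals)

        for tp in (Timepoint.M12, Timepoint.M24):
            for metric in ("eq5d_index", "eq_vas"):
                deltas = {
                    g: (
                        wide.loc[wide["institution"] == g, f"{metric}_{tp.value}"]
                        - wide.loc[wide["institution"] == g, f"{metric}_BASELINE"]
                    ).dropna().tolist()
                    for g in institutions
                }
                b.continuous(b.rows2, "change", f"delta_{metric}_{tp.value}", deltas)

            tl = traffic[traffic["timepoint"] == tp.value]
            computable = tl[tl["computable"]]
            denom_comp = {
                g: int((computable["institution"] == g).sum()) for g in institutions
            }
            for flag in ("improved", "deteriorated"):
                counts = {
                    g: {
                        "yes": int(
                            (computable[flag] & (computable["institution"] == g)).sum()
                        ),
                        "no": denom_comp[g]
                        - int((computable[flag] & (computable["institution"] == g)).sum()),
                    }
                    for g in institutions
                }
                b.categorical(
                    b.rows2, "change", f"{flag}_{tp.value}", counts, denom_comp,
                    ["yes", "no"],
                )

            denom_ev = {g: int((tl["institution"] == g).sum()) for g in institutions}
            color_counts = {
                g: tl.loc[tl["institution"] == g, "final"].value_counts().to_dict()
                for g in institutions
            }
            b.categorical(
                b.rows2, "traffic_light", f"final_{tp.value}", color_counts, denom_ev,
                [c.value for c in (Color.GREEN, Color.YELLOW, Color.RED)],
            )

        denom_stab = {g: int((stability["institution"] == g).sum()) for g in institutions}
        stab_counts = {
            g: stability.loc[
                stability["institution"] == g, "stability_class"
            ].value_counts().to_dict()
            for g in institutions
        }
        b.categorical(
            b.rows2, "stability", "stability_class", stab_counts, denom_stab,
            [c.value for c in StabilityClass],
        )

    table1 = pd.DataFrame(b.rows1, columns=TIDY_COLUMNS)
    table2 = pd.DataFrame(b.rows2, columns=TIDY_COLUMNS)
    tests = pd.DataFrame(b.tests, columns=["test", "statistic", "df", "p"])
    return BenchmarkReport(institutions=institutions, table1=table1, table2=table2, tests=tests)


def _values_wide(assignments: pd.DataFrame) -> pd.DataFrame:
    """One row per episode with index/VAS per timepoint (evaluable windows only)."""
    columns = ["episode_id", "institution"] + [
        f"{metric}_{tp.value}" for metric in ("eq5d_index", "eq_vas") for tp in Timepoint
    ]
    ev = assignments[assignments["evaluable"]].copy()
    if ev.empty:
        return pd.DataFrame(columns=columns)
    ev["eq_vas"] = ev["eq_vas"].astype(float)
    wide = ev.pivot_table(
        index=["episode_id", "institution"],
        columns="timepoint",
        values=["eq5d_index", "eq_vas"],
        aggfunc="first",
    )
    wide.columns = [f"{metric}_{tp}" for metric, tp in wide.columns]
    for tp in Timepoint:
        for metric in ("eq5d_index", "eq_vas"):
            col = f"{metric}_{tp.value}"
            if col not in wide.columns:
                wide[col] = np.nan
    return wide.reset_index()


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    exclusions: pd.DataFrame
    assignments: pd.DataFrame
    evaluability: pd.DataFrame
    traffic: pd.DataFrame
    stability: pd.DataFrame
    report: BenchmarkReport

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        self.assignments.to_csv(out / "window_assignments.csv", index=False)
        self.evaluability.to_csv(out / "evaluability.csv", index=False)
        self.traffic.to_csv(out / "traffic_light.csv", index=False)
        self.stability.to_csv(out / "stability.csv", index=False)
        self.report.write(out)


def run_pipeline(
    episodes: pd.DataFrame,
    observations: pd.DataFrame,
    mapping: BehaviorMapping,
    *,
    thresholds: Thresholds | None = None,
    windows: Mapping[Timepoint, WindowSpec] | None = None,
    escalate_on_deterioration: bool = True,
    covariates: Sequence[str] = (),
    exclude_unknown_from_tests: bool = True,
    today=None,
) -> PipelineResult:
    """Run eligibility -> window selection -> traffic lights -> stability -> report."""
    thresholds = thresholds or Thresholds()
    cohort, exclusions = build_analysis_cohort(episodes, mapping, today=today)
    assignments = assign_windows(cohort, observations, windows or DEFAULT_WINDOWS)
    evaluability = evaluability_table(assignments, cohort)
    traffic = classify_followups(
        assignments, thresholds, escalate_on_deterioration=escalate_on_deterioration
    )
    stability = assign_stability(traffic, assignments, thresholds)
    report = build_benchmark_report(
        cohort,
        assignments,
        traffic,
        stability,
        covariates=covariates,
        exclude_unknown_from_tests=exclude_unknown_from_tests,
    )
    return PipelineResult(
        cohort=cohort,
        exclusions=exclusions,
        assignments=assignments,
        evaluability=evaluability,
        traffic=traffic,
        stability=stability,
        report=report,
    )
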