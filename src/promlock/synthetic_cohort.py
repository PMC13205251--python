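"""Synthetic two-institution episode cohorts with known latent trajectories.

The study data this pipeline was designed for are not public, so every
downstream stage is exercised against simulated registries.  The generator
emulates the salient features of routine-care PROM capture in a sarcoma
service: two institutions of unequal size, surgery-dominant treatment
anchors, a high-ceiling baseline with dip-and-recover or late-decline
courses, irregular visit timing, and sparse, optionally health-dependent
(MNAR) questionnaire completion.

Each episode carries a latent health trajectory h(t) in [0, 1]:

    h(t) = h0                                                   for t < 0
    h(t) = clamp( plateau - (plateau - (h0 - dip)) * exp(-r t)
                  - slope * max(0, t - onset), 0, 1 )           for t >= 0

i.e. an immediate post-treatment dip of depth ``dip`` recovering at rate
``r`` toward ``plateau``, with an optional linear late decline.  Observed
PROMs are noisy readouts of h: the EQ-5D-5L index maps affinely from
[0, 1] health onto [index_floor, 1.00] (value sets permit negative
utilities; the floor defaults to -0.60) and is rounded to 2 decimals; the
VAS maps onto 0..100.

Visit retention implements the missingness mechanism at the visit level:
a visit yields any PROM with probability
``logistic(logit(p_observe) + mnar_slope * (h - 0.5))``, so ``mnar_slope=0``
is MCAR and positive slopes make sicker episodes quieter.  Metric-level
dropout (index or VAS individually absent) is a separate MCAR probability.

Internally all timing is integer day offsets from a per-episode T0;
calendar dates are materialized only in the exported registry.  Identical
config + seed gives bit-identical output tables.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "ARCHETYPES",
    "GeneratorConfig",
    "LatentTrajectory",
    "latent_health",
    "emit_prom",
    "sample_trajectory",
    "generate_cohort",
    "write_cohort",
    "default_behavior_mapping",
    "red_equivalent_health",
]

ARCHETYPES = ("STABLE_HIGH", "DIP_RECOVER", "LATE_DECLINE", "PERSISTENT_LOW")

#: First possible synthetic T0; the registry spans roughly 19 months of accrual.
_T0_EPOCH = dt.date(2021, 10, 1)
_T0_SPAN_DAYS = 578

# Illustrative histology labels per tier.  "Unclassified lesion" is
# deliberately absent from default_behavior_mapping() so that the
# unmapped-label -> UNCLEAR path is exercised end to end.
_LABELS = {
    "MALIGNANT": (
        "Myxofibrosarcoma",
        "Leiomyosarcoma",
        "Undifferentiated pleomorphic sarcoma",
        "Liposarcoma, myxoid",
    ),
    "INTERMEDIATE": (
        "Desmoid-type fibromatosis",
        "Atypical lipomatous tumor",
        "Giant cell tumour of bone",
    ),
    "BENIGN": ("Lipoma", "Schwannoma", "Haemangioma"),
    "UNCLEAR": ("Spindle cell lesion NOS", "Unclassified lesion"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the two-institution setting the pipeline targets:
    410 + 319 episodes, ~91% surgery / ~6.6% radiotherapy / ~2.3% systemic
    anchors (remainder unanchored), a tier mix whose eligible fraction is
    ~68% malignant vs ~32% intermediate, and per-visit capture sparse enough
    to give locked-window evaluability in the 10-20% range.
    """

    n_episodes_a: int = 410
    n_episodes_b: int = 319
    seed: int = 0
    p_anchor_surgery: float = 0.90
    p_anchor_radiotherapy: float = 0.066
    p_anchor_systemic: float = 0.023
    p_malignant: float = 0.55
    p_intermediate: float = 0.26
    p_benign: float = 0.13
    p_unclear: float = 0.06
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "STABLE_HIGH": 0.45,
            "DIP_RECOVER": 0.30,
            "LATE_DECLINE": 0.15,
            "PERSISTENT_LOW": 0.10,
        }
    )
    #: (target day from T0, jitter SD in days) per scheduled visit.
    visit_schedule: Sequence[tuple[float, float]] = (
        (-30.0, 25.0),
        (45.0, 20.0),
        (120.0, 30.0),
        (270.0, 35.0),
        (365.0, 30.0),
        (550.0, 40.0),
        (730.0, 45.0),
    )
    p_extra_visit: float = 0.15
    p_observe: float = 0.10
    mnar_slope: float = 0.0
    p_drop_index: float = 0.05
    p_drop_vas: float = 0.05
    index_noise_sd: float = 0.05
    vas_noise_sd: float = 7.0
    index_floor: float = -0.60

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first offending field."""
        for name in ("n_episodes_a", "n_episodes_b"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be non-negative")
        prob_fields = (
            "p_anchor_surgery",
            "p_anchor_radiotherapy",
            "p_anchor_systemic",
            "p_malignant",
            "p_intermediate",
            "p_benign",
            "p_unclear",
            "p_extra_visit",
            "p_observe",
            "p_drop_index",
            "p_drop_vas",
        )
        for name in prob_fields:
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.p_anchor_surgery + self.p_anchor_radiotherapy + self.p_anchor_systemic > 1 + 1e-9:
            raise ConfigError("p_anchor_surgery/radiotherapy/systemic must sum to at most 1")
        tier_sum = self.p_malignant + self.p_intermediate + self.p_benign + self.p_unclear
        if abs(tier_sum - 1.0) > 1e-9:
            raise ConfigError(f"tier mix (p_malignant..p_unclear) must sum to 1, got {tier_sum}")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ConfigError(f"archetype_mix contains unknown archetypes {sorted(unknown)}")
        if abs(sum(self.archetype_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("archetype_mix must sum to 1")
        if any(p < 0 for p in self.archetype_mix.values()):
            raise ConfigError("archetype_mix proportions must be non-negative")
        for day, sd in self.visit_schedule:
            if sd < 0:
                raise ConfigError(f"visit_schedule jitter SD must be non-negative, got {sd}")
        for name in ("index_noise_sd", "vas_noise_sd"):
            if float(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not -1.0 <= self.index_floor < 1.0:
            raise ConfigError(f"index_floor must lie in [-1, 1), got {self.index_floor}")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class LatentTrajectory:
    archetype: str
    h0: float
    dip: float
    recover_rate: float
    plateau: float
    decline_onset: float = 0.0
    decline_slope: float = 0.0


def latent_health(traj: LatentTrajectory, day: float) -> float:
    """True health in [0, 1] at an integer day offset from T0 (total function)."""
    if day < 0:
        return traj.h0
    # exp(-r*0) must be 1 even for an infinite recovery rate
    factor = math.exp(-traj.recover_rate * day) if day > 0 else 1.0
    h = (
        traj.plateau
        - (traj.plateau - (traj.h0 - traj.dip)) * factor
        - traj.decline_slope * max(0.0, day - traj.decline_onset)
    )
    return min(1.0, max(0.0, h))


def red_equivalent_health(index_red: float = 0.75, index_floor: float = -0.60) -> float:
    """Latent health whose noiseless index readout sits at the RED threshold."""
    return (index_red - index_floor) / (1.0 - index_floor)


def emit_prom(
    h: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[float | None, int | None]:
    """Noisy (index, vas) readout of latent health; either field may drop out."""
    index_raw = cfg.index_floor + (1.0 - cfg.index_floor) * h
    if cfg.index_noise_sd > 0:
        index_raw += rng.normal(0.0, cfg.index_noise_sd)
    index: float | None = round(min(1.0, max(cfg.index_floor, index_raw)), 2)
    vas_raw = 100.0 * h
    if cfg.vas_noise_sd > 0:
        vas_raw += rng.normal(0.0, cfg.vas_noise_sd)
    vas: int | None = int(round(min(100.0, max(0.0, vas_raw))))
    if rng.random() < cfg.p_drop_index:
        index = None
    if rng.random() < cfg.p_drop_vas:
        vas = None
    return index, vas


_ARCHETYPE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    # near-ceiling baseline, shallow dip, quick recovery, no decline
    "STABLE_HIGH": {"h0": (0.92, 1.0), "dip": (0.03, 0.12), "rate": (0.02, 0.05)},
    # near-ceiling baseline, deep dip, slow but complete recovery
    "DIP_RECOVER": {"h0": (0.92, 1.0), "dip": (0.30, 0.50), "rate": (0.008, 0.02)},
    # recovers first, then loses health linearly from the second year on
    "LATE_DECLINE": {
        "h0": (0.90, 1.0),
        "dip": (0.15, 0.35),
        "rate": (0.01, 0.03),
        "onset": (365.0, 550.0),
        "slope": (0.0008, 0.002),
    },
    # low baseline and a plateau well below the acceptability range
    "PERSISTENT_LOW": {"h0": (0.45, 0.65), "dip": (0.10, 0.30), "rate": (0.005, 0.02)},
}


def sample_trajectory(archetype: str, rng: np.random.Generator) -> LatentTrajectory:
    """Draw latent-trajectory parameters for one episode of the given archetype."""
    r = _ARCHETYPE_RANGES[archetype]
    h0 = rng.uniform(*r["h0"])
    dip = rng.uniform(*r["dip"])
    rate = rng.uniform(*r["rate"])
    if archetype == "PERSISTENT_LOW":
        plateau = rng.uniform(0.25, 0.45)
    else:
        plateau = h0
    onset = rng.uniform(*r["onset"]) if "onset" in r else 0.0
    slope = rng.uniform(*r["slope"]) if "slope" in r else 0.0
    return LatentTrajectory(
        archetype=archetype,
        h0=h0,
        dip=dip,
        recover_rate=rate,
        plateau=plateau,
        decline_onset=onset,
        decline_slope=slope,
    )


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _retention_probability(h: float, cfg: GeneratorConfig) -> float:
    """Visit-level probability of yielding any PROM, MNAR-tilted by health."""
    if cfg.p_observe <= 0.0:
        return 0.0
    if cfg.p_observe >= 1.0:
        return 1.0
    logit = math.log(cfg.p_observe / (1.0 - cfg.p_observe))
    return _logistic(logit + cfg.mnar_slope * (h - 0.5))


EPISODE_COLUMNS = [
    "episode_id",
    "institution",
    "histology_label",
    "sex",
    "margin_status",
    "metastasis_at_dx",
    "surgery_date",
    "rt_start_date",
    "systemic_start_date",
]
OBSERVATION_COLUMNS = ["episode_id", "obs_date", "eq5d_index", "eq_vas"]
TRUTH_COLUMNS = [
    "episode_id",
    "institution",
    "archetype",
    "behavior_tier",
    "anchor_source",
    "t0",
    "h0",
    "dip",
    "recover_rate",
    "plateau",
    "decline_onset",
    "decline_slope",
    "h_12m",
    "h_24m",
]


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (episodes, observations, truth) tables.

    Episodes include benign / unclear / unanchored records so that the
    eligibility screen is exercised; the truth table records each episode's
    archetype, latent parameters and true health at the 12 m / 24 m targets
    for recovery tests.  Dates are ISO-8601 strings; missing cells are empty.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    tier_names = ("MALIGNANT", "INTERMEDIATE", "BENIGN", "UNCLEAR")
    tier_p = np.array([cfg.p_malignant, cfg.p_intermediate, cfg.p_benign, cfg.p_unclear])
    arch_names = tuple(cfg.archetype_mix)
    arch_p = np.array([cfg.archetype_mix[a] for a in arch_names])
    anchor_p = np.array(
        [
            cfg.p_anchor_surgery,
            cfg.p_anchor_radiotherapy,
            cfg.p_anchor_systemic,
            max(0.0, 1.0 - cfg.p_anchor_surgery - cfg.p_anchor_radiotherapy - cfg.p_anchor_systemic),
        ]
    )
    anchor_p = anchor_p / anchor_p.sum()

    episode_rows: list[dict[str, object]] = []
    obs_rows: list[dict[str, object]] = []
    truth_rows: list[dict[str, object]] = []

    for institution, n in (("A", int(cfg.n_episodes_a)), ("B", int(cfg.n_episodes_b))):
        for i in range(n):
            eid = f"{institution}-{i:04d}"
            t0 = _T0_EPOCH + dt.timedelta(days=int(rng.integers(0, _T0_SPAN_DAYS)))
            anchor = ("SURGERY", "RADIOTHERAPY", "SYSTEMIC", "NONE")[
                int(rng.choice(4, p=anchor_p))
            ]
            surgery = rt = systemic = ""
            if anchor == "SURGERY":
                surgery = t0.isoformat()
                if rng.random() < 0.30:
                    rt = (t0 + dt.timedelta(days=int(rng.integers(20, 80)))).isoformat()
                if rng.random() < 0.20:
                    systemic = (t0 + dt.timedelta(days=int(rng.integers(30, 120)))).isoformat()
            elif anchor == "RADIOTHERAPY":
                rt = t0.isoformat()
                if rng.random() < 0.30:
                    systemic = (t0 + dt.timedelta(days=int(rng.integers(10, 90)))).isoformat()
            elif anchor == "SYSTEMIC":
                systemic = t0.isoformat()

            tier = tier_names[int(rng.choice(4, p=tier_p))]
            label = _LABELS[tier][int(rng.integers(0, len(_LABELS[tier])))]
            sex = "F" if rng.random() < 0.47 else "M"
            margin = ("R0", "R1", "R2", "Unknown")[
                int(rng.choice(4, p=[0.55, 0.18, 0.04, 0.23]))
            ]
            mets = ("Yes", "No", "Unknown")[int(rng.choice(3, p=[0.12, 0.85, 0.03]))]
            episode_rows.append(
                {
                    "episode_id": eid,
                    "institution": institution,
                    "histology_label": label,
                    "sex": sex,
                    "margin_status": margin,
                    "metastasis_at_dx": mets,
                    "surgery_date": surgery,
                    "rt_start_date": rt,
                    "systemic_start_date": systemic,
                }
            )

            archetype = arch_names[int(rng.choice(len(arch_names), p=arch_p))]
            traj = sample_trajectory(archetype, rng)
            truth_rows.append(
                {
                    "episode_id": eid,
                    "institution": institution,
                    "archetype": archetype,
                    "behavior_tier": tier,
                    "anchor_source": anchor,
                    "t0": t0.isoformat(),
                    "h0": round(traj.h0, 6),
                    "dip": round(traj.dip, 6),
                    "recover_rate": round(traj.recover_rate, 6),
                    "plateau": round(traj.plateau, 6),
                    "decline_onset": round(traj.decline_onset, 2),
                    "decline_slope": round(traj.decline_slope, 8),
                    "h_12m": round(latent_health(traj, 270), 6),
                    "h_24m": round(latent_health(traj, 730), 6),
                }
            )

            visit_days: list[int] = []
            for target, jitter in cfg.visit_schedule:
                day = target + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
                visit_days.append(int(round(day)))
            n_extra = int(rng.binomial(len(cfg.visit_schedule), cfg.p_extra_visit))
            for _ in range(n_extra):
                visit_days.append(int(rng.integers(-60, 801)))

            for day in visit_days:
                h = latent_health(traj, day)
                if rng.random() >= _retention_probability(h, cfg):
                    continue
                index, vas = emit_prom(h, cfg, rng)
                obs_rows.append(
                    {
                        "episode_id": eid,
                        "obs_date": (t0 + dt.timedelta(days=day)).isoformat(),
                        "eq5d_index": f"{index:.2f}" if index is not None else "",
                        "eq_vas": str(vas) if vas is not None else "",
                    }
                )

    episodes = pd.DataFrame(episode_rows, columns=EPISODE_COLUMNS)
    observations = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return episodes, observations, truth


def default_behavior_mapping() -> pd.DataFrame:
    """Illustrative histology -> tier mapping matching the generator's labels.

    One generated label ("Unclassified lesion") is intentionally unmapped and
    one is explicitly mapped to UNCLEAR, so both routes into the UNCLEAR tier
    occur in simulated cohorts.
    """
    rows = []
    for tier, labels in _LABELS.items():
        for label in labels:
            if label == "Unclassified lesion":
                continue
            rows.append(
                {
                    "histology_label": label,
                    "tier": tier,
                    "confidence": "high" if tier != "UNCLEAR" else "low",
                    "rationale": "synthetic illustrative mapping entry",
                }
            )
    return pd.DataFrame(rows, columns=["histology_label", "tier", "confidence", "rationale"])


def write_cohort(cfg: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write episodes.csv, observations.csv, truth.csv and behavior_mapping.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    episodes, observations, truth = generate_cohort(cfg)
    paths = {
        "episodes": out / "episodes.csv",
        "observations": out / "observations.csv",
        "truth": out / "truth.csv",
        "mapping": out / "behavior_mapping.csv",
    }
    episodes.to_csv(paths["episodes"], index=False)
    observations.to_csv(paths["observations"], index=False)
    truth.to_csv(paths["truth"], index=False)
    default_behavior_mapping().to_csv(paths["mapping"], index=False)
    return paths
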