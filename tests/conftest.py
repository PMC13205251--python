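import pandas as pd
import pytest

from promlock import BehaviorMapping, GeneratorConfig, default_behavior_mapping

#: Schedule with visits exactly at every window target and no jitter.
EXACT_SCHEDULE = ((-30.0, 0.0), (45.0, 0.0), (270.0, 0.0), (365.0, 0.0), (730.0, 0.0))


@pytest.fixture(scope="session")
def mapping() -> BehaviorMapping:
    return BehaviorMapping.from_frame(default_behavior_mapping())


def full_capture_config(**overrides) -> GeneratorConfig:
    """Generator settings with every scheduled visit observed and both metrics kept."""
    base = dict(
        n_episodes_a=40,
        n_episodes_b=30,
        seed=11,
        visit_schedule=EXACT_SCHEDULE,
        p_extra_visit=0.0,
        p_observe=1.0,
        mnar_slope=0.0,
        p_drop_index=0.0,
        p_drop_vas=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def make_episodes(rows) -> pd.DataFrame:
    """Episode frame from (episode_id, institution, label, surgery, rt, systemic)."""
    return pd.DataFrame(
        [
            {
                "episode_id": r[0],
                "institution": r[1],
                "histology_label": r[2],
                "sex": "F",
                "margin_status": "R0",
                "metastasis_at_dx": "No",
                "surgery_date": r[3],
                "rt_start_date": r[4],
                "systemic_start_date": r[5],
            }
            for r in rows
        ]
    )


def make_observations(rows) -> pd.DataFrame:
    """Observation frame from (episode_id, obs_date, index, vas) tuples."""
    return pd.DataFrame(
        rows, columns=["episode_id", "obs_date", "eq5d_index", "eq_vas"]
    )
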