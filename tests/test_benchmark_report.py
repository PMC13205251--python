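"""Statistical primitives against independent oracles; report table discipline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promlock import (
    AnalysisError,
    BehaviorMapping,
    GeneratorConfig,
    build_benchmark_report,
    default_behavior_mapping,
    generate_cohort,
    mann_whitney_u,
    median_iqr,
    pearson_chi_square,
    run_pipeline,
)

FIXED_TABLES = [
    [[55, 7, 13], [29, 8, 7]],
    [[43, 10, 3], [14, 7, 7]],
    [[384, 20, 6], [279, 29, 11]],
    [[64, 346], [43, 276]],
    [[12, 1], [3, 9]],
]


def _chi_square_by_hand(table):
    """Textbook Sum (O-E)^2/E with margin-product expected counts."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    x2 = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            x2 += (obs[i, j] - e) ** 2 / e
    return x2


class TestPearsonChiSquare:
    @pytest.mark.parametrize("table", FIXED_TABLES)
    def test_matches_hand_computation(self, table):
        x2, df, p = pearson_chi_square(table)
        assert x2 == pytest.approx(_chi_square_by_hand(table), abs=1e-10)
        assert df == (len(table) - 1) * (len(table[0]) - 1)
        assert p == pytest.approx(stats.chi2.sf(x2, df), abs=1e-12)

    def test_proportional_rows_give_zero_statistic(self):
        x2, _, p = pearson_chi_square([[10, 20], [10, 20]])
        assert x2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_zero_columns_are_dropped(self):
        x2_full, df_full, _ = pearson_chi_square([[5, 0, 9], [3, 0, 11]])
        x2_red, df_red, _ = pearson_chi_square([[5, 9], [3, 11]])
        assert x2_full == pytest.approx(x2_red) and df_full == df_red == 1

    @pytest.mark.parametrize(
        "table",
        [
            [[1, 2, 3]],  # single row
            [[0, 0], [0, 0]],  # everything zero
            [[1, 0], [2, 0]],  # one informative column after dropping
            [[0, 0], [5, 6]],  # zero row margin
        ],
    )
    def test_degenerate_tables_raise(self, table):
        with pytest.raises(AnalysisError):
            pearson_chi_square(table)


def _mwu_oracle(x, y):
    """Brute-force two-sided permutation p for the Mann-Whitney U statistic.

    Independent of the implementation: builds midranks by explicit counting
    and enumerates which pooled positions belong to the first sample.
    """
    pooled = sorted(list(x) + list(y))
    def midrank(v):
        less = sum(1 for w in pooled if w < v)
        equal = sum(1 for w in pooled if w == v)
        return less + (equal + 1) / 2.0
    nx, ny = len(x), len(y)
    mu = nx * ny / 2.0
    obs_u = sum(midrank(v) for v in x) - nx * (nx + 1) / 2.0
    all_ranks = [midrank(v) for v in pooled]
    hits = total = 0
    for pick in itertools.combinations(range(nx + ny), nx):
        u = sum(all_ranks[i] for i in pick) - nx * (nx + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(obs_u - mu) - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitneyU:
    def test_identical_samples_are_null(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == 4.5
        assert p >= 0.99

    def test_complete_separation_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(2 / 20)  # exact enumeration over C(6,3)=20

    def test_midranks_match_permutation_oracle_under_ties(self):
        x, y = [1, 1, 2], [1, 2, 2]
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(_mwu_oracle(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_the_crossover(self):
        x = [3.1, 4.2, 5.0, 6.3, 7.7, 2.2]
        y = [4.0, 5.5, 6.1, 8.0, 9.2, 7.1]
        _, p_exact = mann_whitney_u(x, y, method="exact")
        _, p_asym = mann_whitney_u(x, y, method="asymptotic")
        assert abs(p_exact - p_asym) < 0.05

    def test_empty_sample_raises(self):
        with pytest.raises(AnalysisError):
            mann_whitney_u([], [1.0])


class TestMedianIqr:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([-42], (-42, -42, -42)),
            ([1, 2, 3, 4], (2.5, 1.75, 3.25)),
            ([5, 5, 5, 5, 5], (5, 5, 5)),
        ],
    )
    def test_linear_interpolation_quartiles(self, values, expected):
        assert median_iqr(values) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(AnalysisError):
            median_iqr([])


class TestReport:
    def test_empty_cohort_yields_empty_report_with_headers(self, mapping):
        empty_eps = pd.DataFrame(
            columns=[
                "episode_id", "institution", "histology_label",
                "surgery_date", "rt_start_date", "systemic_start_date",
            ]
        )
        empty_obs = pd.DataFrame(columns=["episode_id", "obs_date", "eq5d_index", "eq_vas"])
        result = run_pipeline(empty_eps, empty_obs, mapping)
        assert result.report.table1.empty and result.report.table2.empty
        assert list(result.report.table1.columns)  # headers survive

    def test_denominator_discipline_on_synthetic_cohorts(self, mapping):
        cfg = GeneratorConfig(n_episodes_a=150, n_episodes_b=120, seed=13)
        eps, obs, _ = generate_cohort(cfg)
        result = run_pipeline(eps, obs, mapping, covariates=("sex", "margin_status"))
        rep = result.report
        for table in (rep.table1, rep.table2):
            cat = table.dropna(subset=["n", "denominator"])
            assert (cat["n"] <= cat["denominator"]).all()
            assert (cat["n"] >= 0).all()
        eligible = {
            g: int((result.cohort["institution"] == g).sum()) for g in rep.institutions
        }
        ev_rows = rep.table1[(rep.table1.section == "evaluability")]
        for g, n in eligible.items():
            assert (ev_rows[ev_rows.group == g]["denominator"] == n).all()
        # traffic-light denominators equal the evaluable n at the timepoint
        for tp in ("M12", "M24"):
            tl = rep.table2[
                (rep.table2.variable == f"final_{tp}") & (rep.table2.group != "OVERALL")
            ]
            for g in rep.institutions:
                n_ev = int(
                    (
                        (result.traffic["timepoint"] == tp)
                        & (result.traffic["institution"] == g)
                    ).sum()
                )
                assert (tl[tl.group == g]["denominator"] == n_ev).all()
        # stability denominators equal the dual-evaluable n
        stab = rep.table2[rep.table2.section == "stability"]
        for g in rep.institutions:
            n_dual = int((result.stability["institution"] == g).sum())
            assert (stab[stab.group == g]["denominator"] == n_dual).all()

    def test_end_to_end_determinism(self, tmp_path, mapping):
        cfg = GeneratorConfig(n_episodes_a=80, n_episodes_b=60, seed=5)
        outputs = []
        for name in ("run1", "run2"):
            eps, obs, _ = generate_cohort(cfg)
            result = run_pipeline(eps, obs, mapping)
            out = tmp_path / name
            result.write(out)
            outputs.append({p.name: p.read_bytes() for p in out.iterdir()})
        assert outputs[0] == outputs[1]
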