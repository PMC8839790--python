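"""HMF statistics: assumption checks, ANOVA, post hoc tests from summary
statistics, compact letter displays."""

import numpy as np
import pandas as pd
import pytest

from aquahoney import (
    check_assumptions,
    control_comparison,
    games_howell_from_summary,
    letter_display,
    posthoc,
    reference_hmf_summary,
    tukey_from_summary,
    two_way_anova,
)
from aquahoney.exceptions import DesignError, SupportError
from aquahoney.hmf import PosthocResult, one_way_anova_summary


def raw_from_summary(summary: pd.DataFrame, label_col: str) -> pd.DataFrame:
    """Raw triplets (m - s, m, m + s) matching each summary row's mean and
    sample SD exactly."""
    rows = []
    for r in summary.itertuples(index=False):
        m, s = r.mean, r.sd
        lab = getattr(r, label_col)
        for v in (m - s, m, m + s):
            rows.append((lab, v))
    return pd.DataFrame(rows, columns=[label_col, "hmf_mg_kg"])


class TestAssumptions:
    def test_identical_groups_levene_p_is_one(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(6) + 10
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 6), "hmf_mg_kg": np.tile(base, 3)}
        )
        _, levene_p = check_assumptions(df, "g")
        assert levene_p == pytest.approx(1.0, abs=1e-12)

    def test_heteroscedastic_groups_detected(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "g": np.repeat(["a", "b", "c"], 10),
                "hmf_mg_kg": np.concatenate(
                    [np.linspace(4.99, 5.01, 10), rng.normal(5, 3, 10), rng.normal(5, 3, 10)]
                ),
            }
        )
        _, levene_p = check_assumptions(df, "g")
        assert levene_p < 0.05

    def test_tiny_group_rejected(self):
        df = pd.DataFrame({"g": ["a", "a", "a", "b", "b"], "hmf_mg_kg": range(5)})
        with pytest.raises(SupportError):
            check_assumptions(df, "g")


class TestTwoWayAnova:
    def test_pure_temperature_effect_has_no_interaction(self):
        rows = []
        effect = {40: 1.0, 60: 2.0, 80: 4.0, 100: 8.0}
        jitter = iter(np.linspace(-0.01, 0.01, 48))
        for t, m in [(t, m) for t in (40, 60, 80, 100) for m in (60, 120, 180, 240)]:
            for _ in range(3):
                rows.append((t, m, effect[t] + next(jitter)))
        df = pd.DataFrame(rows, columns=["temperature_C", "time_min", "hmf_mg_kg"])
        tab = two_way_anova(df).set_index("effect")
        assert tab.loc["temperature", "p"] < 1e-6
        # the interaction explains (almost) nothing next to the main effect
        assert tab.loc["interaction", "F"] < 1.0

    def test_empty_cells_rejected(self):
        df = pd.DataFrame(
            {
                "temperature_C": [40, 40, 40, 60, 60, 60],
                "time_min": [60, 60, 60, 120, 120, 120],
                "hmf_mg_kg": [1, 2, 3, 4, 5, 6.0],
            }
        )
        with pytest.raises(DesignError):
            two_way_anova(df)


class TestPosthocFromSummaries:
    def test_published_extremes_are_separated(self):
        # 100 degC column: 60 min vs 240 min (printed letters a vs d)
        summ = pd.DataFrame(
            {"g": ["60", "240"], "mean": [40.3, 463.6], "sd": [0.8, 28.3], "n": [3, 3]}
        )
        res = games_howell_from_summary(summ)
        assert bool(res.pairs["significant"].iloc[0])

    def test_identical_cells_p_is_one(self):
        summ = pd.DataFrame(
            {"g": ["a", "b"], "mean": [5.0, 5.0], "sd": [1.0, 1.0], "n": [3, 3]}
        )
        res = games_howell_from_summary(summ)
        assert res.pairs["p"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_summary_equals_raw_reconstruction(self):
        ref = reference_hmf_summary()
        summ = ref[(ref.honey_type == "sunflower") & (ref.temperature_C == 100)].copy()
        summ["g"] = summ["time_min"].astype(str)
        summ = summ[["g", "mean", "sd", "n"]]
        res_sum = games_howell_from_summary(summ)
        raw = raw_from_summary(summ, "g")
        res_raw = posthoc(raw, homogeneous=False, by="g")
        merged = res_sum.pairs.merge(
            res_raw.pairs, on=["group_a", "group_b"], suffixes=("_s", "_r")
        )
        np.testing.assert_allclose(
            merged["statistic_s"], merged["statistic_r"], atol=1e-9
        )
        np.testing.assert_allclose(merged["p_s"], merged["p_r"], atol=1e-9)

    def test_matches_pingouin_games_howell(self):
        pg = pytest.importorskip("pingouin")
        summ = pd.DataFrame(
            {
                "g": ["a", "b", "c"],
                "mean": [10.0, 14.0, 30.0],
                "sd": [1.0, 2.5, 6.0],
                "n": [3, 3, 3],
            }
        )
        raw = raw_from_summary(summ, "g")
        ours = games_howell_from_summary(summ).pairs
        ref = pg.pairwise_gameshowell(data=raw, dv="hmf_mg_kg", between="g")
        for r in ref.itertuples(index=False):
            row = ours[(ours.group_a == r.A) & (ours.group_b == r.B)]
            assert row["p"].iloc[0] == pytest.approx(r.pval, abs=1e-6)
            assert row["df"].iloc[0] == pytest.approx(r.df, abs=1e-6)

    def test_tukey_agrees_with_games_howell_on_equal_variance_pair(self):
        summ = pd.DataFrame(
            {"g": ["a", "b"], "mean": [10.0, 13.0], "sd": [1.2, 1.2], "n": [3, 3]}
        )
        p_t = tukey_from_summary(summ).pairs["p"].iloc[0]
        p_gh = games_howell_from_summary(summ).pairs["p"].iloc[0]
        assert p_t == pytest.approx(p_gh, abs=1e-3)

    def test_summary_mode_requires_homogeneity_flag(self):
        summ = pd.DataFrame(
            {"g": ["a", "b"], "mean": [1.0, 2.0], "sd": [0.1, 0.1], "n": [3, 3]}
        )
        with pytest.raises(SupportError):
            posthoc(summ)

    def test_n_below_two_rejected(self):
        summ = pd.DataFrame(
            {"g": ["a", "b"], "mean": [1.0, 2.0], "sd": [0.1, 0.1], "n": [1, 3]}
        )
        with pytest.raises(SupportError):
            games_howell_from_summary(summ)


class TestPublishedTableLetters:
    """Qualitative separations of the published HMF table, recomputed from
    its printed mean/SD/n summaries."""

    def _column(self, honey, temp):
        ref = reference_hmf_summary()
        sub = ref[(ref.honey_type == honey) & (ref.temperature_C == temp)].copy()
        sub["g"] = sub["time_min"].astype(str)
        return sub[["g", "mean", "sd", "n"]]

    def test_sunflower_40C_column_all_equivalent(self):
        res = games_howell_from_summary(self._column("sunflower", 40))
        assert not res.pairs["significant"].any()
        letters = letter_display(res, ["60", "120", "180", "240"])
        assert set(letters.values()) == {"a"}

    def test_sunflower_100C_column_60min_separates(self):
        res = games_howell_from_summary(self._column("sunflower", 100))
        letters = letter_display(res, ["60", "120", "180", "240"])
        assert letters["60"] == "a"
        assert all("a" not in letters[g] for g in ("120", "180", "240"))


class TestControlComparison:
    def test_control_vs_itself_not_starred(self):
        summ = pd.DataFrame(
            {
                "g": ["ctrl", "copy", "high"],
                "mean": [10.0, 10.0, 60.0],
                "sd": [1.0, 1.0, 2.0],
                "n": [3, 3, 3],
            }
        )
        stars = control_comparison(summ, "ctrl", homogeneous=False)
        flag = dict(zip(stars.level, stars.star))
        assert not flag["copy"] and flag["high"]

    def test_missing_control_rejected(self):
        summ = pd.DataFrame(
            {"g": ["a", "b"], "mean": [1.0, 2.0], "sd": [0.1, 0.1], "n": [3, 3]}
        )
        with pytest.raises(DesignError):
            control_comparison(summ, "ctrl", homogeneous=False)

    def test_one_way_anova_summary_matches_scipy_on_raw(self):
        from scipy import stats

        summ = pd.DataFrame(
            {
                "g": ["a", "b", "c"],
                "mean": [10.0, 12.0, 30.0],
                "sd": [1.0, 2.0, 3.0],
                "n": [3, 3, 3],
            }
        )
        raw = raw_from_summary(summ, "g")
        F, p = one_way_anova_summary(summ["mean"], summ["sd"], summ["n"])
        groups = [g["hmf_mg_kg"].to_numpy() for _, g in raw.groupby("g")]
        F_ref, p_ref = stats.f_oneway(*groups)
        assert F == pytest.approx(F_ref, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-9)


class TestLetterDisplay:
    def _result(self, sig_pairs, groups):
        rows = []
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                sig = (a, b) in sig_pairs or (b, a) in sig_pairs
                rows.append((a, b, 5.0, 4.0, 0.01 if sig else 0.5, sig))
        return PosthocResult(
            pd.DataFrame(
                rows,
                columns=["group_a", "group_b", "statistic", "df", "p", "significant"],
            ),
            "tukey",
        )

    def test_all_pairs_significant_gives_distinct_letters(self):
        groups = ["1", "2", "3", "4"]
        res = self._result(
            {(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]}, groups
        )
        assert letter_display(res, groups) == {"1": "a", "2": "b", "3": "c", "4": "d"}

    def test_no_pair_significant_shares_one_letter(self):
        groups = ["1", "2", "3", "4"]
        assert set(letter_display(self._result(set(), groups), groups).values()) == {"a"}

    def test_chain_where_only_extremes_differ(self):
        groups = ["1", "2", "3", "4"]
        letters = letter_display(self._result({("1", "4")}, groups), groups)
        assert letters == {"1": "a", "2": "ab", "3": "ab", "4": "b"}
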