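"""Inferential layer: t/F identities, Scheffé conservativeness,
reliability, ANCOVA, behavioral tests, topography, asymmetry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from fnirsbci import stats as fs
from fnirsbci.montage import default_layout
from fnirsbci.synthetic import simulate_purchases, simulate_questionnaire


def _means_table(values: dict[tuple[str, int], np.ndarray]) -> pd.DataFrame:
    """(subject, session) -> per-channel means, as the tidy table."""
    rows = []
    for (subject, session), v in values.items():
        for ch, x in enumerate(v, start=1):
            rows.append({"subject": subject, "session": session,
                         "channel": ch, "mean_dhbo": float(x)})
    return pd.DataFrame(rows)


def test_stars_thresholds():
    assert fs.stars(0.0005) == "***"
    assert fs.stars(0.005) == "**"
    assert fs.stars(0.049) == "*"
    assert fs.stars(0.05) == ""


class TestChannelContrast:
    def test_identical_groups_t_zero_p_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 15))
        vals = {}
        for i in range(6):
            vals[(f"S{i}", 1)] = base[i]
            vals[(f"S{i}b", 2)] = base[i]
        out = fs.channel_contrast(_means_table(vals))
        assert np.allclose(out["t"], 0, atol=1e-12)
        assert np.allclose(out["p"], 1, atol=1e-12)

    def test_matches_hand_coded_t_formula(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        vals = {}
        for i, x in enumerate(a):
            vals[(f"A{i}", 1)] = np.full(15, x)
        for i, x in enumerate(b):
            vals[(f"B{i}", 2)] = np.full(15, x)
        out = fs.channel_contrast(_means_table(vals))
        row = out[out["channel"] == 1].iloc[0]
        if row["equal_var"]:
            sp = np.sqrt(((len(a) - 1) * a.var(ddof=1)
                          + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2))
            t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        else:
            t_hand = ((a.mean() - b.mean())
                      / np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
        assert np.isclose(row["t"], t_hand, atol=1e-10)

    def test_zero_variance_both_groups_rejected(self):
        vals = {("A", 1): np.ones(15), ("B", 1): np.ones(15),
                ("C", 2): np.ones(15), ("D", 2): np.ones(15)}
        with pytest.raises(ValueError, match="zero variance"):
            fs.channel_contrast(_means_table(vals))

    def test_bonferroni_never_smaller(self):
        rng = np.random.default_rng(2)
        vals = {}
        for i in range(8):
            vals[(f"A{i}", 1)] = rng.normal(size=15)
            vals[(f"B{i}", 2)] = rng.normal(size=15)
        plain = fs.channel_contrast(_means_table(vals))
        bonf = fs.channel_contrast(_means_table(vals), correction="bonferroni")
        assert (bonf["p_adj"].to_numpy() >= plain["p_adj"].to_numpy() - 1e-15).all()


class TestRoiAnova:
    def test_equal_roi_means_give_small_f(self):
        layout = default_layout()
        rng = np.random.default_rng(3)
        vals = {(f"S{i}", 1): np.full(15, 1.0) + 1e-6 * rng.normal(size=15)
                for i in range(10)}
        res = fs.roi_anova(_means_table(vals), layout, session=1)
        assert res["p"] > 0.1

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        f, p = st.f_oneway(a, b)
        t, _ = st.ttest_ind(a, b, equal_var=True)
        assert np.isclose(f, t ** 2, atol=1e-10)
        pairs = fs.scheffe_pairs({"x": a, "y": b})
        assert np.isclose(pairs["F_contrast"].iloc[0], t ** 2, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_scheffe_p_never_below_unadjusted(self, seed):
        rng = np.random.default_rng(seed)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, rng.integers(5, 12))
                  for i in range(4)}
        pairs = fs.scheffe_pairs(groups)
        assert (pairs["p_scheffe"] >= pairs["p_unadjusted"] - 1e-15).all()

    def test_roi_with_single_observation_rejected(self):
        layout = default_layout()
        vals = {("S0", 1): np.arange(15.0), ("S1", 1): np.arange(15.0) + 1}
        table = _means_table(vals)
        table = table[~((table["subject"] == "S1"))]
        with pytest.raises(ValueError, match="fewer than 2"):
            fs.roi_anova(table, layout, session=1)


class TestSummaryAnova:
    def test_printed_self_report_contrast(self):
        res = fs.summary_anova(4.52, 1.35, 30, 3.26, 1.46, 30)
        assert res["df"] == (1, 58)
        assert abs(res["F"] - 12.02) / 12.02 < 0.01

    def test_equal_means_f_zero(self):
        assert fs.summary_anova(3.0, 1.0, 20, 3.0, 2.0, 25)["F"] == 0.0

    def test_matches_raw_anova_on_exact_moment_data(self):
        """Construct groups with exactly the requested moments and
        compare with scipy's raw-data ANOVA."""
        def make(m, sd, n, seed):
            x = np.random.default_rng(seed).normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return m + sd * x
        a = make(4.1, 1.2, 14, 0)
        b = make(2.9, 0.8, 19, 1)
        f_raw, p_raw = st.f_oneway(a, b)
        res = fs.summary_anova(4.1, 1.2, 14, 2.9, 0.8, 19)
        assert np.isclose(res["F"], f_raw, atol=1e-8)
        assert np.isclose(res["p"], p_raw, atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fs.summary_anova(1, 1, 1, 2, 1, 30)
        with pytest.raises(ValueError):
            fs.summary_anova(1, 0, 10, 2, 1, 30)


class TestAncova:
    @staticmethod
    def _scores(rng, gender_effect=0.0, session_effect=1.0, n=30):
        rows = []
        for session in (1, 2):
            genders = rng.permutation(["male"] * 13 + ["female"] * 17)
            for i in range(n):
                g = genders[i]
                score = (3.0 + session_effect * (session == 1)
                         + gender_effect * (g == "male") + rng.normal(0, 1))
                rows.append({"score": score, "session": session, "gender": g})
        return pd.DataFrame(rows)

    def test_single_gender_rejected(self, rng):
        df = self._scores(rng)
        df["gender"] = "female"
        with pytest.raises(ValueError, match="both genders"):
            fs.ancova_gender(df)

    def test_null_gender_adjusted_matches_unadjusted(self):
        """With no true gender effect the adjusted session F stays close
        to the plain one-way ANOVA F (nested-model oracle)."""
        rng = np.random.default_rng(5)
        df = self._scores(rng, gender_effect=0.0)
        res = fs.ancova_gender(df)
        f_plain, _ = st.f_oneway(df.loc[df["session"] == 1, "score"],
                                 df.loc[df["session"] == 2, "score"])
        assert abs(res["session_F"] - f_plain) / f_plain < 0.15

    def test_gender_p_uniform_under_null(self):
        """Covariate p over replicates is uniform (KS test)."""
        rng = np.random.default_rng(6)
        ps = [fs.ancova_gender(self._scores(rng))["gender_p"]
              for _ in range(120)]
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_cross_check_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        df = self._scores(rng, gender_effect=0.4)
        df["gender_num"] = (df["gender"] == "male").astype(int)
        res = fs.ancova_gender(df)
        pg = pingouin.ancova(data=df, dv="score", between="session",
                             covar="gender_num")
        pcol = "p_unc" if "p_unc" in pg.columns else "p-unc"
        p_pg = float(pg.loc[pg["Source"] == "session", pcol].iloc[0])
        assert np.isclose(res["session_p"], p_pg, atol=1e-8)


class TestCronbach:
    def test_identical_items_alpha_one(self):
        rows = []
        rng = np.random.default_rng(8)
        for r in range(10):
            s = int(rng.integers(1, 6))
            for j in range(4):
                rows.append({"respondent_id": r, "construct": "impulse_buying",
                             "item_id": f"i{j}", "score": s,
                             "condition": "c", "gender": "female"})
        rep = fs.cronbach_alpha(pd.DataFrame(rows))
        assert np.isclose(rep.cronbach_alpha, 1.0, atol=1e-12)
        assert rep.reliable

    def test_hand_computed_toy_table(self):
        # 4 respondents x 3 items
        scores = np.array([[1, 2, 2], [3, 3, 4], [4, 4, 5], [2, 3, 3]])
        rows = [{"respondent_id": r, "construct": "time_pressure",
                 "item_id": f"i{j}", "score": int(scores[r, j]),
                 "condition": "c", "gender": "male"}
                for r in range(4) for j in range(3)]
        k = 3
        item_vars = scores.var(axis=0, ddof=1).sum()
        total_var = scores.sum(axis=1).var(ddof=1)
        alpha_hand = k / (k - 1) * (1 - item_vars / total_var)
        rep = fs.cronbach_alpha(pd.DataFrame(rows))
        assert np.isclose(rep.cronbach_alpha, alpha_hand, atol=1e-12)

    def test_cross_check_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df, _ = simulate_questionnaire(rng, "time_pressure",
                                       {"c": (3.5, 1.0, 25)})
        wide = df.pivot_table(index="respondent_id", columns="item_id",
                              values="score")
        alpha_pg = pingouin.cronbach_alpha(data=wide)[0]
        rep = fs.cronbach_alpha(df)
        assert np.isclose(rep.cronbach_alpha, alpha_pg, atol=1e-10)

    def test_reliability_rule(self):
        assert fs.ReliabilityReport("x", 0.872, 3, 30).reliable
        assert not fs.ReliabilityReport("x", 0.69, 3, 30).reliable

    def test_zero_total_variance_rejected(self):
        rows = [{"respondent_id": r, "construct": "impulse_buying",
                 "item_id": f"i{j}", "score": 3, "condition": "c",
                 "gender": "male"} for r in range(4) for j in range(3)]
        with pytest.raises(ValueError, match="variance"):
            fs.cronbach_alpha(pd.DataFrame(rows))


class TestPurchaseTests:
    def test_identical_sessions_t_zero(self, rng):
        df1 = simulate_purchases(rng, {1: {"alcohol": (40, 1.0)}}, 20)
        df2 = df1.copy()
        df2["session"] = 2
        out = fs.purchase_tests(pd.concat([df1, df2]))
        assert np.allclose(out["t"], 0, atol=1e-12)

    def test_printed_sums_give_positive_session1_bias(self):
        """At the study's category sums, session 1 totals exceed
        session 2 in expectation (Monte-Carlo direction check)."""
        from fnirsbci.synthetic import DEFAULT_PURCHASE_SUMS
        rng = np.random.default_rng(9)
        ts = []
        for _ in range(40):
            df = simulate_purchases(rng, DEFAULT_PURCHASE_SUMS, 30)
            out = fs.purchase_tests(df)
            ts.append(float(out.loc[out["category"] == "total", "t"].iloc[0]))
        assert np.mean(ts) > 1.0  # right direction, clearly nonzero

    def test_all_zero_category_flagged(self):
        rows = [{"respondent_id": i, "session": s, "category": "cigarettes",
                 "count": 0} for i in range(10) for s in (1, 2)]
        out = fs.purchase_tests(pd.DataFrame(rows))
        assert out["degenerate"].all()
        assert (out["t"] == 0).all()


class TestTopography:
    def test_single_active_channel_maps_to_one(self):
        layout = default_layout()
        v = np.zeros(15)
        v[4] = 0.7
        tm = fs.topographic_map(_means_table({("S0", 1): v, ("S0b", 2): np.zeros(15)}),
                                layout)
        assert np.isclose(tm.normalized[1][4], 1.0)
        assert np.allclose(np.delete(tm.normalized[1], 4), 0.0)
        assert np.allclose(tm.normalized[2], 0.0)

    def test_negation_flips_map(self):
        layout = default_layout()
        rng = np.random.default_rng(10)
        v = rng.normal(size=15)
        t1 = fs.topographic_map(_means_table({("a", 1): v, ("b", 2): 0.5 * v}), layout)
        t2 = fs.topographic_map(_means_table({("a", 1): -v, ("b", 2): -0.5 * v}), layout)
        for s in (1, 2):
            assert np.allclose(t1.normalized[s], -t2.normalized[s], atol=1e-12)
            assert np.all(np.abs(t1.normalized[s]) <= 1 + 1e-12)

    def test_idw_exact_at_channel_positions(self):
        layout = default_layout()
        rng = np.random.default_rng(11)
        v = rng.normal(size=15)
        tm = fs.topographic_map(_means_table({("a", 1): v, ("b", 2): v}), layout)
        # re-evaluate the interpolant exactly at a channel site
        from fnirsbci.stats import _idw
        xy = np.array([layout.positions[ch] for ch in layout.channel_ids])
        out = _idw(xy, tm.normalized[1], np.array([xy[6, 0]]),
                   np.array([xy[6, 1]]))
        assert np.isclose(out[0, 0], tm.normalized[1][6], atol=1e-12)

    def test_all_zero_means_give_zero_map(self):
        layout = default_layout()
        tm = fs.topographic_map(
            _means_table({("a", 1): np.zeros(15), ("b", 2): np.zeros(15)}), layout)
        assert np.allclose(tm.normalized[1], 0.0)


class TestAsymmetry:
    def test_mirror_symmetric_means_zero_index(self):
        layout = default_layout()
        v = np.zeros(15)
        for ch in range(1, 8):
            v[ch - 1] = ch
            v[15 - ch] = ch  # mirror channel 16-ch
        out = fs.asymmetry_index(_means_table({("S0", 1): v}), layout)
        assert np.isclose(out["asymmetry"].iloc[0], 0.0, atol=1e-12)

    def test_right_two_left_one(self):
        layout = default_layout()
        v = np.zeros(15)
        v[:7] = 2.0   # right channels 1-7
        v[8:] = 1.0   # left channels 9-15
        v[7] = 99.0   # midline excluded
        out = fs.asymmetry_index(_means_table({("S0", 1): v}), layout)
        assert np.isclose(out["asymmetry"].iloc[0], 1.0)

    def test_hemisphere_relabel_flips_sign(self):
        layout = default_layout()
        rng = np.random.default_rng(12)
        v = rng.normal(size=15)
        out = fs.asymmetry_index(_means_table({("S0", 1): v}), layout)
        # swap hemispheres by mirroring the channel values
        v_sw = v.copy()
        for ch in range(1, 8):
            v_sw[ch - 1], v_sw[15 - ch] = v[15 - ch], v[ch - 1]
        out_sw = fs.asymmetry_index(_means_table({("S0", 1): v_sw}), layout)
        assert np.isclose(out["asymmetry"].iloc[0],
                          -out_sw["asymmetry"].iloc[0], atol=1e-12)
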