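"""Statistical battery tests: oracles, cross-checks and recovery runs."""

import numpy as np
import pandas as pd
import pytest

import pingouin as pg
from statsmodels.stats.anova import AnovaRM

from eegfd import stats as st


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(20.0)
        res = st.correlate(x, 2 * x + 1, method="pearson")
        assert res.statistic == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_monotone_nonlinear_spearman(self):
        x = np.arange(1.0, 21.0)
        res = st.correlate(x, np.exp(x / 3), method="spearman")
        assert res.statistic == pytest.approx(1.0)

    def test_auto_gate_prefers_pearson_for_gaussian(self, rng):
        x = rng.standard_normal(200)
        y = x + rng.standard_normal(200)
        res = st.correlate(x, y, method="auto")
        assert res.effect["method"] == "pearson"

    def test_auto_gate_switches_to_spearman_for_skewed(self, rng):
        x = rng.standard_normal(200)
        y = np.exp(3 + x + rng.standard_normal(200))  # heavily skewed
        res = st.correlate(x, y, method="auto")
        assert res.effect["method"] == "spearman"

    def test_monte_carlo_recovery_of_rho(self):
        rng = np.random.default_rng(7)
        cov = [[1, 0.3], [0.3, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=1000)
        res = st.correlate(xy[:, 0], xy[:, 1], method="pearson")
        assert res.statistic == pytest.approx(0.3, abs=0.1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.correlate(np.ones(10), np.arange(10.0))


class TestFitQuadratic:
    def test_exact_parabola_recovered(self):
        age = np.linspace(20, 90, 41)
        hfd = -2e-5 * age**2 + 2.4e-3 * age + 1.87
        res = st.fit_quadratic(age, hfd)
        assert res.effect["r2"] == pytest.approx(1.0, abs=1e-9)
        assert res.effect["a"] == pytest.approx(-2e-5, abs=1e-12)
        assert res.effect["vertex_age"] == pytest.approx(60.0, abs=1e-6)

    def test_vertex_recovery_under_noise(self):
        rng = np.random.default_rng(11)
        age = np.concatenate([rng.uniform(20, 50, 24), rng.uniform(51, 85, 17)])
        hfd = 1.945 - 2e-5 * (age - 60) ** 2 + rng.normal(0, 0.01, 41)
        res = st.fit_quadratic(age, hfd)
        assert res.effect["a"] < 0
        assert res.effect["vertex_age"] == pytest.approx(60, abs=8)

    def test_constant_response_gives_zero_coefficients(self):
        age = np.linspace(20, 80, 20)
        res = st.fit_quadratic(age, np.full(20, 1.9))
        assert res.effect["a"] == pytest.approx(0.0, abs=1e-12)
        assert res.effect["b"] == pytest.approx(0.0, abs=1e-10)
        assert res.effect["r2"] == 0.0

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            st.fit_quadratic([50, 50, 50, 50], [1, 2, 3, 4])


class TestPartialCorrelation:
    def test_y_equal_to_control_partials_to_zero(self, rng):
        c = rng.standard_normal(50)
        x = rng.standard_normal(50)
        res = st.partial_correlation(x, c, c)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_recursion_formula_oracle(self, rng):
        x, y, c = rng.standard_normal((3, 200))
        y = y + 0.5 * c
        x = x + 0.3 * c
        rxy = np.corrcoef(x, y)[0, 1]
        rxc = np.corrcoef(x, c)[0, 1]
        ryc = np.corrcoef(y, c)[0, 1]
        closed = (rxy - rxc * ryc) / np.sqrt((1 - rxc**2) * (1 - ryc**2))
        res = st.partial_correlation(x, y, c)
        assert res.statistic == pytest.approx(closed, abs=1e-9)

    def test_independent_control_leaves_r_nearly_unchanged(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2000)
        y = 0.5 * x + rng.standard_normal(2000)
        c = rng.standard_normal(2000)
        raw = np.corrcoef(x, y)[0, 1]
        res = st.partial_correlation(x, y, c)
        assert res.statistic == pytest.approx(raw, abs=0.05)

    def test_agrees_with_pingouin(self, rng):
        x, y, c = rng.standard_normal((3, 60))
        df = pd.DataFrame({"x": x, "y": y + 0.4 * c, "c": c})
        res = st.partial_correlation(df["x"], df["y"], df["c"])
        ref = pg.partial_corr(df, x="x", y="y", covar="c")
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)


def _mixed_long(frame, groups):
    rows = []
    for i, (sid, row) in enumerate(frame.iterrows()):
        for j, v in enumerate(row):
            rows.append({"subj": sid, "grp": groups[i], "w": j, "y": v})
    return pd.DataFrame(rows)


class TestMixedANOVA:
    def test_matches_pingouin_one_within_balanced(self, rng):
        n = 12
        Y, groups = [], []
        for g in range(2):
            base = rng.normal(0, 1, (n, 1))
            Y.append(base + rng.normal(0, 1, (n, 4)) + 0.4 * g * np.arange(4))
            groups += [f"G{g}"] * n
        frame = pd.DataFrame(np.vstack(Y), index=[f"s{i}" for i in range(2 * n)])
        mine = st.mixed_rm_anova(frame, groups, within=[("w", 4)])
        ref = pg.mixed_anova(
            data=_mixed_long(frame, groups), dv="y", within="w",
            between="grp", subject="subj", correction=True,
        ).set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        assert mine.loc["w", "F"] == pytest.approx(ref.loc["w", "F"], rel=1e-9)
        assert mine.loc["w*group", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert mine.loc["w", "p"] == pytest.approx(ref.loc["w", "p_unc"], rel=1e-6)
        # epsilon conventions differ (pooled within-group vs total
        # covariance), so only rough agreement is expected here
        assert mine.loc["w", "eps_gg"] == pytest.approx(ref.loc["w", "eps"], abs=0.1)

    def test_gg_epsilon_matches_pingouin_single_group(self, rng):
        Y = rng.normal(0, 1, (30, 5)) + rng.normal(0, 1, (30, 1)) * np.linspace(0.5, 2, 5)
        frame = pd.DataFrame(Y)
        mine = st.mixed_rm_anova(frame, ["G"] * 30, within=[("w", 5)])
        assert mine.loc["w", "eps_gg"] == pytest.approx(
            float(pg.epsilon(frame, correction="gg")), abs=1e-9
        )

    def test_matches_anovarm_two_within_no_between(self, rng):
        n = 10
        Y = rng.normal(0, 1, (n, 6)) + rng.normal(0, 1, (n, 1))
        frame = pd.DataFrame(Y)
        mine = st.mixed_rm_anova(frame, ["G"] * n, within=[("a", 3), ("b", 2)])
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(n), 6),
                "a": np.tile(np.repeat(np.arange(3), 2), n),
                "b": np.tile(np.arange(2), 3 * n),
                "y": Y.ravel(),
            }
        )
        ref = AnovaRM(long, "y", "subj", within=["a", "b"]).fit().anova_table
        for eff, key in (("a", "a"), ("b", "b"), ("a*b", "a:b")):
            assert mine.loc[eff, "F"] == pytest.approx(
                ref.loc[key, "F Value"], rel=1e-9
            )
            assert mine.loc[eff, "p"] == pytest.approx(
                ref.loc[key, "Pr > F"], rel=1e-6
            )

    def test_gg_epsilon_near_one_under_compound_symmetry(self, rng):
        n = 200
        Y = rng.normal(0, 1, (n, 5)) + 2.0 * rng.normal(0, 1, (n, 1))
        frame = pd.DataFrame(Y)
        out = st.mixed_rm_anova(frame, ["G"] * n, within=[("w", 5)])
        assert out.loc["w", "eps_gg"] == pytest.approx(1.0, abs=0.05)

    def test_missing_cells_listed(self):
        frame = pd.DataFrame(np.ones((4, 4)))
        frame.iloc[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            st.mixed_rm_anova(frame, ["A", "A", "B", "B"], within=[("w", 4)])

    def test_single_subject_groups_rejected(self):
        frame = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValueError, match="insufficient"):
            st.mixed_rm_anova(frame, ["A", "B", "C"], within=[("w", 2)])

    def test_group_main_effect_detected_without_within_effect(self):
        # power check against the generating model: a pure between-group
        # shift must light up 'group' and leave the interaction null
        rng = np.random.default_rng(5)
        hits_group, hits_int = 0, 0
        for _ in range(50):
            Y, groups = [], []
            for g, delta in enumerate((0.0, 1.0, 2.0)):
                Y.append(delta + rng.normal(0, 1, (20, 1)) + rng.normal(0, 0.5, (20, 4)))
                groups += [f"G{g}"] * 20
            frame = pd.DataFrame(np.vstack(Y))
            out = st.mixed_rm_anova(frame, groups, within=[("w", 4)])
            hits_group += out.loc["group", "p"] < 0.05
            hits_int += out.loc["w*group", "p_corr"] < 0.05
        assert hits_group >= 45  # power >= .9 at this effect size
        assert hits_int <= 8  # interaction stays near the nominal rate


class TestPosthocs:
    def test_bonferroni_family_of_two(self, rng):
        values = {}
        groups = {}
        for g, mu in (("YC", 0.0), ("EC", 0.0), ("AD", 2.0)):
            for i in range(15):
                sid = f"{g}{i}"
                values[sid] = float(rng.normal(mu, 1))
                groups[sid] = g
        out = st.posthoc_group_tests(values, groups)
        assert [r.name for r in out] == ["YC vs EC", "EC vs AD"]
        for r in out:
            assert r.correction == "bonferroni"
            assert r.effect["family_size"] == 2
            assert r.p == pytest.approx(min(1.0, 2 * r.p_uncorrected))
        assert out[1].p < 0.05 and out[0].p > 0.05

    def test_identical_groups_rarely_flagged(self):
        false_hits = 0
        for rep in range(100):
            rng = np.random.default_rng(900 + rep)
            values, groups = {}, {}
            for g in ("YC", "EC", "AD"):
                for i in range(12):
                    sid = f"{g}{i}"
                    values[sid] = float(rng.normal(0, 1))
                    groups[sid] = g
            out = st.posthoc_group_tests(values, groups)
            false_hits += any(r.p < 0.05 for r in out)
        assert false_hits <= 7  # >= 93% clean null replicates


class TestHArSAnova:
    @staticmethod
    def _profiles(rng, shift_group=None, region="parietal", delta=0.01, n=15):
        profs, groups = {}, {}
        for g in ("YC", "EC", "AD"):
            for i in range(n):
                sid = f"{g}{i}"
                base = {r: float(rng.normal(0, 0.005))
                        for r in ("frontal", "central", "temporal", "parietal", "occipital")}
                if g == shift_group:
                    base[region] += delta
                profs[sid] = base
                groups[sid] = g
        return profs, groups

    def test_null_rate_on_symmetric_cohort(self):
        hits = 0
        for rep in range(60):
            rng = np.random.default_rng(100 + rep)
            profs, groups = self._profiles(rng)
            out = st.hars_anova(profs, groups)
            hits += sum(e["omnibus"].p < 0.05 for e in out.values())
        rate = hits / (60 * 5)
        assert 0.0 <= rate < 0.12

    def test_shifted_group_flagged_with_correct_posthoc(self, rng):
        profs, groups = self._profiles(rng, shift_group="AD", delta=0.02, n=20)
        out = st.hars_anova(profs, groups)
        assert out["parietal"]["omnibus"].p < 0.05
        ec_ad = [r for r in out["parietal"]["posthoc"] if "EC vs AD" in r.name][0]
        assert ec_ad.p < 0.05
        yc_ec = [r for r in out["parietal"]["posthoc"] if "YC vs EC" in r.name][0]
        assert yc_ec.p > 0.05


class TestMatching:
    @staticmethod
    def _cov(rng, n=20, shift=0.0):
        rows = []
        for g in ("EC", "AD"):
            for i in range(n):
                rows.append(
                    {
                        "group": g,
                        "age": float(rng.normal(70 + (shift if g == "AD" else 0), 5)),
                        "education_years": float(rng.normal(9, 4)),
                        "mmse": float(rng.normal(24, 3)),
                        "sex": "M" if rng.random() < 0.4 else "F",
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_give_t0_p1(self):
        rows = []
        for g in ("EC", "AD"):
            for age in (60.0, 70.0, 80.0):
                rows.append({"group": g, "age": age, "sex": "M" if age < 75 else "F"})
        out = st.matching_tests(pd.DataFrame(rows), pairs=[("EC", "AD")],
                                columns=("age",))
        assert out[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert out[0].p == pytest.approx(1.0)

    def test_noncentrality_oracle(self):
        # means 0 vs 1, sigma 1, n = 50/50: E|t| ~ sqrt(n/2) = 5
        rng = np.random.default_rng(21)
        ts = []
        for _ in range(300):
            rows = [{"group": "EC", "age": float(v)} for v in rng.normal(0, 1, 50)]
            rows += [{"group": "AD", "age": float(v)} for v in rng.normal(1, 1, 50)]
            out = st.matching_tests(pd.DataFrame(rows), pairs=[("EC", "AD")],
                                    columns=("age",))
            ts.append(abs(out[0].statistic))
        assert np.mean(ts) == pytest.approx(np.sqrt(25.0), abs=0.5)

    def test_single_subject_group_skipped(self, caplog):
        rows = [{"group": "EC", "age": 70.0}] + [
            {"group": "AD", "age": float(a)} for a in (70, 72, 74)
        ]
        with caplog.at_level("INFO"):
            out = st.matching_tests(pd.DataFrame(rows), pairs=[("EC", "AD")],
                                    columns=("age",))
        assert out == []

    def test_sex_compared_both_ways(self, rng):
        out = st.matching_tests(self._cov(rng), pairs=[("EC", "AD")])
        names = [r.name for r in out]
        assert "sex: EC vs AD" in names
        assert "sex chi2: EC vs AD" in names
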