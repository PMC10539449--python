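"""Statistical battery: ANOVA oracle equivalence, Bayes factors, power,
nonparametrics, assumption routing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from racquetvr import stats as st
from conftest import make_long_table


class TestMixedAnova:
    def test_matches_pingouin_on_balanced_data(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(3):
            df = make_long_table(rng, n_per_group=15, group_shift=0.8,
                                 interaction=0.5)
            mine = st.mixed_anova_2x2(df, "y")
            ref = pg.mixed_anova(data=df, dv="value", within="condition",
                                 between="group",
                                 subject="participant_id").set_index("Source")
            for eff, src in [("group", "group"), ("condition", "condition"),
                             ("interaction", "Interaction")]:
                assert mine[eff].value == pytest.approx(ref.loc[src, "F"], rel=1e-9)
                assert mine[eff].p == pytest.approx(ref.loc[src, "p_unc"], rel=1e-9)
                assert mine[eff].effect_size == pytest.approx(
                    ref.loc[src, "np2"], rel=1e-9)

    def test_matches_direct_cell_mean_ss_oracle(self, rng):
        # brute-force balanced split-plot decomposition from cell means
        df = make_long_table(rng, n_per_group=12, group_shift=0.5,
                             cond_shift=0.3, interaction=0.4)
        mine = st.mixed_anova_2x2(df, "y")
        wide = df.pivot_table(index="participant_id", columns="condition",
                              values="value")
        grp = df.drop_duplicates("participant_id").set_index(
            "participant_id")["group"].reindex(wide.index)
        y = wide.to_numpy()  # (subjects, 2) columns control/cued
        g = (grp == "ASD").to_numpy()
        n = g.sum()
        grand = y.mean()
        subj_mean = y.mean(axis=1)
        cell = np.array([[y[g, 0].mean(), y[g, 1].mean()],
                         [y[~g, 0].mean(), y[~g, 1].mean()]])
        gm = cell.mean(axis=1)
        cm = cell.mean(axis=0)
        ss_group = 2 * n * ((gm - grand) ** 2).sum()
        ss_subj = 2 * sum(
            (subj_mean[i] - gm[0 if g[i] else 1]) ** 2 for i in range(len(g)))
        ss_cond = 2 * n * ((cm - grand) ** 2).sum()
        ss_inter = n * ((cell - gm[:, None] - cm[None, :] + grand) ** 2).sum()
        ss_err_w = sum(
            (y[i, c] - subj_mean[i] - cell[0 if g[i] else 1, c]
             + gm[0 if g[i] else 1]) ** 2
            for i in range(len(g)) for c in (0, 1))
        df_err = len(g) - 2
        assert mine["group"].value == pytest.approx(
            ss_group / (ss_subj / df_err), rel=1e-9)
        assert mine["condition"].value == pytest.approx(
            ss_cond / (ss_err_w / df_err), rel=1e-9)
        assert mine["interaction"].value == pytest.approx(
            ss_inter / (ss_err_w / df_err), rel=1e-9)
        # SS identity on the full decomposition
        ss_total = ((y - grand) ** 2).sum()
        assert ss_total == pytest.approx(
            ss_group + ss_subj + ss_cond + ss_inter + ss_err_w, rel=1e-9)

    def test_partial_eta_squared_reproduces_f(self, rng):
        df = make_long_table(rng, n_per_group=10, interaction=0.6)
        res = st.mixed_anova_2x2(df, "y")
        for eff in res.values():
            df1, df2 = eff.df
            pes = eff.effect_size
            assert eff.value == pytest.approx(
                (pes / (1 - pes)) * df2 / df1, rel=1e-9)

    def test_degenerate_constant_data_flagged(self):
        rows = [dict(participant_id=f"P{i}", group="ASD" if i < 5 else "NT",
                     condition=c, outcome_name="y", value=1.0)
                for i in range(10) for c in ("control", "cued")]
        res = st.mixed_anova_2x2(pd.DataFrame(rows), "y")
        assert math.isnan(res["interaction"].value)
        assert "degenerate" in res["interaction"].note

    def test_too_few_participants_error(self):
        rows = [dict(participant_id=f"P{i}", group="ASD" if i == 0 else "NT",
                     condition=c, outcome_name="y", value=float(i + ord(c[0])))
                for i in range(3) for c in ("control", "cued")]
        with pytest.raises(ValueError):
            st.mixed_anova_2x2(pd.DataFrame(rows), "y")

    def test_interaction_type1_error_calibrated(self):
        # the full 10k-replicate check lives in the acceptance suite; this is a
        # fast regression guard
        rate = st.interaction_type1_rate(n_per_group=22, n_sims=1500, seed=7)
        assert 0.03 < rate < 0.07


class TestBayesFactors:
    def test_matches_independent_quadrature_oracle(self):
        # oracle: substitution g = u/(1-u) and dense Simpson integration
        def oracle(t, n, r=0.707):
            df = n - 1
            u = np.linspace(1e-9, 1 - 1e-9, 400_001)
            g = u / (1 - u)
            jac = 1 / (1 - u) ** 2
            integrand = ((1 + n * g * r**2) ** -0.5
                         * (1 + t**2 / ((1 + n * g * r**2) * df)) ** (-(df + 1) / 2)
                         * (2 * np.pi) ** -0.5 * g**-1.5 * np.exp(-1 / (2 * g))
                         * jac)
            num = np.trapezoid(integrand, u)
            den = (1 + t**2 / df) ** (-(df + 1) / 2)
            return num / den

        for t, n in [(2.5, 30), (0.0, 20), (4.0, 15), (-1.7, 44)]:
            assert st.jzs_ttest_bf(t, n) == pytest.approx(
                oracle(t, n), rel=1e-6)

    def test_matches_pingouin_default(self):
        pg = pytest.importorskip("pingouin")
        for t, n in [(2.5, 30), (4.64, 21), (0.18, 21)]:
            assert st.jzs_ttest_bf(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-9)

    def test_null_favoured_at_zero_evidence(self):
        assert st.jzs_ttest_bf(0.0, 20) < 1.0

    def test_monotone_in_t(self):
        bfs = [st.jzs_ttest_bf(t, 40) for t in np.linspace(0, 6, 13)]
        assert all(b > a for a, b in zip(bfs, bfs[1:]))
        assert bfs[-1] > 1e3

    def test_bic_bf_direction(self):
        # strong effect: adding the parameter halves the RSS
        assert st.bic_bf(100.0, 50.0, 40, 1) > 1
        assert st.bic_bf(100.0, 99.9, 40, 1) < 1


class TestPosthocsAndNonparametrics:
    def test_identical_paired_samples(self, rng):
        df = make_long_table(rng, n_per_group=8)
        wide = df.pivot_table(index="participant_id", columns="condition",
                              values="value").reset_index()
        df.loc[df.condition == "cued", "value"] = (
            df.loc[df.condition == "control", "value"].to_numpy())
        res = st.posthoc_tests(df, "y")
        within = [r for r in res if "cued_vs_control" in r.name]
        for r in within:
            assert r.value == 0.0 and r.p == 1.0

    def test_bonferroni_arithmetic_and_bounds(self, rng):
        df = make_long_table(rng, n_per_group=10, group_shift=0.3)
        res = st.posthoc_tests(df, "y")
        assert len(res) == 4
        for r in res:
            assert r.correction == "bonferroni"
            assert r.p <= 1.0

    def test_mannwhitney_matches_exhaustive_rank_oracle(self, rng):
        # brute force: U = number of (a, b) pairs with a > b (+ half ties)
        for _ in range(10):
            a = rng.integers(0, 12, size=8).astype(float)
            b = rng.integers(0, 12, size=9).astype(float)
            u_scipy = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
            u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert u_scipy == pytest.approx(u_brute)
            # U + U' = n1 * n2
            u2 = sps.mannwhitneyu(b, a, alternative="two-sided").statistic
            assert u_scipy + u2 == len(a) * len(b)

    def test_nonparametric_routing_uses_u_test(self, rng):
        df = make_long_table(rng, n_per_group=10, group_shift=1.0)
        res = st.posthoc_tests(df, "y", nonparametric=True)
        between = [r for r in res if "ASD_vs_NT" in r.name]
        assert all(r.statistic_name == "U" for r in between)


class TestCorrelations:
    def test_outcome_equal_to_trait_gives_r_one(self, rng):
        df = make_long_table(rng, n_per_group=10)
        df["value"] = df["AQ_total"]
        res = st.trait_correlations(df, "y")
        aq = [r for r in res if "AQ_total" in r.name]
        assert all(r.value == pytest.approx(1.0) for r in aq)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        df = make_long_table(rng, n_per_group=12)
        base = st.trait_correlations(df, "y", nonparametric=True)
        df2 = df.copy()
        df2["value"] = np.exp(df2["value"])  # monotone transform
        trans = st.trait_correlations(df2, "y", nonparametric=True)
        for a, b in zip(base, trans):
            assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_spearman_matches_rank_formula_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho = sps.spearmanr(x, y).statistic
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        d2 = ((rx - ry) ** 2).sum()
        assert rho == pytest.approx(1 - 6 * d2 / (10 * 99), abs=1e-12)

    def test_zero_variance_flagged(self, rng):
        df = make_long_table(rng, n_per_group=6)
        df["value"] = 3.0
        res = st.trait_correlations(df, "y")
        assert all(r.note == "zero variance" for r in res)


class TestAssumptionChecks:
    def test_shapiro_passes_on_gaussian_data(self):
        rng = np.random.default_rng(0)
        passes = 0
        for s in range(50):
            x = rng.standard_normal(200)
            passes += sps.shapiro(x).pvalue > 0.05
        assert passes >= 44  # ~ alpha false-positive rate

    def test_levene_rejection_near_alpha_under_null(self):
        rng = np.random.default_rng(1)
        rej = sum(sps.levene(rng.standard_normal(22), rng.standard_normal(22),
                             center="mean").pvalue < 0.05
                  for _ in range(400))
        assert 0.02 < rej / 400 < 0.09

    def test_skewed_cell_routes_nonparametric(self, rng):
        df = make_long_table(rng, n_per_group=22)
        df.loc[df.group == "ASD", "value"] = rng.exponential(
            1.0, (df.group == "ASD").sum()) ** 3
        report = st.assumption_checks(df, "y")
        assert report["nonnormal"]

    def test_constant_cell_does_not_crash(self, rng):
        df = make_long_table(rng, n_per_group=5)
        df.loc[df.group == "ASD", "value"] = 1.0
        report = st.assumption_checks(df, "y")
        assert report["shapiro"]["ASD/control"]["note"] == "degenerate"


class TestPower:
    def test_noncentral_f_search_oracle(self):
        # direct check of the returned N for the fixed-effects interaction
        N = st.required_sample_size(0.47, design="fixed_interaction")
        lam = 0.47**2 * N
        crit = sps.f.isf(0.05, 1, N - 4)
        assert sps.ncf.sf(crit, 1, N - 4, lam) >= 0.80
        lam_prev = 0.47**2 * (N - 2)
        crit_prev = sps.f.isf(0.05, 1, N - 6)
        assert sps.ncf.sf(crit_prev, 1, N - 6, lam_prev) < 0.80

    def test_all_supported_families_within_study_bound(self):
        for fam in st._FAMILIES:
            assert st.required_sample_size(0.47, design=fam) <= 40

    def test_n_strictly_increasing_in_power(self):
        ns = [st.required_sample_size(0.47, power=p) for p in (0.5, 0.8, 0.95)]
        assert ns[0] < ns[1] < ns[2]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            st.required_sample_size(-1.0)
        with pytest.raises(ValueError):
            st.required_sample_size(0.47, design="latin_square")


class TestFullBattery:
    def _summary(self, rng, interaction=0.0):
        frames = []
        for out in st.OUTCOMES:
            df = make_long_table(rng, n_per_group=12, interaction=interaction)
            df["outcome_name"] = out
            frames.append(df)
        # baseline pitch rows for the manipulation check
        base = frames[-2][frames[-2].condition == "control"].copy()
        base["condition"] = "baseline"
        base = base[base.outcome_name == "fixation_pitch"]
        base["value"] = base["value"] - 1.0 + rng.normal(0, 0.3, len(base))
        frames.append(base)
        return pd.concat(frames, ignore_index=True)

    def test_report_contains_seven_anova_blocks(self, rng):
        report = st.run_full_battery(self._summary(rng))
        assert set(report["outcomes"]) == set(st.OUTCOMES)
        for block in report["outcomes"].values():
            assert set(block["anova"]) == {"group", "condition", "interaction"}
        assert report["manipulation_check"] is not None
        assert report["manipulation_check"]["p"] < 0.001

    def test_null_battery_flags_little(self, rng):
        report = st.run_full_battery(self._summary(rng))
        ps = [block["anova"]["interaction"]["p"]
              for block in report["outcomes"].values()]
        assert sum(p < 0.05 for p in ps) <= 2  # ~ alpha-level false positives

    def test_missing_outcome_reported_absent(self, rng):
        df = self._summary(rng)
        df = df[df.outcome_name != "rom"]
        report = st.run_full_battery(df)
        assert report["outcomes"]["rom"].get("absent")

    def test_report_is_json_serialisable(self, rng):
        import json

        from racquetvr.io import _json_default

        json.dumps(st.run_full_battery(self._summary(rng)),
                   default=_json_default)
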