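"""The study's inferential layer.

For every sensorimotor outcome a 2 (group: ASD vs NT) x 2 (condition:
control vs cued) mixed-model ANOVA is computed from the classical
sums-of-squares decomposition of the split-plot design, with partial
eta-squared effect sizes, Bonferroni-corrected post-hoc t-tests (or
Mann-Whitney U when the outcome failed Shapiro-Wilk normality in any
cell), Pearson/Spearman trait correlations, and Bayes factors: the
Jeffreys-Zellner-Siow default (Cauchy scale 0.707) for t-tests via
numerical integration, and a BIC approximation for ANOVA effects (which
will differ numerically from Monte-Carlo g-prior ANOVA Bayes factors).
Two-tailed tests throughout, alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.integrate import quad

__all__ = [
    "ALPHA",
    "StatResult",
    "mixed_anova_2x2",
    "posthoc_tests",
    "trait_correlations",
    "assumption_checks",
    "jzs_ttest_bf",
    "bic_bf",
    "required_sample_size",
    "run_full_battery",
    "interaction_type1_rate",
    "OUTCOMES",
]

ALPHA = 0.05
JZS_SCALE = 0.707

#: the seven ANOVA outcomes, in the order the results are reported
OUTCOMES = (
    "interception_rate",
    "peak_velocity",
    "rom",
    "fixation_onset",
    "fixation_duration",
    "fixation_pitch",
    "fixation_pitch_sd",
)


@dataclass
class StatResult:
    """One inferential result: the statistic, df, p, effect size and BF10."""

    name: str
    statistic_name: str           # "F" | "t" | "U" | "W" | "r" | "rho"
    value: float
    df: tuple
    p: float
    effect_size: Optional[float] = None
    effect_size_name: str = ""
    bf10: Optional[float] = None
    bf_method: str = ""
    correction: str = "none"
    note: str = ""

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.p is not None and self.p < alpha

    def to_dict(self) -> dict:
        return {
            "name": self.name, "statistic": self.statistic_name,
            "value": _r(self.value), "df": list(self.df), "p": _r(self.p),
            "effect_size": _r(self.effect_size),
            "effect_size_name": self.effect_size_name,
            "bf10": _r(self.bf10), "bf_method": self.bf_method,
            "correction": self.correction, "note": self.note,
        }


def _r(x, nd=6):
    if x is None:
        return None
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return None if math.isnan(x) else ("inf" if x > 0 else "-inf")
    return round(float(x), nd)


# ---------------------------------------------------------------------------
# mixed 2x2 ANOVA (one between-, one within-subject factor, 2 levels each)


def _pivot_outcome(table: pd.DataFrame, outcome: str):
    """Long table -> (y_control, y_cued, group codes), listwise-deleting
    participants missing either condition."""
    sub = table[table["outcome_name"] == outcome] if "outcome_name" in table else table
    wide = sub.pivot_table(index="participant_id", columns="condition",
                           values="value", aggfunc="first")
    groups = sub.drop_duplicates("participant_id").set_index("participant_id")["group"]
    wide = wide.dropna(subset=["control", "cued"])
    g = groups.reindex(wide.index)
    return (wide["control"].to_numpy(dtype=float),
            wide["cued"].to_numpy(dtype=float),
            (g == "ASD").to_numpy())


def _mixed_anova_core(y_ctrl: np.ndarray, y_cued: np.ndarray,
                      is_g1: np.ndarray) -> dict:
    """Split-plot decomposition on subject means and condition differences.

    With two levels per factor the between-stratum reduces to a two-sample
    comparison of subject means and the within-stratum to comparisons of
    condition differences; unequal group sizes are handled with unweighted
    (type-III) marginal means.  Returns F, df, p, partial eta^2 and the SS
    components per effect.
    """
    m = 0.5 * (y_ctrl + y_cued)
    d = y_cued - y_ctrl
    n1 = int(is_g1.sum())
    n2 = int(len(is_g1) - n1)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 participants per group")
    N = n1 + n2
    inv = 1.0 / n1 + 1.0 / n2
    m1, m2 = m[is_g1].mean(), m[~is_g1].mean()
    d1, d2 = d[is_g1].mean(), d[~is_g1].mean()
    ss_subj = 2.0 * (np.sum((m[is_g1] - m1) ** 2) + np.sum((m[~is_g1] - m2) ** 2))
    ss_group = 2.0 * (m1 - m2) ** 2 / inv
    s_dd = np.sum((d[is_g1] - d1) ** 2) + np.sum((d[~is_g1] - d2) ** 2)
    ss_err_w = s_dd / 2.0
    c = 0.5 * (d1 + d2)  # unweighted condition contrast
    ss_cond = 2.0 * c**2 / inv
    ss_inter = 0.5 * (d1 - d2) ** 2 / inv
    df_err = N - 2
    out = {}
    degenerate = ss_subj <= 0 or ss_err_w <= 0
    for eff, ss, ss_err in (
        ("group", ss_group, ss_subj),
        ("condition", ss_cond, ss_err_w),
        ("interaction", ss_inter, ss_err_w),
    ):
        if degenerate or ss_err <= 0:
            F = p = pe2 = float("nan")
        else:
            F = (ss / 1.0) / (ss_err / df_err)
            p = float(sps.f.sf(F, 1, df_err))
            pe2 = ss / (ss + ss_err)
        out[eff] = {"F": F, "df": (1, df_err), "p": p, "pes": pe2,
                    "ss": ss, "ss_err": ss_err, "degenerate": degenerate}
    out["_data"] = {"m": m, "d": d, "is_g1": is_g1, "n1": n1, "n2": n2}
    return out


def mixed_anova_2x2(table: pd.DataFrame, outcome: str) -> dict[str, StatResult]:
    """Mixed 2x2 ANOVA for one outcome from the long table.

    Returns StatResults for the group and condition main effects and the
    group-by-condition interaction, each with a BIC-approximate BF10.
    Participants missing a condition are listwise-deleted.
    """
    y0, y1, g1 = _pivot_outcome(table, outcome)
    core = _mixed_anova_core(y0, y1, g1)
    data = core.pop("_data")
    m, d, is_g1, N = data["m"], data["d"], data["is_g1"], data["n1"] + data["n2"]
    gmeans = np.where(is_g1, m[is_g1].mean(), m[~is_g1].mean())
    dmeans = np.where(is_g1, d[is_g1].mean(), d[~is_g1].mean())
    bf = {
        "group": bic_bf(np.sum((m - m.mean()) ** 2),
                        np.sum((m - gmeans) ** 2), N, 1),
        "condition": bic_bf(np.sum(d**2), np.sum((d - d.mean()) ** 2), N, 1),
        "interaction": bic_bf(np.sum((d - d.mean()) ** 2),
                              np.sum((d - dmeans) ** 2), N, 1),
    }
    out = {}
    for eff, r in core.items():
        out[eff] = StatResult(
            name=f"{outcome}:{eff}", statistic_name="F", value=r["F"],
            df=r["df"], p=r["p"], effect_size=r["pes"],
            effect_size_name="partial_eta_sq", bf10=bf[eff],
            bf_method="bic_approx",
            note="degenerate (zero variance)" if r["degenerate"] else "",
        )
    return out


# ---------------------------------------------------------------------------
# Bayes factors


def jzs_ttest_bf(t: float, n1: int, n2: Optional[int] = None,
                 scale: float = JZS_SCALE) -> float:
    """Default JZS (Cauchy-prior) Bayes factor for a t statistic.

    One-sample/paired when ``n2`` is None (effective N = n1, df = n1 - 1),
    two-sample otherwise (N = n1*n2/(n1+n2), df = n1+n2-2).  Computed by
    numerical integration of the Zellner-Siow marginal likelihood.
    """
    if n2 is None:
        N, df = n1, n1 - 1
    else:
        N, df = n1 * n2 / (n1 + n2), n1 + n2 - 2
    if df <= 0:
        return float("nan")
    t2 = t * t
    r2 = scale * scale

    def integrand(g):
        return ((1 + N * g * r2) ** -0.5
                * (1 + t2 / ((1 + N * g * r2) * df)) ** (-(df + 1) / 2)
                * (2 * math.pi) ** -0.5 * g ** -1.5 * math.exp(-1 / (2 * g)))

    num, _ = quad(integrand, 0, np.inf, limit=200)
    den = (1 + t2 / df) ** (-(df + 1) / 2)
    if den == 0.0:  # overwhelming evidence: null likelihood underflows
        return float("inf")
    return float(num / den)


def bic_bf(rss0: float, rss1: float, n: int, k_extra: int) -> Optional[float]:
    """BIC-approximate BF10 for nested linear models: model 1 adds
    ``k_extra`` parameters and leaves residual SS ``rss1``."""
    if rss1 <= 0 or rss0 <= 0 or n <= k_extra:
        return None
    d_bic = n * math.log(rss1 / rss0) + k_extra * math.log(n)
    return float(math.exp(-0.5 * d_bic))


def _corr_bf(r: float, n: int) -> Optional[float]:
    """BF10 for a (Pearson or rank) correlation via the JZS linear-model
    route: the correlation is re-expressed as the one-predictor regression
    t statistic and fed to the default t-test BF."""
    if n < 4 or not np.isfinite(r) or abs(r) >= 1:
        return None
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return jzs_ttest_bf(t, n)


# ---------------------------------------------------------------------------
# post-hoc tests, correlations, assumptions


def posthoc_tests(table: pd.DataFrame, outcome: str,
                  family: Optional[list] = None,
                  nonparametric: bool = False) -> list[StatResult]:
    """Follow-up comparisons with Bonferroni correction.

    Default family: between-group comparison within each condition plus the
    within-group control-vs-cued comparison in each group (family size 4).
    Between-group tests use independent t (or Mann-Whitney U when the
    outcome was routed nonparametric); within-group tests are paired t (or
    Wilcoxon signed-rank).  Raw p is multiplied by the family size, capped
    at 1.
    """
    y0, y1, g1 = _pivot_outcome(table, outcome)
    if family is None:
        family = [("between", "control"), ("between", "cued"),
                  ("within", "ASD"), ("within", "NT")]
    k = len(family)
    results = []
    for kind, which in family:
        if kind == "between":
            a = (y0 if which == "control" else y1)[g1]
            b = (y0 if which == "control" else y1)[~g1]
            if min(len(a), len(b)) < 3:
                raise ValueError("need n >= 3 per cell for post-hoc tests")
            if nonparametric:
                u = sps.mannwhitneyu(a, b, alternative="two-sided")
                stat, statname, p = float(u.statistic), "U", float(u.pvalue)
                es = None
            else:
                tt = sps.ttest_ind(a, b)
                stat, statname, p = float(tt.statistic), "t", float(tt.pvalue)
                es = _cohens_d_ind(a, b)
            bf = jzs_ttest_bf(
                float(sps.ttest_ind(a, b).statistic), len(a), len(b))
            name = f"{outcome}:ASD_vs_NT@{which}"
            df = (len(a) + len(b) - 2,)
        else:
            sel = g1 if which == "ASD" else ~g1
            a, b = y1[sel], y0[sel]
            if len(a) < 3:
                raise ValueError("need n >= 3 per cell for post-hoc tests")
            if nonparametric:
                diffs = a - b
                if np.allclose(diffs, 0):
                    stat, statname, p = 0.0, "W", 1.0
                else:
                    w = sps.wilcoxon(a, b)
                    stat, statname, p = float(w.statistic), "W", float(w.pvalue)
                es = None
            else:
                if np.allclose(a - b, (a - b)[0]) and np.std(a - b) == 0 and (a - b)[0] == 0:
                    stat, statname, p, es = 0.0, "t", 1.0, 0.0
                else:
                    tt = sps.ttest_rel(a, b)
                    stat, statname, p = float(tt.statistic), "t", float(tt.pvalue)
                    es = _cohens_d_paired(a, b)
            d = a - b
            tpaired = 0.0 if np.std(d, ddof=1) == 0 else float(
                d.mean() / (d.std(ddof=1) / math.sqrt(len(d))))
            bf = jzs_ttest_bf(tpaired, len(a))
            name = f"{outcome}:cued_vs_control@{which}"
            df = (len(a) - 1,)
        results.append(StatResult(
            name=name, statistic_name=statname, value=stat, df=df,
            p=min(1.0, p * k), effect_size=es, effect_size_name="cohens_d",
            bf10=bf, bf_method="jzs", correction="bonferroni",
        ))
    return results


def _cohens_d_ind(a, b):
    sp = math.sqrt(((len(a) - 1) * np.var(a, ddof=1)
                    + (len(b) - 1) * np.var(b, ddof=1)) / (len(a) + len(b) - 2))
    return float((np.mean(a) - np.mean(b)) / sp) if sp > 0 else float("nan")


def _cohens_d_paired(a, b):
    d = np.asarray(a) - np.asarray(b)
    s = d.std(ddof=1)
    return float(d.mean() / s) if s > 0 else float("nan")


def trait_correlations(table: pd.DataFrame, outcome: str,
                       traits=("AQ_total", "IUS_total"),
                       nonparametric: bool = False) -> list[StatResult]:
    """Trait-outcome correlations per condition: Pearson r, or Spearman rho
    for outcomes routed nonparametric."""
    sub = table[table["outcome_name"] == outcome] if "outcome_name" in table else table
    out = []
    for cond in ("control", "cued"):
        cell = sub[sub["condition"] == cond].dropna(subset=["value"])
        for trait in traits:
            x = cell[trait].to_numpy(dtype=float)
            y = cell["value"].to_numpy(dtype=float)
            n = len(x)
            if n < 4:
                raise ValueError("need >= 4 complete pairs for correlation")
            note = ""
            if np.std(x) == 0 or np.std(y) == 0:
                r, p, note = float("nan"), float("nan"), "zero variance"
            elif nonparametric:
                r, p = sps.spearmanr(x, y)
            else:
                r, p = sps.pearsonr(x, y)
            out.append(StatResult(
                name=f"{outcome}:{trait}@{cond}",
                statistic_name="rho" if nonparametric else "r",
                value=float(r), df=(n - 2,), p=float(p),
                effect_size=float(r), effect_size_name="r",
                bf10=_corr_bf(float(r), n) if note == "" else None,
                bf_method="jzs_regression", note=note,
            ))
    return out


def assumption_checks(table: pd.DataFrame, outcome: str) -> dict:
    """Shapiro-Wilk per group-by-condition cell and Levene's test
    (center=mean) across groups per condition.

    ``nonnormal`` is True when any cell fails Shapiro-Wilk at alpha, which
    routes the outcome's follow-ups to the nonparametric branch.
    """
    y0, y1, g1 = _pivot_outcome(table, outcome)
    cells = {
        ("ASD", "control"): y0[g1], ("ASD", "cued"): y1[g1],
        ("NT", "control"): y0[~g1], ("NT", "cued"): y1[~g1],
    }
    shapiro = {}
    nonnormal = False
    for key, v in cells.items():
        if len(v) < 3 or np.std(v) == 0:
            shapiro["/".join(key)] = {"W": None, "p": None, "note": "degenerate"}
            continue
        w = sps.shapiro(v)
        shapiro["/".join(key)] = {"W": float(w.statistic), "p": float(w.pvalue)}
        nonnormal = nonnormal or w.pvalue < ALPHA
    levene = {}
    for cond, (a, b) in (("control", (y0[g1], y0[~g1])),
                         ("cued", (y1[g1], y1[~g1]))):
        if np.std(a) == 0 and np.std(b) == 0:
            levene[cond] = {"W": None, "p": None, "note": "degenerate"}
            continue
        lv = sps.levene(a, b, center="mean")
        levene[cond] = {"W": float(lv.statistic), "p": float(lv.pvalue)}
    return {"shapiro": shapiro, "levene": levene, "nonnormal": nonnormal}


# ---------------------------------------------------------------------------
# a-priori power


#: supported design families for the sample-size search; m = within levels,
#: k = groups, rho = assumed repeated-measures correlation
_FAMILIES = ("fixed_interaction", "fixed_between", "rm_between",
             "rm_within", "rm_interaction")


def required_sample_size(f: float, alpha: float = 0.05, power: float = 0.80,
                         design: str = "fixed_interaction", rho: float = 0.5,
                         n_max: int = 10_000) -> int:
    """Smallest total N whose noncentral-F power reaches the target.

    ``f`` is Cohen's effect size; ``design`` picks the 2x2 family:
    fixed-effects interaction/between (lambda = f^2 N) or the
    repeated-measures variants whose noncentrality is boosted by the
    within-subject correlation ``rho``.  N is rounded up to a multiple of
    the group count (2).
    """
    if f <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("require f > 0, 0 < alpha < 1, 0 < power < 1")
    if design not in _FAMILIES:
        raise ValueError(f"design must be one of {_FAMILIES}")
    m, k = 2, 2
    for N in range(2 * k, n_max + 1, k):
        if design == "fixed_interaction":
            df1, df2, lam = 1, N - m * k, f * f * N
        elif design == "fixed_between":
            df1, df2, lam = 1, N - k, f * f * N
        elif design == "rm_between":
            df1, df2 = k - 1, N - k
            lam = f * f * N * m / (1 + (m - 1) * rho)
        elif design == "rm_within":
            df1, df2 = m - 1, (N - k) * (m - 1)
            lam = f * f * N * m / (1 - rho)
        else:  # rm_interaction
            df1, df2 = (k - 1) * (m - 1), (N - k) * (m - 1)
            lam = f * f * N * m / (1 - rho)
        if df2 < 1:
            continue
        crit = sps.f.isf(alpha, df1, df2)
        if sps.ncf.sf(crit, df1, df2, lam) >= power:
            return N
    raise RuntimeError("sample-size search did not converge")


# ---------------------------------------------------------------------------
# the full battery


def run_full_battery(summary: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Run the complete inferential report on a participant-level summary.

    ``summary`` is long format: one row per participant x condition x
    outcome with columns participant_id, group, condition, outcome_name,
    value, AQ_total, IUS_total.  Conditions 'control' and 'cued' feed the
    ANOVAs; 'baseline' rows of fixation_pitch feed the manipulation check
    (paired t, baseline vs control, both groups pooled).  Missing outcomes
    are reported as absent and the run continues.
    """
    report: dict = {"schema_version": 1, "alpha": alpha, "outcomes": {},
                    "manipulation_check": None}

    pitch = summary[summary["outcome_name"] == "fixation_pitch"]
    wide = pitch.pivot_table(index="participant_id", columns="condition",
                             values="value", aggfunc="first")
    if {"baseline", "control"}.issubset(wide.columns):
        pair = wide.dropna(subset=["baseline", "control"])
        if len(pair) >= 3:
            d = pair["control"] - pair["baseline"]
            tt = sps.ttest_rel(pair["control"], pair["baseline"])
            tval = float(tt.statistic)
            report["manipulation_check"] = StatResult(
                name="fixation_pitch:control_vs_baseline",
                statistic_name="t", value=tval, df=(len(pair) - 1,),
                p=float(tt.pvalue), effect_size=_cohens_d_paired(
                    pair["control"], pair["baseline"]),
                effect_size_name="cohens_d",
                bf10=jzs_ttest_bf(tval, len(pair)), bf_method="jzs",
            ).to_dict()

    exp = summary[summary["condition"].isin(["control", "cued"])]
    for outcome in OUTCOMES:
        sub = exp[exp["outcome_name"] == outcome]
        block: dict = {}
        if sub.empty:
            report["outcomes"][outcome] = {"absent": True}
            continue
        try:
            checks = assumption_checks(sub, outcome)
            anova = mixed_anova_2x2(sub, outcome)
            block["assumptions"] = checks
            block["anova"] = {k: v.to_dict() for k, v in anova.items()}
            if any(v.significant(alpha) for v in anova.values()):
                block["posthoc"] = [
                    r.to_dict() for r in posthoc_tests(
                        sub, outcome, nonparametric=checks["nonnormal"])
                ]
            block["correlations"] = [
                r.to_dict() for r in trait_correlations(
                    sub, outcome, nonparametric=checks["nonnormal"])
            ]
        except (ValueError, KeyError) as e:
            block["error"] = str(e)
        report["outcomes"][outcome] = block
    return report


# ---------------------------------------------------------------------------
# calibration utilities


def interaction_type1_rate(n_per_group: int = 22, n_sims: int = 10_000,
                           seed: int = 0, alpha: float = ALPHA) -> float:
    """Monte-Carlo type-I error of the interaction test under the global
    null (i.i.d. standard-normal cells)."""
    rng = np.random.default_rng(seed)
    g1 = np.zeros(2 * n_per_group, dtype=bool)
    g1[:n_per_group] = True
    rejections = 0
    for _ in range(n_sims):
        y0 = rng.standard_normal(2 * n_per_group)
        y1 = rng.standard_normal(2 * n_per_group)
        core = _mixed_anova_core(y0, y1, g1)
        if core["interaction"]["p"] < alpha:
            rejections += 1
    return rejections / n_sims
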