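"""HMF (5-hydroxymethylfurfural) statistics stage.

Assumption checks (Shapiro–Wilk normality per group, Levene variance
homogeneity), one- and two-way ANOVA, Tukey HSD or Games–Howell post hoc
pairwise comparisons, control-vs-level star flags, and compact letter
displays.

Both post hoc tests are computable from summary statistics (mean, SD, n)
alone, so the stage can also run on published mean ± SD tables — the
module ships the study's published HMF summary
(:data:`REFERENCE_HMF_SUMMARY`) for that mode. Routing follows the
variance check: Levene p >= 0.05 -> Tukey (pooled variance, studentized
range); otherwise Games–Howell (Welch degrees of freedom per pair).
Significance is fixed at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, MatrixError, SupportError
from .spectra import CONTROL

__all__ = [
    "REFERENCE_HMF_SUMMARY",
    "reference_hmf_summary",
    "summarize",
    "check_assumptions",
    "one_way_anova_summary",
    "two_way_anova",
    "PosthocResult",
    "tukey_from_summary",
    "games_howell_from_summary",
    "posthoc",
    "control_comparison",
    "letter_display",
]

ALPHA = 0.05

#: published HMF summary (mg/kg, mean +/- SD of n = 3 replicate bottles)
#: of the heat-treatment experiment the synthetic generator emulates.
REFERENCE_HMF_SUMMARY = """\
honey_type,temperature_C,time_min,mean,sd,n
sunflower,CONTROL,0,18.5,0.3,3
sunflower,40,60,20.2,1.5,3
sunflower,60,60,16.2,1.0,3
sunflower,80,60,17.6,0.2,3
sunflower,100,60,40.3,0.8,3
sunflower,40,120,17.3,1.3,3
sunflower,60,120,20.5,0.7,3
sunflower,80,120,31.8,1.3,3
sunflower,100,120,155.1,2.7,3
sunflower,40,180,18.4,1.6,3
sunflower,60,180,19.9,1.8,3
sunflower,80,180,37.2,0.6,3
sunflower,100,180,241.5,7.4,3
sunflower,40,240,17.5,1.4,3
sunflower,60,240,19.5,2.0,3
sunflower,80,240,52.0,2.7,3
sunflower,100,240,463.6,28.3,3
bastard_indigo,CONTROL,0,14.7,1.6,3
bastard_indigo,40,60,14.1,2.8,3
bastard_indigo,60,60,18.0,2.3,3
bastard_indigo,80,60,11.9,1.1,3
bastard_indigo,100,60,16.7,0.9,3
bastard_indigo,40,120,15.1,3.5,3
bastard_indigo,60,120,15.8,0.6,3
bastard_indigo,80,120,14.3,1.0,3
bastard_indigo,100,120,81.4,4.0,3
bastard_indigo,40,180,15.7,1.1,3
bastard_indigo,60,180,21.1,3.5,3
bastard_indigo,80,180,19.8,0.6,3
bastard_indigo,100,180,146.4,2.3,3
bastard_indigo,40,240,12.9,1.4,3
bastard_indigo,60,240,13.7,1.3,3
bastard_indigo,80,240,28.2,1.1,3
bastard_indigo,100,240,306.0,17.8,3
acacia,CONTROL,0,7.0,0.4,3
acacia,40,60,9.1,1.3,3
acacia,60,60,7.7,0.3,3
acacia,80,60,8.0,0.4,3
acacia,100,60,16.1,1.7,3
acacia,40,120,8.0,0.6,3
acacia,60,120,8.8,1.4,3
acacia,80,120,13.3,0.9,3
acacia,100,120,44.7,4.3,3
acacia,40,180,8.6,1.0,3
acacia,60,180,9.6,0.3,3
acacia,80,180,12.2,0.8,3
acacia,100,180,89.1,2.8,3
acacia,40,240,10.0,1.1,3
acacia,60,240,9.6,0.9,3
acacia,80,240,18.8,2.4,3
acacia,100,240,211.6,5.0,3
"""


def reference_hmf_summary() -> pd.DataFrame:
    """The published HMF summary table as a tidy DataFrame."""
    df = pd.read_csv(StringIO(REFERENCE_HMF_SUMMARY))
    df["temperature_C"] = df["temperature_C"].map(
        lambda v: CONTROL if str(v) == CONTROL else int(v)
    )
    return df


def summarize(
    df: pd.DataFrame, by, value: str = "hmf_mg_kg"
) -> pd.DataFrame:
    """Group raw values into (label, mean, sd, n) rows; sd is the sample SD."""
    by = [by] if isinstance(by, str) else list(by)
    g = df.groupby(by, sort=False, observed=True)[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    return out


# ----------------------------------------------------------------------
# assumption checks and ANOVA


def check_assumptions(df: pd.DataFrame, by, value: str = "hmf_mg_kg"):
    """Shapiro–Wilk per group and Levene (center = mean) across groups.

    Returns ``(normality table, levene p-value)``.
    """
    by = [by] if isinstance(by, str) else list(by)
    groups = []
    rows = []
    for key, sub in df.groupby(by, sort=False, observed=True):
        v = sub[value].to_numpy(dtype=float)
        if v.size < 3:
            raise SupportError(
                f"group {key!r} has n={v.size} < 3; Shapiro–Wilk needs >= 3"
            )
        w, p = stats.shapiro(v)
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, v.size, float(w), float(p)))
        groups.append(v)
    normality = pd.DataFrame(rows, columns=[*by, "n", "shapiro_W", "shapiro_p"])
    _, levene_p = stats.levene(*groups, center="mean")
    return normality, float(levene_p)


def one_way_anova_summary(means, sds, ns) -> tuple[float, float]:
    """One-way ANOVA F and p from group summary statistics."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    k = means.size
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    msb = float((ns * (means - grand) ** 2).sum() / (k - 1))
    msw = float(((ns - 1) * sds**2).sum() / (N - k))
    if msw == 0:
        return np.inf, 0.0
    F = msb / msw
    return F, float(stats.f.sf(F, k - 1, N - k))


def two_way_anova(df: pd.DataFrame, value: str = "hmf_mg_kg") -> pd.DataFrame:
    """Type-II two-way ANOVA (temperature x time) on the 4x4 factorial.

    Control rows (which have no factorial cell) are excluded.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = df[df["temperature_C"] != CONTROL].copy()
    d = d[d["time_min"] != 0]
    if d.empty:
        raise DesignError("no factorial rows (all control?)")
    cells = d.groupby(["temperature_C", "time_min"], observed=True).size()
    temps = d["temperature_C"].nunique()
    times = d["time_min"].nunique()
    if len(cells) < temps * times:
        raise DesignError("the temperature x time factorial has empty cells")
    d = d.rename(columns={value: "y"})
    d["temp"] = d["temperature_C"].astype(str)
    d["time"] = d["time_min"].astype(str)
    fit = smf.ols("y ~ C(temp) * C(time)", data=d).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    out = pd.DataFrame(
        {
            "effect": ["temperature", "time", "interaction"],
            "df": [
                tab.loc["C(temp)", "df"],
                tab.loc["C(time)", "df"],
                tab.loc["C(temp):C(time)", "df"],
            ],
            "F": [
                tab.loc["C(temp)", "F"],
                tab.loc["C(time)", "F"],
                tab.loc["C(temp):C(time)", "F"],
            ],
            "p": [
                tab.loc["C(temp)", "PR(>F)"],
                tab.loc["C(time)", "PR(>F)"],
                tab.loc["C(temp):C(time)", "PR(>F)"],
            ],
        }
    )
    return out


# ----------------------------------------------------------------------
# post hoc from summary statistics


@dataclass(frozen=True)
class PosthocResult:
    """All pairwise comparisons; ``pairs`` columns: group_a, group_b,
    statistic (studentized range q), df, p, significant."""

    pairs: pd.DataFrame
    method: str

    def p_matrix(self, groups) -> pd.DataFrame:
        m = pd.DataFrame(np.ones((len(groups), len(groups))), index=groups, columns=groups)
        for r in self.pairs.itertuples(index=False):
            m.loc[r.group_a, r.group_b] = r.p
            m.loc[r.group_b, r.group_a] = r.p
        return m


def _as_summary_arrays(groups: pd.DataFrame):
    req = {"mean", "sd", "n"}
    if not req.issubset(groups.columns):
        raise SupportError("summary table needs columns mean, sd, n")
    labels = [c for c in groups.columns if c not in req]
    lab = (
        groups[labels[0]].to_numpy()
        if len(labels) == 1
        else groups[labels].astype(str).agg("|".join, axis=1).to_numpy()
    )
    ns = groups["n"].to_numpy(dtype=int)
    if (ns < 2).any():
        raise SupportError("every group needs n >= 2")
    return lab, groups["mean"].to_numpy(float), groups["sd"].to_numpy(float), ns


def tukey_from_summary(groups: pd.DataFrame) -> PosthocResult:
    """Tukey HSD from (mean, sd, n): pooled variance, studentized range."""
    lab, means, sds, ns = _as_summary_arrays(groups)
    k = means.size
    N = int(ns.sum())
    df_w = N - k
    msw = float(((ns - 1) * sds**2).sum() / df_w)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            rows.append((lab[i], lab[j], float(q), float(df_w), p, p < ALPHA))
    pairs = pd.DataFrame(
        rows, columns=["group_a", "group_b", "statistic", "df", "p", "significant"]
    )
    return PosthocResult(pairs, "tukey")


def games_howell_from_summary(groups: pd.DataFrame) -> PosthocResult:
    """Games–Howell from (mean, sd, n): per-pair Welch df, no pooled
    variance — robust to heteroscedasticity."""
    lab, means, sds, ns = _as_summary_arrays(groups)
    k = means.size
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = sds[i] ** 2 / ns[i], sds[j] ** 2 / ns[j]
            se = np.sqrt(vi + vj)
            if se == 0:
                q, df_ij, p = (0.0, float(ns[i] + ns[j] - 2), 1.0)
                if means[i] != means[j]:
                    q, p = np.inf, 0.0
            else:
                t = abs(means[i] - means[j]) / se
                q = t * np.sqrt(2.0)
                df_ij = (vi + vj) ** 2 / (
                    vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1)
                )
                p = float(stats.studentized_range.sf(q, k, df_ij))
            rows.append((lab[i], lab[j], float(q), float(df_ij), p, p < ALPHA))
    pairs = pd.DataFrame(
        rows, columns=["group_a", "group_b", "statistic", "df", "p", "significant"]
    )
    return PosthocResult(pairs, "games_howell")


def posthoc(groups, homogeneous: bool | None = None, value: str = "hmf_mg_kg", by=None) -> PosthocResult:
    """Pairwise post hoc comparisons.

    ``groups`` is either a summary DataFrame (label columns + mean, sd, n)
    or a raw DataFrame (then ``by`` names the grouping column(s) and the
    homogeneity flag, when not given, is decided by Levene's test at 0.05).
    """
    if isinstance(groups, pd.DataFrame) and {"mean", "sd", "n"}.issubset(groups.columns):
        summary = groups
        if homogeneous is None:
            raise SupportError("summary mode needs an explicit homogeneity flag")
    else:
        if by is None:
            raise SupportError("raw mode needs the grouping column(s)")
        if homogeneous is None:
            _, levene_p = check_assumptions(groups, by, value)
            homogeneous = levene_p >= ALPHA
        summary = summarize(groups, by, value)
    if len(summary) < 2:
        raise SupportError("need at least two groups")
    return tukey_from_summary(summary) if homogeneous else games_howell_from_summary(summary)


def control_comparison(
    groups,
    control_label,
    homogeneous: bool | None = None,
    value: str = "hmf_mg_kg",
    by=None,
) -> pd.DataFrame:
    """Star flags: which levels differ from the control (p < 0.05).

    Runs a one-way ANOVA over all levels first; when it is not significant
    no level is starred. Pairwise level-vs-control p-values come from the
    routed post hoc over the full comparison family.
    """
    if isinstance(groups, pd.DataFrame) and {"mean", "sd", "n"}.issubset(groups.columns):
        summary = groups.copy()
        if homogeneous is None:
            raise SupportError("summary mode needs an explicit homogeneity flag")
    else:
        if by is None:
            raise SupportError("raw mode needs the grouping column(s)")
        if homogeneous is None:
            _, levene_p = check_assumptions(groups, by, value)
            homogeneous = levene_p >= ALPHA
        summary = summarize(groups, by, value)
    lab, means, sds, ns = _as_summary_arrays(summary)
    if control_label not in set(lab):
        raise DesignError(f"control level {control_label!r} missing")
    _, p_anova = one_way_anova_summary(means, sds, ns)
    ph = (
        tukey_from_summary(summary) if homogeneous else games_howell_from_summary(summary)
    )
    rows = []
    for level in lab:
        if level == control_label:
            continue
        pair = ph.pairs[
            ((ph.pairs["group_a"] == level) & (ph.pairs["group_b"] == control_label))
            | ((ph.pairs["group_b"] == level) & (ph.pairs["group_a"] == control_label))
        ]
        p = float(pair["p"].iloc[0])
        rows.append((level, p, p_anova < ALPHA and p < ALPHA))
    return pd.DataFrame(rows, columns=["level", "p_vs_control", "star"])


# ----------------------------------------------------------------------
# compact letter display


def letter_display(result: PosthocResult, groups: list) -> dict:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise p >= 0.05. Letters are
    assigned in the given group order (e.g. ascending time or temperature).
    """
    groups = list(groups)
    pm = result.p_matrix(groups)
    for a in groups:
        for b in groups:
            if a != b and pd.isna(pm.loc[a, b]):
                raise MatrixError(f"missing pairwise comparison ({a!r}, {b!r})")
    columns: list[set] = [set(groups)]
    for ia, a in enumerate(groups):
        for b in groups[ia + 1 :]:
            if pm.loc[a, b] >= ALPHA:
                continue
            new_cols = []
            for col in columns:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb columns contained in another
            columns = []
            for c in new_cols:
                if any(c < o for o in new_cols) or c in columns:
                    continue
                columns.append(c)
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups}
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters
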