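"""Group statistics for the dwell-time analysis.

Every statistic can be computed either from raw per-participant metrics
or — where mathematically possible — directly from printed group
summaries (n, mean, SD), so published descriptive tables are
independently verifiable without the raw data.

Implemented here:

* group descriptives with t-based 95% CIs and an n-weighted pooled row;
* Welch's heteroscedastic one-way ANOVA (variance-weighted group means,
  Welch–Satterthwaite denominator df) with classical ω²;
* Games–Howell pairwise post-hoc p-values (studentized range, per-pair
  Welch df) together with pooled-variance Tukey-HSD confidence
  intervals — both constructions are emitted with explicit labels
  because published post-hoc tables sometimes mix the two;
* Hedges g (small-sample corrected standardized mean difference) with
  large-sample normal CIs;
* a classical two-way mixed ANOVA (between groups x 2-level within
  factor) via the exact sum/difference decomposition, with ω² per
  effect and Holm–Bonferroni adjustment;
* per-group simple main effects of the within factor (paired contrasts,
  generalized eta squared, Holm-adjusted);
* ANCOVA (Type-II) over individual-level covariates;
* a-priori power analysis for one-way ANOVA via the noncentral F
  distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "WelchAnovaResult",
    "PairwiseResult",
    "MixedAnovaResult",
    "PowerSpec",
    "summarize_groups",
    "summaries_from_raw",
    "levene_test",
    "shapiro_wilk",
    "welch_anova",
    "games_howell",
    "hedges_g",
    "holm_bonferroni",
    "mixed_anova",
    "simple_main_effects",
    "ancova",
    "power_min_n",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptives: n, mean, sample SD, 95% t-based CI."""

    group: str
    n: int
    mean: float
    sd: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)

    def with_ci(self, conf: float = 0.95) -> "GroupSummary":
        half = stats.t.ppf(0.5 + conf / 2, self.n - 1) * self.sd / np.sqrt(self.n)
        return GroupSummary(
            self.group, self.n, self.mean, self.sd, self.mean - half, self.mean + half
        )


@dataclass(frozen=True)
class WelchAnovaResult:
    F: float
    df1: int
    df2: float
    p: float
    omega_sq: float


@dataclass(frozen=True)
class PairwiseResult:
    """One pairwise comparison (reversal flips the signs of diff and g)."""

    pair: tuple[str, str]
    mean_diff: float
    ci_low: float        # pooled-variance Tukey-HSD construction
    ci_high: float
    p_adj: float         # Games–Howell (studentized range, Welch df)
    hedges_g: float
    g_ci_low: float
    g_ci_high: float


@dataclass(frozen=True)
class PowerSpec:
    effect_size_f: float
    alpha: float
    power: float
    k_groups: int
    min_total_n: int
    min_per_group_n: int
    achieved_power: float


def _as_summaries(groups) -> list[GroupSummary]:
    """Accept raw value arrays (dict/list) or GroupSummary lists."""
    if isinstance(groups, dict):
        return [
            GroupSummary(
                str(name),
                len(v),
                float(np.mean(v)),
                float(np.std(v, ddof=1)),
            )
            for name, v in groups.items()
        ]
    groups = list(groups)
    if groups and isinstance(groups[0], GroupSummary):
        return groups
    return [
        GroupSummary(
            f"g{i}", len(v), float(np.mean(v)), float(np.std(v, ddof=1))
        )
        for i, v in enumerate(groups)
    ]


def summaries_from_raw(
    df: pd.DataFrame, value_col: str, group_col: str = "group"
) -> list[GroupSummary]:
    """Per-group n/mean/sd summaries from a raw metrics table."""
    return [
        GroupSummary(str(g), len(v), float(v.mean()), float(v.std(ddof=1)))
        for g, v in df.groupby(group_col, sort=False)[value_col]
    ]


def summarize_groups(groups, total_label: str = "Total sample") -> pd.DataFrame:
    """Descriptives table with 95% CIs plus an n-weighted pooled row.

    The pooled mean is the n-weighted mean of group means; the pooled SD
    is derived from the exact total sum of squares (within + between),
    which reproduces the raw-data total SD from summaries alone.
    """
    gs = [g.with_ci() for g in _as_summaries(groups)]
    if any(g.n < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    n = np.array([g.n for g in gs])
    m = np.array([g.mean for g in gs])
    s = np.array([g.sd for g in gs])
    N = int(n.sum())
    gm = float((n * m).sum() / N)
    ss_total = float(((n - 1) * s**2).sum() + (n * (m - gm) ** 2).sum())
    sd_total = float(np.sqrt(ss_total / (N - 1)))
    total = GroupSummary(total_label, N, gm, sd_total).with_ci()
    rows = [g.__dict__ for g in gs] + [total.__dict__]
    return pd.DataFrame(rows)


def levene_test(groups) -> tuple[float, float]:
    """Classic (mean-centered) Levene test for equality of variances."""
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(arrays) < 2 or any(len(a) < 3 for a in arrays):
        raise ValueError("Levene needs >= 2 groups with n >= 3 each")
    F, p = stats.levene(*arrays, center="mean")
    return float(F), float(p)


def shapiro_wilk(residuals) -> tuple[float, float]:
    """Shapiro–Wilk normality test on model residuals."""
    W, p = stats.shapiro(np.asarray(residuals, dtype=float))
    return float(W), float(p)


def welch_anova(groups) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA from raw data or summaries.

    Weights ``w_i = n_i / s_i^2``; the test statistic is

        F = [ Σ w_i (x̄_i − x̄_w)² / (k−1) ] / [ 1 + 2(k−2)Λ/(k²−1) ]

    with ``Λ = Σ (1 − w_i/Σw)²/(n_i−1)`` and denominator df
    ``df2 = (k²−1)/(3Λ)``.  ω² is reported from the classical one-way
    decomposition ``(SS_b − df1·MS_w)/(SS_t + MS_w)`` on the same data
    (ω² has no canonical Welch form).
    """
    gs = _as_summaries(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([g.n for g in gs], dtype=float)
    m = np.array([g.mean for g in gs])
    s = np.array([g.sd for g in gs])
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(s <= 0):
        raise ValueError("zero within-group variance: Welch weights undefined")

    w = n / s**2
    mw = float((w * m).sum() / w.sum())
    A = float((w * (m - mw) ** 2).sum() / (k - 1))
    lam = float(((1 - w / w.sum()) ** 2 / (n - 1)).sum())
    F = A / (1 + 2 * (k - 2) * lam / (k**2 - 1))
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(F, df1, df2))

    N = n.sum()
    gm = float((n * m).sum() / N)
    ss_b = float((n * (m - gm) ** 2).sum())
    ss_w = float(((n - 1) * s**2).sum())
    ms_w = ss_w / (N - k)
    omega = (ss_b - df1 * ms_w) / (ss_b + ss_w + ms_w)
    return WelchAnovaResult(float(F), df1, float(df2), p, float(omega))


def hedges_g(gi: GroupSummary, gj: GroupSummary, conf: float = 0.95):
    """Hedges g with a large-sample normal confidence interval.

    Pooled SD over the pair, Cohen d, then the small-sample correction
    ``J = 1 − 3/(4(n_i+n_j) − 9)``.
    """
    ni, nj = gi.n, gj.n
    if ni < 2 or nj < 2:
        raise ValueError("Hedges g needs n >= 2 per group")
    sp = np.sqrt(((ni - 1) * gi.sd**2 + (nj - 1) * gj.sd**2) / (ni + nj - 2))
    d = (gi.mean - gj.mean) / sp
    J = 1 - 3 / (4 * (ni + nj) - 9)
    g = d * J
    se = J * np.sqrt((ni + nj) / (ni * nj) + d**2 / (2 * (ni + nj - 2)))
    z = stats.norm.ppf(0.5 + conf / 2)
    return float(g), (float(g - z * se), float(g + z * se))


def games_howell(groups, conf: float = 0.95) -> list[PairwiseResult]:
    """All pairwise comparisons: Games–Howell p, Tukey-HSD-style CI, Hedges g.

    p-values use the studentized-range distribution with per-pair
    Welch–Satterthwaite df on the unpooled standard error (Games–Howell
    proper).  Confidence intervals use the pooled-variance Tukey HSD
    construction ``diff ± q_crit(conf, k, N−k)/√2 · s_p √(1/n_i+1/n_j)``,
    emitted alongside because published tables often pair GH p-values
    with Tukey intervals.
    """
    gs = _as_summaries(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("need at least two groups")
    N = sum(g.n for g in gs)
    ss_w = sum((g.n - 1) * g.sd**2 for g in gs)
    sp = np.sqrt(ss_w / (N - k))
    q_crit = stats.studentized_range.ppf(conf, k, N - k)

    results = []
    for gi, gj in combinations(gs, 2):
        diff = gi.mean - gj.mean
        se2 = gi.sd**2 / gi.n + gj.sd**2 / gj.n
        if se2 > 0:
            df_pair = se2**2 / (
                (gi.sd**2 / gi.n) ** 2 / (gi.n - 1)
                + (gj.sd**2 / gj.n) ** 2 / (gj.n - 1)
            )
            q = abs(diff) / np.sqrt(se2 / 2)
            p = float(stats.studentized_range.sf(q, k, df_pair))
        else:
            p = 1.0
        half = q_crit / np.sqrt(2) * sp * np.sqrt(1 / gi.n + 1 / gj.n)
        g, (g_lo, g_hi) = hedges_g(gi, gj, conf)
        results.append(
            PairwiseResult(
                pair=(gi.group, gj.group),
                mean_diff=float(diff),
                ci_low=float(diff - half),
                ci_high=float(diff + half),
                p_adj=min(p, 1.0),
                hedges_g=g,
                g_ci_low=g_lo,
                g_ci_high=g_hi,
            )
        )
    return results


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm–Bonferroni step-down adjustment (monotone, >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


@dataclass(frozen=True)
class MixedAnovaResult:
    """Classical mixed ANOVA: between groups x 2-level within factor."""

    table: pd.DataFrame            # effect, F, df1, df2, p, p_holm, omega_sq
    simple_effects: pd.DataFrame | None = None

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _mixed_components(df: pd.DataFrame, within_cols=("closer", "further")):
    """Shared sums-of-squares pieces for the 2-level mixed design."""
    a = df[within_cols[0]].to_numpy(dtype=float)
    b = df[within_cols[1]].to_numpy(dtype=float)
    groups = df["group"].to_numpy()
    labels = pd.unique(groups)
    k = len(labels)
    N = len(df)
    subj_mean = (a + b) / 2
    d = a - b
    # between-subjects stratum: one-way ANOVA on subject means (x2 scaling)
    gm = subj_mean.mean()
    ss_group = 2 * sum(
        (subj_mean[groups == g].mean() - gm) ** 2 * (groups == g).sum()
        for g in labels
    )
    ss_subj = 2 * sum(
        ((subj_mean[groups == g] - subj_mean[groups == g].mean()) ** 2).sum()
        for g in labels
    )
    # within-subjects stratum from the difference scores: d = closer - further
    d_means = np.array([d[groups == g].mean() for g in labels])
    n_g = np.array([(groups == g).sum() for g in labels])
    ss_err_d = sum(((d[groups == g] - d[groups == g].mean()) ** 2).sum() for g in labels)
    return labels, k, N, n_g, d, d_means, ss_group, ss_subj, ss_err_d, a, b


def mixed_anova(
    df: pd.DataFrame, within_cols: tuple[str, str] = ("closer", "further")
) -> MixedAnovaResult:
    """Mixed ANOVA with a between-subjects group factor and a two-level
    within-subjects factor (closer vs further object).

    Uses the exact sum/difference decomposition valid for two within
    levels: the group effect is the one-way ANOVA of subject means over
    MS subjects-within-groups with (k−1, N−k) df; the within main effect
    tests the unweighted mean of per-group difference-score means
    (Type-III convention, robust to unequal group sizes) with (1, N−k)
    df; the interaction is the between-group effect of the difference
    scores with (k−1, N−k) df.  Sphericity holds trivially with two
    levels.  ω² per effect uses the repeated-measures form
    ``df·(MS_eff − MS_err) / (SS_total + MS_subj)``; p-values are
    Holm–Bonferroni adjusted over the three omnibus effects.

    ``df`` needs columns participant_id, group, and the two within-level
    columns; participants with a missing cell are dropped with a warning.
    """
    df = df.rename(
        columns={
            "mean_closer_dwell_ms": "closer",
            "mean_further_dwell_ms": "further",
        }
    )
    complete = df[list(within_cols)].notna().all(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {(~complete).sum()} participants with a missing cell",
            stacklevel=2,
        )
        df = df[complete]
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups")

    (labels, k, N, n_g, d, d_means, ss_group, ss_subj, ss_err_d, a, b) = (
        _mixed_components(df, within_cols)
    )
    ms_subj = ss_subj / (N - k)
    ms_group = ss_group / (k - 1)
    F_between = ms_group / ms_subj

    # within stratum: SS on the original scale is half the difference-score SS;
    # the type main effect tests the unweighted mean of per-group d-means
    ss_type = (d_means.mean() ** 2) / ((1 / n_g).sum() / k**2) / 2
    dw = float(d_means @ (n_g / N))
    ss_inter = float((n_g * (d_means - dw) ** 2).sum() / 2)
    ms_err = ss_err_d / (N - k) / 2
    if ms_err == 0:  # degenerate: no within-cell variation
        F_within = 0.0 if ss_type == 0 else np.inf
        F_inter = 0.0 if ss_inter == 0 else np.inf
    else:
        F_within = (ss_type / 1) / ms_err
        F_inter = (ss_inter / (k - 1)) / ms_err

    gm_all = np.concatenate([a, b]).mean()
    ss_total = float(((np.concatenate([a, b]) - gm_all) ** 2).sum())

    def omega(ss_eff, df_eff, ms_error):
        ms_eff = ss_eff / df_eff
        return max(0.0, df_eff * (ms_eff - ms_error)) / (ss_total + ms_subj)

    rows = [
        ("group", F_between, k - 1, N - k, stats.f.sf(F_between, k - 1, N - k),
         omega(ss_group, k - 1, ms_subj)),
        ("type", F_within, 1, N - k, stats.f.sf(F_within, 1, N - k),
         omega(ss_type, 1, ms_err)),
        ("group:type", F_inter, k - 1, N - k, stats.f.sf(F_inter, k - 1, N - k),
         omega(ss_inter, k - 1, ms_err)),
    ]
    table = pd.DataFrame(
        rows, columns=["effect", "F", "df1", "df2", "p", "omega_sq"]
    )
    table["p_holm"] = holm_bonferroni(table["p"].to_numpy())
    table = table[["effect", "F", "df1", "df2", "p", "p_holm", "omega_sq"]]
    return MixedAnovaResult(table=table)


def simple_main_effects(
    df: pd.DataFrame,
    within_cols: tuple[str, str] = ("closer", "further"),
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-group simple main effect of the within factor.

    For each group: the paired closer-minus-further contrast with a
    t-based CI, its F test (squared paired t, df (1, n−1)), generalized
    eta squared with subject variance in the denominator, and
    Holm–Bonferroni adjustment across the groups.
    """
    df = df.rename(
        columns={
            "mean_closer_dwell_ms": "closer",
            "mean_further_dwell_ms": "further",
        }
    )
    rows = []
    for g, sub in df.groupby("group", sort=False):
        a = sub[within_cols[0]].to_numpy(dtype=float)
        b = sub[within_cols[1]].to_numpy(dtype=float)
        n = len(sub)
        d = a - b
        diff = d.mean()
        se = d.std(ddof=1) / np.sqrt(n)
        if se > 0:
            t_stat = diff / se
            F = t_stat**2
            p = float(stats.f.sf(F, 1, n - 1))
        else:
            F, p = 0.0, 1.0
        half = stats.t.ppf(0.5 + conf / 2, n - 1) * se
        # within-group decomposition for generalized eta squared
        ss_type = n * diff**2 / 2
        subj = (a + b) / 2
        ss_subj = 2 * ((subj - subj.mean()) ** 2).sum()
        ss_err = ((d - diff) ** 2).sum() / 2
        denom = ss_type + ss_subj + ss_err
        eta_g = ss_type / denom if denom > 0 else 0.0
        rows.append(
            {
                "group": str(g),
                "n": n,
                "mean_diff": float(diff),
                "ci_low": float(diff - half),
                "ci_high": float(diff + half),
                "F": float(F),
                "p": p,
                "eta_sq_g": float(eta_g),
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_bonferroni(out["p"].to_numpy())
    return out


def ancova(
    df: pd.DataFrame,
    dv: str = "mean_focal_dwell_ms",
    group_col: str = "group",
    covariates: tuple[str, ...] = (
        "municipality_size",
        "gender",
        "age",
        "lived_abroad",
        "n_siblings",
        "ses",
        "study_area",
    ),
) -> pd.DataFrame:
    """ANCOVA: dwell ~ group + covariates, Type-II SS, partial eta squared.

    Categorical covariates (object dtype or boolean) enter as factors;
    covariates constant across participants are dropped with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.copy()
    kept = []
    for c in covariates:
        if c not in data.columns:
            continue
        if data[c].nunique(dropna=True) < 2:
            warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
            continue
        kept.append(c)
    terms = [f"C({group_col})"]
    for c in kept:
        if data[c].dtype == object or data[c].dtype == bool:
            terms.append(f"C({c})")
        else:
            terms.append(c)
    formula = f"{dv} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        index=lambda s: s.replace(f"C({group_col})", group_col)
        .replace("C(", "")
        .replace(")", "")
    )
    ss_res = aov.loc["Residual", "sum_sq"]
    aov["partial_eta_sq"] = aov["sum_sq"] / (aov["sum_sq"] + ss_res)
    aov.loc["Residual", "partial_eta_sq"] = np.nan
    return aov


def power_min_n(
    f: float, alpha: float = 0.05, power: float = 0.80, k: int = 5
) -> PowerSpec:
    """Minimum total N for a one-way fixed-effects ANOVA.

    Scans equal-group totals (N divisible by k) for the smallest N whose
    noncentral-F tail beyond ``F_crit(alpha; k−1, N−k)`` with
    noncentrality ``λ = f²·N`` reaches the target power.
    """
    if not (f > 0 and 0 < alpha < 1 and 0 < power < 1 and k >= 2):
        raise ValueError("invalid power-analysis parameters")

    def achieved(N: int) -> float:
        df1, df2 = k - 1, N - k
        fc = stats.f.ppf(1 - alpha, df1, df2)
        return float(stats.ncf.sf(fc, df1, df2, f**2 * N))

    N = 2 * k
    while achieved(N) < power:
        N += k
        if N > 10_000_000:
            raise RuntimeError("power target unreachable")
    return PowerSpec(
        effect_size_f=f,
        alpha=alpha,
        power=power,
        k_groups=k,
        min_total_n=N,
        min_per_group_n=N // k,
        achieved_power=achieved(N),
    )
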