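"""Statistical layer for the pipeline's tidy outputs.

Two-way ANOVA interaction (type-II sums of squares), one-way ANOVA with
Tukey-Kramer or Dunnett post hoc comparisons, a Lilliefors-type normality
check, and group-summary reporting with means +/- SEM and significance stars
at the conventional thresholds (* P<0.05, ** P<0.01, *** P<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class InteractionResult:
    """Two-way ANOVA interaction statistic."""

    f_value: float
    df_num: float
    df_den: float
    p_value: float


@dataclass
class NormalityResult:
    """Kolmogorov-Smirnov statistic against a normal with estimated moments.

    ``corrected`` flags that the p-value uses the Lilliefors procedure (an
    approximation to the Dallal-Wilkinson-Lillie corrected p-value).
    """

    statistic: float
    p_value: float
    n: int
    corrected: bool = True


def significance_stars(p: float) -> str:
    """Stars at the conventional thresholds; 'n.s.' when P >= 0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def twoway_interaction(
    data: pd.DataFrame,
    factor_a: str = "age",
    factor_b: str = "genotype",
    value: str = "value",
) -> InteractionResult:
    """Type-II two-way ANOVA interaction term for an A x B design.

    Requires >= 2 levels per factor and a non-empty (>= 1 observation) cell
    for every level combination; an empty design cell is an error naming the
    cell.
    """
    for col in (factor_a, factor_b, value):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    if data[value].isna().any():
        raise ValueError("missing values in tested cells")
    levels_a = data[factor_a].unique()
    levels_b = data[factor_b].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("both factors need >= 2 levels")
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in counts.index:
                raise ValueError(f"empty design cell: ({factor_a}={a!r}, {factor_b}={b!r})")
    df = data.rename(columns={factor_a: "_A", factor_b: "_B", value: "_y"})
    model = smf.ols("_y ~ C(_A) * C(_B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(_A):C(_B)"]
    return InteractionResult(
        f_value=float(row["F"]),
        df_num=float(row["df"]),
        df_den=float(table.loc["Residual", "df"]),
        p_value=float(row["PR(>F)"]),
    )


def _group_arrays(data: pd.DataFrame, group: str, value: str):
    names = list(pd.unique(data[group]))
    arrays = [data.loc[data[group] == g, value].to_numpy(dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for g, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return names, arrays


def oneway_posthoc(
    data: pd.DataFrame,
    group: str = "group",
    value: str = "value",
    method: str = "tukey_kramer",
    control: str | None = None,
) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey-Kramer or Dunnett comparisons.

    Tukey-Kramer compares all pairs using the studentized-range distribution
    with the pooled within-group variance (Kramer's unequal-n form). Dunnett
    compares every group against the named ``control``. Returns a table with
    one row per comparison: group1, group2, mean_diff, p_adj, stars.
    """
    names, arrays = _group_arrays(data, group, value)
    k = len(names)
    n_total = sum(len(a) for a in arrays)
    df_w = n_total - k
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_w = ss_w / df_w
    means = {g: a.mean() for g, a in zip(names, arrays)}
    ns = {g: len(a) for g, a in zip(names, arrays)}

    rows = []
    if method == "tukey_kramer":
        for i in range(k):
            for j in range(i + 1, k):
                gi, gj = names[i], names[j]
                diff = means[gj] - means[gi]
                se = np.sqrt(ms_w / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
                q = abs(diff) / se if se > 0 else np.inf
                p = float(sps.studentized_range.sf(q, k, df_w))
                rows.append(
                    {
                        "group1": gi,
                        "group2": gj,
                        "mean_diff": diff,
                        "p_adj": min(max(p, 0.0), 1.0),
                        "stars": significance_stars(p),
                    }
                )
    elif method == "dunnett":
        if control is None:
            raise ValueError("Dunnett comparisons require a named control group")
        if control not in names:
            raise ValueError(f"control group {control!r} not present")
        treat_names = [g for g in names if g != control]
        treat = [a for g, a in zip(names, arrays) if g != control]
        ctrl = arrays[names.index(control)]
        res = sps.dunnett(*treat, control=ctrl)
        for g, p in zip(treat_names, np.atleast_1d(res.pvalue)):
            rows.append(
                {
                    "group1": control,
                    "group2": g,
                    "mean_diff": means[g] - means[control],
                    "p_adj": float(p),
                    "stars": significance_stars(float(p)),
                }
            )
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    return pd.DataFrame(rows)


def normality_check(values, n_min: int = 5) -> NormalityResult:
    """KS normality test with estimated moments (Lilliefors correction)."""
    x = np.asarray(values, dtype=float)
    if x.size < n_min:
        raise ValueError(f"need at least {n_min} observations, got {x.size}")
    if np.std(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    d, p = lilliefors(x, dist="norm", pvalmethod="table")
    return NormalityResult(statistic=float(d), p_value=float(p), n=int(x.size))


def group_summary(
    data: pd.DataFrame, group_cols: list[str], value: str = "value"
) -> pd.DataFrame:
    """Group means +/- SEM (sd/sqrt(n)) and counts."""
    grouped = data.groupby(group_cols, observed=True)[value]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


def markdown_report(
    data: pd.DataFrame,
    factor_a: str,
    factor_b: str | None = None,
    value: str = "value",
) -> str:
    """Markdown report: group means +/- SEM plus the relevant test results."""
    lines = ["# Quantification report", ""]
    group_cols = [factor_a] + ([factor_b] if factor_b else [])
    summary = group_summary(data, group_cols, value)
    lines.append("## Group summaries (mean ± SEM)")
    lines.append("")
    header = " | ".join(group_cols + ["mean ± SEM", "n"])
    lines.append("| " + header + " |")
    lines.append("|" + " --- |" * (len(group_cols) + 2))
    for rec in summary.itertuples(index=False):
        rec = rec._asdict()
        cells = [str(rec[c]) for c in group_cols]
        cells.append(f"{rec['mean']:.4g} ± {rec['sem']:.4g}")
        cells.append(str(rec["n"]))
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    if factor_b:
        res = twoway_interaction(data, factor_a, factor_b, value)
        lines.append(f"## Two-way ANOVA ({factor_a} x {factor_b}) interaction")
        lines.append("")
        lines.append(
            f"F({res.df_num:.0f}, {res.df_den:.0f}) = {res.f_value:.4g}, "
            f"P = {res.p_value:.4g} ({significance_stars(res.p_value)})"
        )
    else:
        table = oneway_posthoc(data, group=factor_a, value=value)
        lines.append("## One-way ANOVA with Tukey-Kramer post hoc")
        lines.append("")
        lines.append("| group1 | group2 | mean diff | adj. P | |")
        lines.append("| --- | --- | --- | --- | --- |")
        for rec in table.itertuples(index=False):
            lines.append(
                f"| {rec.group1} | {rec.group2} | {rec.mean_diff:.4g} "
                f"| {rec.p_adj:.4g} | {rec.stars} |"
            )
    lines.append("")
    return "\n".join(lines)
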