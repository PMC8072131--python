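"""Group-comparison battery for per-sample and per-object metric tables.

Skewed object-level morphometrics (tortuosity, diameter, eccentricity)
are summarised per sample by the median and compared with the Wilcoxon
rank-sum test; densities, counts and slopes use mean +/- SEM and a
two-way (age x sex) ANOVA with Sidak or Tukey post hoc correction;
diameter distributions are compared with the two-sample
Kolmogorov-Smirnov test.  Reports label object-level and animal-level
results separately to keep pseudo-replication explicit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import RankDeficiencyError

__all__ = [
    "StatResult",
    "rank_sum_test",
    "ks_two_sample",
    "two_way_anova",
    "sidak_adjust",
    "tukey_hsd",
    "posthoc_adjust",
    "summarize_by_group",
    "group_report",
]


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    pvalue: float
    comparison: str = ""
    adjustment: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ValueError(f"p value out of range: {self.pvalue}")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "comparison": self.comparison,
            "adjustment": self.adjustment,
            **{k: v for k, v in self.extra.items()},
        }


# --------------------------------------------------------------------------
# two-sample tests


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(a, b, exact_max_n: int = 8, comparison: str = "") -> StatResult:
    """Wilcoxon rank-sum test (two-sided) with midrank ties.

    The statistic is the rank sum of the first sample.  When
    ``min(n_a, n_b) <= exact_max_n`` the null distribution is enumerated
    exhaustively over all assignments of the pooled ranks (ties included);
    otherwise a normal approximation with tie-corrected variance is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:na].sum())
    n = na + nb
    if min(na, nb) <= exact_max_n:
        eps = 1e-9
        idx = np.arange(n)
        le = ge = total = 0
        for comb in itertools.combinations(idx, na):
            ws = ranks[list(comb)].sum()
            total += 1
            if ws <= w + eps:
                le += 1
            if ws >= w - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le / total, ge / total))
        method = "exact"
    else:
        mu = na * (n + 1) / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        var = na * nb / 12.0 * ((n + 1) - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (w - mu) / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal"
    return StatResult(
        test="wilcoxon_rank_sum",
        statistic=w,
        pvalue=p,
        comparison=comparison,
        extra={"n_a": na, "n_b": nb, "method": method},
    )


def ks_two_sample(a, b, comparison: str = "") -> StatResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return StatResult(
        test="ks_2samp",
        statistic=float(res.statistic),
        pvalue=float(min(1.0, res.pvalue)),
        comparison=comparison,
        extra={"n_a": len(a), "n_b": len(b)},
    )


# --------------------------------------------------------------------------
# two-way ANOVA


def two_way_anova(
    table: pd.DataFrame,
    value: str,
    factor_a: str = "age_group",
    factor_b: str = "sex",
) -> list[StatResult]:
    """Type-II two-way ANOVA on an effect-coded linear model.

    Returns F and p for both main effects and the interaction.  An empty
    design cell makes the interaction model rank deficient and raises
    :class:`RankDeficiencyError` naming the cell.  Degenerate designs with
    zero residual variance are guarded: an effect with zero sum of squares
    reports F = 0 (p = 1), a nonzero effect over a zero error term reports
    F = inf (p = 0).
    """
    df = table[[value, factor_a, factor_b]].dropna().copy()
    levels_a = sorted(df[factor_a].astype(str).unique())
    levels_b = sorted(df[factor_b].astype(str).unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index or counts.loc[(la, lb)] == 0:
                raise RankDeficiencyError(
                    f"empty design cell {factor_a}={la}, {factor_b}={lb}"
                )
    work = pd.DataFrame(
        {
            "y": df[value].astype(float).to_numpy(),
            "fa": df[factor_a].astype(str).to_numpy(),
            "fb": df[factor_b].astype(str).to_numpy(),
        }
    )
    import warnings as _warnings

    with _warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        # saturated designs (zero residual df) are handled explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.ols("y ~ C(fa, Sum) * C(fb, Sum)", data=work).fit()
        aov = sm.stats.anova_lm(model, typ=2)
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    df_resid = float(aov.loc["Residual", "df"])
    ms_resid = ss_resid / df_resid if df_resid > 0 else 0.0
    name_map = {
        "C(fa, Sum)": factor_a,
        "C(fb, Sum)": factor_b,
        "C(fa, Sum):C(fb, Sum)": f"{factor_a}:{factor_b}",
    }
    results = []
    for row, label in name_map.items():
        ss = float(aov.loc[row, "sum_sq"])
        dfe = float(aov.loc[row, "df"])
        if ms_resid > 1e-12 * max(1.0, abs(ss)):
            f = (ss / dfe) / ms_resid
            p = float(sps.f.sf(f, dfe, df_resid))
        elif ss <= 1e-12:
            f, p = 0.0, 1.0
        else:
            f, p = float("inf"), 0.0
        results.append(
            StatResult(
                test="two_way_anova",
                statistic=f,
                pvalue=p,
                comparison=label,
                extra={"sum_sq": ss, "df": dfe, "df_resid": df_resid},
            )
        )
    return results


# --------------------------------------------------------------------------
# post hoc adjustments


def sidak_adjust(pvalues: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Sidak correction ``p' = 1 - (1 - p)^m`` (monotone, p' >= p)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("need m >= 1 comparisons")
    return 1.0 - (1.0 - p) ** m


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> list[StatResult]:
    """All-pairs Tukey HSD via the studentized range over the pooled error term."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    res = sps.tukey_hsd(*arrays)
    out = []
    for i, j in itertools.combinations(range(len(names)), 2):
        out.append(
            StatResult(
                test="tukey_hsd",
                statistic=float(res.statistic[i, j]),
                pvalue=float(res.pvalue[i, j]),
                comparison=f"{names[i]} vs {names[j]}",
                adjustment="tukey",
            )
        )
    return out


def posthoc_adjust(
    pvalues: Optional[Sequence[float]] = None,
    method: str = "sidak",
    groups: Optional[Mapping[str, Sequence[float]]] = None,
    m: Optional[int] = None,
):
    """Multiple-comparison adjustment.

    ``sidak`` adjusts a vector of raw p values; ``tukey`` needs the group
    samples themselves (its p values come from the studentized range, not
    from raw pairwise p values).
    """
    if method == "sidak":
        if pvalues is None:
            raise ValueError("sidak adjustment needs raw p values")
        return sidak_adjust(pvalues, m=m)
    if method == "tukey":
        if groups is None:
            raise ValueError("tukey adjustment needs the group samples")
        return tukey_hsd(groups)
    raise ValueError("method must be 'sidak' or 'tukey'")


# --------------------------------------------------------------------------
# reporting


def summarize_by_group(
    table: pd.DataFrame,
    value: str,
    factors: Sequence[str] = ("age_group", "sex"),
    stat: str = "median",
) -> pd.DataFrame:
    """Per-group summary: median (95% CI half-width left to the caller) or mean +/- SEM."""
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    grouped = table.groupby(list(factors), observed=True)[value]
    if stat == "median":
        out = grouped.median().rename(value).reset_index()
    else:
        agg = grouped.agg(["mean", "sem", "count"])
        out = agg.reset_index().rename(columns={"mean": value})
    out.insert(len(out.columns), "summary", stat)
    return out


def group_report(
    table: pd.DataFrame,
    value: str,
    sample_col: str = "sample_id",
    factor_a: str = "age_group",
    factor_b: str = "sex",
    summary: str = "median",
    posthoc: str = "sidak",
) -> dict:
    """Full comparison battery for one metric.

    Object-level rank-sum comparisons between sexes within each age, a
    two-way ANOVA on per-sample summaries (when the design allows), and
    per-group summaries.  Object-level and per-sample results are labelled
    as such.
    """
    report: dict = {"metric": value, "summary_stat": summary}
    stat = "median" if summary == "median" else "mean"
    report["group_summaries"] = summarize_by_group(
        table, value, (factor_a, factor_b), stat=stat
    ).to_dict(orient="records")

    pairwise = []
    for age, sub in table.groupby(factor_a, observed=True):
        sexes = sorted(sub[factor_b].astype(str).unique())
        if len(sexes) == 2:
            x = sub.loc[sub[factor_b] == sexes[0], value].dropna().to_numpy()
            y = sub.loc[sub[factor_b] == sexes[1], value].dropna().to_numpy()
            if len(x) and len(y):
                r = rank_sum_test(x, y, comparison=f"{factor_a}={age}: {sexes[0]} vs {sexes[1]}")
                pairwise.append(r)
    if pairwise:
        adj = sidak_adjust([r.pvalue for r in pairwise])
        report["object_level_rank_sum"] = [
            {**r.to_dict(), "pvalue_sidak": float(pa)} for r, pa in zip(pairwise, adj)
        ]

    per_sample = (
        table.groupby([sample_col, factor_a, factor_b], observed=True)[value]
        .agg(stat)
        .reset_index()
    )
    report["per_sample_summaries"] = per_sample.to_dict(orient="records")
    try:
        anova = two_way_anova(per_sample, value, factor_a, factor_b)
        report["per_sample_anova"] = [r.to_dict() for r in anova]
    except (RankDeficiencyError, ValueError) as exc:
        report["per_sample_anova"] = {"skipped": str(exc)}
    if posthoc == "tukey":
        groups = {
            f"{a}/{b}": sub[value].to_numpy()
            for (a, b), sub in per_sample.groupby([factor_a, factor_b], observed=True)
            if len(sub) >= 2
        }
        if len(groups) >= 2:
            report["per_sample_posthoc"] = [r.to_dict() for r in tukey_hsd(groups)]
    return report
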