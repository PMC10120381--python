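"""Cohort-level statistics battery.

Group comparisons (Welch t, one-way ANOVA / Kruskal--Wallis with
Bonferroni-corrected post hocs), correlations with Fisher-z confidence
intervals, Shapiro--Wilk gating between parametric and nonparametric paths,
and exhaustive nested-subset OLS model selection by likelihood-ratio tests.

All tests are two-sided at alpha = 0.05 unless stated otherwise.  Reports
come back as :class:`TestReport` records that serialise cleanly to CSV/JSON.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TestReport",
    "ModelComparison",
    "welch_t",
    "pearson_with_ci",
    "spearman",
    "normality_gate",
    "kgroup_compare",
    "stepwise_ols",
]

ALPHA = 0.05


@dataclass
class TestReport:
    """One statistical test, flat enough for a results CSV row."""

    test_name: str
    statistic: float
    df: Optional[float]
    p_value: float
    estimate: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_per_group: Tuple[int, ...] = ()
    adjustment: str = "none"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        return d


SummaryTriple = Tuple[int, float, float]  # (n, mean, sd)


def _as_summary(g) -> SummaryTriple:
    if isinstance(g, tuple) and len(g) == 3 and np.isscalar(g[0]):
        n, m, s = g
        return int(n), float(m), float(s)
    arr = np.asarray(g, float)
    return len(arr), float(np.mean(arr)), float(np.std(arr, ddof=1))


def welch_t(group_a, group_b, *, level: float = 0.95) -> TestReport:
    """Welch two-independent-sample t-test with Satterthwaite df.

    Each group is either a raw sample or a printed summary triple
    ``(n, mean, sd)``; the two give identical results.  The estimate is
    ``mean_a - mean_b`` with a t-based confidence interval.
    """
    n1, m1, s1 = _as_summary(group_a)
    n2, m2, s2 = _as_summary(group_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups: t undefined")
    se = math.sqrt(v1 + v2)
    t = (m1 - m2) / se
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.5 + level / 2, df)
    return TestReport("welch_t", statistic=t, df=df, p_value=p,
                      estimate=m1 - m2, ci_low=m1 - m2 - tcrit * se,
                      ci_high=m1 - m2 + tcrit * se, n_per_group=(n1, n2))


def pearson_with_ci(x=None, y=None, *, r: Optional[float] = None,
                    n: Optional[int] = None, level: float = 0.95) -> TestReport:
    """Pearson correlation with a Fisher-z confidence interval.

    Give either raw samples ``x, y`` or a printed coefficient ``r`` with its
    sample size ``n``.  CI: ``tanh(atanh(r) +/- z / sqrt(n - 3))``; p from
    the t distribution with ``n - 2`` df.
    """
    if r is None:
        xa, ya = np.asarray(x, float), np.asarray(y, float)
        if len(xa) != len(ya):
            raise ValueError("x and y lengths differ")
        n = len(xa)
        if n < 4:
            raise ValueError("need n >= 4")
        r = float(sps.pearsonr(xa, ya).statistic)
    else:
        if n is None or n < 4:
            raise ValueError("need n >= 4 with a summary r")
        r = float(r)
    extra = {}
    if abs(r) >= 1.0:
        # CI degenerates at |r| = 1
        lo = hi = r
        p = 0.0
        extra["degenerate"] = True
    else:
        z = math.atanh(r)
        halfwidth = sps.norm.ppf(0.5 + level / 2) / math.sqrt(n - 3)
        lo, hi = math.tanh(z - halfwidth), math.tanh(z + halfwidth)
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestReport("pearson", statistic=r, df=n - 2, p_value=p, estimate=r,
                      ci_low=lo, ci_high=hi, n_per_group=(n,), extra=extra)


def spearman(x, y, *, mc_permutations: int = 20000, mc_seed: int = 0) -> TestReport:
    """Spearman rank correlation with midrank ties.

    The p-value is exact (all permutations) for n <= 8, a seeded Monte
    Carlo permutation p for 9 <= n <= 10, and the usual t approximation for
    larger samples.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    n = len(xa)
    if n != len(ya):
        raise ValueError("x and y lengths differ")
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rx, ry = sps.rankdata(xa), sps.rankdata(ya)
    rs = float(np.corrcoef(rx, ry)[0, 1])

    cx, cy = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
    if n <= 8:
        perms = np.array(list(itertools.permutations(cx)))
        stats = (perms @ cy) / denom
        p = float(np.mean(np.abs(stats) >= abs(rs) - 1e-12))
        method = "exact_permutation"
    elif n <= 10:
        rng = np.random.default_rng(mc_seed)
        perms = rng.permuted(np.tile(cx, (mc_permutations, 1)), axis=1)
        stats = (perms @ cy) / denom
        p = float((1 + np.sum(np.abs(stats) >= abs(rs) - 1e-12)) / (1 + mc_permutations))
        method = "mc_permutation"
    else:
        p = float(sps.spearmanr(xa, ya).pvalue)
        method = "t_approximation"
    return TestReport("spearman", statistic=rs, df=None, p_value=min(p, 1.0),
                      estimate=rs, n_per_group=(n,), extra={"method": method})


def normality_gate(groups: Union[Dict[str, Sequence[float]], Sequence[Sequence[float]]],
                   alpha: float = ALPHA) -> Tuple[str, pd.DataFrame]:
    """Choose the parametric or nonparametric path by Shapiro--Wilk.

    Returns ``("nonparametric", table)`` if any group rejects normality at
    ``alpha``, else ``("parametric", table)``; the table carries W and p per
    group.
    """
    if not isinstance(groups, dict):
        groups = {str(i): g for i, g in enumerate(groups)}
    rows = []
    nonnormal = False
    for name, g in groups.items():
        arr = np.asarray(g, float)
        if len(arr) < 3:
            raise ValueError(f"group {name!r}: Shapiro-Wilk needs n >= 3")
        if np.ptp(arr) == 0:
            w, p = float("nan"), 0.0  # constant sample: certainly not normal
        else:
            w, p = sps.shapiro(arr)
        nonnormal = nonnormal or (p < alpha)
        rows.append({"group": name, "n": len(arr), "W": float(w), "p": float(p)})
    path = "nonparametric" if nonnormal else "parametric"
    return path, pd.DataFrame(rows)


def _bonferroni(p: float, m: int) -> float:
    return min(p * m, 1.0)


def kgroup_compare(values, grouping, path: str = "auto",
                   alpha: float = ALPHA) -> Tuple[TestReport, pd.DataFrame]:
    """Omnibus k-group comparison with Bonferroni-corrected post hocs.

    Parametric path: one-way ANOVA with pairwise Welch t post hocs.
    Nonparametric: Kruskal--Wallis with pairwise Wilcoxon rank-sum tests.
    ``path="auto"`` picks by the Shapiro--Wilk gate.  Levels with fewer
    than two observations are dropped with a warning in ``extra``.
    """
    values = np.asarray(values, float)
    grouping = np.asarray(grouping)
    levels = pd.unique(grouping)
    samples, dropped = {}, []
    for lev in levels:
        g = values[grouping == lev]
        if len(g) < 2:
            dropped.append(str(lev))
        else:
            samples[str(lev)] = g
    if len(samples) < 2:
        raise ValueError("need at least two levels with n >= 2")
    if path == "auto":
        path, _ = normality_gate(samples, alpha)
    groups = list(samples.values())
    names = list(samples.keys())
    k = len(groups)
    if path == "parametric":
        f, p = sps.f_oneway(*groups)
        report = TestReport("anova_oneway", statistic=float(f),
                            df=float(k - 1), p_value=float(p),
                            n_per_group=tuple(len(g) for g in groups))
    elif path == "nonparametric":
        h, p = sps.kruskal(*groups)
        report = TestReport("kruskal_wallis", statistic=float(h),
                            df=float(k - 1), p_value=float(p),
                            n_per_group=tuple(len(g) for g in groups))
    else:
        raise ValueError(f"path must be 'auto', 'parametric' or 'nonparametric', got {path!r}")
    if dropped:
        report.extra["dropped_levels"] = dropped
    n_pairs = k * (k - 1) // 2
    rows = []
    for (na, ga), (nb, gb) in itertools.combinations(zip(names, groups), 2):
        if path == "parametric":
            stat, praw = sps.ttest_ind(ga, gb, equal_var=False)
            test = "welch_t"
        else:
            stat, praw = sps.ranksums(ga, gb)
            test = "wilcoxon_ranksum"
        rows.append({"group_a": na, "group_b": nb, "test": test,
                     "statistic": float(stat), "p_raw": float(praw),
                     "p_bonferroni": _bonferroni(float(praw), n_pairs)})
    return report, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exhaustive nested-subset OLS with likelihood-ratio selection


@dataclass
class ModelComparison:
    """All candidate OLS subsets of a small predictor pool, compared by
    Gaussian likelihood-ratio tests between nested pairs.

    ``selected`` is the smallest subset no superset improves upon at
    ``alpha`` (ties broken by residual sum of squares).
    """

    outcome: str
    candidates: Tuple[str, ...]
    table: pd.DataFrame            # one row per subset: r2, F, dfs, rss, aic
    coefficients: Dict[Tuple[str, ...], pd.DataFrame]
    lrt: pd.DataFrame              # nested pairs: statistic, df, p
    selected: Tuple[str, ...]
    alpha: float = ALPHA

    @property
    def selected_coefficients(self) -> pd.DataFrame:
        return self.coefficients[self.selected]

    def summary(self) -> str:
        lines = [f"Exhaustive nested OLS for '{self.outcome}'",
                 f"candidates: {', '.join(self.candidates) or '(none)'}",
                 "", self.table.to_string(index=False), "",
                 f"selected model: {'{' + ', '.join(self.selected) + '}' if self.selected else '(intercept only)'}",
                 "", self.selected_coefficients.to_string()]
        return "\n".join(lines)


def _lrt(n: int, rss_reduced: float, rss_full: float, df_diff: int) -> Tuple[float, float]:
    if rss_full <= 0:
        return math.inf, 0.0
    stat = n * math.log(rss_reduced / rss_full)
    return stat, float(sps.chi2.sf(max(stat, 0.0), df_diff))


def stepwise_ols(outcome: str, candidates: Sequence[str], data: pd.DataFrame,
                 alpha: float = ALPHA) -> ModelComparison:
    """Select among all predictor subsets by nested likelihood-ratio tests.

    Fits every subset of ``candidates`` (complete cases only) by OLS with an
    intercept, computes the LRT statistic ``n * ln(RSS_reduced / RSS_full)``
    (chi-square, df = parameter difference) for every nested pair, and
    selects the smallest subset that no superset significantly improves on.
    With a handful of candidate predictors this exhaustive comparison is the
    transparent version of stepwise selection.
    """
    cols = [outcome, *candidates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    df = data[cols].dropna()
    n = len(df)
    if n < len(candidates) + 2:
        raise ValueError(f"only {n} complete cases for {len(candidates)} predictors")
    y = df[outcome].to_numpy(float)

    X_full = sm.add_constant(df[list(candidates)].to_numpy(float))
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        corr = df[list(candidates)].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if len(candidates) > 1 else (candidates[0],)
        raise ValueError(f"rank-deficient design; most collinear predictors: {worst}")

    subsets = [tuple(c) for k in range(len(candidates) + 1)
               for c in itertools.combinations(candidates, k)]
    fits, rows = {}, []
    for sub in subsets:
        X = sm.add_constant(df[list(sub)].to_numpy(float)) if sub else \
            np.ones((n, 1))
        res = sm.OLS(y, X).fit()
        fits[sub] = res
        rows.append({
            "predictors": "+".join(sub) if sub else "(intercept)",
            "k": len(sub), "r2": float(res.rsquared),
            "F": float(res.fvalue) if sub else float("nan"),
            "df_model": int(res.df_model), "df_resid": int(res.df_resid),
            "rss": float(res.ssr), "aic": float(res.aic),
        })
        names = ["const", *sub]
        fits[sub].coef_table = pd.DataFrame(
            {"beta": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues},
            index=names)
    table = pd.DataFrame(rows)

    lrt_rows = []
    for sub in subsets:
        for sup in subsets:
            if len(sup) == len(sub) + 1 and set(sub) < set(sup):
                stat, p = _lrt(n, fits[sub].ssr, fits[sup].ssr, len(sup) - len(sub))
                lrt_rows.append({"reduced": "+".join(sub) or "(intercept)",
                                 "full": "+".join(sup), "statistic": stat,
                                 "df": len(sup) - len(sub), "p": p})
    lrt = pd.DataFrame(lrt_rows)

    def improved_upon(sub) -> bool:
        for sup in subsets:
            if set(sub) < set(sup):
                stat, p = _lrt(n, fits[sub].ssr, fits[sup].ssr, len(sup) - len(sub))
                if p < alpha:
                    return True
        return False

    adequate = [s for s in subsets if not improved_upon(s)]
    selected = min(adequate, key=lambda s: (len(s), fits[s].ssr)) if adequate \
        else max(subsets, key=len)

    return ModelComparison(
        outcome=outcome, candidates=tuple(candidates), table=table,
        coefficients={s: fits[s].coef_table for s in subsets},
        lrt=lrt, selected=selected, alpha=alpha)
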