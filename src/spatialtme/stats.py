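"""Group statistics: frequencies, tissue NLR, t-test, ANOVA, Pearson, KM.

All test statistics are computed from their closed-form definitions;
scipy.stats is used only for reference-distribution tail probabilities.
Results come back as small dataclasses with a ``stars`` property following
the usual convention (* p <= 0.05, ** p <= 0.01, *** p <= 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = [
    "normalized_frequencies",
    "tissue_nlr",
    "TTestResult",
    "unpaired_t_test",
    "AnovaResult",
    "two_way_anova",
    "CorrelationResult",
    "pearson_correlation",
    "kaplan_meier",
    "km_survival_at",
    "LogRankResult",
    "log_rank",
    "p_stars",
    "summarize_tests",
]


def p_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# frequencies and ratios


def normalized_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize per-sample category counts by the sample's total cell count.

    ``counts`` has one row per sample and one column per category; every
    row must have a positive total.  Rows of the result sum to 1.
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total count: {bad}")
    return counts.div(totals, axis=0)


def tissue_nlr(n_neutrophils: int, n_cd4t: int, n_cd8t: int) -> float:
    """Tissue neutrophil-to-lymphocyte ratio: neutrophils / (CD4 T + CD8 T).

    Computed in exact rational arithmetic on the integer counts.  With zero
    lymphocytes the ratio is undefined: NaN is returned with a warning
    rather than an infinite value.
    """
    if min(n_neutrophils, n_cd4t, n_cd8t) < 0:
        raise ValueError("counts must be >= 0")
    lymphocytes = n_cd4t + n_cd8t
    if lymphocytes == 0:
        warnings.warn("tissue NLR undefined: zero lymphocytes", stacklevel=2)
        return float("nan")
    return float(Fraction(int(n_neutrophils), int(lymphocytes)))


# ---------------------------------------------------------------------------
# unpaired t-test


@dataclass
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    variant: str
    mean_diff: float
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return p_stars(self.pvalue)


def unpaired_t_test(x, y, variant: str = "welch") -> TTestResult:
    """Two-sided unpaired t-test (Welch by default; ``variant="student"``
    for the equal-variance form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    nx, ny = len(x), len(y)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = mx - my
    if vx == 0 and vy == 0:
        if diff == 0:
            return TTestResult(0.0, float(nx + ny - 2), 1.0, variant, 0.0,
                               degenerate=True)
        stat = np.inf if diff > 0 else -np.inf
        return TTestResult(float(stat), float(nx + ny - 2), 0.0, variant,
                           float(diff), degenerate=True)
    if variant == "welch":
        se2 = vx / nx + vy / ny
        stat = diff / np.sqrt(se2)
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    elif variant == "student":
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        stat = diff / np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    else:
        raise ValueError("variant must be 'welch' or 'student'")
    p = 2 * t_dist.sf(abs(stat), df)
    return TTestResult(float(stat), float(df), float(min(p, 1.0)), variant,
                       float(diff))


# ---------------------------------------------------------------------------
# two-way ANOVA (Type II sums of squares)


@dataclass
class AnovaResult:
    table: pd.DataFrame  # index: effect; columns: sum_sq, df, F, pvalue

    def pvalue(self, effect: str) -> float:
        return float(self.table.loc[effect, "pvalue"])

    @property
    def stars(self) -> dict:
        return {e: p_stars(p) for e, p in self.table["pvalue"].items()
                if e != "Residual"}


def _dummies(levels: pd.Series) -> np.ndarray:
    return pd.get_dummies(levels, drop_first=True, dtype=float).to_numpy()


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def two_way_anova(values, factor_a, factor_b,
                  include_interaction: bool = True) -> AnovaResult:
    """Fixed-effects two-way ANOVA with Type II sums of squares.

    Type II tests each main effect adjusted for the other main effect (and
    the interaction is tested against the additive model), which coincides
    with the classical decomposition on balanced layouts.  The interaction
    term is dropped automatically when the layout has no replication to
    estimate it.
    """
    y = np.asarray(values, dtype=float)
    fa = pd.Series(pd.Categorical(factor_a))
    fb = pd.Series(pd.Categorical(factor_b))
    if not (len(y) == len(fa) == len(fb)):
        raise ValueError("values and factors must have equal length")
    a_levels, b_levels = len(fa.cat.categories), len(fb.cat.categories)
    if a_levels < 2 or b_levels < 2:
        raise ValueError("each factor needs >= 2 levels")
    n = len(y)
    ones = np.ones((n, 1))
    da = _dummies(fa)
    db = _dummies(fb)
    dab = np.einsum("ni,nj->nij", da, db).reshape(n, -1)

    x_a = np.hstack([ones, da])
    x_b = np.hstack([ones, db])
    x_ab = np.hstack([ones, da, db])
    x_full = np.hstack([ones, da, db, dab])

    df_a, df_b = a_levels - 1, b_levels - 1
    df_ab = df_a * df_b
    rank_full = np.linalg.matrix_rank(x_full)
    if include_interaction and n - rank_full <= 0:
        include_interaction = False  # no replication: additive model
    model = x_full if include_interaction else x_ab
    rss_model = _rss(model, y)
    df_resid = n - np.linalg.matrix_rank(model)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    ss = {
        "factor_a": _rss(x_b, y) - _rss(x_ab, y),
        "factor_b": _rss(x_a, y) - _rss(x_ab, y),
    }
    dfs = {"factor_a": df_a, "factor_b": df_b}
    if include_interaction:
        ss["interaction"] = _rss(x_ab, y) - rss_model
        dfs["interaction"] = df_ab
    mse = rss_model / df_resid

    rows = {}
    for effect, s in ss.items():
        s = max(s, 0.0)
        ms = s / dfs[effect]
        if mse == 0:
            f = 0.0 if s == 0 else np.inf
        else:
            f = ms / mse
        p = 1.0 if f == 0 else float(f_dist.sf(f, dfs[effect], df_resid))
        rows[effect] = {"sum_sq": s, "df": dfs[effect], "F": f, "pvalue": p}
    rows["Residual"] = {"sum_sq": rss_model, "df": df_resid,
                        "F": np.nan, "pvalue": np.nan}
    return AnovaResult(table=pd.DataFrame(rows).T)


# ---------------------------------------------------------------------------
# Pearson correlation


@dataclass
class CorrelationResult:
    r: float
    pvalue: float
    n: int

    @property
    def stars(self) -> str:
        return p_stars(self.pvalue)


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with the t-distribution two-sided p-value
    (t = r sqrt((n-2)/(1-r^2)))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        stat = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * t_dist.sf(abs(stat), n - 2))
    return CorrelationResult(r=r, pvalue=min(p, 1.0), n=n)


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct time with columns ``time, n_at_risk,
    n_events, n_censored, survival``.  At tied times events are handled
    before censorings (censored subjects at time t count as at risk for
    the event at t).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) != len(events):
        raise ValueError("times and events must have equal length")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times)
    n = len(times)
    rows = []
    s = 1.0
    for t in distinct:
        at_risk = int((times >= t).sum())
        d = int(events[times == t].sum())
        c = int((times == t).sum() - d)
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append({"time": t, "n_at_risk": at_risk, "n_events": d,
                     "n_censored": c, "survival": s})
    return pd.DataFrame(rows)


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """Evaluate the right-continuous KM step function at time ``t`` (S(0)=1)."""
    past = km[km["time"] <= t]
    return 1.0 if len(past) == 0 else float(past["survival"].iloc[-1])


@dataclass
class LogRankResult:
    chi2: float
    pvalue: float
    df: int = 1

    @property
    def stars(self) -> str:
        return p_stars(self.pvalue)


def log_rank(times, events, groups) -> LogRankResult:
    """Two-group log-rank test (one degree of freedom).

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the risk sets.  Raises if no
    events occurred at all; a zero-variance comparison (e.g. both groups
    identical with a single shared event time) yields chi2 = 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("log-rank requires exactly two groups")
    if events.sum() == 0:
        raise ValueError("log-rank undefined: all observations censored")
    g1 = groups == levels[0]
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n_total = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d_total = int(events[(times == t)].sum())
        d1 = int(events[(times == t) & g1].sum())
        if n_total < 2:
            continue
        e1 = d_total * n1 / n_total
        v = (d_total * (n1 / n_total) * (1 - n1 / n_total)
             * (n_total - d_total) / (n_total - 1))
        o_minus_e += d1 - e1
        var += v
    if var == 0:
        return LogRankResult(chi2=0.0, pvalue=1.0)
    chi2 = o_minus_e ** 2 / var
    return LogRankResult(chi2=float(chi2), pvalue=float(chi2_dist.sf(chi2, 1)))


# ---------------------------------------------------------------------------
# tidy reporting


def summarize_tests(entries: list[dict]) -> pd.DataFrame:
    """Tidy results table: one row per test with statistic, df, p and stars.

    Each entry is ``{"test": ..., "comparison": ..., "result": <result
    object>}`` where the result is one of the dataclasses above.
    """
    rows = []
    for e in entries:
        r = e["result"]
        if isinstance(r, TTestResult):
            stat, df, p = r.statistic, r.df, r.pvalue
        elif isinstance(r, CorrelationResult):
            stat, df, p = r.r, r.n - 2, r.pvalue
        elif isinstance(r, LogRankResult):
            stat, df, p = r.chi2, r.df, r.pvalue
        else:
            raise TypeError(f"unsupported result type {type(r)!r}")
        rows.append({"test": e["test"], "comparison": e.get("comparison", ""),
                     "statistic": stat, "df": df, "pvalue": p,
                     "stars": p_stars(p)})
    return pd.DataFrame(rows)
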