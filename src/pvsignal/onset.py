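"""Time-to-onset (latency) comparison across drug categories.

Latency is days from therapy start to event occurrence.  Spontaneous
reports only contain observed events, so the cumulative risk curve
1 - S(t) reduces to the empirical CDF; it is nevertheless computed with
the product-limit estimator (via ``lifelines``) so that a censoring
indicator can be passed when reports with unknown outcome dates are to be
treated as censored.  Group comparisons: k-sample log-rank on the curves,
one-way ANOVA with Tukey HSD post hoc summarized as a compact letter
display, and a Welch t-test for the two-group (ocular vs non-ocular) case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .ingest import CleanDatabase, parse_yyyymmdd

__all__ = ["compute_latencies", "cumulative_risk", "log_rank", "anova_cld",
           "welch_t", "compact_letter_display", "group_summary"]


def compute_latencies(db: CleanDatabase, drugs=None) -> pd.DataFrame:
    """Latency records for event cases exposed to the given drugs.

    One row per (case, drug) with both therapy start and event date
    present; records with negative latency (event before start) or missing
    dates are excluded, with counts in the frame's ``attrs['excluded']``.
    Defaults to the database's retained (consensus-candidate) drugs.
    """
    drugs = set(drugs) if drugs is not None else set(db.retained_drugs)
    expo = db.exposures
    sel = expo[expo["generic"].isin(drugs)
               & expo["caseid"].isin(db.event_case_ids)].copy()
    n_all = len(sel)
    sel["start"] = parse_yyyymmdd(sel["start_dt"])
    event_date = parse_yyyymmdd(db.cases["event_dt"])
    sel["event_date"] = sel["caseid"].map(event_date)
    has_dates = sel["start"].notna() & sel["event_date"].notna()
    sel = sel[has_dates]
    n_dates = len(sel)
    sel["latency"] = (sel["event_date"] - sel["start"]).dt.days.astype(float)
    out = sel[sel["latency"] >= 0][["caseid", "generic", "category", "latency"]]
    out = out.rename(columns={"generic": "drug"}).reset_index(drop=True)
    out.attrs["excluded"] = {"missing_dates": n_all - n_dates,
                             "negative_latency": n_dates - len(out)}
    return out


def cumulative_risk(groups: dict[str, np.ndarray],
                    observed: dict[str, np.ndarray] | None = None
                    ) -> dict[str, pd.DataFrame]:
    """Per-group cumulative incidence 1 - S(t) via the product-limit estimator.

    ``observed`` optionally marks which records are events (others are
    right-censored); by default all are events and the curve is the ECDF.
    Returns per group a frame with columns ``t`` and ``cum_risk``.
    """
    if not groups:
        raise ValueError("at least one group required")
    out = {}
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"group {name!r} is empty")
        obs = None if observed is None else observed[name]
        kmf = KaplanMeierFitter()
        kmf.fit(values, event_observed=obs)
        sf = kmf.survival_function_
        out[name] = pd.DataFrame({
            "t": sf.index.to_numpy(dtype=float),
            "cum_risk": 1.0 - sf.iloc[:, 0].to_numpy(),
        })
    return out


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def log_rank(groups: dict[str, np.ndarray]) -> LogRankResult:
    """k-sample log-rank test on uncensored latency groups."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    durations, labels = [], []
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        durations.append(values)
        labels.extend([name] * values.size)
    durations = np.concatenate(durations)
    res = multivariate_logrank_test(durations, np.asarray(labels))
    df = len(groups) - 1
    chi2 = float(res.test_statistic)
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def compact_letter_display(names: list[str], means: np.ndarray,
                           sig: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``sig[i, j]`` is True when groups i and j differ significantly.  Groups
    sharing a letter are not significantly different; letters are assigned
    in ascending order of group mean.
    """
    order = np.argsort(means, kind="stable")
    cols = [set(order.tolist())]  # start: one letter containing everyone
    for ii in range(len(names)):
        for jj in range(ii + 1, len(names)):
            i, j = order[ii], order[jj]
            if not sig[i, j]:
                continue
            for col in list(cols):
                if i in col and j in col:
                    c1 = col - {j}
                    c2 = col - {i}
                    cols.remove(col)
                    cols.extend([c1, c2])
            # absorb columns that became subsets of another
            cols = [c for c in cols
                    if not any(c < other for other in cols)]
    # deduplicate while preserving insertion order
    uniq = []
    for c in cols:
        if c not in uniq:
            uniq.append(c)
    # letter order follows the smallest (by mean rank) member of each column
    rank = {g: r for r, g in enumerate(order.tolist())}
    uniq.sort(key=lambda c: min(rank[g] for g in c))
    letters = {name: "" for name in names}
    for letter_i, col in enumerate(uniq):
        ch = chr(ord("a") + letter_i)
        for g in col:
            letters[names[g]] += ch
    return {name: "".join(sorted(s)) for name, s in letters.items()}


@dataclass
class AnovaCLDResult:
    f: float
    p: float
    letters: dict[str, str]
    tukey: pd.DataFrame
    summary: pd.DataFrame


def anova_cld(groups: dict[str, np.ndarray], alpha: float = 0.05,
              log_scale: bool = False) -> AnovaCLDResult:
    """One-way ANOVA with Tukey HSD post hoc and compact letters.

    F and p come straight from the between/within sums of squares.  The
    Tukey-Kramer adjustment handles unequal group sizes.  Latencies are
    right-skewed; ``log_scale=True`` analyses log(1 + days) instead of raw
    days.  All groups constant with unequal means is reported as F = inf.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrs = []
    for name in names:
        v = np.asarray(groups[name], dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        arrs.append(np.log1p(v) if log_scale else v)
    k = len(arrs)
    ns = np.array([a.size for a in arrs])
    n = int(ns.sum())
    means = np.array([a.mean() for a in arrs])
    grand = np.concatenate(arrs).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        f = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))

    values = np.concatenate(arrs)
    labels = np.concatenate([[name] * a.size for name, a in zip(names, arrs)])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    sig = np.zeros((k, k), dtype=bool)
    pos = {name: i for i, name in enumerate(names)}
    for _, row in tukey.iterrows():
        i, j = pos[str(row["group1"])], pos[str(row["group2"])]
        sig[i, j] = sig[j, i] = bool(row["reject"])
    letters = compact_letter_display(names, means, sig)

    summary = group_summary(groups)
    summary["letters"] = summary.index.map(letters)
    return AnovaCLDResult(f=float(f), p=p, letters=letters, tukey=tukey,
                          summary=summary)


def group_summary(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """n / mean / sd / median per group (raw days)."""
    rows = {}
    for name, v in groups.items():
        v = np.asarray(v, dtype=float)
        rows[name] = {"n": v.size, "mean": v.mean(),
                      "sd": v.std(ddof=1) if v.size > 1 else math.nan,
                      "median": float(np.median(v))}
    return pd.DataFrame(rows).T.rename_axis("group")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(group1, group2) -> WelchResult:
    """Welch unequal-variance t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0)
        return WelchResult(math.inf if x.mean() > y.mean() else -math.inf,
                           float(x.size + y.size - 2), 0.0)
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (vx**2 / (x.size**2 * (x.size - 1))
                   + vy**2 / (y.size**2 * (y.size - 1)))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)
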