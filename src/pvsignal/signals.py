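"""Disproportionality statistics on 2x2 spontaneous-report contingency tables.

For one drug-event pair the database is collapsed to

    =============  ============  ============
                   target event  other events
    =============  ============  ============
    target drug         a             b
    other drugs         c             d
    =============  ============  ============

Four statistics are computed per drug: the reporting odds ratio (ROR), the
proportional reporting ratio (PRR) with its 1-df chi-square, the Bayesian
confidence propagation (BCPNN) information component IC, and the empirical
Bayes geometric mean (EBGM) of the gamma-Poisson shrinker (see
:mod:`pvsignal.mgps`).  A drug is a *consensus signal* when all four
algorithms flag it positive simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .errors import EmptyDatabaseError

__all__ = [
    "ContingencyTable",
    "IntervalEstimate",
    "BCPNNConfig",
    "SignalThresholds",
    "SignalResult",
    "build_contingency",
    "ror",
    "prr",
    "bcpnn_ic",
    "signal_criteria",
    "run_signal_scan",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of a single drug x event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.n == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a two-sided interval.

    ``corrected`` marks a Haldane-Anscombe 0.5 continuity correction;
    ``defined`` is False when the statistic could not be computed at all.
    """

    point: float
    low: float
    high: float
    corrected: bool = False
    defined: bool = True


def build_contingency(db, drug: str, event_cases=None) -> ContingencyTable:
    """Collapse a cleaned database into the 2x2 table for one drug.

    ``db`` is a :class:`pvsignal.ingest.CleanDatabase` (any object with
    ``case_ids``, ``event_case_ids`` and ``exposed_case_ids(drug)`` works).
    ``event_cases`` overrides the database's event-case set.
    """
    all_cases = db.case_ids
    n = len(all_cases)
    if n == 0:
        raise EmptyDatabaseError("no cases in database")
    events = set(event_cases) if event_cases is not None else set(db.event_case_ids)
    exposed = set(db.exposed_case_ids(drug))
    a = len(exposed & events)
    b = len(exposed) - a
    c = len(events) - a
    d = n - a - b - c
    return ContingencyTable(a, b, c, d)


def _cells(table: ContingencyTable, correct_zero: bool):
    """Return (a, b, c, d, corrected) applying the 0.5 rule when needed."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if correct_zero and min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return float(a), float(b), float(c), float(d), False


def ror(table: ContingencyTable, z: float = 1.96,
        correct_zero: bool = True) -> IntervalEstimate:
    """Reporting odds ratio (a*d)/(b*c) with a Wald log-scale interval.

    A zero cell makes the estimate or its variance undefined; by default the
    Haldane-Anscombe correction adds 0.5 to every cell and the result is
    flagged ``corrected``.  With ``correct_zero=False`` a zero cell yields an
    undefined (NaN) result.
    """
    a, b, c, d, corrected = _cells(table, correct_zero)
    if min(a, b, c, d) == 0:
        return IntervalEstimate(math.nan, math.nan, math.nan, defined=False)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_est = math.log(est)
    return IntervalEstimate(est, math.exp(log_est - z * se),
                            math.exp(log_est + z * se), corrected=corrected)


@dataclass(frozen=True)
class PRRResult:
    prr: IntervalEstimate
    chi2: float
    p: float


def prr(table: ContingencyTable, z: float = 1.96, correct_zero: bool = True,
        yates: bool = False) -> PRRResult:
    """Proportional reporting ratio with Wald interval and Pearson chi-square.

    PRR = [a/(a+b)] / [c/(c+d)].  The chi-square is always computed from the
    raw counts, N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)), with an optional Yates
    continuity correction; a zero margin gives chi2 = 0 (the brute-force
    sum over cells with positive expectation is identically zero there).
    A zero in a or c is handled by the 0.5 correction when enabled; a = 0
    without correction yields PRR = 0 with an undefined interval.
    """
    ra, rb, rc, rd = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = ra + rb + rc + rd
    r1, r0, c1, c0 = ra + rb, rc + rd, ra + rc, rb + rd
    if min(r1, r0, c1, c0) == 0:
        chi2 = 0.0
    else:
        num = abs(ra * rd - rb * rc)
        if yates:
            num = max(0.0, num - n / 2.0)
        chi2 = n * num * num / (r1 * r0 * c1 * c0)
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0

    # the 0.5 correction applies only when a or c is zero: zeros in b or d
    # leave both the PRR and its log-variance well defined
    a, b, c, d = ra, rb, rc, rd
    corrected = False
    if correct_zero and (table.a == 0 or table.c == 0):
        a, b, c, d = ra + 0.5, rb + 0.5, rc + 0.5, rd + 0.5
        corrected = True
    if a + b == 0 or c + d == 0:
        return PRRResult(IntervalEstimate(math.nan, math.nan, math.nan,
                                          defined=False), chi2, p)
    if a == 0:
        return PRRResult(IntervalEstimate(0.0, math.nan, math.nan,
                                          defined=False), chi2, p)
    if c == 0:
        return PRRResult(IntervalEstimate(math.inf, math.nan, math.nan,
                                          defined=False), chi2, p)
    est = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    log_est = math.log(est)
    return PRRResult(
        IntervalEstimate(est, math.exp(log_est - z * se),
                         math.exp(log_est + z * se), corrected=corrected),
        chi2, p)


@dataclass(frozen=True)
class BCPNNConfig:
    """Conjugate-prior pseudo-counts for the information component.

    The posterior model treats the joint cell probability and the two
    margin probabilities as independent Beta variables:

        p11 ~ Beta(a + g11,     N - a     + g  - g11)
        p1. ~ Beta(a + b + a1,  N - a - b + a0 - a1)
        p.1 ~ Beta(a + c + b1,  N - a - c + b0 - b1)

    with the joint prior total g = g11 (N + a0)(N + b0) /
    ((a + b + a1)(a + c + b1)), the data-dependent choice that makes the
    prior expectation of IC zero.  Defaults are the conventional
    g11 = a1 = b1 = 1, a0 = b0 = 2.
    """

    gamma11: float = 1.0
    alpha1: float = 1.0
    alpha0: float = 2.0
    beta1: float = 1.0
    beta0: float = 2.0
    z: float = 1.96
    interval: str = "cornish-fisher"  # or "normal"

    def __post_init__(self):
        if min(self.gamma11, self.alpha1, self.alpha0, self.beta1, self.beta0) <= 0:
            raise ValueError("prior pseudo-counts must be positive")
        if self.interval not in ("cornish-fisher", "normal"):
            raise ValueError(f"unknown interval method {self.interval!r}")

    def posterior_betas(self, table: ContingencyTable):
        """(x, y) Beta parameters for (p11, p1., p.1) given the table."""
        a, b, c = table.a, table.b, table.c
        n = table.n
        gamma = (self.gamma11 * (n + self.alpha0) * (n + self.beta0)
                 / ((a + b + self.alpha1) * (a + c + self.beta1)))
        return (
            (a + self.gamma11, n - a + gamma - self.gamma11),
            (a + b + self.alpha1, n - a - b + self.alpha0 - self.alpha1),
            (a + c + self.beta1, n - a - c + self.beta0 - self.beta1),
        )


def _log_beta_cumulants(x: float, y: float, order: int = 4):
    """Cumulants k1..k_order of log(p) for p ~ Beta(x, y)."""
    return [float(special.polygamma(m, x) - special.polygamma(m, x + y))
            for m in range(order)]


def bcpnn_ic(table: ContingencyTable,
             config: BCPNNConfig | None = None) -> IntervalEstimate:
    """Information component IC = E[log2 p11/(p1. p.1) | data] with interval.

    The posterior mean and variance are exact moments of the independent
    Beta posterior model of :class:`BCPNNConfig` (digamma / trigamma).  The
    credible bounds use a Cornish-Fisher quantile built from the exact first
    four posterior cumulants, because the posterior of IC is noticeably
    skewed at small counts; ``interval="normal"`` gives the plain
    IC +/- z*sd bounds instead.
    """
    config = config or BCPNNConfig()
    (x11, y11), (x1, y1), (x2, y2) = config.posterior_betas(table)
    k11 = _log_beta_cumulants(x11, y11)
    k1 = _log_beta_cumulants(x1, y1)
    k2 = _log_beta_cumulants(x2, y2)
    # IC = (L11 - L1 - L2)/ln2; odd cumulants change sign under negation
    c1 = (k11[0] - k1[0] - k2[0]) / LN2
    c2 = (k11[1] + k1[1] + k2[1]) / LN2**2
    c3 = (k11[2] - k1[2] - k2[2]) / LN2**3
    c4 = (k11[3] + k1[3] + k2[3]) / LN2**4
    sd = math.sqrt(c2)
    if config.interval == "normal":
        return IntervalEstimate(c1, c1 - config.z * sd, c1 + config.z * sd)
    g1 = c3 / c2**1.5
    g2 = c4 / c2**2

    def cf_quantile(zq: float) -> float:
        w = (zq + (zq * zq - 1) * g1 / 6
             + (zq**3 - 3 * zq) * g2 / 24
             - (2 * zq**3 - 5 * zq) * g1 * g1 / 36)
        return c1 + sd * w

    return IntervalEstimate(c1, cf_quantile(-config.z), cf_quantile(config.z))


@dataclass(frozen=True)
class SignalThresholds:
    """Positivity criteria (conventional pharmacovigilance defaults).

    ROR:   a >= ror_min_a and interval lower bound > ror_lower.
    PRR:   PRR >= prr_min, chi2 >= chi2_min, a >= prr_min_a.
    BCPNN: IC interval lower bound > ic_lower.
    MGPS:  EB05 > eb05_min.
    """

    ror_min_a: int = 3
    ror_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    prr_min_a: int = 3
    ic_lower: float = 0.0
    eb05_min: float = 2.0


@dataclass
class SignalResult:
    """All four statistics and positivity flags for one drug."""

    drug: str
    category: str
    table: ContingencyTable
    ror: IntervalEstimate
    prr: PRRResult
    ic: IntervalEstimate
    ebgm: "object" = None  # pvsignal.mgps.EBGMResult
    flags: dict = field(default_factory=dict)
    consensus: bool = False

    @property
    def expected(self) -> float:
        return self.table.expected


def signal_criteria(result: SignalResult,
                    thresholds: SignalThresholds | None = None) -> SignalResult:
    """Fill per-algorithm positivity flags and the consensus (AND) flag."""
    t = thresholds or SignalThresholds()
    a = result.table.a
    flags = {
        "ror": bool(result.ror.defined and a >= t.ror_min_a
                    and result.ror.low > t.ror_lower),
        "prr": bool(result.prr.prr.defined and result.prr.prr.point >= t.prr_min
                    and result.prr.chi2 >= t.chi2_min and a >= t.prr_min_a),
        "bcpnn": bool(result.ic.low > t.ic_lower),
        "mgps": bool(result.ebgm is not None and result.ebgm.defined
                     and result.ebgm.eb05 > t.eb05_min),
    }
    result.flags = flags
    result.consensus = all(flags.values())
    return result


def run_signal_scan(db, thresholds: SignalThresholds | None = None,
                    bcpnn_config: BCPNNConfig | None = None,
                    min_count: int = 3,
                    mgps_prior=None) -> list[SignalResult]:
    """Score every retained drug in a cleaned database.

    The MGPS prior is fitted once on the (a, E) pairs of *all* drugs in the
    database (shrinkage borrows strength across the whole scan) unless a
    pre-fitted prior is supplied.  Drugs with fewer than ``min_count`` event
    cases are excluded from the reported results but still contribute to the
    prior fit and to the 2x2 denominators.  Results are sorted consensus
    first, then by descending ROR.
    """
    from . import mgps  # local import: mgps depends on this module's types

    drugs = list(db.drugs)
    if not drugs:
        return []
    tables = {g: build_contingency(db, g) for g in drugs}
    if mgps_prior is None:
        a_arr = np.array([tables[g].a for g in drugs], dtype=float)
        e_arr = np.array([tables[g].expected for g in drugs], dtype=float)
        mgps_prior = mgps.fit_mgps_prior(a_arr, e_arr).prior

    results = []
    for g in drugs:
        tab = tables[g]
        if tab.a < min_count:
            continue
        res = SignalResult(
            drug=g,
            category=db.drug_category(g),
            table=tab,
            ror=ror(tab),
            prr=prr(tab),
            ic=bcpnn_ic(tab, bcpnn_config),
            ebgm=mgps.ebgm(tab.a, tab.expected, mgps_prior),
        )
        results.append(signal_criteria(res, thresholds))
    results.sort(key=lambda r: (not r.consensus,
                                -(r.ror.point if math.isfinite(r.ror.point) else 0.0)))
    return results


def results_to_frame(results: list[SignalResult]):
    """Tabulate scan results (one row per drug, signal-report columns)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "drug": r.drug,
            "category": r.category,
            "a": r.table.a,
            "expected": r.expected,
            "ror": r.ror.point, "ror_low": r.ror.low, "ror_high": r.ror.high,
            "prr": r.prr.prr.point, "prr_low": r.prr.prr.low,
            "prr_high": r.prr.prr.high, "chi2": r.prr.chi2, "p": r.prr.p,
            "ic": r.ic.point, "ic_low": r.ic.low, "ic_high": r.ic.high,
            "ebgm": r.ebgm.ebgm if r.ebgm else math.nan,
            "eb05": r.ebgm.eb05 if r.ebgm else math.nan,
            "eb95": r.ebgm.eb95 if r.ebgm else math.nan,
            "ror_flag": r.flags.get("ror"), "prr_flag": r.flags.get("prr"),
            "bcpnn_flag": r.flags.get("bcpnn"), "mgps_flag": r.flags.get("mgps"),
            "consensus": r.consensus,
        })
    return pd.DataFrame(rows)
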