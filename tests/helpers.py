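"""Independent oracles and small fixtures shared across the test suite.

Everything here is deliberately written from first principles (textbook
formulas, brute-force enumeration, Monte-Carlo sampling, adaptive
quadrature) and stays independent of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from pvsignal.ingest import AttritionLog, CleanDatabase
from pvsignal.signals import ContingencyTable


# ---------------------------------------------------------------------------
# frequentist 2x2 oracles (plain arithmetic, recoded from the definitions)

def ror_oracle(a, b, c, d, z=1.96):
    """Odds ratio with Wald log interval; 0.5 added to all cells on any zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = a * d / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * np.exp(-z * se), est * np.exp(z * se)


def prr_oracle(a, b, c, d, z=1.96):
    if a == 0 or c == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return est, est * np.exp(-z * se), est * np.exp(z * se)


def chi2_bruteforce(a, b, c, d):
    """Pearson chi-square as the sum over cells of (O - E)^2 / E."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    return float(terms.sum())


def random_tables(rng, n, max_cell=500, min_a=0):
    """Random 2x2 tables; cell a at least ``min_a``."""
    out = []
    while len(out) < n:
        a = int(rng.integers(min_a, max_cell))
        b, c, d = (int(rng.integers(0, max_cell)) for _ in range(3))
        if a + b + c + d > 0:
            out.append(ContingencyTable(a, b, c, d))
    return out


# ---------------------------------------------------------------------------
# BCPNN Monte-Carlo posterior oracle

def mc_ic_oracle(table, config, n_draws, rng):
    """Sample the documented independent-Beta conjugate posteriors of the
    joint and margin probabilities and return (mean, 2.5th, 97.5th pct) of
    IC = log2(p11 / (p1. * p.1))."""
    (x11, y11), (x1, y1), (x2, y2) = config.posterior_betas(table)
    p11 = rng.beta(x11, y11, n_draws)
    p1 = rng.beta(x1, y1, n_draws)
    p2 = rng.beta(x2, y2, n_draws)
    ic = np.log2(p11 / (p1 * p2))
    return float(ic.mean()), float(np.percentile(ic, 2.5)), \
        float(np.percentile(ic, 97.5))


# ---------------------------------------------------------------------------
# MGPS adaptive-quadrature oracle

def quad_ebgm_oracle(a, e, prior, probs=(0.05, 0.95)):
    """EBGM and posterior percentiles by numerical integration of the
    posterior gamma-mixture density (no closed forms)."""
    from pvsignal.mgps import posterior_mixture

    g1, g2, q = posterior_mixture(a, e, prior)

    def dens(lam):
        return (q * stats.gamma.pdf(lam, g1[0], scale=1 / g1[1])
                + (1 - q) * stats.gamma.pdf(lam, g2[0], scale=1 / g2[1]))

    ub = max(stats.gamma.ppf(1 - 1e-13, g1[0], scale=1 / g1[1]),
             stats.gamma.ppf(1 - 1e-13, g2[0], scale=1 / g2[1]))
    mean_log = integrate.quad(lambda l: np.log(l) * dens(l), 0, ub,
                              limit=300)[0]

    def cdf(x):
        return integrate.quad(dens, 0, x, limit=300)[0]

    qs = [optimize.brentq(lambda x: cdf(x) - p, 1e-13, ub) for p in probs]
    return float(np.exp(mean_log)), qs[0], qs[1]


# ---------------------------------------------------------------------------
# AUC brute force

def auc_bruteforce(scores, labels):
    """O(n1*n0) pairwise comparison with half-credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


# ---------------------------------------------------------------------------
# hand-built cleaned database

def tiny_db(exposed: dict[str, set], events: set, case_ids=None,
            categories: dict[str, str] | None = None) -> CleanDatabase:
    """Minimal CleanDatabase: explicit exposure sets and event-case set."""
    if case_ids is None:
        case_ids = sorted(set().union(events, *exposed.values()) or {1})
    cases = pd.DataFrame(index=pd.Index(case_ids, name="caseid"))
    rows = [{"caseid": cid, "generic": g,
             "category": (categories or {}).get(g, "other"),
             "route": None, "start_dt": None, "indication": None}
            for g, ids in exposed.items() for cid in ids]
    expo = pd.DataFrame(rows, columns=["caseid", "generic", "category",
                                       "route", "start_dt", "indication"])
    counts = pd.Series({g: len(ids & events) for g, ids in exposed.items()})
    return CleanDatabase(
        cases=cases, exposures=expo, event_case_ids=frozenset(events),
        pt_list=("vitreous floaters",), attrition=AttritionLog(),
        drug_event_counts=counts,
        retained_drugs=tuple(sorted(exposed)),
        category_map=categories or {},
    )
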