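"""Multi-item gamma-Poisson shrinkage (empirical-Bayes EBGM/EB05/EB95).

The observed count a of a drug-event pair is modelled as
Poisson(lambda * E), with E the expected count under independence and the
relative reporting rate lambda drawn from a two-component gamma mixture
prior

    lambda ~ w * Gamma(alpha1, beta1) + (1 - w) * Gamma(alpha2, beta2)

(shape/rate).  Marginally a follows a mixture of negative binomials; the
five hyperparameters are fitted by maximum likelihood over all pairs in the
database.  The posterior for one pair is again a two-component gamma
mixture, from which:

* EBGM  = 2 ** E[log2 lambda | a]  (geometric mean, via digamma),
* EB05 / EB95 = 5th / 95th posterior percentiles (root-finding on the
  mixture CDF) — the conventional 90% shrinkage interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .errors import ConvergenceError

__all__ = ["MGPSPrior", "MGPSFit", "EBGMResult", "fit_mgps_prior",
           "posterior_mixture", "ebgm", "simulate_pairs"]


@dataclass(frozen=True)
class MGPSPrior:
    """Hyperparameters of the two-component gamma mixture (shape/rate)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0 < self.w < 1:
            raise ValueError("mixture weight must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2, self.w])


DEFAULT_START = MGPSPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    """Log-likelihood of the negative-binomial mixture at unconstrained theta.

    theta = (log a1, log b1, log a2, log b2, logit w).
    """
    a1, b1, a2, b2 = np.exp(theta[:4])
    w = special.expit(theta[4])
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    m = np.maximum(lp1, lp2)
    ll = m + np.log(w * np.exp(lp1 - m) + (1 - w) * np.exp(lp2 - m))
    return float(np.sum(ll))


@dataclass
class MGPSFit:
    prior: MGPSPrior
    loglik: float
    converged: bool
    n_pairs: int
    diagnostics: dict


def fit_mgps_prior(a, e, starts: list[MGPSPrior] | None = None,
                   maxiter: int = 2000) -> MGPSFit:
    """Fit the five mixture hyperparameters by maximum marginal likelihood.

    Runs Nelder-Mead from the conventional start (0.2, 0.1, 2, 4, 1/3) and
    from a handful of fixed perturbations of it, keeping the best optimum.
    Raises :class:`ConvergenceError` (carrying the best point found) if no
    start converges.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    keep = e > 0
    a, e = a[keep], e[keep]
    if a.size < 2:
        raise ValueError("need at least 2 pairs with positive expected counts")

    if starts is None:
        s0 = DEFAULT_START
        starts = [
            s0,
            MGPSPrior(1.0, 1.0, 1.0, 1.0, 0.5),
            MGPSPrior(0.5, 0.5, 4.0, 2.0, 0.2),
            MGPSPrior(2.0, 2.0, 0.3, 0.3, 0.7),
        ]

    best = None
    any_converged = False
    for s in starts:
        theta0 = np.concatenate([np.log(s.as_array()[:4]),
                                 [special.logit(s.w)]])
        res = optimize.minimize(
            lambda th: -_mixture_loglik(th, a, e), theta0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    th = best.x
    prior = MGPSPrior(*np.exp(th[:4]), float(special.expit(th[4])))
    fit = MGPSFit(prior=prior, loglik=-float(best.fun),
                  converged=any_converged, n_pairs=int(a.size),
                  diagnostics={"n_iter": int(best.nit),
                               "message": str(best.message)})
    if not any_converged:
        raise ConvergenceError("MGPS hyperparameter fit did not converge",
                               best=fit, diagnostics=fit.diagnostics)
    return fit


def posterior_mixture(a: float, e: float, prior: MGPSPrior):
    """Posterior gamma-mixture parameters (shapes, rates, weight of comp 1)."""
    lp1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    lp2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    m = max(lp1, lp2)
    q = prior.w * math.exp(lp1 - m)
    q = q / (q + (1 - prior.w) * math.exp(lp2 - m))
    return ((prior.alpha1 + a, prior.beta1 + e),
            (prior.alpha2 + a, prior.beta2 + e), q)


@dataclass(frozen=True)
class EBGMResult:
    ebgm: float
    eb05: float
    eb95: float
    defined: bool = True


def _mixture_cdf(lam, g1, g2, q):
    return (q * stats.gamma.cdf(lam, g1[0], scale=1.0 / g1[1])
            + (1 - q) * stats.gamma.cdf(lam, g2[0], scale=1.0 / g2[1]))


def _mixture_ppf(p, g1, g2, q):
    # the mixture quantile lies between the component quantiles
    p1 = stats.gamma.ppf(p, g1[0], scale=1.0 / g1[1])
    p2 = stats.gamma.ppf(p, g2[0], scale=1.0 / g2[1])
    lo, hi = min(p1, p2), max(p1, p2)
    if hi - lo < 1e-14 * max(hi, 1.0):
        return lo
    f = lambda x: _mixture_cdf(x, g1, g2, q) - p
    flo, fhi = f(lo), f(hi)
    # guard against roundoff at the bracket ends
    for _ in range(60):
        if flo <= 0:
            break
        lo *= 0.5
        flo = f(lo)
    for _ in range(60):
        if fhi >= 0:
            break
        hi *= 2.0
        fhi = f(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    return optimize.brentq(f, lo, hi, xtol=1e-13, rtol=1e-13)


def ebgm(a: float, e: float, prior: MGPSPrior,
         interval: tuple[float, float] = (0.05, 0.95)) -> EBGMResult:
    """Shrinkage point estimate and posterior percentile interval.

    EBGM = exp(E[ln lambda | a]); the component expectations of ln lambda
    are psi(shape) - ln(rate).  ``interval`` gives the lower/upper posterior
    probabilities (default the conventional EB05/EB95 90% band; pass
    (0.025, 0.975) for a 95% band).  E = 0 yields an undefined result.
    """
    if e <= 0:
        return EBGMResult(math.nan, math.nan, math.nan, defined=False)
    g1, g2, q = posterior_mixture(a, e, prior)
    mean_log = (q * (special.digamma(g1[0]) - math.log(g1[1]))
                + (1 - q) * (special.digamma(g2[0]) - math.log(g2[1])))
    return EBGMResult(
        ebgm=math.exp(mean_log),
        eb05=_mixture_ppf(interval[0], g1, g2, q),
        eb95=_mixture_ppf(interval[1], g1, g2, q),
    )


def simulate_pairs(n_pairs: int, prior: MGPSPrior, rng,
                   e_log_mean: float = 1.0, e_log_sd: float = 1.0):
    """Draw (a, E, lambda) triples from the gamma-Poisson mixture model.

    E is lognormal (a realistic spread of baseline reporting volumes);
    lambda from the mixture prior; a ~ Poisson(lambda * E).  Used for
    hyperparameter-recovery checks.
    """
    e = rng.lognormal(e_log_mean, e_log_sd, size=n_pairs)
    comp = rng.random(n_pairs) < prior.w
    lam = np.where(comp,
                   rng.gamma(prior.alpha1, 1.0 / prior.beta1, size=n_pairs),
                   rng.gamma(prior.alpha2, 1.0 / prior.beta2, size=n_pairs))
    a = rng.poisson(lam * e)
    return a.astype(float), e, lam
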