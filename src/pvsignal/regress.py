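"""Case/non-case logistic regression with Wald odds-ratio intervals.

Event status (case = report of the target event, non-case = any other
report) is regressed on drug indicators and confounders: age and weight in
quartile bins, sex, country, reporter qualification, administration route,
indication, and duration of drug use.  Fitting is by iteratively
reweighted least squares with step-halving (so the deviance never
increases), covariance from the inverse observed information, and explicit
detection of separation and rank deficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RankDeficiencyError

__all__ = ["Covariate", "DesignSpec", "standard_design", "encode_design",
           "LogisticFit", "fit_logistic", "or_table",
           "AGE_EDGES", "WEIGHT_EDGES"]

#: preset quartile edges (years / kg) used for the age and weight bins
AGE_EDGES = (48.0, 61.0, 71.0)
WEIGHT_EDGES = (57.14, 69.00, 82.10)


@dataclass(frozen=True)
class Covariate:
    """One model term.

    kind: 'binary' (0/1 as-is), 'categorical' (reference-level dummies),
    'quartile' (numeric binned at ``edges``, computed from the analysis
    sample when None), or 'numeric' (untransformed).
    """

    name: str
    kind: str = "categorical"
    reference: str | None = None
    edges: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("binary", "categorical", "quartile", "numeric"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.edges is not None and list(self.edges) != sorted(set(self.edges)):
            raise ValueError(f"edges for {self.name!r} must be strictly increasing")


@dataclass
class DesignSpec:
    covariates: list[Covariate] = field(default_factory=list)
    response: str = "event"


def standard_design(drug_columns: list[str]) -> DesignSpec:
    """The default confounder set: binned age/weight, sex, country, reporter,
    route, indication, continuous time, plus one indicator per drug."""
    cov = [
        Covariate("age", "quartile", edges=AGE_EDGES),
        Covariate("reporter_country", "categorical", reference="non-US"),
        Covariate("sex", "categorical", reference="F"),
        Covariate("indication", "categorical", reference="Erectile dysfunction"),
        Covariate("occp_cod", "categorical", reference="HP"),
        Covariate("route", "categorical", reference="Intramuscular"),
        Covariate("wt", "quartile", edges=WEIGHT_EDGES),
        Covariate("time_days", "numeric"),
    ]
    cov += [Covariate(c, "binary") for c in drug_columns]
    return DesignSpec(covariates=cov)


def _bin_labels(edges: tuple[float, ...]) -> list[str]:
    lab = [f"<{edges[0]:g}"]
    lab += [f"{lo:g}-{hi:g}" for lo, hi in zip(edges, edges[1:])]
    lab.append(f">{edges[-1]:g}")
    return lab


def encode_design(df: pd.DataFrame, spec: DesignSpec):
    """Build the design matrix (with intercept) and response vector.

    Reference-level dummy coding for categoricals; quartile covariates are
    binned at the supplied edges or at sample quartiles; rows missing any
    covariate are dropped (listwise deletion) and the per-covariate missing
    counts are returned in ``X.attrs['missingness']``.
    """
    y_all = df[spec.response]
    cols: dict[str, pd.Series] = {}
    missing = pd.Series(0, index=[c.name for c in spec.covariates], dtype=int)
    keep = y_all.notna()
    for cov in spec.covariates:
        s = df[cov.name]
        if cov.name == "reporter_country" and cov.reference == "non-US":
            s = s.map(lambda v: "US" if v == "US" else ("non-US" if pd.notna(v) else None))
        missing[cov.name] = int(s.isna().sum())
        keep &= s.notna()
        if cov.kind == "binary":
            cols[cov.name] = s.astype(float)
        elif cov.kind == "numeric":
            cols[cov.name] = s.astype(float)
        elif cov.kind == "quartile":
            edges = cov.edges
            if edges is None:
                edges = tuple(np.nanquantile(s.astype(float), [0.25, 0.5, 0.75]))
            labels = _bin_labels(edges)
            binned = pd.cut(s.astype(float),
                            [-np.inf, *edges, np.inf], labels=labels)
            for lab in labels[1:]:  # lowest bin is the reference
                cols[f"{cov.name}:{lab}"] = (binned == lab).astype(float)
        else:  # categorical
            levels = sorted(x for x in s.dropna().unique())
            ref = cov.reference if cov.reference in levels else (
                levels[0] if levels else None)
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{cov.name}:{lev}"] = (s == lev).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "intercept", 1.0)
    X = X[keep]
    y = y_all[keep].astype(float)
    if len(X) == 0:
        raise ValueError(
            "no rows left after listwise deletion; per-covariate missing "
            f"counts: {missing.to_dict()}")
    X.attrs["missingness"] = missing.to_dict()
    X.attrs["n_dropped"] = int((~keep).sum())
    return X, y


@dataclass
class LogisticFit:
    params: pd.Series
    cov: pd.DataFrame
    deviance: float
    deviance_path: list[float]
    n_iter: int
    converged: bool
    separation: bool
    n_obs: int
    n_dropped: int = 0

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())),
                         index=self.params.index)


def _deviance(y, p, w):
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y * np.log(p) + (1 - y) * np.log1p(-p)
    return -2.0 * float(np.sum(w * np.nan_to_num(ll, neginf=-745.0)))


def fit_logistic(X, y, ridge: float = 0.0, max_iter: int = 100,
                 score_tol: float = 1e-8, dev_tol: float = 1e-10,
                 sample_weight=None) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    Convergence when the max absolute score falls below ``score_tol`` or
    the relative deviance change below ``dev_tol``.  ``ridge`` adds an
    optional L2 stabilizer (always reflected in the returned covariance,
    which is the inverse of the penalized observed information).  Perfect
    separation is flagged (diverging coefficients / fitted probabilities at
    the boundary), not silently returned; rank deficiency raises
    :class:`RankDeficiencyError` naming the collinear columns.
    """
    names = list(X.columns) if hasattr(X, "columns") else \
        [f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n, k = Xm.shape
    fw = np.ones(n) if sample_weight is None else \
        np.asarray(sample_weight, dtype=float)
    if fw.shape != (n,) or (fw < 0).any():
        raise ValueError("sample_weight must be nonnegative, one per row")
    if fw.sum() <= k:
        raise ValueError(
            f"need more (weighted) observations ({fw.sum():g}) than columns ({k})")
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")

    # rank check via pivoted QR: name the columns beyond the numerical rank
    _, r = np.linalg.qr(Xm)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, k) * np.finfo(float).eps
    if ridge == 0.0 and (diag < tol).any():
        from scipy.linalg import qr as scipy_qr
        _, rr, piv = scipy_qr(Xm, mode="economic", pivoting=True)
        dd = np.abs(np.diag(rr))
        rank = int((dd > dd.max() * max(n, k) * np.finfo(float).eps).sum())
        raise RankDeficiencyError([names[i] for i in piv[rank:]])

    beta = np.zeros(k)
    ybar = float((fw * yv).sum() / fw.sum())
    p0 = ybar if 0 < ybar < 1 else 0.5
    beta[0] = math.log(p0 / (1 - p0)) if names[0] == "intercept" else 0.0
    eta = Xm @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    dev = _deviance(yv, p, fw) + ridge * beta @ beta
    path = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = fw * p * (1 - p)
        score = Xm.T @ (fw * (yv - p)) - ridge * beta
        info = (Xm * w[:, None]).T @ Xm + ridge * np.eye(k)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving guarantees the (penalized) deviance never increases
        lam = 1.0
        for _ in range(40):
            cand = beta + lam * step
            eta = Xm @ cand
            pc = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
            cand_dev = _deviance(yv, np.clip(pc, 1e-300, 1 - 1e-16), fw) \
                + ridge * cand @ cand
            if cand_dev <= dev + 1e-12:
                break
            lam *= 0.5
        beta, p = cand, np.clip(pc, 1e-12, 1 - 1e-12)
        rel = abs(dev - cand_dev) / (abs(dev) + 1e-300)
        dev = cand_dev
        path.append(dev)
        if np.max(np.abs(score)) < score_tol or rel < dev_tol:
            converged = True
            break

    separation = bool(np.max(np.abs(beta)) > 15.0
                      or np.min(p) < 1e-10 or np.max(p) > 1 - 1e-10)
    w = fw * p * (1 - p)
    info = (Xm * w[:, None]).T @ Xm + ridge * np.eye(k)
    cov = np.linalg.pinv(info)
    cov = (cov + cov.T) / 2.0
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        deviance=float(dev), deviance_path=path, n_iter=it,
        converged=converged, separation=separation, n_obs=n,
        n_dropped=int(getattr(X, "attrs", {}).get("n_dropped", 0)),
    )


def or_table(fit: LogisticFit, z: float = 1.96) -> pd.DataFrame:
    """Per-term odds ratios with Wald intervals and p-values.

    A zero standard error (degenerate fit) gives a point-mass interval and
    is flagged in the ``degenerate`` column.
    """
    se = fit.se
    coef = fit.params
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.abs(coef.to_numpy()) / np.where(se.to_numpy() > 0,
                                                   se.to_numpy(), np.nan)
        p = np.where(se.to_numpy() > 0, 2 * stats.norm.sf(zstat),
                     np.where(coef.to_numpy() == 0, 1.0, 0.0))
    out = pd.DataFrame({
        "term": coef.index,
        "coef": coef.to_numpy(),
        "or": np.exp(coef.to_numpy()),
        "or_low": np.exp(coef.to_numpy() - z * se.to_numpy()),
        "or_high": np.exp(coef.to_numpy() + z * se.to_numpy()),
        "p": p,
        "degenerate": se.to_numpy() == 0,
    }).set_index("term")
    return out.drop(index="intercept", errors="ignore")
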