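"""Cox proportional-hazards estimation with Wald inference and VIF diagnostics.

The partial likelihood is maximized by Newton-Raphson from beta = 0 with
step-halving, using the Efron approximation for tied event times (Breslow
selectable). Standard errors come from the observed information at the
maximum; per-term and global Wald tests use the chi-square reference.

When no two events share a time the contributions reduce to simple reverse
cumulative sums over the risk sets, which is the fast vectorized path taken
automatically; tied event times fall back to an explicit per-event-time loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("agingpanel")

EFRON = "efron"
BRESLOW = "breslow"

#: |beta| beyond this is treated as separation / divergence
SEPARATION_BOUND = 50.0


class DesignError(ValueError):
    """Raised for invalid design matrices or term selections."""


@dataclass
class Design:
    """Aligned (samples x terms) design for one Cox fit.

    ``gene_terms`` marks which columns are panel/candidate genes (the default
    subset for the global Wald test) as opposed to adjustment covariates.
    """

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    term_names: list[str]
    gene_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.ndim != 2:
            raise DesignError("design matrix must be 2-D")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n, p = self.X.shape
        if len(self.term_names) != p:
            raise DesignError("term_names length does not match design columns")
        if len(self.time) != n or len(self.event) != n:
            raise DesignError("time/event length does not match design rows")
        if self.event.sum() < 1:
            raise DesignError("design has no events")
        if not set(self.gene_terms) <= set(self.term_names):
            raise DesignError("gene_terms must be a subset of term_names")
        sd = self.X.std(axis=0)
        if (sd == 0).any():
            bad = self.term_names[int(np.flatnonzero(sd == 0)[0])]
            raise DesignError(f"constant design column: {bad!r}")
        # exact duplicates make the information singular at every beta
        for j in range(p):
            for k in range(j + 1, p):
                if np.array_equal(self.X[:, j], self.X[:, k]):
                    raise DesignError(
                        f"duplicated design columns: {self.term_names[j]!r} "
                        f"and {self.term_names[k]!r}")


@dataclass
class CoxFit:
    """Fitted model: coefficients, Wald inference, and fit diagnostics."""

    term_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray          # (p, 2) on the hazard-ratio scale
    wald_z: np.ndarray
    wald_p: np.ndarray
    global_terms: list[str]
    global_wald_stat: float
    global_df: int
    global_wald_p: float
    log_partial_likelihood: float
    log_likelihood_null: float
    iterations: int
    converged: bool
    n: int
    n_events: int
    ties: str
    flags: list[str] = field(default_factory=list)

    def term(self, name: str) -> dict:
        i = self.term_names.index(name)
        return {
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "hr": float(self.hr[i]),
            "ci95": (float(self.ci95[i, 0]), float(self.ci95[i, 1])),
            "wald_z": float(self.wald_z[i]),
            "wald_p": float(self.wald_p[i]),
        }

    def to_dict(self) -> dict:
        return {
            "term_names": self.term_names,
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "hr": [float(h) for h in self.hr],
            "ci95": [[float(a), float(b)] for a, b in self.ci95],
            "wald_z": [float(z) for z in self.wald_z],
            "wald_p": [float(p) for p in self.wald_p],
            "global_terms": self.global_terms,
            "global_wald_stat": float(self.global_wald_stat),
            "global_df": self.global_df,
            "global_wald_p": float(self.global_wald_p),
            "log_partial_likelihood": float(self.log_partial_likelihood),
            "log_likelihood_null": float(self.log_likelihood_null),
            "iterations": self.iterations,
            "converged": self.converged,
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.ties,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# Partial likelihood, score and information
# ---------------------------------------------------------------------------


def _prepare(design: Design):
    """Sort descending by time; censored sort before events within a time so
    that a prefix cumsum at an event's position covers its whole risk set."""
    order = np.lexsort((design.event, -design.time))
    t = design.time[order]
    d = design.event[order]
    X = design.X[order]
    ev_t = t[d == 1]
    has_tied_events = len(ev_t) != len(np.unique(ev_t))
    return t, d, X, has_tied_events


def _loglik_fast(beta: np.ndarray, t, d, X):
    """No-tied-events path: reverse-cumsum risk-set sums. Efron == Breslow."""
    eta = X @ beta
    eta_max = eta.max()
    w = np.exp(eta - eta_max)              # stabilized
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * X, axis=0)
    ev = np.flatnonzero(d == 1)
    xbar = S1[ev] / S0[ev, None]
    ll = float(eta[ev].sum() - len(ev) * eta_max - np.log(S0[ev]).sum())
    grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
    S2 = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
    info = (S2[ev] / S0[ev, None, None]).sum(axis=0) - xbar.T @ xbar
    return ll, grad, info


def _loglik_ties(beta: np.ndarray, t, d, X, ties: str):
    """General path looping unique event times (Efron or Breslow)."""
    p = X.shape[1]
    eta = X @ beta
    w = np.exp(eta - eta.max())
    logw_shift = eta.max()
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    # iterate unique event times; risk set = all with time >= te
    ev_times = np.unique(t[d == 1])[::-1]
    for te in ev_times:
        risk = t >= te
        tied = (t == te) & (d == 1)
        m = int(tied.sum())
        wR = w[risk]
        XR = X[risk]
        S0 = wR.sum()
        S1 = wR @ XR
        S2 = (wR[:, None] * XR).T @ XR
        wD = w[tied]
        XD = X[tied]
        D0 = wD.sum()
        D1 = wD @ XD
        D2 = (wD[:, None] * XD).T @ XD
        ll += eta[tied].sum() - m * logw_shift
        grad += XD.sum(axis=0)
        for ell in range(m):
            frac = ell / m if ties == EFRON else 0.0
            a0 = S0 - frac * D0
            a1 = S1 - frac * D1
            a2 = S2 - frac * D2
            ll -= np.log(a0)
            grad -= a1 / a0
            info += a2 / a0 - np.outer(a1, a1) / a0**2
    return float(ll), grad, info


def _loglik(beta, t, d, X, ties, fast_ok):
    if fast_ok:
        return _loglik_fast(beta, t, d, X)
    return _loglik_ties(beta, t, d, X, ties)


def log_partial_likelihood(design: Design, beta: np.ndarray,
                           ties: str = EFRON) -> float:
    """Evaluate the (Efron/Breslow) log partial likelihood at ``beta``."""
    t, d, X, tied = _prepare(design)
    ll, _, _ = _loglik(np.asarray(beta, float), t, d, X, ties, not tied)
    return ll


def score_test_at_zero(design: Design, ties: str = EFRON) -> tuple[float, float]:
    """Score (Rao) test of beta = 0: U(0)' I(0)^-1 U(0) ~ chi-square(p).

    For one binary covariate without tied event times this equals the
    log-rank statistic.
    """
    t, d, X, tied = _prepare(design)
    beta0 = np.zeros(X.shape[1])
    _, grad, info = _loglik(beta0, t, d, X, ties, not tied)
    try:
        stat = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        # no covariate variation left in any risk set at an event time
        return float("nan"), float("nan")
    p = float(stats.chi2.sf(stat, X.shape[1]))
    return stat, p


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_cox(
    design: Design,
    ties: str = EFRON,
    global_terms: Sequence[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Newton-Raphson maximum partial-likelihood fit with Wald inference.

    Non-convergence and separation (a coefficient escaping past +-50) yield a
    flagged fit with ``converged=False`` rather than an exception; a constant
    or duplicated design column is a hard error (raised by ``Design``).
    """
    if ties not in (EFRON, BRESLOW):
        raise ValueError(f"unknown tie method {ties!r}")
    t, d, X, tied = _prepare(design)
    fast_ok = not tied
    p = X.shape[1]
    beta = np.zeros(p)
    ll0, grad, info = _loglik(beta, t, d, X, ties, fast_ok)
    ll = ll0
    converged = False
    flags: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flags.append("singular-information")
            break
        # step-halving keeps the likelihood monotone
        new_beta = beta + step
        new_ll, new_grad, new_info = _loglik(new_beta, t, d, X, ties, fast_ok)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _loglik(new_beta, t, d, X, ties, fast_ok)
            halvings += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.abs(beta).max() > SEPARATION_BOUND:
            flags.append("separation")
            break
        if np.abs(step).max() < tol:
            converged = True
            break
    if not converged and not flags:
        flags.append("max-iterations")
    if not converged:
        logger.warning("fit_cox: non-converged fit (%s) after %d iterations",
                       ",".join(flags), it)

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        flags.append("singular-information")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    # a flat likelihood plateau (quasi-separation) can satisfy the step
    # criterion with an absurd SE; such fits are not identifiable
    if converged and (not np.all(np.isfinite(se)) or se.max() > 100.0):
        converged = False
        flags.append("quasi-separation")
        logger.warning("fit_cox: quasi-separated fit (max SE %.3g)", se.max())
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        hr = np.exp(beta)
        ci95 = np.column_stack([np.exp(beta - 1.96 * se),
                                np.exp(beta + 1.96 * se)])
        wald_z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(wald_z))

    if global_terms is None:
        global_terms = design.gene_terms or list(design.term_names)
    global_terms = list(global_terms)
    fit = CoxFit(
        term_names=list(design.term_names),
        beta=beta, se=se, cov=cov, hr=hr, ci95=ci95,
        wald_z=wald_z, wald_p=wald_p,
        global_terms=global_terms,
        global_wald_stat=np.nan, global_df=len(global_terms), global_wald_p=np.nan,
        log_partial_likelihood=ll, log_likelihood_null=ll0,
        iterations=it, converged=converged,
        n=len(t), n_events=int(d.sum()), ties=ties, flags=flags,
    )
    if converged and global_terms:
        stat, df, gp = wald_global(fit, global_terms)
        fit.global_wald_stat, fit.global_df, fit.global_wald_p = stat, df, gp
    return fit


def wald_global(fit: CoxFit, terms: Sequence[str]) -> tuple[float, int, float]:
    """Joint Wald test of the selected coefficients being zero.

    Quadratic form beta_S' [cov_SS]^-1 beta_S against chi-square(|S|).
    """
    terms = list(terms)
    if not terms:
        raise DesignError("wald_global: empty term set")
    unknown = [tm for tm in terms if tm not in fit.term_names]
    if unknown:
        raise DesignError(f"wald_global: term(s) not in fit: {unknown}")
    idx = [fit.term_names.index(tm) for tm in terms]
    b = fit.beta[idx]
    C = fit.cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(C, b))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Collinearity diagnostics
# ---------------------------------------------------------------------------


def vif(covariates: np.ndarray, names: Sequence[str] | None = None,
        threshold: float = 5.0) -> dict[str, dict]:
    """Variance inflation factors: VIF_j = 1/(1 - R^2_j) regressing column j
    on the others (with intercept). Exact collinearity reports +inf, flagged.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    n, p = X.shape
    if n < 3 or p < 2:
        raise DesignError("vif requires >=3 samples and >=2 columns")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    out: dict[str, dict] = {}
    ones = np.ones((n, 1))
    for j in range(p):
        y = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        tss = float(((y - y.mean()) ** 2).sum())
        rss = float((resid ** 2).sum())
        if tss == 0.0:
            raise DesignError(f"vif: constant column {names[j]!r}")
        r2 = 1.0 - rss / tss
        if r2 >= 1.0 - 1e-12:
            value = np.inf
        else:
            value = 1.0 / (1.0 - r2)
        out[names[j]] = {"vif": float(value),
                         "passes": bool(np.isfinite(value) and value < threshold)}
    return out
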