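"""Association and survival statistics, implemented in-package.

Firth-penalized logistic regression (Jeffreys prior) handles binary
endpoints with a very rare exposure, where ordinary maximum likelihood can
separate; the Cox proportional-hazards fit maximizes the Efron-ties partial
likelihood by Newton-Raphson; Kaplan-Meier is the plain product-limit
estimator with right censoring.  Wald intervals are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

GENOME_WIDE_P = 5e-8


class StatsInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# allele frequencies


def case_control_af(dosage: np.ndarray, endpoint: np.ndarray) -> tuple[float, float]:
    """Allele frequency of the exposure allele among cases and controls:
    allele count over twice the class size."""
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(endpoint).astype(bool)
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise StatsInputError("both endpoint classes must be nonempty")
    return float(g[y].sum() / (2 * n_case)), float(g[~y].sum() / (2 * n_ctrl))


# ---------------------------------------------------------------------------
# Firth logistic


@dataclass(frozen=True)
class AssocResult:
    endpoint: str
    beta: float
    or_: float
    ci95: tuple[float, float]
    p: float
    af_case: float
    af_control: float
    converged: bool
    method: str = "firth"
    genome_wide_significant: bool = False
    se: float = float("nan")


def _firth_iterate(X, y, penalty_weight=1.0, max_iter=50, tol=1e-8):
    n, k = X.shape
    beta = np.zeros(k)
    def pll(b):
        eta = X @ b
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = (X * w[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll + penalty_weight * 0.5 * logdet

    current = pll(beta)
    converged = False
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        # hat diagonal of the weighted design: w_i * x_i' I^{-1} x_i
        h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - p + penalty_weight * h * (0.5 - p))
        delta = info_inv @ score
        step = 1.0
        for _ in range(20):  # step-halving on the penalized log-likelihood
            cand = beta + step * delta
            val = pll(cand)
            if val >= current - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        current = val
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return beta, cov, converged


def firth_logistic(
    dosage: np.ndarray,
    endpoint: np.ndarray,
    covariates: np.ndarray | None = None,
    endpoint_name: str = "endpoint",
    penalty_weight: float = 1.0,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> AssocResult:
    """Penalized-likelihood logistic association of a genotype dosage with a
    binary endpoint; finite estimates even under complete separation.

    ``penalty_weight`` scales the Jeffreys-prior adjustment (1 is Firth's
    estimator; as it approaches 0 the estimate approaches the MLE where the
    MLE exists).  Non-convergence is flagged, never raised.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(endpoint, dtype=float)
    if not ((y == 0) | (y == 1)).all():
        raise StatsInputError("endpoint must be binary")
    if y.sum() == 0 or y.sum() == len(y):
        raise StatsInputError("need at least one case and one control")
    cols = [np.ones_like(g), g]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] == len(g) and C.ndim == 2:
            cols.extend(C.T)
        else:
            cols.extend(C)
    X = np.column_stack(cols)
    beta, cov, converged = _firth_iterate(
        X, y, penalty_weight=penalty_weight, max_iter=max_iter, tol=tol
    )
    b = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    z = b / se if se > 0 else 0.0
    pval = float(2 * sps.norm.sf(abs(z)))
    af_case, af_ctrl = case_control_af(g, y)
    return AssocResult(
        endpoint=endpoint_name,
        beta=b,
        or_=float(np.exp(b)),
        ci95=(float(np.exp(b - 1.959963984540054 * se)), float(np.exp(b + 1.959963984540054 * se))),
        p=pval,
        af_case=af_case,
        af_control=af_ctrl,
        converged=bool(converged),
        method="firth",
        genome_wide_significant=pval < GENOME_WIDE_P,
        se=se,
    )


def phewas(
    dosage: np.ndarray,
    phenotypes: pd.DataFrame,
    endpoints: Sequence[str],
    covariates: Sequence[str] = (),
) -> list[AssocResult]:
    """One Firth association per endpoint column; per-endpoint failures are
    flagged (``converged=False``, NaN estimates) and the scan continues."""
    C = phenotypes[list(covariates)].to_numpy(dtype=float) if covariates else None
    results = []
    for name in endpoints:
        y = phenotypes[name].to_numpy()
        try:
            results.append(
                firth_logistic(dosage, y, covariates=C, endpoint_name=name)
            )
        except (StatsInputError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"endpoint {name!r} failed: {exc}", stacklevel=2)
            results.append(
                AssocResult(
                    endpoint=name,
                    beta=float("nan"),
                    or_=float("nan"),
                    ci95=(float("nan"), float("nan")),
                    p=float("nan"),
                    af_case=float("nan"),
                    af_control=float("nan"),
                    converged=False,
                )
            )
    return results


# ---------------------------------------------------------------------------
# regional chi-square


def regional_freq_test(
    carrier_flags: np.ndarray, region_labels: np.ndarray
) -> tuple[float, int, float]:
    """Pearson chi-square of carrier status against region of birth."""
    flags = (np.asarray(carrier_flags) > 0).astype(int)
    labels = np.asarray(region_labels)
    regions, counts = np.unique(labels, return_counts=True)
    if len(regions) < 2:
        raise StatsInputError("need at least two regions")
    table = np.array(
        [
            [int(flags[labels == r].sum()), int((labels == r).sum() - flags[labels == r].sum())]
            for r in regions
        ]
    )
    keep = table.sum(axis=1) > 0
    if not keep.all():
        warnings.warn("dropping regions with zero individuals", stacklevel=2)
        table = table[keep]
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any():
        warnings.warn("chi-square expected counts below 5; test is unreliable",
                      stacklevel=2)
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate; steps at event times only."""

    times: np.ndarray = field(compare=False)  # distinct event times, ascending
    at_risk: np.ndarray = field(compare=False)
    n_events: np.ndarray = field(compare=False)
    survival: np.ndarray = field(compare=False)
    group: str | None = None

    def survival_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right"))
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_curve(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray | None = None,
):
    """Kaplan-Meier estimator with right censoring.

    Returns a single :class:`KMCurve`, or a ``{label: KMCurve}`` dict when
    ``groups`` is given.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if (t <= 0).any():
        raise StatsInputError("times must be positive")
    if groups is not None:
        g = np.asarray(groups)
        out = {}
        for lbl in np.unique(g):
            c = km_curve(t[g == lbl], e[g == lbl])
            out[str(lbl)] = KMCurve(c.times, c.at_risk, c.n_events, c.survival, str(lbl))
        return out
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = len(t)
    at_risk = n - np.searchsorted(t, event_times, side="left")
    d = np.array([int(((t == et) & e).sum()) for et in event_times])
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(
        times=event_times, at_risk=at_risk, n_events=d, survival=surv
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group logrank statistic (chi-square, 1 df) and p-value."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise StatsInputError("logrank test requires exactly two groups")
    mask = g == labels[1]
    event_times = np.unique(t[e])
    O = E = V = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & mask).sum()
        d = int(((t == et) & e).sum())
        d1 = int(((t == et) & e & mask).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V if V > 0 else 0.0
    return float(chi2), float(sps.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


@dataclass(frozen=True)
class CoxFit:
    terms: tuple[str, ...]
    beta: np.ndarray = field(compare=False)
    hr: np.ndarray = field(compare=False)
    se: np.ndarray = field(compare=False)
    ci95: np.ndarray = field(compare=False)  # (k, 2) on the HR scale
    p: np.ndarray = field(compare=False)
    log_likelihood: float = float("nan")
    iterations: int = 0
    converged: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "HR": self.hr,
                "ci_low": self.ci95[:, 0],
                "ci_high": self.ci95[:, 1],
                "p": self.p,
            }
        )


def _efron_loglik_grad_hess(beta, t, e, X):
    """Efron partial likelihood with gradient and Hessian, vectorized.

    Individuals are sorted by time ascending; risk-set aggregates are suffix
    sums.  For a tied event group of size d the k-th factor (k = 0..d-1)
    subtracts k/d of the tied events' own aggregates from the risk set's.
    """
    n, k = X.shape
    eta = X @ beta
    r = np.exp(eta)
    rX = X * r[:, None]
    rXX = np.einsum("ni,nj->nij", X, rX)

    # suffix sums over the risk set (time ascending)
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rX[::-1], axis=0)[::-1]
    S2 = np.cumsum(rXX[::-1], axis=0)[::-1]

    ev_idx = np.nonzero(e)[0]
    t_ev = t[ev_idx]
    # group tied event times
    uniq, start = np.unique(t_ev, return_index=True)
    group_sizes = np.diff(np.append(start, len(ev_idx)))
    first_pos = np.searchsorted(t, uniq, side="left")

    # tied-group own aggregates
    s0_g = np.add.reduceat(r[ev_idx], start)
    s1_g = np.add.reduceat(rX[ev_idx], start, axis=0)
    s2_g = np.add.reduceat(rXX[ev_idx], start, axis=0)

    # expand to one row per (group, k)
    g_of = np.repeat(np.arange(len(uniq)), group_sizes)
    kk = (np.arange(len(ev_idx)) - np.repeat(start, group_sizes)).astype(float)
    frac = kk / np.repeat(group_sizes, group_sizes)

    phi0 = S0[first_pos][g_of] - frac * s0_g[g_of]
    phi1 = S1[first_pos][g_of] - frac[:, None] * s1_g[g_of]
    phi2 = S2[first_pos][g_of] - frac[:, None, None] * s2_g[g_of]

    ll = float(eta[ev_idx].sum() - np.log(phi0).sum())
    mean = phi1 / phi0[:, None]
    grad = X[ev_idx].sum(axis=0) - mean.sum(axis=0)
    hess = -(phi2 / phi0[:, None, None]).sum(axis=0) + np.einsum(
        "gi,gj->ij", mean, mean
    )
    return ll, grad, hess


def cox_fit(
    times: np.ndarray,
    events: np.ndarray,
    covariates: np.ndarray,
    terms: Sequence[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Newton-Raphson maximization of the Efron-ties Cox partial likelihood.

    Standard errors come from the observed information at the optimum;
    intervals and p-values are Wald.  Monotone likelihood (risk-set
    separation) is flagged as non-convergence rather than raised.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(t):
        X = X.T
    n, k = X.shape
    if terms is None:
        terms = tuple(f"x{i}" for i in range(k))
    if not e.any():
        raise StatsInputError("need at least one event")
    if (X.std(axis=0) == 0).any():
        raise StatsInputError("covariate is constant across individuals")

    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]

    beta = np.zeros(k)
    ll, grad, hess = _efron_loglik_grad_hess(beta, t, e, X)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        # converged when the Newton step is negligible or the gradient is
        # flat at the scale of the partial likelihood
        if np.abs(delta).max() < 1e-10 or np.linalg.norm(grad) < tol * max(
            1.0, abs(ll)
        ):
            converged = True
            break
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, grad_new, hess_new = _efron_loglik_grad_hess(cand, t, e, X)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(beta).max() > 50:  # monotone likelihood
            break

    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        converged = False
    if np.abs(beta).max() > 15 or not np.isfinite(se).all() or (se > 50).any():
        converged = False  # estimates drifting without bound: separation
    z = 1.959963984540054
    with np.errstate(over="ignore"):
        ci = np.column_stack([np.exp(beta - z * se), np.exp(beta + z * se)])
    pvals = 2 * sps.norm.sf(np.abs(beta / se))
    return CoxFit(
        terms=tuple(terms),
        beta=beta,
        hr=np.exp(beta),
        se=se,
        ci95=ci,
        p=pvals,
        log_likelihood=ll,
        iterations=iterations,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg carrier frequency


@dataclass(frozen=True)
class HWEEstimate:
    prevalence: float
    q: float
    het_freq: float
    approximate: bool
    reciprocal: float


def hwe_carrier_frequency(prevalence: float, approximate: bool = False) -> HWEEstimate:
    """Heterozygous-carrier frequency implied by a recessive disease
    prevalence under Hardy-Weinberg: ``q = sqrt(prevalence)`` and carriers at
    ``2q(1-q)``, or the common ``2q`` approximation."""
    if not (0.0 < prevalence <= 1.0):
        raise StatsInputError("prevalence must be in (0, 1]")
    q = float(np.sqrt(prevalence))
    het = 2 * q if approximate else 2 * q * (1 - q)
    return HWEEstimate(
        prevalence=prevalence,
        q=q,
        het_freq=het,
        approximate=approximate,
        reciprocal=float("inf") if het == 0 else 1.0 / het,
    )
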