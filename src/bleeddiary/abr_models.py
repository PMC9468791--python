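"""Annualized bleeding rate (ABR) estimation.

Two estimands are provided, matching how bleed endpoints are reported in
hemophilia studies:

* the *calculated* individual ABR, ``n_bleeds / exposure_days * 365.25``, with
  cohort medians and interquartile ranges, and
* the *model-based* ABR: the intercept of an intercept-only negative binomial
  (NB2) regression with the participant's follow-up time entering as a log
  offset.  With exposure measured in years the exponentiated intercept is
  directly the population ABR (events / participant-year).

The NB2 model puts ``y_i ~ NB(mean = lambda * T_i, var = mu + alpha * mu^2)``
where ``T_i`` is exposure in years and ``alpha >= 0`` the overdispersion; the
gamma-Poisson mixture this implies is the standard account of between-patient
heterogeneity in bleeding rates.  Estimation maximizes the exact NB2
log-likelihood over ``(log lambda, log alpha)`` with analytic gradients
(quasi-Newton, fixed deterministic start), and the 95% CI is Wald on
``log lambda``, exponentiated.

For paired designs (the same participants observed under two regimens /
study periods) :func:`fit_paired_nb` fits a log-linear NB2 model with a period
indicator, log-exposure offset and a participant-level normal random intercept,
integrated by adaptive Gauss–Hermite quadrature; the exponentiated period
coefficient is the intraindividual rate ratio.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

from .adjudication import AdjudicatedBleed
from .diary_core import Diary

__all__ = [
    "ExposureCount",
    "NbFit",
    "PairedNbFit",
    "calculated_abr",
    "median_iqr_abr",
    "fit_nb_abr",
    "fit_paired_nb",
    "exposure_counts",
]

DAYS_PER_YEAR = 365.25
_MIN_LOG_ALPHA = -15.0
_MAX_LOG_ALPHA = 10.0


@dataclass(frozen=True)
class ExposureCount:
    participant_id: str
    n_bleeds: int
    exposure_days: float
    period_label: str | None = None

    def __post_init__(self) -> None:
        if self.exposure_days <= 0:
            raise ValueError("exposure_days must be positive")
        if self.n_bleeds < 0 or int(self.n_bleeds) != self.n_bleeds:
            raise ValueError("n_bleeds must be a nonnegative integer")

    @property
    def exposure_years(self) -> float:
        return self.exposure_days / DAYS_PER_YEAR


@dataclass
class NbFit:
    rate_per_year: float
    dispersion: float
    ci95: tuple[float, float]
    loglik: float
    n: int
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.rate_per_year <= hi or np.isnan(lo)):
            raise ValueError("CI must bracket the rate estimate")


@dataclass
class PairedNbFit:
    rate_ratio: float
    ratio_ci95: tuple[float, float]
    period_rates: dict[str, float]
    dispersion: float
    participant_variance: float
    loglik: float
    n: int
    converged: bool = True
    message: str = ""


def calculated_abr(n_bleeds: float, exposure_days: float) -> float:
    """Individual ABR: bleeds per day annualized by 365.25."""
    if exposure_days <= 0:
        raise ValueError("exposure_days must be positive")
    return n_bleeds / exposure_days * DAYS_PER_YEAR


def median_iqr_abr(rates: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles (linear interpolation) of individual ABRs."""
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr_abr needs at least one participant")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# single-group NB2 with offset
# ---------------------------------------------------------------------------

def _nb2_loglik_terms(y, mu, alpha):
    r = 1.0 / alpha
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _nb2_negloglik_grad(theta, y, t_years):
    """Negative log-likelihood and gradient in (log lambda, log alpha)."""
    loglam, logalpha = theta
    lam, alpha = np.exp(loglam), np.exp(logalpha)
    mu = lam * t_years
    r = 1.0 / alpha
    ll = np.sum(_nb2_loglik_terms(y, mu, alpha))
    # d ll / d log lambda
    g_loglam = np.sum((y - mu) * r / (mu + r))
    # d ll / d r, chained to log alpha via dr/dlogalpha = -r
    dll_dr = np.sum(
        special.digamma(y + r)
        - special.digamma(r)
        + np.log(r / (r + mu))
        + 1.0
        - (r + y) / (r + mu)
    )
    g_logalpha = -r * dll_dr
    return -ll, -np.array([g_loglam, g_logalpha])


def _poisson_loglik(y, lam, t_years):
    mu = lam * t_years
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = y * np.log(mu) - mu - special.gammaln(y + 1.0)
    return float(np.sum(np.where((y == 0) & (mu == 0), 0.0, terms)))


def _numerical_hessian(fun, x, eps=1e-5):
    x = np.asarray(x, dtype=float)
    k = x.size
    h = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            f_pp = fun(x + ei + ej)
            f_pm = fun(x + ei - ej)
            f_mp = fun(x - ei + ej)
            f_mm = fun(x - ei - ej)
            h[i, j] = h[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * eps * eps)
    return h


def fit_nb_abr(
    counts: Iterable[ExposureCount],
    fix_alpha: float | None = None,
    conf_level: float = 0.95,
) -> NbFit:
    """Fit the intercept-only NB2 model with log-exposure offset.

    Parameters
    ----------
    counts
        One record per participant (bleed count + exposure days).
    fix_alpha
        If given, the dispersion is held at this value; ``fix_alpha=0`` is the
        Poisson special case with the closed-form MLE ``sum(y) / sum(T)``.

    Returns
    -------
    NbFit with the annual rate, dispersion, Wald CI (on the log-rate scale,
    exponentiated) and the maximized log-likelihood.

    Notes
    -----
    All-zero counts put the rate MLE on the boundary: the fit reports
    ``rate=0`` with the one-sided Poisson-exact upper bound and a warning
    rather than failing.
    """
    counts = list(counts)
    if len(counts) < 1:
        raise ValueError("fit_nb_abr needs at least one participant")
    y = np.array([c.n_bleeds for c in counts], dtype=float)
    t_years = np.array([c.exposure_years for c in counts], dtype=float)
    n = len(counts)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)

    total = y.sum()
    t_total = t_years.sum()

    if total == 0:
        warnings.warn("all counts are zero; rate MLE is on the boundary", RuntimeWarning)
        upper = stats.chi2.ppf(conf_level, 2) / 2.0 / t_total
        return NbFit(
            rate_per_year=0.0, dispersion=0.0, ci95=(0.0, float(upper)),
            loglik=0.0, n=n, converged=True, message="boundary: all counts zero",
        )

    if fix_alpha is not None:
        if fix_alpha < 0:
            raise ValueError("fix_alpha must be nonnegative")
        if fix_alpha == 0.0:
            lam = total / t_total  # closed-form Poisson MLE with offset
            se_log = 1.0 / np.sqrt(total)
            ll = _poisson_loglik(y, lam, t_years)
            return NbFit(
                rate_per_year=float(lam), dispersion=0.0,
                ci95=(float(lam * np.exp(-z * se_log)), float(lam * np.exp(z * se_log))),
                loglik=ll, n=n, message="Poisson (alpha fixed at 0)",
            )
        def nll_fixed(loglam):
            nll, g = _nb2_negloglik_grad(
                np.array([loglam[0], np.log(fix_alpha)]), y, t_years
            )
            return nll, g[:1]
        res = optimize.minimize(
            nll_fixed, x0=[np.log(total / t_total)], jac=True, method="L-BFGS-B"
        )
        loglam = res.x[0]
        var = _numerical_hessian(lambda x: nll_fixed(x)[0], res.x)[0, 0]
        se_log = 1.0 / np.sqrt(var) if var > 0 else np.nan
        lam = np.exp(loglam)
        return NbFit(
            rate_per_year=float(lam), dispersion=float(fix_alpha),
            ci95=(float(lam * np.exp(-z * se_log)), float(lam * np.exp(z * se_log))),
            loglik=float(-res.fun), n=n, converged=bool(res.success),
            message=str(res.message),
        )

    x0 = np.array([np.log(total / t_total), 0.0])  # alpha starts at 1
    res = optimize.minimize(
        _nb2_negloglik_grad, x0=x0, args=(y, t_years), jac=True,
        method="L-BFGS-B",
        bounds=[(None, None), (_MIN_LOG_ALPHA, _MAX_LOG_ALPHA)],
    )
    loglam, logalpha = res.x
    lam, alpha = float(np.exp(loglam)), float(np.exp(logalpha))
    at_boundary = logalpha <= _MIN_LOG_ALPHA + 1e-6
    if at_boundary:
        alpha = 0.0
        se_log = 1.0 / np.sqrt(total)  # Poisson-limit standard error
    else:
        hess = _numerical_hessian(
            lambda x: _nb2_negloglik_grad(x, y, t_years)[0], res.x
        )
        try:
            cov = np.linalg.inv(hess)
            se_log = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            se_log = np.nan
    return NbFit(
        rate_per_year=lam, dispersion=alpha,
        ci95=(float(lam * np.exp(-z * se_log)), float(lam * np.exp(z * se_log))),
        loglik=float(-res.fun), n=n, converged=bool(res.success),
        message="dispersion at Poisson boundary" if at_boundary else str(res.message),
    )


# ---------------------------------------------------------------------------
# paired NB2 with participant random intercept
# ---------------------------------------------------------------------------

def _paired_negloglik(theta, y, t_years, period, index, n_sub, nodes, weights):
    """Marginal negative log-likelihood via adaptive Gauss–Hermite quadrature.

    theta = (beta0, beta1, log alpha, log sigma); participant random intercept
    b_i ~ N(0, sigma^2) on the log-rate scale.  Modes are located per
    participant by safeguarded Newton (the conditional log-joint is strictly
    concave in b), then the quadrature grid is centered and scaled at the mode.
    """
    beta0, beta1, logalpha, logsigma = theta
    alpha = np.exp(logalpha)
    sigma = np.exp(logsigma)
    r = 1.0 / alpha
    eta0 = np.log(t_years) + beta0 + beta1 * period  # linear predictor at b=0

    def joint_parts(b):
        # sum_j log NB(y_ij | mu_ij e^{b_i}) + log N(b_i; 0, sigma^2), grouped by i
        mu = np.exp(eta0 + b[index])
        terms = _nb2_loglik_terms(y, mu, alpha)
        by_sub = np.bincount(index, weights=terms, minlength=n_sub)
        return by_sub - 0.5 * (b / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)

    # Newton iterations for the per-participant mode
    b = np.zeros(n_sub)
    for _ in range(50):
        mu = np.exp(eta0 + b[index])
        g = np.bincount(index, weights=(y - mu) * r / (mu + r), minlength=n_sub) - b / sigma**2
        h = -np.bincount(
            index, weights=r * mu * (r + y) / (mu + r) ** 2, minlength=n_sub
        ) - 1.0 / sigma**2
        step = g / h
        b_new = b - np.clip(step, -5.0, 5.0)
        if np.max(np.abs(b_new - b)) < 1e-9:
            b = b_new
            break
        b = b_new
    scale = 1.0 / np.sqrt(-h)  # h < 0 by concavity

    # AGHQ: integral_i ≈ sqrt(2) s_i sum_k w_k exp(joint(b_ik) + z_k^2)
    log_contrib = np.empty((len(nodes), n_sub))
    for k, (zk, wk) in enumerate(zip(nodes, weights)):
        bk = b + np.sqrt(2.0) * scale * zk
        log_contrib[k] = joint_parts(bk) + zk**2 + np.log(wk)
    m = log_contrib.max(axis=0)
    log_int = m + np.log(np.sum(np.exp(log_contrib - m), axis=0))
    log_int += 0.5 * np.log(2.0) + np.log(scale)
    return -float(np.sum(log_int))


def fit_paired_nb(
    counts: Iterable[ExposureCount],
    reference_period: str | None = None,
    n_quad: int = 15,
    conf_level: float = 0.95,
) -> PairedNbFit:
    """Fit the paired NB2 model for intraindividual period comparisons.

    Every participant must contribute exactly one record per period (two
    periods total); participants missing a period are dropped with a warning.
    The model is ``log mu_ij = log T_ij + beta0 + beta1 * [period j = comparison]
    + b_i`` with ``b_i ~ N(0, sigma^2)`` and NB2 dispersion ``alpha``, and the
    reported ``rate_ratio`` is ``exp(beta1)`` (comparison vs reference period).
    """
    counts = list(counts)
    periods = sorted({c.period_label for c in counts if c.period_label is not None})
    if len(periods) != 2:
        raise ValueError(f"expected exactly two period labels, got {periods}")
    if reference_period is None:
        reference_period = "NIS" if "NIS" in periods else periods[0]
    if reference_period not in periods:
        raise ValueError(f"reference period {reference_period!r} not among {periods}")
    comparison = next(p for p in periods if p != reference_period)

    by_sub: dict[str, dict[str, ExposureCount]] = {}
    for c in counts:
        by_sub.setdefault(c.participant_id, {})[c.period_label] = c
    complete = {pid: recs for pid, recs in by_sub.items() if len(recs) == 2}
    dropped = sorted(set(by_sub) - set(complete))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} participant(s) missing a period: {dropped[:5]}...",
            RuntimeWarning,
        )
    if len(complete) < 2:
        raise ValueError("paired fit needs at least two complete participants")

    pids = sorted(complete)
    y, t_years, period, index = [], [], [], []
    for i, pid in enumerate(pids):
        for lbl in (reference_period, comparison):
            c = complete[pid][lbl]
            y.append(c.n_bleeds)
            t_years.append(c.exposure_years)
            period.append(0.0 if lbl == reference_period else 1.0)
            index.append(i)
    y = np.asarray(y, float)
    t_years = np.asarray(t_years, float)
    period = np.asarray(period, float)
    index = np.asarray(index, int)
    n_sub = len(pids)
    nodes, weights = hermgauss(n_quad)

    ref_mask = period == 0.0
    rate_ref = max(y[ref_mask].sum(), 0.5) / t_years[ref_mask].sum()
    rate_cmp = max(y[~ref_mask].sum(), 0.5) / t_years[~ref_mask].sum()
    x0 = np.array([np.log(rate_ref), np.log(rate_cmp) - np.log(rate_ref), 0.0, np.log(0.5)])

    args = (y, t_years, period, index, n_sub, nodes, weights)
    # variance parameters are bounded away from -inf so that sigma -> 0 /
    # alpha -> 0 fits land on a boundary instead of diverging
    bounds = [(None, None), (None, None), (_MIN_LOG_ALPHA, 5.0), (np.log(1e-3), 3.0)]
    res = optimize.minimize(
        _paired_negloglik, x0=x0, args=args, method="Nelder-Mead", bounds=bounds,
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
    )
    beta0, beta1, logalpha, logsigma = res.x
    hess = _numerical_hessian(lambda x: _paired_negloglik(x, *args), res.x, eps=1e-4)
    # parameters pinned at a bound give a flat likelihood direction; drop them
    # from the curvature block used for the Wald SE
    free = [0, 1]
    for k, (lo, hi) in ((2, bounds[2]), (3, bounds[3])):
        if res.x[k] - lo > 1e-6 and hi - res.x[k] > 1e-6:
            free.append(k)
    try:
        cov = np.linalg.inv(hess[np.ix_(free, free)])
        se_b1 = float(np.sqrt(max(cov[free.index(1), free.index(1)], 0.0)))
    except np.linalg.LinAlgError:
        se_b1 = np.nan
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    ratio = float(np.exp(beta1))
    return PairedNbFit(
        rate_ratio=ratio,
        ratio_ci95=(float(np.exp(beta1 - z * se_b1)), float(np.exp(beta1 + z * se_b1))),
        period_rates={
            reference_period: float(np.exp(beta0)),
            comparison: float(np.exp(beta0 + beta1)),
        },
        dispersion=float(np.exp(logalpha)),
        participant_variance=float(np.exp(logsigma) ** 2),
        loglik=float(-res.fun),
        n=n_sub,
        converged=bool(res.success),
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# bridging adjudicated diaries to per-participant counts
# ---------------------------------------------------------------------------

def exposure_counts(
    diary: Diary,
    adjudicated: Iterable[AdjudicatedBleed],
    which: str = "all",
    period_label: str | None = None,
) -> list[ExposureCount]:
    """Per-participant counts + efficacy exposure for the NB models.

    ``which`` selects the endpoint: ``"all"``, ``"treated"``, ``"untreated"``
    or ``"joint"``.  When the 72-h rule produced collapse groups, each group
    counts once.  Zero-bleed participants are included (they carry exposure).
    """
    if which not in {"all", "treated", "untreated", "joint"}:
        raise ValueError(f"unknown endpoint {which!r}")
    seen_groups: dict[str, set[int]] = {}
    n: dict[str, int] = {p.participant_id: 0 for p in diary.participants}
    for ab in adjudicated:
        if which == "treated" and not ab.treated:
            continue
        if which == "untreated" and ab.treated:
            continue
        if which == "joint" and not ab.joint_bleed:
            continue
        pid = ab.bleed.participant_id
        groups = seen_groups.setdefault(pid, set())
        if ab.collapse_group_id >= 0:
            if ab.collapse_group_id in groups:
                continue
            groups.add(ab.collapse_group_id)
        n[pid] += 1
    return [
        ExposureCount(
            participant_id=p.participant_id,
            n_bleeds=n[p.participant_id],
            exposure_days=float(p.efficacy_days),
            period_label=period_label if period_label is not None else p.study_phase.value,
        )
        for p in diary.participants
    ]
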