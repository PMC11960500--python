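"""The four disproportionality statistics used in spontaneous-report mining.

Frequentist measures
    * ROR — reporting odds ratio (a*d)/(b*c) with a lognormal (Woolf) 95% CI.
    * PRR — proportional reporting ratio [a/(a+b)] / [c/(c+d)], paired with
      a Pearson chi-square on the 2x2 table (no continuity correction by
      default; a Yates-corrected variant is available).

Bayesian measures
    * BCPNN information component IC = log2 of the observed-to-expected
      co-reporting ratio, with its lower two-standard-deviation bound
      IC-2SD estimated either by seeded Monte-Carlo sampling of the
      Dirichlet posterior of the 2x2 cell probabilities (default) or by the
      closed-form gamma approximation of the classical BCPNN with symmetric
      unit priors.
    * MGPS — the DuMouchel gamma-Poisson shrinker.  Observed counts a with
      independence-expected counts E are modelled as Poisson(lambda*E) with
      lambda drawn from a two-component gamma mixture prior fitted by
      maximum marginal likelihood; EBGM is the geometric mean of the
      posterior of lambda and EBGM05 its 5th percentile.

A statistic whose preconditions fail (e.g. a zero comparator cell without
continuity correction) is returned as NaN — an "undefined" flag rather than
an exception — so that downstream signal criteria can simply fail it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable
from .errors import ConfigurationError, FittingError

__all__ = [
    "SignalStatistics", "MgpsPrior", "DUMOUCHEL_INIT",
    "compute_ror", "compute_prr_chi2", "compute_bcpnn_ic",
    "fit_mgps_prior", "compute_ebgm", "compute_all",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SignalStatistics:
    """All disproportionality quantities for one 2x2 table.

    Undefined entries are NaN.  ``rr`` is the observed/expected relative
    reporting ratio a/E; for all-positive tables ``ic == log2(rr)``.
    """

    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic: float
    ic_minus_2sd: float
    ebgm: float
    ebgm05: float
    rr: float


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior of the DuMouchel model.

    ``lambda ~ w * Gamma(alpha1, rate beta1) + (1-w) * Gamma(alpha2, rate
    beta2)``.  ``loglik`` records the marginal log-likelihood at these
    parameters when the prior was fitted.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ConfigurationError("gamma parameters must be positive")
        if not (0.0 < self.w < 1.0):
            raise ConfigurationError("mixture weight must lie in (0, 1)")


#: DuMouchel's canonical starting point (alpha1, beta1, alpha2, beta2, w).
DUMOUCHEL_INIT = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def compute_ror(table: ContingencyTable,
                continuity: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI.

    With a zero cell and ``continuity=False`` all three values are NaN;
    with ``continuity=True`` the Haldane-Anscombe 0.5 is added to every
    cell before computing.
    """
    a, b, c, d = (float(x) for x in table.as_tuple())
    if continuity and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        return (math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, ror * math.exp(-_Z95 * se), ror * math.exp(_Z95 * se))


def compute_prr_chi2(table: ContingencyTable,
                     yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-square.

    The chi-square is the plain four-cell Pearson statistic (no continuity
    correction) unless ``yates=True``; the uncorrected form is what
    published pharmacovigilance chi-squares conventionally report.
    """
    a, b, c, d = table.as_tuple()
    if a + b == 0 or c + d == 0 or c == 0:
        return (math.nan, math.nan)
    prr = (a / (a + b)) / (c / (c + d))
    if (a + c) == 0 or (b + d) == 0:
        return (prr, math.nan)
    chi2, _, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=yates)
    return (prr, float(chi2))


def _ic_point(table: ContingencyTable) -> float:
    a = table.a
    if a == 0 or table.drug_margin == 0 or table.event_margin == 0:
        return math.nan
    return math.log2(a * table.n / (table.drug_margin * table.event_margin))


def compute_bcpnn_ic(table: ContingencyTable, estimator: str = "mc",
                     n_draws: int = 100_000,
                     rng: np.random.Generator | int | None = 0,
                     point_estimate: str = "observed") -> tuple[float, float]:
    """Information component and its lower 2-standard-deviation bound.

    ``estimator="mc"`` draws the 2x2 cell probabilities from the Dirichlet
    posterior with symmetric unit priors (Dirichlet(a+1, b+1, c+1, d+1)),
    forms the IC for each draw and uses the sample standard deviation;
    ``estimator="gamma"`` uses the closed-form variance approximation of
    the classical BCPNN with unit marginal priors.  Both return
    ``(ic, ic - 2*sd)``.

    ``point_estimate="observed"`` (default) reports the observed/expected
    log2 ratio; ``"posterior-mean"`` reports the Monte-Carlo posterior mean
    (mc estimator only).
    """
    ic = _ic_point(table)
    a, b, c, d = table.as_tuple()
    n = table.n
    if estimator == "mc":
        rng = np.random.default_rng(rng)
        draws = rng.dirichlet([a + 1, b + 1, c + 1, d + 1], size=int(n_draws))
        p11 = draws[:, 0]
        p1x = p11 + draws[:, 1]
        px1 = p11 + draws[:, 2]
        ic_draws = np.log2(p11 / (p1x * px1))
        sd = float(np.std(ic_draws, ddof=1))
        if point_estimate == "posterior-mean":
            ic = float(np.mean(ic_draws))
        elif point_estimate != "observed":
            raise ConfigurationError(
                f"unknown point_estimate: {point_estimate!r}")
        return (ic, ic - 2.0 * sd)
    if estimator == "gamma":
        # Bate-style closed form, symmetric unit priors on cell and margins
        a11, a1x, ax1 = 1.0, 1.0, 1.0
        rho, kap = 2.0, 2.0
        gam = a11 * (n + rho) * (n + kap) / ((a + b + a1x) * (a + c + ax1))
        var = (
            (n - a + gam - a11) / ((a + a11) * (1 + n + gam))
            + (n - (a + b) + rho - a1x) / ((a + b + a1x) * (1 + n + rho))
            + (n - (a + c) + kap - ax1) / ((a + c + ax1) * (1 + n + kap))
        ) / (math.log(2.0) ** 2)
        return (ic, ic - 2.0 * math.sqrt(var))
    raise ConfigurationError(f"unknown IC estimator: {estimator!r}")


# -- MGPS ---------------------------------------------------------------------

def _nb_loglik(a: np.ndarray, e: np.ndarray, alpha: float,
               beta: float) -> np.ndarray:
    """log P(a | alpha, beta, E) under the gamma-Poisson marginal."""
    return (special.gammaln(a + alpha) - special.gammaln(alpha)
            - special.gammaln(a + 1.0)
            + alpha * np.log(beta / (beta + e))
            + a * np.log(e / (beta + e)))


def _mixture_loglik(params: Sequence[float], a: np.ndarray,
                    e: np.ndarray) -> float:
    alpha1, beta1, alpha2, beta2, w = params
    w = min(max(float(w), 1e-12), 1.0 - 1e-12)   # guard boundary underflow
    l1 = _nb_loglik(a, e, alpha1, beta1) + math.log(w)
    l2 = _nb_loglik(a, e, alpha2, beta2) + math.log1p(-w)
    return float(np.logaddexp(l1, l2).sum())


def fit_mgps_prior(pairs: Iterable[tuple[float, float]] |
                   Iterable[ContingencyTable],
                   init: Sequence[float] = DUMOUCHEL_INIT,
                   tol: float = 1e-8, max_iter: int = 10_000,
                   n_starts: int = 4,
                   rng: np.random.Generator | int | None = 0) -> MgpsPrior:
    """Fit the two-component gamma mixture by maximum marginal likelihood.

    ``pairs`` is a sequence of (a, E) observed/expected pairs, or of
    contingency tables (converted via a and E=(a+b)(a+c)/N).  Optimization
    is multi-start Nelder-Mead on log/logit-transformed parameters
    (DuMouchel's canonical values seed the first start), which handles the
    flat ridges of the mixture likelihood more robustly than gradient
    steps.  Requires at least 10 pairs; all-zero counts raise
    :class:`FittingError`.
    """
    items = list(pairs)
    if items and isinstance(items[0], ContingencyTable):
        items = [(t.a, t.expected) for t in items]
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 10:
        raise FittingError("need at least 10 (a, E) pairs for a stable fit")
    a, e = arr[:, 0], arr[:, 1]
    if np.any(e <= 0):
        raise FittingError("expected counts must be positive")
    if not np.any(a > 0):
        raise FittingError("degenerate data: all observed counts are zero")

    # gamma parameters are bounded to [1e-6, 1e6]: beyond that the
    # gammaln(a+alpha)-gammaln(alpha) difference cancels catastrophically
    # and the optimizer chases numerical noise instead of likelihood
    log_bound = math.log(1e6)

    def unpack(theta):
        clipped = np.clip(theta[:4], -log_bound, log_bound)
        return (math.exp(clipped[0]), math.exp(clipped[1]),
                math.exp(clipped[2]), math.exp(clipped[3]),
                special.expit(theta[4]))

    def objective(theta):
        try:
            return -_mixture_loglik(unpack(theta), a, e)
        except (OverflowError, FloatingPointError):
            return math.inf

    theta0 = np.array([math.log(init[0]), math.log(init[1]),
                       math.log(init[2]), math.log(init[3]),
                       special.logit(init[4])])
    rng = np.random.default_rng(rng)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(theta0 + rng.normal(scale=1.0, size=5))

    best = None
    for start in starts:
        res = optimize.minimize(objective, start, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": tol,
                                         "maxiter": max_iter})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    a1, b1, a2, b2, w = unpack(best.x)
    w = min(max(float(w), 1e-12), 1.0 - 1e-12)
    ll = -best.fun
    if ll + 1e-9 < _mixture_loglik(init, a, e):
        raise FittingError("optimizer failed to improve on the initial prior")
    return MgpsPrior(alpha1=a1, beta1=b1, alpha2=a2, beta2=b2, w=w,
                     loglik=ll, converged=bool(best.success))


def _posterior(table_a: float, e: float, prior: MgpsPrior):
    """Posterior mixture over lambda: weights and gamma(alpha, rate beta)."""
    l1 = float(_nb_loglik(np.array([table_a]), np.array([e]),
                          prior.alpha1, prior.beta1)[0]) + math.log(prior.w)
    l2 = float(_nb_loglik(np.array([table_a]), np.array([e]),
                          prior.alpha2, prior.beta2)[0]) + math.log1p(-prior.w)
    m = max(l1, l2)
    q1 = math.exp(l1 - m)
    q2 = math.exp(l2 - m)
    z = q1 + q2
    weights = (q1 / z, q2 / z)
    comps = ((prior.alpha1 + table_a, prior.beta1 + e),
             (prior.alpha2 + table_a, prior.beta2 + e))
    return weights, comps


def compute_ebgm(table: ContingencyTable,
                 prior: MgpsPrior) -> tuple[float, float, float]:
    """EBGM, EBGM05 and the raw relative reporting ratio a/E.

    EBGM = 2**E[log2 lambda | a] is the geometric mean of the posterior of
    the Poisson rate multiplier lambda; EBGM05 is its 5th percentile,
    obtained by numerically inverting the posterior-mixture CDF (Brent
    bisection to 1e-6 relative).
    """
    e = table.expected
    if e <= 0:
        return (math.nan, math.nan, math.nan)
    rr = table.a / e
    weights, comps = _posterior(table.a, e, prior)
    mean_log = sum(w * (special.digamma(alpha) - math.log(beta))
                   for w, (alpha, beta) in zip(weights, comps))
    ebgm = math.exp(mean_log)

    def cdf(lam: float) -> float:
        return sum(w * stats.gamma.cdf(lam, alpha, scale=1.0 / beta)
                   for w, (alpha, beta) in zip(weights, comps))

    lo = min(stats.gamma.ppf(1e-4, alpha, scale=1.0 / beta)
             for alpha, beta in comps)
    hi = max(stats.gamma.ppf(1.0 - 1e-6, alpha, scale=1.0 / beta)
             for alpha, beta in comps)
    lo = max(lo, 1e-300)
    ebgm05 = float(optimize.brentq(lambda lam: cdf(lam) - 0.05, lo, hi,
                                   rtol=1e-6))
    return (ebgm, ebgm05, rr)


def compute_all(table: ContingencyTable, prior: MgpsPrior | None = None,
                ic_estimator: str = "mc", n_draws: int = 100_000,
                rng: np.random.Generator | int | None = 0,
                continuity: bool = False) -> SignalStatistics:
    """All four statistics for one table.

    With no fitted ``prior``, EBGM falls back to DuMouchel's canonical
    prior values — adequate for screening, but fit a corpus-wide prior via
    :func:`fit_mgps_prior` for calibrated shrinkage.
    """
    ror, lo, hi = compute_ror(table, continuity=continuity)
    prr, chi2 = compute_prr_chi2(table)
    ic, ic2sd = compute_bcpnn_ic(table, estimator=ic_estimator,
                                 n_draws=n_draws, rng=rng)
    if prior is None:
        prior = MgpsPrior(*DUMOUCHEL_INIT)
    ebgm, ebgm05, rr = compute_ebgm(table, prior)
    return SignalStatistics(ror=ror, ror_low=lo, ror_high=hi, prr=prr,
                            chi2=chi2, ic=ic, ic_minus_2sd=ic2sd,
                            ebgm=ebgm, ebgm05=ebgm05, rr=rr)
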