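"""Per-gene count distributions: Poisson, NB, ZINB.

Log-likelihoods, maximum-likelihood fitting and hypergeometric cell
down-sampling.  The NB is parameterized by the mean ``mu`` and the
dispersion ``phi`` (variance ``mu + phi * mu**2``); ``theta = 1/phi`` is
the size parameter used internally for optimization, boxed to
``[1e-8, 1e8]``.  A fitted ``theta`` at the upper box is reported as
``phi = 0`` (Poisson-like).

The three families are nested (Poisson within NB within ZINB), which the
model-selection stage exploits; fitting therefore guarantees, up to a
numerical slack, that the richer family never loses likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, gammaln, logit, psi, xlogy

from .io_counts import CountMatrix

LOG_THETA_MIN = math.log(1e-8)
LOG_THETA_MAX = math.log(1e8)
_THETA_GRID = [10.0**k for k in range(-8, 5)]  # initial values 1e-8 ... 1e4


@dataclass
class ModelFit:
    """One gene's fitted count model."""

    family: str  # poisson | nb | zinb
    mean: float
    dispersion: float  # phi; 0 means Poisson-like
    zero_mass: float  # pi0, nonzero only for zinb
    loglik: float
    converged: bool
    n_params: int
    degenerate: bool = False


def poisson_logpmf(y, mu):
    y = np.asarray(y, dtype=float)
    return xlogy(y, mu) - mu - gammaln(y + 1.0)


def nb_logpmf(y, mu, phi):
    """Log pmf of NB(mu, phi); the phi -> 0 limit is the Poisson log pmf.

    Accurate through the Poisson limit: for tiny phi the direct
    ``gammaln`` form loses precision (differences of huge values), so a
    ``log1p``-based correction to the Poisson log pmf is used instead.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    y = y.astype(float)
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if phi == 0:
        return poisson_logpmf(y, mu)
    theta = 1.0 / phi
    if theta > 1e6:
        # log f_NB = log f_Pois + sum_{j=1}^{y-1} log1p(j/theta)
        #            - (y + theta) * log1p(mu/theta) + mu
        ymax = int(np.max(y)) if y.size else 0
        cum = np.concatenate(
            [[0.0, 0.0], np.cumsum(np.log1p(np.arange(1, ymax) / theta))]
        ) if ymax >= 1 else np.zeros(2)
        delta = cum[np.minimum(y.astype(int), ymax) + 0]  # index y -> sum over j<y
        l1p = np.log1p(mu / theta)
        return poisson_logpmf(y, mu) + delta - (y + theta) * l1p + mu
    return (
        gammaln(theta + y)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + xlogy(y, mu)
        - (y + theta) * np.log(theta + mu)
        + theta * np.log(theta)
    )


def zinb_logpmf(y, mu, phi, pi0):
    """Log pmf of the zero-inflated NB mixture pi0*1{y=0} + (1-pi0)*NB."""
    if not 0 <= pi0 < 1:
        raise ValueError("pi0 must be in [0, 1)")
    y = np.asarray(y)
    base = nb_logpmf(y, mu, phi)
    if pi0 == 0:
        return base
    out = np.log1p(-pi0) + base
    zero = np.asarray(y) == 0
    if np.any(zero):
        out = np.where(zero, np.logaddexp(math.log(pi0), out), out)
    return out


# ---------------------------------------------------------------------------
# intercept-only fitting


def _nb_loglik_stats(y):
    y = np.asarray(y, dtype=float)
    return y, y.sum(), float(y.size), gammaln(y + 1.0).sum()


def _nb_loglik_fast(y, sumy, n, sum_gln, mu, theta):
    """NB log-likelihood for an i.i.d. sample, sufficient-stat form."""
    return (
        gammaln(theta + y).sum()
        - n * gammaln(theta)
        - sum_gln
        + xlogy(sumy, mu)
        - (sumy + n * theta) * np.log(theta + mu)
        + n * theta * np.log(theta)
    )


def _nb_negloglik_grad(x, y, sumy, n, sum_gln):
    logmu, logtheta = x
    mu, theta = math.exp(logmu), math.exp(logtheta)
    ll = _nb_loglik_fast(y, sumy, n, sum_gln, mu, theta)
    d_logmu = sumy - mu * (sumy + n * theta) / (theta + mu)
    d_theta = (
        psi(theta + y).sum()
        - n * psi(theta)
        + n * math.log(theta / (theta + mu))
        + n
        - (sumy + n * theta) / (theta + mu)
    )
    return -ll, np.array([-d_logmu, -theta * d_theta])


def _profile_theta(y, sumy, n, sum_gln, mu):
    """Maximize the NB log-likelihood over theta at fixed mean."""
    res = minimize_scalar(
        lambda lt: -_nb_loglik_fast(y, sumy, n, sum_gln, mu, math.exp(lt)),
        bounds=(LOG_THETA_MIN, LOG_THETA_MAX),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return math.exp(res.x), -res.fun


def fit_poisson(y) -> ModelFit:
    """Intercept-only Poisson MLE: mean = sample mean."""
    y = np.asarray(y, dtype=float)
    mu = float(y.mean())
    ll = float(poisson_logpmf(y, mu).sum()) if mu > 0 else 0.0
    return ModelFit(
        family="poisson",
        mean=mu,
        dispersion=0.0,
        zero_mass=0.0,
        loglik=ll,
        converged=True,
        n_params=1,
        degenerate=mu == 0,
    )


def fit_nb(y, max_iter: int = 100, ll_tol: float = 1e-6) -> ModelFit:
    """Intercept-only NB MLE via two strategies, keeping the better fit.

    Strategy (a): joint optimization of ``(log mu, log theta)`` started
    from each theta in the grid ``10**-8 ... 10**4``.  Strategy (b):
    alternate a closed-form mean step (the intercept-only mean MLE is the
    sample mean for any theta) with a bounded 1-d search over theta until
    the likelihood change falls below ``ll_tol`` or ``max_iter`` rounds.
    """
    yv = np.asarray(y, dtype=float)
    if yv.size < 2:
        raise ValueError("fit_nb needs at least 2 observations")
    if yv.sum() == 0:
        return ModelFit("nb", 0.0, 0.0, 0.0, 0.0, True, 2, degenerate=True)
    y_, sumy, n, sum_gln = _nb_loglik_stats(yv)
    ybar = sumy / n

    # strategy (b): alternating mean / dispersion steps
    mu_b = ybar
    var = yv.var()
    theta_b = float(np.clip(mu_b**2 / max(var - mu_b, 1e-8), 1e-8, 1e8))
    ll_b = -np.inf
    for _ in range(max_iter):
        mu_b = ybar  # closed-form mean step at fixed theta
        theta_b, ll_new = _profile_theta(y_, sumy, n, sum_gln, mu_b)
        if ll_new - ll_b < ll_tol:
            ll_b = max(ll_b, ll_new)
            break
        ll_b = ll_new

    # strategy (a): joint quasi-Newton from the theta grid
    best = (ll_b, mu_b, theta_b, True)
    x_mu0 = math.log(max(ybar, 1e-12))
    for theta0 in _THETA_GRID:
        res = minimize(
            _nb_negloglik_grad,
            x0=np.array([x_mu0, math.log(theta0)]),
            args=(y_, sumy, n, sum_gln),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-30.0, 30.0), (LOG_THETA_MIN, LOG_THETA_MAX)],
            options={"maxiter": 200},
        )
        ll = -res.fun
        if ll > best[0]:
            best = (ll, math.exp(res.x[0]), math.exp(res.x[1]), bool(res.success))
    ll, mu, theta, ok = best
    phi = 0.0 if math.log(theta) >= LOG_THETA_MAX - 1e-6 else 1.0 / theta
    return ModelFit("nb", float(mu), float(phi), 0.0, float(ll), ok, 2)


def _zinb_negloglik(x, y, zero, nz):
    logmu, logtheta, lgt = x
    mu, theta, pi0 = math.exp(logmu), math.exp(logtheta), expit(lgt)
    phi = 1.0 / theta
    ll_nb0 = nb_logpmf(np.zeros(1), mu, phi)[0]
    ll = np.log1p(-pi0) * nz.size + nb_logpmf(nz, mu, phi).sum()
    if zero:
        ll += zero * np.logaddexp(math.log(pi0), math.log1p(-pi0) + ll_nb0)
    return -ll


def fit_zinb(y, pi0_init: float = 0.01) -> ModelFit:
    """ZINB MLE initialized from the NB fit (mu, theta) and a small pi0."""
    yv = np.asarray(y, dtype=float)
    if yv.size < 3:
        raise ValueError("fit_zinb needs at least 3 observations")
    nb = fit_nb(yv)
    if nb.degenerate:
        return ModelFit("zinb", 0.0, 0.0, 0.0, 0.0, True, 3, degenerate=True)
    zero = int((yv == 0).sum())
    nz = yv[yv > 0]
    theta0 = 1e8 if nb.dispersion == 0 else 1.0 / nb.dispersion
    x0 = np.array(
        [
            math.log(max(nb.mean, 1e-12)),
            float(np.clip(math.log(theta0), LOG_THETA_MIN, LOG_THETA_MAX)),
            logit(pi0_init),
        ]
    )
    lgt_min = logit(1e-9)
    res = minimize(
        _zinb_negloglik,
        x0=x0,
        args=(yv, zero, nz),
        method="L-BFGS-B",
        bounds=[(-30.0, 30.0), (LOG_THETA_MIN, LOG_THETA_MAX), (lgt_min, logit(0.999))],
        options={"maxiter": 300},
    )
    mu, theta, pi0 = math.exp(res.x[0]), math.exp(res.x[1]), float(expit(res.x[2]))
    # keep whichever of {optimum, NB boundary} is better; report boundary pi0 as 0
    ll = -res.fun
    if pi0 <= expit(lgt_min + 1e-6):
        pi0 = 0.0
    if nb.loglik > ll:
        ll, mu, theta, pi0 = nb.loglik, nb.mean, theta0, 0.0
    phi = 0.0 if math.log(theta) >= LOG_THETA_MAX - 1e-6 else 1.0 / theta
    return ModelFit("zinb", float(mu), float(phi), pi0, float(ll), bool(res.success), 3)


# ---------------------------------------------------------------------------
# down-sampling


def subsample_counts(rng: np.random.Generator, column: np.ndarray, nsample: int) -> np.ndarray:
    """Draw ``nsample`` molecules without replacement from a gene-labeled pool.

    This is a multivariate hypergeometric draw over the gene labels of the
    ``column.sum()`` molecules in one cell.
    """
    total = int(column.sum())
    if nsample > total:
        raise ValueError("cannot sample more molecules than the cell contains")
    if nsample == total:
        return column.copy()
    return rng.multivariate_hypergeometric(column, nsample, method="marginals")


def downsample_cells(
    matrix: CountMatrix, depth_quantile: float = 0.10, seed: int | None = None
) -> CountMatrix:
    """Down-sample every cell to a common depth for comparable count values.

    The target depth is the ``depth_quantile`` quantile of per-cell totals
    (an observed total, lower interpolation).  Cells below the target are
    dropped; cells at exactly the target are retained unchanged; every
    other cell is replaced by a without-replacement draw of exactly the
    target number of molecules (multivariate hypergeometric over genes).
    """
    rng = np.random.default_rng(seed)
    totals = matrix.counts.sum(axis=0)
    target = int(np.quantile(totals, depth_quantile, method="lower"))
    if target <= 0:
        raise ValueError("target depth is zero; matrix too shallow to down-sample")
    keep = np.flatnonzero(totals >= target)
    sub = matrix.subset_cells(keep)
    out = np.empty_like(sub.counts)
    for j in range(sub.n_cells):
        out[:, j] = subsample_counts(rng, sub.counts[:, j], target)
    return CountMatrix(out, sub.gene_ids, sub.cell_ids)
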