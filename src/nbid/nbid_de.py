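"""NBID: negative binomial differential expression with independent
per-group dispersions.

For one gene with count ``y_i`` in cell ``i``, NBID models
``y_i ~ NB(n_i * mu_i, phi_{g_i})`` where ``n_i`` is the cell's size
factor (total UMIs by default), ``mu_i`` the gene's proportion and
``phi_{g_i}`` a dispersion private to the cell's group.  The mean model
is a log link::

    log(n_i * mu_i) = beta0 + beta1 * g_i + gamma' x_i

with ``log n_i`` entering as an offset.  The full model maximizes the
likelihood jointly over the coefficients and both group dispersions;
the null drops ``beta1`` but keeps each cell's dispersion fixed at its
group's full-model estimate.  Twice the log-likelihood difference is
referred to chi-square with one degree of freedom.

Allowing each group its own dispersion is the count-model analogue of
the unequal-variance t-test: with enough cells per group there is no
need to pool dispersion information across genes or groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, psi, xlogy
from scipy.stats import chi2

from .count_models import LOG_THETA_MAX, LOG_THETA_MIN
from .io_counts import CountMatrix, cell_totals, tpm_per_group
from .model_selection import bh_fdr

_B_MIN, _B_MAX = -35.0, 35.0


@dataclass
class DesignInfo:
    """Per-cell design: binary group labels, covariates, log offsets."""

    group: np.ndarray  # 0/1 per cell
    offsets: np.ndarray  # log size factor per cell
    covariates: np.ndarray | None = None  # cells x c

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if set(np.unique(self.group)) - {0, 1}:
            raise ValueError("group must be coded 0/1 for a pairwise test")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.group.shape[0]:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.group.shape[0]:
                raise ValueError("covariates must have one row per cell")

    @property
    def n_cells(self) -> int:
        return self.group.shape[0]

    def mean_design(self) -> np.ndarray:
        """Full-model design matrix: intercept, group, covariates."""
        cols = [np.ones(self.n_cells), self.group.astype(float)]
        if self.covariates is not None:
            cols.extend(self.covariates.T)
        return np.column_stack(cols)


@dataclass
class NbidFit:
    beta0: float
    beta1: float
    gamma: np.ndarray
    phi0: float
    phi1: float
    loglik: float
    converged: bool
    flag: str = "ok"


def _nb_ll(y, mu, theta):
    """NB log-likelihood; ``theta`` scalar or per-cell vector."""
    return float(
        np.sum(
            gammaln(theta + y)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + xlogy(y, mu)
            - (y + theta) * np.log(theta + mu)
            + theta * np.log(theta)
        )
    )


# ---------------------------------------------------------------------------
# fast path: no covariates -> the full model decouples by group


def _newton_intercept(y, e, theta, b0):
    """Maximize the fixed-theta NB log-likelihood over a single intercept.

    ``mu_i = e_i * exp(b)``; the log-likelihood is concave in ``b``.
    """
    b = b0
    sumy = y.sum()
    for _ in range(50):
        mu = e * math.exp(b)
        r = theta + mu
        g = sumy - ((y + theta) * mu / r).sum()
        h = -((y + theta) * theta * mu / r**2).sum()
        if h >= 0:
            break
        step = -g / h
        b = float(np.clip(b + step, _B_MIN, _B_MAX))
        if abs(step) < 1e-10:
            break
    return b


def _fit_group_profile(y, e):
    """MLE of (intercept, theta) for one group by profile likelihood."""
    sumy = y.sum()
    se = e.sum()
    if sumy == 0:
        b = _B_MIN
        ll = _nb_ll(y, e * math.exp(b), 1e8)
        return b, 1e8, ll, "separation"
    b_init = math.log(sumy / se)
    state = {"b": b_init}

    def neg_profile(lt):
        theta = math.exp(lt)
        b = _newton_intercept(y, e, theta, state["b"])
        state["b"] = b
        return -_nb_ll(y, e * math.exp(b), theta)

    res = minimize_scalar(
        neg_profile,
        bounds=(LOG_THETA_MIN, LOG_THETA_MAX),
        method="bounded",
        options={"xatol": 1e-4},
    )
    theta = math.exp(res.x)
    b = _newton_intercept(y, e, theta, state["b"])
    return b, theta, _nb_ll(y, e * math.exp(b), theta), "ok"


# ---------------------------------------------------------------------------
# general path: joint quasi-Newton over coefficients and log-dispersions


def _full_negloglik_grad(x, y, X, offsets, g0, g1, equal_disp):
    p = X.shape[1]
    beta = x[:p]
    if equal_disp:
        theta = np.full(y.size, math.exp(x[p]))
    else:
        theta = np.where(g1, math.exp(x[p + 1]), math.exp(x[p]))
    eta = offsets + X @ beta
    mu = np.exp(eta)
    r = theta + mu
    ll = np.sum(
        gammaln(theta + y)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + xlogy(y, mu)
        - (y + theta) * np.log(r)
        + theta * np.log(theta)
    )
    resid = y - (y + theta) * mu / r
    gbeta = X.T @ resid
    dtheta = psi(theta + y) - psi(theta) + np.log(theta / r) + 1.0 - (y + theta) / r
    if equal_disp:
        gtheta = np.array([np.sum(theta * dtheta)])
    else:
        gtheta = np.array([np.sum((theta * dtheta)[g0]), np.sum((theta * dtheta)[g1])])
    return -ll, -np.concatenate([gbeta, gtheta])


def fit_full(y, design: DesignInfo, equal_dispersions: bool = False) -> NbidFit:
    """Joint MLE of the full NBID model (coefficients + group dispersions)."""
    y = np.asarray(y, dtype=float)
    g1 = design.group == 1
    g0 = ~g1
    e = np.exp(design.offsets)
    if y.sum() == 0:
        return NbidFit(_B_MIN, 0.0, np.zeros(0), 0.0, 0.0,
                       _nb_ll(y, e * math.exp(_B_MIN), 1e8), True, "degenerate")

    if design.covariates is None and not equal_dispersions:
        b0g, th0, ll0, f0 = _fit_group_profile(y[g0], e[g0])
        b1g, th1, ll1, f1 = _fit_group_profile(y[g1], e[g1])
        flag = "ok" if f0 == f1 == "ok" else "separation"
        phi0 = 0.0 if th0 >= 1e8 * (1 - 1e-9) else 1.0 / th0
        phi1 = 0.0 if th1 >= 1e8 * (1 - 1e-9) else 1.0 / th1
        return NbidFit(
            beta0=b0g,
            beta1=b1g - b0g,
            gamma=np.zeros(0),
            phi0=phi0,
            phi1=phi1,
            loglik=ll0 + ll1,
            converged=True,
            flag=flag,
        )

    X = design.mean_design()
    p = X.shape[1]
    sep = y[g0].sum() == 0 or y[g1].sum() == 0
    beta_init = np.zeros(p)
    beta_init[0] = math.log(max(y.sum(), 0.5) / e.sum())
    m = y.mean()
    phi_mom = max((y.var() - m) / max(m**2, 1e-12), 1e-4)
    lt_init = float(np.clip(math.log(1.0 / phi_mom), LOG_THETA_MIN, LOG_THETA_MAX))
    n_disp = 1 if equal_dispersions else 2
    bounds = [(_B_MIN, _B_MAX)] * p + [(LOG_THETA_MIN, LOG_THETA_MAX)] * n_disp
    best = None
    for lt0 in {lt_init, 0.0}:
        x0 = np.concatenate([beta_init, np.full(n_disp, lt0)])
        res = minimize(
            _full_negloglik_grad,
            x0=x0,
            args=(y, X, design.offsets, g0, g1, equal_dispersions),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500},
        )
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res.x, bool(res.success))
    ll, x, ok = best
    theta0 = math.exp(x[p])
    theta1 = theta0 if equal_dispersions else math.exp(x[p + 1])
    phi0 = 0.0 if theta0 >= 1e8 * (1 - 1e-9) else 1.0 / theta0
    phi1 = 0.0 if theta1 >= 1e8 * (1 - 1e-9) else 1.0 / theta1
    return NbidFit(
        beta0=float(x[0]),
        beta1=float(x[1]),
        gamma=x[2:p].copy(),
        phi0=phi0,
        phi1=phi1,
        loglik=float(ll),
        converged=ok,
        flag="separation" if sep else "ok",
    )


def fit_null(y, design: DesignInfo, phi0: float, phi1: float) -> NbidFit:
    """Null-model MLE: ``beta1 = 0``, dispersions fixed from the full fit.

    With dispersions held fixed the log-likelihood is concave in the
    remaining coefficients, so a safeguarded Newton iteration suffices.
    """
    y = np.asarray(y, dtype=float)
    g1 = design.group == 1
    theta = np.where(g1, 1.0 / phi1 if phi1 > 0 else 1e8, 1.0 / phi0 if phi0 > 0 else 1e8)
    cols = [np.ones(design.n_cells)]
    if design.covariates is not None:
        cols.extend(design.covariates.T)
    Xn = np.column_stack(cols)
    p = Xn.shape[1]
    beta = np.zeros(p)
    e = np.exp(design.offsets)
    beta[0] = math.log(max(y.sum(), 0.5) / e.sum())
    ll = _nb_ll(y, np.exp(design.offsets + Xn @ beta), theta)
    for _ in range(100):
        mu = np.exp(np.clip(design.offsets + Xn @ beta, -700, 700))
        r = theta + mu
        grad = Xn.T @ (y - (y + theta) * mu / r)
        w = (y + theta) * theta * mu / r**2
        H = (Xn * w[:, None]).T @ Xn
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        for _ in range(30):  # step-halving safeguard
            cand = beta + step
            ll_new = _nb_ll(y, np.exp(np.clip(design.offsets + Xn @ cand, -700, 700)), theta)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = cand
        improved = ll_new - ll
        ll = ll_new
        if improved < 1e-10 and np.abs(step).max() < 1e-8:
            break
    return NbidFit(
        beta0=float(beta[0]),
        beta1=0.0,
        gamma=beta[1:].copy(),
        phi0=phi0,
        phi1=phi1,
        loglik=float(ll),
        converged=True,
    )


def nbid_gene_test(y, design: DesignInfo, equal_dispersions: bool = False) -> dict:
    """Full vs null LRT for one gene; 1 df chi-square p-value."""
    full = fit_full(y, design, equal_dispersions=equal_dispersions)
    null = fit_null(y, design, full.phi0, full.phi1)
    if not full.converged:
        return {
            "beta1": full.beta1, "phi0": full.phi0, "phi1": full.phi1,
            "loglik_full": full.loglik, "loglik_null": null.loglik,
            "lrt_stat": np.nan, "p": np.nan, "flag": "unconverged",
        }
    lrt = max(0.0, 2.0 * (full.loglik - null.loglik))
    return {
        "beta1": full.beta1,
        "phi0": full.phi0,
        "phi1": full.phi1,
        "loglik_full": full.loglik,
        "loglik_null": null.loglik,
        "lrt_stat": lrt,
        "p": float(chi2.sf(lrt, df=1)),
        "flag": full.flag,
    }


def run_nbid(
    matrix: CountMatrix,
    groups,
    covariates=None,
    size_factors=None,
    alpha: float = 0.05,
    min_nonzero_cells: int = 5,
) -> pd.DataFrame:
    """NBID differential expression over all genes of a matrix.

    ``groups`` may use any two labels; the smaller label (sorted order)
    becomes the reference group 0.  Offsets are ``log(size_factors)``
    when given, otherwise log total UMIs per cell; cells with zero total
    and no external size factor are dropped with a warning.  Genes with
    fewer than ``min_nonzero_cells`` nonzero cells are not tested.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != matrix.n_cells:
        raise ValueError("groups must label every cell")
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError("the pairwise test requires exactly two group labels")
    gbin = (groups == labels[1]).astype(int)

    if size_factors is not None:
        sf = np.asarray(size_factors, dtype=float)
        if np.any(sf <= 0):
            raise ValueError("size factors must be positive")
        keep = np.ones(matrix.n_cells, dtype=bool)
    else:
        totals = cell_totals(matrix).totals.astype(float)
        keep = totals > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} cells with zero total UMIs")
        sf = totals
    mat = matrix.subset_cells(np.flatnonzero(keep))
    sf = sf[keep]
    gbin = gbin[keep]
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != matrix.n_cells:
            cov = cov.T
        cov = cov[keep]
    design = DesignInfo(group=gbin, offsets=np.log(sf), covariates=cov)

    tpm = tpm_per_group(mat, gbin)
    tpm0 = tpm[0].to_numpy()
    tpm1 = tpm[1].to_numpy()
    nonzero = (mat.counts > 0).sum(axis=1)
    rows = []
    for g in range(mat.n_genes):
        if nonzero[g] < min_nonzero_cells:
            continue
        res = nbid_gene_test(mat.counts[g], design)
        rows.append(
            {
                "gene_id": mat.gene_ids[g],
                "log2_fold_change": res["beta1"] / math.log(2),
                "mean_tpm_group0": tpm0[g],
                "mean_tpm_group1": tpm1[g],
                "phi0": res["phi0"],
                "phi1": res["phi1"],
                "lrt_stat": res["lrt_stat"],
                "p": res["p"],
                "flag": res["flag"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "log2_fold_change", "mean_tpm_group0", "mean_tpm_group1",
            "phi0", "phi1", "lrt_stat", "p", "flag",
        ],
    )
    table["q"] = bh_fdr(table["p"]) if len(table) else np.nan
    return table
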