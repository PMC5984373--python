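"""Backward model selection per gene: ZINB vs NB, then NB vs Poisson.

Both comparisons test a parameter on the boundary of its space (the zero
mass pi0 = 0, or the dispersion phi = 0), so the likelihood-ratio
statistic is referred to an equal mixture of a point mass at zero and a
chi-square with one degree of freedom.  Decisions are made at an FDR
level via Benjamini-Hochberg, separately within each stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .count_models import fit_nb, fit_poisson, fit_zinb
from .io_counts import CountMatrix, filter_genes


def boundary_lrt_pvalue(loglik_null: float, loglik_alt: float) -> float:
    """P-value of a boundary LRT under the 0.5*chi2(0) + 0.5*chi2(1) null.

    The statistic ``D = max(0, 2*(loglik_alt - loglik_null))`` is clamped
    at zero (the alternative may lose likelihood by numerical slack); the
    p-value is 0.5 at D = 0 and ``0.5 * P(chi2_1 > D)`` beyond.
    """
    if np.isnan(loglik_null) or np.isnan(loglik_alt):
        return float("nan")
    d = max(0.0, 2.0 * (loglik_alt - loglik_null))
    return 0.5 if d == 0 else float(0.5 * chi2.sf(d, df=1))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing values are passed through untouched and do not enter the
    ranking denominator.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def select_models(
    matrix: CountMatrix,
    alpha: float = 0.05,
    delta: float = 0.5,
    min_nonzero_cells: int = 5,
) -> pd.DataFrame:
    """Fit Poisson/NB/ZINB per gene and run the two-stage backward selection.

    Genes whose fitted likelihoods violate the nesting order by more than
    ``delta`` (``L(Poisson) > L(NB) + delta`` or ``L(NB) > L(ZINB) + delta``)
    are marked unconverged and excluded from both BH pools.  Stage 1 tests
    ZINB against NB across converged genes; genes with q < alpha select
    ZINB.  Stage 2 tests NB against Poisson among the remaining genes.
    """
    filtered = filter_genes(matrix, min_nonzero_cells)
    rows = []
    for g in range(filtered.n_genes):
        y = filtered.counts[g]
        fp = fit_poisson(y)
        fn = fit_nb(y)
        fz = fit_zinb(y)
        converged = (
            fp.loglik <= fn.loglik + delta and fn.loglik <= fz.loglik + delta
        )
        rows.append(
            {
                "gene_id": filtered.gene_ids[g],
                "loglik_poisson": fp.loglik,
                "loglik_nb": fn.loglik,
                "loglik_zinb": fz.loglik,
                "converged": converged,
                "p_zinb_vs_nb": boundary_lrt_pvalue(fn.loglik, fz.loglik)
                if converged
                else np.nan,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "loglik_poisson",
            "loglik_nb",
            "loglik_zinb",
            "converged",
            "p_zinb_vs_nb",
        ],
    )
    n = len(table)
    table["q_zinb_vs_nb"] = bh_fdr(table["p_zinb_vs_nb"]) if n else np.nan
    table["p_nb_vs_poisson"] = np.nan
    table["q_nb_vs_poisson"] = np.nan
    table["selected"] = "unconverged"
    if n == 0:
        return table

    conv = table["converged"].to_numpy(bool)
    stage1_reject = conv & (table["q_zinb_vs_nb"].to_numpy() < alpha)
    table.loc[stage1_reject, "selected"] = "zinb"

    # stage 2 runs only on converged genes that did not reject the NB model
    stage2 = conv & ~stage1_reject
    p2 = np.full(n, np.nan)
    for i in np.flatnonzero(stage2):
        p2[i] = boundary_lrt_pvalue(
            table.at[i, "loglik_poisson"], table.at[i, "loglik_nb"]
        )
    table["p_nb_vs_poisson"] = p2
    table["q_nb_vs_poisson"] = bh_fdr(p2)
    q2 = table["q_nb_vs_poisson"].to_numpy()
    table.loc[stage2 & (q2 < alpha), "selected"] = "nb"
    table.loc[stage2 & ~(q2 < alpha), "selected"] = "poisson"
    return table


def summarize_selection(table: pd.DataFrame) -> dict:
    """Counts per selected family, mirroring the per-dataset summary rows."""
    n_tested = len(table)
    n_conv = int(table["converged"].sum()) if n_tested else 0
    counts = table["selected"].value_counts().to_dict() if n_tested else {}
    n_poisson = counts.get("poisson", 0)
    return {
        "genes_tested": n_tested,
        "genes_converged": n_conv,
        "zinb": counts.get("zinb", 0),
        "nb": counts.get("nb", 0),
        "poisson": n_poisson,
        "poisson_pct": 100.0 * n_poisson / n_tested if n_tested else float("nan"),
    }
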