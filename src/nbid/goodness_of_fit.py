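"""Binned chi-square goodness-of-fit for Poisson and NB fits.

Counts are first down-sampled to a common per-cell depth (so count values
are comparable across cells), each observed count value starts as its own
bin, and, scanning from the largest value downward, bins with no more
than ``min_cells`` cells are merged into the next smaller-valued bin.
The Pearson statistic is referred to chi-square with ``k - p - 1``
degrees of freedom, where ``k`` is the number of bins after merging and
``p`` the number of fitted parameters (1 for Poisson, 2 for NB); genes
whose support is too simple to leave at least one degree of freedom are
skipped, not tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, nbinom, poisson

from .count_models import ModelFit, downsample_cells, fit_nb, fit_poisson, nb_logpmf
from .io_counts import CountMatrix, filter_genes
from .model_selection import bh_fdr


@dataclass
class Binning:
    """Merged count-value bins: ``lower[i] <= value <= upper[i]`` per bin."""

    lower: np.ndarray  # inclusive lower integer edge; lower[0] == 0
    upper: np.ndarray  # inclusive upper edge; upper[-1] is open (tail)
    observed: np.ndarray  # cells per bin

    @property
    def k(self) -> int:
        return len(self.observed)


def build_bins(y, min_cells: int = 5) -> Binning:
    """Bin observed count values, merging sparse bins downward.

    Each unique observed value forms an initial bin.  Scanning from the
    largest value, any bin holding no more than ``min_cells`` cells is
    combined with the next smaller-valued bin; the accumulated bin keeps
    merging until it exceeds ``min_cells``.  The smallest-valued bin is
    left as-is even if it ends up with few cells.  Bin edges are then
    widened to partition the whole integer support: the first bin starts
    at 0 and the last is an upper tail.
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty count vector")
    values, counts = np.unique(y, return_counts=True)
    merged: list[tuple[int, int, int]] = []  # (low_value, high_value, cells)
    acc_cells = 0
    acc_high = None
    for v, c in zip(values[::-1], counts[::-1]):
        acc_cells += int(c)
        if acc_high is None:
            acc_high = int(v)
        if acc_cells > min_cells:
            merged.append((int(v), acc_high, acc_cells))
            acc_cells = 0
            acc_high = None
    if acc_high is not None:
        # the smallest-valued bin is left as-is even when sparse
        merged.append((int(values[0]), acc_high, acc_cells))
    merged.reverse()
    lower = np.array([m[0] for m in merged], dtype=np.int64)
    upper = np.array([m[1] for m in merged], dtype=np.int64)
    observed = np.array([m[2] for m in merged], dtype=np.int64)
    # widen to a partition of {0, 1, 2, ...}
    lower[0] = 0
    if len(lower) > 1:
        upper[:-1] = lower[1:] - 1
    return Binning(lower=lower, upper=upper, observed=observed)


def _bin_cdf(fit: ModelFit, x: np.ndarray) -> np.ndarray:
    if fit.family == "poisson" or fit.dispersion == 0:
        return poisson.cdf(x, fit.mean)
    theta = 1.0 / fit.dispersion
    return nbinom.cdf(x, theta, theta / (theta + fit.mean))


def expected_bin_probs(fit: ModelFit, binning: Binning) -> np.ndarray:
    """Model probability of each bin; the top bin absorbs the upper tail."""
    upper_cdf = _bin_cdf(fit, binning.upper.astype(float))
    upper_cdf[-1] = 1.0  # tail closure
    lower_cdf = np.concatenate([[0.0], upper_cdf[:-1]])
    return upper_cdf - lower_cdf


def chisq_gof(y, fit: ModelFit, min_cells: int = 5):
    """Pearson chi-square GOF of ``fit`` on counts ``y``.

    Returns a dict with the binning size ``k``, degrees of freedom
    ``df = k - p - 1``, the statistic and p-value; genes with ``df < 1``
    are returned with decision ``skipped`` and no p-value.
    """
    y = np.asarray(y)
    p_model = 1 if fit.family == "poisson" else 2
    binning = build_bins(y, min_cells=min_cells)
    df = binning.k - p_model - 1
    if df < 1:
        return {
            "family": fit.family,
            "k": binning.k,
            "p_model": p_model,
            "df": df,
            "statistic": np.nan,
            "p": np.nan,
            "decision": "skipped",
        }
    probs = expected_bin_probs(fit, binning)
    n = y.size
    expected = n * probs
    if np.any(expected <= 0):
        return {
            "family": fit.family,
            "k": binning.k,
            "p_model": p_model,
            "df": df,
            "statistic": np.nan,
            "p": np.nan,
            "decision": "skipped",
        }
    stat = float(((binning.observed - expected) ** 2 / expected).sum())
    return {
        "family": fit.family,
        "k": binning.k,
        "p_model": p_model,
        "df": df,
        "statistic": stat,
        "p": float(chi2.sf(stat, df=df)),
        "decision": "tested",
    }


def run_gof(
    matrix: CountMatrix,
    alpha: float = 0.05,
    seed: int | None = None,
    depth_quantile: float = 0.10,
    min_nonzero_cells: int = 6,
    min_cells_per_bin: int = 5,
) -> pd.DataFrame:
    """Down-sample, fit Poisson and NB per gene, and test both fits.

    Pipeline: down-sample every cell to the ``depth_quantile`` total-UMI
    quantile (cells below it are dropped), keep genes with a nonzero
    count in more than five cells (``min_nonzero_cells = 6``), fit both
    families per gene, compute the binned chi-square for each, and BH
    adjust within each family.  ``accept``/``reject`` is at FDR ``alpha``.
    """
    down = downsample_cells(matrix, depth_quantile=depth_quantile, seed=seed)
    kept = filter_genes(down, min_nonzero_cells)
    rows = []
    for g in range(kept.n_genes):
        y = kept.counts[g]
        for fit in (fit_poisson(y), fit_nb(y)):
            rec = chisq_gof(y, fit, min_cells=min_cells_per_bin)
            rec["gene_id"] = kept.gene_ids[g]
            rows.append(rec)
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "family", "k", "p_model", "df", "statistic", "p", "decision"],
    )
    table["q"] = np.nan
    for fam in ("poisson", "nb"):
        mask = (table["family"] == fam).to_numpy()
        table.loc[mask, "q"] = bh_fdr(table.loc[mask, "p"])
    tested = table["decision"] == "tested"
    table.loc[tested & (table["q"] < alpha), "decision"] = "reject"
    table.loc[tested & ~(table["q"] < alpha), "decision"] = "accept"
    return table


def summarize_gof(table: pd.DataFrame) -> dict:
    """Per-family accept/reject counts over tested genes."""
    out = {}
    for fam in ("poisson", "nb"):
        sub = table[(table["family"] == fam) & (table["decision"] != "skipped")]
        n = len(sub)
        rej = int((sub["decision"] == "reject").sum())
        out[f"{fam}_tested"] = n
        out[f"{fam}_reject"] = rej
        out[f"{fam}_reject_pct"] = 100.0 * rej / n if n else float("nan")
        out[f"{fam}_accept_pct"] = 100.0 * (n - rej) / n if n else float("nan")
    return out


def empirical_vs_theoretical(y, fit: ModelFit) -> pd.DataFrame:
    """Paired empirical and model pmf/cdf per observed count value."""
    y = np.asarray(y)
    values, counts = np.unique(y, return_counts=True)
    emp_pmf = counts / y.size
    emp_cdf = np.cumsum(emp_pmf)
    if fit.family == "zinb":
        raise ValueError("pmf/cdf comparison supports poisson and nb fits")
    theo_pmf = np.exp(nb_logpmf(values, fit.mean, fit.dispersion))
    theo_cdf = _bin_cdf(fit, values.astype(float))
    return pd.DataFrame(
        {
            "value": values,
            "empirical_pmf": emp_pmf,
            "theoretical_pmf": theo_pmf,
            "empirical_cdf": emp_cdf,
            "theoretical_cdf": theo_cdf,
        }
    )
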