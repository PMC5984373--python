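"""Scoring DE calls against simulation truth.

Realized FDR at a q-value threshold, precision-recall curves, the
restricted PR-AUC (area counted only where precision exceeds a floor,
i.e. where the realized FDR is acceptably low), and replicate
averaging.  The harness is method-agnostic: any table of per-gene
p/q-values keyed by gene id can be scored, so externally produced
results are evaluated exactly like NBID's own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PRSummary:
    precision_points: np.ndarray = field(default_factory=lambda: np.zeros(0))
    recall_points: np.ndarray = field(default_factory=lambda: np.zeros(0))
    auc_restricted: float = float("nan")
    realized_fdr: float = float("nan")
    n_called: int = 0
    n_false: int = 0
    failed: bool = False


def realized_fdr(qvalues, gene_ids, truth_genes, alpha: float = 0.05):
    """Fraction of q < alpha calls that are not true DE genes.

    Returns ``(fdr, n_false, n_called)``; an empty call set has FDR 0 by
    convention.
    """
    q = np.asarray(qvalues, dtype=float)
    gene_ids = np.asarray(gene_ids)
    truth = set(truth_genes)
    called = gene_ids[~np.isnan(q) & (q < alpha)]
    n_called = called.size
    n_false = int(sum(g not in truth for g in called))
    fdr = n_false / n_called if n_called else 0.0
    return fdr, n_false, n_called


def pr_curve(pvalues, gene_ids, truth_genes) -> PRSummary:
    """Precision/recall at every distinct p-value threshold.

    The call set at a threshold contains every gene with p <= that
    value, so tied p-values enter and leave together.  Missing p-values
    are non-calls at every threshold.
    """
    p = np.asarray(pvalues, dtype=float)
    gene_ids = np.asarray(gene_ids)
    truth = set(truth_genes)
    ok = ~np.isnan(p)
    p, gene_ids = p[ok], gene_ids[ok]
    n_pos = len(truth)
    if p.size == 0 or n_pos == 0:
        return PRSummary()
    order = np.argsort(p, kind="mergesort")
    p, gene_ids = p[order], gene_ids[order]
    is_true = np.array([g in truth for g in gene_ids])
    tp = np.cumsum(is_true)
    called = np.arange(1, p.size + 1)
    # keep only the last index of each run of tied p-values
    last_of_tie = np.r_[p[1:] != p[:-1], True]
    precision = tp[last_of_tie] / called[last_of_tie]
    recall = tp[last_of_tie] / n_pos
    return PRSummary(precision_points=precision, recall_points=recall)


def auc_restricted(curve: PRSummary, precision_floor: float = 0.8) -> float:
    """Trapezoid area under the PR curve where precision > the floor.

    Segments whose endpoints both clear the floor contribute their full
    trapezoid; all other segments contribute nothing.  A perfect curve
    (precision 1 everywhere) scores its entire recalled area, and a
    curve that never exceeds the floor scores 0.
    """
    prec = np.concatenate([[1.0], curve.precision_points])
    rec = np.concatenate([[0.0], curve.recall_points])
    if prec.size < 2:
        return 0.0
    above = prec > precision_floor
    seg = above[1:] & above[:-1]
    widths = np.diff(rec)
    heights = 0.5 * (prec[1:] + prec[:-1])
    return float(np.sum(widths[seg] * heights[seg]))


def auc_full(curve: PRSummary) -> float:
    """Unrestricted trapezoid PR-AUC (floor 0)."""
    return auc_restricted(curve, precision_floor=0.0)


def score_replicate(
    results: pd.DataFrame,
    truth_genes,
    alpha: float = 0.05,
    precision_floor: float = 0.8,
) -> PRSummary:
    """Score one replicate's DE table (columns gene_id, p, q)."""
    curve = pr_curve(results["p"], results["gene_id"], truth_genes)
    fdr, n_false, n_called = realized_fdr(
        results["q"], results["gene_id"], truth_genes, alpha=alpha
    )
    curve.auc_restricted = auc_restricted(curve, precision_floor)
    curve.realized_fdr = fdr
    curve.n_false = n_false
    curve.n_called = n_called
    return curve


def summarize_replicates(per_replicate: list[PRSummary]) -> dict:
    """Average FDR/AUC/counts over replicates, dropping failed ones."""
    if not per_replicate:
        raise ValueError("no replicates to summarize")
    ok = [r for r in per_replicate if not r.failed]
    n_failed = len(per_replicate) - len(ok)
    if not ok:
        return {"n_replicates": 0, "n_failed": n_failed}
    return {
        "n_replicates": len(ok),
        "n_failed": n_failed,
        "mean_fdr": float(np.mean([r.realized_fdr for r in ok])),
        "sd_fdr": float(np.std([r.realized_fdr for r in ok], ddof=1)) if len(ok) > 1 else 0.0,
        "mean_false": float(np.mean([r.n_false for r in ok])),
        "mean_called": float(np.mean([r.n_called for r in ok])),
        "mean_auc_restricted": float(np.nanmean([r.auc_restricted for r in ok])),
    }
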