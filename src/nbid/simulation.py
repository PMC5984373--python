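"""Synthetic UMI matrices and semi-synthetic DE benchmarks.

Three building blocks:

* :func:`generate_nb_matrix` draws a droplet-like NB count matrix with
  gene-specific mean proportions and dispersions and cell-specific
  depths (the stand-in for a real UMI matrix).
* :func:`simulate_swap_de` creates true differential expression by
  exchanging the count rows of two expression-matched 50-gene sets in
  one group only — per-cell totals and the marginal count structure are
  untouched, so every distributional quirk of the base matrix survives.
* :func:`thin_counts` sub-samples molecules without replacement to
  emulate group differences in captured UMIs per cell, and
  :func:`simulate_batch_confounded` assembles groups with unequal
  replicate composition and restricts true DE genes to batch-neutral
  ones (batch-comparison p > 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .count_models import subsample_counts
from .io_counts import CountMatrix

# batch compositions: (group1 from A, group1 from B, group2 from A, group2 from B)
# reference group 9A + 21B; second group either 18A + 22B or 18A + 12B
BATCH_COMPOSITION_PRESETS = {
    "g2_18a_22b": (9, 21, 18, 22),
    "g2_18a_12b": (9, 21, 18, 12),
}


@dataclass
class SimTruth:
    """Ground truth of a simulated DE dataset."""

    de_genes: list[str]
    swap_pairs: list[tuple[str, str]]
    t: float
    fc: float
    group_assignment: np.ndarray
    thinning_ratio_range: tuple[float, float] | None = None
    batch_assignment: np.ndarray | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def generate_nb_matrix(
    n_genes: int = 2000,
    n_cells: int = 1000,
    mean_log_params: tuple[float, float] = (0.0, 1.5),
    dispersion_params: tuple[float, float] = (2.0, 0.15),
    median_depth: float = 1000.0,
    depth_variation: float = 0.3,
    seed: int | None = None,
):
    """Draw an NB count matrix emulating droplet scRNA-seq.

    Gene mean-proportions are log-normal (``mean_log_params`` is the
    location/scale of the underlying normal; proportions are normalized
    to sum to 1 so a cell's expected total equals its depth).  Gene
    dispersions are gamma with (shape, scale) ``dispersion_params``.
    Cell depths are log-normal around ``median_depth`` with log-scale
    standard deviation ``depth_variation`` (0 gives constant depths).
    Counts are ``NB(depth_c * prop_g, phi_g)`` drawn gamma-Poisson.

    Returns ``(CountMatrix, params)`` where ``params`` carries the
    generating proportions, dispersions and depths for recovery tests.
    """
    rng = np.random.default_rng(seed)
    props = rng.lognormal(mean_log_params[0], mean_log_params[1], size=n_genes)
    props /= props.sum()
    phis = rng.gamma(dispersion_params[0], dispersion_params[1], size=n_genes)
    if depth_variation > 0:
        depths = median_depth * rng.lognormal(0.0, depth_variation, size=n_cells)
    else:
        depths = np.full(n_cells, float(median_depth))
    mu = props[:, None] * depths[None, :]
    shape = 1.0 / phis
    lam = rng.gamma(shape[:, None], (mu * phis[:, None]))
    counts = rng.poisson(lam)
    matrix = CountMatrix(
        counts,
        gene_ids=[f"gene{i}" for i in range(n_genes)],
        cell_ids=[f"cell{j}" for j in range(n_cells)],
    )
    params = {"proportions": props, "dispersions": phis, "depths": depths}
    return matrix, params


def generate_replicate_pair(
    n_genes: int = 1000,
    n_cells: int = 150,
    median_depth: float = 5000.0,
    depth_variation: float = 0.3,
    mean_log_params: tuple[float, float] = (0.0, 1.5),
    dispersion_params: tuple[float, float] = (2.0, 0.15),
    shift_frac: float = 0.3,
    shift_log_sd: float = np.log(3),
    seed: int | None = None,
):
    """Two synthetic replicates with a known gene-wise batch shift.

    Both replicates share gene proportions and dispersions; a random
    ``shift_frac`` of genes have their proportion multiplied in
    replicate B by a log-normal factor (log-sd ``shift_log_sd``).  The
    factors are rescaled so the shifted genes' total proportion mass is
    unchanged — this keeps unshifted genes exactly batch-neutral after
    per-cell total-count normalization, which a naive one-sided shift
    would destroy (renormalization would drag every gene along).

    Returns ``(rep_a, rep_b, shifted_mask)``.
    """
    rng = np.random.default_rng(seed)
    props = rng.lognormal(mean_log_params[0], mean_log_params[1], n_genes)
    props /= props.sum()
    phis = rng.gamma(dispersion_params[0], dispersion_params[1], n_genes)
    shifted = rng.random(n_genes) < shift_frac
    fac = np.ones(n_genes)
    fac[shifted] = np.exp(rng.normal(0.0, shift_log_sd, int(shifted.sum())))
    mass = props[shifted].sum()
    fac[shifted] *= mass / (props[shifted] * fac[shifted]).sum()
    mats = []
    for rep_props in (props, props * fac):
        depths = median_depth * rng.lognormal(0.0, depth_variation, n_cells)
        mu = rep_props[:, None] * depths[None, :]
        lam = rng.gamma((1.0 / phis)[:, None], mu * phis[:, None])
        mats.append(rng.poisson(lam))
    gids = [f"gene{i}" for i in range(n_genes)]
    rep_a = CountMatrix(mats[0], gids, [f"a{j}" for j in range(n_cells)])
    rep_b = CountMatrix(mats[1], gids, [f"b{j}" for j in range(n_cells)])
    return rep_a, rep_b, shifted


def _pick_set(order_means, order_idx, threshold, n, exclude):
    """First ``n`` genes (ascending mean) strictly above ``threshold``."""
    picked = []
    for mean, idx in zip(order_means, order_idx):
        if idx in exclude:
            continue
        if mean > threshold:
            picked.append(idx)
            if len(picked) == n:
                return picked
    raise ValueError(
        f"not enough genes with average count above {threshold}: "
        f"needed {n}, found {len(picked)}"
    )


def simulate_swap_de(
    matrix: CountMatrix,
    n_group1: int,
    n_group2: int,
    t: float,
    fc: float,
    n_pairs: int = 50,
    seed: int | None = None,
    eligible_genes=None,
    group_assignment=None,
):
    """Create true DE by swapping two expression-matched gene sets.

    Cells are sampled without replacement and split randomly into two
    groups.  Genes are ranked by average count in group 2; set A is the
    ``n_pairs`` genes with average just above ``t`` and set B the
    ``n_pairs`` genes with average just above ``fc * t``.  The rows of A
    and B are exchanged pairwise in group-2 cells only, giving
    ``2 * n_pairs`` true DE genes with fold changes near ``fc`` and
    ``1/fc`` while conserving every group-2 cell's total.

    ``eligible_genes`` optionally restricts the candidate genes (used by
    the batch-confounded design to enforce batch neutrality), and
    ``group_assignment`` fixes a predetermined per-cell split instead of
    the random sample-and-split (then all cells are used in order).
    """
    if fc <= 1:
        raise ValueError("fc must be > 1")
    if n_group1 + n_group2 > matrix.n_cells:
        raise ValueError("not enough cells for the requested group sizes")
    rng = np.random.default_rng(seed)
    if group_assignment is not None:
        groups = np.asarray(group_assignment, dtype=int)
        if groups.shape[0] != matrix.n_cells:
            raise ValueError("group_assignment must label every cell")
        cells = np.arange(matrix.n_cells)
        sub = matrix
    else:
        chosen = rng.choice(matrix.n_cells, size=n_group1 + n_group2, replace=False)
        cells = chosen[rng.permutation(n_group1 + n_group2)]
        sub = matrix.subset_cells(cells)
        groups = np.concatenate([np.zeros(n_group1, int), np.ones(n_group2, int)])

    g2 = sub.counts[:, groups == 1]
    means2 = g2.mean(axis=1)
    order = np.argsort(means2, kind="mergesort")  # ties broken by gene index
    order_means = means2[order]
    if eligible_genes is not None:
        eligible = set(
            np.flatnonzero(np.isin(np.array(sub.gene_ids), list(eligible_genes)))
        )
        mask = np.array([i in eligible for i in order])
        order, order_means = order[mask], order_means[mask]
    set_a = _pick_set(order_means, order, t, n_pairs, exclude=set())
    set_b = _pick_set(order_means, order, fc * t, n_pairs, exclude=set(set_a))

    counts = sub.counts.copy()
    cols = np.flatnonzero(groups == 1)
    for a, b in zip(set_a, set_b):
        rows_a = counts[a, cols].copy()
        counts[a, cols] = counts[b, cols]
        counts[b, cols] = rows_a
    swapped = CountMatrix(counts, sub.gene_ids, sub.cell_ids)
    pairs = [(sub.gene_ids[a], sub.gene_ids[b]) for a, b in zip(set_a, set_b)]
    truth = SimTruth(
        de_genes=[g for pair in pairs for g in pair],
        swap_pairs=pairs,
        t=t,
        fc=fc,
        group_assignment=groups,
        seed=seed,
        extra={"cells": cells},
    )
    return swapped, truth


def thin_counts(matrix: CountMatrix, cells, ratio_range, seed: int | None = None) -> CountMatrix:
    """Sub-sample the molecules of selected cells without replacement.

    Each selected cell draws its own retention ratio uniformly from
    ``ratio_range`` and keeps ``round(ratio * total)`` molecules (a
    multivariate hypergeometric draw over genes).
    """
    lo, hi = ratio_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("ratio_range must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    cells = np.asarray(cells)
    out = matrix.counts.copy()
    for j in cells:
        ratio = rng.uniform(lo, hi)
        total = int(out[:, j].sum())
        nsample = int(round(ratio * total))
        out[:, j] = subsample_counts(rng, out[:, j], nsample)
    return CountMatrix(out, matrix.gene_ids, matrix.cell_ids)


def simulate_batch_confounded(
    rep_a: CountMatrix,
    rep_b: CountMatrix,
    composition: tuple[int, int, int, int],
    t: float,
    fc: float,
    n_pairs: int = 25,
    neutral_pvalues=None,
    neutral_threshold: float = 0.5,
    seed: int | None = None,
):
    """Assemble a batch-confounded two-group design with batch-neutral DE.

    ``composition = (a1, b1, a2, b2)``: group 1 takes ``a1`` cells from
    replicate A and ``b1`` from replicate B; group 2 takes ``a2`` and
    ``b2``.  Candidate DE genes are restricted to those whose
    between-replicate comparison has p > ``neutral_threshold``
    (``neutral_pvalues`` maps gene id to that p-value; computed here via
    NBID on the two full replicates when not supplied), so detecting a
    true DE gene can never amount to detecting the batch.  Batch labels
    are attached to the truth for covariate adjustment.
    """
    if rep_a.gene_ids != rep_b.gene_ids:
        raise ValueError("replicates must share a gene universe")
    a1, b1, a2, b2 = composition
    if a1 + a2 > rep_a.n_cells or b1 + b2 > rep_b.n_cells:
        raise ValueError("not enough cells in the replicates for the composition")
    rng = np.random.default_rng(seed)

    if neutral_pvalues is None:
        from .nbid_de import run_nbid

        merged = CountMatrix(
            np.concatenate([rep_a.counts, rep_b.counts], axis=1),
            rep_a.gene_ids,
            [f"A_{c}" for c in rep_a.cell_ids] + [f"B_{c}" for c in rep_b.cell_ids],
        )
        batch_de = run_nbid(
            merged, np.array([0] * rep_a.n_cells + [1] * rep_b.n_cells)
        )
        neutral_pvalues = dict(zip(batch_de["gene_id"], batch_de["p"]))
    neutral = [g for g, p in neutral_pvalues.items() if p > neutral_threshold]
    if len(neutral) < 2 * n_pairs:
        raise ValueError(
            f"only {len(neutral)} batch-neutral genes; need {2 * n_pairs}"
        )

    ia = rng.choice(rep_a.n_cells, size=a1 + a2, replace=False)
    ib = rng.choice(rep_b.n_cells, size=b1 + b2, replace=False)
    cols = np.concatenate(
        [
            rep_a.counts[:, ia[:a1]],
            rep_b.counts[:, ib[:b1]],
            rep_a.counts[:, ia[a1:]],
            rep_b.counts[:, ib[b1:]],
        ],
        axis=1,
    )
    cell_ids = (
        [f"g1A_{k}" for k in range(a1)]
        + [f"g1B_{k}" for k in range(b1)]
        + [f"g2A_{k}" for k in range(a2)]
        + [f"g2B_{k}" for k in range(b2)]
    )
    assembled = CountMatrix(cols, rep_a.gene_ids, cell_ids)
    groups = np.array([0] * (a1 + b1) + [1] * (a2 + b2))
    batch = np.array([0] * a1 + [1] * b1 + [0] * a2 + [1] * b2)

    swapped, truth = simulate_swap_de(
        assembled,
        n_group1=a1 + b1,
        n_group2=a2 + b2,
        t=t,
        fc=fc,
        n_pairs=n_pairs,
        seed=int(rng.integers(2**31 - 1)),
        eligible_genes=neutral,
        group_assignment=groups,
    )
    truth.batch_assignment = batch
    truth.extra["neutral_genes"] = neutral
    return swapped, truth
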