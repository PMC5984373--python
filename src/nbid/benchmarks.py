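"""Replicated benchmark scenarios composing the simulation, DE and
evaluation pipelines.

These are the study conditions used throughout the package's own
validation: a droplet-like NB base matrix, gene-swap DE with and
without per-cell UMI thinning in the second group, a pure-null
calibration design, and a batch-confounded design with and without
covariate adjustment.  Each function derives one sub-seed per replicate
from a single master seed (all below 2**31), so runs are reproducible
end to end.
"""

from __future__ import annotations

import numpy as np

from .evaluation import PRSummary, score_replicate
from .model_selection import bh_fdr
from .nbid_de import run_nbid
from .simulation import (
    generate_nb_matrix,
    generate_replicate_pair,
    simulate_batch_confounded,
    simulate_swap_de,
    thin_counts,
)

# swap-DE study conditions: droplet-scale base matrix, two groups of 500
SWAP_DEFAULTS = dict(
    n_genes=2000,
    n_cells=1000,
    median_depth=1000.0,
    n_group=500,
    t=0.5,
    fc=4.0,
    n_pairs=50,
)

THINNING_SCENARIOS = {"none": None, "mild": (0.8, 0.9), "intermediate": (0.5, 0.6)}


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=3 * n).reshape(n, 3)


def swap_fdr_replicate(
    seed_triplet,
    thinning_range=None,
    alpha: float = 0.05,
    **overrides,
) -> PRSummary:
    """One swap-DE replicate: simulate, (optionally) thin, test, score."""
    cfg = {**SWAP_DEFAULTS, **overrides}
    s_base, s_swap, s_thin = (int(s) for s in seed_triplet)
    base, _ = generate_nb_matrix(
        n_genes=cfg["n_genes"],
        n_cells=cfg["n_cells"],
        median_depth=cfg["median_depth"],
        seed=s_base,
    )
    sim, truth = simulate_swap_de(
        base,
        n_group1=cfg["n_group"],
        n_group2=cfg["n_group"],
        t=cfg["t"],
        fc=cfg["fc"],
        n_pairs=cfg["n_pairs"],
        seed=s_swap,
    )
    if thinning_range is not None:
        group2 = np.flatnonzero(truth.group_assignment == 1)
        sim = thin_counts(sim, group2, thinning_range, seed=s_thin)
        truth.thinning_ratio_range = tuple(thinning_range)
    table = run_nbid(sim, truth.group_assignment, alpha=alpha)
    return score_replicate(table, truth.de_genes, alpha=alpha)


def swap_fdr_benchmark(
    seed: int,
    n_replicates: int = 20,
    scenarios=None,
    alpha: float = 0.05,
    **overrides,
) -> dict[str, list[PRSummary]]:
    """Replicated realized-FDR benchmark over the thinning scenarios."""
    scenarios = THINNING_SCENARIOS if scenarios is None else scenarios
    seeds = _spawn_seeds(seed, n_replicates)
    out: dict[str, list[PRSummary]] = {}
    for name, rng_range in scenarios.items():
        out[name] = [
            swap_fdr_replicate(seeds[r], thinning_range=rng_range, alpha=alpha, **overrides)
            for r in range(n_replicates)
        ]
    return out


def null_pvalues(
    seed: int,
    n_genes: int = 2000,
    n_cells_per_group: int = 300,
    median_depth: float = 1000.0,
) -> np.ndarray:
    """NBID p-values under a pure null: no swaps, equal expected depths."""
    base, _ = generate_nb_matrix(
        n_genes=n_genes,
        n_cells=2 * n_cells_per_group,
        median_depth=median_depth,
        seed=seed,
    )
    groups = np.r_[
        np.zeros(n_cells_per_group, int), np.ones(n_cells_per_group, int)
    ]
    table = run_nbid(base, groups)
    return table["p"].to_numpy()


# batch benchmark conditions: the confounded composition proportions
# (9:21 vs 18:12) scaled 8x so each group is large enough for stable
# per-group dispersion estimates; deep plate-protocol-like cells.
BATCH_DEFAULTS = dict(
    n_genes=1000,
    n_cells=280,
    median_depth=5000.0,
    composition=(72, 168, 144, 96),
    t=1.0,
    fc=6.0,
    n_pairs=25,
    tpm_threshold=50.0,
)


def batch_fdr_replicate(
    seed_triplet,
    adjust: bool,
    alpha: float = 0.05,
    **overrides,
) -> PRSummary:
    """One batch-confounded replicate, with or without the batch covariate.

    High-expression filtering (TPM >= ``tpm_threshold`` in at least one
    group) is applied before BH adjustment, mirroring the evaluation of
    confounded small-sample designs on well-measured genes.
    """
    cfg = {**BATCH_DEFAULTS, **overrides}
    s_rep, s_sim, _ = (int(s) for s in seed_triplet)
    rep_a, rep_b, _ = generate_replicate_pair(
        n_genes=cfg["n_genes"],
        n_cells=cfg["n_cells"],
        median_depth=cfg["median_depth"],
        seed=s_rep,
    )
    sim, truth = simulate_batch_confounded(
        rep_a,
        rep_b,
        composition=cfg["composition"],
        t=cfg["t"],
        fc=cfg["fc"],
        n_pairs=cfg["n_pairs"],
        seed=s_sim,
    )
    cov = truth.batch_assignment.astype(float) if adjust else None
    table = run_nbid(sim, truth.group_assignment, covariates=cov, alpha=alpha)
    thr = cfg["tpm_threshold"]
    table = table[
        (table["mean_tpm_group0"] >= thr) | (table["mean_tpm_group1"] >= thr)
    ].copy()
    table["q"] = bh_fdr(table["p"])
    return score_replicate(table, truth.de_genes, alpha=alpha)


def batch_fdr_benchmark(
    seed: int, n_replicates: int = 20, alpha: float = 0.05, **overrides
) -> dict[str, list[PRSummary]]:
    """Replicated batch-confounded FDR benchmark, adjusted and not."""
    seeds = _spawn_seeds(seed, n_replicates)
    return {
        "unadjusted": [
            batch_fdr_replicate(seeds[r], adjust=False, alpha=alpha, **overrides)
            for r in range(n_replicates)
        ],
        "adjusted": [
            batch_fdr_replicate(seeds[r], adjust=True, alpha=alpha, **overrides)
            for r in range(n_replicates)
        ],
    }
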