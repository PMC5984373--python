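"""Batch confounding and covariate adjustment.

Two synthetic replicates share gene parameters except for a known
gene-wise batch shift.  Groups are assembled with unequal replicate
composition (group 1: 9:21 A:B proportions, group 2: 18:12), so the
batch difference masquerades as a group difference.  True DE genes are
restricted to batch-neutral genes (between-replicate p > 0.5) before
swapping, so they are detectable without detecting the batch.

Running NBID with and without the batch label as a covariate shows the
inflated FDR of the unadjusted analysis and its repair by adjustment.
"""

import numpy as np

import nbid

rep_a, rep_b, shifted = nbid.generate_replicate_pair(
    n_genes=800, n_cells=200, median_depth=5000, seed=41
)
sim, truth = nbid.simulate_batch_confounded(
    rep_a, rep_b, composition=(36, 84, 72, 48), t=1.0, fc=6.0, n_pairs=25, seed=42
)

for label, cov in (
    ("without batch covariate", None),
    ("with batch covariate   ", truth.batch_assignment.astype(float)),
):
    table = nbid.run_nbid(sim, truth.group_assignment, covariates=cov)
    # evaluate on well-measured genes (TPM >= 50 in at least one group)
    table = table[
        (table["mean_tpm_group0"] >= 50) | (table["mean_tpm_group1"] >= 50)
    ].copy()
    table["q"] = nbid.bh_fdr(table["p"])
    s = nbid.score_replicate(table, truth.de_genes)
    print(f"{label}: called {s.n_called:3d}, false {s.n_false:3d}, "
          f"realized FDR {s.realized_fdr:.3f}")
# the unadjusted FDR should be far above 0.05; adjustment restores it
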