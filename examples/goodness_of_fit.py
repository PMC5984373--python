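"""Binned chi-square goodness of fit on down-sampled counts.

Cells are first down-sampled without replacement to the 10% quantile of
total UMIs so count values are comparable across cells, then Poisson
and NB fits are tested per gene with a Pearson chi-square over merged
count-value bins (df = k - p - 1).  On NB-generated data the NB model
should almost never be rejected while Poisson is rejected for
overdispersed genes.
"""

import nbid

matrix, params = nbid.generate_nb_matrix(
    n_genes=300, n_cells=400, median_depth=2000, seed=11
)
table = nbid.run_gof(matrix, alpha=0.05, seed=11)
summary = nbid.summarize_gof(table)

print(f"Poisson: tested {summary['poisson_tested']}, "
      f"accepted {summary['poisson_accept_pct']:.1f}%")
print(f"NB:      tested {summary['nb_tested']}, "
      f"rejected {summary['nb_reject_pct']:.1f}%")

# paired empirical vs fitted pmf/cdf for one moderately expressed gene
from nbid import downsample_cells, empirical_vs_theoretical, fit_nb

down = downsample_cells(matrix, seed=11)
gene = int(down.counts.mean(axis=1).argmax())
fit = fit_nb(down.counts[gene])
pair = empirical_vs_theoretical(down.counts[gene], fit)
print(f"\n{down.gene_ids[gene]} (mu={fit.mean:.2f}, phi={fit.dispersion:.2f}):")
print(pair.head(8).to_string(index=False))
# empirical and theoretical pmf columns should track each other closely
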