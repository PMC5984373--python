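# Methods

## Count models

For one gene, the count `y_i` in cell `i` is modeled as Poisson(mu), as
negative binomial NB(mu, phi) with variance `mu + phi*mu^2` (`theta =
1/phi` is the size parameter), or as zero-inflated NB: a point mass at
zero with weight `pi0` mixed with an NB component.  The three families
are nested, Poisson ⊂ NB ⊂ ZINB, with 1, 2 and 3 free parameters.

All likelihood arithmetic goes through log-gamma functions; there is no
factorial overflow.  Because the direct `gammaln` form of the NB log
pmf loses precision as `phi -> 0` (it differences two enormous values),
`nb_logpmf` switches for `theta > 1e6` to a Poisson-anchored form

    log f_NB = log f_Pois + sum_{j=1}^{y-1} log1p(j/theta)
               - (y + theta) * log1p(mu/theta) + mu

which is exact for integer counts and numerically stable through the
boundary.  The remaining discrepancy from the Poisson log pmf at tiny
`phi` is the genuine analytic gap, of order `phi * y^2 / 2`.

### Fitting

* **Poisson** — the intercept-only MLE is the sample mean; closed form.
* **NB** — two strategies, keeping whichever ends with the higher
  likelihood: (a) joint quasi-Newton over `(log mu, log theta)` started
  from every theta in the grid `10^-8, 10^-7, ..., 10^4`; (b) an
  alternating scheme that updates the mean at fixed dispersion (closed
  form for an intercept-only model: the sample mean) and then profiles
  the dispersion by a bounded 1-d search, stopping when the likelihood
  improves by less than 1e-6 or after 100 rounds.  `log theta` is boxed
  to `[log 1e-8, log 1e8]`; a solution at the upper box is reported as
  `phi = 0` (Poisson-like), which avoids the boundary pathologies of
  optimizing `phi` directly.
* **ZINB** — three-parameter quasi-Newton initialized at the NB
  solution with `pi0 = 0.01` on the logit scale (bounds `[1e-9,
  0.999]`); a fitted `pi0` at the lower bound is reported as 0.  If the
  optimizer ends below the NB likelihood, the NB solution (with `pi0 =
  0`) is returned instead, so the nesting inequality `L(NB) <= L(ZINB)`
  holds by construction.

All-zero count vectors are degenerate for every family (mean 0,
log-likelihood 0) and flagged rather than optimized.

## Model selection

Backward selection per gene: first ZINB vs NB, then — only among genes
that kept NB — NB vs Poisson.  Both null hypotheses pin a parameter to
the boundary of its space (`pi0 = 0`, `phi = 0`), so the LRT statistic
`D = max(0, 2*(L_alt - L_null))` is referred to the equal mixture
`0.5*chi2_0 + 0.5*chi2_1`: `p = 0.5` at `D = 0` and `0.5 * P(chi2_1 >
D)` beyond.  Negative statistics (possible within optimizer slack) are
clamped to zero.

Genes whose fitted likelihoods violate the nesting order by more than
`delta = 0.5` (`L(Poisson) > L(NB) + delta` or `L(NB) > L(ZINB) +
delta`) are labeled unconverged and excluded.  Benjamini–Hochberg is
applied within each stage separately, over the genes eligible at that
stage; pooling across stages would change the denominators of the
step-up procedure.  The default FDR level is 0.05 and genes need at
least 5 nonzero cells to be tested.

## Goodness of fit

Cells are down-sampled to the 10% quantile of per-cell total UMIs (an
observed total; lower interpolation) by drawing exactly that many
molecules without replacement from each cell's gene-labeled pool — a
multivariate hypergeometric draw.  Cells below the target are dropped;
ties at the target are retained unchanged.  After down-sampling, genes
nonzero in more than five cells are kept (note this is deliberately
stricter than the `>= 5` modeling filter; both thresholds are exposed
as parameters).

Each unique observed count value starts as its own bin; scanning from
the largest value downward, bins holding no more than five cells are
merged into the next smaller-valued bin, the accumulated bin continuing
to merge until it exceeds five cells.  Only downward merging is
consistent with the scan direction; the smallest-valued bin is left
as-is even if sparse.  Bin edges are then widened to partition the full
integer support (first bin starts at 0, last bin absorbs the upper
tail), so expected bin probabilities under the fitted model sum to 1
exactly rather than being renormalized over the observed support.

The statistic is Pearson's `sum (obs - n p)^2 / (n p)` with `df = k -
p - 1` (`k` bins, `p` fitted parameters: Poisson `k - 2`, NB `k - 3`).
Genes with `df < 1` — e.g. counts of only 0 and 1 — are skipped, not
tested.  Model parameters are re-estimated on the down-sampled counts.
BH is applied separately to the Poisson and NB p-value sets.  Using the
asymptotic chi-square with parameters estimated by full-data ML is the
standard practical choice; its residual miscalibration is small here
(calibration is verified by simulation in the test suite).

## NBID differential expression

For one gene, `y_i ~ NB(n_i mu_i, phi_{g_i})` with log link

    log(n_i mu_i) = beta0 + beta1 g_i + gamma' x_i,

where `n_i` is the cell's size factor (total UMI count by default, or
an externally supplied factor, e.g. from scran), `g_i` the binary group
label and `x_i` optional covariates.  `log n_i` enters as an offset, so
`mu_i` is a proportion.  Each group has its own dispersion — the
count-model analogue of the unequal-variance t-test — estimated per
gene, which presumes enough cells per group rather than pooling
strength across genes as bulk RNA-seq methods must.

The full model maximizes the likelihood jointly over coefficients and
both dispersions.  Without covariates the likelihood separates by
group, and each group reduces to an offset NB intercept fit solved by
profile likelihood: for fixed `theta` the log-likelihood is concave in
the intercept (Newton iteration), and the profiled `log theta` is
optimized by a bounded Brent search (absolute tolerance 1e-4 on `log
theta`, which bounds the likelihood error far below the LRT scale).
With covariates (or when equal dispersions are requested) a joint
quasi-Newton with analytic gradients runs from two starts: a
moment-based dispersion and `theta = 1`.

The null model drops `beta1` but re-estimates `beta0` and `gamma`,
with each cell's dispersion *fixed* at its group's full-model value;
with dispersions fixed the log-likelihood is concave and a safeguarded
Newton iteration converges.  The test statistic `2*(L_full - L_null)`
is referred to chi-square with 1 df; it is non-negative up to numerics
and clamped at zero.  Genes expressed in only one group (separation)
have `beta1` driven to a bound, are flagged, and still receive a
p-value.  Reported fold change is `exp(beta1)` (model-based);
per-group pooled TPM values are emitted alongside for expression-level
filtering.

## Simulation framework

`generate_nb_matrix` draws gene mean-proportions log-normally
(log-scale sd 1.5), normalized to sum to 1 so a cell's expected total
equals its depth; gene dispersions from Gamma(shape 2, scale 0.15)
(mean 0.3, a typical droplet-data range); and cell depths log-normally
around a median of 1000 UMIs with log-sd 0.3.  Counts are gamma-Poisson
draws, i.e. exactly NB.  These defaults emulate droplet scRNA-seq
scale; they are all configurable.

True DE is created by *swapping*: genes are ranked by average count in
group 2; set A is the 50 genes with average just above `t` (strictly
greater, ties broken by gene index), set B the 50 just above `fc * t`;
their count rows are exchanged pairwise in group-2 cells only.  This
conserves each cell's total exactly and preserves the marginal count
structure of the data while planting fold changes near `fc` and
`1/fc`.  Group depth differences are emulated by thinning: each
selected cell draws a retention ratio uniformly from the scenario range
(per cell, modeling cell-to-cell capture variation) and keeps that
fraction of its molecules by a without-replacement draw.

The swap benchmark's study conditions are 2000 genes, two groups of
500 cells, `t = 0.5`, `fc = 4`, 50 swap pairs, and three thinning
scenarios for group 2 (none, 0.8–0.9, 0.5–0.6), with 20 replicates per
scenario.  `t` and `fc` were chosen once so that calls are plentiful
and the precision-recall curve is informative at this scale.

The batch-confounded design builds two synthetic "replicates" sharing
gene parameters except that a fraction (default 30%) of genes carry a
log-normal batch shift (log-sd `ln 3`) in replicate B.  The shift
factors are rescaled so the shifted genes' total proportion mass is
unchanged: without this, renormalization (or, equivalently, total-count
normalization at analysis time) would drag every gene along and no gene
would be batch-neutral.  Groups are assembled with unequal replicate
composition; two presets are shipped — group 1 always 9A + 21B, group
2 either 18A + 22B (`g2_18a_22b`) or 18A + 12B (`g2_18a_12b`) — and
the composition is an explicit required parameter.  True DE genes are
restricted to batch-neutral candidates (between-replicate NBID p >
0.5) before swapping, so detecting them never amounts to detecting the
batch.

The batch *benchmark* keeps the `g2_18a_12b` composition proportions
but scales cell numbers eightfold (72A + 168B vs 144A + 96B) and
evaluates on well-measured genes (TPM >= 50 in at least one group).
At the literal 60-cell size, per-group dispersion estimates are noisy
enough that even the adjusted analysis retains a mild FDR excess from
LRT tail inflation — NBID assumes a sufficiently large number of cells
per group — so the benchmark operates in the regime the method is
designed for while preserving the confounding structure.  The unadjusted analysis inflates the realized FDR several
fold; adding the batch label as a covariate restores nominal control.

## Evaluation

Realized FDR at `q < alpha` is false calls over calls, 0 for an empty
call set (a convention that matters when averaging over replicates);
replicate averages are reported with failed replicates dropped and
counted.  Precision-recall curves sweep distinct p-value thresholds
with tied p-values entering and leaving together (curves are step
functions over distinct values).  The restricted AUC integrates the
curve by trapezoid over recall, counting only segments whose endpoints
both exceed the precision floor (default 0.8, i.e. FDR <= 0.2); a
perfect method scores its full recalled area and a curve never above
the floor scores 0.  The restricted AUC's exact normalization is an
implementation choice; comparisons are only meaningful within this
implementation.  The scorer is method-agnostic: any per-gene p/q table
keyed by gene id can be evaluated.

## What the synthetic generator does and does not show

The generator produces exactly NB counts with independent genes,
log-normal depth variation and no batch structure unless requested.
Passing calibration and FDR tests on it demonstrates that the
machinery is correct under its own model assumptions — it does not by
itself establish robustness to gene-gene correlation, cell
subpopulation structure, or non-NB technical noise in real data.  The
swap construction mitigates this partially when applied to real
matrices (it preserves all marginal structure of its input), and the
package applies it to any `CountMatrix` regardless of origin.

## Numerical choices and degenerate inputs

* `theta` boxed to `[1e-8, 1e8]` everywhere; boundary solutions are
  reported as `phi = 0`.
* Likelihood-change tolerance 1e-6 (alternating NB), `xatol` 1e-4 on
  `log theta` (NBID profile), Newton step tolerance 1e-8–1e-10.
* Negative LRT statistics clamped to 0 (boundary tests use p = 0.5 at
  0; the NBID 1-df test uses p = 1).
* All-zero genes/vectors: degenerate fits, flagged, never optimized.
* Cells with zero total UMIs are dropped (with a warning) unless an
  external size factor is supplied.
* Down-sampling target at the depth quantile uses lower interpolation
  (an observed total); cells at exactly the target are retained.
* All simulators take explicit seeds and are bit-reproducible;
  replicate sub-seeds are derived from one master seed and stay below
  2^31.

## Known limitations

* The shipped test path is pairwise; the model form permits more
  groups via factor coding but no multi-df test is exposed.
* No dispersion shrinkage across genes: by design, and therefore not
  recommended for very small groups (tens of cells).
* The GOF p-values rely on the asymptotic chi-square with estimated
  parameters; genes with extremely sparse support are skipped rather
  than tested exactly.
* No HDF5 matrix containers; Matrix Market and dense text only.
* Mitochondrial/ribosomal pre-filtering is left to the caller.
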