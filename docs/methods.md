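# Methods

## Model

The two-state (telegraph) model of transcription is a birth-and-death process
in a two-state Markovian environment: the promoter switches OFF→ON at rate
`k_on`, ON→OFF at rate `k_off`, transcribes at rate `k_syn` while ON, and
each transcript degrades at rate λ. All rates are expressed per mean mRNA
lifetime (λ ≡ 1), so `k_on` is directly the burst frequency and
`k_syn / k_off` the burst size; no per-gene degradation rate is carried
anywhere in the package. At steady state the transcript count follows the
Poisson-beta law: `p ~ Beta(k_on, k_off)`, `n | p ~ Poisson(p·k_syn)`.

Applying this cross-sectionally assumes ergodicity: the distribution over
sampled cells stands in for the time distribution of a single cell, which
requires the cells to share kinetics (be homogeneous). The O/E machinery
below measures exactly the failure of that assumption.

`k_syn = 0` is admitted as a degenerate, permanently silent allele (point
mass at zero); `k_on` or `k_off` of zero is rejected, since the Beta mixing
distribution is then improper.

## Numerical evaluation of the pmf

The marginal pmf is an integral of a Poisson kernel against the Beta weight.
It is evaluated by Gauss-Jacobi quadrature, whose weight function *is* the
Beta kernel, so endpoint singularities (`k_on < 1` or `k_off < 1`) are exact.
Nodes start at 50 and double to at most 200; the result is accepted when two
successive node counts agree within 1e-10 absolutely, matching the pmf's
error contract. Higher node counts are deliberately avoided: the Jacobi root
recurrence in scipy degrades (to NaN) above a few hundred nodes when a shape
parameter is large, while 50–200 nodes already reach ~1e-11 across
`k_on, k_off ∈ [1e-3, 1e3]`, `k_syn ∈ [0, 1e3]` (verified against 40-digit
arbitrary-precision references).

Whenever the ladder fails to converge or the nodes are unstable, the exact
closed form

    P(n) = k_syn^n / n! · B(k_on+n, k_off) / B(k_on, k_off)
           · 1F1(k_on+n; k_on+k_off+n; −k_syn)

is used instead (scipy's `hyp1f1`, with an arbitrary-precision fallback for
the rare non-finite evaluations), computed in log space to avoid overflow.
`P(0)` is always anchored to this closed form, so `prob_zero` and `pmf` agree
to machine precision by construction. The automatic truncation keeps
cumulative mass ≥ 1 − 1e-9, searching up to `ceil(10·mean + 50)` and
extending in the rare heavier-tailed cases so the tail bound always holds.

The likelihood used in inference evaluates the closed form directly,
vectorized over the unique observed counts: it is machine-accurate in the
fitting region and avoids recomputing Jacobi nodes at every optimizer step.

## Kinetics inference

Per gene and allele, `(k_on, k_off, k_syn)` maximizes the Poisson-beta
log-likelihood of the integer counts (fractional allelic counts are rounded
half-up once, at the inference boundary). Initialization inverts the first
three factorial moments, `E[n^(r)] = k_syn^r (k_on)_r / (k_on+k_off)_r`,
which solve rationally for the three rates; when the sample moments fall
outside the admissible region a generic bursty start is used. Refinement is
Nelder-Mead on log10 parameters inside the box `k_on, k_off ∈ [1e-3, 1e3]`,
`k_syn ∈ [1e-2, 2·max(count)+10]`, relative log-likelihood tolerance 1e-8,
log10-step tolerance 1e-4, at most 2000 evaluations.

A fit is flagged non-converged when the optimizer fails or the solution sits
on the `k_on`/`k_off` bounds or the `k_syn` lower bound. The `k_syn` *upper*
bound is treated differently: in the bursty regime the likelihood is nearly
flat along the (k_off, k_syn) ridge of constant burst size, and the MLE can
drift to that bound while burst frequency and size — the two quantities the
package reports and filters on — remain stable; flagging those fits would
discard sound estimates, so sitting on the `k_syn` ceiling alone is not
treated as failure.

Uncertainty is a cell-level nonparametric bootstrap (default 100 replicates):
replicates that fail to converge are counted (reported as `bf_n`, `bs_n` out
of 100) rather than raised, and the 2.5/97.5 percentiles of the successful
replicates' burst frequency and size form the CI. Genes enter downstream
analyses only when, on both alleles, the fit converged, at least 50
replicates succeeded, and the CI span (upper/lower) is below 10 for both
burst frequency and burst size.

On 200 synthetic genes with burst frequency in [0.5, 2], burst size in
[5, 50] and 1,000 cells, the median |log2(estimate/truth)| is below 0.5 for
both quantities (measured in the acceptance suite). Identifiability is not
promised outside the bursty regime: near-constitutive genes are fitted to
distribution (total-variation) accuracy, not parameter accuracy.

## Allelic counts and missing data

Allele-resolved molecule counts are the product of the per-gene per-cell
total UMI count and the fraction of reads supporting the CAST allele (the
remainder is C57); UMIs are not individually genotyped, so the counts are
real-valued and are kept so. "Expressed" downstream always means allelic
count > 0, with no threshold. A cell with UMIs but no allele-informative
reads is missing for that gene: it is excluded, for that gene on both
alleles, from every observed fraction, likelihood, and O/E computation, and
is serialized as `NA` (TSV) or a sparse mask sidecar (MatrixMarket).
Per-gene mean expression is reported over non-missing cells.

## States, bias, regression

State probabilities factorize through the per-allele `P(0)` under the
independent-alleles assumption; observed fractions average the corresponding
indicator conditions over non-missing cells. Agreement is summarized by
Spearman correlation (average ranks on ties; constant vectors yield NA, never
0). Cross-validation splits cells into random halves (train receives the
extra cell when odd), infers on one half and scores observed fractions on the
other; genes failing inference in a half are dropped, not imputed. The
Poisson baseline replaces `P(0)` by `exp(−mean)` — for bursty genes this
underestimates zeros and so overestimates biallelic expression.

Bias probabilities truncate both pmfs at cumulative mass 1 − 1e-10 and sum
`P(a1 > a2) = Σ_k P(a1 = k)·F2(k−1)`; the triple sums to 1 within 1e-6 and
swapping alleles swaps the two inequality probabilities exactly. The
bias-vs-kinetics regression is ordinary least squares (statsmodels) of
`log10(P(C57>CAST)/P(CAST>C57))` on the log10 fold-changes of burst frequency
and burst size and their interaction, with intercept; genes with a zero
probability on either side are excluded and counted. The dependent variable
is the analytic probability ratio, not the observed fraction ratio, because
the analytic triple is defined for every filtered gene while observed
fractions can be 0 at finite cell numbers.

## Observed-to-expected biallelic expression

Per gene over a cell set, `observed` is the fraction of non-missing cells
expressing both alleles and `expected` is the product of the two per-allele
expressed fractions; both are fractions, so their ratio is dimensionless (an
observed *count* over an expected *fraction* would not be). Independence and
homogeneity give ratio ≈ 1; a gene active in a fraction `w` of cells gives
ratio → 1/w. Calibration uses permutation tests with the add-one estimator
`p = (1 + #extreme)/(n_perm + 1)`; the tail is an explicit argument (lower
for purity claims, upper for heterogeneity claims). Gene-set nulls draw
same-size sets without replacement from the genes with defined ratios in the
cell set under test; cell-set nulls draw same-size cell subsets from all
cells. Expression-matched controls stratify genes into 50 quantile bins of
mean expression (configurable) and resample the focal set's bin profile from
non-focal genes; a bin with too few candidates is an error naming the bin.
The mixing experiment appends n source-cluster cells to a disjoint target
cluster (n = 0 reproduces the target median exactly) and bootstraps the draw
20 times.

## Imbalance simulation

For each gene, n pairs of counts are drawn from the same kinetics
(independent alleles) and scored as `max(#{a1>a2}, #{a2>a1})/n` — the
fraction of cells favouring the more-favoured allele, with ties (including
joint silence) favouring neither. The statistic converges to
`(1 − P(equal))/2` as n grows; at small n its spread around that limit is
what produces spurious imbalance calls. Note the statistic's *level*
increases with expression (high-expressed genes rarely tie, so it approaches
0.5 even with identical alleles), while joint silence pins low-expressed
genes near 0; the false-positive phenomenon is the finite-n spread, which the
tests quantify as the shrinking deviation from the analytic limit and the
vanishing of extreme (> 0.75) values between n = 10 and n = 1,000. Default
pool sizes are 10, 20, 50, 100, 1,000, 10,000 cells.

## Synthetic data

The generator emulates an F1-hybrid allele-resolved UMI experiment: per-gene
kinetics drawn log-uniformly over burst frequency [0.05, 5] and burst size
[2, 100] with `k_syn` log-uniform up to 300 (clamped so `k_off` stays in
[1e-3, 1e3]) — ranges spanning the parameter cloud of fibroblast-scale UMI
data; identical alleles by default, with optional per-gene log2 fold-changes
on burst frequency and/or size applied to the C57 allele (size changes act
through `k_off` at fixed `k_syn`); optional subpopulation mixtures whose
multipliers act on `k_on` by default (burst-frequency-driven heterogeneity,
the biologically typical mode) or on `k_syn` (a multiplier of 0 silences a
gene in that subpopulation — used to build disjoint gene programs);
missingness applied only where the total count is positive, mirroring how
real data loses allele information. Per-gene RNG streams derive from
(seed, gene index), so output is independent of iteration order.

What it does not emulate: sequencing depth and capture-efficiency noise, UMI
errors, doublets, allele-correlated bursting, or mappability differences
between alleles. Passing tests therefore demonstrate internal consistency of
the framework and estimator correctness under the model, not robustness to
technical noise in real libraries.

## Problem sizes and defaults

The acceptance computations use 2,000 genes × 682 cells for state-prediction
self-consistency, 200 genes × 1,000 cells for parameter recovery, 300 genes
at 500/2,000 cells for O/E calibration, and 20 genes at 10 vs 10,000 cells
for imbalance convergence; unit tests use smaller versions of the same
constructions (e.g. bootstrap coverage at 40 replicates on 400 cells).
Pipeline defaults follow the analysis conventions the package implements:
CI-span threshold 10, 100 bootstrap replicates, 100,000 gene-set and 1,000
cell-set permutations, 20 mixing bootstraps, pool sizes as listed above.

## Known limitations

- Burst kinetics are only identifiable in the bursty regime; constitutive
  genes return distribution-accurate but parameter-degenerate fits.
- The independent-alleles assumption is built into every prediction; genes
  with genuinely coordinated alleles will show elevated O/E that the model
  attributes to population heterogeneity.
- The O/E metric loses power for clusters of closely related cell types
  (small kinetics differences), as the mixing experiment on similar clusters
  shows.
- Bias probabilities assume both truncated pmfs are exact; for extremely
  heavy-tailed kinetics the 1 − 1e-10 truncation dominates the 1e-6 sum
  tolerance.
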