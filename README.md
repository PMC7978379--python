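# alleleburst

Allele-level transcriptional bursting and allelic expression patterns in
single cells.

## The problem

Mammalian genes are transcribed in stochastic bursts, independently on each
allele. In allele-sensitive single-cell RNA-seq of F1 hybrid cells (e.g.
CAST/EiJ × C57BL/6J mice, where strain SNPs distinguish the parental alleles),
many autosomal genes are detected from only one allele in any given cell —
autosomal random monoallelic expression (aRME). `alleleburst` provides the
quantitative machinery to ask whether such patterns are *expected* from
bursting alone: it infers per-allele burst kinetics from allele-resolved UMI
counts, predicts the fractions of silent / monoallelic / biallelic cells and
the probabilities of allelic imbalance, quantifies cell-population
heterogeneity from observed-to-expected biallelic co-occurrence, and simulates
how often pooled cells show false-positive allelic imbalance.

It is written for computational biologists analysing allele-resolved
gene × cell count matrices (TSV or MatrixMarket) and works equally on
synthetic data with known ground truth, generated by the built-in simulator.

## The model

The two-state (telegraph) model: a promoter switches OFF→ON at rate
`k_on` and ON→OFF at rate `k_off`; while ON it produces transcripts at rate
`k_syn`; transcripts degrade at rate λ, normalized to 1 so all rates are per
mean mRNA lifetime. The steady-state transcript count follows the
Poisson-beta distribution

    p ~ Beta(k_on, k_off),    n | p ~ Poisson(p · k_syn),

with burst frequency `bf = k_on`, burst size `bs = k_syn / k_off`, and mean
`k_syn · k_on / (k_on + k_off)`. With `P0 = P(n = 0)` per allele and
independent alleles, the per-gene cell-state probabilities factorize:

    P(silent)    = P0_C57 · P0_CAST          P(mono C57)  = (1 − P0_C57) · P0_CAST
    P(mono CAST) = (1 − P0_CAST) · P0_C57    P(biallelic) = (1 − P0_C57) · (1 − P0_CAST)

Allelic bias is the triple P(C57 > CAST), P(CAST > C57), P(C57 = CAST)
computed from the two truncated pmfs, and cluster heterogeneity is measured by
the per-gene ratio of the observed biallelic fraction to the product of the
per-allele expressed fractions (O/E ratio; ≈ 1 in a homogeneous population,
→ 1/w when a gene is active only in a fraction w of cells).

## Worked example

Simulate a small dataset with known kinetics, re-infer the kinetics, predict
state probabilities, and compare them to the observed fractions:

```
alleleburst synth --n-genes 60 --n-cells 300 --seed 42 --out-prefix toy
alleleburst infer --cast toy.CAST.tsv --c57 toy.C57.tsv --n-boot 0 --seed 1 --out kinetics.tsv
alleleburst predict-states --kinetics kinetics.tsv --cast toy.CAST.tsv --c57 toy.C57.tsv --out states.tsv
alleleburst compare --states states.tsv --out rho.tsv
cat rho.tsv
```

prints

```
# alleleburst version=0.1.0
state	spearman
silent	0.9884599878337609
mono_c57	0.9903633024166035
mono_cast	0.9819477566458193
biallelic	0.998109653276183
```

i.e. even at 60 genes × 300 cells, the state fractions predicted from
*re-inferred* kinetics rank-correlate at ρ ≈ 0.98–0.998 with the fractions
observed in the simulated cells — the bursting model predicts its own allelic
expression patterns. The same subcommands run on real allele-resolved
matrices; `alleleburst --help` lists the full pipeline (allelic count
assignment, bootstrap CIs and the CI-span gene filter, cross-validation, bias
probabilities and the bias-vs-kinetics regression, O/E permutation tests,
cluster mixing, imbalance simulation).

Library use mirrors the CLI:

```python
from alleleburst import TwoStateKinetics, prob_zero, state_probabilities

kin = TwoStateKinetics(k_on=0.6, k_off=5.0, k_syn=50.0)   # bf 0.6, bs 10
print(prob_zero(kin))                  # 0.23405... : allele silent in ~23% of cells
print(state_probabilities(kin, kin))   # [0.05478 0.17927 0.17927 0.58668]
```

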