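# miteabc

Approximate Bayesian computation (ABC) inference of the demographic history
of the three male-aggression forms of the social spider mite *Stigmaeopsis
miscanthi*, from mitochondrial COI sequences, together with the
morphometric step that defines the forms in the first place.

The mite forms colonies on Chinese silver grass, and males kill rival males
at a rate that varies geographically: a low-aggression (LW) form in cold
regions, a high-aggression (HG) form in warm regions and a mildly
aggressive (ML) form in the subtropics. This package is for population
geneticists and behavioural ecologists who want to (re)run or stress-test
the two quantitative steps behind that story:

1. **Form classification** — per-individual weapon ratios (leg I length /
   leg III length, each the sum of tibia + tarsus + genu + femur) are
   log-transformed, averaged per population and clustered (Euclidean
   distance, Ward linkage, three clusters → LW / ML / HG).
2. **Demographic model choice and dating** — nine structured-coalescent
   scenarios relating the three forms (hierarchical splits with ML or LW
   ancestral, isolation-with-admixture, simultaneous split) are compared by
   DIYABC-style ABC: a reference table of simulations from the priors,
   rejection to the closest fraction δ of rows by standardized Euclidean
   distance on 33 summary statistics, scenario choice by weighted
   polychotomous logistic regression evaluated at the observed point, and
   parameter posteriors by weighted local-linear regression adjustment on a
   logit scale bounded by the priors. Split times in generations *t* are
   converted to years as *t*/g for g = 8 and 16 generations/year.

The coalescent engine simulates genealogies backward in time (within a
deme of haploid size *N*, *k* lineages coalesce at rate *k*(*k*−1)/(2*N*)
per generation; split events merge demes, admixture events reassign each
lineage with probability *r*) and evolves 618-bp haploid sequences down the
tree under the HKY substitution model with transition/transversion
coefficient κ. The 33 summary statistics are, per form group: number of
haplotypes, segregating sites S, mean and variance of pairwise differences,
Tajima's D, private segregating sites, and the mean count of the rarest
nucleotide at segregating sites; per form-group pair: pooled haplotypes,
pooled S, pooled mean pairwise differences and Hudson–Slatkin–Maddison
F<sub>ST</sub> = 1 − H<sub>w</sub>/H<sub>b</sub>.

Everything is testable without downloads: `miteabc.synthetic_data`
generates study-shaped inputs (41 sequences split 10 LW / 13 ML / 18 HG,
and a 42-population male leg-measurement table) with recorded truth.

## Worked example

The numbered scripts under `analysis/` run the whole study shape on
synthetic data (01 generates inputs under `results/synthetic/`, 02
classifies forms, 03 runs the ABC, 04 runs reduced calibration checks):

```bash
python analysis/01_synthesize_data.py
python analysis/02_classify_morphs.py
python analysis/03_abc_inference.py
```

`02_classify_morphs.py` prints, for the default generator seed:

```
42 populations clustered; agreement with truth: 97.6%
```

i.e. Ward clustering of mean log weapon ratios recovers the generating
form labels for 41 of 42 populations, with the misfit flagged by the
borderline-margin diagnostic — the same behaviour the real data show for
their single borderline population.

`03_abc_inference.py` (2,000 simulations/scenario, δ = 0.01, on a dataset
simulated under scenario 2 — LW splits from ML at the older time t2, HG
from ML at the younger t1) prints:

```
scenario posterior probabilities (95% CI):
            prob   lower   upper
scenario
1         0.0338  0.0000  0.0753
2         0.5034  0.2231  0.7837
...
best scenario: 2 (truth for this synthetic dataset: 2)
```

followed by the parameter posteriors of the winning scenario (mean,
median, mode and 2.5/5/95/97.5% quantiles per parameter), the split times
converted to years at 8 and 16 generations/year, and a posterior-predictive
model check (per-statistic two-sided tail probabilities plus a PCA
projection of the observed point into the simulated cloud; here 1 of 33
statistics flagged at the 0.05 level). The true scenario wins with
posterior probability ~0.50 — single-locus mtDNA data genuinely cannot
separate the hierarchical-split scenarios much more sharply than this, and
competing probability mass concentrates on the scenario that differs only
in which deme is ancestral.

A `miteabc` CLI wraps the same library (`simulate`, `fit`, `check`,
`morph`, `synth`, `convert-time`), e.g.:

```bash
miteabc convert-time 87900
# 87900 generations at 8/year = 10988 years
# 87900 generations at 16/year = 5494 years
```

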