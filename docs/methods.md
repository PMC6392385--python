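# Methods

This note documents the models, numerical choices and limitations of
`miteabc`. It describes what the code computes; every number quoted as a
result is produced by the test suite, the `analysis/` drivers or
`scripts/acceptance.py`.

## Demographic scenarios

Nine models relate the low- (LW), mild- (ML) and high-aggression (HG)
forms, expressed as ordered backward-in-time event lists over three sampled
demes (`miteabc.scenarios`):

| id | events (backward in time) | constraint |
|----|---------------------------|------------|
| 1  | LW→ML at t1, HG→ML at t2  | t1 < t2 |
| 2  | HG→ML at t1, LW→ML at t2  | t1 < t2 |
| 3  | HG→LW at t1, LW→ML at t2  | t1 < t2 |
| 4  | LW→HG at t1, HG→ML at t2  | t1 < t2 |
| 5  | HG→ML at t1, ML→LW at t2  | t1 < t2 |
| 6  | HG→LW at t1, ML→LW at t2  | t1 < t2 |
| 7  | ML admixes (→LW w.p. r, else HG) at t1, HG→LW at t2 | t1 < t2 |
| 8  | ML admixes (→LW w.p. r, else HG) at t1, LW→HG at t2 | t1 < t2 |
| 9  | LW→ML and HG→ML, both at t2 | none (t1 unused) |

"A→B at t" means every lineage of deme A joins deme B at time t
(forward-in-time: A diverged from B at t). Scenarios 3 and 4 are serial
splits; the source prose does not pin which of the two orderings carries
which id, so 3 = LW-first was fixed here and 4 is its mirror. In the
admixture scenarios r is the probability that an ML lineage traces to the
LW-side parent; r = 1 collapses scenario 7 to "ML is a renamed LW colony".

Each deme keeps one constant haploid size (mtDNA is haploid and maternally
inherited, so these are female effective sizes); ancestral demes keep the
size of the deme lineages merge into. No growth, no migration outside
admixture events.

### Priors

All parameters draw independent uniforms, rejection-resampled jointly until
the scenario's t1 < t2 constraint holds:

| parameter | prior | units |
|-----------|-------|-------|
| N_LW, N_ML, N_HG | U(10, 5×10⁵) | haploid individuals |
| t1, t2 | U(10, 4×10⁵) | generations |
| r | U(0.001, 0.999) | — |
| mu | U(10⁻⁸, 10⁻⁷) | substitutions/site/generation |
| kappa | U(0.05, 20) | HKY transition/transversion coefficient |

The exact priors of the original analysis are in its supplementary table,
which is not redistributed; these bounds are reconstructed so that the
published posterior 95% quantiles (N-ML ≈ 4.96×10⁵, t2 ≈ 3.95×10⁵,
mu ≈ 10⁻⁷) abut them, which is how uniform prior bounds betray themselves.
All are overridable in the run configuration.

## Coalescent and mutation model

`miteabc.coalsim` simulates the structured Kingman coalescent in continuous
time: within a deme of size N, k lineages coalesce at rate k(k−1)/(2N) per
generation; the waiting time to the next event is exponential in the total
rate, competing across demes. The continuous-time approximation is
appropriate because N ≫ sample size over the whole prior range. Agreement
with msprime (mass-migration parameterisation, ploidy 1) is enforced in the
test suite by Kolmogorov–Smirnov tests on TMRCA distributions.

Sequences evolve down the genealogy under HKY with stationary frequencies
π (equal by default; empirical frequencies of the observed alignment when
one is supplied, estimated over unambiguous bases). The rate matrix is
normalised so that branch length × mu is the expected number of
substitutions per site. Per branch, the exact transition matrix
P(t) = exp(Q·mu·t) is computed by spectral decomposition of the
reversibly-symmetrised Q (one `eigh` per model, one 4×4 product per
branch). Sites are iid, so each branch is simulated exactly in three
vectorised steps: Bernoulli-select the sites that change state (probability
1 − P_ss per parent base s), then draw new states from the conditional row
P_s·/(1 − P_ss). This is distributionally identical to per-site sampling
from P(t) and fast when substitutions are sparse; a simulation of the full
41×618 study shape takes ~2.5 ms, so the 9×10⁴-row reference table of the
recovery experiment builds in about four minutes on one CPU.

No recombination (mtDNA), no rate heterogeneity among sites (the original
substitution-model selection for this fragment chose HKY without gamma),
no indels.

## Summary statistics

The 33-statistic vector (`miteabc.sumstats`) is fixed-order: per form
group — haplotypes, segregating sites, mean and variance (denominator =
number of pairs) of pairwise differences, Tajima's D, private segregating
sites, mean rarest-nucleotide count at segregating sites; per group pair —
pooled haplotypes, pooled segregating sites, pooled mean pairwise
differences, Hudson–Slatkin–Maddison F_ST. Conventions:

* Gaps and IUPAC ambiguity (real data only) are treated as missing:
  pairwise differences count sites where both rows are unambiguous;
  segregation and parsimony-informativeness are judged on unambiguous
  states only.
* "Private segregating sites" means segregating within the focal group and
  monomorphic in the union of the others (the alternative reading —
  carrying an allele absent elsewhere — is a different statistic and is not
  implemented).
* Degenerate cases return 0 rather than NaN (D with S = 0 or n = 2; F_ST
  with zero between-group diversity) so reference-table rows are always
  complete. Negative F_ST is retained.
* The original analysis reports "39 summary statistics" in its model
  checking; the battery it lists works out to 7×3 + 4×3 = 33. The extra
  six are unexplained there and no guess is encoded here.

Every statistic is checked against an independent brute-force enumeration
in the tests, and Tajima's D additionally against an exact-fraction hand
computation.

## ABC engine

`miteabc.abc` follows the DIYABC workflow:

* **Rejection.** Statistics are centred by the reference-table median and
  scaled by the median absolute deviation (std fallback; constant columns
  dropped); the ⌈δ·n⌉ rows closest to the observed vector in Euclidean
  distance are retained with Epanechnikov weights 1 − (d/d_max)². Default
  δ = 0.01, the conventional "closest 1%".
* **Model choice.** Weighted polychotomous (multinomial) logistic
  regression of the scenario indicator on the standardized statistic
  deviations, fitted by L-BFGS on the reference-category parameterisation;
  posterior probabilities are the fitted category probabilities at zero
  deviation. A ridge penalty on the slopes (10⁻³ per observation)
  stabilises the fit: at realistic retained-set sizes (≈900 rows, 33
  features, 9 categories) the unpenalised likelihood separates routinely,
  which produces degenerate 0/1 probabilities; separation is detected as
  runaway slope magnitudes and escalates the penalty ×100. A
  linear-discriminant pre-projection of the statistics (optional in DIYABC
  v2) was evaluated and degraded scenario recovery on synthetic checks, so
  it is not used. 95% intervals come from the delta method on the
  asymptotic covariance (inverse penalised Hessian) of the intercepts;
  they are labelled CIs, acknowledging that the published table calls its
  intervals "95% HPD" without stating a construction.
* **Parameter estimation.** Retained draws of the chosen scenario are
  logit-transformed to their prior bounds, adjusted by weighted linear
  regression on the statistic deviations (local-linear ABC adjustment),
  back-transformed, and summarised as weighted mean, median, 2.5/5/95/97.5%
  quantiles and mode (Gaussian KDE, Silverman bandwidth, 512-point grid
  inside the prior bounds). Scenario 9 reports no t1; scenarios 7–8 also
  report r. Because each parameter is adjusted independently, an adjusted
  draw can violate t1 < t2; posterior-predictive simulation nudges such
  draws back (t1 ← 0.999·t2).
* **Model checking.** Statistics are simulated from weighted draws of the
  posterior sample, PCA (on standardized statistics) locates the observed
  point in the simulated cloud, and each statistic gets a two-sided
  posterior-predictive tail probability 2·min(P(sim ≤ obs), P(sim ≥ obs)),
  flagged below 0.05.
* **Time conversion.** Years = generations / (generations per year),
  rounded half-up, with 8 and 16 generations/year as the developmental
  bracket for this mite (e.g. 87,900 generations → 5,494–10,988 years).

Determinism: a single run seed expands into per-stage seeds via
`numpy.random.SeedSequence.spawn`, so the reference table, the fit and the
model check can be rerun independently and every output file records the
seed and a configuration hash.

## Morphometric classification

`miteabc.morphotype` computes the weapon ratio (leg I / leg III segment
totals) per male, the natural-log mean per population, and Ward clustering
of the scalar scores cut at three clusters, labelled LW < ML < HG by mean
score. The natural log is a free choice (any base rescales all scores and
cannot change Ward clusters), and the Ward criterion defaults to the
squared-Euclidean "D2" variant with the classical "D" variant switchable —
on scalar data at three clusters they agree in every test case. A
per-population margin (distance to the nearest other cluster centroid
minus distance to own centroid) surfaces borderline populations, since the
real data contain one population whose assignment flips between the
dendrogram and the phylogeny; a manual-override list supports recording
such judgement calls explicitly rather than silently.

## Synthetic data

`miteabc.synthetic_data` makes the package testable without any downloads.

* **Sequences**: one coalescent + HKY simulation shaped like the mtCOI
  data — 41 haploid 618-bp sequences, 10 LW / 13 ML / 18 HG, one sequence
  per sampled population — under scenario 2 at the posterior-median preset
  (N-LW 97,500; N-ML 419,000; N-HG 180,000; t1 87,900; t2 320,000;
  mu 8.70×10⁻⁸; kappa 1.67). These are posterior medians used as a
  realistic anchor, not ground truth. Equal base frequencies by default.
* **Morphometry**: per population (11 LW / 13 ML / 18 HG = 42), 8–22
  males; leg III segments drawn around a 195-µm baseline with 5% body-size
  variation; leg I scaled so each male's log weapon ratio is normal with
  the population's mean and SD 0.02. Population means are normal around
  form means 0.205 / 0.245 / 0.300 (log scale) with SD 0.008. The form
  means put neighbouring forms' individual-level histograms in overlap, as
  observed; the between-population SD is calibrated so that roughly one
  population in ~40 sits on a cluster boundary — the structure the real
  dendrogram exhibits (a single borderline population out of 42). Under
  these settings Ward clustering recovers ~98% of labels on average (min
  ~90%) over 100 seeds.

What passing these tests does **not** show about real data: a single
non-recombining locus carries one genealogy, so scenario choice has an
irreducible variance floor (see below); real alignments carry gaps,
ambiguity and base composition the generator does not emulate (the
statistics handle them, the generator does not produce them); and the
morph generator draws individuals independently, ignoring within-nest
relatedness.

## Scaled problem sizes and what the calibrations show

The recovery experiments run at desk scale, chosen to finish in minutes
while keeping the retained-set size DIYABC-proportionate: reference tables
of 10⁴ simulations per scenario (the original used 10⁶) with δ = 0.01.
At these conditions, on pseudo-observed data simulated under scenario 2 at
the posterior-median preset:

* scenario 2 is the modal winner across replicates, with mean posterior
  probability ≈ 0.40 — strikingly close to the 0.4631 the original
  analysis reports for its real data. Most non-wins go to scenario 5,
  which differs from 2 only in which deme is ancestral below t2; a single
  mitochondrial locus genuinely carries limited information to separate
  them (the engine itself is verified against msprime on exactly this
  model). Recovery fractions around 50–80% per 20-replicate batch are
  therefore expected, and batches near the 50% boundary occur.
* the 95% posterior interval for t2 covers the generating value in roughly
  86–96% of replicates per 50-replicate batch. Mild undercoverage is a
  known property of local-linear ABC at small retained samples,
  compounded here by the truth (3.2×10⁵) sitting near the prior bound
  (4×10⁵) where the logit transform compresses.
* the neutral single-deme calibration reproduces E[π] = 2·N·mu·L within
  Monte-Carlo error and mean Tajima's D ≈ 0.

## Known limitations

* The accession-derived checks (parsimony-informative site counts of the
  real alignments: 114/618 mtCOI, 57/1,310 nuclear) need the GenBank
  alignments on disk (`data/genbank/`); the repository does not
  redistribute them, so that test fails until the user supplies the data.
* Scenario posterior CIs are asymptotic delta-method intervals, not HPDs.
* The admixture fraction r is only weakly identified even in scenarios 7–8
  (single locus); its posterior largely returns the prior.
* No sequential/adaptive ABC, no random-forest model choice, and the
  nuclear locus is not used in the ABC — mtCOI only, as in the original
  design.
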