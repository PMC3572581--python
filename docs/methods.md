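# Methods

`gancova` models percent methylation of gene-associated CpG islands (and
of LINE-1, a global-methylation proxy) in normal rectal mucosa as linear
functions of age, sex, anthropometric and nutritional exposures, selects
the covariate subset for each response with a genetic algorithm, and
judges generalization with double (nested) cross-validation.  This note
records the model, the tunable parameters and their defaults, the
synthetic-data generator that the validation studies run on, and the
numerical and design choices a maintainer would want to know about.

## Response preparation

Percent-methylation responses are min–max autoscaled onto [0.01, 1] on
observed cases, per locus: `x ↦ 0.01·(1−u) + 1·u` with
`u = (x − min)/(max − min)`.  The convex-combination form makes the
observed minimum and maximum map *exactly* to the interval endpoints in
floating point.  Missing cells stay missing; analyses are complete-case
per response.  A constant response is a hard error — the map is
undefined.

Loci whose observed median is below 1% methylation **and** whose Pearson
correlation with age is non-significant (p ≥ 0.05) are excluded by QC;
the thresholds are package defaults and configurable.  LINE-1 is always
retained: it indexes global methylation and is modelled as its own
response, never as a covariate.

PCA1, the composite methylation score, is the first principal component
of the autoscaled multi-gene matrix on complete cases, using the
covariance basis — autoscaling is the route to equal per-gene weighting,
so no second standardisation is applied.  The component sign is fixed so
the loading sum is non-negative (score rises with overall methylation);
scores are then autoscaled like any response.

## The ANCOVA model family

Sex is coded sum-to-zero (+1 male, −1 female).  A candidate model
assigns each covariate one of three states: absent, a single slope
common to both sexes, or sex-split (centred covariate plus its product
with the sex code); a separate flag includes the sex main effect.  The
hierarchy rule — any sex-split covariate forces the sex main effect —
is enforced by construction everywhere (string grammar, chromosome
decoding, design building).  Covariates are centred at the training mean
before products are formed and the centres are frozen for prediction,
which keeps the interaction columns near-orthogonal to the mains and
makes the sex main effect interpretable as the average male–female
offset.

Fits are ordinary least squares.  R² is reported as the squared
correlation between fitted and observed values (identical to the
classical R² for OLS with intercept).  Per-term significance is a
marginal (Type-III-style) F test; with the ±1 coding every non-intercept
column is one term, so F equals the squared t statistic.  Terms are
reported ordered by ascending p.  Per-sex slopes for split terms are
`common ± interaction`.

A Glejser-style wedge diagnostic regresses |residual| on age; a
significantly positive slope indicates the age-increasing
("wedge-shaped") methylation variance these data characteristically
show.  The pipeline diagnoses but does not correct the
heteroscedasticity — models are scored as ordinary least squares
throughout.

## Subset selection

The search space for 16 candidate covariates is 3¹⁶·2 ≈ 86 M models,
searched by a genetic algorithm: one ternary allele per covariate plus a
sex bit, tournament selection (size 2), uniform crossover (0.5 per
locus), per-locus mutation 1/length, elitism 1, population 50, at most
100 generations with patience 20.  Chromosomes are repaired, not
penalised: splits force the sex bit, and covariates beyond the
`max_terms` cap (default 8) are dropped deterministically.

**Fitness** is the cross-validated explained variance
`1 − PRESS/TSS` over sex-stratified 7-fold splits, averaged over 3
independent fold assignments, minus a BIC-style complexity penalty
`ln(n)·df/n` where `df` counts design columns.  Two deliberate choices
sit here:

* *The penalty.*  Unpenalised CV explained variance almost never has
  the generating model as its argmax at these sample sizes — in
  simulation some chance-correlated covariate buys a marginal CV gain in
  essentially every dataset, so repeated search epochs cannot agree on
  one model.  The `ln(n)` penalty (the consistency threshold for subset
  selection) restores a stable optimum and reproduces the high
  epoch-frequency behaviour the method is meant to exhibit.
* *The fold-split averaging.*  A single k-fold assignment leaves enough
  Monte-Carlo noise in the score that borderline terms flip between
  epochs; averaging three assignments makes the per-epoch landscape
  nearly deterministic at modest cost.

Within one GA run all models are scored on identical folds (cached), and
the exhaustive enumerator shares those folds through the same seed
derivation, so GA-vs-oracle comparisons are exact.

**Consensus.**  The search is repeated for 10 independent epochs (seed =
base + epoch index, which also re-randomises the CV folds).  The modal
best-of-run model is reported with its frequency n1CV as a stability
measure; ties are flagged and broken toward the higher mean fitness.
The winner is refit on the full data for the no-CV R² and the ordered
term list.

## Double cross-validation

Generalization is estimated by rerunning the *entire* selection (reduced
to 3 epochs by default, for tractability) inside each of 7 sex-stratified
outer training folds, fitting the selected model there and predicting
the held-out fold.  Pooled out-of-fold predictions give

    2CV% = 100 · (1 − Σ(y − ŷ)² / Σ(y − ȳ_train(fold))²)

with a 95% CI from a subject-level percentile bootstrap (B = 1000) of
the pooled (y, ŷ, ȳ) triples.  A model **passes** iff the CI lower bound
is strictly above zero; failing models render an empty cell in the
summary table.  Fold assignment depends only on subject order, sex and
the seed — never on the response — so a held-out subject's value cannot
leak into its own prediction (verified by a perturbation test).

2CV estimates the generalization of the *procedure* (selection plus
fitting), not of the generating model; when true effects sit near the
selection threshold the procedure's out-of-sample EV is well below the
model's, and the calibration study therefore scores CI coverage against
the replicate's true procedure-level EV, computed by refitting each
outer-fold model and scoring it on a 20,000-subject independent draw.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with a full ground-truth record:

* **Exposures** — per-sex (min, median, max) marginals for 16 variables
  (ages 17–77, 84 males / 101 females at the default cohort size of
  185), realised as scaled Beta(a, b) distributions with a + b = 4 whose
  median matches the target, coupled by a Gaussian copula.  The default
  correlation matrix is built from factor loadings (body size, stature,
  folate status, age/metabolic, leukocyte) so it is PSD by construction;
  it is a declared stand-in, fully user-overridable.
* **Methylation** — per locus, a linear signal on standardized
  covariates (standardization constants frozen from a single large
  calibration draw), an optional shared latent factor inducing the
  co-methylation of seven gene loci, and Gaussian noise whose sd grows
  linearly with age (profile 0.5 + (age − 17)/60, normalised to unit
  mean square): the wedge.  Signals are specified as signed *variance
  shares* per term; coefficients are jointly rescaled on the calibration
  draw so the summed shares equal the locus's target out-of-sample
  explained variance to within the stated ±0.05 calibration gate.
  Values are mapped to percent and clipped to [0, 100], with a warning
  if clipping exceeds 1%.
* **Missingness** — ESR1, MYOD1 and N33 lose the same 11 subjects
  (174/185 complete), mirroring amplification failure.

The default single-response scenario ("PCA1-like", total EV 0.38) uses
age sex-split (share 0.085 main + 0.075 interaction, male slope much
steeper), a small male offset (0.02), plasma folate +0.0667, selenium
−0.0667 and vitamin D −0.0667.  The shares are sized so each generating
term is individually well-determined at n = 185 (per-term partial F of
roughly 15–25): with weaker terms no selection rule can recover the
exact generating model repeatedly, because the per-term evidence sits at
the selection threshold.  The female age slope is positive but shallow —
the price of a decisively detectable interaction inside a fixed variance
budget.

What the generator does **not** emulate: assay chemistry, crypt-level
mosaicism, non-Gaussian methylation error, covariate measurement error,
or real exposure intercorrelations (the shipped matrix is a labelled
guess).  Passing recovery tests therefore show the pipeline's
correctness and calibration under its own assumptions, not that real
rectal-mucosa data satisfy those assumptions.

## Numerical choices and degenerate inputs

* Least squares via Cholesky-solved normal equations inside the CV
  fitness (fast path; LAPACK lstsq fallback on singularity) and via QR
  rank checks in the reporting fit, which names the offending columns on
  rank deficiency.
* Exhaustive-search ties: higher fitness, then fewer design columns,
  then lexically smaller model string.  Epoch-consensus ties: flagged,
  then higher mean fitness.
* Degenerate inputs raise: constant response vectors, all-loci-excluded
  QC, zero-variance PCA panels, n ≤ p fits, folds that would lose a sex
  while the model carries sex terms.
* All stochastic stages derive their seeds from one base seed via
  `numpy.random.SeedSequence`; identical config + seed reproduces every
  output byte-for-byte.

## Validation study sizes

The shipped studies (see `gancova/evaluation.py`) use: 100 random
(n = 60, ≤ 8 column) instances against the normal-equations oracle; 10
seeds of GA vs exhaustive enumeration on a 162-model pool; one
10-epoch recovery run on the default scenario; 100 replicate cohorts
for nested-CV CI coverage plus 20 permuted-response null controls
(reduced GA settings inside the nested loop); 2000 null simulations for
the type-I error of term tests; and 50 random panels against the PCA
eigensolver oracle.

## Known limitations

* Heteroscedastic noise is diagnosed, not modelled; CV scoring weights
  all subjects equally.
* The bootstrap CI treats pooled out-of-fold pairs as exchangeable
  across folds; fold-model variability makes its coverage slightly
  anti-conservative (~90% empirically for a nominal 95%).
* Exact recovery of a generating model is a draw-level event: with
  realistic effect sizes the expected success rate is high but not 1,
  and single-seed checks inherit that variability.
* The GA is a heuristic; optimality is only guaranteed against the
  exhaustive oracle on small candidate pools.
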