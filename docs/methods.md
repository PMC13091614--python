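# Methods

## Problem and model

GenomeStudio-style array callers cluster two-channel intensities
unsupervised, per SNP, assuming high-quality input. For degraded or
low-input DNA this assumption fails in two characteristic ways: total
signal *R* drops while its variability grows, and heterozygous sites lose
one allele's signal ("heterozygote dropout"), so AB observations drift
toward a homozygous cluster and are either miscalled with confidence or
no-called. `snprecall` treats genotype assignment as supervised
classification instead: features engineered from the exported summaries are
mapped to a posterior over {AA, AB, BB}, using the same individuals'
high-input runs as labels.

### Features

For each record with total intensity *r* and angle *θ* (radians,
θ = theta_norm·π/2 — exports are assumed to use the normalized-[0,1]
convention; the conversion is isolated in `features.theta_radians`):

* angle errors `a_AA = θ`, `a_AB = π/4 − θ`, `a_BB = π/2 − θ` — signed, no
  absolute value, because the side of the deviation is informative and
  `a_AA + a_BB = π/2` holds identically;
* subtended arcs `s_g = r · a_g`, coupling angular deviation with signal
  strength (`s_AA + s_BB = r·π/2`);
* the platform scores (GenCall, GenTrain, cluster separation), the raw
  channel summaries (x, y, r, θ);
* per-sample mean and unbiased variance of *r* over the sample's QC-passing
  autosomal records, as proxies for sample quantity/quality. This gives the
  classifier cross-site information an independent per-site caller cannot
  use.

All 15 features are z-scored with statistics fit on the **training
individuals only**; constant features are dropped with a warning. The
normalizer is serialized with the model so prediction is self-contained.

### QC

Fixed order: non-autosomal chromosomes (X, Y, MT, "0") removed; invalid SNP
identifiers (empty, ".", containing a dash) removed; within a sample, all
copies of a duplicated SNP name removed (probe identity is ambiguous, so no
copy is trusted); calls with GenCall < 0.15 (boundary kept) converted to NC
by default — conversion rather than deletion lets the recaller be scored at
sites the platform declined; strict deletion is available via
`QcConfig(drop_low_gencall=True)`.

### Labels, splitting and the two training phases

Each individual's designated high-input run supplies truth labels
(no-calls excluded); lower-input records join on (individual, SNP). All
partitioning is by individual, so no individual contributes to both sides
of any train/validation/test split — including the grid-search folds
(leave-individuals-out `GroupKFold`).

Training runs in two phases. Phase 1 (model selection) down-samples to
equal counts of platform-correct and platform-incorrect records (NC counts
as incorrect) — a *binary* balancing even though the classifier is
3-class, kept deliberately because it concentrates the selection set on the
failure modes while remaining cheap; grid points are scored by mean
multiclass log loss across folds, ties to the earlier grid point. Phase 2
refits the winning configuration on all training examples with
inverse-frequency class weights `w_c = N/(3·N_c)` (a flat genotype prior);
no down-sampling. The weight formula is one natural realization of a flat
prior; others exist.

### Classifier families

* `rmlr` — scikit-learn multinomial `LogisticRegression`, saga solver,
  l1/l2/elastic-net penalties.
* `gbt` — XGBoost with the multiclass softmax cross-entropy objective and
  probability output (`tree_method="hist"`, single-threaded for
  reproducibility). This is the recommended family.
* `nn` — scikit-learn `MLPClassifier`, three hidden layers (default
  50/100/50 — the third layer mirrors the first), ReLU activations, Adam,
  fixed epoch budget (default 50), no early stopping. This family cannot
  apply class weights (the backend has no sample-weight support); it warns
  and trains unweighted.

Probabilities are used raw (no calibration by default): for thresholding
purposes an uncalibrated but monotone score is sufficient. Posterior rows
sum to 1 within 1e-6; argmax ties resolve in AA < AB < BB order.

### Quality and filtering

`Q = −10·log₁₀(1 − max p)`, capped at 99 (saturated tree leaves otherwise
produce infinities; 99 matches VCF convention). Retention is `Q ≥ t`
("minimum threshold" semantics). For head-to-head comparison with the
platform, whose GenCall score is not a probability, sets are matched by
rank and cardinality: with k = min(recaller retained, platform called), the
recaller's top-k by Q are compared with the platform's top-k by GenCall
(ties broken by SNP then sample ID, so results are deterministic). Matching
in both directions is required because at threshold 0 the recaller answers
at every site, including those the platform no-called; comparing unequal
site sets would penalize whichever caller attempts more sites. The
concordance filter retains recalled genotypes only where they equal the
platform call; platform NC is never concordant (NC is not a genotype).

### Metrics

Absolute call rate divides called sites by the chip's autosomal content
(the Omni5-4 constant 4 198 873 is provided as a default constant);
relative call rate divides by the sites assayed for that input; accuracy is
correct/called (uncalled sites cancel from numerator and denominator).
Per-class precision/recall/F1 are one-vs-rest over called sites. Method
comparisons across (input × threshold) strata use the exact two-sided
paired sign test with zeros dropped (the standard exact-test convention).

### Kinship

The between-family KING-robust estimator (see README formula) from shared
heterozygote and opposite-homozygote counts; sites missing in either member
are excluded pairwise to maximize shared information. The estimator is
undefined (error, or NaN in the all-pairs table) when a pair shares no
called sites or either member has no heterozygote. Raw φ is always
reported; clamping is left to presentation layers.

## The simulator

`simulate` generates the statistical structure the pipeline assumes, in
(θ, r) space directly — the pipeline consumes only the channel summaries,
so modelling raw per-channel chemistry would add parameters without adding
testable behaviour.

* **Genotypes**: founders are HWE draws at per-SNP B-allele frequencies
  (uniform on [0.05, 0.95]); offspring receive one uniformly chosen allele
  per parent. The default 8-individual pedigree (two founder pairs, three
  offspring, one half-sib) yields duplicate, first-degree, second-degree
  and unrelated pairs.
* **Clusters**: per-SNP probe offset ~ N(0, 0.02 rad) shifts all three
  cluster angles; observed θ is truncated-normal on [0, π/2] around the
  genotype's cluster angle.
* **Dilution laws** (defaults; input *g* in ng): median intensity
  `exp(log 1.5 + 0.12·log(g/50))` — a log-linear decline to ~36% of the
  50 ng signal at 0.01 ng; log-sd of r `0.25 + 0.05·log₁₀(50/g)`; θ noise
  `0.035 + 0.055·log₁₀(50/g)` rad; a per-sample log-normal intensity effect
  (sd 0.05) creates between-sample variation. These give the observed
  signs — mean signal falls, variability grows, as input falls — and a
  surrogate-caller accuracy/call-rate profile across the series
  (≈99.9%/≈100% at 50 ng degrading to ≈80%/≈87% at 0.01 ng at desk scale)
  of the same shape reported for real dilution series.
* **Heterozygote dropout**: with probability `0.75/(1 + (g/0.03)^0.8)`
  (≈0.3% at 50 ng, ≈70% at 0.01 ng) a true-AB record's cluster angle
  collapses a uniform fraction (0.4–1.0) of the way toward a randomly
  chosen homozygous cluster and its intensity is multiplied by
  U(0.45, 0.7) — one channel's contribution is largely lost. Partial
  collapse reflects allelic imbalance in degraded material: most collapsed
  records cross the caller's decision boundary and are confidently
  miscalled, while remaining jointly recognizable (intermediate θ, low r)
  to a supervised model. Dropout is the sole genotype-dependent error mode;
  AB is therefore the failure-prone class, as observed in practice.
* **Surrogate platform caller** (synthetic stand-in, not the proprietary
  clustering algorithm): calls the nearest cluster angle; its score decays
  linearly with angular distance (zero midway between clusters) and is
  damped by weak intensity (`min(r/0.6, 1)^0.5`); score < 0.15 becomes NC.
  Per-SNP GenTrain/cluster-separation surrogates are anti-correlated with
  probe offset magnitude.

**What the simulator does not model**: batch and plate effects, probe-level
affine miscalibration, linkage disequilibrium between SNPs, population
structure in allele frequencies, genotyping-error correlation across sites
within a sample beyond the shared intensity laws, and the platform's true
clustering behaviour. Passing the end-to-end tests therefore shows the
pipeline recovers structure *of the assumed kind*; it does not certify
performance on any particular real chip or chemistry.

## Numerical and design choices

* Probabilities are floored at 1e-99 before Phred scaling in VCF PL fields;
  GQ is capped at 99; PL is shifted so the minimum is 0 and rounded.
* Missing R columns are recomputed as x + y; files carrying only R and θ
  are tolerated with x, y left unset (no reconstruction is attempted — the
  split is not identifiable from (r, θ) under the Manhattan normalization
  without assuming exact consistency, and fabricated channels would leak
  into features).
* Chromosome strings are kept verbatim; positions are 1-based.
* VCF records sort numerically by chromosome then position; non-numeric
  chromosome names sort after numeric ones, lexicographically.
* Grid-search scoring uses log loss (lower better); "negative log loss" in
  common usage refers to the same quantity with opposite sign conventions —
  the tie-break (first in grid order) and the argmin are unambiguous.
* Problem sizes in the test suite are desk-scale by design: the unit suite
  uses 400–800-SNP grids; the end-to-end check trains on a 20 000-SNP,
  8-individual grid (≈960 000 records), and kinship recovery uses 50 000
  SNPs, where the estimator's sampling error is ≈0.005 — comfortably inside
  the ±0.02 recovery bands.

## Known limitations

* The `nn` family ignores class weights (backend limitation) and uses ReLU
  rather than leaky ReLU.
* Phase-1 binary (correct/incorrect) balancing is kept for fidelity to the
  two-phase design it implements; 3-class balancing is available via
  `downsample_balanced(..., mode="genotype")`.
* Reported Phred qualities are only as calibrated as the underlying
  classifier; with the default gradient-boosted settings, Q ≥ 30 retention
  is conservative (few posteriors exceed 0.999).
* KING-robust is implemented in its between-family form only; no
  within-family switching, IBD segments, or degree classification.
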