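# Methods

## Model and procedure

The package treats breed assignment as a classification problem over
genomic relationships rather than over raw SNPs. Its assumptions:

* genotypes are biallelic allele dosages in {0, 1, 2}, one value per
  animal and SNP; breeds are closed populations (no admixed animals);
* every candidate breed is represented in a labelled reference set;
* relationships computed against the reference set carry enough
  between-breed contrast to separate the breeds.

### Allele frequencies and the GRM

Allele frequencies are computed per breed over the reference animals
(`AF = Σ dosage / (2 × non-missing count)` per SNP) and then averaged
**unweighted across breeds**. The alternative — pooling all reference
animals — would let the largest breed dominate the centring whenever
reference sizes are imbalanced, which is exactly the situation the RS1
design creates. The averaged frequencies `p_j` centre the dosages
(`Z = M − 2P`) and scale the VanRaden method-1 GRM
(`G = ZZ′ / (2 Σ_j p_j(1 − p_j))`). One consistent frequency set is used
for both centring and scaling.

Two consequences matter operationally:

* **Cohort stability.** Because `p_j` depend only on the reference set, a
  validation animal's relationships to the reference animals — and
  therefore its assignment — are identical whether the GRM holds that
  animal alone or together with any number of other validation animals.
  One GRM over reference + all validation animals suffices. Tested to
  1e−12.
* **Zero mean.** The average of all GRM entries is exactly zero only when
  the frequencies are pooled over all animals in the matrix. With the
  reference-anchored, breed-averaged frequencies used for assignment the
  property holds only approximately, and is asserted nowhere for that
  configuration. Negative entries are an artefact of centring, not a
  meaningful "anti-relationship".

Missing dosages are imputed with `2·p_j`, which makes them exactly
relationship-neutral (zero after centring); frequencies themselves are
computed over non-missing calls only. A panel whose frequency set is
entirely fixed (denominator 0) is rejected.

### Relatedness summaries

Each animal is summarized by the mean and the sample SD (n−1) of its
relationships to every breed's reference animals, self-relationships
excluded whenever the animal itself belongs to that breed's reference
set. Self-exclusion is applied uniformly to all methods — it only matters
when scoring reference animals (e.g. SVM training features); validation
animals never have self-relationships to the reference. A target left
with a single usable relationship to some breed keeps its (defined) mean
and gets a NaN SD; zero usable relationships is an error.

### Assignment rules

* `mean_GRM` / `SD_GRM`: argmax over per-breed mean / SD. Exact ties go
  to the lexicographically first breed with `tie_flag` set — determinism
  over silent arbitrary choice.
* `GRM_SVM`: the 2K summaries are standardized by their training
  mean/SD, a linear-kernel SVM is tuned over the cost grid
  0.001–0.9 (11 values) by stratified 10-fold CV accuracy, refit on all
  training animals, and decision scores are mapped to probabilities by
  Platt's logistic scaling (one-vs-one with pairwise coupling for K > 2,
  calibration cross-validated internally). Stratification protects the
  folds of small breeds. **Tie rule:** equal CV accuracies keep the
  *largest* cost. Under heavy regularization the decision values
  compress and the fitted Platt sigmoid degenerates toward uniform
  probabilities, so on separable data (where every cost ties at 100%)
  preferring the smallest cost breaks the highest-probability assignment
  rule even though the decision boundary is perfect.
* `PLS_NSC` baseline: SNPs with a major genotypic frequency ≥ 0.95 in
  the reference set are removed (strict `<` retention, per the wording
  "lower than"), the rest standardized by reference mean and population
  SD (n); PLS-DA on one-hot breed indicators is tuned over 1–50
  components by 10-fold CV accuracy (ties → fewest components; the cap
  is clipped when the data cannot support it), refit on the full
  reference, and a SNP is selected when `|coef| > mean(|coef|) +
  3·SD(|coef|)` for at least one breed (SD over SNPs, n−1). The
  nearest-shrunken-centroid classifier on the selected standardized
  genotypes uses `m_k = sqrt(1/n_k − 1/n)`, `s_0 = median(s_j)`,
  soft-thresholding `d′ = sign(d)·max(|d| − Δ, 0)`, and posterior
  `p_k ∝ π_k exp(−½ Σ_j (x_j − x̄′_kj)²/(s_j+s_0)²)`; Δ is tuned over
  {0.01, 0.05, 0.10, 0.25, 0.50, 1} by 10-fold CV (ties → largest Δ, the
  most parsimonious centroids). Threshold coefficients come from the
  full-data refit, not from CV folds.

### Evaluation protocol

Per repetition, each breed contributes ⌊n/2⌋ animals to validation
(floor for odd sizes); RS1 reference = the remainder, RS2 reference =
up to 50 per breed drawn from that remainder (RS2 ⊆ RS1 within a
repetition, and both share the validation draw — one RNG substream per
breed guarantees this). All methods see the identical split: a paired
design, required for the paired t-test. Per-repetition seeds are
`base_seed + repetition`, so any repetition reproduces in isolation.

Differences between methods are tested with the variance-corrected
resampled paired t-test, `t = x̄ / sqrt((1/n + n2/n1)·σ̂²)`, df = n−1,
two-sided p. `n1`/`n2` are the calibration/validation counts of the fixed
split design — totals for global accuracy, one breed's counts for its
sensitivity, the other breeds' counts for its specificity. Since
`|t_corrected| ≤ |t_naive|` always, the correction can only lose power.
Significance uses Bonferroni bands for six pairwise comparisons: 0.0083,
0.0017, 0.00017, 0.000017 (strict `<`). Percentile-bootstrap 95% CIs of
each method's mean metric (10,000 resamples by default) complement the
tests. Zero-variance differences give the sentinel t = ±∞, p = 0 (or
t = 0, p = 1 when the mean is also zero). Specificity with a single-breed
truth set is reported as undefined (`None`), never coerced.

## Synthetic data: what it emulates and what it does not

The simulator draws each SNP's ancestral frequency uniformly on
[0.05, 0.95] (no SNP near-monomorphic ancestrally), drifts each breed's
frequency independently through a Beta distribution with mean `p` and
variance `fst·p·(1−p)` (Balding–Nichols; `fst = 0` copies `p` exactly
because the Beta parameters diverge), and samples genotypes
Binomial(2, breed frequency). A Hudson ratio-of-averages FST estimator
validates the round trip: the configured `fst` is recovered within 0.02
at 5,000 SNPs and 200 animals per breed.

Deliberately absent: linkage disequilibrium, within-breed family
structure (parents/sibs), mutation, admixture. Two consequences for
interpreting test results:

* mean_GRM and GRM_SVM separate drift-simulated breeds essentially
  perfectly at FST ≈ 0.05, so passing tests demonstrate correctness of
  the machinery, not the field accuracy on real sister breeds;
* SD_GRM performs near chance on simulated panels. Its rationale — more
  variance among relationships to own-breed members — relies on real
  pedigree structure (close relatives vs distant cousins). Under pure
  drift, the across-reference variance of relationships is nearly the
  same for every breed, so the criterion carries almost no signal. The
  tested, and preserved, qualitative property is *relative*: SD_GRM's
  accuracy degrades more than mean_GRM's when the reference shrinks from
  50 to 10 animals per breed.

## Numerical and design choices

* Population SD (n) for genotype standardization; sample SD (n−1) for
  relatedness summaries and PLS coefficient thresholds. Conventions are
  fixed and tested; mixing them silently would change selections.
* Argmax ties detected at relative tolerance 1e−12; CV-accuracy ties at
  absolute 1e−12.
* NSC probabilities computed with max-subtraction in log space.
* The default demonstration FST of 0.05 is a package choice of a
  "closely related sister breeds" difficulty level, not an estimate of
  any particular breed trio.
* Problem sizes in the test suite (e.g. 3 repetitions × 2,000 SNPs × 60
  animals per breed for the baseline-vs-GRM agreement check; 20
  repetitions × 2,000 SNPs × 100 animals per breed for the study-scale
  accuracy check) are the package's choice of desk-scale defaults; at
  many fewer SNPs the reduced-panel baseline genuinely trails the
  all-SNP methods, so SNP count is kept at study scale where the
  comparison is the point.

## Known limitations

* No rejection option: every animal is assigned to one of the reference
  breeds, including genuinely crossbred or out-of-panel animals.
* Linear SVM only; no radial/polynomial kernels.
* No VanRaden methods 2/3, weighted GRMs, or pedigree matrices.
* PLINK support covers the text `.raw` dialect only (counted allele as
  given by the column suffix; no strand or allele flipping); binary
  bed/bim/fam and VCF are out of scope.
* The corrected t-test's `n1`/`n2` use the fixed design counts; RS2's
  realized per-repetition composition varies only in which animals, not
  how many.
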