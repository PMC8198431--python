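# Methods

`metabscreen` reimplements, as a tested pipeline, the analysis workflow of a
serum targeted-metabolomics comparison between two lung-cancer screening
cohorts: a large test cohort ("MOLTEST-like", 123 participants per group)
and a small validation cohort ("SMAC-like", 31 per group), each with three
groups — no lung alterations (Ctr), benign nodules (LN), lung cancer (LC).
Because the original serum data are not public, every stage runs against a
synthetic generator that reproduces the statistical structure the analysis
assumes, with planted ground truth for recovery testing.

## 1. Panel model

The assay is modelled on an Absolute IDQ p400-class kit: 96-well plates,
absolute quantification in uM, ten analyte classes. The default registry
implements the kit's per-class composition literally — 21 amino acids + 21
biogenic amines (42 combined), 55 acylcarnitines, 15 di- + 45 triglycerides
(60), 24 lyso- + 172 phosphatidylcholines (196), 40 sphingolipids, 14
cholesteryl esters, 1 hexose — for a total of 408 entries. Kit marketing
totals this panel as "407 metabolites"; the per-class counts are mutually
consistent and sum to 408, so the registry carries 408 and this one-unit
discrepancy is simply documented. Intra-class splits not fixed by the
per-class enumeration (AA vs amine, DG vs TG, LPC vs PC) follow the kit's
public composition (21/21, 15/45, 24/172); they affect only aggregation
labels, never a statistic's definition. Lipid species beyond the handful
with conventional names get systematic `CLASS(C:D)` identifiers.

Two missingness mechanisms are tracked per cell, because they mean
different things and are treated differently downstream:

* **calibrant failure** — the isotope-labelled internal standard failed;
  the measurement carries no information (empty cell in the export);
* **below LOD** — the compound is present below the plate's limit of
  detection/quantitation (exported as a literal `0`).

## 2. Synthetic cohort generator

Concentrations are log-normal per analyte. On the log2 scale, the value of
analyte *a* in sample *s* on plate *p* is

    y_sa = m_a + u_a(cohort) + c_{s,class(a)} + g_s + e(group) + gamma_p + delta_p * eps_sa

* `m_a ~ N(mu_class, tau_class^2)` — per-analyte baseline drawn from
  class-level hyperparameters. The class means are tuned so that, in
  expectation, cholesteryl esters carry ~55% of total lipid mass, choline
  phospholipids ~25% and glycerides ~14% (the composition of detected serum
  lipids the class-aggregate analysis is built around); amino acids sit near
  100 uM, amines near 1 uM, hexose near 5 mM. Within-class spread
  `tau = 0.7–0.8` log2 units. The paper-style source states no within-class
  dispersion; these are package defaults.
* `u_a ~ N(0, 0.25)` — a per-analyte cohort offset (zero in the reference
  cohort) emulating between-cohort heterogeneity of baselines.
* `c_{s,class} ~ N(0, 0.5)` and `g_s ~ N(0, 0.3)` — per-sample lipid-class
  factors and a global dilution-like shift: the inter-individual
  heterogeneity that dominates real serum metabolomes, and the structure the
  correlation-based imputer exploits.
* `e(group)` — planted log2 fold changes from the effect list, optionally
  scoped to one cohort (so cross-cohort concordance and discordance are both
  generable).
* `gamma_p ~ N(0, 0.3)`, `delta_p = exp(N(0, 0.15))` — additive and
  multiplicative plate (batch) effects on the log2 scale, i.e. exactly the
  model the empirical-Bayes correction assumes.
* `eps_sa ~ N(0, sigma_a^2)`, `sigma_a ~ U(0.35, 0.65)` — per-analyte noise.

**Censoring.** The plate LOD of analyte *a* is the `q_a`-quantile of its
baseline distribution (using `sqrt(sigma_a^2 + 0.5^2 + 0.3^2)` as the
baseline sd) with a small per-plate jitter (0.05 log2 units); a drawn value
below the LOD of its sample's plate is exported as `0` — so the expected
censoring fraction equals `q_a` by construction, which the tests verify by
counting. In the study-like default, `q_a` is drawn from Beta(0.2, 10)
(most analytes essentially uncensored) and ~30% of analytes are
low-abundance with `q_a ~ U(0.55, 0.9)`, reproducing the three-way analyte
partition pattern of the original data (most quantitative, a quarter
presence/absence-only, a few percent excluded). Calibrant failures are
independent Bernoulli per cell (0.5% default; ~6% of analytes fail at a 20%
rate in the study-like default) and override censoring.

**Design.** Samples fill plates sequentially with groups interleaved, so
group and plate are not confounded (a `confounded_plates` toggle exists for
stress tests). The default study-like effect list plants four lipids
reduced in LC in both cohorts — LPC(18:0), PC(32:3), DG(39:0), CE(20:5) —
plus cohort-scoped effects including a triglyceride and an amino acid whose
LC shifts have opposite signs in the two cohorts.

All randomness flows from one `numpy` generator in fixed draw order:
identical seeds give identical datasets bit-for-bit.

## 3. Preprocessing chain

Order is fixed and enforced through the matrix's scale state:
profile missingness → partition analytes → impute calibrant failures →
replace below-LOD zeros → log2 → batch-correct.

* **Partition (10% / 50% rules).** Fractions of each missingness type are
  computed per cohort x group stratum (the stricter reading of "each
  patient's group"; a pooled-groups flag exists). An analyte with a
  calibrant-failure fraction > 0.10 in *any* stratum is excluded; otherwise
  a below-LOD fraction > 0.50 in any stratum sends it to the
  presence/absence (binary) set; the rest are quantitative.
* **kNN imputation.** Each calibrant-failure cell is filled with the mean
  of the k = 3 nearest donors among samples of the same group on the same
  plate, by correlation distance (1 − Pearson over analytes detected in
  both profiles, computed on the log2 scale, ≥ 10 shared analytes
  required). If fewer than 3 eligible donors exist, the pool widens to the
  same cohort+group across plates, then to the stratum median, then the
  global analyte median; every fallback is logged.
* **Below-LOD replacement.** Each censored cell receives an independent
  draw from Normal(LOD/2, (LOD/4)^2) truncated to [0, LOD] of its plate.
  The source method states only "truncated normal between 0 and the LOD";
  centring at LOD/2 with sd LOD/4 puts the mass mid-interval with
  negligible boundary pile-up, and both fractions are configurable. Checked
  against closed-form truncated-normal moments.
* **Batch correction.** Parametric empirical-Bayes location/scale
  adjustment with the plate as the batch: standardize per analyte by the
  grand mean and pooled within-batch variance; estimate per-batch additive
  (gamma) and multiplicative (delta) effects; shrink them through
  method-of-moments normal / inverse-gamma priors fitted across analytes
  within each batch (iterating the coupled posterior equations); adjust and
  restore the grand mean and pooled variance. The implementation is
  hand-written so the fitted parameters can be applied to held-out samples
  (see §5); it matches `scanpy.pp.combat` to ~3e-3, the residual being that
  the scanpy port uses the biased variance for the additive-effect prior
  where the R reference (and this package) uses the unbiased one. No
  biological covariates are protected by default — the source protocol
  names none — but a covariate option exists at the fit level. A single
  batch is a no-op; a batch with one sample or a zero-variance analyte is
  an error.
* **Embedding.** UMAP to 2-D (defaults: 15 neighbours, min-dist 0.1,
  seeded) for dataset-structure visualization only; no statistic consumes
  the embedding.

## 4. Univariate battery

On quantitative analytes, per analyte:

* **Kruskal–Wallis** (tie-corrected, chi-square with k−1 df; all-tied input
  defined as H = 0, p = 1) with **eta-squared** effect size
  `(H − k + 1)/(n − k)`.
* **Conover–Iman posthoc** on the pooled KW ranks: per pair,
  `t = (R̄_i − R̄_j) / sqrt(S^2 · (n−1−H)/(n−k) · (1/n_i + 1/n_j))` with the
  tie-corrected pooled rank variance `S^2`, p from Student t with n−k df.
  Effect size r = |t| / sqrt(n_i + n_j) — the statistic standardized by the
  square root of *the compared pair's* size, which is how the cited
  "Pallant r" usage reads; pairwise p-values are not adjusted across the
  three contrasts (adjustment is across analytes only).
* **Jonckheere–Terpstra** trend across the ordered groups Ctr < LN < LC:
  sum of between-group Mann–Whitney counts (ties 1/2), tie-adjusted normal
  approximation, two-sided p, no continuity correction.
* **BH-FDR** across analytes; pairwise contrasts are reported as
  significant when the analyte passes FDR < alpha *and* the unadjusted
  pairwise p < alpha (alpha = 0.05).
* Per-cohort mode adds a **Lancaster combination** of the two cohorts' KW
  p-values: each p maps to the upper-tail chi-square quantile with w df,
  the sum is referred to chi-square with sum(w) df. Weights are the cohort
  sample sizes rescaled to mean 2, so equal cohorts reduce exactly to
  Fisher's method (an identity the tests assert at 1e-10). Zero p-values
  are clamped to machine epsilon.
* **Concordance**: an analyte is "common" to both cohorts only when
  FDR-significant in each with the same LC-vs-Ctr median direction.
* **Presence/absence analytes** are tested with a chi-square independence
  test on the detected/censored x group table, using the raw (pre-
  replacement) codes; calibrant-failure cells stay out of the table. When
  any expected count is below 5 the asymptotic test is replaced by Fisher's
  exact test (2x2) or a seeded Monte-Carlo permutation chi-square (2xk),
  and the method used is reported per analyte.
* **Effect-size magnitude labels** (N/S/M/L) use the conventional cut-offs
  0.1/0.3/0.5 for r and 0.01/0.06/0.14 for eta-squared; the source figures
  use these grades without printing thresholds, so the values are an
  explicit package decision.
* **Class aggregates** are per-sample sums of linear-scale concentrations
  per class (plus total lipids over the seven lipid classes), tested with
  the same KW machinery.

## 5. Signature classifier

Three-class multinomial logistic regression (MLR), reference class Ctr,
fitted by exact maximum-likelihood Newton iteration (relative log-likelihood
tolerance 1e-8, 200 iterations max, step halving). Perfect separation —
detected by non-convergence, coefficient blow-up, or a log-likelihood at
numerical zero — triggers a refit with a tiny ridge (1e-6), flagged on the
model; BIC always uses the unpenalized log-likelihood of the returned
coefficients with q = (k−1)(features+1) free parameters. The fit is written
in-package because forward selection under nested CV needs on the order of
1e5 exact fits with warm starts; it is cross-checked against statsmodels'
MNLogit maximum likelihood in the tests.

Nested structure, per outer fold (10 folds):

1. Ten samples per group are held out of the large cohort as the fold's
   test set. The folds' test sets are drawn *without replacement*, so the
   ten test sets partition 100 samples per group and the remaining 23 per
   group always train (the source protocol says only "taking ten samples
   from each group"; the partition reading maximizes test coverage).
2. On the remaining pool, 100 MRCV repetitions: stratified 70/30 split;
   greedy forward selection adding the candidate with the lowest BIC and
   stopping when the best improvement is ≤ 2 (the conventional
   evidence-grade reading of "ΔBIC ≤ 2"); MAP classification accuracy
   recorded on both halves.
3. The 100 selection traces are ranked by selection frequency (ties broken
   by mean addition position, then name, for determinism) and cut at the
   elbow of the sorted frequency curve — the point of maximum perpendicular
   deviation from the chord joining its endpoints, earliest point on ties.
4. The final fold model is refit with the consensus features on *all*
   non-test samples of the large cohort (the protocol does not state the
   refit set; all-pool maximizes training data without touching the test
   set), then evaluated on the fold's test set and on the entire validation
   cohort. Metrics: MAP accuracy, macro one-vs-rest AUC from the class
   posteriors ("overall AUC" is not defined in the source; macro-OVR is the
   standard reading), per-class sensitivity/specificity, balanced accuracy
   (mean per-class sensitivity). MAP ties resolve to the fixed class order
   Ctr, LN, LC and are logged.
5. Aggregates over the 10 folds are means with normal-approximation 95%
   CIs (mean ± 1.96·SE).

**Candidate cap.** Forward selection over all ~260 quantitative analytes x
100 repetitions x 10 folds is the dominant cost; by default each fold
pre-screens to the 60 candidates with the smallest pool Kruskal–Wallis p.
The cap is a pipeline parameter (`candidate_cap=None` disables it) and is
recorded in the run log.

**Leakage modes.** The faithful mode preprocesses all samples once,
mirroring the source protocol (whose imputation, LOD replacement and batch
correction see the whole dataset). The `strict` mode refits the entire
preprocessing chain per fold on everything except that fold's test samples
— partition, imputation donor pool, and batch parameters are all
test-blind — and maps the held-out samples through the stored parameters.
Both modes produce the same report structure so their metrics can be
compared directly.

## 6. Pipeline and reproducibility

A single master seed fans out via `numpy.random.SeedSequence.spawn` to the
five stochastic stages (simulation, LOD replacement, embedding, statistics,
classifier); the run log records the config, derived seeds and every
imputation fallback, and identical configs produce byte-identical output
tables. Default parameters reproduce the study-faithful settings:
tolerances 0.10/0.50, k = 3, folds = 10, 10 test samples per group, 100
MRCV repetitions, 70% train fraction, ΔBIC 2, alpha 0.05.

## 7. Problem sizes and calibration checks

The calibration and recovery checks run at the study's scale: 462 samples
x 408 analytes, full 10-fold x 100-repetition nested CV (with the
candidate cap on). Chance-level calibration of the classifier is asserted
on effect-free data (mean held-out accuracy within 3 points of 33.3%,
macro AUC within 0.03 of 0.5); the Kruskal–Wallis type-I error is measured
over 5,000 null simulations of 3 x 30 samples; rank statistics are checked
against brute-force and permutation oracles on 100 random small instances;
batch-correction recovery uses planted ±1 log2 shifts and x2 scales;
signal recovery plants 20 differential analytes (|log2FC| = 1, 123 per
group) for the battery and 5 strong features (log2FC = 1.5) for the
signature.

Two checks use purpose-built scenarios rather than the full default
generator, because the property under test is otherwise ill-posed:

* The **imputation masking experiment** uses a high-heterogeneity scenario
  (class factors 0.8, global shift 0.5, noise 0.3–0.5): correlation-kNN can
  only outperform a stratum mean when samples differ in a correlated way,
  which that fixture provides and a homogeneous one would not.
* The **signature identity-recovery check** plants its five features on
  *independent* analytes (per-sample class factors and global shifts
  zeroed, per-analyte noise raised to a realistic 1.0–1.4 log2 units) with
  complementary (LC, LN) contrast directions. Under the default correlated
  structure, forward-BIC selection legitimately prefers a planted lipid
  plus a same-class reference analyte (the reference cancels the shared
  class-factor noise) over a second planted lipid; and when all five
  effects point at the same contrast at three noise-sd strength, two
  features saturate the three-class discriminant space and the ΔBIC rule
  correctly stops early. Both are correct behaviours of the method — small
  ratio-like signatures are a known phenomenon — but they mean "which
  exact analytes were recovered" is only a meaningful question when the
  planted features are identifiable.

## 8. What the generator does and does not emulate

It emulates: class-structured abundances, two missingness mechanisms with
plate-specific LODs, additive+multiplicative plate effects, inter-
individual heterogeneity, cohort-scoped differential effects, and the two
cohorts' sample sizes. It does **not** emulate: covariate structure
(age/sex/smoking are drawn independently of group, mirroring the matched
design but providing no confounding to adjust for), within-plate
acquisition drift, correlated analyte families beyond the shared class
factors, non-normal heavy tails, or isomer ambiguity. Passing tests
therefore show the pipeline is correct and calibrated under its assumed
model, not that the biological conclusions transfer to any particular real
cohort — the study's own real-data metric values are not reproducible
without the original serum measurements.

## 9. Known limitations

* The Conover p-values rely on the t approximation; the permutation
  comparison in the tests allows 0.03 absolute slack for it.
* The Monte-Carlo exact path of the presence test is seeded but still a
  permutation estimate (9,999 draws).
* Strict mode widens the donor pool definition to "fit samples only" but
  still imputes a held-out sample using its own group label, as the
  underlying protocol does.
* With the candidate cap disabled the classifier is an order of magnitude
  slower; the cap can, in principle, drop a weak consensus feature that
  uncapped selection would find.
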