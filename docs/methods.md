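# Methods

## The severity model

The cohort is a participants × variables table with mild/severe labels
obtained from an expert judge panel by simple majority. The model itself is
a wrapper feature selection: for a pool of p variables, every non-empty
subset is scored by a support vector classifier with polynomial kernel
K(x, z) = (γ⟨x, z⟩ + c₀)^d trained on repeated stratified train/test
repartitions of the cohort. Per repartition the test-set confusion counts
give accuracy (TP+TN)/(TP+TN+FP+FN), sensitivity TP/(TP+FN) and specificity
TN/(TN+FP), with "severe" as the positive class; per-subset metrics are the
arithmetic means over repartitions. Subsets are ranked by mean accuracy
with ties broken toward smaller subsets, then lexicographically — the
"minimum set of parameters" reading of dimensional reduction. The
unweighted mean of mean accuracies over all 2^p − 1 subsets (the *pool mean
accuracy*) summarizes how informative a pool is and is the score used in
candidate screening.

Assumptions worth keeping in view: labels are treated as ground truth even
though judges are imperfect (the learning curve makes the cost of a
disputed label visible); repartitioning controls optimism but train and
test sets still share any cohort-level ascertainment quirk; with n ≈ 35 a
test split holds only ~9 participants, so per-subset accuracies are coarse
(multiples of 1/9) and only averages over many repartitions are stable.

### Hyperparameters

| parameter | default | notes |
|---|---|---|
| train fraction | 0.75 | stratified per class, floor, at least 1 and at most n−1 per class |
| repartitions | 200 (tests/CLI default 50) | per-subset resamples |
| kernel degree d | 3 | optional inner grid d ∈ {1,2,3} |
| γ | 1/p (subset size) | |
| c₀ | 1 | |
| cost C | 1 | optional inner grid C ∈ {0.25,1,4}, selected by inner resampled accuracy (`SVMParams(tune=True)`); the fixed default is the fast path |
| pool cap | 14 variables | exhaustive enumeration refuses more unless overridden; `count_planned_fits(p, R) = 2^p · R` (the empty subset counts as the majority-class baseline) |

Splits are drawn once per search and shared across subsets, so subset
scores differ only through the variables they use, not through split luck.
A split whose test set lacks a class is redrawn with the next random state
and logged; with per-class allocation this cannot occur for classes of ≥2.

Model fits go through scikit-learn's libsvm binding directly; the estimator
wrapper adds ~30× overhead per fit, which matters at 10⁵–10⁶ fits per
screening run. A test asserts the fast path and `sklearn.svm.SVC` return
identical predictions.

### Null calibration

Reporting "random labels give accuracy 0.5" requires care at this sample
size. A single fixed random label vector has two failure modes: an
unbalanced draw sends the SVM to majority-class guessing (accuracy = the
majority fraction, up to ~0.65 at n = 35), and even a balanced draw leaves
chance label–feature correlations (sd of a sample correlation at n = 35 is
~0.17) that every repartition of the *same* data exploits consistently,
giving a ±0.09 spread across draws. `permutation_null` therefore draws a
fresh label permutation per repartition — the standard permutation-null
construction — which preserves class balance, breaks all label–feature
association, and concentrates the pool mean within ~±0.015 of 0.5.

### Screening, importance, learning curve

Candidate screening scores each candidate v by the pool mean accuracy of
{clinical pool} ∪ {v}. At desk scale a seeded random sample of subset
patterns (default budget in the replay: 40; the recovery experiments use
20) is drawn **once** and reused for every candidate, so scores are
comparable; patterns that do not include the candidate slot are shared
across candidates and evaluated once. The cutoff for the "novel biomarker
tier" is the highest score among designated reference variables (the
established biomarkers screened as candidates). Ranks are 1..N by
descending score, ties lexicographic by name.

Variable importance is a model-free filter: the single-variable ROC AUC
against the labels, folded above 0.5 (kernel SVMs expose no coefficients),
computed on the training half of each repartition, averaged, then min–max
scaled to [0, 100]. A constant variable is pinned at the null AUC of 0.5
before scaling and logged.

The learning curve re-runs the exhaustive search on each enrollment-order
prefix and reports the best subset's mean accuracy; prefixes with fewer
than two participants in either class are skipped and reported. On a
separable synthetic cohort the curve plateaus by n ≈ 10–15, and flipping
one participant's label produces a visible dip at the prefix where they
enter.

## Preprocessing

Variables missing for **strictly more than** 70% of participants are
removed (a variable at exactly 70% is retained). Remaining gaps are filled
by a kNN scheme in the style of VIM's kNN: the distance between two
participants is the Euclidean distance over min–max-scaled, mutually
observed continuous variables plus simple matching on mutually observed
binary variables, divided by the number of mutually observed variables;
the imputed value is the median (continuous) or mode (binary, ties → 1) of
the k = 5 nearest donors observing the variable, equidistant donors
ordered by participant index. A participant sharing no observed variable
with any donor falls back to the column median/mode and is logged.
Finally every variable is mapped to [0, 1] by y = (x − min)/(max − min);
constant variables map to 0 with a warning, and the (min, max) pairs are
returned for projecting new data. The sentence "Euclidean distances were
normalized using a min–max procedure" is read the conventional way:
variables are min–max scaled and Euclidean distance computed on scaled
values. The chain filter → impute → normalize is idempotent on its own
output, and imputation never alters observed cells (both asserted).
Whether imputation should precede or follow model-variable selection is
under-determined in this design; the pipeline imputes on the full retained
set, then selects.

## Cluster tendency

k-means uses Lloyd's algorithm with k-means++ initialization, best of 25
starts by within-cluster sum of squares, deterministic given a seed. The
elbow suggestion maximizes the discrete second difference of the WSS curve
normalized by the WSS just past the knee; Monte-Carlo calibration on
uniform-noise matrices (n = 40, p = 2–8) puts this statistic below ~0.8
under the null while well-separated planted clusters score 3–10, so
suggestions below 1.0 are flagged low-confidence.

The Hopkins statistic is H = Σu/(Σu + Σw), with u the nearest-data-neighbor
distances of m = ⌈0.1·n⌉ points sampled uniformly from the data's bounding
box and w the nearest-neighbor distances (self excluded) of m sampled data
points, averaged over 100 draws with a normal-approximation CI. Both
orientations of H exist in the literature; u in the numerator is chosen so
that *higher H = more clusterable*, matching the usage in which a
better-partitioning variable set scores higher. The sampling fraction and
replicate count are not dictated by the design and are exposed as
arguments. Note that H ≈ 0.5 is the null for *uniform* data; a single
Gaussian cloud already scores ~0.55–0.6 because its density gradient is
mild structure.

## Judge panel

Consensus is a simple majority; an exact tie (possible only with an even
panel) raises an error instructing an odd panel or an explicit tie-break.
Any disagreement flags the participant. Agreement is reported as Fleiss'
kappa (the panel has three raters and the design names no statistic;
Fleiss is the standard choice for >2 raters) plus the pairwise Cohen's
kappa matrix for transparency. When all raters use one category for all
participants, chance agreement equals observed agreement and kappa is
reported as undefined (NaN), not as a number.

## Breath test

δ¹³C (‰ vs VPDB) converts to atom percent via R = R_VPDB·(δ/1000 + 1),
atom% = 100·R/(1+R), R_VPDB = 0.0112372; APE is the atom-percent excess
over the pre-dose baseline. The instantaneous fraction of dose excreted is
VCO₂·APE/100/dose (min⁻¹); cumulative percent dose recovery is its
trapezoidal integral ×100, and truncation at 60 min gives the oxidation
capacity fed to the model as a candidate biomarker. VCO₂ is held constant
at its resting measurement over the 2 h window, and no bicarbonate
retention correction is applied (a `retention_factor` hook exists). The
exact recovery formula is the standard one from ¹³C breath-test practice
and is labeled an assumed method. Recovery is invariant to the unit system
as long as VCO₂ and dose share it (asserted mol vs mmol).

## Group statistics

Normality is assessed per group by Shapiro–Wilk at α = 0.05 (the design
leaves the assessment method open); a group smaller than 3 or with zero
range routes non-parametric. Two groups: t-test (paired/unpaired) when all
normal, else Mann–Whitney U (Wilcoxon signed-rank when paired). Three or
more: one-way ANOVA + Tukey when all normal, else Kruskal–Wallis + Dunn.
Dunn's rank comparison (z statistics on mean rank differences with tie
correction) is implemented here because no maintained Python package in
the stack provides it; p-values are Bonferroni-adjusted (conservative,
configurable in principle by swapping the adjustment line). Under the
null the auto-selected two-group branch rejects at 5.0% ± 1 point over
2,000 Monte-Carlo replicates (asserted). Significance stars follow the
usual thresholds (* <0.05 to **** <0.0001). Associations are OLS (Pearson
r, adjusted R², slope p, 95% prediction band) or maximum-likelihood
logistic (odds ratio, Wald p); perfect separation is reported as
non-converged rather than a spurious estimate. The range-overlap report
counts each group's values inside the other's [min, max]; "no overlap" —
the criterion for a biomarker that cleanly separates severe patients from
liver-transplanted ones — requires both counts to be zero.

## Synthetic cohorts: what they emulate, and what they do not

`SimConfig` defaults are the study conditions: 40 participants, 5
liver-transplanted, 12 clinical variables (two binary sequelae: optic
nerve abnormality and sensorineural hearing loss), 2 established
biochemical biomarkers, 459 candidate variables (473 total), 172 variables
with missingness strictly above 70% (so the filter retains 301), 3 judges
flipping the true class with probability 0.1, and MCAR missingness with
per-variable rates in [0, 0.3] elsewhere.

Design choices:

- **Balanced classes.** Severity is assigned by a balanced permutation
  (class prior 1/2), not per-participant coin flips. This encodes a judge
  panel that splits a spectrum roughly in half and is what keeps the
  no-signal pipeline calibrated at 0.5 rather than at a random majority
  fraction.
- **Effects.** Continuous variables are Gaussian class-conditional with a
  standardized mean difference of `effect_size` (default 1.5 — a strong
  but realistic separation for variables chosen *because* they track
  severity) and clinically signed directions (severe: lower FSIQ, growth,
  LVEF, eGFR, blood counts; higher ALT, C3, 2-MC, sequela prevalence).
  Binary sequelae shift prevalence on the logit scale. A log-normal option
  (`heavy_tails`) exercises the non-parametric statistics branch.
- **Transplant.** Transplanted participants are drawn from the severe
  class and keep severe-like clinical sequelae, but their biochemical and
  candidate variables are generated from the mild distribution — organs
  remain at risk after transplant while hepatic propionate oxidation is
  restored. Their true oxidation capacity is likewise mild-like
  (mild ≈ 0.18 ± 0.04 of dose per 2 h, severe ≈ 0.05 ± 0.015).
- **Missingness** is MCAR by default; an MNAR option doubles the
  missingness weight of severe participants, since the real mechanism is
  unknown. High-missingness is planted in the candidate block only, so the
  14 model variables survive filtering as they do in the real design.
- **Breath series** follow a rise-to-plateau enrichment curve
  1 − e^(−t/40 min) sampled at 0/30/60/120 min and scaled so the noiseless
  trapezoid recovery returns the true capacity exactly (round-trip
  asserted to 1e−9); δ noise (default 0.3‰) applies to post-dose samples.

Not emulated: inter-variable correlation structure (variables are
independent given class — real labs co-vary), longitudinal visits,
genotype, diet/medication dynamics, and judge biases correlated between
raters. Passing tests therefore demonstrate that the machinery recovers
planted structure under clean conditions; they do not certify performance
on real cohorts with correlated predictors or informative missingness.

## Problem sizes and determinism

Desk-scale defaults keep every experiment on one CPU: the acceptance
experiments use a 6-variable pool × 200 repartitions for the null, 20
subset patterns × 50 repartitions × 101 candidates × 20 seeds for the
recovery study, and 2,000 replicates for the type-I check. The replay CLI
defaults to 50 repartitions and a 40-pattern screening budget. All
randomness flows from one root seed through `SeedSequence` spawn keys
(stage-indexed child seeds below 2³¹), so identical (config, seed) pairs
reproduce every artifact bit for bit; each pipeline run freezes its
resolved config and a content hash of its inputs.
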