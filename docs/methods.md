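# Methods

This note documents the statistical procedures implemented in `bmage`,
the synthetic cohort model used to exercise them, and the numerical and
design choices a maintainer should know about.

## Analysis procedures

### Differential metabolite screening

The substrate is a samples × features intensity matrix per organ with
zero encoding a missing ion. The chain is:

1. **Missingness filter.** A feature is dropped when its missing
   fraction *strictly exceeds* `max_missing_frac` (default 0.5); a
   feature missing in exactly half the samples is retained. Survivor
   order is preserved.
2. **Normalization.** log2 of positive intensities, then per-sample
   median centering over the sample's observed features. This is one
   concrete, invertible realization of "normalized peak areas"; it
   assumes most features are not differential — with very few features
   (≲10) a single large shift can move the sample median and absorb
   part of its own effect. Zeros are treated as missing throughout,
   never imputed, consistent with the zero-as-missing reading of the
   missingness filter.
3. **Testing.** Per feature, a two-sample Student t-test
   (equal-variance pooled SD by default; Welch available via
   `equal_var=False`) on the normalized values, with
   `log2FC = mean_B − mean_A` of log2 values — i.e. the log ratio of
   back-transformed geometric means. Significance requires
   `p < p_thresh` (default 0.05) *and* `|log2FC| > lfc_thresh`
   (default 0.26, a ≈1.2-fold change; strict inequality). Degenerate
   columns (both groups zero-variance) get p = 1 when the means agree
   and p = 0 otherwise; columns with fewer than two observations in a
   group get p = NaN and are never significant. BH-adjusted q-values
   are reported per table, but the screening rule itself uses the raw
   p, matching the source procedure.
4. **Confound exclusion.** Features significant in the
   vehicle-vs-water contrast are removed from treatment-vs-vehicle
   tables, so remaining hits are treatment-specific.
5. **Direction-consistent overlap.** Features significant in both the
   aging contrast (young vs old) and a treatment contrast are split by
   whether their directions agree — agreement means the treatment
   moves the metabolite toward the young profile.

### ROC biomarker selection

Feature-level AUC is the Mann-Whitney statistic
`(#[treated > control] + ½·ties) / (n₊ n₋)`, computed on the same
normalized values used for testing (one consistent scale for the whole
chain). Because biomarkers may be up- or down-regulated, selection uses
the orientation-free `max(a, 1−a)` with a strict `> 0.85` threshold;
the up/down direction is carried separately from the differential
table. Ties contribute ½ per pair, the standard Mann-Whitney
convention.

### Correlation network

Nodes are (organ, feature) pairs for all differential features; edges
require `|r| > r_thresh` (default 0.8, Pearson on normalized log
intensities; Spearman selectable) and `p < 0.05` from the
`t = r√((n−2)/(1−r²))` transform, computed pairwise-complete over the
animals present in every organ (listwise alignment by animal id).
Constant features are skipped with a warning and remain isolated
nodes. Raw p-values are used, as in the printed threshold rule; no
multiplicity control is applied to edges. Organ hubness is total
degree aggregated by organ; ties rank the denser organ first (a star
center beats its leaf set). Graph layout is out of scope — the edge
list and GraphML are exported for external tools.

### Short time-series trend mining

Four unit-norm, zero-mean templates over T timepoints: a centered
linear ramp (increase; for T = 4 proportional to (−3,−1,1,3)), its
negation, a centered tent (up_down; for T = 4 proportional to
(−1,1,1,−1)), and its negation. A profile's similarity to a template
is the dot product after centering and unit-norming the profile —
exactly the Pearson correlation, making assignment scale- and
location-free. Ties break in the fixed order (increase, decrease,
up_down, down_up); profiles with centered norm below 1e−9 are labelled
`flat` and excluded from enrichment.

The null tallies assignments of every profile under every one of the
T! timepoint permutations (identity included, so p ≥ 1/P; above T = 6
the null falls back to 10,000 seeded sampled permutations). Template
enrichment is the hypergeometric upper tail `P[X ≥ k]` with population
`M = n·P` pooled assignment events, `K` of them on the template, and
`n` draws; this (M, K, n) construction is a declared interpretation,
isolated in `trend_enrichment` so it can be swapped. Significant
(group, template) pairs form clusters at raw `p < alpha` (default
0.05, no multiplicity correction across the four templates); taxa
appearing in more than one cluster are reported as the overlap set.
Cluster membership is by best-template assignment without a similarity
floor, so clusters include weakly-matching taxa — the significance
statement is about the *count*, not each member.

**Compositional drift correction.** Relative abundances are closed to
1, so a genuine trend in a subset of taxa imprints a shared spurious
drift on all other taxa in log space (balanced increasing/decreasing
trends still produce a cosh-shaped dip in total mass that mimics the
tent templates). The trend unit is therefore the group-mean log
relative-abundance profile with a median-of-ratios drift correction:
each taxon's log profile is centered on its own time average, the
per-timepoint median of these deviations across taxa estimates the
shared drift, and one trimming pass drops taxa with residuals beyond
3 MAD (the strongly trending outliers, which bias even the median)
before the final median. When more than half the taxa are outlying —
balanced template designs — the trimmed estimate is unreliable and the
plain median is kept, which is unbiased there by symmetry. A plain CLR
mean is *not* used: it absorbs the minority trend itself and injects
its negative into every null taxon.

Time reversal of a profile swaps increase↔decrease similarities and
leaves the tent similarities unchanged (the tent shapes are
palindromic — a peak remains a peak under reversal); the test suite
asserts this exact involution.

### Microbiome summaries

Counts are scaled to the minimum library size (deterministic scaling
rather than rarefaction, chosen for reproducibility; proportions are
unchanged by the scaling), taxa strictly below `min_rel_abund`
(default 0.001) within a sample are zeroed, and rows are re-closed.
Chao1 uses the bias-corrected form `S_obs + F₁(F₁−1)/(2(F₂+1))` on raw
integer counts; Simpson is reported in the diversity form `1 − Σp²`
(dominance form available). The Fir/Bac ratio divides summed
Firmicutes by summed Bacteroidetes relative abundance and is undefined
(error) at zero Bacteroidetes.

The Mantel test correlates upper-triangle entries of two subject
distance matrices (Spearman by default), permuting subject labels of
the second matrix jointly on rows and columns;
`p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`, one-tailed for positive
association (default 999 permutations, seeded). UniFrac distances
require a phylogeny and are out of scope; Bray-Curtis is provided as
the taxa-space distance.

### BMAge composite score

Z-standardization uses the young group's per-metric mean and sample SD
(n−1 denominator); a zero-SD metric is an error naming the metric.
Sub-scores:

- motor = mean of the six kinematic Z's,
- characteristic = `(Z₁+…+Z₆ − Z_pausing)/7` with the
  pausing-followed-by-sniffing metric (which rises with age) entering
  negated and last,
- behavioral total = (motor + characteristic)/2,
- metabolomic = `(Σ Z_up − Σ Z_down)/n_biomarkers`, with directions
  taken from the treatment-vs-vehicle differential table. The
  parenthesization of the metabolomic score is ambiguous in prose; the
  per-biomarker signed average is the only dimensionless reading and
  is the one implemented. A biomarker missing for an animal
  contributes zero while the denominator stays the full count.

No metric other than pausing is re-signed: the raw Z against the young
reference is used as-is. Taking biomarker directions from the
treatment-vs-vehicle contrast makes both domain scores ≈ 0 for young
animals and negative for aged ones, so the cross-domain regression
(OLS of metabolomic on behavioral score, two-sided slope t-test) has a
positive slope when the domains agree.

## The synthetic cohort model

`generate_cohort` emulates a five-arm design — young reference, aged
water, aged vehicle, low dose, high dose — with `n_per_group = 10`
animals, five organs × 50 features by default.

- **Metabolome.** Feature baselines are uniform on log2 ∈ [14, 24]
  (typical LC-MS intensity range); intensities are log-normal so
  effects are additive on the log2 scale and the 0.26 threshold acts
  linearly. A fraction `aging_fraction = 0.4` of features per organ is
  age-affected with random direction and standardized shift
  `aging_effect = 1.5` (log2-SD units) in all aged arms; a fraction
  `reversal_fraction = 0.6` of those is restored to the young mean in
  the high-dose arm and half-restored in the low-dose arm — the
  100%/50% split encodes a dose-dependent reversal in the simplest
  monotone form.
  2% of entries are zeroed as missing ions.
- **Coupling.** Each animal carries a latent biological-age deviation
  `u ~ N(0,1)`. Residuals of age-affected readouts decompose as
  `c·u + √(1−c²)·ε` with `latent_coupling c = 0.5`, so every affected
  metric correlates r ≈ 0.5 with the latent factor while the total
  residual SD stays `noise_sd` — realized standardized shifts
  therefore converge to the nominal `aging_effect` (the calibration
  the tests check at n = 200). Aging features within an organ
  additionally share a pathway factor (`pathway_coupling = 0.65`,
  signed by each feature's direction), giving the co-regulation
  structure that correlation networks need; without it no
  feature pair reaches |r| > 0.8.
- **Behavior.** Six kinematic and six sequence metrics decline with
  age; pausing-followed-by-sniffing rises. The behavioral aging shift
  is `behavior_effect = 2.0` SD with dose multipliers (0, 1, 1, ⅔, ⅓)
  for (young, water, vehicle, low, high) — motor decline in aged
  rodents is large relative to single-metabolite shifts, and 2 SD
  gives the four-group ordering adequate separation at n = 10 (an a
  priori power consideration, not a fitted value). NOR exploration
  times and Y-maze entry strings are generated from a declining true
  discrimination index and alternation propensity.
- **Sphingolipids.** SM, Cer and DHCer concentrations per tissue are
  log-normal; in the responsive tissues (gut, plasma, muscle) the
  log SM/Cer ratio gains `smcer_effect = 1.0` times the arm's
  youthfulness, reproducing the elevated-ratio signature of treated
  animals.
- **Taxa series.** Genus baselines are log-normal; injected trends add
  `amplitude × template shape` (unit-norm) to a taxon's log abundance
  in its designated treatment arm, plus `N(0, overdispersion)` per
  subject and timepoint. Trending taxa sit `trend_baseline_offset = −3`
  log-units below the null taxa so they contribute little total mass
  and stay clear of the abundance range that anchors the drift
  estimator. Proportions convert to counts at depth 50,000 by
  deterministic rounding (`sampling="expected"`), making
  `overdispersion` the single noise source and the noise-free limit
  exactly monotone; multinomial read sampling is available by option.
  The pipeline default injects 20 decreasing genera in the vehicle
  arm, 20 increasing and 20 decreasing in the high-dose arm, and one
  genus decreasing in both (the cluster-overlap case), out of 120.

**What the generator does not emulate:** batch and injection-order
effects, heteroscedastic intensity-dependent noise, correlated missing
patterns, metabolite identities and pathway membership, phylogenetic
structure among taxa, subject dropout, and any pharmacokinetics.
Passing tests therefore demonstrate correctness and calibration of the
*procedures* under a clean generative model, not robustness to the
full messiness of real LC-MS or 16S data.

## Orchestration and reproducibility

`run_pipeline` executes eight stages (synth, behavior, diff,
biomarkers, network, trends, microbiome, bmage) in dependency order
from a single `RunConfig`. All randomness flows from one root seed
through per-stage `numpy` seed-sequence substreams, so disabling a
downstream stage never changes upstream outputs, and a rerun with the
same config reproduces identical SHA-256 checksums for every table
(floats are written with a fixed `%.10g` format). The report records
seed, thresholds, per-stage summaries and output checksums; failed
stages rename their partial outputs with a `.partial` suffix and raise
an error tagged with the stage name.

## Problem sizes

Defaults were chosen so the complete test suite and the acceptance
script each run in a few minutes on one CPU: the default cohort is
5 × 10 animals with 5 organs × 50 features and 120 genera × 4
timepoints; calibration studies use 2,000 null feature tests, 500 null
trend datasets, and 200 Mantel replicates at 199 permutations (the
p-value grid then makes the nominal rejection rule exact at 10/200);
the composite-score replicate study uses 100 seeded cohorts; the
trend-recovery experiment uses 200 taxa with 50 per template, where the
balanced design also cancels closure drift by symmetry.

## Known limitations

- Trend-cluster detection power is dilution-limited: with 20 injected
  genera among 120, a single cluster is detected at roughly z ≈ 3, but
  two simultaneous clusters in one arm each carry only moderate power;
  the permutation null's expected counts are inflated by the trending
  taxa themselves.
- The hypergeometric (M, K, n) pooling treats assignment events across
  permutations as exchangeable draws; it is conservative for small
  numbers of profiles.
- Equal-variance t-tests assume comparable within-group spread on the
  log scale; the Welch option exists but is not the default because
  the screening convention names Student's test.
- The median-of-ratios drift correction assumes fewer than half the
  taxa trend in any one group (or that trends are balanced); designs
  violating both assumptions will leak drift into null taxa.
- Network edge significance uses raw per-edge p-values by design; at
  50 animals the |r| > 0.8 requirement dominates and the p-threshold
  is essentially inactive.
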