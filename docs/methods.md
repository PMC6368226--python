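# Methods

This note documents the models and procedures `emtsig` implements, the
choices made where the design was genuinely open, what the synthetic data
does and does not emulate, and the numerical conventions that pin down every
result.

## Expression preprocessing

All expression values are log2-scale. Normalization is an additive
median-reference scaling: every sample is shifted so its median equals the
median of the reference sample, defined as the sample whose per-sample
median is the median of all per-sample medians (lower of the two central
samples for an even count, so the reference is always an actual sample).
The operation is idempotent and preserves within-sample ranking. It is a
deliberately simple stand-in for rank-invariant intensity normalization of
raw arrays: the synthetic generator emits already-normalized data, so this
stage is exercised by its own tests rather than by the pipeline. Optional
per-batch mean removal (subtract batch mean, restore grand mean, per
probeset) is available but off by default; it is not empirical-Bayes batch
correction and is not presented as one.

Log2 ratios subtract, per probeset, the mean of the same cell line's
untreated-control samples, removing basal between-line differences. Every
line must have at least one untreated sample; the mean of a line's control
ratios is exactly zero by construction.

Autoscaling centers each probeset row to mean 0 and scales to unit sample
standard deviation (ddof = 1). Zero-variance rows cannot be scaled and are
dropped with a warning rather than raising, because subsetting a small
cohort to signature genes can legitimately produce constant rows.

## PCA

PCA is computed by SVD of the autoscaled samples × probesets matrix, i.e.
correlation-scale PCA; the scale of the original figures is not recorded
beyond the autoscaling of the heatmap values, and correlation-scale is
adopted throughout. Loadings are unit-norm right singular vectors ordered
by decreasing variance; percent variance uses squared singular values over
the total. The base sign convention flips each loading column so its
largest-magnitude entry is positive — purely for determinism; downstream
orientation (below) overrides it.

## Differential screen

Group scheme: *Untreated* = untreated samples of responder and non-responder
lines at every time point; *EMT* / *no-EMT* = all treated samples of
responder / non-responder lines (time points pooled, matching the original
single-analysis treatment of the 2–120 h course); *TGFβ* = EMT ∪ no-EMT;
constitutively mesenchymal lines appear in no group. "Other" in the
vs-other comparisons means all non-excluded samples outside the experimental
group.

Per comparison and probeset we record group means, the difference Δ
(experimental − reference), a strict complete-separation flag (ties count
as overlap — "complete separation" read literally), a two-sided Welch
t-test (the unequal-variance flavor is our choice; the original flavor is
unstated) and a two-sided Mann–Whitney U (exact when both groups have ≤ 10
samples, normal approximation with continuity correction otherwise).
Singleton groups get p = 1 with a warning rather than an error so a
degenerate design still produces a full table.

The screening call is sign-agreement only: direction ±1 when the
experimental mean and Δ share a sign and |Δ| ≥ 0.585 (inclusive), else 0.
No p-value participates at this stage and no multiple-testing correction is
applied; the dual p < 0.002 condition belongs to the pruning stage only.

Categorization: EMT-related requires the three EMT-experimental calls to
agree in a non-zero direction and every *present* (non-zero) no-EMT call to
be opposite; no-EMT-related is the mirror image; TGFβ-related requires the
three vs-Untreated calls to share a sign. Priority when multiple hold:
conflict (both phenotypes) > EMT-related > no-EMT-related > TGFβ-related,
so each probeset gets exactly one category and conflicts never reach the
signature.

## Strongest-probeset pruning and curated list

A categorized probeset survives pruning iff (a) ≥ 1 of its three phenotype
comparisons shows complete separation, (b) the worst (smallest-|Δ|) of the
three has |Δ| ≥ 1.0, and (c) that same worst comparison has both t and
Mann–Whitney p < 0.002. Applying the p condition to all three comparisons
instead is a config option (`check_all_three`); the default attaches both
clauses to the worst comparison, following the sentence structure of the
source protocol. Raising the fold threshold can only shrink the selected
set (tested monotonicity).

Curated probesets are merged in with provenance `curated`; their directions
come from the categorization table, and a curated probeset that was already
selected algorithmically keeps `algorithmic` provenance.

### Packaged fixtures

`reference_signature_synthetic_probesets.tsv` reproduces the published
77-gene signature symbol list across 105 probesets. Only the gene symbols
are authentic: probeset identifiers, the choice of which 28 genes carry a
second probeset (the first 28 alphabetically), and the direction signs are
synthetic placeholders, because the published table prints symbols only.
`curated_probesets_synthetic.tsv` holds the 7-probeset curated list over
its six named genes (DDR1, LTBP1, PDGFB, SMURF1, SNAI1, TGFBR1); which gene
contributes two probesets is not recorded, and DDR1 — a gene with several
probesets on the array family — is the documented assumption.

## Translation filter

Per cohort: subset to shared signature probesets (≥ 3 required, else the
cohort is skipped with a warning), autoscale, PCA, then orient PC1 so that
the majority of loading signs match the signature directions. A probeset
agrees in a cohort when its oriented PC1 loading sign equals its direction;
zero loadings count as disagreement. Probesets agreeing in ≤ 50% (strict
majority retains) of the cohorts in which they are measured are removed;
probesets measured in no cohort are removed with a warning since they
cannot be validated. Only PC1 participates: the original procedure used
first-two-component loadings for visual assessment without a stated numeric
rule, and PC1 carries the signature axis. The decision is invariant to
cohort ordering and to a global sign flip of any cohort's values (the
orientation step absorbs the flip).

## Scoring and stratification

A cohort's score is the oriented PC1 sample score of its autoscaled
signature-gene expression. Orientation makes the correlation between PC1
loadings and signature directions positive, so "high score = more
mesenchymal" deterministically, and the orientation never consults outcome
data. One consequence worth stating: negating the expression matrix negates
the scores exactly (any score that is a projection of the data must), while
leaving loadings and orientation unchanged — which samples look mesenchymal
genuinely reverses under negation.

Median split: score > median → high; the median sample and ties go low (a
documented, test-pinned convention; the original cutoff rule does not say).
K-means stratification runs 2-means with k-means++ seeding, 10 restarts and
a fixed seed on the autoscaled signature-gene expression (raw vs autoscaled
is unstated in the original; autoscaled adopted), labelling the cluster
with the higher mean PC1 score "high" so the labelling is invariant to
cluster indexing.

## Survival analysis

OS records are (os_time, os_event) directly. MFS is the composite endpoint:
patients flagged metastatic at surgery are excluded; time = min(met_time,
os_time) and the event indicator is that of the clock that fired first.
Fixed-horizon ("3-year"/"5-year") analyses administratively censor every
record at 36/60 months — whether the original horizons were truncations or
landmark analyses is unstated, and truncation is adopted and labelled.

Kaplan–Meier estimation uses the product-limit estimator (lifelines) with
events-before-censoring at tied times. The two-group log-rank statistic is
computed in-house from the pooled observed/expected/hypergeometric-variance
sums (1 df, two-sided), which pins the zero-event degenerate case
(statistic 0, p 1) and keeps lifelines available as an independent
cross-check in the tests (they agree to 1e-6 on random data). ΔMFS at a
horizon is S_high(t) − S_low(t) in percentage points, so worse high-group
survival is negative.

## Association tests

Score-vs-binary-group comparisons use a two-sided Welch t-test (the colon
metastasis-at-surgery analysis names a two-sided t-test; Welch is our
flavor choice, also applied per mutation column for consistency, with a
rank-sum alternative behind a flag). Mutation enrichment between high/low
clusters uses the two-sided Fisher exact test under the method-of-small-
p-values definition (sum of all tables with probability ≤ the observed
one), the sample odds ratio (∞ allowed), and reports Benjamini–Hochberg q
alongside the nominal p — no correction is applied by default because the
nominal p is the primary readout.

## Synthetic data

The generators are pure functions of (config, seed) and emulate:

* **Cell-line time course** — defaults: 4 responder, 8 non-responder, 1
  constitutively mesenchymal line; duplicate untreated controls plus
  treated samples at 24 h and 120 h; 30 EMT-up, 30 EMT-down, 20 no-EMT, 20
  shared-TGFβ and 400 null probesets; effect 1.5 log2 units, residual noise
  sd 0.3, per-line baseline sd 1.0. EMT probesets respond only in treated
  responder lines (and constitutively in the mesenchymal line), no-EMT
  probesets only in treated non-responders, shared probesets in all treated
  lines. These defaults mirror the source experiment's scale (12 analyzed
  lines, ~1.5-fold screening threshold) and give the derivation clear but
  not trivial margins.
* **Tumor cohorts** — latent activity z ~ N(0,1) drives signature-gene
  expression (direction × β × z + noise, β = 1, noise sd 0.5) and two
  exponential event clocks with hazards h₀·exp(γ·z), γ = 0.7, the
  metastasis clock on a 2× earlier scale (1/40 vs 1/80 per month);
  censoring uniform on (0, 120) months, independent of z; baseline
  metastases at 2%; stage labels drawn to an early-stage-heavy mix. The
  two-clock construction matches the composite metastasis-or-death endpoint
  without asserting biology beyond it.
* **Colon-style cohort** — 96 patients, 25% metastatic at surgery, carriers'
  z shifted by +1 sd.
* **Mutation cohorts** — carrier probability depends on the sign of z
  (defaults 0.05 vs 0.4 for planted-enriched genes; constant for nulls).

What the generator does *not* emulate: probe-level intensity artifacts,
realistic microarray distributions, batch structure, correlated gene
modules beyond the single latent axis, or informative censoring. Passing
tests therefore demonstrate that the algorithms recover planted structure
under the stated noise model — not that the signature itself is prognostic in
real tumors, which requires the original cohorts.

## Problem sizes and determinism

Property tests and the acceptance script use 20 seeded replicates for
derivation/translation properties and 100 for survival calibration and
power — sizes at which the binomial checks (e.g. ≥ 80/100 rejections at
hazard ratio 2, ≤ 10/100 under the null) are stable across seed bases while
the whole suite runs in well under a minute of simulation time. All
randomness flows through `numpy.random.default_rng(seed)` (and scikit-learn's
`random_state` for k-means); same config + seed reproduces every table
bit-identically.

## Known limitations

* The synthetic probeset identifiers in the packaged signature fixture mean
  probeset-level joins against real array data are not meaningful; only the
  gene-symbol view is.
* The translation filter's numeric rule (PC1-only, strict-majority vote) is
  this package's own formalization of a procedure originally assessed
  visually; alternative rules (PC2 participation, weighted votes) are not
  implemented.
* The normalization stand-in assumes data already on a comparable log2
  scale; it will not rescue raw, unnormalized intensities.
* No Cox modelling, competing risks, or confidence bands; the log-rank /
  KM toolkit covers only what the analysis requires.
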