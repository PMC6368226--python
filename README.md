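# emtsig

Derivation, cross-cohort translation, scoring and survival evaluation of a
TGFβ-induced epithelial-to-mesenchymal-transition (EMT) gene-expression
signature.

## The problem

TGFβ can drive EMT — the phenotypic shift by which epithelial tumor cells
gain migratory, mesenchymal traits — and EMT capacity is implicated in the
development of metastasis in non-small-cell lung cancer. Not every cell line
responds: treating a panel of lung adenocarcinoma lines with TGFβ-1 splits
them into EMT responders and non-responders. The expression changes specific
to the responding lines define a *TGFβ-EMT* signature whose first principal
component, applied to a tumor cohort, scores each tumor's EMT-like state and
stratifies patients for metastasis-free survival (MFS).

`emtsig` implements that entire analysis as a tested, reusable pipeline for
computational biologists: signature derivation from a multi-line treatment
time course, translation of the signature into tumor cohorts, PC1 scoring and
stratification, Kaplan–Meier/log-rank survival analysis, and
mutation-association tests — plus a synthetic-data generator with planted
ground truth so every stage is verifiable without any external downloads.

## The method

**Derivation.** Expression is reduced to log2 ratios per sample versus the
mean of the same cell line's untreated controls. Samples are grouped as
*Untreated*, *EMT* (treated responders), *no-EMT* (treated non-responders) and
*TGFβ* = EMT ∪ no-EMT (constitutively mesenchymal lines are excluded), and
seven two-group comparisons are run (EMT vs no-EMT / other / Untreated, the
no-EMT mirror images, and TGFβ vs Untreated). A probeset is differentially
expressed in a comparison when the experimental-group mean and the group
difference Δ agree in sign and |Δ| ≥ 0.585 (1.5-fold). Probesets are
*EMT-related* when all three EMT comparisons agree in a non-zero direction
and any non-zero no-EMT call is opposite; probesets qualifying for both
phenotypes are conflicts and are dropped.

**Pruning.** EMT-related probesets are kept only if at least one of the three
EMT comparisons shows complete separation (no overlap between groups), the
worst of the three passes |Δ| ≥ 1.0 (2-fold), and both the Welch-t and
Mann–Whitney p-values of that worst comparison are < 0.002. A curated list
of EMT-biology probesets can be merged in.

**Translation.** For each external tumor cohort, the signature genes are
autoscaled and decomposed by PCA; PC1 is oriented so that most loading signs
match the cell-line directions, and probesets whose loading sign contradicts
their direction in a majority of cohorts are removed.

**Scoring and survival.** A cohort's signature score is its oriented PC1
sample score; patients are split at the median score (or by 2-means
clustering). MFS counts metastasis and death as events and excludes patients
metastatic at surgery; groups are compared with the log-rank test, and ΔMFS
reports the high-minus-low difference in Kaplan–Meier survival at 3- or
5-year horizons. Mutation associations use Welch t-tests (scores by carrier
status) and per-gene two-sided Fisher exact tests (carriage by score
cluster).

The package ships a reference signature table reproducing the published
77-gene list over 105 probesets (synthetic probeset identifiers — see
`docs/methods.md`) and the 7-probeset curated list.

## Worked example

Run the full synthetic pipeline (simulate → derive → translate → score →
survive → associate) with the default study design — 4 responder + 8
non-responder + 1 mesenchymal line, two treated time points plus duplicate
controls, 60 planted EMT probesets among 500, then a 150-patient cohort whose
latent EMT activity drives both expression and hazards:

```sh
emtsig run-all --seed 1 --out-dir out/
```

The stage log (`out/report.json`) for seed 1 reads, abbreviated:

```
de_screen           categories: {none: 400, EMT-related: 60, no-EMT-related: 20, TGFB-related: 20}
signature_builder   n_strongest: 60 -> signature of 60 probesets
translation         60 -> 60 probesets (3 simulated cohorts, no discordance planted)
scoring             150 samples, PC1 captures 82.3% of variance, 75 high / 75 low
survival (MFS)      n=148, chi2=53.34, p=2.8e-13, dMFS(36)=-54.1, dMFS(60)=-29.4
associations        colon t=-5.16, p=1.4e-05; top enriched mutation: ZNF831, p=1.7e-10
```

Reading this: the screen recovered exactly the 60 planted EMT probesets (no
false positives among 400 nulls), the cohort's high-score arm has markedly
worse metastasis-free survival (negative ΔMFS, as expected when high score =
more mesenchymal), metastatic-at-surgery colon tumors score higher, and the
planted high-score mutation enrichment is top-ranked. Two patients were
excluded from MFS (simulated baseline metastases), hence n = 148 of 150.

Each stage is also available separately (`emtsig simulate`, `derive`,
`translate`, `score`, `survive`, `associate`) on the documented TSV formats,
and as plain library calls (`emtsig.run_de_screen`, `emtsig.score_cohort`,
...).

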