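"""Score-versus-group comparisons and mutation enrichment.

Three analyses connect the signature score to clinical or genomic
groupings:

* a two-sided Welch t-test of PC1 scores between binary clinical groups
  (e.g. metastatic vs non-metastatic at surgery in a colon cohort);
* the same comparison run per mutation column, wild-type versus carrier
  (a rank-sum alternative is available, since the original test behind
  the mutation panels is not pinned down);
* a per-gene two-sided Fisher's exact test of mutation carriage between
  high- and low-score clusters, using the "small p-values" two-sided
  definition (sum of all tables with probability ≤ the observed one).
  Benjamini–Hochberg q-values are reported alongside, but the nominal p
  is the primary readout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def score_group_ttest(scores: pd.Series, labels: pd.Series):
    """Two-sided Welch t-test of scores between two label classes.

    Returns ``(t, p, group_means)`` where ``group_means`` maps each
    label to its mean score.  The t statistic is signed first-class
    minus second-class in sorted label order.  Both classes need ≥ 2
    samples.
    """
    labels = labels.reindex(scores.index)
    classes = sorted(pd.unique(labels.dropna()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {classes}")
    a = scores[labels == classes[0]]
    b = scores[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    means = {classes[0]: float(a.mean()), classes[1]: float(b.mean())}
    return float(t), float(p), means


def mutation_score_comparison(scores: pd.Series, mutations: pd.DataFrame,
                              method: str = "ttest") -> pd.DataFrame:
    """WT-versus-mutant score comparison per mutation column.

    ``mutations`` holds one 0/1 column per gene (columns may carry a
    ``mut_`` prefix, which is stripped in the output).  Columns with a
    single class are skipped with a warning.  ``method`` is ``ttest``
    (Welch, default) or ``ranksum`` (Mann–Whitney U).  The statistic is
    signed mutant-minus-WT, so a negative value means carriers score
    lower.
    """
    if method not in ("ttest", "ranksum"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for col in mutations.columns:
        flags = mutations[col].reindex(scores.index).astype(float)
        mut = scores[flags == 1]
        wt = scores[flags == 0]
        gene = col[4:] if col.startswith("mut_") else col
        if len(mut) < 2 or len(wt) < 2:
            logger.warning("mutation_score_comparison: %s has a single class; skipped",
                           gene)
            continue
        if method == "ttest":
            stat, p = stats.ttest_ind(mut, wt, equal_var=False)
        else:
            stat, p = stats.mannwhitneyu(mut, wt, alternative="two-sided")
        rows.append((gene, float(stat), float(p), float(mut.mean()),
                     float(wt.mean()), int(len(mut)), int(len(wt))))
    return pd.DataFrame(rows, columns=["gene", "statistic", "p", "mean_mutant",
                                       "mean_wt", "n_mutant", "n_wt"])


def fisher_enrichment(groups: pd.Series, mutations: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Fisher's exact test of mutation carriage by cluster.

    ``groups`` holds "high"/"low" per sample.  For each gene the 2×2
    table (high-mutant, high-WT; low-mutant, low-WT) is tested two-sided.
    The odds ratio is the sample (cross-product) ratio and may be
    infinite.  Returns gene, counts, odds ratio, p and BH q, sorted by p.
    """
    groups = groups.dropna()
    n_high = int((groups == "high").sum())
    n_low = int((groups == "low").sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both clusters must be non-empty")
    if mutations.shape[1] == 0:
        return pd.DataFrame(columns=["gene", "high_mut", "high_wt", "low_mut",
                                     "low_wt", "odds_ratio", "p", "q"])
    rows = []
    for col in mutations.columns:
        flags = mutations[col].reindex(groups.index).astype(bool)
        gene = col[4:] if col.startswith("mut_") else col
        a = int((flags & (groups == "high")).sum())   # high, mutant
        b = n_high - a                                # high, WT
        c = int((flags & (groups == "low")).sum())    # low, mutant
        d = n_low - c                                 # low, WT
        oddsratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((gene, a, b, c, d, float(oddsratio), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "high_mut", "high_wt", "low_mut",
                                      "low_wt", "odds_ratio", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", kind="stable").reset_index(drop=True)
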