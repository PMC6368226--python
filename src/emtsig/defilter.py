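"""Seven-comparison differential-expression screen and probeset categorization.

Samples from a multi-line TGFβ time course are grouped as *Untreated*
(untreated samples of all non-excluded lines, every time point), *EMT*
(treated samples of lines that undergo TGFβ-induced EMT), *no-EMT*
(treated samples of lines that do not), and *TGFβ* = EMT ∪ no-EMT.
Constitutively mesenchymal lines are excluded from every group.

Seven two-group comparisons are run on log2 ratios: EMT vs no-EMT, EMT
vs other, EMT vs Untreated, no-EMT vs EMT, no-EMT vs other, no-EMT vs
Untreated, and TGFβ vs Untreated, where "other" means all non-excluded
samples outside the experimental group.  A probeset is called
differentially expressed in a comparison when the experimental-group
mean and the between-group difference agree in sign and the absolute
difference is ≥ 0.585 log2 units (1.5-fold); this sign-agreement rule is
the screening criterion — p-values (Welch t and Mann–Whitney U) are
carried along but only gate the later strongest-probeset pruning.

Probesets are then categorized: *EMT-related* if all three
EMT-experimental comparisons agree in a non-zero direction and every
non-zero call among the no-EMT-experimental comparisons is opposite (the
condition applies only where such a call exists); *no-EMT-related*
symmetrically; *TGFβ-related* if the three vs-Untreated comparisons
share a non-zero sign.  A probeset meeting both the EMT- and
no-EMT-related criteria behaves oppositely in the two phenotypes and is
flagged *conflict*, excluding it from all downstream stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

# Comparison labels, in the canonical order.
EMT_GROUPINGS = ("EMT_vs_noEMT", "EMT_vs_other", "EMT_vs_untreated")
NOEMT_GROUPINGS = ("noEMT_vs_EMT", "noEMT_vs_other", "noEMT_vs_untreated")
TGFB_GROUPINGS = ("EMT_vs_untreated", "noEMT_vs_untreated", "TGFB_vs_untreated")
COMPARISONS = EMT_GROUPINGS + NOEMT_GROUPINGS + ("TGFB_vs_untreated",)

CATEGORIES = ("EMT-related", "no-EMT-related", "TGFB-related", "none", "conflict")


@dataclass
class FilterConfig:
    """Thresholds of the differential screen and strongest-probeset pruning.

    ``fold_threshold_log2`` (default 0.585 ≈ 1.5-fold) gates the initial
    screen; ``strong_fold_threshold_log2`` (default 1.0 = 2-fold) and
    ``strong_p_cutoff`` (default 0.002, applied to both the t and
    Mann–Whitney p of the worst comparison) gate the pruning stage.
    """

    fold_threshold_log2: float = 0.585
    strong_fold_threshold_log2: float = 1.0
    strong_p_cutoff: float = 0.002

    def __post_init__(self) -> None:
        for name in ("fold_threshold_log2", "strong_fold_threshold_log2", "strong_p_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class GroupScheme:
    """Sample groups of the screen; ``tgfb`` is the EMT ∪ no-EMT union."""

    untreated: list[str]
    emt: list[str]
    no_emt: list[str]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sets = [set(self.untreated), set(self.emt), set(self.no_emt)]
        for i in range(3):
            for j in range(i + 1, 3):
                inter = sets[i] & sets[j]
                if inter:
                    raise ValueError(f"groups overlap on samples: {sorted(inter)}")
        excl = set(self.excluded)
        leaked = excl & (sets[0] | sets[1] | sets[2])
        if leaked:
            raise ValueError(f"excluded samples appear in a group: {sorted(leaked)}")

    @property
    def tgfb(self) -> list[str]:
        return list(self.emt) + list(self.no_emt)

    @property
    def all_included(self) -> list[str]:
        return list(self.untreated) + list(self.emt) + list(self.no_emt)

    @classmethod
    def from_annotation(cls, ann: pd.DataFrame) -> "GroupScheme":
        """Build groups from a cell-line annotation table.

        Treated samples of EMT-responder lines form EMT, treated samples
        of non-EMT lines form no-EMT, untreated samples of both form
        Untreated.  Constitutively-mesenchymal lines are excluded
        entirely (treated and untreated).
        """
        treated = ~ann["treatment"].astype(str).str.lower().isin(
            ["untreated", "u", "0", "false"])
        cls_ = ann["phenotype_class"].astype(str)
        excluded = ann.loc[cls_ == "constitutively-mesenchymal", "sample_id"]
        emt = ann.loc[treated & (cls_ == "EMT-responder"), "sample_id"]
        no_emt = ann.loc[treated & (cls_ == "non-EMT"), "sample_id"]
        untreated = ann.loc[~treated & cls_.isin(["EMT-responder", "non-EMT"]),
                            "sample_id"]
        return cls(list(untreated), list(emt), list(no_emt), list(excluded))


@dataclass
class Comparison:
    label: str
    experimental: list[str]
    reference: list[str]


def enumerate_comparisons(scheme: GroupScheme) -> list[Comparison]:
    """The seven two-group comparisons of the screen, in canonical order."""
    other_than_emt = list(scheme.no_emt) + list(scheme.untreated)
    other_than_noemt = list(scheme.emt) + list(scheme.untreated)
    comps = [
        Comparison("EMT_vs_noEMT", list(scheme.emt), list(scheme.no_emt)),
        Comparison("EMT_vs_other", list(scheme.emt), other_than_emt),
        Comparison("EMT_vs_untreated", list(scheme.emt), list(scheme.untreated)),
        Comparison("noEMT_vs_EMT", list(scheme.no_emt), list(scheme.emt)),
        Comparison("noEMT_vs_other", list(scheme.no_emt), other_than_noemt),
        Comparison("noEMT_vs_untreated", list(scheme.no_emt), list(scheme.untreated)),
        Comparison("TGFB_vs_untreated", scheme.tgfb, list(scheme.untreated)),
    ]
    for c in comps:
        if not c.experimental or not c.reference:
            raise ValueError(f"comparison {c.label} has an empty group")
    return comps


def compare_groups(ratios: ExpressionMatrix, experimental, reference,
                   cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-probeset two-group statistics on log2 ratios.

    Returns a DataFrame indexed by probeset with columns ``mean_exp``,
    ``mean_ref``, ``difference`` (= mean_exp − mean_ref),
    ``complete_separation`` (strict: every experimental value above —
    or below — every reference value), ``t_p`` (two-sided Welch) and
    ``mw_p`` (two-sided Mann–Whitney U; exact when both groups have
    ≤ 10 samples, normal approximation with continuity correction
    otherwise).  Singleton groups get p = 1 with a logged warning.
    """
    experimental, reference = list(experimental), list(reference)
    if not experimental or not reference:
        raise ValueError("both groups must be non-empty")
    if set(experimental) & set(reference):
        raise ValueError("groups must be disjoint")
    A = ratios.values[experimental].to_numpy()
    B = ratios.values[reference].to_numpy()
    mean_exp = A.mean(axis=1)
    mean_ref = B.mean(axis=1)
    sep = (A.min(axis=1) > B.max(axis=1)) | (A.max(axis=1) < B.min(axis=1))
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a < 2 or n_b < 2:
        logger.warning("compare_groups: group of size 1; p-values set to 1")
        t_p = np.ones(A.shape[0])
        mw_p = np.ones(A.shape[0])
    else:
        t_p = stats.ttest_ind(A, B, axis=1, equal_var=False).pvalue
        t_p = np.nan_to_num(t_p, nan=1.0)
        method = "exact" if (n_a <= 10 and n_b <= 10) else "asymptotic"
        mw_p = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided",
                                  method=method).pvalue
        mw_p = np.nan_to_num(np.minimum(mw_p, 1.0), nan=1.0)
    return pd.DataFrame(
        {
            "mean_exp": mean_exp,
            "mean_ref": mean_ref,
            "difference": mean_exp - mean_ref,
            "complete_separation": sep,
            "t_p": t_p,
            "mw_p": mw_p,
        },
        index=ratios.values.index,
    )


def call_de(stats_df: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.Series:
    """Directional DE call per probeset for one comparison.

    +1 when the experimental mean and the difference are both positive
    and |difference| ≥ the fold threshold (inclusive); −1 symmetrically;
    0 otherwise.
    """
    cfg = cfg or FilterConfig()
    d = stats_df["difference"].to_numpy()
    me = stats_df["mean_exp"].to_numpy()
    big = np.abs(d) >= cfg.fold_threshold_log2
    up = (me > 0) & (d > 0) & big
    down = (me < 0) & (d < 0) & big
    return pd.Series(np.where(up, 1, np.where(down, -1, 0)),
                     index=stats_df.index, name="direction")


def categorize(calls: pd.DataFrame) -> pd.DataFrame:
    """Categorize probesets from their seven directional calls.

    ``calls`` is probesets × comparison labels with entries in {−1, 0,
    +1}.  Returns a DataFrame with ``category`` and ``direction``
    columns; direction is 0 for *none* and *conflict*.
    """
    missing = [c for c in COMPARISONS if c not in calls.columns]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")

    def _grouping_ok(exp_cols, opp_cols):
        E = calls[list(exp_cols)].to_numpy()
        O = calls[list(opp_cols)].to_numpy()
        same_sign = (np.abs(E).min(axis=1) > 0) & (np.ptp(np.sign(E), axis=1) == 0)
        d = np.sign(E[:, 0])
        # any non-zero opposite-grouping call must have the opposite sign
        opp_ok = ((O == 0) | (O == -d[:, None])).all(axis=1)
        return same_sign & opp_ok, d

    emt_ok, emt_dir = _grouping_ok(EMT_GROUPINGS, NOEMT_GROUPINGS)
    noemt_ok, noemt_dir = _grouping_ok(NOEMT_GROUPINGS, EMT_GROUPINGS)
    T = calls[list(TGFB_GROUPINGS)].to_numpy()
    tgfb_ok = (np.abs(T).min(axis=1) > 0) & (np.ptp(np.sign(T), axis=1) == 0)
    tgfb_dir = np.sign(T[:, 0])

    n = len(calls)
    category = np.full(n, "none", dtype=object)
    direction = np.zeros(n, dtype=int)
    # priority: conflict > EMT-related > no-EMT-related > TGFB-related
    mask = tgfb_ok
    category[mask] = "TGFB-related"
    direction[mask] = tgfb_dir[mask]
    mask = noemt_ok & ~emt_ok
    category[mask] = "no-EMT-related"
    direction[mask] = noemt_dir[mask]
    mask = emt_ok & ~noemt_ok
    category[mask] = "EMT-related"
    direction[mask] = emt_dir[mask]
    mask = emt_ok & noemt_ok
    category[mask] = "conflict"
    direction[mask] = 0
    n_conflict = int(mask.sum())
    if n_conflict:
        logger.info("categorize: %d conflict probesets removed from further analysis",
                    n_conflict)
    return pd.DataFrame({"category": category, "direction": direction},
                        index=calls.index)


def run_de_screen(ratios: ExpressionMatrix, scheme: GroupScheme,
                  cfg: FilterConfig | None = None):
    """Run all seven comparisons, call DE, and categorize.

    Returns ``(stats_by_comparison, calls, categories)`` where
    ``stats_by_comparison`` maps comparison label → per-probeset stats
    table, ``calls`` is the probesets × 7 direction matrix, and
    ``categories`` has ``category``/``direction`` per probeset.
    """
    cfg = cfg or FilterConfig()
    stats_by_comparison = {}
    calls = {}
    for comp in enumerate_comparisons(scheme):
        st = compare_groups(ratios, comp.experimental, comp.reference, cfg)
        stats_by_comparison[comp.label] = st
        calls[comp.label] = call_de(st, cfg)
    calls_df = pd.DataFrame(calls)[list(COMPARISONS)]
    return stats_by_comparison, calls_df, categorize(calls_df)
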