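"""Signature pruning, curated merging, and tumor-cohort translation.

The categorized probesets from the differential screen are pruned to the
strongest candidates: a probeset is retained only if (a) at least one of
its three phenotype comparisons shows complete separation, (b) the worst
(smallest-|difference|) of the three passes a 2-fold cutoff, and (c) on
that same worst comparison both the Welch-t and Mann–Whitney p-values
are below 0.002.  A short curated list of probesets of EMT-related
biological interest is then merged in.

Because cell lines are a simplified system, signature genes may behave
differently in tumors.  The translation filter scores each external
tumor cohort's expression of the signature genes by PCA and removes
probesets whose first-principal-component loading sign contradicts their
cell-line-derived direction in a majority of cohorts.  PC1 is oriented
per cohort so that the majority of loading signs match the signature
directions, making the test invariant to the arbitrary PC sign and to
global flips of a cohort's values.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defilter
from .defilter import FilterConfig
from .expression import ExpressionMatrix, autoscale, pca

logger = logging.getLogger(__name__)

SIGNATURE_COLUMNS = ("probeset_id", "gene_symbol", "direction", "provenance")


@dataclass
class Signature:
    """Ordered probeset list with gene symbols and direction signs.

    ``entries`` has columns ``probeset_id``, ``gene_symbol``,
    ``direction`` (+1 up- or −1 down-regulated in the EMT-responding
    cell lines) and ``provenance`` (``algorithmic`` or ``curated``).
    """

    entries: pd.DataFrame
    name: str = "signature"

    def __post_init__(self) -> None:
        missing = [c for c in SIGNATURE_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"signature table missing columns: {missing}")
        self.entries = self.entries.reset_index(drop=True)
        ids = self.entries["probeset_id"]
        if ids.duplicated().any():
            raise ValueError(f"duplicate signature probesets: "
                             f"{sorted(set(ids[ids.duplicated()]))}")
        if not self.entries["direction"].isin([-1, 1]).all():
            raise ValueError("signature directions must be +1 or -1")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.entries["probeset_id"])

    @property
    def gene_symbols(self) -> list[str]:
        """Unique gene symbols, first-appearance order."""
        return list(dict.fromkeys(self.entries["gene_symbol"]))

    @property
    def directions(self) -> pd.Series:
        return self.entries.set_index("probeset_id")["direction"]

    def save(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path, name: str = "signature") -> "Signature":
        return cls(pd.read_csv(path, sep="\t"), name=name)


def strongest_filter(categories: pd.DataFrame, stats_by_comparison: dict,
                     cfg: FilterConfig | None = None,
                     category: str = "EMT-related",
                     check_all_three: bool = False) -> list[str]:
    """Prune categorized probesets to the strongest set.

    For each probeset of the requested category, the three
    phenotype-grouping comparisons (the EMT groupings for EMT-related
    probesets) must show (a) complete separation in at least one,
    (b) |difference| ≥ ``strong_fold_threshold_log2`` on the worst
    (smallest-magnitude) comparison, and (c) ``t_p`` and ``mw_p`` below
    ``strong_p_cutoff`` on that worst comparison (on all three when
    ``check_all_three``).  Returns the retained probeset IDs in category
    order.
    """
    cfg = cfg or FilterConfig()
    groupings = {
        "EMT-related": defilter.EMT_GROUPINGS,
        "no-EMT-related": defilter.NOEMT_GROUPINGS,
    }[category]
    missing = [g for g in groupings if g not in stats_by_comparison]
    if missing:
        raise ValueError(f"missing comparison stats: {missing}")
    candidates = categories.index[categories["category"] == category]
    if len(candidates) == 0:
        return []
    tables = []
    for g in groupings:
        st = stats_by_comparison[g]
        absent = [p for p in candidates if p not in st.index]
        if absent:
            raise ValueError(f"candidates missing from comparison {g}: {absent[:5]}")
        tables.append(st.loc[candidates])
    diff = np.column_stack([t["difference"].to_numpy() for t in tables])
    sep = np.column_stack([t["complete_separation"].to_numpy() for t in tables])
    t_p = np.column_stack([t["t_p"].to_numpy() for t in tables])
    mw_p = np.column_stack([t["mw_p"].to_numpy() for t in tables])

    worst = np.argmin(np.abs(diff), axis=1)
    rows = np.arange(len(candidates))
    keep = sep.any(axis=1)
    keep &= np.abs(diff[rows, worst]) >= cfg.strong_fold_threshold_log2
    if check_all_three:
        keep &= (t_p < cfg.strong_p_cutoff).all(axis=1)
        keep &= (mw_p < cfg.strong_p_cutoff).all(axis=1)
    else:
        keep &= t_p[rows, worst] < cfg.strong_p_cutoff
        keep &= mw_p[rows, worst] < cfg.strong_p_cutoff
    return list(candidates[keep])


def add_curated(selected: list[str], curated: pd.DataFrame,
                categories: pd.DataFrame,
                gene_symbols: pd.Series | None = None,
                name: str = "signature") -> Signature:
    """Merge curated probesets into the algorithmically selected set.

    ``curated`` needs ``probeset_id`` and ``gene_symbol`` columns.
    Directions are taken from the categorization table for both selected
    and curated entries; a curated probeset absent from that table (or
    without a non-zero direction) is an error.  A curated probeset
    already selected algorithmically keeps provenance ``algorithmic``.
    """
    rows = []
    for p in selected:
        if p not in categories.index:
            raise ValueError(f"selected probeset {p!r} absent from category table")
        sym = "" if gene_symbols is None else str(gene_symbols.get(p, ""))
        rows.append((p, sym, int(categories.loc[p, "direction"]), "algorithmic"))
    chosen = set(selected)
    for _, rec in curated.iterrows():
        p = rec["probeset_id"]
        if p in chosen:
            continue
        if p not in categories.index:
            raise ValueError(f"curated probeset {p!r} absent from category table")
        d = int(categories.loc[p, "direction"])
        if d == 0:
            raise ValueError(f"curated probeset {p!r} has no direction")
        rows.append((p, str(rec.get("gene_symbol", "")), d, "curated"))
    return Signature(pd.DataFrame(rows, columns=list(SIGNATURE_COLUMNS)), name=name)


def translation_filter(sig: Signature, cohorts: list[ExpressionMatrix],
                       min_agree_fraction: float = 0.5,
                       n_components: int = 2):
    """Remove signature probesets that do not translate into tumors.

    Per cohort: subset to the signature probesets present (a cohort
    sharing fewer than 3 is skipped with a warning), autoscale, PCA, and
    orient PC1 so the majority of loading signs match the signature
    directions.  A probeset *agrees* in a cohort when its oriented PC1
    loading sign equals its signature direction (zero loadings count as
    disagreement).  Probesets agreeing in ≤ ``min_agree_fraction`` of
    the cohorts where they are measured are removed, as are probesets
    measured in no cohort.  Returns ``(filtered Signature, report)``;
    the report records per probeset × cohort the oriented PC1 loading
    and agreement flag, the agreeing-cohort counts and the removal
    decision.  The output never gains entries.
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    dirs = sig.directions
    per_cohort = {}
    loading_cols = {}
    used = 0
    for i, cohort in enumerate(cohorts):
        shared = [p for p in sig.probeset_ids if p in cohort.values.index]
        if len(shared) < 3:
            logger.warning("translation_filter: cohort %d shares %d < 3 signature "
                           "probesets; skipped", i, len(shared))
            continue
        used += 1
        sub = autoscale(cohort.subset_probesets(shared))
        res = pca(sub, min(n_components, min(sub.shape)))
        load = res.loadings["PC1"]
        agree = np.sign(load) == dirs.loc[load.index]
        if agree.sum() * 2 < len(load):  # orient: majority must match
            load = -load
            agree = np.sign(load) == dirs.loc[load.index]
        per_cohort[f"cohort_{i}"] = agree
        loading_cols[f"cohort_{i}_loading"] = load
    if used == 0:
        raise ValueError("all cohorts skipped (insufficient signature overlap)")

    agree_df = pd.DataFrame(per_cohort).reindex(sig.probeset_ids)
    n_eval = agree_df.notna().sum(axis=1)
    n_agree = agree_df.fillna(False).sum(axis=1).astype(int)
    frac = n_agree / n_eval.replace(0, np.nan)
    removed = (n_eval == 0) | (frac <= min_agree_fraction)
    if (n_eval == 0).any():
        logger.warning("translation_filter: %d probesets measured in no cohort; removed",
                       int((n_eval == 0).sum()))
    report = pd.DataFrame(loading_cols).reindex(sig.probeset_ids)
    for c in agree_df.columns:
        report[f"{c}_agrees"] = agree_df[c]
    report["n_cohorts"] = n_eval
    report["n_agree"] = n_agree
    report["removed"] = removed
    kept = sig.entries[~removed.loc[sig.entries["probeset_id"]].to_numpy()]
    return Signature(kept, name=sig.name), report


def apply_include_list(sig: Signature, genes: list[str]) -> Signature:
    """Restrict a signature to the listed gene symbols, order preserved.

    Symbols absent from the signature draw a warning, not an error; an
    empty list yields an empty signature with a warning.
    """
    genes = list(genes)
    if not genes:
        logger.warning("apply_include_list: empty include-list; signature emptied")
    present = set(sig.entries["gene_symbol"])
    missing = [g for g in genes if g not in present]
    if missing:
        logger.warning("apply_include_list: %d listed symbols absent: %s",
                       len(missing), missing[:10])
    keep = sig.entries["gene_symbol"].isin(set(genes))
    return Signature(sig.entries[keep].reset_index(drop=True), name=sig.name)


def _load_fixture(fname: str) -> pd.DataFrame:
    ref = importlib.resources.files("emtsig.data") / fname
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_reference_signature() -> Signature:
    """The packaged 105-probeset / 77-gene reference signature.

    The gene symbols reproduce the published TGFβ-EMT signature gene
    list; the probeset identifiers, the assignment of second probesets
    to 28 of the genes, and the direction signs are synthetic
    placeholders (the published table lists symbols only), as the
    fixture's filename indicates.
    """
    return Signature(_load_fixture("reference_signature_synthetic_probesets.tsv"),
                     name="TGFb-EMT")


def load_curated_probesets() -> pd.DataFrame:
    """The 7-probeset curated include-list of EMT-related interest genes.

    Covers the six genes DDR1, LTBP1, PDGFB, SMURF1, SNAI1 and TGFBR1;
    one gene contributes two probesets.  DDR1 is taken as the
    double-probeset gene (it has several array probesets; the original
    choice is not recorded) and, like the reference signature, the
    probeset identifiers are synthetic placeholders.
    """
    return _load_fixture("curated_probesets_synthetic.tsv")
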