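"""Expression-matrix container, I/O, normalization and PCA.

The central object is :class:`ExpressionMatrix`: a probesets × samples
matrix of log2-scale values together with a probeset → gene-symbol map.
All downstream stages (differential screening, signature translation,
cohort scoring) operate on this container, so its invariants — unique
probeset and sample identifiers, no missing values — are enforced at
construction time.

Normalization here is an additive median-reference scaling on the log2
scale: every sample is shifted so its median matches the median of the
reference sample (the sample whose per-sample median is the median of
all per-sample medians).  It preserves within-sample expression ranking
and is idempotent.

PCA is computed by SVD of the autoscaled (per-probeset mean 0, sd 1)
matrix with a deterministic sign convention: each loading column is
flipped so its largest-magnitude entry is positive.  Downstream scoring
re-orients PC1 against signature directions, so the base convention only
needs to be reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of a sample-annotation table for cell-line experiments.
ANNOTATION_COLUMNS = ("sample_id", "unit_id", "treatment", "time_hours", "phenotype_class")

#: Additional columns required for cohort-type (clinical) annotation tables.
CLINICAL_COLUMNS = ("os_time", "os_event", "met_time", "met_event", "baseline_metastasis", "stage")

#: Recognized phenotype classes (the class describes the cell line and is
#: therefore constant across a line's samples, treated or not).
PHENOTYPE_CLASSES = (
    "EMT-responder",
    "non-EMT",
    "constitutively-mesenchymal",
    "not-applicable",
)


class IngestionError(ValueError):
    """Raised when an input file violates the matrix/annotation invariants."""


@dataclass
class ExpressionMatrix:
    """Probesets × samples matrix of log2-scale expression values.

    Parameters
    ----------
    values
        DataFrame indexed by probeset ID with sample IDs as columns.
        Must be fully numeric with no missing entries.
    gene_symbols
        Series aligned to ``values.index`` mapping each probeset to a
        gene symbol; unmapped probesets carry the empty string.  Many
        probesets may share a symbol.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise IngestionError(f"duplicate probeset IDs: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise IngestionError(f"duplicate sample IDs: {dups}")
        if self.values.isna().any().any():
            bad = np.argwhere(self.values.isna().to_numpy())
            r, c = bad[0]
            raise IngestionError(
                f"missing value at probeset {idx[r]!r}, sample {cols[c]!r}"
            )
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            raise IngestionError("expression values must be numeric")
        self.values = self.values.astype(float)
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series("", index=idx, name="gene_symbol")
        else:
            self.gene_symbols = self.gene_symbols.reindex(idx).fillna("").astype(str)
            self.gene_symbols.name = "gene_symbol"

    # -- convenience accessors -------------------------------------------------
    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probesets(self, probesets) -> "ExpressionMatrix":
        """Restrict to the given probesets (order preserved, must exist)."""
        missing = [p for p in probesets if p not in self.values.index]
        if missing:
            raise KeyError(f"probesets absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(probesets)],
                                self.gene_symbols.loc[list(probesets)])


@dataclass
class PCAResult:
    """SVD-based principal components of an autoscaled matrix.

    ``loadings`` is probesets × components (unit-norm columns), ``scores``
    is samples × components and satisfies scores = Xᵀ · loadings where X
    is the autoscaled probesets × samples matrix.  ``pct_variance`` is
    the percentage of total variance captured per component.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    pct_variance: np.ndarray


def read_expression_matrix(path, mapping_path=None) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    The file has a header row of sample IDs; the first column holds
    probeset IDs.  ``mapping_path`` optionally points to a two-column TSV
    (``probeset_id``, ``gene_symbol``); probesets without a mapping get
    the empty-symbol sentinel.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: dict[str, int] = {}
    for s in samples:
        seen[s] = seen.get(s, 0) + 1
    dup_samples = sorted(s for s, n in seen.items() if n > 1)
    if dup_samples:
        raise IngestionError(f"duplicate sample IDs: {dup_samples}")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                      float_precision="round_trip")
    raw.index = raw.index.astype(str)
    for j, col in enumerate(raw.columns):
        if not np.issubdtype(raw[col].dtype, np.number):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            row = raw.index[bad.to_numpy().argmax()]
            raise IngestionError(
                f"non-numeric value at probeset {row!r}, sample {col!r}"
            )

    symbols = None
    if mapping_path is not None:
        gmap = pd.read_csv(mapping_path, sep="\t", dtype=str)
        if list(gmap.columns[:2]) != ["probeset_id", "gene_symbol"]:
            gmap.columns = ["probeset_id", "gene_symbol"] + list(gmap.columns[2:])
        symbols = gmap.set_index("probeset_id")["gene_symbol"]
    return ExpressionMatrix(raw, symbols)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write TSV that round-trips bit-exactly through :func:`read_expression_matrix`."""
    m.values.to_csv(path, sep="\t", index_label="probeset_id")


def read_annotation(path) -> pd.DataFrame:
    """Read a sample-annotation TSV and check required columns."""
    ann = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS[:2] if c not in ann.columns]
    if missing:
        raise IngestionError(f"annotation missing required columns: {missing}")
    return ann


def validate_annotation(ann: pd.DataFrame, m: ExpressionMatrix) -> None:
    """Every sample in ``m`` must have exactly one annotation row."""
    counts = ann["sample_id"].value_counts()
    bad = [s for s in m.sample_ids if counts.get(s, 0) != 1]
    if bad:
        raise IngestionError(f"samples without exactly one annotation row: {bad}")


def median_reference_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Shift each sample so its median matches the reference sample's median.

    The reference is the sample whose per-sample median is the median of
    all per-sample medians (lower of the two middle samples when the
    sample count is even).  Additive shifts on log2 data play the role a
    rank-invariant intensity normalization would on raw intensities.
    """
    if m.shape[1] < 2:
        logger.warning("median_reference_scale: single-sample matrix returned unchanged")
        return ExpressionMatrix(m.values.copy(), m.gene_symbols)
    meds = m.values.median(axis=0)
    order = np.argsort(meds.to_numpy(), kind="stable")
    ref = meds.iloc[order[(len(order) - 1) // 2]]
    shifted = m.values.add(ref - meds, axis=1)
    return ExpressionMatrix(shifted, m.gene_symbols)


def remove_batch_means(m: ExpressionMatrix, batches: pd.Series) -> ExpressionMatrix:
    """Optional per-batch mean removal (off by default in the pipeline).

    For each probeset, subtracts the batch mean and adds back the grand
    mean, so batch-level additive offsets vanish while the overall level
    is preserved.  ``batches`` maps sample ID → batch label.
    """
    batches = batches.reindex(m.sample_ids)
    if batches.isna().any():
        raise IngestionError("every sample needs a batch label")
    vals = m.values.copy()
    grand = vals.mean(axis=1)
    for _, cols in vals.T.groupby(batches).groups.items():
        block = vals[list(cols)]
        vals[list(cols)] = block.sub(block.mean(axis=1), axis=0).add(grand, axis=0)
    return ExpressionMatrix(vals, m.gene_symbols)


def compute_log_ratios(m: ExpressionMatrix, ann: pd.DataFrame) -> ExpressionMatrix:
    """Log2 ratios of each sample versus its unit's untreated-control mean.

    For sample *s* of unit *u*: ``out[p, s] = m[p, s] − mean over u's
    untreated samples of m[p, ·]``.  Removes basal between-line
    expression differences so treated samples are comparable across
    lines.  Every unit must have at least one untreated sample.
    """
    validate_annotation(ann, m)
    ann = ann.set_index("sample_id").loc[m.sample_ids]
    untreated = ann["treatment"].astype(str).str.lower().isin(["untreated", "u", "0", "false"])
    out = m.values.copy()
    for unit, rows in ann.groupby("unit_id").groups.items():
        unit_samples = list(rows)
        ctrl = [s for s in unit_samples if untreated.loc[s]]
        if not ctrl:
            raise IngestionError(f"unit {unit!r} has no untreated-control samples")
        ctrl_mean = m.values[ctrl].mean(axis=1)
        out[unit_samples] = m.values[unit_samples].sub(ctrl_mean, axis=0)
    return ExpressionMatrix(out, m.gene_symbols)


def autoscale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each probeset row to mean 0 and scale to unit sample sd.

    Zero-variance rows cannot be scaled and are dropped with a logged
    warning (signature subsetting of small cohorts can produce them).
    """
    vals = m.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(vals.index[~keep])
        logger.warning("autoscale: dropping %d zero-variance probesets: %s",
                       len(dropped), dropped[:10])
    scaled = vals.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(scaled, m.gene_symbols.loc[keep])


def pca(m: ExpressionMatrix, n_components: int) -> PCAResult:
    """PCA of an autoscaled matrix via SVD.

    Components are the right singular directions of the samples ×
    probesets matrix, ordered by decreasing variance.  Each loading
    column is flipped so its largest-magnitude entry is positive; scores
    are flipped together with loadings.  ``pct_variance`` uses squared
    singular values over the total across all components.
    """
    n_max = min(m.shape)
    if not 1 <= n_components <= n_max:
        raise ValueError(f"n_components must be in [1, {n_max}], got {n_components}")
    X = m.values.to_numpy().T  # samples × probesets
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    load = Vt[:n_components].T.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            load[:, k] = -load[:, k]
    scores = X @ load
    total = float((s ** 2).sum())
    pct = (s[:n_components] ** 2) / total * 100.0 if total > 0 else np.zeros(n_components)
    comp = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        loadings=pd.DataFrame(load, index=m.values.index, columns=comp),
        scores=pd.DataFrame(scores, index=m.values.columns, columns=comp),
        pct_variance=pct,
    )
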