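"""Loading, validation and preprocessing of two-class expression datasets.

The in-memory container is :class:`ExpressionDataset`: a samples × genes
real matrix with binary labels recoded to {+1, −1}.  Preprocessing follows
the standard microarray pipeline: row-then-column standardization for
already-normalized chips, and the Dudoit thresholding / filtering / log10
procedure for raw Affymetrix-style intensities, optionally followed by a
Fisher's-ratio prescreen down to the top-k discriminant genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ExpressionDataError(ValueError):
    """Base class for dataset validation failures."""


class ParseError(ExpressionDataError):
    """The input file could not be parsed as a numeric expression matrix."""


class LabelError(ExpressionDataError):
    """Labels are missing, mismatched in length, or not exactly two classes."""


class ZeroVarianceError(ExpressionDataError):
    """A row or column has zero variance where standardization requires it."""


class DimensionError(ExpressionDataError):
    """Identifier / matrix dimension mismatch."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A two-class expression dataset: ``values`` is n samples × m genes.

    Labels are ±1; both classes must be present before the dataset is fed
    to any selector.  All entries are finite.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if values.ndim != 2:
            raise DimensionError("values must be a 2-D samples × genes matrix")
        if not np.all(np.isfinite(values)):
            raise ExpressionDataError("expression matrix contains non-finite entries")
        if labels.shape != (values.shape[0],):
            raise LabelError(
                f"got {labels.shape[0] if labels.ndim == 1 else labels.shape} labels "
                f"for {values.shape[0]} samples"
            )
        if not set(np.unique(labels)) <= {-1, 1}:
            raise LabelError("labels must be coded as +1 / -1")
        if not self.gene_ids:
            object.__setattr__(
                self, "gene_ids", [f"g{j}" for j in range(values.shape[1])]
            )
        if not self.sample_ids:
            object.__setattr__(
                self, "sample_ids", [f"s{i}" for i in range(values.shape[0])]
            )
        if len(self.gene_ids) != values.shape[1]:
            raise DimensionError(
                f"{len(self.gene_ids)} gene ids for {values.shape[1]} genes"
            )
        if len(self.sample_ids) != values.shape[0]:
            raise DimensionError(
                f"{len(self.sample_ids)} sample ids for {values.shape[0]} samples"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def require_two_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise LabelError("dataset must contain both classes (+1 and -1)")

    def subset_genes(self, indices) -> "ExpressionDataset":
        indices = np.asarray(indices, dtype=int)
        return replace(
            self,
            values=self.values[:, indices],
            gene_ids=[self.gene_ids[j] for j in indices],
        )

    def subset_samples(self, indices) -> "ExpressionDataset":
        indices = np.asarray(indices, dtype=int)
        return replace(
            self,
            values=self.values[indices, :],
            labels=self.labels[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
        )


def recode_labels(raw) -> np.ndarray:
    """Map an arbitrary two-category label vector to {+1, −1}.

    The first-seen category becomes +1 — a deterministic, documented
    convention so reruns on the same file always agree.
    """
    raw = list(raw)
    seen: list = []
    for item in raw:
        if item not in seen:
            seen.append(item)
    if len(seen) != 2:
        raise LabelError(f"expected exactly 2 classes, found {len(seen)}: {seen}")
    return np.where(np.asarray(raw, dtype=object) == seen[0], 1, -1).astype(int)


def load_expression_matrix(
    path,
    orientation: str = "samples_in_rows",
    label_source: str | None = None,
    labels=None,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus labels into a dataset.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with an identifier header row and an identifier first
        column.
    orientation : {"samples_in_rows", "genes_in_rows"}
        Layout of the file; the returned dataset is always samples × genes.
    label_source : str, optional
        Name of the column (samples-in-rows) or row (genes-in-rows) that
        holds the class labels.  Mutually exclusive with ``labels``.
    labels : sequence, optional
        Labels supplied directly (side-file path already read by the
        caller, or an in-memory vector).
    delimiter : str, optional
        Field separator; inferred from the file extension when omitted.
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc

    if orientation == "genes_in_rows":
        if label_source is not None:
            if label_source not in frame.index:
                raise LabelError(f"label row {label_source!r} not found")
            labels = frame.loc[label_source].tolist()
            frame = frame.drop(index=label_source)
        frame = frame.T
    else:
        if label_source is not None:
            if label_source not in frame.columns:
                raise LabelError(f"label column {label_source!r} not found")
            labels = frame[label_source].tolist()
            frame = frame.drop(columns=label_source)

    if labels is None:
        raise LabelError("no labels: pass label_source or labels")

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values & frame.notna().values)
    if bad.size:
        i, j = bad[0]
        raise ParseError(
            f"non-numeric cell at row {frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    if numeric.isna().values.any():
        i, j = np.argwhere(numeric.isna().values)[0]
        raise ParseError(
            f"missing value at row {frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    if len(labels) != numeric.shape[0]:
        raise LabelError(
            f"{len(labels)} labels for {numeric.shape[0]} samples"
        )
    return ExpressionDataset(
        values=numeric.values.astype(float),
        labels=recode_labels(labels),
        gene_ids=[str(c) for c in numeric.columns],
        sample_ids=[str(r) for r in numeric.index],
    )


def load_mat_dataset(
    path,
    values_key: str | None = None,
    labels_key: str | None = None,
    orientation: str = "samples_in_rows",
) -> ExpressionDataset:
    """Load an expression matrix + labels from a MAT-format archive.

    Handles both the classic (v5, via :func:`scipy.io.loadmat`) and the
    HDF5-backed (v7.3, via h5py) MAT layouts.  When keys are omitted, the
    largest 2-D numeric array is taken as the matrix and the vector whose
    length matches its sample dimension as the labels.
    """
    arrays: dict[str, np.ndarray] = {}
    try:
        from scipy.io import loadmat

        raw = loadmat(path)
        arrays = {
            k: np.asarray(v)
            for k, v in raw.items()
            if not k.startswith("__") and np.asarray(v).dtype.kind in "fiu"
        }
    except NotImplementedError:  # v7.3 HDF5-based archive
        import h5py

        with h5py.File(path, "r") as fh:
            for key in fh:
                data = fh[key]
                if hasattr(data, "shape"):
                    arrays[key] = np.asarray(data).T  # MAT v7.3 stores transposed
    if not arrays:
        raise ParseError(f"no numeric arrays found in {path}")

    if values_key is None:
        values_key = max(arrays, key=lambda k: arrays[k].size)
    values = np.atleast_2d(arrays[values_key].astype(float))
    if orientation == "genes_in_rows":
        values = values.T
    if labels_key is not None:
        labels = np.ravel(arrays[labels_key])
    else:
        candidates = [
            k
            for k, v in arrays.items()
            if k != values_key and np.ravel(v).shape[0] == values.shape[0]
        ]
        if not candidates:
            raise LabelError(f"no label vector of length {values.shape[0]} in {path}")
        labels = np.ravel(arrays[candidates[0]])
    return ExpressionDataset(values=values, labels=recode_labels(labels.tolist()))


def _zscore(matrix: np.ndarray, axis: int, ddof: int, what: str) -> np.ndarray:
    mean = matrix.mean(axis=axis, keepdims=True)
    sd = matrix.std(axis=axis, ddof=ddof, keepdims=True)
    zero = np.ravel(sd) <= 0
    if zero.any():
        raise ZeroVarianceError(
            f"zero-variance {what} at index {int(np.argwhere(zero)[0][0])}"
        )
    return (matrix - mean) / sd


def standardize_rows_then_columns(
    ds: ExpressionDataset, ddof: int = 1
) -> ExpressionDataset:
    """Z-score each sample (row), then each gene (column).

    The final column pass guarantees every gene has mean 0 and unit
    standard deviation, which is what gene-wise kernel scoring consumes.
    Sample (n−1) denominators by default.
    """
    rows_done = _zscore(ds.values, axis=1, ddof=ddof, what="row (sample)")
    both = _zscore(rows_done, axis=0, ddof=ddof, what="column (gene)")
    return replace(ds, values=both)


def dudoit_preprocess(
    ds: ExpressionDataset,
    floor: float = 100.0,
    ceiling: float = 16000.0,
    ratio_min: float = 5.0,
    diff_min: float = 500.0,
) -> ExpressionDataset:
    """Threshold / filter / log-transform raw expression intensities.

    The three steps, applied to raw positive-valued chips: (i) clamp every
    value to [floor, ceiling]; (ii) drop genes whose across-sample
    max/min ≤ ``ratio_min`` or max − min ≤ ``diff_min``; (iii) take the
    base-10 logarithm of the surviving values.  Gene order is preserved.
    """
    clamped = np.clip(ds.values, floor, ceiling)
    assert floor > 0 and np.all(clamped > 0), "clamped values must be positive"
    gmax = clamped.max(axis=0)
    gmin = clamped.min(axis=0)
    keep = (gmax / gmin > ratio_min) & (gmax - gmin > diff_min)
    kept = np.flatnonzero(keep)
    return replace(
        ds,
        values=np.log10(clamped[:, kept]),
        gene_ids=[ds.gene_ids[j] for j in kept],
    )


def fisher_prescreen(ds: ExpressionDataset, k: int) -> ExpressionDataset:
    """Keep the k genes with the largest Fisher's ratio (ties → lower index)."""
    from .selection import fisher_scores

    ds.require_two_classes()
    if k > ds.n_genes:
        raise DimensionError(f"k={k} exceeds the {ds.n_genes} available genes")
    scores = fisher_scores(ds)
    top = np.sort(np.argsort(-scores, kind="stable")[:k])
    return ds.subset_genes(top)
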