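"""Gram matrices and the kernel-column separability statistic.

The central quantity is a t-like score computed on one column of an n × n
kernel matrix: the n similarities in column *j* are split into the
population sharing sample *j*'s class (self-similarity included) and the
opposite-class population, and

    S_j = (mean_same − mean_opp) / (sd_same + sd_opp)

with sample (n−1) standard deviations.  A large positive S_j marks a
sample statistically more similar to its own class than to the other —
a "discriminant sample" in the SVM sense; a negative S_j marks a sample
that contradicts its label.  The problem-level separability M is the sum
of the per-sample scores; selectors maximize M over genes or gene sets.

The denominator is a *sum* of deviations, not a pooled variance: it can
only vanish when both populations are constant, which is handled by a
hard guard (score 0, column flagged degenerate) instead of an additive
epsilon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: below this, a column norm or deviation sum is treated as exactly zero
DEGENERACY_TOL = 1e-12


class KernelError(ValueError):
    """Invalid kernel configuration or input."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel configuration: ``linear`` or ``rbf`` with width ``sigma``.

    The RBF kernel is K(x, y) = exp(−‖x − y‖² / σ); σ is the value the
    tuning grid varies, so any monotone re-parameterization only relabels
    the grid.
    """

    kind: str = "linear"
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise KernelError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf":
            if self.sigma is None or self.sigma <= 0:
                raise KernelError("rbf kernel requires sigma > 0")


@dataclass
class GramMatrix:
    """An n × n kernel matrix together with its normalization state.

    RBF Grams are symmetric with unit diagonal by construction.  Linear
    Grams become column-normalized (each column divided by its diagonal
    entry, so self-similarity is 1) and need not stay symmetric.
    """

    entries: np.ndarray
    spec: KernelSpec
    normalized: bool = False
    degenerate_columns: set[int] = field(default_factory=set)

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass
class SeparabilityResult:
    """Per-sample scores S_i and their sum M for one classification problem."""

    per_sample: np.ndarray
    total: float
    degenerate_columns: set[int] = field(default_factory=set)


def compute_gram(X: np.ndarray, spec: KernelSpec) -> GramMatrix:
    """Build the Gram matrix of the rows of X under ``spec``.

    linear: entries_ij = ⟨x_i, x_j⟩ (unnormalized).
    rbf:    entries_ij = exp(−‖x_i − x_j‖² / σ) — already unit-diagonal.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2 or X.shape[0] < 2:
        raise KernelError("X must be an n × d matrix with n >= 2")
    if not np.all(np.isfinite(X)):
        raise KernelError("X contains non-finite entries")
    if spec.kind == "linear":
        return GramMatrix(entries=X @ X.T, spec=spec, normalized=False)
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-d2 / spec.sigma)
    np.fill_diagonal(K, 1.0)
    return GramMatrix(entries=K, spec=spec, normalized=True)


def normalize_linear_columns(K: GramMatrix) -> GramMatrix:
    """Divide each column by its diagonal entry so self-similarity is 1.

    Columns whose diagonal entry is (numerically) zero are zeroed out and
    recorded as degenerate instead of raising.
    """
    if K.spec.kind != "linear":
        raise KernelError("column normalization applies to linear kernels only")
    if K.normalized:
        raise KernelError("Gram matrix is already normalized")
    diag = np.diag(K.entries).copy()
    degenerate = set(np.flatnonzero(diag < DEGENERACY_TOL).tolist())
    safe = np.where(diag < DEGENERACY_TOL, 1.0, diag)
    entries = K.entries / safe[None, :]
    if degenerate:
        entries[:, sorted(degenerate)] = 0.0
        logger.warning("zeroed %d degenerate linear columns", len(degenerate))
    return GramMatrix(
        entries=entries, spec=K.spec, normalized=True, degenerate_columns=degenerate
    )


def _sd(values: np.ndarray, ddof: int) -> float:
    # a singleton population carries no spread information; treat as 0
    if values.size <= ddof:
        return 0.0
    return float(np.std(values, ddof=ddof))


def column_separability(
    column: np.ndarray,
    self_index: int,
    labels: np.ndarray,
    ddof: int = 1,
) -> tuple[float, bool]:
    """Score one kernel column: (mean_same − mean_opp)/(sd_same + sd_opp).

    Returns ``(score, degenerate)``.  The same-class population includes
    the self-similarity entry.  When both spreads vanish the score is 0
    and the column is flagged degenerate (with a logged warning) rather
    than raising, so synthetic edge cases do not abort pipelines.
    """
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    same = column[labels == labels[self_index]]
    opp = column[labels != labels[self_index]]
    if opp.size == 0:
        raise KernelError("labels must contain both classes")
    denom = _sd(same, ddof) + _sd(opp, ddof)
    if denom < DEGENERACY_TOL:
        warnings.warn(
            f"degenerate kernel column {self_index}: zero spread in both "
            "populations; separability set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, True
    return float((same.mean() - opp.mean()) / denom), False


def _column_class_stats(
    entries: np.ndarray, labels: np.ndarray, ddof: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise mean and spread of the rows in each class.

    Per-sample scoring only needs, for every column j, the mean/sd of the
    entries lying in class + rows and in class − rows — so the whole
    matrix is scored with four vectorized reductions.
    """
    pos = entries[labels == 1, :]
    neg = entries[labels == -1, :]

    def _sds(block: np.ndarray) -> np.ndarray:
        if block.shape[0] <= ddof:
            return np.zeros(block.shape[1])
        return np.std(block, axis=0, ddof=ddof)

    return pos.mean(axis=0), _sds(pos), neg.mean(axis=0), _sds(neg)


def _per_sample_scores(
    entries: np.ndarray, labels: np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column separability scores and degeneracy mask.

    Equivalent to calling :func:`column_separability` on every column;
    degenerate columns (zero total spread) score 0.
    """
    mean_pos, sd_pos, mean_neg, sd_neg = _column_class_stats(entries, labels, ddof)
    denom = sd_pos + sd_neg
    numer = np.where(labels == 1, mean_pos - mean_neg, mean_neg - mean_pos)
    degenerate = denom < DEGENERACY_TOL
    scores = np.where(degenerate, 0.0, numer / np.where(degenerate, 1.0, denom))
    return scores, degenerate


def problem_separability(
    K: GramMatrix, labels: np.ndarray, ddof: int = 1
) -> SeparabilityResult:
    """Per-sample separability of every column of K, and their sum M."""
    labels = np.asarray(labels)
    n = K.n
    if labels.shape != (n,):
        raise KernelError(f"{labels.shape[0]} labels for a {n} x {n} Gram matrix")
    if len(np.unique(labels)) < 2:
        raise KernelError("labels must contain both classes")
    per_sample, degenerate_mask = _per_sample_scores(K.entries, labels, ddof=ddof)
    degenerate = set(K.degenerate_columns) | set(
        np.flatnonzero(degenerate_mask).tolist()
    )
    return SeparabilityResult(
        per_sample=per_sample,
        total=float(per_sample.sum()),
        degenerate_columns=degenerate,
    )


def _separability_total(
    entries: np.ndarray, labels: np.ndarray, ddof: int = 1
) -> float:
    """Total separability M of a normalized Gram matrix (selector hot path)."""
    scores, _ = _per_sample_scores(entries, labels, ddof=ddof)
    return float(scores.sum())
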