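"""Gene selection by kernel-matrix separability, and the Fisher baseline.

Two selectors share the same criterion — the problem separability M, the
sum over samples of the kernel-column t-like score:

* :class:`KernelMatrixGeneSelection` (KMGS) scores every gene as a
  one-dimensional classification problem and ranks genes by M.
* :class:`KernelMatrixForwardSelection` (KMSFS) greedily grows a gene
  set, at each step adding the candidate that maximizes M of the joint
  problem.  An n × n accumulator (inner products for the linear kernel,
  squared distances for the RBF kernel) makes each candidate evaluation a
  rank-one update instead of a full Gram rebuild, so one step costs
  O(m · n²).

Both are presented statsmodels-style: a model object built from an
:class:`~kernelselect.datasets.ExpressionDataset`, whose ``fit()``
returns a results object (:class:`GeneRanking` / :class:`SelectionTrace`)
carrying the scores and a ``summary()`` table.  The functional wrappers
:func:`kmgs_rank` and :func:`kmsfs_select` are thin conveniences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .kernels import (
    DEGENERACY_TOL,
    GramMatrix,
    KernelSpec,
    _separability_total,
    compute_gram,
    normalize_linear_columns,
    problem_separability,
)


class SelectionError(ValueError):
    """Selector preconditions violated."""


class DegenerateDataError(SelectionError):
    """Every gene produced an all-degenerate kernel matrix."""


# ---------------------------------------------------------------------------
# results objects


@dataclass
class GeneRanking:
    """Per-gene separability totals and the induced descending order.

    ``order`` sorts ``scores`` non-increasingly; exact ties go to the
    lower gene index so reruns are reproducible.
    """

    scores: np.ndarray
    order: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    spec: KernelSpec | None = None

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]

    def summary(self, k: int = 10) -> pd.DataFrame:
        k = min(k, len(self.order))
        idx = self.order[:k]
        return pd.DataFrame(
            {
                "rank": np.arange(1, k + 1),
                "gene_index": idx,
                "gene_id": [self.gene_ids[j] for j in idx]
                if self.gene_ids
                else [str(j) for j in idx],
                "separability": self.scores[idx],
            }
        )

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(
            {
                "gene_id": self.gene_ids or [str(j) for j in range(len(self.scores))],
                "rank": np.argsort(self.order, kind="stable") + 1,
                "score": self.scores,
            }
        )
        frame.to_csv(path, index=False)


@dataclass
class SelectionTrace:
    """Chronological record of a greedy forward selection run.

    ``selected`` lists gene indices in the order they were added;
    ``step_scores`` holds the winning separability total at each step;
    ``accumulator`` is the final n × n matrix of accumulated inner
    products (linear) or squared distances (rbf) over the selected genes.
    """

    selected: list[int]
    step_scores: list[float]
    accumulator: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    spec: KernelSpec | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.selected) + 1),
                "gene_index": self.selected,
                "gene_id": [self.gene_ids[j] for j in self.selected]
                if self.gene_ids
                else [str(j) for j in self.selected],
                "separability": self.step_scores,
            }
        )

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model objects


class _KernelSelectorBase:
    def __init__(
        self,
        dataset: ExpressionDataset,
        kernel: str | KernelSpec = "linear",
        sigma: float | None = None,
        ddof: int = 1,
    ) -> None:
        dataset.require_two_classes()
        self.dataset = dataset
        self.spec = (
            kernel if isinstance(kernel, KernelSpec) else KernelSpec(kernel, sigma)
        )
        self.ddof = ddof


class KernelMatrixGeneSelection(_KernelSelectorBase):
    """Rank genes by the separability of their single-gene problem.

    For each gene the n sample values form a one-dimensional training
    set; its kernel matrix (column-normalized for the linear kernel) is
    scored by the problem separability M and genes are ranked by M,
    largest first.
    """

    def fit(self) -> GeneRanking:
        X = self.dataset.values
        y = self.dataset.labels
        m = X.shape[1]
        scores = np.empty(m)
        any_valid = False
        for g in range(m):
            gram = _single_gene_gram(X[:, g], self.spec)
            result = problem_separability(gram, y, ddof=self.ddof)
            scores[g] = result.total
            if len(result.degenerate_columns) < gram.n:
                any_valid = True
        if not any_valid:
            raise DegenerateDataError(
                "every gene produced an all-degenerate kernel matrix"
            )
        order = np.argsort(-scores, kind="stable")
        return GeneRanking(
            scores=scores,
            order=order,
            gene_ids=list(self.dataset.gene_ids),
            spec=self.spec,
        )


class KernelMatrixForwardSelection(_KernelSelectorBase):
    """Greedy forward selection of the gene set maximizing separability.

    Starts from the empty set and a zero n × n accumulator A.  For each
    remaining candidate k the joint-problem statistic is A plus the
    gene's rank-one contribution (outer product of its values for the
    linear kernel; pairwise squared differences for the RBF kernel); the
    candidate Gram is derived from it, scored, and the argmax appended
    (ties → lower gene index).  The accumulator then absorbs the winner's
    contribution, so the trace never rebuilds a Gram from scratch.
    """

    def fit(self, n_genes: int) -> SelectionTrace:
        X = self.dataset.values
        y = self.dataset.labels
        n, m = X.shape
        if n_genes > m:
            raise SelectionError(f"cannot select {n_genes} of {m} genes")
        if n_genes < 1:
            raise SelectionError("n_genes must be positive")

        contributions = _contribution_stack(X, self.spec)  # m × n × n
        accumulator = np.zeros((n, n))
        remaining = np.ones(m, dtype=bool)
        selected: list[int] = []
        step_scores: list[float] = []
        for _ in range(n_genes):
            best_score = -np.inf
            best_gene = -1
            for k in np.flatnonzero(remaining):
                candidate = accumulator + contributions[k]
                entries = _statistic_to_gram_entries(candidate, self.spec)
                score = _separability_total(entries, y, ddof=self.ddof)
                if score > best_score:
                    best_score = score
                    best_gene = int(k)
            selected.append(best_gene)
            step_scores.append(best_score)
            accumulator += contributions[best_gene]
            remaining[best_gene] = False
        return SelectionTrace(
            selected=selected,
            step_scores=step_scores,
            accumulator=accumulator,
            gene_ids=list(self.dataset.gene_ids),
            spec=self.spec,
        )


# short aliases in the field's own vocabulary
KMGS = KernelMatrixGeneSelection
KMSFS = KernelMatrixForwardSelection


# ---------------------------------------------------------------------------
# internals


def _single_gene_gram(values: np.ndarray, spec: KernelSpec) -> GramMatrix:
    gram = compute_gram(values[:, None], spec)
    if spec.kind == "linear":
        gram = normalize_linear_columns(gram)
    return gram


def _contribution_stack(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Per-gene n × n contributions to the accumulated pairwise statistic."""
    if spec.kind == "linear":
        return np.einsum("ig,jg->gij", X, X)
    diff = X[:, None, :] - X[None, :, :]  # n × n × m
    return np.moveaxis(diff**2, -1, 0)


def _statistic_to_gram_entries(stat: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Turn an accumulated statistic into normalized Gram entries."""
    if spec.kind == "rbf":
        return np.exp(-stat / spec.sigma)
    diag = np.diag(stat).copy()
    bad = diag < DEGENERACY_TOL
    safe = np.where(bad, 1.0, diag)
    entries = stat / safe[None, :]
    if bad.any():
        entries[:, bad] = 0.0
    return entries


# ---------------------------------------------------------------------------
# functional surface


def kmgs_rank(
    ds: ExpressionDataset, spec: KernelSpec, ddof: int = 1
) -> GeneRanking:
    """Rank all genes by single-gene problem separability."""
    return KernelMatrixGeneSelection(ds, spec, ddof=ddof).fit()


def kmsfs_select(
    ds: ExpressionDataset, spec: KernelSpec, n_genes: int, ddof: int = 1
) -> SelectionTrace:
    """Greedily select ``n_genes`` genes maximizing joint separability."""
    return KernelMatrixForwardSelection(ds, spec, ddof=ddof).fit(n_genes)


def fisher_scores(ds: ExpressionDataset, ddof: int = 1) -> np.ndarray:
    """Fisher's ratio per gene: (μ⁺ − μ⁻)² / (s⁺² + s⁻²).

    Class-wise means and sample standard deviations across samples.  When
    both class variances vanish the score is +∞ if the class means differ
    and 0 if they coincide.
    """
    ds.require_two_classes()
    pos = ds.values[ds.labels == 1, :]
    neg = ds.values[ds.labels == -1, :]

    def _var(block: np.ndarray) -> np.ndarray:
        if block.shape[0] <= ddof:
            return np.zeros(block.shape[1])
        return np.var(block, axis=0, ddof=ddof)

    num = (pos.mean(axis=0) - neg.mean(axis=0)) ** 2
    den = _var(pos) + _var(neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[(den == 0) & (num > 0)] = np.inf
    scores[(den == 0) & (num == 0)] = 0.0
    return scores
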