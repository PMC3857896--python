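"""External B.632+ bootstrap estimation of SVM error versus gene count.

Error estimation for gene selection is *external*: each bootstrap
training set performs its own gene selection, so held-out samples never
influence which genes the classifier sees.  The resampling design is a
balanced bootstrap — each sample occurs exactly B times in total across
the B resampled sets, which removes one source of Monte-Carlo variance.

The .632+ estimator blends the apparent (resubstitution) error ērr with
the leave-one-out bootstrap error err1 through a weight driven by the
relative overfitting rate against the no-information rate γ:

    err1' = min(err1, γ)
    R     = (err1' − ērr) / (γ − ērr)        (0 when the ratio is undefined)
    w     = 0.632 / (1 − 0.368·R)
    err.632+ = (1 − w)·ērr + w·err1'

Classification throughout is a linear-kernel SVM with regularization C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .datasets import ExpressionDataset
from .kernels import KernelSpec
from .selection import fisher_scores, kmgs_rank, kmsfs_select

logger = logging.getLogger(__name__)


class BootstrapError(ValueError):
    """Balanced bootstrap plan could not satisfy its invariants."""


@dataclass
class BootstrapPlan:
    """B multisets of n sample indices, each sample appearing B times total."""

    B: int
    sets: list[np.ndarray]
    seed: int

    def out_of_bag(self, b: int, n: int) -> np.ndarray:
        return np.setdiff1d(np.arange(n), self.sets[b])

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "B": self.B,
                    "seed": self.seed,
                    "sets": [s.tolist() for s in self.sets],
                },
                fh,
            )


@dataclass
class ErrorCurve:
    """B.632+ error and its components as a function of the gene count."""

    gene_counts: np.ndarray
    b632plus: np.ndarray
    err_bar: np.ndarray
    err1: np.ndarray
    gamma: np.ndarray
    selector: str = ""
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_count": self.gene_counts,
                "err632plus": self.b632plus,
                "err_bar": self.err_bar,
                "err1": self.err1,
                "gamma": self.gamma,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> pd.DataFrame:
        return self.to_frame()


def _plan_valid(sets: list[np.ndarray], labels: np.ndarray, n: int) -> bool:
    for block in sets:
        if np.unique(block).size == n:  # empty out-of-bag
            return False
        if np.unique(labels[block]).size < 2:  # single-class in-bag
            return False
    return True


def balanced_bootstrap(
    n: int, B: int, labels: np.ndarray, seed: int, max_attempts: int = 1000
) -> BootstrapPlan:
    """Draw a balanced bootstrap plan: permute n·B index copies, cut into B blocks.

    Every block must leave a non-empty out-of-bag complement and contain
    both classes in-bag; violating draws trigger a bounded re-permutation.
    Deterministic given ``seed``.
    """
    if n < 4:
        raise BootstrapError("need at least 4 samples")
    if B < 1:
        raise BootstrapError("B must be positive")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(n), B)
    for _ in range(max_attempts):
        perm = rng.permutation(pool)
        sets = [perm[b * n : (b + 1) * n] for b in range(B)]
        if _plan_valid(sets, labels, n):
            return BootstrapPlan(B=B, sets=sets, seed=seed)
    raise BootstrapError(
        f"no valid balanced plan after {max_attempts} permutations "
        f"(n={n}, B={B}, class sizes {np.bincount((labels + 1) // 2, minlength=2)})"
    )


def no_information_rate(labels: np.ndarray, predictions: np.ndarray) -> float:
    """γ = Σ_k p_k (1 − q_k): error expected if predictions were label-independent."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.size == 0 or labels.shape != predictions.shape:
        raise ValueError("labels and predictions must be equal-length, non-empty")
    gamma = 0.0
    for cls in np.unique(labels):
        p = np.mean(labels == cls)
        q = np.mean(predictions == cls)
        gamma += p * (1.0 - q)
    return float(gamma)


def b632plus_combine(err_bar: float, err1: float, gamma: float) -> float:
    """Blend apparent and leave-one-out bootstrap error into err.632+."""
    err1p = min(err1, gamma)
    if gamma > err_bar and err1p > err_bar:
        R = (err1p - err_bar) / (gamma - err_bar)
    else:
        R = 0.0
    R = min(max(R, 0.0), 1.0)
    w = 0.632 / (1.0 - 0.368 * R)
    return float((1.0 - w) * err_bar + w * err1p)


# ---------------------------------------------------------------------------
# selector protocol


def make_selector(name: str, spec: KernelSpec | None = None, fixed=None):
    """Build a ``select(dataset, n_genes) -> ordered gene indices`` callable.

    ``fixed`` yields a data-independent selector (used to isolate the
    external-nesting logic against a standalone oracle).
    """
    if name == "fixed":
        fixed_list = np.asarray(fixed, dtype=int)

        def select(ds: ExpressionDataset, n_genes: int) -> np.ndarray:
            return fixed_list[:n_genes]

    elif name == "fisher":

        def select(ds: ExpressionDataset, n_genes: int) -> np.ndarray:
            scores = fisher_scores(ds)
            return np.argsort(-scores, kind="stable")[:n_genes]

    elif name == "kmgs":

        def select(ds: ExpressionDataset, n_genes: int) -> np.ndarray:
            return kmgs_rank(ds, spec).top(n_genes)

    elif name == "kmsfs":

        def select(ds: ExpressionDataset, n_genes: int) -> np.ndarray:
            return np.asarray(kmsfs_select(ds, spec, n_genes).selected)

    else:
        raise ValueError(f"unknown selector {name!r}")

    select.name = name  # type: ignore[attr-defined]
    return select


def _fit_predict(X_train, y_train, X_test, C: float) -> np.ndarray:
    svm = SVC(kernel="linear", C=C)
    svm.fit(X_train, y_train)
    return svm.predict(X_test)


def external_b632plus_curve(
    ds: ExpressionDataset,
    selector,
    svm_C: float = 1.0,
    G: int = 100,
    plan: BootstrapPlan | None = None,
    B: int = 200,
    seed: int = 0,
    collect_selections: bool = False,
) -> ErrorCurve:
    """B.632+ error versus number of selected genes, selection kept external.

    For every bootstrap set the selector runs on the in-bag samples only;
    a linear SVM is then trained on the in-bag samples restricted to the
    top-g genes and scored on the out-of-bag samples, for g = 1..G.
    err1 averages per-sample out-of-bag misclassification; the apparent
    error and the no-information rate come from the full-dataset
    pipeline; the three combine into err.632+ per gene count.

    With ``collect_selections`` the per-set ranked gene lists (plus the
    full-set list) are attached to the returned curve as
    ``curve.selections`` for frequency analysis.
    """
    ds.require_two_classes()
    if callable(selector):
        select = selector
    else:
        raise TypeError("selector must be a callable from make_selector()")
    n = ds.n_samples
    if G > ds.n_genes:
        raise ValueError(f"G={G} exceeds {ds.n_genes} genes")
    if plan is None:
        plan = balanced_bootstrap(n, B, ds.labels, seed)
    B = plan.B

    counts = np.arange(1, G + 1)

    # per-sample out-of-bag error bookkeeping: errors[g, i] / trials[i]
    oob_errors = np.zeros((G, n))
    oob_trials = np.zeros(n)
    selections = []

    rng = np.random.default_rng(plan.seed + 1)
    for b in range(B):
        in_bag = plan.sets[b]
        oob = plan.out_of_bag(b, n)
        for _ in range(1000):
            try:
                train = ds.subset_samples(in_bag)
                genes = np.asarray(select(train, G))
                preds = np.column_stack(
                    [
                        _fit_predict(
                            train.values[:, genes[:g]],
                            train.labels,
                            ds.values[np.ix_(oob, genes[:g])],
                            svm_C,
                        )
                        for g in counts
                    ]
                )  # |oob| × G
                break
            except Exception as exc:  # degenerate in-bag set: re-draw this block
                logger.warning("re-drawing bootstrap set %d: %s", b, exc)
                in_bag = rng.choice(n, size=n, replace=True)
                oob = np.setdiff1d(np.arange(n), in_bag)
        else:
            raise BootstrapError(f"bootstrap set {b} could not be evaluated")
        if collect_selections:
            selections.append(genes)
        miss = preds != ds.labels[oob][:, None]  # |oob| × G
        oob_errors[:, oob] += miss.T
        oob_trials[oob] += 1

    covered = oob_trials > 0
    if not covered.all():
        logger.warning(
            "%d samples never out-of-bag; excluded from err1", int((~covered).sum())
        )
    per_sample_rate = oob_errors[:, covered] / oob_trials[covered]
    err1 = per_sample_rate.mean(axis=1)

    # apparent error and no-information rate from the full-dataset pipeline
    full_genes = np.asarray(select(ds, G))
    if collect_selections:
        selections.append(full_genes)
    err_bar = np.empty(G)
    gamma = np.empty(G)
    for gi, g in enumerate(counts):
        preds = _fit_predict(
            ds.values[:, full_genes[:g]], ds.labels, ds.values[:, full_genes[:g]], svm_C
        )
        err_bar[gi] = float(np.mean(preds != ds.labels))
        gamma[gi] = no_information_rate(ds.labels, preds)

    b632 = np.array(
        [b632plus_combine(err_bar[g], err1[g], gamma[g]) for g in range(G)]
    )
    curve = ErrorCurve(
        gene_counts=counts,
        b632plus=b632,
        err_bar=err_bar,
        err1=err1,
        gamma=gamma,
        selector=getattr(select, "name", "custom"),
        params={"C": svm_C, "B": B, "G": G},
    )
    if collect_selections:
        curve.selections = selections  # type: ignore[attr-defined]
    return curve
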