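"""Parameter tuning: grid search compared by Friedman ranks with Holm post-hoc.

Each parameter setting yields a B.632+ error for every gene count
g = 1..G; the G per-gene-count errors are treated as repeated measures
(blocks) and the k settings as treatments.  The Friedman rank-sum test —
the non-parametric alternative to repeated-measures ANOVA — detects any
difference in mean rank; if it rejects, the best-ranked setting is
compared against each other with Holm's step-down correction, and the
returned best set contains the best setting plus every setting not
significantly worse than it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import BootstrapPlan, external_b632plus_curve, make_selector
from .kernels import KernelSpec


@dataclass
class FriedmanResult:
    """Mean ranks per treatment, the chi-square statistic and its p-value."""

    mean_ranks: np.ndarray
    statistic: float
    p_value: float
    n_blocks: int
    best_set: list[int] | None = None


def friedman_test(errors: np.ndarray) -> FriedmanResult:
    """Friedman rank-sum test on an N blocks × k treatments error matrix.

    Each block's k values are ranked ascending (smaller error → better →
    rank 1; ties share average ranks); the statistic is
    (12N / (k(k+1))) Σ_j (R̄_j − (k+1)/2)², chi-square with k−1 df.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.ndim != 2 or errors.shape[0] < 2 or errors.shape[1] < 2:
        raise ValueError("need an N x k matrix with N >= 2, k >= 2")
    if not np.all(np.isfinite(errors)):
        raise ValueError("error matrix contains non-finite entries")
    N, k = errors.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, errors)
    mean_ranks = ranks.mean(axis=0)
    statistic = 12.0 * N / (k * (k + 1)) * np.sum((mean_ranks - (k + 1) / 2.0) ** 2)
    p_value = float(stats.chi2.sf(statistic, k - 1))
    return FriedmanResult(
        mean_ranks=mean_ranks,
        statistic=float(statistic),
        p_value=p_value,
        n_blocks=N,
    )


def holm_select(result: FriedmanResult, alpha: float = 0.05) -> list[int]:
    """Best-vs-rest Holm post-hoc: settings not significantly worse than the best.

    z_j = (R̄_j − R̄_best) / sqrt(k(k+1)/(6N)), two-sided normal p-values,
    Holm step-down at level ``alpha``.  If the Friedman test itself did
    not reject at ``alpha``, every setting is returned.
    """
    k = len(result.mean_ranks)
    all_settings = list(range(k))
    if result.p_value >= alpha:
        return all_settings
    best = int(np.argmin(result.mean_ranks))
    others = [j for j in all_settings if j != best]
    se = np.sqrt(k * (k + 1) / (6.0 * result.n_blocks))
    z = np.array([(result.mean_ranks[j] - result.mean_ranks[best]) / se for j in others])
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    order = np.argsort(pvals, kind="stable")
    m = len(others)
    rejected = np.zeros(m, dtype=bool)
    for step, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - step):
            rejected[idx] = True
        else:
            break  # Holm stops at the first non-rejection
    best_set = [best] + [j for j, r in zip(others, rejected) if not r]
    return sorted(best_set)


@dataclass
class GridSearchResult:
    """Chosen (σ, C), the per-setting error tensor and the rank analysis."""

    best_sigma: float | None
    best_C: float
    settings: list[tuple[float | None, float]]
    errors: np.ndarray  # G × k
    friedman: FriedmanResult | None
    best_set: list[int]
    curves: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        ranks = (
            self.friedman.mean_ranks
            if self.friedman is not None
            else np.ones(len(self.settings))
        )
        return pd.DataFrame(
            {
                "sigma": [s for s, _ in self.settings],
                "C": [c for _, c in self.settings],
                "mean_rank": ranks,
                "in_best_set": [j in self.best_set for j in range(len(self.settings))],
            }
        )

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


DEFAULT_SIGMA_GRID = tuple(10.0**e for e in range(-5, 6))  # 11 values
DEFAULT_C_GRID = tuple(10.0**e for e in range(-3, 4))  # 7 values


def grid_search(
    ds,
    selector_name: str,
    sigma_grid=None,
    C_grid=DEFAULT_C_GRID,
    plan: BootstrapPlan | None = None,
    G: int = 100,
    B: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> GridSearchResult:
    """Tune (σ, C) for a selector by Friedman/Holm over B.632+ curves.

    All settings share the same bootstrap plan so the G per-gene-count
    errors are paired across settings.  Linear-kernel selectors and the
    Fisher baseline ignore σ (pass ``sigma_grid=None``), leaving the
    7-value C grid.  Ties in the best set go to the smaller σ, then the
    smaller C.
    """
    from .evaluation import balanced_bootstrap

    if plan is None:
        plan = balanced_bootstrap(ds.n_samples, B, ds.labels, seed)
    uses_sigma = sigma_grid is not None
    sigmas = list(sigma_grid) if uses_sigma else [None]
    Cs = list(C_grid)
    if not Cs or (uses_sigma and not sigmas):
        raise ValueError("parameter grids must be non-empty")
    settings = list(product(sigmas, Cs))

    curves = []
    for sigma, C in settings:
        if selector_name in ("kmgs", "kmsfs"):
            spec = KernelSpec("rbf", sigma) if uses_sigma else KernelSpec("linear")
            selector = make_selector(selector_name, spec)
        else:
            selector = make_selector(selector_name)
        curves.append(
            external_b632plus_curve(ds, selector, svm_C=C, G=G, plan=plan)
        )
    errors = np.column_stack([c.b632plus for c in curves])  # G × k

    if len(settings) == 1:
        sigma, C = settings[0]
        return GridSearchResult(
            best_sigma=sigma,
            best_C=C,
            settings=settings,
            errors=errors,
            friedman=None,
            best_set=[0],
            curves=curves,
        )

    fr = friedman_test(errors)
    best_set = holm_select(fr, alpha=alpha)
    # best-ranked member of the best set; ties → smaller sigma, then smaller C
    candidates = sorted(
        best_set,
        key=lambda j: (
            fr.mean_ranks[j],
            np.inf if settings[j][0] is None else settings[j][0],
            settings[j][1],
        ),
    )
    chosen = candidates[0]
    return GridSearchResult(
        best_sigma=settings[chosen][0],
        best_C=settings[chosen][1],
        settings=settings,
        errors=errors,
        friedman=fr,
        best_set=best_set,
        curves=curves,
    )
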