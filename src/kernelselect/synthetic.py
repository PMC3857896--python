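"""Synthetic microarray-like data with planted ground truth.

The generator draws Gaussian class-conditional genes — the minimal
structure exhibiting both regimes the selectors target:

* *linear* (mean-shift) DEGs: class means separated by δ within-class
  standard deviations, unit spread — detectable by any location statistic
  and by the linear kernel;
* *nonlinear* (variance-shift) DEGs: equal class means but a class-spread
  ratio ρ — invisible to location statistics and to the linear kernel,
  detectable through the RBF kernel;
* null genes: standard normal in both classes.

Gene positions are shuffled so planted genes gain no advantage from
index-based tie-breaking.  The matrix then passes through the standard
row-then-column standardization, exactly like a real dataset would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset, standardize_rows_then_columns


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted gene indices and effect sizes for recovery testing."""

    linear_deg_indices: tuple[int, ...]
    nonlinear_deg_indices: tuple[int, ...]
    null_indices: tuple[int, ...]
    delta: float
    rho: float
    seed: int

    def __post_init__(self) -> None:
        all_idx = (
            set(self.linear_deg_indices)
            | set(self.nonlinear_deg_indices)
            | set(self.null_indices)
        )
        m = (
            len(self.linear_deg_indices)
            + len(self.nonlinear_deg_indices)
            + len(self.null_indices)
        )
        if all_idx != set(range(m)):
            raise ValueError("index sets must partition 0..m-1")
        if self.delta < 0 or self.rho < 1:
            raise ValueError("need delta >= 0 and rho >= 1")


def generate_dataset(
    n_pos: int = 30,
    n_neg: int = 30,
    m: int = 205,
    n_linear_deg: int = 5,
    delta: float = 1.5,
    n_nonlinear_deg: int = 0,
    rho: float = 3.0,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate a two-class expression matrix with planted DEGs.

    Class + samples come first (labels +1), then class − (labels −1).
    Linear DEGs have class means ±δ/2; nonlinear DEGs have spread 1 in
    class + and ρ in class −.  Deterministic given ``seed``.
    """
    if n_linear_deg + n_nonlinear_deg > m:
        raise ValueError("more planted genes than total genes")
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])

    values = rng.standard_normal((n, m))
    positions = rng.permutation(m)
    linear_idx = positions[:n_linear_deg]
    nonlinear_idx = positions[n_linear_deg : n_linear_deg + n_nonlinear_deg]

    values[: n_pos, linear_idx] += delta / 2.0
    values[n_pos:, linear_idx] -= delta / 2.0
    values[n_pos:, nonlinear_idx] *= rho

    ds = ExpressionDataset(
        values=values,
        labels=labels,
        gene_ids=[f"gene_{j}" for j in range(m)],
        sample_ids=[f"sample_{i}" for i in range(n)],
    )
    if standardize:
        ds = standardize_rows_then_columns(ds)
    planted = set(linear_idx.tolist()) | set(nonlinear_idx.tolist())
    truth = SyntheticTruth(
        linear_deg_indices=tuple(sorted(int(j) for j in linear_idx)),
        nonlinear_deg_indices=tuple(sorted(int(j) for j in nonlinear_idx)),
        null_indices=tuple(j for j in range(m) if j not in planted),
        delta=delta,
        rho=rho,
        seed=seed,
    )
    return ds, truth


def write_csv(ds: ExpressionDataset, path, label_column: str = "label") -> None:
    """Write a dataset in the samples-in-rows CSV dialect the loader reads."""
    import pandas as pd

    frame = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.gene_ids)
    frame.insert(0, label_column, ds.labels)
    frame.to_csv(path)


def write_truth(truth: SyntheticTruth, path) -> None:
    import json
    from dataclasses import asdict

    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1)
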