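"""Independent reference implementations used only to check the package.

Everything here is deliberately written the slow, literal way — explicit
Python loops and the ``statistics`` module — and never calls into the
package's own scoring or estimation code paths.
"""

import math
import statistics

import numpy as np
from sklearn.svm import SVC


def oracle_sd(values):
    values = list(values)
    return statistics.stdev(values) if len(values) > 1 else 0.0


def oracle_column_score(column, self_index, labels):
    same = [column[k] for k in range(len(labels)) if labels[k] == labels[self_index]]
    opp = [column[k] for k in range(len(labels)) if labels[k] != labels[self_index]]
    denom = oracle_sd(same) + oracle_sd(opp)
    if denom < 1e-12:
        return 0.0
    return (statistics.mean(same) - statistics.mean(opp)) / denom


def oracle_gram(X, kind, sigma=None):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if kind == "linear":
                K[i, j] = float(np.dot(X[i], X[j]))
            else:
                K[i, j] = math.exp(-float(np.sum((X[i] - X[j]) ** 2)) / sigma)
    if kind == "linear":
        diag = [K[j, j] for j in range(n)]
        for j in range(n):
            if diag[j] < 1e-12:
                K[:, j] = 0.0
            else:
                K[:, j] = K[:, j] / diag[j]
    return K


def oracle_total_separability(X, labels, kind, sigma=None):
    """Two-loop problem separability built from first principles."""
    K = oracle_gram(X, kind, sigma)
    return sum(
        oracle_column_score(K[:, j], j, labels) for j in range(len(labels))
    )


def oracle_kmgs_scores(X, labels, kind, sigma=None):
    return [
        oracle_total_separability(X[:, [g]], labels, kind, sigma)
        for g in range(X.shape[1])
    ]


def oracle_kmsfs(X, labels, kind, sigma, n_genes):
    """Greedy forward selection rebuilding every candidate Gram from scratch."""
    m = X.shape[1]
    selected, scores = [], []
    for _ in range(n_genes):
        best, best_score = None, -math.inf
        for k in range(m):
            if k in selected:
                continue
            total = oracle_total_separability(
                X[:, selected + [k]], labels, kind, sigma
            )
            if total > best_score:
                best, best_score = k, total
        selected.append(best)
        scores.append(best_score)
    return selected, scores


def oracle_b632plus_fixed_genes(values, labels, genes, plan_sets, C):
    """Standard B.632+ for a pre-specified ordered gene list.

    Returns (err_bar, err1, gamma, b632plus), each a list over gene
    counts 1..len(genes).  No gene selection happens anywhere.
    """
    n = len(labels)
    G = len(genes)
    results = {"err_bar": [], "err1": [], "gamma": [], "b632plus": []}
    per_sample = [[[] for _ in range(n)] for _ in range(G)]
    for in_bag in plan_sets:
        in_bag = list(in_bag)
        oob = [i for i in range(n) if i not in set(in_bag)]
        for gi in range(G):
            cols = list(genes[: gi + 1])
            svm = SVC(kernel="linear", C=C)
            svm.fit(values[np.ix_(in_bag, cols)], labels[in_bag])
            preds = svm.predict(values[np.ix_(oob, cols)])
            for pos, i in enumerate(oob):
                per_sample[gi][i].append(int(preds[pos] != labels[i]))
    for gi in range(G):
        cols = list(genes[: gi + 1])
        svm = SVC(kernel="linear", C=C)
        svm.fit(values[:, cols], labels)
        preds = svm.predict(values[:, cols])
        err_bar = float(np.mean(preds != labels))
        gamma = 0.0
        for cls in set(labels.tolist()):
            p = float(np.mean(labels == cls))
            q = float(np.mean(preds == cls))
            gamma += p * (1 - q)
        rates = [
            statistics.mean(hits) for hits in per_sample[gi] if len(hits) > 0
        ]
        err1 = statistics.mean(rates)
        err1p = min(err1, gamma)
        if gamma > err_bar and err1p > err_bar:
            R = (err1p - err_bar) / (gamma - err_bar)
        else:
            R = 0.0
        R = min(max(R, 0.0), 1.0)
        w = 0.632 / (1 - 0.368 * R)
        results["err_bar"].append(err_bar)
        results["err1"].append(err1)
        results["gamma"].append(gamma)
        results["b632plus"].append((1 - w) * err_bar + w * err1p)
    return results


def oracle_two_pass_zscore(matrix):
    """Row z-score then column z-score, scalar arithmetic only (n−1 sds)."""
    matrix = [list(map(float, row)) for row in matrix]
    out = []
    for row in matrix:
        mu, sd = statistics.mean(row), statistics.stdev(row)
        out.append([(v - mu) / sd for v in row])
    cols = list(zip(*out))
    final_cols = []
    for col in cols:
        mu, sd = statistics.mean(col), statistics.stdev(col)
        final_cols.append([(v - mu) / sd for v in col])
    return np.array(list(zip(*final_cols)))
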