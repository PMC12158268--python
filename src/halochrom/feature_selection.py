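"""Feature selection: which color channels discriminate pH best?

Two complementary views are implemented:

* correlation-matrix PCA with the Kaiser criterion (retain components with
  eigenvalue > 1) — the correlation matrix is used rather than the
  covariance matrix because the 12 channels live on mixed scales and the
  eigenvalue-1 reference is only meaningful for standardized features;
* multiclass ReliefF (Kononenko variant): features are weighted by how well
  they separate each sampled instance from its k nearest misses (other
  classes) relative to its k nearest hits (same class), with Manhattan
  distance on range-normalized features.

On the study's data both point at Hue, Saturation and the Lab ``a`` channel
as the most pH-discriminative features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from halochrom.color import CHANNELS


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    loadings: pd.DataFrame   # features x components, unit-norm columns
    retained: int            # Kaiser criterion: count of eigenvalues > 1


def pca_correlation(table: pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the feature correlation matrix.

    Columns of ``table`` are features, rows observations. Loadings follow
    the sign convention that each column's largest-magnitude element is
    positive. Raises ``ValueError`` for fewer than 2 rows or a constant
    column (whose correlations are undefined).
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    stds = X.std(axis=0, ddof=1)
    for j, s in enumerate(stds):
        if s == 0:
            raise ValueError(f"column {table.columns[j]!r} is constant; correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        col = eigvecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            eigvecs[:, j] = -col
    loadings = pd.DataFrame(
        eigvecs,
        index=list(table.columns),
        columns=[f"PC{i + 1}" for i in range(eigvecs.shape[1])],
    )
    # Kaiser rule: strictly greater than 1, with a small numerical guard so
    # an exactly-unit spectrum (identity correlation) retains nothing.
    retained = int(np.sum(eigvals > 1.0 + 1e-9))
    return PCAResult(eigenvalues=eigvals, loadings=loadings, retained=retained)


def relieff(
    table: pd.DataFrame,
    labels,
    k: int = 10,
    n_iter: int | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Multiclass ReliefF feature weights (Kononenko update).

    For each of ``n_iter`` sampled instances R (default: every row, in a
    seed-determined order), the k nearest hits H and, for each other class
    C, the k nearest misses M_C are found by Manhattan distance on
    range-normalized features. The weight of feature f is updated by

        W[f] -= diff(f, R, H) / (n_iter * k)
        W[f] += sum_C  P(C) / (1 - P(class(R))) * diff(f, R, M_C) / (n_iter * k)

    where ``diff`` is the absolute difference scaled by the feature's range
    (defined as 0 for a zero-range feature, so constant features get weight
    exactly 0). Weights lie in [-1, 1] by construction.

    Raises ``ValueError`` if any class has fewer than k + 1 members.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = table.to_numpy(dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match table rows")
    n, p = X.shape
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt <= k:
            raise ValueError(f"class {cls!r} has {cnt} members, need > k={k}")
    priors = {cls: cnt / n for cls, cnt in zip(classes, counts)}

    ranges = X.max(axis=0) - X.min(axis=0)
    nonzero = ranges > 0
    Xn = np.zeros_like(X)
    Xn[:, nonzero] = X[:, nonzero] / ranges[nonzero]  # diff = |xi - xj| on this scale

    rng = np.random.default_rng(seed)
    if n_iter is None or n_iter >= n:
        sample = rng.permutation(n)
    else:
        sample = rng.choice(n, size=n_iter, replace=False)
    m = sample.size

    W = np.zeros(p)
    by_class = {cls: np.flatnonzero(labels == cls) for cls in classes}
    for i in sample:
        dists = np.abs(Xn - Xn[i]).sum(axis=1)
        own = labels[i]
        for cls in classes:
            idx = by_class[cls]
            if cls == own:
                idx = idx[idx != i]
            # stable k-nearest: sort by (distance, index)
            nearest = idx[np.lexsort((idx, dists[idx]))][:k]
            contrib = np.abs(Xn[nearest] - Xn[i]).sum(axis=0) / (m * k)
            if cls == own:
                W -= contrib
            else:
                W += priors[cls] / (1.0 - priors[own]) * contrib
    return {name: float(w) for name, w in zip(table.columns, W)}


def rank_features(weights: dict[str, float], top_n: int) -> list[str]:
    """Channel names sorted by descending weight, ties in canonical order.

    The canonical order is the 12-channel order R, G, B, L, a, b, H, S, V,
    Y, Cb, Cr; unknown names sort after the canonical ones, alphabetically.
    """
    if top_n > len(weights):
        raise ValueError(f"top_n={top_n} exceeds number of features {len(weights)}")
    canon = {name: i for i, name in enumerate(CHANNELS)}
    ordered = sorted(
        weights,
        key=lambda name: (-weights[name], canon.get(name, len(CHANNELS)), name),
    )
    return ordered[:top_n]
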