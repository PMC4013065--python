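"""Multi-class ReliefF attribute weighting.

Classic neighbour-based feature-quality estimation: a feature is good if
it agrees between near neighbours of the same class (hits) and differs
between near neighbours of different classes (misses), with miss
contributions weighted by class prior.  ``diff(f, a, b) = |a_f - b_f| /
range_f`` and instance distance is the Manhattan sum of diffs.
Deterministic when all instances are used (the default); neighbour ties
are broken by instance index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ReliefFRanking:
    weights: pd.Series  # per-feature weight, original column order
    ranking: list[str]  # best first

    def rank_of(self, feature: str) -> int:
        return self.ranking.index(feature) + 1


def relieff_rank(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    k: int = 10,
    m: int | None = None,
    seed: int = 0,
) -> ReliefFRanking:
    """ReliefF weights for features in ``X`` against classes ``y``.

    ``k`` nearest hits and, per other class, ``k`` nearest misses
    contribute to each sampled instance; ``m`` is the number of sampled
    instances (default: all, in index order — deterministic).  If some
    class has fewer than ``k + 1`` members, ``k`` is reduced with a
    warning.  Constant features receive weight exactly 0.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y)
    n, p = Xa.shape
    if ya.shape[0] != n:
        raise ValueError("X and y length mismatch")
    classes, y_idx = np.unique(ya, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    counts = np.bincount(y_idx)
    priors = counts / n

    min_count = counts.min()
    if min_count < k + 1:
        k_eff = max(1, int(min_count) - 1)
        warnings.warn(
            f"smallest class has {min_count} members; reducing k from {k} to {k_eff}",
            stacklevel=2,
        )
        k = k_eff

    rng = np.random.default_rng(seed)
    if m is None or m >= n:
        sample = np.arange(n)
    else:
        sample = rng.choice(n, size=m, replace=False)

    rng_f = np.ptp(Xa, axis=0)
    active = rng_f > 0
    scale = np.where(active, rng_f, 1.0)
    Z = Xa / scale  # diff(f,a,b) = |Z_a - Z_b| for active features

    weights = np.zeros(p)
    m_used = len(sample)
    for i in sample:
        d = np.abs(Z[:, active] - Z[i, active]).sum(axis=1)
        d[i] = np.inf
        order = np.argsort(d, kind="stable")  # ties by index
        ordered_classes = y_idx[order]
        # k nearest hits
        hits = order[ordered_classes == y_idx[i]][:k]
        if hits.size:
            weights -= np.abs(Z[hits] - Z[i]).sum(axis=0) / (m_used * hits.size)
        # k nearest misses per other class, weighted by prior
        denom = 1.0 - priors[y_idx[i]]
        for ci in range(classes.size):
            if ci == y_idx[i]:
                continue
            misses = order[ordered_classes == ci][:k]
            if misses.size:
                w_cls = priors[ci] / denom
                weights += w_cls * np.abs(Z[misses] - Z[i]).sum(axis=0) / (
                    m_used * misses.size
                )
    weights[~active] = 0.0
    series = pd.Series(weights, index=names)
    ranking = list(series.sort_values(ascending=False, kind="stable").index)
    return ReliefFRanking(weights=series, ranking=ranking)
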