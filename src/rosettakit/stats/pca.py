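"""Per-time-point principal component analysis of descriptor tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from rosettakit.descriptors import DESCRIPTOR_NAMES

#: Descriptors shared with the earlier single-time-point rosette study
#: (area, perimeter, compactness, maximum diameter and the hull /
#: enclosing-circle size measures).  Selectable via ``subset="perezperez"``.
PEREZ_PEREZ_SUBSET: tuple[str, ...] = (
    "area",
    "circumference",
    "compactness",
    "maxdiam",
    "mincirclediam",
    "conhullcirc",
    "conhullarea",
)


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # descriptor x component
    percent_variance: np.ndarray
    scores: pd.DataFrame
    dropped_columns: list[str]


def pca_per_timepoint(
    table: pd.DataFrame,
    das: float | None = None,
    subset: list[str] | tuple[str, ...] | str | None = None,
) -> PcaResult:
    """Scaled PCA of the descriptor columns, optionally at one time point.

    Columns are centred and scaled to unit variance (sample sd); the
    percent-variance vector sums to 100.  Zero-variance columns are
    dropped with a warning.  ``das=None`` pools all observations;
    ``subset`` may be a list of descriptor names or the string
    ``"perezperez"`` for the 7-descriptor comparison set.
    """
    if isinstance(subset, str):
        if subset != "perezperez":
            raise ValueError(f"unknown subset {subset!r}")
        cols = list(PEREZ_PEREZ_SUBSET)
    elif subset is not None:
        cols = list(subset)
    else:
        cols = [c for c in DESCRIPTOR_NAMES if c in table.columns]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"descriptor column(s) not in table: {missing}")

    rows = table if das is None else table[table["das"].astype(float) == float(das)]
    X = rows[cols].to_numpy(dtype=float)
    finite = np.all(np.isfinite(X), axis=1)
    X = X[finite]
    if X.shape[0] < 2:
        raise ValueError("need >= 2 complete observations for PCA")

    sd = X.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(cols, sd) if s == 0]
    if dropped:
        warnings.warn(f"dropping zero-variance column(s): {dropped}", stacklevel=2)
        keep = sd > 0
        cols = [c for c, k in zip(cols, keep) if k]
        X, sd = X[:, keep], sd[keep]
    if len(cols) < 2:
        raise ValueError("need >= 2 descriptors with variance for PCA")

    Z = (X - X.mean(axis=0)) / sd
    n_comp = min(Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z)
    percent = pca.explained_variance_ratio_ * 100.0
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PcaResult(
        loadings=pd.DataFrame(pca.components_.T, index=cols, columns=comp_names),
        percent_variance=percent,
        scores=pd.DataFrame(scores, columns=comp_names, index=rows.index[finite]),
        dropped_columns=dropped,
    )
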