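"""Bonferroni outlier test on externally studentized residuals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class OutlierFlag:
    index: int
    studentized: float
    p_raw: float
    p_bonferroni: float


def bonferroni_outlier_test(fit, alpha: float = 0.05) -> list[OutlierFlag]:
    """Flag observations whose externally studentized residual is extreme.

    ``fit`` is a fitted statsmodels OLS/WLS result (or any object whose
    ``get_influence().resid_studentized_external`` exists).  Each
    observation gets a two-sided p-value from the t distribution with
    ``n - k - 1`` degrees of freedom; an observation is flagged iff
    ``p * n < alpha`` (Bonferroni over all n observations).
    """
    influence = fit.get_influence()
    t_ext = np.asarray(influence.resid_studentized_external, dtype=float)
    n = t_ext.size
    k = int(fit.df_model) + 1  # parameters incl. intercept
    df = n - k - 1
    if df < 1:
        raise ValueError(f"too few observations (n={n}) for k={k} parameters")
    p_raw = 2.0 * sps.t.sf(np.abs(t_ext), df)
    p_adj = np.minimum(p_raw * n, 1.0)
    flags = [
        OutlierFlag(int(i), float(t_ext[i]), float(p_raw[i]), float(p_adj[i]))
        for i in np.flatnonzero(p_adj < alpha)
    ]
    return flags


def remove_outliers(
    table: pd.DataFrame,
    descriptor: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[OutlierFlag]]:
    """One-pass outlier removal for a descriptor column of a long table.

    Fits a fixed-effects screening model (ecotype x time cell means) by
    OLS, applies the Bonferroni outlier test to its residuals, and drops
    the flagged rows.  Returns the filtered table and the flags (indexed
    into the input table's positional order).
    """
    if descriptor not in table.columns:
        raise KeyError(f"descriptor column {descriptor!r} not in table")
    sub = table.reset_index(drop=True)
    y = sub[descriptor].to_numpy(dtype=float)
    keep_mask = np.isfinite(y)
    cells = (
        sub["ecotype"].astype(str) + "@" + sub["das"].astype(float).astype(str)
    ).to_numpy()
    X = pd.get_dummies(pd.Series(cells[keep_mask]), drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y[keep_mask], X).fit()
    flags = bonferroni_outlier_test(fit, alpha=alpha)
    kept_positions = np.flatnonzero(keep_mask)
    drop_positions = {int(kept_positions[f.index]) for f in flags}
    flags = [
        OutlierFlag(int(kept_positions[f.index]), f.studentized, f.p_raw, f.p_bonferroni)
        for f in flags
    ]
    filtered = sub.drop(index=sorted(drop_positions)).reset_index(drop=True)
    return filtered, flags
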