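"""Pairwise post-hoc contrasts on a fitted mixed model.

All level pairs of a factor are compared with t contrasts on the fixed
effects; p-values are Bonferroni-adjusted over the C(L, 2) contrasts and
binned into the significance tiers used in the figures (ns / <0.05 /
<0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from rosettakit.stats.lme import LmeResult


@dataclass(frozen=True)
class PairwiseResult:
    contrast: str
    estimate: float
    se: float
    statistic: float
    p_raw: float
    p_adjusted: float

    @property
    def tier(self) -> str:
        if self.p_adjusted < 0.01:
            return "<0.01"
        if self.p_adjusted < 0.05:
            return "<0.05"
        return "ns"


def tukey_pairwise(result: LmeResult, factor: str = "ecotype") -> list[PairwiseResult]:
    """All pairwise level contrasts for ``ecotype`` or ``das``.

    Ecotype contrasts compare level estimates at the mean time;
    time contrasts compare ecotype-averaged marginal means between
    imaging days.  The t reference uses the between-plant df for
    ecotype and the within-plant df for time.
    """
    design = result.design
    beta = result.params.to_numpy()
    cov = result.cov_params.to_numpy()

    if factor == "ecotype":
        levels = design.ecotypes
        rows = None
        df = result.df_between
    elif factor == "das":
        levels = [float(v) for v in design.das_values]
        rows = {v: design.marginal_row(v) for v in levels}
        df = result.df_within
    else:
        raise ValueError(f"factor must be 'ecotype' or 'das', got {factor!r}")
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")

    pairs = list(combinations(levels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        if factor == "ecotype":
            v = design.ecotype_contrast(str(a), str(b))
        else:
            v = rows[a] - rows[b]
        est = float(v @ beta)
        se = float(np.sqrt(v @ cov @ v))
        stat = est / se if se > 0 else np.inf
        p_raw = float(2.0 * sps.t.sf(abs(stat), df))
        out.append(
            PairwiseResult(
                contrast=f"{a} - {b}",
                estimate=est,
                se=se,
                statistic=stat,
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * m),
            )
        )
    return out
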