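"""Transform policy and normality screening for descriptor tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from rosettakit.descriptors import DESCRIPTOR_NAMES

#: Descriptors analysed on the natural-log scale (fixed policy; the
#: Shapiro screen below is advisory only).
LOG_DESCRIPTORS: frozenset[str] = frozenset(
    {
        "mincirclediam",
        "minrectarea",
        "vrectsizey",
        "vrectsizex",
        "area",
        "circumference",
        "maxdiam",
        "bdryround",
        "bdrycount",
        "conhullcirc",
        "conhullarea",
    }
)


@dataclass(frozen=True)
class TransformPolicy:
    """Per-descriptor natural-log flags; defaults to the fixed policy."""

    log_e: frozenset[str] = field(default_factory=lambda: LOG_DESCRIPTORS)

    def __post_init__(self) -> None:
        unknown = set(self.log_e) - set(DESCRIPTOR_NAMES) - {"rragr"}
        if unknown:
            raise ValueError(f"unknown descriptor(s) in log policy: {sorted(unknown)}")

    def flags(self) -> dict[str, bool]:
        return {d: d in self.log_e for d in DESCRIPTOR_NAMES}


def apply_transforms(
    table: pd.DataFrame, policy: TransformPolicy | None = None
) -> pd.DataFrame:
    """Replace log-flagged descriptor columns by their natural logs.

    Raises ``ValueError`` naming the first offending row and column when
    a log-flagged column contains a non-positive value.
    """
    policy = policy or TransformPolicy()
    out = table.copy()
    for col in policy.log_e:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~(vals > 0))
        if bad.size:
            raise ValueError(
                f"non-positive value in log-transformed column {col!r} "
                f"at row {int(bad[0])} (value {vals[bad[0]]!r})"
            )
        out[col] = np.log(vals)
    return out


def shapiro_screen(column: np.ndarray | pd.Series) -> tuple[float, float]:
    """Shapiro-Wilk (W, p) for one numeric vector; advisory only."""
    x = np.asarray(column, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or x.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: Shapiro-Wilk undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)
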