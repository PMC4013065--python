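"""Linear mixed-effects model for longitudinal descriptor tables.

One response descriptor; fixed effects ecotype + time + ecotype:time
(plus time^2 for the size-like "area group" descriptors); a random
intercept per plant; AR(1) correlation between a plant's successive
residuals.  Estimation is (RE)ML with the two covariance parameters
(intercept/residual variance ratio and the AR(1) coefficient) profiled
out and optimised numerically; the fixed effects then follow by
generalised least squares.

statsmodels' ``MixedLM`` cannot combine a random intercept with AR(1)
residuals, so the likelihood is implemented here; the ``rho = 0``
special case is cross-checked against ``MixedLM`` in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from rosettakit.descriptors import AREA_GROUP


@dataclass(frozen=True)
class LmeSpec:
    """Model structure for one descriptor.

    ``quadratic_time`` defaults to membership of the area group.  Time
    is centred before building the design, which leaves the effect tests
    and pairwise contrasts unchanged but conditions the quadratic term.
    """

    descriptor: str
    quadratic_time: bool | None = None
    reml: bool = True

    def wants_quadratic(self) -> bool:
        if self.quadratic_time is not None:
            return self.quadratic_time
        return self.descriptor in AREA_GROUP


@dataclass
class ModelDesign:
    """Fixed-effect design bookkeeping (treatment coding, centred time)."""

    ecotypes: list[str]
    das_values: np.ndarray
    das_mean: float
    quadratic: bool
    has_time: bool
    columns: list[str] = field(default_factory=list)
    blocks: dict[str, slice] = field(default_factory=dict)

    def build(self, ecotype: np.ndarray, das: np.ndarray) -> np.ndarray:
        L = len(self.ecotypes)
        t = das - self.das_mean
        n = len(das)
        cols: list[np.ndarray] = [np.ones(n)]
        names = ["intercept"]
        for e in self.ecotypes[1:]:
            cols.append((ecotype == e).astype(float))
            names.append(f"ecotype[{e}]")
        b_eco = slice(1, L)
        b_time = b_quad = b_inter = slice(0, 0)
        if self.has_time:
            cols.append(t)
            names.append("das_c")
            b_time = slice(L, L + 1)
            nxt = L + 1
            if self.quadratic:
                cols.append(t**2)
                names.append("das_c2")
                b_quad = slice(nxt, nxt + 1)
                nxt += 1
            for e in self.ecotypes[1:]:
                cols.append((ecotype == e).astype(float) * t)
                names.append(f"ecotype[{e}]:das_c")
            b_inter = slice(nxt, nxt + L - 1)
            b_time_all = slice(L, nxt)
        else:
            b_time_all = slice(0, 0)
        self.columns = names
        self.blocks = {
            "ecotype": b_eco,
            "time": b_time_all,  # das (+ das^2)
            "das": b_time,
            "das2": b_quad,
            "interaction": b_inter,
        }
        return np.column_stack(cols)

    def marginal_row(self, das: float) -> np.ndarray:
        """Design row for the ecotype-averaged prediction at one das."""
        L = len(self.ecotypes)
        t = das - self.das_mean
        row = [1.0] + [1.0 / L] * (L - 1)
        if self.has_time:
            row.append(t)
            if self.quadratic:
                row.append(t**2)
            row.extend([t / L] * (L - 1))
        return np.asarray(row)

    def ecotype_contrast(self, a: str, b: str, das: float | None = None) -> np.ndarray:
        """Contrast vector for ecotype a minus b (at centred time 0 by default)."""
        p = len(self.columns)
        v = np.zeros(p)
        t = 0.0 if das is None else das - self.das_mean
        for e, sign in ((a, 1.0), (b, -1.0)):
            if e == self.ecotypes[0]:
                continue
            v[self.columns.index(f"ecotype[{e}]")] = sign
            if self.has_time and t != 0.0:
                v[self.columns.index(f"ecotype[{e}]:das_c")] = sign * t
        return v


@dataclass
class LmeResult:
    """Fitted coefficients, variance components and effect tests."""

    spec: LmeSpec
    design: ModelDesign
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    sigma_e: float
    sigma_b: float
    rho: float
    loglik: float
    n_obs: int
    n_plants: int
    effect_tests: dict[str, dict]
    residuals: np.ndarray
    fitted: np.ndarray
    converged: bool
    df_between: int
    df_within: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse})

    def residual_diagnostics(self) -> dict[str, float]:
        r = self.residuals
        halves = np.array_split(np.sort(np.abs(r)), 2)
        return {
            "mean": float(r.mean()),
            "sd": float(r.std(ddof=1)),
            "skew": float(sps.skew(r)),
            "var_ratio_high_low": float(
                (halves[1].var(ddof=1) + 1e-12) / (halves[0].var(ddof=1) + 1e-12)
            ),
        }


def _group_by_plant(table: pd.DataFrame, descriptor: str, design: ModelDesign):
    """Per-plant (X, y) blocks, plants sorted, occasions sorted by das."""
    blocks = []
    for pid, grp in table.groupby("plant_id", sort=True):
        grp = grp.sort_values("das")
        X = design.build(grp["ecotype"].to_numpy(), grp["das"].to_numpy(dtype=float))
        y = grp[descriptor].to_numpy(dtype=float)
        blocks.append((str(pid), X, y))
    return blocks


def _ar1_corr(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _profiled_negloglik(theta, blocks, n, p, reml):
    """-2 log-likelihood with beta and sigma_e^2 profiled out.

    theta = (atanh(rho), log(gamma)) with gamma = sigma_b^2 / sigma_e^2.
    """
    rho = math.tanh(theta[0])
    gamma = math.exp(theta[1])
    # cache W^-1 and log|W| per block size
    cache: dict[int, tuple[np.ndarray, float]] = {}
    A = np.zeros((p, p))
    c = np.zeros(p)
    yWy = 0.0
    logdet_sum = 0.0
    for _, X, y in blocks:
        m = len(y)
        if m not in cache:
            W = gamma * np.ones((m, m)) + _ar1_corr(m, rho)
            sign, logdet = np.linalg.slogdet(W)
            if sign <= 0:
                return 1e12
            cache[m] = (np.linalg.inv(W), logdet)
        Winv, logdet = cache[m]
        Xw = Winv @ X
        A += X.T @ Xw
        c += Xw.T @ y
        yWy += y @ Winv @ y
        logdet_sum += logdet
    try:
        Achol = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return 1e12
    beta = np.linalg.solve(A, c)
    rss = yWy - c @ beta
    if rss <= 0:
        return 1e12
    if reml:
        df = n - p
        sigma2 = rss / df
        logdet_A = 2.0 * np.log(np.diag(Achol)).sum()
        nll = df * math.log(sigma2) + logdet_sum + logdet_A + df
    else:
        sigma2 = rss / n
        nll = n * math.log(sigma2) + logdet_sum + n
    return nll


def fit_lme(table: pd.DataFrame, spec: LmeSpec) -> LmeResult:
    """Fit the random-intercept + AR(1) model for one descriptor.

    The table needs columns ``plant_id``, ``ecotype``, ``das`` and the
    response column (already on its analysis scale).  Rows with missing
    response are dropped.  With a single time point the time and
    interaction terms are omitted and the AR(1) parameter is fixed at 0,
    reducing to a one-way random-intercept model.
    """
    for col in ("plant_id", "ecotype", "das", spec.descriptor):
        if col not in table.columns:
            raise ValueError(f"missing required column {spec.descriptor!r}" if col == spec.descriptor
                             else f"missing required column {col!r}")
    data = table.dropna(subset=[spec.descriptor]).copy()
    n = len(data)
    ecotypes = sorted(data["ecotype"].astype(str).unique())
    if len(ecotypes) < 2:
        raise ValueError("need >= 2 ecotypes to fit an ecotype effect")
    plants_per_eco = data.groupby("ecotype")["plant_id"].nunique()
    if (plants_per_eco < 2).any():
        bad = plants_per_eco[plants_per_eco < 2].index.tolist()
        raise ValueError(
            f"singular design: ecotype(s) {bad} have a single plant; "
            "the random intercept is confounded with the ecotype effect"
        )
    das_values = np.sort(data["das"].astype(float).unique())
    has_time = das_values.size >= 2
    design = ModelDesign(
        ecotypes=ecotypes,
        das_values=das_values,
        das_mean=float(data["das"].astype(float).mean()),
        quadratic=spec.wants_quadratic() and das_values.size >= 3,
        has_time=has_time,
    )
    data["ecotype"] = data["ecotype"].astype(str)
    blocks = _group_by_plant(data, spec.descriptor, design)
    p = len(design.columns)
    if n <= p + 1:
        raise ValueError(f"too few observations (n={n}) for p={p} fixed effects")
    n_plants = len(blocks)

    estimate_rho = has_time and max(len(y) for _, _, y in blocks) >= 2
    x0 = np.array([math.atanh(0.2) if estimate_rho else 0.0, 0.0])
    if estimate_rho:
        res = optimize.minimize(
            _profiled_negloglik,
            x0,
            args=(blocks, n, p, spec.reml),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400},
        )
        theta = res.x
        converged = bool(res.success)
    else:
        res = optimize.minimize_scalar(
            lambda g: _profiled_negloglik((0.0, g), blocks, n, p, spec.reml),
            bounds=(-10.0, 10.0),
            method="bounded",
        )
        theta = np.array([0.0, res.x])
        converged = bool(res.success)
    rho = math.tanh(theta[0])
    gamma = math.exp(theta[1])

    # final GLS pass at the optimum
    cache: dict[int, np.ndarray] = {}
    A = np.zeros((p, p))
    c = np.zeros(p)
    yWy = 0.0
    for _, X, y in blocks:
        m = len(y)
        if m not in cache:
            cache[m] = np.linalg.inv(gamma * np.ones((m, m)) + _ar1_corr(m, rho))
        Winv = cache[m]
        Xw = Winv @ X
        A += X.T @ Xw
        c += Xw.T @ y
        yWy += y @ Winv @ y
    beta = np.linalg.solve(A, c)
    rss = yWy - c @ beta
    dof = n - p if spec.reml else n
    sigma2_e = rss / dof
    sigma_e = math.sqrt(sigma2_e)
    sigma_b = math.sqrt(gamma * sigma2_e)
    cov_beta = sigma2_e * np.linalg.inv(A)
    bse = np.sqrt(np.diag(cov_beta))

    fitted = np.concatenate([X @ beta for _, X, _ in blocks])
    resid = np.concatenate([y - X @ beta for _, X, y in blocks])

    # containment-style denominator degrees of freedom
    L = len(ecotypes)
    df_between = n_plants - L
    p_within = p - L
    df_within = max(n - n_plants - p_within, 1)
    if df_between < 1:
        warnings.warn("no between-plant degrees of freedom left", stacklevel=2)
        df_between = 1

    effect_tests: dict[str, dict] = {}
    for effect, ddf in (("ecotype", df_between), ("time", df_within), ("interaction", df_within)):
        sl = design.blocks[effect]
        q = sl.stop - sl.start
        if q == 0:
            continue
        b = beta[sl]
        C = cov_beta[sl, sl]
        try:
            stat = float(b @ np.linalg.solve(C, b)) / q
        except np.linalg.LinAlgError:
            continue
        pval = float(sps.f.sf(stat, q, ddf))
        effect_tests[effect] = {"F": stat, "df_num": q, "df_den": ddf, "p": pval}

    nll = _profiled_negloglik(theta, blocks, n, p, spec.reml)
    return LmeResult(
        spec=spec,
        design=design,
        params=pd.Series(beta, index=design.columns),
        bse=pd.Series(bse, index=design.columns),
        cov_params=pd.DataFrame(cov_beta, index=design.columns, columns=design.columns),
        sigma_e=sigma_e,
        sigma_b=sigma_b,
        rho=rho if estimate_rho else 0.0,
        loglik=-0.5 * nll,
        n_obs=n,
        n_plants=n_plants,
        effect_tests=effect_tests,
        residuals=resid,
        fitted=fitted,
        converged=converged,
        df_between=df_between,
        df_within=df_within,
    )
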