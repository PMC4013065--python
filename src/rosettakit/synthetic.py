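"""Synthetic rosettes and descriptor tables with known ground truth.

Two generators:

* :func:`render_rosette` / :func:`render_timecourse` draw procedural
  rosette masks — elliptical leaf blades on petiole bars placed at
  successive phyllotaxis angles — so the segmentation and descriptor
  stages can be tested against planted geometry.
* :func:`simulate_descriptor_table` draws a long-format descriptor table
  from the same generative structure the longitudinal analysis assumes:
  fixed ecotype/time/interaction effects, a per-plant random intercept
  and AR(1) within-plant errors.

Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from rosettakit.descriptors import AREA_GROUP, DESCRIPTOR_NAMES
from rosettakit.segmentation import BinaryMask
from rosettakit.stats.transforms import LOG_DESCRIPTORS

#: Study design constants used throughout the tests: 19 ecotypes,
#: 12 replicate plants per ecotype, imaged on 5 days after stratification.
DEFAULT_N_ECOTYPES = 19
DEFAULT_N_REPS = 12
DEFAULT_DAS = (17, 22, 25, 28, 30)


@dataclass(frozen=True)
class RosettePhenotypeParams:
    """Geometry of one procedural rosette (physical units, mm)."""

    n_leaves: int = 8
    leaf_length: float = 10.0
    leaf_width: float = 5.0
    petiole_length: float = 4.0
    phyllotaxis_angle: float = 137.5
    jitter_sd: float = 0.0
    image_size: int = 400
    px_per_mm: float = 7.31

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if min(self.leaf_length, self.leaf_width, self.px_per_mm) <= 0:
            raise ValueError("leaf dimensions and px_per_mm must be > 0")
        if self.petiole_length < 0 or self.jitter_sd < 0:
            raise ValueError("petiole_length and jitter_sd must be >= 0")


@dataclass(frozen=True)
class GrowthParams:
    """Exponential area growth: area scales as exp(k * (t - t0))."""

    k: float = 0.1
    t0: float | None = None
    petiole_elongation_rate: float = 0.0  # mm/day added to petiole_length

    def __post_init__(self) -> None:
        if not math.isfinite(self.k):
            raise ValueError("growth rate k must be finite")
        if self.k < 0:
            raise ValueError("negative growth rate k not supported")


def render_rosette(params: RosettePhenotypeParams, seed: int = 0) -> BinaryMask:
    """Union of elliptical leaf blades plus petiole bars around the centre.

    Leaf *i* sits at angle ``i * phyllotaxis_angle`` (plus optional
    Gaussian jitter), its blade centred ``petiole_length +
    leaf_length/2`` from the rosette centre and oriented radially.
    Raises if the rendered rosette would exceed the canvas.
    """
    sf = params.px_per_mm
    size = params.image_size
    reach_mm = params.petiole_length + params.leaf_length
    if reach_mm * sf >= size / 2 - 1:
        raise ValueError(
            f"rosette radius {reach_mm:.1f} mm does not fit a {size} px canvas "
            f"at {sf} px/mm"
        )
    rng = np.random.default_rng(seed)
    grid = np.zeros((size, size), dtype=bool)
    c = size / 2.0
    petiole_half_w = max(0.5, params.leaf_width * sf / 6.0)
    for i in range(params.n_leaves):
        ang = math.radians(i * params.phyllotaxis_angle)
        if params.jitter_sd > 0:
            ang += rng.normal(0.0, math.radians(params.jitter_sd))
        dy, dx = math.sin(ang), math.cos(ang)
        blade_r = (params.petiole_length + params.leaf_length / 2.0) * sf
        cy, cx = c + dy * blade_r, c + dx * blade_r
        rr, cc = draw_ellipse(
            cy,
            cx,
            params.leaf_length * sf / 2.0,
            params.leaf_width * sf / 2.0,
            shape=grid.shape,
            rotation=-(ang - math.pi / 2.0),
        )
        grid[rr, cc] = True
        if params.petiole_length > 0:
            # rectangle from centre to blade start, width ~ leaf_width/3
            end = (c + dy * (params.petiole_length + 1) * sf,
                   c + dx * (params.petiole_length + 1) * sf)
            px, py = -dy * petiole_half_w, dx * petiole_half_w
            r_poly = [c + px, end[0] + px, end[0] - px, c - px]
            c_poly = [c + py, end[1] + py, end[1] - py, c - py]
            rr, cc = draw_polygon(r_poly, c_poly, shape=grid.shape)
            grid[rr, cc] = True
    return BinaryMask(grid=grid, scale_factor=sf)


def render_timecourse(
    phen: RosettePhenotypeParams,
    growth: GrowthParams,
    das: tuple[float, ...] = DEFAULT_DAS,
    seed: int = 0,
) -> list[BinaryMask]:
    """Masks at successive imaging dates under exponential area growth.

    Linear dimensions scale as ``exp(k * dt / 2)`` so that extracted
    *areas* grow at relative rate ``k`` — the quantity the growth stage
    estimates.
    """
    t0 = growth.t0 if growth.t0 is not None else das[0]
    masks = []
    for t in das:
        lin = math.exp(growth.k * (t - t0) / 2.0)
        scaled = RosettePhenotypeParams(
            n_leaves=phen.n_leaves,
            leaf_length=phen.leaf_length * lin,
            leaf_width=phen.leaf_width * lin,
            petiole_length=phen.petiole_length * lin
            + growth.petiole_elongation_rate * (t - t0),
            phyllotaxis_angle=phen.phyllotaxis_angle,
            jitter_sd=phen.jitter_sd,
            image_size=phen.image_size,
            px_per_mm=phen.px_per_mm,
        )
        # same seed: leaf placement jitter is a plant property, not noise
        masks.append(render_rosette(scaled, seed=seed))
    return masks


def render_colour_scene(
    mask: BinaryMask,
    fg_colour: tuple[int, int, int] = (40, 140, 40),
    bg_colour: tuple[int, int, int] = (110, 80, 50),
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Flat green-on-brown RGB rendering of a mask, with optional salt noise.

    Exists solely to exercise the colour segmentation stage.
    """
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = bg_colour
    img[mask.grid] = fg_colour
    if noise_fraction > 0:
        n = int(noise_fraction * h * w)
        rr = rng.integers(0, h, n)
        cc = rng.integers(0, w, n)
        img[rr, cc] = fg_colour
    return img


# ---------------------------------------------------------------------------
# descriptor-table simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableEffectSpec:
    """Generative parameters for a longitudinal descriptor table.

    Per descriptor *d*, the response for plant *p* of ecotype *e* at
    (centred) time *t* is::

        Y = baseline_d + offset[e, d] + slope_d * t (+ quad_d * t^2 for
            the area group) + interaction[e, d] * t + b_p + eps

    with ``b_p ~ N(0, intercept_sd^2)`` and ``eps`` an AR(1) process over
    the plant's time points (lag-1 correlation ``rho``, marginal sd
    ``residual_sd``).  Values are on the *analysis* scale (i.e. after any
    log transform); ``simulate_descriptor_table(raw=True)`` exponentiates
    the log-policy columns back to raw units.
    """

    n_ecotypes: int = DEFAULT_N_ECOTYPES
    n_reps: int = DEFAULT_N_REPS
    das: tuple[float, ...] = DEFAULT_DAS
    descriptors: tuple[str, ...] = DESCRIPTOR_NAMES
    ecotype_offset_sd: float = 0.5
    slope: float = 0.05
    quad: float = -0.002
    interaction_sd: float = 0.01
    intercept_sd: float = 0.3
    rho: float = 0.4
    residual_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("AR(1) rho must satisfy 0 <= rho < 1")
        if min(self.intercept_sd, self.residual_sd, self.ecotype_offset_sd,
               self.interaction_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_ecotypes < 1 or self.n_reps < 1 or len(self.das) < 1:
            raise ValueError("design must have >= 1 ecotype, rep and time point")


#: Nominal analysis-scale baselines; keep log-policy columns' raw values
#: positive after exponentiation and give ratio columns plausible centres.
_BASELINES = {
    "mincirclediam": 4.0, "normsmallpax": 10.0, "normlargepax": 12.0,
    "minrectarea": 7.0, "mindistcenbdy": 3.0, "vrectsizey": 4.0,
    "vrectsizex": 4.0, "compactness": 0.55, "normrotmo": 0.12,
    "area": 6.5, "paxratio": 1.3, "circumference": 5.5, "excentricity": 1.3,
    "maxdiam": 4.2, "roundness": 40.0, "bdryround": 4.5, "bdrycount": 5.6,
    "bdrytoarearatio": 0.4, "conhullcirc": 4.6, "conhullarea": 7.0,
}

@dataclass(frozen=True)
class SimulatedTable:
    """A simulated table plus its ground-truth parameter record."""

    table: pd.DataFrame
    truth: dict = field(repr=False, default_factory=dict)


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """AR(1) with marginal sd `sd` and lag-1 correlation `rho`."""
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    innov_sd = sd * math.sqrt(1.0 - rho**2)
    for i in range(1, n):
        eps[i] = rho * eps[i - 1] + rng.normal(0.0, innov_sd)
    return eps


def simulate_descriptor_table(spec: TableEffectSpec, raw: bool = False) -> SimulatedTable:
    """Draw a long-format descriptor table from the generative model.

    Returns the table (columns ``plant_id``, ``ecotype``, ``das`` plus
    one column per descriptor) and the planted ecotype offsets, slopes
    and variance components.  With ``raw=True`` the log-policy columns
    are exponentiated so the table looks like untransformed
    measurements.
    """
    rng = np.random.default_rng(spec.seed)
    ecos = [f"eco{i:02d}" for i in range(spec.n_ecotypes)]
    das = np.asarray(spec.das, dtype=float)
    t_c = das - das.mean()
    n_t = das.size

    offsets = {
        d: rng.normal(0.0, spec.ecotype_offset_sd, spec.n_ecotypes)
        for d in spec.descriptors
    }
    interactions = {
        d: rng.normal(0.0, spec.interaction_sd, spec.n_ecotypes)
        for d in spec.descriptors
    }
    rows = []
    for ei, eco in enumerate(ecos):
        for rep in range(spec.n_reps):
            pid = f"{eco}_r{rep:02d}"
            b = {d: rng.normal(0.0, spec.intercept_sd) for d in spec.descriptors}
            eps = {
                d: _ar1_noise(rng, n_t, spec.rho, spec.residual_sd)
                for d in spec.descriptors
            }
            for ti, t in enumerate(das):
                row = {"plant_id": pid, "ecotype": eco, "das": t}
                for d in spec.descriptors:
                    quad = spec.quad if d in AREA_GROUP else 0.0
                    y = (
                        _BASELINES.get(d, 1.0)
                        + offsets[d][ei]
                        + spec.slope * t_c[ti]
                        + quad * t_c[ti] ** 2
                        + interactions[d][ei] * t_c[ti]
                        + b[d]
                        + eps[d][ti]
                    )
                    row[d] = y
                rows.append(row)
    table = pd.DataFrame(rows)
    if raw:
        for d in spec.descriptors:
            if d in LOG_DESCRIPTORS:
                table[d] = np.exp(table[d])
    truth = {
        "ecotype_offsets": offsets,
        "interactions": interactions,
        "slope": spec.slope,
        "quad": spec.quad,
        "intercept_sd": spec.intercept_sd,
        "rho": spec.rho,
        "residual_sd": spec.residual_sd,
        "baselines": dict(_BASELINES),
        "das_mean": float(das.mean()),
    }
    return SimulatedTable(table=table, truth=truth)
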