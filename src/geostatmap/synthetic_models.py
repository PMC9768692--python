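"""Synthetic validation data: fractal-boundary regions and binary outcomes.

Ground-truth spatial signal is laid out as Koch snowflake / anti-snowflake
polygons -- fractal boundaries exhibit detail across every spatial scale,
which makes them demanding recovery targets for smoothing-based methods.
Binary variables are drawn at uniformly random locations with probabilities
that depend only on region membership:

* univariate noise models: P(Z=1) = 1-gamma inside the shape, gamma outside;
* bivariate noise models: Z1 and Z2 independent, with Z1 active over
  R1 (union) R3 and Z2 active over R2 (union) R3;
* interaction model: regions as in the bivariate layout, with the joint
  distribution over {(0,0),(1,0),(0,1),(1,1)} inside R3 parameterized by an
  interaction strength c3 in [0, 0.5]:
      p0 = 0.025,  p1 = p2 = 0.25 - 0.25*c3,  p3 = 0.475 + 0.5*c3,
  so that p3 rises from 0.475 (independence product 0.725^2 ~ 0.525) to
  0.725 while the off-diagonal outcomes are suppressed.  Outside R3 the
  noise-free bivariate rule applies.

Target maps collect the cells whose outcome probability (marginal for a
variable, joint (1,1) for the interaction term) exceeds 0.5 at the cell
centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon

from .core_grid import GridSpec, ObservationTable

__all__ = [
    "SnowflakeShape",
    "RegionLayout",
    "OutcomeDistribution",
    "MODEL_KINDS",
    "UNIVARIATE_KINDS",
    "BIVARIATE_KINDS",
    "koch_polygon",
    "default_grid",
    "layout_for_model",
    "outcome_distribution",
    "interaction_distribution",
    "probability_field",
    "sample_dataset",
    "target_map",
]

UNIVARIATE_KINDS = ("snowflake", "anti_snowflake", "snowflake_field")
BIVARIATE_KINDS = ("bivariate_snowflake", "bivariate_anti", "interaction")
MODEL_KINDS = UNIVARIATE_KINDS + BIVARIATE_KINDS

# bivariate outcome ordering: index = z1 + 2*z2
BIVARIATE_OUTCOMES = ((0, 0), (1, 0), (0, 1), (1, 1))

_MAX_ORDER = 8


@dataclass(frozen=True)
class SnowflakeShape:
    """Koch snowflake (outward spikes) or anti-snowflake (inward spikes)."""

    center: tuple[float, float]
    circumradius: float
    order: int
    anti: bool
    vertices: np.ndarray

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def geometry(self) -> Polygon | MultiPolygon:
        """Valid geometry for spatial operations.

        The snowflake ring is already valid.  The first anti-snowflake
        iteration's three inward spikes reach exactly the centroid (spike
        height = edge*sqrt(3)/6 = the apothem), so the ring touches itself
        at a point and must be repaired into an equivalent valid
        (multi)polygon of identical area.
        """
        poly = Polygon(self.vertices)
        if poly.is_valid:
            return poly
        return shapely.make_valid(poly)


def _koch_refine(verts: np.ndarray, outward_sign: float) -> np.ndarray:
    """One Koch iteration: replace each edge p->q by p, a, peak, b."""
    p = verts
    q = np.roll(verts, -1, axis=0)
    e = q - p
    a = p + e / 3.0
    b = p + 2.0 * e / 3.0
    mid = (p + q) / 2.0
    # for a CCW polygon, (dy, -dx) points outward
    normal = np.stack([e[:, 1], -e[:, 0]], axis=1)
    peak = mid + outward_sign * normal * (np.sqrt(3.0) / 6.0)
    return np.stack([p, a, peak, b], axis=1).reshape(-1, 2)


def koch_polygon(
    center: tuple[float, float],
    circumradius: float,
    order: int,
    anti: bool = False,
) -> SnowflakeShape:
    """Standard Koch construction on an equilateral triangle.

    The order-0 shape is the triangle itself (apex pointing up); each
    iteration replaces every edge by four, erecting the middle-third
    triangle outward (snowflake) or inward (anti-snowflake).  The vertex
    count is 3 * 4^order.
    """
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    if order < 0:
        raise ValueError("order must be >= 0")
    if order > _MAX_ORDER:
        raise ValueError(f"order {order} refused: vertex count 3*4^order explodes")
    cx, cy = center
    angles = np.deg2rad([90.0, 210.0, 330.0])  # CCW equilateral triangle
    verts = np.stack(
        [cx + circumradius * np.cos(angles), cy + circumradius * np.sin(angles)],
        axis=1,
    )
    sign = -1.0 if anti else 1.0
    for _ in range(order):
        verts = _koch_refine(verts, sign)
    return SnowflakeShape(center=(float(cx), float(cy)),
                          circumradius=float(circumradius),
                          order=order, anti=anti, vertices=verts)


@dataclass
class RegionLayout:
    """Named disjoint signal regions on a grid."""

    grid: GridSpec
    regions: dict[str, Polygon | MultiPolygon]
    model_kind: str

    def membership(self, x: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        """Boolean membership of each point in each region."""
        return {
            name: shapely.contains_xy(geom, x, y)
            for name, geom in self.regions.items()
        }


def default_grid(model_kind: str) -> GridSpec:
    """Default raster domain: 120x120 cells of unit size for univariate
    models (the largest smoothing diameter, 60, is half the grid height),
    240x120 for the bivariate and interaction layouts."""
    if model_kind in UNIVARIATE_KINDS:
        return GridSpec(0.0, 0.0, 1.0, 120, 120)
    if model_kind in BIVARIATE_KINDS:
        return GridSpec(0.0, 0.0, 1.0, 240, 120)
    raise ValueError(f"unknown model kind {model_kind!r}")


def layout_for_model(model_kind: str, grid: GridSpec | None = None,
                     order: int = 4) -> RegionLayout:
    """Deterministic region layout for a synthetic model.

    Univariate: one centred shape (circumradius 3/8 of the short grid side;
    the snowflake field uses a 3x3 array of shapes at circumradius 14/120
    of the short side).  Bivariate/interaction: three shapes left to right
    at circumradius 28/120 of the grid height -- R1 (Z1 only), R3 (joint /
    interaction), R2 (Z2 only).
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if grid is None:
        grid = default_grid(model_kind)
    x0, y0, x1, y1 = grid.extent
    w, h = x1 - x0, y1 - y0
    short = min(w, h)
    anti = model_kind in ("anti_snowflake", "bivariate_anti")

    if model_kind in ("snowflake", "anti_snowflake"):
        shape = koch_polygon(((x0 + x1) / 2, (y0 + y1) / 2), 0.375 * short,
                             order, anti)
        regions = {"R1": shape.geometry}
    elif model_kind == "snowflake_field":
        r = (14.0 / 120.0) * short
        polys = []
        for fy in (1 / 6, 3 / 6, 5 / 6):
            for fx in (1 / 6, 3 / 6, 5 / 6):
                polys.append(
                    koch_polygon((x0 + fx * w, y0 + fy * h), r, order, False).geometry
                )
        regions = {"R1": MultiPolygon(polys)}
    else:  # bivariate / interaction
        r = (28.0 / 120.0) * h
        cy = (y0 + y1) / 2
        names = ("R1", "R3", "R2")  # left, middle, right
        regions = {
            name: koch_polygon((x0 + fx * w, cy), r, order, anti).geometry
            for name, fx in zip(names, (1 / 6, 3 / 6, 5 / 6))
        }

    geoms = list(regions.values())
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            if geoms[i].intersects(geoms[j]):
                raise ValueError("layout regions are not disjoint on this grid")
    return RegionLayout(grid=grid, regions=regions, model_kind=model_kind)


@dataclass(frozen=True)
class OutcomeDistribution:
    """Categorical distribution over binary outcomes: (P(0), P(1)) for a
    univariate model, (p0, p1, p2, p3) over ((0,0),(1,0),(0,1),(1,1)) for a
    bivariate one."""

    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")

    def marginal(self, variable_index: int) -> float:
        """P(Z_variable = 1)."""
        p = self.probabilities
        if len(p) == 2:
            if variable_index != 0:
                raise IndexError("univariate distribution has one variable")
            return p[1]
        return sum(
            pi for pi, out in zip(p, BIVARIATE_OUTCOMES) if out[variable_index] == 1
        )


def interaction_distribution(c3: float) -> OutcomeDistribution:
    """Joint outcome distribution inside region R3 of the interaction model.

    p0 = 0.025; p1 = p2 = 0.25 - 0.25*c3; p3 = 0.475 + 0.5*c3.
    """
    if not (0.0 <= c3 <= 0.5):
        raise ValueError(f"c3 must lie in [0, 0.5], got {c3}")
    p1 = 0.25 - 0.25 * c3
    return OutcomeDistribution((0.025, p1, p1, 0.475 + 0.5 * c3))


def _gamma_checked(gamma: float) -> float:
    if not (0.0 <= gamma < 0.5):
        raise ValueError(
            f"noise parameter gamma must lie in [0, 0.5) (target undefined "
            f"at gamma >= 0.5), got {gamma}"
        )
    return float(gamma)


def probability_field(
    layout: RegionLayout, points: np.ndarray, parameter: float
) -> np.ndarray:
    """Outcome probabilities at arbitrary points, vectorized.

    Returns an (n, 2) array for univariate models or (n, 4) for bivariate /
    interaction models, rows ordered as in :class:`OutcomeDistribution`.
    ``parameter`` is gamma for the noise models and c3 for the interaction
    model.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = points[:, 0], points[:, 1]
    member = layout.membership(x, y)
    kind = layout.model_kind

    if kind in UNIVARIATE_KINDS:
        gamma = _gamma_checked(parameter)
        p1 = np.where(member["R1"], 1.0 - gamma, gamma)
        return np.stack([1.0 - p1, p1], axis=1)

    if kind in ("bivariate_snowflake", "bivariate_anti"):
        gamma = _gamma_checked(parameter)
        pz1 = np.where(member["R1"] | member["R3"], 1.0 - gamma, gamma)
        pz2 = np.where(member["R2"] | member["R3"], 1.0 - gamma, gamma)
        return np.stack(
            [(1 - pz1) * (1 - pz2), pz1 * (1 - pz2), (1 - pz1) * pz2, pz1 * pz2],
            axis=1,
        )

    # interaction model: noise-free bivariate rule outside R3
    r3 = interaction_distribution(parameter).probabilities
    probs = np.zeros((points.shape[0], 4))
    in_r1, in_r2, in_r3 = member["R1"], member["R2"], member["R3"]
    outside = ~(in_r1 | in_r2 | in_r3)
    probs[outside, 0] = 1.0  # (0,0)
    probs[in_r1, 1] = 1.0  # (1,0)
    probs[in_r2, 2] = 1.0  # (0,1)
    probs[in_r3] = np.asarray(r3)
    return probs


def outcome_distribution(
    layout: RegionLayout, point: tuple[float, float], gamma: float
) -> OutcomeDistribution:
    """Outcome distribution of a noise model at a single point."""
    if layout.model_kind == "interaction":
        raise ValueError("use interaction_distribution for the interaction model")
    probs = probability_field(layout, np.asarray([point]), gamma)[0]
    return OutcomeDistribution(tuple(float(v) for v in probs))


def sample_dataset(
    model_kind: str,
    n: int,
    parameter: float,
    seed: int | np.random.Generator,
    grid: GridSpec | None = None,
) -> ObservationTable:
    """Draw a synthetic dataset: n locations uniform over the grid extent
    (continuous coordinates), outcomes from each location's distribution.

    Deterministic for a fixed seed.  ``parameter`` is gamma (noise models)
    or c3 (interaction model).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    layout = layout_for_model(model_kind, grid)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0, y0, x1, y1 = layout.grid.extent
    locs = np.column_stack(
        [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
    )
    probs = probability_field(layout, locs, parameter)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n)
    idx = (u[:, None] >= cum).sum(axis=1)

    if model_kind in UNIVARIATE_KINDS:
        values = idx.astype(float)[:, None]
        names = ["z"]
    else:
        values = np.stack([(idx & 1).astype(float), (idx >> 1).astype(float)], axis=1)
        names = ["z1", "z2"]
    return ObservationTable(locs, values, names)


def target_map(
    model_kind: str,
    variable_or_term: str,
    parameter: float,
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Ground-truth binary map for a variable or the interaction term.

    A cell belongs to the target iff the marginal probability of the
    variable (or the probability of the joint outcome (1,1) for the
    interaction term ``"z1*z2"``) at the cell centre exceeds 0.5.
    """
    layout = layout_for_model(model_kind, grid)
    gx, gy = layout.grid.cell_center_mesh()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    probs = probability_field(layout, pts, parameter)

    term = variable_or_term.replace(" ", "").lower()
    if term in ("z", "z1"):
        p = probs[:, 1] if probs.shape[1] == 2 else probs[:, 1] + probs[:, 3]
    elif term == "z2":
        if probs.shape[1] != 4:
            raise ValueError("z2 is undefined for univariate models")
        p = probs[:, 2] + probs[:, 3]
    elif term in ("z1*z2", "z1xz2"):
        if probs.shape[1] != 4:
            raise ValueError("the interaction term requires a bivariate model")
        p = probs[:, 3]
    else:
        raise ValueError(f"unknown variable or term {variable_or_term!r}")
    return (p > 0.5).reshape(layout.grid.shape)
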