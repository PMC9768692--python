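"""Raster domain and Gaussian-kernel rasterization of point observations.

Irregularly located point observations are turned into a regular-grid
response suitable for mass-univariate regression: each observation
contributes a raster holding an isotropic bivariate Gaussian density
centred on its location, sampled at cell centres and scaled by cell area,
so that a kernel lying fully inside the grid integrates to ~1.

The kernel width is parameterized by its 95% iso-density diameter ``s`` --
the diameter of the circle centred on the kernel mean that contains 95% of
its probability mass.  For an isotropic bivariate normal the circular mass
inside radius r is 1 - exp(-r^2 / (2 sigma^2)), so s and sigma are related
in closed form by ``sigma = (s / 2) / sqrt(2 ln 20)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "ObservationTable",
    "SmoothingKernel",
    "ResponseStack",
    "sigma_from_diameter",
    "rasterize_observation",
    "build_response_stack",
    "density_mask",
]

# 2 ln 20: solves 1 - exp(-r^2/(2 sigma^2)) = 0.95 at r = s/2
_TWO_LN_20 = 2.0 * np.log(20.0)


def sigma_from_diameter(diameter_s: float) -> float:
    """Standard deviation of the isotropic Gaussian whose 95% iso-density
    circle has the given diameter.

    Parameters
    ----------
    diameter_s : float
        95% iso-density diameter, in planar length units.

    Returns
    -------
    float
        sigma = (diameter_s / 2) / sqrt(2 ln 20).
    """
    if not np.isfinite(diameter_s) or diameter_s <= 0:
        raise ValueError(f"smoothing diameter must be positive, got {diameter_s!r}")
    return (diameter_s / 2.0) / np.sqrt(_TWO_LN_20)


def min_diameter_for_cell_size(cell_size: float) -> float:
    """Smallest admissible smoothing diameter for a given cell size.

    The kernel is under-resolved when sigma < cell_size / 2, i.e. when the
    diameter falls below cell_size * sqrt(2 ln 20).
    """
    return cell_size * np.sqrt(_TWO_LN_20)


@dataclass(frozen=True)
class GridSpec:
    """Regular raster geometry tying 0-based cell indices to planar
    coordinates.  Cells are square; cell (j, k) -- column j, row k -- has
    centre (origin_x + (j+0.5)*cell_size, origin_y + (k+0.5)*cell_size),
    with y increasing northward (row 0 is the southernmost row)."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) -- the shape of rasters on this grid."""
        return (self.n_rows, self.n_cols)

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.width,
            self.origin_y + self.height,
        )

    @property
    def diagonal(self) -> float:
        """Length of the grid-extent diagonal."""
        return float(np.hypot(self.width, self.height))

    def cell_centers_x(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def cell_centers_y(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (n_rows, n_cols) holding cell centres."""
        return np.meshgrid(self.cell_centers_x(), self.cell_centers_y())


@dataclass
class ObservationTable:
    """Point observations: N planar locations, each carrying P variables."""

    locations: np.ndarray  # (N, 2) float
    values: np.ndarray  # (N, P) float
    variable_names: list[str]

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.locations.ndim != 2 or self.locations.shape[1] != 2:
            raise ValueError("locations must be an (N, 2) array")
        n = self.locations.shape[0]
        if n < 1:
            raise ValueError("at least one observation is required")
        if self.values.shape[0] != n:
            raise ValueError("locations and values disagree on N")
        if self.values.shape[1] < 1:
            raise ValueError("at least one variable is required")
        if len(self.variable_names) != self.values.shape[1]:
            raise ValueError("variable_names must match the number of value columns")
        if not np.all(np.isfinite(self.locations)):
            raise ValueError("all locations must be finite")

    @property
    def n(self) -> int:
        return self.locations.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x_col: str = "x",
        y_col: str = "y",
        variables: Sequence[str] | None = None,
    ) -> "ObservationTable":
        if variables is None:
            variables = [c for c in df.columns if c not in (x_col, y_col)]
        locs = df[[x_col, y_col]].to_numpy(dtype=float)
        vals = df[list(variables)].to_numpy(dtype=float)
        return cls(locs, vals, list(variables))

    def to_dataframe(self, x_col: str = "x", y_col: str = "y") -> pd.DataFrame:
        df = pd.DataFrame({x_col: self.locations[:, 0], y_col: self.locations[:, 1]})
        for i, name in enumerate(self.variable_names):
            df[name] = self.values[:, i]
        return df


@dataclass(frozen=True)
class SmoothingKernel:
    """Isotropic Gaussian smoothing kernel, parameterized by its 95%
    iso-density diameter.  Hard-truncated at ``truncation_radius`` (default
    4 sigma, discarding < 0.04% of the mass)."""

    diameter_s: float
    sigma: float
    truncation_radius: float

    @classmethod
    def from_diameter(
        cls, diameter_s: float, truncation_sigmas: float = 4.0
    ) -> "SmoothingKernel":
        if truncation_sigmas < 3.0:
            raise ValueError("truncation_radius must be at least 3 sigma")
        sigma = sigma_from_diameter(diameter_s)
        return cls(diameter_s=float(diameter_s), sigma=sigma,
                   truncation_radius=truncation_sigmas * sigma)

    @property
    def peak_density(self) -> float:
        """Peak of the continuous density, 1 / (2 pi sigma^2)."""
        return 1.0 / (2.0 * np.pi * self.sigma**2)


@dataclass
class ResponseStack:
    """Per-observation, per-scale rasterized Gaussian responses.

    ``data[i]`` is an (N, n_rows, n_cols) array for ``scales[i]``.
    """

    grid: GridSpec
    scales: list[float]
    data: list[np.ndarray] = field(repr=False)

    def at_scale(self, diameter_s: float) -> np.ndarray:
        for s, arr in zip(self.scales, self.data):
            if s == diameter_s:
                return arr
        raise KeyError(f"scale {diameter_s} not in stack (has {self.scales})")

    @property
    def n(self) -> int:
        return self.data[0].shape[0]


def _check_resolution(kernel: SmoothingKernel, grid: GridSpec) -> None:
    if kernel.sigma < 0.5 * grid.cell_size:
        raise ValueError(
            "kernel is under-resolved on this grid: smoothing diameter "
            f"{kernel.diameter_s:g} gives sigma {kernel.sigma:g} < half the "
            f"cell size {grid.cell_size:g}; the minimum admissible diameter "
            f"is {min_diameter_for_cell_size(grid.cell_size):.6g}"
        )


def rasterize_observation(
    location: Sequence[float],
    kernel: SmoothingKernel,
    grid: GridSpec,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian response raster of one observation.

    The value at cell (j, k) is the isotropic bivariate normal density
    centred at ``location``, evaluated at the cell centre and multiplied by
    the cell area; it is exactly zero beyond the truncation radius.
    """
    x0, y0 = float(location[0]), float(location[1])
    if not (np.isfinite(x0) and np.isfinite(y0)):
        raise ValueError(f"observation location must be finite, got {location!r}")
    _check_resolution(kernel, grid)

    if out is None:
        out = np.zeros(grid.shape, dtype=float)
    else:
        out[...] = 0.0

    _add_kernel(out, x0, y0, kernel, grid, scale=1.0)
    return out


def _window_indices(c: float, radius: float, origin: float, cell: float,
                    n: int) -> tuple[int, int]:
    """Index range [i0, i1) of cells whose centre lies within ``radius`` of
    coordinate ``c`` along one axis."""
    lo = int(np.ceil((c - radius - origin) / cell - 0.5))
    hi = int(np.floor((c + radius - origin) / cell - 0.5))
    return max(lo, 0), min(hi, n - 1) + 1


def _add_kernel(out: np.ndarray, x0: float, y0: float, kernel: SmoothingKernel,
                grid: GridSpec, scale: float) -> None:
    """Accumulate one truncated Gaussian kernel into ``out`` in place."""
    r = kernel.truncation_radius
    j0, j1 = _window_indices(x0, r, grid.origin_x, grid.cell_size, grid.n_cols)
    k0, k1 = _window_indices(y0, r, grid.origin_y, grid.cell_size, grid.n_rows)
    if j0 >= j1 or k0 >= k1:
        return
    dx = grid.origin_x + (np.arange(j0, j1) + 0.5) * grid.cell_size - x0
    dy = grid.origin_y + (np.arange(k0, k1) + 0.5) * grid.cell_size - y0
    s2 = kernel.sigma**2
    gx = np.exp(-(dx**2) / (2.0 * s2))
    gy = np.exp(-(dy**2) / (2.0 * s2))
    win = np.outer(gy, gx)
    win *= scale * grid.cell_size**2 / (2.0 * np.pi * s2)
    # circular hard truncation
    win[(dy[:, None] ** 2 + dx[None, :] ** 2) > r * r] = 0.0
    out[k0:k1, j0:j1] += win


def build_response_stack(
    obs: ObservationTable,
    scales: Sequence[float],
    grid: GridSpec,
    dtype=np.float64,
) -> ResponseStack:
    """Rasterize every observation at every smoothing scale.

    ``scales`` must be non-empty and strictly increasing.  The result is
    deterministic given its inputs.
    """
    scales = [float(s) for s in scales]
    if len(scales) == 0:
        raise ValueError("scales must be non-empty")
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")

    data = []
    buf = np.zeros(grid.shape, dtype=float)
    for s in scales:
        kernel = SmoothingKernel.from_diameter(s)
        _check_resolution(kernel, grid)
        arr = np.zeros((obs.n,) + grid.shape, dtype=dtype)
        for i in range(obs.n):
            rasterize_observation(obs.locations[i], kernel, grid, out=buf)
            arr[i] = buf
        data.append(arr)
    return ResponseStack(grid=grid, scales=scales, data=data)


def density_mask(
    obs: ObservationTable,
    kernel: SmoothingKernel,
    grid: GridSpec,
    factor: float = 10.0,
) -> np.ndarray:
    """Cells where the combined smoothing density of all observations
    reaches ``factor`` times the peak value of a single kernel raster."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    _check_resolution(kernel, grid)
    total = np.zeros(grid.shape, dtype=float)
    for i in range(obs.n):
        _add_kernel(total, obs.locations[i, 0], obs.locations[i, 1],
                    kernel, grid, scale=1.0)
    peak = kernel.peak_density * grid.cell_size**2
    return total >= factor * peak
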