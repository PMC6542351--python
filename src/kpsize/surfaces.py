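"""Turn geolocated survey-cluster indicators into municipality covariates.

Household-survey indicators (HIV prevalence, female education, adolescent
pregnancy) are observed at cluster points, not for administrative units.  The
pipeline here: triangulate the cluster locations, linearly interpolate the
indicator on a regular grid restricted to the convex hull of the clusters,
then average the valued grid cells falling inside each municipality.  Linear
triangulation is deterministic, never overshoots the observed range, and
reproduces affine surfaces exactly — properties the tests rely on.

Coordinates are treated as planar; for a country of small extent the
difference from geodesic interpolation is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "ClusterPoints",
    "GridSpec",
    "GridSurface",
    "interpolate_clusters",
    "aggregate_to_units",
    "UnitValue",
]


@dataclass(frozen=True)
class ClusterPoints:
    """Cluster locations and the indicator value measured at each."""

    x: np.ndarray
    y: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, float)
        y = np.asarray(self.y, float)
        v = np.asarray(self.value, float)
        if not (len(x) == len(y) == len(v)):
            raise ValueError("x, y, value must have equal length")
        if len(x) < 3:
            raise ValueError("interpolation needs at least 3 cluster points")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "value", v)

    @classmethod
    def from_csv(cls, path) -> "ClusterPoints":
        df = pd.read_csv(path)
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), df["value"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"x": self.x, "y": self.y, "value": self.value}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class GridSpec:
    """A regular grid: cell centers on an nx-by-ny lattice over the ranges."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int = 100
    ny: int = 100

    @classmethod
    def covering(cls, points: ClusterPoints, nx: int = 100, ny: int = 100) -> "GridSpec":
        return cls(
            float(points.x.min()),
            float(points.x.max()),
            float(points.y.min()),
            float(points.y.max()),
            nx,
            ny,
        )

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates as flattened arrays of length nx*ny."""
        dx = (self.x_max - self.x_min) / self.nx
        dy = (self.y_max - self.y_min) / self.ny
        cx = self.x_min + dx * (np.arange(self.nx) + 0.5)
        cy = self.y_min + dy * (np.arange(self.ny) + 0.5)
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return gx.ravel(), gy.ravel()


@dataclass(frozen=True)
class GridSurface:
    """Interpolated values at grid-cell centers; NaN marks cells whose center
    lies outside the convex hull of the cluster points."""

    grid: GridSpec
    values: np.ndarray  # length nx*ny, NaN outside the hull

    @property
    def valued_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        gx, gy = self.grid.centers()
        return pd.DataFrame({"cell_id": np.arange(len(gx)), "x": gx, "y": gy,
                             "value": self.values})


def interpolate_clusters(points: ClusterPoints, grid: GridSpec | None = None) -> GridSurface:
    """Piecewise-linear interpolation of cluster values onto the grid.

    Uses a Delaunay triangulation of the cluster points; cells with centers
    strictly outside the convex hull get no value.  Raises ``ValueError``
    when all points are collinear (no triangulation exists).
    """
    if grid is None:
        grid = GridSpec.covering(points)
    try:
        interp = LinearNDInterpolator(
            np.column_stack([points.x, points.y]), points.value
        )
    except (QhullError, ValueError) as exc:
        raise ValueError(f"cluster points do not span a 2-D hull: {exc}") from None
    gx, gy = grid.centers()
    values = interp(gx, gy)
    return GridSurface(grid=grid, values=np.asarray(values, float))


@dataclass(frozen=True)
class UnitValue:
    """Per-unit summary: the mean over valued cells, or a flagged fallback
    (nearest valued cell) when the unit lies entirely outside the hull."""

    value: float
    imputed: bool


def aggregate_to_units(
    surface: GridSurface, units: Mapping[int, str] | np.ndarray | list
) -> dict[str, UnitValue]:
    """Average the surface within each unit (municipality).

    ``units`` labels every grid cell with its unit (array of length nx*ny, or
    a mapping cell index -> label).  Units with no valued cell receive the
    value of the nearest valued cell (by center distance), flagged
    ``imputed=True`` so that downstream covariates stay complete without
    hiding the extrapolation.  Raises ``ValueError`` if no cell anywhere has
    a value, or a cell is missing a label.
    """
    n = len(surface.values)
    if isinstance(units, Mapping):
        labels = np.array([units.get(i) for i in range(n)], dtype=object)
    else:
        labels = np.asarray(units, dtype=object)
        if len(labels) != n:
            raise ValueError("unit labels must cover every grid cell")
    if any(lbl is None for lbl in labels):
        missing = int(np.argmax([lbl is None for lbl in labels]))
        raise ValueError(f"grid cell {missing} has no unit label")

    valued = surface.valued_mask
    if not valued.any():
        raise ValueError("no grid cell carries a value; surface is empty")

    gx, gy = surface.grid.centers()
    out: dict[str, UnitValue] = {}
    for lbl in sorted({str(x) for x in labels}):
        in_unit = np.array([str(x) == lbl for x in labels])
        vals = surface.values[in_unit & valued]
        if len(vals):
            out[lbl] = UnitValue(value=float(vals.mean()), imputed=False)
        else:
            # unit entirely outside the hull: borrow the nearest valued cell
            cx, cy = gx[in_unit], gy[in_unit]
            vx, vy = gx[valued], gy[valued]
            d2 = (vx[None, :] - cx[:, None]) ** 2 + (vy[None, :] - cy[:, None]) ** 2
            nearest = int(np.unravel_index(np.argmin(d2), d2.shape)[1])
            out[lbl] = UnitValue(value=float(surface.values[valued][nearest]), imputed=True)
    return out
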