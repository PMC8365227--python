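"""Idealized sidewall-aneurysm geometry and its raster grid.

The domain is a 2D planar section: a straight parent channel of height
``parent_diameter`` (the vessel lumen) with a circular sac sitting on the
upper wall, communicating with the channel through a neck chord.  All
lengths are in meters.  "Volumes" are per-unit-depth areas scaled by a
depth equal to ``parent_diameter`` so that reported magnitudes are
order-comparable to a vessel of circular cross-section.

Coordinates: x axial (flow direction), y cross-stream; origin at the
inlet / lower wall.  Cell masks are cell-centered; velocities live on
faces (staggered, see :mod:`aneuflow.flow_solver`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "ResolutionError",
    "PlanePlacementError",
    "AneurysmGeometry",
    "ComputationalGrid",
    "build_sidewall_aneurysm",
    "rasterize",
    "place_planes",
    "channel_grid",
    "SOLID",
    "FLUID_PARENT",
    "FLUID_SAC",
    "NECK_INTERFACE",
]

# cell_mask labels
SOLID = 0
FLUID_PARENT = 1
FLUID_SAC = 2
NECK_INTERFACE = 3


class GeometryError(ValueError):
    """Raised for infeasible geometric parameter combinations."""


class ResolutionError(ValueError):
    """Raised when a raster spacing is too coarse for the geometry."""


class PlanePlacementError(ValueError):
    """Raised when a measurement plane falls outside the parent segment."""


@dataclass(frozen=True)
class AneurysmGeometry:
    """Sidewall sac + straight parent vessel, all dimensions in meters.

    ``sac_center_offset`` is the perpendicular distance of the sac center
    from the parent-vessel wall line; it is derived from the chord
    relation, never set directly.
    """

    parent_diameter: float
    sac_radius: float
    neck_width: float
    parent_length: float
    sac_center_offset: float
    neck_axial_position: float

    def __post_init__(self) -> None:
        if min(self.parent_diameter, self.sac_radius, self.neck_width,
               self.parent_length) <= 0:
            raise GeometryError("all lengths must be positive")
        if self.neck_width > 2.0 * self.sac_radius:
            raise GeometryError(
                "neck chord cannot exceed the sac diameter "
                f"({self.neck_width} > {2 * self.sac_radius})")
        if self.parent_length < 5.0 * self.parent_diameter:
            raise GeometryError(
                "parent_length must allow an entrance length of at least "
                "5 parent diameters")
        half_neck = 0.5 * self.neck_width
        if not (0 <= self.neck_axial_position - half_neck
                and self.neck_axial_position + half_neck <= self.parent_length):
            raise GeometryError("neck must lie fully inside the parent segment")

    @property
    def sac_center(self) -> tuple[float, float]:
        """(x, y) of the sac center; y measured from the lower wall."""
        return (self.neck_axial_position,
                self.parent_diameter + self.sac_center_offset)


def build_sidewall_aneurysm(
    parent_diameter: float,
    sac_radius: float,
    neck_width: float,
    parent_length: float,
    neck_axial_position: float | None = None,
) -> AneurysmGeometry:
    """Construct the sidewall geometry, solving the sac-center offset.

    The sac circle must intersect the upper parent wall in a chord of
    exactly ``neck_width``; the circle-chord relation gives the offset
    ``sqrt(r^2 - (w/2)^2)``.  ``neck_width == 2*sac_radius`` is the
    hemispherical-cap limit (offset 0).
    """
    if min(parent_diameter, sac_radius, neck_width, parent_length) <= 0:
        raise GeometryError("all lengths must be positive")
    if neck_width > 2.0 * sac_radius:
        raise GeometryError(
            "infeasible chord: neck_width exceeds the sac diameter")
    offset = math.sqrt(max(sac_radius**2 - (0.5 * neck_width) ** 2, 0.0))
    if neck_axial_position is None:
        neck_axial_position = 0.5 * parent_length
    return AneurysmGeometry(
        parent_diameter=parent_diameter,
        sac_radius=sac_radius,
        neck_width=neck_width,
        parent_length=parent_length,
        sac_center_offset=offset,
        neck_axial_position=neck_axial_position,
    )


@dataclass
class ComputationalGrid:
    """Uniform cell raster of the domain plus measurement-plane indices.

    ``cell_mask`` holds one of {SOLID, FLUID_PARENT, FLUID_SAC,
    NECK_INTERFACE} per cell.  ``j_wall`` is the index of the horizontal
    face row coinciding with the upper parent wall (the neck chord line).
    Plane A/B are u-face column indices; plane C is the set of open
    v-face columns on the chord row.
    """

    geometry: AneurysmGeometry | None
    spacing: float
    nx: int
    ny: int
    cell_mask: np.ndarray  # (nx, ny) int8
    j_wall: int
    neck_columns: np.ndarray  # column indices of open chord faces
    plane_a: int | None = None
    plane_b: int | None = None
    inter_plane_volume: float | None = None  # V_m, m^3 (area x depth)
    extras: dict = field(default_factory=dict)

    @property
    def channel_height(self) -> float:
        """Lumen height of the parent channel at the inlet."""
        return self.j_wall * self.spacing

    @property
    def depth(self) -> float:
        """Out-of-plane depth used to scale areas to volumes."""
        return self.channel_height

    @property
    def fluid(self) -> np.ndarray:
        return self.cell_mask > SOLID

    @property
    def plane_c_length(self) -> float:
        return self.neck_columns.size * self.spacing

    def fluid_area(self, mask_value: int | None = None) -> float:
        """Raster area (m^2) of all fluid cells or of one label."""
        if mask_value is None:
            n = int(np.count_nonzero(self.fluid))
        else:
            n = int(np.count_nonzero(self.cell_mask == mask_value))
        return n * self.spacing**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        h = self.spacing
        x = (np.arange(self.nx) + 0.5) * h
        y = (np.arange(self.ny) + 0.5) * h
        return np.meshgrid(x, y, indexing="ij")


def rasterize(geom: AneurysmGeometry, spacing: float) -> ComputationalGrid:
    """Rasterize the geometry onto a uniform cell grid.

    The parent wall line must land on a grid line; the chord row of the
    raster is classified by the chord span itself so that the open neck
    length tracks ``neck_width`` to within one cell.
    """
    if spacing > geom.parent_diameter / 20.0:
        raise ResolutionError(
            "spacing must resolve the lumen with at least 20 cells "
            f"(max {geom.parent_diameter / 20.0:g} m, got {spacing:g} m)")
    h = spacing
    j_wall = int(round(geom.parent_diameter / h))
    nx = int(round(geom.parent_length / h))
    cx, cy = geom.sac_center
    y_top = geom.parent_diameter + geom.sac_center_offset + geom.sac_radius
    ny = int(math.ceil(y_top / h)) + 1

    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xc, yc, indexing="ij")

    mask = np.full((nx, ny), SOLID, dtype=np.int8)
    mask[:, :j_wall] = FLUID_PARENT

    in_circle = (X - cx) ** 2 + (Y - cy) ** 2 < geom.sac_radius**2
    sac = in_circle & (np.arange(ny)[None, :] >= j_wall)
    # chord row: open wherever the wall-line chord spans the cell center,
    # so the raster neck length stays within one cell of neck_width
    half = 0.5 * geom.neck_width
    chord_cols = np.abs(xc - geom.neck_axial_position) < half
    sac[:, j_wall] = chord_cols
    mask[sac] = FLUID_SAC

    # parent cells immediately below an open chord face
    below = chord_cols & (mask[:, j_wall - 1] == FLUID_PARENT)
    mask[below, j_wall - 1] = NECK_INTERFACE

    neck_columns = np.flatnonzero(chord_cols)
    return ComputationalGrid(
        geometry=geom, spacing=h, nx=nx, ny=ny, cell_mask=mask,
        j_wall=j_wall, neck_columns=neck_columns)


def channel_grid(height: float, length: float,
                 spacing: float) -> ComputationalGrid:
    """A plain rectangular channel (no sac): the zero-neck fixture used
    for analytic validation runs."""
    if height <= 0 or length <= 0 or spacing <= 0:
        raise GeometryError("all lengths must be positive")
    ny = int(round(height / spacing))
    nx = int(round(length / spacing))
    if ny < 4:
        raise ResolutionError("need at least 4 cells across the lumen")
    mask = np.full((nx, ny), FLUID_PARENT, dtype=np.int8)
    return ComputationalGrid(
        geometry=None, spacing=spacing, nx=nx, ny=ny, cell_mask=mask,
        j_wall=ny, neck_columns=np.empty(0, dtype=np.int64))


def place_planes(grid: ComputationalGrid, a_offset: float,
                 b_offset: float) -> ComputationalGrid:
    """Place planes A (upstream) and B (downstream) of the neck edges.

    Offsets are measured from the neck edges outward.  Plane C is already
    fixed on the neck chord by :func:`rasterize`.  Stores the inter-plane
    fluid volume V_m (raster area between the planes, including the sac,
    times the unit-depth convention).
    """
    geom = grid.geometry
    if geom is None:
        raise PlanePlacementError("grid has no aneurysm geometry")
    h = grid.spacing
    x_left = geom.neck_axial_position - 0.5 * geom.neck_width - a_offset
    x_right = geom.neck_axial_position + 0.5 * geom.neck_width + b_offset
    if a_offset < 0 or b_offset < 0:
        raise PlanePlacementError("plane offsets must be non-negative")
    if x_left < 0 or x_right > geom.parent_length:
        raise PlanePlacementError("plane station outside the parent segment")
    ia = int(round(x_left / h))
    ib = int(round(x_right / h))
    if ia >= ib:
        raise PlanePlacementError("plane A must lie upstream of plane B")
    grid.plane_a = ia
    grid.plane_b = ib
    n_cells = int(np.count_nonzero(grid.fluid[ia:ib, :]))
    grid.inter_plane_volume = n_cells * h * h * grid.depth
    return grid
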