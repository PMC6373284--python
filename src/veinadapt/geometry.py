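"""Cross-sectional geometry of the vein graft.

The 2D cross section is a Cartesian grid carrying three closed Lagrangian
membranes (lumen wall, internal elastic lamina, external wall) that bound
four regions: lumen, tunica intima, tunica media, and the external support
tissue.  Smooth muscle cells are disc particles living between the lumen
wall and the external wall; the remaining wall volume is extracellular
matrix tracked as a gridded density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree
from shapely.geometry import LinearRing

__all__ = [
    "LUMEN", "INTIMA", "MEDIA", "EXTERNAL",
    "SimulationGrid", "MembraneCurve", "VesselCrossSection",
    "CellAgent", "AgentPopulation", "ECMField",
    "InvalidGeometryError", "PackingError",
    "build_basic_geometry", "seed_cells",
    "boundary_displacement", "occlusion_fraction",
]

LUMEN, INTIMA, MEDIA, EXTERNAL = 0, 1, 2, 3
LAYER_NAMES = {INTIMA: "intima", MEDIA: "media"}


class InvalidGeometryError(ValueError):
    """Radii out of order or otherwise impossible vessel geometry."""


class PackingError(RuntimeError):
    """Requested SMC fraction cannot be packed into the wall."""


@dataclass
class SimulationGrid:
    """Regular Cartesian grid, cell-centered scalar sampling, mm units."""

    nx: int
    ny: int
    h: float
    origin: tuple[float, float]  # coordinate of cell center (0, 0)

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise InvalidGeometryError("grid step h must be positive")

    @classmethod
    def enclosing(cls, r_outer: float, h: float, margin_cells: int = 5) -> "SimulationGrid":
        """Square grid centered on the vessel axis enclosing radius ``r_outer``
        with at least ``margin_cells`` cells of margin on every side."""
        half = r_outer + margin_cells * h
        n = 2 * int(math.ceil(half / h)) + 1
        origin = (-(n - 1) / 2 * h, -(n - 1) / 2 * h)
        return cls(nx=n, ny=n, h=h, origin=origin)

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.h * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.h * np.arange(self.ny)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)  # (Y-major arrays of shape (ny, nx))

    def encloses_radius(self, r: float, margin_cells: int = 4) -> bool:
        m = margin_cells * self.h
        return (self.x[0] <= -r - m and self.x[-1] >= r + m
                and self.y[0] <= -r - m and self.y[-1] >= r + m)


@dataclass
class MembraneCurve:
    """Closed elastic membrane discretized as an ordered polygon.

    ``points`` holds the vertices without repeating the first one; segment i
    connects point i to point (i+1) mod n.  ``porosity_threshold`` is the
    membrane tension level above which an SMC may pass through (used for the
    IEL only).
    """

    points: np.ndarray                 # (n, 2), mm
    rest_lengths: np.ndarray           # (n,), mm
    stiffness: float = 1.0             # force / length
    porosity_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        if len(self.points) < 16:
            raise InvalidGeometryError("membrane needs at least 16 points")
        if len(self.rest_lengths) != len(self.points):
            raise InvalidGeometryError("one rest length per segment required")

    @classmethod
    def circle(cls, radius: float, spacing: float, center=(0.0, 0.0),
               stiffness: float = 1.0, porosity_threshold: float = 0.0) -> "MembraneCurve":
        n = max(16, int(math.ceil(2.0 * math.pi * radius / spacing)))
        theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        pts = np.column_stack([center[0] + radius * np.cos(theta),
                               center[1] + radius * np.sin(theta)])
        seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        return cls(points=pts, rest_lengths=seg, stiffness=stiffness,
                   porosity_threshold=porosity_threshold)

    def segment_vectors(self) -> np.ndarray:
        return np.roll(self.points, -1, axis=0) - self.points

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors(), axis=1)

    def perimeter(self) -> float:
        return float(self.segment_lengths().sum())

    def enclosed_area(self) -> float:
        """Signed-area magnitude by the shoelace formula."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def is_simple(self) -> bool:
        try:
            return bool(LinearRing(self.points).is_simple)
        except Exception:
            return False

    def max_spacing(self) -> float:
        return float(self.segment_lengths().max())

    def path(self) -> MplPath:
        return MplPath(self.points, closed=False)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized point-in-polygon test on (m, 2) coordinates."""
        return self.path().contains_points(np.atleast_2d(xy))

    def copy(self) -> "MembraneCurve":
        return MembraneCurve(self.points.copy(), self.rest_lengths.copy(),
                             self.stiffness, self.porosity_threshold)


@dataclass
class CellAgent:
    """A smooth muscle cell as a disc particle."""

    id: int
    position: tuple[float, float]
    radius: float
    layer: int                 # INTIMA or MEDIA
    mitosis_clock: float       # h, in [0, mitotic cycle)
    ecm_clock: float           # h, in [0, ECM cycle)
    alive: bool = True


class AgentPopulation:
    """Array-of-struct store for SMC agents (vectorized motility/plasticity).

    ``CellAgent`` objects are views produced on demand; the arrays are the
    source of truth.
    """

    def __init__(self, radius: float):
        self.radius = float(radius)
        self.ids = np.empty(0, dtype=int)
        self.pos = np.empty((0, 2), dtype=float)
        self.layer = np.empty(0, dtype=int)
        self.mitosis_clock = np.empty(0, dtype=float)
        self.ecm_clock = np.empty(0, dtype=float)
        self._next_id = 0

    def __len__(self) -> int:
        return len(self.ids)

    def add(self, pos, layer, mitosis_clock=0.0, ecm_clock=0.0) -> int:
        new_id = self._next_id
        self._next_id += 1
        self.ids = np.append(self.ids, new_id)
        self.pos = np.vstack([self.pos, np.asarray(pos, float).reshape(1, 2)])
        self.layer = np.append(self.layer, int(layer))
        self.mitosis_clock = np.append(self.mitosis_clock, float(mitosis_clock))
        self.ecm_clock = np.append(self.ecm_clock, float(ecm_clock))
        return new_id

    def remove(self, mask: np.ndarray) -> None:
        keep = ~np.asarray(mask, bool)
        self.ids = self.ids[keep]
        self.pos = self.pos[keep]
        self.layer = self.layer[keep]
        self.mitosis_clock = self.mitosis_clock[keep]
        self.ecm_clock = self.ecm_clock[keep]

    def index_of(self, agent_id: int) -> int:
        idx = np.nonzero(self.ids == agent_id)[0]
        if len(idx) == 0:
            raise KeyError(f"no agent with id {agent_id}")
        return int(idx[0])

    def agents(self) -> list[CellAgent]:
        return [CellAgent(int(i), (float(p[0]), float(p[1])), self.radius,
                          int(l), float(mc), float(ec))
                for i, p, l, mc, ec in zip(self.ids, self.pos, self.layer,
                                           self.mitosis_clock, self.ecm_clock)]

    def count(self, layer: int | None = None) -> int:
        if layer is None:
            return len(self)
        return int(np.sum(self.layer == layer))

    def copy(self) -> "AgentPopulation":
        out = AgentPopulation(self.radius)
        out.ids = self.ids.copy()
        out.pos = self.pos.copy()
        out.layer = self.layer.copy()
        out.mitosis_clock = self.mitosis_clock.copy()
        out.ecm_clock = self.ecm_clock.copy()
        out._next_id = self._next_id
        return out


@dataclass
class ECMField:
    """Extracellular-matrix occupancy density on the grid (dimensionless)."""

    density: np.ndarray
    element_radius: float

    @property
    def element_area(self) -> float:
        return math.pi * self.element_radius ** 2

    def copy(self) -> "ECMField":
        return ECMField(self.density.copy(), self.element_radius)


class VesselCrossSection:
    """Grid + the three membranes + the region labeling they induce."""

    def __init__(self, grid: SimulationGrid, lumen_wall: MembraneCurve,
                 iel: MembraneCurve, external_wall: MembraneCurve):
        self.grid = grid
        self.lumen_wall = lumen_wall
        self.iel = iel
        self.external_wall = external_wall
        self.region_mask = np.full((grid.ny, grid.nx), EXTERNAL, dtype=np.int8)
        self.update_region_mask()

    def update_region_mask(self) -> None:
        X, Y = self.grid.cell_centers()
        pts = np.column_stack([X.ravel(), Y.ravel()])
        in_lumen = self.lumen_wall.contains(pts)
        in_iel = self.iel.contains(pts)
        in_outer = self.external_wall.contains(pts)
        mask = np.full(len(pts), EXTERNAL, dtype=np.int8)
        mask[in_outer] = MEDIA
        mask[in_iel] = INTIMA
        mask[in_lumen] = LUMEN
        self.region_mask = mask.reshape(self.grid.ny, self.grid.nx)

    # --- area queries -------------------------------------------------
    def region_area(self, region: int) -> float:
        """Area of a region from the grid labeling (O(h) accurate)."""
        return float(np.sum(self.region_mask == region)) * self.grid.h ** 2

    def lumen_area(self) -> float:
        return self.lumen_wall.enclosed_area()

    def intimal_area(self) -> float:
        return self.iel.enclosed_area() - self.lumen_wall.enclosed_area()

    def medial_area(self) -> float:
        return self.external_wall.enclosed_area() - self.iel.enclosed_area()

    def wall_area(self) -> float:
        return self.external_wall.enclosed_area() - self.lumen_wall.enclosed_area()

    def membranes(self) -> tuple[MembraneCurve, MembraneCurve, MembraneCurve]:
        return self.lumen_wall, self.iel, self.external_wall

    def assert_simple(self) -> None:
        for name, m in zip(("lumen_wall", "iel", "external_wall"), self.membranes()):
            if not m.is_simple():
                raise InvalidGeometryError(f"membrane {name} self-intersects")

    def layer_of(self, xy: np.ndarray) -> np.ndarray:
        """Region label (LUMEN/INTIMA/MEDIA/EXTERNAL) of each point."""
        xy = np.atleast_2d(xy)
        out = np.full(len(xy), EXTERNAL, dtype=int)
        out[self.external_wall.contains(xy)] = MEDIA
        out[self.iel.contains(xy)] = INTIMA
        out[self.lumen_wall.contains(xy)] = LUMEN
        return out

    def copy(self) -> "VesselCrossSection":
        out = VesselCrossSection.__new__(VesselCrossSection)
        out.grid = self.grid
        out.lumen_wall = self.lumen_wall.copy()
        out.iel = self.iel.copy()
        out.external_wall = self.external_wall.copy()
        out.region_mask = self.region_mask.copy()
        return out


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def build_basic_geometry(r_lumen: float, r_iel: float, r_outer: float,
                         grid: SimulationGrid | None = None,
                         h: float | None = None,
                         membrane_stiffness: float = 1.0,
                         iel_porosity_threshold: float = 0.0) -> VesselCrossSection:
    """Concentric-circle vessel cross section (the pre-adaptation state).

    Membranes are discretized at spacing ``h`` (half the 2h bound, so
    interpolation stencils never skip a segment).
    """
    if not (0.0 < r_lumen < r_iel < r_outer):
        raise InvalidGeometryError(
            f"radii must satisfy 0 < r_lumen < r_iel < r_outer, got "
            f"({r_lumen}, {r_iel}, {r_outer})")
    if grid is None:
        if h is None:
            raise InvalidGeometryError("provide either a grid or a grid step h")
        grid = SimulationGrid.enclosing(r_outer, h)
    if not grid.encloses_radius(r_outer):
        raise InvalidGeometryError("grid does not enclose the outer membrane with margin")
    s = grid.h
    lumen = MembraneCurve.circle(r_lumen, s, stiffness=membrane_stiffness)
    iel = MembraneCurve.circle(r_iel, s, stiffness=membrane_stiffness,
                               porosity_threshold=iel_porosity_threshold)
    outer = MembraneCurve.circle(r_outer, s, stiffness=membrane_stiffness)
    return VesselCrossSection(grid, lumen, iel, outer)


def seed_cells(section: VesselCrossSection, smc_fraction: float,
               rng_seed: int | np.random.Generator = 0,
               r_smc: float | None = None, r_ecm: float | None = None,
               mitotic_cycle: float = 12.0, ecm_cycle: float = 2.0,
               max_rejections: int = 100_000,
               ) -> tuple[AgentPopulation, ECMField]:
    """Populate the wall with SMC discs at the requested area fraction.

    Disc centers are drawn by rejection sampling between the lumen wall and
    the external wall with at most 10% radius overlap between discs; the
    remaining wall is uniform ECM.  Cell clocks start at uniformly random
    phase so divisions desynchronize from the first step.
    """
    if not (0.0 <= smc_fraction < 1.0):
        raise ValueError("smc_fraction must lie in [0, 1)")
    from .params import DEFAULTS as _DEF
    if r_smc is None:
        r_smc = _DEF["geometry"]["r_smc"]
    if r_ecm is None:
        r_ecm = _DEF["geometry"]["r_ecm"]
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    pop = AgentPopulation(radius=r_smc)
    wall_area = section.wall_area()
    disc_area = math.pi * r_smc ** 2
    n_cells = int(round(smc_fraction * wall_area / disc_area))

    outer = section.external_wall
    lumen = section.lumen_wall
    lo = outer.points.min(axis=0)
    hi = outer.points.max(axis=0)
    min_sep = 2.0 * r_smc * 0.9   # <=10% radius overlap allowed
    placed: list[np.ndarray] = []
    rejections = 0
    while len(placed) < n_cells:
        cand = lo + rng.random(2) * (hi - lo)
        inside = outer.contains(cand[None, :])[0] and not lumen.contains(cand[None, :])[0]
        ok = inside
        if ok and placed:
            d2 = np.sum((np.asarray(placed) - cand) ** 2, axis=1)
            ok = bool(np.min(d2) >= min_sep ** 2)
        if ok:
            placed.append(cand)
            rejections = 0
        else:
            rejections += 1
            if rejections > max_rejections:
                raise PackingError(
                    f"could not place {n_cells} discs of radius {r_smc} "
                    f"(placed {len(placed)}) — fraction infeasible for geometry")
    if placed:
        arr = np.asarray(placed)
        layers = section.layer_of(arr)
        for p, layer in zip(arr, layers):
            layer = layer if layer in (INTIMA, MEDIA) else MEDIA
            pop.add(p, layer,
                    mitosis_clock=rng.random() * mitotic_cycle,
                    ecm_clock=rng.random() * ecm_cycle)

    density = np.zeros((section.grid.ny, section.grid.nx))
    wall = (section.region_mask == INTIMA) | (section.region_mask == MEDIA)
    density[wall] = 1.0 - smc_fraction
    return pop, ECMField(density=density, element_radius=r_ecm)


def boundary_displacement(old: MembraneCurve, new: MembraneCurve) -> float:
    """Symmetric (Hausdorff) point-set distance between two closed curves, mm."""
    ta, tb = cKDTree(old.points), cKDTree(new.points)
    d_ab = ta.query(new.points)[0].max()
    d_ba = tb.query(old.points)[0].max()
    return float(max(d_ab, d_ba))


def occlusion_fraction(section: VesselCrossSection, initial_lumen_area: float) -> float:
    """Fraction of the initial lumen area lost to wall encroachment, in [0, 1]."""
    if initial_lumen_area <= 0:
        raise ValueError("initial_lumen_area must be positive")
    return float(np.clip(1.0 - section.lumen_area() / initial_lumen_area, 0.0, 1.0))
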