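"""Macroscopic agents: vesicles, filaments, polygonal regions.

Vesicles are sphere-like agents (disc in the 2D slice) carrying two
compartments (membrane surface and lumenal cargo).  They are indexed onto
the numerical grid every accepted step: the fraction of a vesicle's
membrane assigned to each overlapped grid cell is proportional to the
overlap of the disc perimeter with that cell, so membrane species
exchange locally with the underlying reaction space.  Displacements
proposed by the dynamics modules are resolved with a discard policy: a
move that would overlap another vesicle, cross a membrane face, or leave
the domain keeps the old position.

Coordinate convention: grid point (i, j) (row, col; (0,0) top-left) owns
the square cell [j*ds, (j+1)*ds) x [i*ds, (i+1)*ds) in (x, y) physical
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Vesicle", "Filament", "VolumeRegion", "index_vesicle",
           "VesicleIndex", "resolve_displacement", "displacement_decision",
           "point_in_polygon", "segment_crosses_face"]


@dataclass
class Vesicle:
    """Sphere-like agent with state, position, radius, and two compartments.

    Concentrations: ``membrane`` holds per-area surface densities
    (uM*um), ``cargo`` per-volume concentrations (uM).  ``associations``
    maps grid points (i, j) -> perimeter fraction; refreshed every
    accepted step.
    """

    id: int
    position: np.ndarray
    radius: float
    state: str = "unattached"
    membrane: dict[str, float] = field(default_factory=dict)
    cargo: dict[str, float] = field(default_factory=dict)
    associations: dict[tuple[int, int], float] = field(default_factory=dict)
    filament: "Filament | None" = None
    segment: int | None = None
    birth_time: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)

    @property
    def surface_area(self) -> float:
        """Membrane area of the (pseudo-3D) sphere: 4 pi r^2."""
        return 4.0 * math.pi * self.radius ** 2

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius ** 3

    def membrane_amount(self, entity: str) -> float:
        return self.membrane.get(entity, 0.0) * self.surface_area

    def cargo_amount(self, entity: str) -> float:
        return self.cargo.get(entity, 0.0) * self.volume


@dataclass
class Filament:
    """Line-like agent: ordered vertices with a plus and a minus end.

    By convention the vertex sequence runs from the minus end to the plus
    end; motors specify which end they walk toward.
    """

    points: np.ndarray
    kind: str = "actin"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("filament needs at least two vertices")
        seg = np.diff(self.points, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) <= 0):
            raise ValueError("filament segments must have positive length")

    @property
    def n_segments(self) -> int:
        return len(self.points) - 1

    def segment_vector(self, k: int) -> np.ndarray:
        return self.points[k + 1] - self.points[k]

    def nearest(self, p: np.ndarray) -> tuple[int, float, np.ndarray]:
        """(segment index, distance, closest point) from p to the filament."""
        best = (0, np.inf, self.points[0])
        for k in range(self.n_segments):
            a, b = self.points[k], self.points[k + 1]
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            q = a + t * ab
            d = float(np.hypot(*(p - q)))
            if d < best[1]:
                best = (k, d, q)
        return best


def point_in_polygon(p, vertices) -> bool:
    """Even-odd rule with the documented tie rule: a point exactly on a
    polygon edge or vertex counts as inside."""
    x, y = float(p[0]), float(p[1])
    pts = np.asarray(vertices, dtype=float)
    n = len(pts)
    inside = False
    for k in range(n):
        x1, y1 = pts[k]
        x2, y2 = pts[(k + 1) % n]
        # on-segment check (boundary counts as inside)
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


@dataclass
class VolumeRegion:
    """Volume-like agent: a simple polygon with attached behaviors."""

    name: str
    vertices: np.ndarray
    barrier: bool = False          # vesicles may not cross the boundary
    properties: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least three vertices")

    def contains(self, p) -> bool:
        return point_in_polygon(p, self.vertices)


# ---------------------------------------------------------------------------
# Spatial indexing: perimeter fractions per grid cell
# ---------------------------------------------------------------------------

def index_vesicle(v: Vesicle, ds: float, n_rows: int, n_cols: int
                  ) -> dict[tuple[int, int], float]:
    """Fraction of the vesicle's perimeter inside each grid cell.

    Exact piecewise computation: all angles at which the circle crosses a
    grid line partition the perimeter into arcs; each arc lies in exactly
    one cell, classified at its midpoint.  Fractions sum to 1.  Requires
    r < ds (configuration error otherwise).
    """
    if v.radius >= ds:
        raise ValueError(
            f"vesicle {v.id}: radius {v.radius} must be smaller than the "
            f"grid spacing {ds}")
    cx, cy = float(v.position[0]), float(v.position[1])
    r = v.radius
    crossings: list[float] = []
    # vertical grid lines x = k*ds intersecting the circle
    for k in range(int(math.floor((cx - r) / ds)) + 1,
                   int(math.floor((cx + r) / ds)) + 1):
        u = (k * ds - cx) / r
        if -1.0 < u < 1.0:
            a = math.acos(u)
            crossings.extend((a, 2 * math.pi - a))
    # horizontal grid lines y = k*ds
    for k in range(int(math.floor((cy - r) / ds)) + 1,
                   int(math.floor((cy + r) / ds)) + 1):
        u = (k * ds - cy) / r
        if -1.0 < u < 1.0:
            a = math.asin(u)
            crossings.extend((a % (2 * math.pi), (math.pi - a) % (2 * math.pi)))
    angles = sorted(set(crossings))
    if not angles:
        angles = [0.0]
    fractions: dict[tuple[int, int], float] = {}
    m = len(angles)
    for k in range(m):
        a0 = angles[k]
        a1 = angles[(k + 1) % m] if k + 1 < m else angles[0] + 2 * math.pi
        if a1 <= a0:
            a1 += 2 * math.pi
        mid = (a0 + a1) / 2.0
        px, py = cx + r * math.cos(mid), cy + r * math.sin(mid)
        cell = (min(max(int(py // ds), 0), n_rows - 1),
                min(max(int(px // ds), 0), n_cols - 1))
        fractions[cell] = fractions.get(cell, 0.0) + (a1 - a0) / (2 * math.pi)
    return fractions


class VesicleIndex:
    """Cell -> vesicles map used for local collision queries."""

    def __init__(self, ds: float, n_rows: int, n_cols: int):
        self.ds, self.n_rows, self.n_cols = ds, n_rows, n_cols
        self.cells: dict[tuple[int, int], list[Vesicle]] = {}

    def rebuild(self, vesicles) -> None:
        self.cells = {}
        for v in vesicles:
            v.associations = index_vesicle(v, self.ds, self.n_rows, self.n_cols)
            for cell in v.associations:
                self.cells.setdefault(cell, []).append(v)

    def neighbors(self, v: Vesicle):
        """Vesicles sharing or adjacent to the cells of v (excluding v)."""
        seen: dict[int, Vesicle] = {}
        for (i, j) in v.associations:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for o in self.cells.get((i + di, j + dj), ()):
                        if o.id != v.id:
                            seen[o.id] = o
        return list(seen.values())


# ---------------------------------------------------------------------------
# Collision handling and displacement control
# ---------------------------------------------------------------------------

def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _segs_intersect(p1, p2, q1, q2) -> bool:
    d1 = _cross2(q2 - q1, p1 - q1)
    d2 = _cross2(q2 - q1, p2 - q1)
    d3 = _cross2(p2 - p1, q1 - p1)
    d4 = _cross2(p2 - p1, q2 - p1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def face_segment(face, ds: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical endpoints of the face separating two adjacent grid points."""
    (i, j), (i2, j2) = face
    if (i2, j2) == (i, j + 1):      # vertical wall at x=(j+1)*ds
        return (np.array([(j + 1) * ds, i * ds]),
                np.array([(j + 1) * ds, (i + 1) * ds]))
    if (i2, j2) == (i + 1, j):      # horizontal wall at y=(i+1)*ds
        return (np.array([j * ds, (i + 1) * ds]),
                np.array([(j + 1) * ds, (i + 1) * ds]))
    raise ValueError(f"not a face between adjacent points: {face}")


def segment_crosses_face(p_from, p_to, face, ds: float) -> bool:
    a, b = face_segment(face, ds)
    return _segs_intersect(np.asarray(p_from, float), np.asarray(p_to, float),
                           a, b)


def faces_as_arrays(faces, ds: float) -> tuple[np.ndarray, np.ndarray]:
    """Stack face endpoints into (n, 2) arrays for vectorized tests."""
    if not faces:
        return np.zeros((0, 2)), np.zeros((0, 2))
    a = np.empty((len(faces), 2))
    b = np.empty((len(faces), 2))
    for k, face in enumerate(faces):
        a[k], b[k] = face_segment(face, ds)
    return a, b


def _path_hits_faces(p1, p2, fa: np.ndarray, fb: np.ndarray) -> bool:
    """True if segment p1-p2 strictly crosses any face segment."""
    if fa.shape[0] == 0:
        return False
    e = fb - fa
    d1 = e[:, 0] * (p1[1] - fa[:, 1]) - e[:, 1] * (p1[0] - fa[:, 0])
    d2 = e[:, 0] * (p2[1] - fa[:, 1]) - e[:, 1] * (p2[0] - fa[:, 0])
    m = (d1 > 0) != (d2 > 0)
    if not m.any():
        return False
    seg = p2 - p1
    d3 = seg[0] * (fa[m, 1] - p1[1]) - seg[1] * (fa[m, 0] - p1[0])
    d4 = seg[0] * (fb[m, 1] - p1[1]) - seg[1] * (fb[m, 0] - p1[0])
    return bool(((d3 > 0) != (d4 > 0)).any())


def resolve_displacement(v: Vesicle, proposed: np.ndarray, space,
                         index: VesicleIndex,
                         closed_faces=None,
                         barriers=(),
                         face_arrays: tuple[np.ndarray, np.ndarray] | None = None
                         ) -> np.ndarray:
    """Accept the proposed position or discard the update.

    The move is discarded (position unchanged) if the proposed disc would
    overlap another vesicle, if the center path crosses a membrane face or
    a barrier-region boundary, or if the center would leave the domain.
    Only local interaction partners (vesicles in shared or adjacent cells)
    are tested.
    """
    proposed = np.asarray(proposed, dtype=float)
    old = v.position
    W, H = space.n_cols * space.ds, space.n_rows * space.ds
    if not (v.radius <= proposed[0] <= W - v.radius
            and v.radius <= proposed[1] <= H - v.radius):
        return old
    for o in index.neighbors(v):
        if np.hypot(*(proposed - o.position)) < v.radius + o.radius:
            return old
    if face_arrays is None:
        if closed_faces is None:
            closed_faces = space.membrane_faces()
        face_arrays = faces_as_arrays(closed_faces, space.ds)
    if _path_hits_faces(old, proposed, *face_arrays):
        return old
    for reg in barriers:
        if reg.barrier and reg.contains(old) != reg.contains(proposed):
            return old
    return proposed


def displacement_decision(total_displacements, d_ref: float,
                          theta_plus: float, theta_minus: float) -> str:
    """'decrease' | 'increase' | 'neutral' from D(a) = log10(|dp|/d_ref).

    Decrease is requested if any agent moved too far (D > theta_plus);
    an increase is allowed only if every agent moved very little
    (D < theta_minus); stationary agents score -inf.
    """
    if d_ref <= 0:
        raise ValueError("d_ref must be positive")
    decision = "increase"
    for dp in total_displacements:
        norm = float(np.hypot(*np.asarray(dp, dtype=float)))
        D = -np.inf if norm == 0 else math.log10(norm / d_ref)
        if D > theta_plus:
            return "decrease"
        if D >= theta_minus:
            decision = "neutral"
    return decision
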