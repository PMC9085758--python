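"""Compartmentalized pseudo-3D simulation space built from raster images.

The simulated system is a 2D slice of fixed height.  Each pixel of a
raster layout becomes one grid point of spacing ``ds``; contiguous areas of
equal color become regions, and boundaries between differently colored
areas become membrane faces which block diffusive flux (and can carry
surface concentrations).  Grid indices are 0-based (row, col) with pixel
(0, 0) at top-left.

Units: lengths in um, volumes in um^3 (interior volume per point is
ds^2 * height), areas in um^2 (face area is ds * ds: segment length times
the grid step, the pseudo-3D convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = ["Region", "SimulationSpace", "Membrane", "from_raster",
           "segment_area", "ConfigError", "GeometryError"]


class ConfigError(ValueError):
    pass


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Region:
    """A compartment class: topological descriptor plus diffusive restriction."""

    name: str
    restriction: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.restriction <= 1.0):
            raise ConfigError(
                f"region {self.name!r}: restriction must lie in [0, 1]")


# A face is identified by the ordered pair of adjacent grid points it
# separates: ((i, j), (i2, j2)) with (i2, j2) the right or down neighbor.
Face = tuple[tuple[int, int], tuple[int, int]]


def segment_area(length: float, ds: float) -> float:
    """Area of a membrane surface segment: segment length x grid spacing."""
    if length < 0:
        raise GeometryError("segment length must be non-negative")
    return length * ds


@dataclass
class Membrane:
    """Surface-like agent: a set of grid faces carrying one compartment.

    Concentrations are per-area (amount / um^2 expressed as uM * um, i.e.
    a molar surface density); each face owns one well of the compartment so
    localized processes (pits, fusion sites) interact with single faces.
    """

    name: str
    faces: list[Face]
    ds: float
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    # optional binding of pools to blocks of a live state vector, so that
    # membrane chemistry participates in the error-controlled integration
    _layout: object = None
    _get_y: object = None
    _prefix: str = ""

    def bind_state(self, layout, get_y, prefix: str) -> None:
        """Resolve concentrations from blocks '<prefix>.<entity>' of the
        state vector returned by get_y() instead of local arrays."""
        self._layout, self._get_y, self._prefix = layout, get_y, prefix

    def conc(self, entity: str) -> np.ndarray | None:
        """Per-face surface densities of an entity (live view or None)."""
        if self._layout is not None:
            name = f"{self._prefix}.{entity}"
            if name in self._layout:
                return self._layout.view(self._get_y(), name)
            return None
        return self.concentrations.get(entity)

    def ensure(self, entity: str) -> np.ndarray:
        arr = self.conc(entity)
        if arr is not None:
            return arr
        if self._layout is not None:
            raise KeyError(
                f"membrane {self.name}: entity {entity!r} has no state block")
        return self.concentrations.setdefault(
            entity, np.zeros(self.n_faces, dtype=float))

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def face_area(self) -> float:
        return segment_area(self.ds, self.ds)

    @property
    def total_area(self) -> float:
        return self.n_faces * self.face_area

    def set_uniform(self, entity: str, surface_density: float) -> None:
        if self._layout is not None:
            self.ensure(entity)[:] = surface_density
        else:
            self.concentrations[entity] = np.full(
                self.n_faces, surface_density, dtype=float)

    def total_amount(self, entity: str) -> float:
        """Total amount on the membrane in uM * um^3 units."""
        c = self.conc(entity)
        if c is None:
            return 0.0
        return float(np.sum(c) * self.face_area)

    def face_centers(self) -> np.ndarray:
        """Midpoint (x, y) of each face in physical coordinates."""
        out = np.empty((self.n_faces, 2))
        for k, ((i, j), (i2, j2)) in enumerate(self.faces):
            # center between the two grid point centers
            y = (i + i2) / 2.0 + 0.5
            x = (j + j2) / 2.0 + 0.5
            out[k] = (x * self.ds, y * self.ds)
        return out


class SimulationSpace:
    """Rectangular grid of spacing ds with regions, membranes, and fields.

    Fields (concentration arrays, shape (n_rows, n_cols), unit uM) live in
    ``fields``; diffusion is controlled by the per-point restriction array
    and the face-open masks ``open_h``/``open_v`` (False across membranes).
    """

    def __init__(self, region_ids: np.ndarray, regions: list[Region],
                 ds: float, height: float = 1.0):
        if ds <= 0:
            raise ConfigError("grid spacing ds must be positive")
        self.region_ids = np.asarray(region_ids, dtype=int)
        self.regions = regions
        self.ds = float(ds)
        self.height = float(height)
        self.n_rows, self.n_cols = self.region_ids.shape
        self.restriction = np.empty(self.region_ids.shape, dtype=float)
        for k, reg in enumerate(regions):
            self.restriction[self.region_ids == k] = reg.restriction
        # faces between horizontally / vertically adjacent points; True = open
        self.open_h = np.ones((self.n_rows, max(self.n_cols - 1, 0)), bool)
        self.open_v = np.ones((max(self.n_rows - 1, 0), self.n_cols), bool)
        self._close_region_boundaries()
        self.fields: dict[str, np.ndarray] = {}
        self.membranes: dict[str, Membrane] = {}

    # -- geometry ---------------------------------------------------------
    def _close_region_boundaries(self) -> None:
        ids = self.region_ids
        if self.n_cols > 1:
            self.open_h[:] = ids[:, :-1] == ids[:, 1:]
        if self.n_rows > 1:
            self.open_v[:] = ids[:-1, :] == ids[1:, :]

    def open_passage(self, face: Face) -> None:
        """Open a single face (a membrane gap / passage)."""
        (i, j), (i2, j2) = face
        if (i2, j2) == (i, j + 1):
            self.open_h[i, j] = True
        elif (i2, j2) == (i + 1, j):
            self.open_v[i, j] = True
        else:
            raise GeometryError(f"face {face} does not join adjacent points")

    def membrane_faces(self) -> list[Face]:
        """All closed faces (between differently colored regions)."""
        faces: list[Face] = []
        rr, cc = np.nonzero(~self.open_h)
        faces.extend((((int(i), int(j)), (int(i), int(j) + 1)))
                     for i, j in zip(rr, cc))
        rr, cc = np.nonzero(~self.open_v)
        faces.extend((((int(i), int(j)), (int(i) + 1, int(j))))
                     for i, j in zip(rr, cc))
        return faces

    def add_membrane(self, name: str, faces: list[Face] | None = None) -> Membrane:
        """Register a membrane agent on the given faces (default: all
        closed faces)."""
        if faces is None:
            faces = self.membrane_faces()
        for (i, j), (i2, j2) in faces:
            if abs(i - i2) + abs(j - j2) != 1:
                raise GeometryError(
                    f"membrane face (({i},{j}),({i2},{j2})) must join "
                    "neighboring grid points")
        m = Membrane(name, faces, self.ds)
        self.membranes[name] = m
        return m

    @property
    def point_volume(self) -> float:
        """Interior volume per grid point (um^3)."""
        return self.ds ** 2 * self.height

    @property
    def total_volume(self) -> float:
        return self.point_volume * self.n_rows * self.n_cols

    def region_mask(self, name: str) -> np.ndarray:
        for k, reg in enumerate(self.regions):
            if reg.name == name:
                return self.region_ids == k
        raise KeyError(name)

    # -- fields -----------------------------------------------------------
    def add_field(self, entity: str, value: float | np.ndarray = 0.0) -> np.ndarray:
        f = np.zeros((self.n_rows, self.n_cols), dtype=float)
        f += value
        self.fields[entity] = f
        return f

    def total_amount(self, entity: str) -> float:
        """Total interior amount (uM * um^3) of an entity field."""
        return float(np.sum(self.fields[entity]) * self.point_volume)

    # -- raster round trip ------------------------------------------------
    def to_raster(self, color_map: dict[str, tuple[int, int, int]]) -> Image.Image:
        rgb = np.zeros((self.n_rows, self.n_cols, 3), np.uint8)
        for k, reg in enumerate(self.regions):
            rgb[self.region_ids == k] = color_map[reg.name]
        return Image.fromarray(rgb, "RGB")

    def to_table(self):
        """Compartment map as a DataFrame (i, j, descriptor, r)."""
        import pandas as pd
        ii, jj = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols),
                             indexing="ij")
        return pd.DataFrame({
            "i": ii.ravel(), "j": jj.ravel(),
            "descriptor": [self.regions[k].name
                           for k in self.region_ids.ravel()],
            "r": self.restriction.ravel(),
        })


def from_raster(image, ds: float,
                color_map: dict[tuple[int, int, int], Region],
                height: float = 1.0) -> SimulationSpace:
    """Build a SimulationSpace from a raster image.

    Each pixel becomes one grid point; every pixel color must appear in
    ``color_map`` (RGB tuple -> Region).  Boundaries between differently
    colored areas become closed membrane faces.
    """
    import os
    if isinstance(image, (str, bytes, os.PathLike)) or hasattr(image, "read"):
        image = Image.open(image)
    rgb = np.asarray(image.convert("RGB"))
    n_rows, n_cols = rgb.shape[:2]

    regions = list(color_map.values())
    ids = np.full((n_rows, n_cols), -1, dtype=int)
    for k, (color, _) in enumerate(color_map.items()):
        mask = np.all(rgb == np.asarray(color, np.uint8), axis=-1)
        ids[mask] = k
    if np.any(ids < 0):
        bad = np.argwhere(ids < 0)
        offenders = ", ".join(
            f"({i},{j})={tuple(int(v) for v in rgb[i, j])}"
            for i, j in bad[:5])
        raise ConfigError(
            f"{len(bad)} pixel(s) with unmapped colors; first: {offenders}")
    return SimulationSpace(ids, regions, ds, height)
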