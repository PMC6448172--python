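"""3D regions of interest reconstructed from stacked planar contours.

Organs delineated on axial slices are represented as stacks of closed 2D
polygons.  A 3D model is obtained by extruding each contour over a z-slab,
with three configurable choices that treatment planning systems differ on:

* **contour interpolation** — insert a shape-based midway contour between
  every pair of consecutive delineated contours.  The midway contour is the
  zero level set (marching squares) of the average of the two signed
  Euclidean distance fields, sampled on a common grid;
* **outer slab mode** — ``full`` extends the top and bottom contour by half
  the slice thickness beyond their planes, ``partial`` cuts the organ off at
  the outermost contour planes;
* **intersection policy** — a point inside an organ that is subtracted from
  a host organ (e.g. urethra from prostate) is not counted as part of the
  host.

Polygon predicates, areas and distances are delegated to shapely; marching
squares to scikit-image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage import measure

__all__ = [
    "Contour",
    "StructureSet",
    "RoiSettings",
    "Slab",
    "SlabModel",
    "RoiModel",
    "GridFrame",
    "GeometryError",
    "DegenerateRoiWarning",
    "signed_distance_field",
    "interpolate_midway",
    "build_slab_model",
    "build_roi_model",
    "point_in_roi",
    "roi_volume",
    "bounding_box",
]

CM3_PER_MM3 = 1e-3


class GeometryError(ValueError):
    """Degenerate or inconsistent contour geometry."""


class DegenerateRoiWarning(UserWarning):
    """ROI reconstruction produced a zero-volume model."""


def _shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class Contour:
    """A closed planar polygon at one slice height (mm, implicitly closed)."""

    z_mm: float
    vertices: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("contour needs >= 3 (x, y) vertices")
        # drop an explicitly repeated closing vertex
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if _shoelace_area(v) < 0:  # normalize to counter-clockwise
            v = v[::-1]
        if abs(_shoelace_area(v)) <= 0:
            raise GeometryError("contour has zero area")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise GeometryError(f"contour at z={self.z_mm} is not a simple polygon")
        return poly

    @property
    def area_mm2(self) -> float:
        return _shoelace_area(self.vertices)


@dataclass
class StructureSet:
    """Named organs as z-sorted contour stacks sharing one slice thickness."""

    rois: dict[str, list[Contour]]
    slice_thickness_mm: float = 3.3

    def __post_init__(self) -> None:
        for name, contours in self.rois.items():
            zs = [c.z_mm for c in contours]
            if sorted(zs) != zs:
                self.rois[name] = sorted(contours, key=lambda c: c.z_mm)
            zs = [c.z_mm for c in self.rois[name]]
            if len(set(zs)) != len(zs):
                raise GeometryError(f"ROI {name!r} has more than one contour on a slice")

    def organ_names(self) -> list[str]:
        return list(self.rois)


@dataclass(frozen=True)
class RoiSettings:
    """The computation-setting tuple under study.

    ``intersection_policy`` maps a host organ to the organs subtracted from
    it, e.g. ``{"prostate": ("urethra",), "bladder": ("urethra",)}``; an
    empty mapping means every intersection is counted in both organs.
    """

    interpolate: bool = True
    outer_slab: str = "partial"  # "full" | "partial"
    intersection_policy: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    grid_spacing_mm: float = 0.82

    def __post_init__(self) -> None:
        if self.outer_slab not in ("full", "partial"):
            raise ValueError("outer_slab must be 'full' or 'partial'")
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid_spacing_mm must be positive")
        object.__setattr__(
            self,
            "intersection_policy",
            {h: tuple(subs) for h, subs in dict(self.intersection_policy).items()},
        )

    def subtracted_from(self, organ: str) -> tuple[str, ...]:
        return self.intersection_policy.get(organ, ())


@dataclass(frozen=True)
class GridFrame:
    """A common 2D sampling grid: origin, spacing and node counts."""

    x0: float
    y0: float
    spacing: float
    nx: int
    ny: int

    @classmethod
    def covering(cls, contours: Iterable[Contour], spacing: float, margin_cells: int = 2) -> "GridFrame":
        vs = np.vstack([c.vertices for c in contours])
        lo = vs.min(axis=0) - margin_cells * spacing
        hi = vs.max(axis=0) + margin_cells * spacing
        nx = int(np.ceil((hi[0] - lo[0]) / spacing)) + 1
        ny = int(np.ceil((hi[1] - lo[1]) / spacing)) + 1
        return cls(float(lo[0]), float(lo[1]), float(spacing), nx, ny)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + self.spacing * np.arange(self.nx)
        ys = self.y0 + self.spacing * np.arange(self.ny)
        return np.meshgrid(xs, ys)  # shapes (ny, nx)


def signed_distance_field(contour: Contour, frame: GridFrame) -> np.ndarray:
    """Signed in-plane Euclidean distance to the contour on a grid.

    Positive inside the polygon, negative outside, zero on the boundary;
    array shape (ny, nx) with rows along y.
    """
    poly = contour.polygon
    xx, yy = frame.mesh()
    pts = shapely.points(xx.ravel(), yy.ravel())
    dist = shapely.distance(pts, poly.exterior).reshape(xx.shape)
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    return np.where(inside, dist, -dist)


def interpolate_midway(c1: Contour, c2: Contour, spacing: float = 0.82) -> Contour | None:
    """Shape-based midway contour between two consecutive slice contours.

    Averages the two signed distance fields on a shared grid and extracts
    the zero level set with marching squares (linear edge interpolation,
    saddle cells resolved by the cell-corner average).  Returns the
    largest-area closed component, or None when the averaged field has no
    zero crossing (vanishing mid-slab).
    """
    frame = GridFrame.covering([c1, c2], spacing)
    avg = 0.5 * (signed_distance_field(c1, frame) + signed_distance_field(c2, frame))
    if avg.max() <= 0:
        return None
    paths = measure.find_contours(avg, 0.0)
    z_mid = 0.5 * (c1.z_mm + c2.z_mm)
    best, best_area = None, 0.0
    for path in paths:
        if len(path) < 4 or not np.allclose(path[0], path[-1]):
            continue  # open path touching the frame edge; margin makes this rare
        verts = np.column_stack(
            [frame.x0 + path[:, 1] * frame.spacing, frame.y0 + path[:, 0] * frame.spacing]
        )
        area = abs(_shoelace_area(verts[:-1]))
        if area > best_area:
            best, best_area = verts[:-1], area
    if best is None:
        return None
    return Contour(z_mid, best)


@dataclass(frozen=True)
class Slab:
    """One contour extruded over a half-open z-interval [z_low, z_high)."""

    contour: Contour | None  # None encodes a vanished (zero-area) mid-slab
    z_low: float
    z_high: float

    @property
    def thickness_mm(self) -> float:
        return self.z_high - self.z_low

    @property
    def area_mm2(self) -> float:
        return self.contour.area_mm2 if self.contour is not None else 0.0


@dataclass
class SlabModel:
    """Stack of contour-extruded slabs tiling the ROI's z-extent."""

    slabs: list[Slab]

    def __post_init__(self) -> None:
        self._z_low = np.array([s.z_low for s in self.slabs])
        self._z_high = np.array([s.z_high for s in self.slabs])
        self._polygons = []
        for s in self.slabs:
            if s.contour is None:
                self._polygons.append(None)
            else:
                poly = s.contour.polygon
                shapely.prepare(poly)
                self._polygons.append(poly)

    def slab_index(self, z_mm: np.ndarray) -> np.ndarray:
        """Index of the slab containing each z, or -1 outside the stack."""
        z = np.asarray(z_mm, dtype=float)
        idx = np.searchsorted(self._z_low, z, side="right") - 1
        idx = np.where((idx >= 0) & (z < self._z_high[np.clip(idx, 0, None)]), idx, -1)
        return idx

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Vectorized membership; boundary points count as members."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = np.zeros(pts.shape[0], dtype=bool)
        idx = self.slab_index(pts[:, 2])
        for i in np.unique(idx):
            if i < 0 or self._polygons[i] is None:
                continue
            sel = idx == i
            out[sel] = shapely.intersects_xy(self._polygons[i], pts[sel, 0], pts[sel, 1])
        return out

    def volume_cm3(self) -> float:
        return sum(s.area_mm2 * s.thickness_mm for s in self.slabs) * CM3_PER_MM3

    def z_extent(self) -> tuple[float, float]:
        if not self.slabs:
            return (0.0, 0.0)
        return float(self._z_low[0]), float(self._z_high[-1])


def build_slab_model(
    contours: Sequence[Contour],
    settings: RoiSettings,
    slice_thickness_mm: float,
) -> SlabModel:
    """Extrude a contour stack into slabs under the given settings.

    With interpolation on, a midway contour is inserted between every pair of
    consecutive delineated contours; every contour then fills the half-open
    interval reaching to the midpoints towards its neighbours.  The outermost
    contour extends half the slice thickness beyond its plane in ``full``
    mode and stops at its plane in ``partial`` mode.
    """
    if not contours:
        raise GeometryError("need at least one contour")
    stack: list[Contour | None] = sorted(contours, key=lambda c: c.z_mm)
    zs = [c.z_mm for c in stack]
    if settings.interpolate and len(stack) >= 2:
        merged: list[tuple[float, Contour | None]] = []
        for a, b in zip(stack[:-1], stack[1:]):
            merged.append((a.z_mm, a))
            mid = interpolate_midway(a, b, settings.grid_spacing_mm)
            merged.append((0.5 * (a.z_mm + b.z_mm), mid))
        merged.append((stack[-1].z_mm, stack[-1]))
        zs = [z for z, _ in merged]
        stack = [c for _, c in merged]

    half_outer = slice_thickness_mm / 2.0 if settings.outer_slab == "full" else 0.0
    zs_arr = np.asarray(zs)
    lowers = np.empty(len(zs))
    uppers = np.empty(len(zs))
    lowers[0] = zs_arr[0] - half_outer
    uppers[-1] = zs_arr[-1] + half_outer
    mids = 0.5 * (zs_arr[:-1] + zs_arr[1:])
    lowers[1:] = mids
    uppers[:-1] = mids

    slabs = [Slab(c, lo, hi) for c, lo, hi in zip(stack, lowers, uppers)]
    model = SlabModel(slabs)
    if model.volume_cm3() == 0:
        warnings.warn(
            "slab model has zero volume (single contour with partial outer slabs?)",
            DegenerateRoiWarning,
            stacklevel=2,
        )
    return model


@dataclass
class RoiModel:
    """A host organ's slab model plus the models of organs subtracted from it."""

    organ: str
    slab_model: SlabModel
    subtracted: dict[str, SlabModel]
    settings: RoiSettings

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        member = self.slab_model.contains(pts)
        for sub in self.subtracted.values():
            if member.any():
                member &= ~sub.contains(pts)
        return member

    def volume_cm3(self) -> float:
        return roi_volume(self)

    def bounding_box(self) -> np.ndarray:
        return bounding_box(self.slab_model)


def build_roi_model(structure_set: StructureSet, organ: str, settings: RoiSettings) -> RoiModel:
    """Build an organ's slab model and those of its subtracted organs.

    The subtracted organs' models are built with the same interpolation and
    outer-slab settings as the host's.
    """
    if organ not in structure_set.rois:
        raise KeyError(f"organ {organ!r} not in structure set")
    for sub in settings.subtracted_from(organ):
        if sub not in structure_set.rois:
            raise GeometryError(f"intersection policy names unknown organ {sub!r}")
    host = build_slab_model(structure_set.rois[organ], settings, structure_set.slice_thickness_mm)
    subtracted = {
        sub: build_slab_model(structure_set.rois[sub], settings, structure_set.slice_thickness_mm)
        for sub in settings.subtracted_from(organ)
    }
    return RoiModel(organ, host, subtracted, settings)


def point_in_roi(point_mm: Sequence[float], roi: RoiModel) -> bool:
    """Membership of a single point under the ROI's settings.

    Points on the polygon boundary or exactly on a slab's lower plane count
    as members; points inside a subtracted organ's own slab model do not.
    """
    return bool(roi.contains(np.asarray(point_mm, dtype=float)[None, :])[0])


def _overlap_volume_cm3(host: SlabModel, sub: SlabModel) -> float:
    """Exact slab-wise intersection volume of two slab models."""
    total = 0.0
    for hs, hp in zip(host.slabs, host._polygons):
        if hp is None:
            continue
        for ss, sp in zip(sub.slabs, sub._polygons):
            if sp is None:
                continue
            dz = min(hs.z_high, ss.z_high) - max(hs.z_low, ss.z_low)
            if dz <= 0:
                continue
            inter = hp.intersection(sp)
            if not inter.is_empty:
                total += inter.area * dz
    return total * CM3_PER_MM3


def roi_volume(roi: RoiModel) -> float:
    """ROI volume in cm³: slab prism volumes minus subtracted overlaps."""
    vol = roi.slab_model.volume_cm3()
    for sub in roi.subtracted.values():
        vol -= _overlap_volume_cm3(roi.slab_model, sub)
    return vol


def bounding_box(model: SlabModel) -> np.ndarray:
    """Minimal axis-aligned box [[xmin,ymin,zmin],[xmax,ymax,zmax]] (mm)."""
    los, his = [], []
    for s in model.slabs:
        if s.contour is None:
            continue
        v = s.contour.vertices
        los.append([v[:, 0].min(), v[:, 1].min(), s.z_low])
        his.append([v[:, 0].max(), v[:, 1].max(), s.z_high])
    if not los:
        raise GeometryError("bounding box of a degenerate model")
    return np.array([np.min(los, axis=0), np.max(his, axis=0)])
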