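"""Rigid transforms, biplanar projection geometry and silhouette extraction.

Conventions
-----------
* World frame: millimetres, z is the vertical axis, the imaging isocenter is
  the origin.
* Rigid pose: intrinsic Euler Z-Y-X rotation (degrees) about the mesh
  centroid, applied before the translation (mm). Rotating about the centroid
  keeps rotational and translational pose errors decoupled.
* Pixel coordinates: 0-based, x = column, y = row, pixel centers at integer
  coordinates. The world origin projects to the image center
  ((rows-1)/2, (cols-1)/2) in every view of a rig built here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import trimesh
import yaml
from scipy.spatial.transform import Rotation

from . import _raster
from .errors import (
    DegenerateRigError,
    InvalidTransformError,
    ParameterError,
    ProjectionOutOfBoundsError,
)

__all__ = [
    "Mesh",
    "RigidTransform",
    "ProjectionView",
    "SilhouetteProjection",
    "apply_transform",
    "make_biplanar_rig",
    "project_points",
    "project_silhouette",
    "load_mesh",
    "save_mesh",
    "save_pose",
    "load_pose",
    "save_rig",
    "load_rig",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mesh:
    """Triangulated surface in millimetres."""

    vertices: np.ndarray  # (N, 3) float64
    faces: np.ndarray  # (F, 3) int64
    watertight: bool = False

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 4:
            raise ParameterError("mesh needs >= 4 vertices of dimension 3")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ParameterError("faces must be (F, 3) vertex-index triplets")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            raise ParameterError("face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid pose: Euler Z-Y-X degrees, translation mm."""

    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.as_array())):
            raise InvalidTransformError("transform parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rx, self.ry, self.rz, self.tx, self.ty, self.tz], dtype=float
        )

    @classmethod
    def from_array(cls, a) -> "RigidTransform":
        a = np.asarray(a, dtype=float)
        return cls(*a.tolist())

    def rotation(self) -> Rotation:
        """Intrinsic Z-Y-X rotation: R = Rz(rz) @ Ry(ry) @ Rx(rx)."""
        return Rotation.from_euler("ZYX", [self.rz, self.ry, self.rx], degrees=True)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    def inverse(self) -> "RigidTransform":
        """Inverse pose under centroid-pivot application semantics.

        If ``m2 = apply_transform(m, t)`` then
        ``apply_transform(m2, t.inverse())`` recovers ``m`` exactly, because
        the centroid of ``m2`` is the centroid of ``m`` shifted by the
        translation.
        """
        rz, ry, rx = self.rotation().inv().as_euler("ZYX", degrees=True)
        return RigidTransform(rx, ry, rz, -self.tx, -self.ty, -self.tz)


@dataclass(frozen=True)
class ProjectionView:
    """One calibrated X-ray camera: point source plus flat detector."""

    view_angle: float  # degrees about the vertical (z) world axis
    source: np.ndarray  # (3,) mm
    detector_origin: np.ndarray  # (3,) mm, center of pixel (row 0, col 0)
    detector_axes: np.ndarray  # (2, 3): row 0 = column direction, row 1 = row direction
    pixel_spacing: float  # mm / pixel
    image_size: tuple[int, int]  # (rows, cols)

    def __post_init__(self):
        axes = np.asarray(self.detector_axes, dtype=float)
        if axes.shape != (2, 3):
            raise ParameterError("detector_axes must be (2, 3)")
        g = axes @ axes.T
        if not np.allclose(g, np.eye(2), atol=1e-9):
            raise ParameterError("detector axes must be orthonormal")
        if self.pixel_spacing <= 0:
            raise ParameterError("pixel_spacing must be positive")
        n = np.cross(axes[0], axes[1])
        src = np.asarray(self.source, dtype=float)
        det = np.asarray(self.detector_origin, dtype=float)
        if abs(np.dot(src - det, n)) < 1e-9:
            raise ParameterError("source lies on the detector plane")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "detector_origin", det)
        object.__setattr__(self, "detector_axes", axes)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.detector_axes[0], self.detector_axes[1])

    @property
    def principal_point(self) -> tuple[float, float]:
        """(row, col) where the world origin projects."""
        rc = project_points(np.zeros((1, 3)), self)[0]
        return (float(rc[1]), float(rc[0]))


@dataclass
class SilhouetteProjection:
    """Projected silhouette of a mesh in one view.

    ``contour`` is the ordered, closed chain of outer-boundary pixels in
    global image coordinates (x = col, y = row); pixels may lie outside the
    image when the projection overhangs the detector. ``interior_mask`` is
    materialized lazily at full image size; the raster actually produced by
    projection is the local window ``mask_window`` anchored at
    ``window_origin`` (row, col), which is what the cost terms consume.
    """

    contour: np.ndarray  # (n, 2) float64 (x, y)
    tangents: np.ndarray  # (n, 2) unit vectors
    mask_window: np.ndarray  # (h, w) bool, local silhouette raster
    window_origin: tuple[int, int]  # (row, col) of window pixel (0, 0)
    image_size: tuple[int, int]
    n_contour: int = field(init=False)
    n_interior: int = field(init=False)

    def __post_init__(self):
        self.n_contour = int(self.contour.shape[0])
        self.n_interior = int(self._in_image_count())

    def _in_image_count(self) -> int:
        r0, c0 = self.window_origin
        rows, cols = self.image_size
        h, w = self.mask_window.shape
        ra, rb = max(0, -r0), min(h, rows - r0)
        ca, cb = max(0, -c0), min(w, cols - c0)
        if ra >= rb or ca >= cb:
            return 0
        return int(self.mask_window[ra:rb, ca:cb].sum())

    @cached_property
    def interior_mask(self) -> np.ndarray:
        full = np.zeros(self.image_size, dtype=bool)
        r0, c0 = self.window_origin
        rows, cols = self.image_size
        h, w = self.mask_window.shape
        ra, rb = max(0, -r0), min(h, rows - r0)
        ca, cb = max(0, -c0), min(w, cols - c0)
        if ra < rb and ca < cb:
            full[r0 + ra : r0 + rb, c0 + ca : c0 + cb] = self.mask_window[
                ra:rb, ca:cb
            ]
        return full


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def transform_vertices(
    vertices: np.ndarray, centroid: np.ndarray, t: RigidTransform
) -> np.ndarray:
    """Fast path: v' = R (v - c) + c + translation."""
    R = t.rotation().as_matrix()
    return (vertices - centroid) @ R.T + centroid + t.translation


def apply_transform(mesh: Mesh, t: RigidTransform) -> Mesh:
    """Rigidly move a mesh: rotate about its centroid, then translate."""
    if not isinstance(t, RigidTransform):
        t = RigidTransform(*t)
    v = transform_vertices(mesh.vertices, mesh.centroid, t)
    return Mesh(vertices=v, faces=mesh.faces.copy(), watertight=mesh.watertight)


def make_biplanar_rig(
    angle_a: float = 45.0,
    angle_b: float = 135.0,
    source_distance: float = 1000.0,
    pixel_spacing: float = 0.2,
    image_size: tuple[int, int] = (512, 512),
    detector_offset: float = 200.0,
) -> tuple[ProjectionView, ProjectionView]:
    """Build two calibrated views whose principal rays meet at the origin.

    ``angle_a``/``angle_b`` place each source in the horizontal plane at the
    given azimuth; the detector sits ``detector_offset`` mm behind the
    isocenter, perpendicular to the principal ray.
    """
    if source_distance <= 0:
        raise ParameterError("source_distance must be positive")
    if abs((angle_a - angle_b) % 180.0) < 1e-9:
        raise DegenerateRigError(
            f"view angles {angle_a} and {angle_b} coincide modulo 180 degrees"
        )
    views = []
    for ang in (angle_a, angle_b):
        th = np.deg2rad(ang)
        u = np.array([np.cos(th), np.sin(th), 0.0])
        source = source_distance * u
        det_center = -detector_offset * u
        ax_col = np.array([-np.sin(th), np.cos(th), 0.0])
        ax_row = np.array([0.0, 0.0, -1.0])  # rows increase downward
        rows, cols = image_size
        origin = (
            det_center
            - ax_col * pixel_spacing * (cols - 1) / 2.0
            - ax_row * pixel_spacing * (rows - 1) / 2.0
        )
        views.append(
            ProjectionView(
                view_angle=float(ang),
                source=source,
                detector_origin=origin,
                detector_axes=np.vstack([ax_col, ax_row]),
                pixel_spacing=float(pixel_spacing),
                image_size=(int(rows), int(cols)),
            )
        )
    return views[0], views[1]


def project_points(points: np.ndarray, view: ProjectionView) -> np.ndarray:
    """Perspective-project world points to (x=col, y=row) pixel coordinates."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    n = view.normal
    src = view.source
    o = view.detector_origin
    denom = (p - src) @ n
    num = np.dot(o - src, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    q = src + t[:, None] * (p - src)
    d = q - o
    x = (d @ view.detector_axes[0]) / view.pixel_spacing
    y = (d @ view.detector_axes[1]) / view.pixel_spacing
    return np.column_stack([x, y])


def _contour_tangents(pts: np.ndarray) -> np.ndarray:
    """Unit tangents along a closed polyline via central differences."""
    n = pts.shape[0]
    if n == 1:
        return np.array([[1.0, 0.0]])
    w = 2 if n >= 5 else 1
    d = np.roll(pts, -w, axis=0) - np.roll(pts, w, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    norm[norm == 0] = 1.0
    return d / norm[:, None]


def project_silhouette(
    mesh: Mesh, t: RigidTransform, view: ProjectionView
) -> SilhouetteProjection:
    """Project a posed mesh into a view and extract its outer silhouette.

    All projected triangles are rasterized into a binary raster, the largest
    connected component is kept, holes are filled, and the outer boundary is
    traced into an ordered, counter-clockwise pixel chain with unit tangents
    from central differences.
    """
    tris, xmn, xmx, ymn, ymx, ok = _raster.project_mesh_tris(
        mesh.vertices,
        mesh.faces,
        t.rotation().as_matrix(),
        mesh.centroid,
        t.translation,
        view.source,
        view.detector_origin,
        view.detector_axes[0],
        view.detector_axes[1],
        view.normal,
        view.pixel_spacing,
    )
    if not ok:
        raise ProjectionOutOfBoundsError(
            "mesh is not strictly between the source and the detector plane"
        )
    rows, cols = view.image_size
    if xmx < 0 or ymx < 0 or xmn > cols - 1 or ymn > rows - 1:
        raise ProjectionOutOfBoundsError("projection falls entirely off the detector")
    c0 = int(np.floor(xmn)) - 2
    r0 = int(np.floor(ymn)) - 2
    w = int(np.ceil(xmx)) - c0 + 3
    h = int(np.ceil(ymx)) - r0 + 3
    tris[:, :, 0] -= c0
    tris[:, :, 1] -= r0

    mask = np.zeros((h, w), dtype=bool)
    # watertight oriented surfaces need only their front-facing triangles,
    # and their union is hole-free by construction
    cull = 1 if mesh.watertight else 0
    _raster.fill_triangles(mask, tris, cull)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ProjectionOutOfBoundsError("empty silhouette raster")
    if cull == 0:
        mask, n_mask = _raster.clean_mask(mask)

    byx = _raster.trace_outer_boundary(mask)
    contour = np.column_stack([byx[:, 1] + c0, byx[:, 0] + r0]).astype(float)
    x, y = contour[:, 0], contour[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    # a traced outer boundary must account for (almost) all mask pixels;
    # if not, the silhouette has several blobs or holes -> full cleanup
    if cull == 1 and n_mask > abs(area2) / 2 + 2 * len(contour) + 16:
        mask, n_mask = _raster.clean_mask(mask)
        byx = _raster.trace_outer_boundary(mask)
        contour = np.column_stack([byx[:, 1] + c0, byx[:, 0] + r0]).astype(float)
        x, y = contour[:, 0], contour[:, 1]
        area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    # enforce counter-clockwise orientation (positive shoelace area in (x, y))
    if area2 < 0:
        contour = contour[::-1].copy()
    tangents = _contour_tangents(contour)
    return SilhouetteProjection(
        contour=contour,
        tangents=tangents,
        mask_window=mask,
        window_origin=(r0, c0),
        image_size=(rows, cols),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_mesh(path) -> Mesh:
    """Read an STL/PLY/OBJ surface (millimetre units assumed)."""
    tm = trimesh.load_mesh(str(path), process=False)
    if isinstance(tm, trimesh.Scene):
        tm = trimesh.util.concatenate(list(tm.geometry.values()))
    # formats like STL store unmerged per-face vertices
    tm.merge_vertices()
    return Mesh(
        vertices=np.asarray(tm.vertices, dtype=np.float64),
        faces=np.asarray(tm.faces, dtype=np.int64),
        watertight=bool(tm.is_watertight and tm.is_winding_consistent),
    )


def save_mesh(mesh: Mesh, path) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def save_pose(t: RigidTransform, path) -> None:
    doc = {k: float(getattr(t, k)) for k in ("rx", "ry", "rz", "tx", "ty", "tz")}
    Path(path).write_text(yaml.safe_dump(doc))


def load_pose(path) -> RigidTransform:
    doc = yaml.safe_load(Path(path).read_text())
    return RigidTransform(**{k: float(doc[k]) for k in ("rx", "ry", "rz", "tx", "ty", "tz")})


def save_rig(rig: tuple[ProjectionView, ProjectionView], path, **extra) -> None:
    a, b = rig
    doc = {
        "angle_a": a.view_angle,
        "angle_b": b.view_angle,
        "source_distance": float(np.linalg.norm(a.source)),
        "pixel_spacing": a.pixel_spacing,
        "image_size": list(a.image_size),
        "detector_offset": float(
            np.linalg.norm(
                a.detector_origin
                + a.detector_axes[0] * a.pixel_spacing * (a.image_size[1] - 1) / 2
                + a.detector_axes[1] * a.pixel_spacing * (a.image_size[0] - 1) / 2
            )
        ),
    }
    doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc))


def load_rig(path) -> tuple[ProjectionView, ProjectionView]:
    doc = yaml.safe_load(Path(path).read_text())
    return make_biplanar_rig(
        angle_a=doc["angle_a"],
        angle_b=doc["angle_b"],
        source_distance=doc["source_distance"],
        pixel_spacing=doc["pixel_spacing"],
        image_size=tuple(doc["image_size"]),
        detector_offset=doc.get("detector_offset", 200.0),
    )
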