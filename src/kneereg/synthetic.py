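"""Ground-truth phantom scenes and registration-error metrics.

Real implant CAD surfaces and radiographs are proprietary, so accuracy is
measured on synthetic analogues that reproduce the hazards the method must
survive:

* a *femoral-like* phantom: an asymmetric bi-condylar shape (two unequal
  condyle spheres bridged by a block) whose silhouette has no mirror
  symmetry;
* a *tibial-like* phantom: a near-symmetric tray plus stem, reproducing the
  mirrored-pose ambiguity that makes single-view registration of tibial
  trays unreliable;
* rendered biplanar images in which the metallic component is near-saturated
  (much brighter than everything else), elongated bone-like clutter ridges
  of intermediate intensity cross the field (some overlapping the
  component), and additive Gaussian noise models the imaging chain.

Scenes regenerate bit-identically from their parameters and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .errors import ParameterError
from .geometry import (
    Mesh,
    ProjectionView,
    RigidTransform,
    load_mesh,
    load_rig,
    make_biplanar_rig,
    project_silhouette,
    save_mesh,
    save_rig,
    transform_vertices,
)
from .preprocess import load_image, save_image

__all__ = [
    "GroundTruthScene",
    "TrialResult",
    "make_phantom_mesh",
    "render_ground_truth",
    "make_scene",
    "sample_random_transform",
    "pose_rmse",
    "per_dof_errors",
]


@dataclass
class GroundTruthScene:
    """A phantom mesh, its true pose, the rig, and the rendered image pair."""

    mesh: Mesh
    true_pose: RigidTransform
    rig: tuple[ProjectionView, ProjectionView]
    images: tuple[np.ndarray, np.ndarray]
    kind: str
    clutter_seed: int
    noise_sigma: float
    n_clutter: int

    def save(self, directory) -> None:
        """Write the scene bundle: STL mesh, two PNGs, scene.yaml."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_mesh(self.mesh, d / "mesh.stl")
        save_image(self.images[0], d / "view_a.png")
        save_image(self.images[1], d / "view_b.png")
        pose = {k: float(getattr(self.true_pose, k))
                for k in ("rx", "ry", "rz", "tx", "ty", "tz")}
        save_rig(
            self.rig,
            d / "scene.yaml",
            true_pose=pose,
            kind=self.kind,
            clutter_seed=int(self.clutter_seed),
            noise_sigma=float(self.noise_sigma),
            n_clutter=int(self.n_clutter),
        )

    @classmethod
    def load(cls, directory) -> "GroundTruthScene":
        d = Path(directory)
        doc = yaml.safe_load((d / "scene.yaml").read_text())
        return cls(
            mesh=load_mesh(d / "mesh.stl"),
            true_pose=RigidTransform(**doc["true_pose"]),
            rig=load_rig(d / "scene.yaml"),
            images=(load_image(d / "view_a.png"), load_image(d / "view_b.png")),
            kind=doc.get("kind", "unknown"),
            clutter_seed=doc.get("clutter_seed", 0),
            noise_sigma=doc.get("noise_sigma", 0.0),
            n_clutter=doc.get("n_clutter", 0),
        )


@dataclass
class TrialResult:
    """One registration trial scored against the known true pose."""

    component_kind: str
    similarity_mode: str
    theta_true: RigidTransform
    theta_init: RigidTransform
    theta_est: RigidTransform
    rmse_initial: float
    rmse_final: float
    dof_errors: np.ndarray  # |drx|,|dry|,|drz| deg, |dtx|,|dty|,|dtz| mm
    final_E: float = np.nan
    final_V: float = np.nan
    final_C: float = np.nan
    seed: int = 0
    failed: bool = False


# ---------------------------------------------------------------------------
# phantom meshes
# ---------------------------------------------------------------------------

def _mesh_from_trimesh(tm: trimesh.Trimesh) -> Mesh:
    return Mesh(
        vertices=np.asarray(tm.vertices, dtype=np.float64),
        faces=np.asarray(tm.faces, dtype=np.int64),
        watertight=bool(tm.is_watertight and tm.is_winding_consistent),
    )


def make_phantom_mesh(kind: str, size_mm: float = 50.0, seed: int = 0) -> Mesh:
    """Deterministic watertight phantom of a knee-implant component.

    ``femoral_like`` builds two unequal condyle spheres bridged by a block:
    the unequal radii remove any silhouette mirror symmetry. ``tibial_like``
    builds a flat tray with a central stem, which is nearly mirror-symmetric
    and therefore carries the symmetrical-pose hazard. The seed applies a
    small (+/-3%) global scale jitter and, for the femoral phantom, jitters
    the condyle radius ratio, so repeated components differ slightly.
    """
    if size_mm <= 0:
        raise ParameterError("size_mm must be positive")
    rng = np.random.default_rng(seed)
    scale = 1.0 + 0.03 * (2.0 * rng.random() - 1.0)
    s = size_mm * scale
    if kind == "femoral_like":
        # two unequal condyle rolls (capped cylinders, axes along y) plus a
        # bridging block; unequal radii and offset axes leave no rotation
        # axis that keeps the silhouette invariant
        ratio = 0.72 + 0.06 * (2.0 * rng.random() - 1.0)
        r_big = 0.20 * s
        r_small = ratio * r_big
        rot_y = trimesh.transformations.rotation_matrix(np.pi / 2, [1, 0, 0])
        big = trimesh.creation.cylinder(radius=r_big, height=0.30 * s,
                                        sections=24, transform=rot_y)
        big.apply_translation([-0.25 * s, 0.0, 0.0])
        small = trimesh.creation.cylinder(radius=r_small, height=0.28 * s,
                                          sections=24, transform=rot_y)
        small.apply_translation([0.27 * s, 0.02 * s, 0.05 * s])
        bridge = trimesh.creation.box(extents=[0.62 * s, 0.26 * s, 0.18 * s])
        bridge.apply_translation([0.0, 0.0, 0.10 * s])
        tm = trimesh.util.concatenate([big, small, bridge])
        tm = trimesh.Trimesh(
            *trimesh.remesh.subdivide(tm.vertices, tm.faces), process=False
        )
    elif kind == "tibial_like":
        tray = trimesh.creation.box(extents=[1.0 * s, 0.65 * s, 0.14 * s])
        stem = trimesh.creation.cylinder(radius=0.10 * s, height=0.55 * s,
                                         sections=24)
        stem.apply_translation([0.0, 0.0, -0.30 * s])
        tm = trimesh.util.concatenate([tray, stem])
        tm = trimesh.Trimesh(
            *trimesh.remesh.subdivide(tm.vertices, tm.faces), process=False
        )
    else:
        raise ParameterError(f"unknown phantom kind: {kind!r}")
    tm.merge_vertices()
    tm.apply_translation(-tm.vertices.mean(axis=0))
    return _mesh_from_trimesh(tm)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _soft_tissue_field(shape, rng) -> np.ndarray:
    """Smooth low-frequency intensity variation (soft-tissue thickness)."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    out = np.zeros(shape, dtype=np.float64)
    for _ in range(3):
        cy = rng.uniform(0, rows)
        cx = rng.uniform(0, cols)
        sy = rng.uniform(120.0, 250.0)
        sx = rng.uniform(120.0, 250.0)
        amp = rng.uniform(0.05, 0.18)
        out += amp * np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    return out


def _clutter_field(shape, bbox, n_clutter, rng) -> np.ndarray:
    """Bone-like clutter: near-vertical cortical shafts crossing the field.

    In a knee radiograph the femoral shaft enters from above and the tibia
    and fibula leave below, roughly parallel to the vertical axis; their
    cortical margins are long, crisp edges that compete with the implant
    contour. Each shaft is an elongated super-Gaussian ridge (flat core,
    steep flanks) with a mildly random tilt; half are biased to pass
    through the component so bone and implant silhouettes overlap.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    out = np.zeros(shape, dtype=np.float64)
    r0, r1, c0, c1 = bbox
    for i in range(n_clutter):
        if rng.random() < 0.5 and r1 > r0 and c1 > c0:
            # bias toward the component so clutter overlaps the silhouette
            cy = rng.uniform(r0 - 30, r1 + 30)
            cx = rng.uniform(c0 - 30, c1 + 30)
        else:
            cy = rng.uniform(0, rows)
            cx = rng.uniform(0, cols)
        # shaft direction: vertical +/- 25 degrees
        phi = np.pi / 2 + np.deg2rad(rng.uniform(-25.0, 25.0))
        sl = rng.uniform(200.0, 400.0)  # shaft half-length scale (px)
        ss = rng.uniform(8.0, 22.0)  # shaft half-width (px)
        amp = rng.uniform(0.3, 0.6)
        u = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
        v = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
        # super-Gaussian cross-profile: flat medullary core, crisp cortex
        out += amp * np.exp(-0.5 * ((u / sl) ** 2 + (v / ss) ** 4))
    return np.clip(out, 0.0, 0.65)


def render_ground_truth(
    mesh: Mesh,
    true_pose: RigidTransform,
    rig: tuple[ProjectionView, ProjectionView],
    noise_sigma: float = 0.05,
    n_clutter: int = 6,
    clutter_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the biplanar ground-truth image pair.

    The component silhouette is drawn near-saturated (0.95) over a dark
    background (0.15) carrying bone-like clutter ridges; i.i.d. Gaussian
    noise of the given sigma is added and values are clipped to [0, 1].
    With ``noise_sigma = 0`` and ``n_clutter = 0`` the image is exactly the
    silhouette on a flat background.
    """
    images = []
    for v_idx, view in enumerate(rig):
        sil = project_silhouette(mesh, true_pose, view)
        img = np.full(view.image_size, 0.15, dtype=np.float64)
        if n_clutter > 0:
            rng = np.random.default_rng(clutter_seed + 7919 * v_idx)
            r0, c0 = sil.window_origin
            h, w = sil.mask_window.shape
            img += _soft_tissue_field(view.image_size, rng)
            img += _clutter_field(
                view.image_size, (r0, r0 + h, c0, c0 + w), n_clutter, rng
            )
            img = np.clip(img, 0.0, 0.8)
        img[sil.interior_mask] = 0.95
        if noise_sigma > 0:
            nrng = np.random.default_rng(clutter_seed + 104729 * (v_idx + 1))
            img = img + nrng.normal(0.0, noise_sigma, size=img.shape)
        images.append(np.clip(img, 0.0, 1.0))
    return images[0], images[1]


def sample_random_transform(
    rot_range_deg: float, trans_range_mm: float, rng: np.random.Generator
) -> RigidTransform:
    """Uniform, independent per-DOF perturbation on +/- the given ranges."""
    if rot_range_deg < 0 or trans_range_mm < 0:
        raise ParameterError("perturbation ranges must be >= 0")
    r = rng.uniform(-rot_range_deg, rot_range_deg, size=3)
    t = rng.uniform(-trans_range_mm, trans_range_mm, size=3)
    return RigidTransform(r[0], r[1], r[2], t[0], t[1], t[2])


def make_scene(
    kind: str,
    seed: int = 0,
    size_mm: float = 50.0,
    rig: tuple[ProjectionView, ProjectionView] | None = None,
    noise_sigma: float = 0.05,
    n_clutter: int = 6,
    mesh_seed: int | None = None,
) -> GroundTruthScene:
    """Generate a complete ground-truth scene from one seed.

    The true pose is itself drawn (uniformly within +/-5 deg / +/-5 mm of
    the isocenter pose) so every scene has a different ground truth. The
    phantom size (50 mm) and pose range keep the component inside the
    ~85 mm isocenter field of view of the default rig. ``mesh_seed``, when
    given, decouples the mesh jitter from the scene seed so one mesh can be
    reused under many transforms.
    """
    if rig is None:
        rig = make_biplanar_rig()
    rng = np.random.default_rng(seed)
    mesh = make_phantom_mesh(
        kind, size_mm=size_mm, seed=seed if mesh_seed is None else mesh_seed
    )
    true_pose = sample_random_transform(5.0, 5.0, rng)
    images = render_ground_truth(
        mesh, true_pose, rig,
        noise_sigma=noise_sigma, n_clutter=n_clutter, clutter_seed=seed,
    )
    return GroundTruthScene(
        mesh=mesh, true_pose=true_pose, rig=rig, images=images, kind=kind,
        clutter_seed=seed, noise_sigma=noise_sigma, n_clutter=n_clutter,
    )


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def pose_rmse(mesh: Mesh, theta_est: RigidTransform,
              theta_true: RigidTransform) -> float:
    """Root-mean-square distance (mm) between mesh vertices under two poses."""
    c = mesh.centroid
    v_est = transform_vertices(mesh.vertices, c, theta_est)
    v_true = transform_vertices(mesh.vertices, c, theta_true)
    d2 = np.sum((v_est - v_true) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def per_dof_errors(theta_est: RigidTransform,
                   theta_true: RigidTransform) -> np.ndarray:
    """Absolute per-parameter errors: rotations in degrees wrapped to
    [0, 180], translations in mm."""
    d = theta_est.as_array() - theta_true.as_array()
    rot = np.abs((d[:3] + 180.0) % 360.0 - 180.0)
    return np.concatenate([rot, np.abs(d[3:])])
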