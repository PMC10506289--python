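"""Cost terms of the hybrid registration energy.

The registration energy over a six-parameter pose theta is

    C(theta) = E(theta) + beta * V(theta)

* E is the directional edge-potential-field cost: for each pixel of the
  projected external contour in each view, the potential
  Phi = exp(-rho * d) (d = Euclidean distance to the nearest detected edge)
  is weighted by |cos alpha|, the alignment between the contour tangent and
  the tangent of that nearest edge, and averaged with a minus sign. E lies
  in [-2, 0]; -2 means both projected contours sit exactly on image edges
  with matching directions.

* V is the normalized object-specificity cost: superpixel labels that occur
  both inside and outside the projected interior are penalized,
  vartheta = sum_h p_h * |{s: z_s = l_h, s outside}| with p_h the fraction
  of interior pixels carrying label l_h, and V = vartheta_1/N_1 +
  vartheta_2/N_2 over the two views. V = 0 when the labels inside the
  silhouette occur nowhere outside it.

Edge fields and label maps depend only on the images, so they are computed
once per registration and shared across all cost evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    NoEdgesError,
    ParameterError,
    ProjectionOutOfBoundsError,
    UndefinedSpecificityError,
)
from .geometry import (
    Mesh,
    ProjectionView,
    RigidTransform,
    SilhouetteProjection,
    project_silhouette,
)
from .preprocess import EdgeMap, LabelMap

__all__ = [
    "EdgePotentialField",
    "CostBreakdown",
    "CostScene",
    "PENALTY_COST",
    "compute_potential_field",
    "edge_cost",
    "object_specificity",
    "region_cost",
    "hybrid_cost",
    "evaluate_cost",
]

#: Returned when a candidate pose projects (mostly) outside an image; large
#: and finite so the stochastic search stays bounded without exceptions.
PENALTY_COST = 10.0


@dataclass(frozen=True)
class EdgePotentialField:
    """Per-pixel edge potential Phi plus the tangent of the nearest edge."""

    phi: np.ndarray  # (rows, cols) float64 in (0, 1]
    nearest_edge_tangent: np.ndarray  # (rows, cols, 2) unit vectors
    rho: float  # smoothing factor, 1/pixels

    @property
    def image_size(self) -> tuple[int, int]:
        return self.phi.shape


@dataclass(frozen=True)
class CostBreakdown:
    """All terms of one evaluation of C = E + beta * V."""

    E: float
    V: float
    C: float
    beta: float
    e_parts: tuple[float, float]  # per-view contributions to E (each <= 0)
    v_parts: tuple[float, float]  # per-view vartheta/N
    penalty: bool = False


@dataclass(frozen=True)
class CostScene:
    """Static, pose-independent inputs to the cost: mesh, rig, fields, labels."""

    mesh: Mesh
    views: tuple[ProjectionView, ProjectionView]
    fields: tuple[EdgePotentialField, EdgePotentialField]
    labels: tuple[LabelMap, LabelMap]


def compute_potential_field(edges: EdgeMap, rho: float = 0.005) -> EdgePotentialField:
    """Edge potential field Phi = exp(-rho * distance to the nearest edge).

    The exact Euclidean distance transform also yields, per pixel, the index
    of the nearest edge pixel, whose stored tangent is propagated so the
    directional term can reuse the same nearest-edge assignment.
    """
    if rho <= 0:
        raise ParameterError("rho must be positive")
    if not edges.edges.any():
        raise NoEdgesError("edge map is empty; potential field undefined")
    dist, (iy, ix) = ndimage.distance_transform_edt(
        ~edges.edges, return_indices=True
    )
    phi = np.exp(-rho * dist)
    nearest_tangent = edges.tangents[iy, ix]
    return EdgePotentialField(phi=phi, nearest_edge_tangent=nearest_tangent, rho=rho)


def _edge_cost_one_view(
    sil: SilhouetteProjection, field: EdgePotentialField
) -> float:
    """-(1/n) sum Phi * |cos alpha| over one view's contour pixels.

    Contour pixels are snapped to the integer grid for the field lookup;
    pixels outside the image contribute Phi = 0 but still count toward n.
    """
    n = sil.n_contour
    if n == 0:
        raise ParameterError("degenerate silhouette: empty contour")
    rows, cols = field.image_size
    px = np.rint(sil.contour[:, 0]).astype(np.intp)
    py = np.rint(sil.contour[:, 1]).astype(np.intp)
    inb = (px >= 0) & (px < cols) & (py >= 0) & (py < rows)
    if not inb.any():
        return 0.0
    px = px[inb]
    py = py[inb]
    phi = field.phi[py, px]
    et = field.nearest_edge_tangent[py, px]
    ct = sil.tangents[inb]
    cos_a = np.abs(et[:, 0] * ct[:, 0] + et[:, 1] * ct[:, 1])
    return -float(np.dot(phi, cos_a)) / n


def edge_cost(
    sil_1: SilhouetteProjection,
    field_1: EdgePotentialField,
    sil_2: SilhouetteProjection,
    field_2: EdgePotentialField,
) -> float:
    """Directional edge cost E over both views; E in [-2, 0]."""
    return _edge_cost_one_view(sil_1, field_1) + _edge_cost_one_view(sil_2, field_2)


def _interior_label_counts(labels: LabelMap, sil: SilhouetteProjection) -> np.ndarray:
    """Pixel count of each label inside the projected interior (in-image)."""
    r0, c0 = sil.window_origin
    rows, cols = labels.labels.shape
    h, w = sil.mask_window.shape
    ra, rb = max(0, -r0), min(h, rows - r0)
    ca, cb = max(0, -c0), min(w, cols - c0)
    if ra >= rb or ca >= cb:
        return np.zeros(labels.n_labels, dtype=np.int64)
    win = sil.mask_window[ra:rb, ca:cb]
    lab = labels.labels[r0 + ra : r0 + rb, c0 + ca : c0 + cb]
    return np.bincount(lab[win], minlength=labels.n_labels)


def _specificity_from_counts(counts_in: np.ndarray, labels: LabelMap) -> float:
    n_int = int(counts_in.sum())
    if n_int == 0:
        raise UndefinedSpecificityError("projected interior is empty")
    exterior = labels.label_sizes - counts_in
    return float(np.dot(counts_in, exterior)) / n_int


def object_specificity(labels: LabelMap, interior: np.ndarray) -> float:
    """vartheta = sum_h p_h |{s: z_s = l_h, s outside the interior}|.

    Zero exactly when every label occurring inside the interior occurs
    nowhere outside it. The per-label totals |{s: z_s = l_h}| come from the
    label map's precomputed sizes; only the interior proportions p_h depend
    on the pose.
    """
    interior = np.asarray(interior, dtype=bool)
    if interior.shape != labels.labels.shape:
        raise ParameterError("label map and interior mask shapes differ")
    if not interior.any():
        raise UndefinedSpecificityError("interior mask is empty")
    counts_in = np.bincount(labels.labels[interior], minlength=labels.n_labels)
    return _specificity_from_counts(counts_in, labels)


def region_cost(theta_1: float, n_1: int, theta_2: float, n_2: int) -> float:
    """Normalized region cost V = vartheta_1/N_1 + vartheta_2/N_2."""
    if n_1 <= 0 or n_2 <= 0:
        raise UndefinedSpecificityError("interior pixel count must be positive")
    return theta_1 / n_1 + theta_2 / n_2


def _penalty(beta: float) -> CostBreakdown:
    return CostBreakdown(
        E=0.0, V=0.0, C=PENALTY_COST, beta=beta,
        e_parts=(0.0, 0.0), v_parts=(0.0, 0.0), penalty=True,
    )


def evaluate_cost(
    t: RigidTransform,
    scene: CostScene,
    beta: float = 10.0,
    mode: str = "hybrid",
) -> CostBreakdown:
    """Project the mesh under pose ``t`` into both views and evaluate the cost.

    ``mode`` selects which energy drives C: "hybrid" (E + beta*V),
    "potential_field" (E only) or "object_specificity" (V only). Candidate
    poses whose projection leaves an image (or mostly does) receive the
    finite ``PENALTY_COST`` instead of raising, so a stochastic search can
    wander near the image border safely.
    """
    if mode not in ("hybrid", "potential_field", "object_specificity"):
        raise ParameterError(f"unknown similarity mode: {mode!r}")
    sils = []
    for view in scene.views:
        try:
            sil = project_silhouette(scene.mesh, t, view)
        except ProjectionOutOfBoundsError:
            return _penalty(beta)
        rows, cols = view.image_size
        x, y = sil.contour[:, 0], sil.contour[:, 1]
        frac_out = np.mean((x < 0) | (x > cols - 1) | (y < 0) | (y > rows - 1))
        if frac_out > 0.5 or sil.n_interior == 0:
            return _penalty(beta)
        sils.append(sil)

    e_parts = (0.0, 0.0)
    if mode in ("hybrid", "potential_field"):
        e_parts = (
            _edge_cost_one_view(sils[0], scene.fields[0]),
            _edge_cost_one_view(sils[1], scene.fields[1]),
        )
    E = e_parts[0] + e_parts[1]

    v_parts = (0.0, 0.0)
    if mode in ("hybrid", "object_specificity"):
        vp = []
        for sil, labels in zip(sils, scene.labels):
            counts = _interior_label_counts(labels, sil)
            vp.append(_specificity_from_counts(counts, labels) / sil.n_interior)
        v_parts = (vp[0], vp[1])
    V = v_parts[0] + v_parts[1]

    # the reported beta is the weight actually applied, so C = E + beta*V
    # holds exactly in every mode (single-similarity modes zero one term)
    if mode == "potential_field":
        beta = 0.0
    C = E + beta * V
    return CostBreakdown(E=E, V=V, C=C, beta=beta, e_parts=e_parts, v_parts=v_parts)


def hybrid_cost(
    t: RigidTransform, scene: CostScene, beta: float = 10.0
) -> CostBreakdown:
    """Hybrid cost C(theta) = E(theta) + beta * V(theta) with all sub-terms."""
    return evaluate_cost(t, scene, beta=beta, mode="hybrid")
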