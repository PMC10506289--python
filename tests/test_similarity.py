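"""Edge potential field, directional edge cost, object specificity, hybrid."""

import numpy as np
import pytest

from kneereg.errors import (
    NoEdgesError,
    ParameterError,
    UndefinedSpecificityError,
)
from kneereg.geometry import RigidTransform, SilhouetteProjection
from kneereg.pipeline import build_cost_scene
from kneereg.preprocess import EdgeMap, LabelMap
from kneereg.similarity import (
    EdgePotentialField,
    compute_potential_field,
    edge_cost,
    evaluate_cost,
    hybrid_cost,
    object_specificity,
    region_cost,
)
from kneereg.synthetic import sample_random_transform


def _edge_map_from_mask(edges, tangent=None):
    t = np.zeros(edges.shape + (2,))
    if tangent is not None:
        t[edges] = tangent
    return EdgeMap(edges=edges, tangents=t)


def _silhouette(contour, tangents, image_size):
    """Assemble a SilhouetteProjection directly from contour data."""
    mask = np.zeros((4, 4), dtype=bool)
    mask[1:3, 1:3] = True  # placeholder interior
    return SilhouetteProjection(
        contour=np.asarray(contour, float),
        tangents=np.asarray(tangents, float),
        mask_window=mask,
        window_origin=(0, 0),
        image_size=image_size,
    )


class TestPotentialField:
    def test_phi_is_one_on_edges(self):
        edges = np.zeros((16, 16), bool)
        edges[8, 3] = edges[2, 12] = True
        f = compute_potential_field(_edge_map_from_mask(edges), rho=0.1)
        assert f.phi[8, 3] == 1.0 and f.phi[2, 12] == 1.0

    def test_closed_form_at_distance_ten(self):
        edges = np.zeros((8, 32), bool)
        edges[4, 5] = True
        f = compute_potential_field(_edge_map_from_mask(edges), rho=0.1)
        assert f.phi[4, 15] == pytest.approx(np.exp(-1.0), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_nearest_edge_search(self, seed):
        rng = np.random.default_rng(seed)
        edges = rng.random((20, 20)) < 0.05
        if not edges.any():
            edges[7, 13] = True
        rho = 0.07
        f = compute_potential_field(_edge_map_from_mask(edges), rho=rho)
        ey, ex = np.nonzero(edges)
        yy, xx = np.mgrid[0:20, 0:20]
        d2 = (yy[..., None] - ey) ** 2 + (xx[..., None] - ex) ** 2
        brute = np.exp(-rho * np.sqrt(d2.min(axis=-1)))
        np.testing.assert_allclose(f.phi, brute, atol=1e-9)

    def test_phi_decreases_with_distance(self):
        edges = np.zeros((16, 64), bool)
        edges[:, 0] = True
        f = compute_potential_field(_edge_map_from_mask(edges), rho=0.05)
        assert np.all(np.diff(f.phi[8]) < 0)

    def test_empty_edge_map_rejected(self):
        with pytest.raises(NoEdgesError):
            compute_potential_field(_edge_map_from_mask(np.zeros((8, 8), bool)))


class TestEdgeCost:
    def test_perfect_alignment_gives_minus_two(self):
        # contour pixels on edge pixels, tangents aligned: each view -> -1
        edges = np.zeros((16, 16), bool)
        edges[5, 4:10] = True
        em = _edge_map_from_mask(edges, tangent=[1.0, 0.0])
        f = compute_potential_field(em, rho=0.1)
        contour = [[x, 5] for x in range(4, 10)]
        tangents = [[1.0, 0.0]] * 6
        sil = _silhouette(contour, tangents, (16, 16))
        assert edge_cost(sil, f, sil, f) == pytest.approx(-2.0, abs=1e-12)

    def test_perpendicular_tangents_give_zero(self):
        edges = np.zeros((16, 16), bool)
        edges[5, 4:10] = True
        em = _edge_map_from_mask(edges, tangent=[1.0, 0.0])
        f = compute_potential_field(em, rho=0.1)
        contour = [[x, 5] for x in range(4, 10)]
        tangents = [[0.0, 1.0]] * 6  # perpendicular to every nearest edge
        sil = _silhouette(contour, tangents, (16, 16))
        assert edge_cost(sil, f, sil, f) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_per_pixel_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        edges = rng.random((32, 32)) < 0.08
        edges[0, 0] = True
        ang = rng.uniform(0, 2 * np.pi, edges.sum())
        em = EdgeMap(edges=edges, tangents=np.zeros((32, 32, 2)))
        em.tangents[edges] = np.column_stack([np.cos(ang), np.sin(ang)])
        f = compute_potential_field(em, rho=0.05)
        pts = rng.integers(0, 32, size=(16, 2)).astype(float)
        ca = rng.uniform(0, 2 * np.pi, 16)
        tg = np.column_stack([np.cos(ca), np.sin(ca)])
        sil = _silhouette(pts, tg, (32, 32))
        # independent term-by-term evaluation
        expected = 0.0
        for (x, y), t in zip(pts.astype(int), tg):
            et = f.nearest_edge_tangent[y, x]
            expected += f.phi[y, x] * abs(t[0] * et[0] + t[1] * et[1])
        expected = -expected / 16
        assert edge_cost(sil, f, sil, f) == pytest.approx(2 * expected, abs=1e-9)

    def test_out_of_image_pixels_contribute_zero(self):
        edges = np.zeros((16, 16), bool)
        edges[5, 5] = True
        em = _edge_map_from_mask(edges, tangent=[1.0, 0.0])
        f = compute_potential_field(em, rho=0.1)
        sil_in = _silhouette([[5, 5]], [[1.0, 0.0]], (16, 16))
        sil_mixed = _silhouette(
            [[5, 5], [-7, 5]], [[1.0, 0.0], [1.0, 0.0]], (16, 16)
        )
        one_view_in = edge_cost(sil_in, f, sil_in, f) / 2
        one_view_mixed = edge_cost(sil_mixed, f, sil_mixed, f) / 2
        assert one_view_mixed == pytest.approx(one_view_in / 2, abs=1e-12)


class TestObjectSpecificity:
    def test_specific_labels_give_zero(self):
        labels = np.zeros((10, 10), int)
        labels[2:6, 2:6] = 1
        lm = LabelMap.from_labels(labels, requested_k=2)
        interior = labels == 1
        assert object_specificity(lm, interior) == 0.0

    def test_single_label_closed_form(self):
        labels = np.zeros((10, 10), int)
        lm = LabelMap.from_labels(labels, requested_k=1)
        interior = np.zeros((10, 10), bool)
        interior[:4, :5] = True  # n = 20 of N_img = 100
        assert object_specificity(lm, interior) == pytest.approx(80.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 5, size=(24, 24))
        interior = rng.random((24, 24)) < 0.3
        interior[12, 12] = True
        lm = LabelMap.from_labels(labels, requested_k=5)
        # brute-force set cardinalities per label
        n = interior.sum()
        expected = 0.0
        for h in range(5):
            p_h = np.sum(interior & (labels == h)) / n
            expected += p_h * np.sum(~interior & (labels == h))
        assert object_specificity(lm, interior) == pytest.approx(expected, abs=1e-9)

    def test_empty_interior_rejected(self):
        lm = LabelMap.from_labels(np.zeros((8, 8), int), requested_k=1)
        with pytest.raises(UndefinedSpecificityError):
            object_specificity(lm, np.zeros((8, 8), bool))


class TestRegionCost:
    def test_perfect_specificity(self):
        assert region_cost(0.0, 100, 0.0, 150) == 0.0

    def test_arithmetic(self):
        assert region_cost(50.0, 100, 30.0, 200) == pytest.approx(0.65, abs=1e-12)

    def test_scale_invariance(self):
        assert region_cost(50.0, 100, 30.0, 200) == pytest.approx(
            region_cost(150.0, 300, 30.0, 200), abs=1e-12
        )

    def test_zero_interior_rejected(self):
        with pytest.raises(UndefinedSpecificityError):
            region_cost(1.0, 0, 1.0, 10)


@pytest.fixture(scope="module")
def cost_scene(clean_scene):
    return build_cost_scene(clean_scene.mesh, clean_scene.images, clean_scene.rig)


class TestHybridCost:
    def test_beta_zero_reduces_to_edge_cost(self, cost_scene, clean_scene):
        cb = hybrid_cost(clean_scene.true_pose, cost_scene, beta=0.0)
        assert cb.C == cb.E

    def test_linear_combination_exact(self, cost_scene, clean_scene):
        cb = hybrid_cost(clean_scene.true_pose, cost_scene, beta=7.5)
        assert cb.C == pytest.approx(cb.E + 7.5 * cb.V, abs=1e-12)

    def test_bounds_of_terms(self, cost_scene, clean_scene):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = sample_random_transform(8.0, 8.0, rng)
            cb = hybrid_cost(t, cost_scene)
            if not cb.penalty:
                assert -2.0 <= cb.E <= 0.0
                assert cb.V >= 0.0

    def test_truth_beats_nearby_perturbations(self, cost_scene, clean_scene):
        c0 = hybrid_cost(clean_scene.true_pose, cost_scene).C
        rng = np.random.default_rng(7)
        base = clean_scene.true_pose.as_array()
        for _ in range(20):
            d = sample_random_transform(5.0, 5.0, rng).as_array()
            if np.abs(d).max() < 0.5:
                continue
            c = hybrid_cost(RigidTransform.from_array(base + d), cost_scene).C
            assert c0 < c

    def test_precomputed_inputs_not_mutated(self, cost_scene, clean_scene):
        phi_before = cost_scene.fields[0].phi.copy()
        lab_before = cost_scene.labels[0].labels.copy()
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = sample_random_transform(6.0, 6.0, rng)
            evaluate_cost(t, cost_scene, mode="hybrid")
        np.testing.assert_array_equal(cost_scene.fields[0].phi, phi_before)
        np.testing.assert_array_equal(cost_scene.labels[0].labels, lab_before)

    def test_far_out_of_image_pose_gets_penalty(self, cost_scene):
        cb = evaluate_cost(RigidTransform(0, 0, 0, 0, 0, -60.0), cost_scene)
        assert cb.penalty and cb.C == 10.0

    def test_unknown_mode_rejected(self, cost_scene):
        with pytest.raises(ParameterError):
            evaluate_cost(RigidTransform(), cost_scene, mode="fancy")
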