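"""Similarity registration, 3D nucleus extraction/splitting, iso-surfaces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from mamrud import phantom, reconstruct
from mamrud.errors import ValidationError
from mamrud.reconstruct import NucleusSet, _nucleus_table
from mamrud.transform import SimilarityTransform2D, fit_similarity

TRIANGLE = np.array([[10.0, 20.0], [40.0, 80.0], [90.0, 30.0]])

params = st.tuples(
    st.floats(0.5, 2.0),  # scale
    st.floats(-np.pi, np.pi),  # rotation
    st.floats(-20, 20),  # tx
    st.floats(-20, 20),  # ty
)


def make(p):
    s, r, tx, ty = p
    return SimilarityTransform2D(scale=s, rotation=r, translation=(tx, ty))


class TestTransformGroup:
    @given(p=params)
    @settings(max_examples=50, deadline=None)
    def test_inverse_composes_to_identity(self, p):
        t = make(p)
        assert np.allclose(t.compose(t.inverse()).matrix, np.eye(3), atol=1e-9)

    @given(p=params, q=params)
    @settings(max_examples=50, deadline=None)
    def test_closure_and_no_reflection(self, p, q):
        composed = make(p).compose(make(q))
        linear = composed.matrix[:2, :2]
        assert np.linalg.det(linear) > 0
        assert composed.scale == pytest.approx(p[0] * q[0], rel=1e-9)

    def test_reflective_matrix_rejected(self):
        flip = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            SimilarityTransform2D.from_matrix(flip)


class TestFitSimilarity:
    def test_identical_points_give_identity(self):
        assert fit_similarity(TRIANGLE, TRIANGLE).is_identity(tol=1e-9)

    def test_constructed_transform_recovered_to_1e6(self):
        true = SimilarityTransform2D(scale=1.1, rotation=np.deg2rad(30), translation=(5.0, -3.0))
        fitted = fit_similarity(TRIANGLE, true.apply(TRIANGLE))
        assert fitted.scale == pytest.approx(1.1, abs=1e-6)
        assert fitted.rotation == pytest.approx(np.deg2rad(30), abs=1e-6)
        assert fitted.translation == pytest.approx((5.0, -3.0), abs=1e-6)

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValidationError):
            fit_similarity(line, line)

    def test_duplicate_points_rejected(self):
        dup = np.array([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        with pytest.raises(ValidationError):
            fit_similarity(dup, dup)

    def test_noisy_fit_beats_coarse_grid_search(self):
        rng = np.random.default_rng(0)
        true = SimilarityTransform2D(scale=1.05, rotation=0.2, translation=(3.0, -2.0))
        dst = true.apply(TRIANGLE) + rng.normal(0, 0.5, TRIANGLE.shape)
        fitted = fit_similarity(TRIANGLE, dst)
        fit_res = np.sum((fitted.apply(TRIANGLE) - dst) ** 2)
        best = np.inf
        for s in np.linspace(0.95, 1.15, 9):
            for th in np.linspace(0.1, 0.3, 9):
                for tx in np.linspace(1.0, 5.0, 9):
                    for ty in np.linspace(-4.0, 0.0, 9):
                        cand = SimilarityTransform2D(scale=s, rotation=th, translation=(tx, ty))
                        best = min(best, np.sum((cand.apply(TRIANGLE) - dst) ** 2))
        assert fit_res <= best + 1e-9


@pytest.fixture(scope="module")
def perturbed():
    spec = phantom.PhantomSpec(rng_seed=5, n_sections=6)
    sections, truth = phantom.generate_stack(spec)
    moved, transforms = phantom.perturb_stack(
        sections, max_shift_px=4, max_rot_rad=0.05, max_scale_dev=0.02, seed=11
    )
    base = np.array([[40.0, 60.0], [40.0, 200.0], [80.0, 128.0]])
    points = {s.index: transforms[k].apply(base) for k, s in enumerate(sections)}
    return sections, moved, transforms, points


class TestAlignStack:

    def test_recovered_transforms_invert_applied_ones(self, perturbed):
        _, moved, applied, points = perturbed
        _, recovered = reconstruct.align_stack(moved, points)
        for rec, app in zip(recovered, applied):
            assert np.allclose(rec.matrix, app.inverse().matrix, atol=1e-9)

    def test_round_trip_restores_images(self, perturbed):
        originals, moved, _, points = perturbed
        aligned, _ = reconstruct.align_stack(moved, points)
        diffs = [
            np.abs(a.image.astype(float) - o.image.astype(float)).mean()
            for a, o in zip(aligned, originals)
        ]
        assert max(diffs) < 10.0

    def test_alignment_reduces_control_point_residual(self, perturbed):
        _, moved, _, points = perturbed
        indices = [s.index for s in moved]
        _, recovered = reconstruct.align_stack(moved, points)
        before = reconstruct.control_point_residual(points, [None] * len(moved), indices)
        after = reconstruct.control_point_residual(points, recovered, indices)
        assert after < before
        assert after < 1e-6

    def test_identity_points_give_identity_transforms(self, perturbed):
        originals, _, _, _ = perturbed
        pts = {s.index: TRIANGLE for s in originals}
        _, recovered = reconstruct.align_stack(originals, pts)
        assert all(t.is_identity(tol=1e-9) for t in recovered)

    def test_missing_control_points_skips_with_warning(self, perturbed):
        _, moved, _, points = perturbed
        partial = {k: v for k, v in points.items() if k != moved[2].index}
        with pytest.warns(RuntimeWarning):
            aligned, recovered = reconstruct.align_stack(moved, partial)
        assert recovered[2] is None
        assert (aligned[2].image == moved[2].image).all()

    def test_single_section_returned_unchanged(self, perturbed):
        originals, _, _, _ = perturbed
        aligned, transforms = reconstruct.align_stack(originals[:1], {})
        assert (aligned[0].image == originals[0].image).all()
        assert transforms[0].is_identity()


def sparse_phantom(seed=9):
    spec = phantom.PhantomSpec(
        rng_seed=seed,
        n_sections=7,
        brdu_fraction={"ectoderm": 0.0, "core": 0.0, "periphery": 0.0, "mesenchyme": 0.05},
    )
    return phantom.generate_stack(spec)


class TestExtractLabelVoxels:
    def test_no_brdu_gives_empty_set(self):
        spec = phantom.PhantomSpec(
            rng_seed=3,
            n_sections=4,
            brdu_fraction={"ectoderm": 0.0, "core": 0.0, "periphery": 0.0, "mesenchyme": 0.0},
        )
        sections, _ = phantom.generate_stack(spec)
        nuclei = reconstruct.extract_label_voxels(sections)
        assert nuclei.count == 0

    def test_size_filter_removes_speckle(self):
        sections, _ = sparse_phantom()
        img = sections[0].image.copy()
        img[2:3, 2:4] = phantom.BRDU_COLOR  # a 2-px speckle in the background
        sections[0].image = img
        nuclei = reconstruct.extract_label_voxels(sections, size_window=(10, 10**6))
        assert not nuclei.labels[0, 2, 2:4].any()

    def test_invalid_threshold_rejected(self):
        sections, _ = sparse_phantom()
        with pytest.raises(ValidationError):
            reconstruct.extract_label_voxels(sections, threshold=1.5)

    def test_inverted_gray_range(self):
        sections, _ = sparse_phantom()
        gray = reconstruct.to_inverted_gray(sections[0].image)
        assert 0.0 <= gray.min() and gray.max() <= 1.0
        # dark DAB pixels map high, pale background low
        assert gray[tuple(np.argwhere((sections[0].image == phantom.BRDU_COLOR).all(-1))[0])] > 0.65


class TestSplitTouching:
    @staticmethod
    def ball(center, r, shape=(1, 40, 60)):
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= r**2

    def as_set(self, mask):
        labels, _ = ndi.label(mask, structure=np.ones((3, 3, 3)))
        return NucleusSet(labels, (1.0, 1.0, 1.0), _nucleus_table(labels, (1.0, 1.0, 1.0)))

    def test_single_sphere_unchanged(self):
        nuclei = self.as_set(self.ball((0, 20, 20), 6))
        split = reconstruct.split_touching(nuclei, min_separation_um=6)
        assert split.count == 1

    def test_two_overlapping_spheres_split_with_true_centroids(self):
        fused = self.ball((0, 20, 20), 6) | self.ball((0, 20, 29), 6)
        nuclei = self.as_set(fused)
        assert nuclei.count == 1
        split = reconstruct.split_touching(nuclei, min_separation_um=6)
        assert split.count == 2
        centroids = np.sort(split.table["centroid_x_um"].to_numpy())
        assert np.allclose(centroids, [20.0, 29.0], atol=1.0)

    def test_three_in_a_row_chain_split(self):
        chain = (
            self.ball((0, 20, 15), 6) | self.ball((0, 20, 24), 6) | self.ball((0, 20, 33), 6)
        )
        split = reconstruct.split_touching(self.as_set(chain), min_separation_um=6)
        assert split.count == 3

    def test_split_conserves_foreground_exactly(self):
        chain = self.ball((0, 20, 15), 6) | self.ball((0, 20, 24), 6)
        nuclei = self.as_set(chain)
        split = reconstruct.split_touching(nuclei, min_separation_um=6)
        assert ((split.labels > 0) == (nuclei.labels > 0)).all()

    def test_stack_pipeline_recovers_ground_truth_count(self):
        sections, truth = sparse_phantom(seed=9)
        raw = reconstruct.extract_label_voxels(sections, size_window=(5, 400))
        split = reconstruct.split_touching(raw, min_separation_um=4.0)
        assert split.count == int(truth.nuclei["brdu"].sum())


class TestIsosurface:
    def test_sphere_mesh_volume_within_5pct(self):
        zz, yy, xx = np.ogrid[:50, :50, :50]
        ball = (zz - 25) ** 2 + (yy - 25) ** 2 + (xx - 25) ** 2 <= 20**2
        mesh = reconstruct.isosurface(ball, (1.0, 1.0, 1.0), "MR")
        assert mesh.enclosed_volume_um3() == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.05)
        assert mesh.tissue == "MR"

    def test_faces_index_valid_vertices(self):
        zz, yy, xx = np.ogrid[:10, :10, :10]
        ball = (zz - 5) ** 2 + (yy - 5) ** 2 + (xx - 5) ** 2 <= 3**2
        mesh = reconstruct.isosurface(ball, (1.0, 1.0, 1.0), "nuclei")
        assert len(mesh.vertices) > 0
        assert mesh.faces.max() < len(mesh.vertices)

    def test_anisotropic_spacing_scales_z_extent(self):
        zz, yy, xx = np.ogrid[:11, :60, :60]
        ball = ((zz - 5) * 5.0) ** 2 + (yy - 30.0) ** 2 + (xx - 30.0) ** 2 <= 25**2
        mesh = reconstruct.isosurface(ball, (5.0, 1.0, 1.0), "MR")
        z_extent = mesh.vertices[:, 0].max() - mesh.vertices[:, 0].min()
        slice_extent = 11  # occupied slices if spacing were ignored
        assert z_extent == pytest.approx(5 * (2 * 25 / 5), rel=0.15)
        assert z_extent > 3 * slice_extent

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            reconstruct.isosurface(np.zeros((5, 5, 5), dtype=bool), (1.0, 1.0, 1.0), "MR")

    def test_mesh_export_ply(self, tmp_path):
        zz, yy, xx = np.ogrid[:10, :10, :10]
        ball = (zz - 5) ** 2 + (yy - 5) ** 2 + (xx - 5) ** 2 <= 3**2
        mesh = reconstruct.isosurface(ball, (1.0, 1.0, 1.0), "ectoderm")
        out = tmp_path / "ect.ply"
        mesh.save_ply(out)
        assert out.read_bytes().startswith(b"ply")
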