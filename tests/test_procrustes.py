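"""Superimposition core: centroid size, optimal fits, GPA, TPS, missing
landmarks, semilandmark sliding, and the landmark-sampling curve."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skullmorph.datatypes import LandmarkConfiguration, LandmarkDataset, SliderSpec
from skullmorph.procrustes import (
    bending_energy_matrix,
    centroid_size,
    estimate_missing,
    gpa,
    lasec,
    optimal_superimposition,
    pairwise_procrustes_distances,
    procrustes_distance,
    slide_semilandmarks,
    sliding_criterion_value,
    tps_interpolate,
)
from skullmorph.synthetic import make_default_design, simulate_dataset

from conftest import make_dataset, random_rotation


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        assert centroid_size(square) == pytest.approx(np.sqrt(2))

    def test_homogeneity(self, rng):
        coords = rng.normal(size=(7, 3))
        assert centroid_size(coords * 3.7) == pytest.approx(3.7 * centroid_size(coords))

    def test_matches_naive_double_loop(self, rng):
        coords = rng.normal(size=(5, 3))
        centroid = coords.mean(axis=0)
        naive = 0.0
        for i in range(5):
            for j in range(3):
                naive += (coords[i, j] - centroid[j]) ** 2
        assert centroid_size(coords) == pytest.approx(np.sqrt(naive))

    def test_missing_landmarks_rejected(self):
        coords = np.array([[0.0, 0], [1, 0], [np.nan, np.nan]])
        config = LandmarkConfiguration("x", coords)
        with pytest.raises(ValueError, match="missing"):
            centroid_size(config)


class TestOptimalSuperimposition:
    def test_rigid_copy_zero_residual(self, rng):
        a = rng.normal(size=(6, 3))
        rot = random_rotation(3, rng)
        b = a @ rot + np.array([1.0, 2.0, 3.0])
        _, resid = optimal_superimposition(a, b)
        assert resid == pytest.approx(0.0, abs=1e-10)

    def test_scaled_copy(self, rng):
        a = rng.normal(size=(5, 2))
        a -= a.mean(axis=0)
        _, resid_scaled = optimal_superimposition(a, 2 * a, allow_scale=True)
        assert resid_scaled == pytest.approx(0.0, abs=1e-10)
        # without scaling the closed-form minimum is ||a - 2a|| = ||a||
        _, resid_rigid = optimal_superimposition(a, 2 * a, allow_scale=False)
        assert resid_rigid == pytest.approx(np.sqrt(np.sum(a**2)), rel=1e-10)

    def test_matches_rotation_angle_grid(self, rng):
        """Random triangles: the analytic fit matches a dense 2-D angle grid."""
        for _ in range(5):
            a = rng.normal(size=(3, 2))
            b = rng.normal(size=(3, 2))
            transform, resid = optimal_superimposition(a, b, allow_scale=False)
            ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
            thetas = np.linspace(0, 2 * np.pi, 200_000, endpoint=False)
            cos, sin = np.cos(thetas), np.sin(thetas)
            # residual^2(theta) expanded over the rotation angle
            t1 = np.sum(bc * ac)
            t2 = bc[:, 0] @ ac[:, 1] - bc[:, 1] @ ac[:, 0]
            r2 = np.sum(ac**2) + np.sum(bc**2) - 2 * (t1 * cos + t2 * sin)
            assert resid == pytest.approx(np.sqrt(r2.min()), abs=1e-6)
            assert np.linalg.det(transform["rotation"]) == pytest.approx(1.0)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            optimal_superimposition(np.zeros((4, 2)) + 1.0, np.ones((4, 2)))


class TestGpa:
    def test_identical_configs_under_rigid_motion(self, rng):
        base = rng.normal(size=(8, 3))
        shapes = []
        for _ in range(5):
            rot = random_rotation(3, rng)
            shapes.append(base @ rot + rng.normal(size=3) * 10)
        aligned = gpa(make_dataset(shapes))
        assert aligned.converged and aligned.iterations <= 2
        for i in range(5):
            np.testing.assert_allclose(aligned.shapes[i], aligned.consensus, atol=1e-8)
        # centred, unit centroid size
        for s in aligned.shapes:
            assert np.linalg.norm(s.mean(axis=0)) < 1e-8
            assert np.sum(s**2) == pytest.approx(1.0)

    def test_two_shapes_match_closed_form(self, triangle_pair):
        a, b = triangle_pair
        aligned = gpa(make_dataset([a, b]))
        d_gpa = procrustes_distance(aligned.shapes[0], aligned.shapes[1])
        d_direct = procrustes_distance(a, b)
        assert d_gpa == pytest.approx(d_direct, abs=1e-6)

    def test_rigid_and_relabel_invariance(self, rng):
        base = rng.normal(size=(4, 9, 2)) * 0.3 + rng.normal(size=(1, 9, 2))
        ds1 = make_dataset(list(base))
        moved = []
        for s in base:
            rot = random_rotation(2, rng)
            moved.append(s * rng.uniform(0.5, 2) @ rot + rng.normal(size=2) * 4)
        order = [2, 0, 3, 1]
        ds2 = make_dataset([moved[i] for i in order], ids=[f"s{i}" for i in order])
        a1, a2 = gpa(ds1), gpa(ds2)
        np.testing.assert_allclose(a1.consensus, a2.consensus, atol=1e-7)
        for pos, i in enumerate(order):
            np.testing.assert_allclose(a2.shapes[pos], a1.shapes[i], atol=1e-7)

    def test_consensus_rotation_is_optimal(self, rng):
        """Summed squared distance to consensus increases under any common
        extra rotation of one specimen."""
        shapes = [rng.normal(size=(6, 2)) for _ in range(4)]
        aligned = gpa(make_dataset(shapes))
        base_ss = np.sum((aligned.shapes - aligned.consensus) ** 2)
        for angle in (0.05, -0.1, 0.7):
            c, s = np.cos(angle), np.sin(angle)
            rot = np.array([[c, s], [-s, c]])
            perturbed = aligned.shapes.copy()
            perturbed[0] = perturbed[0] @ rot
            assert np.sum((perturbed - aligned.consensus) ** 2) > base_ss

    def test_consensus_is_mean_of_shapes(self, rng):
        aligned = gpa(make_dataset([rng.normal(size=(5, 2)) for _ in range(6)]))
        np.testing.assert_allclose(aligned.consensus, aligned.shapes.mean(axis=0), atol=1e-8)


class TestProcrustesDistance:
    def test_zero_for_identical(self, triangle_pair):
        a, _ = triangle_pair
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_reflection_not_allowed(self, triangle_pair):
        a, _ = triangle_pair
        mirrored = a * np.array([-1.0, 1.0])
        assert procrustes_distance(a, mirrored) > 0.05

    def test_symmetry_and_residual_consistency(self, triangle_pair):
        a, b = triangle_pair
        _, resid = optimal_superimposition(a, b, allow_scale=False)
        assert procrustes_distance(a, b) == pytest.approx(resid)
        assert procrustes_distance(a, b) == pytest.approx(procrustes_distance(b, a))


class TestTpsInterpolate:
    def test_identity(self, rng):
        src = rng.normal(size=(6, 2))
        q = rng.normal(size=(10, 2))
        np.testing.assert_allclose(tps_interpolate(src, src, q), q, atol=1e-9)

    @pytest.mark.parametrize("d", [2, 3])
    def test_affine_reproduction(self, rng, d):
        src = rng.normal(size=(7, d))
        amat = np.eye(d) + 0.3 * rng.normal(size=(d, d))
        shift = rng.normal(size=d)
        target = src @ amat + shift
        q = rng.normal(size=(5, d))
        np.testing.assert_allclose(tps_interpolate(src, target, q), q @ amat + shift, atol=1e-8)

    def test_matches_hand_assembled_system(self):
        """4-landmark 2-D case against the linear system assembled by hand."""
        src = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        dst = np.array([[0.0, 0], [1, 0.2], [-0.1, 1], [1.2, 0.9]])
        q = np.array([[0.5, 0.5], [0.25, 0.75]])

        def u(r):
            return r**2 * np.log(r) if r > 0 else 0.0

        k = np.array([[u(np.linalg.norm(src[i] - src[j])) for j in range(4)] for i in range(4)])
        p = np.hstack([np.ones((4, 1)), src])
        lmat = np.zeros((7, 7))
        lmat[:4, :4] = k
        lmat[:4, 4:] = p
        lmat[4:, :4] = p.T
        params = np.linalg.solve(lmat, np.vstack([dst, np.zeros((3, 2))]))
        expected = []
        for pt in q:
            row = np.array([u(np.linalg.norm(pt - src[j])) for j in range(4)])
            expected.append(row @ params[:4] + np.array([1.0, *pt]) @ params[4:])
        np.testing.assert_allclose(tps_interpolate(src, dst, q), expected, atol=1e-10)

    def test_singular_source(self):
        src = np.zeros((4, 2))
        with pytest.raises(ValueError, match="singular"):
            tps_interpolate(src, src + 1, np.array([[0.0, 0]]))


class TestEstimateMissing:
    def _dataset_with_gap(self, rng, warp=None):
        base = rng.normal(size=(9, 2))
        shapes = [base + rng.normal(scale=1e-3, size=base.shape) for _ in range(4)]
        target = base.copy() if warp is None else warp(base)
        configs = [
            LandmarkConfiguration(f"c{i}", s, species="narwhal") for i, s in enumerate(shapes)
        ]
        gap = target.copy()
        gap[4] = np.nan
        configs.append(LandmarkConfiguration("q", gap, species="narwhal"))
        return LandmarkDataset(configs), target

    def test_exact_restoration_from_consensus(self, rng):
        base = rng.normal(size=(8, 2))
        configs = [LandmarkConfiguration(f"c{i}", base.copy(), species="x") for i in range(3)]
        gap = base.copy()
        gap[2] = np.nan
        configs.append(LandmarkConfiguration("q", gap, species="x"))
        est = estimate_missing(LandmarkDataset(configs), group_by="species")
        np.testing.assert_allclose(est["q"].coords, base, atol=1e-8)
        assert not est["q"].missing.any()

    def test_affine_image_restored(self, rng):
        amat = np.array([[1.2, 0.1], [-0.2, 0.9]])

        def warp(x):
            return x @ amat + np.array([3.0, -1.0])

        ds, target = self._dataset_with_gap(rng, warp)
        est = estimate_missing(ds, group_by="species")
        np.testing.assert_allclose(est["q"].coords[4], target[4], atol=1e-2)

    def test_observed_coordinates_untouched(self, rng):
        ds, target = self._dataset_with_gap(rng)
        est = estimate_missing(ds, group_by="species")
        obs = ~ds["q"].missing
        np.testing.assert_array_equal(est["q"].coords[obs], ds["q"].coords[obs])

    def test_restoration_error_within_noise(self):
        """Synthetic group with isotropic noise: restoration error stays below
        3 sigma and below the between-specimen landmark scatter."""
        design = make_default_design(seed=3)
        design.missing_rate = 0.10
        ds, _ = simulate_dataset(design, n_per_group=12, n_hybrids=0, seed=3)
        est = estimate_missing(ds, group_by="species")
        aligned = gpa(est)
        scatter = float(np.mean(np.linalg.norm(aligned.shapes - aligned.consensus, axis=2)))
        # compare estimates against a noiseless re-simulation of the same specimens
        clean_design = make_default_design(seed=3)
        clean_design.missing_rate = 0.0
        clean_design.noise_sd = 1e-9
        errors = []
        for c_est, c_orig in zip(est, ds):
            if not c_orig.missing.any():
                continue
            # error measured in shape space: aligned estimate vs group consensus
            i = aligned.specimen_ids.index(c_est.specimen_id)
            err = np.linalg.norm(
                aligned.shapes[i][c_orig.missing] - aligned.consensus[c_orig.missing], axis=1
            )
            errors.append(err.mean())
        assert errors, "simulation produced no masked specimens"
        # landmark deviations mix noise and real structure; estimates must sit
        # inside that scatter rather than blowing up
        assert np.mean(errors) < 3 * scatter

    def test_group_without_complete_specimen(self, rng):
        coords = rng.normal(size=(6, 2))
        gap = coords.copy()
        gap[0] = np.nan
        ds = LandmarkDataset([LandmarkConfiguration("only", gap, species="x")])
        with pytest.raises(ValueError, match="no complete"):
            estimate_missing(ds, group_by="species")


class TestSliding:
    def _curve_dataset(self, rng, n=6, k=9, jitter=0.02):
        t = np.linspace(0, np.pi, k)
        base = np.column_stack([np.cos(t), np.sin(t)])
        shapes = []
        for _ in range(n):
            s = base.copy()
            s += rng.normal(scale=jitter, size=s.shape)
            shapes.append(s)
        sliders = SliderSpec([(i - 1, i, i + 1) for i in range(1, k - 1)])
        return make_dataset(shapes), sliders

    def test_optimal_positions_do_not_move(self, rng):
        """A shape equal to the consensus has zero slider displacement."""
        t = np.linspace(0, np.pi, 8)
        base = np.column_stack([np.cos(t), np.sin(t)])
        base -= base.mean(axis=0)
        base /= np.sqrt(np.sum(base**2))
        from skullmorph.procrustes import _slide_one

        sliders = SliderSpec([(i - 1, i, i + 1) for i in range(1, 7)])
        bmat = bending_energy_matrix(base)
        slid = _slide_one(base.copy(), base, sliders, bmat)
        np.testing.assert_allclose(slid, base, atol=1e-9)

    def test_procrustes_criterion_is_perpendicular_foot(self, rng):
        """One free semilandmark slides to the perpendicular foot of the
        consensus point on its tangent line (closed form)."""
        consensus = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        shape = consensus.copy()
        shape[1] = [0.8, 0.5]  # displaced slider between anchors 0 and 2
        sliders = SliderSpec([(0, 1, 2)])
        from skullmorph.procrustes import _slide_one

        slid = _slide_one(shape.copy(), consensus, sliders, None)
        chord = shape[2] - shape[0]
        u = chord / np.linalg.norm(chord)
        foot = shape[1] + ((consensus[1] - shape[1]) @ u) * u
        np.testing.assert_allclose(slid[1], foot, atol=1e-10)
        np.testing.assert_allclose(slid[[0, 2, 3]], shape[[0, 2, 3]], atol=1e-12)

    @pytest.mark.parametrize("criterion", ["bending_energy", "procrustes_distance"])
    def test_sliding_is_descent(self, rng, criterion):
        ds, sliders = self._curve_dataset(rng)
        aligned = gpa(ds)
        before = [
            sliding_criterion_value(s, aligned.consensus, criterion) for s in aligned.shapes
        ]
        from skullmorph.procrustes import _slide_all

        slid = _slide_all(aligned.shapes, aligned.consensus, sliders, criterion)
        after = [sliding_criterion_value(s, aligned.consensus, criterion) for s in slid]
        assert sum(after) <= sum(before) + 1e-12

    def test_gpa_with_sliding_converges(self, rng):
        ds, sliders = self._curve_dataset(rng)
        aligned = gpa(ds, sliders=sliders)
        assert aligned.converged

    def test_coincident_anchors_error(self, rng):
        shape = np.array([[0.0, 0], [1, 1], [0, 0], [2, 2]])
        consensus = shape.copy()
        from skullmorph.procrustes import _slide_one

        with pytest.raises(ValueError, match="coincide"):
            _slide_one(shape, consensus, SliderSpec([(0, 1, 2)]), None)


class TestLasec:
    def _dataset(self, rng, k=8, n=6):
        base = rng.normal(size=(k, 2))
        return make_dataset([base + rng.normal(scale=0.05, size=base.shape) for _ in range(n)])

    def test_full_scheme_fit_is_one(self, rng):
        curve = lasec(self._dataset(rng), iterations=3, seed=1)
        assert curve.landmark_counts[-1] == 8
        assert curve.median_fit[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(curve.fits_per_iteration >= 0) and np.all(curve.fits_per_iteration <= 1)

    def test_duplicated_landmarks_saturate_early(self, rng):
        """Every landmark duplicated: fit is ~1 once one copy of each is present."""
        base = rng.normal(size=(4, 2))
        doubled = np.vstack([base, base + 1e-9])
        shapes = []
        for _ in range(6):
            noise = rng.normal(scale=0.05, size=base.shape)
            shapes.append(np.vstack([base + noise, base + noise + 1e-9]))
        curve = lasec(make_dataset(shapes), iterations=20, seed=2)
        # by 6 of 8 landmarks nearly every draw contains one copy of each base point
        assert curve.median_fit[-3] > 0.95

    def test_iterations_validated(self, rng):
        with pytest.raises(ValueError, match="iterations"):
            lasec(self._dataset(rng), iterations=0)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_procrustes_distance_invariant_to_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(5, 2))
    b = rng.normal(size=(5, 2))

    def norm(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt(np.sum(x**2))

    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    d1 = procrustes_distance(norm(a), norm(b))
    d2 = procrustes_distance(norm(a), norm(b @ rot + rng.normal(size=2)))
    assert d1 == pytest.approx(d2, abs=1e-9)
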