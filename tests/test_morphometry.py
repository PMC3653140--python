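import numpy as np
import pytest

from neuritemri import (
    LineSegmentSet,
    NeuronGenParams,
    WatsonConfig,
    decompose_paths,
    extract_segments,
    fa_from_eigenvalues,
    fit_line_odr,
    generate_bundle,
    generate_neuron,
    interpolate,
    line_length_sweep,
    parse_swc,
    scatter_matrix,
    segments_from_tree,
)
from neuritemri.swc import UnbranchedPath

from conftest import random_rotation, segments_at


def straight_path(length, step=1.0, direction=(0, 0, 1.0), radius=1.0):
    n = int(round(length / step)) + 1
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    coords = np.outer(np.arange(n) * step, d)
    return UnbranchedPath(coords=coords, radii=np.full(n, radius))


class TestOdr:
    def test_collinear_points_exact(self):
        fit = fit_line_odr([(0, 0, 0), (0, 0, 1), (0, 0, 2)])
        assert np.allclose(fit.direction, [0, 0, 1])
        assert np.allclose(fit.centroid, [0, 0, 1])
        assert not fit.degenerate

    def test_sign_convention_nonnegative_z(self):
        fit = fit_line_odr([(0, 0, 0), (1, 1, -1), (2, 2, -2)])
        assert fit.direction[2] > 0

    def test_noisy_line_within_half_degree_of_grid_oracle(self):
        rng = np.random.default_rng(5)
        true = np.array([1.0, 2.0, 3.0])
        true /= np.linalg.norm(true)
        t = np.linspace(0, 10, 100)
        pts = np.outer(t, true) + 0.01 * rng.standard_normal((100, 3))
        fit = fit_line_odr(pts)

        # independent oracle: exhaustive search on a fine local direction grid
        c = pts.mean(axis=0)
        X = pts - c

        def cost(u):
            proj = X @ u
            return float((X * X).sum() - (proj * proj).sum())

        best_u, best_c = true, cost(true)
        e1 = np.cross(true, [1.0, 0, 0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(true, e1)
        for a in np.linspace(-0.02, 0.02, 81):
            for b in np.linspace(-0.02, 0.02, 81):
                u = true + a * e1 + b * e2
                u /= np.linalg.norm(u)
                cu = cost(u)
                if cu < best_c:
                    best_u, best_c = u, cu
        angle_to_oracle = np.degrees(np.arccos(min(1.0, abs(fit.direction @ best_u))))
        angle_to_truth = np.degrees(np.arccos(min(1.0, abs(fit.direction @ true))))
        assert angle_to_oracle < 0.05
        assert angle_to_truth < 0.5

    def test_planar_square_flags_degenerate(self):
        fit = fit_line_odr([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])
        assert fit.degenerate

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            fit_line_odr([(1, 1, 1), (1, 1, 1), (1, 1, 1)])


class TestExtractSegments:
    def test_floor_rule_and_discard(self):
        segs = extract_segments([straight_path(25.0)], 10.0)
        assert len(segs) == 2

    def test_subthreshold_path_yields_nothing(self):
        segs = extract_segments([straight_path(7.0)], 10.0)
        assert len(segs) == 0

    def test_segment_radius_is_run_mean(self):
        p = straight_path(10.0)
        p.radii = np.linspace(1.0, 2.0, len(p.radii))
        segs = extract_segments([p], 10.0)
        assert segs.radii[0] == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_count_bounded_by_per_path_floor_sum(self, seed):
        tree = interpolate(generate_neuron(NeuronGenParams(total_length=600.0, seed=seed)), 1.0)
        paths = decompose_paths(tree)
        l = 10.0
        tol = 1e-4  # matches the extraction rule's run-closing slack
        segs = extract_segments(paths, l)
        floor_sum = sum(int((p.length + tol) // l) for p in paths)
        assert len(segs) == floor_sum  # straight-walk oracle: leftovers < l discarded per path
        assert len(segs) <= int((sum(p.length for p in paths) + len(paths) * tol) // l)
        assert len(segs) >= len([p for p in paths if p.length >= l])

    def test_weights_normalized(self):
        tree = interpolate(generate_neuron(NeuronGenParams(total_length=400.0, seed=9)), 1.0)
        segs = extract_segments(decompose_paths(tree), 10.0)
        assert segs.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(segs.weights, segs.radii**2 / np.sum(segs.radii**2))


class TestScatterMatrix:
    def test_aligned_segments(self):
        s = LineSegmentSet.from_radii(np.tile([0, 0, 1.0], (5, 1)), [1, 2, 3, 4, 5.0], 10.0)
        sm = scatter_matrix(s)
        assert np.allclose(sm.eigenvalues, [1, 0, 0], atol=1e-12)
        assert np.allclose(np.abs(sm.eigenvectors[:, 0]), [0, 0, 1])

    def test_isotropic_tripod(self):
        s = LineSegmentSet.from_radii(np.eye(3), [1.0, 1.0, 1.0], 10.0)
        sm = scatter_matrix(s)
        assert np.allclose(sm.matrix, np.eye(3) / 3)
        assert fa_from_eigenvalues(sm.eigenvalues) == pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_directions(self):
        s = LineSegmentSet.from_radii(np.array([[1.0, 0, 0], [0, 0, 1.0]]), [1.0, 1.0], 10.0)
        sm = scatter_matrix(s)
        assert np.allclose(sm.eigenvalues, [0.5, 0.5, 0.0], atol=1e-12)

    def test_trace_one_and_psd_on_random_trees(self):
        for seed in (0, 5):
            segs = segments_at(generate_neuron(NeuronGenParams(total_length=500.0, seed=seed)))
            sm = scatter_matrix(segs)
            assert np.trace(sm.matrix) == pytest.approx(1.0, abs=1e-9)
            assert sm.eigenvalues[2] >= -1e-12
            assert sm.eigenvalues[0] >= sm.eigenvalues[1] >= sm.eigenvalues[2]

    def test_rotation_equivariance(self, random_tree):
        R = random_rotation(17)
        segs = segments_at(random_tree)
        sm = scatter_matrix(segs)
        rot = LineSegmentSet(
            directions=segs.directions @ R.T,
            radii=segs.radii,
            length=segs.length,
            weights=segs.weights,
        )
        sm_rot = scatter_matrix(rot)
        assert np.allclose(sm_rot.matrix, R @ sm.matrix @ R.T, atol=1e-9)
        assert np.allclose(sm_rot.eigenvalues, sm.eigenvalues, atol=1e-9)
        assert sm_rot.fa == pytest.approx(sm.fa, abs=1e-9)

    def test_fa_increases_with_aligned_fraction(self):
        rng = np.random.default_rng(3)
        iso = rng.standard_normal((400, 3))
        iso /= np.linalg.norm(iso, axis=1, keepdims=True)
        aligned = np.tile([0, 0, 1.0], (400, 1))
        fas = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            n_al = int(400 * frac)
            dirs = np.vstack([aligned[:n_al], iso[n_al:]])
            s = LineSegmentSet.from_radii(dirs, np.ones(400), 10.0)
            fas.append(scatter_matrix(s).fa)
        assert all(b > a for a, b in zip(fas, fas[1:]))


class TestFa:
    @pytest.mark.parametrize(
        "eigs, expected",
        [
            ((1 / 3, 1 / 3, 1 / 3), 0.0),
            ((1.0, 0.0, 0.0), 1.0),
            # direct one-line evaluation: sqrt(1.5*((0.6-1/3)**2+(0.3-1/3)**2+(0.1-1/3)**2)/(0.36+0.09+0.01))
            ((0.6, 0.3, 0.1), 0.6426845869),
        ],
    )
    def test_known_values(self, eigs, expected):
        assert fa_from_eigenvalues(eigs) == pytest.approx(expected, abs=1e-7)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fa_from_eigenvalues((0.0, 0.0, 0.0))


class TestGoldenRegression:
    def test_fixture_morphometry_frozen(self, fixture_trees, goldens):
        for name, tree in fixture_trees.items():
            segs = segments_at(tree, goldens[name]["line_length"])
            sm = scatter_matrix(segs)
            assert len(segs) == goldens[name]["n_segments"], name
            assert np.allclose(sm.eigenvalues, goldens[name]["tau"], atol=1e-9), name
            assert sm.fa == pytest.approx(goldens[name]["fa_t"], abs=1e-9), name


class TestLineLengthSweep:
    def test_straight_cable_is_maximally_anisotropic_at_all_lengths(self, fixture_trees):
        df = line_length_sweep(fixture_trees["single_cable"], lengths=[5, 10, 20], min_segments=1)
        assert np.allclose(df["fa_t"], 1.0, atol=1e-9)

    def test_isotropic_tree_stays_below_monte_carlo_null(self):
        # large isotropic arbor; null threshold from matched-N isotropic draws
        tree = generate_neuron(NeuronGenParams(tropism_strength=0.0, total_length=6000.0, seed=21))
        df = line_length_sweep(tree, lengths=[5, 10, 15, 20, 25], min_segments=1)
        assert (df["fa_t"] < 0.15).all()
        rng = np.random.default_rng(0)
        for _, row in df.iterrows():
            n = int(row["n_segments"])
            null = []
            for _ in range(200):
                u = rng.standard_normal((n, 3))
                u /= np.linalg.norm(u, axis=1, keepdims=True)
                null.append(scatter_matrix(LineSegmentSet.from_radii(u, np.ones(n), row["l"])).fa)
            # the tree's own steps are correlated along branches, so allow
            # headroom over the iid null's upper tail
            assert row["fa_t"] < 3.0 * np.quantile(null, 0.95)

    def test_aligned_tree_fa_weakly_increases_with_length(self):
        tree = generate_neuron(NeuronGenParams(tropism_strength=1.0, total_length=6000.0, seed=22))
        df = line_length_sweep(tree, lengths=[5, 15, 25], min_segments=1)
        assert df["fa_t"].iloc[-1] >= df["fa_t"].iloc[0] - 0.02

    def test_exclusion_flag_below_min_segments(self, fixture_trees):
        df = line_length_sweep(fixture_trees["single_cable"], lengths=[10], min_segments=100)
        assert bool(df["excluded"].iloc[0])


class TestBundleClosure:
    def test_scatter_matches_watson_sample_second_moment(self):
        cfg = WatsonConfig(kappa=5.0, n_cylinders=500, seed=8)
        bundle = generate_bundle(cfg, cable_length=10.0, radius=0.5)
        segs = segments_from_tree(bundle, line_length=10.0)
        assert len(segs) == 500  # one segment per straight cable
        sm = scatter_matrix(segs)
        from neuritemri import sample_watson

        u = sample_watson(cfg)
        T_direct = (u[:, :, None] * u[:, None, :]).mean(axis=0)
        assert np.allclose(sm.matrix, T_direct, atol=1e-6)
        tau_direct = np.sort(np.linalg.eigvalsh(T_direct))[::-1]
        assert np.allclose(sm.eigenvalues, tau_direct, atol=1e-6)
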