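import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camstates.state_clustering import (
    FeatureMatrix,
    adjacency,
    choose_k,
    cluster_states,
    estimate_sigma,
    frame_distance_matrix,
    iiad_featurize,
    kabsch_rmsd,
    random_walk_matrix,
    representative_frame,
    spectral_cluster_distance_matrix,
    spectral_embed,
    spherical_kmeans,
)
from camstates.structure_io import AtomRecord, Ensemble, Topology
from camstates.synthetic_data import SyntheticConfig, generate_ensemble


def _point_ensemble(frames):
    """Frames of bare carbon atoms from an (n_frames, n_atoms, 3) array."""
    frames = np.asarray(frames, dtype=float)
    atoms = [
        AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A")
        for i in range(frames.shape[1])
    ]
    return Ensemble(Topology(atoms), frames)


class TestFeaturize:
    def test_single_pair_inverse_distance(self):
        ens = _point_ensemble([[[0, 0, 0], [2, 0, 0]]])
        f = iiad_featurize(ens, [0, 1])
        assert f.values.shape == (1, 1)
        assert f.values[0, 0] == pytest.approx(0.5)

    def test_canonical_pair_order(self):
        ens = _point_ensemble([[[0, 0, 0], [1, 0, 0], [0, 2, 0]]])
        f = iiad_featurize(ens, [0, 1, 2])
        assert [tuple(p) for p in f.pair_list] == [(0, 1), (0, 2), (1, 2)]

    def test_scaling(self):
        coords = np.random.default_rng(0).normal(size=(3, 5, 3)) * 4.0
        ens = _point_ensemble(coords)
        ens2 = _point_ensemble(coords * 2.0)
        f1 = iiad_featurize(ens, range(5))
        f2 = iiad_featurize(ens2, range(5))
        assert np.allclose(f2.values, f1.values / 2.0)

    def test_pair_stride_subsamples(self):
        coords = np.random.default_rng(0).normal(size=(2, 6, 3)) * 5.0
        ens = _point_ensemble(coords)
        full = iiad_featurize(ens, range(6), pair_stride=1)
        sub = iiad_featurize(ens, range(6), pair_stride=3)
        assert np.allclose(sub.values, full.values[:, ::3])

    def test_coincident_atoms_rejected(self):
        ens = _point_ensemble([[[0, 0, 0], [0, 0, 0]]])
        with pytest.raises(FloatingPointError, match="frame 0"):
            iiad_featurize(ens, [0, 1])


class TestFrameDistances:
    def test_identical_frames_zero(self):
        coords = np.tile(np.random.default_rng(1).normal(size=(1, 4, 3)), (3, 1, 1))
        f = iiad_featurize(_point_ensemble(coords * 3), range(4))
        d = frame_distance_matrix(f)
        assert np.allclose(d.values, 0.0)

    def test_simple_two_frame_distance(self):
        f = FeatureMatrix(
            values=np.array([[0.5], [0.25]]),
            atom_indices=np.array([0, 1]),
            pair_list=np.array([[0, 1]]),
        )
        d = frame_distance_matrix(f)
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.1, 1.0, size=(10, 7))
        f = FeatureMatrix(x, np.arange(4), np.arange(14).reshape(7, 2))
        d = frame_distance_matrix(f, block_size=3).values
        brute = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                brute[i, j] = np.linalg.norm(x[i] - x[j])
        assert np.max(np.abs(d - brute)) < 1e-12

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_metric_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.05, 2.0, size=(6, 5))
        f = FeatureMatrix(x, np.arange(4), np.arange(10).reshape(5, 2))
        d = frame_distance_matrix(f).values
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestSigmaAndKernel:
    def test_sigma_enumeration(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        # nearest-neighbour distances (1, 1, 2) -> mean 4/3
        assert estimate_sigma(d) == pytest.approx(4.0 / 3.0)

    def test_equidistant_frames(self):
        d = np.full((4, 4), 2.5)
        np.fill_diagonal(d, 0.0)
        assert estimate_sigma(d) == pytest.approx(2.5)

    def test_duplicates_only_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="deduplicate"):
            estimate_sigma(d)

    def test_adjacency_closed_forms(self):
        sigma = 1.7
        d = np.array([[0.0, 0.0], [0.0, 0.0]])
        assert adjacency(d, sigma)[0, 1] == pytest.approx(1.0)
        d = np.array([[0.0, sigma * np.sqrt(2.0)], [sigma * np.sqrt(2.0), 0.0]])
        assert adjacency(d, sigma)[0, 1] == pytest.approx(np.exp(-1.0))

    def test_adjacency_matches_direct_evaluation(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        a = adjacency(d, 1.0)
        assert np.allclose(a, np.exp(-(d**2) / 2.0))
        assert np.allclose(np.diag(a), 1.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            adjacency(np.zeros((2, 2)), 0.0)


class TestNormalizedSpectrum:
    def test_hand_two_node_case(self):
        a = np.ones((2, 2))
        lmat, evals, evecs = random_walk_matrix(a)
        assert np.allclose(lmat, 0.5)
        assert np.allclose(evals, [1.0, 0.0], atol=1e-12)

    def test_top_eigenpair_property(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.2, 2.0, size=(8, 8))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        a = adjacency(d, 1.0)
        _, evals, evecs = random_walk_matrix(a)
        assert evals[0] == pytest.approx(1.0, abs=1e-9)
        # eigenvector of eigenvalue 1 is proportional to sqrt(degree)
        deg = np.sqrt(a.sum(axis=1))
        v = evecs[:, 0]
        assert np.allclose(np.abs(v / np.linalg.norm(v)), deg / np.linalg.norm(deg))
        assert np.all(evals >= -1.0 - 1e-9) and np.all(evals <= 1.0 + 1e-9)

    def test_block_diagonal_multiplicity(self):
        block = np.ones((3, 3))
        a = np.zeros((6, 6))
        a[:3, :3] = block
        a[3:, 3:] = block
        _, evals, _ = random_walk_matrix(a)
        assert evals[0] == pytest.approx(1.0, abs=1e-9)
        assert evals[1] == pytest.approx(1.0, abs=1e-9)
        assert evals[2] < 0.99

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.1, 1.5, size=(15, 6))
        f = FeatureMatrix(x, np.arange(4), np.arange(12).reshape(6, 2))
        d = frame_distance_matrix(f).values
        sigma = estimate_sigma(d)
        a = adjacency(d, sigma)
        lmat, evals, _ = random_walk_matrix(a)
        # brute-force dense reference
        a_ref = np.exp(-(d**2) / (2 * sigma**2))
        np.fill_diagonal(a_ref, 1.0)
        deg = np.diag(1.0 / np.sqrt(a_ref.sum(axis=1)))
        l_ref = deg @ a_ref @ deg
        evals_ref = np.sort(np.linalg.eigvalsh(l_ref))[::-1]
        assert np.max(np.abs(a - a_ref)) < 1e-10
        assert np.max(np.abs(lmat - l_ref)) < 1e-10
        assert np.max(np.abs(evals - evals_ref)) < 1e-10

    def test_zero_degree_rejected(self):
        a = np.eye(2) * 0.0
        with pytest.raises(ValueError, match="zero row sum"):
            random_walk_matrix(a)


class TestChooseK:
    def test_stated_eigengap(self):
        lam = [1.0, 0.98, 0.55, 0.50, 0.48]
        assert choose_k(lam, (2, 4)) == 2

    def test_tie_takes_smallest(self):
        lam = [1.0, 0.8, 0.6, 0.4, 0.2, 0.0]
        assert choose_k(lam, (2, 4)) == 2

    def test_three_block_planted(self):
        block = np.ones((4, 4))
        a = np.zeros((12, 12))
        for i in range(3):
            a[4 * i : 4 * i + 4, 4 * i : 4 * i + 4] = block
        a += 1e-3  # weak coupling keeps the graph connected
        _, evals, _ = random_walk_matrix(a)
        assert choose_k(evals, (2, 6)) == 3

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            choose_k([1.0, 0.5, 0.2], (3, 1))


class TestEmbeddingAndKMeans:
    def _two_component_graph(self):
        a = np.zeros((6, 6))
        a[:3, :3] = np.ones((3, 3))
        a[3:, 3:] = np.ones((3, 3))
        return a

    def test_rows_unit_norm(self):
        _, _, evecs = random_walk_matrix(self._two_component_graph() + 1e-4)
        emb = spectral_embed(evecs, 2)
        assert np.allclose(np.linalg.norm(emb, axis=1), 1.0, atol=1e-12)

    def test_two_components_map_to_two_points(self):
        _, _, evecs = random_walk_matrix(self._two_component_graph())
        emb = spectral_embed(evecs, 2)
        # each component collapses to a single point on the circle
        assert np.allclose(emb[:3], emb[0], atol=1e-9)
        assert np.allclose(emb[3:], emb[3], atol=1e-9)
        assert np.linalg.norm(emb[0] - emb[3]) > 1.0

    def test_sign_flip_invariance(self):
        _, _, evecs = random_walk_matrix(self._two_component_graph() + 1e-4)
        emb = spectral_embed(evecs, 2)
        emb_flipped = spectral_embed(evecs * np.array([-1.0, 1.0, -1.0, 1.0, 1.0, 1.0]) [None, :], 2)
        assert np.allclose(emb, emb_flipped)
        l1 = cluster_states(emb, 2, seed=0)
        l2 = cluster_states(emb_flipped, 2, seed=0)
        assert np.array_equal(l1, l2)

    def test_antipodal_sets_perfectly_split(self):
        theta = np.concatenate(
            [np.linspace(-0.1, 0.1, 10), np.pi + np.linspace(-0.1, 0.1, 10)]
        )
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        labels = spherical_kmeans(pts, 2, seed=0)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        labels = spherical_kmeans(pts, 3, seed=2)
        perm = rng.permutation(30)
        labels_p = spherical_kmeans(pts[perm], 3, seed=2)
        # same partition after permutation (labels canonical by first appearance)
        same = labels[perm][:, None] == labels[perm][None, :]
        same_p = labels_p[:, None] == labels_p[None, :]
        assert np.array_equal(same, same_p)


class TestRepresentative:
    def test_identical_frames_tie_smallest_index(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 4, 3)), (5, 1, 1))
        ens = _point_ensemble(coords)
        reps = representative_frame(ens, np.zeros(5, dtype=int), range(4))
        assert reps[0] == 0

    def test_average_structure_selected(self):
        # A and C share an orientation frame (C = 2A), so B = (A+C)/2 is
        # the geometric middle and minimizes the summed pairwise RMSD
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 3)) * 3.0
        c = 2.0 * a
        b = 0.5 * (a + c)
        ens = _point_ensemble(np.stack([a, b, c]))
        reps = representative_frame(ens, np.zeros(3, dtype=int), range(4))
        # exhaustive check of the pairwise-RMSD sums
        frames = [a, b, c]
        totals = [
            sum(kabsch_rmsd(x, y) for y in frames) for x in frames
        ]
        assert int(np.argmin(totals)) == 1
        assert reps[0] == 1

    def test_superposition_invariance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(3, 5, 3)) * 2.0
        ens = _point_ensemble(coords)
        reps = representative_frame(ens, np.zeros(3, dtype=int), range(5))
        # rigidly rotate one frame: selection unchanged
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        coords2 = coords.copy()
        coords2[2] = coords2[2] @ rot.T + 5.0
        reps2 = representative_frame(_point_ensemble(coords2), np.zeros(3, dtype=int), range(5))
        assert reps[0] == reps2[0]

    def test_kabsch_rmsd_zero_for_rotated_copy(self):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(6, 3))
        theta = 1.1
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        assert kabsch_rmsd(p, p @ rot.T + 2.0) < 1e-10


class TestEndToEnd:
    def test_rigid_motion_invariance(self, frozen_config):
        import dataclasses

        cfg = dataclasses.replace(frozen_config, n_frames=8, coord_noise_sd=0.1)
        ens, _ = generate_ensemble(cfg)
        sel = np.flatnonzero(ens.topology.names.astype(str) == "CA")
        d1 = frame_distance_matrix(iiad_featurize(ens, sel)).values
        rng = np.random.default_rng(0)
        coords = ens.coordinates.copy()
        for f in range(coords.shape[0]):
            q = rng.normal(size=(3, 3))
            u, _, vt = np.linalg.svd(q)
            rot = u @ vt
            if np.linalg.det(rot) < 0:
                rot[:, -1] *= -1
            coords[f] = coords[f] @ rot.T + rng.normal(size=3) * 10
        moved = Ensemble(ens.topology, coords)
        d2 = frame_distance_matrix(iiad_featurize(moved, sel)).values
        assert np.max(np.abs(d1 - d2)) < 1e-9

    def test_planted_state_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = SyntheticConfig(n_frames=150, seed=21)
        ens, truth = generate_ensemble(cfg)
        top = ens.topology
        sel = np.flatnonzero(
            (top.residue_seqs <= 40) & (top.names.astype(str) == "CA")
        )
        feats = iiad_featurize(ens, sel)
        d = frame_distance_matrix(feats)
        model = spectral_cluster_distance_matrix(d.values, k=None, k_range=(2, 8), seed=0)
        assert model.k == 4
        assert adjusted_rand_score(truth.frame_state, model.labels) >= 0.9
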