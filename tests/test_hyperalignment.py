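"""Procrustes alignment, searchlight hyperalignment, and projection."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from hyperdecode import hyperalignment, surface, synthetic
from hyperdecode.hyperalignment import (
    compose_to_reference,
    procrustes,
    project_to_reference,
    searchlight_hyperalign,
    zscore_rows,
)
from hyperdecode.surface import Searchlight, make_searchlights


class TestProcrustes:
    def test_self_alignment_is_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 6))
        np.testing.assert_allclose(procrustes(X, X), np.eye(6), atol=1e-10)

    def test_exact_rotation_recovery(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 5))
        Q = ortho_group.rvs(5, random_state=rng)
        R = procrustes(X, X @ Q)
        assert np.linalg.norm(R - Q) < 1e-8

    def test_matches_grid_search_oracle_2d(self):
        # brute-force search over parametrized 2x2 rotations/reflections
        rng = np.random.default_rng(2)
        X = rng.standard_normal((3, 2))
        Y = rng.standard_normal((3, 2))
        best, best_err = None, np.inf
        for theta in np.linspace(0, 2 * np.pi, 20001):
            c, s = np.cos(theta), np.sin(theta)
            for M in (
                np.array([[c, -s], [s, c]]),
                np.array([[c, s], [s, -c]]),  # reflection
            ):
                err = np.linalg.norm(X @ M - Y)
                if err < best_err:
                    best, best_err = M, err
        R = procrustes(X, Y)
        assert np.linalg.norm(X @ R - Y) <= best_err + 1e-6
        assert np.linalg.norm(R - best) < 1e-3

    def test_degenerate_zero_input_warns_identity(self):
        with pytest.warns(UserWarning, match="degenerate"):
            R = procrustes(np.zeros((4, 3)), np.zeros((4, 3)))
        np.testing.assert_array_equal(R, np.eye(3))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            procrustes(np.zeros((4, 3)), np.zeros((5, 3)))


def _disjoint_searchlights(n_nodes, k):
    """Tile nodes into disjoint 'searchlights' (no overlap -> orthogonal
    aggregated maps)."""
    sls = []
    for start in range(0, n_nodes - k + 1, k):
        members = np.arange(start, start + k)
        sls.append(Searchlight(int(members[0]), members, float(k)))
    return sls


class TestSearchlightHyperalign:
    def test_identical_subjects_reproduce_input(self):
        rng = np.random.default_rng(3)
        base = zscore_rows(rng.standard_normal((12, 60)))
        model = searchlight_hyperalign(
            [base.copy() for _ in range(3)], _disjoint_searchlights(12, 4)
        )
        for s in range(3):
            out = model[s].apply(base)
            assert np.linalg.norm(out - base) / np.linalg.norm(base) < 1e-6

    def test_recovers_known_block_rotations(self):
        # subjects are block-rotated copies of a shared series; composing
        # subject maps through the common space must realign them
        rng = np.random.default_rng(4)
        n_nodes, k = 12, 4
        latent = zscore_rows(rng.standard_normal((n_nodes, 120)))
        sls = _disjoint_searchlights(n_nodes, k)
        subjects, rotations = [], []
        for s in range(4):
            blocks = [ortho_group.rvs(k, random_state=rng) for _ in sls]
            W = np.zeros((n_nodes, n_nodes))
            for sl, Q in zip(sls, blocks):
                W[np.ix_(sl.member_nodes, sl.member_nodes)] = Q
            subjects.append(W @ latent)
            rotations.append(W)
        model = searchlight_hyperalign(subjects, sls, n_iterations=3)
        ref = model[0]
        for s in range(1, 4):
            mapped = project_to_reference(subjects[s], model[s], ref)
            target = subjects[0]
            corr = np.corrcoef(mapped.ravel(), target.ravel())[0, 1]
            assert corr > 0.99

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            searchlight_hyperalign(
                [np.zeros((6, 10))], _disjoint_searchlights(6, 3)
            )

    def test_mismatched_node_counts_rejected(self):
        with pytest.raises(ValueError):
            searchlight_hyperalign(
                [np.zeros((6, 10)), np.zeros((7, 10))],
                _disjoint_searchlights(6, 3),
            )

    def test_retraining_on_aligned_data_is_identity(self):
        rng = np.random.default_rng(5)
        n_nodes, k = 12, 4
        sls = _disjoint_searchlights(n_nodes, k)
        latent = zscore_rows(rng.standard_normal((n_nodes, 150)))
        subjects = []
        for s in range(3):
            W = np.zeros((n_nodes, n_nodes))
            for sl in sls:
                W[np.ix_(sl.member_nodes, sl.member_nodes)] = ortho_group.rvs(
                    k, random_state=rng
                )
            subjects.append(
                W @ latent + 0.05 * rng.standard_normal((n_nodes, 150))
            )
        model = searchlight_hyperalign(subjects, sls)
        aligned = [model[s].apply(zscore_rows(subjects[s])) for s in range(3)]
        model2 = searchlight_hyperalign(aligned, sls)
        for s in range(3):
            dense = model2[s].matrix.toarray()
            assert np.linalg.norm(dense - np.eye(n_nodes)) < 0.25

    def test_no_mixing_across_medial_wall(self):
        mesh = surface.two_hemisphere_mesh(subdivisions=1)
        rng = np.random.default_rng(6)
        data = [
            zscore_rows(rng.standard_normal((mesh.n_vertices, 50)))
            for _ in range(2)
        ]
        sls = make_searchlights(mesh, 8.0)
        model = searchlight_hyperalign(data, sls, n_iterations=1)
        masked = np.flatnonzero(mesh.medial_wall)
        for s in range(2):
            dense = np.abs(model[s].matrix.toarray())
            assert dense[masked, :].max() == 0
            assert dense[:, masked].max() == 0


def test_alignment_gain_on_matched_condition_patterns(tiny_fixture):
    """Matched condition patterns correlate near zero across subjects under
    anatomical correspondence and strongly after hyperalignment — the
    mechanism that makes between-subject decoding possible."""
    import itertools

    fx = tiny_fixture
    core = fx.world.regions["core"]
    means = {}
    for mode in ("anat", "hyper"):
        ss = fx.samples[mode]["personal"]
        cors = [
            np.corrcoef(ss.data[a, j][core], ss.data[b, j][core])[0, 1]
            for a, b in itertools.combinations(range(ss.n_subjects), 2)
            for j in range(ss.data.shape[1])
        ]
        means[mode] = float(np.mean(cors))
    assert abs(means["anat"]) < 0.2
    assert means["hyper"] > 0.8


class TestProjection:
    def setup_model(self, seed=7):
        rng = np.random.default_rng(seed)
        n_nodes, k = 8, 4
        sls = _disjoint_searchlights(n_nodes, k)
        latent = zscore_rows(rng.standard_normal((n_nodes, 90)))
        subjects = []
        for s in range(3):
            W = np.zeros((n_nodes, n_nodes))
            for sl in sls:
                W[np.ix_(sl.member_nodes, sl.member_nodes)] = ortho_group.rvs(
                    k, random_state=rng
                )
            subjects.append(W @ latent)
        return searchlight_hyperalign(subjects, sls), n_nodes

    def test_reference_roundtrip_is_identity(self):
        model, n_nodes = self.setup_model()
        rng = np.random.default_rng(8)
        data = rng.standard_normal((n_nodes, 5))
        ref = model[model.reference_subject]
        # disjoint searchlights keep the aggregated map orthogonal
        out = project_to_reference(data, ref, ref)
        np.testing.assert_allclose(out, data, atol=1e-6)

    def test_zero_maps_to_zero(self):
        model, n_nodes = self.setup_model()
        out = project_to_reference(np.zeros((n_nodes, 3)), model[1], model[0])
        assert np.abs(out).max() == 0

    def test_composition_equals_sequential_application(self):
        model, n_nodes = self.setup_model()
        rng = np.random.default_rng(9)
        data = rng.standard_normal((n_nodes, 6))
        combined = project_to_reference(data, model[2], model[0])
        step1 = model[2].apply(data)
        step2 = model[0].matrix.T @ step1
        assert np.abs(combined - step2).max() < 1e-10

    def test_mesh_mismatch_rejected(self):
        model, _ = self.setup_model()
        from scipy.sparse import identity

        bad = hyperalignment.AlignmentMap(0, identity(5, format="csr"), 4.0)
        with pytest.raises(ValueError):
            compose_to_reference(model[1], bad)


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        from scipy.sparse import random as sparse_random

        m = sparse_random(9, 9, density=0.3, random_state=rng, format="csr")
        amap = hyperalignment.AlignmentMap(2, m, 20.0)
        path = tmp_path / "map.tsv"
        hyperalignment.save_alignment_map(amap, path, header={"iterations": 3})
        loaded = hyperalignment.load_alignment_map(path)
        assert loaded.subject == 2
        assert loaded.radius == 20.0
        assert np.abs((loaded.matrix - m).toarray()).max() < 1e-10
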