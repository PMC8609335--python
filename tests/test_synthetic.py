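"""Synthetic world generation: determinism, structure, and noise model."""

import numpy as np
import pytest

from hyperdecode import synthetic
from hyperdecode.glm import HRFSpec
from hyperdecode.pipeline import generate_chained_pair
from hyperdecode.sequence import build_run_designs
from hyperdecode.surface import two_hemisphere_mesh
from hyperdecode.synthetic import (
    NuisanceSpec,
    WorldConfig,
    emit_subject_movie,
    emit_subject_task_runs,
    generate_world,
)


@pytest.fixture(scope="module")
def small_mesh():
    return two_hemisphere_mesh(subdivisions=1)


def small_config(**kw):
    defaults = dict(n_subjects=3, n_runs=1, movie_length=80, seed=0)
    defaults.update(kw)
    return WorldConfig(**defaults)


class TestGenerateWorld:
    def test_same_seed_identical_worlds(self, small_mesh):
        w1 = generate_world(small_config(), small_mesh)
        w2 = generate_world(small_config(), small_mesh)
        np.testing.assert_array_equal(
            w1.condition_patterns, w2.condition_patterns
        )
        np.testing.assert_array_equal(w1.movie_latents, w2.movie_latents)
        for m1, m2 in zip(w1.mixings, w2.mixings):
            assert (m1 != m2).nnz == 0

    def test_zero_snr_gives_pure_noise_patterns(self, small_mesh):
        w = generate_world(
            small_config(snr_core=0.0, snr_extended=0.0), small_mesh
        )
        assert np.abs(w.condition_patterns).max() == 0.0

    def test_identity_component_structure(self, small_mesh):
        w = generate_world(small_config(), small_mesh)
        meta = w.condition_meta
        # view-invariance: identity component identical across views
        for fam in ["personal", "visual"]:
            for i in range(4):
                cols = meta.index[
                    (meta["familiarity"] == fam) & (meta["identity"] == i)
                ]
                ref = w.identity_component[:, cols[0]]
                for c in cols[1:]:
                    np.testing.assert_array_equal(
                        w.identity_component[:, c], ref
                    )
        # exactly 4 distinct identity vectors per familiarity
        pers = meta.index[meta["familiarity"] == "personal"]
        uniq = {tuple(w.identity_component[:, c]) for c in pers}
        assert len(uniq) == 4

    def test_region_information_layout(self, small_mesh):
        w = generate_world(small_config(), small_mesh)
        core, ext, null = (
            w.regions["core"], w.regions["extended"], w.regions["null"]
        )
        meta = w.condition_meta
        pers = meta.index[meta["familiarity"] == "personal"]
        vis = meta.index[meta["familiarity"] == "visual"]
        id_comp = w.identity_component
        assert np.abs(id_comp[core][:, pers]).max() > 0
        assert np.abs(id_comp[core][:, vis]).max() > 0
        assert np.abs(id_comp[ext][:, pers]).max() > 0
        assert np.abs(id_comp[ext][:, vis]).max() == 0  # visual: core only
        assert np.abs(w.condition_patterns[null]).max() == 0

    def test_patterns_decompose_into_components(self, small_mesh):
        w = generate_world(small_config(), small_mesh)
        np.testing.assert_allclose(
            w.condition_patterns,
            w.identity_component + w.view_component + w.familiarity_component,
            atol=1e-12,
        )

    def test_mixing_blocks_are_orthogonal(self, small_mesh):
        w = generate_world(small_config(), small_mesh)
        for s in range(w.config.n_subjects):
            M = w.mixings[s].toarray()
            np.testing.assert_allclose(M @ M.T, np.eye(M.shape[0]), atol=1e-9)

    def test_invalid_configs_rejected(self, small_mesh):
        with pytest.raises(ValueError):
            WorldConfig(n_subjects=1)
        with pytest.raises(ValueError):
            WorldConfig(snr_core=-1.0)
        with pytest.raises(ValueError):
            WorldConfig(
                region_partition={"core": [1, 2], "extended": [2, 3]}
            )
        with pytest.raises(ValueError):
            generate_world(
                small_config(
                    region_partition={"core": [], "extended": []}
                ),
                small_mesh,
            )


class TestEmitMovie:
    def test_shape_and_determinism(self, small_mesh):
        w = generate_world(small_config(), small_mesh)
        m1 = emit_subject_movie(w, 0)
        m2 = emit_subject_movie(w, 0)
        assert m1.shape == (small_mesh.n_vertices, 80)
        np.testing.assert_array_equal(m1, m2)
        assert not np.array_equal(m1, emit_subject_movie(w, 1))

    def test_columns_not_constant(self, small_mesh):
        w = generate_world(small_config(), small_mesh)
        movie = emit_subject_movie(w, 0)
        assert np.all(movie.std(axis=1) > 0)

    def test_noiseless_identity_mixing_recovers_latents(self, small_mesh):
        import scipy.sparse as sp

        w = generate_world(small_config(movie_snr=1.0), small_mesh)
        w.mixings[0] = sp.identity(small_mesh.n_vertices, format="csr")
        movie = emit_subject_movie(w, 0)
        noise = movie - w.movie_latents
        # residual is the unit-variance sensor noise, uncorrelated with signal
        cortex = small_mesh.cortex_vertices
        corr = np.corrcoef(
            noise[cortex].ravel(), w.movie_latents[cortex].ravel()
        )[0, 1]
        assert abs(corr) < 0.02
        assert noise.std() == pytest.approx(1.0, rel=0.05)

    def test_between_subject_anatomical_correlation_near_zero(self, small_mesh):
        w = generate_world(
            small_config(movie_length=200, movie_snr=5.0), small_mesh
        )
        m0 = emit_subject_movie(w, 0)
        m1 = emit_subject_movie(w, 1)
        cortex = small_mesh.cortex_vertices
        corrs = [
            np.corrcoef(m0[v], m1[v])[0, 1] for v in cortex
        ]
        assert abs(np.mean(corrs)) < 0.05

    def test_out_of_range_subject(self, small_mesh):
        w = generate_world(small_config(), small_mesh)
        with pytest.raises(ValueError):
            emit_subject_movie(w, 99)


@pytest.fixture(scope="module")
def runs_setup(small_mesh):
    w = generate_world(small_config(n_runs=1), small_mesh)
    a, b = generate_chained_pair(21, seed=5)
    designs = build_run_designs(a, b, n_runs=2, trials_per_run=63)
    return w, designs


class TestEmitTaskRuns:

    def test_run_shapes_and_nuisance_columns(self, runs_setup):
        w, designs = runs_setup
        runs, tables, responses = emit_subject_task_runs(
            w, 0, designs, ["personal", "visual"]
        )
        assert len(runs) == 2
        n_scans = designs[0].n_scans(1.25)
        # 15 s lead-in + 64 trials x 5 s + 15 s lead-out at TR 1.25
        assert n_scans == 280
        assert runs[0].shape == (w.mesh.n_vertices, n_scans)
        for table in tables.values():
            assert table.shape[1] == 12  # 6 motion-like + 6 physio-like

    def test_determinism(self, runs_setup):
        w, designs = runs_setup
        r1, _, _ = emit_subject_task_runs(w, 1, designs, ["personal", "visual"])
        r2, _, _ = emit_subject_task_runs(w, 1, designs, ["personal", "visual"])
        np.testing.assert_array_equal(r1[0], r2[0])

    def test_single_event_noiseless_is_scaled_hrf(self, small_mesh):
        from hyperdecode.sequence import RunDesign, Trial, TrialTiming

        w = generate_world(small_config(), small_mesh)
        timing = TrialTiming()
        design = RunDesign(
            0,
            [Trial(0, 15.0, 5.0, False, False)],
            21,
            timing,
        )
        quiet = NuisanceSpec(motion_amp=0.0, physio_amp=0.0, drift_amp=0.0)
        runs, _, _ = emit_subject_task_runs(
            w, 0, [design], ["personal"], nuisance=quiet
        )
        hrf = HRFSpec()
        n_scans = design.n_scans(1.25)
        reg = hrf.regressor([15.0], [hrf.duration], [1.0], n_scans, 1.25)
        pat = w.subject_patterns(0)[:, 0]
        expected = np.outer(pat, reg)
        # correlation between emitted signal (noise included) and expected
        # shape is high on the strongest-responding node
        node = int(np.argmax(np.abs(pat)))
        emitted = runs[0][node]
        assert abs(np.corrcoef(emitted, expected[node])[0, 1]) > 0.8

    def test_invalid_tr_rejected(self, runs_setup):
        w, designs = runs_setup
        with pytest.raises(ValueError):
            emit_subject_task_runs(w, 0, designs, ["personal", "visual"],
                                   tr=0.0)

    def test_responses_mark_identity_repeats(self, runs_setup):
        w, designs = runs_setup
        _, _, responses = emit_subject_task_runs(
            w, 0, designs, ["personal", "visual"]
        )
        labels = [t for t in designs[0].trials]
        onset_by_time = {t.onset: t for t in labels}
        for onset in responses[0]:
            trial = onset_by_time[onset - 1.0]
            assert not trial.is_null

    def test_run_export(self, runs_setup, tmp_path):
        w, designs = runs_setup
        runs, tables, _ = emit_subject_task_runs(
            w, 0, designs[:1], ["personal"]
        )
        synthetic.write_run(
            tmp_path / "run-00", runs[0], tables[0], 1.25, 0, w.config
        )
        assert (tmp_path / "run-00_bold.tsv").exists()
        assert (tmp_path / "run-00_confounds.tsv").exists()
        assert (tmp_path / "run-00.json").exists()
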