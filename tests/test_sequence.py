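"""T1I1 sequence generation, validation, efficiency and run partitioning."""

import itertools

import numpy as np
import pytest

from hyperdecode import glm, sequence
from hyperdecode.sequence import (
    RankDeficientDesignError,
    RelationshipMatrix,
    TrialSequence,
    TrialTiming,
    build_run_designs,
    generate_t1i1,
    has_block_property,
    is_t1i1,
    select_top_sequences,
    sequence_efficiency,
    stimulus_relationships,
)


def enumerate_t1i1(n: int):
    """Exhaustive independent enumerator of all valid T1I1 sequences."""
    found = []

    def extend(seq, used):
        if len(seq) == n * n + 1:
            if seq[0] == seq[-1]:
                found.append(tuple(seq))
            return
        for c in range(n):
            if (seq[-1], c) not in used:
                extend(seq + [c], used | {(seq[-1], c)})

    for s0 in range(n):
        extend([s0], set())
    # the full-length walk uses every pair exactly once by construction
    return {s for s in found}


class TestGenerate:
    def test_21_labels_full_invariants(self):
        seq = generate_t1i1(21, seed=0)
        assert len(seq) == 21**2 + 1 == 442
        ok, report = is_t1i1(seq)
        assert ok, report
        assert has_block_property(seq)

    def test_two_labels_pairs_exhaustive(self):
        seq = generate_t1i1(2, seed=1)
        assert len(seq) == 5
        pairs = set(zip(seq.labels[:-1], seq.labels[1:]))
        assert pairs == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_reversal_preserves_validity(self):
        for seed in range(5):
            seq = generate_t1i1(21, seed=seed)
            assert is_t1i1(seq.reversed())[0]

    def test_determinism_and_seed_variation(self):
        a = generate_t1i1(21, seed=7)
        b = generate_t1i1(21, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        c = generate_t1i1(21, seed=8)
        assert not np.array_equal(a.labels, c.labels)

    def test_small_alphabet_rejected(self):
        with pytest.raises(ValueError):
            generate_t1i1(1)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_small_n_outputs_certified_by_enumerator(self, n):
        valid = enumerate_t1i1(n)
        assert valid  # the enumerator itself finds solutions
        rng = np.random.default_rng(0)
        import warnings

        for _ in range(5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                seq = generate_t1i1(n, rng)
            assert tuple(int(x) for x in seq.labels) in valid

    def test_block_property_holds_for_21_label_concatenations(self):
        from hyperdecode.pipeline import generate_chained_pair

        a, b = generate_chained_pair(21, seed=3)
        concat = np.concatenate([a.labels, b.labels[1:]])
        windows = concat[: (len(concat) // 21) * 21].reshape(-1, 21)
        for w in windows:
            assert len(np.unique(w)) == 21


class TestValidator:
    def test_constant_sequence_reported(self):
        seq = TrialSequence(np.zeros(5, dtype=int), 2)
        ok, report = is_t1i1(seq)
        assert not ok
        assert (0, 1) in report["missing_pairs"]
        assert (1, 0) in report["missing_pairs"]
        assert (1, 1) in report["missing_pairs"]

    def test_deletion_breaks_length(self):
        seq = generate_t1i1(3, seed=0, block_balanced=False)
        truncated = TrialSequence(seq.labels[:-1], 3)
        ok, report = is_t1i1(truncated)
        assert not ok
        assert not report["length_ok"] or not report["endpoints_ok"]


class TestEfficiency:
    def small_rels(self, n=3):
        return [RelationshipMatrix("same", np.eye(n))]

    def test_reverse_has_equal_efficiency_for_symmetric_relations(self):
        seq = generate_t1i1(3, seed=2, block_balanced=False)
        rels = self.small_rels()
        e1 = sequence_efficiency(seq, rels)
        e2 = sequence_efficiency(seq.reversed(), rels)
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_all_ones_relation_flags_rank_deficiency(self):
        seq = generate_t1i1(3, seed=0, block_balanced=False)
        rels = [RelationshipMatrix("ones", np.ones((3, 3)))]
        with pytest.raises(RankDeficientDesignError):
            sequence_efficiency(seq, rels)

    def test_hrf_amplitude_scales_efficiency_quadratically(self):
        seq = generate_t1i1(3, seed=4, block_balanced=False)
        rels = self.small_rels()
        base = glm.HRFSpec()
        e1 = sequence_efficiency(seq, rels, base)

        # doubling the response amplitude doubles the regressors
        class Doubled(glm.HRFSpec):
            def kernel(self, dt):
                return 2.0 * super().kernel(dt)

        e2 = sequence_efficiency(seq, rels, Doubled())
        assert e2 == pytest.approx(4.0 * e1, rel=1e-6)

    def test_mismatched_matrix_size_rejected(self):
        seq = generate_t1i1(3, seed=0, block_balanced=False)
        with pytest.raises(ValueError):
            sequence_efficiency(seq, [RelationshipMatrix("big", np.eye(5))])

    def test_select_top_matches_full_sort(self):
        rng = np.random.default_rng(0)
        candidates = [generate_t1i1(3, rng, block_balanced=False)
                      for _ in range(6)]
        rels = self.small_rels()
        scores = [sequence_efficiency(s, rels) for s in candidates]
        order = np.argsort(-np.asarray(scores), kind="stable")
        top = select_top_sequences(candidates, rels, k=3)
        for got, idx in zip(top, order[:3]):
            np.testing.assert_array_equal(got.labels, candidates[idx].labels)

    def test_duplicate_best_candidate_kept_together(self):
        rng = np.random.default_rng(1)
        cands = [generate_t1i1(3, rng, block_balanced=False) for _ in range(3)]
        rels = self.small_rels()
        scores = [sequence_efficiency(s, rels) for s in cands]
        best = cands[int(np.argmax(scores))]
        dup = [best, TrialSequence(best.labels.copy(), 3)] + [
            c for c in cands if c is not best
        ]
        top = select_top_sequences(dup, rels, k=2)
        np.testing.assert_array_equal(top[0].labels, best.labels)
        np.testing.assert_array_equal(top[1].labels, best.labels)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_top_sequences([], self.small_rels(), k=1)


class TestRelationships:
    def test_standard_layout_shapes_and_symmetry(self):
        rels = stimulus_relationships()
        assert [r.name for r in rels] == [
            "identity", "head_view", "mirror_symmetry"]
        for r in rels:
            assert r.values.shape == (21, 21)
            np.testing.assert_array_equal(r.values, r.values.T)
            assert np.all(np.diag(r.values) == 1)

    def test_identity_relation_groups_views(self):
        ident = stimulus_relationships()[0].values
        assert ident[0, 4] == 1  # same identity, different view
        assert ident[0, 5] == 0  # different identity
        assert ident[0, 20] == 0  # null unrelated


class TestRunDesigns:
    def test_default_partition_counts(self):
        from hyperdecode.pipeline import generate_chained_pair

        a, b = generate_chained_pair(21, seed=0)
        runs = build_run_designs(a, b)
        assert len(runs) == 10
        for run in runs:
            body = [t for t in run.trials if not t.is_lead]
            assert len(body) == 63
            counts = np.bincount([t.label for t in body], minlength=21)
            assert np.all(counts == 3)  # every image 3x, null 3x
            assert sum(t.is_null for t in body) == 3

    def test_lead_trial_rule(self):
        from hyperdecode.pipeline import generate_chained_pair

        a, b = generate_chained_pair(21, seed=2)
        runs = build_run_designs(a, b)
        assert runs[0].trials[0].is_lead
        assert runs[0].trials[0].label == runs[0].trials[1].label
        for prev, run in zip(runs, runs[1:]):
            assert run.trials[0].label == prev.trials[-1].label

    def test_single_run_reproduces_concatenation(self):
        a = generate_t1i1(4, seed=0, block_balanced=False)
        rng = np.random.default_rng(1)
        while True:
            b = generate_t1i1(4, rng, block_balanced=False)
            if b.labels[0] == a.labels[-1]:
                break
        concat = np.concatenate([a.labels, b.labels[1:]])
        runs = build_run_designs(a, b, n_runs=1, trials_per_run=len(concat))
        body = [t.label for t in runs[0].trials if not t.is_lead]
        np.testing.assert_array_equal(body, concat)

    def test_mismatched_chain_rejected(self):
        a = generate_t1i1(4, seed=0, block_balanced=False)
        b = generate_t1i1(4, seed=1, block_balanced=False)
        if b.labels[0] == a.labels[-1]:
            b = TrialSequence(np.roll(b.labels, 1), 4)
        with pytest.raises(ValueError):
            build_run_designs(a, b)

    def test_onsets_and_durations(self):
        from hyperdecode.pipeline import generate_chained_pair

        a, b = generate_chained_pair(21, seed=1)
        run = build_run_designs(a, b)[0]
        onsets = np.array([t.onset for t in run.trials])
        assert np.all(np.diff(onsets) > 0)
        assert onsets[0] == 15.0  # lead-in fixation
        assert np.allclose(np.diff(onsets), 5.0)
        assert run.duration == 15.0 + 64 * 5.0 + 15.0

    def test_trial_micro_timing_consistency(self):
        timing = TrialTiming()
        assert timing.stimulus_duration == pytest.approx(1.6)
        with pytest.raises(ValueError):
            TrialTiming(fixation=3.0)

    def test_events_table_roundtrip(self, tmp_path):
        from hyperdecode.pipeline import generate_chained_pair

        a, b = generate_chained_pair(21, seed=1)
        run = build_run_designs(a, b)[0]
        path = tmp_path / "events.tsv"
        sequence.write_events_tsv(run, path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == [
            "onset", "duration", "trial_type", "is_null", "is_lead"]
        assert len(df) == 64
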