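"""Carry-over counterbalanced (Type-1 Index-1) trial sequences and run designs.

A T1I1 sequence over ``n`` labels is a serially balanced sequence of length
``n**2 + 1`` whose first and last elements coincide and in which every
ordered pair of labels — including repeats — occurs exactly once as adjacent
elements.  Equivalently, it is an Eulerian circuit of the complete directed
graph with self-loops on ``n`` vertices.  Presenting stimuli in such an
order balances first-order carry-over effects: every condition precedes
every condition (itself included) exactly once.

The sequences generated here carry one further structural property: every
aligned ``n``-trial block is a permutation of the labels, with the ``n``
self-pairs falling exactly on the block boundaries.  This is what makes the
run partition clean — 63-trial runs built from a 21-label design contain
each stimulus image exactly three times and exactly three null trials.  The
bare Eulerian property does not imply it (``AABBA`` is a valid 2-label T1I1
sequence whose first block ``AA`` misses a label), so the generator searches
specifically for block-balanced circuits with a randomized backtracking
search.  Block-balanced sequences do not exist for very small alphabets
(there are none for 3 labels); in that case the generator falls back to a
plain Eulerian circuit with a warning.

Experiment layout convention: with 21 labels, labels ``0..19`` are stimulus
images (identity ``label // 5``, head view ``label % 5``) and label ``20``
(the last label) is the null/fixation trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .glm import HRFSpec

#: search outcome codes for the jitted backtracking search
_FOUND, _EXHAUSTED, _CAPPED = 0, 1, 2


class RankDeficientDesignError(ValueError):
    """Raised when an efficiency design is rank-deficient."""


@dataclass(frozen=True)
class TrialSequence:
    """Ordered label sequence over an alphabet of ``n_labels``."""

    labels: np.ndarray
    n_labels: int

    def __post_init__(self):
        object.__setattr__(
            self, "labels", np.asarray(self.labels, dtype=np.int64)
        )

    def __len__(self) -> int:
        return len(self.labels)

    def reversed(self) -> "TrialSequence":
        """The inverted sequence; inversion preserves the T1I1 property."""
        return TrialSequence(self.labels[::-1].copy(), self.n_labels)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric binary relation between labels, used for efficiency scoring."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.array_equal(v, v.T):
            raise ValueError("relationship matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n_labels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TrialTiming:
    """Micro-timing of one stimulus trial and of the run lead-in/lead-out.

    A 5 s trial holds three 500 ms presentations of the same image separated
    by 50 ms gaps (1.6 s of stimulation, which is also the boxcar duration
    used for HRF convolution) followed by 3.4 s of fixation.
    """

    trial_duration: float = 5.0
    presentation: float = 0.5
    gap: float = 0.05
    n_presentations: int = 3
    fixation: float = 3.4
    lead_in: float = 15.0
    lead_out: float = 15.0

    @property
    def stimulus_duration(self) -> float:
        """Active stimulation time within a trial (boxcar for the HRF)."""
        return (
            self.n_presentations * self.presentation
            + (self.n_presentations - 1) * self.gap
        )

    def __post_init__(self):
        active = self.stimulus_duration + self.fixation
        if abs(active - self.trial_duration) > 1e-9:
            raise ValueError(
                f"micro-timing sums to {active} s, not {self.trial_duration} s"
            )


@dataclass(frozen=True)
class Trial:
    label: int
    onset: float
    duration: float
    is_null: bool
    is_lead: bool


@dataclass
class RunDesign:
    """One run: an ordered list of timed trials plus the extra lead trial."""

    run_index: int
    trials: list
    n_labels: int
    timing: TrialTiming = field(default_factory=TrialTiming)

    @property
    def stimulus_trials(self) -> list:
        return [t for t in self.trials if not (t.is_null or t.is_lead)]

    @property
    def duration(self) -> float:
        last = self.trials[-1]
        return last.onset + last.duration + self.timing.lead_out

    def n_scans(self, tr: float) -> int:
        return int(np.ceil(self.duration / tr - 1e-9))


# ---------------------------------------------------------------------------
# generation


@njit(cache=True)
def _search_t1i1(n, seed, block_balanced, max_steps):  # pragma: no cover
    """Randomized DFS for an Eulerian circuit of K_n* with self-loops.

    With ``block_balanced`` the walk is additionally constrained so that
    every aligned n-element window is a permutation (self-pairs exactly on
    the boundaries, each vertex ending exactly one block, the last block
    ending at the start vertex).
    """
    np.random.seed(seed)
    L = n * n
    seq = np.zeros(L + 1, np.int64)
    used = np.zeros((n, n), np.bool_)
    ends_used = np.zeros(n, np.bool_)
    in_block = np.zeros(n, np.bool_)
    cand = np.zeros((L + 1, n), np.int64)
    cand_cnt = np.zeros(L + 1, np.int64)
    s0 = np.random.randint(0, n)
    seq[0] = s0
    in_block[s0] = True

    pos = 1
    # fill candidates for position pos
    steps = 0
    filling = True
    while True:
        if filling:
            prev = seq[pos - 1]
            cnt = 0
            if pos == L:
                if not used[prev, prev] and (not block_balanced or prev == s0):
                    cand[pos, 0] = prev
                    cnt = 1
            elif block_balanced:
                bpos = pos % n
                if bpos == 0:
                    if not used[prev, prev]:
                        cand[pos, 0] = prev
                        cnt = 1
                else:
                    last_block = pos // n == n - 1
                    for c in range(n):
                        if in_block[c] or used[prev, c]:
                            continue
                        if bpos == n - 1:
                            if last_block:
                                if c != s0:
                                    continue
                            elif ends_used[c] or c == s0:
                                continue
                        cand[pos, cnt] = c
                        cnt += 1
            else:
                for c in range(n):
                    if not used[prev, c]:
                        cand[pos, cnt] = c
                        cnt += 1
            # Fisher-Yates shuffle
            for i in range(cnt - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                tmp = cand[pos, i]
                cand[pos, i] = cand[pos, j]
                cand[pos, j] = tmp
            cand_cnt[pos] = cnt
            filling = False

        steps += 1
        if steps > max_steps:
            return _CAPPED, seq[:0]

        if cand_cnt[pos] > 0:
            cand_cnt[pos] -= 1
            c = cand[pos, cand_cnt[pos]]
            prev = seq[pos - 1]
            used[prev, c] = True
            seq[pos] = c
            if block_balanced and pos < L:
                bpos = pos % n
                if bpos == 0:
                    for t in range(n):
                        in_block[t] = False
                in_block[c] = True
                if bpos == n - 1:
                    ends_used[c] = True
            if pos == L:
                return _FOUND, seq
            pos += 1
            filling = True
        else:
            pos -= 1
            if pos == 0:
                return _EXHAUSTED, seq[:0]
            c = seq[pos]
            prev = seq[pos - 1]
            used[prev, c] = False
            if block_balanced and pos < L:
                bpos = pos % n
                if bpos == n - 1:
                    ends_used[c] = False
                if bpos == 0:
                    for t in range(n):
                        in_block[t] = False
                    for t in range(pos - n, pos):
                        in_block[seq[t]] = True
                else:
                    in_block[c] = False


def generate_t1i1(
    n_labels: int,
    seed=None,
    block_balanced: str | bool = "auto",
    max_steps: int = 5_000_000,
    max_restarts: int = 20,
) -> TrialSequence:
    """Generate a random T1I1 sequence over ``n_labels`` labels.

    Parameters
    ----------
    n_labels : int
        Alphabet size (>= 2). 21 for the standard 20-condition + null layout.
    seed : int, Generator or None
        Randomness source; fixed seeds give reproducible sequences.
    block_balanced : "auto", True or False
        Require every aligned n-trial block to be a permutation of the
        labels.  "auto" tries the balanced search and falls back to a plain
        Eulerian circuit (with a warning) when no balanced sequence exists.
    """
    if n_labels < 2:
        raise ValueError("n_labels must be >= 2")
    rng = np.random.default_rng(seed)
    want_blocks = block_balanced in (True, "auto")
    for mode in ([True, False] if block_balanced == "auto" else [bool(want_blocks)]):
        for _ in range(max_restarts):
            child = int(rng.integers(0, 2**31 - 1))
            status, seq = _search_t1i1(n_labels, child, mode, max_steps)
            if status == _FOUND:
                return TrialSequence(seq, n_labels)
            if status == _EXHAUSTED:
                break  # no circuit for this mode (s0 is immaterial by symmetry)
        if mode and block_balanced == "auto":
            warnings.warn(
                f"no block-balanced T1I1 sequence found for {n_labels} labels; "
                "falling back to a plain Eulerian circuit"
            )
    raise RuntimeError(
        f"T1I1 search failed for n_labels={n_labels} "
        f"(step cap {max_steps}, {max_restarts} restarts)"
    )


def is_t1i1(seq: TrialSequence) -> tuple[bool, dict]:
    """Validate the T1I1 invariants; returns (ok, violation report).

    The report lists the violated length/endpoint conditions and any
    missing or duplicated ordered label pairs.
    """
    labels = np.asarray(seq.labels)
    n = seq.n_labels
    report = {"length_ok": len(labels) == n * n + 1, "missing_pairs": [],
              "duplicate_pairs": []}
    report["endpoints_ok"] = len(labels) > 0 and labels[0] == labels[-1]
    counts = np.zeros((n, n), dtype=int)
    for a, b in zip(labels[:-1], labels[1:]):
        counts[a, b] += 1
    for a in range(n):
        for b in range(n):
            if counts[a, b] == 0:
                report["missing_pairs"].append((a, b))
            elif counts[a, b] > 1:
                report["duplicate_pairs"].append((a, b))
    ok = (
        report["length_ok"]
        and report["endpoints_ok"]
        and not report["missing_pairs"]
        and not report["duplicate_pairs"]
    )
    return ok, report


def has_block_property(seq: TrialSequence) -> bool:
    """True if every aligned n-trial window of the first n^2 trials is a
    permutation of the labels."""
    n = seq.n_labels
    labels = seq.labels[: n * n]
    if len(labels) < n * n:
        return False
    blocks = labels.reshape(n, n)
    return all(len(np.unique(b)) == n for b in blocks)


# ---------------------------------------------------------------------------
# stimulus relationship matrices (21-label layout)


def stimulus_relationships(
    n_identities: int = 4, n_views: int = 5, mirror_pairs=((0, 4), (1, 3))
) -> list:
    """Identity, head-view and mirror-symmetry relations for the standard
    layout (labels = identity * n_views + view, last label = null).

    Views are ordered left profile, left 3/4, frontal, right 3/4, right
    profile, so the mirror-symmetric view pairs are (0, 4) and (1, 3).
    """
    n = n_identities * n_views + 1
    ident = np.eye(n)
    view = np.eye(n)
    mirror = np.eye(n)
    mirror_set = {frozenset(p) for p in mirror_pairs}
    for a in range(n - 1):
        ia, va = divmod(a, n_views)
        for b in range(n - 1):
            ib, vb = divmod(b, n_views)
            if ia == ib:
                ident[a, b] = 1
            if va == vb:
                view[a, b] = 1
            if frozenset((va, vb)) in mirror_set:
                mirror[a, b] = 1
    return [
        RelationshipMatrix("identity", ident),
        RelationshipMatrix("head_view", view),
        RelationshipMatrix("mirror_symmetry", mirror),
    ]


# ---------------------------------------------------------------------------
# efficiency scoring


def sequence_efficiency(
    seq: TrialSequence,
    rels: list,
    hrf: HRFSpec = None,
    tr: float = 1.25,
    trial_duration: float = 5.0,
) -> float:
    """Detection-power efficiency of a sequence for carry-over regressors.

    For each relationship matrix, a parametric regressor takes at trial
    ``t`` the relation between the labels at ``t - 1`` and ``t``
    (mean-centered across trials, so a constant relation yields a null
    regressor), is convolved with the HRF at TR resolution over the full
    response support, and entered into a design with an intercept.  The
    score is the inverse of the summed estimator variances of the
    relationship regressors, ``1 / trace((X'X)^-1)`` restricted to those
    columns.  Deterministic; raises :class:`RankDeficientDesignError` on
    degenerate or collinear designs.
    """
    if hrf is None:
        hrf = HRFSpec()
    labels = seq.labels
    # cover the full HRF tail so time-reversal symmetry is exact
    n_scans = int(np.ceil((len(labels) * trial_duration + hrf.length) / tr))
    onsets = np.arange(len(labels)) * trial_duration
    cols = []
    for rel in rels:
        if rel.n_labels != seq.n_labels:
            raise ValueError(
                f"relationship matrix {rel.name!r} is {rel.n_labels}-label, "
                f"sequence is {seq.n_labels}-label"
            )
        amps = np.zeros(len(labels))
        amps[1:] = rel.values[labels[:-1], labels[1:]]
        amps[1:] -= amps[1:].mean()
        col = hrf.regressor(onsets, np.full(len(labels), hrf.duration), amps,
                            n_scans, tr)
        if np.linalg.norm(col) < 1e-10:
            raise RankDeficientDesignError(
                f"relationship {rel.name!r} is constant across the sequence "
                "(null regressor after centering)"
            )
        cols.append(col)
    X = np.column_stack([np.ones(n_scans)] + cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError(
            "efficiency design is rank-deficient (collinear relationship "
            "regressors)"
        )
    xtx_inv = np.linalg.inv(X.T @ X)
    return 1.0 / np.trace(xtx_inv[1:, 1:])


def select_top_sequences(
    candidates: list,
    rels: list,
    hrf: HRFSpec = None,
    tr: float = 1.25,
    k: int = 2,
    trial_duration: float = 5.0,
) -> list:
    """The ``k`` candidates with the highest efficiency (stable on ties)."""
    if not candidates:
        raise ValueError("no candidate sequences")
    if k > len(candidates):
        raise ValueError("k exceeds the number of candidates")
    scores = np.array(
        [sequence_efficiency(s, rels, hrf, tr, trial_duration) for s in candidates]
    )
    order = np.argsort(-scores, kind="stable")
    return [candidates[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# run partitioning


def build_run_designs(
    seq_a: TrialSequence,
    seq_b: TrialSequence,
    n_runs: int = 10,
    trials_per_run: int = 63,
    timing: TrialTiming = None,
    null_label: int = None,
) -> list:
    """Partition two chained T1I1 sequences into timed runs.

    ``seq_b`` must start with ``seq_a``'s final label; the concatenation
    drops that duplicated element, which keeps the aligned block structure
    intact.  The first ``n_runs * trials_per_run`` trials are split in
    order.  Each run is prepended with an extra lead trial — the run's own
    first label for run 0, the previous run's last label afterwards — which
    is excluded from ``trials_per_run``.
    """
    if seq_a.n_labels != seq_b.n_labels:
        raise ValueError("sequences must share an alphabet")
    if seq_b.labels[0] != seq_a.labels[-1]:
        raise ValueError(
            "the second sequence must start with the first sequence's final label"
        )
    concat = np.concatenate([seq_a.labels, seq_b.labels[1:]])
    return build_run_designs_from_labels(
        concat, seq_a.n_labels, n_runs, trials_per_run, timing, null_label
    )


def invert_concatenation(concat: np.ndarray) -> np.ndarray:
    """Trial stream for counterbalanced participants: the reversed stream.

    Reversal preserves the carry-over balance (an inverted serially balanced
    sequence is serially balanced); dropping the leading duplicate element
    restores the aligned block structure, so run partitions keep each label
    appearing equally often per run.
    """
    rev = np.asarray(concat)[::-1]
    if len(rev) > 1 and rev[0] == rev[1]:
        rev = rev[1:]
    return rev.copy()


def build_run_designs_from_labels(
    concat: np.ndarray,
    n_labels: int,
    n_runs: int = 10,
    trials_per_run: int = 63,
    timing: TrialTiming = None,
    null_label: int = None,
) -> list:
    """Split an already-concatenated label stream into timed runs."""
    if timing is None:
        timing = TrialTiming()
    concat = np.asarray(concat)
    if n_runs * trials_per_run > len(concat):
        raise ValueError(
            f"{n_runs} runs x {trials_per_run} trials exceed the "
            f"{len(concat)}-trial concatenation"
        )
    if null_label is None:
        null_label = n_labels - 1
    runs = []
    for r in range(n_runs):
        chunk = concat[r * trials_per_run : (r + 1) * trials_per_run]
        lead = chunk[0] if r == 0 else runs[-1].trials[-1].label
        trials = [
            Trial(int(lead), timing.lead_in, timing.trial_duration,
                  bool(lead == null_label), True)
        ]
        for i, lab in enumerate(chunk):
            onset = timing.lead_in + (i + 1) * timing.trial_duration
            trials.append(
                Trial(int(lab), onset, timing.trial_duration,
                      bool(lab == null_label), False)
            )
        runs.append(RunDesign(r, trials, n_labels, timing))
    return runs


def invert_run_label_order(seq: TrialSequence) -> TrialSequence:
    """Per-participant counterbalancing: the reversed sequence (still T1I1)."""
    return seq.reversed()


def events_table(run: RunDesign):
    """BIDS-style events table (onset, duration, trial_type, flags)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "onset": [t.onset for t in run.trials],
            "duration": [t.duration for t in run.trials],
            "trial_type": [t.label for t in run.trials],
            "is_null": [int(t.is_null) for t in run.trials],
            "is_lead": [int(t.is_lead) for t in run.trials],
        }
    )


def write_events_tsv(run: RunDesign, path, sidecar_path=None) -> None:
    """Events table as TSV, with an optional JSON sidecar recording the run
    index, alphabet size and trial timing."""
    events_table(run).to_csv(path, sep="\t", index=False)
    if sidecar_path is not None:
        import json
        from dataclasses import asdict

        with open(sidecar_path, "w") as fh:
            json.dump(
                {"run_index": run.run_index, "n_labels": run.n_labels,
                 "timing": asdict(run.timing)},
                fh, indent=1,
            )
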