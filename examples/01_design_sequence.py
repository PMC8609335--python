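"""Generate carry-over counterbalanced trial sequences and split them into runs.

Builds T1I1 sequences over 21 labels (20 face images + 1 null trial), scores
their design efficiency for identity / head-view / mirror-symmetry carry-over
effects, and partitions the two best into 10 scanner runs.
"""

import numpy as np

from hyperdecode import glm, sequence
from hyperdecode.pipeline import generate_chained_pair

rng = np.random.default_rng(0)
candidates = [sequence.generate_t1i1(21, rng) for _ in range(20)]
ok, _ = sequence.is_t1i1(candidates[0])
print(f"generated {len(candidates)} T1I1 sequences, length {len(candidates[0])} "
      f"(21^2 + 1), valid: {ok}")

rels = sequence.stimulus_relationships()
scores = [sequence.sequence_efficiency(s, rels, glm.HRFSpec()) for s in candidates]
best = sequence.select_top_sequences(candidates, rels, glm.HRFSpec(), k=2)
print(f"efficiency range: {min(scores):.1f} .. {max(scores):.1f}; "
      f"kept the top {len(best)} sequences")

seq_a, seq_b = generate_chained_pair(21, seed=1)
runs = sequence.build_run_designs(seq_a, seq_b, n_runs=10, trials_per_run=63)
counts = np.bincount([t.label for t in runs[0].trials if not t.is_lead])
print(f"{len(runs)} runs of {len(runs[0].trials) - 1} trials "
      f"(+1 lead trial); every label appears exactly {counts.min()}x "
      f"per run; run duration {runs[0].duration:.0f} s")
# Each of the 20 images appears exactly 3x per run (and 3 null trials),
# because every aligned 21-trial window of the sequence contains all labels.
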