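"""Permutation + bootstrap inference on decoding accuracy maps.

Shuffles identity labels within each (subject, view) cell, reruns decoding,
bootstraps fold-level accuracies into a null distribution of mean accuracy,
and reports bias-corrected empirical p-values with BH-FDR correction.  Two
worlds make the contrast: one with planted identity information (small
meshes smear signal broadly, so its searchlights all detect it) and one
with no signal anywhere, where observed accuracy hovers at chance and
p-values are large.
"""

from dataclasses import replace

import numpy as np

from hyperdecode import decoding, inference, pipeline, synthetic
from hyperdecode.surface import make_searchlights


def statmap_for(fixture, n_centers=4, n_permutations=30, seed=0):
    samples = fixture.samples["hyper"]["personal"]
    rng = np.random.default_rng(seed)
    centers = np.sort(rng.choice(fixture.mesh.cortex_vertices, n_centers,
                                 replace=False))
    sls = make_searchlights(fixture.mesh, 10.0, centers)
    node_sets = [sl.member_nodes for sl in sls]
    observed = decoding.searchlight_mvpc(samples, sls, fixture.folds)
    scheme = inference.PermutationScheme(n_permutations, seed)
    permuted = inference.permuted_accuracies(
        samples, node_sets, fixture.folds, scheme)
    return inference.accuracy_statmap(observed, permuted,
                                      n_bootstrap=1000, seed=seed + 1)


signal = pipeline.make_fixture("tiny", seed=0)
quiet_cfg = replace(
    signal.config,
    world=replace(signal.config.world, snr_core=0.0, snr_extended=0.0),
)
quiet = pipeline.make_fixture(config=quiet_cfg)

for name, fixture in [("signal world", signal), ("signal-free world", quiet)]:
    stat = statmap_for(fixture)
    print(f"\n{name}: center  observed   p        q      significant")
    for loc, o, p, q, s in zip(stat.locations, stat.observed, stat.p, stat.q,
                               stat.significant):
        print(f"  {loc:4d}      {o:.3f}   {p:.4f}  {q:.4f}  {bool(s)}")
# In the signal world every searchlight on this small mesh carries the
# planted code (alignment spreads information across the hemisphere), so
# observed accuracies are high and p-values small; with no signal, observed
# accuracy sits near the 0.25 chance level and nothing survives FDR.
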