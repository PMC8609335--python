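"""End-to-end orchestration: design -> simulate -> GLM -> hyperalign ->
decode -> infer, with seeded reproducibility and a run manifest.

The pipeline's stages are ordinary library calls; this module wires them
together, fans a single global seed out to per-stage child seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``, and records
what was produced.  ``make_fixture`` builds the two standard synthetic
datasets used throughout the tests and examples:

* ``tiny`` — 4 subjects, 42-vertex icosphere hemispheres, 2 runs per
  familiarity condition; builds and decodes in well under a minute.
* ``demo`` — 14 subjects, 642-vertex hemispheres, 10 runs per familiarity:
  the full study layout (70 cross-validation folds, 400 regressors of
  interest), with enough cortex for signal regions and signal-free null
  territory to coexist at the standard searchlight radii.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import decoding, glm, hyperalignment, inference, sequence, surface, synthetic

STAGES = ("design", "simulate", "glm", "hyperalign", "decode", "infer")


@dataclass
class PipelineConfig:
    """Serializable configuration for a full run."""

    world: synthetic.WorldConfig = field(default_factory=synthetic.WorldConfig)
    mesh_subdivisions: int = 2
    mesh_spacing: float = 3.0
    tr: float = 1.25
    trials_per_run: int = 63
    n_candidates: int = 10
    poly_order: int = 3
    highpass_hz: float = 0.0066
    hyper_radius: float = 20.0
    hyper_iterations: int = 3
    hyper_center_spacing: float = None  # None: searchlight on every vertex
    reference_subject: int = 0
    decode_radius: float = 10.0
    n_permutations: int = 100
    n_bootstrap: int = 10_000
    alpha: float = 0.05
    counterbalance_inversion: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.world.n_subjects < 2:
            raise ValueError("pipeline requires at least 2 subjects")

    def to_dict(self) -> dict:
        d = asdict(self)
        rp = d["world"]["region_partition"]
        if rp is not None:
            d["world"]["region_partition"] = {
                k: np.asarray(v).tolist() for k, v in rp.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["world"] = synthetic.WorldConfig(**d["world"])
        return cls(**d)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed (< 2**31)."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1, np.uint32)[0] % (2**31))


@dataclass
class FixtureData:
    """In-memory result of a full simulate->glm->hyperalign run."""

    config: PipelineConfig
    mesh: surface.SurfaceMesh
    world: synthetic.GroundTruth
    run_designs: list  # parity-0 (original-stream) run designs
    familiarities: list
    design: glm.DesignMatrix  # parity-0 design matrix
    patterns: list  # per subject PatternSet (anatomical space)
    model: hyperalignment.CommonSpaceModel
    folds: list
    samples: dict  # {"hyper"|"anat": {familiarity: SampleSet}}
    run_designs_by_parity: list = None  # [even-subject runs, odd-subject runs]


def generate_chained_pair(
    n_labels: int, seed, max_tries: int = 200
) -> tuple:
    """Two T1I1 sequences with the second starting at the first's final
    label, so their concatenation stays block-aligned."""
    rng = np.random.default_rng(seed)
    seq_a = sequence.generate_t1i1(n_labels, rng)
    last = int(seq_a.labels[-1])
    for _ in range(max_tries):
        seq_b = sequence.generate_t1i1(n_labels, rng)
        if int(seq_b.labels[0]) == last:
            return seq_a, seq_b
    raise RuntimeError("no chainable sequence found")


def build_design_suite(config: PipelineConfig) -> tuple:
    """T1I1-derived run designs for both familiarity conditions.

    Candidate sequences are scored with the identity / head-view /
    mirror-symmetry relationship matrices and the two most efficient are
    used, one per familiarity; each is chained with a matching second
    sequence and split into runs.

    Returns ``(run_designs_by_parity, familiarities)``: one run-design list
    per participant parity.  Even-numbered participants receive the original
    trial streams; odd-numbered participants receive the inverted streams
    (sequence inversion preserves carry-over balance), which decorrelates
    the design-induced noise structure between the two participant groups.
    With inversion disabled both parities share the original designs.
    """
    world = config.world
    n_labels = world.n_identities * world.n_views + 1
    seed = config.stage_seed("design")
    rng = np.random.default_rng(seed)
    rels = sequence.stimulus_relationships(world.n_identities, world.n_views)
    hrf = glm.HRFSpec()
    candidates = [
        sequence.generate_t1i1(n_labels, rng) for _ in range(config.n_candidates)
    ]
    top = sequence.select_top_sequences(
        candidates, rels, hrf, config.tr, k=min(2, len(candidates))
    )
    designs_by_parity = [[], []]
    familiarities = []
    fams = synthetic.FAMILIARITIES[: world.n_familiarities]
    for i, fam in enumerate(fams):
        seq_a = top[i % len(top)]
        seq_b = None
        last = int(seq_a.labels[-1])
        while seq_b is None:
            cand = sequence.generate_t1i1(n_labels, rng)
            if int(cand.labels[0]) == last:
                seq_b = cand
        concat = np.concatenate([seq_a.labels, seq_b.labels[1:]])
        streams = [concat]
        if config.counterbalance_inversion:
            streams.append(sequence.invert_concatenation(concat))
        else:
            streams.append(concat)
        for parity, stream in enumerate(streams):
            runs = sequence.build_run_designs_from_labels(
                stream, n_labels, world.n_runs, config.trials_per_run
            )
            designs_by_parity[parity].extend(runs)
        familiarities.extend([fam] * world.n_runs)
    return designs_by_parity, familiarities


def make_fixture(
    scale: str = "tiny", seed: int = 0, config: PipelineConfig = None
) -> FixtureData:
    """Build a complete synthetic dataset and carry it through pattern
    estimation and hyperalignment.

    ``scale`` is "tiny" (4 subjects, 42-vertex hemispheres, 2 runs per
    condition) or "demo" (the full 14-subject, 10-run layout on 642-vertex
    hemispheres).  A custom :class:`PipelineConfig` overrides both.
    """
    if config is None:
        if scale == "tiny":
            config = PipelineConfig(
                world=synthetic.WorldConfig(
                    n_subjects=4, n_runs=2, movie_length=150, seed=seed
                ),
                mesh_subdivisions=1,
                n_candidates=2,
                seed=seed,
            )
        elif scale == "demo":
            config = PipelineConfig(
                world=replace(synthetic.WorldConfig(), seed=seed),
                mesh_subdivisions=3,
                mesh_spacing=5.0,
                hyper_center_spacing=7.0,
                seed=seed,
            )
        else:
            raise ValueError("scale must be 'tiny' or 'demo'")

    mesh = surface.two_hemisphere_mesh(
        subdivisions=config.mesh_subdivisions, spacing_mm=config.mesh_spacing
    )
    designs_by_parity, familiarities = build_design_suite(config)
    world = synthetic.generate_world(config.world, mesh)

    hrf = glm.HRFSpec()
    design_mats = [
        glm.build_design(
            runs,
            hrf,
            config.tr,
            responses={
                r: synthetic.simulate_responses(
                    rd, n_views=config.world.n_views
                )
                for r, rd in enumerate(runs)
            },
            poly_order=config.poly_order,
            familiarities=familiarities,
            n_views=config.world.n_views,
        )
        for runs in designs_by_parity
    ]

    patterns, movies = [], []
    for s in range(config.world.n_subjects):
        parity = s % 2
        run_designs_s = designs_by_parity[parity]
        design = design_mats[parity]
        runs, confounds, _ = synthetic.emit_subject_task_runs(
            world, s, run_designs_s, familiarities, config.tr, hrf
        )
        cleaned = [
            glm.project_out_nuisance(
                run, confounds[r].to_numpy(), config.highpass_hz, config.tr
            )
            for r, run in enumerate(runs)
        ]
        ts = np.concatenate(cleaned, axis=1)
        patterns.append(glm.fit_glm(ts, design))
        movie = synthetic.emit_subject_movie(world, s)
        movie = glm.project_out_nuisance(
            movie, None, config.highpass_hz, config.tr
        )
        movies.append(hyperalignment.zscore_rows(movie))

    centers = None
    if config.hyper_center_spacing is not None:
        centers = surface.sparse_centers(
            mesh, config.hyper_center_spacing,
            rng=config.stage_seed("hyperalign"),
        )
    align_sls = surface.make_searchlights(mesh, config.hyper_radius, centers)
    model = hyperalignment.searchlight_hyperalign(
        movies,
        align_sls,
        n_iterations=config.hyper_iterations,
        reference_subject=config.reference_subject,
    )

    ref_map = model[config.reference_subject]
    aligned_patterns = []
    for s, ps in enumerate(patterns):
        proj = hyperalignment.project_to_reference(
            ps.data.T, model[s], ref_map
        ).T
        aligned_patterns.append(
            glm.PatternSet(proj, ps.meta, statistic=ps.statistic)
        )

    fams = synthetic.FAMILIARITIES[: config.world.n_familiarities]
    samples = {"hyper": {}, "anat": {}}
    for fam in fams:
        samples["hyper"][fam] = decoding.average_runs(aligned_patterns, fam)
        samples["anat"][fam] = decoding.average_runs(patterns, fam)
    folds = decoding.make_folds(config.world.n_subjects, config.world.n_views)
    return FixtureData(
        config,
        mesh,
        world,
        designs_by_parity[0],
        familiarities,
        design_mats[0],
        patterns,
        model,
        folds,
        samples,
        run_designs_by_parity=designs_by_parity,
    )


# ---------------------------------------------------------------------------
# on-disk pipeline with manifest


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Per-stage output hashes, seeds and wall times for a pipeline run."""

    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list, seed: int, wall: float):
        self.stages[stage] = {
            "outputs": {str(p.name): _hash_file(p) for p in outputs},
            "seed": seed,
            "wall_seconds": round(wall, 3),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=1)


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    decode_centers: list = None,
    verbose: bool = True,
) -> RunManifest:
    """Execute all stages, write plain-text outputs and a manifest.

    Stage order: design, simulate (via the in-memory fixture), glm,
    hyperalign, decode (searchlight over ``decode_centers`` or all cortex
    vertices), infer.  A stage failure raises with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    stage = "design"
    try:
        t0 = time.time()
        fixture = make_fixture(config=config)
        files = []
        for r, run in enumerate(fixture.run_designs):
            p = out / f"run-{r:02d}_events.tsv"
            sequence.write_events_tsv(run, p)
            files.append(p)
        cfg_path = out / "config.json"
        with open(cfg_path, "w") as fh:
            json.dump(config.to_dict(), fh, indent=1)
        files.append(cfg_path)
        manifest.record("design", files, config.stage_seed("design"),
                        time.time() - t0)

        stage = "glm"
        t0 = time.time()
        files = []
        for s, ps in enumerate(fixture.patterns):
            p = out / f"sub-{s:02d}_patterns.tsv"
            ps.save_tsv(p)
            files.append(p)
        manifest.record("glm", files, config.stage_seed("glm"),
                        time.time() - t0)

        stage = "hyperalign"
        t0 = time.time()
        files = []
        for s in range(config.world.n_subjects):
            p = out / f"sub-{s:02d}_alignment.tsv"
            hyperalignment.save_alignment_map(
                fixture.model[s], p,
                header={"iterations": config.hyper_iterations,
                        "reference": config.reference_subject},
            )
            files.append(p)
        manifest.record("hyperalign", files, config.stage_seed("hyperalign"),
                        time.time() - t0)

        stage = "decode"
        t0 = time.time()
        sls = surface.make_searchlights(
            fixture.mesh, config.decode_radius, decode_centers
        )
        results = {}
        files = []
        for fam, samp in fixture.samples["hyper"].items():
            res = decoding.searchlight_mvpc(samp, sls, fixture.folds)
            results[fam] = res
            p = out / f"accuracy_{fam}.tsv"
            res.save_tsv(p)
            files.append(p)
        manifest.record("decode", files, config.stage_seed("decode"),
                        time.time() - t0)

        stage = "infer"
        t0 = time.time()
        scheme = inference.PermutationScheme(
            config.n_permutations, config.stage_seed("infer")
        )
        node_sets = [sl.member_nodes for sl in sls]
        perm = {
            fam: inference.permuted_accuracies(
                fixture.samples["hyper"][fam], node_sets, fixture.folds, scheme
            )
            for fam in results
        }
        files = []
        for fam, res in results.items():
            stat = inference.accuracy_statmap(
                res, perm[fam], config.n_bootstrap,
                config.stage_seed("infer"), config.alpha,
            )
            p = out / f"statmap_{fam}.tsv"
            stat.save_tsv(p)
            files.append(p)
        if len(results) == 2:
            fams = list(results)
            diff = inference.difference_map(
                results[fams[0]], results[fams[1]],
                perm[fams[0]], perm[fams[1]],
                n_bootstrap=config.n_bootstrap,
                seed=config.stage_seed("infer") + 1,
                alpha=config.alpha,
            )
            p = out / "statmap_difference.tsv"
            diff.save_tsv(p)
            files.append(p)
        manifest.record("infer", files, config.stage_seed("infer"),
                        time.time() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    manifest.save(out / "manifest.json")
    if verbose:
        for name, info in manifest.stages.items():
            print(f"  stage {name}: {info['wall_seconds']} s, "
                  f"{len(info['outputs'])} outputs")
    return manifest
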