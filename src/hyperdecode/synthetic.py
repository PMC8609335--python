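"""Multi-subject synthetic data with known shared structure and ground truth.

The generator embodies the assumption that functional alignment tests:
condition information is encoded in a format that is shared across brains
up to a subject-specific local linear change of basis.  A "world" holds

* a shared latent movie time series (node x time, in a template basis),
* shared condition response patterns for familiarity x identity x view,
  decomposed into a view-invariant identity component, a view component and
  a familiarity component, and
* one block-orthogonal mixing transform per subject: the cortex is tiled
  into contiguous geodesic patches and each patch gets an independent random
  rotation, so a searchlight-local alignment model is the correct model
  class while anatomical (vertex-wise) correspondence carries no signal.

Region structure mirrors the core/extended distinction of the face
perception literature: identity information is present in "core-like"
vertices for both familiarity conditions, in "extended-like" vertices for
the personally familiar condition only, and absent elsewhere (null
vertices, which receive pure noise and anchor chance-level and type-I
calibration checks).

Subject-level emissions are deterministic given the world seed: each
(subject, run) draws its noise from a dedicated child of the world's seed
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.stats import ortho_group

from .glm import HRFSpec
from .surface import SurfaceMesh, two_hemisphere_mesh

FAMILIARITIES = ("personal", "visual")


@dataclass
class WorldConfig:
    """Study-condition parameters for the synthetic world.

    ``n_runs`` is per familiarity condition (familiarity is blocked by run,
    so a subject contributes ``2 * n_runs`` task runs).  SNRs are signal
    standard deviations relative to unit sensor noise.
    """

    n_subjects: int = 14
    n_identities: int = 4
    n_views: int = 5
    n_familiarities: int = 2
    n_runs: int = 10
    movie_length: int = 300
    snr_core: float = 2.0
    snr_extended: float = 1.5
    movie_snr: float = 2.0
    block_radius_mm: float = 8.0
    ar_coef: float = 0.0
    region_partition: dict = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if min(self.snr_core, self.snr_extended, self.movie_snr) < 0:
            raise ValueError("SNRs must be >= 0")
        if self.region_partition is not None:
            core = np.asarray(self.region_partition["core"])
            ext = np.asarray(self.region_partition["extended"])
            if np.intersect1d(core, ext).size:
                raise ValueError("core and extended regions must be disjoint")
            if core.size == 0 and ext.size == 0:
                raise ValueError("region partition is empty")

    @property
    def n_conditions(self) -> int:
        return self.n_familiarities * self.n_identities * self.n_views


@dataclass
class NuisanceSpec:
    """Amplitudes of the synthetic confound model per task run."""

    n_motion: int = 6
    n_physio: int = 6
    motion_amp: float = 1.0
    physio_amp: float = 1.0
    drift_amp: float = 2.0
    drift_order: int = 3


@dataclass
class GroundTruth:
    """A generated world: latents, condition patterns, mixings, bookkeeping."""

    config: WorldConfig
    mesh: SurfaceMesh
    movie_latents: np.ndarray  # (n_nodes, movie_length), template basis
    condition_patterns: np.ndarray  # (n_nodes, n_conditions)
    condition_meta: pd.DataFrame  # familiarity, identity, view per condition
    identity_component: np.ndarray  # (n_nodes, n_conditions), view-invariant
    view_component: np.ndarray
    familiarity_component: np.ndarray
    mixings: list  # per subject sparse (n_nodes x n_nodes), block-orthogonal
    blocks: list  # list of vertex-index arrays tiling the cortex
    regions: dict  # 'core' / 'extended' / 'null' vertex-index arrays
    seed_seq: np.random.SeedSequence = field(repr=False, default=None)

    def subject_patterns(self, subject: int) -> np.ndarray:
        """Noiseless condition patterns in the subject's vertex basis."""
        return self.mixings[subject] @ self.condition_patterns

    def rng_for(self, *key) -> np.random.Generator:
        """Deterministic child generator for a (purpose, subject, run) key."""
        return np.random.default_rng(
            np.random.SeedSequence(self.config.seed, spawn_key=tuple(key))
        )


def default_region_partition(
    mesh: SurfaceMesh, core_radius: float = 9.0, extended_radius: float = 9.0
) -> dict:
    """Core disk on the left hemisphere, extended disk on the right.

    Each disk is centered on the vertex of its hemisphere farthest from the
    medial wall (the lateral pole).
    """
    from .surface import geodesic_disk

    regions = {}
    for hemi, name, radius in (
        (0, "core", core_radius),
        (1, "extended", extended_radius),
    ):
        hemi_idx = np.flatnonzero((mesh.hemisphere == hemi) & ~mesh.medial_wall)
        x = mesh.coords[hemi_idx, 0]
        center = hemi_idx[np.argmin(x) if hemi == 0 else np.argmax(x)]
        disk = geodesic_disk(mesh, int(center), radius)
        regions[name] = disk[mesh.hemisphere[disk] == hemi]
    return regions


def tile_cortex(
    mesh: SurfaceMesh, block_radius: float, rng, min_block_size: int = 4
) -> list:
    """Disjoint contiguous patches covering the cortex (geodesic Voronoi
    around greedily chosen centers at least ``block_radius`` apart).

    Patches smaller than ``min_block_size`` are dissolved into their
    neighbors: a near-trivial rotation block would leave those vertices
    anatomically aligned across subjects, which the generator must avoid.
    """
    cortex = mesh.cortex_vertices
    remaining = set(cortex.tolist())
    centers = []
    order = rng.permutation(cortex)
    for v in order:
        if v in remaining:
            centers.append(int(v))
            d = mesh.geodesic_from(int(v))[0]
            remaining -= set(np.flatnonzero(d <= block_radius).tolist())
        if not remaining:
            break
    while True:
        dists = mesh.geodesic_from(centers)  # (n_centers, n_vertices)
        owner = np.argmin(dists, axis=0)
        sizes = np.array(
            [(owner[cortex] == k).sum() for k in range(len(centers))]
        )
        small = np.flatnonzero(sizes < min_block_size)
        if small.size == 0 or len(centers) <= 1:
            break
        centers = [c for k, c in enumerate(centers) if k not in set(small)]
    return [
        np.asarray(sorted(cortex[owner[cortex] == k]), dtype=np.intp)
        for k in range(len(centers))
    ]


def _block_orthogonal(mesh: SurfaceMesh, blocks: list, rng) -> csr_matrix:
    """Sparse block-orthogonal transform: a random rotation per patch,
    identity on the medial wall."""
    rows, cols, vals = [], [], []
    for b in blocks:
        k = len(b)
        Q = ortho_group.rvs(k, random_state=rng) if k > 1 else np.ones((1, 1))
        r, c = np.meshgrid(b, b, indexing="ij")
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(Q.ravel())
    masked = np.flatnonzero(mesh.medial_wall)
    rows.append(masked)
    cols.append(masked)
    vals.append(np.ones(len(masked)))
    n = mesh.n_vertices
    return coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()


def generate_world(config: WorldConfig, mesh: SurfaceMesh = None) -> GroundTruth:
    """Build a deterministic synthetic world from ``config.seed``."""
    if mesh is None:
        mesh = two_hemisphere_mesh(subdivisions=2)
    if config.region_partition is None:
        regions = default_region_partition(mesh)
    else:
        regions = {
            "core": np.asarray(config.region_partition["core"], dtype=np.intp),
            "extended": np.asarray(
                config.region_partition["extended"], dtype=np.intp
            ),
        }
    core, ext = regions["core"], regions["extended"]
    if core.size == 0 and ext.size == 0:
        raise ValueError("region partition is empty")
    cortex = mesh.cortex_vertices
    regions = {
        "core": core,
        "extended": ext,
        "null": np.setdiff1d(cortex, np.concatenate([core, ext])),
    }

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    n = mesh.n_vertices
    nf, ni, nv = config.n_familiarities, config.n_identities, config.n_views
    fams = FAMILIARITIES[:nf]
    meta = pd.DataFrame(
        [
            {"familiarity": f, "identity": i, "view": v}
            for f in fams
            for i in range(ni)
            for v in range(nv)
        ]
    )

    # per-node signal scale by region
    snr = np.zeros(n)
    snr[core] = config.snr_core
    snr[ext] = config.snr_extended

    # identity basis: view-invariant, per familiarity; masked per region
    identity_comp = np.zeros((n, len(meta)))
    view_comp = np.zeros((n, len(meta)))
    fam_comp = np.zeros((n, len(meta)))
    id_basis = {f: rng.standard_normal((n, ni)) for f in fams}
    view_basis = rng.standard_normal((n, nv))
    fam_basis = rng.standard_normal((n, nf))
    # where identity information lives: core for both conditions,
    # extended only for the personally familiar condition
    id_support = {f: np.zeros(n) for f in fams}
    for f in fams:
        id_support[f][core] = config.snr_core
    id_support[fams[0]][ext] = config.snr_extended  # "personal"
    for j, row in meta.iterrows():
        f, i, v = row["familiarity"], row["identity"], row["view"]
        identity_comp[:, j] = id_support[f] * id_basis[f][:, i]
        view_comp[:, j] = 0.5 * snr * view_basis[:, v]
        fam_comp[:, j] = 0.5 * snr * fam_basis[:, list(fams).index(f)]
    patterns = identity_comp + view_comp + fam_comp

    latents = np.zeros((n, config.movie_length))
    latents[cortex] = rng.standard_normal((len(cortex), config.movie_length))

    blocks = tile_cortex(mesh, config.block_radius_mm, rng)
    mixings = [
        _block_orthogonal(mesh, blocks, rng) for _ in range(config.n_subjects)
    ]
    return GroundTruth(
        config=config,
        mesh=mesh,
        movie_latents=latents,
        condition_patterns=patterns,
        condition_meta=meta,
        identity_component=identity_comp,
        view_component=view_comp,
        familiarity_component=fam_comp,
        mixings=mixings,
        blocks=blocks,
        regions=regions,
        seed_seq=ss,
    )


def _ar1_noise(rng, shape, ar_coef):
    noise = rng.standard_normal(shape)
    if ar_coef:
        for t in range(1, shape[1]):
            noise[:, t] = ar_coef * noise[:, t - 1] + np.sqrt(
                1 - ar_coef**2
            ) * noise[:, t]
    return noise


def emit_subject_movie(world: GroundTruth, subject: int) -> np.ndarray:
    """Movie-watching series for one subject: mixed shared latents + noise.

    Returns (n_nodes, movie_length); masked nodes carry pure noise.
    """
    cfg = world.config
    if not 0 <= subject < cfg.n_subjects:
        raise ValueError(f"subject {subject} out of range")
    signal = world.mixings[subject] @ (cfg.movie_snr * world.movie_latents)
    rng = world.rng_for(0, subject)
    noise = _ar1_noise(rng, signal.shape, cfg.ar_coef)
    return signal + noise


def simulate_responses(run_design, rt: float = 1.0, n_views: int = 5) -> dict:
    """Onsets of 'same' button presses: 1-back identity repeats.

    The task is same/different identity relative to the previous trial; the
    GLM models only the 'same' responses.
    """
    onsets = []
    prev_identity = None
    for t in run_design.trials:
        if t.is_null:
            prev_identity = None
            continue
        identity = t.label // n_views
        if prev_identity is not None and identity == prev_identity:
            onsets.append(t.onset + rt)
        prev_identity = identity
    return onsets


def emit_subject_task_runs(
    world: GroundTruth,
    subject: int,
    run_designs: list,
    familiarities: list,
    tr: float = 1.25,
    hrf: HRFSpec = None,
    nuisance: NuisanceSpec = None,
):
    """BOLD-like task runs for one subject.

    Each run is the HRF-convolved condition responses (shared patterns
    passed through the subject's mixing), plus polynomial drift, nuisance
    series (``n_motion`` motion-like random walks and ``n_physio``
    physiological-like oscillations, both of which also leak into the data),
    plus unit-variance sensor noise.

    Returns ``(runs, nuisance_tables, responses)``: per-run (n_nodes,
    n_scans) arrays, per-run 12-column DataFrames, and per-run 'same'
    button-press onsets keyed by run index.
    """
    cfg = world.config
    if tr <= 0:
        raise ValueError("TR must be positive")
    if not run_designs:
        raise ValueError("run_designs must be nonempty")
    if hrf is None:
        hrf = HRFSpec()
    if nuisance is None:
        nuisance = NuisanceSpec()
    fams = list(FAMILIARITIES[: cfg.n_familiarities])
    n = world.mesh.n_vertices
    subject_pats = world.subject_patterns(subject)  # n_nodes x n_conditions
    meta = world.condition_meta
    runs, tables, responses = [], {}, {}
    from .glm import _legendre_drift

    for r, (run, fam) in enumerate(zip(run_designs, familiarities)):
        n_scans = run.n_scans(tr)
        rng = world.rng_for(1, subject, r)
        Y = np.zeros((n, n_scans))
        # condition responses (lead trials drive their condition too)
        by_label = {}
        for t in run.trials:
            if t.is_null:
                continue
            by_label.setdefault(t.label, []).append(t.onset)
        for label, ons in by_label.items():
            identity, view = label // cfg.n_views, label % cfg.n_views
            cond = meta.index[
                (meta["familiarity"] == fam)
                & (meta["identity"] == identity)
                & (meta["view"] == view)
            ][0]
            reg = hrf.regressor(
                ons, np.full(len(ons), hrf.duration), np.ones(len(ons)),
                n_scans, tr)
            Y += np.outer(subject_pats[:, cond], reg)
        # drift: per-node random polynomial trend
        drift_basis = _legendre_drift(n_scans, nuisance.drift_order)[:, 1:]
        drift_coef = nuisance.drift_amp * rng.standard_normal(
            (n, drift_basis.shape[1])
        )
        Y += drift_coef @ drift_basis.T
        # nuisance series: motion-like random walks + physio-like oscillations
        steps = rng.standard_normal((n_scans, nuisance.n_motion))
        motion = np.cumsum(steps, axis=0) / np.sqrt(n_scans)
        t_sec = np.arange(n_scans) * tr
        phases = rng.uniform(0, 2 * np.pi, nuisance.n_physio)
        freqs = rng.uniform(0.08, 0.35, nuisance.n_physio)
        physio = np.sin(
            2 * np.pi * freqs[None, :] * t_sec[:, None] + phases[None, :]
        ) + 0.3 * rng.standard_normal((n_scans, nuisance.n_physio))
        table = pd.DataFrame(
            np.column_stack([motion, physio]),
            columns=[f"motion_{i}" for i in range(nuisance.n_motion)]
            + [f"physio_{i}" for i in range(nuisance.n_physio)],
        )
        loadings = np.column_stack(
            [
                nuisance.motion_amp
                * rng.standard_normal((n, nuisance.n_motion)),
                nuisance.physio_amp
                * rng.standard_normal((n, nuisance.n_physio)),
            ]
        )
        Y += loadings @ table.to_numpy().T
        Y += _ar1_noise(rng, (n, n_scans), cfg.ar_coef)
        runs.append(Y)
        tables[r] = table
        responses[r] = simulate_responses(run, n_views=cfg.n_views)
    return runs, tables, responses


def write_run(path_prefix, run: np.ndarray, table: pd.DataFrame, tr: float,
              seed: int, config: WorldConfig) -> None:
    """Plain-text export: numeric table per run + JSON sidecar."""
    import json
    from dataclasses import asdict

    np.savetxt(f"{path_prefix}_bold.tsv", run, delimiter="\t", fmt="%.6g")
    table.to_csv(f"{path_prefix}_confounds.tsv", sep="\t", index=False)
    cfg = asdict(config)
    cfg["region_partition"] = None if config.region_partition is None else {
        k: np.asarray(v).tolist() for k, v in config.region_partition.items()
    }
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump({"tr": tr, "seed": seed, "config": cfg}, fh, indent=1)
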