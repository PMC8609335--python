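"""Searchlight hyperalignment into a common model space.

Functional alignment estimates, for every subject, an orthogonal
transformation of their local response space that brings time-locked
responses (here, movie watching) into register with other subjects'
responses.  The estimation is done independently within overlapping
searchlights; per-searchlight rotations are aggregated into one sparse
whole-cortex transformation per subject.  Any subject's vertex basis can
serve as the common space's reference: projecting another subject into the
reference space composes that subject's forward map with the transpose
(inverse, for orthogonal maps) of the reference subject's map, applied as a
single linear operation.

Template estimation follows the iterative scheme of the searchlight
hyperalignment literature: the template is seeded from the reference
subject, refined by re-aligning every subject to the running group mean,
and transforms are re-estimated against the final template on the last
pass.  The pass count is a configuration knob (default 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.sparse import coo_matrix, csr_matrix


@dataclass
class AlignmentMap:
    """Sparse vertex-space -> common-space linear map for one subject.

    ``matrix`` applies to (n_nodes, n_samples) data as ``matrix @ data``.
    Entries outside the union of searchlight supports are zero.
    """

    subject: int
    matrix: csr_matrix
    radius: float

    def apply(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        if data.shape[0] != self.matrix.shape[1]:
            raise ValueError(
                f"data has {data.shape[0]} nodes, map expects "
                f"{self.matrix.shape[1]}"
            )
        return self.matrix @ data


@dataclass
class CommonSpaceModel:
    """Per-subject alignment maps plus training metadata."""

    maps: list
    reference_subject: int
    radius: float
    n_iterations: int
    aggregation: str

    def __getitem__(self, subject: int) -> AlignmentMap:
        return self.maps[subject]


def zscore_rows(data: np.ndarray) -> np.ndarray:
    """Z-score each row (node time series); constant rows become zero."""
    data = np.asarray(data, dtype=float)
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (data - mu) / sd


def procrustes(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal transformation R minimizing ||source @ R - target||_F.

    Inputs are (samples, features); the SVD solution allows reflections and
    applies no scaling or translation (z-score columns beforehand if
    centering is wanted).  Degenerate all-zero input yields the identity
    with a warning.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have matching shapes")
    if not np.any(source) or not np.any(target):
        warnings.warn("degenerate all-zero input; returning identity")
        return np.eye(source.shape[1])
    R, _ = orthogonal_procrustes(source, target)
    return R


def searchlight_hyperalign(
    movie_data: list,
    searchlights: list,
    n_iterations: int = 3,
    reference_subject: int = 0,
    aggregation: str = "sum",
) -> CommonSpaceModel:
    """Estimate per-subject whole-cortex alignment maps from movie data.

    Parameters
    ----------
    movie_data : list of (n_nodes, n_time) arrays
        One per subject, all on the same mesh; rows are z-scored
        internally (z-scoring is idempotent, so pre-normalized input is
        unchanged).
    searchlights : list of Searchlight
        Local neighborhoods within which rotations are estimated; typically
        radius 20 mm disks.
    aggregation : "sum" or "mean"
        Overlapping searchlight rotations are summed into the sparse
        whole-cortex map; "mean" divides each entry by the number of
        contributing searchlights.

    The estimate is deterministic given the subject order.
    """
    if len(movie_data) < 2:
        raise ValueError("at least 2 subjects are required")
    n_nodes = movie_data[0].shape[0]
    if any(d.shape[0] != n_nodes for d in movie_data):
        raise ValueError("all subjects must have the same node count")
    if aggregation not in ("sum", "mean"):
        raise ValueError("aggregation must be 'sum' or 'mean'")
    data = [zscore_rows(d) for d in movie_data]
    n_subjects = len(data)

    rows = [[] for _ in range(n_subjects)]
    cols = [[] for _ in range(n_subjects)]
    vals = [[] for _ in range(n_subjects)]
    count_r, count_c = [], []

    order = [reference_subject] + [
        s for s in range(n_subjects) if s != reference_subject
    ]
    for sl in searchlights:
        ndx = sl.member_nodes
        X = [d[ndx].T for d in data]  # (time, k) per subject
        k = len(ndx)
        transforms = [np.eye(k) for _ in range(n_subjects)]
        # pass 1: template seeded from the reference, refined by a running mean
        template = X[reference_subject].copy()
        for i, s in enumerate(order[1:], start=1):
            R = procrustes(X[s], template)
            transforms[s] = R
            template = (template * i + X[s] @ R) / (i + 1)
        # subsequent passes: re-align everyone to the group mean
        for _ in range(1, n_iterations):
            template = np.mean(
                [X[s] @ transforms[s] for s in range(n_subjects)], axis=0
            )
            for s in range(n_subjects):
                transforms[s] = procrustes(X[s], template)
        rr, cc = np.meshgrid(ndx, ndx, indexing="ij")
        for s in range(n_subjects):
            rows[s].append(rr.ravel())
            cols[s].append(cc.ravel())
            # aligned (node x time) = R.T @ data[ndx]
            vals[s].append(transforms[s].T.ravel())
        count_r.append(rr.ravel())
        count_c.append(cc.ravel())

    counts = None
    if aggregation == "mean":
        counts = coo_matrix(
            (
                np.ones(sum(len(a) for a in count_r)),
                (np.concatenate(count_r), np.concatenate(count_c)),
            ),
            shape=(n_nodes, n_nodes),
        ).tocsr()
    maps = []
    radius = searchlights[0].radius if searchlights else 0.0
    for s in range(n_subjects):
        m = coo_matrix(
            (
                np.concatenate(vals[s]),
                (np.concatenate(rows[s]), np.concatenate(cols[s])),
            ),
            shape=(n_nodes, n_nodes),
        ).tocsr()
        if counts is not None:
            m = m.multiply(counts.power(-1)).tocsr()
        maps.append(AlignmentMap(s, m, radius))
    return CommonSpaceModel(
        maps, reference_subject, radius, n_iterations, aggregation
    )


def compose_to_reference(
    map_subject: AlignmentMap, map_reference: AlignmentMap
) -> csr_matrix:
    """Single-step operator projecting a subject into the reference's space:
    forward map into the common space followed by the transpose of the
    reference's map."""
    if map_subject.matrix.shape != map_reference.matrix.shape:
        raise ValueError("alignment maps built on different meshes")
    return (map_reference.matrix.T @ map_subject.matrix).tocsr()


def project_to_reference(
    data: np.ndarray,
    map_subject: AlignmentMap,
    map_reference: AlignmentMap,
) -> np.ndarray:
    """Project (n_nodes, n_samples) data into the reference subject's space."""
    op = compose_to_reference(map_subject, map_reference)
    data = np.asarray(data, dtype=float)
    if data.shape[0] != op.shape[1]:
        raise ValueError("data node dimension does not match the maps")
    return op @ data


# ---------------------------------------------------------------------------
# serialization


def save_alignment_map(amap: AlignmentMap, path, header: dict = None) -> None:
    """Sparse triplet table (row, col, value) with a JSON header line."""
    import json

    coo = amap.matrix.tocoo()
    meta = {"subject": amap.subject, "radius": amap.radius,
            "shape": list(coo.shape)}
    if header:
        meta.update(header)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("row\tcol\tvalue\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{v:.12g}\n")


def load_alignment_map(path) -> AlignmentMap:
    import json

    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# "))
        fh.readline()
        rows, cols, vals = [], [], []
        for line in fh:
            r, c, v = line.split("\t")
            rows.append(int(r))
            cols.append(int(c))
            vals.append(float(v))
    m = coo_matrix(
        (vals, (rows, cols)), shape=tuple(meta["shape"])
    ).tocsr()
    return AlignmentMap(meta["subject"], m, meta["radius"])
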