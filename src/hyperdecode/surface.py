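"""Cortical surface stand-ins: meshes, geodesic neighborhoods, searchlights, ROIs.

The analyses in this package operate on triangulated surface meshes.  Real
studies use high-resolution anatomical templates (tens of thousands of nodes
per hemisphere); here synthetic meshes are subdivided icospheres scaled so
that the typical inter-vertex spacing is about 3 mm, which keeps the
millimeter radii used throughout (3 / 10 / 15 / 20 mm) meaningful at desk
scale.

The geodesic metric is the graph-geodesic: shortest path along mesh edges
with Euclidean edge weights.  This is not the exact polyhedral geodesic, but
it is the standard approximation for searchlight definitions and is easy to
verify against an independent all-pairs shortest-path oracle.  Vertices
flagged as medial wall are removed from the graph entirely, so neighborhoods
never include, or route through, the medial wall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra


class InvalidCenterError(ValueError):
    """Raised when a disk/ROI center is masked or out of range."""


class DuplicateCenterError(ValueError):
    """Raised when two refined ROI centers coincide."""


@dataclass
class SurfaceMesh:
    """Triangulated surface with per-vertex medial-wall mask and hemisphere tag.

    Parameters
    ----------
    coords : (n, 3) float array
        Vertex positions in mm.
    triangles : (m, 3) int array
        Vertex-index triples.
    medial_wall : (n,) bool array, optional
        True for vertices excluded from all analyses. Defaults to all False.
    hemisphere : (n,) int array, optional
        Hemisphere tag per vertex (0 = left, 1 = right). Defaults to all 0.
    """

    coords: np.ndarray
    triangles: np.ndarray
    medial_wall: np.ndarray = None
    hemisphere: np.ndarray = None
    _adjacency: csr_matrix = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.intp)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise ValueError("triangle indices out of range")
        if self.medial_wall is None:
            self.medial_wall = np.zeros(n, dtype=bool)
        self.medial_wall = np.asarray(self.medial_wall, dtype=bool)
        if self.hemisphere is None:
            self.hemisphere = np.zeros(n, dtype=int)
        self.hemisphere = np.asarray(self.hemisphere, dtype=int)
        if self.medial_wall.shape != (n,) or self.hemisphere.shape != (n,):
            raise ValueError("per-vertex arrays must have length n")

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def cortex_vertices(self) -> np.ndarray:
        """Indices of non-masked (analysis-eligible) vertices."""
        return np.flatnonzero(~self.medial_wall)

    def adjacency(self) -> csr_matrix:
        """Sparse symmetric edge-weight matrix over non-masked vertices.

        Edges incident to medial-wall vertices are dropped, so shortest
        paths cannot cross the mask.
        """
        if self._adjacency is None:
            tri = self.triangles
            i = np.concatenate([tri[:, 0], tri[:, 1], tri[:, 2]])
            j = np.concatenate([tri[:, 1], tri[:, 2], tri[:, 0]])
            keep = ~(self.medial_wall[i] | self.medial_wall[j])
            i, j = i[keep], j[keep]
            w = np.linalg.norm(self.coords[i] - self.coords[j], axis=1)
            n = self.n_vertices
            a = coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
            # duplicate entries: keep the minimum edge weight
            a.sum_duplicates()
            counts = coo_matrix(
                (np.ones(2 * len(w)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
            )
            counts.sum_duplicates()
            a.data /= counts.data
            self._adjacency = a.tocsr()
        return self._adjacency

    def geodesic_from(self, centers) -> np.ndarray:
        """Geodesic distances from one or more source vertices.

        Returns an array of shape (len(centers), n_vertices); masked or
        unreachable vertices get +inf.
        """
        centers = np.atleast_1d(np.asarray(centers, dtype=np.intp))
        return dijkstra(self.adjacency(), directed=False, indices=centers)


@dataclass(frozen=True)
class Searchlight:
    """A geodesic disk on the mesh: a center vertex and its members."""

    center_node: int
    member_nodes: np.ndarray
    radius: float

    def __post_init__(self):
        if self.center_node not in self.member_nodes:
            raise ValueError("center_node must be a member")

    def __len__(self) -> int:
        return len(self.member_nodes)


@dataclass
class ROIMap:
    """Named, pairwise-disjoint regions of interest on a mesh."""

    roi_names: list
    assignment: np.ndarray  # per-vertex ROI index, -1 = unassigned
    center_nodes: np.ndarray  # per-ROI center vertex

    def nodes(self, name: str) -> np.ndarray:
        idx = self.roi_names.index(name)
        return np.flatnonzero(self.assignment == idx)


def icosphere_mesh(subdivisions: int = 2, spacing_mm: float = 3.0) -> SurfaceMesh:
    """Single icosphere scaled so the mean edge length equals ``spacing_mm``."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    edges = ico.edges_unique
    mean_edge = np.linalg.norm(
        ico.vertices[edges[:, 0]] - ico.vertices[edges[:, 1]], axis=1
    ).mean()
    scale = spacing_mm / mean_edge
    return SurfaceMesh(np.asarray(ico.vertices) * scale, np.asarray(ico.faces))


def two_hemisphere_mesh(
    subdivisions: int = 2,
    spacing_mm: float = 3.0,
    medial_wall_frac: float = 0.08,
) -> SurfaceMesh:
    """Two icosphere 'hemispheres' side by side with medial-wall masks.

    The hemispheres face each other along the x axis; vertices within the
    polar cap (a fraction ``medial_wall_frac`` of each sphere's vertices
    closest to the facing pole) are flagged as medial wall.
    """
    hemi = icosphere_mesh(subdivisions, spacing_mm)
    n = hemi.n_vertices
    radius = np.linalg.norm(hemi.coords, axis=1).mean()
    gap = 0.5 * radius
    left = hemi.coords - np.array([radius + gap, 0.0, 0.0])
    right = hemi.coords + np.array([radius + gap, 0.0, 0.0])
    coords = np.vstack([left, right])
    triangles = np.vstack([hemi.triangles, hemi.triangles + n])
    # medial wall: cap facing the midline (+x pole for left, -x for right)
    n_mask = max(1, int(round(medial_wall_frac * n)))
    x = hemi.coords[:, 0]
    left_mask_idx = np.argsort(-x)[:n_mask]
    right_mask_idx = np.argsort(x)[:n_mask]
    medial = np.zeros(2 * n, dtype=bool)
    medial[left_mask_idx] = True
    medial[right_mask_idx + n] = True
    hemisphere = np.r_[np.zeros(n, int), np.ones(n, int)]
    return SurfaceMesh(coords, triangles, medial, hemisphere)


def geodesic_disk(mesh: SurfaceMesh, center: int, radius: float) -> np.ndarray:
    """All non-masked vertices within geodesic ``radius`` of ``center``.

    Includes the center itself. Raises :class:`InvalidCenterError` for a
    masked or out-of-range center, ValueError for a negative radius.
    """
    center = int(center)
    if center < 0 or center >= mesh.n_vertices:
        raise InvalidCenterError(f"center {center} out of range")
    if mesh.medial_wall[center]:
        raise InvalidCenterError(f"center {center} is in the medial wall")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    dist = mesh.geodesic_from(center)[0]
    return np.flatnonzero(dist <= radius)


def make_searchlights(mesh: SurfaceMesh, radius: float, centers=None) -> list:
    """One :class:`Searchlight` per center (default: every non-masked vertex).

    A sparse subset of centers may be passed; member disks always obey the
    ``geodesic_disk`` contract.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if centers is None:
        centers = mesh.cortex_vertices
    centers = np.asarray(centers, dtype=np.intp)
    if mesh.medial_wall[centers].any():
        raise InvalidCenterError("searchlight centers must be non-masked")
    dists = mesh.geodesic_from(centers)
    return [
        Searchlight(int(c), np.flatnonzero(d <= radius), radius)
        for c, d in zip(centers, dists)
    ]


def sparse_centers(mesh: SurfaceMesh, spacing: float, rng=None) -> np.ndarray:
    """A subset of cortex vertices such that every cortex vertex lies within
    geodesic ``spacing`` of some chosen center (greedy covering).

    Useful for placing overlapping searchlights on a coarser grid than the
    mesh itself, e.g. for alignment estimation.
    """
    rng = np.random.default_rng(rng)
    cortex = mesh.cortex_vertices
    remaining = set(cortex.tolist())
    centers = []
    for v in rng.permutation(cortex):
        if v in remaining:
            centers.append(int(v))
            d = mesh.geodesic_from(int(v))[0]
            remaining -= set(np.flatnonzero(d <= spacing).tolist())
        if not remaining:
            break
    return np.asarray(sorted(centers), dtype=np.intp)


def define_rois(
    tmap: np.ndarray,
    seed_peaks: dict,
    mesh: SurfaceMesh,
    refine_radius: float = 3.0,
    roi_radius: float = 15.0,
    thresholds: tuple = (1.96, 1.65),
) -> ROIMap:
    """Build disjoint ROIs from a statistic map and named seed vertices.

    Each seed is first refined to the vertex with the maximum ``tmap`` value
    within ``refine_radius`` of it, considering only vertices exceeding the
    first threshold (falling back to the second, laxer threshold if none
    pass).  ROIs are then the geodesic disks of ``roi_radius`` around the
    refined centers; any vertex falling in more than one disk is assigned to
    the ROI with the nearer center (ties go to the ROI listed first, with a
    warning), so the result is pairwise disjoint.

    Parameters
    ----------
    tmap : (n_vertices,) array
        Per-vertex statistic (e.g. a contrast t-value).
    seed_peaks : dict name -> vertex index
        Approximate peak locations; must be distinct and non-masked.
    """
    tmap = np.asarray(tmap, dtype=float)
    names = list(seed_peaks)
    seeds = [int(seed_peaks[k]) for k in names]
    if len(set(seeds)) != len(seeds):
        raise ValueError("seed peaks must be distinct")
    centers = []
    for name, seed in zip(names, seeds):
        disk = geodesic_disk(mesh, seed, refine_radius)
        for thr in thresholds:
            eligible = disk[tmap[disk] >= thr]
            if eligible.size:
                centers.append(int(eligible[np.argmax(tmap[eligible])]))
                break
        else:
            raise ValueError(
                f"no vertex within {refine_radius} mm of seed {name!r} "
                f"passes either threshold {thresholds}"
            )
    if len(set(centers)) != len(centers):
        raise DuplicateCenterError(f"refined centers collide: {centers}")
    dists = mesh.geodesic_from(centers)  # (n_rois, n_vertices)
    within = dists <= roi_radius
    masked_dists = np.where(within, dists, np.inf)
    assignment = np.full(mesh.n_vertices, -1, dtype=int)
    any_within = within.any(axis=0)
    # argmin returns the first minimum -> ties resolved to the earlier seed
    best = np.argmin(masked_dists, axis=0)
    assignment[any_within] = best[any_within]
    n_ties = int(
        ((masked_dists == masked_dists[best, np.arange(len(best))]).sum(axis=0) > 1)[
            any_within
        ].sum()
    )
    if n_ties:
        warnings.warn(
            f"{n_ties} vertices equidistant from two ROI centers; "
            "assigned to the ROI listed first"
        )
    return ROIMap(names, assignment, np.asarray(centers, dtype=np.intp))


# ---------------------------------------------------------------------------
# mesh / per-vertex map I/O


def save_mesh_text(mesh: SurfaceMesh, path) -> None:
    """Plain-text mesh: vertex table then triangle table (0-based indices)."""
    with open(path, "w") as fh:
        fh.write(f"# vertices {mesh.n_vertices} triangles {len(mesh.triangles)}\n")
        fh.write("# x y z medial_wall hemisphere\n")
        for p, m, h in zip(mesh.coords, mesh.medial_wall, mesh.hemisphere):
            fh.write(f"{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t{int(m)}\t{int(h)}\n")
        fh.write("# triangles\n")
        for t in mesh.triangles:
            fh.write(f"{t[0]}\t{t[1]}\t{t[2]}\n")


def load_mesh_text(path) -> SurfaceMesh:
    with open(path) as fh:
        header = fh.readline().split()
        n_vert, n_tri = int(header[2]), int(header[4])
        fh.readline()
        verts = [fh.readline().split() for _ in range(n_vert)]
        fh.readline()
        tris = [fh.readline().split() for _ in range(n_tri)]
    arr = np.asarray(verts, dtype=float)
    return SurfaceMesh(
        arr[:, :3],
        np.asarray(tris, dtype=np.intp),
        arr[:, 3].astype(bool),
        arr[:, 4].astype(int),
    )


def save_mesh_gifti(mesh: SurfaceMesh, path) -> None:
    """GIFTI surface export (coordinates + triangles)."""
    import nibabel as nib

    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                mesh.coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))


def load_mesh_gifti(path) -> SurfaceMesh:
    import nibabel as nib

    img = nib.load(str(path))
    coords = img.darrays[0].data.astype(float)
    tris = img.darrays[1].data.astype(np.intp)
    return SurfaceMesh(coords, tris)


def save_vertex_map(values: np.ndarray, path) -> None:
    """Per-vertex map as a two-column table (node_id, value)."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write("node_id\tvalue\n")
        for i, v in enumerate(values):
            fh.write(f"{i}\t{v}\n")


def load_vertex_map(path) -> np.ndarray:
    data = np.loadtxt(path, skiprows=1)
    order = np.argsort(data[:, 0])
    return data[order, 1]
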