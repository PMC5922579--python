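"""Cortical surface geometry: icospheres, geodesic distances, searchlights.

Synthetic cortical sheets are modelled as icosahedral spheres (one per
hemisphere).  All distances are graph geodesics along mesh edges weighted by
Euclidean edge length; this matches node-spacing-based cortical distances and
is exactly testable against a brute-force Dijkstra oracle.  Node indices are
0-based everywhere, and every tie is broken by lowest node index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

__all__ = [
    "SurfaceMesh",
    "SearchlightAtlas",
    "DistanceBins",
    "make_icosphere",
    "bilateral_mesh",
    "geodesic_distances",
    "build_searchlights",
    "coarse_target_centers",
]

# golden-ratio construction of the base icosahedron (12 vertices, 20 faces)
_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=float,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=int,
)


@dataclass
class SurfaceMesh:
    """Triangulated cortical sheet (one or two hemispheres).

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    triangles : (t, 3) int array
        Triples of vertex indices.
    hemispheres : (n,) array of {"left", "right"}
        Hemisphere label per vertex.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    hemispheres: np.ndarray
    _adjacency: sparse.csr_matrix | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.hemispheres = np.asarray(self.hemispheres)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.triangles.size and self.triangles.max() >= self.n_nodes:
            raise ValueError("triangle index out of range")
        tri = self.triangles
        if tri.size and (
            (tri[:, 0] == tri[:, 1])
            | (tri[:, 1] == tri[:, 2])
            | (tri[:, 0] == tri[:, 2])
        ).any():
            raise ValueError("degenerate triangle (repeated vertex)")

    @property
    def n_nodes(self) -> int:
        return self.vertices.shape[0]

    def hemisphere_of(self, node: int) -> str:
        return str(self.hemispheres[node])

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) int array, sorted."""
        tri = self.triangles
        pairs = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
        pairs = np.sort(pairs, axis=1)
        return np.unique(pairs, axis=0)

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric sparse adjacency weighted by Euclidean edge length."""
        if self._adjacency is None:
            e = self.edges
            w = np.linalg.norm(
                self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
            )
            n = self.n_nodes
            a = sparse.coo_matrix(
                (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                shape=(n, n),
            )
            self._adjacency = a.tocsr()
        return self._adjacency

    @property
    def mean_edge_length(self) -> float:
        e = self.edges
        return float(
            np.linalg.norm(
                self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
            ).mean()
        )

    def is_closed_manifold(self) -> bool:
        """True when every edge belongs to exactly two triangles."""
        tri = self.triangles
        pairs = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
        pairs = np.sort(pairs, axis=1)
        _, counts = np.unique(pairs, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def to_dict(self) -> dict:
        return {
            "index_base": 0,
            "vertices": self.vertices.tolist(),
            "triangles": self.triangles.tolist(),
            "hemispheres": [str(h) for h in self.hemispheres],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceMesh":
        return cls(
            np.asarray(d["vertices"], dtype=float),
            np.asarray(d["triangles"], dtype=int),
            np.asarray(d["hemispheres"]),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "SurfaceMesh":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save_gifti(self, path) -> None:
        """Write geometry as a GIFTI surface file (coordinates + topology)."""
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    self.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    self.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))

    @classmethod
    def load_gifti(cls, path, hemisphere: str = "left") -> "SurfaceMesh":
        import nibabel as nib

        img = nib.load(str(path))
        verts = tris = None
        for da in img.darrays:
            if da.intent == 1008:  # POINTSET
                verts = np.asarray(da.data, dtype=float)
            elif da.intent == 1009:  # TRIANGLE
                tris = np.asarray(da.data, dtype=int)
        if verts is None or tris is None:
            raise ValueError(f"{path} is not a GIFTI surface geometry file")
        hemis = np.full(verts.shape[0], hemisphere)
        return cls(verts, tris, hemis)


@dataclass
class SearchlightAtlas:
    """Overlapping geodesic-disk searchlights, one centred on every node."""

    radius_mm: float
    centers: np.ndarray  # (n_searchlights,) node ids
    members: list  # list of 1-D int arrays, ascending node index

    @property
    def n_searchlights(self) -> int:
        return len(self.centers)

    def to_dict(self) -> dict:
        return {
            "index_base": 0,
            "radius_mm": self.radius_mm,
            "entries": [
                {"center": int(c), "members": m.tolist()}
                for c, m in zip(self.centers, self.members)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SearchlightAtlas":
        return cls(
            float(d["radius_mm"]),
            np.array([e["center"] for e in d["entries"]], dtype=int),
            [np.asarray(e["members"], dtype=int) for e in d["entries"]],
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "SearchlightAtlas":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DistanceBins:
    """Per-node geodesic distance bins for point-spread-function curves.

    ``distances_mm`` are the nominal bin distances (default 0, 3, 6, 9, 12).
    Bin 0 contains only the node itself (geodesic distance exactly 0); bin k
    contains nodes whose distance falls in the half-open interval
    ``[d_k - h, d_k + h)`` where ``h`` is half the smallest gap between
    nominal distances, so bins are disjoint by construction.
    """

    distances_mm: tuple
    bins: list  # bins[node][k] -> int array of nodes in bin k of `node`

    DEFAULT_DISTANCES = (0.0, 3.0, 6.0, 9.0, 12.0)

    @property
    def n_bins(self) -> int:
        return len(self.distances_mm)

    @classmethod
    def from_mesh(
        cls,
        mesh: SurfaceMesh,
        distances_mm: tuple | None = None,
        n_bins: int | None = None,
        spacing_mm: float | None = None,
    ) -> "DistanceBins":
        """Build bins for every node of ``mesh``.

        Either pass explicit nominal ``distances_mm`` or let them be multiples
        of ``spacing_mm`` (default: the mesh's mean edge length), which adapts
        the bins to the mesh's node spacing.
        """
        if distances_mm is None:
            if n_bins is None:
                distances_mm = cls.DEFAULT_DISTANCES
            else:
                if spacing_mm is None:
                    spacing_mm = mesh.mean_edge_length
                distances_mm = tuple(spacing_mm * k for k in range(n_bins))
        distances_mm = tuple(float(d) for d in distances_mm)
        if sorted(distances_mm) != list(distances_mm) or distances_mm[0] != 0.0:
            raise ValueError("nominal distances must be ascending and start at 0")
        gaps = np.diff(distances_mm)
        half = float(gaps.min()) / 2.0 if gaps.size else 1.0
        cutoff = distances_mm[-1] + half
        n = mesh.n_nodes
        dmat = _pairwise_geodesic(mesh, limit=cutoff)
        bins = []
        for v in range(n):
            row = dmat[v]
            reach = np.flatnonzero(np.isfinite(row))
            per = [np.array([v], dtype=int)]
            for d in distances_mm[1:]:
                sel = reach[(row[reach] >= d - half) & (row[reach] < d + half)]
                per.append(sel[sel != v])
            bins.append(per)
        return cls(distances_mm, bins)


def make_icosphere(
    subdivision_factor: int, radius_mm: float, hemisphere: str = "left"
) -> SurfaceMesh:
    """Icosahedral sphere via linear (factor-``l``) subdivision.

    Each base face is split into ``l**2`` triangles on a barycentric grid and
    the vertices projected to a sphere of ``radius_mm``, yielding exactly
    ``10 * l**2 + 2`` vertices.
    """
    if not (isinstance(subdivision_factor, (int, np.integer)) and subdivision_factor >= 1):
        raise ValueError("subdivision_factor must be a positive integer")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")

    ell = int(subdivision_factor)
    verts: list = [v for v in _ICO_VERTS]
    registry: dict = {("v", i): i for i in range(12)}
    faces: list = []

    def vertex_id(face, i, j):
        a, b, c = face
        # barycentric weights (ell - i - j, i, j) over corners (a, b, c)
        k = ell - i - j
        if k == ell:
            return registry[("v", a)]
        if i == ell:
            return registry[("v", b)]
        if j == ell:
            return registry[("v", c)]
        if j == 0:  # edge a-b, step i from a
            key = ("e", a, b, i) if a < b else ("e", b, a, ell - i)
        elif i == 0:  # edge a-c, step j from a
            key = ("e", a, c, j) if a < c else ("e", c, a, ell - j)
        elif k == 0:  # edge b-c, step j from b
            key = ("e", b, c, j) if b < c else ("e", c, b, ell - j)
        else:
            key = None
        if key is not None and key in registry:
            return registry[key]
        p = (k * _ICO_VERTS[a] + i * _ICO_VERTS[b] + j * _ICO_VERTS[c]) / ell
        verts.append(p)
        idx = len(verts) - 1
        if key is not None:
            registry[key] = idx
        return idx

    for face in _ICO_FACES:
        grid = {}
        for i in range(ell + 1):
            for j in range(ell + 1 - i):
                grid[(i, j)] = vertex_id(face, i, j)
        for i in range(ell):
            for j in range(ell - i):
                faces.append([grid[(i, j)], grid[(i + 1, j)], grid[(i, j + 1)]])
                if i + j < ell - 1:
                    faces.append(
                        [grid[(i + 1, j)], grid[(i + 1, j + 1)], grid[(i, j + 1)]]
                    )

    v = np.asarray(verts, dtype=float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * radius_mm
    hemis = np.full(v.shape[0], hemisphere)
    return SurfaceMesh(v, np.asarray(faces, dtype=int), hemis)


def bilateral_mesh(left: SurfaceMesh, right: SurfaceMesh) -> SurfaceMesh:
    """Concatenate two hemisphere meshes into one bilateral mesh.

    Right-hemisphere node indices are offset by ``left.n_nodes``; no edge
    crosses hemispheres.  The two spheres are translated apart along x so that
    Euclidean coordinates never overlap across hemispheres.
    """
    hl = set(map(str, np.unique(left.hemispheres)))
    hr = set(map(str, np.unique(right.hemispheres)))
    if hl & hr:
        raise ValueError("hemisphere labels of the two meshes must differ")
    rl = np.linalg.norm(left.vertices, axis=1).max()
    rr = np.linalg.norm(right.vertices, axis=1).max()
    shift = 1.1 * (rl + rr)
    lv = left.vertices - np.array([shift / 2.0, 0.0, 0.0])
    rv = right.vertices + np.array([shift / 2.0, 0.0, 0.0])
    verts = np.vstack([lv, rv])
    tris = np.vstack([left.triangles, right.triangles + left.n_nodes])
    hemis = np.concatenate([left.hemispheres, right.hemispheres])
    return SurfaceMesh(verts, tris, hemis)


def _pairwise_geodesic(
    mesh: SurfaceMesh, limit: float = np.inf, sources: np.ndarray | None = None
) -> np.ndarray:
    """Geodesic distances from ``sources`` (default: all nodes) to all nodes."""
    adj = mesh.adjacency
    if sources is None:
        sources = np.arange(mesh.n_nodes)
    out = np.empty((len(sources), mesh.n_nodes))
    step = 512
    for k in range(0, len(sources), step):
        idx = sources[k : k + step]
        out[k : k + step] = csgraph.dijkstra(
            adj, directed=False, indices=idx, limit=limit
        )
    return out


def geodesic_distances(
    mesh: SurfaceMesh, source: int, cutoff_mm: float = np.inf
) -> dict:
    """Geodesic distance (mm) from ``source`` along mesh edges.

    Returns a ``{node: distance}`` map omitting nodes beyond ``cutoff_mm``.
    Paths never cross hemispheres because no edge does.
    """
    if not 0 <= source < mesh.n_nodes:
        raise ValueError(f"source {source} outside mesh of {mesh.n_nodes} nodes")
    row = _pairwise_geodesic(mesh, limit=cutoff_mm, sources=np.array([source]))[0]
    keep = np.flatnonzero(np.isfinite(row) & (row <= cutoff_mm))
    return {int(i): float(row[i]) for i in keep}


def build_searchlights(mesh: SurfaceMesh, radius_mm: float) -> SearchlightAtlas:
    """One geodesic-disk searchlight per node, members ordered by node index."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    dmat = _pairwise_geodesic(mesh, limit=radius_mm * (1 + 1e-12))
    members = []
    for v in range(mesh.n_nodes):
        row = dmat[v]
        m = np.flatnonzero(np.isfinite(row) & (row <= radius_mm))
        members.append(m.astype(int))
    return SearchlightAtlas(float(radius_mm), np.arange(mesh.n_nodes), members)


def coarse_target_centers(fine: SurfaceMesh, coarse: SurfaceMesh) -> np.ndarray:
    """Map each coarse node to its nearest fine node (Euclidean, same hemisphere).

    Ties break to the lowest fine index.  When the coarse mesh is a subsampled
    version of the fine mesh the mapping hits coincident vertices exactly.
    """
    if fine.n_nodes == 0 or coarse.n_nodes == 0:
        raise ValueError("meshes must be non-empty")
    out = np.empty(coarse.n_nodes, dtype=int)
    for hemi in np.unique(coarse.hemispheres):
        cidx = np.flatnonzero(coarse.hemispheres == hemi)
        fidx = np.flatnonzero(fine.hemispheres == hemi)
        if fidx.size == 0:
            raise ValueError(f"fine mesh lacks hemisphere {hemi!r}")
        fv = fine.vertices[fidx]
        # brute-force argmin keeps the lowest-index tie-break exact
        for c in cidx:
            d2 = ((fv - coarse.vertices[c]) ** 2).sum(axis=1)
            out[c] = fidx[int(np.argmin(d2))]
    return out


def searchlights_at(
    mesh: SurfaceMesh, centers: np.ndarray, radius_mm: float
) -> SearchlightAtlas:
    """Geodesic-disk searchlights centred on an explicit list of nodes.

    Used for coarse connectivity-target searchlights, whose centres live on a
    subsampled grid rather than on every node.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    centers = np.asarray(centers, dtype=int)
    dmat = _pairwise_geodesic(mesh, limit=radius_mm * (1 + 1e-12), sources=centers)
    members = []
    for k in range(len(centers)):
        row = dmat[k]
        m = np.flatnonzero(np.isfinite(row) & (row <= radius_mm))
        if m.size == 0:
            warnings.warn(f"searchlight at node {centers[k]} is empty")
        members.append(m.astype(int))
    return SearchlightAtlas(float(radius_mm), centers, members)
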