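"""Whole-cortex hyperalignment: run field hyperalignment in every searchlight
and aggregate the local orthogonal transforms into one sparse whole-cortex
transformation matrix per subject.

Aggregation simply sums, for every (cortical locus, model dimension) pair,
the corresponding entries of all searchlight transforms containing that pair
— equivalent to zero-padding each local transform to full ``m x m`` and
summing.  Because searchlights overlap, nearby locus/dimension pairs co-occur
in more searchlights than distant pairs and so are weighted more strongly;
pairs farther apart than twice the searchlight radius are structurally zero.
The aggregate is sparse and deliberately non-orthogonal: it is this locality
constraint that keeps the remapping of information within cortical
neighborhoods.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

from .data import zscore
from .procrustes import hyperalign_field
from .surface import SearchlightAtlas, SurfaceMesh, build_searchlights

__all__ = [
    "WholeCortexTransform",
    "hyperalign_all_searchlights",
    "aggregate_transforms",
    "apply_transform",
    "backproject",
    "select_features",
    "SearchlightHyperalignment",
]


class WholeCortexTransform:
    """Sparse ``m x m`` whole-cortex transformation for one subject."""

    def __init__(self, matrix: sparse.spmatrix, subject_id: str = "", provenance: dict | None = None):
        mat = sparse.csr_matrix(matrix)
        mat.sum_duplicates()
        mat.eliminate_zeros()
        mat.sort_indices()
        self.matrix = mat
        self.subject_id = subject_id
        self.provenance = provenance or {}

    @property
    def shape(self):
        return self.matrix.shape

    @property
    def zero_fraction(self) -> float:
        m = self.matrix.shape[0] * self.matrix.shape[1]
        return 1.0 - self.matrix.nnz / m

    def to_triplets(self):
        """Canonical (row, col, value) triplet arrays, row-major sorted."""
        coo = self.matrix.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return coo.row[order], coo.col[order], coo.data[order]


def hyperalign_all_searchlights(
    data: list,
    atlas: SearchlightAtlas,
    feature_masks: list | None = None,
    reference_index: int = 0,
) -> list:
    """Field hyperalignment in every searchlight.

    Returns ``transforms[j][i]``: the orthogonal transform of subject ``i``
    in searchlight ``j``.  Searchlights are independent, so processing order
    does not affect any result.
    """
    out = []
    for j in range(atlas.n_searchlights):
        members = _members_for(atlas, j, feature_masks, len(data))
        sub = [x[:, mem] for x, mem in zip(data, members)]
        if any(s.shape[1] < 1 for s in sub):
            raise ValueError(f"searchlight {j} has no loci after selection")
        transforms, _ = hyperalign_field(sub, reference_index=reference_index)
        out.append(transforms)
    return out


def _members_for(atlas, j, feature_masks, n_subjects):
    """Per-subject member node lists for searchlight ``j``."""
    if feature_masks is None:
        return [atlas.members[j]] * n_subjects
    return [feature_masks[i][j] for i in range(n_subjects)]


def aggregate_transforms(
    field_transforms: list,
    atlas: SearchlightAtlas,
    m: int,
    member_lists: list | None = None,
    model_member_lists: list | None = None,
    subject_id: str = "",
) -> WholeCortexTransform:
    """Sum zero-padded searchlight transforms into one sparse ``m x m`` matrix.

    Parameters
    ----------
    field_transforms : list of (m_j, m_j) arrays, one per searchlight
        Local transforms for a single subject.
    member_lists, model_member_lists : lists of node-id arrays, optional
        Row (subject locus) and column (model dimension) indices per
        searchlight; both default to the atlas member lists.
    """
    rows, cols, vals = [], [], []
    for j, r in enumerate(field_transforms):
        mem = atlas.members[j] if member_lists is None else member_lists[j]
        model_mem = mem if model_member_lists is None else model_member_lists[j]
        if (np.max(mem, initial=-1) >= m) or (np.max(model_mem, initial=-1) >= m):
            raise ValueError(f"searchlight {j} has node ids outside the mesh")
        block = r[: len(mem), : len(model_mem)]
        rows.append(np.repeat(mem, len(model_mem)))
        cols.append(np.tile(model_mem, len(mem)))
        vals.append(block.ravel())
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    )
    return WholeCortexTransform(mat, subject_id=subject_id)


def apply_transform(data: np.ndarray, transform) -> np.ndarray:
    """Map native-space data (samples x loci) into the common model space."""
    mat = transform.matrix if isinstance(transform, WholeCortexTransform) else transform
    data = np.asarray(data, dtype=float)
    if data.shape[1] != mat.shape[0]:
        raise ValueError(
            f"data has {data.shape[1]} columns but transform is {mat.shape}"
        )
    if sparse.issparse(mat):
        return np.asarray((mat.T @ data.T).T)
    return data @ mat


def backproject(model_data: np.ndarray, transform) -> np.ndarray:
    """Map common-space data back into a subject's anatomy via the transpose."""
    mat = transform.matrix if isinstance(transform, WholeCortexTransform) else transform
    model_data = np.asarray(model_data, dtype=float)
    if model_data.shape[1] != mat.shape[1]:
        raise ValueError(
            f"model data has {model_data.shape[1]} columns but transform is {mat.shape}"
        )
    if sparse.issparse(mat):
        return np.asarray((mat @ model_data.T).T)
    return model_data @ mat.T


def select_features(
    data: list, atlas: SearchlightAtlas, fraction: float = 0.70
) -> list:
    """Per-subject, per-searchlight retained-locus masks from training data.

    Each locus is scored, per subject, by the correlation of its training
    time series with the mean time series of the same locus in all other
    subjects; the top ``ceil(fraction * m_j)`` loci per searchlight are kept
    (ties to the lowest node index).  Returned masks are ascending node-id
    arrays, ``masks[subject][searchlight]``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_sub = len(data)
    if n_sub < 2:
        raise ValueError("feature selection needs at least 2 subjects")
    z = [zscore(x, warn_constant=False) for x in data]
    total = np.sum(z, axis=0)
    n = z[0].shape[0]
    scores = []
    for i in range(n_sub):
        others = zscore((total - z[i]) / (n_sub - 1), warn_constant=False)
        scores.append((z[i] * others).sum(axis=0) / n)
    masks = []
    for i in range(n_sub):
        per_sl = []
        for members in atlas.members:
            k = int(np.ceil(fraction * len(members)))
            s = scores[i][members]
            # descending score, ties to the lowest node index
            order = np.lexsort((members, -s))
            per_sl.append(np.sort(members[order[:k]]))
        masks.append(per_sl)
    return masks


class SearchlightHyperalignment(BaseEstimator):
    """Whole-cortex hyperalignment over overlapping surface searchlights.

    ``fit`` expects a list of per-subject ``(n_samples, n_loci)`` matrices
    (rows may be time points for response hyperalignment or connectivity
    targets for connectivity hyperalignment) and derives one sparse
    whole-cortex transform per subject.

    Parameters
    ----------
    mesh : SurfaceMesh, optional
        Surface on which searchlights are defined (ignored when ``atlas``
        is given).
    radius_mm : float, default 20.0
        Searchlight geodesic radius.
    atlas : SearchlightAtlas, optional
        Precomputed searchlights.
    reference_index : int, default 0
        Reference subject for the local iterations; model dimensions follow
        this subject's (retained) loci.
    feature_fraction : float or None, default None
        When set, retain this fraction of loci per searchlight using a
        between-subject correlation score computed on the fit data.

    Attributes
    ----------
    transforms_ : list of WholeCortexTransform
    model_ : (n_samples, n_loci) ndarray
        Mean of the transformed fit data.
    atlas_ : SearchlightAtlas
    feature_masks_ : list or None
    """

    def __init__(
        self,
        mesh: SurfaceMesh | None = None,
        radius_mm: float = 20.0,
        atlas: SearchlightAtlas | None = None,
        reference_index: int = 0,
        feature_fraction: float | None = None,
    ):
        self.mesh = mesh
        self.radius_mm = radius_mm
        self.atlas = atlas
        self.reference_index = reference_index
        self.feature_fraction = feature_fraction

    def fit(self, X: list, y=None) -> "SearchlightHyperalignment":
        if len(X) < 2:
            raise ValueError("need at least 2 subjects")
        X = [np.asarray(x, dtype=float) for x in X]
        m = X[0].shape[1]
        atlas = self.atlas
        if atlas is None:
            if self.mesh is None:
                raise ValueError("provide either an atlas or a mesh")
            atlas = build_searchlights(self.mesh, self.radius_mm)
        self.atlas_ = atlas
        if self.feature_fraction is not None:
            self.feature_masks_ = select_features(X, atlas, self.feature_fraction)
        else:
            self.feature_masks_ = None

        acc = [([], [], []) for _ in X]  # (rows, cols, vals) per subject
        for j in range(atlas.n_searchlights):
            members = _members_for(atlas, j, self.feature_masks_, len(X))
            sub = [x[:, mem] for x, mem in zip(X, members)]
            if any(s.shape[1] < 1 for s in sub):
                raise ValueError(f"searchlight {j} has no loci after selection")
            transforms, _ = hyperalign_field(
                sub, reference_index=self.reference_index
            )
            model_mem = members[self.reference_index]
            for i, r in enumerate(transforms):
                mem = members[i]
                block = r[: len(mem), : len(model_mem)]
                rows, cols, vals = acc[i]
                rows.append(np.repeat(mem, len(model_mem)))
                cols.append(np.tile(model_mem, len(mem)))
                vals.append(block.ravel())

        provenance = {
            "radius_mm": float(atlas.radius_mm),
            "reference_index": int(self.reference_index),
            "feature_fraction": self.feature_fraction,
        }
        self.transforms_ = []
        for i, (rows, cols, vals) in enumerate(acc):
            mat = sparse.coo_matrix(
                (
                    np.concatenate(vals),
                    (np.concatenate(rows), np.concatenate(cols)),
                ),
                shape=(m, m),
            )
            self.transforms_.append(
                WholeCortexTransform(mat, subject_id=str(i), provenance=provenance)
            )
        self.model_ = np.mean(
            [apply_transform(x, t) for x, t in zip(X, self.transforms_)], axis=0
        )
        self.n_subjects_ = len(X)
        return self

    def transform(self, X: np.ndarray, subject: int = 0) -> np.ndarray:
        """Map one subject's native-space data into the common space."""
        return apply_transform(X, self.transforms_[subject])

    def inverse_transform(self, X: np.ndarray, subject: int = 0) -> np.ndarray:
        """Map common-space data back into one subject's anatomy."""
        return backproject(X, self.transforms_[subject])
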