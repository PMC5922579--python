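"""Orthogonal Procrustes solver and iterative hyperalignment of one cortical
field.

Hyperalignment treats the loci of a cortical field as axes of a
high-dimensional space and finds, per subject, the orthogonal (improper
rotations allowed) transformation that best maps that subject's data matrix
onto a group template, by a three-level generalized-Procrustes-style
iteration:

* level 1 — subjects are folded in one at a time: subject 2 is aligned to
  the reference subject, and each later subject to the running average of the
  previous subject's aligned data and the previous running target;
* level 2 — each subject is re-aligned, from its *original* data, to the
  unweighted mean of all *other* subjects' level-1 aligned data; level-1
  transforms are then discarded and the model is the mean of level-2 aligned
  data;
* level 3 — final transforms are recomputed against that model, and the model
  is refreshed as the mean of the final aligned data.

No isotropic scaling is applied (inputs are z-scored upstream), and no
translation is removed beyond the column centering implied by z-scoring.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

__all__ = ["orthogonal_procrustes", "hyperalign_field", "FieldHyperalignment"]


def _pad_columns(x: np.ndarray, width: int) -> np.ndarray:
    """Zero-pad columns of ``x`` on the right up to ``width``."""
    if x.shape[1] == width:
        return x
    out = np.zeros((x.shape[0], width), dtype=float)
    out[:, : x.shape[1]] = x
    return out


def orthogonal_procrustes(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal matrix ``R`` minimizing ``||source @ R - target||_F``.

    ``R = U V^T`` from the SVD ``U s V^T = source^T @ target``; reflections
    (det = -1) are permitted and no scaling factor is applied.  When the
    column counts differ, the narrower matrix is zero-padded on the right so
    the solution is square in the wider dimensionality (mapping the narrower
    space into the wider one).  For rank-deficient cross-products, the full
    SVD supplies a deterministic orthonormal completion of the null space.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape[0] != target.shape[0]:
        raise ValueError("source and target must have equal row counts")
    if not (np.isfinite(source).all() and np.isfinite(target).all()):
        raise ValueError("non-finite values in Procrustes inputs")
    width = max(source.shape[1], target.shape[1])
    source = _pad_columns(source, width)
    target = _pad_columns(target, width)
    u, _, vt = linalg.svd(source.T @ target, full_matrices=True)
    return u @ vt


def hyperalign_field(
    data: list, reference_index: int = 0, details: bool = False
):
    """Three-level iterative hyperalignment of one cortical field.

    Parameters
    ----------
    data : list of (n, m_i) arrays
        One matrix per subject; rows (samples) must agree across subjects.
        Columns may differ; narrower matrices are zero-padded to the
        reference subject's width.
    reference_index : int
        Subject whose space seeds level 1 (the "reference subject").

    Returns
    -------
    transforms : list of (m, m) arrays
        Final per-subject orthogonal transforms, in input order.
    model : (n, m) array
        Mean of the final transformed matrices.

    With ``details=True`` a third value is returned: a dict with the
    intermediate ``level1`` and ``level2`` transform lists.
    """
    if len(data) < 2:
        raise ValueError("hyperalignment needs at least 2 subjects")
    n = data[0].shape[0]
    for k, b in enumerate(data):
        if b.shape[0] != n:
            raise ValueError(
                f"subject {k} has {b.shape[0]} rows, expected {n}"
            )
    if not 0 <= reference_index < len(data):
        raise ValueError("reference_index outside the cohort")

    width = data[reference_index].shape[1]
    width = max([width] + [b.shape[1] for b in data])
    mats = [_pad_columns(np.asarray(b, dtype=float), width) for b in data]
    order = [reference_index] + [
        i for i in range(len(mats)) if i != reference_index
    ]

    # level 1: fold subjects in, target = (previous aligned + previous target)/2
    aligned1 = [None] * len(mats)
    level1 = [None] * len(mats)
    level1[order[0]] = np.eye(width)
    aligned1[order[0]] = mats[order[0]]
    target = mats[order[0]]
    for i in order[1:]:
        r = orthogonal_procrustes(mats[i], target)
        level1[i] = r
        aligned1[i] = mats[i] @ r
        target = (aligned1[i] + target) / 2.0

    # level 2: re-align original data to mean of all *other* subjects' level-1
    total1 = np.sum(aligned1, axis=0)
    level2 = []
    aligned2 = []
    for i, b in enumerate(mats):
        others_mean = (total1 - aligned1[i]) / (len(mats) - 1)
        r = orthogonal_procrustes(b, others_mean)
        level2.append(r)
        aligned2.append(b @ r)
    model = np.mean(aligned2, axis=0)

    # level 3: final transforms against the level-2 model; refresh the model
    transforms = [orthogonal_procrustes(b, model) for b in mats]
    model = np.mean([b @ r for b, r in zip(mats, transforms)], axis=0)
    if details:
        return transforms, model, {"level1": level1, "level2": level2}
    return transforms, model


class FieldHyperalignment(BaseEstimator):
    """Hyperalignment of a single cortical field (ROI or searchlight).

    A scikit-learn style estimator: ``fit`` takes a list of per-subject
    ``(n_samples, n_loci)`` matrices and derives one orthogonal transform per
    subject plus the group model matrix.

    Parameters
    ----------
    reference_index : int, default 0
        Subject whose space seeds the level-1 iteration.

    Attributes
    ----------
    transforms_ : list of (m, m) ndarray
        Final orthogonal transform per subject.
    model_ : (n, m) ndarray
        Group model matrix (mean of final aligned data).
    n_subjects_ : int
    """

    def __init__(self, reference_index: int = 0):
        self.reference_index = reference_index

    def fit(self, X: list, y=None) -> "FieldHyperalignment":
        self.transforms_, self.model_ = hyperalign_field(
            X, reference_index=self.reference_index
        )
        self.n_subjects_ = len(X)
        return self

    def transform(self, X: list) -> list:
        """Apply the fitted per-subject transforms to new matrices."""
        if len(X) != self.n_subjects_:
            raise ValueError("need one matrix per fitted subject")
        width = self.transforms_[0].shape[0]
        return [
            _pad_columns(np.asarray(b, dtype=float), width) @ r
            for b, r in zip(X, self.transforms_)
        ]

    def fit_transform(self, X: list, y=None) -> list:
        return self.fit(X).transform(X)
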