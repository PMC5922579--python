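"""Synthetic multi-subject cortical cohorts with known ground truth.

The generator emulates the statistical structure connectivity hyperalignment
assumes: a latent functional time series per cortical node that is shared
across subjects (a spatially smooth coarse-scale component plus a node-unique
fine-scale component), remixed within local neighborhoods by an
individual-specific orthogonal map per subject — the "individual-specific
topographic basis functions" picture — plus i.i.d. Gaussian sensor noise.
Each session redraws the latent series from the same spatial covariance, so
connectivity structure is stable across sessions while time courses are not,
as in resting-state acquisitions; within a session, the latent series is
common to all subjects, so response hyperalignment is applicable too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .data import BrainDataMatrix, SubjectCohort, zscore
from .surface import SurfaceMesh, bilateral_mesh, make_icosphere, _pairwise_geodesic

__all__ = ["SyntheticSpec", "GroundTruth", "generate_cohort", "make_two_fold_sessions"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    Defaults are the desk-scale study conditions: a bilateral subdivision-8
    icosphere (1284 nodes) with ~6.6 mm node spacing, 10 subjects, 400 time
    points per session, two sessions, orthogonal mixing within 10 mm
    neighborhoods (half the 20 mm searchlight radius used downstream, so the
    misalignment is recoverable), 15 mm coarse-scale smoothness, and noise SD
    0.4 relative to unit signal SD.
    """

    subdivision: int = 8
    sphere_radius_mm: float = 50.0
    n_subjects: int = 10
    n_timepoints: int = 400
    n_sessions: int = 2
    latent_rank: int | None = None
    mixing_radius_mm: float = 10.0
    smoothness_mm: float = 15.0
    coarse_fraction: float = 0.5
    noise_sd: float = 0.4
    preserve_local_mean: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "subdivision",
            "sphere_radius_mm",
            "n_subjects",
            "n_timepoints",
            "n_sessions",
            "mixing_radius_mm",
            "smoothness_mm",
            "noise_sd",
        ):
            v = getattr(self, name)
            if v is None or v < 0 or (name != "noise_sd" and v <= 0):
                raise ValueError(f"invalid SyntheticSpec field: {name}={v!r}")
        if not 0.0 <= self.coarse_fraction <= 1.0:
            raise ValueError("coarse_fraction must be in [0, 1]")
        if self.latent_rank is not None and self.latent_rank < 1:
            raise ValueError("latent_rank must be positive or None")


@dataclass
class GroundTruth:
    """What the generator knows: the latent series, neighborhoods, and the
    per-subject orthogonal mixing blocks."""

    latent: dict  # session label -> (n_timepoints, m) z-scored array
    neighborhoods: list  # list of int arrays partitioning the mesh
    mixing_blocks: list  # mixing_blocks[subject][neighborhood] -> (k, k)
    mesh: SurfaceMesh = field(repr=False, default=None)

    def mixing_matrix(self, subject: int) -> sparse.csr_matrix:
        """Subject's full block-orthogonal mixing map as a sparse matrix."""
        rows, cols, vals = [], [], []
        for nb, block in zip(self.neighborhoods, self.mixing_blocks[subject]):
            rows.append(np.repeat(nb, len(nb)))
            cols.append(np.tile(nb, len(nb)))
            vals.append(block.ravel())
        m = self.mesh.n_nodes
        return sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(m, m),
        ).tocsr()


def _partition_neighborhoods(mesh: SurfaceMesh, radius_mm: float) -> list:
    """Greedy non-overlapping geodesic neighborhoods, centers by index order."""
    dmat = _pairwise_geodesic(mesh, limit=radius_mm * (1 + 1e-12))
    unassigned = np.ones(mesh.n_nodes, dtype=bool)
    out = []
    for v in range(mesh.n_nodes):
        if not unassigned[v]:
            continue
        row = dmat[v]
        nb = np.flatnonzero(unassigned & np.isfinite(row) & (row <= radius_mm))
        unassigned[nb] = False
        out.append(nb)
    return out


def _haar_orthogonal(k: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-distributed orthogonal matrix (QR with sign correction)."""
    a = rng.standard_normal((k, k))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _mean_preserving_orthogonal(k: int, rng: np.random.Generator) -> np.ndarray:
    """Orthogonal matrix fixing the constant vector, Haar on its complement.

    Individual topographic idiosyncrasy rearranges fine-scale structure but
    leaves local-average (coarse-scale) activity in register across subjects
    — which is what makes anatomical alignment work at the coarse scale.
    A map with ``Q @ 1 = 1`` preserves every neighborhood mean while freely
    remixing the orthogonal (fine-scale) subspace.
    """
    if k == 1:
        return np.ones((1, 1))
    # Householder basis whose first column is the normalized constant vector
    e = np.zeros(k)
    e[0] = 1.0
    u = e - np.full(k, 1.0 / np.sqrt(k))
    u /= np.linalg.norm(u)
    h = np.eye(k) - 2.0 * np.outer(u, u)
    inner = np.eye(k)
    inner[1:, 1:] = _haar_orthogonal(k - 1, rng)
    return h @ inner @ h.T


def _smoothing_operator(mesh: SurfaceMesh, smoothness_mm: float) -> sparse.csr_matrix:
    """Column-normalized Gaussian geodesic kernel: white input -> unit-variance
    spatially correlated output with correlation length ``smoothness_mm``."""
    cutoff = 3.0 * smoothness_mm
    dmat = _pairwise_geodesic(mesh, limit=cutoff)
    rows, cols, vals = [], [], []
    for j in range(mesh.n_nodes):
        row = dmat[j]
        src = np.flatnonzero(np.isfinite(row))
        w = np.exp(-(row[src] ** 2) / (2.0 * smoothness_mm**2))
        w = w / np.sqrt((w**2).sum())
        rows.append(src)
        cols.append(np.full(src.size, j))
        vals.append(w)
    m = mesh.n_nodes
    return sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    ).tocsr()


def _latent_session(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    smoother: sparse.csr_matrix,
    neighborhoods: list,
) -> np.ndarray:
    m = smoother.shape[0]
    coarse = rng.standard_normal((spec.n_timepoints, m)) @ smoother
    if spec.latent_rank is None:
        fine = rng.standard_normal((spec.n_timepoints, m))
    else:
        fine = np.empty((spec.n_timepoints, m))
        for nb in neighborhoods:
            k = min(spec.latent_rank, len(nb))
            basis = rng.standard_normal((spec.n_timepoints, k))
            load = rng.standard_normal((k, len(nb)))
            fine[:, nb] = basis @ load
    a = np.sqrt(spec.coarse_fraction)
    b = np.sqrt(1.0 - spec.coarse_fraction)
    return zscore(a * coarse + b * fine, warn_constant=False)


def generate_cohort(spec: SyntheticSpec) -> tuple[SubjectCohort, GroundTruth]:
    """Generate a multi-subject, multi-session cohort with ground truth.

    Subject ``i``'s native data in session ``s`` is
    ``latent_s @ W_i + noise_sd * E_is`` where ``W_i`` is block-orthogonal
    within non-overlapping geodesic neighborhoods (identical across sessions,
    as an individual trait) and ``E_is`` is white Gaussian noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    left = make_icosphere(spec.subdivision, spec.sphere_radius_mm, "left")
    right = make_icosphere(spec.subdivision, spec.sphere_radius_mm, "right")
    mesh = bilateral_mesh(left, right)

    neighborhoods = _partition_neighborhoods(mesh, spec.mixing_radius_mm)
    smoother = _smoothing_operator(mesh, spec.smoothness_mm)

    make_block = (
        _mean_preserving_orthogonal if spec.preserve_local_mean else _haar_orthogonal
    )
    mixing_blocks = [
        [make_block(len(nb), rng) for nb in neighborhoods]
        for _ in range(spec.n_subjects)
    ]

    subject_ids = [f"sub{i:02d}" for i in range(spec.n_subjects)]
    cohort = SubjectCohort(subject_ids, mesh=mesh)
    latent = {}
    gt = GroundTruth(latent, neighborhoods, mixing_blocks, mesh=mesh)
    for s in range(spec.n_sessions):
        label = f"session{s + 1}"
        z = _latent_session(spec, rng, smoother, neighborhoods)
        latent[label] = z
        for i, subj in enumerate(subject_ids):
            w = gt.mixing_matrix(i)
            native = np.asarray((w.T @ z.T).T)
            if spec.noise_sd > 0:
                native = native + spec.noise_sd * rng.standard_normal(native.shape)
            cohort.add(
                BrainDataMatrix(
                    native,
                    sample_kind="timepoints",
                    subject_id=subj,
                    session=label,
                )
            )
    return cohort, gt


def make_two_fold_sessions(spec: SyntheticSpec) -> tuple[SubjectCohort, GroundTruth]:
    """Cohort with disjoint derivation/validation sessions (labels
    ``session1`` / ``session2``)."""
    if spec.n_sessions < 2:
        raise ValueError("two-fold sessions require n_sessions >= 2")
    return generate_cohort(spec)
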