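"""Connectivity and response hyperalignment of whole-cortex cohorts.

Connectivity hyperalignment (CHA) derives a common model connectome from a
training session: coarse target searchlights supply a reduced set of shared
connectivity-target profiles; each subject's connectivity matrix (targets x
loci, Pearson correlations) is hyperaligned in overlapping surface
searchlights; the local orthogonal transforms are aggregated into one sparse
whole-cortex transformation per subject; and the model matrix is the mean of
the transformed connectivity matrices.  Response hyperalignment (RHA) is the
degenerate case where the rows are time-locked response samples instead of
connectivity targets, so it requires time-synchronized data.

Transforms must only ever be applied to data that played no role in their
derivation; helpers here enforce that session hygiene.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .data import SubjectCohort, zscore
from .searchlight import SearchlightHyperalignment, apply_transform
from .surface import (
    SearchlightAtlas,
    SurfaceMesh,
    build_searchlights,
    coarse_target_centers,
    make_icosphere,
    bilateral_mesh,
    searchlights_at,
)
from .targets import ConnectivityTargetSet, connectivity_profiles, derive_target_components

__all__ = [
    "CommonModel",
    "ConnectivityHyperalignment",
    "ResponseHyperalignment",
    "derive_common_model",
    "run_rha",
    "default_coarse_atlas",
]


@dataclass
class CommonModel:
    """A derived common model: model data matrix, per-subject whole-cortex
    transforms, and provenance."""

    model: np.ndarray
    transforms: list  # WholeCortexTransform per subject, cohort order
    subject_ids: list
    reference_subject: str
    derivation_session: str
    config: dict = field(default_factory=dict)
    target_set: ConnectivityTargetSet | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.transforms)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()[:16]

    def check_session(self, session: str) -> None:
        """Refuse data from the derivation session (cross-validation hygiene)."""
        if session == self.derivation_session:
            raise ValueError(
                f"session {session!r} was used to derive this model; "
                "validation requires independent data"
            )

    def apply(self, values: np.ndarray, subject: int) -> np.ndarray:
        """Z-score and map one subject's native data into the common space."""
        return apply_transform(zscore(values, warn_constant=False),
                               self.transforms[subject])


def default_coarse_atlas(
    mesh: SurfaceMesh,
    fine_subdivision: int,
    sphere_radius_mm: float,
    coarse_subdivision: int | None = None,
    target_radius_mm: float = 13.0,
) -> SearchlightAtlas:
    """Coarse target searchlights on a subsampled icosahedral grid.

    The coarse grid's subdivision defaults to a quarter of the fine grid's
    (mirroring the full-scale ico32 -> ico8 target-grid ratio); coarse nodes
    are mapped to their nearest fine nodes and used as searchlight centres.
    """
    if coarse_subdivision is None:
        coarse_subdivision = max(1, fine_subdivision // 4)
    cl = make_icosphere(coarse_subdivision, sphere_radius_mm, "left")
    cr = make_icosphere(coarse_subdivision, sphere_radius_mm, "right")
    coarse = bilateral_mesh(cl, cr)
    centers = coarse_target_centers(mesh, coarse)
    return searchlights_at(mesh, centers, target_radius_mm)


class ConnectivityHyperalignment(BaseEstimator):
    """Derive a common model connectome from one training session.

    Parameters
    ----------
    mesh : SurfaceMesh
        Shared cortical surface.
    atlas : SearchlightAtlas, optional
        Hyperalignment searchlights (default: one 20 mm searchlight per node).
    target_atlas : SearchlightAtlas, optional
        Coarse connectivity-target searchlights (default: 13 mm searchlights
        on a subsampled icosahedral grid).
    radius_mm, target_radius_mm : float
        Searchlight radii used when atlases are built internally.
    n_target_components : int, default 3
        Components per target searchlight.
    reference_index : int, default 0
        Reference subject (seeds the iteration; model dimensions follow its
        loci).
    feature_fraction : float or None
        Optional per-searchlight feature selection fraction.

    Attributes
    ----------
    common_model_ : CommonModel
    transforms_ : list of WholeCortexTransform
    model_ : (3 * n_targets, n_loci) ndarray
    target_set_ : ConnectivityTargetSet
    """

    def __init__(
        self,
        mesh: SurfaceMesh | None = None,
        atlas: SearchlightAtlas | None = None,
        target_atlas: SearchlightAtlas | None = None,
        radius_mm: float = 20.0,
        target_radius_mm: float = 13.0,
        n_target_components: int = 3,
        reference_index: int = 0,
        feature_fraction: float | None = None,
        fine_subdivision: int | None = None,
        sphere_radius_mm: float | None = None,
    ):
        self.mesh = mesh
        self.atlas = atlas
        self.target_atlas = target_atlas
        self.radius_mm = radius_mm
        self.target_radius_mm = target_radius_mm
        self.n_target_components = n_target_components
        self.reference_index = reference_index
        self.feature_fraction = feature_fraction
        self.fine_subdivision = fine_subdivision
        self.sphere_radius_mm = sphere_radius_mm

    def _resolve_atlases(self):
        atlas = self.atlas
        if atlas is None:
            atlas = build_searchlights(self.mesh, self.radius_mm)
        target_atlas = self.target_atlas
        if target_atlas is None:
            if self.fine_subdivision is None or self.sphere_radius_mm is None:
                raise ValueError(
                    "provide target_atlas, or fine_subdivision and "
                    "sphere_radius_mm so a coarse grid can be built"
                )
            target_atlas = default_coarse_atlas(
                self.mesh,
                self.fine_subdivision,
                self.sphere_radius_mm,
                target_radius_mm=self.target_radius_mm,
            )
        return atlas, target_atlas

    def fit(self, X: list, y=None, subject_ids=None, session: str = "train"):
        """Derive the model from per-subject training time series.

        ``X`` is a list of ``(n_timepoints, n_loci)`` arrays in cohort order.
        """
        if len(X) < 2:
            raise ValueError("need at least 2 subjects")
        X = [np.asarray(x, dtype=float) for x in X]
        atlas, target_atlas = self._resolve_atlases()
        self.atlas_, self.target_atlas_ = atlas, target_atlas

        self.target_set_ = derive_target_components(
            X,
            target_atlas,
            n_components=self.n_target_components,
            reference_index=self.reference_index,
        )
        # per-subject derivation connectivity matrices (targets x loci),
        # column z-scored so the Procrustes step needs no translation term
        conn = [
            zscore(
                connectivity_profiles(x, ts), warn_constant=False
            )
            for x, ts in zip(X, self.target_set_.subject_series)
        ]
        sl = SearchlightHyperalignment(
            atlas=atlas,
            reference_index=self.reference_index,
            feature_fraction=self.feature_fraction,
        ).fit(conn)
        self.transforms_ = sl.transforms_
        self.model_ = sl.model_
        if subject_ids is None:
            subject_ids = [str(i) for i in range(len(X))]
        for t, sid in zip(self.transforms_, subject_ids):
            t.subject_id = sid
        config = {
            "method": "cha",
            "radius_mm": float(atlas.radius_mm),
            "target_radius_mm": float(target_atlas.radius_mm),
            "n_target_components": int(self.n_target_components),
            "reference_index": int(self.reference_index),
            "feature_fraction": self.feature_fraction,
            "subject_order": list(subject_ids),
            "session": session,
        }
        self.common_model_ = CommonModel(
            model=self.model_,
            transforms=self.transforms_,
            subject_ids=list(subject_ids),
            reference_subject=subject_ids[self.reference_index],
            derivation_session=session,
            config=config,
            target_set=self.target_set_,
        )
        return self

    def transform(self, X: np.ndarray, subject: int = 0) -> np.ndarray:
        """Z-score and map one subject's (held-out) data into common space."""
        return self.common_model_.apply(np.asarray(X, dtype=float), subject)


class ResponseHyperalignment(BaseEstimator):
    """Hyperalignment driven by time-synchronized response matrices.

    Identical machinery to :class:`ConnectivityHyperalignment`, with the
    z-scored response time series themselves as the rows to be aligned; all
    subjects must therefore have the same number of time points.
    """

    def __init__(
        self,
        mesh: SurfaceMesh | None = None,
        atlas: SearchlightAtlas | None = None,
        radius_mm: float = 20.0,
        reference_index: int = 0,
        feature_fraction: float | None = None,
    ):
        self.mesh = mesh
        self.atlas = atlas
        self.radius_mm = radius_mm
        self.reference_index = reference_index
        self.feature_fraction = feature_fraction

    def fit(self, X: list, y=None, subject_ids=None, session: str = "train"):
        if len(X) < 2:
            raise ValueError("need at least 2 subjects")
        n_rows = {x.shape[0] for x in X}
        if len(n_rows) != 1:
            raise ValueError(
                "RHA requires responses synchronized across subjects; "
                f"got row counts {sorted(n_rows)}"
            )
        X = [zscore(np.asarray(x, dtype=float), warn_constant=False) for x in X]
        atlas = self.atlas
        if atlas is None:
            atlas = build_searchlights(self.mesh, self.radius_mm)
        self.atlas_ = atlas
        sl = SearchlightHyperalignment(
            atlas=atlas,
            reference_index=self.reference_index,
            feature_fraction=self.feature_fraction,
        ).fit(X)
        self.transforms_ = sl.transforms_
        self.model_ = sl.model_
        if subject_ids is None:
            subject_ids = [str(i) for i in range(len(X))]
        config = {
            "method": "rha",
            "radius_mm": float(atlas.radius_mm),
            "reference_index": int(self.reference_index),
            "subject_order": list(subject_ids),
            "session": session,
        }
        self.common_model_ = CommonModel(
            model=self.model_,
            transforms=self.transforms_,
            subject_ids=list(subject_ids),
            reference_subject=subject_ids[self.reference_index],
            derivation_session=session,
            config=config,
        )
        return self

    def transform(self, X: np.ndarray, subject: int = 0) -> np.ndarray:
        return self.common_model_.apply(np.asarray(X, dtype=float), subject)


def save_model(model: CommonModel, path) -> None:
    """Serialize a CommonModel: matrices in HDF5, provenance as JSON sidecar.

    Sparse transforms are stored as canonical row-major (row, col, value)
    triplets so serialization is byte-stable for a given derivation.
    """
    import h5py
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "model.h5", "w") as fh:
        fh.create_dataset("model", data=model.model, track_times=False)
        for i, t in enumerate(model.transforms):
            r, c, v = t.to_triplets()
            g = fh.create_group(f"transforms/{i:03d}")
            g.create_dataset("row", data=r, track_times=False)
            g.create_dataset("col", data=c, track_times=False)
            g.create_dataset("value", data=v, track_times=False)
            g.attrs["shape"] = t.shape
            g.attrs["subject_id"] = t.subject_id
    sidecar = {
        "subject_ids": model.subject_ids,
        "reference_subject": model.reference_subject,
        "derivation_session": model.derivation_session,
        "config": model.config,
        "config_hash": model.config_hash(),
    }
    with open(path / "provenance.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def load_model(path) -> CommonModel:
    import h5py
    from pathlib import Path

    from scipy import sparse

    from .searchlight import WholeCortexTransform

    path = Path(path)
    with open(path / "provenance.json") as fh:
        sidecar = json.load(fh)
    transforms = []
    with h5py.File(path / "model.h5", "r") as fh:
        model = fh["model"][()]
        for key in sorted(fh["transforms"]):
            g = fh["transforms"][key]
            mat = sparse.coo_matrix(
                (g["value"][()], (g["row"][()], g["col"][()])),
                shape=tuple(g.attrs["shape"]),
            )
            transforms.append(
                WholeCortexTransform(mat, subject_id=str(g.attrs["subject_id"]))
            )
    return CommonModel(
        model=model,
        transforms=transforms,
        subject_ids=list(sidecar["subject_ids"]),
        reference_subject=sidecar["reference_subject"],
        derivation_session=sidecar["derivation_session"],
        config=sidecar["config"],
    )


def derive_common_model(
    cohort: SubjectCohort, session: str, **params
) -> CommonModel:
    """Functional front end: CHA of one cohort session."""
    est = ConnectivityHyperalignment(mesh=cohort.mesh, **params)
    est.fit(
        cohort.session_matrices(session),
        subject_ids=cohort.subject_ids,
        session=session,
    )
    return est.common_model_


def run_rha(cohort: SubjectCohort, session: str, **params) -> CommonModel:
    """Functional front end: RHA of one cohort session."""
    est = ResponseHyperalignment(mesh=cohort.mesh, **params)
    est.fit(
        cohort.session_matrices(session),
        subject_ids=cohort.subject_ids,
        session=session,
    )
    return est.common_model_
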