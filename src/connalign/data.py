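"""Core data containers, column normalization, and cohort I/O.

The native on-disk container is an HDF5 file keyed ``subject/session`` with a
JSON manifest alongside it; round trips are bit exact.  Adapters read and
write GIFTI functional time series for interoperability with surface-based
neuroimaging tools.  Layout is sample-major everywhere: rows are samples
(time points, connectivity targets, or maps), columns are cortical loci.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "BrainDataMatrix",
    "SubjectCohort",
    "RoiSet",
    "zscore_columns",
    "zscore",
    "read_cohort",
    "write_cohort",
    "read_gifti_timeseries",
    "write_gifti_timeseries",
]

SAMPLE_KINDS = ("timepoints", "connectivity_targets", "maps")
SPACES = ("native", "common")


@dataclass
class BrainDataMatrix:
    """An ``n_samples x n_loci`` data matrix for one subject and session."""

    values: np.ndarray
    sample_kind: str = "timepoints"
    subject_id: str = ""
    session: str = ""
    space: str = "native"
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (samples x loci) array")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        if self.sample_kind not in SAMPLE_KINDS:
            raise ValueError(f"sample_kind must be one of {SAMPLE_KINDS}")
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]


def zscore(x: np.ndarray, warn_constant: bool = True) -> np.ndarray:
    """Column-wise z-scoring with the population-SD convention (divide by n).

    Constant columns become all-zero (with a warning): correlations with them
    are undefined and downstream code treats them as zero-signal loci.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to z-score")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population convention: ddof=0
    const = sd == 0
    if const.any() and warn_constant:
        warnings.warn(
            f"{int(const.sum())} constant column(s) set to zero during z-scoring"
        )
    sd_safe = np.where(const, 1.0, sd)
    out = (x - mu) / sd_safe
    out[:, const] = 0.0
    return out


def zscore_columns(data: BrainDataMatrix) -> BrainDataMatrix:
    """Return a column-standardized copy of ``data`` (mean 0, population SD 1)."""
    return replace(data, values=zscore(data.values), zscored=True)


class SubjectCohort:
    """Per-subject, per-session data matrices on a shared surface mesh."""

    def __init__(self, subject_ids, mesh=None):
        self.subject_ids = list(subject_ids)
        self.mesh = mesh
        self._data: dict = {}

    def add(self, data: BrainDataMatrix) -> None:
        if self.mesh is not None and data.n_loci != self.mesh.n_nodes:
            raise ValueError(
                f"subject {data.subject_id!r} session {data.session!r}: "
                f"{data.n_loci} loci but mesh has {self.mesh.n_nodes} nodes"
            )
        self._data[(data.subject_id, data.session)] = data

    def get(self, subject_id: str, session: str) -> BrainDataMatrix:
        key = (subject_id, session)
        if key not in self._data:
            raise KeyError(
                f"no data for subject {subject_id!r}, session {session!r}"
            )
        return self._data[key]

    def session_matrices(self, session: str) -> list:
        """Values for every subject in cohort order for one session."""
        return [self.get(s, session).values for s in self.subject_ids]

    @property
    def sessions(self) -> list:
        return sorted({k[1] for k in self._data})

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def items(self):
        return self._data.items()


def write_cohort(cohort: SubjectCohort, path) -> None:
    """Write a cohort to ``path`` (directory): ``cohort.h5`` + ``manifest.json``.

    Optionally includes the mesh as JSON so a cohort file is self-contained.
    """
    import h5py

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"index_base": 0, "subjects": cohort.subject_ids, "entries": []}
    with h5py.File(path / "cohort.h5", "w") as fh:
        for (subj, sess), dm in sorted(cohort.items()):
            ds = fh.create_dataset(f"{subj}/{sess}", data=dm.values)
            ds.attrs["sample_kind"] = dm.sample_kind
            ds.attrs["space"] = dm.space
            ds.attrs["zscored"] = dm.zscored
            manifest["entries"].append(
                {
                    "subject": subj,
                    "session": sess,
                    "n_samples": dm.n_samples,
                    "n_loci": dm.n_loci,
                    "sample_kind": dm.sample_kind,
                }
            )
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    if cohort.mesh is not None:
        cohort.mesh.save_json(path / "mesh.json")


def read_cohort(path, mesh=None) -> SubjectCohort:
    """Read a cohort written by :func:`write_cohort`; round trip is exact."""
    import h5py

    from .surface import SurfaceMesh

    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if mesh is None and (path / "mesh.json").exists():
        mesh = SurfaceMesh.load_json(path / "mesh.json")
    cohort = SubjectCohort(manifest["subjects"], mesh=mesh)
    with h5py.File(path / "cohort.h5", "r") as fh:
        for entry in manifest["entries"]:
            subj, sess = entry["subject"], entry["session"]
            if subj not in fh or sess not in fh[subj]:
                raise ValueError(
                    f"manifest lists subject {subj!r} session {sess!r} "
                    "but the container has no such matrix"
                )
            ds = fh[subj][sess]
            if list(ds.shape) != [entry["n_samples"], entry["n_loci"]]:
                raise ValueError(
                    f"shape mismatch for subject {subj!r} session {sess!r}: "
                    f"manifest says {(entry['n_samples'], entry['n_loci'])}, "
                    f"stored {ds.shape}"
                )
            cohort.add(
                BrainDataMatrix(
                    ds[()],
                    sample_kind=str(ds.attrs["sample_kind"]),
                    subject_id=subj,
                    session=sess,
                    space=str(ds.attrs["space"]),
                    zscored=bool(ds.attrs["zscored"]),
                )
            )
    return cohort


def write_gifti_timeseries(values: np.ndarray, path) -> None:
    """Write an ``n_samples x n_loci`` matrix as a GIFTI functional file.

    GIFTI stores one node-major data array per sample; this adapter transposes
    from the package's sample-major layout.
    """
    import nibabel as nib

    values = np.asarray(values, dtype=np.float32)
    darrays = [
        nib.gifti.GiftiDataArray(row, intent="NIFTI_INTENT_TIME_SERIES")
        for row in values
    ]
    nib.save(nib.gifti.GiftiImage(darrays=darrays), str(path))


def read_gifti_timeseries(path) -> np.ndarray:
    """Read a GIFTI functional file into sample-major layout (samples x loci)."""
    import nibabel as nib

    img = nib.load(str(path))
    if not img.darrays:
        raise ValueError(f"{path} contains no data arrays")
    return np.vstack([np.asarray(da.data, dtype=float) for da in img.darrays])


def write_nifti_timeseries(values: np.ndarray, path) -> None:
    """Write samples x loci data as a NIfTI pseudo-volume (loci, 1, 1, samples)."""
    import nibabel as nib

    values = np.asarray(values, dtype=np.float32)
    vol = values.T[:, None, None, :]
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def read_nifti_timeseries(path) -> np.ndarray:
    """Read a pseudo-volume NIfTI file into sample-major layout."""
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4 or vol.shape[1] != 1 or vol.shape[2] != 1:
        raise ValueError(
            f"{path}: expected an (n_loci, 1, 1, n_samples) pseudo-volume, "
            f"got shape {vol.shape}"
        )
    return vol[:, 0, 0, :].T


class RoiSet:
    """Named regions of interest, each an arbitrary (possibly overlapping)
    list of node ids."""

    def __init__(self, rois: dict):
        self.rois = {str(k): np.asarray(v, dtype=int) for k, v in rois.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.rois[name]

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)

    def validate(self, n_nodes: int) -> None:
        for name, nodes in self.rois.items():
            if nodes.size and (nodes.min() < 0 or nodes.max() >= n_nodes):
                raise ValueError(f"ROI {name!r} has node ids outside the mesh")

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"index_base": 0, "rois": {k: v.tolist() for k, v in self.rois.items()}},
                fh,
            )

    @classmethod
    def load_json(cls, path) -> "RoiSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["rois"] if "rois" in d else d)

    @classmethod
    def load_text(cls, path) -> "RoiSet":
        """Read a BED-like two-column text file: ``name<TAB>node`` per line
        (0-based node ids; '#' comment lines ignored)."""
        rois: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, node = line.split()
                rois.setdefault(name, []).append(int(node))
        return cls(rois)
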