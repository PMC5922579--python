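"""Connectivity targets: reduced target sets from coarse searchlights.

Deriving a whole-cortex common model from full connectomes would require an
``m x m`` connectivity matrix per subject; instead, derivation uses a reduced
target set.  Coarse target searchlights tile the cortex (at full scale, 1284
centres whose top-3 components give 3852 target profiles).  Because a naive
per-subject PCA would not give functionally corresponding components across
subjects, target components are derived from a group matrix: member loci of
each target searchlight are first hyperaligned across subjects using their
correlations with the mean time series of all target searchlights, the
aligned matrices are averaged, and an SVD of the group mean supplies the top
components; each subject's component time series is then the corresponding
weighted sum of its own member-locus time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .data import zscore
from .procrustes import hyperalign_field
from .surface import SearchlightAtlas

__all__ = [
    "ConnectivityTargetSet",
    "mean_target_timeseries",
    "target_correlation_matrix",
    "derive_target_components",
    "connectivity_profiles",
]


def _corr_columns(a: np.ndarray, b: np.ndarray, warn_constant: bool = True) -> np.ndarray:
    """Pearson correlations between all columns of ``a`` and of ``b``.

    Constant columns yield correlation 0 (with a warning), by convention.
    """
    if a.shape[0] != b.shape[0]:
        raise ValueError("series must share the number of time points")
    za = zscore(a, warn_constant=warn_constant)
    zb = zscore(b, warn_constant=warn_constant)
    return (za.T @ zb) / a.shape[0]


@dataclass
class ConnectivityTargetSet:
    """Reduced connectivity-target set shared across a cohort.

    Attributes
    ----------
    centers : (n_targets,) int array
        Fine-mesh node ids of the coarse target searchlight centres.
    members : list of int arrays
        Member loci per target searchlight.
    group_weights : list of (m_t, k) arrays
        Group component weights per target (mutually orthonormal columns;
        sign fixed so the largest-|weight| entry is positive).
    subject_weights : list of lists
        ``subject_weights[i][t]``: subject ``i``'s (m_t, k) weights mapping
        its member-locus series onto the group components.
    subject_series : list of (n_timepoints, k * n_targets) arrays
        Per-subject component time series (z-scored), the CHA target
        profiles.
    n_components : int
    """

    centers: np.ndarray
    members: list
    group_weights: list
    subject_weights: list
    subject_series: list
    n_components: int

    @property
    def n_targets(self) -> int:
        return len(self.centers)

    @property
    def n_profiles(self) -> int:
        return sum(w.shape[1] for w in self.group_weights)


def mean_target_timeseries(
    data: np.ndarray, target_atlas: SearchlightAtlas
) -> np.ndarray:
    """Mean z-scored time series per target searchlight.

    Column ``t`` is the unweighted mean over member loci of the z-scored
    locus time series of target searchlight ``t``.
    """
    z = zscore(np.asarray(data, dtype=float), warn_constant=False)
    cols = []
    for members in target_atlas.members:
        if len(members) == 0:
            raise ValueError("empty target searchlight")
        cols.append(z[:, members].mean(axis=1))
    return np.column_stack(cols)


def target_correlation_matrix(
    data: np.ndarray, members: np.ndarray, mean_series: np.ndarray
) -> np.ndarray:
    """``(n_targets, n_members)`` correlations between every target's mean
    series and every member locus of one target searchlight."""
    data = np.asarray(data, dtype=float)
    return _corr_columns(mean_series, data[:, members])


def derive_target_components(
    data: list,
    target_atlas: SearchlightAtlas,
    n_components: int = 3,
    reference_index: int = 0,
    zscore_series: bool = True,
) -> ConnectivityTargetSet:
    """Shared target components for every coarse target searchlight.

    Parameters
    ----------
    data : list of (n_timepoints, n_loci) arrays
        One training time-series matrix per subject.
    n_components : int, default 3
        Components kept per target searchlight (fewer if the searchlight has
        fewer loci, with a warning).
    zscore_series : bool, default True
        Z-score the per-subject component time series before use as
        connectivity targets.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 subjects")
    mean_series = [mean_target_timeseries(x, target_atlas) for x in data]
    z = [zscore(np.asarray(x, dtype=float), warn_constant=False) for x in data]
    n_tp = z[0].shape[0]

    group_weights, subject_weights = [], []
    per_subject_cols = [[] for _ in data]
    for t, members in enumerate(target_atlas.members):
        mats = [
            target_correlation_matrix(x, members, ms)
            for x, ms in zip(data, mean_series)
        ]
        transforms, _ = hyperalign_field(mats, reference_index=reference_index)
        group_mean = np.mean([c @ r for c, r in zip(mats, transforms)], axis=0)
        k = min(n_components, min(group_mean.shape))
        if k < n_components:
            warnings.warn(
                f"target searchlight {t} supports only {k} component(s)"
            )
        _, _, vt = linalg.svd(group_mean, full_matrices=False)
        v = vt[:k].T  # (m_t, k) right singular vectors
        # deterministic sign: largest-|weight| entry of each component positive
        for c in range(k):
            peak = np.argmax(np.abs(v[:, c]))
            if v[peak, c] < 0:
                v[:, c] = -v[:, c]
        group_weights.append(v)
        subject_weights.append([r[: len(members)] @ v for r in transforms])
        for i in range(len(data)):
            per_subject_cols[i].append(z[i][:, members] @ subject_weights[t][i])

    subject_series = []
    for i in range(len(data)):
        series = np.concatenate(per_subject_cols[i], axis=1)
        if zscore_series:
            series = zscore(series, warn_constant=False)
        subject_series.append(series)

    subj_w = [[subject_weights[t][i] for t in range(target_atlas.n_searchlights)]
              for i in range(len(data))]
    return ConnectivityTargetSet(
        centers=np.asarray(target_atlas.centers, dtype=int),
        members=list(target_atlas.members),
        group_weights=group_weights,
        subject_weights=subj_w,
        subject_series=subject_series,
        n_components=n_components,
    )


def connectivity_profiles(
    timeseries: np.ndarray, target_series: np.ndarray | None = None
) -> np.ndarray:
    """Connectivity matrix: rows are targets, columns are loci.

    Entry ``(t, s)`` is the Pearson correlation of target ``t``'s series with
    locus ``s``'s series.  With ``target_series=None`` the full connectome is
    computed (targets are all loci; the unit diagonal is retained).
    """
    timeseries = np.asarray(timeseries, dtype=float)
    if timeseries.shape[0] < 3:
        raise ValueError("need at least 3 time points for connectivity")
    if target_series is None:
        target_series = timeseries
    return _corr_columns(
        np.asarray(target_series, dtype=float), timeseries, warn_constant=True
    )
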