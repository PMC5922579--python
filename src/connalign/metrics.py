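"""Validation statistics for common model connectomes.

All intersubject statistics follow the leave-one-out scheme: a subject's data
are compared with the plain (raw-correlation) mean of all other subjects'
data, and only the resulting correlation values are Fisher-z transformed
before averaging across subjects and folds (clipped at |r| <= 1 - 1e-7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import RoiSet, zscore
from .surface import DistanceBins, SearchlightAtlas, SurfaceMesh

__all__ = [
    "IscMap",
    "PsfCurve",
    "BsmvpcResult",
    "isc_connectivity",
    "wsc_connectivity",
    "psf",
    "rdm_isc",
    "bsmvpc",
    "map_isc",
    "filter_control",
    "bootstrap_ci",
    "roi_aggregate",
    "fisher_mean",
]

_CLIP = 1.0 - 1e-7


def fisher_mean(r: np.ndarray, axis=0) -> np.ndarray:
    """Fisher-z average of correlation values along ``axis``."""
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return np.tanh(z.mean(axis=axis))


def _colwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation between matching columns of two (n, m) matrices.

    Constant columns contribute correlation 0 (with a warning)."""
    if a.shape != b.shape:
        raise ValueError("matrices must have equal shapes")
    const = (a.std(axis=0) == 0) | (b.std(axis=0) == 0)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant profile(s) contribute ISC 0"
        )
    za = zscore(a, warn_constant=False)
    zb = zscore(b, warn_constant=False)
    return (za * zb).sum(axis=0) / a.shape[0]


@dataclass
class IscMap:
    """Per-node correlation map, Fisher-averaged across subjects/folds."""

    values: np.ndarray
    alignment: str = ""

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class PsfCurve:
    """Point-spread function: mean profile correlation per distance bin."""

    distances_mm: np.ndarray
    values: np.ndarray  # NaN for skipped (empty) bins
    slope: float  # per mm; positive = correlation falls off with distance
    scope: str = "whole_cortex"


@dataclass
class BsmvpcResult:
    """Between-subject multivariate pattern classification accuracies."""

    accuracies: np.ndarray  # per searchlight, % correct (subject mean)
    chance_pct: float
    window: int
    n_candidates: int


def _loo_means(mats: list) -> list:
    total = np.sum(mats, axis=0)
    n = len(mats)
    return [(total - m) / (n - 1) for m in mats]


def isc_connectivity(profiles: list, alignment: str = "") -> IscMap:
    """Intersubject correlation of connectivity profiles per cortical locus.

    ``profiles`` is a list of (n_targets, n_loci) connectivity matrices, one
    per subject.  Each subject's profile at a locus (a column) is correlated
    with the mean of the other subjects' profiles at the same locus; values
    are Fisher-averaged across subjects.
    """
    if len(profiles) < 3:
        raise ValueError("leave-one-out ISC needs at least 3 subjects")
    others = _loo_means(profiles)
    rs = np.stack(
        [_colwise_corr(p, o) for p, o in zip(profiles, others)]
    )
    return IscMap(fisher_mean(rs, axis=0), alignment=alignment)


def wsc_connectivity(
    profiles_a: list, profiles_b: list, alignment: str = "within_subject"
) -> IscMap:
    """Within-subject between-session correlation of connectivity profiles."""
    if len(profiles_a) != len(profiles_b):
        raise ValueError("need both sessions for every subject")
    rs = np.stack(
        [_colwise_corr(a, b) for a, b in zip(profiles_a, profiles_b)]
    )
    return IscMap(fisher_mean(rs, axis=0), alignment=alignment)


def _pair_corr_means(zp: np.ndarray, zo: np.ndarray, bins: DistanceBins):
    """Per-bin (sum of pair correlations, pair count) for one subject."""
    n_tp, m = zp.shape
    sums = np.zeros(bins.n_bins)
    counts = np.zeros(bins.n_bins, dtype=int)
    for v in range(m):
        col = zp[:, v]
        for k, nbrs in enumerate(bins.bins[v]):
            if nbrs.size == 0:
                continue
            r = (zo[:, nbrs].T @ col) / n_tp
            sums[k] += r.sum()
            counts[k] += r.size
    return sums, counts


def psf(
    profiles: list,
    bins: DistanceBins,
    other_profiles: list | None = None,
    alignment: str = "",
    scope: str = "whole_cortex",
) -> PsfCurve:
    """Spatial point-spread function of connectivity-profile correlations.

    For each subject, the profile at each locus is correlated with profiles
    at loci in each distance bin of either the leave-one-out mean of other
    subjects (intersubject mode, default) or the same subject's other session
    (``other_profiles`` given; within-subject mode).  Per-subject bin means
    are Fisher-averaged across subjects, and the slope is the negated OLS fit
    of bin means against nominal bin distance, so a steeper fall-off gives a
    larger (positive) slope.
    """
    if other_profiles is None:
        others = _loo_means(profiles)
    else:
        if len(other_profiles) != len(profiles):
            raise ValueError("need other-session profiles for every subject")
        others = other_profiles
    per_subject = []
    for p, o in zip(profiles, others):
        zp = zscore(p, warn_constant=False)
        zo = zscore(o, warn_constant=False)
        sums, counts = _pair_corr_means(zp, zo, bins)
        with np.errstate(invalid="ignore"):
            per_subject.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
    per_subject = np.stack(per_subject)
    empty = np.isnan(per_subject).any(axis=0)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty distance bin(s) skipped")
    vals = np.full(bins.n_bins, np.nan)
    keep = ~empty
    vals[keep] = fisher_mean(per_subject[:, keep], axis=0)
    d = np.asarray(bins.distances_mm)[keep]
    v = vals[keep]
    if d.size >= 2:
        slope = -np.polyfit(d, v, 1)[0]
    else:
        slope = np.nan
    return PsfCurve(np.asarray(bins.distances_mm), vals, float(slope), scope=scope)


def _rdm_vector(patterns: np.ndarray) -> np.ndarray:
    """Vectorized upper triangle (no diagonal) of the time-point-by-time-point
    pattern-correlation matrix."""
    n_tp, k = patterns.shape
    z = zscore(patterns.T, warn_constant=False)  # standardize each pattern
    rdm = (z.T @ z) / k
    iu = np.triu_indices(n_tp, k=1)
    return rdm[iu]


def rdm_isc(responses: list, atlas: SearchlightAtlas, alignment: str = "") -> IscMap:
    """ISC of local representational geometry, one value per searchlight.

    Each subject's searchlight RDM (pairwise correlations between time-point
    patterns; flattened upper triangle, diagonal excluded) is correlated with
    the mean of the other subjects' RDMs.
    """
    if len(responses) < 3:
        raise ValueError("leave-one-out ISC needs at least 3 subjects")
    if responses[0].shape[0] < 3:
        raise ValueError("need at least 3 time points for an RDM")
    out = np.empty(atlas.n_searchlights)
    for j, members in enumerate(atlas.members):
        rdms = [_rdm_vector(x[:, members]) for x in responses]
        others = _loo_means(rdms)
        rs = [
            _colwise_corr(r[:, None], o[:, None])[0]
            for r, o in zip(rdms, others)
        ]
        out[j] = fisher_mean(np.asarray(rs), axis=0)
    return IscMap(out, alignment=alignment)


def _windowed(x: np.ndarray, window: int) -> np.ndarray:
    """(n_candidates, window * n_loci) sliding-window row stack."""
    n_tp, k = x.shape
    n_cand = n_tp - window + 1
    sw = np.lib.stride_tricks.sliding_window_view(x, (window, k))[:, 0]
    return sw.reshape(n_cand, window * k)


def bsmvpc(
    responses: list,
    atlas: SearchlightAtlas,
    window: int = 6,
    alignment: str = "",
) -> BsmvpcResult:
    """Between-subject classification of time segments per searchlight.

    Each subject's ``window``-sample local response pattern at every sliding
    start index is matched, by 1-nearest-neighbor correlation distance,
    against the other subjects' mean patterns at all candidate start indices
    (``n_candidates = n_timepoints - window + 1``); ties go to the lowest
    start index.  Accuracy is the percentage of correctly matched segments,
    averaged over subjects; chance is ``100 / n_candidates``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_tp = responses[0].shape[0]
    if n_tp < window:
        raise ValueError("fewer time points than the window length")
    n_cand = n_tp - window + 1
    others = _loo_means(responses)
    acc = np.zeros(atlas.n_searchlights)
    for j, members in enumerate(atlas.members):
        per_subj = []
        for x, o in zip(responses, others):
            wp = _windowed(x[:, members], window)
            wo = _windowed(o[:, members], window)
            zp = zscore(wp.T, warn_constant=False).T  # row-standardize
            zo = zscore(wo.T, warn_constant=False).T
            corr = (zp @ zo.T) / wp.shape[1]
            pred = np.argmax(corr, axis=1)
            per_subj.append(100.0 * np.mean(pred == np.arange(n_cand)))
        acc[j] = np.mean(per_subj)
    return BsmvpcResult(acc, 100.0 / n_cand, window, n_cand)


def map_isc(maps: list, alignment: str = "") -> np.ndarray:
    """Leave-one-out ISC of per-node maps; one value per map (row)."""
    if len(maps) < 3:
        raise ValueError("leave-one-out ISC needs at least 3 subjects")
    others = _loo_means(maps)
    rs = np.stack(
        [_colwise_corr(m.T, o.T) for m, o in zip(maps, others)]
    )  # (n_subjects, n_maps), correlating over nodes
    return fisher_mean(rs, axis=0)


def filter_control(
    cohort,
    derivation_session: str,
    validation_session: str,
    **cha_params,
) -> list:
    """Hyperalignment-filtered but anatomically aligned validation data.

    Derives one common model per reference subject; subject ``k``'s
    validation data are transformed into the model whose reference is subject
    ``k + 1`` (cyclically), so every connectome is filtered by hyperalignment
    while the correspondence across subjects is by node index only.  Returns
    the list of transformed validation time-series arrays in cohort order.
    """
    from .cha import ConnectivityHyperalignment

    train = cohort.session_matrices(derivation_session)
    val = cohort.session_matrices(validation_session)
    n = len(train)
    if n < 2:
        raise ValueError("filter control needs at least 2 subjects")
    out = [None] * n
    for ref in range(n):
        est = ConnectivityHyperalignment(
            mesh=cohort.mesh, reference_index=ref, **cha_params
        )
        est.fit(train, subject_ids=cohort.subject_ids, session=derivation_session)
        k = (ref - 1) % n  # the subject whose next-in-cycle reference is `ref`
        out[k] = est.transform(val[k], subject=k)
    return out


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    level: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean over subject resamples.

    Returns ``(mean, ci_low, ci_high)``; seeded and reproducible.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 subjects")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return float(values.mean()), float(lo), float(hi)


def roi_aggregate(node_map: np.ndarray, rois: RoiSet) -> dict:
    """Mean of a node-wise map within each (possibly overlapping) ROI."""
    node_map = np.asarray(node_map, dtype=float)
    return {name: float(node_map[rois[name]].mean()) for name in rois}
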