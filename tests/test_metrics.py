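"""Validation statistics: ISC, WSC, PSF, RDM ISC, bsMVPC, bootstrap, ROIs."""

import numpy as np
import pytest

from connalign import (
    DistanceBins,
    RoiSet,
    SearchlightAtlas,
    bootstrap_ci,
    bsmvpc,
    isc_connectivity,
    map_isc,
    psf,
    rdm_isc,
    roi_aggregate,
    wsc_connectivity,
)
from connalign.metrics import fisher_mean


def loo_isc_oracle(profiles):
    """Explicit leave-one-out loop, Fisher-averaged, per node."""
    n = len(profiles)
    m = profiles[0].shape[1]
    out = np.empty(m)
    for v in range(m):
        rs = []
        for i in range(n):
            others = np.mean(
                [profiles[k][:, v] for k in range(n) if k != i], axis=0
            )
            rs.append(np.corrcoef(profiles[i][:, v], others)[0, 1])
        out[v] = np.tanh(np.mean(np.arctanh(np.clip(rs, -1 + 1e-7, 1 - 1e-7))))
    return out


class TestIsc:
    def test_identical_subjects_isc_one(self, rng):
        p = rng.standard_normal((30, 6))
        isc = isc_connectivity([p.copy() for _ in range(4)])
        np.testing.assert_allclose(isc.values, 1.0, atol=1e-6)

    def test_independent_profiles_near_zero(self, rng):
        profiles = [rng.standard_normal((3852, 20)) for _ in range(4)]
        isc = isc_connectivity(profiles)
        assert np.mean(np.abs(isc.values) < 0.05) > 0.99

    def test_matches_loop_oracle(self, rng):
        profiles = [rng.standard_normal((12, 5)) for _ in range(3)]
        isc = isc_connectivity(profiles)
        np.testing.assert_allclose(isc.values, loo_isc_oracle(profiles), atol=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        profiles = [rng.standard_normal((12, 5)) for _ in range(3)]
        base = isc_connectivity(profiles).values
        scaled = [2.5 * p + 1.0 for p in profiles]
        np.testing.assert_allclose(
            isc_connectivity(scaled).values, base, atol=1e-10
        )

    def test_constant_profile_contributes_zero(self, rng):
        profiles = [rng.standard_normal((10, 3)) for _ in range(3)]
        profiles[0][:, 1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            isc = isc_connectivity(profiles)
        assert np.isfinite(isc.values).all()

    def test_needs_three_subjects(self, rng):
        with pytest.raises(ValueError):
            isc_connectivity([rng.standard_normal((5, 3))] * 2)


class TestWsc:
    def test_identical_sessions(self, rng):
        p = [rng.standard_normal((20, 4)) for _ in range(3)]
        wsc = wsc_connectivity(p, [x.copy() for x in p])
        np.testing.assert_allclose(wsc.values, 1.0, atol=1e-6)

    def test_independent_sessions_near_zero(self, rng):
        a = [rng.standard_normal((2000, 10)) for _ in range(3)]
        b = [rng.standard_normal((2000, 10)) for _ in range(3)]
        assert np.abs(wsc_connectivity(a, b).values).max() < 0.1

    def test_matches_loop_oracle(self, rng):
        a = [rng.standard_normal((15, 4)) for _ in range(3)]
        b = [rng.standard_normal((15, 4)) for _ in range(3)]
        wsc = wsc_connectivity(a, b)
        for v in range(4):
            rs = [np.corrcoef(x[:, v], y[:, v])[0, 1] for x, y in zip(a, b)]
            assert wsc.values[v] == pytest.approx(fisher_mean(np.asarray(rs)), abs=1e-10)


class TestPsf:
    def test_profiles_constant_across_mesh_flat_curve(self, ico2_pair, rng):
        col = rng.standard_normal(30)
        p = np.tile(col[:, None], (1, ico2_pair.n_nodes))
        bins = DistanceBins.from_mesh(ico2_pair, n_bins=3)
        curve = psf([p.copy() for _ in range(3)], bins)
        np.testing.assert_allclose(
            curve.values[np.isfinite(curve.values)], curve.values[0], atol=1e-6
        )
        assert curve.slope == pytest.approx(0.0, abs=1e-6)

    def test_locus_unique_profiles_steep_psf(self, ico2_pair, rng):
        """Distinct profiles per node, shared across subjects: bin-0
        correlation is 1, far bins are near zero, slope positive."""
        p = rng.standard_normal((40, ico2_pair.n_nodes))
        bins = DistanceBins.from_mesh(ico2_pair, n_bins=3)
        curve = psf([p + 0.01 * rng.standard_normal(p.shape) for _ in range(3)], bins)
        assert curve.values[0] > 0.99
        assert curve.values[0] > curve.values[1] + 0.5
        assert curve.slope > 0

    def test_slope_equals_hand_ols(self, ico2_pair, rng):
        profiles = [rng.standard_normal((30, ico2_pair.n_nodes)) for _ in range(3)]
        bins = DistanceBins.from_mesh(ico2_pair, n_bins=3)
        curve = psf(profiles, bins)
        keep = np.isfinite(curve.values)
        d = curve.distances_mm[keep]
        v = curve.values[keep]
        dm = d - d.mean()
        slope_hand = (dm * (v - v.mean())).sum() / (dm**2).sum()
        assert curve.slope == pytest.approx(-slope_hand, abs=1e-12)

    def test_bin0_close_to_isc_map_mean(self, ico2_pair, rng):
        shared = rng.standard_normal((25, ico2_pair.n_nodes))
        profiles = [
            shared + 0.5 * rng.standard_normal(shared.shape) for _ in range(4)
        ]
        bins = DistanceBins.from_mesh(ico2_pair, n_bins=2)
        curve = psf(profiles, bins)
        isc = isc_connectivity(profiles)
        assert curve.values[0] == pytest.approx(isc.values.mean(), abs=0.02)

    def test_within_subject_mode(self, ico2_pair, rng):
        a = [rng.standard_normal((20, ico2_pair.n_nodes)) for _ in range(3)]
        bins = DistanceBins.from_mesh(ico2_pair, n_bins=2)
        curve = psf(a, bins, other_profiles=[x.copy() for x in a])
        assert curve.values[0] == pytest.approx(1.0, abs=1e-6)

    def test_empty_bin_skipped_with_warning(self, ico2_pair, rng):
        profiles = [rng.standard_normal((20, ico2_pair.n_nodes)) for _ in range(3)]
        edge = ico2_pair.mean_edge_length
        bins = DistanceBins.from_mesh(
            ico2_pair, distances_mm=(0.0, 0.3 * edge, edge)
        )
        with pytest.warns(UserWarning, match="empty"):
            curve = psf(profiles, bins)
        assert np.isnan(curve.values[1])


class TestRdmIsc:
    def test_identical_subjects(self, rng):
        x = rng.standard_normal((12, 8))
        atlas = SearchlightAtlas(5.0, np.array([0]), [np.arange(8)])
        isc = rdm_isc([x.copy() for _ in range(3)], atlas)
        np.testing.assert_allclose(isc.values, 1.0, atol=1e-6)

    def test_upper_triangle_length(self):
        n = 40
        iu = np.triu_indices(n, k=1)
        assert iu[0].size == n * (n - 1) // 2

    def test_matches_loop_oracle(self, rng):
        data = [rng.standard_normal((4, 3)) for _ in range(3)]
        atlas = SearchlightAtlas(5.0, np.array([0]), [np.arange(3)])
        got = rdm_isc(data, atlas).values[0]
        rdms = []
        for x in data:
            rdm = np.corrcoef(x)  # 4x4 pattern correlations
            rdms.append(np.array([rdm[i, j] for i in range(4) for j in range(i + 1, 4)]))
        rs = []
        for i in range(3):
            others = np.mean([rdms[k] for k in range(3) if k != i], axis=0)
            rs.append(np.corrcoef(rdms[i], others)[0, 1])
        assert got == pytest.approx(fisher_mean(np.asarray(rs)), abs=1e-10)

    def test_too_few_timepoints(self, rng):
        atlas = SearchlightAtlas(5.0, np.array([0]), [np.arange(3)])
        with pytest.raises(ValueError):
            rdm_isc([rng.standard_normal((2, 3))] * 3, atlas)


class TestBsmvpc:
    def test_identical_subjects_perfect(self, rng):
        x = rng.standard_normal((30, 5))
        atlas = SearchlightAtlas(5.0, np.array([0]), [np.arange(5)])
        res = bsmvpc([x.copy() for _ in range(3)], atlas, window=6)
        assert res.accuracies[0] == pytest.approx(100.0)
        assert res.n_candidates == 25
        assert res.chance_pct == pytest.approx(4.0)

    def test_null_accuracy_within_binomial_band(self, rng):
        """Independent data, 200 candidates: accuracy consistent with the
        1/200 chance level (99% binomial band on pooled trials)."""
        from scipy import stats

        atlas = SearchlightAtlas(5.0, np.array([0]), [np.arange(8)])
        data = [rng.standard_normal((205, 8)) for _ in range(4)]
        res = bsmvpc(data, atlas, window=6)
        assert res.n_candidates == 200
        trials = 4 * 200
        correct = res.accuracies[0] / 100.0 * trials
        hi = stats.binom.ppf(0.995, trials, 1 / 200)
        assert correct <= hi

    def test_scaling_invariance(self, rng):
        atlas = SearchlightAtlas(5.0, np.array([0]), [np.arange(4)])
        data = [rng.standard_normal((20, 4)) for _ in range(3)]
        a = bsmvpc(data, atlas, window=3)
        b = bsmvpc([7.0 * x for x in data], atlas, window=3)
        np.testing.assert_allclose(a.accuracies, b.accuracies)

    def test_chance_decreases_with_candidates(self, rng):
        atlas = SearchlightAtlas(5.0, np.array([0]), [np.arange(3)])
        data = [rng.standard_normal((30, 3)) for _ in range(3)]
        short = bsmvpc([d[:15] for d in data], atlas, window=3)
        long = bsmvpc(data, atlas, window=3)
        assert long.chance_pct < short.chance_pct

    def test_window_errors(self, rng):
        atlas = SearchlightAtlas(5.0, np.array([0]), [np.arange(3)])
        data = [rng.standard_normal((10, 3))] * 3
        with pytest.raises(ValueError):
            bsmvpc(data, atlas, window=0)
        with pytest.raises(ValueError):
            bsmvpc(data, atlas, window=11)


class TestMapIsc:
    def test_identical_maps(self, rng):
        m = rng.standard_normal((5, 30))
        np.testing.assert_allclose(
            map_isc([m.copy() for _ in range(3)]), 1.0, atol=1e-6
        )

    def test_alternating_sign_flips_give_minus_one(self, rng):
        m = rng.standard_normal((2, 30))
        vals = map_isc([m, -m, m, -m])
        np.testing.assert_allclose(vals, -1.0, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        maps = [rng.standard_normal((3, 12)) for _ in range(4)]
        got = map_isc(maps)
        for t in range(3):
            rs = []
            for i in range(4):
                others = np.mean(
                    [maps[k][t] for k in range(4) if k != i], axis=0
                )
                rs.append(np.corrcoef(maps[i][t], others)[0, 1])
            assert got[t] == pytest.approx(fisher_mean(np.asarray(rs)), abs=1e-10)


class TestBootstrap:
    def test_degenerate_zero_width(self):
        mean, lo, hi = bootstrap_ci(np.full(8, 0.3), n_boot=500, seed=0)
        assert mean == lo == hi == pytest.approx(0.3)

    def test_seeded_rerun_identical(self, rng):
        vals = rng.standard_normal(10)
        assert bootstrap_ci(vals, n_boot=1000, seed=5) == bootstrap_ci(
            vals, n_boot=1000, seed=5
        )

    def test_interval_brackets_mean(self, rng):
        vals = rng.normal(2.0, 0.5, 30)
        mean, lo, hi = bootstrap_ci(vals, n_boot=2000, seed=1)
        assert lo < mean < hi

    def test_errors(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0]), n_boot=10)
        with pytest.raises(ValueError):
            bootstrap_ci(np.ones(5), n_boot=0)


class TestFilterControl:
    @pytest.fixture(scope="class")
    def identical_cohort(self, ico2_pair):
        from connalign import BrainDataMatrix, SubjectCohort

        rng = np.random.default_rng(9)
        cohort = SubjectCohort(["a", "b", "c"], mesh=ico2_pair)
        per_session = {
            s: rng.standard_normal((100, ico2_pair.n_nodes))
            for s in ("session1", "session2")
        }
        for subj in cohort.subject_ids:
            for sess, vals in per_session.items():
                cohort.add(
                    BrainDataMatrix(vals.copy(), subject_id=subj, session=sess)
                )
        return cohort

    def test_identical_subjects_equal_cha_filtering(self, identical_cohort):
        """With identical subjects every reference gives the same model, so
        the filter control equals the CHA-transformed data exactly."""
        import warnings

        from connalign import (
            build_searchlights,
            default_coarse_atlas,
            filter_control,
        )
        from connalign.cha import ConnectivityHyperalignment

        cohort = identical_cohort
        atlas = build_searchlights(cohort.mesh, 27.0)
        tatlas = default_coarse_atlas(
            cohort.mesh, 2, 25.0, coarse_subdivision=1, target_radius_mm=14.0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fc = filter_control(
                cohort, "session1", "session2", atlas=atlas, target_atlas=tatlas
            )
            est = ConnectivityHyperalignment(
                mesh=cohort.mesh, atlas=atlas, target_atlas=tatlas
            ).fit(cohort.session_matrices("session1"))
            val = cohort.session_matrices("session2")
            cha = [est.transform(v, i) for i, v in enumerate(val)]
        for a, b in zip(fc, cha):
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_cyclic_assignment_covers_all_subjects(self, identical_cohort):
        import warnings

        from connalign import build_searchlights, default_coarse_atlas, filter_control

        cohort = identical_cohort
        atlas = build_searchlights(cohort.mesh, 27.0)
        tatlas = default_coarse_atlas(
            cohort.mesh, 2, 25.0, coarse_subdivision=1, target_radius_mm=14.0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fc = filter_control(
                cohort, "session1", "session2", atlas=atlas, target_atlas=tatlas
            )
        assert len(fc) == cohort.n_subjects
        assert all(x is not None and x.shape == (100, cohort.mesh.n_nodes) for x in fc)


class TestRoiAggregate:
    def test_single_node_roi(self):
        vals = np.arange(10.0)
        out = roi_aggregate(vals, RoiSet({"one": [3]}))
        assert out["one"] == 3.0

    def test_overlapping_rois_independent(self):
        vals = np.arange(6.0)
        out = roi_aggregate(vals, RoiSet({"a": [0, 1, 2], "b": [2, 3]}))
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(2.5)

    def test_matches_loop_mean(self, rng):
        vals = rng.standard_normal(20)
        nodes = [1, 4, 7, 19]
        out = roi_aggregate(vals, RoiSet({"r": nodes}))
        assert out["r"] == pytest.approx(sum(vals[n] for n in nodes) / 4)
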