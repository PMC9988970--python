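import numpy as np
import pytest

from ventfc import generate_montage, simulate_recording
from ventfc.synthetic import (CohortSpec, RecordingParams, VVTrajectorySpec,
                              attenuate_correlation, simulate_cohort,
                              simulate_session_records, simulate_vv_trajectory,
                              study_cohort_spec)


class TestSimulateRecording:
    def test_sample_count_matches_duration(self, montage20):
        rec, _ = simulate_recording(montage20, 408.0, 10.17, seed=0)
        assert rec.intensity.shape == (4149, 20, 2)  # floor(408 * 10.17)

    def test_seed_determinism_bit_identical(self, montage20):
        a, _ = simulate_recording(montage20, 160.0, 10.17, seed=5)
        b, _ = simulate_recording(montage20, 160.0, 10.17, seed=5)
        assert np.array_equal(a.intensity, b.intensity)

    def test_different_seeds_differ(self, montage20):
        a, _ = simulate_recording(montage20, 160.0, 10.17, seed=5)
        b, _ = simulate_recording(montage20, 160.0, 10.17, seed=6)
        assert not np.array_equal(a.intensity, b.intensity)

    def test_non_psd_target_raises_naming_eigenvalue(self, montage20):
        bad = np.full((20, 20), 0.99)
        bad[0, 1] = bad[1, 0] = -0.99
        np.fill_diagonal(bad, 1.0)
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_recording(montage20, 160.0, 10.17,
                               RecordingParams(correlation=bad), seed=0)

    def test_too_short_session_rejected(self, montage20):
        with pytest.raises(ValueError):
            simulate_recording(montage20, 100.0, 10.17, seed=0)

    def test_fs_must_resolve_cardiac(self, montage20):
        with pytest.raises(ValueError):
            simulate_recording(montage20, 300.0, 5.0, seed=0)

    def test_identity_target_yields_uncorrelated_band(self, montage20):
        """With identity target and no artifacts, band-limited channel
        correlations stay within +/-0.15 of zero at 408 s."""
        params = RecordingParams(correlation=np.eye(20), motion_rate_per_min=0,
                                 dropout_rate_per_min=0, cardiac_free_rate=0,
                                 drift_sd=0.0)
        rec, _ = simulate_recording(montage20, 408.0, 10.17, params, seed=3)
        # the OD is dominated by the band-limited latent (cardiac and noise
        # carry ~1% of its variance), so its correlations read out the latent
        od = -np.log(rec.intensity[:, :, 0] / rec.intensity[:, :, 0].mean(0))
        corr = np.corrcoef(od, rowvar=False)
        off = corr[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_realized_correlation_converges_to_target(self, montage20):
        """30-minute session: latent-band empirical correlations within 0.1
        of the structured target for every pair."""
        from ventfc.montage import default_target_correlation
        target = default_target_correlation(montage20)
        params = RecordingParams(motion_rate_per_min=0, dropout_rate_per_min=0,
                                 cardiac_free_rate=0, drift_sd=0.0)
        rec, _ = simulate_recording(montage20, 1800.0, 10.17, params, seed=4)
        od = -np.log(rec.intensity[:, :, 0] / rec.intensity[:, :, 0].mean(0))
        corr = np.corrcoef(od, rowvar=False)
        assert np.abs(corr - target).max() <= 0.1

    def test_dropout_intervals_have_near_zero_intensity(self, montage20):
        params = RecordingParams(dropout_rate_per_min=0.5)
        rec, truth = simulate_recording(montage20, 300.0, 10.17, params, seed=8)
        assert truth.dropout_intervals_s
        s, e, ch = truth.dropout_intervals_s[0]
        i0, i1 = int(s * 10.17) + 1, int(e * 10.17) - 1
        assert np.all(rec.intensity[i0:i1, ch, :] < 0.02)


class TestVVTrajectory:
    def test_linear_growth_no_noise(self):
        spec = VVTrajectorySpec(n_sessions=4, baseline_left_ml=10.0,
                                baseline_right_ml=10.0, growth_ml_per_week=2.0)
        left, right, total, ga = simulate_vv_trajectory(spec)
        assert np.allclose(left, [10, 12, 14, 16])
        assert np.allclose(right, [10, 12, 14, 16])
        assert np.array_equal(total, left + right)

    def test_diversion_step_applied_between_sessions(self):
        spec = VVTrajectorySpec(n_sessions=4, baseline_left_ml=20.0,
                                baseline_right_ml=20.0, growth_ml_per_week=0.0,
                                diversion_events={2: (-9.93, -10.0)})
        _, _, total, _ = simulate_vv_trajectory(spec)
        assert total[2] - total[1] == pytest.approx(-19.93)

    def test_zero_growth_zero_noise_constant(self):
        spec = VVTrajectorySpec(n_sessions=5, growth_ml_per_week=0.0)
        left, right, total, _ = simulate_vv_trajectory(spec)
        assert np.allclose(left, left[0]) and np.allclose(total, total[0])

    def test_total_is_exact_sum_with_noise(self):
        spec = VVTrajectorySpec(n_sessions=6, noise_sd_ml=1.5)
        left, right, total, _ = simulate_vv_trajectory(spec, seed=3)
        assert np.array_equal(total, left + right)

    def test_overshooting_step_clipped_to_floor(self, caplog):
        spec = VVTrajectorySpec(n_sessions=3, baseline_left_ml=5.0,
                                baseline_right_ml=5.0, growth_ml_per_week=0.0,
                                diversion_events={1: (-50.0, -50.0)})
        left, right, total, _ = simulate_vv_trajectory(spec)
        assert left.min() == pytest.approx(spec.floor_ml)
        assert (total > 0).all()

    def test_single_session_rejected(self):
        with pytest.raises(ValueError):
            simulate_vv_trajectory(VVTrajectorySpec(n_sessions=1))


class TestAttenuation:
    def test_closed_form_example(self, montage20):
        """beta = 0.002/mL on |rho0| = 0.5: VV 10 -> 0.48, VV 60 -> 0.38."""
        r0 = np.eye(20)
        i, j = montage20.channel_indices("left")[:2]
        r0[i, j] = r0[j, i] = 0.5
        a10 = attenuate_correlation(r0, 0.002, 10.0, 10.0, montage20)
        a60 = attenuate_correlation(r0, 0.002, 60.0, 60.0, montage20)
        assert a10[i, j] == pytest.approx(0.48)
        assert a60[i, j] == pytest.approx(0.38)

    def test_null_coupling_preserves_targets(self, montage20):
        from ventfc.montage import default_target_correlation
        r0 = default_target_correlation(montage20)
        out = attenuate_correlation(r0, 0.0, 30.0, 50.0, montage20)
        assert np.allclose(out, r0)

    def test_signs_preserved(self, montage20):
        from ventfc.montage import default_target_correlation
        r0 = default_target_correlation(montage20)
        out = attenuate_correlation(r0, 0.002, 40.0, 40.0, montage20)
        nz = (out != 0) & ~np.eye(20, dtype=bool)
        assert np.all(np.sign(out[nz]) == np.sign(r0[nz]))

    def test_full_attenuation_warns_not_raises(self, montage20):
        r0 = np.eye(20)
        i, j = 0, 1
        r0[i, j] = r0[j, i] = 0.1
        with pytest.warns(UserWarning, match="zero"):
            attenuate_correlation(r0, 1.0, 100.0, 100.0, montage20)


class TestCohorts:
    def test_study_arm_sizes(self):
        nd = study_cohort_spec("no_diversion")
        dv = study_cohort_spec("diversion")
        assert (nd.n_patients, nd.sessions_range) == (23, (2, 8))
        assert (dv.n_patients, dv.sessions_range) == (7, (3, 15))

    def test_sessions_per_patient_within_range(self):
        spec = study_cohort_spec("no_diversion", n_patients=6)
        recs = simulate_session_records(spec, seed=0)
        counts = {}
        for r in recs:
            counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
        assert all(2 <= c <= 8 for c in counts.values())
        assert len(counts) == 6

    def test_record_level_cohort_deterministic(self, montage_small):
        spec = study_cohort_spec("diversion", n_patients=3)
        a = simulate_session_records(spec, montage_small, seed=9)
        b = simulate_session_records(spec, montage_small, seed=9)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert ra.patient_id == rb.patient_id
            assert ra.vv_total_ml == rb.vv_total_ml
            assert np.array_equal(ra.connectivity.values, rb.connectivity.values)

    def test_vv_bookkeeping_and_ordering(self, montage_small):
        spec = study_cohort_spec("diversion", n_patients=4)
        recs = simulate_session_records(spec, montage_small, seed=2)
        by_pat = {}
        for r in recs:
            by_pat.setdefault(r.patient_id, []).append(r)
        for sess in by_pat.values():
            ga = [s.ga_weeks for s in sess]
            assert ga == sorted(ga) and len(set(ga)) == len(ga)
            for s in sess:
                assert s.vv_total_ml == pytest.approx(s.vv_left_ml + s.vv_right_ml)
                assert s.vv_left_ml > 0 and s.vv_right_ml > 0

    def test_diversion_patients_have_events_with_preceding_session(self, montage_small):
        spec = study_cohort_spec("diversion", n_patients=5)
        recs = simulate_session_records(spec, montage_small, seed=3)
        events = [r for r in recs if r.diversion_event_before]
        assert events
        assert all(r.order_index >= 1 for r in events)

    def test_full_cohort_carries_recordings_and_truth(self):
        spec = study_cohort_spec("no_diversion", n_patients=2, duration_s=160.0)
        patients = simulate_cohort(spec, seed=1)
        assert len(patients) == 2
        sess = patients[0].sessions[0]
        assert sess["recording"].intensity.shape[1] == 20
        assert sess["truth"].coupling_slope == spec.coupling_slope

    def test_sessions_minimum_enforced(self):
        with pytest.raises(ValueError):
            CohortSpec(sessions_range=(1, 5))
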