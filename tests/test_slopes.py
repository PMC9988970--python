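import numpy as np
import pytest

from ventfc.containers import ChannelValidity, ConnectivityMatrix, SessionRecord
from ventfc.slopes import (abs_sfc, case_study_series, diversion_paired_tests,
                           ga_posthoc, pair_vv, slope_lme, slope_ols, valid_pairs)
from ventfc.synthetic import simulate_session_records, study_cohort_spec


def _record(montage, pid, vv_l, vv_r, ga, values, event=False, group="no_diversion",
            idx=0):
    conn = ConnectivityMatrix(values, "HbT", ChannelValidity.all_valid(values.shape[0]),
                              montage)
    return SessionRecord(pid, group, ga, vv_l, vv_r, vv_l + vv_r, conn,
                         diversion_event_before=event, order_index=idx)


def _uniform_matrix(n, value):
    v = np.full((n, n), value)
    np.fill_diagonal(v, 1.0)
    return v


class TestAbsSfc:
    def test_elementwise_and_missing(self):
        m = np.array([[1.0, -0.7], [np.nan, 0.0]])
        out = abs_sfc(m)
        assert out[0, 1] == 0.7 and out[1, 1] == 0.0
        assert np.isnan(out[1, 0])

    def test_invariant_under_sign_flips(self, rng):
        m = rng.normal(0, 0.5, (6, 6))
        flip = np.diag(rng.choice([-1.0, 1.0], 6))
        assert np.allclose(abs_sfc(flip @ m @ flip), abs_sfc(m))


class TestPairVV:
    def test_hemisphere_vv_selection(self, montage_small):
        li, lj = montage_small.channel_indices("left")[:2]
        ri = montage_small.channel_indices("right")[0]
        rec = _record(montage_small, "p1", 10.0, 20.0, 30.0, _uniform_matrix(6, 0.5))
        assert pair_vv([rec], (li, lj)).vv_ml.iloc[0] == 10.0
        right_pair = tuple(montage_small.channel_indices("right")[:2])
        assert pair_vv([rec], right_pair).vv_ml.iloc[0] == 20.0
        assert pair_vv([rec], (li, ri), "mean").vv_ml.iloc[0] == 15.0
        assert pair_vv([rec], (li, ri), "left").vv_ml.iloc[0] == 10.0
        assert pair_vv([rec], (li, ri), "total").vv_ml.iloc[0] == 30.0

    def test_missing_sfc_drops_session(self, montage_small):
        v = _uniform_matrix(6, 0.5)
        v[0, 1] = v[1, 0] = np.nan
        rec = _record(montage_small, "p1", 10.0, 10.0, 30.0, v)
        assert len(pair_vv([rec], (0, 1))) == 0
        assert len(pair_vv([rec], (0, 2))) == 1


class TestSlopeOLS:
    def test_two_point_slope(self, montage_small):
        recs = []
        for pid in ("a", "b"):
            recs.append(_record(montage_small, pid, 10, 10, 30, _uniform_matrix(6, 0.5)))
            recs.append(_record(montage_small, pid, 20, 20, 31, _uniform_matrix(6, 0.4)))
        res = slope_ols(recs)
        assert np.allclose(res.pairs.slope.dropna(), -0.01)

    def test_identical_negative_slopes_give_negative_t(self, montage_small, rng):
        recs = []
        for p in range(6):
            for k, vv in enumerate((10, 20, 30)):
                val = 0.5 - 0.01 * vv + rng.normal(0, 1e-4)
                recs.append(_record(montage_small, f"p{p}", vv, vv, 30 + k,
                                    _uniform_matrix(6, val), idx=k))
        res = slope_ols(recs)
        assert (res.hemispheres.t < -10).all()

    def test_constant_vv_patient_dropped(self, montage_small, caplog):
        recs = [
            _record(montage_small, "const", 15, 15, 30, _uniform_matrix(6, 0.5)),
            _record(montage_small, "const", 15, 15, 31, _uniform_matrix(6, 0.4)),
            _record(montage_small, "ok", 10, 10, 30, _uniform_matrix(6, 0.5)),
            _record(montage_small, "ok", 20, 20, 31, _uniform_matrix(6, 0.4)),
        ]
        with caplog.at_level("WARNING"):
            res = slope_ols(recs)
        assert (res.pairs.n_patients == 1).all()

    def test_parameter_recovery_on_synthetic_cohort(self, montage_small):
        """Generator coupling beta = 0.002 -> mean estimated slope near -0.002."""
        spec = study_cohort_spec("diversion")
        base = np.eye(6)
        for h in (0, 1):
            for i in range(3):
                for j in range(i + 1, 3):
                    base[3 * h + i, 3 * h + j] = base[3 * h + j, 3 * h + i] = 0.5
        slopes = []
        for rep in range(20):
            recs = simulate_session_records(spec, montage_small, seed=rep,
                                            base_correlation=base)
            res = slope_ols(recs, include_inter=False)
            slopes.extend(res.hemispheres.slope.tolist())
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - (-0.002)) < 2 * se + 5e-4


class TestSlopeLME:
    def test_single_patient_rejected(self, montage_small):
        recs = [_record(montage_small, "p", 10, 10, 30, _uniform_matrix(6, 0.5)),
                _record(montage_small, "p", 20, 20, 31, _uniform_matrix(6, 0.4))]
        with pytest.raises(ValueError):
            slope_lme(recs)

    def test_fixed_effect_recovers_common_slope(self, montage_small, rng):
        recs = []
        for p in range(6):
            offset = rng.normal(0.5, 0.05)
            for k, vv in enumerate((10, 20, 30, 40)):
                val = offset - 0.002 * vv + rng.normal(0, 0.01)
                recs.append(_record(montage_small, f"p{p}", vv, vv, 30 + k,
                                    _uniform_matrix(6, val), idx=k))
        res = slope_lme(recs, include_inter=False)
        ok = res.pairs.slope.dropna()
        assert len(ok)
        assert np.allclose(ok, -0.002, atol=5e-4)

    def test_method_consistency_with_ols_on_balanced_design(self, montage_small, rng):
        recs = []
        for p in range(8):
            offset = rng.normal(0.5, 0.02)
            for k, vv in enumerate((10, 20, 30)):
                val = offset - 0.003 * vv + rng.normal(0, 0.005)
                recs.append(_record(montage_small, f"p{p}", vv, vv, 30 + k,
                                    _uniform_matrix(6, val), idx=k))
        ols = slope_ols(recs, include_inter=False)
        lme = slope_lme(recs, include_inter=False)
        merged = ols.pairs.merge(lme.pairs, on=["ch_i", "ch_j"], suffixes=("_o", "_l"))
        for _, row in merged.iterrows():
            if np.isfinite(row.slope_l) and np.isfinite(row.se_o):
                assert abs(row.slope_o - row.slope_l) < 2 * max(row.se_o, 1e-6) + 1e-4


class TestGAPosthoc:
    def test_recovers_vv_growth(self, montage_small, rng):
        recs = []
        for p in range(6):
            base = rng.uniform(8, 15)
            for k in range(5):
                ga = 28 + k
                vv = base + 2.0 * k + rng.normal(0, 0.2)
                recs.append(_record(montage_small, f"p{p}", vv / 2, vv / 2, ga,
                                    _uniform_matrix(6, 0.5), idx=k))
        res = ga_posthoc(recs)
        row = res[res.outcome == "vv_total_ml"].iloc[0]
        assert abs(row.ga_slope - 2.0) < 2 * row.se + 0.2

    def test_constant_vv_zero_slope(self, montage_small):
        recs = []
        for p in range(3):
            for k in range(3):
                recs.append(_record(montage_small, f"p{p}", 10, 10, 28 + k,
                                    _uniform_matrix(6, 0.5), idx=k))
        res = ga_posthoc(recs)
        row = res[res.outcome == "vv_total_ml"].iloc[0]
        assert row.ga_slope == pytest.approx(0.0, abs=1e-8)


class TestDiversionPairedTests:
    def test_equal_pre_post_zero_delta(self, montage20):
        v = _uniform_matrix(20, 0.5)
        recs = [
            _record(montage20, "p", 30, 30, 30.0, v, group="diversion", idx=0),
            _record(montage20, "p", 30, 30, 30.003, v, event=True,
                    group="diversion", idx=1),
        ]
        out = diversion_paired_tests(recs)
        assert out["deltas"].d_vv_total_ml.iloc[0] == 0.0
        assert out["deltas"].filter(like="d_abs_sfc").iloc[0].abs().max() == 0.0

    def test_step_magnitude_recovered(self, montage20):
        spec = study_cohort_spec("diversion")
        recs = simulate_session_records(spec, montage20, seed=4)
        out = diversion_paired_tests(recs)
        tests = out["tests"].set_index("measure")
        row = tests.loc["d_vv_total_ml"]
        se = row.sd / np.sqrt(row.n)
        expected = spec.diversion_step_left_ml + spec.diversion_step_right_ml
        assert abs(row["mean"] - expected) < 2 * se + 1.0

    def test_event_without_pre_session_skipped(self, montage20):
        v = _uniform_matrix(20, 0.5)
        recs = [_record(montage20, "p", 30, 30, 30.0, v, event=True,
                        group="diversion", idx=0),
                _record(montage20, "p", 25, 25, 31.0, v, group="diversion", idx=1)]
        out = diversion_paired_tests(recs)
        assert len(out["deltas"]) == 0


class TestCaseStudySeries:
    def test_shape_and_sorting(self, montage20):
        v = _uniform_matrix(20, 0.5)
        recs = [_record(montage20, "p", 30, 30, 34.0, v, idx=2),
                _record(montage20, "p", 20, 20, 30.0, v, idx=0),
                _record(montage20, "p", 25, 25, 32.0, v, event=True, idx=1)]
        out = case_study_series(recs)
        table = out["table"]
        assert len(table) == 3
        assert list(table.ga_weeks) == [30.0, 32.0, 34.0]
        assert {"vv_left_ml", "vv_right_ml"} <= set(table.columns)
        assert sum(c.startswith("abs_sfc_") for c in table.columns) == 4
        assert out["event_ga_weeks"] == [32.0]

    def test_no_events_empty_markers(self, montage20):
        v = _uniform_matrix(20, 0.5)
        recs = [_record(montage20, "p", 20, 20, 30.0, v),
                _record(montage20, "p", 25, 25, 31.0, v, idx=1)]
        assert case_study_series(recs)["event_ga_weeks"] == []

    def test_requires_single_patient_multiple_sessions(self, montage20):
        v = _uniform_matrix(20, 0.5)
        with pytest.raises(ValueError):
            case_study_series([_record(montage20, "p", 20, 20, 30.0, v)])
        with pytest.raises(ValueError):
            case_study_series([_record(montage20, "a", 20, 20, 30.0, v),
                               _record(montage20, "b", 25, 25, 31.0, v)])


def test_valid_pairs_hemisphere_partition(montage20):
    left = valid_pairs(montage20, "left")
    right = valid_pairs(montage20, "right")
    inter = valid_pairs(montage20, "inter")
    assert len(left) == len(right) == 45
    assert len(inter) == 100
    assert len(valid_pairs(montage20)) == 190
    assert len(valid_pairs(montage20, include_inter=False)) == 90
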