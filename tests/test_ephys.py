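"""fEPSP pipeline: baseline normalization, phase quantification, group stats."""

import numpy as np
import pytest

from tmaskit import (
    LFS_PROTOCOL,
    SlopeSeries,
    TBS_PROTOCOL,
    compare_groups,
    group_summary,
    normalize_to_baseline,
    quantify_phase,
    read_slope_csv,
    write_slope_csv,
)


def make_series(slopes, animal="a1", group="TMAS"):
    t = np.arange(1.0, len(slopes) + 1.0)
    return SlopeSeries(animal, group, t, np.asarray(slopes, dtype=float))


def full_series(baseline=0.5, ltp_pct=344.0, dp_pct=150.0):
    vals = np.concatenate(
        [
            np.full(30, baseline),
            np.full(90, baseline * ltp_pct / 100.0),
            np.full(90, baseline * dp_pct / 100.0),
        ]
    )
    return make_series(vals)


class TestProtocols:
    def test_tbs_pulse_arithmetic(self):
        assert TBS_PROTOCOL.total_pulses == 180  # 30 trains x 6 pulses
        assert TBS_PROTOCOL.intra_train_rate_hz == 100.0

    def test_lfs_pulse_arithmetic(self):
        assert LFS_PROTOCOL.total_pulses == 900
        assert LFS_PROTOCOL.duration_s == 900.0


class TestNormalization:
    def test_constant_series_goes_to_100(self):
        n = normalize_to_baseline(full_series(ltp_pct=100.0, dp_pct=100.0))
        np.testing.assert_allclose(n.slope, 100.0)

    def test_hand_value(self):
        s = full_series(baseline=0.5)
        s.slope[40] = 1.72
        n = normalize_to_baseline(s)
        assert n.slope[40] == pytest.approx(344.0)

    def test_baseline_mean_exactly_100(self):
        rng = np.random.default_rng(7)
        s = make_series(0.5 + 0.05 * rng.standard_normal(210))
        n = normalize_to_baseline(s)
        assert n.slope[n.baseline_mask()].mean() == pytest.approx(100.0, abs=1e-9)

    def test_nonpositive_baseline_rejected(self):
        s = full_series()
        s.slope[:30] = 0.0
        with pytest.raises(ValueError):
            normalize_to_baseline(s)


class TestQuantifyPhase:
    def test_constant_plateau(self):
        n = normalize_to_baseline(full_series(ltp_pct=343.9))
        q = quantify_phase(n, "LTP")
        assert q.endpoint_pct == pytest.approx(343.9)
        assert q.window_mean_pct == pytest.approx(343.9)

    def test_linear_rise_closed_form(self):
        # 100 -> 200 linearly over the 90 LTP samples: endpoint 200, mean of
        # last 10 samples = average of an arithmetic sequence
        vals = np.concatenate(
            [np.full(30, 1.0), np.linspace(100, 200, 90) / 100.0, np.full(90, 1.0)]
        )
        n = normalize_to_baseline(make_series(vals))
        q = quantify_phase(n, "LTP")
        expected_window = np.linspace(100, 200, 90)[-10:].mean()  # 194.94...
        assert q.endpoint_pct == pytest.approx(200.0)
        assert q.window_mean_pct == pytest.approx(expected_window)

    def test_dp_window_uses_lfs_marker(self):
        n = normalize_to_baseline(full_series(dp_pct=74.4))
        q = quantify_phase(n, "DP")
        assert q.window_mean_pct == pytest.approx(74.4)

    def test_window_mean_permutation_invariant(self):
        rng = np.random.default_rng(8)
        s = normalize_to_baseline(make_series(0.5 + 0.1 * rng.random(210)))
        q = quantify_phase(s, "LTP")
        shuffled = s.slope.copy()
        idx = np.where(s.phase_mask("LTP"))[0][-10:]
        shuffled[idx] = shuffled[rng.permutation(idx)]
        s2 = SlopeSeries("a1", "TMAS", s.time_min, shuffled, normalized=True)
        assert quantify_phase(s2, "LTP").window_mean_pct == pytest.approx(
            q.window_mean_pct
        )

    def test_short_window_errors(self):
        vals = np.full(38, 1.0)  # only 8 post-TBS samples
        with pytest.raises(ValueError):
            quantify_phase(normalize_to_baseline(make_series(vals)), "LTP")

    def test_unnormalized_series_rejected(self):
        with pytest.raises(ValueError):
            quantify_phase(full_series(), "LTP")


class TestGroupStats:
    def test_mean_and_sem_hand_values(self):
        g = group_summary([340.0, 344.0, 348.0], "TMAS")
        assert g.mean_pct == pytest.approx(344.0)
        assert g.sem_pct == pytest.approx(4.0 / np.sqrt(3.0))

    def test_single_animal_sem_missing(self):
        g = group_summary([200.0], "TUS")
        assert g.mean_pct == 200.0 and np.isnan(g.sem_pct)

    def test_equal_values_zero_sem(self):
        assert group_summary([5.0, 5.0, 5.0], "Con").sem_pct == 0.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_summary([], "Con")


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        a = [340.0, 344.0, 348.0, 342.0]
        stat, p = compare_groups(a, a)
        assert p > 0.99

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(9)
        a = 343.9 + 5.0 * rng.standard_normal(6)
        b = 74.4 + 5.0 * rng.standard_normal(6)
        _, p = compare_groups(a, b)
        assert p < 0.001

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        a, b = rng.random(6), 1 + rng.random(6)
        assert compare_groups(a, b)[1] == pytest.approx(compare_groups(b, a)[1])

    def test_degenerate_zero_variance(self):
        assert compare_groups([5.0, 5.0], [5.0, 5.0])[1] == 1.0
        assert compare_groups([5.0, 5.0], [6.0, 6.0])[1] == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestSeriesValidation:
    def test_irregular_sampling_rejected(self):
        with pytest.raises(ValueError):
            SlopeSeries("a", "g", np.array([1.0, 2.0, 4.0]), np.ones(3))

    def test_marker_order_enforced(self):
        with pytest.raises(ValueError):
            SlopeSeries(
                "a", "g", np.arange(1.0, 211.0), np.ones(210),
                tbs_time_min=120.0, lfs_time_min=30.0,
            )


def test_csv_round_trip(tmp_path):
    series = [full_series(), full_series(baseline=0.8)]
    series[1].animal_id = "a2"
    path = tmp_path / "slopes.csv"
    write_slope_csv(series, path)
    back = read_slope_csv(path)
    assert len(back) == 2
    np.testing.assert_allclose(back[0].slope, series[0].slope)
    assert back[1].animal_id == "a2"
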