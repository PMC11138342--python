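"""Bleed-threshold equations, TR calibration, 1FP/2FP classification,
saturation flagging and amplitude-based cluster sizing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from difc import (
    BleedCalibration,
    CalibrationError,
    ChannelId,
    MatchedDetection,
    PeakCandidate,
    TwoLambdaPeak,
    bleed_max_secondary,
    classify_two_lambda,
    estimate_bleed_ratio,
    find_two_lambda,
    flag_saturation,
    size_cluster,
)


def det(color, t, amp_mv=200.0, amp_sigma=None, width=0.03):
    if amp_sigma is None:
        amp_sigma = amp_mv / 2.0
    peaks = {}
    for probe in (1, 2):
        peaks[probe] = PeakCandidate(
            channel=ChannelId(probe, color),
            time_s=t + (0.1 if probe == 2 else 0.0),
            index=0,
            amplitude_mV=amp_mv,
            amplitude_sigma=amp_sigma,
            width_s=width,
            snr_db=20.0,
        )
    return MatchedDetection(
        color=color, peak_p1=peaks[1], peak_p2=peaks[2],
        direction="forward", delay_s=0.1, speed_mm_s=30.0, match_score=0.0,
    )


class TestBleedMaxSecondary:
    def test_zero_tr_reference_point(self):
        # 10*(0*10+5)/(10-5) = 10
        assert bleed_max_secondary(10.0, 0.0) == pytest.approx(10.0)

    def test_inversion_consistency(self):
        # the TR calibrated from (100, 10) puts the threshold back at 10
        assert bleed_max_secondary(100.0, 0.045) == pytest.approx(10.0)

    def test_domain_error_at_threshold(self):
        with pytest.raises(ValueError):
            bleed_max_secondary(5.0, 0.05)
        with pytest.raises(ValueError):
            bleed_max_secondary(4.0, 0.05)

    @given(st.floats(5.001, 1e4), st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_strictly_monotone_in_tr(self, i_pr, tr1, dtr):
        lo = bleed_max_secondary(i_pr, tr1)
        hi = bleed_max_secondary(i_pr, tr1 + dtr + 1e-9)
        assert hi > lo

    def test_asymptote_is_tr(self):
        for tr in (0.01, 0.057, 0.089):
            ratios = [bleed_max_secondary(ip, tr) / ip for ip in (1e3, 1e5, 1e7)]
            assert abs(ratios[-1] - tr) < 1e-5
            assert ratios == sorted(ratios, reverse=True)  # approaches from above

    def test_divergence_near_threshold(self):
        assert bleed_max_secondary(5.0 + 1e-9, 0.0) > 1e8


class TestEstimateBleedRatio:
    def test_single_point_value(self):
        # (10*95 - 500)/10000 = 0.045
        calib = estimate_bleed_ratio([(100.0, 10.0)])
        assert calib.TR == pytest.approx(0.045)

    def test_single_point_matches_numeric_inversion(self):
        from scipy.optimize import brentq

        i_pr, i_sec = 137.0, 11.5
        calib = estimate_bleed_ratio([(i_pr, i_sec)])
        tr_oracle = brentq(
            lambda tr: bleed_max_secondary(i_pr, tr) - i_sec, 0.0, 1.0
        )
        assert calib.TR == pytest.approx(tr_oracle, rel=1e-10)

    def test_max_rule_over_points(self):
        # TR_i = 0.045 for (100,10); a second, cleaner point contributes less
        calib = estimate_bleed_ratio([(100.0, 6.0), (100.0, 10.0)])
        assert calib.TR == pytest.approx(0.045)

    def test_zero_secondary_clamps_to_zero(self):
        calib = estimate_bleed_ratio([(100.0, 0.0)])
        assert calib.TR == 0.0

    def test_empty_points_raise(self):
        with pytest.raises(CalibrationError):
            estimate_bleed_ratio([])

    def test_sub_threshold_point_rejected_with_warning(self):
        with pytest.warns(UserWarning):
            calib = estimate_bleed_ratio([(4.0, 1.0), (100.0, 10.0)])
        assert calib.TR == pytest.approx(0.045)
        with pytest.raises(CalibrationError), pytest.warns(UserWarning):
            estimate_bleed_ratio([(4.0, 1.0)])

    @given(
        st.lists(
            st.tuples(st.floats(5.5, 500.0), st.floats(0.0, 60.0)),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_zero_false_positives_on_any_calibration_set(self, points):
        """The max rule forces every calibration point at or below the
        threshold its own TR defines."""
        calib = estimate_bleed_ratio(points)
        for i_pr, i_sec in points:
            assert i_sec <= bleed_max_secondary(i_pr, calib.TR) * (1 + 1e-12)

    @given(st.floats(5.001, 1e4), st.floats(0.0, 1e3))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, i_pr, i_sec):
        """Threshold and calibration are mutual inverses when TR_i >= 0."""
        t = 5.0
        tr_i = (i_sec * (i_pr - t) - t * i_pr) / i_pr**2
        if tr_i < 0:
            return
        assert bleed_max_secondary(i_pr, tr_i) == pytest.approx(i_sec, rel=1e-9)


class TestFindTwoLambda:
    def test_same_time_same_probe_pair(self):
        g, o = det("green", 1.0, 300.0), det("orange", 1.0, 100.0)
        two, singles = find_two_lambda([g], [o], 0.01)
        assert singles == []
        (p,) = two
        assert p.primary_color == "green"
        assert p.I_pr == pytest.approx(150.0)
        assert p.I_sec == pytest.approx(50.0)

    def test_green_only_passes_through(self):
        two, singles = find_two_lambda([det("green", 1.0)], [], 0.01)
        assert two == [] and len(singles) == 1

    def test_separated_times_do_not_pair(self):
        two, singles = find_two_lambda(
            [det("green", 1.0)], [det("orange", 2.0)], 0.01
        )
        assert two == [] and len(singles) == 2

    def test_each_detection_pairs_at_most_once(self):
        g = [det("green", 1.000)]
        o = [det("orange", 1.001), det("orange", 1.002)]
        two, singles = find_two_lambda(g, o, 0.01)
        assert len(two) == 1 and len(singles) == 1
        assert two[0].orange_det.time_s == pytest.approx(1.001)


class TestClassifyTwoLambda:
    CG = BleedCalibration("green", 0.045, ())
    CO = BleedCalibration("orange", 0.089, ())

    def _peak(self, i_pr, i_sec, primary="green", saturated=False):
        g_amp, o_amp = (i_pr, i_sec) if primary == "green" else (i_sec, i_pr)
        return TwoLambdaPeak(
            green_det=det("green", 1.0, amp_mv=g_amp * 2, amp_sigma=g_amp),
            orange_det=det("orange", 1.0, amp_mv=o_amp * 2, amp_sigma=o_amp),
            saturated=saturated,
        )

    def test_below_threshold_is_one_fp(self):
        assert classify_two_lambda(self._peak(100, 9.9), self.CG, self.CO) == "oneFP"

    def test_above_threshold_is_two_fp(self):
        assert classify_two_lambda(self._peak(100, 10.1), self.CG, self.CO) == "twoFP"

    def test_primary_color_selects_calibration(self):
        # orange primary at I_pr=100: threshold = 100*(0.089*100+5)/95 = 14.6
        peak = self._peak(100, 12.0, primary="orange")
        assert classify_two_lambda(peak, self.CG, self.CO) == "oneFP"
        peak = self._peak(100, 15.0, primary="orange")
        assert classify_two_lambda(peak, self.CG, self.CO) == "twoFP"

    def test_saturated_is_indeterminate(self):
        peak = self._peak(100, 50, saturated=True)
        assert classify_two_lambda(peak, self.CG, self.CO) == "indeterminate"

    def test_calibration_set_self_classification_is_clean(self, rng):
        """Classifying the calibration run with its own TR yields zero 2FP."""
        pts = [(float(ip), float(sec)) for ip, sec in
               zip(rng.uniform(20, 400, 50), rng.uniform(0, 25, 50))]
        calib = estimate_bleed_ratio(pts, "green")
        for i_pr, i_sec in pts:
            peak = self._peak(i_pr, i_sec)
            assert classify_two_lambda(peak, calib, self.CO) != "twoFP"


class TestFlagSaturation:
    def test_above_limit_flagged(self):
        assert flag_saturation(det("green", 1.0, amp_mv=1600.0))

    def test_exactly_at_limit_not_flagged(self):
        assert not flag_saturation(det("green", 1.0, amp_mv=1500.0))

    def test_modest_amplitudes_not_flagged(self):
        assert not flag_saturation(det("green", 1.0, amp_mv=100.0))

    def test_two_lambda_checks_all_four_peaks(self):
        peak = TwoLambdaPeak(
            green_det=det("green", 1.0, amp_mv=100.0),
            orange_det=det("orange", 1.0, amp_mv=1600.0),
        )
        assert flag_saturation(peak)


class TestSizeCluster:
    def test_two_cell_detection_is_not_a_cluster(self):
        sized = size_cluster(det("green", 1.0, amp_mv=200.0), 100.0, 100.0)
        assert sized.n_green == 2 and not sized.is_cluster
        assert sized.kind == "single_1FP"

    def test_three_point_four_cells_rounds_to_cluster(self):
        sized = size_cluster(det("green", 1.0, amp_mv=340.0), 100.0, 100.0)
        assert sized.n_green == 3 and sized.is_cluster
        assert sized.kind == "cluster_1FP"

    def test_every_two_fp_is_a_cluster(self):
        peak = TwoLambdaPeak(
            green_det=det("green", 1.0, amp_mv=100.0),
            orange_det=det("orange", 1.0, amp_mv=200.0),
            classification="twoFP",
        )
        sized = size_cluster(peak, 100.0, 100.0)
        assert sized.kind == "cluster_2FP"
        assert sized.n_green >= 1 and sized.n_orange >= 1
        assert sized.n_orange == 2

    def test_bleed_correction_shrinks_minority_count(self):
        # primary green 1000 mV; secondary orange 80 mV of which
        # TR*1000 = 45 mV is bleed -> 35 mV -> 1 cell, not 2
        calib_g = BleedCalibration("green", 0.045, ())
        peak = TwoLambdaPeak(
            green_det=det("green", 1.0, amp_mv=1000.0),
            orange_det=det("orange", 1.0, amp_mv=80.0, amp_sigma=40.0),
            classification="twoFP",
        )
        sized = size_cluster(peak, 100.0, 40.0, calib_green=calib_g)
        assert sized.n_orange == 1
        uncorrected = size_cluster(peak, 100.0, 40.0)
        assert uncorrected.n_orange == 2

    def test_one_fp_two_lambda_attributed_to_primary(self):
        peak = TwoLambdaPeak(
            green_det=det("green", 1.0, amp_mv=500.0),
            orange_det=det("orange", 1.0, amp_mv=30.0, amp_sigma=15.0),
            classification="oneFP",
        )
        sized = size_cluster(peak, 100.0, 100.0)
        assert sized.kind == "cluster_1FP"
        assert sized.n_green == 5 and sized.n_orange == 0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            size_cluster(det("green", 1.0), 0.0, 100.0)
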