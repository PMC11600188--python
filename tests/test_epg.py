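"""Electropherogram calibration, MW axis, and band quantification."""

import numpy as np
import pytest

from pronephros import (
    LadderPeak,
    Trace,
    fit_ladder_powerlaw,
    map_mw_axis,
    quantify_band,
    time_correct,
)
from pronephros.epg import _window_integral
from pronephros.errors import FitError
from pronephros.synthetic import generate_electropherogram

LADDER = [(5, 50.0, 20.0), (15, 50.0, 26.0), (50, 50.0, 34.0),
          (150, 50.0, 43.0), (240, 50.0, 50.0)]


def make_peaks(times, ratios):
    return [
        LadderPeak(mw_kda=10.0 * (i + 1), amount_ng=50.0, time_s=t, ratio=r)
        for i, (t, r) in enumerate(zip(times, ratios))
    ]


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        t = np.linspace(20, 60, 8)
        peaks = make_peaks(t, 2.0 * t**-0.5)
        cal = fit_ladder_powerlaw(peaks)
        assert cal.a == pytest.approx(2.0, rel=1e-10)
        assert cal.b == pytest.approx(-0.5, abs=1e-10)

    def test_constant_ratio_gives_flat_calibration(self):
        peaks = make_peaks(np.linspace(20, 60, 5), np.full(5, 3.0))
        cal = fit_ladder_powerlaw(peaks)
        assert cal.a == pytest.approx(3.0)
        assert cal.b == pytest.approx(0.0, abs=1e-12)

    def test_noisy_exponent_within_tenth(self):
        rng = np.random.default_rng(9)
        t = np.linspace(18, 62, 12)
        ratios = 2.0 * t**-0.5 * (1 + rng.normal(0, 0.05, 12))
        cal = fit_ladder_powerlaw(make_peaks(t, ratios))
        assert cal.b == pytest.approx(-0.5, abs=0.1)

    def test_ratio_from_area_pair(self):
        p = LadderPeak(10, 50, 30, raw_area=20.0, corrected_area=10.0)
        assert p.correction_ratio() == 0.5

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(FitError):
            fit_ladder_powerlaw(make_peaks([10.0, 20.0], [1.0, -1.0]))
        with pytest.raises(FitError):
            fit_ladder_powerlaw([LadderPeak(10, 50, 30, ratio=1.0)])


class TestTimeCorrect:
    def test_identity_calibration(self):
        sim = generate_electropherogram([(15, 40.0)], LADDER, decay_exponent=0.0)
        cal = fit_ladder_powerlaw(sim.ladder_peaks)
        assert cal.a == pytest.approx(1.0) and cal.b == pytest.approx(0.0, abs=1e-12)
        with np.errstate(all="ignore"):
            corr = time_correct(sim.sample, cal)
        assert np.allclose(corr.signal, sim.sample.signal)

    def test_equal_amount_ladder_areas_equalised(self):
        sim = generate_electropherogram([], LADDER, decay_exponent=-0.6)
        cal = fit_ladder_powerlaw(sim.ladder_peaks)
        corr = time_correct(sim.ladder_trace, cal)
        areas = [
            _window_integral(corr.time, corr.signal, p.time_s - 2.5, p.time_s + 2.5)
            for p in sim.ladder_peaks
        ]
        assert (max(areas) - min(areas)) / np.mean(areas) < 0.01
        # uncorrected areas are NOT equal (the falloff is real)
        raw_areas = [
            _window_integral(
                sim.ladder_trace.time, sim.ladder_trace.signal,
                p.time_s - 2.5, p.time_s + 2.5,
            )
            for p in sim.ladder_peaks
        ]
        assert (max(raw_areas) - min(raw_areas)) / np.mean(raw_areas) > 0.3

    def test_scaling_linearity(self):
        trace = Trace(np.linspace(10, 20, 50), np.linspace(0, 5, 50))
        from pronephros import PowerLawCalibration

        c1 = PowerLawCalibration(a=1.5, b=-0.3, t_min=10, t_max=20)
        c2 = PowerLawCalibration(a=3.0, b=-0.3, t_min=10, t_max=20)
        assert np.allclose(
            time_correct(trace, c2).signal, 2.0 * time_correct(trace, c1).signal
        )


class TestMWAxis:
    def test_knots_and_geometric_midpoint(self):
        peaks = [LadderPeak(10, 50, 20, ratio=1), LadderPeak(100, 50, 40, ratio=1)]
        mapping = map_mw_axis(peaks)
        assert mapping.mw_for_time(20) == pytest.approx(10)
        assert mapping.mw_for_time(40) == pytest.approx(100)
        assert mapping.mw_for_time(30) == pytest.approx(np.sqrt(10 * 100))

    def test_round_trip_identity(self):
        peaks = [LadderPeak(mw, 50, t, ratio=1) for mw, _, t in
                 [(5, 0, 20), (15, 0, 26), (50, 0, 34), (240, 0, 50)]]
        mapping = map_mw_axis(peaks)
        for mw in (5.0, 7.3, 15.0, 88.0, 240.0):
            assert mapping.mw_for_time(mapping.time_for_mw(mw)) == pytest.approx(mw)

    def test_non_monotone_ladder_rejected(self):
        peaks = [LadderPeak(10, 50, 30, ratio=1), LadderPeak(100, 50, 20, ratio=1)]
        with pytest.raises(FitError):
            map_mw_axis(peaks)


class TestQuantifyBand:
    @pytest.fixture()
    def corrected_run(self):
        sim = generate_electropherogram(
            [(15.0, 40.0), (65.0, 80.0)], LADDER, decay_exponent=-0.6
        )
        cal = fit_ladder_powerlaw(sim.ladder_peaks)
        sample = time_correct(sim.sample, cal)
        mapping = map_mw_axis(sim.ladder_peaks)
        blank = Trace(sim.sample.time, np.zeros_like(sim.sample.time), "water")
        ref = (sim.ladder_peaks[1].corrected_area, sim.ladder_peaks[1].amount_ng)
        return sample, blank, mapping, ref

    def test_sample_equals_baseline_gives_zero(self, corrected_run):
        sample, blank, mapping, ref = corrected_run
        q = quantify_band(sample, sample, (10, 40), mapping, ref)
        assert q.amount_ng == 0.0

    def test_known_band_recovered_within_two_percent(self, corrected_run):
        sample, blank, mapping, ref = corrected_run
        q = quantify_band(sample, blank, (10, 40), mapping, ref)
        assert q.amount_ng == pytest.approx(40.0, rel=0.02)
        q2 = quantify_band(sample, blank, (50, 240), mapping, ref)
        assert q2.amount_ng == pytest.approx(80.0, rel=0.02)

    def test_out_of_window_band_near_zero(self):
        sim = generate_electropherogram([(65.0, 80.0)], LADDER, decay_exponent=-0.6)
        cal = fit_ladder_powerlaw(sim.ladder_peaks)
        sample = time_correct(sim.sample, cal)
        mapping = map_mw_axis(sim.ladder_peaks)
        blank = Trace(sim.sample.time, np.zeros_like(sim.sample.time))
        ref = (sim.ladder_peaks[1].corrected_area, sim.ladder_peaks[1].amount_ng)
        q = quantify_band(sample, blank, (10, 40), mapping, ref)
        assert q.amount_ng < 0.5  # only Gaussian tail leakage

    def test_detector_gain_invariance(self, corrected_run):
        sample, blank, mapping, ref = corrected_run
        gained = Trace(sample.time, 5.0 * sample.signal)
        ref_gained = (5.0 * ref[0], ref[1])
        a = quantify_band(sample, blank, (10, 40), mapping, ref)
        b = quantify_band(gained, blank, (10, 40), mapping, ref_gained)
        assert b.amount_ng == pytest.approx(a.amount_ng, rel=1e-9)

    def test_additive_over_disjoint_windows(self, corrected_run):
        sample, blank, mapping, ref = corrected_run
        whole = quantify_band(sample, blank, (5, 240), mapping, ref)
        parts = [
            quantify_band(sample, blank, w, mapping, ref).amount_ng
            for w in [(5, 30), (30, 240)]
        ]
        assert sum(parts) == pytest.approx(whole.amount_ng, rel=1e-6)

    def test_window_outside_span_rejected(self, corrected_run):
        sample, blank, mapping, ref = corrected_run
        with pytest.raises(ValueError):
            quantify_band(sample, blank, (1, 40), mapping, ref)

    def test_negative_estimate_floored_with_warning(self, corrected_run):
        sample, blank, mapping, ref = corrected_run
        with pytest.warns(UserWarning, match="floored"):
            q = quantify_band(blank, sample, (10, 40), mapping, ref)
        assert q.amount_ng == 0.0 and q.clipped


class TestGenerator:
    def test_deterministic_traces(self):
        a = generate_electropherogram([(15, 40)], LADDER, -0.6, seed=3, noise_sd=2.0)
        b = generate_electropherogram([(15, 40)], LADDER, -0.6, seed=3, noise_sd=2.0)
        assert np.array_equal(a.sample.signal, b.sample.signal)

    def test_single_band_identity_when_no_decay(self):
        sim = generate_electropherogram([(15.0, 40.0)], LADDER, decay_exponent=0.0)
        raw_area = _window_integral(
            sim.sample.time, sim.sample.signal,
            sim.band_truth["time_s"][0] - 3, sim.band_truth["time_s"][0] + 3,
        )
        assert raw_area == pytest.approx(40.0, rel=0.01)

    def test_empty_ladder_rejected(self):
        with pytest.raises(ValueError):
            generate_electropherogram([(15, 40)], [], -0.5)
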