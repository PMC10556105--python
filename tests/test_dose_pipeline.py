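"""Inverse pipeline: dose maps, per-LDR calibration, steps, orientation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from rcfdose import beam_phantom as bp
from rcfdose import dose_pipeline as dp
from rcfdose import moem_sensor as ms
from rcfdose.exceptions import CalibrationError, ConfigurationError
from rcfdose.film_model import (
    LED_GREEN,
    ODMap,
    SCANNER_RED,
    dose_to_netod,
    fit_calibration,
)


def quintic_curve(lo=0.0, hi=8.0):
    """A calibration fitted to the forward response on a dense grid."""
    doses = np.linspace(lo, hi, 14)
    return fit_calibration(doses, dose_to_netod(doses, SCANNER_RED))


class TestScannerDoseMap:
    def test_equal_scans_give_zero_dose(self):
        curve = quintic_curve()
        pix = np.full((40, 40), 30000.0)
        scanlike = type("S", (), {"pixels": pix, "pixel_pitch": 0.25})
        dmap, stats = dp.scanner_dose_map(scanlike, scanlike, curve=curve)
        assert stats.mean == pytest.approx(0.0, abs=1e-6)

    def test_uniform_film_round_trip(self):
        curve = quintic_curve()
        od = ODMap(np.full((100, 100), curve(2.5)), 0.25)
        dmap, stats = dp.scanner_dose_map(od, curve=curve,
                                          roi_mm=(2.0, 2.0, 20.0, 20.0))
        assert stats.mean == pytest.approx(2.5, abs=1e-3)
        assert stats.sd == pytest.approx(0.0, abs=1e-6)

    def test_saturated_pixels_masked_and_counted(self):
        curve = quintic_curve()
        pix = np.full((10, 10), 30000.0)
        exposed = pix.copy()
        exposed[0, 0] = 65535.0
        e = type("S", (), {"pixels": exposed, "pixel_pitch": 0.25})
        u = type("S", (), {"pixels": pix, "pixel_pitch": 0.25})
        _, stats = dp.scanner_dose_map(e, u, curve=curve, saturation=65535)
        assert stats.n_masked == 1

    def test_roi_clipping_flagged(self):
        curve = quintic_curve()
        od = ODMap(np.full((20, 20), curve(1.0)), 0.25)
        _, stats = dp.scanner_dose_map(od, curve=curve,
                                       roi_mm=(-1.0, 0.0, 10.0, 3.0))
        assert stats.roi_clipped


def synthetic_frames(doses, gains, base=None):
    """Noiseless analytic count curves: count_i(d) = gain_i * f(d)."""
    if base is None:
        def base(d):
            return 3600.0 - 380.0 * d + 8.0 * d ** 2
    frames = []
    for d in doses:
        counts = {i + 1: g * base(d) for i, g in enumerate(gains)}
        frames.append((d, ms.ADCFrame(counts=counts, n_reads=1, seed=0)))
    return frames


class TestLdrCalibration:
    doses = (0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

    def test_identical_responses_unit_factors(self):
        cal = dp.calibrate_ldrs(synthetic_frames(self.doses, [1.0, 1.0, 1.0]))
        assert all(f == pytest.approx(1.0, abs=1e-9)
                   for f in cal.conversion_factors.values())

    def test_cloned_gain_recovers_inverse_factor(self):
        cal = dp.calibrate_ldrs(synthetic_frames(self.doses, [1.0, 1.10]))
        assert cal.conversion_factors[2] == pytest.approx(1 / 1.10, abs=1e-3)

    def test_reference_factor_exactly_one(self):
        cal = dp.calibrate_ldrs(synthetic_frames(self.doses, [0.93, 1.07]))
        assert cal.conversion_factors[1] == 1.0

    def test_missing_ldr_named(self):
        frames = synthetic_frames(self.doses, [1.0, 1.0])
        del frames[3][1].counts[2]
        with pytest.raises(CalibrationError, match=r"\[2\]"):
            dp.calibrate_ldrs(frames)

    def test_too_few_dose_levels(self):
        with pytest.raises(CalibrationError, match="7"):
            dp.calibrate_ldrs(synthetic_frames((0.5, 1, 2, 3, 4), [1.0]))


class TestAdcToDose:
    doses = (0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

    def test_round_trip_at_calibration_levels(self):
        gains = [1.0, 1.05, 0.92]
        frames = synthetic_frames(self.doses, gains)
        cal = dp.calibrate_ldrs(frames)
        for d, frame in frames:
            out = dp.adc_to_dose(frame, cal)
            np.testing.assert_allclose(out.dose_gy, d, atol=1e-3)

    def test_all_zero_counts_flagged(self):
        frames = synthetic_frames(self.doses, [1.0, 1.0])
        cal = dp.calibrate_ldrs(frames)
        zero = ms.ADCFrame(counts={1: 0.0, 2: 0.0}, n_reads=1, seed=0)
        out = dp.adc_to_dose(zero, cal)
        assert out.out_of_range.all()
        assert out.dose_gy.isna().all()

    def test_uncalibrated_ldr_rejected(self):
        cal = dp.calibrate_ldrs(synthetic_frames(self.doses, [1.0]))
        frame = ms.ADCFrame(counts={1: 2000.0, 9: 2000.0}, n_reads=1, seed=0)
        with pytest.raises(CalibrationError, match=r"\[9\]"):
            dp.adc_to_dose(frame, cal)


class TestStepAnalysis:
    def setup_films(self, phantom, dispersion=0.0):
        beam = bp.BeamModel(field_dispersion_target=dispersion)
        _, od = bp.irradiate_film(3.0, beam, phantom=phantom,
                                  film_size_mm=(36.0, 24.0), seed=1,
                                  od_noise_sigma=0.0)
        _, od_bg = bp.irradiate_film(3.0, beam, film_size_mm=(36.0, 24.0),
                                     seed=2, od_noise_sigma=0.0)
        return beam, od, od_bg

    def test_background_equal_measurement_recovers_nominal(self):
        beam = bp.xray_60kv_paper()
        _, od = bp.irradiate_film(3.0, beam, film_size_mm=(36.0, 24.0), seed=3,
                                  od_noise_sigma=0.0)
        phantom = bp.StaircasePhantom(material="Al", steps=((12.0, 3.0),),
                                      pitch=12.0, origin=12.0)
        table = dp.step_analysis(od, phantom, od, zones=3, curve=quintic_curve())
        # no real steps in the film: every zone of every region ~ 3 Gy
        np.testing.assert_allclose(table.mean_dose_gy, 3.0, atol=0.02)

    def test_known_ratios_recovered(self):
        phantom = bp.StaircasePhantom(material="Al", steps=((12.0, 3.0), (12.0, 6.0)),
                                      pitch=12.0, origin=12.0)
        beam, od, od_bg = self.setup_films(phantom)
        table = dp.step_analysis(od, phantom, od_bg, zones=3,
                                 curve=quintic_curve())
        r1 = bp.step_dose_ratio(beam, "Al", 3.0)
        r2 = bp.step_dose_ratio(beam, "Al", 6.0)
        mid = table[table.zone == "middle"].set_index("step_id").mean_dose_gy
        assert mid[0] == pytest.approx(3.0, rel=0.01)
        assert mid[1] == pytest.approx(3.0 / r1, rel=0.01)
        assert mid[2] == pytest.approx(3.0 / r2, rel=0.01)

    def test_three_plateaus_distinguishable(self):
        phantom = bp.StaircasePhantom(material="Al", steps=((12.0, 3.0), (12.0, 6.0)),
                                      pitch=12.0, origin=12.0)
        _, od, od_bg = self.setup_films(phantom, dispersion=20.0)
        table = dp.step_analysis(od, phantom, od_bg, zones=3,
                                 curve=quintic_curve())
        mid = table[table.zone == "middle"].sort_values("step_id")
        doses, sds = mid.mean_dose_gy.to_numpy(), mid.sd_gy.to_numpy()
        # consecutive plateaus separated by more than combined spread
        for k in range(2):
            assert doses[k] - doses[k + 1] > sds[k] + sds[k + 1]

    def test_zone_means_consistent_on_homogeneous_field(self):
        phantom = bp.StaircasePhantom(material="Al", steps=((12.0, 3.0),),
                                      pitch=12.0, origin=12.0)
        beam = bp.cs137_paper()
        _, od = bp.irradiate_film(3.0, beam, film_size_mm=(36.0, 24.0), seed=5)
        _, od_bg = bp.irradiate_film(3.0, beam, film_size_mm=(36.0, 24.0), seed=6)
        t3 = dp.step_analysis(od, phantom, od_bg, zones=3, curve=quintic_curve())
        t1 = dp.step_analysis(od, phantom, od_bg, zones=1, curve=quintic_curve())
        for sid in t1.step_id:
            whole = t1[t1.step_id == sid]
            zones = t3[t3.step_id == sid]
            spread = (zones.sd_gy + float(whole.sd_gy.iloc[0])).to_numpy()
            assert np.all(np.abs(zones.mean_dose_gy.to_numpy()
                                 - float(whole.mean_dose_gy.iloc[0])) <= spread)


class TestDoseRatioTable:
    def test_reference_over_itself(self):
        t = dp.make_step_table({0: 2.9})
        r = dp.dose_ratio_table(t, reference_step=0)
        assert r.ratio.iloc[0] == 1.00

    def test_invariant_under_uniform_rescaling(self):
        t1 = dp.make_step_table({0: 2.9, 1: 0.98, 2: 0.49})
        t2 = dp.make_step_table({0: 5.8, 1: 1.96, 2: 0.98})
        r1 = dp.dose_ratio_table(t1).ratio_full.to_numpy()
        r2 = dp.dose_ratio_table(t2).ratio_full.to_numpy()
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_zero_reference_rejected(self):
        from rcfdose.exceptions import DomainError
        with pytest.raises(DomainError):
            dp.dose_ratio_table(dp.make_step_table({0: 0.0, 1: 1.0}))


@pytest.fixture(scope="module")
def setup():
    beam = bp.xray_60kv_paper()
    array = ms.dosimoems_v1()
    phantom = bp.StaircasePhantom(material="Al",
                                  steps=((12.0, 3.0), (12.0, 6.0)),
                                  pitch=12.0, origin=12.0)
    res = dp.moem_branch_experiment(5, cal_doses=dp.WIDE_CAL_DOSES,
                                    film_size_mm=(60.0, 30.0))
    return beam, array, phantom, res["calibration"]


class TestOrientation:
    def test_round_trip_r(self, setup):
        beam, array, phantom, cal = setup
        _, od = bp.irradiate_film(3.0, beam, phantom=phantom,
                                  film_size_mm=(36.0, 36.0),
                                  response=LED_GREEN, seed=42)
        frame = ms.scan_film(od, array, seed=7)
        res = dp.detect_orientation(frame, cal, phantom, array, 3.0, beam=beam)
        assert res.orientation == "R"

    def test_round_trip_r90(self, setup):
        beam, array, phantom, cal = setup
        rotated = bp.StaircasePhantom(material="Al", steps=phantom.steps,
                                      pitch=phantom.pitch, origin=phantom.origin,
                                      orientation="y")
        _, od = bp.irradiate_film(3.0, beam, phantom=rotated,
                                  film_size_mm=(36.0, 36.0),
                                  response=LED_GREEN, seed=42)
        frame = ms.scan_film(od, array, seed=7)
        res = dp.detect_orientation(frame, cal, phantom, array, 3.0, beam=beam)
        assert res.orientation == "R+90"

    def test_uniform_film_undetermined(self, setup):
        beam, array, _, cal = setup
        _, od = bp.irradiate_film(3.0, beam, film_size_mm=(36.0, 36.0),
                                  response=LED_GREEN, seed=42)
        frame = ms.scan_film(od, array, seed=7)
        res = dp.detect_orientation(frame, cal, None, array, 3.0, beam=beam)
        assert res.orientation == "undetermined"


class TestLdrStepRoute:
    def test_per_ldr_step_table(self):
        beam = bp.xray_60kv_paper()
        array = ms.dosimoems_v1()
        phantom = bp.StaircasePhantom(material="Al",
                                      steps=((12.0, 3.0), (12.0, 6.0)),
                                      pitch=12.0, origin=12.0)
        res = dp.moem_branch_experiment(5, cal_doses=dp.WIDE_CAL_DOSES,
                                        film_size_mm=(60.0, 30.0))
        cal = res["calibration"]
        _, od = bp.irradiate_film(3.0, beam, phantom=phantom,
                                  film_size_mm=(36.0, 36.0),
                                  response=LED_GREEN, seed=11)
        _, od_bg = bp.irradiate_film(3.0, beam, film_size_mm=(36.0, 36.0),
                                     response=LED_GREEN, seed=12)
        meas = dp.adc_to_dose(_restrict(ms.scan_film(od, array, seed=3), cal), cal)
        bg = dp.adc_to_dose(_restrict(ms.scan_film(od_bg, array, seed=4), cal), cal)
        table = dp.step_analysis(meas, phantom, bg, zones=3, array=array)
        by_step = table.groupby("step_id").mean_dose_gy.mean()
        assert by_step[0] > by_step[1] > by_step[2]
        assert by_step[0] == pytest.approx(3.0, rel=0.1)


def _restrict(frame, cal):
    keep = set(frame.counts) & set(cal.conversion_factors)
    return ms.ADCFrame(counts={i: frame.counts[i] for i in keep},
                       n_reads=frame.n_reads, seed=frame.seed,
                       boundary=frame.boundary & keep, bad=frame.bad & keep)
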