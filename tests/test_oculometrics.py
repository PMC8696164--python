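import math

import numpy as np
import pytest

from ocutrack.errors import ConfigError, InsufficientDataError
from ocutrack.oculometrics import (
    PupilTrace,
    SineStimulus,
    compute_etm,
    grating_schedule,
    reactivity_speeds,
    sine_brightness,
    trace_from_records,
)
from ocutrack.synthetic import ground_truth_record, okr_scene, plr_scene


def scene_trace(scene):
    t = np.arange(scene.n_frames) / scene.fps
    area = math.pi * scene.pupil_a * scene.pupil_b
    return PupilTrace(time_s=t, area=area, azimuth=scene.azimuth_deg, azimuth_units="deg")


class TestSineBrightness:
    def test_starts_at_half(self):
        assert sine_brightness(0.0, 3.0) == pytest.approx(0.5)

    def test_quarter_period_peak(self):
        assert sine_brightness(15.0, 1.0) == pytest.approx(1.0)

    def test_whole_cycles_return_to_half(self):
        assert sine_brightness(60.0, 6.0) == pytest.approx(0.5)

    def test_nonpositive_freq_rejected(self):
        with pytest.raises(ValueError):
            sine_brightness(1.0, 0.0)

    def test_bounded_in_unit_interval(self):
        t = np.linspace(0, 120, 1000)
        b = sine_brightness(t, 7.0)
        assert b.min() >= 0.0 and b.max() <= 1.0


class TestReactivitySpeeds:
    @pytest.mark.parametrize("ratio", [1.0, 1.5, 2.0, 3.0])
    def test_scripted_asymmetry_recovered(self, ratio):
        scene = plr_scene(
            freq_cpm=6, duration_s=30, fps=60, asymmetry=ratio, waveform="triangle", noise_sigma=0
        )
        res = reactivity_speeds(scene_trace(scene), SineStimulus(freq=6, duration_s=30))
        assert res.v_c / res.v_d == pytest.approx(ratio, rel=0.10)

    def test_constant_area_gives_zero_speeds(self):
        t = np.arange(0, 30, 1 / 60)
        tr = PupilTrace(time_s=t, area=np.full_like(t, 400.0))
        res = reactivity_speeds(tr, SineStimulus(freq=6, duration_s=30))
        assert res.v_c == 0.0 and res.v_d == 0.0

    def test_symmetric_sinusoid_balances_phases(self):
        scene = plr_scene(freq_cpm=6, duration_s=30, fps=60, waveform="sine", noise_sigma=0)
        res = reactivity_speeds(scene_trace(scene), SineStimulus(freq=6, duration_s=30))
        assert res.v_c == pytest.approx(res.v_d, rel=0.02)

    def test_fewer_than_two_cycles_rejected(self):
        t = np.arange(0, 15, 1 / 60)  # 1.5 cycles at 6 cycles/min
        tr = PupilTrace(time_s=t, area=400 + 10 * np.sin(t))
        with pytest.raises(InsufficientDataError):
            reactivity_speeds(tr, SineStimulus(freq=6, duration_s=15))

    def test_heavy_blink_gaps_rejected(self):
        scene = plr_scene(freq_cpm=6, duration_s=30, fps=60, noise_sigma=0)
        tr = scene_trace(scene)
        tr.area[: len(tr.area) // 4] = np.nan  # 25% gap
        with pytest.raises(InsufficientDataError):
            reactivity_speeds(tr, SineStimulus(freq=6, duration_s=30))

    def test_small_blink_gaps_tolerated(self):
        scene = plr_scene(
            freq_cpm=6, duration_s=30, fps=60, asymmetry=2.0, waveform="triangle", noise_sigma=0
        )
        tr = scene_trace(scene)
        tr.area[100:190] = np.nan  # 5% gap
        res = reactivity_speeds(tr, SineStimulus(freq=6, duration_s=30))
        assert res.v_c / res.v_d == pytest.approx(2.0, rel=0.10)

    def test_constriction_dominance_yields_small_p(self):
        scene = plr_scene(
            freq_cpm=12, duration_s=60, fps=60, asymmetry=2.0, waveform="triangle", noise_sigma=0
        )
        res = reactivity_speeds(scene_trace(scene), SineStimulus(freq=12, duration_s=60))
        assert res.p_value < 0.05


class TestPlrEntrainment:
    def test_area_anticorrelates_with_brightness_at_scripted_latency(self):
        latency = 0.5
        scene = plr_scene(freq_cpm=6, duration_s=60, fps=60, latency_s=latency, noise_sigma=0)
        tr = scene_trace(scene)
        stim = SineStimulus(freq=6, duration_s=60)
        b = stim.brightness(tr.time_s)
        a = tr.area - tr.area.mean()
        nb = -(b - b.mean())
        lags = np.arange(-180, 181)  # +/- 3 s at 60 Hz
        cc = [np.dot(np.roll(nb, k), a) for k in lags]
        best_lag_s = lags[int(np.argmax(cc))] / 60.0
        assert abs(best_lag_s - latency) <= 1.0


class TestComputeEtm:
    def test_scripted_sawtooth_counts_fast_phases(self):
        scene = okr_scene(duration_s=60, fps=60, n_fast=10, noise_sigma=0)
        res = compute_etm(scene_trace(scene), threshold=10.0)
        assert len(res.events) == 10
        assert res.rate_per_min == pytest.approx(10.0, rel=0.01)

    def test_flat_azimuth_yields_zero_rate(self):
        t = np.arange(0, 60, 1 / 60)
        tr = PupilTrace(time_s=t, area=np.full_like(t, 100.0), azimuth=np.zeros_like(t))
        res = compute_etm(tr, threshold=10.0)
        assert res.rate_per_min == 0.0 and res.events == []

    def test_downsampling_preserves_event_count(self):
        scene = okr_scene(duration_s=60, fps=60, n_fast=10, noise_sigma=0)
        tr = scene_trace(scene)
        half = PupilTrace(
            time_s=tr.time_s[::2], area=tr.area[::2], azimuth=tr.azimuth[::2], azimuth_units="deg"
        )
        assert len(compute_etm(half, threshold=10.0).events) == 10

    def test_nonpositive_threshold_rejected(self):
        t = np.arange(0, 10, 1 / 60)
        tr = PupilTrace(time_s=t, area=np.full_like(t, 1.0), azimuth=np.zeros_like(t))
        with pytest.raises(ValueError):
            compute_etm(tr, threshold=0.0)

    def test_reflex_absent_scenario_is_quiet(self):
        intact = okr_scene(duration_s=60, fps=60, n_fast=10, reflex_intact=True, noise_sigma=0)
        absent = okr_scene(
            duration_s=60, fps=60, n_fast=10, reflex_intact=False, rng_seed=5, noise_sigma=0
        )
        r_in = compute_etm(scene_trace(intact), threshold=10.0).rate_per_min
        r_out = compute_etm(scene_trace(absent), threshold=10.0).rate_per_min
        assert r_in >= 5.0 * r_out


class TestGratingSchedule:
    def test_default_protocol_spans_268_seconds(self):
        epochs = grating_schedule()
        assert len(epochs) == 8
        assert epochs[-1].t_end == pytest.approx(8 * 30 + 7 * 4)
        assert {e.direction_deg for e in epochs} == {0.0, 180.0}
        assert all(e.spatial_freq_cpd == 0.05 and e.speed_deg_s == 5.0 for e in epochs)

    def test_single_trial_has_no_gap(self):
        epochs = grating_schedule(trials=1)
        assert len(epochs) == 1
        assert (epochs[0].t_start, epochs[0].t_end) == (0.0, 30.0)

    def test_two_short_trials_with_gap(self):
        epochs = grating_schedule(trials=2, on_s=10, gap_s=5)
        assert [(e.t_start, e.t_end) for e in epochs] == [(0.0, 10.0), (15.0, 25.0)]

    def test_empty_directions_rejected(self):
        with pytest.raises(ConfigError):
            grating_schedule(directions=())


class TestTraceFromRecords:
    def test_blink_records_become_nan_gaps(self):
        scene = okr_scene(duration_s=2, fps=60, n_fast=2, noise_sigma=0)
        recs = []
        from ocutrack.core import TrackingRecord

        for i in range(scene.n_frames):
            d = ground_truth_record(scene, i)
            d.pop("truth")
            d.pop("azimuth_deg", None)
            recs.append(TrackingRecord.from_dict(d))
        # knock out two frames as blinks
        recs[5] = TrackingRecord(frame_index=5, time_s=5 / 60, pupil=None, crs=[], blink=True, method="blink")
        tr = trace_from_records(recs, deg_per_px=1.0)
        assert np.isnan(tr.area[5])
        assert tr.azimuth_units == "deg"
        assert len(tr.time_s) == scene.n_frames
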