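"""Thermography spot quantification and scent-marking metrics."""

import numpy as np
import pytest

from lutphysio.io_formats import events_from_records
from lutphysio.mvt import (
    CalibrationError,
    CalibrationModel,
    SpotRecord,
    analyze_frame,
    calibrate,
    classify_spots,
    estimate_volume,
    find_template,
    marking_metrics,
    segment_spots,
    session_summary,
)
from lutphysio.synthetic import (
    SimParams,
    SpotSpec,
    make_spot_specs,
    simulate_thermal_frame,
)


class TestSegmentation:
    def test_blank_frame_has_no_regions(self):
        assert segment_spots(np.full((100, 100), 60, dtype=np.uint8)) == []

    def test_synthetic_frame_recovers_all_regions(self):
        p = SimParams(seed=40)
        img, truth = simulate_thermal_frame(make_spot_specs(p), p)
        spots = segment_spots(img)
        assert len(spots) == len(truth.spot_truth)
        # areas within 2% of the rasterized truth
        for ts in truth.spot_truth:
            best = min(
                spots,
                key=lambda s: (s.centroid[0] - ts["centroid"][0]) ** 2
                + (s.centroid[1] - ts["centroid"][1]) ** 2,
            )
            assert best.area_px == pytest.approx(ts["area_px"], rel=0.02)

    def test_touching_spots_merge_into_one_region(self):
        img = np.full((100, 100), 60, dtype=np.uint8)
        img[40:50, 30:50] = 180
        img[50:60, 30:50] = 180  # adjacent -> single component
        spots = segment_spots(img)
        assert len(spots) == 1
        assert spots[0].area_px == 400

    def test_fixed_threshold_mode(self):
        img = np.full((50, 50), 100, dtype=np.uint8)
        img[10:20, 10:30] = 150
        spots = segment_spots(img, threshold_mode="fixed", fixed_threshold=128)
        assert len(spots) == 1 and spots[0].area_px == 200


class TestCalibration:
    def test_2000_px_template_gives_200_per_cm2(self):
        tpl = SpotRecord("t", (0, 0), area_px=2000)
        model = calibrate(tpl, known_area_cm2=10.0)
        assert model.px_per_cm2 == 200.0

    def test_known_area_recovered_within_2pct(self):
        p = SimParams(seed=41, image_noise_sd=0.0)
        img, truth = simulate_thermal_frame(
            [SpotSpec((300, 400), (11.72, 11.72), "void")], p  # ~3 cm2 at 144 px/cm2
        )
        spots, model = analyze_frame(img)
        spot = [s for s in spots if s.klass != "template"][0]
        assert spot.area_cm2 == pytest.approx(3.0, rel=0.02)

    def test_doubling_resolution_doubles_px_density_not_cm2(self):
        p1 = SimParams(seed=42, px_per_cm2=144.0, image_noise_sd=0.0)
        p2 = SimParams(seed=42, px_per_cm2=288.0, image_noise_sd=0.0,
                       frame_shape=(680, 900))
        r1 = np.sqrt(1.5 * 144.0 / np.pi)
        r2 = np.sqrt(1.5 * 288.0 / np.pi)
        img1, _ = simulate_thermal_frame([SpotSpec((300, 400), (r1, r1), "void")], p1)
        img2, _ = simulate_thermal_frame([SpotSpec((300, 400), (r2, r2), "void")], p2)
        s1, m1 = analyze_frame(img1)
        s2, m2 = analyze_frame(img2)
        assert m2.px_per_cm2 == pytest.approx(2 * m1.px_per_cm2, rel=0.02)
        a1 = [s for s in s1 if s.klass != "template"][0].area_cm2
        a2 = [s for s in s2 if s.klass != "template"][0].area_cm2
        assert a2 == pytest.approx(a1, rel=0.03)

    def test_missing_template_errors(self):
        with pytest.raises(CalibrationError):
            find_template([])


class TestVolume:
    def test_zero_area_zero_volume(self):
        model = CalibrationModel(100.0, volume_slope_ul_per_cm2=50.0)
        assert estimate_volume(0.0, model) == 0.0

    def test_linear_curve_arithmetic(self):
        model = CalibrationModel(100.0, volume_slope_ul_per_cm2=50.0,
                                 volume_intercept_ul=0.0)
        assert estimate_volume(2.0, model) == pytest.approx(100.0)

    def test_generator_volumes_recovered_exactly_through_shared_curve(self):
        p = SimParams(seed=43, image_noise_sd=0.0)
        img, truth = simulate_thermal_frame(make_spot_specs(p), p)
        spots, _ = analyze_frame(img)
        for ts in truth.spot_truth:
            if ts["klass"] == "template":
                continue
            best = min(
                (s for s in spots if s.klass != "template"),
                key=lambda s: (s.centroid[0] - ts["centroid"][0]) ** 2
                + (s.centroid[1] - ts["centroid"][1]) ** 2,
            )
            assert best.volume_ul == pytest.approx(ts["volume_ul"], rel=1e-9)

    def test_area_outside_validity_rejected(self):
        model = CalibrationModel(100.0, area_max_cm2=20.0)
        with pytest.raises(ValueError, match="validity"):
            estimate_volume(25.0, model)


class TestClassification:
    def _spot(self, area_cm2, centroid, model):
        return SpotRecord("s0", centroid, int(area_cm2 * model.px_per_cm2),
                          area_cm2=area_cm2)

    def test_large_corner_spot_is_void(self):
        model = CalibrationModel(144.0)
        s = self._spot(2.0, (20, 20), model)
        out = classify_spots([s], (480, 640), model)
        assert out[0].klass == "void"

    def test_small_central_spot_is_leak_or_mark(self):
        model = CalibrationModel(144.0)
        s = self._spot(0.3, (240, 320), model)
        assert classify_spots([s], (480, 640), model)[0].klass == "leak"
        assert classify_spots([s], (480, 640), model, mode="marking")[0].klass == "mark"

    def test_programmed_labels_recovered(self):
        for seed in range(5):
            p = SimParams(seed=seed)
            img, truth = simulate_thermal_frame(make_spot_specs(p), p)
            spots, _ = analyze_frame(img)
            for ts in truth.spot_truth:
                best = min(
                    spots,
                    key=lambda s: (s.centroid[0] - ts["centroid"][0]) ** 2
                    + (s.centroid[1] - ts["centroid"][1]) ** 2,
                )
                assert best.klass == ts["klass"]

    def test_translation_and_rotation_invariance(self):
        p = SimParams(seed=44, image_noise_sd=0.0)
        base = SpotSpec((250, 300), (15.0, 10.0), "leak")
        shifted = SpotSpec((280, 350), (15.0, 10.0), "leak")
        rotated = SpotSpec((250, 300), (10.0, 15.0), "leak")
        areas = []
        for spec in (base, shifted, rotated):
            img, _ = simulate_thermal_frame([spec], p)
            spots, _ = analyze_frame(img)
            areas.append([s for s in spots if s.klass != "template"][0].area_cm2)
        assert areas[1] == pytest.approx(areas[0], rel=0.02)
        assert areas[2] == pytest.approx(areas[0], rel=0.02)


def _mark_events(times, voids=()):
    recs = [
        {"event_id": f"m{i}", "animal_id": "a", "kind": "mark",
         "t_align_s": t, "t_start_s": t, "t_end_s": t}
        for i, t in enumerate(times)
    ]
    recs += [
        {"event_id": f"v{i}", "animal_id": "a", "kind": "void",
         "t_align_s": t, "t_start_s": t, "t_end_s": t}
        for i, t in enumerate(voids)
    ]
    return events_from_records(recs)


class TestMarking:
    def test_early_abundant_marker_is_dominant(self):
        ev = _mark_events([360.0 + 10 * i for i in range(15)])
        out = marking_metrics(ev, stimulus_time_s=300.0, session_end_s=3600.0)
        assert out["dominance_flag"]
        assert out["latency_s"] == pytest.approx(60.0)

    def test_nine_marks_is_subordinate(self):
        ev = _mark_events([330.0 + 10 * i for i in range(9)])
        out = marking_metrics(ev, 300.0, 3600.0)
        assert not out["dominance_flag"] and out["mark_count"] == 9

    def test_boundary_latency_299_vs_301(self):
        early = _mark_events([300.0 + 299.0 + 10 * i for i in range(10)])
        late = _mark_events([300.0 + 301.0 + 10 * i for i in range(10)])
        assert marking_metrics(early, 300.0, 3600.0)["dominance_flag"]
        assert not marking_metrics(late, 300.0, 3600.0)["dominance_flag"]

    def test_no_marks_latency_censored(self):
        out = marking_metrics(_mark_events([]), 300.0, 3600.0)
        assert out["latency_censored"] and not out["dominance_flag"]
        assert out["latency_s"] == pytest.approx(3300.0)

    def test_corner_voids_not_counted_as_marks(self):
        ev = _mark_events([400.0 + 5 * i for i in range(12)],
                          voids=[500.0, 900.0])
        out = marking_metrics(ev, 300.0, 3600.0)
        assert out["mark_count"] == 12


class TestSummary:
    def test_zero_spots_all_zero(self):
        rec = session_summary([])
        assert rec["n_voids"] == 0 and rec["n_leaks"] == 0
        assert rec["mean_void_volume_ul"] == 0.0

    def test_programmed_counts_recovered(self):
        p = SimParams(seed=45, n_void_spots=3, n_leak_spots=7)
        img, _ = simulate_thermal_frame(make_spot_specs(p), p)
        spots, _ = analyze_frame(img)
        rec = session_summary(spots)
        assert (rec["n_voids"], rec["n_leaks"]) == (3, 7)

    def test_two_run_average(self):
        from lutphysio.mvt import average_runs

        a = {"n_voids": 4, "n_leaks": 2}
        b = {"n_voids": 6, "n_leaks": 0}
        out = average_runs(a, b)
        assert out == {"n_voids": 5.0, "n_leaks": 1.0}
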