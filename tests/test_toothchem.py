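import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinchem.errors import (
    CalibrationError,
    GeometryError,
    PhantomError,
    WindowError,
)
from kinchem.toothchem import (
    NIST_SRM_1486,
    PhantomBand,
    PhantomSpec,
    RatioPoint,
    RawLineScan,
    ROIPolygon,
    SRMSpec,
    calibrate_ba,
    collagen_qc,
    crown_formation_time,
    georeference_scan,
    layer_thickness,
    parse_roi_file,
    reduce_scan,
    roi_statistics,
    surface_contamination_flag,
    synth_scan,
)


def _scan(series, blank_s=1.0, dwell=0.25, speed=40.0, start=(0, 0), end=None):
    n_sample = len(next(iter(series.values()))) - int(round(blank_s / dwell))
    if end is None:
        end = (n_sample * dwell * speed, 0.0)
    return RawLineScan(
        line_id="t",
        start_xy=start,
        end_xy=end,
        dwell_time_s=dwell,
        scan_speed_um_s=speed,
        blank_window_s=blank_s,
        intensities={k: np.asarray(v, float) for k, v in series.items()},
    )


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

def test_signal_equal_to_blank_mean_reduces_to_zero():
    raw = _scan({"43Ca": [100, 100, 100, 100] + [100] * 6})
    red = reduce_scan(raw)
    assert np.all(red.corrected["43Ca"] == 0.0)


def test_lod_rule_arithmetic():
    # blank with sample SD exactly 10 -> LOD 30; corrected 25 -> 0, 35 -> 35
    a, b = 100 - 5 * np.sqrt(2), 100 + 5 * np.sqrt(2)
    blank = [a, b, a, b][:2]  # two points: sd = |a-b|/sqrt(2) = 10
    raw = _scan({"138Ba": blank + [125.0, 135.0]}, blank_s=0.5)
    red = reduce_scan(raw)
    assert red.blank_sds["138Ba"] == pytest.approx(10.0)
    assert red.lods["138Ba"] == pytest.approx(30.0)
    assert red.corrected["138Ba"][0] == 0.0  # 25 < LOD
    assert red.corrected["138Ba"][1] == pytest.approx(35.0)


def test_negative_corrected_clamped_to_zero():
    raw = _scan({"43Ca": [100, 100, 100, 100, 50, 60]})
    red = reduce_scan(raw)
    assert np.all(red.corrected["43Ca"] >= 0.0)


def test_no_corrected_value_inside_lod_gap():
    rng = np.random.default_rng(3)
    raw = _scan({"138Ba": np.concatenate([rng.normal(100, 5, 40), rng.normal(110, 5, 60)])},
                blank_s=10.0)
    red = reduce_scan(raw)
    vals = red.corrected["138Ba"]
    lod = red.lods["138Ba"]
    assert not np.any((vals > 0) & (vals < lod))


def test_reduction_idempotent_on_blank_zero_scan():
    rng = np.random.default_rng(4)
    raw = _scan({"138Ba": np.concatenate([rng.normal(100, 5, 40), rng.normal(500, 5, 60)])},
                blank_s=10.0)
    once = reduce_scan(raw)
    again = reduce_scan(
        _scan({"138Ba": np.concatenate([np.zeros(40), once.corrected["138Ba"]])},
              blank_s=10.0)
    )
    assert np.array_equal(once.corrected["138Ba"], again.corrected["138Ba"])


def test_blank_window_too_long_errors():
    with pytest.raises(WindowError):
        reduce_scan(_scan({"43Ca": [1.0, 2.0, 3.0]}, blank_s=10.0))


def test_blank_window_needs_two_points():
    with pytest.raises(WindowError):
        reduce_scan(_scan({"43Ca": [1.0, 2.0, 3.0]}, blank_s=0.25))


def test_isotope_series_length_mismatch_rejected():
    with pytest.raises(GeometryError):
        _scan({"43Ca": [1, 2, 3, 4], "138Ba": [1, 2, 3]})


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_calibration_at_srm_ratio_returns_certified_value():
    assert float(calibrate_ba(0.7, 0.7)) == pytest.approx(281.0)


def test_calibration_half_ratio():
    assert float(calibrate_ba(0.35, 0.7)) == pytest.approx(140.5)


def test_calibration_zero_srm_ratio_errors():
    with pytest.raises(CalibrationError):
        calibrate_ba(0.5, 0.0)


def test_calibration_linearity():
    base = float(calibrate_ba(0.2, 0.5))
    assert float(calibrate_ba(0.6, 0.5)) == pytest.approx(3 * base)


def test_custom_srm():
    srm = SRMSpec("other", 100.0, 5.0)
    assert float(calibrate_ba(0.5, 0.5, srm)) == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# georeferencing
# ---------------------------------------------------------------------------

def test_single_point_at_start():
    raw = _scan({"43Ca": [100.0, 100.0, 150.0]}, blank_s=0.5, start=(5, 7), end=(50, 7))
    pts = georeference_scan(reduce_scan(raw))
    assert len(pts) == 1
    assert (pts[0].x_um, pts[0].y_um) == (5.0, 7.0)


def test_equal_spacing_including_endpoints():
    series = {"43Ca": [100.0] * 2 + [200.0] * 10}
    raw = _scan(series, blank_s=0.5, start=(0, 0), end=(90, 0))
    pts = georeference_scan(reduce_scan(raw))
    assert [p.x_um for p in pts] == pytest.approx(list(np.arange(0.0, 91.0, 10.0)))


def test_coincident_endpoints_with_many_points_errors():
    raw = _scan({"43Ca": [100.0, 100.0, 1.0, 2.0]}, blank_s=0.5, start=(1, 1), end=(1, 1))
    with pytest.raises(GeometryError):
        georeference_scan(reduce_scan(raw))


def test_zeroed_denominator_yields_undefined_ratio():
    # Ca signal equal to blank -> corrected 0 -> Ba/Ca undefined at that point
    raw = _scan({"43Ca": [100, 100, 500, 100], "138Ba": [10, 10, 60, 60]}, blank_s=0.5)
    pts = georeference_scan(reduce_scan(raw))
    assert np.isfinite(pts[0].ratios["138Ba/43Ca"])
    assert np.isnan(pts[1].ratios["138Ba/43Ca"])


# ---------------------------------------------------------------------------
# ROI statistics
# ---------------------------------------------------------------------------

def _pts(values, xs=None):
    xs = xs if xs is not None else range(len(values))
    return [RatioPoint(float(x), 0.0, {"138Ba/43Ca": float(v)}) for x, v in zip(xs, values)]


SQUARE = ROIPolygon("sq", [(-1, -1), (10, -1), (10, 1), (-1, 1)])


def test_constant_roi_stats():
    rows = roi_statistics(_pts([7.0] * 5), [SQUARE])
    row = rows[0]
    assert row.n_points == 5
    assert row.mean == row.median == 7.0
    assert row.sd == 0.0


def test_percentile_oracle_linear_interpolation():
    rows = roi_statistics(_pts([1, 2, 3, 4, 5]), [SQUARE])
    row = rows[0]
    assert row.median == 3.0
    assert row.p25 == 2.0
    assert row.p75 == 4.0
    assert row.p5 == pytest.approx(np.percentile([1, 2, 3, 4, 5], 5))


def test_point_outside_all_polygons_counted_nowhere():
    far = ROIPolygon("far", [(100, 100), (101, 100), (101, 101), (100, 101)])
    rows = roi_statistics(_pts([1.0]), [far])
    assert rows[0].n_points == 0


def test_empty_roi_warns_and_is_nan():
    far = ROIPolygon("far", [(100, 100), (101, 100), (101, 101), (100, 101)])
    with pytest.warns(UserWarning, match="far"):
        rows = roi_statistics(_pts([1.0]), [far])
    assert np.isnan(rows[0].mean)


def test_boundary_point_counts_inside():
    square = ROIPolygon("b", [(0, 0), (2, 0), (2, 2), (0, 2)])
    pts = [RatioPoint(0.0, 0.0, {"138Ba/43Ca": 1.0})]  # on the corner
    assert roi_statistics(pts, [square])[0].n_points == 1


def test_overlapping_rois_both_count():
    a = ROIPolygon("a", [(-1, -1), (3, -1), (3, 1), (-1, 1)])
    b = ROIPolygon("b", [(1, -1), (5, -1), (5, 1), (1, 1)])
    rows = roi_statistics(_pts([1, 2, 3, 4], xs=[0, 1, 2, 3]), [a, b])
    assert rows[0].n_points == 4  # x in [0,3]
    assert rows[1].n_points == 3  # x in [1,3]


def test_undefined_ratios_excluded():
    pts = _pts([1.0, np.nan, 3.0])
    row = roi_statistics(pts, [SQUARE])[0]
    assert row.n_points == 2
    assert row.mean == 2.0


def test_self_intersecting_polygon_rejected():
    with pytest.raises(GeometryError):
        ROIPolygon("bow", [(0, 0), (1, 1), (1, 0), (0, 1)])


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=40))
def test_percentile_row_ordering_invariant(values):
    row = roi_statistics(_pts(values, xs=np.linspace(0, 9, len(values))), [SQUARE])[0]
    assert row.p5 <= row.p25 <= row.median <= row.p75 <= row.p95


def test_parse_roi_wkt(tmp_path):
    p = tmp_path / "rois.wkt"
    p.write_text("dentin\tPOLYGON ((0 0, 1 0, 1 1, 0 1, 0 0))\n")
    rois = parse_roi_file(p)
    assert rois[0].label == "dentin"
    assert rois[0].polygon.area == pytest.approx(1.0)


def test_parse_roi_csv(tmp_path):
    p = tmp_path / "rois.csv"
    p.write_text("label,x_um,y_um\nA,0,0\nA,1,0\nA,1,1\nB,5,5\nB,6,5\nB,6,6\n")
    rois = parse_roi_file(p)
    assert [r.label for r in rois] == ["A", "B"]


# ---------------------------------------------------------------------------
# layer thickness
# ---------------------------------------------------------------------------

def test_thickness_no_supra_points_zero():
    res = layer_thickness([0.1, 0.1, 0.1], (0.2, 0.01), 0.25, 40.0)
    assert res.n_supra_points == 0
    assert res.thickness_um == 0.0


def test_thickness_arithmetic_example():
    # threshold 0.23; 5 surface-adjacent points above it; 0.25 s x 40 um/s -> 50 um
    vals = [0.2, 0.2, 0.2, 0.3, 0.3, 0.3, 0.3, 0.3]
    res = layer_thickness(vals, (0.20, 0.01), 0.25, 40.0)
    assert res.threshold == pytest.approx(0.23)
    assert res.n_supra_points == 5
    assert res.thickness_um == pytest.approx(50.0)
    assert res.uncertainty_um == 20.0


def test_interior_spike_does_not_count():
    vals = [0.2, 0.9, 0.2, 0.3, 0.3]
    res = layer_thickness(vals, (0.2, 0.01), 0.25, 40.0)
    assert res.n_supra_points == 2


def test_empty_points_error():
    with pytest.raises(GeometryError):
        layer_thickness([], (0.2, 0.01), 0.25, 40.0)


def test_thickness_phantom_oracle():
    spec = PhantomSpec(
        bands=[
            PhantomBand("dentin", 150, 0.30),
            PhantomBand("pre_nnl", 120, 0.20),
            PhantomBand("post_nnl", 100, 0.42),
        ],
        noise_sd=0.0,
    )
    scans, truth = synth_scan(spec, seed=0)
    red = reduce_scan(scans[0])
    pts = georeference_scan(red)
    spacing = truth["point_spacing_um"]
    vals = [p.ratios["138Ba/43Ca"] for p in pts if 151 < p.x_um]
    pre = [p.ratios["138Ba/43Ca"] for p in pts if 151 < p.x_um < 269]
    res = layer_thickness(vals, (np.mean(pre), np.std(pre, ddof=1)), spec.dwell_time_s,
                          spec.scan_speed_um_s)
    assert abs(res.thickness_um - 100.0) <= spacing


# ---------------------------------------------------------------------------
# crown formation time
# ---------------------------------------------------------------------------

def test_crown_time_zero_segments_intercept_only():
    total, per = crown_formation_time([], (0.5, 12.0))
    assert total == 12.0
    assert per == []


def test_crown_time_cumulative_arithmetic():
    total, per = crown_formation_time([100, 200], (0.5, 0.0))
    assert total == pytest.approx(150.0)
    assert per == pytest.approx([50.0, 100.0])


def test_crown_time_concatenation_consistency():
    t1, _ = crown_formation_time([120, 80, 50], (0.31, 4.0))
    t2, _ = crown_formation_time([250], (0.31, 4.0))
    assert t1 == pytest.approx(t2)


def test_crown_time_missing_regression_errors():
    with pytest.raises(ValueError):
        crown_formation_time([100], None)


def test_crown_time_per_segment_rule():
    total, per = crown_formation_time([100, 100], (0.5, 1.0), rule="per_segment")
    assert per == [51.0, 51.0]
    assert total == 102.0


def test_crown_time_negative_segment_rejected():
    with pytest.raises(ValueError):
        crown_formation_time([-5], (0.5, 0.0))


# ---------------------------------------------------------------------------
# collagen QC
# ---------------------------------------------------------------------------

def test_collagen_good_preservation():
    ratio, ok = collagen_qc(42.0, 15.0)
    assert ratio == pytest.approx((42 / 12.011) / (15 / 14.007))
    assert 2.9 <= ratio <= 3.6
    assert ok


def test_collagen_degraded_fails():
    ratio, ok = collagen_qc(40.0, 10.0)
    assert ratio == pytest.approx((40 / 12.011) / (10 / 14.007))
    assert not ok


def test_collagen_zero_nitrogen_errors():
    with pytest.raises(ZeroDivisionError):
        collagen_qc(40.0, 0.0)


# ---------------------------------------------------------------------------
# phantom generator
# ---------------------------------------------------------------------------

def _default_spec(noise=0.0, **kw):
    return PhantomSpec(
        bands=[
            PhantomBand("dentin", 150, 0.30),
            PhantomBand("pre_nnl", 120, 0.20),
            PhantomBand("post_nnl", 80, 0.30),
        ],
        noise_sd=noise,
        **kw,
    )


def test_phantom_noise_zero_ratios_exact():
    scans, truth = synth_scan(_default_spec(), seed=1)
    pts = georeference_scan(reduce_scan(scans[0]))
    # away from band boundaries the ratio equals the band level exactly
    for p in pts:
        if 10 < p.x_um < 140:
            assert p.ratios["138Ba/43Ca"] == pytest.approx(0.30, abs=1e-12)


def test_phantom_deterministic():
    s1, _ = synth_scan(_default_spec(noise=100.0), seed=7)
    s2, _ = synth_scan(_default_spec(noise=100.0), seed=7)
    assert np.array_equal(s1[0].intensities["138Ba"], s2[0].intensities["138Ba"])


def test_phantom_zero_width_rejected():
    with pytest.raises(PhantomError):
        PhantomBand("x", 0.0, 0.3)


def test_phantom_roi_means_recover_band_levels():
    spec = PhantomSpec(
        bands=[PhantomBand("pre", 200, 0.20), PhantomBand("post", 200, 0.26)],
        noise_sd=500.0,
    )
    scans, truth = synth_scan(spec, seed=3)
    pts = georeference_scan(reduce_scan(scans[0]))
    margin = truth["point_spacing_um"]
    rois = [
        ROIPolygon("pre", [(margin, -1), (200 - margin, -1), (200 - margin, 1), (margin, 1)]),
        ROIPolygon("post", [(200 + margin, -1), (400 - margin, -1), (400 - margin, 1),
                            (200 + margin, 1)]),
    ]
    rows = roi_statistics(pts, rois)
    for row, level in zip(rows, (0.20, 0.26)):
        se = row.sd / np.sqrt(row.n_points)
        assert abs(row.mean - level) < 3 * se + 1e-9


def test_phantom_thirty_percent_step_orders_means():
    # a >=30% pre->post step must always order post mean above pre mean
    for seed in range(5):
        spec = PhantomSpec(
            bands=[PhantomBand("pre", 150, 0.20), PhantomBand("post", 150, 0.26)],
            noise_sd=800.0,
        )
        scans, truth = synth_scan(spec, seed=seed)
        pts = georeference_scan(reduce_scan(scans[0]))
        m = truth["point_spacing_um"]
        rois = [
            ROIPolygon("pre", [(m, -1), (150 - m, -1), (150 - m, 1), (m, 1)]),
            ROIPolygon("post", [(150 + m, -1), (300 - m, -1), (300 - m, 1), (150 + m, 1)]),
        ]
        rows = roi_statistics(pts, rois)
        assert rows[1].mean > rows[0].mean


def test_surface_contamination_flag():
    spec = _default_spec(al_gradient_um=20.0)
    scans, _ = synth_scan(spec, seed=2)
    pts = georeference_scan(reduce_scan(scans[0]))
    assert surface_contamination_flag(pts) is True
    clean, _ = synth_scan(_default_spec(), seed=2)
    pts_clean = georeference_scan(reduce_scan(clean[0]))
    assert surface_contamination_flag(pts_clean) is False


def test_phantom_multiple_lines_georeferenced_apart():
    scans, _ = synth_scan(_default_spec(), seed=0, n_lines=3, line_spacing_um=30.0)
    assert [s.start_xy[1] for s in scans] == [0.0, 30.0, 60.0]
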