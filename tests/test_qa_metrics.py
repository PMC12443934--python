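import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomqa.errors import (
    InsufficientDataError,
    PlacementError,
    UndefinedSNRError,
    ValidationError,
)
from phantomqa.mr_simulator import SEQUENCE_PRESETS, NoiseModel, SliceImage, render_slice
from phantomqa.qa_metrics import (
    QAReport,
    RegionSpec,
    analyze_image,
    auto_place_regions,
    average_distance,
    compare_scans,
    compute_cnr,
    compute_snr,
    inter_vial_distances,
    rician_corrected_snr,
)
from phantomqa.vial_detection import DetectionParams, VialROI, detect_vials


def _roi(x, y):
    return VialROI(center_xy=(x, y), center_world=(x, y), radius=8.0, fit_score=1.0)


def _report(distances, snr=100.0, cnr=99.0, spacing=1.5):
    return QAReport(distances=list(distances),
                    average_distance=sum(distances) / len(distances),
                    snr=snr, cnr=cnr, regions=[], pixel_spacing=spacing)


class TestInterVialDistances:
    def test_published_flat_top_t2w_row(self):
        rois = [_roi(0.0, 0.0), _roi(24.0, 0.0), _roi(46.5, 0.0), _roi(72.0, 0.0)]
        assert inter_vial_distances(rois) == pytest.approx([24.0, 22.5, 25.5])

    def test_coincident_centers(self):
        assert inter_vial_distances([_roi(1.0, 1.0), _roi(1.0, 1.0)]) == [0.0]

    def test_3_4_5_triangle(self):
        assert inter_vial_distances([_roi(0.0, 0.0), _roi(3.0, 4.0)]) == [5.0]

    def test_insufficient_rois(self):
        with pytest.raises(InsufficientDataError):
            inter_vial_distances([_roi(0.0, 0.0)])

    def test_pixel_centers_with_spacing(self):
        rois = [VialROI(center_xy=(0.0, 0.0), center_world=None, radius=8.0,
                        fit_score=1.0),
                VialROI(center_xy=(10.0, 0.0), center_world=None, radius=8.0,
                        fit_score=1.0)]
        assert inter_vial_distances(rois, spacing=1.5) == [15.0]


class TestAverageDistance:
    @pytest.mark.parametrize(
        "distances,expected",
        [
            ([24.0, 22.5, 25.5], 24.0),  # published flat-top T2w row
            ([24.1, 24.1, 25.6], 24.6),  # published domed-top T1w row (0.1 mm)
            ([24.0, 25.5, 24.0], 24.5),  # published domed-top T2w row
            ([24.0, 24.0, 24.0], 24.0),  # published flat-top T1w row
        ],
    )
    def test_published_rows(self, distances, expected):
        assert round(average_distance(distances), 1) == expected

    def test_constant_list(self):
        assert average_distance([7.25, 7.25, 7.25]) == 7.25

    def test_empty_refused(self):
        with pytest.raises(InsufficientDataError):
            average_distance([])

    @given(st.lists(st.floats(0.1, 100), min_size=1, max_size=8),
           st.integers(2, 5))
    @settings(max_examples=25, deadline=None)
    def test_mean_idempotent_under_concatenation(self, distances, k):
        one = average_distance(distances)
        many = average_distance(distances * k)
        assert many == pytest.approx(one, rel=1e-12)


class TestCompareScans:
    def test_flat_top_zero_difference(self):
        a = _report([24.0, 24.0, 24.0], spacing=1.6)
        b = _report([24.0, 22.5, 25.5], spacing=1.5)
        cmp = compare_scans(a, b)
        assert cmp.difference == pytest.approx(0.0, abs=1e-12)
        assert cmp.relative_percent == pytest.approx(0.0, abs=1e-12)
        assert cmp.within_pixel

    def test_domed_top_difference(self):
        a = _report([24.1, 24.1, 25.6], spacing=1.6)
        b = _report([24.0, 25.5, 24.0], spacing=1.5)
        cmp = compare_scans(a, b)
        assert cmp.difference == pytest.approx(0.1, abs=1e-9)
        assert cmp.relative_percent == pytest.approx(100 * 0.1 / 24.55, rel=1e-6)
        assert cmp.relative_percent <= 1.0  # the published "within 1%" claim
        assert cmp.within_pixel

    def test_identical_reports(self):
        a = _report([20.0, 20.0])
        cmp = compare_scans(a, a)
        assert cmp.difference == 0.0 and cmp.relative_percent == 0.0
        assert cmp.within_pixel


def _img(array, spacing=1.5):
    return SliceImage(np.asarray(array, dtype=float), (spacing, spacing), (0.0, 0.0))


class TestSnrCnr:
    def _setup(self, signal_value=10.0, noise_std=2.0, noise_mean=0.0):
        rng = np.random.default_rng(5)
        px = np.zeros((40, 40))
        px[:20] = signal_value
        noise_block = rng.normal(noise_mean, noise_std, (10, 20)).clip(0)
        # force exact sample stats by standardizing
        noise_block = (noise_block - noise_block.mean()) / noise_block.std(ddof=1)
        noise_block = noise_block * noise_std + noise_mean
        noise_block -= noise_block.min()  # keep non-negative
        px[25:35, 0:20] = noise_block
        img = _img(px)
        signal = RegionSpec("signal", (5, 5), (5, 5))
        noise = [RegionSpec("noise", (25, 0), (10, 10)),
                 RegionSpec("noise", (25, 10), (10, 10))]
        return img, signal, noise

    def test_snr_simple_ratio(self):
        img, signal, noise = self._setup(signal_value=10.0, noise_std=2.0)
        pooled = np.concatenate([n.pixels(img).ravel() for n in noise])
        expected = 10.0 / np.std(pooled, ddof=1)
        assert compute_snr(img, signal, noise) == pytest.approx(expected, rel=1e-12)

    def test_snr_zero_signal(self):
        img, signal, noise = self._setup(signal_value=0.0)
        assert compute_snr(img, signal, noise) == 0.0

    def test_cnr_equal_means_zero(self):
        px = np.full((40, 40), 5.0)
        px[25:35, 0:20] = np.tile([4.0, 6.0], (10, 10))  # mean 5, nonzero std
        img = _img(px)
        signal = RegionSpec("signal", (0, 0), (5, 5))
        noise = [RegionSpec("noise", (25, 0)), RegionSpec("noise", (25, 10))]
        assert compute_cnr(img, signal, noise) == pytest.approx(0.0, abs=1e-12)

    def test_cnr_worked_example(self):
        # mean signal 12, mean noise 2, noise std 2 -> CNR 5
        px = np.zeros((40, 40))
        px[0:5, 0:5] = 12.0
        vals = np.array([0.0, 4.0] * 100)  # mean 2, sample std ~2.005
        px[25:35, 0:20] = vals.reshape(10, 20)
        img = _img(px)
        signal = RegionSpec("signal", (0, 0), (5, 5))
        noise = [RegionSpec("noise", (25, 0)), RegionSpec("noise", (25, 10))]
        std = np.std(vals, ddof=1)
        assert compute_cnr(img, signal, noise) == pytest.approx((12 - 2) / std)

    def test_cnr_below_snr_when_noise_mean_positive(self):
        img, signal, noise = self._setup(signal_value=10.0, noise_mean=3.0)
        assert compute_cnr(img, signal, noise) < compute_snr(img, signal, noise)

    def test_zero_noise_std_undefined(self):
        px = np.zeros((40, 40))
        px[0:5, 0:5] = 9.0
        img = _img(px)
        signal = RegionSpec("signal", (0, 0), (5, 5))
        noise = [RegionSpec("noise", (25, 0))]
        with pytest.raises(UndefinedSNRError):
            compute_snr(img, signal, noise)

    def test_region_outside_image_rejected(self):
        img = _img(np.ones((20, 20)))
        with pytest.raises(ValidationError):
            RegionSpec("noise", (15, 15)).pixels(img)

    @given(st.floats(0.01, 1e4))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        img, signal, noise = self._setup()
        scaled = _img(img.pixels * c)
        assert compute_snr(scaled, signal, noise) == pytest.approx(
            compute_snr(img, signal, noise), rel=1e-9)
        assert compute_cnr(scaled, signal, noise) == pytest.approx(
            compute_cnr(img, signal, noise), rel=1e-9)

    def test_global_offset_changes_snr_not_cnr(self):
        # documented asymmetry: CNR is offset-invariant, SNR is not
        img, signal, noise = self._setup(signal_value=10.0, noise_mean=1.0)
        shifted = _img(img.pixels + 5.0)
        assert compute_cnr(shifted, signal, noise) == pytest.approx(
            compute_cnr(img, signal, noise), rel=1e-9)
        assert compute_snr(shifted, signal, noise) > compute_snr(img, signal, noise)

    def test_snr_recovers_known_sigma(self, row_geometry):
        # corrected estimate vs the simulator's effective sigma, 20 seeds
        seq = SEQUENCE_PRESETS["t2w_coronal"]
        sigma = 2.4
        ratios = []
        for seed in range(20):
            img, vials = render_slice(row_geometry, seq,
                                      noise=NoiseModel("rician", sigma, seed=seed))
            rois = detect_vials(img, DetectionParams(expected_count=4))
            signal, noise = auto_place_regions(img, rois, mode="t2w")
            snr = rician_corrected_snr(img, signal, noise)
            s = float(np.mean(signal.pixels(img)))
            expected = s / (sigma / math.sqrt(seq.averages))
            ratios.append(snr / expected)
        assert abs(np.mean(ratios) - 1.0) < 0.1


class TestAutoPlaceRegions:
    def test_t1w_signal_inside_oil_vial(self, fixture_set):
        scan = fixture_set["t1w_flat"]
        rois = detect_vials(scan.image, DetectionParams(expected_count=4))
        signal, noise = auto_place_regions(scan.image, rois, mode="t1w")
        oil = next(v for v in scan.vials if v.material == "oil")
        r0, c0 = signal.top_left
        center = (c0 + 2.0, r0 + 2.0)
        dist = math.hypot(center[0] - oil.center_px[0], center[1] - oil.center_px[1])
        assert dist < oil.radius_px

    def test_t2w_signal_in_background_water(self, fixture_set):
        scan = fixture_set["t2w_flat"]
        rois = detect_vials(scan.image, DetectionParams(expected_count=4))
        signal, noise = auto_place_regions(scan.image, rois, mode="t2w")
        r0, c0 = signal.top_left
        center = np.array([c0 + 2.0, r0 + 2.0])
        for v in scan.vials:
            d = math.hypot(center[0] - v.center_px[0], center[1] - v.center_px[1])
            assert d > v.radius_px
        # inside the water fill: intensity near the water signal
        water_mean = float(np.mean(signal.pixels(scan.image)))
        assert water_mean > 0.5 * max(v.signal for v in scan.vials)

    def test_noise_regions_in_air(self, fixture_set):
        scan = fixture_set["t2w_flat"]
        rois = detect_vials(scan.image, DetectionParams(expected_count=4))
        _, noise = auto_place_regions(scan.image, rois, mode="t2w")
        assert len(noise) == 2
        for spec in noise:
            assert spec.size == (10, 10)
            assert float(np.mean(spec.pixels(scan.image))) < 20.0  # air, not water

    def test_all_foreground_placement_error(self):
        img = _img(np.full((60, 60), 7.0))
        with pytest.raises(PlacementError):
            auto_place_regions(img, [], mode="t2w")


class TestQAReport:
    def test_average_must_match_mean(self):
        with pytest.raises(ValidationError):
            QAReport(distances=[1.0, 2.0], average_distance=2.0, snr=1.0,
                     cnr=1.0, regions=[], pixel_spacing=1.5)

    def test_round_trip_dict(self):
        rep = _report([24.0, 22.5, 25.5])
        back = QAReport.from_dict(rep.to_dict())
        assert back.distances == rep.distances
        assert back.average_distance == rep.average_distance

    def test_analyze_image_end_to_end(self, fixture_set):
        scan = fixture_set["t2w_flat"]
        rois = detect_vials(scan.image, DetectionParams(expected_count=4))
        rep = analyze_image(scan.image, rois, mode="t2w")
        assert len(rep.distances) == 3
        assert rep.average_distance == pytest.approx(24.0, abs=0.15)
        assert rep.snr > 0 and rep.cnr < rep.snr
        assert rep.pixel_spacing == 1.5
        assert "image_hash" in rep.provenance
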