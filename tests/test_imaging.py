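"""Nucleus segmentation, positivity scoring, and foci counting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cisflux import synthetic
from cisflux.imaging import (
    FociDetector,
    PositivityScorer,
    classify_positive,
    derive_threshold,
    detect_foci,
    max_project,
    measure_nuclei,
    segment_nuclei,
)


def _disk_image(centers, radius=10, shape=(200, 200), value=1000.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


class TestSegmentation:
    def test_blank_image_yields_no_nuclei(self):
        assert segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_well_separated_disks_counted_and_located(self, image_scenario):
        image, truth = synthetic.gen_nuclei_image(image_scenario)
        labels = segment_nuclei(image[0], min_distance=8, min_area=30)
        assert labels.max() == truth["n_nuclei"]
        found = measure_nuclei(labels, image[0])
        true_centers = np.array([[n["center_y"], n["center_x"]]
                                 for n in truth["nuclei"]])
        for cy, cx in found[["centroid_y", "centroid_x"]].to_numpy():
            dist = np.min(np.hypot(true_centers[:, 0] - cy,
                                   true_centers[:, 1] - cx))
            assert dist < 2.0

    def test_touching_disks_split_by_watershed(self):
        # two disks overlapping by a small neck: distinct distance maxima
        img = _disk_image([(100, 90), (100, 108)], radius=10)
        labels = segment_nuclei(img, sigma=1.0, min_distance=8, min_area=30)
        assert labels.max() == 2

    def test_exact_counts_across_seeds(self):
        for seed in range(5):
            scn = synthetic.ImageScenario(
                n_nuclei=12, image_size=(300, 300), background_sd=5.0,
                foci_per_nucleus=("fixed", 0), seed=seed)
            image, truth = synthetic.gen_nuclei_image(scn)
            labels = segment_nuclei(image[0], min_distance=8, min_area=30)
            assert labels.max() == truth["n_nuclei"]


class TestMeasurement:
    def test_uniform_channel_means(self):
        img = _disk_image([(50, 50)], radius=8)
        labels = segment_nuclei(img, min_distance=5, min_area=20)
        rec = measure_nuclei(labels, np.full_like(img, 7.0))
        assert np.allclose(rec["mean_intensity"], 7.0)

    def test_mean_is_pixel_average(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = labels[0, 1] = 1
        chan = np.zeros((4, 4))
        chan[0, 0], chan[0, 1] = 10.0, 20.0
        rec = measure_nuclei(labels, chan)
        assert rec.loc[0, "mean_intensity"] == pytest.approx(15.0)

    def test_empty_label_map_gives_empty_table(self):
        rec = measure_nuclei(np.zeros((8, 8), int), np.zeros((8, 8)))
        assert rec.empty

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            measure_nuclei(np.zeros((4, 4), int), np.zeros((5, 5)))


class TestPositivity:
    def test_zero_sd_threshold_is_mean(self):
        thr = derive_threshold([10.0, 10.0, 10.0])
        assert thr.threshold == pytest.approx(10.0)

    def test_mean_plus_one_sample_sd(self):
        thr = derive_threshold([8.0, 10.0, 12.0])
        assert thr.control_mean == pytest.approx(10.0)
        assert thr.control_sd == pytest.approx(2.0)  # n-1 denominator
        assert thr.threshold == pytest.approx(12.0)

    def test_single_control_errors(self):
        with pytest.raises(ValueError):
            derive_threshold([5.0])

    def test_cell_exactly_at_threshold_is_not_positive(self):
        thr = derive_threshold([8.0, 10.0, 12.0])
        records = pd.DataFrame({"mean_intensity": [12.0, 12.0001]})
        out, pct = classify_positive(records, thr)
        assert list(out["positive"]) == [False, True]
        assert pct == pytest.approx(50.0)

    def test_all_below_threshold_zero_percent(self):
        thr = derive_threshold([100.0, 110.0, 120.0])
        _, pct = classify_positive(pd.DataFrame({"mean_intensity": [1.0, 2.0]}), thr)
        assert pct == 0.0

    def test_empty_population_errors(self):
        thr = derive_threshold([1.0, 2.0])
        with pytest.raises(ValueError):
            classify_positive(pd.DataFrame({"mean_intensity": []}), thr)

    def test_gaussian_null_scores_one_minus_phi_of_one(self, rng):
        x = rng.normal(500.0, 40.0, 10_000)
        scorer = PositivityScorer().fit(x)
        expected = 100.0 * (1.0 - stats.norm.cdf(1.0))
        assert scorer.percent_positive(x) == pytest.approx(expected, abs=1.5)

    def test_percent_positive_invariant_under_joint_affine_rescale(self, rng):
        control = rng.normal(300.0, 50.0, 500)
        treated = rng.normal(400.0, 60.0, 500)
        base = PositivityScorer().fit(control).percent_positive(treated)
        scaled = PositivityScorer().fit(3.0 * control + 17.0).percent_positive(
            3.0 * treated + 17.0)
        assert scaled == pytest.approx(base)


class TestFoci:
    def test_uniform_channel_has_no_foci(self):
        labels = _disk_image([(32, 32)], radius=8, shape=(64, 64)).astype(int)
        labels[labels > 0] = 1
        _, counts = detect_foci(np.full((64, 64), 5.0), labels, prominence=1.0)
        assert counts["foci_count"].sum() == 0

    def test_single_gaussian_spot_detected(self):
        yy, xx = np.mgrid[0:64, 0:64]
        labels = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 100).astype(int)
        chan = 100.0 * labels + 500.0 * np.exp(
            -((yy - 32.0) ** 2 + (xx - 32.0) ** 2) / (2 * 1.5**2))
        _, counts = detect_foci(chan, labels, min_distance=3, prominence=50.0)
        assert counts.loc[0, "foci_count"] == 1

    def test_degenerate_three_foci_scenario_recovered(self):
        recovered = []
        for seed in range(4):
            scn = synthetic.ImageScenario(
                n_nuclei=8, image_size=(300, 300), radius_range=(10, 13),
                background_sd=8.0, foci_per_nucleus=("fixed", 3),
                focus_amplitude=900.0, focus_sigma=1.5, seed=seed)
            image, truth = synthetic.gen_nuclei_image(scn)
            labels = segment_nuclei(image[0], min_distance=8, min_area=30)
            assert labels.max() == truth["n_nuclei"]
            _, counts = detect_foci(image[1], labels, min_distance=3)
            recovered.extend(counts["foci_count"].tolist())
        frac_exact = np.mean(np.asarray(recovered) == 3)
        assert frac_exact >= 0.95

    def test_counts_monotone_in_prominence(self):
        scn = synthetic.ImageScenario(
            n_nuclei=6, image_size=(256, 256), background_sd=10.0,
            foci_per_nucleus=("poisson", 4.0), seed=11)
        image, _ = synthetic.gen_nuclei_image(scn)
        labels = segment_nuclei(image[0], min_distance=8, min_area=30)
        totals = []
        for prom in (0.0, 50.0, 200.0, 800.0):
            _, counts = detect_foci(image[1], labels, prominence=prom)
            totals.append(counts["foci_count"].sum())
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        img = rng.uniform(size=(1, 16, 16))
        assert np.array_equal(max_project(img), img[0])

    def test_disjoint_spots_union(self):
        a = np.zeros((8, 8)); a[2, 2] = 5.0
        b = np.zeros((8, 8)); b[6, 6] = 7.0
        out = max_project(np.stack([a, b]))
        assert out[2, 2] == 5.0 and out[6, 6] == 7.0

    def test_empty_stack_errors(self):
        with pytest.raises(ValueError):
            max_project(np.zeros((0, 8, 8)))
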