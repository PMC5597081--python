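"""2D pipeline stages against generator truth and hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from gjflux import image2d, pipeline, simulate
from gjflux.image2d import (
    EARLY_ENDOSOME,
    LYSOSOME,
    SURFACE,
    GainField,
    ImageSet,
    aggregate_plate,
    aggregate_well,
    assign_compartments,
    compute_gain_field,
    correct_illumination,
    detect_punctae,
    partition_transfected,
    quantify_tracts,
    segment_cells,
    segment_nuclei,
    sum_slices,
    surface_objects,
)


def _disk_image(shape, centers, radius, level=100.0, bg=5.0):
    img = np.full(shape, bg)
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    for r0, c0 in centers:
        img[np.hypot(rr - r0, cc - c0) <= radius] = level
    return img


class TestGainField:
    def test_constant_image_gives_unit_gain(self):
        gain = compute_gain_field([np.full((256, 256), 7.0)])
        np.testing.assert_allclose(gain.field, 1.0, atol=1e-9)

    def test_smooth_gain_recovered(self):
        truth = simulate.make_gain_field((512, 512), 0.2, seed=0)
        image = 50.0 * truth
        gain = compute_gain_field([image])
        r = np.corrcoef(gain.field.ravel(), truth.ravel())[0, 1]
        assert r > 0.99

    def test_hot_pixel_robustness(self):
        image = np.full((512, 512), 100.0)
        image[100, 100] = 1e6
        gain = compute_gain_field([image])
        assert np.max(np.abs(gain.field - 1.0)) < 1e-3

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            compute_gain_field([np.ones((64, 64))], window_px=200)

    def test_empty_list(self):
        with pytest.raises(ValueError):
            compute_gain_field([])

    def test_gainfield_validation(self):
        with pytest.raises(ValueError):
            GainField(np.full((4, 4), 2.0))  # mean != 1
        with pytest.raises(ValueError):
            GainField(np.array([[1.5, 0.5], [2.0, 0.0]]))  # non-positive


class TestCorrectIllumination:
    def test_unit_gain_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 10, (32, 32))
        out = correct_illumination(img, GainField(np.ones((32, 32))))
        np.testing.assert_array_equal(out, img)

    def test_algebraic_inverse(self):
        g = simulate.make_gain_field((64, 64), 0.2, seed=2)
        s = np.random.default_rng(1).uniform(1, 5, (64, 64))
        out = correct_illumination(s * g, GainField(g))
        np.testing.assert_allclose(out, s, rtol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            correct_illumination(np.ones((8, 8)), GainField(np.ones((4, 4))))


class TestSegmentNuclei:
    def test_exact_count_on_synthetic(self, default_field):
        imageset, truth = default_field
        labels = segment_nuclei(imageset["DNA"])
        assert labels.max() == len(truth.nucleus_centroids)

    def test_small_object_excluded(self):
        img = _disk_image((128, 128), [(64, 64)], radius=5)  # diameter 10
        labels = segment_nuclei(img)
        assert labels.max() == 0

    def test_in_gate_object_kept(self):
        img = _disk_image((128, 128), [(64, 64)], radius=15)  # diameter 30
        labels = segment_nuclei(img)
        assert labels.max() == 1

    def test_bridge_split_by_watershed(self):
        img = _disk_image((128, 128), [(64, 40), (64, 88)], radius=16)
        img[63:65, 40:88] = 100.0  # 2-px bridge
        labels = segment_nuclei(img)
        assert labels.max() == 2

    def test_empty_image_empty_mask(self):
        labels = segment_nuclei(np.zeros((64, 64)))
        assert labels.max() == 0


class TestSegmentCells:
    def test_single_nucleus_in_disk(self):
        cell_img = _disk_image((128, 128), [(64, 64)], radius=40, level=50, bg=0)
        nuclei = np.zeros((128, 128), dtype=np.int32)
        rr = np.arange(128)[:, None]
        cc = np.arange(128)[None, :]
        nuclei[np.hypot(rr - 64, cc - 64) <= 12] = 1
        cells = segment_cells(nuclei, cell_img, threshold=25.0)
        disk = cell_img > 25.0
        assert (cells > 0).sum() == pytest.approx(disk.sum(), rel=0.02)
        assert cells.max() == 1

    def test_bijection_with_nuclei(self, default_field, default_result):
        imageset, _ = default_field
        nuclei = default_result.nuclei_mask
        cells = default_result.cell_mask
        assert cells.max() == nuclei.max()
        for lab in range(1, int(nuclei.max()) + 1):
            assert (cells[nuclei == lab] == lab).all()

    def test_assignment_against_truth(self, default_field, default_result):
        _, truth = default_field
        seg = default_result.cell_mask
        tru = truth.cell_label_mask
        agree = 0
        jaccards = []
        for lab in range(1, int(seg.max()) + 1):
            m = seg == lab
            overlap = tru[m]
            tlab = np.bincount(overlap[overlap > 0]).argmax()
            t = tru == tlab
            agree += (m & t).sum()
            jaccards.append((m & t).sum() / (m | t).sum())
        assert agree / (tru > 0).sum() >= 0.95
        assert min(jaccards) >= 0.8

    def test_nucleus_outside_foreground_degenerates(self):
        nuclei = np.zeros((64, 64), dtype=np.int32)
        nuclei[10:14, 10:14] = 1
        cells = segment_cells(nuclei, np.zeros((64, 64)), threshold=10.0)
        assert (cells == 1).sum() >= (nuclei == 1).sum()


class TestPartitionTransfected:
    def test_all_dark_gfp_all_false(self):
        cells = np.ones((32, 32), dtype=np.int32)
        cells[16:] = 2
        calls = partition_transfected(cells, np.zeros((32, 32)))
        assert calls == {1: False, 2: False}

    def test_zero_threshold_override_all_true(self):
        cells = np.ones((32, 32), dtype=np.int32)
        cells[16:] = 2
        calls = partition_transfected(cells, np.full((32, 32), 5.0), threshold=0.0)
        assert calls == {1: True, 2: True}

    def test_missing_gfp_channel_errors(self):
        with pytest.raises(ValueError):
            partition_transfected(np.ones((8, 8), dtype=np.int32), None)

    def test_bimodal_accuracy(self):
        params = simulate.MonolayerParams(seed=7, transfected_fraction=0.4)
        imageset, truth = simulate.make_monolayer(params)
        res = pipeline.quantify_field(
            imageset, cfg=pipeline.FieldConfig(partition_transfected=True)
        )
        seg = res.cell_mask
        tru = truth.cell_label_mask
        correct = 0
        for lab in range(1, int(seg.max()) + 1):
            overlap = tru[seg == lab]
            tlab = np.bincount(overlap[overlap > 0]).argmax()
            correct += res.transfected.get(lab, False) == (
                tlab in truth.transfected_cells
            )
        assert correct / seg.max() >= 0.98


class TestDetectPunctae:
    def _spot_field(self, centers, diameter, shape=(256, 256), bg=5.0):
        img = np.full(shape, bg)
        for r, c in centers:
            simulate._render_gaussian_spot(img, r, c, diameter, 150.0)
        return img

    def test_count_on_noiseless_spots(self):
        centers = [(40 + 40 * i, 40 + 40 * j) for i in range(5) for j in range(2)]
        img = self._spot_field(centers, diameter=12.0)
        cells = np.ones(img.shape, dtype=np.int32)
        result = detect_punctae(img, cells)
        assert len(result) == 10

    def test_small_spot_excluded(self):
        img = self._spot_field([(64, 64)], diameter=4.0)
        cells = np.ones(img.shape, dtype=np.int32)
        assert len(detect_punctae(img, cells)) == 0

    def test_spot_outside_cells_excluded(self):
        img = self._spot_field([(30, 30), (120, 120)], diameter=12.0)
        cells = np.zeros(img.shape, dtype=np.int32)
        cells[80:, 80:] = 1  # only the second spot lives inside a cell
        result = detect_punctae(img, cells)
        assert len(result) == 1
        assert result.table["cell_label"].iloc[0] == 1

    def test_monotone_gate(self, default_field, default_result):
        imageset = default_result.imageset
        cells = default_result.cell_mask
        n_wide = len(detect_punctae(imageset["CX43"], cells, d_min=8, d_max=20))
        n_narrow = len(detect_punctae(imageset["CX43"], cells, d_min=10, d_max=18))
        assert n_narrow <= n_wide

    def test_diameter_measurement_unbiased(self):
        img = self._spot_field([(100, 100)], diameter=14.0)
        cells = np.ones(img.shape, dtype=np.int32)
        result = detect_punctae(img, cells)
        assert result.table["equivalent_diameter_px"].iloc[0] == pytest.approx(
            14.0, abs=0.5
        )


class TestSurfaceObjects:
    def test_blank_channel(self):
        mask, stats = surface_objects(np.zeros((64, 64)))
        assert not mask.any()
        assert stats["area_px"] == 0

    def test_rim_coverage(self, default_field):
        imageset, truth = default_field
        mask, _ = surface_objects(imageset["ITGA3"])
        rim = truth.rim_mask
        assert (mask & rim).sum() / rim.sum() >= 0.9

    def test_area_additive_over_disjoint_fields(self):
        a = np.zeros((64, 64))
        a[:10, :10] = 100.0
        b = np.zeros((64, 64))
        b[-10:, -10:] = 100.0
        _, sa = surface_objects(a, threshold=50.0)
        _, sb = surface_objects(b, threshold=50.0)
        _, sab = surface_objects(a + b, threshold=50.0)
        assert sa["area_px"] + sb["area_px"] == sab["area_px"]

    def test_area_in_physical_units(self):
        img = np.zeros((32, 32))
        img[:4, :4] = 100.0
        _, stats = surface_objects(img, threshold=50.0, pixel_size_um=0.5)
        assert stats["area_um2"] == pytest.approx(16 * 0.25)


class TestAssignCompartments:
    def test_all_surface(self, default_result):
        cx43 = default_result.cx43
        surface = np.ones(default_result.cell_mask.shape, dtype=bool)
        fractions, _ = assign_compartments(cx43, surface, {})
        assert fractions.as_tuple() == (100.0, 0.0, 0.0)

    def test_bad_marker_kind(self, default_result):
        with pytest.raises(ValueError):
            assign_compartments(
                default_result.cx43,
                default_result.surface_mask,
                {"RAB11": default_result.marker_punctae["EEA1"]},
            )

    def test_sum_is_100(self, default_result):
        f = default_result.fractions
        assert f.pct_surface + f.pct_early_endosome + f.pct_lysosome == pytest.approx(
            100.0, abs=1e-6
        )

    def test_recovery_against_truth(self, default_field, default_result):
        _, truth = default_field
        got = np.array(default_result.fractions.as_tuple())
        want = np.array(truth.compartment_fractions_pct())
        assert np.abs(got - want).max() <= 3.0

    def test_no_classified_puncta_errors(self):
        table = pd.DataFrame(columns=image2d._PUNCTA_COLUMNS)
        empty = image2d.PunctaSet(table=table, label_mask=np.zeros((8, 8), np.int32))
        with pytest.raises(ValueError):
            assign_compartments(empty, np.zeros((8, 8), bool), {})

    def test_centroid_mode(self, default_field, default_result):
        fractions, _ = assign_compartments(
            default_result.cx43,
            default_result.surface_mask,
            default_result.marker_punctae,
            mode="centroid",
        )
        total = sum(fractions.as_tuple())
        assert total == pytest.approx(100.0, abs=1e-6)


class TestAggregation:
    def test_single_site_identity(self):
        df = pd.DataFrame(
            [{"well_id": "w1", "site_id": "s1", "punctae_per_cell": 12.5}]
        )
        out = aggregate_well(df)
        assert out["punctae_per_cell"] == 12.5
        assert out["n_sites"] == 1

    def test_well_mean(self):
        df = pd.DataFrame(
            {
                "well_id": ["w1"] * 3,
                "site_id": ["a", "b", "c"],
                "punctae_per_cell": [10.0, 20.0, 30.0],
            }
        )
        assert aggregate_well(df)["punctae_per_cell"] == 20.0

    def test_mixed_wells_error(self):
        df = pd.DataFrame(
            {"well_id": ["w1", "w2"], "site_id": ["a", "b"], "x": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="mixed wells"):
            aggregate_well(df)

    def test_hierarchical_vs_pooled_on_unbalanced_fixture(self):
        # well w1 sites (1, 2); well w2 site (4): hierarchical mean is
        # (1.5 + 4)/2 = 2.75, pooled mean is 7/3 — hand-computed oracle
        df = pd.DataFrame(
            {
                "condition": ["c"] * 3,
                "well_id": ["w1", "w1", "w2"],
                "site_id": ["s1", "s2", "s1"],
                "value": [1.0, 2.0, 4.0],
            }
        )
        wells, conditions = aggregate_plate(df)
        assert sorted(wells["value"]) == [1.5, 4.0]
        assert conditions["value"].iloc[0] == pytest.approx(2.75)
        assert conditions["value"].iloc[0] != pytest.approx(7.0 / 3.0)

    def test_balanced_equals_pooled(self):
        df = pd.DataFrame(
            {
                "condition": ["c"] * 4,
                "well_id": ["w1", "w1", "w2", "w2"],
                "site_id": list("abab"),
                "value": [1.0, 3.0, 5.0, 7.0],
            }
        )
        _, conditions = aggregate_plate(df)
        assert conditions["value"].iloc[0] == pytest.approx(4.0)


class TestTractDensitometry:
    def test_single_slice_projection(self):
        stack = np.random.default_rng(0).uniform(size=(1, 16, 16))
        np.testing.assert_array_equal(sum_slices(stack), stack[0])

    def test_projection_sums(self):
        stack = np.ones((5, 8, 8))
        np.testing.assert_allclose(sum_slices(stack), 5.0)

    def test_roi_constant_value(self):
        img = np.full((64, 64), 7.0)
        square = np.array([[10.0, 10.0], [10.0, 30.0], [30.0, 30.0], [30.0, 10.0]])
        other = np.array([[40.0, 40.0], [40.0, 50.0], [50.0, 50.0], [50.0, 40.0]])
        quant = quantify_tracts(img, [square, other])
        row = quant.per_roi.iloc[0]
        assert row["mgv"] == pytest.approx(7.0)
        assert row["integrated_density"] == pytest.approx(row["area_px"] * 7.0)

    def test_weighted_mean_mgv_hand_oracle(self):
        # tracts (area 100, MGV 10) and (area 300, MGV 20):
        # weighted mean = (100*10 + 300*20)/400 = 17.5
        img = np.zeros((60, 60))
        img[0:10, 0:10] = 10.0  # 100 px at 10
        img[20:35, 20:40] = 20.0  # 300 px at 20
        roi1 = np.array([[-0.5, -0.5], [-0.5, 9.5], [9.5, 9.5], [9.5, -0.5]])
        roi2 = np.array([[19.5, 19.5], [19.5, 39.5], [34.5, 39.5], [34.5, 19.5]])
        quant = quantify_tracts(img, [roi1, roi2])
        areas = quant.per_roi["area_px"].tolist()
        assert areas == [100.0, 300.0]
        assert quant.weighted_mean_mgv == pytest.approx(17.5)
        assert quant.total_integrated_density == pytest.approx(17.5 * 400)

    def test_integrated_density_identity(self, rng):
        img = rng.uniform(0, 50, (64, 64))
        roi1 = np.array([[5.0, 5.0], [5.0, 25.0], [25.0, 25.0], [25.0, 5.0]])
        roi2 = np.array([[30.0, 30.0], [30.0, 55.0], [55.0, 55.0], [55.0, 30.0]])
        quant = quantify_tracts(img, [roi1, roi2])
        for row in quant.per_roi.itertuples():
            assert row.integrated_density == pytest.approx(row.area_px * row.mgv)

    def test_wrong_roi_count(self):
        with pytest.raises(ValueError):
            quantify_tracts(np.ones((8, 8)), [np.array([[0, 0], [0, 4], [4, 4]])])

    def test_empty_roi_errors(self):
        degenerate = np.array([[0.2, 0.2], [0.2, 0.3], [0.3, 0.3]])
        square = np.array([[1.0, 1.0], [1.0, 5.0], [5.0, 5.0], [5.0, 1.0]])
        with pytest.raises(ValueError):
            quantify_tracts(np.ones((8, 8)), [degenerate, square])


class TestImageSet:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ImageSet(channels={"DNA": np.ones((4, 4)), "CX43": np.ones((5, 5))})

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            ImageSet(channels={"DNA": -np.ones((4, 4))})
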