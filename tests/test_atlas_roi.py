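"""ROI front end: atlas handling, smoothing, normalization, extraction."""

import numpy as np
import pandas as pd
import pytest

from metabnet.atlas import (
    RegionAtlas,
    exclude_cerebellum,
    flag_cerebellar_by_name,
    load_aal_centroids,
    load_aal_table,
)
from metabnet.series import SubjectSeries
from metabnet.synthetic import simulate_phantom_volume
from metabnet.volumes import (
    IntensityVolume,
    build_subject_series,
    extract_roi_means,
    fwhm_to_sigma,
    normalize_by_cerebellum,
    smooth_volume,
)


class TestExcludeCerebellum:
    def test_packaged_aal_table_leaves_90_cerebral_regions(self):
        atlas = RegionAtlas(label_table=load_aal_table())
        assert atlas.n_regions == 116
        reduced = exclude_cerebellum(atlas)
        assert reduced.n_regions == 90
        assert not any(
            n.startswith(("Cerebelum", "Vermis")) for n in reduced.names
        )

    def test_name_prefix_flagging_matches_packaged_flags(self):
        table = load_aal_table()
        reflagged = flag_cerebellar_by_name(table.assign(cerebellar=0))
        pd.testing.assert_series_equal(reflagged["cerebellar"], table["cerebellar"])

    def test_no_flags_is_identity(self, toy_label_table):
        table = toy_label_table.assign(cerebellar=0)
        atlas = RegionAtlas(label_table=table)
        out = exclude_cerebellum(atlas)
        pd.testing.assert_frame_equal(out.label_table, table)

    def test_filter_preserves_order(self, toy_label_table):
        atlas = RegionAtlas(label_table=toy_label_table)
        out = exclude_cerebellum(atlas)
        assert out.codes.tolist() == [1, 2, 3]
        assert out.names == ["Frontal_L", "Frontal_R", "Occipital_L"]

    def test_all_cerebellar_is_an_error(self, toy_label_table):
        table = toy_label_table.assign(cerebellar=1)
        with pytest.raises(ValueError, match="empty parcellation"):
            exclude_cerebellum(RegionAtlas(label_table=table))

    def test_volume_codes_masked_to_background(self, toy_atlas):
        out = exclude_cerebellum(toy_atlas)
        assert set(np.unique(out.label_volume)) == {0, 1, 2, 3}


class TestSmoothing:
    def test_sigma_conversion_closed_form(self):
        # 16 mm FWHM on 2 mm voxels: sigma = 16 / (2 sqrt(2 ln 2)) / 2
        sigma = fwhm_to_sigma(16.0, (2.0, 2.0, 2.0))
        expected = 16.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / 2.0
        assert sigma == pytest.approx([expected] * 3, abs=1e-12)
        assert expected == pytest.approx(3.3973, abs=1e-4)

    def test_uniform_volume_unchanged_in_interior(self):
        vol = IntensityVolume(np.full((12, 12, 12), 3.0))
        out = smooth_volume(vol, fwhm_mm=4.0)
        # constant-zero boundary erodes edges; the deep interior stays flat
        assert out.voxels[5:7, 5:7, 5:7] == pytest.approx(3.0, rel=1e-6)

    def test_point_source_spreads_and_conserves_mass(self):
        vox = np.zeros((31, 31, 31))
        vox[15, 15, 15] = 100.0
        out = smooth_volume(IntensityVolume(vox), fwhm_mm=8.0)
        assert out.voxels.max() < 100.0
        assert out.voxels.sum() == pytest.approx(100.0, rel=0.01)

    def test_nonpositive_fwhm_rejected(self):
        vol = IntensityVolume(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            smooth_volume(vol, fwhm_mm=0.0)


class TestCerebellarNormalization:
    def test_divides_by_cerebellar_mean(self, toy_atlas):
        vox = np.ones(toy_atlas.label_volume.shape)
        vox[toy_atlas.label_volume >= 4] = 2.0
        out = normalize_by_cerebellum(IntensityVolume(vox), toy_atlas)
        assert out.voxels[toy_atlas.label_volume >= 4].mean() == pytest.approx(1.0)
        assert out.voxels[toy_atlas.label_volume == 1] == pytest.approx(0.5)

    def test_idempotent(self, toy_atlas):
        rng = np.random.default_rng(0)
        vol = IntensityVolume(rng.uniform(0.5, 2.0, toy_atlas.label_volume.shape))
        once = normalize_by_cerebellum(vol, toy_atlas)
        twice = normalize_by_cerebellum(once, toy_atlas)
        assert np.allclose(once.voxels, twice.voxels, atol=1e-10)

    def test_hand_computed_divisor(self, toy_label_table):
        # cerebellar voxels {1, 2, 3} -> reference mean 2.0
        vol3 = np.zeros((3, 1, 1))
        labels = np.zeros((3, 1, 1), dtype=int)
        labels[:, 0, 0] = [4, 4, 4]
        vol3[:, 0, 0] = [1.0, 2.0, 3.0]
        atlas = RegionAtlas(label_table=toy_label_table, label_volume=labels)
        out = normalize_by_cerebellum(IntensityVolume(vol3), atlas)
        assert out.voxels[:, 0, 0] == pytest.approx([0.5, 1.0, 1.5])

    def test_zero_reference_rejected(self, toy_atlas):
        vol = IntensityVolume(np.zeros(toy_atlas.label_volume.shape))
        with pytest.raises(ValueError, match="invalid reference region"):
            normalize_by_cerebellum(vol, toy_atlas)


class TestRoiExtraction:
    def test_constant_volume_gives_constant_means(self, toy_atlas):
        vol = IntensityVolume(np.full(toy_atlas.label_volume.shape, 5.0))
        means = extract_roi_means(vol, toy_atlas)
        assert means == pytest.approx(np.full(5, 5.0))

    def test_toy_region_arithmetic_mean(self, toy_label_table):
        labels = np.zeros((4, 1, 1), dtype=int)
        labels[:, 0, 0] = 1
        vox = np.zeros((4, 1, 1))
        vox[:, 0, 0] = [1.0, 2.0, 3.0, 4.0]
        atlas = RegionAtlas(label_table=toy_label_table.iloc[:1], label_volume=labels)
        means = extract_roi_means(IntensityVolume(vox), atlas)
        assert means[0] == pytest.approx(2.5)

    def test_dimension_mismatch_rejected(self, toy_atlas):
        with pytest.raises(ValueError, match="dimensions"):
            extract_roi_means(IntensityVolume(np.ones((2, 2, 2))), toy_atlas)

    def test_background_relabeling_is_irrelevant(self, toy_atlas):
        rng = np.random.default_rng(1)
        vox = rng.uniform(1, 2, toy_atlas.label_volume.shape)
        base = extract_roi_means(IntensityVolume(vox), toy_atlas)
        # move background voxels around: swap intensity values only there
        vox2 = vox.copy()
        bg = toy_atlas.label_volume == 0
        vox2[bg] = rng.permutation(vox[bg])
        again = extract_roi_means(IntensityVolume(vox2), toy_atlas)
        assert again == pytest.approx(base)

    def test_empty_region_flagged_nan(self, toy_label_table):
        labels = np.ones((2, 2, 2), dtype=int)  # only region 1 present
        atlas = RegionAtlas(
            label_table=toy_label_table.iloc[:2], label_volume=labels
        )
        means = extract_roi_means(IntensityVolume(np.ones((2, 2, 2))), atlas)
        assert means[0] == pytest.approx(1.0)
        assert np.isnan(means[1])


class TestBuildSubjectSeries:
    def test_identical_volumes_give_identical_rows(self, toy_atlas):
        vol = IntensityVolume(np.full(toy_atlas.label_volume.shape, 2.0))
        series = build_subject_series([vol] * 3, toy_atlas, group_label="g", normalize=False)
        assert series.n_subjects == 3
        assert np.allclose(series.values[0], series.values[1])
        assert np.allclose(series.values[1], series.values[2])

    def test_cerebellar_columns_dropped(self, toy_atlas):
        vol = IntensityVolume(np.ones(toy_atlas.label_volume.shape))
        series = build_subject_series([vol], toy_atlas, normalize=False)
        assert series.region_ids.tolist() == [1, 2, 3]

    def test_no_volumes_is_an_error(self, toy_atlas):
        with pytest.raises(ValueError, match="at least one volume"):
            build_subject_series([], toy_atlas)

    def test_mismatched_shapes_rejected(self, toy_atlas):
        v1 = IntensityVolume(np.ones(toy_atlas.label_volume.shape))
        v2 = IntensityVolume(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="inconsistent"):
            build_subject_series([v1, v2], toy_atlas)

    def test_composition_matches_per_phantom_extraction(self, toy_atlas):
        means = {1: 1.2, 2: 0.8, 3: 1.5, 4: 1.0, 5: 1.0}
        vols = [
            simulate_phantom_volume(toy_atlas, means, noise_sd=0.05, seed=s)
            for s in range(5)
        ]
        series = build_subject_series(vols, toy_atlas, normalize=False)
        expected = np.vstack([extract_roi_means(v, toy_atlas)[:3] for v in vols])
        assert np.allclose(series.values, expected)

    def test_planted_means_recovered_as_noise_vanishes(self, toy_atlas):
        means = {1: 1.2, 2: 0.8, 3: 1.5, 4: 2.0, 5: 2.0}
        errors = []
        for noise in (0.2, 0.02, 0.0):
            vol = simulate_phantom_volume(toy_atlas, means, noise_sd=noise, seed=7)
            got = extract_roi_means(vol, toy_atlas)
            errors.append(np.abs(got - np.array([1.2, 0.8, 1.5, 2.0, 2.0])).max())
        assert errors[0] > errors[2]
        assert errors[2] == pytest.approx(0.0, abs=1e-12)

    def test_normalization_uses_cerebellar_reference(self, toy_atlas):
        # cerebellar mean 2.0 -> cerebral outputs halved
        means = {1: 1.2, 2: 0.8, 3: 1.5, 4: 2.0, 5: 2.0}
        vol = simulate_phantom_volume(toy_atlas, means, noise_sd=0.0)
        series = build_subject_series([vol], toy_atlas, normalize=True)
        assert series.values[0] == pytest.approx([0.6, 0.4, 0.75])


def test_packaged_centroids_cover_the_cerebral_regions():
    atlas = exclude_cerebellum(RegionAtlas(label_table=load_aal_table()))
    coords = load_aal_centroids()
    assert set(atlas.codes) <= set(coords["code"])


def test_series_tsv_round_trip(tmp_path):
    series = SubjectSeries.from_array(
        np.arange(12, dtype=float).reshape(3, 4), group_label="g"
    )
    path = tmp_path / "g.tsv"
    series.to_tsv(path)
    back = SubjectSeries.from_tsv(path, group_label="g")
    assert np.allclose(back.values, series.values)
    assert back.region_ids.tolist() == series.region_ids.tolist()
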