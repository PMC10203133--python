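"""Evaluation metrics: region SNR, correlation, wedge occupancy, matching."""

import numpy as np
import pytest

from conftest import cc, make_phantom
from resttomo.metrics import (
    MatchResult,
    RegionPair,
    estimate_snr_db,
    ncc_map,
    offset_statistics,
    pearson_cc,
    propose_region_pairs,
    slice_average,
    template_match,
    wedge_energy_fraction,
)
from resttomo.pair_factory import extract_subvolumes
from resttomo.tomo_forward import (
    DensityVolume,
    TiltScheme,
    project,
    wbp_reconstruct,
    wedge_mask,
)


class TestSliceAverage:
    def test_single_slice_is_exact(self, phantom):
        np.testing.assert_array_equal(
            slice_average(phantom, 5, 1), phantom.values[5]
        )

    def test_identical_slices_average_to_themselves(self):
        plane = np.random.default_rng(0).normal(size=(16, 16))
        vol = DensityVolume(np.tile(plane, (16, 1, 1)), 1.0)
        np.testing.assert_allclose(slice_average(vol, 2, 10), plane, atol=1e-12)

    def test_noise_variance_reduced_tenfold(self):
        rng = np.random.default_rng(1)
        vol = DensityVolume(rng.normal(size=(10, 128, 128)), 1.0)
        avg = slice_average(vol, 0, 10)
        assert np.var(avg) == pytest.approx(0.1, rel=0.2)

    def test_out_of_range_rejected(self, phantom):
        with pytest.raises(ValueError, match="out of range"):
            slice_average(phantom, 60, 10)


class TestRegionSNR:
    def test_equal_variance_regions_give_zero_db(self):
        rng = np.random.default_rng(2)
        micro = rng.normal(size=(200, 400))
        regions = [
            RegionPair((0, 2 * i * 20, 50, 2 * i * 20 + 20),
                       (100, 2 * i * 20, 150, 2 * i * 20 + 20))
            for i in range(10)
        ]
        est = estimate_snr_db(micro, regions)
        assert abs(est.mean_db) < 0.5

    def test_exact_tenfold_variance_gives_ten_db(self):
        # deterministic pixels: background pattern of sd s, signal of sd
        # s*sqrt(10) -> exactly 10*log10(10) = 10 dB
        base = np.tile([1.0, -1.0], 200).reshape(20, 20)
        micro = np.zeros((60, 20))
        micro[0:20] = base * np.sqrt(10.0)
        micro[40:60] = base
        est = estimate_snr_db(micro, [RegionPair((0, 0, 20, 20), (40, 0, 60, 20))])
        assert est.mean_db == pytest.approx(10.0, abs=1e-9)

    def test_additive_signal_snr(self):
        # background N(0,1); signal region = independent N(0,1) + N(0,3):
        # v_s ~ 1 + 3 = 4 -> 10 log10 4 = 6.02 dB
        rng = np.random.default_rng(3)
        regions, micro = [], np.zeros((1100, 100))
        for i in range(10):
            r = 110 * i
            micro[r : r + 50] = rng.normal(0, 1, (50, 100)) + rng.normal(
                0, np.sqrt(3.0), (50, 100)
            )
            micro[r + 55 : r + 105] = rng.normal(0, 1, (50, 100))
            regions.append(RegionPair((r, 0, r + 50, 50),
                                      (r + 55, 0, r + 105, 50)))
        est = estimate_snr_db(micro, regions)
        assert est.mean_db == pytest.approx(10 * np.log10(4.0), abs=0.5)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        micro = rng.normal(size=(100, 100))
        regions = [RegionPair((0, 0, 30, 30), (60, 60, 100, 100))]
        a = estimate_snr_db(micro, regions).mean_db
        b = estimate_snr_db(micro + 42.0, regions).mean_db
        c = estimate_snr_db(micro * 3.5, regions).mean_db
        assert a == pytest.approx(b, abs=1e-9)
        assert a == pytest.approx(c, abs=1e-9)

    def test_zero_background_variance_rejected(self):
        micro = np.zeros((50, 50))
        micro[0:10, 0:10] = np.random.default_rng(0).normal(size=(10, 10))
        with pytest.raises(ValueError, match="zero variance"):
            estimate_snr_db(micro, [RegionPair((0, 0, 10, 10), (20, 20, 40, 40))])

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionPair((0, 0, 20, 20), (10, 10, 30, 30))

    def test_proposed_pairs_are_valid(self):
        rng = np.random.default_rng(5)
        micro = rng.normal(size=(256, 256))
        micro[40:80, 40:80] += rng.normal(0, 3, (40, 40))
        pairs = propose_region_pairs(micro, n=5, size=32, seed=0)
        est = estimate_snr_db(micro, pairs)
        assert est.n_regions == 5


class TestPearson:
    def test_self_correlation_is_one(self, phantom):
        assert pearson_cc(phantom, phantom) == 1.0

    def test_affine_invariance(self, phantom):
        a = phantom.values
        assert pearson_cc(a, -a) == -1.0
        assert pearson_cc(a, 2.5 * a + 7.0) == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(32, 32, 32))
        b = rng.normal(size=(32, 32, 32))
        assert abs(pearson_cc(a, b)) < 0.05

    def test_zero_variance_rejected(self, phantom):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_cc(phantom.values, np.zeros_like(phantom.values))

    def test_mask_restricts_support(self, phantom):
        mask = np.zeros(phantom.values.shape, dtype=bool)
        mask[10:30, 10:30, 10:30] = True
        other = phantom.values.copy()
        other[~mask] = np.random.default_rng(7).normal(size=int((~mask).sum()))
        assert pearson_cc(phantom.values, other, mask=mask) == pytest.approx(1.0)


class TestWedgeOccupancy:
    def test_full_coverage_gives_zero(self, phantom):
        assert wedge_energy_fraction(phantom, TiltScheme(-90, 90, 1)) == 0.0

    def test_white_noise_fraction_matches_voxel_count(self):
        rng = np.random.default_rng(8)
        vol = DensityVolume(rng.normal(size=(64, 64, 64)), 1.0)
        scheme = TiltScheme(-60, 60, 2)
        frac = wedge_energy_fraction(vol, scheme)
        expect = 1.0 - wedge_mask(64, scheme).mask.mean()
        assert frac == pytest.approx(expect, rel=0.02)

    def test_wbp_reconstruction_starves_the_wedge(self, phantom):
        scheme = TiltScheme(-60, 60, 2)
        rec = wbp_reconstruct(project(phantom, scheme))
        rng = np.random.default_rng(9)
        baseline = wedge_energy_fraction(
            DensityVolume(rng.normal(size=(64, 64, 64)), 1.0), scheme
        )
        assert wedge_energy_fraction(rec, scheme) < 0.05 * baseline


class TestTemplateMatch:
    @pytest.fixture()
    def scene(self, toy_model):
        from resttomo.structure_dynamics import model_to_density

        template = model_to_density(toy_model, 4.44, 16, resolution_A=16.0)
        tomo = np.zeros((48, 48, 48))
        tomo[12:28, 20:36, 6:22] += template.values  # centre (14, 28, 20) xyz
        return DensityVolume(tomo, 4.44), template, (14, 28, 20)

    def test_self_match_at_insertion_point(self, scene):
        tomo, template, centre = scene
        matches = template_match(tomo, template, angular_step_deg=360.0,
                                 cc_threshold=0.5)
        assert len(matches) >= 1
        assert matches[0].peak_coord_vox == centre
        assert matches[0].cc > 0.99

    def test_grid_rotation_recovered(self, scene):
        from resttomo.tomo_forward import RigidTransform, apply_transform

        tomo, template, centre = scene
        rot = apply_transform(template, RigidTransform((0.0, 90.0, 0.0)))
        scene_r = np.zeros((48, 48, 48))
        scene_r[12:28, 20:36, 6:22] += rot.values
        matches = template_match(
            DensityVolume(scene_r, 4.44), template,
            angular_step_deg=90.0, cc_threshold=0.5,
        )
        assert matches[0].euler_deg[1] == pytest.approx(90.0)
        assert matches[0].cc > 0.95

    def test_fft_ncc_agrees_with_brute_force(self):
        rng = np.random.default_rng(10)
        tomo = rng.normal(size=(16, 16, 16))
        tpl = tomo[4:12, 6:14, 2:10].copy()
        fft_map = ncc_map(tomo, tpl)
        # brute-force spatial NCC at every fully-interior placement
        t = tpl - tpl.mean()
        tn = np.sqrt((t**2).sum())
        for z in range(4, 9):
            for y in range(4, 9):
                for x in range(4, 9):
                    win = tomo[z - 4 : z + 4, y - 4 : y + 4, x - 4 : x + 4]
                    w = win - win.mean()
                    denom = np.sqrt((w**2).sum()) * tn
                    expected = (w * t).sum() / denom
                    assert fft_map[z, y, x] == pytest.approx(expected, abs=1e-6)

    def test_threshold_above_one_warns_empty(self, scene):
        tomo, template, _ = scene
        with pytest.warns(UserWarning, match="matches nothing"):
            out = template_match(tomo, template, cc_threshold=1.5)
        assert out == []


class TestOffsetStats:
    def test_exact_matches_have_zero_offsets(self):
        matches = [MatchResult((10, 20, 30), (0, 0, 0), 0.9),
                   MatchResult((40, 50, 60), (0, 0, 0), 0.8)]
        stats = offset_statistics(matches, [(10, 20, 30), (40, 50, 60)], 5)
        assert stats.n_matched == 2
        assert stats.rms_xyz == (0.0, 0.0, 0.0)

    def test_displacement_reported_exactly(self):
        matches = [MatchResult((11, 22, 33), (0, 0, 0), 0.9)]
        stats = offset_statistics(matches, [(10, 20, 30)], 10)
        assert stats.offsets[0] == (1.0, 2.0, 3.0)

    def test_far_peaks_leave_truth_unmatched(self):
        matches = [MatchResult((90, 90, 90), (0, 0, 0), 0.9)]
        stats = offset_statistics(matches, [(10, 20, 30)], 5)
        assert stats.n_matched == 0
        assert stats.unmatched_truth == [(10, 20, 30)]

    def test_duplicate_truth_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            offset_statistics([], [(1, 2, 3), (1, 2, 3)], 5)

    def test_one_to_one_greedy_by_cc(self):
        # two peaks near one truth: only the higher-cc peak claims it
        matches = [MatchResult((10, 20, 30), (0, 0, 0), 0.7),
                   MatchResult((11, 20, 30), (0, 0, 0), 0.9)]
        stats = offset_statistics(matches, [(10, 20, 30)], 5)
        assert stats.n_matched == 1
        assert stats.offsets[0] == (1.0, 0.0, 0.0)
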