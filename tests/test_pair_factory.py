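"""Training-pair construction, normalization, extraction, manifests."""

import hashlib

import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import cc, make_phantom
from resttomo.pair_factory import (
    OrientationRecord,
    build_pairs_strategy1,
    build_pairs_strategy2,
    extract_subvolumes,
    normalize_volume,
    regenerate_from_manifest,
    simulate_tomogram,
    split_pairs,
)
from resttomo.structure_dynamics import generate_toy_model, model_to_density
from resttomo.tomo_forward import (
    CTFParams,
    DensityVolume,
    RigidTransform,
    TiltScheme,
    apply_transform,
)


@pytest.fixture(scope="module")
def conformations(toy_model):
    return [toy_model]


@pytest.fixture(scope="module")
def reference(toy_model):
    return model_to_density(toy_model, 4.44, 32, resolution_A=14.0)


class TestNormalize:
    def test_zscore(self, phantom):
        out = normalize_volume(phantom)
        assert abs(out.values.mean()) < 1e-6
        assert abs(out.values.std() - 1.0) < 1e-6

    def test_idempotent(self, phantom):
        once = normalize_volume(phantom)
        twice = normalize_volume(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-6)

    def test_constant_volume_flagged_degenerate(self):
        vol = DensityVolume(np.full((8, 8, 8), 5.0), 1.0)
        out = normalize_volume(vol)
        assert out.degenerate
        np.testing.assert_array_equal(out.values, 0.0)


class TestStrategy1:
    def test_identity_record_returns_reference(self, reference):
        rec = OrientationRecord("p0", RigidTransform())
        pairs = build_pairs_strategy1([reference], reference, [rec],
                                      particle_ids=["p0"], normalized=False)
        np.testing.assert_array_equal(pairs[0].target_vol.values, reference.values)

    def test_empty_records_give_empty_pairs(self, reference):
        assert build_pairs_strategy1([], reference, []) == []

    def test_unmatched_id_reported(self, reference):
        rec = OrientationRecord("other", RigidTransform())
        with pytest.raises(KeyError, match="p0"):
            build_pairs_strategy1([reference], reference, [rec], particle_ids=["p0"])

    def test_record_order_irrelevant(self, reference):
        recs = [
            OrientationRecord("a", RigidTransform((10.0, 20.0, 30.0))),
            OrientationRecord("b", RigidTransform((40.0, 50.0, 60.0))),
        ]
        subs = [reference, reference.copy()]
        fwd = build_pairs_strategy1(subs, reference, recs, particle_ids=["a", "b"])
        rev = build_pairs_strategy1(subs, reference, recs[::-1], particle_ids=["a", "b"])
        for p, q in zip(fwd, rev):
            np.testing.assert_array_equal(p.target_vol.values, q.target_vol.values)

    def test_voxel_size_mismatch_rejected(self, reference):
        bad = DensityVolume(reference.values, voxel_A=2.0)
        rec = OrientationRecord("0", RigidTransform())
        with pytest.raises(ValueError, match="voxel size"):
            build_pairs_strategy1([bad], reference, [rec])

    def test_ground_truth_matches_noise_free_simulation(self, toy_model, reference):
        # a particle simulated with transform t must correlate with the
        # reference mapped through the same t
        t = RigidTransform((25.0, 40.0, -60.0), (1.0, -2.0, 0.5))
        particle = apply_transform(reference, t)
        rec = OrientationRecord("0", t)
        pairs = build_pairs_strategy1([particle], reference, [rec], normalized=False)
        assert cc(pairs[0].target_vol.values, particle.values) > 0.99

    def test_one_voxel_shift_rolls_output(self, reference):
        t0 = OrientationRecord("0", RigidTransform((15.0, 30.0, 45.0)))
        t1 = OrientationRecord("0", RigidTransform((15.0, 30.0, 45.0), (1.0, 0.0, 0.0)))
        a = build_pairs_strategy1([reference], reference, [t0], normalized=False)[0]
        b = build_pairs_strategy1([reference], reference, [t1], normalized=False)[0]
        rolled = np.roll(a.target_vol.values, 1, axis=2)
        rolled[:, :, 0] = 0
        inner = (slice(2, -2),) * 3
        np.testing.assert_allclose(
            b.target_vol.values[inner], rolled[inner], atol=1e-3 * np.abs(rolled).max()
        )


class TestStrategy2:
    def test_high_snr_full_coverage_nearly_perfect(self, conformations):
        pairs, _ = build_pairs_strategy2(
            conformations, box=32, voxel_A=4.44,
            scheme=TiltScheme(-90, 89, 3), ctf=None, snr=1e9,
            n_per_conf=3, seed=0,
        )
        ccs = [cc(p.input_vol.values, p.target_vol.values) for p in pairs]
        assert np.mean(ccs) > 0.9

    def test_degradation_monotonic_in_noise_and_coverage(self, conformations):
        configs = [
            (1e9, TiltScheme(-90, 89, 3)),
            (1.0, TiltScheme(-60, 60, 3)),
            (0.1, TiltScheme(-40, 40, 3)),
        ]
        medians = []
        for snr, scheme in configs:
            pairs, _ = build_pairs_strategy2(
                conformations, box=32, voxel_A=4.44, scheme=scheme,
                ctf=None, snr=snr, n_per_conf=8, seed=1,
            )
            medians.append(np.median([
                cc(p.input_vol.values, p.target_vol.values) for p in pairs
            ]))
        assert medians[0] > medians[1] > medians[2]

    def test_quality_correlates_with_conditions(self, conformations):
        # Spearman over per-pair CC: decreasing in noise, increasing in coverage
        snrs = [10.0, 1.0, 0.3, 0.1]
        per_snr = []
        for s in snrs:
            pairs, _ = build_pairs_strategy2(
                conformations, box=32, voxel_A=4.44,
                scheme=TiltScheme(-60, 60, 4), ctf=None, snr=s,
                n_per_conf=6, seed=2,
            )
            per_snr.extend(
                (s, cc(p.input_vol.values, p.target_vol.values)) for p in pairs
            )
        rho, p = spearmanr([a for a, _ in per_snr], [b for _, b in per_snr])
        assert rho > 0 and p < 0.01

    def test_manifest_regenerates_bit_identical(self, conformations):
        pairs, manifest = build_pairs_strategy2(
            conformations, box=24, voxel_A=4.44,
            scheme=TiltScheme(-50, 50, 10), ctf=CTFParams(), snr=0.5,
            n_per_conf=3, seed=3,
        )
        again = regenerate_from_manifest(manifest, conformations)
        for p, q in zip(pairs, again):
            np.testing.assert_array_equal(p.input_vol.values, q.input_vol.values)
            np.testing.assert_array_equal(p.target_vol.values, q.target_vol.values)

    def test_manifest_hash_stable(self, conformations):
        _, m1 = build_pairs_strategy2(
            conformations, box=24, voxel_A=4.44,
            scheme=TiltScheme(-50, 50, 10), ctf=None, snr=0.5, n_per_conf=2, seed=4,
        )
        _, m2 = build_pairs_strategy2(
            conformations, box=24, voxel_A=4.44,
            scheme=TiltScheme(-50, 50, 10), ctf=None, snr=0.5, n_per_conf=2, seed=4,
        )
        h = lambda m: hashlib.sha256(m.to_json().encode()).hexdigest()
        assert h(m1) == h(m2)

    def test_normalization_flag(self, conformations):
        pairs, _ = build_pairs_strategy2(
            conformations, box=24, voxel_A=4.44,
            scheme=TiltScheme(-50, 50, 10), ctf=None, snr=1.0,
            n_per_conf=1, seed=5, normalized=True,
        )
        for p in pairs:
            assert abs(p.input_vol.values.mean()) < 1e-6
            assert abs(p.input_vol.values.std() - 1) < 1e-6


class TestSplit:
    def test_split_fractions_and_determinism(self, conformations):
        pairs, _ = build_pairs_strategy2(
            conformations, box=24, voxel_A=4.44,
            scheme=TiltScheme(-50, 50, 25), ctf=None, snr=1.0,
            n_per_conf=10, seed=6,
        )
        tr1, va1 = split_pairs(pairs, validation_fraction=0.2, seed=0)
        tr2, va2 = split_pairs(pairs, validation_fraction=0.2, seed=0)
        assert len(va1) == 2 and len(tr1) == 8
        assert [id(p) for p in tr1] == [id(p) for p in tr2]


class TestExtraction:
    def test_full_volume_crop_is_identity(self, phantom):
        c = phantom.box // 2
        crops = extract_subvolumes(phantom, [(c, c, c)], phantom.box)
        np.testing.assert_array_equal(crops[0].values, phantom.values)

    def test_corner_crop_zero_padded(self, phantom):
        crops = extract_subvolumes(phantom, [(0, 0, 0)], 16, pad_policy="zero")
        v = crops[0].values
        # the crop spans [-8, 8) on each axis: the out-of-volume halves are 0
        assert np.all(v[:8, :, :] == 0.0)
        assert np.all(v[:, :8, :] == 0.0)
        assert np.all(v[:, :, :8] == 0.0)
        np.testing.assert_array_equal(v[8:, 8:, 8:], phantom.values[:8, :8, :8])

    def test_reject_policy_names_centre(self, phantom):
        with pytest.raises(ValueError, match=r"\(0, 0, 0\)"):
            extract_subvolumes(phantom, [(0, 0, 0)], 16, pad_policy="reject")

    def test_crop_paste_round_trip(self, phantom):
        box = 16
        centre = (20, 30, 25)
        crop = extract_subvolumes(phantom, [centre], box)[0]
        cx, cy, cz = centre
        h = box // 2
        region = phantom.values[cz - h : cz + h, cy - h : cy + h, cx - h : cx + h]
        np.testing.assert_array_equal(crop.values, region)

    def test_odd_box_rejected(self, phantom):
        with pytest.raises(ValueError, match="even"):
            extract_subvolumes(phantom, [(8, 8, 8)], 15)


class TestSimulateTomogram:
    def test_particles_separated_and_inside(self, toy_model):
        degraded, gt, centers, transforms = simulate_tomogram(
            [toy_model], n_particles=4, box=96, voxel_A=4.44,
            scheme=TiltScheme(-60, 60, 6), ctf=None, snr=1.0, seed=0,
            particle_box=32,
        )
        assert len(centers) == 4 and len(transforms) == 4
        arr = np.asarray(centers)
        assert arr.min() >= 18 and arr.max() < 96 - 18
        for i in range(4):
            for j in range(i + 1, 4):
                assert np.linalg.norm(arr[i] - arr[j]) >= 32 * 1.25

    def test_ground_truth_contains_particles_at_centres(self, toy_model):
        _, gt, centers, _ = simulate_tomogram(
            [toy_model], n_particles=3, box=96, voxel_A=4.44,
            scheme=TiltScheme(-60, 60, 6), ctf=None, snr=1e9, seed=1,
            particle_box=32,
        )
        for cx, cy, cz in centers:
            ball = gt.values[cz - 8 : cz + 8, cy - 8 : cy + 8, cx - 8 : cx + 8]
            assert ball.sum() > 0.2 * gt.values.sum() / 3
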