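"""Contracts of the three anonymization operators and their composition."""

import warnings

import numpy as np
import pytest
from scipy import ndimage, stats

from mrideface.defacer import (
    AirNoiseRange,
    DetectionRegions,
    bounding_box,
    deface,
    deface_ears,
    deface_eyes,
    deface_nose,
    doubled_box,
    estimate_air_noise,
    eye_shell,
    nose_zone,
    periocular_box,
)
from mrideface.detector import separate_instances
from mrideface.io_formats import Volume
from mrideface.phantom import PhantomSpec, make_head_phantom


@pytest.fixture(scope="module")
def phantom_with_regions():
    vol, labels = make_head_phantom(PhantomSpec(seed=3))
    return vol, labels, separate_instances(labels)


class TestAirNoise:
    def test_estimate_tracks_constructed_background(self, phantom_with_regions):
        vol, _, _ = phantom_with_regions
        sigma = PhantomSpec().air_noise_sigma
        air = estimate_air_noise(vol)
        assert air.lo == 0.0
        assert 1.0 * sigma <= air.hi <= 4.0 * sigma

    def test_noise_free_volume_gives_degenerate_range(self):
        vol, _ = make_head_phantom(
            PhantomSpec(seed=0, air_noise_sigma=0.0))
        air = estimate_air_noise(vol)
        assert (air.lo, air.hi) == (0.0, 0.0)

    def test_invariant_to_tissue_intensity_scale(self, phantom_with_regions):
        vol, labels, _ = phantom_with_regions
        scaled = vol.with_data(
            np.where(labels.data == 0, vol.data, vol.data * 10))
        a = estimate_air_noise(vol)
        b = estimate_air_noise(scaled)
        assert b.hi == pytest.approx(a.hi, rel=0.05)

    def test_uniform_bright_volume_falls_back_with_warning(self):
        vol = Volume(np.full((32, 32, 32), 500.0), (1, 1, 1), np.eye(4))
        with pytest.warns(UserWarning, match="no air"):
            air = estimate_air_noise(vol)
        assert air.hi == pytest.approx(5.0)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            AirNoiseRange(2.0, 1.0)


class TestNose:
    def test_doubled_box_matches_brute_force_enumeration(self):
        vol = Volume(np.random.default_rng(0).random((64, 64, 64)),
                     (1, 1, 1), np.eye(4))
        mask = np.zeros((64, 64, 64), dtype=bool)
        mask[10:20, 10:20, 10:20] = True
        out = deface_nose(vol, mask)
        # oracle: enumerate the doubled box voxel by voxel
        expected = np.zeros_like(mask)
        for i in range(64):
            for j in range(64):
                for k in range(64):
                    if 5 <= i < 25 and 5 <= j < 25 and 5 <= k < 25:
                        expected[i, j, k] = True
        assert int(expected.sum()) == 8000
        assert (out.data[expected] == 0).all()
        np.testing.assert_array_equal(out.data[~expected], vol.data[~expected])

    def test_edge_mask_clips_without_out_of_bounds(self):
        vol = Volume(np.ones((32, 32, 32)), (1, 1, 1), np.eye(4))
        mask = np.zeros((32, 32, 32), dtype=bool)
        mask[0:4, 28:32, 14:18] = True
        out = deface_nose(vol, mask)
        box = doubled_box(bounding_box(mask), (32, 32, 32))
        assert box[0][0] == 0 and box[1][1] == 32
        zone = nose_zone(vol, mask)
        assert (out.data[zone] == 0).all()
        np.testing.assert_array_equal(out.data[~zone], vol.data[~zone])

    def test_empty_mask_is_noop_with_warning(self, phantom_with_regions):
        vol, _, _ = phantom_with_regions
        with pytest.warns(UserWarning, match="empty"):
            out = deface_nose(vol, np.zeros(vol.data.shape, dtype=bool))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_phantom_nose_box_zeroed_outside_untouched(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        out = deface_nose(vol, regions.nose)
        zone = nose_zone(vol, regions.nose)
        assert (out.data[zone] == 0).all()
        np.testing.assert_array_equal(out.data[~zone], vol.data[~zone])


class TestEyes:
    def test_shell_is_single_valued(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        shell, fill = eye_shell(vol, regions.eye_left, regions.eye_right)
        out = deface_eyes(vol, regions.eye_left, regions.eye_right)
        assert shell.sum() > 0
        values = np.unique(out.data[shell])
        assert values.size == 1 and values[0] == fill

    def test_voxels_deeper_than_shell_untouched(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        out = deface_eyes(vol, regions.eye_left, regions.eye_right)
        shell, _ = eye_shell(vol, regions.eye_left, regions.eye_right)
        np.testing.assert_array_equal(out.data[~shell], vol.data[~shell])
        # explicitly: >2 voxels behind the surface, per column, is unchanged
        changed = out.data != vol.data
        for x, z in {(x, z) for x, _, z in np.argwhere(changed)}:
            ys = np.nonzero(changed[x, :, z])[0]
            assert ys.max() - ys.min() <= 4  # never thicker than the +-2 shell

    def test_flat_slab_shell_is_exact(self):
        """Known surface plane -> modified set is exactly the +-2 slab."""
        rng = np.random.default_rng(0)
        k = 30
        data = np.where(np.arange(48)[None, :, None] <= k,
                        100.0 + rng.normal(0, 2, (48, 48, 48)), 0.0)
        data += np.abs(rng.normal(0, 1.0, (48, 48, 48))) * (data == 0)
        vol = Volume(np.clip(data, 0, None), (1, 1, 1), np.eye(4))
        eye = np.zeros((48, 48, 48), dtype=bool)
        eye[20:26, 24:29, 20:26] = True
        out = deface_eyes(vol, eye, np.zeros_like(eye))
        box = periocular_box(eye, (48, 48, 48))
        changed = out.data != vol.data
        expected = np.zeros_like(changed)
        expected[box[0][0]:box[0][1], k - 2:k + 3, box[2][0]:box[2][1]] = True
        np.testing.assert_array_equal(changed, expected)

    def test_reapplication_is_a_fixed_point(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        once = deface_eyes(vol, regions.eye_left, regions.eye_right)
        twice = deface_eyes(once, regions.eye_left, regions.eye_right)
        np.testing.assert_array_equal(twice.data, once.data)

    def test_both_empty_masks_warn_and_preserve(self, phantom_with_regions):
        vol, _, _ = phantom_with_regions
        empty = np.zeros(vol.data.shape, dtype=bool)
        with pytest.warns(UserWarning, match="empty"):
            out = deface_eyes(vol, empty, empty)
        np.testing.assert_array_equal(out.data, vol.data)


class TestEars:
    def test_replacements_within_air_range_and_uniform(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        air = estimate_air_noise(vol)
        out = deface_ears(vol, regions.ear_left, regions.ear_right, air, seed=1)
        mask = regions.ear_left | regions.ear_right
        values = out.data[mask]
        assert values.size >= 1000
        assert ((values >= air.lo) & (values <= air.hi)).all()
        p = stats.kstest(values, stats.uniform(air.lo, air.hi - air.lo).cdf).pvalue
        assert p >= 0.01
        np.testing.assert_array_equal(out.data[~mask], vol.data[~mask])

    def test_deterministic_given_seed(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        a = deface_ears(vol, regions.ear_left, regions.ear_right, seed=7)
        b = deface_ears(vol, regions.ear_left, regions.ear_right, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_degenerate_air_range_sets_constant(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        out = deface_ears(vol, regions.ear_left, regions.ear_right,
                          AirNoiseRange(3.0, 3.0), seed=0)
        mask = regions.ear_left | regions.ear_right
        assert (out.data[mask] == 3.0).all()


class TestComposite:
    def test_all_toggles_off_is_identity(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        out, report = deface(vol, regions,
                             {"nose": False, "eyes": False, "ears": False})
        np.testing.assert_array_equal(out.data, vol.data)
        assert report["total_modified_voxels"] == 0

    def test_phantom_processes_five_features_with_nonzero_counts(
            self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        out, report = deface(vol, regions, seed=2)
        assert regions.n_present() == 5
        assert all(f["modified_voxels"] > 0 for f in report["features"].values())

    def test_modified_total_equals_union_of_operator_zones(
            self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        out, report = deface(vol, regions, seed=2)
        union = sum(f["modified_voxels"] for f in report["features"].values())
        assert report["total_modified_voxels"] == union

    def test_unclaimed_voxels_bit_identical(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        out, report = deface(vol, regions, seed=2)
        changed = int((out.data != vol.data).sum())
        assert changed <= report["total_modified_voxels"]

    def test_deterministic_given_seed(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        a, _ = deface(vol, regions, seed=11)
        b, _ = deface(vol, regions, seed=11)
        np.testing.assert_array_equal(a.data, b.data)

    def test_double_application_changes_only_ear_voxels(
            self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        once, _ = deface(vol, regions, seed=4)
        twice, _ = deface(once, regions, seed=4)
        diff = twice.data != once.data
        ears = regions.mask("ear_left") | regions.mask("ear_right")
        assert not (diff & ~ears).any()

    def test_brain_interior_is_never_modified(self, phantom_with_regions):
        """Voxels > 3 under the head surface, outside the nose box, survive."""
        vol, labels, regions = phantom_with_regions
        out, _ = deface(vol, regions, seed=2)
        spec = PhantomSpec()
        axes = [(np.arange(n) - (n - 1) / 2.0) * s
                for n, s in zip(spec.grid_size, spec.spacing)]
        x, y, z = np.meshgrid(*axes, indexing="ij")
        rx, ry, rz = spec.head_radii
        head = (x / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2 <= 1.0
        interior = ndimage.binary_erosion(head, iterations=4)
        interior &= ~nose_zone(vol, regions.nose)
        np.testing.assert_array_equal(out.data[interior], vol.data[interior])

    def test_lattice_spacing_affine_preserved(self, phantom_with_regions):
        vol, _, regions = phantom_with_regions
        out, _ = deface(vol, regions, seed=0)
        assert out.data.shape == vol.data.shape
        assert out.spacing == vol.spacing
        np.testing.assert_array_equal(out.affine, vol.affine)

    def test_overlapping_region_masks_rejected(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[0, 0, 0] = True
        with pytest.raises(ValueError, match="disjoint"):
            DetectionRegions(m, m, np.zeros_like(m), np.zeros_like(m),
                             np.zeros_like(m))
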