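"""Phantom geometry against supersampled-integration and
connected-component oracles, plus determinism and NIfTI round-trips."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from snet3d.phantoms import (GeometryError, IntensityModel, ShellSpec,
                             TubeTreeSpec, load_manifest, load_nifti,
                             make_dataset, make_shell_phantom,
                             make_tube_phantom, shell_band_indicator)

CLEAN = IntensityModel(fg_mean=1.0, bg_mean=0.0, noise_sd=0.0, bias_amplitude=0.0)


def supersampled_volume(indicator, shape, factor=3):
    """Oracle: fraction-weighted voxel volume of an indicator function,
    integrated on a factor^3-supersampled grid."""
    axes = [np.arange(n * factor) / factor - 0.5 + 0.5 / factor for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    return indicator(pts).sum() / factor ** 3


class TestShell:
    spec = ShellSpec(center=(24, 24, 24), semi_axes=(10.0, 10.0, 10.0),
                     wall_thickness=2.0)

    def test_deterministic_under_seed(self):
        a = make_shell_phantom(self.spec, (48,) * 3, IntensityModel(), 7)
        b = make_shell_phantom(self.spec, (48,) * 3, IntensityModel(), 7)
        assert np.array_equal(a.volume, b.volume)
        assert np.array_equal(a.mask, b.mask)
        c = make_shell_phantom(self.spec, (48,) * 3, IntensityModel(), 8)
        assert not np.array_equal(a.volume, c.volume)

    def test_degenerate_intensity_model_reproduces_mask(self):
        case = make_shell_phantom(self.spec, (48,) * 3, CLEAN, 0)
        assert np.array_equal(case.volume, case.mask.astype(np.float32))

    def test_voxel_count_matches_supersampled_band_integral(self):
        case = make_shell_phantom(self.spec, (48,) * 3, CLEAN, 0)
        oracle = supersampled_volume(
            lambda pts: shell_band_indicator(self.spec, pts), (48,) * 3)
        assert abs(case.mask.sum() - oracle) / oracle < 0.15
        # and the analytic sphere-band volume agrees too
        assert abs(case.mask.sum() - 4 * np.pi * 100 * 2) / (800 * np.pi) < 0.15

    def test_oriented_anisotropic_shell_within_band_integral(self):
        spec = ShellSpec(center=(24, 24, 24), semi_axes=(14.0, 9.0, 11.0),
                         wall_thickness=3.0, orientation=(0.4, 1.0, 2.2))
        case = make_shell_phantom(spec, (48,) * 3, CLEAN, 3)
        oracle = supersampled_volume(
            lambda pts: shell_band_indicator(spec, pts), (48,) * 3)
        assert abs(case.mask.sum() - oracle) / oracle < 0.15

    def test_wall_thickness_recovered_by_distance_transform(self):
        for t in (2.0, 3.0, 4.0):
            spec = ShellSpec(center=(32, 32, 32), semi_axes=(12.0, 12.0, 12.0),
                             wall_thickness=t)
            case = make_shell_phantom(spec, (64,) * 3, CLEAN, 0)
            inradius = ndimage.distance_transform_edt(case.mask).max()
            assert abs(2 * inradius - t) <= 1.0

    def test_out_of_bounds_shell_rejected(self):
        with pytest.raises(GeometryError, match="exceeds"):
            make_shell_phantom(self.spec, (24,) * 3, CLEAN, 0)

    def test_threshold_recovers_mask_without_noise(self):
        model = IntensityModel(fg_mean=2.0, bg_mean=-1.0, noise_sd=0.0,
                               bias_amplitude=0.0)
        case = make_shell_phantom(self.spec, (48,) * 3, model, 0)
        recovered = (case.volume > 0.5).astype(np.uint8)  # (fg+bg)/2
        assert np.array_equal(recovered, case.mask)


class TestTubeTree:
    def test_single_segment_voxel_count_matches_capsule_oracle(self):
        spec = TubeTreeSpec(root=(8, 24, 24), root_radius=3.0, depth=0,
                            segment_length=30.0, direction=(1.0, 0.3, 0.1))
        case = make_tube_phantom(spec, (48,) * 3, CLEAN, 5)
        d = np.asarray(spec.direction) / np.linalg.norm(spec.direction)
        a = np.asarray(spec.root)
        b = a + d * spec.segment_length

        def capsule(pts):
            ab = b - a
            t = np.clip(((pts - a) @ ab) / (ab @ ab), 0, 1)
            closest = a + t[..., None] * ab
            return np.linalg.norm(pts - closest, axis=-1) <= spec.root_radius

        oracle = supersampled_volume(capsule, (48,) * 3)
        assert abs(case.mask.sum() - oracle) / oracle < 0.15

    def test_aneurysm_sac_adds_expected_volume(self):
        base = TubeTreeSpec(root=(10, 32, 32), root_radius=2.5, depth=1,
                            segment_length=14.0, direction=(1.0, 0.0, 0.0))
        sac = TubeTreeSpec(**{**base.__dict__, "aneurysm": (1, 5.0)})
        m0 = make_tube_phantom(base, (64,) * 3, CLEAN, 4).mask.astype(bool)
        m1 = make_tube_phantom(sac, (64,) * 3, CLEAN, 4).mask.astype(bool)
        added = int(m1.sum()) - int(m0.sum())
        # oracle: voxelized sphere at node 1 (end of the root segment),
        # minus its overlap with the sac-free tree
        node1 = np.asarray(base.root) + np.array([14.0, 0, 0])
        zz, yy, xx = np.meshgrid(*[np.arange(64.0)] * 3, indexing="ij")
        sphere = (np.sqrt((zz - node1[0]) ** 2 + (yy - node1[1]) ** 2
                          + (xx - node1[2]) ** 2) <= 5.0)
        expected = int((sphere & ~m0).sum())
        assert expected > 0.8 * (4 / 3 * np.pi * 125 - m0.sum())  # sanity
        assert abs(added - expected) / expected < 0.15

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_single_connected_component(self, seed):
        rng = np.random.default_rng(seed)
        spec = TubeTreeSpec(
            root=(8, 32, 32),
            root_radius=float(rng.uniform(1.5, 4.0)),
            depth=int(rng.integers(1, 4)),
            radius_decay=float(rng.uniform(0.55, 0.8)),
            segment_length=float(rng.uniform(8, 15)),
            direction=(1.0, 0.0, 0.0),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            case = make_tube_phantom(spec, (64,) * 3, CLEAN, seed)
        _, n = ndimage.label(case.mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_radius_below_half_voxel_stops_branching(self):
        deep = TubeTreeSpec(root=(8, 32, 32), root_radius=1.0, depth=6,
                            radius_decay=0.5, segment_length=6.0,
                            direction=(1.0, 0.0, 0.0))
        shallow = TubeTreeSpec(**{**deep.__dict__, "depth": 1})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = make_tube_phantom(deep, (64,) * 3, CLEAN, 0).mask
            b = make_tube_phantom(shallow, (64,) * 3, CLEAN, 0).mask
        # generations beyond radius 0.5 are never drawn
        assert np.array_equal(a, b)

    def test_clipping_warns(self):
        spec = TubeTreeSpec(root=(28, 16, 16), root_radius=3.0, depth=0,
                            segment_length=40.0, direction=(1.0, 0.0, 0.0))
        with pytest.warns(UserWarning, match="clipped"):
            make_tube_phantom(spec, (32,) * 3, CLEAN, 0)


class TestDataset:
    def test_write_load_roundtrip_and_determinism(self, tmp_path):
        out = tmp_path / "ds"
        m1 = make_dataset(3, "shell", None, (48,) * 3, 42, out)
        files = sorted(p.name for p in out.glob("*.nii.gz"))
        assert len(files) == 6 and (out / "manifest.json").exists()
        # manifest round-trip: specs survive JSON serialization
        loaded = load_manifest(out)
        assert all(isinstance(c["spec"], ShellSpec) for c in loaded["cases"])
        # masks on disk equal regenerated in-memory masks
        for rec in loaded["cases"]:
            mask, spacing = load_nifti(out / rec["mask"])
            case = make_shell_phantom(rec["spec"], (48,) * 3,
                                      IntensityModel(), rec["seed"])
            assert spacing == (1.0, 1.0, 1.0)
            assert np.array_equal(mask, case.mask)
        # identical re-run overwrites with identical bytes-level content
        m2 = make_dataset(3, "shell", None, (48,) * 3, 42, out)
        assert m1 == m2

    def test_bad_inputs_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="n_cases"):
            make_dataset(0, "shell", None, (48,) * 3, 0, tmp_path)
        with pytest.raises(ValueError, match="geometry"):
            make_dataset(1, "cube", None, (48,) * 3, 0, tmp_path)
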