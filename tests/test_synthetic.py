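"""Generator contracts: determinism, bead statistics, warping, cell scenes."""

import numpy as np
import pytest

from stemmech.core import VoxelVolume
from stemmech.fields import closed_form_traction, evaluate_displacement
from stemmech.synthetic import (
    CellSceneConfig,
    SceneConfig,
    deform_volume,
    generate_bead_volume,
    generate_cell_image,
    make_scene_pair,
)


class TestBeadVolume:
    def test_same_seed_bit_identical(self, small_config):
        a, _ = generate_bead_volume(small_config)
        b, _ = generate_bead_volume(small_config)
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self, small_config):
        from dataclasses import replace

        a, _ = generate_bead_volume(small_config)
        b, _ = generate_bead_volume(replace(small_config, rng_seed=99))
        assert not np.array_equal(a.data, b.data)

    def test_single_bead_renders_at_its_center(self):
        cfg = SceneConfig(
            rng_seed=0,
            volume_shape=(32, 32, 32),
            voxel_size=(0.4, 0.2, 0.2),
            noise_sd=0.0,
            bead_positions_um=np.array([[6.4, 3.2, 3.2]]),  # voxel (16, 16, 16)
        )
        vol, _ = generate_bead_volume(cfg)
        assert np.unravel_index(np.argmax(vol.data), vol.shape) == (16, 16, 16)

    def test_poisson_bead_count_matches_density(self):
        # 0.02 beads/μm³ over a 20 × 40 × 40 μm domain: mean count 640
        cfg = SceneConfig(
            rng_seed=123,
            volume_shape=(50, 200, 200),
            voxel_size=(0.4, 0.2, 0.2),
            bead_density=0.02,
        )
        _, truth = generate_bead_volume(cfg)
        n = len(truth.bead_positions_um)
        assert abs(n - 640) < 4 * np.sqrt(640)

    def test_too_few_beads_rejected(self):
        cfg = SceneConfig(rng_seed=0, volume_shape=(16, 16, 16), bead_density=1e-6)
        with pytest.raises(ValueError, match="beads"):
            generate_bead_volume(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(volume_shape=(8, 128, 128))
        with pytest.raises(ValueError):
            SceneConfig(bead_sigma_um=-1.0)
        with pytest.raises(ValueError):
            SceneConfig(bead_density=0.0)


class TestDeformVolume:
    def test_zero_field_is_identity(self, small_volume):
        out = deform_volume(small_volume, {"name": "constant", "shift_um": (0, 0, 0)})
        assert np.allclose(out.data, small_volume.data, atol=1e-9)

    def test_integer_voxel_shift_equals_roll_in_interior(self, small_volume):
        dz, dy, dx = small_volume.voxel_size
        out = deform_volume(small_volume, {"name": "constant", "shift_um": (2 * dx, 0, 0)})
        rolled = np.roll(small_volume.data, 2, axis=2)
        interior = (slice(None), slice(None), slice(4, -4))
        assert np.allclose(out.data[interior], rolled[interior], atol=1e-6)

    def test_fractional_shift_matches_fourier_shift_theorem(self):
        # a 0.3-voxel x-shift multiplies the spectrum by the analytic phase ramp
        rng = np.random.default_rng(5)
        base = rng.normal(size=(24, 24, 24))
        from scipy import ndimage

        # periodic band-limited field: the Fourier-shift oracle is exact for it
        smooth = ndimage.gaussian_filter(base, 2.0, mode="wrap")
        vol = VoxelVolume(smooth, (0.4, 0.2, 0.2))
        shift_vox = 0.3
        out = deform_volume(vol, {"name": "constant", "shift_um": (shift_vox * 0.2, 0, 0)})
        k = np.fft.fftfreq(24)
        expected = np.real(
            np.fft.ifftn(np.fft.fftn(smooth) * np.exp(-2j * np.pi * k * shift_vox)[None, None, :])
        )
        interior = (slice(4, -4),) * 3
        err = np.abs(out.data[interior] - expected[interior]).max()
        assert err < 0.01 * np.abs(smooth).max()

    def test_excessive_displacement_rejected(self, small_volume):
        with pytest.raises(ValueError, match="quarter"):
            deform_volume(small_volume, {"name": "constant", "shift_um": (50.0, 0, 0)})

    def test_nonfinite_field_rejected(self, small_volume):
        with pytest.raises(ValueError, match="finite"):
            deform_volume(small_volume, {"name": "constant", "shift_um": (np.nan, 0, 0)})


class TestClosedFormTraction:
    def test_simple_shear_values(self, gel14):
        t = closed_form_traction({"name": "shear", "gamma": 0.01}, gel14, np.arange(4.0), np.arange(4.0))
        assert np.allclose(t.tx, 14000 * 0.01 / (2 * 1.5))  # 46.67 Pa
        assert np.allclose(t.txy, 46.666, atol=1e-2)
        assert np.allclose(t.tzz, 0.0)

    def test_uniaxial_values(self, gel14):
        t = closed_form_traction({"name": "uniaxial", "beta": 0.01}, gel14, np.arange(4.0), np.arange(4.0))
        assert np.allclose(t.tzz, 14000 * 0.01 / 1.5)  # 93.33 Pa
        assert np.allclose(t.txy, 0.0)

    @pytest.mark.parametrize(
        "spec",
        [
            {"name": "constant", "shift_um": (1.0, -2.0, 0.5)},
            {"name": "rotation", "omega_rad": 0.01, "center_um": (5.0, 5.0)},
        ],
    )
    def test_rigid_motion_gives_zero_traction(self, spec, gel14):
        t = closed_form_traction(spec, gel14, np.arange(5.0), np.arange(5.0))
        assert np.allclose(t.tx, 0) and np.allclose(t.ty, 0) and np.allclose(t.tz, 0)

    @pytest.mark.parametrize("name,param,key", [("shear", "gamma", "txy"), ("uniaxial", "beta", "tzz")])
    def test_amplitude_linearity(self, name, param, key, gel14):
        y = x = np.arange(3.0)
        t1 = closed_form_traction({"name": name, param: 0.004}, gel14, y, x)
        t3 = closed_form_traction({"name": name, param: 0.012}, gel14, y, x)
        assert np.allclose(getattr(t3, key), 3.0 * getattr(t1, key))

    def test_unknown_spec_rejected(self, gel14):
        with pytest.raises(ValueError, match="unknown"):
            closed_form_traction({"name": "vortex"}, gel14, np.arange(3.0), np.arange(3.0))


class TestScenePair:
    def test_acquisition_noise_is_independent(self, small_config):
        ref, deformed, _ = make_scene_pair(small_config, {"name": "constant", "shift_um": (0, 0, 0)})
        # zero displacement: any difference between the volumes is pure noise,
        # whose variance should be the sum of two independent realizations
        resid = (ref.data - deformed.data).std()
        assert resid == pytest.approx(np.sqrt(2) * small_config.noise_sd, rel=0.1)

    def test_pair_is_deterministic(self, small_config):
        spec = {"name": "shear", "gamma": 0.01}
        r1, d1, _ = make_scene_pair(small_config, spec)
        r2, d2, _ = make_scene_pair(small_config, spec)
        assert np.array_equal(r1.data, r2.data) and np.array_equal(d1.data, d2.data)


class TestCellScene:
    def test_fa_count_matches_ground_truth(self, cell_scene):
        cfg, channels, truth = cell_scene
        assert truth.n_fa_true == cfg.n_fa_puncta == len(truth.fa_centers_px)

    def test_fa_channel_has_exact_component_count(self):
        from skimage import measure

        cfg = CellSceneConfig(rng_seed=3, n_fa_puncta=12, noise_sd=0.0)
        channels, truth = generate_cell_image(cfg)
        bright = channels["fa"] > (cfg.background_level + 20.0 + 75.0)  # above half punctum height
        assert measure.label(bright, connectivity=2).max() == 12

    def test_puncta_separation_invariant(self, cell_scene):
        cfg, _, truth = cell_scene
        d = truth.fa_centers_px
        diameter_px = 2 * np.sqrt(cfg.fa_area_um2 / np.pi) / cfg.pixel_size_um
        for i in range(len(d)):
            for j in range(i + 1, len(d)):
                assert np.hypot(*(d[i] - d[j])) >= 3 * diameter_px - 1e-9

    def test_unit_ratio_means_equal_nuc_cyto_sums(self):
        cfg = CellSceneConfig(rng_seed=1, yap_nc_ratio_true=1.0, noise_sd=0.0)
        channels, truth = generate_cell_image(cfg)
        yap = channels["yap"]
        bg = cfg.background_level
        nuc_sum = (yap[truth.nuc_mask] - bg).sum()
        cyto_sum = (yap[truth.cell_mask & ~truth.nuc_mask] - bg).sum()
        assert nuc_sum == pytest.approx(cyto_sum, rel=1e-9)

    def test_masks_are_nested_and_inside_domain(self, cell_scene):
        _, _, truth = cell_scene
        assert truth.nuc_mask[truth.cell_mask].sum() == truth.nuc_mask.sum()

    def test_impossible_packing_raises(self):
        cfg = CellSceneConfig(rng_seed=0, n_fa_puncta=500)
        with pytest.raises(ValueError, match="puncta"):
            generate_cell_image(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CellSceneConfig(nuc_radius_um=20.0, cell_radius_um=15.0)
        with pytest.raises(ValueError):
            CellSceneConfig(yap_nc_ratio_true=0.0)
        with pytest.raises(ValueError):
            CellSceneConfig(channels=("actin", "tubulin"))
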