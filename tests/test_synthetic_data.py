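"""Phantom generators: determinism, forward-model linearity, expansion."""

from dataclasses import replace

import numpy as np
import pytest

from vista import resolution as res
from vista import synthetic_data as sd
from vista.synthetic_data import StructureKind


class TestBeadStacks:
    def test_identical_seeds_bitwise_identical(self):
        a, _ = sd.generate_bead_stack(n_beads=5, seed=3)
        b, _ = sd.generate_bead_stack(n_beads=5, seed=3)
        assert np.array_equal(a.voxels, b.voxels)
        c, _ = sd.generate_bead_stack(n_beads=5, seed=4)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_point_emitter_profile_is_psf(self):
        """delta ⊗ Gaussian = Gaussian: fitted FWHM equals the PSF FWHM."""
        vol, truth = sd.generate_bead_stack(diameter=0.0, psf_fwhm=320.0,
                                            pixel_size=80.0, n_beads=5, seed=2)
        rep = res.calibrate_from_stack(vol, bead_diameter=0.0)
        assert rep.measured_fwhm == pytest.approx(320.0, abs=1.0)

    def test_finite_bead_profile_matches_forward_model(self):
        """A 100 nm bead under a 314.43 nm PSF measures ~320 nm."""
        vol, _ = sd.generate_bead_stack(diameter=100.0, psf_fwhm=314.4304,
                                        pixel_size=80.0, n_beads=20, seed=7)
        rep = res.calibrate_from_stack(vol, bead_diameter=100.0)
        assert rep.measured_fwhm == pytest.approx(320.0, abs=2.0)

    def test_renderer_supersampling_consistency(self):
        """Default and 10x-oversampled renderers agree on fitted FWHM."""
        v5, _ = sd.generate_bead_stack(100.0, 320.0, 80.0, 10, seed=5,
                                       supersample=5)
        v10, _ = sd.generate_bead_stack(100.0, 320.0, 80.0, 10, seed=5,
                                        supersample=10)
        f5 = res.calibrate_from_stack(v5, 100.0).measured_fwhm
        f10 = res.calibrate_from_stack(v10, 100.0).measured_fwhm
        assert abs(f5 - f10) < 2.0

    def test_truth_centers_are_separated(self):
        _, truth = sd.generate_bead_stack(n_beads=10, psf_fwhm=320.0,
                                          pixel_size=80.0, seed=0)
        c = truth.bead_centers
        d = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 3 * 320.0 / 80.0

    def test_impossible_placement_raises(self):
        with pytest.raises(sd.PlacementError):
            sd.generate_bead_stack(n_beads=50, psf_fwhm=320.0, pixel_size=80.0,
                                   field_yx=(20, 20), seed=0)


class TestTissuePhantom:
    def test_deterministic(self):
        spec = sd.default_phantom_spec(11)
        a, _ = sd.generate_tissue_phantom(spec)
        b, _ = sd.generate_tissue_phantom(spec)
        for k in a:
            assert np.array_equal(a[k].voxels, b[k].voxels)

    def test_nuclei_only_spec_gives_matching_supports(self):
        spec = sd.PhantomSpec(
            field_shape=(4, 64, 64),
            structures=[sd.StructureSpec(StructureKind.NUCLEUS, count=3,
                                         size_nm=900.0)],
            noise=sd.NOISELESS, seed=5)
        channels, truth = sd.generate_tissue_phantom(spec)
        assert set(channels) == {"CH3-2940", "DAPI"}
        srs = channels["CH3-2940"].voxels
        dapi = channels["DAPI"].voxels
        # identical support up to PSF blur: high-signal sets coincide
        assert np.array_equal(srs > 0.5 * srs.max(), dapi > 0.5 * dapi.max())

    def test_default_spec_truth_maps_distinct_and_inside_composite(
            self, noiseless_phantom):
        spec, channels, truth = noiseless_phantom
        maps = list(truth.density_maps.values())
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                assert not np.array_equal(maps[i], maps[j])
        srs = channels["CH3-2940"].voxels
        for m in truth.density_maps.values():
            if m.any():
                assert srs[m >= 0.5].mean() > srs.mean()

    def test_doubling_density_doubles_contribution(self, noiseless_phantom):
        spec, _, truth = noiseless_phantom
        double = replace(spec, structures=[
            replace(s, protein_density=2 * s.protein_density)
            if s.kind is StructureKind.SOMA else s for s in spec.structures])
        base = sd.srs_forward_model(truth, spec, noise=False).voxels
        dbl = sd.srs_forward_model(truth, double, noise=False).voxels
        soma = truth.density_maps[StructureKind.SOMA]
        extra = dbl - base  # exactly one extra soma contribution
        dens = spec.density_of(StructureKind.SOMA)
        assert np.sum(extra) == pytest.approx(dens * np.sum(soma), rel=1e-3)


class TestForwardModel:
    def test_zero_retention_zero_background_is_black(self, noiseless_phantom):
        spec, _, truth = noiseless_phantom
        img = sd.srs_forward_model(truth, spec, noise=False,
                                   retention_override=0.0)
        assert np.all(img.voxels == 0)

    def test_background_additivity(self, noiseless_phantom):
        spec, _, truth = noiseless_phantom
        with_bg = replace(spec, background=sd.BackgroundSpec(
            gel_ch2_weight=0.05, water_oh_weight=0.02))
        a = sd.srs_forward_model(truth, spec, noise=False).voxels
        b = sd.srs_forward_model(truth, with_bg, noise=False).voxels
        outside = ~truth.structure_mask()
        # mean background far from structures equals the configured sum
        assert (b - a)[outside].mean() == pytest.approx(0.07, rel=0.05)

    def test_composite_equals_bruteforce_component_sum(self, noiseless_phantom):
        spec, _, truth = noiseless_phantom
        composite = sd.srs_forward_model(truth, spec, noise=False).voxels
        acc = np.zeros(spec.field_shape)
        for kind, dmap in truth.density_maps.items():
            single = sd.PhantomTruth(density_maps={kind: dmap})
            acc += sd.srs_forward_model(single, spec, noise=False).voxels
        assert np.allclose(composite, acc, atol=1e-5)


class TestExpansion:
    def test_ratio_one_no_distortion_is_identity(self, noiseless_phantom):
        spec, channels, truth = noiseless_phantom
        pre, post, _ = sd.simulate_expansion(channels, truth, spec,
                                             ratio=1.0, seed=0)
        assert np.allclose(post["CH3-2940"].voxels,
                           pre["CH3-2940"].voxels, atol=1e-5)

    def test_fourfold_expansion_dilutes_64x(self, noiseless_phantom):
        spec, channels, truth = noiseless_phantom
        pre, post, tp = sd.simulate_expansion(channels, truth, spec,
                                              ratio=4.0, seed=2)
        m_pre = pre["CH3-2940"].voxels[truth.structure_mask()].mean()
        m_post = post["CH3-2940"].voxels[tp.structure_mask()].mean()
        assert m_pre / m_post == pytest.approx(64.0, rel=0.10)

    def test_geometry_scales_by_ratio(self, noiseless_phantom):
        """A feature of pre-size L measures ratio x L in the post image."""
        spec, channels, truth = noiseless_phantom
        _, _, tp = sd.simulate_expansion(channels, truth, spec,
                                         ratio=4.2, seed=3)
        pre_m = truth.density_maps[StructureKind.NUCLEUS][..., :] >= 0.5
        post_m = tp.density_maps[StructureKind.NUCLEUS] >= 0.5
        # in-plane extent of the union support along y
        def extent(mask):
            rows = np.where(mask.any(axis=(0, 2)))[0]
            return rows[-1] - rows[0] + 1
        assert extent(post_m) / extent(pre_m) == pytest.approx(4.2, rel=0.05)
        assert tp.expansion_ratio == 4.2

    def test_signal_conservation_without_distortion(self, noiseless_phantom):
        spec, channels, truth = noiseless_phantom
        pre, post, _ = sd.simulate_expansion(channels, truth, spec,
                                             ratio=3.0, seed=4)
        s_pre = float(pre["CH3-2940"].voxels.sum())
        s_post = float(post["CH3-2940"].voxels.sum())
        assert s_post == pytest.approx(s_pre, rel=0.01)

    def test_distortion_field_has_requested_magnitude(self, noiseless_phantom):
        spec, channels, truth = noiseless_phantom
        _, post, tp = sd.simulate_expansion(channels, truth, spec, ratio=2.0,
                                            distortion_rms=200.0, seed=5)
        assert tp.distortion_rms_nm == 200.0
        # distorted image differs from the undistorted render
        _, post0, _ = sd.simulate_expansion(channels, truth, spec, ratio=2.0,
                                            distortion_rms=0.0, seed=5)
        assert not np.allclose(post["CH3-2940"].voxels,
                               post0["CH3-2940"].voxels)

    def test_invalid_ratio_rejected(self, noiseless_phantom):
        spec, channels, truth = noiseless_phantom
        with pytest.raises(ValueError):
            sd.simulate_expansion(channels, truth, spec, ratio=0.5)


class TestDegradeGroundTruth:
    def test_sigma_zero_is_identity(self, noiseless_phantom):
        _, channels, _ = noiseless_phantom
        v = channels["DAPI"]
        out = sd.degrade_ground_truth(v, 0.0, seed=1)
        assert np.array_equal(out.voxels, v.voxels)

    def test_noise_std_matches_sigma(self):
        from vista.core_io import ImageVolume
        v = ImageVolume(np.full((1, 128, 128), 5.0, dtype=np.float32))
        out = sd.degrade_ground_truth(v, 0.3, seed=2)
        assert float(out.voxels.std()) == pytest.approx(0.3, rel=0.05)

    def test_seeded_determinism(self):
        from vista.core_io import ImageVolume
        v = ImageVolume(np.zeros((1, 32, 32), dtype=np.float32))
        a = sd.degrade_ground_truth(v, 1.0, seed=9)
        b = sd.degrade_ground_truth(v, 1.0, seed=9)
        assert np.array_equal(a.voxels, b.voxels)

    def test_negative_sigma_rejected(self):
        from vista.core_io import ImageVolume
        v = ImageVolume(np.zeros((1, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            sd.degrade_ground_truth(v, -1.0)
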