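"""Digital phantom builders and the photoacoustic forward model."""

import numpy as np
import pytest

from paoximetry.fluence import BeamSpec, MCConfig, VoxelPhantom
from paoximetry.optics import TissueSpec, WavelengthGrid
from paoximetry.synth import (
    LUMEN,
    ForwardConfig,
    PhantomScene,
    GroundTruth,
    build_abdomen_phantom,
    build_tube_phantom,
    simulate_pa_stack,
    so2_sweep_dataset,
)

GRID2 = WavelengthGrid([808.0, 1064.0])


class TestTubePhantom:
    def test_fully_oxygenated_lumen_has_no_deoxy(self):
        scene = build_tube_phantom(1.0)
        c_o, c_d = scene.truth.label_concentrations[LUMEN]
        assert c_d == 0.0 and c_o == pytest.approx(2.3e-3)

    def test_half_saturation_splits_total(self):
        scene = build_tube_phantom(0.5, c_thb=2.3e-3)
        c_o, c_d = scene.truth.label_concentrations[LUMEN]
        assert c_o == pytest.approx(1.15e-3)
        assert c_d == pytest.approx(1.15e-3)

    def test_pbs_lumen_has_undefined_so2(self):
        scene = build_tube_phantom(1.0, lumen_content="PBS")
        assert scene.truth.region_so2["lumen"] is None
        so2_map = scene.truth.voxel_so2(scene.phantom.labels)
        assert np.isnan(so2_map).all()

    def test_tube_depth(self):
        scene = build_tube_phantom(1.0, slab_thickness_mm=3.0, gel_gap_mm=1.0,
                                   tube_od_mm=2.0)
        assert scene.region_depths_mm["lumen"] == pytest.approx(5.0)
        # lumen centroid depth matches the tube axis within a voxel
        zc = np.nonzero(scene.regions["lumen"].any(axis=1))[0]
        centroid = (zc.mean() + 0.5) * scene.phantom.voxel_mm
        assert abs(centroid - 5.0) <= scene.phantom.voxel_mm

    def test_tube_deeper_than_grid_rejected(self):
        with pytest.raises(ValueError, match="deeper"):
            build_tube_phantom(1.0, gel_gap_mm=20.0)

    def test_bad_so2_rejected(self):
        with pytest.raises(ValueError):
            build_tube_phantom(1.5)


class TestAbdomenPhantom:
    def test_bleached_kidney_is_hemoglobin_free(self):
        scene = build_abdomen_phantom(1.0, hemoglobin_bleached=True)
        c_o, c_d = scene.truth.label_concentrations[3]
        assert c_o == 0.0 and c_d == 0.0
        assert all(v is None for v in scene.truth.region_so2.values())

    def test_deoxygenated_kidney(self):
        scene = build_abdomen_phantom(0.0, kidney_bvf=0.2, c_thb=2.3e-3)
        c_o, c_d = scene.truth.label_concentrations[3]
        assert c_o == 0.0
        assert c_d == pytest.approx(0.2 * 2.3e-3)

    def test_roi_centroid_depths(self):
        scene = build_abdomen_phantom(1.0, roi_depths_mm=(6.0, 9.0, 12.0))
        for name, depth in scene.region_depths_mm.items():
            zc = np.nonzero(scene.regions[name].any(axis=1))[0]
            centroid = (zc.mean() + 0.5) * scene.phantom.voxel_mm
            assert abs(centroid - depth) <= scene.phantom.voxel_mm

    def test_roi_outside_kidney_rejected(self):
        with pytest.raises(ValueError, match="roi depth"):
            build_abdomen_phantom(1.0, roi_depths_mm=(2.0,))


class TestForwardModel:
    def test_zero_noise_frames_identical(self, table):
        scene = build_tube_phantom(1.0)
        stack = simulate_pa_stack(scene, GRID2, BeamSpec(0.5, 25.0),
                                  ForwardConfig(noise_sd=0.0, n_frames=5, seed=1),
                                  table)
        for i in range(1, 5):
            assert np.array_equal(stack.data[:, 0], stack.data[:, i])

    def test_grueneisen_linearity(self, table):
        scene = build_tube_phantom(0.5)
        kw = dict(noise_sd=0.03, n_frames=2, seed=9)
        s1 = simulate_pa_stack(scene, GRID2, BeamSpec(0.5, 25.0),
                               ForwardConfig(grueneisen=1.0, **kw), table)
        s2 = simulate_pa_stack(scene, GRID2, BeamSpec(0.5, 25.0),
                               ForwardConfig(grueneisen=2.0, **kw), table)
        assert np.allclose(s2.data, 2.0 * s1.data)

    def test_seeded_reproducibility(self, table):
        scene = build_tube_phantom(0.5)
        mk = lambda: simulate_pa_stack(  # noqa: E731
            scene, GRID2, BeamSpec(0.5, 25.0),
            ForwardConfig(noise_sd=0.05, seed=77), table)
        assert np.array_equal(mk().data, mk().data)

    def test_single_absorber_in_vacuum_closed_form(self, table):
        """One absorbing voxel under vacuum: amplitude is
        Gamma * F * mu_a * exp(-mu_eff * half voxel)."""
        absorber = TissueSpec("a", extra_mu_a=2.0, musp_500=10.0,
                              musp_power=0.0, g=0.0)
        labels = np.zeros((10, 5, 5), np.int32)
        labels[4, 2, 2] = 1
        phantom = VoxelPhantom(labels, 0.2, {0: None, 1: absorber})
        region = labels[:, 2, :] == 1
        scene = PhantomScene(
            phantom=phantom, regions={"spot": region},
            region_depths_mm={"spot": 0.9},
            truth=GroundTruth(region_so2={"spot": None},
                              label_concentrations={1: (0.0, 0.0)}),
        )
        stack = simulate_pa_stack(scene, GRID2, BeamSpec(0.2, 4.0),
                                  ForwardConfig(noise_sd=0.0, seed=0), table)
        mu_eff_mm = np.sqrt(3 * 2.0 * 12.0) / 10.0
        expected = 1.0 * 4.0 * 2.0 * np.exp(-mu_eff_mm * 0.1)
        got = stack.data[0, 0][region][0]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_linear_in_concentration_at_fixed_fluence(self, table):
        # doubling hemoglobin scales the lumen amplitude by < 2x through
        # self-shading, but with a fixed external fluence map the first
        # (shallowest) lumen row at 1064 nm scales nearly linearly
        s1 = build_tube_phantom(1.0, c_thb=1.0e-3)
        s2 = build_tube_phantom(1.0, c_thb=2.0e-3)
        mu1 = s1.phantom.mu_a_map(1064.0, table)
        mu2 = s2.phantom.mu_a_map(1064.0, table)
        lum = s1.phantom.labels == LUMEN
        assert np.allclose(mu2[lum], 2.0 * mu1[lum])


class TestSweep:
    def test_duplicate_seeds_rejected(self, table):
        with pytest.raises(ValueError, match="distinct"):
            so2_sweep_dataset(GRID2, BeamSpec(0.5, 25.0), table,
                              replicates=2, seeds=[3, 3])

    def test_zero_jitter_single_replicate_matches_base(self, table):
        out = so2_sweep_dataset(
            GRID2, BeamSpec(0.5, 25.0), table, so2_levels=(1.0,),
            replicates=1, seeds=[5], jitter_fraction=0.0,
            fcfg=ForwardConfig(noise_sd=0.0),
        )
        _, so2, scene, stack = out[0]
        base = build_tube_phantom(1.0)
        assert scene.params["slab_thickness_mm"] == pytest.approx(3.0)
        assert scene.params["c_thb"] == pytest.approx(2.3e-3)
        assert np.array_equal(scene.phantom.labels, base.phantom.labels)

    def test_jitter_sampling_scale(self):
        # 5% jitter over many replicates: empirical sd within 20%
        rng_draws = []
        seeds = list(range(100))
        for seed in seeds:
            rng = np.random.default_rng(seed)
            rng_draws.append(3.0 * max(0.1, 1.0 + 0.05 * rng.standard_normal()))
        sd = np.std(rng_draws, ddof=1)
        assert abs(sd - 0.15) / 0.15 < 0.2


class TestSpectralColoring:
    def test_slab_colors_spectrum_vacuum_does_not(self, table):
        """The ratio measured-spectrum / true blood absorption is flat
        without overburden and strongly wavelength-dependent through
        the porcine slab."""
        grid = WavelengthGrid(np.arange(690.0, 951.0, 20.0))
        wl = grid.wavelengths
        ratios = {}
        for vacuum in (True, False):
            scene = build_tube_phantom(1.0, vacuum_overburden=vacuum)
            stack = simulate_pa_stack(scene, grid, BeamSpec(0.5, 25.0),
                                      ForwardConfig(noise_sd=0.0, seed=3), table)
            # top lumen row only: minimal self-shading
            lumen = scene.regions["lumen"]
            top = np.zeros_like(lumen)
            top[np.nonzero(lumen.any(axis=1))[0][0]] = lumen[
                np.nonzero(lumen.any(axis=1))[0][0]]
            sig = np.array([stack.data[i, 0][top].mean() for i in range(len(grid))])
            mu = np.array([
                scene.phantom.mu_a_map(w, table)[scene.phantom.labels == LUMEN][0]
                for w in wl])
            r = sig / mu
            ratios[vacuum] = np.std(r) / np.mean(r)
        assert ratios[False] > 5 * ratios[True]

    def test_bleached_kidney_darker_at_1064(self, table):
        grid = WavelengthGrid([1064.0])
        beam = BeamSpec(1.3, 5.5)
        amp = {}
        for bleached in (False, True):
            scene = build_abdomen_phantom(1.0, hemoglobin_bleached=bleached)
            stack = simulate_pa_stack(scene, grid, beam,
                                      ForwardConfig(noise_sd=0.0, seed=4), table)
            roi = scene.regions["roi_6mm"]
            amp[bleached] = stack.data[0, 0][roi].mean()
        assert amp[True] < amp[False]
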