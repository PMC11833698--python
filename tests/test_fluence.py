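"""Monte Carlo transport physics and the 1-D diffusion surrogate."""

import numpy as np
import pytest

from paoximetry.fluence import (
    BeamSpec,
    MCConfig,
    TissueOpticalProperties,
    VoxelPhantom,
    analytic_fluence_1d,
    analytic_fluence_map,
    fluence_spectrum,
    local_fluence,
    mu_eff_cm,
    sample_hg_cosines,
    simulate_fluence,
)
from paoximetry.optics import TissueSpec


def homogeneous_phantom(mu_a_cm, musp_cm, shape=(40, 24, 24), voxel=0.2, g=0.0):
    spec = TissueSpec("medium", extra_mu_a=mu_a_cm,
                      musp_500=musp_cm, musp_power=0.0, g=g)
    return VoxelPhantom(np.zeros(shape, np.int32), voxel, {0: spec})


def ledger_closure(ledger):
    return (ledger["absorbed"] + ledger["escaped"] + ledger["roulette_killed"]
            - ledger["roulette_boost"] - ledger["launched"])


class TestEnergyConservation:
    def test_ledger_closes_with_roulette_active(self, table):
        # wide scattering-dominated medium so weights decay until
        # roulette fires
        ph = homogeneous_phantom(1.0, 60.0, shape=(60, 40, 40))
        fm = simulate_fluence(ph, BeamSpec(0.3, 1.0), 800.0,
                              MCConfig(n_photons=5_000, seed=11), table)
        assert fm.ledger["roulette_killed"] + fm.ledger["roulette_boost"] > 0
        assert abs(ledger_closure(fm.ledger)) < 1e-6 * fm.ledger["launched"]
        assert fm.ledger["absorbed_fraction"] + fm.ledger["escaped_fraction"] == (
            pytest.approx(1.0, abs=1e-12))

    def test_no_absorber_escapes_exactly(self, table):
        ph = homogeneous_phantom(0.0, 5.0, shape=(16, 16, 16))
        fm = simulate_fluence(ph, BeamSpec(0.3, 1.0), 800.0,
                              MCConfig(n_photons=5_000, seed=2), table)
        assert fm.ledger["absorbed"] == 0.0
        assert fm.ledger["escaped"] == fm.ledger["launched"]
        assert not fm.valid.any()


class TestBeerLambertLimit:
    def test_pure_absorber_depth_profile(self, table):
        # mu_s = 0: fluence inside the beam follows exp(-mu_a z)
        mu_a = 5.0  # cm^-1
        ph = homogeneous_phantom(mu_a, 0.0, shape=(40, 30, 30))
        beam = BeamSpec(0.4, 1.0)
        runs = []
        for seed in (1, 2, 3):
            fm = simulate_fluence(ph, beam, 800.0,
                                  MCConfig(n_photons=60_000, seed=seed), table)
            xs = (np.arange(30) + 0.5) * 0.2
            rr = (xs[None, :] - 3.0) ** 2 + (xs[:, None] - 3.0) ** 2
            runs.append(fm.values[:, rr < 1.2 ** 2].mean(axis=1))
        runs = np.array(runs)
        depth = (np.arange(40) + 0.5) * 0.02  # cm
        expected = np.exp(-mu_a * depth)
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(len(runs))
        sel = slice(0, 25)  # depths with adequate statistics
        assert np.all(np.abs(mean[sel] - expected[sel]) < 3 * se[sel] + 0.02)


class TestReproducibility:
    def test_bitwise_identical_given_seed(self, table):
        ph = homogeneous_phantom(1.0, 10.0, shape=(20, 16, 16))
        cfg = MCConfig(n_photons=10_000, seed=123)
        a = simulate_fluence(ph, BeamSpec(0.3, 1.0), 900.0, cfg, table)
        b = simulate_fluence(ph, BeamSpec(0.3, 1.0), 900.0, cfg, table)
        assert np.array_equal(a.values, b.values)
        assert a.ledger == b.ledger

    def test_different_seed_differs(self, table):
        ph = homogeneous_phantom(1.0, 10.0, shape=(20, 16, 16))
        a = simulate_fluence(ph, BeamSpec(0.3, 1.0), 900.0,
                             MCConfig(n_photons=10_000, seed=1), table)
        b = simulate_fluence(ph, BeamSpec(0.3, 1.0), 900.0,
                             MCConfig(n_photons=10_000, seed=2), table)
        assert not np.array_equal(a.values, b.values)


class TestConvergence:
    def test_se_scales_inverse_sqrt(self, table):
        ph = homogeneous_phantom(2.0, 10.0, shape=(24, 16, 16))
        beam = BeamSpec(0.3, 1.0)
        roi = np.zeros((24, 16), bool)
        roi[8:12, 6:10] = True
        ses = []
        for n in (2_000, 200_000):
            vals = [
                local_fluence(simulate_fluence(
                    ph, beam, 800.0, MCConfig(n_photons=n, seed=s), table), roi, 1.0)
                for s in range(5)
            ]
            ses.append(np.std(vals, ddof=1))
        ratio = ses[0] / ses[1]          # expect ~sqrt(100) = 10
        assert 5.0 < ratio < 20.0


class TestHenyeyGreenstein:
    def test_isotropic_mean_cosine(self):
        n = 200_000
        cts = sample_hg_cosines(0.0, n, seed=5)
        se = cts.std(ddof=1) / np.sqrt(n)
        assert abs(cts.mean()) < 3 * se

    @pytest.mark.parametrize("g", [0.5, 0.9])
    def test_mean_cosine_equals_g(self, g):
        n = 200_000
        cts = sample_hg_cosines(g, n, seed=7)
        se = cts.std(ddof=1) / np.sqrt(n)
        assert abs(cts.mean() - g) < 3 * se
        assert np.all(np.abs(cts) <= 1.0)


class BruteForceWalker:
    """Independent single-purpose photon walker (pure numpy, per-photon
    loop): same physics — optical-depth consumption across voxels,
    implicit capture, isotropic scattering — coded separately from the
    production kernel, as a cross-check oracle."""

    def __init__(self, mu_a_mm, mu_s_mm, voxel, shape):
        self.mu_a, self.mu_s = mu_a_mm, mu_s_mm  # per-label arrays
        self.voxel, self.shape = voxel, shape

    def run(self, labels, n_photons, beam_r, cx, cy, rng):
        nz, ny, nx = self.shape
        dep = np.zeros(self.shape)
        vox = self.voxel
        for _ in range(n_photons):
            r = beam_r * np.sqrt(rng.random())
            th = 2 * np.pi * rng.random()
            p = np.array([cx + r * np.cos(th), cy + r * np.sin(th), 1e-9])
            u = np.array([0.0, 0.0, 1.0])
            w = 1.0
            tau = -np.log(rng.random())
            for _step in range(20_000):
                idx = np.floor(p / vox).astype(int)
                ix, iy, iz = idx[0], idx[1], idx[2]
                if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
                    break
                lab = labels[iz, iy, ix]
                mut = self.mu_a[lab] + self.mu_s[lab]
                bounds = np.where(u > 0, (idx + 1) * vox, idx * vox)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ts = np.where(u != 0, (bounds - p) / u, np.inf)
                t_exit = ts.min()
                if mut * t_exit < tau:
                    tau -= mut * t_exit
                    p = p + u * (t_exit + vox * 1e-6)
                    continue
                p = p + u * (tau / mut)
                dw = w * self.mu_a[lab] / mut
                dep[iz, iy, ix] += dw
                w -= dw
                tau = -np.log(rng.random())
                ct = 2 * rng.random() - 1.0
                st = np.sqrt(1 - ct * ct)
                ph = 2 * np.pi * rng.random()
                u = np.array([st * np.cos(ph), st * np.sin(ph), ct])
                if w < 1e-4:
                    break
        return dep


def test_two_layer_agreement_with_brute_force(table):
    """On-axis fluence in a two-layer slab matches an independently
    coded brute-force walker within combined statistical error."""
    top = TissueSpec("top", extra_mu_a=1.0, musp_500=15.0, musp_power=0.0, g=0.0)
    bottom = TissueSpec("bottom", extra_mu_a=4.0, musp_500=5.0, musp_power=0.0, g=0.0)
    shape, vox = (24, 16, 16), 0.25
    labels = np.zeros(shape, np.int32)
    labels[10:] = 1
    ph = VoxelPhantom(labels, vox, {0: top, 1: bottom})
    beam = BeamSpec(0.3, 1.0)
    roi = np.zeros((shape[0], shape[2]), bool)
    roi[12:15, 6:10] = True

    prod = [
        local_fluence(simulate_fluence(
            ph, beam, 800.0,
            MCConfig(n_photons=40_000, seed=s, use_similarity=False), table),
            roi, 1.0)
        for s in (1, 2, 3)
    ]

    mu_a = np.array([0.1, 0.4])   # mm^-1, same media as above
    mu_s = np.array([1.5, 0.5])
    walker = BruteForceWalker(mu_a, mu_s, vox, shape)
    beam_area = np.pi * beam.radius_mm ** 2
    oracle = []
    n_bf = 15_000
    for s in (4, 5, 6):
        dep = walker.run(labels, n_bf, beam.radius_mm, 2.0, 2.0,
                         np.random.default_rng(s))
        phi = dep / (mu_a[labels] * vox ** 3) * beam_area / n_bf
        mid = phi[:, shape[1] // 2, :]
        oracle.append(mid[roi].mean())

    m_p, m_o = np.mean(prod), np.mean(oracle)
    se = np.sqrt(np.var(prod, ddof=1) / 3 + np.var(oracle, ddof=1) / 3)
    assert abs(m_p - m_o) < 3 * se + 0.02 * m_o


class TestAnalyticSurrogate:
    def test_zero_attenuation_layer_transparent(self):
        props = TissueOpticalProperties(0.0, 0.0, 0.0)
        assert analytic_fluence_1d([(props, 10.0)], 10.0) == pytest.approx(1.0)

    def test_single_layer_closed_form(self):
        # mu_a = 0.1, mu_s' = 10 cm^-1 -> mu_eff = sqrt(3*0.1*10.1) = 1.7407
        props = TissueOpticalProperties(0.1, 10.0 / (1 - 0.0), 0.0)
        val = analytic_fluence_1d([(props, 10.0)], 10.0)
        assert val == pytest.approx(np.exp(-1.74069), rel=1e-4)

    def test_layer_order_invariance(self):
        a = TissueOpticalProperties(0.5, 20.0, 0.0)
        b = TissueOpticalProperties(2.0, 5.0, 0.0)
        z = 6.0
        f1 = analytic_fluence_1d([(a, 3.0), (b, 3.0)], z)
        f2 = analytic_fluence_1d([(b, 3.0), (a, 3.0)], z)
        assert f1 == pytest.approx(f2)

    def test_negative_thickness_rejected(self):
        props = TissueOpticalProperties(0.1, 1.0, 0.0)
        with pytest.raises(ValueError):
            analytic_fluence_1d([(props, -1.0)], 1.0)

    def test_mu_eff_definition(self):
        assert mu_eff_cm(0.1, 10.0) == pytest.approx(np.sqrt(3 * 0.1 * 10.1))


class TestLocalFluence:
    def test_surface_of_transparent_phantom_returns_surface_fluence(self, table):
        ph = homogeneous_phantom(1e-6, 0.0, shape=(10, 10, 10))
        fm = analytic_fluence_map(ph, 800.0, table)
        roi = np.zeros((10, 10), bool)
        roi[0, :] = True
        assert local_fluence(fm, roi, 25.0) == pytest.approx(25.0, rel=1e-4)

    def test_zero_surface_fluence(self, table):
        ph = homogeneous_phantom(1.0, 0.0, shape=(10, 10, 10))
        fm = analytic_fluence_map(ph, 800.0, table)
        roi = np.ones((10, 10), bool)
        assert local_fluence(fm, roi, 0.0) == 0.0

    def test_empty_roi_rejected(self, table):
        ph = homogeneous_phantom(1.0, 0.0, shape=(10, 10, 10))
        fm = analytic_fluence_map(ph, 800.0, table)
        with pytest.raises(ValueError):
            local_fluence(fm, np.zeros((10, 10), bool), 1.0)

    def test_invalid_voxels_excluded_with_warning(self, table):
        vac = TissueSpec("vac")
        absb = TissueSpec("abs", extra_mu_a=1.0)
        labels = np.zeros((10, 8, 8), np.int32)
        labels[5:] = 1
        ph = VoxelPhantom(labels, 0.2, {0: vac, 1: absb})
        fm = simulate_fluence(ph, BeamSpec(0.3, 1.0), 800.0,
                              MCConfig(n_photons=3_000, seed=1), table)
        roi = np.ones((10, 8), bool)
        with pytest.warns(UserWarning, match="mu_a = 0"):
            local_fluence(fm, roi, 1.0)


class TestFluenceSpectrum:
    def test_single_wavelength_equals_local_fluence(self, table):
        ph = homogeneous_phantom(1.0, 5.0, shape=(16, 12, 12))
        beam = BeamSpec(0.3, 10.0)
        roi = np.zeros((16, 12), bool)
        roi[5:8, 4:8] = True
        cfg = MCConfig(n_photons=5_000, seed=9)
        spec = fluence_spectrum(ph, beam, [800.0], roi, cfg, table, mode="mc")
        assert spec.shape == (1,)
        assert spec[0] > 0

    def test_lower_mu_eff_gives_higher_fluence_surrogate(self, table):
        # water-dominated medium: mu_eff(1064) < mu_eff(975), so the
        # surrogate delivers more light at depth at 1064 nm
        spec = TissueSpec("aqueous", f_water=1.0, musp_500=10.0,
                          musp_power=0.0, g=0.0)
        ph = VoxelPhantom(np.zeros((50, 20, 20), np.int32), 0.2, {0: spec})
        beam = BeamSpec(0.5, 1.0)
        roi2d = np.zeros((50, 20), bool)
        roi2d[47:50, 7:13] = True
        out = fluence_spectrum(ph, beam, [975.0, 1064.0], roi2d,
                               MCConfig(n_photons=1_000, seed=3), table,
                               mode="analytic_1d")
        assert out[1] > out[0]

    def test_nir2_penetrates_porcine_deeper_mc(self, table, tissues):
        # 1064 vs 690 nm through porcine muscle: reduced scattering in
        # the second window wins despite higher water absorption
        spec = tissues["porcine_muscle"]
        ph = VoxelPhantom(np.zeros((50, 20, 20), np.int32), 0.2, {0: spec})
        beam = BeamSpec(0.5, 1.0)
        roi3d = np.zeros((50, 20, 20), bool)
        roi3d[30:36, 6:14, 6:14] = True  # ~6.5 mm: adequate statistics
        out_mc = fluence_spectrum(ph, beam, [690.0, 1064.0], roi3d,
                                  MCConfig(n_photons=60_000, seed=3), table,
                                  mode="mc")
        assert out_mc[1] > out_mc[0]


class TestPhantomValidation:
    def test_missing_label_rejected(self, table):
        labels = np.ones((4, 4, 4), np.int32)
        with pytest.raises(ValueError, match="missing"):
            VoxelPhantom(labels, 0.2, {0: TissueSpec("a")})

    def test_bad_voxel_edge(self):
        with pytest.raises(ValueError):
            VoxelPhantom(np.zeros((4, 4, 4), np.int32), 0.0, {0: None})

    def test_mc_config_invariants(self):
        with pytest.raises(ValueError):
            MCConfig(n_photons=0)
        with pytest.raises(ValueError):
            MCConfig(roulette_threshold=1.5)
        with pytest.raises(ValueError):
            MCConfig(survival_multiplier=1.0)
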