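"""Synthetic-data generator: digital tissue phantoms and forward-model
photoacoustic image stacks.

Two scenes are built:

* a tube phantom — a slab of porcine muscle over a thin-walled tube of
  whole blood (or PBS) embedded in gelatin, imaged through the slab;
* a layered abdomen — planar skin and subcutaneous fat over a
  blood-perfused kidney block, with analysis regions at several depths.

The forward model is the initial-pressure map
``p0 = Gamma * mu_a(voxel, lambda) * Phi(voxel, lambda)`` — all
absorbers contribute, so water/lipid coloring is present — sampled on
the transducer midplane, with multiplicative per-frame noise emulating
pulse-to-pulse laser energy fluctuation.  No acoustic propagation or
reconstruction is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fluence import (
    BeamSpec,
    FluenceMap,
    MCConfig,
    VoxelPhantom,
    analytic_fluence_map,
    simulate_fluence,
)
from .optics import ExtinctionTable, TissueSpec, WavelengthGrid, load_tissue_specs

#: Default whole-blood total hemoglobin, mol/L (~150 g/L).
DEFAULT_C_THB = 2.3e-3

#: Default kidney blood volume fraction.
DEFAULT_KIDNEY_BVF = 0.2

# Scene label ids
VACUUM, SLAB, GELATIN, TUBE_WALL, LUMEN = 0, 1, 2, 3, 4
SKIN, FAT, KIDNEY = 1, 2, 3


@dataclass
class GroundTruth:
    """True chromophore content of the generated scene."""

    region_so2: dict[str, float | None]      # None where no hemoglobin
    label_concentrations: dict[int, tuple[float, float]]  # label -> (c_HbO2, c_Hb)

    def voxel_so2(self, labels: np.ndarray) -> np.ndarray:
        """Per-voxel sO2 map; NaN where total hemoglobin is zero."""
        out = np.full(labels.shape, np.nan)
        for lab, (co, cd) in self.label_concentrations.items():
            if co + cd > 0:
                out[labels == lab] = co / (co + cd)
        return out


@dataclass
class PhantomScene:
    """A voxel phantom with named target regions on the imaging midplane."""

    phantom: VoxelPhantom
    regions: dict[str, np.ndarray]        # name -> 2D (z, x) bool mask
    region_depths_mm: dict[str, float]
    truth: GroundTruth
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        nz, _, nx = self.phantom.shape
        for name, mask in self.regions.items():
            if mask.shape != (nz, nx):
                raise ValueError(f"region {name!r} not aligned to midplane")
            if not mask.any():
                raise ValueError(f"region {name!r} is empty")


@dataclass(frozen=True)
class ForwardConfig:
    """Forward-model settings.

    ``noise_sd`` is the fractional standard deviation of the
    multiplicative per-frame amplitude factor (pulse-to-pulse laser
    energy variation, <=5% in the emulated system).
    """

    grueneisen: float = 1.0
    noise_sd: float = 0.05
    n_frames: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.grueneisen <= 0:
            raise ValueError("Grueneisen factor must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_frames < 1:
            raise ValueError("at least one frame required")


@dataclass
class PAImageStack:
    """Multi-wavelength amplitude stack indexed (wavelength, frame, z, x),
    arbitrary pressure units."""

    data: np.ndarray
    grid: WavelengthGrid
    voxel_mm: float
    provenance: dict = field(default_factory=dict)
    fluence_mid: np.ndarray | None = None  # (wavelength, z, x) oracle fluence

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("stack must be (wavelength, frame, z, x)")
        if self.data.shape[0] != len(self.grid):
            raise ValueError("wavelength axis does not match the grid")

    def frame_mean(self) -> np.ndarray:
        return self.data.mean(axis=1)


def _default_materials() -> dict[str, TissueSpec]:
    return load_tissue_specs()


def build_tube_phantom(
    blood_so2: float,
    slab_thickness_mm: float = 3.0,
    tube_id_mm: float = 1.5,
    tube_od_mm: float = 2.0,
    lumen_content: str = "blood",
    c_thb: float = DEFAULT_C_THB,
    gel_gap_mm: float = 1.0,
    voxel_mm: float = 0.2,
    depth_mm: float = 12.0,
    width_mm: float = 16.0,
    thickness_mm: float = 8.0,
    tissues: dict[str, TissueSpec] | None = None,
    vacuum_overburden: bool = False,
) -> PhantomScene:
    """Porcine slab over a blood-filled tube embedded in gelatin.

    The tube axis lies along x in the transducer midplane at depth
    ``slab + gap + od/2``.  ``vacuum_overburden`` replaces everything
    above the tube with vacuum (a no-coloring control).
    """
    if not 0.0 <= blood_so2 <= 1.0:
        raise ValueError("blood sO2 must lie in [0, 1]")
    if lumen_content not in ("blood", "PBS"):
        raise ValueError("lumen content must be 'blood' or 'PBS'")
    tissues = tissues or _default_materials()
    nz = round(depth_mm / voxel_mm)
    ny = round(thickness_mm / voxel_mm)
    nx = round(width_mm / voxel_mm)
    z_tube = slab_thickness_mm + gel_gap_mm + tube_od_mm / 2.0
    if z_tube + tube_od_mm / 2.0 >= depth_mm:
        raise ValueError("tube deeper than the phantom grid")

    z = (np.arange(nz) + 0.5) * voxel_mm
    y = (np.arange(ny) + 0.5) * voxel_mm
    labels = np.full((nz, ny, nx), GELATIN, np.int32)
    labels[z < slab_thickness_mm, :, :] = SLAB
    r2 = (z[:, None] - z_tube) ** 2 + (y[None, :] - thickness_mm / 2.0) ** 2
    wall = r2 <= (tube_od_mm / 2.0) ** 2
    lumen = r2 <= (tube_id_mm / 2.0) ** 2
    # (z, y) masks broadcast along x
    labels[wall, :] = TUBE_WALL
    labels[lumen, :] = LUMEN
    if vacuum_overburden:
        above = z < (z_tube - tube_od_mm / 2.0)
        labels[above, :, :] = VACUUM

    blood = tissues["blood"].with_blood(blood_so2, c_thb)
    lumen_spec = blood if lumen_content == "blood" else tissues["PBS"]
    materials = {
        VACUUM: None,
        SLAB: tissues["porcine_muscle"],
        GELATIN: tissues["gelatin"],
        TUBE_WALL: tissues["tube_wall"],
        LUMEN: lumen_spec,
    }
    phantom = VoxelPhantom(labels, voxel_mm, materials)

    iy = phantom.midplane_index
    lumen_mid = labels[:, iy, :] == LUMEN
    # "around the tube" analysis ROI: the tube cross-section plus a thin
    # margin, as drawn on a reconstructed image
    margin_mm = 2.0 * voxel_mm
    tube_mid = np.zeros((nz, nx), dtype=bool)
    tube_band = np.abs(z - z_tube) <= (tube_od_mm / 2.0 + margin_mm)
    tube_mid[tube_band, :] = True
    if lumen_content == "blood":
        so2_val: float | None = blood_so2
        concentrations = {LUMEN: (blood.c_hbo2, blood.c_hb)}
    else:
        so2_val = None  # no hemoglobin: sO2 undefined
        concentrations = {LUMEN: (0.0, 0.0)}
    region_so2 = {"lumen": so2_val, "tube": so2_val}
    truth = GroundTruth(region_so2=region_so2, label_concentrations=concentrations)
    return PhantomScene(
        phantom=phantom,
        regions={"lumen": lumen_mid, "tube": tube_mid},
        region_depths_mm={"lumen": z_tube, "tube": z_tube},
        truth=truth,
        params={
            "scene": "tube_phantom",
            "blood_so2": blood_so2,
            "slab_thickness_mm": slab_thickness_mm,
            "tube_id_mm": tube_id_mm,
            "tube_od_mm": tube_od_mm,
            "lumen_content": lumen_content,
            "c_thb": c_thb,
            "gel_gap_mm": gel_gap_mm,
            "voxel_mm": voxel_mm,
            "vacuum_overburden": vacuum_overburden,
        },
    )


def build_abdomen_phantom(
    kidney_so2: float,
    skin_mm: float = 1.0,
    fat_mm: float = 3.0,
    roi_depths_mm: tuple[float, ...] = (6.0, 9.0, 12.0),
    hemoglobin_bleached: bool = False,
    kidney_bvf: float = DEFAULT_KIDNEY_BVF,
    c_thb: float = DEFAULT_C_THB,
    voxel_mm: float = 0.2,
    depth_mm: float = 16.0,
    width_mm: float = 20.0,
    thickness_mm: float = 10.0,
    roi_half_height_mm: float = 1.0,
    roi_half_width_mm: float = 2.0,
    tissues: dict[str, TissueSpec] | None = None,
) -> PhantomScene:
    """Layered rat abdomen: skin and fat over a perfused kidney block.

    Analysis regions are midplane boxes centered at the requested
    depths.  ``hemoglobin_bleached`` zeroes kidney hemoglobin,
    emulating peroxide-bleached tissue.
    """
    if not 0.0 <= kidney_so2 <= 1.0:
        raise ValueError("kidney sO2 must lie in [0, 1]")
    if skin_mm < 0 or fat_mm < 0:
        raise ValueError("layer thicknesses must be non-negative")
    tissues = tissues or _default_materials()
    nz = round(depth_mm / voxel_mm)
    ny = round(thickness_mm / voxel_mm)
    nx = round(width_mm / voxel_mm)
    kidney_top = skin_mm + fat_mm
    for d in roi_depths_mm:
        if not (kidney_top < d < depth_mm):
            raise ValueError(f"roi depth {d} mm outside the kidney extent")

    z = (np.arange(nz) + 0.5) * voxel_mm
    labels = np.full((nz, ny, nx), KIDNEY, np.int32)
    labels[z < kidney_top, :, :] = FAT
    labels[z < skin_mm, :, :] = SKIN

    c_kid = 0.0 if hemoglobin_bleached else kidney_bvf * c_thb
    kidney = tissues["kidney"].with_blood(kidney_so2, c_kid)
    materials = {SKIN: tissues["skin"], FAT: tissues["fat"], KIDNEY: kidney}
    phantom = VoxelPhantom(labels, voxel_mm, materials)

    x = (np.arange(nx) + 0.5) * voxel_mm
    cx = width_mm / 2.0
    regions, depths = {}, {}
    for d in roi_depths_mm:
        mask = (np.abs(z[:, None] - d) <= roi_half_height_mm) & (
            np.abs(x[None, :] - cx) <= roi_half_width_mm
        )
        name = f"roi_{d:g}mm"
        regions[name] = mask
        depths[name] = d
    so2_val = None if c_kid == 0 else kidney_so2
    truth = GroundTruth(
        region_so2={name: so2_val for name in regions},
        label_concentrations={KIDNEY: (kidney.c_hbo2, kidney.c_hb)},
    )
    return PhantomScene(
        phantom=phantom,
        regions=regions,
        region_depths_mm=depths,
        truth=truth,
        params={
            "scene": "abdomen_phantom",
            "kidney_so2": kidney_so2,
            "skin_mm": skin_mm,
            "fat_mm": fat_mm,
            "roi_depths_mm": tuple(roi_depths_mm),
            "hemoglobin_bleached": hemoglobin_bleached,
            "kidney_bvf": kidney_bvf,
            "c_thb": c_thb,
            "voxel_mm": voxel_mm,
        },
    )


def simulate_pa_stack(
    scene: PhantomScene,
    grid: WavelengthGrid,
    beam: BeamSpec,
    fcfg: ForwardConfig,
    table: ExtinctionTable,
    mccfg: MCConfig | None = None,
    fluence_mode: str = "analytic_1d",
    prop_scale: dict[int, tuple[float, float]] | None = None,
) -> PAImageStack:
    """Forward-simulate a multi-wavelength PA image stack.

    Per wavelength, the noiseless midplane amplitude is
    ``Gamma * mu_a * Phi`` and every frame carries an independent
    multiplicative factor ``max(0, 1 + N(0, noise_sd))``.  The fluence
    actually used is retained on the stack (``fluence_mid``) so oracle
    fluence correction is possible downstream.
    """
    phantom = scene.phantom
    iy = phantom.midplane_index
    rng = np.random.default_rng(fcfg.seed)
    nz, _, nx = phantom.shape
    nwl = len(grid)
    data = np.empty((nwl, fcfg.n_frames, nz, nx))
    phi_mid = np.empty((nwl, nz, nx))
    for i, wl in enumerate(grid.wavelengths):
        if fluence_mode == "mc":
            if mccfg is None:
                raise ValueError("mc fluence mode requires an MCConfig")
            sub = replace(
                mccfg,
                seed=int(np.random.SeedSequence([mccfg.seed, i]).generate_state(1)[0] % (2**31)),
            )
            fmap = simulate_fluence(phantom, beam, wl, sub, table, prop_scale)
        elif fluence_mode == "analytic_1d":
            fmap = analytic_fluence_map(phantom, wl, table, beam, prop_scale)
        else:
            raise ValueError(f"unknown fluence mode {fluence_mode!r}")
        mu_a_mid = phantom.mu_a_map(wl, table)[:, iy, :]
        clean = (fcfg.grueneisen * beam.surface_fluence_mj_cm2
                 * mu_a_mid * fmap.midplane())
        phi_mid[i] = fmap.midplane()
        factors = np.maximum(0.0, 1.0 + fcfg.noise_sd * rng.standard_normal(fcfg.n_frames))
        data[i] = clean[None, :, :] * factors[:, None, None]
    return PAImageStack(
        data=data,
        grid=grid,
        voxel_mm=phantom.voxel_mm,
        provenance={
            "scene": dict(scene.params),
            "seed": fcfg.seed,
            "fluence_mode": fluence_mode,
            "beam_diameter_cm": beam.diameter_cm,
            "surface_fluence_mj_cm2": beam.surface_fluence_mj_cm2,
            "noise_sd": fcfg.noise_sd,
            "n_frames": fcfg.n_frames,
        },
        fluence_mid=phi_mid,
    )


def so2_sweep_dataset(
    grid: WavelengthGrid,
    beam: BeamSpec,
    table: ExtinctionTable,
    so2_levels=(1.0, 0.0),
    replicates: int = 3,
    seeds=None,
    jitter_fraction: float = 0.05,
    base_seed: int = 0,
    scene_kwargs: dict | None = None,
    fcfg: ForwardConfig | None = None,
    mccfg: MCConfig | None = None,
    fluence_mode: str = "analytic_1d",
):
    """Replicated oxygenation sweep of the tube phantom.

    Each replicate emulates an independently prepared phantom: slab
    thickness and total hemoglobin are jittered by a Gaussian fraction
    of their nominal values.  Yields (replicate, so2, scene, stack).
    """
    scene_kwargs = dict(scene_kwargs or {})
    fcfg = fcfg or ForwardConfig()
    if seeds is None:
        seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(base_seed).spawn(replicates)
        ]
    if len(seeds) != replicates:
        raise ValueError("need one seed per replicate")
    if len(set(seeds)) != len(seeds):
        raise ValueError("replicate seeds must be distinct")
    nominal_slab = scene_kwargs.pop("slab_thickness_mm", 3.0)
    nominal_cthb = scene_kwargs.pop("c_thb", DEFAULT_C_THB)
    out = []
    for rep, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        slab = nominal_slab * max(0.1, 1.0 + jitter_fraction * rng.standard_normal())
        cthb = nominal_cthb * max(0.1, 1.0 + jitter_fraction * rng.standard_normal())
        for so2 in so2_levels:
            scene = build_tube_phantom(
                so2, slab_thickness_mm=slab, c_thb=cthb, **scene_kwargs
            )
            stack = simulate_pa_stack(
                scene, grid, beam,
                ForwardConfig(
                    grueneisen=fcfg.grueneisen, noise_sd=fcfg.noise_sd,
                    n_frames=fcfg.n_frames,
                    seed=int(rng.integers(2**31)),
                ),
                table, mccfg=mccfg, fluence_mode=fluence_mode,
            )
            out.append((rep, so2, scene, stack))
    return out
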