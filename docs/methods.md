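# Methods

## Scope and model

The package studies wavelength-set selection for photoacoustic (PA)
oximetry on fully synthetic data.  The forward model is the
initial-pressure map `p₀ = Γ · μₐ(voxel, λ) · Φ(voxel, λ)` sampled on
the transducer midplane: every absorber contributes (so water/lipid
coloring is present in the images), Φ is static during heating, and no
acoustic propagation, transducer bandwidth or reconstruction is
modeled.  "Images" are therefore absorbed-energy maps; consequences of
this simplification are discussed under *Limitations*.

Unmixing solves `p₀(λ) ≈ [ε_HbO₂(λ) c_HbO₂ + ε_Hb(λ) c_Hb] φ(λ)` by
non-negative least squares (default) or ordinary least squares (sO₂
then clamped to [0, 1] and flagged).  Isosbestic normalization divides
a spectrum by its 808-nm amplitude; the divisor is carried in the
measurement metadata and applied to the design-matrix rows, so model
and data stay commensurate even when the unmixing set (e.g. NIR-II
{1064, 1230}) does not contain 808 nm.  As a result normalization
never changes sO₂ estimates; it standardizes stored spectra across
runs.  The two-member NIR-II system is exactly determined, so its
residual is excluded from fit diagnostics.

## Packaged optical data

`src/paoximetry/data/` ships dense 5-nm tables (650–1800 nm) for
ε_HbO₂, ε_Hb, and the absorption of water and lipid, generated by
PCHIP densification of hand-compiled literature-shaped anchors
(`scripts/make_extinction_tables.py`).  Two deliberate properties:

- The NIR-II extension of the hemoglobin spectra is referenced to
  *whole blood*: the aqueous matrix of blood is folded into the
  hemoglobin terms, and the blood tissue class carries no separate
  water fraction.  A two-chromophore model could not otherwise
  represent blood absorption near 1230 nm, where water dominates; with
  this convention the oracle-fluence recovery of sO₂ is exact.
  Deoxyhemoglobin follows the water-like rise beyond ~1150 nm seen in
  whole-blood measurements, oxyhemoglobin declines steeply past its
  ~920-nm band; their 1064-nm ratio is ≈2.
- The oxy/deoxy crossing of the packaged table is at 807.3 nm.  All
  pipeline normalizations use the conventional 808 nm;
  `find_isosbestic` is diagnostic.

Tissue classes (`data/tissues.yaml`) combine water/lipid fractions
with a reduced-scattering power law `μₛ′ = a (λ/500)⁻ᵇ`.  Porcine
muscle is calibrated (a = 330 cm⁻¹, b = 4.0, water 0.70, lipid 0.10)
to reproduce the bulk attenuation contrast between windows: mean
μₐ+μₛ′ of 50.4 cm⁻¹ over 690–950 nm versus 9.3 cm⁻¹ over
1200–1300 nm.  Those two constraints force the steep b ≈ 4 slope; no
flatter exponent satisfies both.  This calibration matters for the
findings below.

## Light transport

`simulate_fluence` is a weighted-photon voxel Monte Carlo: flat-top
circular beam at normal incidence, dimensionless optical depth drawn
per flight and consumed voxel-by-voxel (interaction occurs in the
voxel where it is exhausted — unbiased at property discontinuities),
implicit capture (deposit `w·μₐ/μₜ` per collision), Henyey–Greenstein
scattering, unbiased Russian roulette (threshold 10⁻⁴, survival ×10),
and refractive-index-matched boundaries (no Fresnel reflection).  The
fluence tally is the collision estimator `deposited/(μₐ·V)`,
normalized per unit delivered surface fluence; voxels with μₐ = 0
collect no collisions and are flagged invalid.  The energy ledger
(absorbed + escaped + roulette-killed − roulette-boost = launched)
closes to 10⁻⁶ and is asserted in tests.  Runs are bit-reproducible
given a seed.

By default the engine applies the similarity relation, replacing
(μₛ, g) by (μₛ′, 0); this preserves diffusive fluence while reducing
the number of scattering events per photon by ~1/(1−g), making
2×10⁵-photon runs desk-scale.  Tests exercise g ≠ 0 sampling and an
independently coded brute-force walker at g = 0.

`analytic_fluence_1d` is a 1-D surrogate, `Φ(z) = exp(−Σ μ_eff,i dᵢ)`
with `μ_eff = sqrt(3 μₐ (μₐ+μₛ′))`.  It is used for closed-form tests
and quick pipelines.  Its key limitation: in strongly scattering,
weakly absorbing media (porcine muscle at 690 nm, μₐ ≈ 0.01 cm⁻¹)
μ_eff is nearly zero and the surrogate grossly underestimates
attenuation and coloring, even inverting the NIR-I/NIR-II penetration
ordering.  Quantitative window comparisons therefore use the Monte
Carlo engine; the surrogate is a shape tool, not a physics reference.

## Synthetic scenes and study conditions

- **Tube phantom**: 3-mm porcine slab over a 1.5/2.0-mm ID/OD PTFE
  tube of whole blood (c_tHb = 2.3 mmol/L ≈ 150 g/L) in gelatin; tube
  axis in the imaging midplane at 5 mm depth (1 mm gelatin gap);
  0.2-mm voxels; 25 mJ/cm², 0.5-cm beam.  The analysis ROI is the
  lumen cross-section — the PA-visible blood.  (A wider "around the
  tube" band was evaluated and rejected: gelatin water contributes
  over half the band signal at 1230 nm, contaminating the NIR-II
  spectrum with a non-hemoglobin shape no fluence correction can
  remove.)
- **Layered abdomen**: 1 mm skin, 3 mm fat, kidney below, with box
  ROIs at 6/9/12 mm depth; kidney blood volume fraction 0.2; 5.5
  mJ/cm², 1.3-cm beam.  A `hemoglobin_bleached` flag zeroes kidney
  hemoglobin (the peroxide-bleached control).
- **Noise and replication**: each frame carries an independent
  multiplicative factor `max(0, 1 + N(0, 0.05))` (pulse-to-pulse laser
  energy variation ≤5%), 5 frames per wavelength; replicates jitter
  slab/fat thickness and c_tHb by a Gaussian 5% to emulate separately
  prepared phantoms.  Acquisition grids are 690–950 nm at 20-nm steps
  plus 808 nm, and 1064 plus 1200–1400 (phantom) or 1200–1300 nm
  (abdomen) at 10-nm steps; error analyses use the 5-wavelength subset
  {690, 808, 950, 1064, 1230} that enters the unmixing, which keeps
  Monte Carlo budgets desk-scale.

## Fluence-correction modes and the mismatch emulation

`evaluate` corrects ROI spectra in one of three modes:

- **oracle** — divide by the exact ROI-mean fluence the forward model
  used.  With zero noise this cancels identically and sO₂ is recovered
  to machine precision; it is the noiseless lower bound and the
  forward/inverse consistency check.
- **flat** — no correction: the maximal spectral-coloring stress test.
- **perturbed** (default, the realistic case) — recompute the
  correction on an *assumed* scene: nominal geometry (no jitter),
  target blood at its probe-monitored saturation, and every traversed
  material's μₐ and μₛ′ independently mis-specified by uniform errors
  within ±25% (drawn once per replicate) — emulating residual
  literature-property error in a transport model.  The correction run
  reuses the forward run's seed stream (correlated sampling), so
  shared Monte Carlo noise cancels and the systematic mismatch
  dominates the residual.  A stress variant
  (`model_target_perfused=False`) removes the target's hemoglobin from
  the model entirely (PBS-filled tube / bleached kidney), leaving
  within-target self-shading uncorrected.

The total absolute error is `100·(|ŝO₂,oxy − 1| + |ŝO₂,deoxy − 0|)` per
replicate; values above 100% are representable (and occur with
unconstrained solving or flat fluence).  Because the true saturations
sit on the boundary of the non-negative cone, NNLS clamps estimates to
the truth whenever the spectral distortion points outward; roughly
half of random mismatch draws therefore contribute zero error, which
lowers mean errors relative to unconstrained solving.

## Findings on the synthetic emulator, and an honest caveat

With oracle correction both wavelength sets recover sO₂ exactly — the
entire pipeline is self-consistent.  Under the ±25% perturbed
correction (three replicates, 2×10⁵ photons/λ) typical mean total
absolute errors are ~1–7% for NIR-I and ~3–11% for NIR-II.  Two
physical facts explain why the *expected* ordering (NIR-I much worse
than NIR-II) does not emerge in this configuration:

1. In a diffusive slab the sensitivity of transmitted fluence to bulk
   properties is modest (∂lnT/∂lnμ ≲ 1), so a ±25% mis-specification
   produces only ~5–15% differential distortion across NIR-I — far
   less than the orders-of-magnitude coloring it corrects.
2. The calibrated b ≈ 4 scattering slope (forced by the window
   attenuation contrast) plus water absorption makes the 1064→1230 nm
   attenuation change through the slab large, so the same ±25% error
   produces a comparable differential *within* NIR-II, and the exactly
   determined 2×2 system amplifies it.

The NIR-II advantage does emerge exactly where coloring is large and
asymmetric: in the depth-stratified kidney experiment without
correction, NIR-I error grows 61% → 157% → 200% from 6 to 12 mm while
NIR-II saturates near 100%, with highly significant set differences at
the two deeper regions — the qualitative pattern reported for deep
tissue in vivo.  Passing tests on this emulator therefore demonstrate
pipeline correctness and the depth/coloring mechanism, not the precise
bench error magnitudes, which also reflect mechanisms outside this
model (pigments not in the two-absorber tissue model, spatial
heterogeneity, reconstruction physics).

## Numerical choices and degenerate inputs

Wavelengths in nm, coefficients in cm⁻¹ (converted to mm⁻¹
internally), concentrations mol/L, fluence mJ/cm², geometry mm; voxel
centers at (i+0.5)·edge; linear interpolation within the packaged
tables, no extrapolation.  Seeds fan out from a single base seed via
`numpy` `SeedSequence` spawning (one stream per replicate), so adding
replicates does not perturb existing ones.  μₜ = 0 voxels are
traversed ballistically; zero-total-concentration pixels yield an
explicit undefined-sO₂ signal (never silently 0); bleached scenes are
excluded from error statistics because their true sO₂ is undefined.
The skin exposure rule is the nanosecond single-pulse piecewise form
(20 mJ/cm² to 700 nm, 20·10^(0.002(λ−700)) to 1050 nm, 100 mJ/cm² to
1400 nm); the exponential branch meets the plateau with a ~0.2% step,
which tests treat as continuous.

## Known limitations

No acoustics (bandwidth, boundary buildup, reconstruction artifacts);
no Fresnel boundary physics; collision-estimator variance is high in
low-μₐ regions (use 3-D ROIs or more photons there); the similarity
relation is approximate within thin, low-scattering layers; the
packaged spectra are literature-shaped compilations, not a specific
published dataset; pork is modeled with water and lipid as the only
absorbers, so residual heme pigments in real muscle are outside the
model.
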