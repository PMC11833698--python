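# Named tissue classes used by the synthetic phantoms.
#
# Fields map onto TissueSpec: chromophore volume fractions /
# concentrations, reduced-scattering power law mu_s' = musp_500 *
# (lambda/500 nm)^(-musp_power) [cm^-1], anisotropy g and refractive
# index n.  Hemoglobin content of blood / perfused tissue is set at
# scene-build time via TissueSpec.with_blood, not here.
#
# porcine_muscle is calibrated so that its total attenuation
# (mu_a + mu_s') averages ~50 cm^-1 over 690-950 nm and stays below
# 10 cm^-1 over 1200-1300 nm (a >= 5x window contrast); the calibration
# constants are musp_500 = 330, musp_power = 4.0 with water/lipid
# fractions 0.70/0.10 against the packaged chromophore tables.

gelatin:
  f_water: 0.90
  musp_500: 2.0
  musp_power: 1.0
  g: 0.90
  n: 1.35

porcine_muscle:
  f_water: 0.70
  f_lipid: 0.10
  musp_500: 330.0
  musp_power: 4.0
  g: 0.90
  n: 1.37

skin:
  f_water: 0.50
  f_lipid: 0.10
  musp_500: 48.0
  musp_power: 1.6
  g: 0.90
  n: 1.40

fat:
  f_water: 0.20
  f_lipid: 0.70
  musp_500: 35.0
  musp_power: 0.7
  g: 0.90
  n: 1.44

kidney:
  f_water: 0.80
  musp_500: 27.0
  musp_power: 1.5
  g: 0.90
  n: 1.37

# Whole blood: the packaged hemoglobin extinction table is referenced
# to whole blood (its NIR-II extension is derived from whole-blood
# absorption spectra), so the aqueous matrix of blood is already part
# of the hemoglobin terms and no separate water fraction is added here.
blood:
  musp_500: 22.0
  musp_power: 1.1
  g: 0.98
  n: 1.38

PBS:
  f_water: 1.0
  musp_500: 0.1
  musp_power: 1.0
  g: 0.90
  n: 1.33

tube_wall:
  f_water: 0.01
  musp_500: 60.0
  musp_power: 0.3
  g: 0.90
  n: 1.35
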