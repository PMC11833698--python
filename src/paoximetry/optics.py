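"""Chromophore spectra and tissue optical properties.

This module packages tabulated optical data — molar extinction of oxy-
and deoxyhemoglobin and absorption of water and lipid, 650-1800 nm —
and derives the quantities the rest of the pipeline needs: absorption
and reduced-scattering coefficients of named tissue classes, total
attenuation, the hemoglobin isosbestic point, and the ANSI-style
maximum permissible skin exposure for nanosecond pulses.

Units follow the package convention: wavelengths in nm, optical
coefficients in cm^-1, molar extinction in cm^-1 M^-1, concentrations
in mol/L, geometry elsewhere in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

LN10 = np.log(10.0)

#: Wavelength used by the pipeline for isosbestic normalization.  The
#: packaged table's exact crossing may differ by a few nm; 808 nm is the
#: conventional operating point and is used for all normalizations.
ISOSBESTIC_NM = 808.0

TABLE_RANGE_NM = (650.0, 1800.0)


class WavelengthRangeError(ValueError):
    """Requested wavelength falls outside the packaged table range."""


class IsosbesticAmbiguityError(ValueError):
    """Zero or multiple extinction-difference sign changes in the window."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing set of optical wavelengths (nm) within the
    packaged table range."""

    wavelengths: np.ndarray

    def __init__(self, wavelengths):
        wl = np.asarray(wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1D array")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < TABLE_RANGE_NM[0] or wl[-1] > TABLE_RANGE_NM[1]:
            raise WavelengthRangeError(
                f"grid [{wl[0]}, {wl[-1]}] nm outside table range {TABLE_RANGE_NM}"
            )
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def __contains__(self, wavelength: float) -> bool:
        return bool(np.any(np.isclose(self.wavelengths, wavelength)))

    def index_of(self, wavelength: float) -> int:
        idx = np.flatnonzero(np.isclose(self.wavelengths, wavelength))
        if idx.size == 0:
            raise ValueError(f"{wavelength} nm not a member of this grid")
        return int(idx[0])


class ExtinctionTable:
    """Packaged chromophore spectra with linear interpolation.

    Chromophores: ``HbO2`` and ``Hb`` (molar extinction, cm^-1 M^-1),
    ``water`` and ``lipid`` (absorption coefficient, cm^-1).  Values are
    interpolated linearly between table nodes; requests outside the
    tabulated range raise :class:`WavelengthRangeError` rather than
    extrapolating.
    """

    CHROMOPHORES = ("HbO2", "Hb", "water", "lipid")

    def __init__(self, wavelengths, spectra: dict, provenance: dict | None = None):
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("table grid must be strictly increasing")
        self.spectra = {k: np.asarray(v, dtype=float) for k, v in spectra.items()}
        for name, vals in self.spectra.items():
            if vals.shape != self.wavelengths.shape:
                raise ValueError(f"spectrum {name!r} not congruent with grid")
            if np.any(vals <= 0):
                raise ValueError(f"spectrum {name!r} must be strictly positive")
        self.provenance = dict(provenance or {})

    @classmethod
    def from_package_data(cls) -> "ExtinctionTable":
        """Load the versioned CSVs shipped inside the package."""
        root = resources.files("paoximetry").joinpath("data")
        hb = pd.read_csv(root / "hemoglobin_extinction.csv", comment="#")
        water = pd.read_csv(root / "water_absorption.csv", comment="#")
        lipid = pd.read_csv(root / "lipid_absorption.csv", comment="#")
        wl = hb["wavelength_nm"].to_numpy(float)
        if not (
            np.array_equal(wl, water["wavelength_nm"].to_numpy(float))
            and np.array_equal(wl, lipid["wavelength_nm"].to_numpy(float))
        ):
            raise ValueError("packaged chromophore tables disagree on grid")
        return cls(
            wl,
            {
                "HbO2": hb["eps_HbO2_cm1M1"].to_numpy(float),
                "Hb": hb["eps_Hb_cm1M1"].to_numpy(float),
                "water": water["mu_a_cm1"].to_numpy(float),
                "lipid": lipid["mu_a_cm1"].to_numpy(float),
            },
            provenance={
                "HbO2": "compiled table v1", "Hb": "compiled table v1",
                "water": "compiled table v1", "lipid": "compiled table v1",
            },
        )

    def _check_range(self, wavelength_nm) -> np.ndarray:
        wl = np.asarray(wavelength_nm, dtype=float)
        if np.any(wl < self.wavelengths[0]) or np.any(wl > self.wavelengths[-1]):
            raise WavelengthRangeError(
                f"wavelength {wavelength_nm} nm outside table range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        return wl

    def extinction(self, chromophore: str, wavelength_nm):
        """Piecewise-linear interpolation of a packaged spectrum.

        Exact at table nodes; no extrapolation.
        """
        if chromophore not in self.spectra:
            raise KeyError(f"unknown chromophore {chromophore!r}")
        wl = self._check_range(wavelength_nm)
        out = np.interp(wl, self.wavelengths, self.spectra[chromophore])
        return float(out) if np.isscalar(wavelength_nm) else out


@dataclass(frozen=True)
class TissueOpticalProperties:
    """Single-wavelength optical properties of one medium."""

    mu_a: float      # absorption coefficient, cm^-1
    mu_s: float      # scattering coefficient, cm^-1
    g: float         # scattering anisotropy
    n: float = 1.37  # refractive index

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must be in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_s_prime(self) -> float:
        return self.mu_s * (1.0 - self.g)


@dataclass
class TissueSpec:
    """Parameterization of a named tissue class.

    Absorption is composed from chromophore content:
    ``mu_a = ln(10) * (eps_HbO2 c_HbO2 + eps_Hb c_Hb)
    + f_water mu_a,water + f_lipid mu_a,lipid``;
    reduced scattering follows the power law
    ``mu_s' = a (lambda/500)^(-b)`` with amplitude ``a`` referenced to
    500 nm, and ``mu_s = mu_s'/(1-g)``.
    """

    name: str
    c_hbo2: float = 0.0        # mol/L
    c_hb: float = 0.0          # mol/L
    f_water: float = 0.0       # volume fraction
    f_lipid: float = 0.0       # volume fraction
    musp_500: float = 0.0      # a: reduced scattering at 500 nm, cm^-1
    musp_power: float = 1.0    # b: scattering power-law exponent
    g: float = 0.9
    n: float = 1.37
    extra_mu_a: float = 0.0    # wavelength-flat absorption offset, cm^-1

    def __post_init__(self):
        if self.c_hbo2 < 0 or self.c_hb < 0:
            raise ValueError("chromophore concentrations must be non-negative")
        for f in (self.f_water, self.f_lipid):
            if not 0.0 <= f <= 1.0:
                raise ValueError("volume fractions must lie in [0, 1]")
        if self.musp_500 < 0:
            raise ValueError("scattering amplitude must be non-negative")
        if self.extra_mu_a < 0:
            raise ValueError("extra_mu_a must be non-negative")

    @property
    def c_thb(self) -> float:
        return self.c_hbo2 + self.c_hb

    def with_blood(self, so2: float, c_thb: float) -> "TissueSpec":
        """Copy of this spec with hemoglobin set to the given saturation
        and total concentration (mol/L)."""
        if not 0.0 <= so2 <= 1.0:
            raise ValueError("sO2 must lie in [0, 1]")
        if c_thb < 0:
            raise ValueError("total hemoglobin must be non-negative")
        return TissueSpec(
            name=self.name, c_hbo2=so2 * c_thb, c_hb=(1.0 - so2) * c_thb,
            f_water=self.f_water, f_lipid=self.f_lipid,
            musp_500=self.musp_500, musp_power=self.musp_power,
            g=self.g, n=self.n, extra_mu_a=self.extra_mu_a,
        )


def mu_a_from_spec(spec: TissueSpec, wavelength_nm, table: ExtinctionTable):
    """Absorption coefficient (cm^-1) of a tissue spec at one or more
    wavelengths: hemoglobin terms (Beer's law, ln 10 conversion) plus
    water/lipid background plus any flat offset."""
    eps_o = table.extinction("HbO2", wavelength_nm)
    eps_d = table.extinction("Hb", wavelength_nm)
    mu = LN10 * (eps_o * spec.c_hbo2 + eps_d * spec.c_hb)
    if spec.f_water > 0:
        mu = mu + spec.f_water * table.extinction("water", wavelength_nm)
    if spec.f_lipid > 0:
        mu = mu + spec.f_lipid * table.extinction("lipid", wavelength_nm)
    return mu + spec.extra_mu_a


def reduced_scattering(spec: TissueSpec, wavelength_nm):
    """Reduced scattering coefficient mu_s' (cm^-1) from the power law
    ``a (lambda/500)^(-b)``."""
    wl = np.asarray(wavelength_nm, dtype=float)
    out = spec.musp_500 * (wl / 500.0) ** (-spec.musp_power)
    return float(out) if np.isscalar(wavelength_nm) else out


def scattering_coefficient(spec: TissueSpec, wavelength_nm):
    """mu_s = mu_s'/(1-g); g = 1 is a degenerate anisotropy."""
    if spec.g >= 1.0:
        raise ValueError("g = 1 leaves mu_s undefined (degenerate anisotropy)")
    return reduced_scattering(spec, wavelength_nm) / (1.0 - spec.g)


def total_attenuation(spec: TissueSpec, wavelength_nm, table: ExtinctionTable):
    """mu_a + mu_s' (cm^-1) — the bulk attenuation scale used to compare
    optical windows."""
    return mu_a_from_spec(spec, wavelength_nm, table) + reduced_scattering(
        spec, wavelength_nm
    )


def optical_properties(
    spec: TissueSpec, wavelength_nm: float, table: ExtinctionTable
) -> TissueOpticalProperties:
    """Bundle (mu_a, mu_s, g, n) for one tissue at one wavelength."""
    return TissueOpticalProperties(
        mu_a=float(mu_a_from_spec(spec, wavelength_nm, table)),
        mu_s=float(scattering_coefficient(spec, wavelength_nm)),
        g=spec.g,
        n=spec.n,
    )


def mpe_skin(wavelength_nm: float) -> float:
    """Maximum permissible single-pulse skin exposure (mJ/cm^2) for
    nanosecond pulses, ANSI-style piecewise rule.

    20 mJ/cm^2 for 400-700 nm; 20 * 10^(0.002 (lambda-700)) for
    700-1050 nm; 100 mJ/cm^2 for 1050-1400 nm.  Continuous at both
    branch boundaries.
    """
    wl = float(wavelength_nm)
    if wl < 400.0 or wl > 1400.0:
        raise WavelengthRangeError(
            f"MPE rule supported for 400-1400 nm, got {wl} nm"
        )
    if wl <= 700.0:
        return 20.0
    if wl <= 1050.0:
        return 20.0 * 10.0 ** (0.002 * (wl - 700.0))
    return 100.0


def find_isosbestic(
    table: ExtinctionTable, window_nm: tuple[float, float] = (750.0, 850.0)
) -> float:
    """Locate the oxy/deoxy extinction crossing within a window.

    The root of the linearly interpolated difference is returned.  Zero
    or multiple sign changes raise :class:`IsosbesticAmbiguityError`.
    This is a diagnostic — pipeline normalizations use the configured
    :data:`ISOSBESTIC_NM`.
    """
    lo, hi = window_nm
    table._check_range([lo, hi])
    wl = table.wavelengths
    mask = (wl >= lo) & (wl <= hi)
    # include boundary values so the scan covers the full window
    grid = np.unique(np.concatenate([[lo], wl[mask], [hi]]))
    diff = table.extinction("HbO2", grid) - table.extinction("Hb", grid)
    sign = np.sign(diff)
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if changes.size != 1:
        raise IsosbesticAmbiguityError(
            f"expected exactly one extinction crossing in {window_nm}, "
            f"found {changes.size}"
        )
    i = changes[0]
    x0, x1, y0, y1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def load_tissue_specs(path: str | Path | None = None) -> dict[str, TissueSpec]:
    """Load the named tissue classes from YAML (packaged file by default)."""
    if path is None:
        text = resources.files("paoximetry").joinpath("data/tissues.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    specs = {}
    for name, kv in raw.items():
        specs[name] = TissueSpec(name=name, **kv)
    return specs
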