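"""Linear spectral unmixing of oxy- and deoxyhemoglobin.

The measured amplitude at each wavelength is modeled as
``p0(lambda) = Gamma [eps_HbO2(lambda) c_HbO2 + eps_Hb(lambda) c_Hb]
Phi(lambda)``; with a fluence assumption Phi this is a linear system in
the two concentrations, solved by (non-negative) least squares, and
oxygen saturation follows as ``sO2 = c_HbO2 / (c_HbO2 + c_Hb)``.  The
Grueneisen factor and any overall scale are absorbed into the arbitrary
concentration units, so sO2 is scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .optics import ExtinctionTable
from .preprocess import SpectrumMeasurement


class UndefinedSO2Error(ZeroDivisionError):
    """Total hemoglobin concentration is zero: sO2 is undefined."""


@dataclass(frozen=True)
class WavelengthSet:
    """Named set of unmixing wavelengths (nm)."""

    name: str
    wavelengths: tuple[float, ...]

    def __post_init__(self):
        if len(self.wavelengths) < 2:
            raise ValueError("an unmixing set needs at least two wavelengths")

#: The conventional first-window set.
NIR1 = WavelengthSet("NIR1", (690.0, 808.0, 950.0))
#: The second-window set.
NIR2 = WavelengthSet("NIR2", (1064.0, 1230.0))


@dataclass
class UnmixingResult:
    c_hbo2: float
    c_hb: float
    so2: float | None            # None when total concentration is zero
    residual_norm: float | None  # None for exactly determined systems
    condition_number: float
    wavelength_set: str
    solver: str
    fluence_assumption: str
    clamped: bool = False        # OLS estimate fell outside [0, 1]

    @property
    def defined(self) -> bool:
        return self.so2 is not None


def compute_so2(c_hbo2: float, c_hb: float) -> float:
    """sO2 = c_HbO2 / (c_HbO2 + c_Hb); raises UndefinedSO2Error when the
    total concentration is not positive."""
    total = c_hbo2 + c_hb
    if total <= 0:
        raise UndefinedSO2Error("total hemoglobin concentration is zero")
    return c_hbo2 / total


def design_matrix(
    wset: WavelengthSet,
    table: ExtinctionTable,
    phi: np.ndarray | None = None,
    norm_meta: dict | None = None,
) -> np.ndarray:
    """(n_lambda x 2) model matrix: rows [eps_HbO2 phi, eps_Hb phi].

    ``norm_meta`` carries the measurement's normalization record; an
    isosbestic divisor recorded there is applied to the rows so model
    and data stay commensurate even when the isosbestic wavelength is
    not a member of the set (the NIR-II case).
    """
    wl = np.asarray(wset.wavelengths, dtype=float)
    if phi is None:
        phi = np.ones_like(wl)
    else:
        phi = np.asarray(phi, dtype=float)
        if phi.shape != wl.shape:
            raise ValueError("fluence vector must match the wavelength set")
        if np.any(phi <= 0):
            raise ValueError("fluence must be positive")
    a = np.column_stack([
        table.extinction("HbO2", wl) * phi,
        table.extinction("Hb", wl) * phi,
    ])
    if norm_meta and "iso_divisor" in norm_meta:
        a = a / float(norm_meta["iso_divisor"])
    return a


def _solve(a: np.ndarray, y: np.ndarray, solver: str):
    if solver == "nnls":
        c, rnorm = nnls(a, y)
        return c, rnorm, False
    if solver == "ols":
        c, *_ = np.linalg.lstsq(a, y, rcond=None)
        rnorm = float(np.linalg.norm(a @ c - y))
        return c, rnorm, True
    raise ValueError(f"unknown solver {solver!r}")


def linear_unmix(
    s: SpectrumMeasurement,
    wset: WavelengthSet,
    table: ExtinctionTable,
    phi: np.ndarray | None = None,
    solver: str = "nnls",
    fluence_assumption: str = "flat",
) -> UnmixingResult:
    """Unmix an ROI spectrum into relative chromophore concentrations.

    The measurement must cover every member of the set.  With the
    default non-negative solver, concentrations are >= 0 and sO2 lies in
    [0, 1]; the ordinary solver reports unconstrained estimates with
    sO2 clamped to [0, 1] and the clamp flagged.
    """
    idx = [s.grid.index_of(w) for w in wset.wavelengths]
    y = s.mean[idx]
    if np.all(y == 0):
        raise ValueError("all-zero spectrum cannot be unmixed")
    a = design_matrix(wset, table, phi, s.meta)
    if np.linalg.matrix_rank(a) < 2:
        raise ValueError("design matrix is rank deficient")
    cond = float(np.linalg.cond(a))
    c, rnorm, unconstrained = _solve(a, y, solver)
    clamped = False
    try:
        so2 = compute_so2(float(c[0]), float(c[1]))
    except UndefinedSO2Error:
        so2 = None
    if so2 is not None and unconstrained:
        if so2 < 0.0 or so2 > 1.0:
            clamped = True
            so2 = float(np.clip(so2, 0.0, 1.0))
    exactly_determined = len(idx) == 2 and solver == "nnls" and np.all(c > 0)
    return UnmixingResult(
        c_hbo2=float(c[0]),
        c_hb=float(c[1]),
        so2=so2,
        residual_norm=None if len(idx) == 2 else float(rnorm),
        condition_number=cond,
        wavelength_set=wset.name,
        solver=solver,
        fluence_assumption=fluence_assumption,
        clamped=clamped,
    )


def unmix_image(
    stack,
    wset: WavelengthSet,
    table: ExtinctionTable,
    phi_map: np.ndarray | None = None,
    solver: str = "nnls",
):
    """Pixelwise unmixing of a frame-averaged stack.

    ``phi_map`` is an optional (n_set_wavelengths, z, x) fluence map
    congruent with the stack.  Returns (so2_map, c_hbo2_map, c_hb_map);
    pixels with zero total concentration are NaN in the sO2 map.
    """
    mean = stack.frame_mean()
    idx = [stack.grid.index_of(w) for w in wset.wavelengths]
    sub = mean[idx]  # (n_set, z, x)
    nz, nx = sub.shape[1:]
    if phi_map is not None:
        phi_map = np.asarray(phi_map, dtype=float)
        if phi_map.shape != sub.shape:
            raise ValueError("fluence map not congruent with the stack")
    base = design_matrix(wset, table)
    so2_map = np.full((nz, nx), np.nan)
    c_o = np.zeros((nz, nx))
    c_d = np.zeros((nz, nx))
    for i in range(nz):
        for j in range(nx):
            y = sub[:, i, j]
            if not np.any(y > 0):
                continue
            if phi_map is not None:
                a = base * phi_map[:, i, j][:, None]
            else:
                a = base
            c, _, unconstrained = _solve(a, y, solver)
            c_o[i, j], c_d[i, j] = c
            total = c[0] + c[1]
            if total > 0:
                val = c[0] / total
                so2_map[i, j] = np.clip(val, 0.0, 1.0) if unconstrained else val
    return so2_map, c_o, c_d
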