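"""From image stacks to normalized per-ROI spectra.

The measurement chain mirrors the experimental analysis: average the
pixels inside a region of interest, average across repeated frames,
divide by the modeled local fluence, and normalize at the hemoglobin
isosbestic point so runs are comparable.  Fluence correction is always
applied before isosbestic normalization; every normalization step is
recorded append-only in the measurement metadata so the unmixing design
matrix can be transformed identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import ISOSBESTIC_NM, WavelengthGrid
from .synth import PAImageStack


@dataclass(frozen=True)
class ROIMask:
    """2D boolean mask aligned to the stack's (z, x) plane."""

    mask: np.ndarray
    label: str = "roi"
    depth_mm: float | None = None

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("ROI mask must be 2D with at least one pixel")
        object.__setattr__(self, "mask", m)

    def subtract(self, exclusion: np.ndarray) -> "ROIMask":
        """Remove artifact pixels (e.g. an out-of-plane bubble) from the ROI."""
        out = self.mask & ~np.asarray(exclusion, dtype=bool)
        return ROIMask(out, label=self.label, depth_mm=self.depth_mm)


@dataclass
class SpectrumMeasurement:
    """ROI-averaged amplitude spectrum with frame scatter and an
    append-only record of applied normalizations."""

    grid: WavelengthGrid
    mean: np.ndarray
    frame_sd: np.ndarray
    state: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.frame_sd = np.asarray(self.frame_sd, dtype=float)
        if self.mean.shape != (len(self.grid),) or self.frame_sd.shape != self.mean.shape:
            raise ValueError("spectrum arrays not congruent with the grid")
        self.meta.setdefault("history", [])

    def _derive(self, mean, sd, state, note: dict) -> "SpectrumMeasurement":
        meta = {k: v for k, v in self.meta.items() if k != "history"}
        meta.update(note)
        meta["history"] = list(self.meta["history"]) + [state]
        return SpectrumMeasurement(self.grid, mean, sd, state=state, meta=meta)


def roi_spectrum(stack: PAImageStack, roi: ROIMask) -> SpectrumMeasurement:
    """Average a stack over ROI pixels, then over frames.

    The per-wavelength standard deviation across frame means is
    retained as the frame scatter.
    """
    nz, nx = stack.data.shape[2:]
    if roi.mask.shape != (nz, nx):
        raise ValueError("ROI not aligned to the stack plane")
    per_frame = stack.data[:, :, roi.mask].mean(axis=2)  # (wavelength, frame)
    return SpectrumMeasurement(
        grid=stack.grid,
        mean=per_frame.mean(axis=1),
        frame_sd=per_frame.std(axis=1, ddof=0),
        state="raw",
        meta={"roi": roi.label, "roi_depth_mm": roi.depth_mm,
              "roi_pixels": int(roi.mask.sum()), "history": []},
    )


def fluence_correct(s: SpectrumMeasurement, phi: np.ndarray,
                    source: str = "model") -> SpectrumMeasurement:
    """Divide the spectrum by a per-wavelength local fluence estimate.

    Must precede isosbestic normalization (the pipeline convention);
    non-positive fluence values are rejected.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (len(s.grid),):
        raise ValueError("fluence vector not congruent with the grid")
    if np.any(phi <= 0):
        raise ValueError("fluence must be positive at every wavelength")
    if s.state == "isosbestic":
        raise ValueError(
            "fluence correction must be applied before isosbestic normalization"
        )
    return s._derive(s.mean / phi, s.frame_sd / phi, "fluence_corrected",
                     {"fluence_source": source})


def isosbestic_normalize(
    s: SpectrumMeasurement, iso_nm: float = ISOSBESTIC_NM
) -> SpectrumMeasurement:
    """Normalize a spectrum to unit amplitude at the isosbestic point.

    ``iso_nm`` must be an exact grid member (no interpolation), with a
    positive amplitude there.  The divisor is carried in the metadata so
    the unmixing design matrix can be scaled identically — including
    when the unmixing set does not contain the isosbestic wavelength.
    Idempotent.
    """
    idx = s.grid.index_of(iso_nm)
    divisor = s.mean[idx]
    if divisor <= 0:
        raise ValueError(f"amplitude at {iso_nm} nm is not positive")
    out = s._derive(s.mean / divisor, s.frame_sd / divisor, "isosbestic",
                    {"iso_nm": float(iso_nm)})
    # cumulative divisor across repeated normalizations
    out.meta["iso_divisor"] = s.meta.get("iso_divisor", 1.0) * float(divisor)
    return out


def absorption_normalize_pair(
    s: SpectrumMeasurement, reference_mu_a: np.ndarray,
    iso_nm: float = ISOSBESTIC_NM,
):
    """Scale a measured spectrum and a reference absorption spectrum to 1
    at the isosbestic point for shape comparison.

    Returns ``(s_scaled, ref_scaled, residual)`` where the residual is
    the per-wavelength difference of the two unit-scaled shapes.
    """
    ref = np.asarray(reference_mu_a, dtype=float)
    if ref.shape != (len(s.grid),):
        raise ValueError("reference spectrum not congruent with the grid")
    idx = s.grid.index_of(iso_nm)
    if ref[idx] <= 0:
        raise ValueError(f"reference amplitude at {iso_nm} nm is not positive")
    s_norm = isosbestic_normalize(s, iso_nm)
    ref_scaled = ref / ref[idx]
    return s_norm, ref_scaled, s_norm.mean - ref_scaled
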