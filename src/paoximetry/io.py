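"""File I/O and pipeline orchestration.

Arrays (image stacks, fluence maps) persist to NPZ with a JSON-encoded
metadata payload; spectra to CSV; reports and manifests to JSON.  Every
write-then-read round-trip is the identity for payload and metadata.
``run_pipeline`` drives simulate -> preprocess -> unmix -> evaluate
from a single YAML/JSON config and writes a checksummed manifest so a
bundle is reproducible from config plus seed alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fluence import FluenceMap
from .optics import WavelengthGrid
from .preprocess import SpectrumMeasurement
from .synth import PAImageStack

_SCHEMA_VERSION = 1


class FileIntegrityError(IOError):
    """Persisted artifact is unreadable or structurally inconsistent."""


def _meta_json(meta: dict) -> str:
    return json.dumps(meta, default=lambda o: (
        o.tolist() if isinstance(o, np.ndarray) else str(o)))


def save_stack(path, stack: PAImageStack) -> None:
    np.savez_compressed(
        path,
        data=stack.data,
        wavelengths=stack.grid.wavelengths,
        voxel_mm=stack.voxel_mm,
        provenance=_meta_json(stack.provenance),
        schema=_SCHEMA_VERSION,
        **({"fluence_mid": stack.fluence_mid}
           if stack.fluence_mid is not None else {}),
    )


def load_stack(path) -> PAImageStack:
    try:
        with np.load(path, allow_pickle=False) as f:
            schema = int(f["schema"])
            if schema > _SCHEMA_VERSION:
                raise FileIntegrityError(
                    f"{path}: written by a newer schema ({schema})")
            return PAImageStack(
                data=f["data"],
                grid=WavelengthGrid(f["wavelengths"]),
                voxel_mm=float(f["voxel_mm"]),
                provenance=json.loads(str(f["provenance"])),
                fluence_mid=f["fluence_mid"] if "fluence_mid" in f else None,
            )
    except FileIntegrityError:
        raise
    except Exception as exc:
        raise FileIntegrityError(f"cannot read PA stack from {path}: {exc}") from exc


def save_fluence_map(path, fmap: FluenceMap) -> None:
    np.savez_compressed(
        path,
        values=fmap.values,
        valid=fmap.valid,
        wavelength_nm=fmap.wavelength_nm,
        voxel_mm=fmap.voxel_mm,
        ledger=_meta_json(fmap.ledger),
        schema=_SCHEMA_VERSION,
    )


def load_fluence_map(path) -> FluenceMap:
    try:
        with np.load(path, allow_pickle=False) as f:
            return FluenceMap(
                values=f["values"],
                valid=f["valid"],
                wavelength_nm=float(f["wavelength_nm"]),
                voxel_mm=float(f["voxel_mm"]),
                ledger=json.loads(str(f["ledger"])),
            )
    except Exception as exc:
        raise FileIntegrityError(f"cannot read fluence map from {path}: {exc}") from exc


def save_spectrum_csv(path, s: SpectrumMeasurement) -> None:
    """CSV with '#' metadata comments and header wavelength_nm,mean,sd,state."""
    with open(path, "w") as f:
        f.write(f"# paoximetry {__version__} spectrum\n")
        f.write(f"# state: {s.state}\n")
        for key in ("roi", "iso_nm", "iso_divisor", "fluence_source"):
            if key in s.meta:
                f.write(f"# {key}: {s.meta[key]}\n")
        f.write("wavelength_nm,mean,sd,state\n")
        for wl, m, sd in zip(s.grid.wavelengths, s.mean, s.frame_sd):
            f.write(f"{wl},{m:.17g},{sd:.17g},{s.state}\n")


def load_spectrum_csv(path) -> SpectrumMeasurement:
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    required = {"wavelength_nm", "mean", "sd"}
    if not required <= set(df.columns):
        raise FileIntegrityError(f"{path}: missing columns {required - set(df.columns)}")
    df = df.sort_values("wavelength_nm")
    state = str(df["state"].iloc[0]) if "state" in df else meta.get("state", "raw")
    out_meta = {"history": []}
    if "iso_divisor" in meta:
        out_meta["iso_divisor"] = float(meta["iso_divisor"])
    if "iso_nm" in meta:
        out_meta["iso_nm"] = float(meta["iso_nm"])
    return SpectrumMeasurement(
        grid=WavelengthGrid(df["wavelength_nm"].to_numpy(float)),
        mean=df["mean"].to_numpy(float),
        frame_sd=df["sd"].to_numpy(float),
        state=state,
        meta=out_meta,
    )


def report_to_dict(report) -> dict:
    return {
        "schema": _SCHEMA_VERSION,
        "version": __version__,
        "summary": report.summary,
        "anova": report.anova,
        "seeds": report.seeds,
        "config": report.config,
        "errors": report.errors.to_dict(orient="records"),
        "estimates": report.estimates.to_dict(orient="records"),
    }


def save_report(path, report) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2,
                                     default=float))


def save_error_table_csv(path, report) -> None:
    """Long-format error table: set, roi, replicate, total_error_pct."""
    report.errors.to_csv(path, index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run a configured experiment end to end and write an artifact
    bundle with a checksummed manifest.

    The config is a dictionary (or a YAML/JSON path) with keys
    ``experiment`` ("phantom" | "depth") and any
    :class:`~paoximetry.evaluate.ExperimentConfig` field.  Unknown keys
    are reported as schema errors naming the field.
    """
    from .evaluate import (ExperimentConfig, run_depth_experiment,
                           run_phantom_experiment)

    if not isinstance(config, dict):
        config = load_config(config)
    cfg = dict(config)
    experiment = cfg.pop("experiment", "phantom")
    if experiment not in ("phantom", "depth"):
        raise ValueError(f"config field 'experiment': unknown value {experiment!r}")
    allowed = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(
            "unknown config field(s): " + ", ".join(sorted(unknown)))
    for key in ("wavelengths", "analysis_regions"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = tuple(cfg[key])
    ecfg = ExperimentConfig(**cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = run_phantom_experiment if experiment == "phantom" else run_depth_experiment
    report = runner(ecfg)
    save_report(out / "report.json", report)
    save_error_table_csv(out / "errors.csv", report)
    chash = config_hash({"experiment": experiment, **cfg})
    manifest = {
        "version": __version__,
        "config_hash": chash,
        "seed": ecfg.base_seed,
        "outputs": {
            name: file_sha256(out / name)
            for name in ("report.json", "errors.csv")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
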