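"""Fluence penetration: scattering versus absorption across windows.

Monte Carlo fluence at 10 mm depth in porcine muscle at 690, 808 and
1064 nm.  Despite higher water absorption, the reduced scattering of
the second window delivers more light at depth.  Writes
results/fluence_penetration.json.
"""

import json
from pathlib import Path

import numpy as np

from paoximetry.fluence import BeamSpec, MCConfig, VoxelPhantom, fluence_spectrum
from paoximetry.optics import ExtinctionTable, load_tissue_specs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = ExtinctionTable.from_package_data()
    pork = load_tissue_specs()["porcine_muscle"]
    labels = np.zeros((60, 30, 30), np.int32)  # 12 mm deep, 0.2 mm voxels
    phantom = VoxelPhantom(labels, 0.2, {0: pork})
    beam = BeamSpec(1.3, 1.0)
    roi = np.zeros((60, 30, 30), bool)
    roi[48:53, 10:20, 10:20] = True  # ~10 mm depth block, on axis

    wavelengths = [690.0, 808.0, 1064.0]
    phi = fluence_spectrum(phantom, beam, wavelengths, roi,
                           MCConfig(n_photons=400_000, seed=11), table,
                           mode="mc")
    out = {f"phi_at_10mm_{int(w)}nm": v for w, v in zip(wavelengths, phi)}
    out["ratio_1064_over_690"] = phi[2] / phi[0] if phi[0] > 0 else float("inf")
    OUT.mkdir(exist_ok=True)
    (OUT / "fluence_penetration.json").write_text(json.dumps(out, indent=2))
    for k, v in out.items():
        print(f"{k}: {v:.3g}")
    print(f"\n1064 nm delivers {out['ratio_1064_over_690']:.1f}x the "
          "690 nm fluence at 10 mm depth in porcine muscle: reduced "
          "scattering outweighs the increased water absorption.")


if __name__ == "__main__":
    main()
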