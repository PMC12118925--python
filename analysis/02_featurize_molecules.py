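"""Featurize a synthetic study into the three molecular representations.

Vibrational spectra are Gaussian-smoothed onto an 800-bin bounded frequency
scale, mass spectra are windowed to 213 integer m/z bins (50-262), and
SMILES become 1024-bit path fingerprints; fusion is plain concatenation.

Writes results/feature_shapes.json and results/mean_spectra.csv; the full
feature matrices are large and go under scratch/ only.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from odorml import SmoothingConfig, SynthConfig, fuse_features, smiles_to_fingerprint
from odorml.featurize import smooth_vibrational, window_mass_spectrum
from odorml.synth import generate_study

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

cfg = SynthConfig(n_molecules=400, n_labels=30, cardinality_target=2.5, seed=2024)
study = generate_study(cfg)

smoothing = SmoothingConfig()  # sigma 10 cm^-1, L 5 cm^-1, BFS 1-4000
VS = np.vstack([smooth_vibrational(p, smoothing).values for p in study.vs_peaks])
MS = np.vstack([window_mass_spectrum(p).values for p in study.ms_peaks])
FP = np.vstack([smiles_to_fingerprint(s) for s in study.smiles])
fused, slices = fuse_features([VS, MS, FP])

shapes = {
    "vs_bins": VS.shape[1],
    "ms_bins": MS.shape[1],
    "fp_bits": FP.shape[1],
    "fused_width": fused.shape[1],
    "n_molecules": fused.shape[0],
}
(OUT / "feature_shapes.json").write_text(json.dumps(shapes, indent=1))

ms_grid = window_mass_spectrum(study.ms_peaks[0]).grid
pd.DataFrame(
    {
        "vs_wavenumber": smoothing.grid,
        "vs_mean_intensity": VS.mean(0),
    }
).to_csv(OUT / "mean_spectra.csv", index=False)
pd.DataFrame({"mz": ms_grid, "ms_mean_intensity": MS.mean(0)}).to_csv(
    OUT / "mean_mass_spectrum.csv", index=False
)

scratch = ROOT / "scratch"
scratch.mkdir(exist_ok=True)
np.save(scratch / "fused_features.npy", fused)

print("Feature shapes:", shapes)
print(
    f"\nFinding: VS gives {shapes['vs_bins']} descriptors (4000/L at "
    f"L=5 cm^-1), MS gives {shapes['ms_bins']} (inclusive 50-262 m/z), "
    f"fingerprints {shapes['fp_bits']} bits; fused width "
    f"{shapes['fused_width']}."
)
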