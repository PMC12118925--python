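"""Quantify label imbalance and the effect of random resampling on it.

Reproduces the imbalance-table design of the study: Card, Dens, CVIR,
MaxIR, MeanIR for the original label matrix and after ML-RUS / ML-ROS at
10%, 20% and 30%.

Writes results/imbalance_table.csv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from odorml import MultiLabelDataset, SynthConfig
from odorml.imbalance import imbalance_report
from odorml.resampling import ResampleConfig, resample
from odorml.synth import generate_label_matrix

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = SynthConfig(seed=2024)
Y = generate_label_matrix(cfg)
D = MultiLabelDataset(X=np.zeros((cfg.n_molecules, 1)), Y=Y)

rows = [{"method": "original", "n": D.n_instances, **imbalance_report(D.Y).to_dict()}]
for mode in ("RUS", "ROS"):
    for pct in (10, 20, 30):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            out = resample(D, ResampleConfig(mode=mode, percentage=pct, seed=7))
        rows.append(
            {
                "method": f"ML-{mode} ({pct}%)",
                "n": out.n_instances,
                **imbalance_report(out.Y).to_dict(),
            }
        )

table = pd.DataFrame(rows).drop(columns="n_labels_excluded").round(3)
table.to_csv(OUT / "imbalance_table.csv", index=False)
print(table.to_string(index=False))

base = rows[0]
ros10 = next(r for r in rows if r["method"] == "ML-ROS (10%)")
print(
    f"\nFinding: ML-ROS at 10% lowers MeanIR from {base['MeanIR']:.2f} to "
    f"{ros10['MeanIR']:.2f} and CVIR from {base['CVIR']:.3f} to "
    f"{ros10['CVIR']:.3f} while Card/Dens stay essentially unchanged — the "
    "direction expected when cloning minority-label molecules."
)
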