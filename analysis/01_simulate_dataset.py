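"""Generate the synthetic odor study and check its label statistics.

Emulates the published dataset structure: ~2600 molecules x 109 odor
labels, head label ~27%, tail <1%, ~3.16 labels/molecule.  Also draws a
random half of the molecules and runs the two-sample K-S test between the
full and subset per-label proportions — the check used to argue a subset is
representative of its parent dataset.

Writes results/label_statistics.csv and results/dataset_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from odorml import SynthConfig
from odorml.evaluation import ks_compare, label_proportions
from odorml.imbalance import imbalance_report
from odorml.synth import generate_label_matrix

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = SynthConfig(seed=2024)  # defaults are the study conditions
Y = generate_label_matrix(cfg)
props = label_proportions(Y)

rng = np.random.default_rng(2024)
half = rng.choice(cfg.n_molecules, size=cfg.n_molecules // 2, replace=False)
props_half = label_proportions(Y[half])
D, p = ks_compare(props, props_half)

rep = imbalance_report(Y)
summary = {
    "n_molecules": cfg.n_molecules,
    "n_labels": cfg.n_labels,
    **{k: round(v, 4) for k, v in rep.to_dict().items()},
    "head_frequency": round(float(props[0]), 4),
    "tail_frequency": round(float(props[-1]), 4),
    "ks_full_vs_half_D": round(D, 4),
    "ks_full_vs_half_p": round(p, 4),
}
(OUT / "dataset_summary.json").write_text(json.dumps(summary, indent=1))

pd.DataFrame(
    {
        "label_rank": np.arange(cfg.n_labels),
        "proportion_full": props,
        "proportion_half_subset": props_half,
        "irlbl": rep.irlbl,
    }
).to_csv(OUT / "label_statistics.csv", index=False)

print("Synthetic study label statistics")
for k, v in summary.items():
    print(f"  {k}: {v}")
print(
    "\nFinding: the generated labels reproduce the long-tail structure "
    f"(head {summary['head_frequency']:.0%}, tail {summary['tail_frequency']:.1%}, "
    f"Card {summary['Card']}), and a random half-subset is statistically "
    f"indistinguishable from the full set (K-S D={D:.3f}, p={p:.2f})."
)
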