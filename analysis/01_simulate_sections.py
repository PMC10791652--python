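"""Generate a synthetic immunofluorescence dataset with known ground truth.

Writes dual-channel section TIFFs and matching islet-mask TIFFs (binary
large files, kept under scratch/) plus the ground-truth JSON the later
steps compare against.

Run from the repository root:  python analysis/01_simulate_sections.py
"""

import json
from pathlib import Path

from isletquant.pipeline import RunConfig, run_simulate

OUT = Path("scratch/simulated_dataset")

config = RunConfig(
    mode="simulate",
    output_dir=str(OUT),
    seed=1,
    n_sections=3,  # three sections of one synthetic animal
)
run_simulate(config)

truth = json.loads((OUT / "ground_truth.json").read_text())
total = sum(t["n_islets"] for t in truth)
print(f"wrote {len(truth)} sections to {OUT}")
print(f"total islets placed: {total}")
for t in truth:
    print(
        f"  section {t['section']}: {t['n_islets']} islets, "
        f"true pooled beta-cell {t['true_beta_percent_pooled']:.2f}%, "
        f"size classes {t['true_counts_by_class']}"
    )
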