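"""Measure the simulated sections and compare against ground truth.

Runs the full morphometry pipeline (color correction, per-islet Otsu/Kapur
segmentation, area and diameter measurement, per-animal pooling) on the
dataset from step 01 and writes the per-islet and per-animal CSVs under
results/. Requires analysis/01_simulate_sections.py to have been run.

Run from the repository root:  python analysis/02_measure_morphometry.py
"""

import json
from pathlib import Path

import pandas as pd

from isletquant.pipeline import RunConfig, run_measure

SIM = Path("scratch/simulated_dataset")
OUT = Path("results/morphometry")

run_measure(
    RunConfig(mode="measure", input_dir=str(SIM), output_dir=str(OUT)),
    animal_id="synthetic-animal-1",
)

truth = json.loads((SIM / "ground_truth.json").read_text())
true_total = sum(t["n_islets"] for t in truth)
true_beta = [t["true_beta_percent_pooled"] for t in truth]

islets = pd.read_csv(OUT / "islets.csv")
summary = pd.read_csv(OUT / "summary.csv").iloc[0]

print(f"measured {len(islets)} islets (truth: {true_total})")
print(
    f"pooled beta-cell area: {summary.beta_cell_percent:.2f}% "
    f"(per-section truths: {', '.join(f'{b:.2f}%' for b in true_beta)})"
)
print(
    f"size classes: {int(summary.n_small_islets)} small (<100 um), "
    f"{int(summary.n_large_islets)} large"
)
print(f"mean islet area: {summary.mean_islet_area_um2:.0f} um^2")
print(f"tables written to {OUT}")
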