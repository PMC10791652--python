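"""End-to-end runs: simulate a dataset, measure sections, normalize assays.

Every run echoes its full configuration (including defaults) plus the
package version into a ``manifest.json`` next to the outputs, so results are
self-describing and reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from isletquant.assays import fit_dose_response, fold_over_basal, stimulation_index
from isletquant.image_io import (
    FluorescenceSection,
    IsletRegionSet,
    read_islet_masks,
    read_section_image,
    write_mask_tiff,
    write_measurements,
    write_section_tiff,
)
from isletquant.morphometry import (
    IsletMeasurement,
    measure_islet,
    summarize_pancreas,
)
from isletquant.segmentation import segment_islet_region
from isletquant.synthetic import IsletImageParams, generate_islet_image

logger = logging.getLogger("isletquant")

__all__ = ["RunConfig", "measure_section", "run_simulate", "run_measure", "run_assay"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run; every tunable that affects output."""

    mode: str = "measure"  # measure | simulate | assay
    input_dir: str | None = None
    output_dir: str = "isletquant_out"
    pixel_size_um: float = 0.65
    connectivity: int = 8
    n_bins: int = 256
    size_cutoff_um: float = 100.0
    index_mode: str = "total"  # total | lysate
    basal_condition: str = "basal"
    fix_bottom: float | None = None
    seed: int = 0
    # simulate-only knobs (defaults mirror IsletImageParams)
    n_sections: int = 1
    simulate_params: dict = dataclasses.field(default_factory=dict)
    # assay-only inputs
    secretion_csv: str | None = None
    dose_response_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_manifest(out_dir: Path, config: RunConfig, extra: dict | None = None) -> None:
    from isletquant import __version__

    manifest = {"isletquant_version": __version__, "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def measure_section(
    section: FluorescenceSection,
    regions: IsletRegionSet,
    n_bins: int = 256,
    size_cutoff_um: float = 100.0,
) -> list[IsletMeasurement]:
    """Segment and measure every islet region of one section."""
    measurements = []
    for rid in regions.region_ids:
        seg = segment_islet_region(section, regions, rid, n_bins=n_bins)
        if seg.degenerate_flags:
            logger.warning(
                "region %d degenerate: %s", rid, ", ".join(sorted(seg.degenerate_flags))
            )
        measurements.append(
            measure_islet(
                seg,
                regions,
                pixel_size_um=section.pixel_size_um,
                section=section,
                size_cutoff_um=size_cutoff_um,
            )
        )
    return measurements


def run_simulate(config: RunConfig) -> Path:
    """Write a synthetic dataset (sections, masks, ground truth, manifest)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_records = []
    for i in range(config.n_sections):
        params = IsletImageParams(
            pixel_size_um=config.pixel_size_um,
            seed=config.seed + i,
            **config.simulate_params,
        )
        section, mask, truth = generate_islet_image(params)
        write_section_tiff(out_dir / f"section_{i:02d}.tif", section)
        write_mask_tiff(out_dir / f"mask_{i:02d}.tif", mask)
        truth_records.append(
            {
                "section": i,
                "n_islets": truth.n_islets,
                "true_beta_percent_pooled": truth.true_beta_percent_pooled,
                "true_counts_by_class": truth.true_counts_by_class,
                "true_beta_fraction_per_islet": {
                    str(k): v for k, v in truth.true_beta_fraction_per_islet.items()
                },
                "params": params.to_dict(),
            }
        )
        logger.info("simulated section %d: %d islets", i, truth.n_islets)
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth_records, indent=2, sort_keys=True) + "\n"
    )
    _write_manifest(out_dir, config)
    return out_dir


def _find_pairs(input_dir: Path) -> list[tuple[Path, Path]]:
    sections = sorted(input_dir.glob("section_*.tif"))
    pairs = []
    for sec_path in sections:
        mask_path = input_dir / sec_path.name.replace("section_", "mask_")
        if not mask_path.exists():
            raise FileNotFoundError(f"no mask found for {sec_path.name}")
        pairs.append((sec_path, mask_path))
    return pairs


def run_measure(config: RunConfig, animal_id: str = "animal") -> Path:
    """Measure all section/mask pairs under ``config.input_dir``.

    Writes ``islets.csv`` (one row per islet, thresholds included),
    ``summary.csv`` (per-animal aggregate) and ``manifest.json``. Fails fast
    on a mismatched pair, removing partial outputs.
    """
    if config.input_dir is None:
        raise ValueError("run_measure requires input_dir")
    input_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    islets_csv = out_dir / "islets.csv"
    summary_csv = out_dir / "summary.csv"

    measurements: list[IsletMeasurement] = []
    try:
        for i, (sec_path, mask_path) in enumerate(_find_pairs(input_dir)):
            section = read_section_image(
                sec_path,
                pixel_size_um=config.pixel_size_um,
                animal_id=animal_id,
                series_index=i,
            )
            try:
                regions = read_islet_masks(
                    mask_path, section, connectivity=config.connectivity
                )
            except ValueError as exc:
                raise ValueError(f"{mask_path.name}: {exc}") from exc
            logger.info("section %s: %d islet regions", sec_path.name, regions.n_regions)
            measurements.extend(
                measure_section(
                    section,
                    regions,
                    n_bins=config.n_bins,
                    size_cutoff_um=config.size_cutoff_um,
                )
            )
        write_measurements(measurements, islets_csv)
        write_measurements([summarize_pancreas(measurements, animal_id)], summary_csv)
        _write_manifest(out_dir, config, {"n_islets_measured": len(measurements)})
    except Exception:
        for path in (islets_csv, summary_csv, out_dir / "manifest.json"):
            path.unlink(missing_ok=True)
        raise
    return out_dir


def run_assay(config: RunConfig) -> Path:
    """Normalize tabular assay data: folds, stimulation indices, 4PL fit."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.secretion_csv is not None:
        frame = pd.read_csv(config.secretion_csv)
        from isletquant.assays import SecretionSample

        samples = [
            SecretionSample(
                condition=str(r.condition),
                secreted_ng_ml=float(r.secreted_ng_ml),
                content_ng_ml=(
                    float(r.content_ng_ml) if pd.notna(r.content_ng_ml) else None
                ),
                replicate=int(getattr(r, "replicate", 0)),
                animal_or_prep_id=str(getattr(r, "animal_or_prep_id", "")),
            )
            for r in frame.itertuples(index=False)
        ]
        folds = fold_over_basal(samples, config.basal_condition)
        out = frame.copy()
        out["fold_over_basal"] = folds
        out["stimulation_index_percent"] = [
            (
                stimulation_index(s.secreted_ng_ml, s.content_ng_ml, config.index_mode)
                if s.content_ng_ml is not None
                else np.nan
            )
            for s in samples
        ]
        out.to_csv(out_dir / "secretion_normalized.csv", index=False, float_format="%.9g")

    if config.dose_response_csv is not None:
        dr = pd.read_csv(config.dose_response_csv)
        fit = fit_dose_response(
            dr["dose_uM"].to_numpy(),
            dr["response"].to_numpy(),
            fix_bottom=config.fix_bottom,
        )
        (out_dir / "dose_response_fit.json").write_text(
            json.dumps(dataclasses.asdict(fit), indent=2, sort_keys=True) + "\n"
        )

    _write_manifest(out_dir, config)
    return out_dir
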