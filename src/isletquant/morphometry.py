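"""Per-islet morphometry and per-animal aggregation.

Areas are pixel counts scaled by ``pixel_size_um**2``. The islet "diameter"
is the equivalent-circle diameter ``d = 2 * sqrt(A / pi)`` — deterministic
and orientation-free — and islets are classed small when ``d < cutoff``
(default 100 µm, strict inequality: an islet of exactly 100 µm is large).

Per-animal beta/delta-cell percentages are POOLED, area-weighted ratios
(total hormone-positive area over total islet area across all the animal's
sections), not means of per-islet percentages.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from isletquant.image_io import FluorescenceSection, IsletRegionSet
from isletquant.segmentation import SegmentationResult

__all__ = [
    "IsletMeasurement",
    "PancreasSummary",
    "measure_islet",
    "classify_islet_size",
    "summarize_pancreas",
    "equivalent_diameter_um",
]

SIZE_CUTOFF_UM_DEFAULT = 100.0


@dataclasses.dataclass
class IsletMeasurement:
    """Areas, thresholds and size class of one islet region."""

    animal_id: str
    series_index: int
    islet_id: int
    area_um2: float
    insulin_area_um2: float
    sst_area_um2: float
    otsu_threshold: float | None
    kapur_threshold: float | None
    equiv_diameter_um: float
    size_class: str
    touches_border: bool

    def __post_init__(self) -> None:
        if self.area_um2 < 0:
            raise ValueError("area_um2 must be non-negative")
        if self.insulin_area_um2 > self.area_um2 + 1e-9:
            raise ValueError("insulin area exceeds islet area")
        if self.sst_area_um2 > self.area_um2 + 1e-9:
            raise ValueError("somatostatin area exceeds islet area")


@dataclasses.dataclass
class PancreasSummary:
    """Per-animal aggregate over all analyzed sections.

    ``beta_cell_percent`` is 100 * (total insulin-positive area) / (total
    islet area); None when the animal has no islets.
    """

    animal_id: str
    n_islets: int
    total_islet_area_um2: float
    mean_islet_area_um2: float | None
    beta_cell_percent: float | None
    delta_cell_percent: float | None
    n_small_islets: int
    n_large_islets: int


def equivalent_diameter_um(area_um2: float) -> float:
    """Diameter of the circle with the given area: 2 * sqrt(A / pi)."""
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def classify_islet_size(
    equiv_diameter_um: float, cutoff_um: float = SIZE_CUTOFF_UM_DEFAULT
) -> str:
    """"small" iff diameter < cutoff (strict); otherwise "large"."""
    if cutoff_um <= 0:
        raise ValueError("cutoff_um must be positive")
    return "small" if equiv_diameter_um < cutoff_um else "large"


def _touches_border(region_mask: np.ndarray, bbox: tuple[slice, slice], shape) -> bool:
    r, c = bbox
    h, w = shape
    if r.start == 0 and region_mask[0].any():
        return True
    if r.stop == h and region_mask[-1].any():
        return True
    if c.start == 0 and region_mask[:, 0].any():
        return True
    if c.stop == w and region_mask[:, -1].any():
        return True
    return False


def measure_islet(
    seg: SegmentationResult,
    regions: IsletRegionSet,
    pixel_size_um: float,
    section: FluorescenceSection | None = None,
    size_cutoff_um: float = SIZE_CUTOFF_UM_DEFAULT,
) -> IsletMeasurement:
    """Convert one islet's segmentation into physical-unit measurements."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    region_mask = regions.region_mask(seg.region_id)[seg.bbox]
    n_pixels = int(region_mask.sum())
    if n_pixels == 0:
        raise ValueError(f"region {seg.region_id} has zero pixels")
    px_area = pixel_size_um**2
    area = n_pixels * px_area
    diameter = equivalent_diameter_um(area)
    return IsletMeasurement(
        animal_id=section.animal_id if section is not None else "",
        series_index=section.series_index if section is not None else 0,
        islet_id=seg.region_id,
        area_um2=area,
        insulin_area_um2=int(seg.insulin_mask.sum()) * px_area,
        sst_area_um2=int(seg.sst_mask.sum()) * px_area,
        otsu_threshold=seg.otsu_threshold,
        kapur_threshold=seg.kapur_threshold,
        equiv_diameter_um=diameter,
        size_class=classify_islet_size(diameter, size_cutoff_um),
        touches_border=_touches_border(region_mask, seg.bbox, regions.labels.shape),
    )


def summarize_pancreas(
    measurements: Sequence[IsletMeasurement], animal_id: str
) -> PancreasSummary:
    """Aggregate an animal's islet measurements into one summary row.

    All measurements must carry the same ``animal_id``; an empty list yields
    zero counts with undefined (None) percentages and mean area.
    """
    measurements = list(measurements)
    for m in measurements:
        if m.animal_id != animal_id:
            raise ValueError(
                f"measurement for animal {m.animal_id!r} mixed into summary "
                f"for {animal_id!r}"
            )
    n = len(measurements)
    if n == 0:
        return PancreasSummary(
            animal_id=animal_id,
            n_islets=0,
            total_islet_area_um2=0.0,
            mean_islet_area_um2=None,
            beta_cell_percent=None,
            delta_cell_percent=None,
            n_small_islets=0,
            n_large_islets=0,
        )
    total_area = sum(m.area_um2 for m in measurements)
    total_insulin = sum(m.insulin_area_um2 for m in measurements)
    total_sst = sum(m.sst_area_um2 for m in measurements)
    n_small = sum(1 for m in measurements if m.size_class == "small")
    return PancreasSummary(
        animal_id=animal_id,
        n_islets=n,
        total_islet_area_um2=total_area,
        mean_islet_area_um2=total_area / n,
        beta_cell_percent=100.0 * total_insulin / total_area if total_area > 0 else None,
        delta_cell_percent=100.0 * total_sst / total_area if total_area > 0 else None,
        n_small_islets=n_small,
        n_large_islets=n - n_small,
    )
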