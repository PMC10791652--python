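"""Reading fluorescence section images and islet perimeter masks; CSV output.

Sections arrive as RGB TIFFs or as per-channel grayscale planes. Islet
perimeter masks are hand-drawn, pixel-aligned binary (any nonzero pixel is
inside an islet) or pre-labeled images; binary masks are converted to labeled
regions by connected-component labeling. Region ids follow raster-scan order
of each component's first pixel so outputs are reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from imageio.v3 import imread as _imread
from scipy import ndimage

__all__ = [
    "FluorescenceSection",
    "IsletRegionSet",
    "MEASUREMENT_COLUMNS",
    "SUMMARY_COLUMNS",
    "read_section_image",
    "read_islet_masks",
    "label_mask",
    "write_measurements",
    "read_measurements",
]

#: Column order of the per-islet measurement CSV.
MEASUREMENT_COLUMNS = [
    "animal_id",
    "series_index",
    "islet_id",
    "area_um2",
    "insulin_area_um2",
    "sst_area_um2",
    "otsu_threshold",
    "kapur_threshold",
    "equiv_diameter_um",
    "size_class",
    "touches_border",
]

#: Column order of the per-animal summary CSV.
SUMMARY_COLUMNS = [
    "animal_id",
    "n_islets",
    "total_islet_area_um2",
    "mean_islet_area_um2",
    "beta_cell_percent",
    "delta_cell_percent",
    "n_small_islets",
    "n_large_islets",
]


@dataclasses.dataclass
class FluorescenceSection:
    """A dual/triple-channel fluorescence image of one pancreas section.

    Channels follow the staining convention: red = somatostatin (delta
    cells), green = insulin (beta cells), blue = nuclear stain (carried but
    unused by the analysis). ``pixel_size_um`` is the edge length of one
    pixel in micrometres (0.65 µm for the slide-scanner exports this
    pipeline was designed around).
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray | None = None
    pixel_size_um: float = 0.65
    animal_id: str = ""
    series_index: int = 0
    section_spacing_um: float = 250.0

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.green = np.asarray(self.green)
        if self.red.ndim != 2 or self.green.ndim != 2:
            raise ValueError("channel arrays must be 2-D")
        if self.red.shape != self.green.shape:
            raise ValueError(
                f"channel shapes differ: red {self.red.shape} vs green {self.green.shape}"
            )
        if self.blue is not None:
            self.blue = np.asarray(self.blue)
            if self.blue.shape != self.red.shape:
                raise ValueError("blue channel shape differs from red/green")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.section_spacing_um <= 0:
            raise ValueError("section_spacing_um must be positive")
        for name in ("red", "green", "blue"):
            chan = getattr(self, name)
            if chan is not None and np.any(np.asarray(chan) < 0):
                raise ValueError(f"{name} channel contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclasses.dataclass
class IsletRegionSet:
    """Labeled islet regions aligned to one section.

    ``labels`` is a 2-D integer array: 0 is background, k > 0 marks islet
    region k. Each region is one connected component under ``connectivity``
    (4 or 8). ``region_ids`` lists the nonzero labels in ascending order,
    which by construction is raster-scan order of each component's first
    pixel.
    """

    labels: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label array must be 2-D")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def region_mask(self, region_id: int) -> np.ndarray:
        if region_id not in self.region_ids:
            raise KeyError(f"region id {region_id} not present")
        return self.labels == region_id


def _as_channel_stack(arr: np.ndarray) -> np.ndarray:
    """Coerce an image array to shape (n_channels, H, W)."""
    if arr.ndim == 2:
        return arr[None, :, :]
    if arr.ndim == 3:
        # channel-last (H, W, C) vs channel-first (C, H, W): treat the small
        # axis (<= 4) as channels, preferring the last axis (RGB convention).
        if arr.shape[-1] <= 4:
            return np.moveaxis(arr, -1, 0)
        if arr.shape[0] <= 4:
            return arr
    raise ValueError(f"unsupported image dimensionality {arr.shape}")


def read_section_image(
    path: str | Path | Sequence[str | Path],
    pixel_size_um: float = 0.65,
    channel_order: str = "rgb",
    animal_id: str = "",
    series_index: int = 0,
    section_spacing_um: float = 250.0,
) -> FluorescenceSection:
    """Read a section image and split it into color channels.

    Parameters
    ----------
    path
        Either one multi-channel (RGB) TIFF/PNG, or a sequence of
        per-channel grayscale files in the order given by ``channel_order``.
    pixel_size_um
        Physical pixel edge length in µm.
    channel_order
        A permutation of "rgb" (or "rg" for two channels) mapping image
        planes to red/green/blue. Default "rgb": plane 0 = somatostatin
        (red), plane 1 = insulin (green), plane 2 = nuclei (blue).
    """
    channel_order = channel_order.lower()
    if not set(channel_order) <= set("rgb") or len(set(channel_order)) != len(channel_order):
        raise ValueError(f"invalid channel_order {channel_order!r}")

    if isinstance(path, (str, Path)):
        try:
            arr = _imread(Path(path))
        except FileNotFoundError:
            raise
        except Exception as exc:  # pragma: no cover - backend specific
            raise IOError(f"could not read image {path}: {exc}") from exc
        planes = _as_channel_stack(np.asarray(arr))
    else:
        loaded = [np.asarray(_imread(Path(p))) for p in path]
        shapes = {a.shape for a in loaded}
        if len(shapes) > 1:
            raise ValueError(f"per-channel planes have mismatched shapes: {shapes}")
        if any(a.ndim != 2 for a in loaded):
            raise ValueError("per-channel files must be 2-D grayscale")
        planes = np.stack(loaded)

    if planes.shape[0] < 2:
        raise ValueError(
            f"expected at least 2 channels, got {planes.shape[0]} (shape {planes.shape})"
        )
    if len(channel_order) > planes.shape[0]:
        raise ValueError(
            f"channel_order {channel_order!r} names {len(channel_order)} planes "
            f"but the image has {planes.shape[0]}"
        )

    by_color: dict[str, np.ndarray] = {}
    for color, plane in zip(channel_order, planes):
        by_color[color] = plane
    if "r" not in by_color or "g" not in by_color:
        raise ValueError("channel_order must map both a red and a green plane")

    return FluorescenceSection(
        red=by_color["r"],
        green=by_color["g"],
        blue=by_color.get("b"),
        pixel_size_um=pixel_size_um,
        animal_id=animal_id,
        series_index=series_index,
        section_spacing_um=section_spacing_um,
    )


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_mask(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labeling with raster-order label assignment.

    ``scipy.ndimage.label`` assigns labels in the order components are first
    met in a raster scan, which is exactly the deterministic ordering this
    pipeline guarantees.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, _ = ndimage.label(mask != 0, structure=_STRUCTURES[connectivity])
    return labels


def read_islet_masks(
    path: str | Path | np.ndarray,
    section: FluorescenceSection,
    connectivity: int = 8,
) -> IsletRegionSet:
    """Read the islet perimeter mask matching ``section`` and label regions.

    Binary masks (any nonzero pixel = inside an islet) are split into
    connected components. Already-labeled masks are accepted as-is after
    checking that each label forms a single connected component (overlapping
    or fragmented hand-drawn regions are rejected rather than silently
    merged).
    """
    if isinstance(path, np.ndarray):
        mask = np.asarray(path)
    else:
        mask = np.asarray(_imread(Path(path)))
    if mask.ndim == 3:
        # Color-exported masks: collapse to "any channel nonzero".
        mask = mask.max(axis=-1 if mask.shape[-1] <= 4 else 0)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if mask.shape != section.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match section shape {section.shape}"
        )

    uniq = np.unique(mask)
    nonzero = uniq[uniq != 0]
    is_binary = len(nonzero) <= 1
    if is_binary:
        labels = label_mask(mask, connectivity)
    else:
        labels = mask.astype(np.int64, copy=True)
        if np.any(labels < 0):
            raise ValueError("labeled mask contains negative labels")
        structure = _STRUCTURES[connectivity]
        for rid in nonzero:
            _, n = ndimage.label(labels == rid, structure=structure)
            if n != 1:
                raise ValueError(
                    f"labeled mask region {int(rid)} is not a single connected "
                    f"component ({n} pieces); overlapping or fragmented perimeters?"
                )
    return IsletRegionSet(labels=labels, connectivity=connectivity)


def _records_to_frame(records: Sequence, columns: list[str]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=columns)
    return frame


def write_measurements(records: Sequence, path: str | Path) -> None:
    """Write per-islet measurements or per-animal summaries to CSV.

    The header is fixed (see ``MEASUREMENT_COLUMNS`` / ``SUMMARY_COLUMNS``);
    an empty record list produces a header-only per-islet CSV. Floats are
    serialized with 9 significant digits so the file round-trips to equal
    values at measurement precision.
    """
    from isletquant.morphometry import IsletMeasurement, PancreasSummary

    records = list(records)
    if not records:
        frame = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    elif isinstance(records[0], IsletMeasurement):
        frame = _records_to_frame(records, MEASUREMENT_COLUMNS)
    elif isinstance(records[0], PancreasSummary):
        frame = _records_to_frame(records, SUMMARY_COLUMNS)
    else:
        raise TypeError(f"unsupported record type {type(records[0]).__name__}")
    frame.to_csv(path, index=False, float_format="%.9g")


def read_measurements(path: str | Path):
    """Read a per-islet measurement CSV back into IsletMeasurement records."""
    from isletquant.morphometry import IsletMeasurement

    frame = pd.read_csv(path)
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        for key in ("otsu_threshold", "kapur_threshold"):
            if pd.isna(d[key]):
                d[key] = None
        records.append(IsletMeasurement(**d))
    return records


def write_section_tiff(path: str | Path, section: FluorescenceSection) -> None:
    """Write a section as an RGB(-like) TIFF, channel-last, dtype preserved."""
    blue = section.blue
    if blue is None:
        blue = np.zeros_like(section.red)
    stack = np.stack([section.red, section.green, blue], axis=-1)
    tifffile.imwrite(Path(path), stack, photometric="rgb")


def write_mask_tiff(path: str | Path, labels: np.ndarray) -> None:
    """Write a labeled islet mask as a 16-bit grayscale TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many regions for a 16-bit mask")
    tifffile.imwrite(Path(path), labels.astype(np.uint16), photometric="minisblack")
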