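"""Color correction and per-islet histogram thresholding.

Two classic global-threshold criteria are applied per islet region rather
than per image, so each islet is segmented against its own local intensity
statistics:

* Otsu's method for the green (insulin) channel — choose the histogram split
  maximizing the between-class variance
  ``sigma_B^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))**2``,
  where w are the class probability masses and mu the class means of the bin
  centers. By the law of total variance this is equivalent to minimizing the
  within-class variance.
* Kapur's method for the red (somatostatin) channel — choose the split
  maximizing the summed Shannon entropies ``H0(t) + H1(t)`` of the two
  classes' normalized bin probabilities (natural log; ``0 * ln 0 := 0``).

Both return the upper EDGE of the winning bin; hormone-positive foreground is
every pixel STRICTLY above that edge. Ties are broken toward the smallest
split, which favors the larger (more sensitive) foreground. Constant regions
are degenerate: no threshold is returned and the region contributes zero
positive area, with a flag, rather than falling back to a global threshold.

Before any thresholding the red and green channels are mutually corrected by
subtracting each from the other (both differences taken from the ORIGINAL
arrays, clamped at zero). With similar background offsets in both channels
this cancels the background and the spectral bleed-through, leaving only the
channel-specific signal.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from isletquant.image_io import FluorescenceSection, IsletRegionSet

__all__ = [
    "IntensityHistogram",
    "SegmentationResult",
    "cross_channel_correct",
    "build_histogram",
    "otsu_threshold",
    "kapur_threshold",
    "segment_islet_region",
]


@dataclasses.dataclass
class IntensityHistogram:
    """Equal-width intensity histogram over one islet region.

    ``counts[i]`` is the number of region pixels falling in
    ``[bin_edges[i], bin_edges[i+1])`` (last bin closed on the right, the
    numpy convention). A constant region yields a single degenerate bin.
    """

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.counts.ndim != 1 or self.bin_edges.ndim != 1:
            raise ValueError("counts and bin_edges must be 1-D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts) + 1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def is_degenerate(self) -> bool:
        """True when fewer than two bins are populated (no split exists)."""
        return int(np.count_nonzero(self.counts)) < 2


@dataclasses.dataclass
class SegmentationResult:
    """Per-islet hormone-positive masks and the thresholds that produced them.

    Masks are cropped to the region's bounding box (``bbox`` slices index the
    full section) and are zero outside the islet region. A threshold is None
    exactly when the corresponding channel is constant over the region
    (flagged in ``degenerate_flags``).
    """

    region_id: int
    insulin_mask: np.ndarray
    sst_mask: np.ndarray
    otsu_threshold: float | None
    kapur_threshold: float | None
    degenerate_flags: frozenset[str]
    bbox: tuple[slice, slice]


def cross_channel_correct(
    red: np.ndarray, green: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual red/green correction: each channel minus the other, clamped at 0.

    Both differences are taken from the original arrays (symmetric, not
    sequential), so the corrected red keeps only red-dominant signal and the
    corrected green only green-dominant signal.
    """
    red = np.asarray(red)
    green = np.asarray(green)
    if red.shape != green.shape:
        raise ValueError(f"shape mismatch: red {red.shape} vs green {green.shape}")
    red_f = red.astype(np.float64)
    green_f = green.astype(np.float64)
    red_corr = np.maximum(red_f - green_f, 0.0)
    green_corr = np.maximum(green_f - red_f, 0.0)
    return red_corr, green_corr


def build_histogram(values: np.ndarray, n_bins: int = 256) -> IntensityHistogram:
    """Histogram a region's intensities into equal-width bins over [min, max].

    The range spans the region's own minimum to maximum (inclusive), so the
    thresholds adapt to each islet's local dynamic range regardless of bit
    depth. A constant region yields a single degenerate bin.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("cannot histogram an empty region")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    lo = float(values.min())
    hi = float(values.max())
    if lo == hi:
        return IntensityHistogram(
            counts=np.array([values.size]), bin_edges=np.array([lo, lo + 1.0])
        )
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return IntensityHistogram(counts=counts, bin_edges=edges)


def _class_stats(h: IntensityHistogram):
    """Cumulative class mass/mean helpers shared by both criteria."""
    total = h.counts.sum()
    p = h.counts / total
    centers = h.bin_centers
    w0 = np.cumsum(p)[:-1]          # class-0 mass for splits t = 0 .. n-2
    w1 = 1.0 - w0
    m0 = np.cumsum(p * centers)[:-1]
    m_total = float(np.sum(p * centers))
    return p, centers, w0, w1, m0, m_total


def _canonical_argmax(objective: np.ndarray, counts: np.ndarray) -> int:
    """First maximizer, walked back across empty bins.

    Splits that differ only by trailing EMPTY class-0 bins induce the same
    partition and are mathematically tied; rounding can break such ties
    either way, so the smallest-t representative of the winning partition is
    returned deterministically.
    """
    t = int(np.argmax(objective))  # argmax already picks the first bitwise maximum
    while t > 0 and counts[t] == 0:
        t -= 1
    return t


def otsu_threshold(h: IntensityHistogram) -> float | None:
    """Between-class-variance maximizing threshold; None if degenerate.

    Candidate splits put bins ``0..t`` in class 0 and ``t+1..`` in class 1;
    the returned value is ``bin_edges[t* + 1]``, the upper edge of the last
    class-0 bin. Ties go to the smallest t.
    """
    if h.is_degenerate:
        return None
    _, _, w0, w1, m0, m_total = _class_stats(h)
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m_total - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(valid, sigma_b, -np.inf)
    t_star = _canonical_argmax(sigma_b, h.counts)
    return float(h.bin_edges[t_star + 1])


def kapur_threshold(h: IntensityHistogram) -> float | None:
    """Maximum-entropy (Kapur) threshold; None if degenerate.

    Maximizes ``H0(t) + H1(t)`` where ``H_c = -sum (p_i/P_c) ln(p_i/P_c)``
    over the class's bins; empty bins contribute zero and splits leaving a
    class empty are invalid. Ties go to the smallest t.
    """
    if h.is_degenerate:
        return None
    total = h.counts.sum()
    p = h.counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    P0 = np.cumsum(p)[:-1]
    P1 = 1.0 - P0
    S0 = np.cumsum(plogp)[:-1]
    S_total = float(plogp.sum())
    valid = (P0 > 0) & (P1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        H0 = np.log(np.where(P0 > 0, P0, 1.0)) - S0 / np.where(P0 > 0, P0, 1.0)
        H1 = np.log(np.where(P1 > 0, P1, 1.0)) - (S_total - S0) / np.where(
            P1 > 0, P1, 1.0
        )
    objective = np.where(valid, H0 + H1, -np.inf)
    if not np.any(valid):
        return None
    t_star = _canonical_argmax(objective, h.counts)
    return float(h.bin_edges[t_star + 1])


def segment_islet_region(
    section: FluorescenceSection,
    regions: IsletRegionSet,
    region_id: int,
    n_bins: int = 256,
) -> SegmentationResult:
    """Segment one islet region into insulin- and somatostatin-positive masks.

    The full section is color-corrected once; the region's corrected pixels
    are histogrammed locally; Otsu's threshold is applied to corrected green
    (insulin) and Kapur's to corrected red (somatostatin). Foreground is
    strictly above the returned edge and confined to the region.
    """
    region_mask_full = regions.region_mask(region_id)  # KeyError on unknown id
    red_corr, green_corr = cross_channel_correct(section.red, section.green)

    rows = np.any(region_mask_full, axis=1).nonzero()[0]
    cols = np.any(region_mask_full, axis=0).nonzero()[0]
    bbox = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    region_mask = region_mask_full[bbox]
    green_box = green_corr[bbox]
    red_box = red_corr[bbox]

    flags: set[str] = set()

    green_hist = build_histogram(green_box[region_mask], n_bins=n_bins)
    otsu = otsu_threshold(green_hist)
    if otsu is None:
        flags.add("constant_green")
        insulin_mask = np.zeros_like(region_mask)
    else:
        insulin_mask = (green_box > otsu) & region_mask

    red_hist = build_histogram(red_box[region_mask], n_bins=n_bins)
    kapur = kapur_threshold(red_hist)
    if kapur is None:
        flags.add("constant_red")
        sst_mask = np.zeros_like(region_mask)
    else:
        sst_mask = (red_box > kapur) & region_mask

    return SegmentationResult(
        region_id=int(region_id),
        insulin_mask=insulin_mask,
        sst_mask=sst_mask,
        otsu_threshold=otsu,
        kapur_threshold=kapur,
        degenerate_flags=frozenset(flags),
        bbox=bbox,
    )
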