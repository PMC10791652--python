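"""Color correction and Otsu/Kapur thresholding against independent oracles."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

from isletquant import (
    IntensityHistogram,
    build_histogram,
    cross_channel_correct,
    kapur_threshold,
    otsu_threshold,
    read_islet_masks,
    segment_islet_region,
)
from isletquant.synthetic import IsletImageParams, generate_islet_image


# --- independent exhaustive-search oracles (shared with the acceptance suite)


def canonical_t(t, counts):
    """Smallest-t representative of a partition: walk back over empty bins."""
    while t > 0 and counts[t] == 0:
        t -= 1
    return t


def otsu_oracle(counts, edges):
    """Brute-force between-class-variance maximization over all splits."""
    counts = np.asarray(counts, dtype=float)
    if np.count_nonzero(counts) < 2:
        return None
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    best, best_t = -1.0, None
    for t in range(len(counts) - 1):
        w0 = p[: t + 1].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = (p[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (p[t + 1 :] * centers[t + 1 :]).sum() / w1
        s = w0 * w1 * (mu0 - mu1) ** 2
        if s > best:
            best, best_t = s, t
    return edges[canonical_t(best_t, counts) + 1]


def kapur_oracle(counts, edges):
    """Brute-force two-class entropy-sum maximization over all splits."""
    counts = np.asarray(counts, dtype=float)
    if np.count_nonzero(counts) < 2:
        return None
    p = counts / counts.sum()
    best, best_t = -np.inf, None
    for t in range(len(counts) - 1):
        P0 = p[: t + 1].sum()
        P1 = 1.0 - P0
        if P0 <= 0 or P1 <= 0:
            continue
        q0 = p[: t + 1][p[: t + 1] > 0] / P0
        q1 = p[t + 1 :][p[t + 1 :] > 0] / P1
        H = -(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum()
        if H > best:
            best, best_t = H, t
    if best_t is None:
        return None
    return edges[canonical_t(best_t, counts) + 1]


def random_histogram(rng, max_bins=256, max_mass=100_000):
    n_bins = int(rng.integers(8, max_bins + 1))
    mass = int(rng.integers(10, max_mass + 1))
    conc = rng.uniform(0.05, 2.0)
    counts = rng.multinomial(mass, rng.dirichlet(np.full(n_bins, conc)))
    edges = np.arange(n_bins + 1, dtype=float)
    return IntensityHistogram(counts=counts, bin_edges=edges)


# --- cross-channel correction -------------------------------------------------


def test_mutual_subtraction_is_symmetric_and_clamped():
    red, green = np.array([5.0, 10.0]), np.array([3.0, 20.0])
    r, g = cross_channel_correct(red, green)
    np.testing.assert_array_equal(r, [2.0, 0.0])
    np.testing.assert_array_equal(g, [0.0, 10.0])


def test_correction_identity_and_symmetry_cases():
    red = np.array([[3.0, 7.0]])
    r, g = cross_channel_correct(red, np.zeros_like(red))
    np.testing.assert_array_equal(r, red)
    assert not g.any()
    r, g = cross_channel_correct(red, red)
    assert not r.any() and not g.any()


def test_correction_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape mismatch"):
        cross_channel_correct(np.zeros((2, 2)), np.zeros((3, 2)))


# --- histogram construction ---------------------------------------------------


def test_uniform_256_values_give_unit_counts():
    h = build_histogram(np.arange(256), n_bins=256)
    np.testing.assert_array_equal(h.counts, np.ones(256, dtype=int))
    assert h.bin_edges[0] == 0 and h.bin_edges[-1] == 255


def test_constant_region_gives_degenerate_single_bin():
    h = build_histogram(np.full(50, 7.0))
    assert h.n_bins == 1
    assert h.is_degenerate
    assert h.counts[0] == 50


def test_histogram_matches_direct_tally(rng):
    values = np.concatenate(
        [rng.normal(40, 5, 600), rng.normal(180, 12, 400)]
    )
    h = build_histogram(values, n_bins=64)
    assert h.counts.sum() == 1000
    # independent tally: explicit bin arithmetic with right-closed last bin
    lo, hi = values.min(), values.max()
    width = (hi - lo) / 64
    tally = np.zeros(64, dtype=int)
    for v in values:
        idx = min(int((v - lo) / width), 63)
        tally[idx] += 1
    # allow the float-boundary convention to differ on exact edges only
    assert int(np.abs(h.counts - tally).sum()) <= 2


def test_empty_region_raises():
    with pytest.raises(ValueError, match="empty"):
        build_histogram(np.array([]))


# --- thresholds: frozen examples ----------------------------------------------

EIGHT_BIN_COUNTS = np.array([5, 10, 2, 0, 3, 8, 7, 1])
EIGHT_BIN_EDGES = np.arange(9, dtype=float)


def two_spike_histogram():
    counts = np.zeros(256, dtype=int)
    counts[10] = counts[200] = 100
    return IntensityHistogram(counts=counts, bin_edges=np.arange(257, dtype=float))


def test_otsu_two_spike_tie_breaks_to_smallest_split():
    # every split in [10, 199] separates the spikes equally; smallest wins
    assert otsu_threshold(two_spike_histogram()) == 11.0


def test_kapur_two_spike_zero_entropy_tie_breaks_small():
    assert kapur_threshold(two_spike_histogram()) == 11.0


def test_otsu_eight_bin_example_matches_exhaustive_search():
    h = IntensityHistogram(counts=EIGHT_BIN_COUNTS, bin_edges=EIGHT_BIN_EDGES)
    got = otsu_threshold(h)
    assert got == otsu_oracle(EIGHT_BIN_COUNTS, EIGHT_BIN_EDGES)
    assert got == 3.0  # frozen brute-force result (split after bin 2)


def test_kapur_eight_bin_example_matches_exhaustive_search():
    h = IntensityHistogram(counts=EIGHT_BIN_COUNTS, bin_edges=EIGHT_BIN_EDGES)
    got = kapur_threshold(h)
    assert got == kapur_oracle(EIGHT_BIN_COUNTS, EIGHT_BIN_EDGES)
    assert got == 3.0  # frozen brute-force result


def test_kapur_uniform_four_bins_prefers_even_split():
    h = IntensityHistogram(counts=np.ones(4, dtype=int), bin_edges=np.arange(5.0))
    # H0+H1 = ln2+ln2 at the middle split vs ln1+ln3-contributions elsewhere
    assert kapur_threshold(h) == 2.0


def test_degenerate_histograms_return_none():
    h = build_histogram(np.full(10, 3.0))
    assert otsu_threshold(h) is None
    assert kapur_threshold(h) is None
    single = IntensityHistogram(counts=np.array([5, 0, 0]), bin_edges=np.arange(4.0))
    assert otsu_threshold(single) is None
    assert kapur_threshold(single) is None


# --- thresholds: properties ---------------------------------------------------


def test_oracle_equivalence_on_random_histograms(rng):
    for _ in range(100):
        h = random_histogram(rng)
        assert otsu_threshold(h) == otsu_oracle(h.counts, h.bin_edges)
        assert kapur_threshold(h) == kapur_oracle(h.counts, h.bin_edges)


def test_otsu_agrees_with_skimage_on_integer_histograms(rng):
    """Independent library cross-check with matched binning.

    skimage returns the bin CENTER of the last class-0 bin; with unit bins
    centered on the integers that is our returned edge minus 0.5.
    """
    for _ in range(50):
        values = rng.integers(0, 256, size=500)
        if values.min() == values.max():
            continue
        counts = np.bincount(values, minlength=256)
        edges = np.arange(257, dtype=float) - 0.5
        h = IntensityHistogram(counts=counts, bin_edges=edges)
        ours = otsu_threshold(h)
        theirs = skimage_otsu(hist=(counts, np.arange(256.0)))
        assert ours == pytest.approx(theirs + 0.5)


def test_variance_decomposition_at_every_split(rng):
    """Law of total variance: within + between = total at each split."""
    h = random_histogram(rng, max_bins=64, max_mass=10_000)
    counts = h.counts.astype(float)
    centers = h.bin_centers
    p = counts / counts.sum()
    mu = (p * centers).sum()
    total_var = (p * (centers - mu) ** 2).sum()
    for t in range(h.n_bins - 1):
        w0 = p[: t + 1].sum()
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (p[t + 1 :] * centers[t + 1 :]).sum() / w1
        var0 = (p[: t + 1] * (centers[: t + 1] - mu0) ** 2).sum() / w0
        var1 = (p[t + 1 :] * (centers[t + 1 :] - mu1) ** 2).sum() / w1
        within = w0 * var0 + w1 * var1
        between = w0 * w1 * (mu0 - mu1) ** 2
        assert within + between == pytest.approx(total_var, rel=1e-9)


def test_thresholds_shift_with_constant_intensity_offset(rng):
    values = rng.integers(0, 200, size=2000)
    shift = 37
    h0 = build_histogram(values, n_bins=64)
    h1 = build_histogram(values + shift, n_bins=64)
    assert otsu_threshold(h1) == pytest.approx(otsu_threshold(h0) + shift, rel=1e-12)
    assert kapur_threshold(h1) == pytest.approx(kapur_threshold(h0) + shift, rel=1e-12)


# --- per-region segmentation --------------------------------------------------


def test_separable_islet_recovers_true_masks_exactly(separable_scene):
    section, mask, truth = separable_scene
    regions = read_islet_masks(mask, section)
    insulin = np.zeros(section.shape, dtype=bool)
    sst = np.zeros(section.shape, dtype=bool)
    for rid in regions.region_ids:
        seg = segment_islet_region(section, regions, rid)
        insulin[seg.bbox] |= seg.insulin_mask
        sst[seg.bbox] |= seg.sst_mask
    np.testing.assert_array_equal(insulin, truth.true_insulin_mask)
    np.testing.assert_array_equal(sst, truth.true_sst_mask)


def test_constant_region_sets_degenerate_flags():
    z = np.full((30, 30), 17, dtype=np.uint16)
    from isletquant import FluorescenceSection

    section = FluorescenceSection(red=z, green=z)
    mask = np.zeros((30, 30), dtype=np.uint8)
    mask[5:15, 5:15] = 1
    regions = read_islet_masks(mask, section)
    seg = segment_islet_region(section, regions, 1)
    assert seg.degenerate_flags == {"constant_green", "constant_red"}
    assert seg.otsu_threshold is None and seg.kapur_threshold is None
    assert not seg.insulin_mask.any() and not seg.sst_mask.any()


def test_unknown_region_id_raises(separable_scene):
    section, mask, _ = separable_scene
    regions = read_islet_masks(mask, section)
    with pytest.raises(KeyError):
        segment_islet_region(section, regions, 999)


def test_masks_confined_to_region(default_scene):
    section, mask, _ = default_scene
    regions = read_islet_masks(mask, section)
    for rid in regions.region_ids:
        seg = segment_islet_region(section, regions, rid)
        region_box = regions.region_mask(rid)[seg.bbox]
        assert not (seg.insulin_mask & ~region_box).any()
        assert not (seg.sst_mask & ~region_box).any()
        frac = seg.insulin_mask.sum() / region_box.sum()
        assert 0.0 <= frac <= 1.0
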