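"""Seeded synthetic dual-channel islet images and assay tables with ground truth.

The image generator emulates what the morphometry pipeline consumes: a
section with disk-shaped islets, an interior concentric insulin-positive
(beta cell) region covering a stated fraction of the islet area, peripheral
somatostatin-positive (delta cell) blobs, symmetric red/green spectral
bleed-through, a flat background offset and additive Gaussian noise, stored
as 16-bit integers. Disks are geometrically simple but give exact analytic
and pixel-count areas, so every measurement has a checkable truth.

Default optical conditions: background 20, hormone signal 180 counts above
background, noise sigma 10 (signal-to-noise ~16 — typical of a well-exposed
slide-scanner export), bleed-through fraction 0.1. Geometry defaults: 0.65
um pixels, five islets per 768x768 section, log-normal islet diameters with
median 80 um (sigma_log 0.35, so sections contain islets on both sides of
the 100 um size-class cutoff), beta cells 60% of islet area as typical of
mouse islets.

Assay generators draw log-normal secretion samples around stated group
means with a stated coefficient of variation, produce hormone-content
values jointly with secretion so stimulation indices have an exact stated
truth, and sample dose-response data from a known 4-parameter logistic.

All randomness flows from one explicit seed through one numpy Generator.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from isletquant.assays import CaTrace, SecretionSample, four_param_logistic
from isletquant.image_io import FluorescenceSection, label_mask

__all__ = [
    "IsletImageParams",
    "SyntheticGroundTruth",
    "generate_islet_image",
    "generate_secretion_data",
    "generate_dose_response",
    "generate_ca_trace",
]


@dataclasses.dataclass
class IsletImageParams:
    """Everything that shapes one synthetic section; seed makes it exact."""

    image_size_px: tuple[int, int] = (768, 768)
    n_islets: int = 5
    diameter_median_um: float = 80.0
    diameter_log_sigma: float = 0.35
    beta_area_fraction: float = 0.6
    delta_blob_count: int = 8
    delta_blob_radius_um: float = 5.0
    background_level: float = 20.0
    insulin_level: float = 180.0
    sst_level: float = 180.0
    noise_sigma: float = 10.0
    bleedthrough_alpha: float = 0.1
    pixel_size_um: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_islets < 0:
            raise ValueError("n_islets must be >= 0")
        if not 0 <= self.beta_area_fraction <= 1:
            raise ValueError("beta_area_fraction must be in [0, 1]")
        if not 0 <= self.bleedthrough_alpha < 1:
            raise ValueError("bleedthrough_alpha must be in [0, 1)")
        for name in ("background_level", "insulin_level", "sst_level", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size_px"] = list(self.image_size_px)
        return d


@dataclasses.dataclass
class SyntheticGroundTruth:
    """True masks and bookkeeping the recovery tests compare against."""

    true_islet_labels: np.ndarray
    true_insulin_mask: np.ndarray
    true_sst_mask: np.ndarray
    true_beta_fraction_per_islet: dict[int, float]
    true_counts_by_class: dict[str, int]
    params: IsletImageParams

    @property
    def n_islets(self) -> int:
        return int(self.true_islet_labels.max(initial=0))

    @property
    def true_beta_percent_pooled(self) -> float | None:
        """100 * total true insulin-positive pixels / total islet pixels."""
        total = int((self.true_islet_labels > 0).sum())
        if total == 0:
            return None
        return 100.0 * int(self.true_insulin_mask.sum()) / total


def _disk(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def generate_islet_image(
    params: IsletImageParams,
) -> tuple[FluorescenceSection, np.ndarray, SyntheticGroundTruth]:
    """Render one synthetic section, its islet mask, and its ground truth.

    Islets are placed by rejection sampling without overlap (a 3-pixel gap
    keeps 8-connected components distinct); placement failure after 10,000
    attempts raises with the offending constraint. The returned mask array
    holds raster-order region labels; the ground truth is keyed on the same
    labels.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    shape = (h, w)

    # --- geometry -----------------------------------------------------------
    mu = math.log(params.diameter_median_um)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, r_px)
    islet_union = np.zeros(shape, dtype=bool)
    insulin_true = np.zeros(shape, dtype=bool)
    sst_true = np.zeros(shape, dtype=bool)

    attempts = 0
    while len(placed) < params.n_islets:
        if attempts >= 10_000:
            raise RuntimeError(
                f"could not place {params.n_islets} non-overlapping islets of "
                f"median diameter {params.diameter_median_um} um in a "
                f"{h}x{w} image after 10000 attempts"
            )
        attempts += 1
        d_um = float(rng.lognormal(mean=mu, sigma=params.diameter_log_sigma))
        r_px = (d_um / 2.0) / params.pixel_size_um
        margin = r_px + 3.0
        if 2 * margin >= min(h, w):
            continue  # islet larger than the image; redraw
        cy = float(rng.uniform(margin, h - margin))
        cx = float(rng.uniform(margin, w - margin))
        if any(
            math.hypot(cy - py, cx - px) < r_px + pr + 3.0 for py, px, pr in placed
        ):
            continue
        placed.append((cy, cx, r_px))

        islet = _disk(shape, cy, cx, r_px)
        islet_union |= islet

        # interior beta-cell disk with the requested area fraction
        r_beta = r_px * math.sqrt(params.beta_area_fraction)
        beta = _disk(shape, cy, cx, r_beta) & islet
        insulin_true |= beta

        # peripheral delta-cell blobs in the annulus outside the beta core
        # blob centers anywhere in the annulus; blobs are clipped to the
        # islet and to the outside of the beta core, so even small islets
        # carry some somatostatin signal
        blob_r = params.delta_blob_radius_um / params.pixel_size_um
        lo = r_beta
        hi = max(r_px - blob_r, lo + 1e-6)
        if params.delta_blob_count > 0 and r_px > r_beta + 0.5:
            angles = rng.uniform(0.0, 2.0 * math.pi, size=params.delta_blob_count)
            radii = rng.uniform(lo, hi, size=params.delta_blob_count)
            for ang, rad in zip(angles, radii):
                by = cy + rad * math.sin(ang)
                bx = cx + rad * math.cos(ang)
                blob = _disk(shape, by, bx, blob_r) & islet & ~insulin_true
                sst_true |= blob

    labels = label_mask(islet_union, connectivity=8)
    n_found = int(labels.max(initial=0))
    if n_found != len(placed):  # pragma: no cover - guarded by the 3 px gap
        raise RuntimeError("islet placement produced merged components")

    # --- optics -------------------------------------------------------------
    a = params.bleedthrough_alpha
    green_sig = np.where(insulin_true, params.insulin_level, 0.0)
    red_sig = np.where(sst_true, params.sst_level, 0.0)
    green_obs = green_sig + a * red_sig + params.background_level
    red_obs = red_sig + a * green_sig + params.background_level
    blue_obs = np.full(shape, params.background_level)
    if params.noise_sigma > 0:
        green_obs = green_obs + rng.normal(0.0, params.noise_sigma, size=shape)
        red_obs = red_obs + rng.normal(0.0, params.noise_sigma, size=shape)
        blue_obs = blue_obs + rng.normal(0.0, params.noise_sigma, size=shape)

    def _quantize(x: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(x), 0, 65535).astype(np.uint16)

    section = FluorescenceSection(
        red=_quantize(red_obs),
        green=_quantize(green_obs),
        blue=_quantize(blue_obs),
        pixel_size_um=params.pixel_size_um,
        animal_id=f"synthetic-seed{params.seed}",
        series_index=0,
    )

    # --- bookkeeping (recomputed from the emitted masks, hence exact) -------
    beta_frac: dict[int, float] = {}
    px_area = params.pixel_size_um**2
    n_small = n_large = 0
    for rid in range(1, n_found + 1):
        region = labels == rid
        npix = int(region.sum())
        beta_frac[rid] = int((insulin_true & region).sum()) / npix
        d_um = 2.0 * math.sqrt(npix * px_area / math.pi)
        if d_um < 100.0:
            n_small += 1
        else:
            n_large += 1

    truth = SyntheticGroundTruth(
        true_islet_labels=labels,
        true_insulin_mask=insulin_true,
        true_sst_mask=sst_true,
        true_beta_fraction_per_islet=beta_frac,
        true_counts_by_class={"small": n_small, "large": n_large},
        params=params,
    )
    return section, labels, truth


def _lognormal_around_mean(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal draw with the requested MEAN and coefficient of variation."""
    if mean == 0:
        return 0.0
    if cv == 0:
        return mean
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=math.sqrt(sigma2)))


def generate_secretion_data(
    n_per_group: int,
    group_means: dict[str, float],
    cv: float,
    seed: int,
    index_percent: float | dict[str, float] = 10.0,
) -> list[SecretionSample]:
    """Secretion samples around stated group means with stated noise.

    Each sample's hormone content is generated jointly with its secretion so
    that the per-sample stimulation index (percent of total content) equals
    ``index_percent`` exactly: ``content = secreted * (100/idx - 1)``.
    """
    if n_per_group < 0 or cv < 0:
        raise ValueError("n_per_group and cv must be non-negative")
    rng = np.random.default_rng(seed)
    samples: list[SecretionSample] = []
    for condition in group_means:  # insertion order: deterministic
        mean = group_means[condition]
        if mean < 0:
            raise ValueError(f"mean for {condition!r} must be non-negative")
        idx = (
            index_percent[condition]
            if isinstance(index_percent, dict)
            else index_percent
        )
        if not 0 < idx <= 100:
            raise ValueError("index_percent must be in (0, 100]")
        for rep in range(n_per_group):
            secreted = _lognormal_around_mean(rng, mean, cv)
            content = secreted * (100.0 / idx - 1.0)
            samples.append(
                SecretionSample(
                    condition=condition,
                    secreted_ng_ml=secreted,
                    content_ng_ml=content,
                    replicate=rep,
                    animal_or_prep_id=f"prep{rep}",
                )
            )
    return samples


def generate_dose_response(
    bottom: float,
    top: float,
    ec50: float,
    hill: float,
    doses_uM: list[float] | np.ndarray,
    reps: int = 1,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Responses from a known 4PL plus Normal(0, sigma) noise, seeded."""
    doses = np.repeat(np.asarray(doses_uM, dtype=float), reps)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    responses = four_param_logistic(doses, bottom, top, ec50, hill)
    if sigma > 0:
        responses = responses + rng.normal(0.0, sigma, size=doses.shape)
    return doses, responses


def generate_ca_trace(
    n_points: int = 120,
    baseline_ratio: float = 1.0,
    step_amplitude: float = 0.5,
    step_index: int = 60,
    f380_level: float = 100.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    time_step_s: float = 2.0,
) -> CaTrace:
    """Fura-2 trace whose F340/F380 ratio steps by a known amplitude.

    F380 is held near a constant level; F340 carries the ratio. Gaussian
    noise is added to both raw channels, so the realized delta ratio
    fluctuates around ``step_amplitude`` with a predictable SE.
    """
    if step_index < 1 or step_index >= n_points:
        raise ValueError("step_index must fall inside the trace")
    rng = np.random.default_rng(seed)
    ratio = np.full(n_points, baseline_ratio)
    ratio[step_index:] += step_amplitude
    f380 = np.full(n_points, f380_level) + rng.normal(0.0, noise_sd, n_points)
    f340 = ratio * f380_level + rng.normal(0.0, noise_sd, n_points)
    f380 = np.clip(f380, 1.0, None)
    return CaTrace(f340=f340, f380=f380, time_step_s=time_step_s)
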