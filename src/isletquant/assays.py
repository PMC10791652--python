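"""Hormone-secretion, qPCR and Ca2+-trace normalizations and the 4PL fit.

Conventions:

* Fold over basal divides each sample's secreted concentration by the mean
  of the unstimulated (basal) group, so basal samples average to fold 1.
* The stimulation index expresses secretion as a percentage of TOTAL hormone
  content, ``100 * secreted / (secreted + residual_content)`` — i.e. the
  total includes the secreted fraction; ``mode="lysate"`` gives the
  alternative ``100 * secreted / residual_content``.
* Dose-response curves are fitted with the four-parameter logistic
  ``r(d) = bottom + (top - bottom) / (1 + (EC50 / d)**hill)`` by least
  squares on log-dose; the EC50 standard error comes from the local
  curvature (delta method on log EC50). On fold-over-basal data the bottom
  can be fixed at 1.
* Relative qPCR expression is ``2**(-dCt)`` with ``dCt = Ct_target -
  Ct_reference``.
* Fura-2 traces are summarized as the ratio ``F340/F380`` per time point and
  the delta ratio = mean ratio over a response window minus mean over a
  baseline window.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SecretionSample",
    "DoseResponseFit",
    "CaTrace",
    "fold_over_basal",
    "stimulation_index",
    "four_param_logistic",
    "fit_dose_response",
    "delta_ct",
    "percent_of_control",
    "ca_delta_ratio",
    "compare_two_groups",
    "compare_multiple_groups",
    "holm_sidak_tests",
]


@dataclasses.dataclass
class SecretionSample:
    """One secretion measurement: condition label, concentration, replicate."""

    condition: str
    secreted_ng_ml: float
    content_ng_ml: float | None = None
    replicate: int = 0
    animal_or_prep_id: str = ""

    def __post_init__(self) -> None:
        if self.secreted_ng_ml < 0:
            raise ValueError("secreted_ng_ml must be non-negative")
        if self.content_ng_ml is not None and self.content_ng_ml < 0:
            raise ValueError("content_ng_ml must be non-negative")


@dataclasses.dataclass
class DoseResponseFit:
    """Result of a 4PL fit. ``se_ec50`` is a standard error (delta method)."""

    ec50: float
    hill: float
    bottom: float
    top: float
    se_ec50: float
    converged: bool
    extrapolated: bool = False


@dataclasses.dataclass
class CaTrace:
    """Background-corrected fura-2 excitation pair sampled at fixed cadence."""

    f340: np.ndarray
    f380: np.ndarray
    time_step_s: float = 2.0
    roi_side_um: float = 13.0

    def __post_init__(self) -> None:
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if self.f340.shape != self.f380.shape or self.f340.ndim != 1:
            raise ValueError("f340 and f380 must be 1-D and the same length")
        if self.time_step_s <= 0:
            raise ValueError("time_step_s must be positive")


def fold_over_basal(
    samples: Sequence[SecretionSample], basal_condition: str
) -> list[float]:
    """Per-sample secreted concentration divided by the basal-group mean."""
    basal = [s.secreted_ng_ml for s in samples if s.condition == basal_condition]
    if not basal:
        raise ValueError(f"no samples with basal condition {basal_condition!r}")
    basal_mean = float(np.mean(basal))
    if basal_mean <= 0:
        raise ValueError("basal mean is zero; fold over basal undefined")
    return [s.secreted_ng_ml / basal_mean for s in samples]


def stimulation_index(
    secreted: float, residual_content: float, mode: str = "total"
) -> float:
    """Secretion as percent of hormone content.

    ``mode="total"`` (default): 100 * secreted / (secreted + residual);
    ``mode="lysate"``: 100 * secreted / residual.
    """
    if secreted < 0 or residual_content < 0:
        raise ValueError("inputs must be non-negative")
    if mode == "total":
        denom = secreted + residual_content
        if denom == 0:
            raise ValueError("secreted + residual_content must be positive")
        return 100.0 * secreted / denom
    if mode == "lysate":
        if residual_content == 0:
            raise ValueError("residual content is zero; lysate mode undefined")
        return 100.0 * secreted / residual_content
    raise ValueError(f"unknown mode {mode!r}")


def four_param_logistic(
    dose: np.ndarray, bottom: float, top: float, ec50: float, hill: float
) -> np.ndarray:
    """r(d) = bottom + (top - bottom) / (1 + (EC50 / d)**hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


def fit_dose_response(
    doses_uM: Sequence[float],
    responses: Sequence[float],
    fix_bottom: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit with an honest convergence flag.

    Requires at least 4 distinct doses (3 with ``fix_bottom``). Degenerate
    data (constant responses) yields ``converged=False`` without raising.
    The EC50 is flagged ``extrapolated`` when it falls outside the dose
    support.
    """
    doses = np.asarray(doses_uM, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if doses.shape != resp.shape:
        raise ValueError("doses and responses must have the same length")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    n_distinct = len(np.unique(doses))
    needed = 3 if fix_bottom is not None else 4
    if n_distinct < needed:
        raise ValueError(
            f"need >= {needed} distinct doses ({n_distinct} given)"
        )

    failed = DoseResponseFit(
        ec50=math.nan, hill=math.nan,
        bottom=fix_bottom if fix_bottom is not None else math.nan,
        top=math.nan, se_ec50=math.nan, converged=False,
    )
    if np.ptp(resp) == 0:
        return failed

    # Fit log10(EC50) for scale-free optimization.
    log_d_mid = float(np.log10(np.median(doses)))
    r_lo, r_hi = float(resp.min()), float(resp.max())

    if fix_bottom is None:
        def model(d, bottom, top, log_ec50, hill):
            return four_param_logistic(d, bottom, top, 10.0**log_ec50, hill)
        p0 = [r_lo, r_hi, log_d_mid, 1.0]
    else:
        def model(d, top, log_ec50, hill):
            return four_param_logistic(d, fix_bottom, top, 10.0**log_ec50, hill)
        p0 = [r_hi, log_d_mid, 1.0]

    try:
        with warnings.catch_warnings():
            # zero-dof (saturated) fits recover parameters but have no SE
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(model, doses, resp, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError):
        return failed
    if not np.all(np.isfinite(popt)):
        return failed

    if fix_bottom is None:
        bottom, top, log_ec50, hill = popt
        i_log = 2
    else:
        bottom = fix_bottom
        top, log_ec50, hill = popt
        i_log = 1
    ec50 = float(10.0**log_ec50)
    var_log = float(pcov[i_log, i_log]) if np.all(np.isfinite(pcov)) else math.nan
    # delta method: d(EC50)/d(log10 EC50) = EC50 * ln 10
    se_ec50 = ec50 * math.log(10.0) * math.sqrt(var_log) if var_log >= 0 else math.nan
    # a saturated (zero-dof) fit recovers parameters but has no SE
    converged = bool(np.isfinite(ec50) and ec50 > 0)
    return DoseResponseFit(
        ec50=ec50,
        hill=float(hill),
        bottom=float(bottom),
        top=float(top),
        se_ec50=se_ec50,
        converged=converged,
        extrapolated=not (doses.min() <= ec50 <= doses.max()),
    )


def delta_ct(ct_target: float, ct_reference: float) -> tuple[float, float]:
    """(dCt, relative expression 2**-dCt) for one target/reference pair.

    Replicate Ct values should be averaged BEFORE subtraction; pass the
    means here.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    dct = ct_target - ct_reference
    return dct, 2.0 ** (-dct)


def percent_of_control(rel_expression: float, rel_expression_control: float) -> float:
    """Relative expression as a percentage of a control's relative expression."""
    if rel_expression_control <= 0:
        raise ValueError("control relative expression must be positive")
    return 100.0 * rel_expression / rel_expression_control


def ca_delta_ratio(
    trace: CaTrace,
    baseline_window: slice | Sequence[int],
    response_window: slice | Sequence[int],
) -> tuple[np.ndarray, float]:
    """Ratio series F340/F380 and the response-minus-baseline delta ratio."""
    n = len(trace.f340)

    def _resolve(win) -> np.ndarray:
        idx = np.arange(n)[win] if isinstance(win, slice) else np.asarray(win, dtype=int)
        if idx.size == 0:
            raise ValueError("window selects no samples")
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError("window outside trace length")
        return idx

    base_idx = _resolve(baseline_window)
    resp_idx = _resolve(response_window)
    used = np.concatenate([base_idx, resp_idx])
    if np.any(trace.f380[used] <= 0):
        raise ValueError("f380 must be strictly positive within both windows")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = trace.f340 / trace.f380
    delta = float(np.mean(ratio[resp_idx]) - np.mean(ratio[base_idx]))
    return ratio, delta


# --- thin pass-throughs to standard test routines (figure-legend statistics) ---


def compare_two_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed unpaired t test; returns (statistic, p value)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def compare_multiple_groups(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA; returns (F statistic, p value)."""
    res = stats.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def holm_sidak_tests(
    pairs: Sequence[tuple[Sequence[float], Sequence[float]]]
) -> list[float]:
    """Multiple unpaired t tests with Holm-Sidak adjusted p values."""
    from statsmodels.stats.multitest import multipletests

    raw = [compare_two_groups(a, b)[1] for a, b in pairs]
    if not raw:
        return []
    return list(multipletests(raw, method="holm-sidak")[1])
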