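"""Tumor-discrimination metrics: CVR, AUROC, and the time of maximum contrast.

The contrast-to-variability ratio

    CVR = |mu_T - mu_B| / sqrt(sigma_T^2 + sigma_B^2)

compares the mean pixel signal in the tumor (mu_T) and background (mu_B)
regions against their pooled pixel-level spread; it tracks how well an ideal
observer could discriminate the two tissues.  AUROC is the nonparametric
(Mann-Whitney) probability that a randomly chosen tumor pixel outranks a
randomly chosen background pixel, with ties counted one half.

``find_tmax`` locates the frame of maximum CVR and the surrounding window in
which CVR stays at or above 98% of that maximum, the practically useful
imaging window for surgery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import mannwhitneyu

from .kinetics import bp_ratio

__all__ = [
    "RegionSamples",
    "MetricTimeSeries",
    "ContrastWindow",
    "cvr",
    "cvr_from_moments",
    "auroc",
    "metric_time_series",
    "find_tmax",
]


@dataclass(frozen=True)
class RegionSamples:
    """Pixel signal samples from the tumor and background regions."""

    tumor: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "tumor", np.asarray(self.tumor, dtype=float))
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if not (np.all(np.isfinite(self.tumor)) and np.all(np.isfinite(self.background))):
            raise ValueError("region samples must be finite")


@dataclass
class MetricTimeSeries:
    """CVR and AUROC per frame for one imaging protocol."""

    t: np.ndarray
    cvr: np.ndarray
    auroc: np.ndarray | None = None
    protocol: Literal["SA", "PA"] = "SA"


@dataclass(frozen=True)
class ContrastWindow:
    """Time of maximum CVR and the >= 98%-of-maximum window around it."""

    t_max: float
    cvr_max: float
    t_start_98: float
    t_end_98: float

    @property
    def duration(self) -> float:
        return self.t_end_98 - self.t_start_98


def cvr(samples: RegionSamples) -> float:
    """Contrast-to-variability ratio of tumor vs background pixel samples.

    Standard deviations are sample SDs (ddof=1), so each region needs at
    least two pixels.  A zero pooled variance is undefined and raises.
    """
    tum, bkg = samples.tumor, samples.background
    if tum.size < 2 or bkg.size < 2:
        raise ValueError("each region needs >= 2 samples for a sample SD")
    pooled = tum.var(ddof=1) + bkg.var(ddof=1)
    if pooled == 0:
        raise ValueError("zero pooled variance: CVR undefined")
    return float(abs(tum.mean() - bkg.mean()) / np.sqrt(pooled))


def cvr_from_moments(mu_T: float, mu_B: float, sd_T: float, sd_B: float) -> float:
    """CVR from region means and SDs (used with analytic noise models)."""
    pooled = sd_T**2 + sd_B**2
    if pooled <= 0:
        raise ValueError("zero pooled variance: CVR undefined")
    return abs(mu_T - mu_B) / np.sqrt(pooled)


def auroc(samples: RegionSamples) -> float:
    """Rank-based AUROC: P(tumor pixel > background pixel), ties counted 1/2."""
    tum, bkg = samples.tumor, samples.background
    if tum.size == 0 or bkg.size == 0:
        raise ValueError("both regions must be nonempty")
    u = mannwhitneyu(tum, bkg, alternative="two-sided").statistic
    return float(u / (tum.size * bkg.size))


def metric_time_series(
    stack_T: np.ndarray,
    stack_C: np.ndarray | None,
    tumor_mask: np.ndarray,
    background_mask: np.ndarray,
    t: np.ndarray,
    protocol: Literal["SA", "PA"] = "SA",
    compute_auroc: bool = True,
) -> MetricTimeSeries:
    """Per-frame CVR (and AUROC) from a dual-channel image time series.

    SA uses targeted-channel pixel values directly; PA uses the pixelwise
    binding-potential ratio of the targeted and control channels, so it
    requires ``stack_C``.  Masks must be disjoint and nonempty.  Frames in
    which a region has undefined pixels (e.g. zero control signal in the PA
    ratio) ignore those pixels.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if np.any(tumor_mask & background_mask):
        raise ValueError("tumor and background masks overlap")
    if not tumor_mask.any() or not background_mask.any():
        raise ValueError("masks must be nonempty")
    stack_T = np.asarray(stack_T, dtype=float)
    t = np.asarray(t, dtype=float)
    if stack_T.shape[0] != t.size:
        raise ValueError("stack and time grid lengths differ")
    if protocol == "PA":
        if stack_C is None:
            raise ValueError("PA protocol requires the control stack")
        stack_C = np.asarray(stack_C, dtype=float)
        if stack_C.shape != stack_T.shape:
            raise ValueError("channel stacks must have the same shape")

    cvrs = np.empty(t.size)
    aucs = np.empty(t.size) if compute_auroc else None
    for i in range(t.size):
        if protocol == "PA":
            frame = bp_ratio(stack_T[i], stack_C[i])
        else:
            frame = stack_T[i]
        tum = frame[tumor_mask]
        bkg = frame[background_mask]
        tum = tum[np.isfinite(tum)]
        bkg = bkg[np.isfinite(bkg)]
        samples = RegionSamples(tum, bkg)
        # frames with no usable pixels or zero pooled variance (e.g. the
        # all-zero injection frame) are undefined, not an error
        try:
            cvrs[i] = cvr(samples)
        except ValueError:
            cvrs[i] = np.nan
        if compute_auroc:
            try:
                aucs[i] = auroc(samples)
            except ValueError:
                aucs[i] = np.nan
    return MetricTimeSeries(t=t, cvr=cvrs, auroc=aucs, protocol=protocol)


def _crossing_time(t0, t1, c0, c1, level):
    """Linear interpolation of the time at which the curve crosses `level`."""
    if c1 == c0:
        return t0
    return t0 + (level - c0) * (t1 - t0) / (c1 - c0)


def find_tmax(
    series: MetricTimeSeries,
    smooth_window: int | None = None,
) -> ContrastWindow:
    """Locate the CVR maximum and its 98%-of-maximum window.

    The peak is the first frame attaining the maximum; window edges are
    found by linear interpolation between frames at the 0.98*max level.  An
    optional centered moving average (odd ``smooth_window``) can be applied
    first for noisy experimental curves.
    """
    t = np.asarray(series.t, dtype=float)
    c = np.asarray(series.cvr, dtype=float)
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        c = np.convolve(np.pad(c, pad, mode="edge"), kernel, mode="valid")
    finite = np.isfinite(c)
    if not finite.any():
        raise ValueError("CVR series is all-NaN")
    cmax = np.nanmax(c)
    imax = int(np.nanargmax(c))
    level = 0.98 * cmax

    i = imax
    while i > 0 and np.isfinite(c[i - 1]) and c[i - 1] >= level:
        i -= 1
    if i == 0 or not np.isfinite(c[i - 1]):
        t_start = t[i]
    else:
        t_start = _crossing_time(t[i - 1], t[i], c[i - 1], c[i], level)

    j = imax
    n = t.size
    while j < n - 1 and np.isfinite(c[j + 1]) and c[j + 1] >= level:
        j += 1
    if j == n - 1 or not np.isfinite(c[j + 1]):
        t_end = t[j]
    else:
        t_end = _crossing_time(t[j], t[j + 1], c[j], c[j + 1], level)

    return ContrastWindow(
        t_max=float(t[imax]),
        cvr_max=float(cmax),
        t_start_98=float(t_start),
        t_end_98=float(t_end),
    )
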