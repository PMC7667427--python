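"""Closed-form time-to-maximum-contrast predictions.

For single-agent (SA) imaging the time of maximum tumor contrast is set by
the competition between uptake of the targeted agent in tumor and normal
tissue:

    Tmax_SA = ln(K1n / K1t) / (k2n - k2a),

where ``K1t``/``K1n`` are the tumor/normal extravasation rates, ``k2n`` the
normal-tissue efflux rate, and ``k2a = k2t / (1 + BP)`` the apparent tumor
efflux rate slowed by reversible receptor binding (binding potential BP).
The expression can be negative (contrast is then maximal immediately after
injection); such values are clamped to zero and flagged.

For paired-agent (PA) imaging the prediction depends only on the tumor
efflux rate and the binding potential:

    Tmax_PA = 10 / (k2t - k2a) * ln[(1/k2t^2 - 1/k2a^2) /
                                    (2/k2t^2 - 2/(k2t*k2a))].

Both log arguments are negative whenever k2a < k2t, so the difference of
logs is evaluated as the log of the (positive) ratio, which simplifies
algebraically to ln((2 + BP)/2).  The leading factor of 10 is an empirical
proportionality correction to the underlying derivation and is kept as
printed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SAInputs",
    "PAInputs",
    "SAPrediction",
    "k2_apparent",
    "tmax_sa",
    "tmax_pa",
    "tmax_lookup_grid",
]


@dataclass(frozen=True)
class SAInputs:
    """Parameters for the single-agent prediction (all rates 1/min)."""

    K1_tumor: float
    K1_normal: float
    k2_tumor: float
    k2_normal: float
    BP: float

    def __post_init__(self) -> None:
        for name in ("K1_tumor", "K1_normal", "k2_tumor", "k2_normal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.BP < 0:
            raise ValueError("BP must be nonnegative")


@dataclass(frozen=True)
class PAInputs:
    """Parameters for the paired-agent prediction."""

    k2_tumor: float
    BP: float

    def __post_init__(self) -> None:
        if self.k2_tumor <= 0:
            raise ValueError("k2_tumor must be positive")
        if self.BP < 0:
            raise ValueError("BP must be nonnegative")


@dataclass(frozen=True)
class SAPrediction:
    """SA prediction with a flag for immediately maximal contrast."""

    tmax: float
    contrast_immediate: bool = False


def k2_apparent(k2: float, BP: float) -> float:
    """Apparent efflux rate k2/(1+BP) of a reversibly bound agent (1/min)."""
    if k2 < 0 or BP < 0:
        raise ValueError("k2 and BP must be nonnegative")
    return k2 / (1.0 + BP)


def tmax_sa(x: SAInputs) -> SAPrediction:
    """Predicted time of maximum single-agent contrast (min).

    Negative raw values mean the tumor outpaces normal tissue from the
    start; they are clamped to zero with ``contrast_immediate`` set.
    """
    k2a = k2_apparent(x.k2_tumor, x.BP)
    denom = x.k2_normal - k2a
    if denom == 0:
        raise ZeroDivisionError("k2_normal equals the apparent tumor efflux rate")
    raw = np.log(x.K1_normal / x.K1_tumor) / denom
    if raw <= 0:
        return SAPrediction(tmax=0.0, contrast_immediate=True)
    return SAPrediction(tmax=float(raw))


def tmax_pa(x: PAInputs) -> float:
    """Predicted time of maximum paired-agent contrast (min).

    Requires BP > 0 so that k2a < k2 and the log argument is defined.
    """
    if x.BP == 0:
        raise ZeroDivisionError("BP = 0 makes k2a = k2: PA prediction singular")
    k2 = x.k2_tumor
    k2a = k2_apparent(k2, x.BP)
    num = 1.0 / k2**2 - 1.0 / k2a**2
    den = 2.0 / k2**2 - 2.0 / (k2 * k2a)
    return float(10.0 / (k2 - k2a) * np.log(num / den))


def tmax_lookup_grid(
    axis1: np.ndarray,
    axis2: np.ndarray,
    protocol: str,
    k2_normal: float | None = None,
) -> np.ndarray:
    """Grid of predicted Tmax values for lookup-table style plots.

    SA convention: ``axis1`` is the normal-to-tumor extravasation ratio
    K1n/K1t, ``axis2`` is the apparent tumor efflux rate k2a, and the
    normal efflux rate ``k2_normal`` must be supplied explicitly.  PA
    convention: ``axis1`` is BP and ``axis2`` is the tumor k2.  Singular
    cells are returned as NaN.  Shape is (len(axis2), len(axis1)).
    """
    axis1 = np.asarray(axis1, dtype=float)
    axis2 = np.asarray(axis2, dtype=float)
    out = np.full((axis2.size, axis1.size), np.nan)
    if protocol == "SA":
        if k2_normal is None:
            raise ValueError("SA grid requires an explicit k2_normal")
        for i, k2a in enumerate(axis2):
            denom = k2_normal - k2a
            for j, ratio in enumerate(axis1):
                if ratio <= 0 or denom == 0:
                    continue
                raw = np.log(ratio) / denom
                out[i, j] = max(raw, 0.0)
    elif protocol == "PA":
        for i, k2 in enumerate(axis2):
            for j, bp in enumerate(axis1):
                if bp <= 0 or k2 <= 0:
                    continue
                out[i, j] = tmax_pa(PAInputs(k2_tumor=k2, BP=bp))
    else:
        raise ValueError("protocol must be 'SA' or 'PA'")
    return out
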