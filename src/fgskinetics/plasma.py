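"""Biexponential plasma input functions.

The blood-plasma concentration of an intravenously injected imaging agent is
modeled as a biexponential decay,

    Cp(t) = scale * (A * exp(-alpha * t) + B * exp(-beta * t)),

where ``A``/``alpha`` describe the fast distribution phase and ``B``/``beta``
the slow elimination phase.  Time is in minutes, rate constants in 1/min, and
``scale`` (nM) maps the unitless biexponential onto an absolute plasma
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlasmaInput"]


@dataclass(frozen=True)
class PlasmaInput:
    """Biexponential plasma input function.

    Parameters
    ----------
    A : float
        Distribution-phase fraction (unitless, >= 0).
    alpha : float
        Distribution-phase decay constant (1/min, > 0).
    B : float
        Elimination-phase fraction (unitless, >= 0).
    beta : float
        Elimination-phase decay constant (1/min, > 0).
    scale : float, optional
        Reference plasma concentration (nM) multiplying the unitless
        biexponential.  Default 1.
    """

    A: float
    alpha: float
    B: float
    beta: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.A < 0 or self.B < 0:
            raise ValueError("A and B must be nonnegative")
        if self.A + self.B <= 0:
            raise ValueError("A + B must be positive")
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")

    def concentration(self, t):
        """Plasma concentration Cp(t) in nM.

        ``t`` may be a scalar or array of times in minutes; negative times
        raise ``ValueError``.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        out = self.scale * (
            self.A * np.exp(-self.alpha * t) + self.B * np.exp(-self.beta * t)
        )
        return out if out.ndim else float(out)

    @classmethod
    def monoexponential(cls, rate: float, scale: float = 1.0) -> "PlasmaInput":
        """Single-exponential input exp(-rate*t), as used in analytical work."""
        return cls(A=1.0, alpha=rate, B=0.0, beta=rate, scale=scale)


def plasma_concentration(p: PlasmaInput, t):
    """Functional alias for :meth:`PlasmaInput.concentration`."""
    return p.concentration(t)
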