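"""Packaged parameter presets for imaging-agent classes.

``AGENT_PRESETS`` holds the per-class plasma and tissue kinetic parameters
used for the mouse-mimicking simulations: biexponential plasma constants
(A, alpha, B, beta), tumor/normal K1 and k2 means and SDs (1/min), and the
in-vitro binding constants kon (1/nM/min), koff (1/min), and KD (nM).  The
A431 tumor line has its own, higher-uptake K1/k2 statistics for the peptide
agent; all other entries describe U251 xenografts.

``CLASS_RANGES`` holds the human-cancer parameter ranges (uniform min/max)
for the four hypothetical agent classes of the Monte-Carlo study: peptides,
low-molecular-weight antibody fragments (centyrins, affibodies, knottins),
high-MW fragments (Fab, diabody, scFv), and whole antibodies (IgG,
minibody).
"""

from __future__ import annotations

from dataclasses import dataclass

from .plasma import PlasmaInput

__all__ = [
    "AgentPreset",
    "ClassRanges",
    "AGENT_PRESETS",
    "CLASS_RANGES",
    "agent_preset",
    "class_ranges",
]


@dataclass(frozen=True)
class AgentPreset:
    """Plasma and tissue kinetics of one imaging-agent class in one tumor line."""

    name: str
    plasma: PlasmaInput
    K1_tumor: float
    K1_tumor_sd: float
    k2_tumor: float
    k2_tumor_sd: float
    K1_normal: float
    K1_normal_sd: float
    k2_normal: float
    k2_normal_sd: float
    kon: float
    koff: float
    KD_printed: float

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant derived from koff/kon (nM)."""
        return self.koff / self.kon


@dataclass(frozen=True)
class ClassRanges:
    """Uniform sampling ranges (min, max) for one hypothetical agent class."""

    name: str
    K1_tumor: tuple[float, float]
    k2_tumor: tuple[float, float]
    K1_normal: tuple[float, float]
    k2_normal: tuple[float, float]
    BP: tuple[float, float]

    def __post_init__(self) -> None:
        for field_name in ("K1_tumor", "k2_tumor", "K1_normal", "k2_normal", "BP"):
            lo, hi = getattr(self, field_name)
            if not (0 < lo <= hi):
                raise ValueError(f"{field_name} range must satisfy 0 < min <= max")


_PLASMA = {
    "peptide": PlasmaInput(A=0.02, alpha=0.3, B=2e-3, beta=6e-4),
    "affibody": PlasmaInput(A=0.6, alpha=0.2, B=0.4, beta=5e-3),
    "antibody": PlasmaInput(A=0.4, alpha=0.03, B=0.5, beta=3e-4),
}

AGENT_PRESETS: dict[str, AgentPreset] = {
    "peptide-U251": AgentPreset(
        name="peptide-U251",
        plasma=_PLASMA["peptide"],
        K1_tumor=0.4, K1_tumor_sd=0.2,
        k2_tumor=0.2, k2_tumor_sd=0.2,
        K1_normal=0.1, K1_normal_sd=0.03,
        k2_normal=0.02, k2_normal_sd=0.01,
        kon=0.1, koff=0.1, KD_printed=1.0,
    ),
    "peptide-A431": AgentPreset(
        name="peptide-A431",
        plasma=_PLASMA["peptide"],
        K1_tumor=0.3, K1_tumor_sd=0.2,
        k2_tumor=0.2, k2_tumor_sd=0.2,
        K1_normal=0.1, K1_normal_sd=0.04,
        k2_normal=0.03, k2_normal_sd=0.01,
        kon=0.1, koff=0.1, KD_printed=1.0,
    ),
    "affibody-U251": AgentPreset(
        name="affibody-U251",
        plasma=_PLASMA["affibody"],
        K1_tumor=0.01, K1_tumor_sd=0.04,
        k2_tumor=0.3, k2_tumor_sd=0.6,
        K1_normal=0.01, K1_normal_sd=0.02,
        k2_normal=0.3, k2_normal_sd=0.2,
        kon=0.04, koff=0.1, KD_printed=3.0,
    ),
    "antibody-U251": AgentPreset(
        name="antibody-U251",
        plasma=_PLASMA["antibody"],
        K1_tumor=2e-4, K1_tumor_sd=0.0,
        k2_tumor=8e-3, k2_tumor_sd=0.0,
        K1_normal=2e-4, K1_normal_sd=0.0,
        k2_normal=8e-3, k2_normal_sd=0.0,
        kon=0.16, koff=0.07, KD_printed=0.4,
    ),
}

CLASS_RANGES: dict[str, ClassRanges] = {
    "peptide": ClassRanges(
        name="peptide",
        K1_tumor=(0.18, 0.63),
        k2_tumor=(0.29, 1.03),
        K1_normal=(0.16, 0.43),
        k2_normal=(0.26, 0.7),
        BP=(13.5, 67.5),
    ),
    "lowmw": ClassRanges(
        name="lowmw",
        K1_tumor=(0.0198, 0.0952),
        k2_tumor=(0.032, 0.156),
        K1_normal=(0.0196, 0.0906),
        k2_normal=(0.032, 0.148),
        BP=(13.12, 15.0),
    ),
    "highmw": ClassRanges(
        name="highmw",
        K1_tumor=(0.002, 0.01),
        k2_tumor=(3.28e-3, 0.0164),
        K1_normal=(0.002, 0.01),
        k2_normal=(0.003, 0.016),
        BP=(0.187, 3.75),
    ),
    "antibody": ClassRanges(
        name="antibody",
        K1_tumor=(2.1e-4, 5.6e-3),
        k2_tumor=(2.4e-4, 9.1e-3),
        K1_normal=(3.1e-4, 5.6e-3),
        k2_normal=(5.1e-4, 9.2e-3),
        BP=(0.0185, 0.037),
    ),
}

# Elimination-phase plasma decay constants used when the Monte-Carlo study
# runs with a monoexponential plasma input.  Peptides and antibodies take
# their class's fitted elimination constant; low-MW fragments take the
# affibody value; high-MW fragments (no fitted class of their own) take the
# geometric mean of the affibody and antibody values.
CLASS_PLASMA_DECAY: dict[str, float] = {
    "peptide": 6e-4,
    "lowmw": 5e-3,
    "highmw": (5e-3 * 3e-4) ** 0.5,
    "antibody": 3e-4,
}

# Biexponential plasma models for the study's optional full-input mode.
CLASS_PLASMA_BIEXP: dict[str, PlasmaInput] = {
    "peptide": _PLASMA["peptide"],
    "lowmw": _PLASMA["affibody"],
    "highmw": PlasmaInput(A=0.5, alpha=0.08, B=0.45, beta=(5e-3 * 3e-4) ** 0.5),
    "antibody": _PLASMA["antibody"],
}

# Class-adaptive noise-free simulation grids for the study: (t_end_min, dt_min).
CLASS_TIME_GRIDS: dict[str, tuple[float, float]] = {
    "peptide": (600.0, 0.25),
    "lowmw": (600.0, 0.25),
    "highmw": (7200.0, 2.0),
    "antibody": (7200.0, 2.0),
}


def agent_preset(agent: str, cell_line: str = "U251") -> AgentPreset:
    """Look up a mouse-experiment preset by agent class and tumor line."""
    key = f"{agent}-{cell_line}"
    if key not in AGENT_PRESETS:
        raise KeyError(
            f"unknown preset {key!r}; available: {sorted(AGENT_PRESETS)}"
        )
    return AGENT_PRESETS[key]


def class_ranges(name: str) -> ClassRanges:
    """Look up the human-cancer parameter ranges for a study class."""
    if name not in CLASS_RANGES:
        raise KeyError(f"unknown class {name!r}; available: {sorted(CLASS_RANGES)}")
    return CLASS_RANGES[name]
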