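"""Versioned physical and biological constants used across the package.

Everything here is a *default*: operations take these values as parameters
so that alternative constants (e.g. a different biomass yield) can be
supplied without touching any computation code.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Molar mass (g mol-1) and signed charge for the major ions handled by the
#: milliequivalent conversion. IUPAC 2021 atomic weights.
ION_PROPERTIES: dict[str, tuple[float, int]] = {
    "Na": (22.98977, +1),
    "K": (39.0983, +1),
    "Ca": (40.078, +2),
    "Mg": (24.305, +2),
    "Cl": (35.453, -1),
    "SO4": (96.06, -2),
    "HCO3": (61.0168, -1),
    "CO3": (60.008, -2),
}

CATIONS = tuple(k for k, (_, z) in ION_PROPERTIES.items() if z > 0)
ANIONS = tuple(k for k, (_, z) in ION_PROPERTIES.items() if z < 0)

#: Molar mass of O2, g mol-1.
O2_MOLAR_MASS = 31.998


@dataclass(frozen=True)
class AgeTracerConstants:
    """Constants for tritium / radiocarbon groundwater dating.

    tritium_half_life
        Half-life of tritium in years.
    tritium_detection
        Analytical precision of the liquid scintillation method, TU; samples
        at or below this are treated as tritium-absent.
    libby_mean_life
        Conventional (Libby) radiocarbon mean life in years; the uncorrected
        age is ``-libby_mean_life * ln(F14C)``.
    c14_age_ceiling
        Age (years BP) at which the radiocarbon method saturates; older
        results are flagged as at-detection-limit.
    """

    tritium_half_life: float = 12.4
    tritium_detection: float = 0.8
    libby_mean_life: float = 8033.0
    c14_age_ceiling: float = 40_000.0

    def __post_init__(self) -> None:
        for name in (
            "tritium_half_life",
            "tritium_detection",
            "libby_mean_life",
            "c14_age_ceiling",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BudgetConstants:
    """Defaults converting respired O2 into sustainable cell abundance.

    yield_biomass
        Dry biomass produced per mol O2 respired (g mol-1). Literature
        aerobic-heterotroph growth yields cluster around ~10 g dry mass per
        mol O2 once maintenance is accounted for; treat as configurable.
    cell_mass
        Dry mass per microbial cell (g). 2e-13 g (200 fg) is a standard
        planktonic-cell literature value; groundwater cells are often
        smaller, which would make the sustainable-cell estimate conservative.
    """

    yield_biomass: float = 10.0
    cell_mass: float = 2e-13
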