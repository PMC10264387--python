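"""Methane/CO2 and sulfate isotope systematics: enrichment factors,
genetic-zone classification of methane, and Rayleigh modelling of microbial
sulfate reduction.

The CO2-CH4 enrichment factor eps_C separates methanogenic pathways:
hydrogenotrophic (CO2-reducing) methanogenesis imposes large carbon
fractionation (eps_C roughly >= 65 per mil), aceticlastic/methylotrophic
methanogenesis less (~40-65), while microbial methane oxidation preferentially
removes light methane, leaving a 13C-enriched residue at low concentration
and compressing eps_C. Zone boundaries are configuration, not constants: the
published fields are drawn graphically, so the defaults here are a
conventional reconstruction (flagged in output metadata).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .conventions import epsilon_between, rayleigh_residual_delta


def epsilon_co2_ch4(d13c_co2: float, d13c_ch4: float) -> float:
    """Exact CO2-CH4 carbon enrichment factor, per mil.

    eps = ((1000 + dCO2) / (1000 + dCH4) - 1) * 1000. Note the exact form is
    not antisymmetric under argument exchange.
    """
    return float(epsilon_between(d13c_co2, d13c_ch4))


class MethaneProcess(str, enum.Enum):
    HYDROGENOTROPHIC = "hydrogenotrophic"
    ACETICLASTIC_METHYLOTROPHIC = "aceticlastic_methylotrophic"
    OXIDATION_INFLUENCED = "oxidation_influenced"
    MIXED_INDETERMINATE = "mixed_indeterminate"


@dataclass(frozen=True)
class MethaneZones:
    """Genetic-zone boundaries in (eps_C, d13C-CH4, concentration) space.

    Boundaries are closed on the enriched/hydrogenotrophic side
    (eps_C >= eps_hydrogenotrophic_min classifies as hydrogenotrophic).
    ``boundary_margin`` controls the near-boundary confidence note.
    """

    eps_hydrogenotrophic_min: float = 65.0
    eps_acmr_min: float = 40.0
    ch4_low: float = 1.0  # mg L-1
    d13c_ch4_enriched: float = -50.0  # per mil V-PDB
    d13c_ch4_hydrogenotrophic_max: float = -60.0  # fallback axis
    boundary_margin: float = 2.0
    reconstructed: bool = True  # boundaries are a reconstruction, not published


@dataclass(frozen=True)
class MethaneSystematics:
    """One sample's methane/CO2 measurements; eps_c derived on construction."""

    ch4: float | None = None
    d13c_ch4: float | None = None
    d2h_ch4: float | None = None
    d13c_co2: float | None = None

    @property
    def epsilon_c(self) -> float | None:
        if self.d13c_co2 is None or self.d13c_ch4 is None:
            return None
        return epsilon_co2_ch4(self.d13c_co2, self.d13c_ch4)


@dataclass(frozen=True)
class MethaneClassification:
    label: MethaneProcess
    epsilon_c: float | None
    notes: tuple[str, ...] = ()


def classify_methane_process(
    sys: MethaneSystematics, zones: MethaneZones = MethaneZones()
) -> MethaneClassification:
    """Assign exactly one genetic label to a methane sample.

    Zone lookup order: oxidation influence (low concentration with enriched
    residual methane), then hydrogenotrophic (large eps_C, or strongly
    depleted d13C-CH4 when CO2 data are missing), then
    aceticlastic/methylotrophic, else mixed/indeterminate. Indeterminate is
    a valid outcome, never an exception. A note is attached when the sample
    sits within ``boundary_margin`` of a zone edge, and when classification
    had to proceed on degraded inputs.
    """
    notes: list[str] = []
    if zones.reconstructed:
        notes.append("zone boundaries are a config-default reconstruction")
    if sys.d13c_ch4 is None:
        notes.append("no d13C-CH4: indeterminate")
        return MethaneClassification(MethaneProcess.MIXED_INDETERMINATE, None, tuple(notes))
    eps = sys.epsilon_c
    if eps is None:
        notes.append("d13C-CO2 missing; classified on d13C-CH4 and concentration only")

    low_ch4 = sys.ch4 is not None and sys.ch4 < zones.ch4_low
    enriched = sys.d13c_ch4 > zones.d13c_ch4_enriched

    if low_ch4 and enriched:
        if sys.ch4 is not None and abs(sys.ch4 - zones.ch4_low) < 0.1 * zones.ch4_low:
            notes.append("CH4 concentration near the low-concentration boundary")
        return MethaneClassification(MethaneProcess.OXIDATION_INFLUENCED, eps, tuple(notes))

    if eps is not None:
        if abs(eps - zones.eps_hydrogenotrophic_min) < zones.boundary_margin or (
            abs(eps - zones.eps_acmr_min) < zones.boundary_margin
        ):
            notes.append("eps_C within the boundary margin of a zone edge")
        if eps >= zones.eps_hydrogenotrophic_min:
            return MethaneClassification(MethaneProcess.HYDROGENOTROPHIC, eps, tuple(notes))
        if eps >= zones.eps_acmr_min:
            return MethaneClassification(
                MethaneProcess.ACETICLASTIC_METHYLOTROPHIC, eps, tuple(notes)
            )
        if eps < zones.eps_acmr_min:
            return MethaneClassification(MethaneProcess.OXIDATION_INFLUENCED, eps, tuple(notes))

    # eps unavailable: fall back to the d13C-CH4 axis alone
    if sys.d13c_ch4 <= zones.d13c_ch4_hydrogenotrophic_max:
        return MethaneClassification(MethaneProcess.HYDROGENOTROPHIC, eps, tuple(notes))
    if enriched:
        return MethaneClassification(MethaneProcess.OXIDATION_INFLUENCED, eps, tuple(notes))
    return MethaneClassification(MethaneProcess.MIXED_INDETERMINATE, eps, tuple(notes))


def rayleigh_sulfate(d34s_0: float, f: float, epsilon_s: float) -> float:
    """d34S of residual sulfate after reduction to fraction f remaining.

    Same Rayleigh form (and implementation) as O2 respiration: sulfate
    reducers preferentially consume 32S-sulfate, enriching the residual pool
    as concentration falls.
    """
    return float(rayleigh_residual_delta(d34s_0, f, epsilon_s))


@dataclass(frozen=True)
class SulfateSystematics:
    so4: float = 0.0  # mg L-1
    d34s_so4: float | None = None  # per mil V-CDT
    d18o_so4: float | None = None  # per mil V-SMOW

    def __post_init__(self) -> None:
        if self.so4 < 0:
            raise ValueError("sulfate concentration must be >= 0")
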