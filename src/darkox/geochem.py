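"""Domain types, milliequivalent chemistry, water-type (hydrochemical facies)
classification, and groundwater age-tracer utilities.

Water-type labels follow the geochemical-evolution sequence of prairie
aquifer systems: young tritium-bearing low-TDS Ca-HCO3 waters, intermediate
waters, and two old tritium-dead facies distinguished by whether sulfate is
the dominant anion (sulfate-rich Na/Mg-SO4 waters from pyrite oxidation and
evaporite dissolution) or not (sulfate-poor, typically methanic Na-HCO3-Cl
waters).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

from .constants import ANIONS, CATIONS, ION_PROPERTIES, AgeTracerConstants


class BelowDetection:
    """A measurement below the analytical detection limit.

    Carries the limit itself so downstream operations can decide how to
    treat the censored value; it is never silently coerced to zero.
    """

    __slots__ = ("limit",)

    def __init__(self, limit: float = 0.0):
        self.limit = float(limit)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.limit:g}"

    def __eq__(self, other) -> bool:
        return isinstance(other, BelowDetection) and other.limit == self.limit

    def __hash__(self) -> int:
        return hash(("BelowDetection", self.limit))


def is_below_detection(value) -> bool:
    return isinstance(value, BelowDetection)


class WaterType(str, enum.Enum):
    YOUNG = "young"
    INTERMEDIATE = "intermediate"
    OLD_SULFATE_RICH = "old_sulfate_rich"
    OLD_SULFATE_POOR = "old_sulfate_poor"
    UNCLASSIFIED = "unclassified"


@dataclass
class WellSample:
    """One groundwater sample: ions, field parameters, tracers, gases, isotopes.

    Concentrations are mg L-1, depth m, temperature degC, tritium TU, f14c
    fraction modern, delta values per mil against the standard named in the
    field comment. ``do_measured`` may be a :class:`BelowDetection` flag.
    """

    well_id: str
    sample_id: str
    depth: float | None = None
    temperature: float | None = None
    ions: dict[str, float] = field(default_factory=dict)
    tds: float | None = None
    do_measured: float | BelowDetection | None = None
    orp: float | None = None  # mV
    ec: float | None = None  # uS cm-1
    tritium: float | BelowDetection | None = None  # TU
    f14c: float | None = None  # fraction modern
    ch4: float | None = None  # mg L-1
    d13c_ch4: float | None = None  # per mil V-PDB
    d13c_co2: float | None = None  # per mil V-PDB
    d2h_ch4: float | None = None  # per mil V-SMOW
    d34s_so4: float | None = None  # per mil V-CDT
    d18o_so4: float | None = None  # per mil V-SMOW
    d18o_h2o: float | None = None  # per mil V-SMOW
    water_type: WaterType = WaterType.UNCLASSIFIED

    def __post_init__(self) -> None:
        for name, value in self.ions.items():
            if name not in ION_PROPERTIES:
                raise ValueError(f"unknown ion {name!r}")
            if value is not None and value < 0:
                raise ValueError(f"ion {name} concentration must be >= 0")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.tds is not None and self.tds < 0:
            raise ValueError("tds must be >= 0")
        if self.f14c is not None and not (0.0 <= self.f14c <= 1.5):
            raise ValueError("f14c must lie in [0, 1.5]")
        if (
            self.tritium is not None
            and not is_below_detection(self.tritium)
            and self.tritium < 0
        ):
            raise ValueError("tritium must be >= 0")
        if (
            self.do_measured is not None
            and not is_below_detection(self.do_measured)
            and self.do_measured < 0
        ):
            raise ValueError("dissolved oxygen must be >= 0")
        if self.ch4 is not None and self.ch4 < 0:
            raise ValueError("ch4 must be >= 0")


# ---------------------------------------------------------------------------
# Milliequivalent chemistry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeqResult:
    """Milliequivalent concentrations and charge-family fractions."""

    cation_meq: dict[str, float]
    anion_meq: dict[str, float]
    cation_fractions: dict[str, float]
    anion_fractions: dict[str, float]


class DegenerateIonsError(ValueError):
    """All cations (or all anions) are zero; meq fractions are undefined."""


def meq_per_litre(ion: str, mg_per_litre: float) -> float:
    """Convert one ion's mg L-1 to meq L-1 via meq = mg / (M / |z|)."""
    molar_mass, charge = ION_PROPERTIES[ion]
    return mg_per_litre / (molar_mass / abs(charge))


def meq_fractions(ions: Mapping[str, float]) -> MeqResult:
    """Cation and anion milliequivalent fractions (each family sums to 1).

    This is the conversion underlying Piper-diagram coordinates. Ions absent
    from the mapping are treated as zero. Raises
    :class:`DegenerateIonsError` when a whole charge family is zero.
    """
    cat = {i: meq_per_litre(i, ions.get(i, 0.0) or 0.0) for i in CATIONS}
    an = {i: meq_per_litre(i, ions.get(i, 0.0) or 0.0) for i in ANIONS}
    cat_total = sum(cat.values())
    an_total = sum(an.values())
    if cat_total <= 0:
        raise DegenerateIonsError("all cation concentrations are zero")
    if an_total <= 0:
        raise DegenerateIonsError("all anion concentrations are zero")
    return MeqResult(
        cation_meq=cat,
        anion_meq=an,
        cation_fractions={i: v / cat_total for i, v in cat.items()},
        anion_fractions={i: v / an_total for i, v in an.items()},
    )


def dominant_anion(ions: Mapping[str, float]) -> str:
    """Anion with the largest milliequivalent fraction."""
    fractions = meq_fractions(ions).anion_fractions
    return max(fractions, key=fractions.get)


def ca_na_ratio(ions: Mapping[str, float]) -> float:
    """Calcium/sodium *mass* ratio (mg L-1 over mg L-1), the residence-time proxy."""
    na = ions.get("Na", 0.0) or 0.0
    if na <= 0:
        raise ValueError("Ca/Na ratio undefined: Na is zero or missing")
    return (ions.get("Ca", 0.0) or 0.0) / na


# ---------------------------------------------------------------------------
# Age tracers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class C14Age:
    """Uncorrected radiocarbon age with censoring flags."""

    years_bp: float
    at_ceiling: bool = False
    modern: bool = False


def uncorrected_c14_age(
    f14c: float, constants: AgeTracerConstants = AgeTracerConstants()
) -> C14Age:
    """Uncorrected age t = -libby_mean_life * ln(F14C), years BP.

    ``f14c > 1`` (post-bomb carbon) returns age 0 with a ``modern`` flag;
    ages at or beyond the method ceiling carry an ``at_ceiling`` flag.
    """
    if f14c <= 0:
        raise ValueError("F14C must be > 0 for a finite age")
    if f14c > 1.0:
        return C14Age(0.0, modern=True)
    age = -constants.libby_mean_life * math.log(f14c)
    return C14Age(age, at_ceiling=age >= constants.c14_age_ceiling)


def tritium_decay(
    a0: float, t: float, constants: AgeTracerConstants = AgeTracerConstants()
) -> float:
    """Remaining tritium activity after t years: a0 * 2**(-t / half_life)."""
    if a0 < 0:
        raise ValueError("initial activity must be >= 0")
    if t < 0:
        raise ValueError("elapsed time must be >= 0")
    return a0 * 2.0 ** (-t / constants.tritium_half_life)


# ---------------------------------------------------------------------------
# Water-type classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterTypeRules:
    """Config-driven facies rules; defaults are the TDS bounds of the
    geochemical-evolution sequence (young < 400, old > 900, sulfate-rich
    > 1700 mg L-1). Ties at a bound resolve to the younger class."""

    tds_young_max: float = 400.0
    tds_old_min: float = 900.0
    tds_sulfate_rich_min: float = 1700.0
    tritium_detection: float = 0.8
    f14c_modern_min: float = 0.9  # proxy used only when tritium is missing
    age_constants: AgeTracerConstants = AgeTracerConstants()


@dataclass(frozen=True)
class Classification:
    water_type: WaterType
    trace: tuple[str, ...]
    flags: tuple[str, ...] = ()


def classify_water_type(
    sample: WellSample, rules: WaterTypeRules = WaterTypeRules()
) -> Classification:
    """Deterministic, auditable water-type label.

    Default rule set (first match wins, trace records every rule fired):

    1. missing TDS, or missing both tritium and F14C -> unclassified
    2. tracer-modern and TDS < tds_young_max           -> young
    3. tracer-dead and TDS > tds_sulfate_rich_min
       and SO4 is the dominant anion (meq)             -> old_sulfate_rich
    4. tracer-dead and TDS > tds_old_min
       and SO4 not dominant                            -> old_sulfate_poor
    5. otherwise                                       -> intermediate

    "Tracer-modern" means tritium above the detection limit; when tritium is
    absent from the record, F14C >= f14c_modern_min is used as the modern
    proxy. A tritium-positive sample whose F14C sits at the radiocarbon
    ceiling is contradictory and is flagged (not fatal). This function is
    total on complete records: it never raises for any numeric input.
    """
    trace: list[str] = []
    flags: list[str] = []

    tritium = sample.tritium
    if is_below_detection(tritium):
        tritium = 0.0
    if sample.tds is None or (tritium is None and sample.f14c is None):
        trace.append("missing TDS or both age tracers -> unclassified")
        return Classification(WaterType.UNCLASSIFIED, tuple(trace), tuple(flags))

    if tritium is not None:
        modern = tritium > rules.tritium_detection
        trace.append(
            f"tritium {tritium:g} TU {'>' if modern else '<='} "
            f"detection {rules.tritium_detection:g} TU"
        )
    else:
        modern = sample.f14c >= rules.f14c_modern_min
        trace.append(
            f"tritium missing; F14C {sample.f14c:g} "
            f"{'>=' if modern else '<'} modern proxy {rules.f14c_modern_min:g}"
        )

    if tritium is not None and tritium > rules.tritium_detection and sample.f14c is not None:
        age = uncorrected_c14_age(sample.f14c, rules.age_constants) if sample.f14c > 0 else None
        if age is not None and age.at_ceiling:
            flags.append(
                "contradictory tracers: tritium-positive but F14C at the age ceiling"
            )

    so4_dominant = False
    try:
        dom = dominant_anion(sample.ions)
        so4_dominant = dom == "SO4"
        trace.append(f"dominant anion (meq): {dom}")
    except (DegenerateIonsError, KeyError):
        trace.append("anion data absent; SO4 dominance unknown (treated as not dominant)")

    tds = sample.tds
    if modern and tds < rules.tds_young_max:
        trace.append(f"TDS {tds:g} < {rules.tds_young_max:g} -> young")
        return Classification(WaterType.YOUNG, tuple(trace), tuple(flags))
    if not modern and tds > rules.tds_sulfate_rich_min and so4_dominant:
        trace.append(
            f"TDS {tds:g} > {rules.tds_sulfate_rich_min:g} and SO4 dominant -> old_sulfate_rich"
        )
        return Classification(WaterType.OLD_SULFATE_RICH, tuple(trace), tuple(flags))
    if not modern and tds > rules.tds_old_min and not so4_dominant:
        trace.append(
            f"TDS {tds:g} > {rules.tds_old_min:g} and SO4 not dominant -> old_sulfate_poor"
        )
        return Classification(WaterType.OLD_SULFATE_POOR, tuple(trace), tuple(flags))
    trace.append("no young/old rule fired -> intermediate")
    return Classification(WaterType.INTERMEDIATE, tuple(trace), tuple(flags))
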