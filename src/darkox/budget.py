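"""Oxygen budget: convert consumed dissolved O2 into the cell abundance it
could sustain, convert microscope grid counts into cells per mL, and compare
the two across wells.

The premise: recharging groundwater enters the subsurface at air saturation
for the recharge temperature; the difference between that saturation value
and the measured DO is the oxygen respired along the flow path. Multiplying
by a biomass yield (g dry mass per mol O2) and dividing by per-cell dry mass
gives the standing stock of cells that the consumed oxygen could have built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import O2_MOLAR_MASS, BudgetConstants
from .geochem import BelowDetection, WellSample, is_below_detection
from .solubility import o2_saturation


@dataclass(frozen=True)
class BudgetParams:
    """Parameters of the oxygen-to-cells conversion.

    recharge_temperature
        Water temperature at infiltration, degC; defaults to 5.0, a regional
        mean annual shallow-groundwater temperature for mid-latitude prairie
        settings. Override per study area.
    yield_biomass / cell_mass
        See :class:`darkox.constants.BudgetConstants`; they are parameters
        here, never hard-coded in operations.
    """

    recharge_temperature: float = 5.0
    salinity: float = 0.0
    pressure: float = 760.0
    yield_biomass: float = BudgetConstants.yield_biomass
    cell_mass: float = BudgetConstants.cell_mass
    do_detection_limit: float = 0.01  # mg L-1, optical sensor resolution

    def __post_init__(self) -> None:
        if self.yield_biomass <= 0 or self.cell_mass <= 0:
            raise ValueError("yield_biomass and cell_mass must be > 0")


@dataclass(frozen=True)
class ConsumedO2:
    mol_per_litre: float
    below_detection: bool = False
    supersaturated: bool = False


def consumed_o2(sample: WellSample, params: BudgetParams = BudgetParams()) -> ConsumedO2:
    """O2 consumed since recharge: max(0, saturation(recharge T) - measured), mol L-1.

    A below-detection DO measurement means essentially all the recharged
    oxygen was consumed: the remaining DO is treated as 0 mg L-1 and the
    result flagged. Measured DO above saturation is clipped to zero
    consumption with a supersaturation flag.
    """
    if sample.do_measured is None:
        raise ValueError(f"sample {sample.sample_id}: no DO measurement")
    sat = float(o2_saturation(params.recharge_temperature, params.salinity, params.pressure))
    if is_below_detection(sample.do_measured):
        return ConsumedO2(sat / O2_MOLAR_MASS / 1000.0, below_detection=True)
    do = float(sample.do_measured)
    if do > sat:
        return ConsumedO2(0.0, supersaturated=True)
    return ConsumedO2((sat - do) / O2_MOLAR_MASS / 1000.0)


def cells_sustained(consumed_mol_per_litre: float,
                    params: BudgetParams = BudgetParams()) -> float:
    """Cells mL-1 sustainable by the consumed O2: c * Y / m_cell / 1000.

    Linear in the consumed amount, in the yield, and in 1/cell_mass.
    """
    if consumed_mol_per_litre < 0:
        raise ValueError("consumed O2 must be >= 0")
    return consumed_mol_per_litre * params.yield_biomass / params.cell_mass / 1000.0


@dataclass(frozen=True)
class CellCountRecord:
    """Per-filter microscope counts: ~40 ocular-grid fields per filter."""

    sample_id: str
    counts_per_grid: tuple[int, ...]
    grid_area: float  # mm2
    filter_area: float  # mm2
    volume_filtered: float  # mL of original (undiluted) sample
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts_per_grid) == 0:
            raise ValueError("at least one grid count is required")
        if any(c < 0 for c in self.counts_per_grid):
            raise ValueError("grid counts must be >= 0")
        if self.grid_area <= 0 or self.filter_area <= 0 or self.volume_filtered <= 0:
            raise ValueError("areas and volume must be > 0")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be > 0")


@dataclass(frozen=True)
class CellDensity:
    cells_per_ml: float
    se: float
    n_grids: int
    degenerate_variance: bool = False


def cells_per_mL(record: CellCountRecord) -> CellDensity:
    """Cell density: mean(grid counts) * (filter/grid area) * dilution / volume.

    The standard error propagates grid-to-grid variance through the same
    scale factor. Identical counts in every grid give SE = 0 and a
    degenerate-variance flag.
    """
    counts = np.asarray(record.counts_per_grid, dtype=float)
    scale = (record.filter_area / record.grid_area) * record.dilution_factor / record.volume_filtered
    mean = float(counts.mean()) * scale
    if len(counts) > 1:
        se = float(counts.std(ddof=1) / math.sqrt(len(counts))) * scale
    else:
        se = float("nan")
    degenerate = len(counts) > 1 and float(counts.std(ddof=1)) == 0.0
    return CellDensity(mean, se, len(counts), degenerate_variance=degenerate)


@dataclass(frozen=True)
class WellVerdict:
    well_id: str
    consumed_mol_per_litre: float
    cells_sustained_per_ml: float
    cells_observed_per_ml: float
    sufficient: bool
    below_detection: bool


@dataclass(frozen=True)
class CohortBudget:
    """Cohort summary of the oxygen-budget comparison.

    ``fraction`` is n_sufficient / n_assessed among wells with DO above the
    detection limit; below-detection wells are counted separately (their
    consumed O2 equals full saturation but the comparison is not meaningful
    without a measured endpoint).
    """

    n_assessed: int
    n_sufficient: int
    fraction: float
    n_below_detection: int
    per_well: tuple[WellVerdict, ...]
    sensitivity: dict[str, float] = field(default_factory=dict)


def budget_comparison(
    samples: Sequence[tuple[WellSample, CellCountRecord]],
    params: BudgetParams = BudgetParams(),
    temperature_sensitivity: float = 5.0,
) -> CohortBudget:
    """Compare oxygen-sustainable vs observed cells per well.

    Wells sampled repeatedly are collapsed to per-well means of consumed O2
    and observed density before the comparison (the unit of interest is the
    aquifer/well, not the sample). The ``sensitivity`` mapping reports the
    cohort fraction recomputed with the recharge temperature shifted by
    +/- ``temperature_sensitivity`` degC.
    """
    if len(samples) == 0:
        raise ValueError("budget_comparison requires at least one well")

    def cohort_fraction(at_temperature: float):
        p = BudgetParams(
            recharge_temperature=at_temperature,
            salinity=params.salinity,
            pressure=params.pressure,
            yield_biomass=params.yield_biomass,
            cell_mass=params.cell_mass,
            do_detection_limit=params.do_detection_limit,
        )
        by_well: dict[str, dict] = {}
        for well, counts in samples:
            c = consumed_o2(well, p)
            d = cells_per_mL(counts)
            acc = by_well.setdefault(
                well.well_id,
                {"consumed": [], "observed": [], "below": []},
            )
            acc["consumed"].append(c.mol_per_litre)
            acc["observed"].append(d.cells_per_ml)
            acc["below"].append(c.below_detection)
        verdicts = []
        n_below = 0
        for well_id, acc in by_well.items():
            consumed_mean = float(np.mean(acc["consumed"]))
            observed_mean = float(np.mean(acc["observed"]))
            below = all(acc["below"])
            sustained = cells_sustained(consumed_mean, p)
            if below:
                n_below += 1
            verdicts.append(
                WellVerdict(
                    well_id=well_id,
                    consumed_mol_per_litre=consumed_mean,
                    cells_sustained_per_ml=sustained,
                    cells_observed_per_ml=observed_mean,
                    sufficient=sustained >= observed_mean,
                    below_detection=below,
                )
            )
        assessed = [v for v in verdicts if not v.below_detection]
        n_sufficient = sum(v.sufficient for v in assessed)
        frac = n_sufficient / len(assessed) if assessed else float("nan")
        return verdicts, len(assessed), n_sufficient, frac, n_below

    verdicts, n_assessed, n_sufficient, frac, n_below = cohort_fraction(
        params.recharge_temperature
    )
    if n_assessed == 0:
        raise ValueError("no well has DO above the detection limit")
    sensitivity = {}
    for shift in (-temperature_sensitivity, +temperature_sensitivity):
        t = params.recharge_temperature + shift
        try:
            _, _, _, f_s, _ = cohort_fraction(t)
        except ValueError:
            f_s = float("nan")
        sensitivity[f"{shift:+g}C"] = f_s
    return CohortBudget(
        n_assessed=n_assessed,
        n_sufficient=n_sufficient,
        fraction=frac,
        n_below_detection=n_below,
        per_well=tuple(verdicts),
        sensitivity=sensitivity,
    )
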