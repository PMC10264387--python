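"""Oxygen budget: how many cells could the consumed O2 sustain?

Uses the hypoxic-old-water case: recharge at 10 degC saturates at
~11.29 mg/L; a measured 0.52 mg/L means ~10.77 mg/L (3.4e-4 mol/L) was
respired along the flow path.
"""

from darkox import BudgetParams, CellCountRecord, WellSample, cells_per_mL, cells_sustained, consumed_o2

params = BudgetParams(recharge_temperature=10.0)
well = WellSample("GW-old", "GW-old-1", depth=80.0, do_measured=0.52)

c = consumed_o2(well, params)
sustained = cells_sustained(c.mol_per_litre, params)
print(f"consumed O2: {c.mol_per_litre:.3e} mol/L")
print(f"cells sustainable: {sustained:.2e} cells/mL "
      f"(yield {params.yield_biomass} g/mol O2, cell mass {params.cell_mass:g} g)")

# compare with a microscope count: 40 ocular grids on one filter
counts = CellCountRecord("GW-old-1", (23, 27, 25, 24, 26, 25, 28, 22) * 5,
                         grid_area=0.015625, filter_area=227.0,
                         volume_filtered=1.0, dilution_factor=11.0)
density = cells_per_mL(counts)
print(f"observed: {density.cells_per_ml:.2e} +/- {density.se:.1e} cells/mL "
      f"({density.n_grids} grids)")
print(f"oxygen budget {'suffices' if sustained >= density.cells_per_ml else 'falls short'}: "
      "consumed O2 alone can account for the standing stock of cells"
      if sustained >= density.cells_per_ml else "")
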