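# darkox

Tools for linking groundwater geochemistry to microbial productivity in
aquifer ecosystems — in particular for asking whether the dissolved oxygen
found in old, nominally anoxic groundwaters can be explained by the
atmosphere at all, or whether some of it must be produced *in situ*
("dark oxygen", e.g. by microbial dismutation of chlorite, nitric oxide, or
peroxide).

The package is a library first: import it from Python, or use the thin
`darkox` CLI for the common stages. It covers five connected analyses:

1. **Water types and ages.** Milliequivalent (Piper) chemistry, the Ca/Na
   mass ratio as a residence-time proxy, rule-based hydrochemical facies
   classification (young / intermediate / old sulfate-rich / old
   sulfate-poor) with an auditable rule trace, tritium decay
   (t½ = 12.4 y) and uncorrected radiocarbon ages t = −8033·ln(F¹⁴C).
2. **The O₂/Ar–δ¹⁸O dark-oxygen model.** Argon is biologically inert, so
   the O₂/Ar ratio isolates biological O₂ gain/loss. Respiration follows a
   Rayleigh law, δ(f) = (1000 + δ₀)·f^(−ε/1000) − 1000 (residual pool
   enriched, ε > 0), dropping O₂/Ar while raising δ¹⁸O; air contamination
   pulls samples back toward the air-equilibrated point (O₂/Ar = 1,
   δ¹⁸O = +23.9‰); adding isotopically light O₂ (δ_source ≈ −20‰,
   inherited from the groundwater) raises O₂/Ar while *lowering* δ¹⁸O.
   No respiration/contamination combination reaches that quadrant, so the
   classifier can prove a sample needs a non-atmospheric O₂ source, and the
   two-observable inversion recovers (f_resp, x_prod) and the dark fraction
   of the current pool.
3. **Oxygen budget.** Consumed O₂ = saturation at recharge (Benson–Krause)
   minus measured DO; multiplied by a biomass yield (g dry mass per mol O₂)
   and divided by per-cell mass this gives the cell standing stock the
   oxygen could sustain, compared per well against DAPI grid counts.
4. **CH₄/SO₄ isotope systematics.** CO₂–CH₄ enrichment factors, genetic
   zone classification of methane (hydrogenotrophic vs
   aceticlastic/methylotrophic vs oxidation-influenced), and Rayleigh
   modelling of microbial sulfate reduction.
5. **Community and guilds.** Seeded rarefaction, alpha diversity (richness,
   Shannon, inverse Simpson, Chao1), Bray–Curtis, genus→guild aggregation,
   exact Wilcoxon rank-sum tests, and guild-versus-DO summaries on a
   pseudo-log axis that keeps anoxic (zero-DO) samples.

A synthetic cohort generator (`darkox.simulate`) reproduces the joint
geochemistry–age–community structure with recorded ground truth, so every
stage can be exercised and validated without any external data.

## Worked example

```python
from darkox import (AIR_EQUILIBRATED, GasIsotopeObservation, ScenarioParams,
                    classify_scenario, forward_dark_o2, invert_dark_o2)

# a well whose O2 pool was respired to 85% and then topped up with
# dark O2 amounting to 25% of the air-equilibrated amount
em = forward_dark_o2(ScenarioParams(f_resp=0.85, x_prod=0.25))
print(em.o2_ar, em.d18o)          # 1.100 +16.24 per mil

reps = [GasIsotopeObservation("GW1", i, em.o2_ar, em.d18o) for i in (1, 2, 3)]
print(classify_scenario(reps).label.value)   # requires_light_source

inv = invert_dark_o2(GasIsotopeObservation("GW1", 1, em.o2_ar, em.d18o))
print(round(inv.dark_fraction, 3))           # 0.227
```

The observation sits in the diagnostic quadrant (O₂/Ar above, δ¹⁸O below
the air-equilibrated point), which no respiration or air-contamination
scenario can reach — hence the `requires_light_source` verdict — and the
inversion attributes 22.7% of the current O₂ pool to in-situ production.

More narrative scripts live in `examples/` (one per capability); each
prints the numbers it computes and a line on what they mean.

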