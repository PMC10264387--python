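# Methods

This note records the models implemented in `darkox`, their assumptions,
the defaults that matter, and the choices made where the design was open.

## Isotope notation and the shared Rayleigh form

Delta values are per-mil deviations of an isotope ratio from a named
standard (V-SMOW for O/H, V-PDB for C, V-CDT for S):
δ = (R/R_std − 1)·1000. Enrichment factors ε = (α − 1)·1000. All
conversions round-trip to machine precision (property-tested).

Both O₂ respiration and sulfate reduction use one Rayleigh implementation:

    δ(f) = (1000 + δ₀) · f^(−ε/1000) − 1000

for the residual pool when fraction `f` remains. **Sign convention:** ε > 0
means the residual pool is *enriched* as it is consumed (the consumed flux
is isotopically light). Both conventions circulate in the literature; this
one is fixed package-wide and stated on every API that takes an ε.
`f = 0` is singular and raises; `f > 1` is rejected.

## The O₂/Ar–δ¹⁸O dark-oxygen model

State is a point (O₂/Ar, δ¹⁸O-O₂), with O₂/Ar normalized so the
air-equilibrated endmember sits at 1. Argon is treated as biologically and
chemically conservative, so every process acts on O₂ only:

* **Respiration** (`rayleigh_respiration`): O₂/Ar scales by f_resp, δ
  follows the Rayleigh form. Default ε_resp = 18‰, with 0–25‰ scanned in
  classification, since respiratory fractionation varies among communities.
* **Dark-O₂ addition** (`mix_o2_pools`): an O₂ amount x_prod (expressed as
  a fraction of the air-equilibrated amount) with δ_source (default −20‰,
  consistent with O₂ generated from −18.6‰ water) is mixed in. Mixed δ is
  the O₂-amount-weighted mean of deltas (delta-linear convention) — the
  standard small-delta approximation. An exact ratio-space computation is
  available behind `exact=True`; the two agree to <0.01‰ for |δ| ≤ 50‰,
  far below the ±0.1‰ measurement precision.
* **Air contamination** (`air_contamination`): replacement mixing with the
  air-equilibrated endmember parameterised by the replaced water fraction
  x_air ∈ [0,1], so x_air = 1 returns the endmember exactly. The δ
  arithmetic is the same amount-weighted mean.

The forward composition order is respiration → production → contamination.
This order is a convention; commuting respiration and production changes
predictions by less than measurement σ over the parameter ranges involved.

**Inversion.** With s = O₂/Ar(obs)/O₂/Ar(eq) = f_resp + x_prod fixed by
argon conservation, the δ balance

    f·(δ_Rayleigh(f) − δ_source) = s·(δ_obs − δ_source)

is strictly monotone in f (the residual pool is always heavier than the
produced O₂), so the root is unique on (0, min(1, s)] and found by Brent's
method to 1e−14. forward∘invert reproduces observations to better than
1e−9 over a dense parameter grid. Observations outside the model manifold
(e.g. heavier *and* more O₂-rich than air-equilibrated) are flagged
infeasible rather than forced. One consequence worth knowing: at a given
elevated O₂/Ar the highest reachable δ¹⁸O is on the pure mixing line
(f = 1); respiring first does not help, because the extra production
needed to restore O₂/Ar dilutes the pool with light O₂ faster than
Rayleigh enrichment raises it.

**Scenario classification** tests nested nulls in order — air-equilibrated,
respiration-only, respiration+contamination, and finally
requires-light-source — each at 3× the propagated replicate-mean σ
(instrument precision ±0.1‰ / ±0.05 by default, widened by replicate
scatter when that is larger). The ordering makes the classifier
conservative: a sample is only assigned in-situ production when no
atmospheric scenario fits, which is the scientifically safe direction. The
key structural fact, verified by exhaustive sweep, is that the quadrant
{O₂/Ar above, δ¹⁸O below the air-equilibrated point} is unreachable by any
respiration/contamination combination for any ε ∈ [0, 25]‰.

The +23.9‰ air-equilibrated reference treats dissolved and atmospheric O₂
as isotopically indistinguishable; the ~0.7‰ solubility-equilibrium
enrichment is not separately modelled, and the endmember is a parameter so
users who care can move it.

## Oxygen budget

DO saturation uses the Benson–Krause closed form (11.288 mg/L at 10 °C,
S = 0, 760 mmHg, matching published tables) with Henry-law pressure
proportionality and no vapour-pressure correction — adequate for
field-sonde percent-saturation conversions. Consumed O₂ is
max(0, saturation at recharge − measured DO)/32 g mol⁻¹. Recharge
temperature defaults to 5 °C (a mid-latitude prairie mean annual
groundwater temperature); the cohort comparison reports its sensitivity to
±5 °C alongside the result. Below-detection DO is a typed flag, never a
numeric zero: such wells have consumed essentially all recharged O₂, but
they are excluded from the sufficiency comparison (and counted), because
the comparison needs a measured endpoint.

Cells sustained = consumed · Y / m_cell / 1000 (per mL). Defaults
Y = 10 g dry biomass per mol O₂ and m_cell = 2×10⁻¹³ g are literature-scale
values kept in a documented constants module; they are parameters of every
operation, never hard-coded, because published yields and per-cell masses
span a factor of a few. Grid counts convert to density as
mean(counts)·(filter area/grid area)·dilution/volume with the SE from
grid-to-grid variance. Repeated samples of a well are collapsed to
per-well means before the cohort comparison: the unit of interest is the
aquifer, not the sample.

## Water types and age tracers

The facies rules encode the geochemical-evolution sequence with TDS bounds
<400 / >900 / >1700 mg/L and tritium detection at 0.8 TU. Ties at a TDS
bound resolve to the younger class (conservative against over-claiming old
water). SO₄ dominance is decided on milliequivalent fractions. When
tritium is absent from a record, F¹⁴C ≥ 0.9 serves as the tracer-modern
proxy. The classifier is total on complete records, returns the full rule
trace for audit, and flags (without failing) contradictory tracers
(tritium-positive with F¹⁴C at the ~40 kyr ceiling). The exact
facies-assignment procedure behind such datasets is typically part
analyst judgement; these rules are therefore configuration with defaults,
not constants.

Radiocarbon ages use the Libby mean life 8033 y and a 40 kyr method
ceiling, both overridable; F¹⁴C > 1 returns age 0 with a modern flag.

## Methane and sulfate systematics

ε_C(CO₂–CH₄) uses the exact ratio form (not the δ difference). Genetic
zone boundaries — ε_C ≥ 65‰ hydrogenotrophic, 40–65‰
aceticlastic/methylotrophic, oxidation influence when CH₄ < 1 mg/L with
δ¹³C-CH₄ > −50‰ (or ε_C < 40‰) — are a reconstruction of conventional
genetic-diagram fields; they are config-driven, marked as reconstructed in
output metadata, closed on the enriched side, and near-boundary samples
carry a confidence note. δ²H-CH₄ is carried as data and used only as an
optional secondary axis.

## Community analyses

Rarefaction is a multivariate-hypergeometric draw (without replacement),
so rarefied totals are exact and zero taxa stay zero. One global seed
governs all draws; per-sample substream seeds derive deterministically
from (seed, sample_id), so subsetting a table does not change any sample's
draw. Samples below the requested depth are excluded and listed. The
expected rarefied richness has the closed form
E[S] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)), computed in log-space, and the
stochastic draw is validated against it.

Shannon entropy uses the natural log (stated in output metadata). Chao1 is
S_obs + F₁²/(2F₂), with the bias-corrected fallback S_obs + F₁(F₁−1)/2
when doubletons are absent. Richness, Shannon and inverse Simpson are
delegated to scikit-bio; Bray–Curtis to scipy.

The Wilcoxon rank-sum test enumerates all group assignments exactly
(tie-aware midranks) for combined n ≤ 20 and switches to the
tie-corrected normal approximation above; p-values are two-sided and
uncorrected for multiplicity. The guild map ships as an editable TSV of
(rank, name, guild) rows covering named genera of the major guilds
(methanogens, ANME, aerobic methanotrophs, methylotrophs, sulfate
reducers, sulfur and hydrogen oxidizers, dismutation-capable taxa); it is
deliberately incomplete beyond those genera, and unmapped taxa pool into
"Other". DO axes use an asinh-based pseudo-log10 with linear threshold
0.01 mg/L so truly anoxic samples stay on the plot at coordinate 0.

## Synthetic cohorts

The generator draws wells per water type with TDS uniform inside the
class bounds, Ca/Na lognormal around medians 3.5 / 0.5 / 0.12 / 0.01
(young / intermediate / sulfate-rich / sulfate-poor), anion budgets that
make SO₄ meq-dominant only in the sulfate-rich class, tritium 3–15 TU in
young wells and below-detection otherwise, F¹⁴C from modern to
ceiling-level, CH₄ lognormal and elevated in old sulfate-poor wells, DO
lognormal falling from ~5 mg/L (young) to ~0.5 mg/L (old, with a 15%
below-detection probability), and cell densities log-uniform in
10⁴–10⁵ / 10⁵–10⁶ / 10⁶–10⁷ cells/mL for young / intermediate / old.
δ¹⁸O-H₂O is N(−18.6, 2.0)‰. Gas-isotope replicates (3 per well) come from
the forward model with Gaussian instrument noise (0.1‰, 0.05); young wells
are air-equilibrated, intermediate wells respiration-only, and a
configurable share of old wells (default 60%) carries x_prod ∈ 0.08–0.30.
Grid counts are Poisson around the density implied by the counting
geometry; ASV tables are Dirichlet-multinomial around guild profiles in
which aerobic guilds peak at hypoxic DO (~0.5 mg/L), methanogens rise with
CH₄ in anoxia, and sulfate reducers with SO₄. All randomness flows from
one master seed through four named substreams (geochem, isotopes, counts,
community).

What the generator does *not* emulate: spatial structure and flow paths,
charge-balanced ion chemistry (budgets are mass-plausible, not
equilibrated), seasonal resampling, taxonomically realistic lineage depth,
biofilm-attached biomass, or correlated measurement error. Passing
recovery tests therefore demonstrates the correctness and noise-robustness
of the estimators under the stated generating model, not field validity.

## Problem sizes and numerical choices

Recovery and false-positive metrics use 200-well cohorts at the printed
instrument noise; the rarefaction Monte-Carlo uses 500–1000 seeded draws;
the inversion grid check uses 50×50 parameter combinations. Root-finding
tolerances are 1e−14 (absolute) on f; mixing conservation holds to 1e−12
relative; classification tolerances default to 3× the propagated σ of the
replicate mean. Degenerate inputs (all-zero ion families, empty replicate
lists, all-zero count vectors, f = 0) raise typed errors; censored values
are explicit `BelowDetection` flags end to end.

## Known limitations

* The sufficiency fraction of the oxygen budget depends directly on the
  yield and per-cell-mass constants; with different published constants
  the cohort fraction moves accordingly. The defaults are literature-scale
  and documented, not canonical.
* The scenario classifier's nested ordering deliberately prefers
  atmospheric explanations; samples with small true x_prod near the
  measurement tolerance are labelled respiration- or
  contamination-consistent (never the reverse error).
* Methane zone boundaries and the guild map are reconstructions/partial
  lists and should be overridden for serious use on real data.
* Uncorrected ¹⁴C ages ignore geochemical dilution corrections by design;
  they are comparative, not calendar, ages.
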