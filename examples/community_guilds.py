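"""Community analysis on a synthetic cohort: rarefaction, alpha diversity,
guild aggregation, and a two-group diversity test."""

import numpy as np

from darkox import (
    GeneratorConfig,
    aggregate_guilds,
    generate_cohort,
    group_difference,
    load_guild_map,
)
from darkox.community import alpha_diversity_table, rarefy_table

cohort = generate_cohort(GeneratorConfig(master_seed=4))

rt = rarefy_table(cohort.asv_counts, depth=1008, seed=4)
print(f"rarefied {len(rt.counts)} samples to {rt.depth} reads"
      + (f"; excluded below depth: {rt.excluded}" if rt.excluded else ""))

diversity = alpha_diversity_table(rt.counts)
print("\nalpha diversity (first rows):")
print(diversity.head(4).round(2))

fractions = aggregate_guilds(cohort.asv_counts, cohort.taxonomy, load_guild_map())
print("\nmean guild fractions across the cohort:")
print(fractions.mean().sort_values(ascending=False).round(3))

# do old wells host less diverse communities than young wells?
ages = cohort.ground_truth.loc[diversity.index, "water_type"]
is_old = ages.str.startswith("old")
if is_old.any() and (~is_old).any():
    res = group_difference(
        diversity["shannon"].to_numpy(),
        np.where(is_old, "old", "not_old"),
    )
    print(f"\nShannon old vs rest: rank-sum={res.statistic:.0f}, "
          f"p={res.p_value:.3f} ({res.method}, uncorrected)")
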