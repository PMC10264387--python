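"""ASV-table handling: seeded rarefaction, alpha diversity, Bray-Curtis
dissimilarity, genus-to-guild aggregation, two-group rank tests, and
guild-versus-oxygen summaries.

Tables are plain pandas objects: a samples x ASVs integer count DataFrame
and a taxonomy DataFrame indexed by ASV id with the seven ranks
(domain, phylum, class, order, family, genus, species).
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.stats import mannwhitneyu
from skbio.diversity import alpha as skbio_alpha

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def sample_seed(global_seed: int, sample_id: str) -> int:
    """Deterministic per-sample substream seed from (global seed, sample id)."""
    return int(
        np.random.SeedSequence(
            [int(global_seed), zlib.crc32(sample_id.encode())]
        ).generate_state(1)[0]
    )


def rarefy(counts, depth: int, seed: int) -> np.ndarray:
    """Subsample one sample's count vector to ``depth`` reads without replacement.

    The draw is multivariate hypergeometric, so the output sums exactly to
    ``depth``, never creates counts where the input was zero, and is
    reproducible under a fixed seed. Raises if the sample has fewer reads
    than the requested depth (table-level wrappers exclude such samples).
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), int(depth))


@dataclass(frozen=True)
class RarefiedTable:
    counts: pd.DataFrame
    excluded: tuple[str, ...]  # samples below the requested depth
    depth: int
    seed: int


def rarefy_table(counts: pd.DataFrame, depth: int, seed: int) -> RarefiedTable:
    """Rarefy every row of a samples x ASVs table; under-depth samples are
    excluded with a flag rather than raising."""
    rows, excluded = {}, []
    for sid, row in counts.iterrows():
        if int(row.sum()) < depth:
            excluded.append(str(sid))
            continue
        rows[sid] = rarefy(row.to_numpy(), depth, sample_seed(seed, str(sid)))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)
    return RarefiedTable(out, tuple(excluded), depth, seed)


def expected_rarefied_richness(counts, depth: int) -> float:
    """Closed-form expected richness under subsampling without replacement:
    E[S] = sum_i 1 - C(N - N_i, d) / C(N, d). Used as the analytical oracle
    for the stochastic rarefaction draw."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    if depth > n_total:
        raise ValueError("depth exceeds total reads")
    # log-space ratio of binomial coefficients, stable for large N
    from scipy.special import gammaln

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    log_denom = log_choose(n_total, depth)
    probs_absent = np.where(
        n_total - counts >= depth,
        np.exp(log_choose(n_total - counts, depth) - log_denom),
        0.0,
    )
    return float(np.sum(1.0 - probs_absent))


# ---------------------------------------------------------------------------
# Alpha / beta diversity
# ---------------------------------------------------------------------------


def chao1(counts) -> float:
    """Chao1 estimated richness: S_obs + F1^2 / (2 F2), falling back to the
    bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) when doubletons are absent."""
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1**2 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity(counts) -> dict[str, float]:
    """Observed richness, Shannon entropy (natural log), inverse Simpson,
    and Chao1 (bias-corrected when doubletons are absent) for one sample."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("alpha diversity undefined for an all-zero sample")
    return {
        "richness": float(skbio_alpha.sobs(counts)),
        "shannon": float(skbio_alpha.shannon(counts, base=math.e)),
        "inverse_simpson": float(skbio_alpha.enspie(counts)),
        "chao1": chao1(counts),
    }


def alpha_diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {sid: alpha_diversity(row.to_numpy()) for sid, row in counts.iterrows()}
    ).T


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/sum(a+b), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(a, b))


# ---------------------------------------------------------------------------
# Guild aggregation
# ---------------------------------------------------------------------------


def load_guild_map(path=None) -> pd.DataFrame:
    """Load a guild map TSV with columns (rank, name, guild).

    Without a path, loads the packaged map covering the genera named in the
    source study's guild figure (hydrogenotrophic methanogens, ANME, aerobic
    methanotrophs, methylotrophs, sulfate reducers, sulfur oxidizers,
    hydrogen oxidizers, dismutation-capable taxa). The shipped map is data,
    not code, and is deliberately incomplete beyond those named genera.
    """
    if path is None:
        ref = resources.files("darkox.data") / "guild_map.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def aggregate_guilds(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    guild_map: pd.DataFrame,
    fallback_ranks: Sequence[str] = ("family", "order"),
) -> pd.DataFrame:
    """Samples x guilds relative abundances (rows sum to 1, incl. "Other").

    Each ASV is matched to a guild by genus first, then by the configured
    higher-rank fallbacks; unmatched ASVs pool into "Other". An empty guild
    map yields an all-"Other" table (with no error: the map is data).
    """
    lookup: dict[tuple[str, str], str] = {}
    for _, row in guild_map.iterrows():
        lookup[(str(row["rank"]), str(row["name"]))] = str(row["guild"])

    def guild_of(asv: str) -> str:
        if asv not in taxonomy.index:
            return "Other"
        lineage = taxonomy.loc[asv]
        for rank in ("genus", *fallback_ranks):
            name = lineage.get(rank)
            if pd.notna(name) and (rank, str(name)) in lookup:
                return lookup[(rank, str(name))]
        return "Other"

    guilds = pd.Series({asv: guild_of(asv) for asv in counts.columns})
    grouped = counts.T.groupby(guilds).sum().T
    totals = grouped.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cannot normalize an all-zero sample")
    return grouped.div(totals, axis=0)


# ---------------------------------------------------------------------------
# Two-group rank test
# ---------------------------------------------------------------------------


def _tie_ranks(pooled: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(pooled)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first group
    p_value: float
    method: str  # "exact" or "normal_approx"


def group_difference(values: Sequence[float], groups: Sequence) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test between exactly two groups.

    For combined n <= 20 the p-value is computed by exact enumeration of all
    group assignments (tie-aware, via midranks); above that, the
    tie-corrected normal approximation is used. P-values are reported
    uncorrected for multiplicity.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("group_difference requires exactly two group labels")
    mask_a = groups == labels[0]
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    n = n_a + n_b
    ranks = _tie_ranks(values)
    w_obs = float(ranks[mask_a].sum())

    if n <= 20:
        mean_w = n_a * (n + 1) / 2.0
        dev_obs = abs(w_obs - mean_w)
        hits = total = 0
        for combo in itertools.combinations(range(n), n_a):
            w = float(ranks[list(combo)].sum())
            total += 1
            if abs(w - mean_w) >= dev_obs - 1e-12:
                hits += 1
        return RankSumResult(w_obs, hits / total, "exact")

    res = mannwhitneyu(values[mask_a], values[~mask_a], alternative="two-sided",
                       method="asymptotic")
    return RankSumResult(w_obs, float(res.pvalue), "normal_approx")


# ---------------------------------------------------------------------------
# Guild vs oxygen
# ---------------------------------------------------------------------------


def pseudo_log10(x, linthresh: float = 0.01):
    """Pseudo-log10 transform (asinh-based) that keeps zeros finite, used to
    plot DO including truly anoxic (zero) samples."""
    x = np.asarray(x, dtype=float)
    return np.arcsinh(x / (2.0 * linthresh)) / np.log(10.0)


def guild_vs_oxygen(
    guild_fractions: pd.DataFrame,
    well_table: pd.DataFrame,
    do_column: str = "do_measured",
    age_column: str = "water_type",
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[str, ...]]:
    """Join guild fractions with per-sample geochemistry.

    Returns (tidy per-sample rows, per-age-class summaries, unmatched ids).
    The tidy table has one row per (sample, guild) with the DO value, its
    pseudo-log10 coordinate, and the age class; summaries give quartiles,
    median and mean of each guild's fraction per age class. Samples without
    a geochemistry match are reported, never silently dropped.
    """
    unmatched = tuple(
        str(s) for s in guild_fractions.index if s not in well_table.index
    )
    matched = [s for s in guild_fractions.index if s in well_table.index]
    rows = []
    for sid in matched:
        do = well_table.loc[sid, do_column]
        age = well_table.loc[sid, age_column]
        for guild, frac in guild_fractions.loc[sid].items():
            rows.append(
                {
                    "sample_id": sid,
                    "guild": guild,
                    "fraction": float(frac),
                    "do_mg_per_l": do,
                    "do_pseudo_log10": float(pseudo_log10(do)) if pd.notna(do) else np.nan,
                    "age_class": age,
                }
            )
    tidy = pd.DataFrame(rows)
    if tidy.empty:
        return tidy, pd.DataFrame(), unmatched
    summary = (
        tidy.groupby(["age_class", "guild"])["fraction"]
        .agg(
            q1=lambda s: s.quantile(0.25),
            median="median",
            q3=lambda s: s.quantile(0.75),
            mean="mean",
            n="count",
        )
        .reset_index()
    )
    return tidy, summary, unmatched
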