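"""Readers/writers, run configuration, and the pipeline driver.

Tables are UTF-8 TSV/CSV; "<x" tokens parse to below-detection flags (never
numeric values); a column dictionary maps arbitrary input headers to the
canonical WellSample fields. Every pipeline run emits a JSON summary whose
provenance block (config hash, seed, package version) makes re-runs
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .budget import BudgetParams, CellCountRecord, budget_comparison
from .community import (
    aggregate_guilds,
    alpha_diversity_table,
    guild_vs_oxygen,
    load_guild_map,
    rarefy_table,
)
from .constants import ION_PROPERTIES
from .geochem import (
    BelowDetection,
    WaterTypeRules,
    WellSample,
    classify_water_type,
    is_below_detection,
)
from .o2model import GasIsotopeObservation, classify_scenario

CANONICAL_WELL_COLUMNS = (
    "well_id",
    "sample_id",
    "depth",
    "temperature",
    "tds",
    "do_measured",
    "orp",
    "ec",
    "tritium",
    "f14c",
    "ch4",
    "d13c_ch4",
    "d13c_co2",
    "d2h_ch4",
    "d34s_so4",
    "d18o_so4",
    "d18o_h2o",
    *(f"ion_{i}" for i in ION_PROPERTIES),
)

_NUMERIC_WELL_FIELDS = tuple(
    c for c in CANONICAL_WELL_COLUMNS if c not in ("well_id", "sample_id")
)


def _parse_cell(value):
    """Parse one table cell: floats, empty -> None, '<x' -> BelowDetection."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        s = value.strip()
        if s == "" or s.lower() in ("na", "nan"):
            return None
        if s.startswith("<"):
            return BelowDetection(float(s[1:]))
        return float(s)
    return float(value)


def read_well_table(path, column_map: Mapping[str, str] | None = None) -> list[WellSample]:
    """Read a per-sample well geochemistry CSV/TSV into WellSample records.

    ``column_map`` maps input headers to canonical field names (ions as
    ``ion_Na`` etc.). Unknown unmapped columns raise with the candidate
    list; malformed numerics raise with the row index.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    unknown = [c for c in df.columns if c not in CANONICAL_WELL_COLUMNS]
    if unknown:
        raise ValueError(
            f"unknown columns {unknown}; map them to one of {sorted(CANONICAL_WELL_COLUMNS)}"
        )
    for required in ("well_id", "sample_id"):
        if required not in df.columns:
            raise ValueError(f"required column {required!r} missing")

    samples = []
    for idx, row in df.iterrows():
        kwargs: dict = {"well_id": str(row["well_id"]), "sample_id": str(row["sample_id"])}
        ions: dict[str, float] = {}
        for col in df.columns:
            if col in ("well_id", "sample_id"):
                continue
            try:
                value = _parse_cell(row[col])
            except ValueError as exc:
                raise ValueError(f"row {idx}: malformed value in {col!r}: {row[col]!r}") from exc
            if col.startswith("ion_"):
                if value is not None and not is_below_detection(value):
                    ions[col[4:]] = value
            else:
                kwargs[col] = value
        kwargs["ions"] = ions
        samples.append(WellSample(**kwargs))
    return samples


def write_well_table(samples: list[WellSample], path) -> None:
    """Write WellSamples to TSV on the canonical schema (round-trips with
    :func:`read_well_table`)."""
    rows = []
    for s in samples:
        row: dict = {"well_id": s.well_id, "sample_id": s.sample_id}
        for name in _NUMERIC_WELL_FIELDS:
            if name.startswith("ion_"):
                value = s.ions.get(name[4:])
            else:
                value = getattr(s, name)
            if value is None:
                row[name] = ""
            elif is_below_detection(value):
                row[name] = f"<{value.limit:g}"
            else:
                row[name] = repr(float(value))
        rows.append(row)
    pd.DataFrame(rows, columns=list(CANONICAL_WELL_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_gas_table(path) -> list[GasIsotopeObservation]:
    """Read replicate gas-isotope observations (sample_id, replicate, o2_ar,
    d18o_o2, optional per-row sigma columns)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    obs = []
    for _, row in df.iterrows():
        kwargs = dict(
            sample_id=str(row["sample_id"]),
            replicate=int(row["replicate"]),
            o2_ar=float(row["o2_ar"]),
            d18o_o2=float(row["d18o_o2"]),
        )
        for opt in ("sigma_d18o", "sigma_o2ar"):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[opt] = float(row[opt])
        obs.append(GasIsotopeObservation(**kwargs))
    return obs


def read_cell_counts(
    path,
    grid_area: float,
    filter_area: float,
    volume_filtered: float = 1.0,
    dilution_factor: float = 1.0,
) -> list[CellCountRecord]:
    """Read long-format per-grid counts (sample_id, grid, count); the filter
    geometry comes from configuration, not the table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    records = []
    for sid, grp in df.groupby("sample_id", sort=True):
        records.append(
            CellCountRecord(
                sample_id=str(sid),
                counts_per_grid=tuple(int(c) for c in grp["count"]),
                grid_area=grid_area,
                filter_area=filter_area,
                volume_filtered=volume_filtered,
                dilution_factor=dilution_factor,
            )
        )
    return records


def read_asv_tables(counts_path, taxonomy_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a samples x ASVs count TSV and an ASV taxonomy TSV.

    The taxonomy may carry either seven rank columns or a single
    semicolon-delimited ``lineage`` column.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    if "lineage" in taxonomy.columns:
        ranks = ("domain", "phylum", "class", "order", "family", "genus", "species")
        split = taxonomy["lineage"].str.split(";", expand=True)
        split.columns = ranks[: split.shape[1]]
        taxonomy = split
    if counts.shape[1] != len(taxonomy.index) or set(counts.columns) != set(taxonomy.index):
        raise ValueError("taxonomy rows must match count columns 1:1")
    return counts, taxonomy


# ---------------------------------------------------------------------------
# Run configuration & pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    output_dir: str
    well_table: str | None = None
    gas_table: str | None = None
    cell_counts: str | None = None
    asv_counts: str | None = None
    taxonomy: str | None = None
    guild_map: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    rarefaction_depth: int = 1008
    epsilon_range: tuple[float, float] = (0.0, 25.0)
    delta_source: float = -20.0
    budget: dict = field(default_factory=dict)
    rules: dict = field(default_factory=dict)
    cell_geometry: dict = field(
        default_factory=lambda: {
            "grid_area": 0.015625,
            "filter_area": 227.0,
            "volume_filtered": 1.0,
            "dilution_factor": 11.0,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "epsilon_range" in data:
            data["epsilon_range"] = tuple(data["epsilon_range"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["epsilon_range"] = list(self.epsilon_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        data = dataclasses.asdict(self)
        data["epsilon_range"] = list(self.epsilon_range)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]


def _float_format(x) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.10g}"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every feasible stage in dependency order and write tidy outputs.

    Stages with missing inputs are skipped with a notice in the summary;
    a failing stage halts only its dependents. Returns the JSON-ready
    summary dict (also written to ``summary.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
        },
        "stages": {},
    }
    rules = WaterTypeRules(**config.rules) if config.rules else WaterTypeRules()
    budget_params = BudgetParams(**config.budget) if config.budget else BudgetParams()

    samples = None
    if config.well_table:
        samples = read_well_table(config.well_table, config.column_map or None)
        results, traces = [], {}
        for s in samples:
            cls = classify_water_type(s, rules)
            results.append(
                {
                    "well_id": s.well_id,
                    "sample_id": s.sample_id,
                    "tds": s.tds,
                    "water_type": cls.water_type.value,
                    "flags": "; ".join(cls.flags),
                }
            )
            traces[s.sample_id] = list(cls.trace)
        _write_tsv(pd.DataFrame(results), out / "water_types.tsv")
        (out / "water_type_traces.json").write_text(json.dumps(traces, indent=1))
        summary["stages"]["classify_water"] = {
            "n_samples": len(results),
            "counts": pd.DataFrame(results)["water_type"].value_counts().to_dict(),
        }
    else:
        summary["stages"]["classify_water"] = "skipped: no well table"

    if config.gas_table:
        obs = read_gas_table(config.gas_table)
        by_sample: dict[str, list[GasIsotopeObservation]] = {}
        for o in obs:
            by_sample.setdefault(o.sample_id, []).append(o)
        rows = []
        for sid, reps in sorted(by_sample.items()):
            v = classify_scenario(
                reps, epsilon_range=config.epsilon_range, delta_source=config.delta_source
            )
            rows.append(
                {
                    "sample_id": sid,
                    "label": v.label.value,
                    "f_resp": v.fitted.f_resp,
                    "x_prod": v.fitted.x_prod,
                    "x_air": v.fitted.x_air,
                    "dark_fraction": v.dark_fraction,
                    "residual": v.residual,
                    "mean_o2_ar": v.mean_o2_ar,
                    "mean_d18o": v.mean_d18o,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "scenario_verdicts.tsv")
        summary["stages"]["o2_model"] = {
            "n_samples": len(rows),
            "labels": pd.DataFrame(rows)["label"].value_counts().to_dict(),
        }
    else:
        summary["stages"]["o2_model"] = "skipped: no gas-isotope table"

    if config.cell_counts and samples is not None:
        geometry = config.cell_geometry
        records = read_cell_counts(config.cell_counts, **geometry)
        by_sample_rec = {r.sample_id: r for r in records}
        pairs = [
            (s, by_sample_rec[s.sample_id])
            for s in samples
            if s.sample_id in by_sample_rec and s.do_measured is not None
        ]
        if pairs:
            cohort = budget_comparison(pairs, budget_params)
            _write_tsv(
                pd.DataFrame([dataclasses.asdict(v) for v in cohort.per_well]),
                out / "budget_per_well.tsv",
            )
            summary["stages"]["o2_budget"] = {
                "n_assessed": cohort.n_assessed,
                "n_sufficient": cohort.n_sufficient,
                "fraction": cohort.fraction,
                "n_below_detection": cohort.n_below_detection,
                "sensitivity": cohort.sensitivity,
            }
        else:
            summary["stages"]["o2_budget"] = "skipped: no overlapping samples with DO"
    else:
        summary["stages"]["o2_budget"] = "skipped: needs well table and cell counts"

    if config.asv_counts and config.taxonomy:
        counts, taxonomy = read_asv_tables(config.asv_counts, config.taxonomy)
        rt = rarefy_table(counts, config.rarefaction_depth, config.seed)
        diversity = alpha_diversity_table(rt.counts) if len(rt.counts) else pd.DataFrame()
        diversity.index.name = "sample_id"
        _write_tsv(diversity.reset_index(), out / "alpha_diversity.tsv")
        gm = load_guild_map(config.guild_map)
        fractions = aggregate_guilds(counts, taxonomy, gm)
        fractions.index.name = "sample_id"
        _write_tsv(fractions.reset_index(), out / "guild_fractions.tsv")
        summary["stages"]["diversity"] = {
            "n_samples": int(len(rt.counts)),
            "excluded_below_depth": list(rt.excluded),
            "depth": config.rarefaction_depth,
        }
        if samples is not None:
            well_df = pd.DataFrame(
                {
                    "sample_id": [s.sample_id for s in samples],
                    "do_measured": [
                        (math.nan if is_below_detection(s.do_measured) else s.do_measured)
                        for s in samples
                    ],
                    "water_type": [classify_water_type(s, rules).water_type.value for s in samples],
                }
            ).set_index("sample_id")
            tidy, guild_summary, unmatched = guild_vs_oxygen(fractions, well_df)
            _write_tsv(tidy, out / "guild_vs_oxygen.tsv")
            _write_tsv(guild_summary, out / "guild_vs_oxygen_summary.tsv")
            summary["stages"]["guilds"] = {
                "n_rows": int(len(tidy)),
                "unmatched_samples": list(unmatched),
            }
        else:
            summary["stages"]["guilds"] = "skipped: no well table to join"
    else:
        summary["stages"]["diversity"] = "skipped: needs ASV counts and taxonomy"
        summary["stages"].setdefault("guilds", "skipped: needs ASV counts and taxonomy")

    config.to_yaml(out / "run_config.yaml")
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
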