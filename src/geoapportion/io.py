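"""File dialects, pipeline configuration and the end-to-end driver.

Matrices travel as TSV, record-style inputs as CSV, summaries as JSON;
everything UTF-8 with Unix newlines. Every writer here produces files
its paired reader accepts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from geoapportion import __version__
from geoapportion.census import fraction_table, producer_fraction
from geoapportion.massbalance import (
    CellYield,
    Uncertain,
    build_contribution_table,
    contribution_table_frame,
)
from geoapportion.ordination import rda, top_loadings
from geoapportion.qpcr import (
    GEOA_GROUPS,
    normalize_concentration,
    process_plate,
    summarize_geoa,
)
from geoapportion.screen import (
    DEFAULT_PRODUCER_RULES,
    TaxonomyAssignment,
    parse_lineage,
    producer_abundance_table,
    richness,
    top_taxa,
)

logger = logging.getLogger("geoapportion")

#: Closed unit vocabulary for measurement records.
MEASUREMENT_UNITS = ("ng/kg", "ng/L", "pg/g", "ng/cm2", "ng/intestine")


def read_otu_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV count matrix: first column otu_id, one column per sample.

    Counts must be integers; duplicate OTU ids are rejected and parse
    failures report row/column coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "otu_id":
        raise ValueError(f"first column must be 'otu_id', got {df.columns[0]!r}")
    ids = df["otu_id"]
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate otu_id values: {dupes}")
    out = df.set_index("otu_id")
    parsed = pd.DataFrame(index=out.index)
    for col in out.columns:
        vals = []
        for row_i, raw in enumerate(out[col]):
            try:
                f = float(raw)
                if f != int(f):
                    raise ValueError
                vals.append(int(f))
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {raw!r} at row {out.index[row_i]!r}, column {col!r}"
                ) from None
        parsed[col] = vals
    return parsed


def write_otu_table(otu_table: pd.DataFrame, path: str | Path) -> None:
    out = otu_table.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyAssignment]:
    """Read a TSV of otu_id + semicolon-delimited lineage.

    Rank prefixes (``k__`` etc.) are accepted and stripped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if list(df.columns[:2]) != ["otu_id", "lineage"]:
        raise ValueError("taxonomy file must have columns otu_id, lineage")
    out = {}
    for row in df.itertuples():
        out[row.otu_id] = TaxonomyAssignment(row.otu_id, parse_lineage(row.lineage))
    return out


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read geosmin measurement records: farm, compartment, value, se, unit.

    Units must come from the closed vocabulary; a missing SE is recorded
    as NaN (absent), never silently as 0.
    """
    df = pd.read_csv(path)
    required = {"farm", "compartment", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement file missing columns: {sorted(missing)}")
    bad = sorted(set(df["unit"]) - set(MEASUREMENT_UNITS))
    if bad:
        raise ValueError(f"unknown units {bad}; allowed units: {list(MEASUREMENT_UNITS)}")
    if "se" not in df.columns:
        df["se"] = float("nan")
    df["value"] = df["value"].astype(float)
    df["se"] = df["se"].astype(float)
    return df


def write_measurements(measurements: pd.DataFrame, path: str | Path) -> None:
    measurements.to_csv(path, index=False, lineterminator="\n")


def read_qpcr_plate(path: str | Path) -> pd.DataFrame:
    """Read a plate CSV; an empty cq cell means no amplification (NaN)."""
    df = pd.read_csv(path)
    required = {"sample_id", "assay_id", "replicate", "cq", "is_standard", "standard_copies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate file missing columns: {sorted(missing)}")
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    df["is_standard"] = df["is_standard"].astype(bool)
    return df


def write_qpcr_plate(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False, lineterminator="\n")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "farm", "compartment", "sampled_size", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False, lineterminator="\n")


@dataclass
class PipelineConfig:
    """Paths and parameters driving one full pipeline run."""

    plate: str = "plate.csv"
    samples: str = "samples.csv"
    otu_table: str = "otu_table.tsv"
    taxonomy: str = "taxonomy.tsv"
    measurements: str = "measurements.csv"
    mucous_area_cm2: float = 3075.0
    fish_mass_kg: float = 1.0
    qpcr_scaling: float = 1.0
    extraction_yield: float = 1.0
    copies_per_cell: float = 1.0
    ordination_transform: str = "hellinger"
    seed: int = 0
    out_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".") -> dict:
    """Execute qpcr -> census -> screen -> ordinate -> massbalance.

    Writes every stage's TSV plus a ``summary.json`` carrying package
    version, seed and config hash. A stage failure aborts with the stage
    name attached to the exception.
    """
    base = Path(base_dir)
    out = base / config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "schema_version": 1,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    stage = "qpcr"
    try:
        plate = read_qpcr_plate(base / config.plate)
        samples = read_samples(base / config.samples)
        per_assay = process_plate(plate)
        geoa = summarize_geoa(per_assay)
        merged = geoa.merge(samples, on="sample_id", how="left")
        merged["concentration"] = [
            normalize_concentration(
                row.total,
                row.sampled_size,
                scaling=config.qpcr_scaling,
                extraction_yield=config.extraction_yield,
            )
            for row in merged.itertuples()
        ]
        wide16 = per_assay[per_assay["assay_id"] == "16s"][["sample_id", "copies"]]
        merged = merged.merge(
            wide16.rename(columns={"copies": "copies_16s"}), on="sample_id", how="left"
        )
        merged["concentration_16s"] = [
            normalize_concentration(
                row.copies_16s,
                row.sampled_size,
                scaling=config.qpcr_scaling,
                extraction_yield=config.extraction_yield,
            )
            if np.isfinite(row.copies_16s)
            else float("nan")
            for row in merged.itertuples()
        ]
        merged.to_csv(out / "geoa_quant.tsv", sep="\t", index=False, lineterminator="\n")
        logger.info("qpcr: quantified %d samples", len(merged))

        stage = "census"
        merged["fraction_pct"] = [
            producer_fraction(row.total, row.copies_16s)
            if np.isfinite(row.copies_16s)
            else float("nan")
            for row in merged.itertuples()
        ]
        census_tbl = fraction_table(merged.dropna(subset=["fraction_pct"]))
        census_tbl.to_csv(out / "census_table.tsv", sep="\t", index=False, lineterminator="\n")
        summary["census"] = {
            "mean_fraction_pct_by_compartment": merged.groupby("compartment")["fraction_pct"]
            .mean()
            .to_dict()
        }

        stage = "screen"
        otu = read_otu_table(base / config.otu_table)
        taxonomy = read_taxonomy(base / config.taxonomy)
        comp_of = samples.set_index("sample_id")["compartment"].to_dict()
        groups = {s: comp_of.get(s, "unknown") for s in otu.columns}
        screen_tbl = producer_abundance_table(otu, taxonomy, groups, DEFAULT_PRODUCER_RULES)
        screen_tbl.to_csv(out / "producer_abundance.tsv", sep="\t", index=False, lineterminator="\n")
        tt = top_taxa(otu, 15, groups)
        tt.to_csv(out / "top_taxa.tsv", sep="\t", lineterminator="\n")
        rich = pd.DataFrame(
            [
                {"sample_id": s, "observed": richness(otu[s])[0], "chao1": richness(otu[s])[1]}
                for s in otu.columns
            ]
        )
        rich.to_csv(out / "richness.tsv", sep="\t", index=False, lineterminator="\n")

        stage = "ordinate"
        meas = read_measurements(base / config.measurements)
        water = meas[(meas["compartment"] == "water")].set_index("farm")["value"].to_dict()
        conc = merged.set_index("sample_id")
        common = [s for s in otu.columns if s in conc.index]
        ord_summary = None
        if len(common) >= 4:
            community = otu[common].T
            constraints = pd.DataFrame(
                {
                    "geosmin": [water.get(conc.loc[s, "farm"], float("nan")) for s in common],
                    "geoa_total": [conc.loc[s, "concentration"] for s in common],
                },
                index=common,
            ).dropna()
            community = community.loc[constraints.index]
            if len(constraints) >= 4 and constraints.nunique().min() > 1:
                res = rda(community, constraints, config.ordination_transform)
                res.site_scores.to_csv(out / "rda_scores.tsv", sep="\t", lineterminator="\n")
                res.otu_loadings.to_csv(out / "rda_loadings.tsv", sep="\t", lineterminator="\n")
                n_axes = res.otu_loadings.shape[1]
                ord_summary = {
                    "constrained_variance_pct": res.constrained_variance_pct,
                    "transform": res.transform,
                    "top_loadings": {} if n_axes == 0 else top_loadings(res, 10).to_dict(),
                }
        summary["ordination"] = ord_summary

        stage = "massbalance"
        meas_str = meas.assign(farm=meas["farm"].astype(str))
        flesh = meas_str[meas_str["compartment"] == "flesh"].set_index("farm")
        water_m = meas_str[meas_str["compartment"] == "water"].set_index("farm")
        densities: dict[str, dict[str, Uncertain]] = {}
        for farm, grp in merged.assign(farm=merged["farm"].astype(str)).groupby("farm"):
            densities[str(farm)] = {}
            for comp, cg in grp.groupby("compartment"):
                vals = cg["concentration"].to_numpy(dtype=float)
                se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
                densities[str(farm)][comp] = Uncertain(float(np.mean(vals)), se)
        measurements_u: dict[str, dict[str, Uncertain]] = {}
        for farm in densities:
            entry = {}
            if farm in flesh.index:
                r = flesh.loc[farm]
                entry["flesh"] = Uncertain(float(r["value"]), float(r["se"]) if np.isfinite(r["se"]) else 0.0)
            if farm in water_m.index:
                r = water_m.loc[farm]
                entry["water"] = Uncertain(float(r["value"]), float(r["se"]) if np.isfinite(r["se"]) else 0.0)
            measurements_u[farm] = entry
        cy = CellYield(73e-18, 67e-18)
        rows = build_contribution_table(
            densities,
            measurements_u,
            cy,
            mucous_area_cm2=config.mucous_area_cm2,
            fish_mass_kg=config.fish_mass_kg,
            copies_per_cell=config.copies_per_cell,
        )
        frame = contribution_table_frame(rows)
        frame.to_csv(out / "contribution_table.tsv", sep="\t", index=False, lineterminator="\n")
        summary["massbalance"] = {
            r.farm_id: {
                "contribution_pct": round(r.contribution_pct, 1)
                if math.isfinite(r.contribution_pct)
                else None,
                "mucous_ng_per_intestine": None
                if r.mucous_production is None
                else r.mucous_production.value,
            }
            for r in rows
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return summary


def write_dataset(dataset, directory: str | Path, config: PipelineConfig | None = None) -> PipelineConfig:
    """Write a SyntheticDataset in the dialects the pipeline reads."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()
    write_qpcr_plate(dataset.qpcr_plate, d / cfg.plate)
    write_samples(dataset.samples, d / cfg.samples)
    write_otu_table(dataset.otu_table, d / cfg.otu_table)
    write_taxonomy(dataset.taxonomy, d / cfg.taxonomy)
    write_measurements(dataset.measurements, d / cfg.measurements)
    return cfg
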