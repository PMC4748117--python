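"""Readers, writers, sample filtering and the end-to-end pipeline.

CSV dialect: comma-separated, UTF-8, header required, '.' decimal, empty
cell = missing.  Delta columns are named d15N, d18O, d17O, D17O.  Group
labels are a closed vocabulary (snow, inflow, lake, snowmelt, other);
unknown labels are errors, not silent passes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .budget import (
    DEFAULT_NOX_BUDGET,
    DEFAULT_SNOW_NO3_UM,
    MassBalanceInputs,
    anthropogenic_share,
    budget_frame,
    nox_budget_apportionment,
    snow_ammonium_d15N,
)
from .corrections import CorrectionParameters, SampleRecord, ValidationError
from .mixing import (
    MixingFitConfig,
    SourceProfile,
    default_source_profiles,
    fit_mixing_model,
    summarize_apportionment,
)
from .synth import SAMPLE_COLUMNS, default_dataset

logger = logging.getLogger("isomix")

__all__ = [
    "AnalysisConfig",
    "read_samples_csv",
    "write_samples_csv",
    "records_to_frame",
    "frame_to_records",
    "filter_samples",
    "load_source_config",
    "dump_source_config",
    "run_pipeline",
]

REQUIRED_COLUMNS = ["sample_id", "group", "d15N", "d18O", "no3_uM", "nh4_uM"]
NUMERIC_COLUMNS = ["d15N", "d18O", "d17O", "D17O", "no3_uM", "nh4_uM"]


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration."""

    samples_path: Optional[Union[str, Path]] = None  # None -> synthetic data
    sources_path: Optional[Union[str, Path]] = None  # None -> defaults
    output_dir: Union[str, Path] = "isomix_output"
    min_no3_uM: float = 1.6
    excluded_groups: tuple[str, ...] = ("snowmelt",)
    fit: MixingFitConfig = field(default_factory=MixingFitConfig)
    corrections: CorrectionParameters = field(default_factory=CorrectionParameters)
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_no3_uM < 0:
            raise ValidationError("min_no3_uM must be >= 0")


def read_samples_csv(path: Union[str, Path]) -> list[SampleRecord]:
    """Read and validate a sample CSV into records.

    Rows with missing Δ¹⁷O are retained with ``d15N_corrected_flag=False``;
    malformed numeric cells are reported with their row numbers.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("%s: empty data section", path)
        return []

    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # 1-based + header line
            raise ValidationError(
                f"{path}: malformed numeric cells in column {col!r}, "
                f"file rows {rows}"
            )
        df[col] = num
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in df.iterrows():
        def get(col, default=None):
            v = row.get(col, default)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return v

        flag = get("d15N_corrected_flag", True)
        if isinstance(flag, str):
            flag = flag.strip().lower() in ("true", "1", "yes")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                d15N=float(row["d15N"]),
                d18O=float(row["d18O"]),
                d17O=get("d17O"),
                D17O=get("D17O"),
                no3_uM=float(row["no3_uM"]),
                nh4_uM=float(row["nh4_uM"]),
                d15N_corrected_flag=bool(flag),
            )
        )
    return records


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    return pd.DataFrame([dataclasses.asdict(r) for r in records])[SAMPLE_COLUMNS]


def write_samples_csv(
    records: Sequence[SampleRecord], path: Union[str, Path]
) -> None:
    records_to_frame(records).to_csv(path, index=False)


def filter_samples(
    records: Sequence[SampleRecord],
    config: Optional[AnalysisConfig] = None,
    for_fitting: bool = True,
) -> tuple[list[SampleRecord], list[tuple[SampleRecord, str]]]:
    """Partition records into (kept, excluded-with-reason).

    Exclusion rules, applied in order: nitrate at or below the
    concentration threshold (strict '>' is required to keep), membership
    in an excluded transitional group, and — when ``for_fitting`` — a
    missing Δ¹⁷O (the anomaly tracer cannot be imputed).  Idempotent:
    filtering the kept list again excludes nothing.
    """
    config = config or AnalysisConfig()
    kept: list[SampleRecord] = []
    excluded: list[tuple[SampleRecord, str]] = []
    for r in records:
        if not r.no3_uM > config.min_no3_uM:
            excluded.append((r, "below_no3_threshold"))
        elif r.group in config.excluded_groups:
            excluded.append((r, "transitional_group"))
        elif for_fitting and r.D17O is None:
            excluded.append((r, "missing_D17O"))
        else:
            kept.append(r)
    return kept, excluded


# --- source / fit configuration files -----------------------------------

def load_source_config(
    path: Union[str, Path]
) -> tuple[list[SourceProfile], MixingFitConfig]:
    """Load source profiles and fit settings from a YAML file.

    Layout::

        sources:
          AON:
            d15N: {mean: 0.9, sd: 1.2}
            D17O: {mean: 23.7, sd: 5.6}
          ...
        fit:
          iterations: 500000
          burn_in: 50000
          ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "sources" not in doc:
        raise ValidationError(f"{path}: no 'sources' section")
    sources = []
    for name, tracers in doc["sources"].items():
        means, sds, offsets = {}, {}, {}
        for tracer, spec in tracers.items():
            means[tracer] = float(spec["mean"])
            sds[tracer] = float(spec["sd"])
            if "offset" in spec:
                offsets[tracer] = float(spec["offset"])
        sources.append(
            SourceProfile(name=name, means=means, sds=sds, offsets=offsets)
        )
    fit_kwargs = dict(doc.get("fit", {}))
    if "tracers" in fit_kwargs:
        fit_kwargs["tracers"] = tuple(fit_kwargs["tracers"])
    fit = MixingFitConfig(**fit_kwargs)
    return sources, fit


def dump_source_config(
    sources: Sequence[SourceProfile],
    fit: MixingFitConfig,
    path: Union[str, Path],
) -> None:
    doc = {
        "sources": {
            s.name: {
                t: {
                    "mean": s.means[t],
                    "sd": s.sds[t],
                    **(
                        {"offset": s.offsets[t]} if t in s.offsets else {}
                    ),
                }
                for t in s.means
            }
            for s in sources
        },
        "fit": {
            "tracers": list(fit.tracers),
            "iterations": fit.iterations,
            "burn_in": fit.burn_in,
            "thin": fit.thin,
            "dirichlet_alpha": fit.dirichlet_alpha,
            "sigma_prior_upper": fit.sigma_prior_upper,
            "seed": fit.seed,
            "proposal_scale": fit.proposal_scale,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# --- end-to-end pipeline ------------------------------------------------

def run_pipeline(config: AnalysisConfig) -> dict:
    """Corrections are assumed done; filter, fit per group, write reports.

    Reads the sample table (or generates the default synthetic one when no
    path is given), filters per the exclusion rules, fits the mixing model
    separately for inflows and lakes, computes the snow ammonium mass
    balance and the NOx budget scaled by the lake AON share, and writes
    summary CSVs plus a provenance log to the output directory.

    Returns a report bundle dict with the summaries, budget frame and
    output paths.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.samples_path is not None:
        records = read_samples_csv(config.samples_path)
        logger.info("read %d samples from %s", len(records), config.samples_path)
    else:
        records = frame_to_records(default_dataset(seed=config.seed))
        logger.info("generated %d synthetic samples (seed=%d)",
                    len(records), config.seed)

    if config.sources_path is not None:
        sources, fit_cfg = load_source_config(config.sources_path)
    else:
        sources, fit_cfg = default_source_profiles(), config.fit

    kept, excluded = filter_samples(records, config)
    logger.info("filtering: kept %d, excluded %d", len(kept), len(excluded))

    frame = records_to_frame(kept)
    summaries = {}
    summary_rows = []
    for i, group in enumerate(("inflow", "lake")):
        sub = frame[frame["group"] == group]
        if sub.empty:
            logger.warning("no %s samples survive filtering; skipping fit", group)
            continue
        cfg = dataclasses.replace(fit_cfg, seed=config.seed + i)
        draws = fit_mixing_model(sub, sources, cfg)
        summary = summarize_apportionment(draws)
        summaries[group] = summary
        df = summary.to_frame(rounded=False)
        df.insert(0, "group", group)
        summary_rows.append(df)

    report: dict = {"summaries": summaries, "outputs": {}}
    if summary_rows:
        summary_df = pd.concat(summary_rows, ignore_index=True)
        p = out_dir / "apportionment_summary.csv"
        summary_df.to_csv(p, index=False, float_format="%.6f")
        report["outputs"]["apportionment"] = p

    snow = records_to_frame([r for r in records if r.group == "snow"])
    inflow = records_to_frame([r for r in records if r.group == "inflow"])
    if not snow.empty and not inflow.empty:
        mb = MassBalanceInputs(
            d15N_inflow=float(inflow["d15N"].mean()),
            d15N_snow=float(snow["d15N"].mean()),
            nh4_snow=float(snow["nh4_uM"].mean()),
            no3_snow=float(snow["no3_uM"].mean()),
        )
        report["snow_nh4_d15N"] = snow_ammonium_d15N(mb)

    if "lake" in summaries:
        aon = summaries["lake"].mpe["AON"] if "AON" in summaries["lake"].mpe else None
        if aon is not None:
            budget = nox_budget_apportionment(DEFAULT_NOX_BUDGET, aon)
            bdf = budget_frame(budget)
            p = out_dir / "nox_budget.csv"
            bdf.to_csv(p, index=False)
            report["outputs"]["budget"] = p
            report["budget"] = bdf
    if "inflow" in summaries:
        mpes = summaries["inflow"].mpe
        fert = next(
            (v for k, v in mpes.items() if "Fertilizer" in k), None
        )
        total = sum(tg for _, tg in DEFAULT_NOX_BUDGET)
        fossil_frac = DEFAULT_NOX_BUDGET[0][1] / total
        if fert is not None and "AON" in mpes:
            report["anthropogenic_share"] = anthropogenic_share(
                fert, mpes["AON"], fossil_frac
            )

    excl_df = pd.DataFrame(
        [{"sample_id": r.sample_id, "group": r.group, "reason": reason}
         for r, reason in excluded]
    )
    p = out_dir / "excluded_samples.csv"
    excl_df.to_csv(p, index=False)
    report["outputs"]["excluded"] = p

    provenance = {
        "seed": config.seed,
        "min_no3_uM": config.min_no3_uM,
        "excluded_groups": list(config.excluded_groups),
        "iterations": fit_cfg.iterations,
        "burn_in": fit_cfg.burn_in,
        "tracers": list(fit_cfg.tracers),
        "n_samples_in": len(records),
        "n_samples_kept": len(kept),
    }
    p = out_dir / "provenance.json"
    with open(p, "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    report["outputs"]["provenance"] = p
    return report
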