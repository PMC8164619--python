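"""End-to-end assembly: survey -> summaries -> simulation -> report tables.

A single YAML config drives the run.  Outputs are plain CSVs — a survey
summary table, a per-stratum LADD/HI percentile table, and a per-region
median-HI table — plus a JSON manifest recording the config snapshot, seed,
iteration count, package version and input digests, so any output file can
be traced to the run that produced it.  Re-running the same config and seed
reproduces byte-identical CSVs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import os
from typing import NamedTuple

import pandas as pd
import yaml

from . import __version__
from .config_io import (
    load_constants,
    load_table1_summaries,
    load_table2_groups,
    read_concentration_survey,
    summarize_concentrations,
    write_concentration_survey,
)
from .distributions import fit_concentration_model, from_summary
from .exposure import ExposureParams, regional_hi_table, run_all_groups
from .synthetic import ConsumptionGroup, generate_concentration_survey

logger = logging.getLogger("dietpra")

__all__ = ["DailyRfd", "derive_daily_rfd", "default_config", "run_pipeline"]


class DailyRfd(NamedTuple):
    """A weekly tolerable intake converted to a daily reference dose."""

    display: float  # rounded to 2 decimals, as guidance documents print it
    exact: float  # unrounded, used in computation


def derive_daily_rfd(twi: float) -> DailyRfd:
    """Convert a tolerable weekly intake (ug/kg bw/week) to a daily dose."""
    if twi <= 0:
        raise ValueError(f"twi must be positive, got {twi}")
    exact = twi / 7.0
    return DailyRfd(display=round(exact, 2), exact=exact)


def default_config() -> dict:
    """The packaged default run: synthetic survey, 100,000 draws, seed 1."""
    return {
        "survey": "synthetic",
        "groups": None,  # packaged consumption-strata table
        "constants": None,  # packaged reference constants
        "simulation": {
            "iterations": 100_000,
            "seed": 1,
            "rfd": None,  # None -> EFSA daily reference dose from constants
            "af": 1.0,
            "ed": 1.0,
            "at": 1.0,
        },
        "synthetic": {"censor_threshold": None},  # None -> constants default
        "outputs": "results",
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = default_config()
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _atomic_write_csv(df: pd.DataFrame, path: str, **kwargs) -> None:
    tmp = f"{path}.tmp"
    df.to_csv(tmp, index=False, **kwargs)
    os.replace(tmp, path)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict) -> dict[str, str]:
    """Execute the full assessment; returns a name -> path map of outputs.

    Stages: (1) obtain a sample-level survey (synthetic, or a user CSV, or
    skip straight to printed summaries); (2) summarize it; (3) fit the
    pooled concentration model; (4) simulate LADD/HI percentiles for every
    consumption stratum; (5) simulate the per-region median-HI map for the
    19–65-year male stratum; (6) write tables and manifest.  Any stage
    failure aborts with a stage-labelled error.
    """
    sim = config["simulation"]
    constants = load_constants(config.get("constants"))
    rfd = sim.get("rfd") or constants.rfd_efsa
    params = ExposureParams(
        af=sim.get("af", 1.0),
        ed=sim.get("ed", 1.0),
        at=sim.get("at", 1.0),
        rfd=rfd,
        iterations=sim.get("iterations", 100_000),
        seed=sim.get("seed", 1),
    )
    outdir = config.get("outputs", "results")
    os.makedirs(outdir, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "survey"
    try:
        targets = load_table1_summaries()
        regional_targets = [t for t in targets if t.region != "Total"]
        survey_source = config.get("survey", "synthetic")
        records = None
        if survey_source == "synthetic":
            threshold = (
                config.get("synthetic", {}).get("censor_threshold")
                or constants.censor_threshold_default
            )
            records = generate_concentration_survey(
                regional_targets, censor_threshold=threshold, seed=params.seed
            )
            survey_path = os.path.join(outdir, "survey.csv")
            write_concentration_survey(records, survey_path)
            outputs["survey"] = survey_path
            logger.info("stage %s: generated %d records (seed %d)",
                        stage, len(records), params.seed)
        elif survey_source not in (None, "summaries"):
            records = read_concentration_survey(survey_source)
            logger.info("stage %s: read %d records from %s",
                        stage, len(records), survey_source)

        stage = "summarize"
        if records is not None:
            summary_rows = summarize_concentrations(records, group_by="region")
            summary_rows += summarize_concentrations(records, group_by="none")
            summary_df = pd.DataFrame(
                [
                    (s.region, s.n, s.mean, s.sd, s.median, s.max, s.detect_rate)
                    for s in summary_rows
                ],
                columns=["region", "n", "mean", "sd", "median", "max", "detect_rate"],
            )
        else:
            summary_df = pd.DataFrame(
                [
                    (s.region, s.n, s.mean, s.sd, s.median, s.max, s.detect_rate)
                    for s in targets
                ],
                columns=["region", "n", "mean", "sd", "median", "max", "detect_rate"],
            )
        summary_path = os.path.join(outdir, "survey_summary.csv")
        _atomic_write_csv(summary_df, summary_path, float_format="%.6g")
        outputs["survey_summary"] = summary_path

        stage = "concentration model"
        if records is not None:
            conc_model = fit_concentration_model(records)
        else:
            (total,) = [t for t in targets if t.region == "Total"]
            conc_model = from_summary(total)

        stage = "group simulation"
        groups = [
            ConsumptionGroup.from_row(row)
            for row in load_table2_groups(config.get("groups")).itertuples(index=False)
        ]
        summaries = run_all_groups(conc_model, groups, params)
        group_df = pd.DataFrame(
            [
                (
                    s.group, s.ladd_p50, s.ladd_p90, s.ladd_p95,
                    s.hi_p50, s.hi_p90, s.hi_p95,
                )
                for s in summaries
            ],
            columns=[
                "group", "ladd_p50", "ladd_p90", "ladd_p95",
                "hi_p50", "hi_p90", "hi_p95",
            ],
        )
        group_path = os.path.join(outdir, "group_exposure.csv")
        _atomic_write_csv(group_df.round(6), group_path)
        outputs["group_exposure"] = group_path
        logger.info("stage %s: %d strata x %d draws", stage, len(groups),
                    params.iterations)

        stage = "regional simulation"
        (adult_male,) = [g for g in groups if g.label == "19-65 years, male"]
        hi_map = regional_hi_table(regional_targets, adult_male, params)
        regional_df = pd.DataFrame(
            sorted(hi_map.items()), columns=["region", "hi_p50"]
        )
        regional_path = os.path.join(outdir, "regional_hi.csv")
        _atomic_write_csv(regional_df.round(6), regional_path)
        outputs["regional_hi"] = regional_path

        stage = "manifest"
        manifest = {
            "package": "dietpra",
            "version": __version__,
            "seed": params.seed,
            "iterations": params.iterations,
            "rfd": params.rfd,
            "config": config,
            "input_digests": {
                name: _sha256(path)
                for name, path in outputs.items()
                if name == "survey"
            },
            "output_digests": {
                name: _sha256(path) for name, path in outputs.items()
            },
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        manifest_path = os.path.join(outdir, "manifest.json")
        tmp = manifest_path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, manifest_path)
        outputs["manifest"] = manifest_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs
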