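"""End-to-end orchestration: simulate/load → validate → stage → norm → compare.

A run writes into its output directory: ``cohort.csv`` (if simulated),
``staged.csv``, ``models.json``, ``scored.csv``, ``tables/*.csv``, an
optional figure, ``manifest.json`` (config hash, seed, row counts at every
filter step — enough to audit filter-count conservation) and ``run.log``.
Identical configuration and seed reproduce identical outputs byte for byte;
timestamps appear only in the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import comparisons, norming, staging
from .config import CohortConfig, RunConfig
from .schema import read_cohort, validate_schema, write_cohort
from .simulate import generate_cohort, ppmi_like_config

logger = logging.getLogger("nsdcog")


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _setup_logging(out_dir: Path, level: str) -> None:
    logger.setLevel(level.upper())
    logger.handlers = [h for h in logger.handlers
                       if not isinstance(h, logging.FileHandler)]
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute one full run; returns the manifest dictionary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "tables").mkdir(exist_ok=True)
    _setup_logging(out_dir, config.log_level)

    if config.input_csv is not None:
        logger.info("loading cohort from %s", config.input_csv)
        cohort = read_cohort(config.input_csv)
    else:
        cohort_cfg = (
            ppmi_like_config(config.seed)
            if config.cohort == "ppmi_like"
            else config.cohort.model_copy(update={"seed": config.seed})
        )
        assert isinstance(cohort_cfg, CohortConfig)
        logger.info("simulating cohort (%d groups, seed %d)",
                    len(cohort_cfg.groups), config.seed)
        if config.cohort == "ppmi_like":
            from .simulate import make_ppmi_like_cohort

            cohort = make_ppmi_like_cohort(config.seed)
        else:
            cohort = generate_cohort(cohort_cfg)
        write_cohort(cohort, out_dir / "cohort.csv")

    report = validate_schema(cohort)
    for w in report.warnings:
        logger.warning("schema: %s", w)
    report.raise_if_invalid()

    staged = staging.stage_cohort(cohort, config.thresholds)
    write_cohort(staged, out_dir / "staged.csv")
    role_counts = staged["cohort_role"].value_counts().to_dict()
    reasons = (
        staged.loc[staged["cohort_role"] == "excluded", "exclusion_reason"]
        .value_counts()
        .to_dict()
    )
    logger.info("roles: %s", role_counts)

    reference = staged[staged["cohort_role"] == "robust_hc"]
    models = norming.fit_all_norms(reference, config.norming)
    norming.save_models(models, out_dir / "models.json")
    scored = norming.apply_norms(staged, models)
    write_cohort(scored, out_dir / "scored.csv")

    tables = comparisons.build_tables(scored, config.comparisons)
    for name, frame in tables.items():
        frame.to_csv(out_dir / "tables" / f"{name}.csv", index=False)
    if config.make_plot and len(tables["figure1"]):
        comparisons.plot_css_by_subgroup(tables["figure1"],
                                         out_dir / "figure1.png")

    n = len(cohort)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_input": n,
        "n_analysis": int(role_counts.get("analysis", 0)),
        "n_robust_hc": int(role_counts.get("robust_hc", 0)),
        "n_excluded": int(role_counts.get("excluded", 0)),
        "exclusions_by_reason": {k: int(v) for k, v in sorted(reasons.items())},
        "stage_counts": {
            k: int(v)
            for k, v in staged["stage"].value_counts(dropna=False)
            .rename(lambda s: "unevaluable" if pd.isna(s) else str(s))
            .sort_index()
            .items()
        },
        "subgroup_counts": {
            k: int(v)
            for k, v in staged.loc[staged["cohort_role"] == "analysis", "subgroup"]
            .value_counts()
            .sort_index()
            .items()
        },
        "css_evaluable": int(scored["css_evaluable"].sum()),
    }
    if (manifest["n_analysis"] + manifest["n_robust_hc"]
            + manifest["n_excluded"]) != n:
        raise RuntimeError("cohort partition lost participants")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", manifest)
    return manifest
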