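"""Configuration models for the simulator, staging thresholds and pipeline.

All tunable quantities live here as pydantic models so that invalid
configurations fail fast with the offending field named, and so that every
run can serialise its exact configuration into the run manifest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .schema import COGNITIVE_TESTS


class CognitiveTestEffect(BaseModel):
    """Linear covariate model for one raw cognitive score.

    ``score = intercept + age_slope*age + education_slope*education
    + male_slope*1[male] + residual_sd * (group shift + noise)``.
    """

    intercept: float
    age_slope: float = 0.0
    education_slope: float = 0.0
    male_slope: float = 0.0
    residual_sd: float = Field(gt=0)


def default_test_effects() -> dict[str, CognitiveTestEffect]:
    """Covariate effects typical of published norms for this battery.

    Magnitudes: performance declines with age (strongest for processing
    speed), rises with education, and women outperform men on verbal
    memory while men score slightly higher on line orientation.
    """
    return {
        "hvlt_immediate": CognitiveTestEffect(
            intercept=30.0, age_slope=-0.10, education_slope=0.15,
            male_slope=-1.5, residual_sd=4.5,
        ),
        "hvlt_delayed": CognitiveTestEffect(
            intercept=11.0, age_slope=-0.05, education_slope=0.05,
            male_slope=-0.7, residual_sd=2.0,
        ),
        "jlo": CognitiveTestEffect(
            intercept=11.5, age_slope=-0.02, education_slope=0.10,
            male_slope=0.8, residual_sd=2.0,
        ),
        "sdmt": CognitiveTestEffect(
            intercept=62.0, age_slope=-0.45, education_slope=0.60,
            male_slope=-2.0, residual_sd=8.0,
        ),
        "lns": CognitiveTestEffect(
            intercept=12.0, age_slope=-0.06, education_slope=0.25,
            male_slope=0.0, residual_sd=2.5,
        ),
        "fluency": CognitiveTestEffect(
            intercept=25.0, age_slope=-0.10, education_slope=0.30,
            male_slope=-0.5, residual_sd=4.5,
        ),
    }


class GroupSpec(BaseModel):
    """Generative recipe for one enrollment group."""

    label: str
    n: int = Field(ge=0)

    age_mean: float = Field(gt=0)
    age_sd: float = Field(ge=0)
    prop_male: float = Field(ge=0, le=1, default=0.6)
    education_mean: float = 16.0
    education_sd: float = Field(ge=0, default=3.0)

    saa_positive_prob: float = Field(ge=0, le=1, default=0.0)
    # DaTscan lowest-putamen SBR as percent of the age/sex-expected value;
    # truncation bounds let a group be constructed entirely above or below
    # the 75% deficit cutoff.
    pct_expected_sbr_mean: float = 100.0
    pct_expected_sbr_sd: float = Field(ge=0, default=10.0)
    pct_expected_sbr_min: float = Field(gt=0, default=5.0)
    pct_expected_sbr_max: float = 160.0

    upsit_mean: float = 50.0
    upsit_sd: float = Field(ge=0, default=25.0)
    upsit_min: float = Field(ge=0, le=100, default=0.0)
    upsit_max: float = Field(ge=0, le=100, default=100.0)

    irbd_prob: float = Field(ge=0, le=1, default=0.0)  # PSG-confirmed RBD
    rbdsq_mean: float = 1.5
    rbdsq_sd: float = Field(ge=0, default=1.5)
    rbdsq_min: int = Field(ge=0, le=13, default=0)
    rbdsq_max: int = Field(ge=0, le=13, default=13)
    self_reported_rbd_prob: float = Field(ge=0, le=1, default=0.0)
    dream_enactment_prob: float = Field(ge=0, le=1, default=0.0)

    pd_med_prob: float = Field(ge=0, le=1, default=0.0)
    clonazepam_prob: float = Field(ge=0, le=1, default=0.0)
    subthreshold_parkinsonism_prob: float = Field(ge=0, le=1, default=0.0)
    updrs11_one_prob: float = Field(ge=0, le=1, default=0.10)
    updrs11_two_prob: float = Field(ge=0, le=1, default=0.0)
    apathy_gt1_prob: float = Field(ge=0, le=1, default=0.05)
    functional_impairment_prob: float = Field(ge=0, le=1, default=0.0)
    gds15_mean: float = 1.3
    gds15_sd: float = Field(ge=0, default=2.0)

    moca_mean: float = 27.5
    moca_sd: float = Field(ge=0, default=1.5)
    moca_min: int = Field(ge=0, le=30, default=0)
    moca_max: int = Field(ge=0, le=30, default=30)
    #: MoCA points gained per unit of the latent cognitive shift (z units)
    moca_shift_weight: float = 1.5
    #: lower clip for the year-1 MoCA (set to 26 to construct robust HCs)
    moca_year1_min: int = Field(ge=0, le=30, default=0)

    #: mean displacement of all six test scores, in residual-SD (z) units
    cognitive_shift: float = 0.0

    @model_validator(mode="after")
    def _check_bounds(self) -> "GroupSpec":
        if self.updrs11_one_prob + self.updrs11_two_prob > 1:
            raise ValueError("updrs11_one_prob + updrs11_two_prob exceeds 1")
        if self.upsit_min > self.upsit_max:
            raise ValueError("upsit_min exceeds upsit_max")
        if self.rbdsq_min > self.rbdsq_max:
            raise ValueError("rbdsq_min exceeds rbdsq_max")
        if self.pct_expected_sbr_min > self.pct_expected_sbr_max:
            raise ValueError("pct_expected_sbr_min exceeds pct_expected_sbr_max")
        if self.moca_min > self.moca_max:
            raise ValueError("moca_min exceeds moca_max")
        return self


class CohortConfig(BaseModel):
    """Full recipe for a synthetic case-control cohort."""

    groups: list[GroupSpec]
    test_effects: dict[str, CognitiveTestEffect] = Field(default_factory=default_test_effects)
    #: common-factor correlation between the six tests' noise terms
    #: (0 = independent noise; >0 adds a shared per-participant factor)
    common_factor_correlation: float = Field(ge=0, lt=1, default=0.0)
    expected_sbr_mean: float = Field(gt=0, default=2.1)
    expected_sbr_sd: float = Field(ge=0, default=0.3)
    education_missing_rate: float = Field(ge=0, le=1, default=0.0)
    moca_year1_missing_rate: float = Field(ge=0, le=1, default=0.0)
    test_missing_rate: float = Field(ge=0, le=1, default=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_tests(self) -> "CohortConfig":
        missing = set(COGNITIVE_TESTS) - set(self.test_effects)
        if missing:
            raise ValueError(f"test_effects missing entries for: {sorted(missing)}")
        return self


class StagingThresholds(BaseModel):
    """Cutoffs operationalising NSD-ISS stage 2 and the robust-HC filter.

    Defaults follow the PPMI operationalisation: hyposmia is UPSIT
    age/sex-adjusted percentile ≤ 15 (inclusive); DaT deficit is lowest
    putamen SBR strictly below 75% of the age/sex-expected value; RBD
    screening evidence is RBDSQ ≥ 6; the stage-2 cognitive criterion is
    MDS-UPDRS item 1.1 = 1 with MoCA > 25; the stage-3 cognitive rule is
    item 1.1 = 2 with MoCA ≥ 25.
    """

    upsit_percentile_cutoff: float = Field(ge=0, le=100, default=15.0)
    dat_percent_expected_cutoff: float = Field(gt=0, default=75.0)
    rbdsq_cutoff: int = Field(ge=0, le=13, default=6)
    stage2_cognitive_updrs_value: int = Field(ge=0, le=4, default=1)
    stage2_cognitive_moca_min: int = Field(ge=0, le=30, default=26)
    stage3_cognitive_updrs_value: int = Field(ge=0, le=4, default=2)
    stage3_cognitive_moca_min: int = Field(ge=0, le=30, default=25)
    robust_hc_moca_baseline_min: int = Field(ge=0, le=30, default=27)
    robust_hc_moca_year1_min: int = Field(ge=0, le=30, default=26)
    robust_hc_max_moca_drop: int = Field(ge=0, default=2)


class NormOptions(BaseModel):
    """Options for the regression-based norming step."""

    #: "rmse" = degrees-of-freedom-corrected root-mean-square residual;
    #: "population" = maximum-likelihood (1/n) residual SD
    residual_scale: Literal["rmse", "population"] = "rmse"
    min_reference_n: int = Field(ge=5, default=10)


class ComparisonOptions(BaseModel):
    test: Literal["pooled", "welch"] = "pooled"


class RunConfig(BaseModel):
    """One end-to-end pipeline run (simulate → stage → norm → compare)."""

    seed: int = 0
    #: path to an existing participant CSV; if None, a cohort is simulated
    input_csv: Optional[str] = None
    #: cohort recipe used when input_csv is None ("ppmi_like" uses the
    #: built-in preset emulating the published baseline composition)
    cohort: CohortConfig | Literal["ppmi_like"] = "ppmi_like"
    thresholds: StagingThresholds = Field(default_factory=StagingThresholds)
    norming: NormOptions = Field(default_factory=NormOptions)
    comparisons: ComparisonOptions = Field(default_factory=ComparisonOptions)
    make_plot: bool = False
    log_level: str = "INFO"


def load_yaml(path, model):
    """Load any of the config models from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return model.model_validate(data)


def dump_yaml(config: BaseModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


def load_run_config(path: str | Path) -> RunConfig:
    return load_yaml(path, RunConfig)
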