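"""Synthetic case-control cohort generator.

Emulates the participant-level structure the downstream analysis assumes:
raw cognitive scores follow a linear model in age, sex and education with
Gaussian residuals; a per-group *cognitive shift*, expressed in residual-SD
(z) units, displaces all six scores so that configured shifts equal the
expected displacement of the cognitive summary score after norming.
Biomarkers (SAA status, DaTscan percent-of-expected SBR), olfaction (UPSIT
percentile), RBD indicators, staging items and MoCA are drawn per group
from truncated distributions, which allows groups to be constructed
entirely on one side of a staging cutoff.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import CohortConfig, GroupSpec
from .schema import COGNITIVE_TESTS, COLUMNS, coerce_cohort


def _trunc_normal(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws; degenerate sd returns the clipped mean."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _bounded_int(rng, mean, sd, lo, hi, size):
    draws = _trunc_normal(rng, mean, sd, lo - 0.49, hi + 0.49, size)
    return np.clip(np.round(draws), lo, hi).astype(int)


def _generate_group(rng: np.random.Generator, spec: GroupSpec,
                    config: CohortConfig) -> pd.DataFrame:
    n = spec.n
    cols: dict[str, np.ndarray | list] = {}
    cols["participant_id"] = [f"{spec.label}-{i:04d}" for i in range(n)]
    cols["group_label"] = [spec.label] * n

    age = rng.normal(spec.age_mean, spec.age_sd, n)
    age = np.clip(age, 18.0, 100.0)
    male = rng.random(n) < spec.prop_male
    education = np.clip(
        np.round(rng.normal(spec.education_mean, spec.education_sd, n)), 0, 30
    )
    cols["age"] = np.round(age, 2)
    cols["sex"] = np.where(male, "male", "female")
    cols["education_years"] = education

    cols["saa_positive"] = rng.random(n) < spec.saa_positive_prob
    expected_sbr = np.maximum(
        rng.normal(config.expected_sbr_mean, config.expected_sbr_sd, n), 0.5
    )
    pct = _trunc_normal(
        rng, spec.pct_expected_sbr_mean, spec.pct_expected_sbr_sd,
        spec.pct_expected_sbr_min, spec.pct_expected_sbr_max, n,
    )
    cols["expected_sbr"] = np.round(expected_sbr, 3)
    cols["lowest_putamen_sbr"] = np.round(expected_sbr * pct / 100.0, 3)

    cols["upsit_percentile"] = np.round(
        _trunc_normal(rng, spec.upsit_mean, spec.upsit_sd,
                      spec.upsit_min, spec.upsit_max, n), 1
    )

    psg = rng.random(n) < spec.irbd_prob
    cols["psg_confirmed_rbd"] = psg
    cols["rbdsq_total"] = _bounded_int(
        rng, spec.rbdsq_mean, spec.rbdsq_sd, spec.rbdsq_min, spec.rbdsq_max, n
    )
    cols["self_reported_rbd_dx"] = (~psg) & (
        rng.random(n) < spec.self_reported_rbd_prob
    )
    cols["dream_enactment"] = rng.random(n) < spec.dream_enactment_prob

    cols["pd_med_use"] = rng.random(n) < spec.pd_med_prob
    cols["clonazepam_use"] = rng.random(n) < spec.clonazepam_prob
    cols["subthreshold_parkinsonism"] = (
        rng.random(n) < spec.subthreshold_parkinsonism_prob
    )
    u = rng.random(n)
    cols["updrs_1_1"] = np.where(
        u < spec.updrs11_two_prob, 2,
        np.where(u < spec.updrs11_two_prob + spec.updrs11_one_prob, 1, 0),
    )
    cols["updrs_apathy"] = np.where(
        rng.random(n) < spec.apathy_gt1_prob, 2, (rng.random(n) < 0.2).astype(int)
    )
    cols["functional_impairment_any_track"] = (
        rng.random(n) < spec.functional_impairment_prob
    )
    cols["gds15"] = _bounded_int(rng, spec.gds15_mean, spec.gds15_sd, 0, 15, n)

    # shared cognitive factor: drives inter-test correlation (if enabled)
    # and couples MoCA to the same latent cognition as the battery
    rho = config.common_factor_correlation
    factor = rng.normal(0.0, 1.0, n)
    latent = spec.cognitive_shift + np.sqrt(rho) * factor

    moca_loc = spec.moca_mean + spec.moca_shift_weight * latent
    moca_draw = rng.normal(moca_loc, spec.moca_sd)
    moca = np.clip(np.round(moca_draw), spec.moca_min, spec.moca_max).astype(int)
    cols["moca_baseline"] = moca
    drop = rng.choice([-1, 0, 1, 2], size=n, p=[0.25, 0.45, 0.20, 0.10])
    cols["moca_year1"] = np.clip(moca - drop, spec.moca_year1_min, 30)

    for test in COGNITIVE_TESTS:
        eff = config.test_effects[test]
        noise = np.sqrt(rho) * factor + np.sqrt(1 - rho) * rng.normal(0, 1, n)
        score = (
            eff.intercept
            + eff.age_slope * age
            + eff.education_slope * education
            + eff.male_slope * male
            + eff.residual_sd * (spec.cognitive_shift + noise)
        )
        cols[test] = np.round(score, 3)

    return pd.DataFrame(cols)


def _inject_missing(rng, df: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    n = len(df)
    if config.education_missing_rate > 0:
        mask = rng.random(n) < config.education_missing_rate
        df.loc[mask, "education_years"] = pd.NA
    if config.moca_year1_missing_rate > 0:
        mask = rng.random(n) < config.moca_year1_missing_rate
        df.loc[mask, "moca_year1"] = pd.NA
    if config.test_missing_rate > 0:
        for test in COGNITIVE_TESTS:
            mask = rng.random(n) < config.test_missing_rate
            df.loc[mask, test] = pd.NA
    return df


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a participant table from a :class:`CohortConfig`.

    Deterministic under a fixed ``config.seed``: the same configuration
    always yields an identical table.
    """
    rng = np.random.default_rng(config.seed)
    frames = [_generate_group(rng, spec, config) for spec in config.groups]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(COLUMNS)
    )
    df = coerce_cohort(df)
    return _inject_missing(rng, df, config)


# ---------------------------------------------------------------------------
# PPMI-like preset: group sizes, demographics and cognitive shifts matching
# the published baseline composition of the early-NSD hyposmia analysis.
# ---------------------------------------------------------------------------

#: (label, n, cognitive shift in z units) for the five constructed groups
PPMI_LIKE_GROUPS = (
    ("hc", 158, 0.0),
    ("stage2a_hyposmia", 58, 0.07),
    ("stage2a_irbd", 43, -0.26),
    ("stage2b_hyposmia", 179, -0.20),
    ("stage2b_irbd", 48, -0.47),
)


def ppmi_like_config(seed: int = 0) -> CohortConfig:
    """Cohort recipe emulating the published baseline study composition.

    Five groups: 158 robust healthy controls (SAA−, normosmic, stable
    MoCA ≥ 27), and four SAA+ hyposmic stage-2 groups split by DaTscan
    deficit (2A ≥ 75% of expected SBR, 2B < 75%) and PSG-confirmed iRBD.
    Group sizes, age/education/sex margins and CSS shifts follow the
    published group summaries; the common-factor correlation of 0.30
    gives the composite score an SD near the reported 0.6–0.7.
    """
    common = dict(prop_male=0.61)
    hc = GroupSpec(
        label="hc", n=158, age_mean=58.96, age_sd=11.69,
        education_mean=16.1, education_sd=3.0,
        saa_positive_prob=0.0,
        pct_expected_sbr_mean=100.0, pct_expected_sbr_sd=10.0,
        pct_expected_sbr_min=80.0, pct_expected_sbr_max=140.0,
        upsit_mean=60.0, upsit_sd=20.0, upsit_min=20.0, upsit_max=99.0,
        rbdsq_mean=1.0, rbdsq_sd=1.0, rbdsq_max=5,
        subthreshold_parkinsonism_prob=0.03, updrs11_one_prob=0.09,
        apathy_gt1_prob=0.04, gds15_mean=1.2,
        moca_mean=28.3, moca_sd=1.1, moca_min=27, moca_year1_min=26,
        cognitive_shift=0.0, **common,
    )

    def stage2(label, n, shift, deficit, irbd, subthresh, updrs1):
        pct = dict(
            pct_expected_sbr_mean=55.0, pct_expected_sbr_sd=12.0,
            pct_expected_sbr_min=20.0, pct_expected_sbr_max=74.5,
        ) if deficit else dict(
            pct_expected_sbr_mean=95.0, pct_expected_sbr_sd=9.0,
            pct_expected_sbr_min=76.0, pct_expected_sbr_max=130.0,
        )
        rbd = dict(
            irbd_prob=1.0, rbdsq_mean=8.0, rbdsq_sd=2.5, clonazepam_prob=0.385,
        ) if irbd else dict(
            irbd_prob=0.0, rbdsq_mean=1.5, rbdsq_sd=1.2, rbdsq_max=5,
        )
        age = dict(age_mean=64.98, age_sd=8.23, education_mean=16.4,
                   education_sd=3.4) if deficit else dict(
            age_mean=66.93, age_sd=5.86, education_mean=16.9, education_sd=3.3)
        return GroupSpec(
            label=label, n=n, saa_positive_prob=1.0,
            upsit_mean=7.0, upsit_sd=4.0, upsit_min=0.5, upsit_max=15.0,
            subthreshold_parkinsonism_prob=subthresh, updrs11_one_prob=updrs1,
            apathy_gt1_prob=0.09, gds15_mean=1.35,
            moca_mean=27.0, moca_sd=2.0, moca_min=20,
            cognitive_shift=shift, **pct, **rbd, **age, **common,
        )

    groups = [
        hc,
        stage2("stage2a_hyposmia", 58, 0.07, deficit=False, irbd=False,
               subthresh=0.09, updrs1=0.17),
        stage2("stage2a_irbd", 43, -0.26, deficit=False, irbd=True,
               subthresh=0.09, updrs1=0.17),
        stage2("stage2b_hyposmia", 179, -0.20, deficit=True, irbd=False,
               subthresh=0.60, updrs1=0.16),
        stage2("stage2b_irbd", 48, -0.47, deficit=True, irbd=True,
               subthresh=0.60, updrs1=0.16),
    ]
    return CohortConfig(groups=groups, common_factor_correlation=0.30, seed=seed)


def make_ppmi_like_cohort(seed: int = 0) -> pd.DataFrame:
    """Generate the PPMI-like cohort preset and inject its known missingness.

    Three stage-2B hyposmia-only participants lose their education value
    (making their summary score not evaluable) and one healthy control
    loses a single test score, mirroring the footnoted missing-data counts
    of the emulated study.
    """
    df = generate_cohort(ppmi_like_config(seed))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 17]))
    idx_2b = df.index[df["group_label"] == "stage2b_hyposmia"]
    df.loc[rng.choice(idx_2b, size=3, replace=False), "education_years"] = pd.NA
    idx_hc = df.index[df["group_label"] == "hc"]
    df.loc[rng.choice(idx_hc, size=1), "sdmt"] = pd.NA
    return df
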