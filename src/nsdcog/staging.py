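"""NSD-ISS stage-2 classification, analysis-cohort filters and subgrouping.

Implements the biological anchors (CSF α-synuclein SAA positivity; DaTscan
deficit defined as lowest putamen SBR < 75% of the age/sex-expected value),
the three stage-2 track criteria (cognitive: MDS-UPDRS item 1.1 = 1 with
MoCA > 25; motor: subthreshold parkinsonism or PD medication; non-motor:
hyposmia or PSG-confirmed iRBD), the stage-3+ exclusions, the analysis
inclusion filters (hyposmic, untreated, complete battery) with
hyposmia-only vs comorbid-iRBD purity rules, and the robust healthy-control
selection used as the norming reference.

Every participant ends in exactly one of three roles — ``analysis``,
``robust_hc`` or ``excluded`` — and excluded participants carry a single
reason code, assigned in a fixed order (SAA → DaT availability → stage 3 →
stage 2 → hyposmia → PD medication → battery completeness → RBD purity) so
the audit trail is deterministic.
"""

from __future__ import annotations

import pandas as pd

from .config import StagingThresholds
from .schema import COGNITIVE_TESTS

STAGE_LEVELS = ("non_nsd", "stage1", "stage2A", "stage2B", "stage3plus_excluded")
SUBGROUP_LEVELS = ("hyposmia_only", "hyposmia_irbd", "excluded", "not_applicable")

#: exclusion reason codes, in evaluation order
EXCLUSION_REASONS = (
    "dat_missing",
    "stage3",
    "not_stage2",
    "not_hyposmic",
    "pd_meds",
    "incomplete_battery",
    "rbd_unconfirmed",
    "hc_hyposmic_or_missing_upsit",
    "hc_moca_baseline",
    "hc_moca_year1_missing",
    "hc_moca_year1",
    "hc_moca_drop",
)


class StagingError(ValueError):
    """Raised when a record cannot be staged (e.g. missing SAA status)."""


def _as_series(x):
    if isinstance(x, pd.Series):
        return x, False
    return pd.Series([x]), True


def classify_hyposmia(upsit_percentile, thresholds: StagingThresholds | None = None):
    """Hyposmia: UPSIT age/sex-adjusted percentile ≤ cutoff (inclusive).

    A missing percentile yields a missing (indeterminate) result; such
    participants are excluded downstream rather than classified.
    """
    thresholds = thresholds or StagingThresholds()
    ser, scalar = _as_series(upsit_percentile)
    vals = ser.astype("Float64")
    present = vals.dropna().astype(float)
    if ((present < 0) | (present > 100)).any():
        raise StagingError("upsit_percentile outside [0, 100]")
    out = vals <= thresholds.upsit_percentile_cutoff
    out[vals.isna()] = pd.NA
    out = out.astype("boolean")
    if scalar:
        v = out.iloc[0]
        return None if v is pd.NA else bool(v)
    return out


def classify_dat_deficit(lowest_putamen_sbr, expected_sbr,
                         thresholds: StagingThresholds | None = None):
    """DaT deficit: observed SBR strictly below cutoff% of expected SBR."""
    thresholds = thresholds or StagingThresholds()
    sbr, scalar = _as_series(lowest_putamen_sbr)
    exp, _ = _as_series(expected_sbr)
    sbr = sbr.astype("Float64")
    exp = pd.Series(exp.values, index=sbr.index).astype("Float64")
    for name, v in (("lowest_putamen_sbr", sbr), ("expected_sbr", exp)):
        if (v.dropna().astype(float) <= 0).any():
            raise StagingError(f"{name} must be positive")
    pct = 100.0 * sbr / exp
    out = (pct < thresholds.dat_percent_expected_cutoff).astype("boolean")
    out[pct.isna()] = pd.NA
    if scalar:
        v = out.iloc[0]
        return None if v is pd.NA else bool(v)
    return out


def classify_rbd_evidence(records: pd.DataFrame,
                          thresholds: StagingThresholds | None = None):
    """Return ``(irbd_confirmed, rbd_evidence_any)`` boolean series.

    Confirmed iRBD requires polysomnography. *Any* evidence additionally
    counts an RBDSQ at or above the screening cutoff, a self-reported RBD
    diagnosis without PSG confirmation, or self-reported dream enactment.
    """
    thresholds = thresholds or StagingThresholds()
    psg = records["psg_confirmed_rbd"].fillna(False).astype(bool)
    rbdsq_high = (
        records["rbdsq_total"].astype("Float64") >= thresholds.rbdsq_cutoff
    ).fillna(False).astype(bool)
    any_ev = (
        psg
        | rbdsq_high
        | records["self_reported_rbd_dx"].fillna(False).astype(bool)
        | records["dream_enactment"].fillna(False).astype(bool)
    )
    return psg, any_ev


def meets_stage2_tracks(records: pd.DataFrame, hyposmia: pd.Series,
                        irbd_confirmed: pd.Series,
                        thresholds: StagingThresholds | None = None):
    """Evaluate the three stage-2 track criteria.

    cognitive: item 1.1 equals the stage-2 value and MoCA above the
    stage-2 floor (missing item/MoCA → indeterminate, returned as NA);
    motor: subthreshold parkinsonism or PD medication; non-motor:
    hyposmia or confirmed iRBD.
    """
    thresholds = thresholds or StagingThresholds()
    updrs = records["updrs_1_1"].astype("Int64")
    moca = records["moca_baseline"].astype("Int64")
    cognitive = (
        (updrs == thresholds.stage2_cognitive_updrs_value)
        & (moca >= thresholds.stage2_cognitive_moca_min)
    ).astype("boolean")
    cognitive[updrs.isna() | moca.isna()] = pd.NA
    motor = (
        records["subthreshold_parkinsonism"].fillna(False).astype(bool)
        | records["pd_med_use"].fillna(False).astype(bool)
    )
    nonmotor = (
        hyposmia.astype("boolean").fillna(False).astype(bool)
        | irbd_confirmed.astype(bool)
    )
    return cognitive, motor, nonmotor


def assign_stage(records: pd.DataFrame,
                 thresholds: StagingThresholds | None = None) -> pd.DataFrame:
    """Compute per-participant NSD-ISS stage assignments.

    Returns a frame (aligned to ``records``) with the biological anchors,
    track flags and the stage label: ``non_nsd`` for SAA-negative rows,
    ``stage3plus_excluded`` when any-track functional impairment or the
    stage-3 cognitive rule (item 1.1 = 2 with MoCA ≥ 25) applies,
    ``stage1`` when no track criterion is met, else ``stage2A``/``2B`` by
    DaT deficit. SAA-positive rows with a missing DaTscan are flagged
    ``dat_unevaluable`` with a missing stage.
    """
    thresholds = thresholds or StagingThresholds()
    if records["saa_positive"].isna().any():
        bad = records.loc[records["saa_positive"].isna(), "participant_id"]
        raise StagingError(f"missing SAA status for: {list(bad)[:5]}")
    nsd = records["saa_positive"].astype(bool)
    hyposmia = classify_hyposmia(records["upsit_percentile"], thresholds)
    dat_deficit = classify_dat_deficit(
        records["lowest_putamen_sbr"], records["expected_sbr"], thresholds
    )
    irbd, rbd_any = classify_rbd_evidence(records, thresholds)
    cognitive, motor, nonmotor = meets_stage2_tracks(
        records, hyposmia, irbd, thresholds
    )

    updrs = records["updrs_1_1"].astype("Int64")
    moca = records["moca_baseline"].astype("Int64")
    stage3 = (
        records["functional_impairment_any_track"].fillna(False).astype(bool)
        | (
            (updrs == thresholds.stage3_cognitive_updrs_value)
            & (moca >= thresholds.stage3_cognitive_moca_min)
        ).fillna(False).astype(bool)
    )
    any_track = cognitive.fillna(False).astype(bool) | motor | nonmotor
    dat_unevaluable = nsd & dat_deficit.isna()

    stage = pd.Series(pd.NA, index=records.index, dtype="string")
    stage[~nsd] = "non_nsd"
    ok = nsd & ~dat_unevaluable
    stage[ok & stage3] = "stage3plus_excluded"
    stage[ok & ~stage3 & ~any_track] = "stage1"
    is2 = ok & ~stage3 & any_track
    stage[is2 & dat_deficit.fillna(False).astype(bool)] = "stage2B"
    stage[is2 & ~dat_deficit.fillna(True).astype(bool)] = "stage2A"

    return pd.DataFrame(
        {
            "nsd": nsd,
            "dat_deficit": dat_deficit,
            "dat_unevaluable": dat_unevaluable,
            "stage": stage,
            "meets_stage2_cognitive": cognitive,
            "meets_stage2_motor": motor,
            "meets_stage2_nonmotor": nonmotor,
            "hyposmia": hyposmia,
            "irbd_confirmed": irbd,
            "rbd_evidence_any": rbd_any,
        },
        index=records.index,
    )


def select_robust_hc(records: pd.DataFrame,
                     thresholds: StagingThresholds | None = None) -> pd.Series:
    """Mask of participants eligible for the robust norming reference.

    Requires SAA-negative status, no hyposmia (missing UPSIT excludes),
    baseline MoCA at or above the robust floor, a present year-1 MoCA at
    or above its floor, and at most the allowed baseline→year-1 drop.
    """
    thresholds = thresholds or StagingThresholds()
    hyposmia = classify_hyposmia(records["upsit_percentile"], thresholds)
    saa_neg = ~records["saa_positive"].fillna(True).astype(bool)
    non_hyposmic = (~hyposmia).fillna(False).astype(bool)
    moca0 = records["moca_baseline"].astype("Int64")
    moca1 = records["moca_year1"].astype("Int64")
    ok0 = (moca0 >= thresholds.robust_hc_moca_baseline_min).fillna(False)
    ok1 = (moca1 >= thresholds.robust_hc_moca_year1_min).fillna(False)
    drop_ok = ((moca0 - moca1) <= thresholds.robust_hc_max_moca_drop).fillna(False)
    return (saa_neg & non_hyposmic & ok0 & ok1 & drop_ok).astype(bool)


def _battery_complete(records: pd.DataFrame) -> pd.Series:
    return records[list(COGNITIVE_TESTS)].notna().all(axis=1)


def filter_analysis_cohort(records: pd.DataFrame, assignments: pd.DataFrame,
                           thresholds: StagingThresholds | None = None):
    """Apply the analysis inclusion filters to stage-2 participants.

    Keeps stage-2A/2B participants who are hyposmic, untreated, with a
    complete six-score battery, and assigns the subgroup: ``hyposmia_irbd``
    for PSG-confirmed iRBD, ``hyposmia_only`` for those with no RBD
    evidence at all; participants with unconfirmed RBD evidence are
    excluded from both subgroups. Returns ``(analysis_frame,
    exclusion_log)`` where the log has one reason per dropped stage-2
    participant.
    """
    thresholds = thresholds or StagingThresholds()
    stage2 = assignments["stage"].isin(["stage2A", "stage2B"]).fillna(False)
    reason = pd.Series(pd.NA, index=records.index, dtype="string")

    hyp = assignments["hyposmia"]
    not_hyp = ~hyp.fillna(False).astype(bool)  # normosmic or missing UPSIT
    meds = records["pd_med_use"].fillna(False).astype(bool)
    incomplete = ~_battery_complete(records)
    irbd = assignments["irbd_confirmed"].astype(bool)
    rbd_any = assignments["rbd_evidence_any"].astype(bool)
    impure = ~irbd & rbd_any

    reason[stage2 & not_hyp] = "not_hyposmic"
    reason[stage2 & ~not_hyp & meds] = "pd_meds"
    reason[stage2 & ~not_hyp & ~meds & incomplete] = "incomplete_battery"
    reason[stage2 & ~not_hyp & ~meds & ~incomplete & impure] = "rbd_unconfirmed"

    keep = stage2 & reason.isna()
    subgroup = pd.Series("not_applicable", index=records.index, dtype="string")
    subgroup[stage2] = "excluded"
    subgroup[keep & irbd] = "hyposmia_irbd"
    subgroup[keep & ~rbd_any] = "hyposmia_only"

    analysis = records.loc[keep].copy()
    analysis["stage"] = assignments.loc[keep, "stage"]
    analysis["subgroup"] = subgroup[keep]
    log = pd.DataFrame(
        {
            "participant_id": records.loc[stage2 & ~keep, "participant_id"],
            "reason": reason[stage2 & ~keep],
        }
    ).reset_index(drop=True)
    return analysis, log


def stage_cohort(records: pd.DataFrame,
                 thresholds: StagingThresholds | None = None) -> pd.DataFrame:
    """Stage a cohort and partition it into the three analysis roles.

    Returns a copy of ``records`` with the assignment columns plus
    ``cohort_role`` (``analysis`` / ``robust_hc`` / ``excluded``),
    ``subgroup`` and ``exclusion_reason``. Every participant receives
    exactly one role; excluded participants carry the first failing
    reason in the fixed evaluation order.
    """
    thresholds = thresholds or StagingThresholds()
    assignments = assign_stage(records, thresholds)
    out = records.copy()
    for col in assignments.columns:
        out[col] = assignments[col]

    reason = pd.Series(pd.NA, index=out.index, dtype="string")
    role = pd.Series("excluded", index=out.index, dtype="string")
    subgroup = pd.Series("not_applicable", index=out.index, dtype="string")

    nsd = assignments["nsd"]
    # SAA-positive path
    reason[nsd & assignments["dat_unevaluable"]] = "dat_missing"
    reason[(assignments["stage"] == "stage3plus_excluded").fillna(False)] = "stage3"
    reason[(assignments["stage"] == "stage1").fillna(False)] = "not_stage2"
    analysis, log = filter_analysis_cohort(records, assignments, thresholds)
    # map analysis-filter reasons back by participant_id
    rmap = dict(zip(log["participant_id"], log["reason"]))
    mask = records["participant_id"].isin(rmap)
    reason[mask] = records.loc[mask, "participant_id"].map(rmap)
    keep_ids = set(analysis["participant_id"])
    in_analysis = records["participant_id"].isin(keep_ids)
    stage2 = assignments["stage"].isin(["stage2A", "stage2B"]).fillna(False)
    subgroup[stage2 & ~in_analysis] = "excluded"
    role[in_analysis] = "analysis"
    subgroup[in_analysis] = analysis.set_index("participant_id").loc[
        records.loc[in_analysis, "participant_id"], "subgroup"
    ].values

    # SAA-negative path: robust healthy-control selection
    hyp = assignments["hyposmia"]
    saa_neg = ~nsd
    moca0 = out["moca_baseline"].astype("Int64")
    moca1 = out["moca_year1"].astype("Int64")
    robust = select_robust_hc(records, thresholds)
    role[robust] = "robust_hc"
    hc_fail = saa_neg & ~robust
    reason[hc_fail & ~(~hyp).fillna(False).astype(bool)] = (
        "hc_hyposmic_or_missing_upsit"
    )
    cond = hc_fail & reason.isna()
    reason[cond & ~(moca0 >= thresholds.robust_hc_moca_baseline_min).fillna(False)] = (
        "hc_moca_baseline"
    )
    cond = hc_fail & reason.isna()
    reason[cond & moca1.isna()] = "hc_moca_year1_missing"
    cond = hc_fail & reason.isna()
    reason[cond & (moca1 < thresholds.robust_hc_moca_year1_min).fillna(False)] = (
        "hc_moca_year1"
    )
    cond = hc_fail & reason.isna()
    reason[cond] = "hc_moca_drop"

    reason[role != "excluded"] = pd.NA
    out["cohort_role"] = role
    out["subgroup"] = subgroup
    out["exclusion_reason"] = reason
    return out
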