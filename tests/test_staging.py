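"""Staging rules: boundary behaviour, filters, partition, oracle equivalence."""

import pandas as pd
import pytest

from nsdcog import (StagingThresholds, assign_stage, classify_dat_deficit,
                    classify_hyposmia, classify_rbd_evidence,
                    filter_analysis_cohort, meets_stage2_tracks,
                    select_robust_hc, stage_cohort)
from nsdcog.staging import StagingError

from helpers import make_record, oracle_stage, random_records, records_frame

THR = StagingThresholds()


@pytest.mark.parametrize("percentile,expected", [
    (15.0, True),    # cutoff is inclusive
    (15.1, False),
    (0.0, True),
    (100.0, False),
    (None, None),    # missing → indeterminate
])
def test_hyposmia_boundaries(percentile, expected):
    assert classify_hyposmia(percentile, THR) is expected


def test_hyposmia_rejects_out_of_range():
    with pytest.raises(StagingError):
        classify_hyposmia(-0.1, THR)
    with pytest.raises(StagingError):
        classify_hyposmia(101.0, THR)


@pytest.mark.parametrize("sbr,expected_sbr,deficit", [
    (0.70, 1.00, True),
    (0.80, 1.00, False),
    (0.75, 1.00, False),  # strictly below 75%, boundary excluded
])
def test_dat_deficit_boundaries(sbr, expected_sbr, deficit):
    assert classify_dat_deficit(sbr, expected_sbr, THR) is deficit


def test_dat_deficit_requires_positive_inputs():
    with pytest.raises(StagingError):
        classify_dat_deficit(0.0, 1.0, THR)
    with pytest.raises(StagingError):
        classify_dat_deficit(1.0, -2.0, THR)


@pytest.mark.parametrize("psg,rbdsq,self_rep,dream,confirmed,any_ev", [
    (True, 8, False, False, True, True),
    (False, 6, False, False, False, True),   # RBDSQ at cutoff counts
    (False, 3, False, False, False, False),
    (False, 0, True, False, False, True),
    (False, 0, False, True, False, True),
])
def test_rbd_evidence(psg, rbdsq, self_rep, dream, confirmed, any_ev):
    df = records_frame([make_record(
        psg_confirmed_rbd=psg, rbdsq_total=rbdsq,
        self_reported_rbd_dx=self_rep, dream_enactment=dream,
    )])
    irbd, rbd_any = classify_rbd_evidence(df, THR)
    assert bool(irbd.iloc[0]) is confirmed
    assert bool(rbd_any.iloc[0]) is any_ev


@pytest.mark.parametrize("updrs,moca,cognitive", [
    (1, 26, True),
    (1, 25, False),   # MoCA must exceed 25
    (0, 30, False),
    (2, 30, False),   # item value must equal 1
])
def test_stage2_cognitive_track(updrs, moca, cognitive):
    df = records_frame([make_record(updrs_1_1=updrs, moca_baseline=moca)])
    hyp = classify_hyposmia(df["upsit_percentile"], THR)
    irbd, _ = classify_rbd_evidence(df, THR)
    cog, motor, nonmotor = meets_stage2_tracks(df, hyp, irbd, THR)
    assert bool(cog.iloc[0]) is cognitive


def test_stage2_motor_and_nonmotor_tracks():
    df = records_frame([
        make_record(subthreshold_parkinsonism=True),
        make_record(pd_med_use=True),
        make_record(upsit_percentile=10.0),
        make_record(psg_confirmed_rbd=True),
        make_record(),
    ])
    hyp = classify_hyposmia(df["upsit_percentile"], THR)
    irbd, _ = classify_rbd_evidence(df, THR)
    cog, motor, nonmotor = meets_stage2_tracks(df, hyp, irbd, THR)
    assert list(motor) == [True, True, False, False, False]
    assert list(nonmotor) == [False, False, True, True, False]


def test_cognitive_track_indeterminate_when_items_missing():
    df = records_frame([make_record(updrs_1_1=None),
                        make_record(moca_baseline=None)])
    hyp = classify_hyposmia(df["upsit_percentile"], THR)
    irbd, _ = classify_rbd_evidence(df, THR)
    cog, *_ = meets_stage2_tracks(df, hyp, irbd, THR)
    assert cog.isna().all()


@pytest.mark.parametrize("overrides,stage", [
    (dict(saa_positive=True, lowest_putamen_sbr=1.70, expected_sbr=2.0,
          upsit_percentile=10.0), "stage2A"),           # 85% of expected
    (dict(saa_positive=True, lowest_putamen_sbr=1.20, expected_sbr=2.0,
          upsit_percentile=10.0), "stage2B"),           # 60% of expected
    (dict(saa_positive=False), "non_nsd"),
    (dict(saa_positive=True, upsit_percentile=50.0), "stage1"),
    (dict(saa_positive=True, upsit_percentile=10.0,
          functional_impairment_any_track=True), "stage3plus_excluded"),
    (dict(saa_positive=True, upsit_percentile=10.0, updrs_1_1=2,
          moca_baseline=26), "stage3plus_excluded"),    # item 1.1=2, MoCA ≥25
])
def test_assign_stage(overrides, stage):
    df = records_frame([make_record(**overrides)])
    out = assign_stage(df, THR)
    assert out.loc[0, "stage"] == stage


def test_missing_datscan_flags_unevaluable():
    df = records_frame([make_record(saa_positive=True, lowest_putamen_sbr=None,
                                    upsit_percentile=5.0)])
    out = assign_stage(df, THR)
    assert bool(out.loc[0, "dat_unevaluable"])
    assert pd.isna(out.loc[0, "stage"])


def test_missing_saa_is_a_staging_error():
    df = records_frame([make_record(saa_positive=None)])
    with pytest.raises(StagingError, match="SAA"):
        assign_stage(df, THR)


@pytest.mark.parametrize("overrides,included", [
    (dict(), True),                                  # MoCA 28 → 28, normosmic
    (dict(moca_baseline=27, moca_year1=24), False),  # 3-point drop
    (dict(saa_positive=True), False),
    (dict(upsit_percentile=10.0), False),
    (dict(moca_baseline=26), False),
    (dict(moca_year1=25), False),
    (dict(moca_year1=None), False),
    (dict(moca_baseline=30, moca_year1=28), True),   # drop of exactly 2
])
def test_robust_hc_selection(overrides, included):
    df = records_frame([make_record(**overrides)])
    assert bool(select_robust_hc(df, THR).iloc[0]) is included


@pytest.mark.parametrize("overrides,reason", [
    (dict(pd_med_use=True), "pd_meds"),
    (dict(rbdsq_total=7), "rbd_unconfirmed"),   # screening evidence, no PSG
    (dict(sdmt=None), "incomplete_battery"),
    (dict(dream_enactment=True), "rbd_unconfirmed"),
])
def test_analysis_exclusion_reasons(overrides, reason):
    base = dict(saa_positive=True, upsit_percentile=10.0,
                lowest_putamen_sbr=1.2, expected_sbr=2.0)
    df = records_frame([make_record(**base, **overrides)])
    analysis, log = filter_analysis_cohort(df, assign_stage(df, THR), THR)
    assert len(analysis) == 0
    assert log.loc[0, "reason"] == reason


def test_subgroup_purity():
    base = dict(saa_positive=True, upsit_percentile=10.0,
                lowest_putamen_sbr=1.2, expected_sbr=2.0)
    df = records_frame([
        make_record(**base),                                 # clean hyposmia
        make_record(**base, psg_confirmed_rbd=True, rbdsq_total=9),  # iRBD
        make_record(**base, self_reported_rbd_dx=True),      # impure
    ])
    analysis, log = filter_analysis_cohort(df, assign_stage(df, THR), THR)
    assert list(analysis["subgroup"]) == ["hyposmia_only", "hyposmia_irbd"]
    assert list(log["reason"]) == ["rbd_unconfirmed"]


def test_partition_into_exactly_one_role(ppmi_cohort):
    staged = stage_cohort(ppmi_cohort, THR)
    roles = staged["cohort_role"]
    assert set(roles.unique()) <= {"analysis", "robust_hc", "excluded"}
    assert (
        (roles == "excluded").astype(bool).tolist()
        == staged["exclusion_reason"].notna().tolist()
    )
    n = len(staged)
    assert (roles == "analysis").sum() + (roles == "robust_hc").sum() + (
        roles == "excluded"
    ).sum() == n


def test_stage_exclusivity_invariants(staged):
    is2a = staged["stage"] == "stage2A"
    is2b = staged["stage"] == "stage2B"
    assert not (is2a & is2b).any()
    assert staged.loc[is2a, "nsd"].all()
    assert not staged.loc[is2a, "dat_deficit"].astype(bool).any()
    assert staged.loc[is2b, "dat_deficit"].astype(bool).all()
    irbd_rows = staged["subgroup"] == "hyposmia_irbd"
    assert staged.loc[irbd_rows, "psg_confirmed_rbd"].all()
    only_rows = staged["subgroup"] == "hyposmia_only"
    assert not staged.loc[only_rows, "rbd_evidence_any"].any()


def test_ppmi_like_cohort_reproduces_constructed_group_sizes(staged):
    analysis = staged[staged["cohort_role"] == "analysis"]
    sizes = analysis.groupby(["stage", "subgroup"]).size()
    assert sizes[("stage2A", "hyposmia_only")] == 58
    assert sizes[("stage2A", "hyposmia_irbd")] == 43
    assert sizes[("stage2B", "hyposmia_only")] == 179
    assert sizes[("stage2B", "hyposmia_irbd")] == 48
    assert (staged["cohort_role"] == "robust_hc").sum() == 158


def test_brute_force_oracle_agreement_on_random_records():
    df = random_records(1000, seed=42)
    staged = stage_cohort(df, THR)
    for idx, row in df.iterrows():
        want = oracle_stage(row, THR)
        got_stage = staged.loc[idx, "stage"]
        assert (want["stage"] is None and pd.isna(got_stage)) or (
            got_stage == want["stage"]
        ), f"stage mismatch at {idx}"
        assert staged.loc[idx, "cohort_role"] == want["role"], f"role at {idx}"
        assert staged.loc[idx, "subgroup"] == want["subgroup"], f"subgroup at {idx}"
        got_reason = staged.loc[idx, "exclusion_reason"]
        assert (want["reason"] is None and pd.isna(got_reason)) or (
            got_reason == want["reason"]
        ), f"reason mismatch at {idx}: {got_reason} != {want['reason']}"
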