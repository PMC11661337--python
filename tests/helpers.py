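"""Shared test utilities: record builders and independent rule oracles.

The oracles here are deliberately written as per-record straight-line code,
independent of the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from nsdcog import CohortConfig, GroupSpec
from nsdcog.schema import COGNITIVE_TESTS, coerce_cohort

NA = None  # rendered as pd.NA through coerce_cohort


def make_record(**overrides) -> dict:
    """A fully populated, staging-neutral participant record."""
    rec = {
        "participant_id": "p-0001",
        "sex": "male",
        "group_label": "test",
        "age": 65.0,
        "education_years": 16.0,
        "saa_positive": False,
        "lowest_putamen_sbr": 2.0,
        "expected_sbr": 2.0,
        "upsit_percentile": 50.0,
        "rbdsq_total": 1,
        "psg_confirmed_rbd": False,
        "self_reported_rbd_dx": False,
        "dream_enactment": False,
        "pd_med_use": False,
        "clonazepam_use": False,
        "subthreshold_parkinsonism": False,
        "functional_impairment_any_track": False,
        "moca_baseline": 28,
        "moca_year1": 28,
        "updrs_1_1": 0,
        "updrs_apathy": 0,
        "gds15": 1,
        "hvlt_immediate": 28.0,
        "hvlt_delayed": 10.0,
        "jlo": 12.0,
        "sdmt": 45.0,
        "lns": 11.0,
        "fluency": 22.0,
    }
    rec.update(overrides)
    return rec


def records_frame(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records)
    for i in df.index:
        df.loc[i, "participant_id"] = f"p-{i:04d}"
    return coerce_cohort(df)


def single_group_config(n: int, shift: float = 0.0, seed: int = 0,
                        label: str = "g", **group_kw) -> CohortConfig:
    kwargs = dict(age_mean=63.0, age_sd=8.0, prop_male=0.55,
                  education_mean=16.0, education_sd=3.0)
    kwargs.update(group_kw)
    spec = GroupSpec(label=label, n=n, cognitive_shift=shift, **kwargs)
    return CohortConfig(groups=[spec], seed=seed)


# ---------------------------------------------------------------------------
# Independent staging oracle (straight-line, per record)
# ---------------------------------------------------------------------------

def _get(row, col):
    v = row[col]
    return None if pd.isna(v) else v


def oracle_stage(row, thr) -> dict:
    """Re-derive stage, role, subgroup and exclusion reason for one row."""
    saa = bool(row["saa_positive"])
    upsit = _get(row, "upsit_percentile")
    hyp = None if upsit is None else upsit <= thr.upsit_percentile_cutoff
    sbr, exp = _get(row, "lowest_putamen_sbr"), _get(row, "expected_sbr")
    dat = (
        None if sbr is None or exp is None
        else 100.0 * sbr / exp < thr.dat_percent_expected_cutoff
    )
    psg = bool(row["psg_confirmed_rbd"])
    rbdsq = _get(row, "rbdsq_total")
    rbd_any = (
        psg
        or (rbdsq is not None and rbdsq >= thr.rbdsq_cutoff)
        or bool(row["self_reported_rbd_dx"])
        or bool(row["dream_enactment"])
    )
    updrs, moca = _get(row, "updrs_1_1"), _get(row, "moca_baseline")
    cog = (
        None if updrs is None or moca is None
        else updrs == thr.stage2_cognitive_updrs_value
        and moca >= thr.stage2_cognitive_moca_min
    )
    motor = bool(row["subthreshold_parkinsonism"]) or bool(row["pd_med_use"])
    nonmotor = hyp is True or psg
    stage3 = bool(row["functional_impairment_any_track"]) or (
        updrs is not None and moca is not None
        and updrs == thr.stage3_cognitive_updrs_value
        and moca >= thr.stage3_cognitive_moca_min
    )
    complete = all(_get(row, t) is not None for t in COGNITIVE_TESTS)

    out = {"stage": None, "role": "excluded", "subgroup": "not_applicable",
           "reason": None}
    if not saa:
        out["stage"] = "non_nsd"
        moca1 = _get(row, "moca_year1")
        if hyp is not False:
            out["reason"] = "hc_hyposmic_or_missing_upsit"
        elif moca is None or moca < thr.robust_hc_moca_baseline_min:
            out["reason"] = "hc_moca_baseline"
        elif moca1 is None:
            out["reason"] = "hc_moca_year1_missing"
        elif moca1 < thr.robust_hc_moca_year1_min:
            out["reason"] = "hc_moca_year1"
        elif moca - moca1 > thr.robust_hc_max_moca_drop:
            out["reason"] = "hc_moca_drop"
        else:
            out["role"] = "robust_hc"
        return out

    if dat is None:
        out["reason"] = "dat_missing"
        return out
    if stage3:
        out.update(stage="stage3plus_excluded", reason="stage3")
        return out
    if not (cog is True or motor or nonmotor):
        out.update(stage="stage1", reason="not_stage2")
        return out
    out["stage"] = "stage2B" if dat else "stage2A"
    out["subgroup"] = "excluded"
    if hyp is not True:
        out["reason"] = "not_hyposmic"
    elif bool(row["pd_med_use"]):
        out["reason"] = "pd_meds"
    elif not complete:
        out["reason"] = "incomplete_battery"
    elif psg:
        out.update(role="analysis", subgroup="hyposmia_irbd", reason=None)
    elif rbd_any:
        out["reason"] = "rbd_unconfirmed"
    else:
        out.update(role="analysis", subgroup="hyposmia_only", reason=None)
    return out


def random_records(n: int, seed: int) -> pd.DataFrame:
    """Random records biased toward staging boundaries and missingness."""
    rng = np.random.default_rng(seed)

    def maybe(value, p_missing=0.1):
        return NA if rng.random() < p_missing else value

    recs = []
    for _ in range(n):
        moca = int(rng.choice([20, 24, 25, 26, 27, 28, 30]))
        recs.append(make_record(
            saa_positive=bool(rng.random() < 0.6),
            upsit_percentile=maybe(float(rng.choice(
                [0.0, 5.0, 14.9, 15.0, 15.1, 40.0, 90.0]))),
            lowest_putamen_sbr=maybe(float(rng.choice([1.0, 1.4, 1.5, 1.6, 2.2])),
                                     0.05),
            expected_sbr=2.0,
            rbdsq_total=maybe(int(rng.choice([0, 3, 5, 6, 7, 12]))),
            psg_confirmed_rbd=bool(rng.random() < 0.25),
            self_reported_rbd_dx=bool(rng.random() < 0.15),
            dream_enactment=bool(rng.random() < 0.15),
            pd_med_use=bool(rng.random() < 0.15),
            subthreshold_parkinsonism=bool(rng.random() < 0.3),
            functional_impairment_any_track=bool(rng.random() < 0.1),
            moca_baseline=maybe(moca, 0.05),
            moca_year1=maybe(int(np.clip(moca - rng.integers(-1, 4), 0, 30))),
            updrs_1_1=maybe(int(rng.choice([0, 1, 1, 2])), 0.05),
            sdmt=maybe(45.0),
            fluency=maybe(22.0, 0.05),
        ))
    return records_frame(recs)
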