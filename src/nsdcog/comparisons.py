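"""Group-comparison statistics and the study-style summary tables.

Two-sample t-tests (pooled-variance by default, Welch optional), Pearson
chi-square without continuity correction for categorical characteristics,
and Cohen's d with the (n−1)-weighted pooled standard deviation:

    d = |mean_A − mean_B| / s_p,
    s_p = sqrt(((n_A−1)·sd_A² + (n_B−1)·sd_B²) / (n_A + n_B − 2)).

Effect sizes are reported as magnitudes with the direction recorded
separately. All statistics are computable either from raw samples or from
sufficient statistics (mean, SD, n), which makes published table cells
directly checkable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import ComparisonOptions


class ComparisonError(ValueError):
    """Raised for undefined comparisons (n < 2, zero pooled SD, ...)."""


@dataclass
class GroupSummary:
    """Descriptives for one group on one variable."""

    label: str
    n: int
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float


@dataclass
class GroupComparison:
    """One pairwise test between groups A and B."""

    label_a: str
    label_b: str
    kind: str  # pooled_t | welch_t | chi_square
    n_a: int
    n_b: int
    p_value: float
    statistic: float
    df: float
    mean_a: Optional[float] = None
    mean_b: Optional[float] = None
    sd_a: Optional[float] = None
    sd_b: Optional[float] = None
    #: signed A − B difference; cohens_d is its magnitude in pooled-SD units
    mean_difference: Optional[float] = None
    pooled_sd: Optional[float] = None
    cohens_d: Optional[float] = None
    direction: Optional[str] = None  # "A<B", "A>B" or "A=B"

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def pooled_sd(sd_a: float, n_a: int, sd_b: float, n_b: int) -> float:
    """(n−1)-weighted pooled standard deviation."""
    if n_a < 2 or n_b < 2:
        raise ComparisonError("pooled SD requires n >= 2 in each group")
    if sd_a < 0 or sd_b < 0:
        raise ComparisonError("standard deviations must be non-negative")
    return float(
        np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    )


def cohens_d(mean_a: float, sd_a: float, n_a: int,
             mean_b: float, sd_b: float, n_b: int) -> float:
    """Cohen's d magnitude, |mean_A − mean_B| / pooled SD."""
    sp = pooled_sd(sd_a, n_a, sd_b, n_b)
    if sp == 0:
        if mean_a == mean_b:
            return 0.0
        raise ComparisonError("zero pooled SD with unequal means: d undefined")
    return float(abs(mean_a - mean_b) / sp)


def _direction(mean_a: float, mean_b: float) -> str:
    if mean_a < mean_b:
        return "A<B"
    if mean_a > mean_b:
        return "A>B"
    return "A=B"


def two_sample_t_from_summaries(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    kind: str = "pooled",
    label_a: str = "A", label_b: str = "B",
) -> GroupComparison:
    """Two-sample t-test from sufficient statistics (mean, SD, n)."""
    if n_a < 2 or n_b < 2:
        raise ComparisonError("t-test requires n >= 2 in each group")
    equal_var = kind == "pooled"
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    if equal_var:
        dof = float(n_a + n_b - 2)
    else:  # Welch–Satterthwaite
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        dof = float(
            (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        )
    sp = pooled_sd(sd_a, n_a, sd_b, n_b)
    d = cohens_d(mean_a, sd_a, n_a, mean_b, sd_b, n_b) if sp > 0 else 0.0
    return GroupComparison(
        label_a=label_a, label_b=label_b,
        kind="pooled_t" if equal_var else "welch_t",
        n_a=n_a, n_b=n_b,
        p_value=float(res.pvalue), statistic=float(res.statistic), df=dof,
        mean_a=float(mean_a), mean_b=float(mean_b),
        sd_a=float(sd_a), sd_b=float(sd_b),
        mean_difference=float(mean_a - mean_b), pooled_sd=sp, cohens_d=d,
        direction=_direction(mean_a, mean_b),
    )


def two_sample_t(values_a, values_b, kind: str = "pooled",
                 label_a: str = "A", label_b: str = "B") -> GroupComparison:
    """Two-sample t-test on raw samples (missing values dropped)."""
    a = pd.Series(values_a).dropna().astype(float).to_numpy()
    b = pd.Series(values_b).dropna().astype(float).to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ComparisonError("t-test requires n >= 2 non-missing per group")
    return two_sample_t_from_summaries(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        kind=kind, label_a=label_a, label_b=label_b,
    )


def chi_square_2xk(table, label_a: str = "A", label_b: str = "B") -> GroupComparison:
    """Pearson chi-square on a 2×k contingency table, no continuity correction."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ComparisonError("need a 2-D table with at least 2 columns")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ComparisonError("counts must be non-negative integers")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ComparisonError("table has an all-zero row or column")
    res = stats.chi2_contingency(counts, correction=False)
    return GroupComparison(
        label_a=label_a, label_b=label_b, kind="chi_square",
        n_a=int(counts[0].sum()), n_b=int(counts[1:].sum()),
        p_value=float(res.pvalue), statistic=float(res.statistic),
        df=float(res.dof),
    )


def summarize_group(values, label: str) -> GroupSummary:
    """Mean/SD and median/IQR descriptives for one group."""
    v = pd.Series(values).dropna().astype(float)
    if len(v) < 1:
        raise ComparisonError(f"group {label!r} has no non-missing values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return GroupSummary(
        label=label, n=len(v), mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        median=float(med), iqr_low=float(q1), iqr_high=float(q3),
    )


# ---------------------------------------------------------------------------
# Study-style report tables
# ---------------------------------------------------------------------------

def _pairs(labels):
    return [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]


def _continuous_row(variable, groups: dict[str, pd.Series], kind: str):
    row: dict[str, object] = {"variable": variable, "type": "continuous"}
    for label, vals in groups.items():
        s = summarize_group(vals, label)
        row[f"{label}_n"] = s.n
        row[f"{label}_mean"] = round(s.mean, 3)
        row[f"{label}_sd"] = round(s.sd, 3)
        row[f"{label}_median"] = round(s.median, 3)
        row[f"{label}_iqr"] = f"({s.iqr_low:.2f}, {s.iqr_high:.2f})"
    for a, b in _pairs(list(groups)):
        try:
            cmp_ = two_sample_t(groups[a], groups[b], kind=kind,
                                label_a=a, label_b=b)
            row[f"p_{a}_vs_{b}"] = cmp_.p_value
            row[f"d_{a}_vs_{b}"] = cmp_.cohens_d
        except ComparisonError:
            row[f"p_{a}_vs_{b}"] = np.nan
    return row


def _categorical_row(variable, groups: dict[str, pd.Series]):
    """groups maps label -> boolean series (the characteristic)."""
    row: dict[str, object] = {"variable": variable, "type": "categorical"}
    counts: dict[str, tuple[int, int]] = {}
    for label, flags in groups.items():
        f = pd.Series(flags).dropna().astype(bool)
        counts[label] = (int(f.sum()), int((~f).sum()))
        total = len(f)
        row[f"{label}_n"] = int(f.sum())
        row[f"{label}_pct"] = round(100.0 * f.sum() / total, 1) if total else np.nan
    for a, b in _pairs(list(groups)):
        try:
            cmp_ = chi_square_2xk([counts[a], counts[b]], label_a=a, label_b=b)
            row[f"p_{a}_vs_{b}"] = cmp_.p_value
        except ComparisonError:
            row[f"p_{a}_vs_{b}"] = np.nan
    return row


def _stage_groups(staged: pd.DataFrame) -> dict[str, pd.DataFrame]:
    groups = {
        "HC": staged[staged["cohort_role"] == "robust_hc"],
        "2A": staged[
            (staged["cohort_role"] == "analysis") & (staged["stage"] == "stage2A")
        ],
        "2B": staged[
            (staged["cohort_role"] == "analysis") & (staged["stage"] == "stage2B")
        ],
    }
    for label in list(groups):
        if len(groups[label]) == 0:
            warnings.warn(f"group {label} is empty and was omitted", stacklevel=3)
            del groups[label]
    return groups


def build_tables(scored: pd.DataFrame,
                 options: ComparisonOptions | None = None) -> dict[str, pd.DataFrame]:
    """Build the three study-style reports from a staged + scored cohort.

    ``table1``: characteristics (sex, age, education, GDS-15, apathy,
    stage-2 track criteria, non-motor subgroup) by HC / 2A / 2B with
    pairwise p-values. ``table2``: MoCA and CSS by the same groups.
    ``table3``: CSS by RBD subgroup, overall and within 2A / 2B, with the
    pairwise comparisons (including Cohen's d) in
    ``table3_comparisons``. ``figure1`` holds the group means ± SD behind
    the bar-chart view of table 3.
    """
    options = options or ComparisonOptions()
    kind = options.test
    groups = _stage_groups(scored)

    rows = [
        _categorical_row("sex_male", {g: df["sex"] == "male"
                                      for g, df in groups.items()}),
        _continuous_row("age", {g: df["age"] for g, df in groups.items()}, kind),
        _continuous_row("education_years",
                        {g: df["education_years"] for g, df in groups.items()}, kind),
        _continuous_row("gds15", {g: df["gds15"] for g, df in groups.items()}, kind),
        _categorical_row("updrs_apathy_gt1",
                         {g: df["updrs_apathy"].astype("Float64") > 1
                          for g, df in groups.items()}),
        _categorical_row("meets_stage2_cognitive",
                         {g: df["meets_stage2_cognitive"].fillna(False)
                          for g, df in groups.items()}),
        _categorical_row("meets_stage2_motor",
                         {g: df["meets_stage2_motor"] for g, df in groups.items()}),
        _categorical_row("meets_stage2_nonmotor",
                         {g: df["meets_stage2_nonmotor"] for g, df in groups.items()}),
        _categorical_row("comorbid_irbd",
                         {g: df["subgroup"] == "hyposmia_irbd"
                          for g, df in groups.items()}),
    ]
    table1 = pd.DataFrame(rows)

    rows = [
        _continuous_row("moca_baseline",
                        {g: df["moca_baseline"] for g, df in groups.items()}, kind),
        _continuous_row("css", {g: df["css"] for g, df in groups.items()}, kind),
    ]
    table2 = pd.DataFrame(rows)

    panels = {"overall": ("stage2A", "stage2B"), "stage2A": ("stage2A",),
              "stage2B": ("stage2B",)}
    hc = groups.get("HC")
    sum_rows, cmp_rows = [], []
    analysis = scored[scored["cohort_role"] == "analysis"]
    for panel, stages in panels.items():
        sub = analysis[analysis["stage"].isin(stages)]
        panel_groups: dict[str, pd.Series] = {}
        if hc is not None and len(hc):
            panel_groups["HC"] = hc["css"]
        for sg, label in (("hyposmia_only", "hyposmia_only"),
                          ("hyposmia_irbd", "hyposmia_irbd")):
            vals = sub.loc[sub["subgroup"] == sg, "css"]
            if vals.notna().sum() == 0:
                warnings.warn(
                    f"subgroup {sg} empty in panel {panel}; omitted", stacklevel=2
                )
                continue
            panel_groups[label] = vals
        for label, vals in panel_groups.items():
            s = summarize_group(vals, label)
            sum_rows.append({"panel": panel, "group": label, "n": s.n,
                             "mean": s.mean, "sd": s.sd, "median": s.median,
                             "iqr_low": s.iqr_low, "iqr_high": s.iqr_high})
        for a, b in _pairs(list(panel_groups)):
            try:
                c = two_sample_t(panel_groups[a], panel_groups[b], kind=kind,
                                 label_a=a, label_b=b)
            except ComparisonError:
                continue
            cmp_rows.append({"panel": panel, **c.as_dict()})
    table3 = pd.DataFrame(sum_rows)
    table3_comparisons = pd.DataFrame(cmp_rows)

    figure1 = table3[table3["panel"].isin(["stage2A", "stage2B"])][
        ["panel", "group", "n", "mean", "sd"]
    ].reset_index(drop=True)

    return {
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "table3_comparisons": table3_comparisons,
        "figure1": figure1,
    }


def plot_css_by_subgroup(figure1: pd.DataFrame, path) -> None:
    """Bar chart of mean CSS ± SD by subgroup within stages 2A and 2B."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    panels = list(dict.fromkeys(figure1["panel"]))
    width = 0.35
    offsets = {"hyposmia_only": -width / 2, "hyposmia_irbd": width / 2,
               "HC": -1.5 * width}
    colors = {"HC": "#999999", "hyposmia_only": "#4878cf",
              "hyposmia_irbd": "#d65f5f"}
    for group in dict.fromkeys(figure1["group"]):
        sub = figure1[figure1["group"] == group]
        x = [panels.index(p) + offsets.get(group, 0) for p in sub["panel"]]
        ax.bar(x, sub["mean"], width=width * 0.9, yerr=sub["sd"],
               capsize=3, label=group, color=colors.get(group))
    ax.set_xticks(range(len(panels)))
    ax.set_xticklabels(panels)
    ax.set_ylabel("Cognitive summary score (z)")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
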