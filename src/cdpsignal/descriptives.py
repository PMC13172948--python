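"""Stratified descriptive summaries of report characteristics.

One column per exposure group; characteristics are age bin, sex,
resolved CDP role, serious-outcome labels and reporter-country region.
Percentages always use the group's report total as denominator, and a
report assigned to several groups contributes to each of their columns
(groups are not mutually exclusive).  Missing values form their own
category and are never merged into a substantive one.  Outcome rows are
the one documented exception to column conservation: a report can carry
several outcomes, so outcome counts may exceed the group total.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exposure import ExposureAssignment, ROLE_PRIORITY, group_role_table
from .faers_io import ReportSet

#: left-closed age bins used in cannabis epidemiology
AGE_BIN_EDGES = (0.0, 13.0, 18.0, 36.0, 55.0, 70.0, float("inf"))
AGE_BIN_LABELS = ("0-12", "13-17", "18-35", "36-54", "55-69", "70+")

OUTCOME_LABELS = {
    "HO": "hospitalization",
    "LT": "life-threatening",
    "DE": "death",
    "OT": "other",
    "DS": "disability",
    "CA": "congenital anomaly",
    "RI": "required intervention",
}

#: default Europe membership for region mapping (EU/EEA/UK/CH)
EUROPE_CODES = frozenset(
    "AT BE BG HR CY CZ DK EE FI FR DE GR HU IE IT LV LT LU MT NL PL PT RO SK SI "
    "ES SE GB UK NO IS CH LI".split()
)

REGIONS = ("Canada", "United States", "Europe", "Other", "Missing")


def assign_age_bin(age_years: float | None) -> str:
    """Bin an age in years; NaN/None -> 'missing'."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "missing"
    if age_years < 0:
        return "missing"
    for lo, hi, label in zip(AGE_BIN_EDGES[:-1], AGE_BIN_EDGES[1:], AGE_BIN_LABELS):
        if lo <= age_years < hi:
            return label
    return AGE_BIN_LABELS[-1]


def map_outcome_codes(codes: Iterable[str]) -> set[str]:
    """Map outcome codes to labels; unknown codes warn and count as 'other'."""
    out = set()
    for code in codes:
        label = OUTCOME_LABELS.get(code)
        if label is None:
            warnings.warn(f"unknown outcome code {code!r}; counted as 'other'")
            label = "other"
        out.add(label)
    return out


def map_country_region(country: str | None, europe: frozenset = EUROPE_CODES) -> str:
    """Collapse a reporter-country code to the five summary regions."""
    if country is None or (isinstance(country, float) and np.isnan(country)) or country is pd.NA:
        return "Missing"
    code = str(country).strip().upper()
    if not code:
        return "Missing"
    if code == "CA":
        return "Canada"
    if code == "US":
        return "United States"
    if code in europe:
        return "Europe"
    return "Other"


def _age_bin_series(age: pd.Series) -> pd.Series:
    binned = pd.cut(
        age, bins=list(AGE_BIN_EDGES), labels=list(AGE_BIN_LABELS),
        right=False, include_lowest=True,
    ).astype(object)
    return pd.Series(np.where(age.isna(), "missing", binned), index=age.index)


def demographic_table(
    rs: ReportSet,
    assignment: ExposureAssignment,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-form stratified summary (Table-1 style).

    Returns columns (group, characteristic, category, count, pct); within
    each (group, characteristic) except ``outcome`` the counts sum to the
    group total, and pct * group_total == 100 * count exactly before any
    rounding.  Empty groups yield all-zero columns rather than errors.
    """
    demo = rs.demo.set_index("case_id")
    roles = group_role_table(rs, assignment).set_index(["case_id", "group"])["role"]
    if groups is None:
        groups = sorted(assignment.case_groups["group"].unique())

    outc_labeled = rs.outcomes.copy()
    outc_labeled["label"] = [
        OUTCOME_LABELS.get(c, "other") for c in outc_labeled["code"]
    ]
    outc_by_case = outc_labeled.drop_duplicates(["case_id", "label"])

    rows = []
    for g in groups:
        cases = sorted(assignment.cases(g) & set(rs.case_ids))
        total = len(cases)
        sub = demo.loc[cases] if total else demo.iloc[0:0]

        def _emit(characteristic: str, counts: dict) -> None:
            for category, n in counts.items():
                pct = 100.0 * n / total if total else 0.0
                rows.append((g, characteristic, category, int(n), pct))

        age_counts = _age_bin_series(sub["age_years"]).value_counts()
        _emit("age", {lab: int(age_counts.get(lab, 0))
                      for lab in list(AGE_BIN_LABELS) + ["missing"]})
        sex_counts = sub["sex"].value_counts()
        _emit("sex", {lab: int(sex_counts.get(lab, 0))
                      for lab in ("female", "male", "missing")})
        role_counts = (
            roles.reindex([(c, g) for c in cases]).value_counts()
            if total else pd.Series(dtype=int)
        )
        _emit("role", {r: int(role_counts.get(r, 0)) for r in ROLE_PRIORITY})
        outc_counts = (
            outc_by_case[outc_by_case["case_id"].isin(cases)]["label"].value_counts()
        )
        _emit("outcome", {lab: int(outc_counts.get(lab, 0))
                          for lab in OUTCOME_LABELS.values()})
        region = sub["country"].map(map_country_region).value_counts() if total else pd.Series(dtype=int)
        _emit("region", {r: int(region.get(r, 0)) for r in REGIONS})
        rows.append((g, "total", "reports", total, 100.0 if total else 0.0))

    return pd.DataFrame(
        rows, columns=["group", "characteristic", "category", "count", "pct"]
    )


def render_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide presentation view: one column per group, 'count (pct%)' cells."""
    wide = summary.copy()
    wide["cell"] = [
        f"{n} ({p:.1f})" for n, p in zip(wide["count"], wide["pct"])
    ]
    return wide.pivot_table(
        index=["characteristic", "category"], columns="group",
        values="cell", aggfunc="first", sort=False,
    )
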