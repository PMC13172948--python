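"""Disproportionality statistics for exposure-group x event screening.

For one exposure group and one MedDRA-style preferred term (PT), reports
in the analysis window are cross-classified as

    ============== =========== ===========
                    PT present  PT absent
    exposed             a           b
    comparator          c           d
    ============== =========== ===========

with the comparator defaulting to *all other reports* (other exposure
groups included).  Three estimators are computed:

- ROR = ad / bc, Wald 95% CI on the log scale,
  ``exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``;
- PRR = [a/(a+b)] / [c/(c+d)], Wald 95% CI
  ``exp(ln PRR +/- z * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))``;
- the Bayesian information component (IC) of the BCPNN framework in its
  gamma-Poisson shrinkage form: with expected count E = (a+b)(a+c)/N and
  a ~ Poisson(mu), the prior mu ~ Gamma(1/2, rate 1/(2E)) (prior mean E)
  gives the posterior mu ~ Gamma(a + 1/2, rate 1 + 1/(2E)); then
  IC = log2((a + 1/2) / (E + 1/2)) — exactly log2 of the posterior mean
  over E — and the 95% credible bounds are log2 of posterior quantiles
  over E.

Signal rules: ROR/PRR flag when the CI lower bound exceeds 1; IC flags
when the credible lower bound (IC_025) exceeds 0.  Shrinkage makes the
IC conservative at small counts, which is why screening pipelines use it
as the primary hypothesis-free filter.

Zero cells leave ROR/PRR undefined (NaN markers, never exceptions) unless
the optional Haldane continuity correction (+0.5 to every cell) is
requested; no estimate is manufactured by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import ExposureAssignment
from .faers_io import ReportSet

__all__ = [
    "ContingencyTable", "IntervalEstimate", "SignalEstimate", "ScreenConfig",
    "build_contingency", "ror", "prr", "ic", "ic_lower_approx",
    "screen_all", "stratify_by_indication",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts for one exposure-group x PT pair."""

    a: int  # exposed with the event
    b: int  # exposed without the event
    c: int  # comparator with the event
    d: int  # comparator without the event

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        if self.n == 0:
            return float("nan")
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lo: float
    hi: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.point)


_UNDEFINED = IntervalEstimate(float("nan"), float("nan"), float("nan"))


def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    return float(stats.norm.ppf((1.0 + level) / 2.0))


def ror(t: ContingencyTable, level: float = 0.95, continuity: bool = False) -> IntervalEstimate:
    """Reporting odds ratio with a Wald interval on the log scale."""
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if continuity and min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0.0:
        return _UNDEFINED
    z = _z(level)
    point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return IntervalEstimate(
        point, float(np.exp(np.log(point) - z * se)), float(np.exp(np.log(point) + z * se))
    )


def prr(t: ContingencyTable, level: float = 0.95, continuity: bool = False) -> IntervalEstimate:
    """Proportional reporting ratio with a Wald interval on the log scale."""
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if continuity and (a == 0.0 or c == 0.0):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a == 0.0 or c == 0.0 or (a + b) == 0.0 or (c + d) == 0.0:
        return _UNDEFINED
    z = _z(level)
    point = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return IntervalEstimate(
        point, float(np.exp(np.log(point) - z * se)), float(np.exp(np.log(point) + z * se))
    )


def ic(t: ContingencyTable, level: float = 0.95) -> IntervalEstimate:
    """Information component with gamma-posterior credible bounds."""
    e = t.expected
    if not np.isfinite(e) or e <= 0.0:
        return _UNDEFINED
    a = float(t.a)
    lo_q, hi_q = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    shape = a + 0.5
    scale = 1.0 / (1.0 + 0.5 / e)
    q = stats.gamma.ppf([lo_q, hi_q], shape, scale=scale)
    point = float(np.log2((a + 0.5) / (e + 0.5)))
    return IntervalEstimate(point, float(np.log2(q[0] / e)), float(np.log2(q[1] / e)))


def ic_lower_approx(a: float, expected: float) -> float:
    """Two-term closed-form approximation to IC_025.

    ``IC - 3.3 (a + 1/2)^(-1/2) - 2.4 (a + 1/2)^(-1)``; accurate to a
    fraction of a bit for a >= 10, useful as a fast cross-check and as an
    alternative flagging rule (``ic_method='approx'``).
    """
    icp = np.log2((a + 0.5) / (expected + 0.5))
    return float(icp - 3.3 * (a + 0.5) ** -0.5 - 2.4 * (a + 0.5) ** -1.0)


# ---------------------------------------------------------------------------
# vectorised core used by screening
# ---------------------------------------------------------------------------


def _estimates_arrays(a, b, c, d, level: float, ic_method: str = "gamma") -> dict:
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    z = _z(level)
    n = a + b + c + d
    e = (a + b) * (a + c) / n

    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        ror_pt = np.where(ok, a * d / (b * c), np.nan)
        ror_se = np.where(ok, np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), np.nan)
        ror_lo = np.exp(np.log(ror_pt) - z * ror_se)
        ror_hi = np.exp(np.log(ror_pt) + z * ror_se)

        okp = (a > 0) & (c > 0)
        prr_pt = np.where(okp, (a / (a + b)) / (c / (c + d)), np.nan)
        prr_se = np.where(okp, np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)), np.nan)
        prr_lo = np.exp(np.log(prr_pt) - z * prr_se)
        prr_hi = np.exp(np.log(prr_pt) + z * prr_se)

        ic_pt = np.log2((a + 0.5) / (e + 0.5))
        shape = a + 0.5
        scale = 1.0 / (1.0 + 0.5 / e)
        lo_q, hi_q = (1.0 - level) / 2.0, (1.0 + level) / 2.0
        ic_lo = np.log2(stats.gamma.ppf(lo_q, shape, scale=scale) / e)
        ic_hi = np.log2(stats.gamma.ppf(hi_q, shape, scale=scale) / e)
        if ic_method == "approx":
            ic_lo = ic_pt - 3.3 * (a + 0.5) ** -0.5 - 2.4 * (a + 0.5) ** -1.0
        elif ic_method != "gamma":
            raise ValueError(f"unknown ic_method {ic_method!r}")

    return {
        "expected": e,
        "ror": ror_pt, "ror_lo": ror_lo, "ror_hi": ror_hi,
        "prr": prr_pt, "prr_lo": prr_lo, "prr_hi": prr_hi,
        "ic": ic_pt, "ic_lo": ic_lo, "ic_hi": ic_hi,
        "flag_ror": np.nan_to_num(ror_lo, nan=-np.inf) > 1.0,
        "flag_prr": np.nan_to_num(prr_lo, nan=-np.inf) > 1.0,
        "flag_ic": np.nan_to_num(ic_lo, nan=-np.inf) > 0.0,
    }


@dataclass(frozen=True)
class SignalEstimate:
    """All three estimators and flags for one group x PT pair."""

    group: str
    pt: str
    soc: str
    a: int
    expected: float
    ror: IntervalEstimate
    prr: IntervalEstimate
    ic: IntervalEstimate

    @property
    def flag_ror(self) -> bool:
        return bool(self.ror.lo > 1.0) if self.ror.defined else False

    @property
    def flag_prr(self) -> bool:
        return bool(self.prr.lo > 1.0) if self.prr.defined else False

    @property
    def flag_ic(self) -> bool:
        return bool(self.ic.lo > 0.0) if self.ic.defined else False


@dataclass(frozen=True)
class ScreenConfig:
    """Options for hypothesis-free screening."""

    min_count: int = 1            # smallest a to report (no a-priori AE list)
    comparator: str = "all-others"  # or "exclude-all-cdp"
    level: float = 0.95
    ic_method: str = "gamma"      # or "approx" (closed-form lower bound)
    continuity: bool = False      # Haldane +0.5 for ROR/PRR zero cells

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.comparator not in ("all-others", "exclude-all-cdp"):
            raise ValueError(f"unknown comparator policy {self.comparator!r}")


def _exposure_split(
    rs: ReportSet, assignment: ExposureAssignment, group: str, comparator: str
) -> tuple[set, set]:
    exposed = assignment.cases(group) & set(rs.case_ids)
    if not exposed:
        raise ValueError(f"empty exposure margin: no reports assigned to {group!r}")
    all_cases = set(rs.case_ids)
    if comparator == "exclude-all-cdp":
        comp = all_cases - assignment.any_cdp_cases()
    else:
        comp = all_cases - exposed
    return exposed, comp


def build_contingency(
    rs: ReportSet,
    assignment: ExposureAssignment,
    group: str,
    pt: str,
    comparator: str = "all-others",
) -> ContingencyTable:
    """2x2 table for one pair; the unit of counting is the deduplicated report."""
    exposed, comp = _exposure_split(rs, assignment, group, comparator)
    with_pt = set(rs.reactions.loc[rs.reactions["pt"] == pt, "case_id"])
    a = len(exposed & with_pt)
    c = len(comp & with_pt)
    return ContingencyTable(a, len(exposed) - a, c, len(comp) - c)


def screen_all(
    rs: ReportSet,
    assignment: ExposureAssignment,
    group: str,
    pt_soc: Mapping[str, str] | None = None,
    config: ScreenConfig = ScreenConfig(),
    pt_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row of estimates per PT observed >= min_count times in the group.

    Returns a DataFrame (group, pt, pt_name, soc, a, expected, ror/prr/ic
    points and bounds, flags); ``attrs['n_tests']`` records how many pairs
    were estimated, for any downstream multiplicity accounting.
    """
    exposed, comp = _exposure_split(rs, assignment, group, config.comparator)
    reac = rs.reactions.drop_duplicates(["case_id", "pt"])
    in_exp = reac["case_id"].isin(exposed)
    in_comp = reac["case_id"].isin(comp)
    a_counts = reac.loc[in_exp, "pt"].value_counts()
    c_counts = reac.loc[in_comp, "pt"].value_counts()
    a_counts = a_counts[a_counts >= config.min_count]
    if a_counts.empty:
        warnings.warn(f"group {group!r}: no PT reaches min_count={config.min_count}")
    pts = a_counts.index.to_numpy()
    a = a_counts.to_numpy(dtype=float)
    c = c_counts.reindex(pts).fillna(0).to_numpy(dtype=float)
    b = float(len(exposed)) - a
    d = float(len(comp)) - c
    if config.continuity:
        zero = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
        a = a + 0.5 * zero
        b = b + 0.5 * zero
        c = c + 0.5 * zero
        d = d + 0.5 * zero
    est = _estimates_arrays(a, b, c, d, config.level, config.ic_method)
    soc_lookup = pt_soc or {}
    unmapped = [p for p in pts if p not in soc_lookup]
    if pt_soc is not None and unmapped:
        warnings.warn(f"{len(unmapped)} PTs missing from the SOC lookup; set to 'unmapped'")
    name_lookup = pt_names or {}
    out = pd.DataFrame(
        {
            "group": group,
            "pt": pts,
            "pt_name": [name_lookup.get(p, p) for p in pts],
            "soc": [soc_lookup.get(p, "unmapped") for p in pts],
            "a": a_counts.to_numpy(),
            "expected": est["expected"],
            "ror": est["ror"], "ror_lo": est["ror_lo"], "ror_hi": est["ror_hi"],
            "prr": est["prr"], "prr_lo": est["prr_lo"], "prr_hi": est["prr_hi"],
            "ic": est["ic"], "ic_lo": est["ic_lo"], "ic_hi": est["ic_hi"],
            "flag_ror": est["flag_ror"],
            "flag_prr": est["flag_prr"],
            "flag_ic": est["flag_ic"],
        }
    ).sort_values("pt", kind="mergesort").reset_index(drop=True)
    out.attrs["n_tests"] = int(len(out))
    out.attrs["n_exposed"] = int(len(exposed))
    out.attrs["n_comparator"] = int(len(comp))
    return out


def stratify_by_indication(
    rs: ReportSet,
    assignment: ExposureAssignment,
    group: str,
    indication_pts: Iterable[str],
) -> tuple[ReportSet | None, ReportSet | None]:
    """Split reports by presence of an indication PT, for subgroup screening.

    Reports of *group* are split on whether a mention of the group's terms
    carries one of ``indication_pts``; comparator reports are split on
    whether any of their mentions does.  Either stratum may be ``None``
    (with a warning) when empty.
    """
    ind = set(indication_pts)
    exposed = assignment.cases(group) & set(rs.case_ids)
    if not exposed:
        raise ValueError(f"empty exposure margin: no reports assigned to {group!r}")

    drugs = rs.drugs[["case_id", "drug_seq", "verbatim_name"]].copy()
    from .exposure import normalize_term  # local import to avoid cycle at module load

    drugs["group"] = drugs["verbatim_name"].map(
        lambda t: assignment.term_to_group.get(normalize_term(t)) if pd.notna(t) else None
    )
    indi = rs.indications[rs.indications["pt"].isin(ind)]
    flagged_mentions = indi.merge(drugs, on=["case_id", "drug_seq"], how="left")
    # exposed reports: indication must sit on a mention of the group's terms
    exp_with = set(
        flagged_mentions.loc[flagged_mentions["group"] == group, "case_id"]
    ) & exposed
    # comparator reports: any mention with the indication counts
    any_with = set(indi["case_id"])
    with_cases = exp_with | (any_with - exposed)
    without_cases = set(rs.case_ids) - with_cases

    out = []
    for label, cases in (("with", with_cases), ("without", without_cases)):
        if not (cases & exposed):
            warnings.warn(f"indication stratum {label!r} has no {group} reports; skipped")
            out.append(None)
        else:
            out.append(rs.subset(cases))
    return out[0], out[1]
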