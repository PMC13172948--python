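"""Cannabis-derived-product (CDP) exposure discovery and group assignment.

FAERS-style databases record drug names verbatim, so CDP exposure cannot
be read off a coded field.  The workflow here mirrors standard practice:

1. surface candidate terms with a fixed list of case-insensitive
   substring queries (:data:`QUERY_STRINGS`),
2. classify each distinct normalized term with a curated mapping table
   into one of seven exposure groups — or exclude it, and
3. assign every report the set of groups of its mapped drug mentions
   (reports are not mutually exclusive across groups).

Substring search is deliberately high-sensitivity; specificity is the
mapping table's job.  Newly discovered terms missing from the mapping are
routed to a review queue, never silently dropped.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .faers_io import ReportSet

#: the fourteen case-insensitive substring queries used to surface
#: candidate cannabinoid terms from verbatim drug names
QUERY_STRINGS: tuple[str, ...] = (
    "cannab", "canab", "mariju", "marih", "thc", "cbd", "nabixi",
    "dronab", "nabilo", "cesam", "syndros", "marino", "epidiol", "sative",
)

#: the seven exposure groups: three pharmaceutical, four non-pharmaceutical
PHARMACEUTICAL_GROUPS: tuple[str, ...] = ("Epidiolex", "Rx THC", "Sativex")
NON_PHARMACEUTICAL_GROUPS: tuple[str, ...] = ("THC", "THC/CBD", "CBD", "Cannabis")
GROUPS: tuple[str, ...] = PHARMACEUTICAL_GROUPS + NON_PHARMACEUTICAL_GROUPS
EXCLUDED = "EXCLUDED"

#: role priority when a report mentions a group's terms more than once
ROLE_PRIORITY: tuple[str, ...] = ("PS", "SS", "I", "C")

_WS_RUN = re.compile(r"\s+")
_EDGE_PUNCT = " \t.,;:!?'\"`~^*-_()[]{}"


def normalize_term(term: str) -> str:
    """Uppercase, collapse whitespace runs, strip edge punctuation.

    Idempotent; no stemming — matching operates on raw reported names.
    """
    s = _WS_RUN.sub(" ", str(term)).strip()
    s = s.strip(_EDGE_PUNCT)
    return s.upper()


def matching_queries(term: str, queries: Sequence[str] = QUERY_STRINGS) -> list[str]:
    """Queries that match *term* as case-insensitive substrings."""
    low = str(term).lower()
    return [q for q in queries if q in low]


# ---------------------------------------------------------------------------
# term inventory
# ---------------------------------------------------------------------------

@dataclass
class TermInventory:
    """Distinct candidate terms with per-term report counts."""

    table: pd.DataFrame  # columns: verbatim_term, report_count, matched_queries

    def __len__(self) -> int:
        return len(self.table)

    @property
    def terms(self) -> set[str]:
        return set(self.table["verbatim_term"])


def find_candidate_terms(
    rs: ReportSet, queries: Sequence[str] = QUERY_STRINGS
) -> TermInventory:
    """Surface every normalized drug-name string matching >=1 query.

    ``report_count`` is the number of distinct reports mentioning the term.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    for q in queries:
        if not q or q != q.lower():
            raise ValueError(f"queries must be non-empty lowercase strings, got {q!r}")
    drugs = rs.drugs[["case_id", "verbatim_name"]].dropna(subset=["verbatim_name"]).copy()
    drugs["norm"] = drugs["verbatim_name"].map(normalize_term)
    uniq = drugs[["norm"]].drop_duplicates()
    low = uniq["norm"].str.lower()
    mask = pd.Series(False, index=uniq.index)
    matched: dict[str, list[str]] = {}
    for q in queries:
        hit = low.str.contains(q, regex=False)
        mask |= hit
        for t in uniq.loc[hit, "norm"]:
            matched.setdefault(t, []).append(q)
    hits = set(uniq.loc[mask, "norm"])
    counts = (
        drugs[drugs["norm"].isin(hits)]
        .drop_duplicates(["case_id", "norm"])
        .groupby("norm")["case_id"]
        .size()
    )
    table = pd.DataFrame(
        {
            "verbatim_term": counts.index,
            "report_count": counts.values,
            "matched_queries": [";".join(matched[t]) for t in counts.index],
        }
    ).sort_values("report_count", ascending=False, kind="mergesort").reset_index(drop=True)
    return TermInventory(table)


# ---------------------------------------------------------------------------
# curated mapping
# ---------------------------------------------------------------------------

MAPPING_COLUMNS = ("verbatim_term", "group", "matched_query", "note")


def validate_mapping(mapping: pd.DataFrame) -> pd.DataFrame:
    """Validate a term->group mapping table; returns a normalized copy."""
    if mapping.empty:
        raise ValueError("mapping table is empty")
    for col in ("verbatim_term", "group"):
        if col not in mapping.columns:
            raise ValueError(f"mapping table missing required column {col!r}")
    out = mapping.copy()
    if "matched_query" not in out.columns:
        out["matched_query"] = ""
    if "note" not in out.columns:
        out["note"] = ""
    out["verbatim_term"] = out["verbatim_term"].map(normalize_term)
    out["group"] = out["group"].astype(str).str.strip()
    bad = sorted(set(out["group"]) - set(GROUPS) - {EXCLUDED})
    if bad:
        raise ValueError(
            f"unknown group labels {bad}; allowed: {list(GROUPS) + [EXCLUDED]}"
        )
    dups = out["verbatim_term"][out["verbatim_term"].duplicated()].unique()
    if len(dups):
        raise ValueError(f"duplicate terms after normalization: {sorted(dups)[:5]}")
    # fill/repair matched_query; terms outside the query closure (curated
    # synonyms the substring search can never surface on its own) are kept
    # but warned about, since they will not appear in a discovered inventory
    fixed, orphans = [], []
    for term, q in zip(out["verbatim_term"], out["matched_query"].fillna("")):
        hits = matching_queries(term)
        if not hits:
            orphans.append(term)
            fixed.append("")
        else:
            fixed.append(q if q in hits else hits[0])
    if orphans:
        warnings.warn(
            f"{len(orphans)} mapped terms match no query string and cannot be "
            f"rediscovered by the substring search (e.g. {orphans[:3]})"
        )
    out["matched_query"] = fixed
    out["note"] = out["note"].fillna("")
    return out[list(MAPPING_COLUMNS)].reset_index(drop=True)


def load_mapping_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a delimited term-mapping table (TSV or CSV)."""
    p = Path(path)
    sep = "\t" if p.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(p, sep=sep, dtype=str, keep_default_na=False)
    return validate_mapping(df)


def summarize_inventory(mapping: pd.DataFrame) -> pd.DataFrame:
    """Per-group unique-term counts with percentages over retained terms.

    Returns one row per exposure group plus ``EXCLUDED`` and ``TOTAL``
    rows; percentages use the retained (non-excluded) total as
    denominator and are NaN for the excluded and total rows.
    """
    mapping = validate_mapping(mapping)
    counts = mapping["group"].value_counts()
    n_excluded = int(counts.get(EXCLUDED, 0))
    retained = int(len(mapping) - n_excluded)
    rows = []
    for g in GROUPS:
        n = int(counts.get(g, 0))
        rows.append((g, n, 100.0 * n / retained if retained else float("nan")))
    rows.append((EXCLUDED, n_excluded, float("nan")))
    rows.append(("TOTAL", int(len(mapping)), float("nan")))
    return pd.DataFrame(rows, columns=["group", "n_terms", "pct_of_retained"])


# ---------------------------------------------------------------------------
# report-level assignment
# ---------------------------------------------------------------------------

@dataclass
class ExposureAssignment:
    """Report -> exposure-group assignment plus the review queue.

    ``case_groups`` holds one row per (case_id, group) pair; a report may
    appear under several groups.  ``review_terms`` lists candidate terms
    that matched a query but are absent from the mapping.
    """

    case_groups: pd.DataFrame  # columns: case_id, group
    review_terms: list[str]
    term_to_group: dict[str, str]

    def cases(self, group: str) -> set[str]:
        sub = self.case_groups
        return set(sub.loc[sub["group"] == group, "case_id"])

    def any_cdp_cases(self) -> set[str]:
        return set(self.case_groups["case_id"])

    def groups_of(self, case_id: str) -> set[str]:
        sub = self.case_groups
        return set(sub.loc[sub["case_id"] == case_id, "group"])


def assign_groups(
    rs: ReportSet,
    mapping: pd.DataFrame,
    queries: Sequence[str] = QUERY_STRINGS,
    strict: bool = False,
) -> ExposureAssignment:
    """Assign each report the exposure groups of its mapped mentions.

    Mentions whose normalized name is mapped to ``EXCLUDED`` contribute no
    group.  Candidate terms (query hits) absent from the mapping go to the
    review queue; with ``strict=True`` a non-empty queue raises.
    """
    mapping = validate_mapping(mapping)
    term_to_group = dict(zip(mapping["verbatim_term"], mapping["group"]))

    drugs = rs.drugs[["case_id", "verbatim_name"]].dropna(subset=["verbatim_name"]).copy()
    drugs["norm"] = drugs["verbatim_name"].map(normalize_term)
    drugs["group"] = drugs["norm"].map(term_to_group)

    mapped = drugs.dropna(subset=["group"])
    case_groups = (
        mapped[mapped["group"] != EXCLUDED][["case_id", "group"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )

    unmapped = drugs[drugs["group"].isna()]
    review = sorted(
        {t for t in unmapped["norm"].unique() if matching_queries(t, queries)}
    )
    if strict and review:
        raise ValueError(
            f"{len(review)} candidate terms are unmapped (strict mode); "
            f"first few: {review[:5]}"
        )
    return ExposureAssignment(case_groups, review, term_to_group)


def resolve_report_role(record, group: str, term_to_group: dict[str, str]) -> str | None:
    """Highest-priority role (PS > SS > I > C) among a report's mentions of *group*."""
    best = None
    for mention in record.drugs:
        if term_to_group.get(normalize_term(mention.verbatim_name)) == group:
            if best is None or ROLE_PRIORITY.index(mention.role) < ROLE_PRIORITY.index(best):
                best = mention.role
    return best


def group_role_table(rs: ReportSet, assignment: ExposureAssignment) -> pd.DataFrame:
    """Vectorised per-(case, group) resolved role (PS > SS > I > C)."""
    drugs = rs.drugs[["case_id", "verbatim_name", "role"]].dropna(subset=["verbatim_name"]).copy()
    drugs["norm"] = drugs["verbatim_name"].map(normalize_term)
    drugs["group"] = drugs["norm"].map(assignment.term_to_group)
    sub = drugs.dropna(subset=["group"])
    sub = sub[sub["group"] != EXCLUDED].copy()
    prio = {r: i for i, r in enumerate(ROLE_PRIORITY)}
    sub["prio"] = sub["role"].map(prio)
    best = sub.sort_values("prio", kind="mergesort").groupby(
        ["case_id", "group"], sort=False
    ).head(1)
    return best[["case_id", "group", "role"]].reset_index(drop=True)
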