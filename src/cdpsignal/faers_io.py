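"""Reading, linking and deduplicating FAERS-dialect quarterly bundles.

A quarterly bundle is a set of '$'-delimited ASCII tables (DEMO, DRUG,
REAC, OUTC, INDI) sharing a per-version ``primaryid`` and a per-case
``caseid``.  Cases accumulate follow-up versions across quarters; the
analysis unit is the *deduplicated* report: all fields from the most
recent version, anchored on the earliest receipt quarter.

The in-memory container, :class:`ReportSet`, is DataFrame-backed so that
screening over hundreds of thousands of reports stays vectorised;
:meth:`ReportSet.records` yields row-level :class:`ReportRecord`
dataclasses for inspection and small-scale work.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from ._quarters import quarter_index, quarter_of_date

logger = logging.getLogger(__name__)

TABLES = ("DEMO", "DRUG", "REAC", "OUTC", "INDI")
MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")

ROLE_CODES = ("PS", "SS", "I", "C")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: canonical column layout per table (the '$'-delimited dialect)
COLUMNS: Mapping[str, tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod", "sex", "occr_country"),
    "DRUG": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "caseid", "pt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
    "INDI": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
}

#: historical header spellings accepted on read (old name -> canonical)
HEADER_SYNONYMS: Mapping[str, str] = {
    "isr": "primaryid",
    "case": "caseid",
    "gndr_cod": "sex",
    "reporter_country": "occr_country",
    "drug_rec_act": "pt",
}

# age unit codes -> factor converting the stored value to years
AGE_UNIT_FACTORS: Mapping[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


# ---------------------------------------------------------------------------
# row-level record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugMention:
    """One drug row of a report: verbatim name, asserted role, indications."""

    verbatim_name: str
    role: str  # PS | SS | I | C
    indications: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.verbatim_name:
            raise ValueError("verbatim_name must be non-empty")
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown role code {self.role!r}")


@dataclass
class ReportRecord:
    """One deduplicated spontaneous report."""

    case_id: str
    version_id: str
    init_quarter: str
    age_years: float | None
    sex: str  # female | male | missing
    country: str | None
    drugs: list[DrugMention]
    reactions: frozenset
    outcomes: frozenset


class ReportSet:
    """Deduplicated reports over a period, stored as linked DataFrames.

    Frames (all keyed by ``case_id``):

    - ``demo``: one row per case — version_id, init_quarter, age_years,
      sex, country
    - ``drugs``: one row per drug mention — drug_seq, verbatim_name, role
    - ``reactions``: one row per (case, PT)
    - ``outcomes``: one row per (case, outcome code)
    - ``indications``: one row per (case, drug_seq, indication PT)
    """

    def __init__(
        self,
        demo: pd.DataFrame,
        drugs: pd.DataFrame,
        reactions: pd.DataFrame,
        outcomes: pd.DataFrame,
        indications: pd.DataFrame,
        period: tuple[str, str],
        provenance: dict | None = None,
    ) -> None:
        self.demo = demo.reset_index(drop=True)
        self.drugs = drugs.reset_index(drop=True)
        self.reactions = reactions.reset_index(drop=True)
        self.outcomes = outcomes.reset_index(drop=True)
        self.indications = indications.reset_index(drop=True)
        self.period = period
        self.provenance = provenance or {}
        if self.demo["case_id"].duplicated().any():
            raise ValueError("case_ids must be unique after deduplication")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.demo)

    @property
    def case_ids(self) -> pd.Series:
        return self.demo["case_id"]

    def subset(self, case_ids: Iterable[str]) -> "ReportSet":
        keep = set(case_ids)
        return ReportSet(
            self.demo[self.demo["case_id"].isin(keep)],
            self.drugs[self.drugs["case_id"].isin(keep)],
            self.reactions[self.reactions["case_id"].isin(keep)],
            self.outcomes[self.outcomes["case_id"].isin(keep)],
            self.indications[self.indications["case_id"].isin(keep)],
            period=self.period,
            provenance=dict(self.provenance),
        )

    def records(self) -> Iterator[ReportRecord]:
        """Yield one :class:`ReportRecord` per case (row-level view)."""
        drugs_by_case = {k: v for k, v in self.drugs.groupby("case_id")}
        reac_by_case = self.reactions.groupby("case_id")["pt"].apply(frozenset).to_dict()
        outc_by_case = self.outcomes.groupby("case_id")["code"].apply(frozenset).to_dict()
        indi_by_key: dict = {}
        for (cid, seq), grp in self.indications.groupby(["case_id", "drug_seq"]):
            indi_by_key[(cid, seq)] = frozenset(grp["pt"])
        for row in self.demo.itertuples(index=False):
            mentions = []
            dsub = drugs_by_case.get(row.case_id)
            if dsub is not None:
                for d in dsub.itertuples(index=False):
                    mentions.append(
                        DrugMention(
                            verbatim_name=d.verbatim_name,
                            role=d.role,
                            indications=indi_by_key.get((row.case_id, d.drug_seq), frozenset()),
                        )
                    )
            age = None if pd.isna(row.age_years) else float(row.age_years)
            country = None if pd.isna(row.country) else row.country
            yield ReportRecord(
                case_id=row.case_id,
                version_id=row.version_id,
                init_quarter=row.init_quarter,
                age_years=age,
                sex=row.sex,
                country=country,
                drugs=mentions,
                reactions=reac_by_case.get(row.case_id, frozenset()),
                outcomes=outc_by_case.get(row.case_id, frozenset()),
            )

    # -- comparison (used by round-trip tests and determinism checks) ------
    @staticmethod
    def _norm(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        return df.sort_values(keys, kind="mergesort").reset_index(drop=True)

    def equals(self, other: "ReportSet") -> bool:
        a = self._norm(self.demo, ["case_id"])
        b = self._norm(other.demo, ["case_id"])
        if not a.equals(b):
            return False
        for name, keys in [
            ("drugs", ["case_id", "drug_seq"]),
            ("reactions", ["case_id", "pt"]),
            ("outcomes", ["case_id", "code"]),
            ("indications", ["case_id", "drug_seq", "pt"]),
        ]:
            if not self._norm(getattr(self, name), keys).equals(
                self._norm(getattr(other, name), keys)
            ):
                return False
        return True

    # -- persistence (tab-separated store used by the CLI) ------------------
    def to_store(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("demo", "drugs", "reactions", "outcomes", "indications"):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "period.txt").write_text(f"{self.period[0]}\t{self.period[1]}\n")

    @classmethod
    def from_store(cls, store_dir: str | Path) -> "ReportSet":
        store = Path(store_dir)
        frames = {}
        for name in ("demo", "drugs", "reactions", "outcomes", "indications"):
            frames[name] = pd.read_csv(
                store / f"{name}.tsv", sep="\t", dtype=str, keep_default_na=False
            ).replace({"": pd.NA})
        demo = frames["demo"]
        demo["age_years"] = pd.to_numeric(demo["age_years"], errors="coerce")
        demo["sex"] = demo["sex"].fillna("missing")
        start, end = (store / "period.txt").read_text().split()
        return cls(
            demo, frames["drugs"], frames["reactions"], frames["outcomes"],
            frames["indications"], period=(start, end),
        )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_age(value, unit_code) -> float:
    """Convert a FAERS (value, unit) age pair to years.

    Returns NaN for missing values, unknown unit codes, or negative values
    (the latter with a warning — data rows never raise).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    s = str(value).strip()
    if not s:
        return float("nan")
    try:
        v = float(s)
    except ValueError:
        warnings.warn(f"unparseable age value {value!r}; treated as missing")
        return float("nan")
    if v < 0:
        warnings.warn(f"negative age value {value!r}; treated as missing")
        return float("nan")
    unit = str(unit_code).strip().upper() if unit_code is not None else ""
    factor = AGE_UNIT_FACTORS.get(unit)
    if factor is None:
        return float("nan")
    return v * factor


def _parse_age_series(age: pd.Series, unit: pd.Series) -> pd.Series:
    v = pd.to_numeric(age.replace({"": None}), errors="coerce")
    factors = unit.fillna("").str.strip().str.upper().map(AGE_UNIT_FACTORS)
    out = v * factors
    out[v < 0] = np.nan
    return out.astype(float)


def _read_table(path: Path, table: str, quarter: str) -> pd.DataFrame:
    expected = COLUMNS[table]
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = [HEADER_SYNONYMS.get(h.strip().lower(), h.strip().lower())
                  for h in header_line.split("$")]
        if set(expected) - set(header):
            missing = sorted(set(expected) - set(header))
            raise ValueError(
                f"{table} {quarter}: missing columns {missing} in header {header}"
            )
        ncol = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("$")
            if len(parts) != ncol:
                raise ValueError(
                    f"{table} {quarter}: malformed row at line {lineno}: "
                    f"expected {ncol} fields, got {len(parts)}"
                )
            rows.append(parts)
    df = pd.DataFrame(rows, columns=header, dtype=str)
    # explicit missing markers: empty string -> NA, verbatim text preserved
    df = df.replace({"": pd.NA})
    return df[list(expected)]


def read_quarter(bundle_dir: str | Path, quarter: str) -> dict[str, pd.DataFrame]:
    """Parse one quarter's tables from *bundle_dir*.

    DEMO, DRUG and REAC are mandatory; OUTC/INDI default to empty frames.
    Verbatim text is preserved; missing fields become ``pd.NA``, never
    empty strings or zeros.
    """
    quarter_index(quarter)  # validates label
    bundle = Path(bundle_dir)
    tables: dict[str, pd.DataFrame] = {}
    for table in TABLES:
        path = bundle / f"{table}{quarter}.txt"
        if not path.exists():
            if table in MANDATORY_TABLES:
                raise FileNotFoundError(
                    f"mandatory table {table} for quarter {quarter} not found at {path}"
                )
            tables[table] = pd.DataFrame(columns=list(COLUMNS[table]))
            continue
        tables[table] = _read_table(path, table, quarter)
    tables["quarter"] = quarter  # type: ignore[assignment]
    return tables


# ---------------------------------------------------------------------------
# linking and deduplication
# ---------------------------------------------------------------------------

def _normalize_sex(s: pd.Series) -> pd.Series:
    up = s.fillna("").str.strip().str.upper()
    return up.map({"F": "female", "M": "male"}).fillna("missing")


def link_and_deduplicate(quarters: Iterable[dict]) -> ReportSet:
    """Collapse case versions across quarters into one record per case.

    Keeps every non-date field from the most recent version (highest
    ``caseversion``; ties broken by latest receipt date, then by
    lexicographic ``primaryid``, with a warning) and anchors the record on
    the earliest receipt quarter across versions.  Records with no
    reaction PT are dropped with a logged count: a report without an event
    cannot enter any contingency table.
    """
    quarters = list(quarters)
    if not quarters:
        raise ValueError("no quarterly tables supplied")
    demo = pd.concat([q["DEMO"] for q in quarters], ignore_index=True)
    drug = pd.concat([q["DRUG"] for q in quarters], ignore_index=True)
    reac = pd.concat([q["REAC"] for q in quarters], ignore_index=True)
    outc = pd.concat([q["OUTC"] for q in quarters], ignore_index=True)
    indi = pd.concat([q["INDI"] for q in quarters], ignore_index=True)

    demo = demo.copy()
    demo["caseversion_n"] = pd.to_numeric(demo["caseversion"], errors="coerce")
    dup_versions = demo.duplicated(subset=["caseid", "caseversion"], keep=False)
    if dup_versions.any():
        warnings.warn(
            f"{int(dup_versions.sum())} DEMO rows share a (caseid, caseversion); "
            "tie broken by receipt date then primaryid"
        )
    demo = demo.sort_values(
        ["caseid", "caseversion_n", "fda_dt", "primaryid"], kind="mergesort"
    )
    latest = demo.groupby("caseid", sort=False).tail(1).copy()
    init_quarter = (
        demo.assign(q=demo["fda_dt"].map(quarter_of_date))
        .groupby("caseid", sort=False)["q"]
        .min()  # labels "YYYYQn" sort correctly as strings within plausible years
    )
    latest["init_quarter"] = latest["caseid"].map(init_quarter)

    winning = latest.set_index("primaryid")
    keep_pid = set(winning.index)

    out_demo = pd.DataFrame(
        {
            "case_id": latest["caseid"].values,
            "version_id": latest["primaryid"].values,
            "init_quarter": latest["init_quarter"].values,
            "age_years": _parse_age_series(
                latest["age"].astype("string"), latest["age_cod"].astype("string")
            ).values,
            "sex": _normalize_sex(latest["sex"].astype("string")).values,
            "country": latest["occr_country"].values,
        }
    )

    def _take(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        sub = df[df["primaryid"].isin(keep_pid)].copy()
        sub["case_id"] = sub["caseid"]
        return sub[["case_id"] + cols].reset_index(drop=True)

    out_drugs = _take(drug, ["drug_seq", "role_cod", "drugname"]).rename(
        columns={"role_cod": "role", "drugname": "verbatim_name"}
    )
    out_reac = _take(reac, ["pt"]).drop_duplicates()
    out_outc = _take(outc, ["outc_cod"]).rename(columns={"outc_cod": "code"}).drop_duplicates()
    out_indi = _take(indi, ["indi_drug_seq", "indi_pt"]).rename(
        columns={"indi_drug_seq": "drug_seq", "indi_pt": "pt"}
    ).drop_duplicates()

    with_reaction = set(out_reac["case_id"])
    no_reac = ~out_demo["case_id"].isin(with_reaction)
    if no_reac.any():
        logger.info("dropping %d reports with no reaction PT", int(no_reac.sum()))
        keep_cases = set(out_demo.loc[~no_reac, "case_id"])
        out_demo = out_demo[~no_reac]
        out_drugs = out_drugs[out_drugs["case_id"].isin(keep_cases)]
        out_outc = out_outc[out_outc["case_id"].isin(keep_cases)]
        out_indi = out_indi[out_indi["case_id"].isin(keep_cases)]

    qs = sorted(out_demo["init_quarter"].unique(), key=quarter_index)
    period = (qs[0], qs[-1]) if qs else ("0001Q1", "0001Q1")
    return ReportSet(
        out_demo, out_drugs, out_reac, out_outc, out_indi,
        period=period,
        provenance={"n_input_demo_rows": int(len(demo))},
    )


def restrict_period(rs: ReportSet, start: str, end: str) -> ReportSet:
    """Keep reports whose initial receipt quarter lies in [start, end]."""
    i, j = quarter_index(start), quarter_index(end)
    if i > j:
        raise ValueError(f"inverted period bounds: {start} > {end}")
    idx = rs.demo["init_quarter"].map(quarter_index)
    keep = rs.demo.loc[(idx >= i) & (idx <= j), "case_id"]
    out = rs.subset(keep)
    out.period = (start, end)
    return out


def read_bundles(bundle_dir: str | Path, quarters: Iterable[str]) -> ReportSet:
    """Read several quarters from one directory and deduplicate."""
    return link_and_deduplicate(read_quarter(bundle_dir, q) for q in quarters)
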