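"""Quarterly-bundle parsing, case linkage/deduplication, period logic."""

import numpy as np
import pandas as pd
import pytest

import cdpsignal as cs
from cdpsignal._quarters import quarter_index, quarter_label, quarter_of_date, quarter_range
from cdpsignal.faers_io import link_and_deduplicate, parse_age, read_quarter


class TestQuarters:
    @pytest.mark.parametrize("label,date", [("1999Q1", "19990101"), ("2023Q1", "20230101")])
    def test_label_date_round_trip(self, label, date):
        assert quarter_of_date(date) == label
        assert quarter_label(quarter_index(label)) == label

    def test_range_inclusive(self):
        assert len(quarter_range("2018Q2", "2023Q1")) == 20

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            quarter_index("2018Q5")
        with pytest.raises(ValueError):
            quarter_range("2020Q1", "2019Q4")


class TestParseAge:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (730, "DY", 730 / 365.25),
            (5, "DEC", 50.0),
            (24, "MON", 2.0),
            (1, "YR", 1.0),
            (8766, "HR", 1.0),
        ],
    )
    def test_unit_conversion(self, value, unit, expected):
        assert parse_age(value, unit) == pytest.approx(expected)

    def test_missing_and_unknown_are_nan(self):
        assert np.isnan(parse_age(None, "YR"))
        assert np.isnan(parse_age("", "YR"))
        assert np.isnan(parse_age(30, "XX"))

    def test_negative_warns_never_raises(self):
        with pytest.warns(UserWarning, match="negative"):
            assert np.isnan(parse_age(-4, "YR"))


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def tiny_bundle(tmp_path):
    _write(tmp_path / "DEMO2019Q1.txt", [
        "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$occr_country",
        "1231$123$1$20190215$$$F$US",
        "4561$456$1$20190301$34.0$YR$M$CA",
    ])
    _write(tmp_path / "DRUG2019Q1.txt", [
        "primaryid$caseid$drug_seq$role_cod$drugname",
        "1231$123$1$PS$CBD OIL",
        "4561$456$1$C$COMPOUND 001",
    ])
    _write(tmp_path / "REAC2019Q1.txt", [
        "primaryid$caseid$pt",
        "1231$123$PT_X",
        "4561$456$PT_Y",
    ])
    return tmp_path


class TestReadQuarter:
    def test_verbatim_and_missing_contract(self, tiny_bundle):
        tables = read_quarter(tiny_bundle, "2019Q1")
        demo = tables["DEMO"]
        assert len(demo) == 2
        row = demo[demo["caseid"] == "123"].iloc[0]
        assert pd.isna(row["age"])  # empty field is missing, never 0
        assert tables["DRUG"]["drugname"].tolist() == ["CBD OIL", "COMPOUND 001"]

    def test_missing_mandatory_table_names_it(self, tiny_bundle):
        (tiny_bundle / "REAC2019Q1.txt").unlink()
        with pytest.raises(FileNotFoundError, match="REAC.*2019Q1"):
            read_quarter(tiny_bundle, "2019Q1")

    def test_malformed_row_reports_line_number(self, tiny_bundle):
        with open(tiny_bundle / "DRUG2019Q1.txt", "a") as fh:
            fh.write("9$9$1$PS\n")  # 4 fields instead of 5
        with pytest.raises(ValueError, match="line 4"):
            read_quarter(tiny_bundle, "2019Q1")

    def test_historical_header_spelling_accepted(self, tiny_bundle):
        path = tiny_bundle / "DEMO2019Q1.txt"
        text = path.read_text().replace("$sex$", "$gndr_cod$")
        path.write_text(text)
        tables = read_quarter(tiny_bundle, "2019Q1")
        assert set(tables["DEMO"]["sex"]) == {"F", "M"}

    def test_optional_tables_default_empty(self, tiny_bundle):
        tables = read_quarter(tiny_bundle, "2019Q1")
        assert tables["OUTC"].empty and tables["INDI"].empty


def _quarter_tables(demo_rows, drug_rows, reac_rows):
    cols = {
        "DEMO": ["primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod", "sex", "occr_country"],
        "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
        "REAC": ["primaryid", "caseid", "pt"],
        "OUTC": ["primaryid", "caseid", "outc_cod"],
        "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
    }
    def df(rows, table):
        out = pd.DataFrame(rows, columns=cols[table], dtype=str)
        return out.replace({"": pd.NA}) if len(out) else out
    return {
        "DEMO": df(demo_rows, "DEMO"), "DRUG": df(drug_rows, "DRUG"),
        "REAC": df(reac_rows, "REAC"), "OUTC": df([], "OUTC"), "INDI": df([], "INDI"),
    }


class TestLinkAndDeduplicate:
    def test_latest_version_wins_earliest_date_anchors(self):
        q1 = _quarter_tables(
            [("1230001", "123", "1", "20190215", "", "", "F", "US")],
            [("1230001", "123", "1", "PS", "CBD OIL")],
            [("1230001", "123", "PT_X")],
        )
        q2 = _quarter_tables(
            [("1230002", "123", "2", "20200801", "34.0", "YR", "F", "US")],
            [("1230002", "123", "1", "PS", "CBD OIL")],
            [("1230002", "123", "PT_X")],
        )
        rs = link_and_deduplicate([q1, q2])
        assert len(rs) == 1
        rec = next(rs.records())
        assert rec.age_years == pytest.approx(34.0)
        assert rec.init_quarter == "2019Q1"
        assert rec.version_id == "1230002"

    def test_no_duplicates_is_identity_count(self, tiny_bundle):
        rs = link_and_deduplicate([read_quarter(tiny_bundle, "2019Q1")])
        assert len(rs) == 2

    def test_dedup_is_idempotent(self, small_sim, tmp_path):
        rs, _ = small_sim
        cs.write_quarterly_bundle(rs, tmp_path)
        quarters = sorted({p.name[4:-4] for p in tmp_path.glob("DEMO*.txt")})
        rs1 = cs.read_bundles(tmp_path, quarters)
        # write the deduplicated set back out and re-ingest
        out2 = tmp_path / "again"
        cs.write_quarterly_bundle(rs1, out2)
        rs2 = cs.read_bundles(out2, sorted({p.name[4:-4] for p in out2.glob("DEMO*.txt")}))
        assert len(rs1) == len(rs2)
        assert set(rs1.case_ids) == set(rs2.case_ids)

    def test_duplicate_version_id_warns(self):
        q = _quarter_tables(
            [
                ("1230001", "123", "1", "20190215", "", "", "F", "US"),
                ("1230009", "123", "1", "20190315", "20.0", "YR", "F", "US"),
            ],
            [("1230009", "123", "1", "PS", "CBD OIL")],
            [("1230009", "123", "PT_X"), ("1230001", "123", "PT_X")],
        )
        with pytest.warns(UserWarning, match="caseversion"):
            rs = link_and_deduplicate([q])
        assert len(rs) == 1
        assert next(rs.records()).age_years == pytest.approx(20.0)

    def test_reactionless_reports_dropped(self):
        q = _quarter_tables(
            [
                ("11", "1", "1", "20190215", "", "", "F", "US"),
                ("21", "2", "1", "20190215", "", "", "M", "US"),
            ],
            [("11", "1", "1", "PS", "X"), ("21", "2", "1", "PS", "Y")],
            [("11", "1", "PT_X")],
        )
        rs = link_and_deduplicate([q])
        assert set(rs.case_ids) == {"1"}


class TestRestrictPeriod:
    def _rs(self):
        from conftest import build_reportset

        rows = [
            ("a", "2017Q4", 30.0, "male", "US"),
            ("b", "2018Q2", 30.0, "male", "US"),
            ("c", "2023Q1", 30.0, "male", "US"),
            ("d", "2023Q2", 30.0, "male", "US"),
        ]
        return build_reportset(rows, reactions=[(x, "PT") for x in "abcd"])

    def test_inclusive_bounds(self):
        kept = cs.restrict_period(self._rs(), "2018Q2", "2023Q1")
        assert set(kept.case_ids) == {"b", "c"}

    def test_full_window_is_identity(self):
        rs = self._rs()
        assert len(cs.restrict_period(rs, "2017Q4", "2023Q2")) == len(rs)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            cs.restrict_period(self._rs(), "2023Q1", "2018Q2")

    def test_narrowing_is_monotone(self, small_sim):
        rs, _ = small_sim
        wide = cs.restrict_period(rs, "2018Q2", "2023Q1")
        narrow = cs.restrict_period(rs, "2019Q1", "2020Q4")
        assert set(narrow.case_ids) <= set(wide.case_ids)


class TestGeneratorManifestConservation:
    def test_dedup_count_matches_manifest(self, small_sim, tmp_path):
        rs, truth = small_sim
        assert truth.manifest["n_duplicated_cases"] > 0
        cs.write_quarterly_bundle(rs, tmp_path)
        quarters = sorted({p.name[4:-4] for p in tmp_path.glob("DEMO*.txt")})
        rs2 = cs.read_bundles(tmp_path, quarters)
        assert len(rs2) == truth.manifest["n_cases"]

    def test_round_trip_identity_on_all_fields(self, small_sim, tmp_path):
        rs, _ = small_sim
        cs.write_quarterly_bundle(rs, tmp_path)
        quarters = sorted({p.name[4:-4] for p in tmp_path.glob("DEMO*.txt")})
        rs2 = cs.read_bundles(tmp_path, quarters)
        assert rs.equals(rs2)

    def test_per_quarter_counts_match_manifest(self, small_sim):
        rs, truth = small_sim
        counts = rs.demo["init_quarter"].value_counts().to_dict()
        assert counts == truth.manifest["per_quarter_init_counts"]
        window = sorted(truth.manifest["per_quarter_init_counts"])[:4]
        kept = cs.restrict_period(rs, window[0], window[-1])
        assert len(kept) == sum(
            truth.manifest["per_quarter_init_counts"][q] for q in window
        )

    def test_missingness_conserved_through_ingest(self, small_sim, tmp_path):
        rs, truth = small_sim
        cs.write_quarterly_bundle(rs, tmp_path)
        quarters = sorted({p.name[4:-4] for p in tmp_path.glob("DEMO*.txt")})
        rs2 = cs.read_bundles(tmp_path, quarters)
        assert int(rs2.demo["age_years"].isna().sum()) == truth.manifest["n_missing_age_final"]
        assert int((rs2.demo["sex"] == "missing").sum()) == truth.manifest["n_missing_sex"]
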