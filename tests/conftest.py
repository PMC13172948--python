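import numpy as np
import pandas as pd
import pytest

import cdpsignal as cs
from cdpsignal.faers_io import ReportSet


@pytest.fixture(scope="session")
def small_config():
    return cs.GeneratorConfig(n_reports=4000, seed=7)


@pytest.fixture(scope="session")
def small_vocab(small_config):
    return cs.make_vocabulary(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, small_vocab):
    """4000-report simulated universe with duplicates and misspellings."""
    return cs.sample_reports(small_config, small_vocab)


@pytest.fixture(scope="session")
def small_assignment(small_sim):
    rs, truth = small_sim
    return cs.assign_groups(rs, truth.mapping_table())


def build_reportset(rows, drugs=None, reactions=None, outcomes=None, indications=None):
    """Hand-built ReportSet from terse row tuples.

    ``rows``: (case_id, init_quarter, age_years, sex, country);
    ``drugs``: (case_id, seq, role, name);
    ``reactions``: (case_id, pt); ``outcomes``: (case_id, code);
    ``indications``: (case_id, seq, pt).
    """
    demo = pd.DataFrame(
        [
            {
                "case_id": r[0],
                "version_id": r[0] + "1",
                "init_quarter": r[1],
                "age_years": np.nan if r[2] is None else float(r[2]),
                "sex": r[3],
                "country": pd.NA if r[4] is None else r[4],
            }
            for r in rows
        ]
    )
    def frame(data, cols):
        return pd.DataFrame(data or [], columns=cols)

    quarters = sorted(demo["init_quarter"])
    return ReportSet(
        demo,
        frame(drugs, ["case_id", "drug_seq", "role", "verbatim_name"]),
        frame(reactions, ["case_id", "pt"]),
        frame(outcomes, ["case_id", "code"]),
        frame(indications, ["case_id", "drug_seq", "pt"]),
        period=(quarters[0], quarters[-1]),
    )


@pytest.fixture
def tiny_reportset():
    """Five reports: two CBD-exposed (one with PT_X), three background."""
    rows = [
        ("c1", "2019Q1", 5.0, "female", "US"),
        ("c2", "2019Q2", 40.0, "male", "CA"),
        ("c3", "2019Q3", None, "missing", "DE"),
        ("c4", "2019Q4", 72.0, "female", None),
        ("c5", "2020Q1", 33.0, "male", "JP"),
    ]
    drugs = [
        ("c1", "1", "PS", "CBD OIL"),
        ("c2", "1", "C", "CANNABIDIOL"),
        ("c3", "1", "PS", "COMPOUND 001"),
        ("c4", "1", "SS", "COMPOUND 002"),
        ("c5", "1", "PS", "COMPOUND 003"),
    ]
    reactions = [
        ("c1", "PT_X"), ("c2", "PT_Y"), ("c3", "PT_X"),
        ("c4", "PT_Y"), ("c5", "PT_Z"),
    ]
    return build_reportset(rows, drugs, reactions)


@pytest.fixture
def cbd_mapping():
    return pd.DataFrame(
        {
            "verbatim_term": ["CBD OIL", "CANNABIDIOL", "EPIDIOLEX", "CANNABINOL"],
            "group": ["CBD", "CBD", "Epidiolex", "EXCLUDED"],
        }
    )
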