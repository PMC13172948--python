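"""Estimator correctness: closed forms, intervals, shrinkage, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cdpsignal as cs
from cdpsignal.disproportionality import (
    ContingencyTable,
    ScreenConfig,
    ic_lower_approx,
)

from _oracles import ic_oracle, prr_oracle, ror_oracle

T = ContingencyTable(10, 90, 100, 9900)
T_NULL = ContingencyTable(10, 90, 990, 8910)


class TestPointEstimates:
    def test_ror_worked_example(self):
        est = cs.ror(T)
        assert est.point == pytest.approx(11.0)
        assert est.lo == pytest.approx(5.559, abs=2e-3)
        assert est.hi == pytest.approx(21.765, abs=5e-3)

    def test_prr_worked_example(self):
        est = cs.prr(T)
        assert est.point == pytest.approx(10.0)
        assert est.lo == pytest.approx(5.382, abs=5e-4)
        assert est.hi == pytest.approx(18.584, abs=5e-3)

    def test_ic_worked_example(self):
        # E = 110*100/10100; IC = log2(10.5 / (E + 0.5))
        est = cs.ic(T)
        e = 110 * 100 / 10100
        assert est.point == pytest.approx(np.log2(10.5 / (e + 0.5)))
        assert est.point == pytest.approx(2.724, abs=5e-4)

    def test_independence_table_is_null(self):
        assert cs.ror(T_NULL).point == pytest.approx(1.0)
        assert cs.prr(T_NULL).point == pytest.approx(1.0)
        est = cs.ic(T_NULL)
        assert est.point == pytest.approx(0.0, abs=1e-12)
        # posterior mass below the null: clearly no signal
        assert est.lo == pytest.approx(-1.0301, abs=2e-3)
        assert est.lo < 0

    def test_ror_symmetry_under_margin_swap(self):
        swapped = ContingencyTable(T.a, T.c, T.b, T.d)
        assert cs.ror(swapped).point == pytest.approx(cs.ror(T).point)

    def test_prr_approaches_ror_for_rare_events(self):
        t = ContingencyTable(5, 9995, 50, 99950)
        assert cs.prr(t).point == pytest.approx(cs.ror(t).point, rel=0.05)

    def test_ic_zero_when_observed_equals_expected(self):
        t = ContingencyTable(20, 180, 980, 8820)  # E = 200*1000/10000 = 20
        assert cs.ic(t).point == pytest.approx(0.0, abs=1e-12)


class TestUndefinedAndCorrections:
    @pytest.mark.parametrize("t", [
        ContingencyTable(0, 100, 50, 9850),
        ContingencyTable(5, 0, 50, 9850),
        ContingencyTable(5, 100, 0, 9850),
    ])
    def test_zero_cells_yield_undefined_markers_not_exceptions(self, t):
        est = cs.ror(t)
        assert not est.defined

    def test_haldane_correction_defines_the_estimate(self):
        t = ContingencyTable(5, 100, 0, 9850)
        assert not cs.ror(t).defined
        assert cs.ror(t, continuity=True).defined
        assert cs.prr(t, continuity=True).defined

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ContingencyTable(-1, 2, 3, 4)


@st.composite
def tables(draw):
    return ContingencyTable(
        draw(st.integers(1, 10_000)), draw(st.integers(1, 10_000)),
        draw(st.integers(1, 10_000)), draw(st.integers(1, 10_000)),
    )


class TestProperties:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(tables())
    def test_matches_independent_oracle(self, t):
        abcd = (t.a, t.b, t.c, t.d)
        for impl, oracle in [(cs.ror, ror_oracle), (cs.prr, prr_oracle), (cs.ic, ic_oracle)]:
            est = impl(t)
            ref = oracle(*abcd)
            for got, want in zip((est.point, est.lo, est.hi), ref):
                assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(tables())
    def test_interval_ordering(self, t):
        for est in (cs.ror(t), cs.prr(t), cs.ic(t)):
            assert est.lo <= est.point <= est.hi

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(tables())
    def test_shrinkage_pulls_ic_toward_zero(self, t):
        e = t.expected
        if abs(t.a - e) < 1e-9:
            return
        raw = np.log2(t.a / e)
        assert abs(cs.ic(t).point) <= abs(raw) + 1e-12

    def test_ic_converges_to_raw_log_ratio_at_large_counts(self):
        a, e_ratio = 100_000, 2.0
        # margins chosen so E = a / e_ratio
        n = 4 * a
        ab = 2 * a
        ac = int(a / e_ratio * n / ab)
        t = ContingencyTable(a, ab - a, ac - a, n - ab - ac + a)
        assert cs.ic(t).point == pytest.approx(np.log2(a / t.expected), abs=2e-5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(tables(), st.integers(1, 50))
    def test_ror_prr_strictly_increasing_in_a(self, t, bump):
        t2 = ContingencyTable(t.a + bump, t.b, t.c, t.d)
        assert cs.ror(t2).point > cs.ror(t).point
        assert cs.prr(t2).point > cs.prr(t).point

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(1, 100), st.integers(1, 100), st.integers(1, 100),
        st.integers(100_000, 1_000_000), st.integers(1, 50),
    )
    def test_ic_strictly_increasing_in_a_when_comparator_dominates(self, a, b, c, d, bump):
        # IC monotonicity in a needs N >> a^2 (both margins grow with a);
        # equality occurs at degenerate tables, e.g. a=3, b=c=d=1 vs a=4
        t, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + bump, b, c, d)
        assert cs.ic(t2).point > cs.ic(t).point

    def test_ic_not_monotone_at_degenerate_tables(self):
        # exact counterexample: both evaluate to log2(21/19)
        assert cs.ic(ContingencyTable(4, 1, 1, 1)).point == pytest.approx(
            cs.ic(ContingencyTable(3, 1, 1, 1)).point
        )

    def test_gamma_lower_bound_close_to_published_approximation(self):
        from scipy import stats

        for a in (10, 30, 100, 1000, 10_000):
            for ratio in (0.1, 0.5, 1.0, 2.0, 10.0):
                e = a / ratio
                exact = float(np.log2(
                    stats.gamma.ppf(0.025, a + 0.5, scale=1 / (1 + 0.5 / e)) / e
                ))
                assert abs(exact - ic_lower_approx(a, e)) < 0.25


class TestContingencyAndScreening:
    def test_five_report_enumeration(self, tiny_reportset, cbd_mapping):
        asn = cs.assign_groups(tiny_reportset, cbd_mapping)
        t = cs.build_contingency(tiny_reportset, asn, "CBD", "PT_X")
        assert (t.a, t.b, t.c, t.d, t.n) == (1, 1, 1, 2, 5)

    def test_repeated_pt_counts_once(self, tiny_reportset, cbd_mapping):
        rs = tiny_reportset
        rs.reactions = pd.concat(
            [rs.reactions, pd.DataFrame([{"case_id": "c1", "pt": "PT_X"}])],
            ignore_index=True,
        )
        asn = cs.assign_groups(rs, cbd_mapping)
        assert cs.build_contingency(rs, asn, "CBD", "PT_X").a == 1

    def test_empty_exposure_margin_raises(self, tiny_reportset, cbd_mapping):
        asn = cs.assign_groups(tiny_reportset, cbd_mapping)
        with pytest.raises(ValueError, match="empty exposure margin"):
            cs.build_contingency(tiny_reportset, asn, "Sativex", "PT_X")

    def test_screen_counts_and_min_count_filter(self, small_sim, small_assignment):
        rs, truth = small_sim
        sig1 = cs.screen_all(rs, small_assignment, "Cannabis")
        exposed = small_assignment.cases("Cannabis")
        n_pts_seen = rs.reactions[rs.reactions["case_id"].isin(exposed)]["pt"].nunique()
        assert len(sig1) == n_pts_seen
        sig3 = cs.screen_all(rs, small_assignment, "Cannabis", config=ScreenConfig(min_count=3))
        assert (sig3["a"] >= 3).all()
        assert len(sig3) < len(sig1)

    def test_a_conservation_over_screening(self, small_sim, small_assignment):
        rs, _ = small_sim
        sig = cs.screen_all(rs, small_assignment, "Cannabis")
        exposed = small_assignment.cases("Cannabis")
        reac = rs.reactions.drop_duplicates(["case_id", "pt"])
        total = int(reac["case_id"].isin(exposed).sum())
        assert int(sig["a"].sum()) == total

    def test_flag_rules_hold_across_full_output(self, small_sim, small_assignment):
        rs, _ = small_sim
        for group in ("Cannabis", "Epidiolex"):
            sig = cs.screen_all(rs, small_assignment, group)
            assert (sig["flag_ic"] == (sig["ic_lo"] > 0)).all()
            ror_lo = sig["ror_lo"].fillna(-np.inf)
            prr_lo = sig["prr_lo"].fillna(-np.inf)
            assert (sig["flag_ror"] == (ror_lo > 1)).all()
            assert (sig["flag_prr"] == (prr_lo > 1)).all()

    def test_comparator_policy_changes_margin(self, small_sim, small_assignment):
        rs, _ = small_sim
        t_default = cs.build_contingency(rs, small_assignment, "CBD", "PT0000")
        t_strict = cs.build_contingency(
            rs, small_assignment, "CBD", "PT0000", comparator="exclude-all-cdp"
        )
        assert t_strict.c + t_strict.d < t_default.c + t_default.d

    def test_soc_lookup_attached_and_unmapped_logged(self, small_sim, small_assignment, small_vocab):
        rs, _ = small_sim
        lookup = small_vocab.pt_soc_lookup()
        sig = cs.screen_all(rs, small_assignment, "Cannabis", lookup)
        assert set(sig["soc"]) <= set(lookup.values())
        partial = {k: v for k, v in lookup.items() if k != "PT0000"}
        with pytest.warns(UserWarning, match="SOC lookup"):
            sig2 = cs.screen_all(rs, small_assignment, "Cannabis", partial)
        assert (sig2.loc[sig2["pt"] == "PT0000", "soc"] == "unmapped").all()


class TestIndicationStratification:
    def test_partition_sizes(self, cbd_mapping):
        from conftest import build_reportset

        rows = [(f"c{i}", "2019Q1", 30.0, "male", "US") for i in range(10)]
        drugs = [(f"c{i}", "1", "PS", "CBD OIL") for i in range(10)]
        reactions = [(f"c{i}", "PT_X") for i in range(10)]
        indications = [(f"c{i}", "1", "IND_SEIZ") for i in range(4)]
        rs = build_reportset(rows, drugs, reactions, indications=indications)
        asn = cs.assign_groups(rs, cbd_mapping)
        with_s, without_s = cs.stratify_by_indication(rs, asn, "CBD", {"IND_SEIZ"})
        assert len(with_s) == 4 and len(without_s) == 6

    def test_empty_indication_set_puts_all_in_without(self, tiny_reportset, cbd_mapping):
        asn = cs.assign_groups(tiny_reportset, cbd_mapping)
        with pytest.warns(UserWarning, match="skipped"):
            with_s, without_s = cs.stratify_by_indication(tiny_reportset, asn, "CBD", set())
        assert with_s is None
        assert len(without_s) == len(tiny_reportset)
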