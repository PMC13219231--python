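"""2×2 construction, ROR point estimate, Wald CI, zero-cell correction,
signal rule and the batch screen."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from dispro import (ContingencyTable, DegenerateTableError,
                    DisproportionalityResult, EventTermList, SignalCriteria,
                    ZeroCellError, build_contingency, classify_signal,
                    compute_ror, results_to_frame, screen)
from tests.conftest import mk_case

cells = st.integers(min_value=1, max_value=100000)


class TestBuildContingency:
    def toy_universe(self):
        """12 hand-enumerated cases: 3 exposed to drug X (2 with event E),
        4 of the 9 unexposed have E."""
        inc = [mk_case("I1", drug="X", event="E"),
               mk_case("I2", drug="X", event="E")]
        bg = [mk_case("B1", drug="X"),
              *[mk_case(f"E{i}", events=("E",)) for i in range(4)],
              *[mk_case(f"N{i}") for i in range(5)]]
        return inc, bg

    def test_toy_universe_counts(self):
        inc, bg = self.toy_universe()
        t = build_contingency(inc, bg, "X", "E")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 4, 5)

    def test_event_absent_everywhere(self):
        inc, bg = self.toy_universe()
        t = build_contingency(inc, bg, "X", "F")
        assert (t.a, t.c) == (0, 0)
        assert t.a + t.b == 3 and t.n == 12

    def test_cell_conservation_over_grid(self, fixture_filtered):
        fr = fixture_filtered
        universe = len(fr.included) + len(fr.background)
        for drug in ("canagliflozin", "empagliflozin", "dapagliflozin"):
            for event in EventTermList.default():
                t = build_contingency(fr.included, fr.background, drug, event)
                assert t.n == universe

    def test_unexposed_drug_is_degenerate(self):
        inc, bg = self.toy_universe()
        with pytest.raises(DegenerateTableError):
            build_contingency(inc, bg, "luseogliflozin", "E")


class TestComputeRor:
    def test_known_table_point_estimate_and_ci(self):
        # 10*9900/(90*100) = 11 exactly; CI from the log-scale Wald formula
        r = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert r.ror == pytest.approx(11.0, rel=1e-12)
        assert r.ci_low == pytest.approx(5.5596, abs=2e-4)
        assert r.ci_high == pytest.approx(21.7642, abs=2e-4)
        assert not r.correction_applied and r.signal

    def test_symmetric_table_is_null(self):
        r = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low * r.ci_high == pytest.approx(1.0, rel=1e-9)
        assert not r.signal

    def test_haldane_correction_on_zero_cell(self):
        r = compute_ror(ContingencyTable(0, 100, 50, 9850),
                        correction_policy="haldane_if_zero")
        # corrected cells (0.5, 100.5, 50.5, 9850.5)
        assert r.correction_applied
        assert r.ror == pytest.approx((0.5 * 9850.5) / (100.5 * 50.5),
                                      rel=1e-12)
        assert r.ror == pytest.approx(0.9704, abs=1e-4)

    def test_zero_cell_with_policy_none_raises(self):
        with pytest.raises(ZeroCellError):
            compute_ror(ContingencyTable(0, 100, 50, 9850),
                        correction_policy="none")

    def test_positive_table_never_corrected(self):
        r = compute_ror(ContingencyTable(1, 1, 1, 1))
        assert not r.correction_applied

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_matches_exact_rational_oracle(self, a, b, c, d):
        r = compute_ror(ContingencyTable(a, b, c, d))
        oracle = Fraction(a * d, b * c)
        assert abs(r.ror - oracle) / oracle <= 1e-12
        z = norm.ppf(0.975)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert r.ci_low == pytest.approx(
            math.exp(math.log(a * d / (b * c)) - z * se), rel=1e-10)
        assert r.ci_high == pytest.approx(
            math.exp(math.log(a * d / (b * c)) + z * se), rel=1e-10)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_exchange_symmetry(self, a, b, c, d):
        # swapping exposure and background inverts the ROR and reflects
        # the CI on the log scale
        r1 = compute_ror(ContingencyTable(a, b, c, d))
        r2 = compute_ror(ContingencyTable(c, d, a, b))
        assert r1.ror * r2.ror == pytest.approx(1.0, rel=1e-12)
        assert r1.ci_low * r2.ci_high == pytest.approx(1.0, rel=1e-9)

    @given(a=st.integers(1, 1000), b=st.integers(1, 1000),
           c=st.integers(1, 1000), d=st.integers(1, 1000))
    def test_monotone_in_each_cell(self, a, b, c, d):
        base = compute_ror(ContingencyTable(a, b, c, d)).ror
        assert compute_ror(ContingencyTable(a + 1, b, c, d)).ror > base
        assert compute_ror(ContingencyTable(a, b, c, d + 1)).ror > base
        assert compute_ror(ContingencyTable(a, b + 1, c, d)).ror < base
        assert compute_ror(ContingencyTable(a, b, c + 1, d)).ror < base

    def test_invalid_alpha_and_policy_rejected(self):
        with pytest.raises(ValueError):
            compute_ror(ContingencyTable(1, 1, 1, 1), alpha=1.5)
        with pytest.raises(ValueError):
            compute_ror(ContingencyTable(1, 1, 1, 1),
                        correction_policy="jeffreys")


def result(ror, ci_low):
    return DisproportionalityResult(
        drug="x", event="e", table=None, ror=ror, ci_low=ci_low,
        ci_high=ci_low * 10, alpha=0.05, correction_applied=False,
        signal=False)


class TestSignalRule:
    @pytest.mark.parametrize("ror,ci_low,expected", [
        (2.01, 1.01, True),
        (3.00, 0.99, False),
        (2.00, 1.50, False),   # threshold itself never signals
        (2.01, 1.00, False),
        (1.99, 5.00, False),
    ])
    def test_strict_inequalities(self, ror, ci_low, expected):
        assert classify_signal(result(ror, ci_low)) is expected

    def test_custom_thresholds(self):
        crit = SignalCriteria(ror_threshold=1.0, ci_low_threshold=0.5)
        assert classify_signal(result(1.5, 0.6), crit)


class TestScreen:
    def test_grid_bound_and_order(self, fixture_filtered):
        fr = fixture_filtered
        events = list(EventTermList.default())
        res = screen(fr.included, fr.background,
                     ("canagliflozin", "empagliflozin"), events)
        assert len(res) == 24
        assert [r.drug for r in res] == ["canagliflozin"] * 12 + \
            ["empagliflozin"] * 12
        assert [r.event for r in res][:12] == events

    def test_deterministic(self, fixture_filtered):
        fr = fixture_filtered
        events = list(EventTermList.default())
        r1 = screen(fr.included, fr.background, ("canagliflozin",), events)
        r2 = screen(fr.included, fr.background, ("canagliflozin",), events)
        assert r1 == r2

    def test_absent_drug_reported_with_status_flag(self, fixture_filtered):
        fr = fixture_filtered
        res = screen(fr.included, fr.background, ("luseogliflozin",),
                     ["Toe amputation"])
        assert len(res) == 1 and res[0].status == "no_exposure"
        assert res[0].ror is None and not res[0].signal

    def test_zero_a_cell_still_reported_under_haldane(self):
        inc = [mk_case("I1", drug="X", event="E")]
        bg = [mk_case("B1", drug="Y", pair=False),
              mk_case("B2", events=("F",))]
        res = screen(inc, bg, ["Y"], ["E"])
        assert res[0].status == "ok" and res[0].correction_applied
        assert 0 < res[0].ror

    def test_frame_export_columns(self, fixture_filtered):
        fr = fixture_filtered
        df = results_to_frame(screen(fr.included, fr.background,
                                     ("canagliflozin",), ["Toe amputation"]))
        assert list(df.columns) == ["drug", "event", "a", "b", "c", "d",
                                    "ror", "ci_low", "ci_high", "alpha",
                                    "correction_applied", "signal", "status"]

    def test_bonferroni_hook_widens_interval(self, fixture_filtered):
        fr = fixture_filtered
        plain = screen(fr.included, fr.background, ("canagliflozin",),
                       ["Toe amputation"])[0]
        adj = screen(fr.included, fr.background, ("canagliflozin",),
                     ["Toe amputation"], n_comparisons=48)[0]
        assert adj.ci_low < plain.ci_low < plain.ci_high < adj.ci_high
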