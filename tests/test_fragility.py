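import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragix import ContingencyTable, fragility_index, fragility_quotient, nplfu_exceeds_fi
from fragix.exact import _fisher_p

from _oracles import fragility_scan_exact


def tables(max_arm=12):
    return st.tuples(
        st.integers(0, max_arm), st.integers(0, max_arm),
        st.integers(0, max_arm), st.integers(0, max_arm),
    ).filter(lambda t: t[0] + t[1] >= 1 and t[2] + t[3] >= 1)


class TestFragilityIndex:
    def test_worked_example_p_path(self):
        """(0/5 vs 5/5 events): p walks 2/252 -> 12/252 -> 42/252, so FI=2."""
        t = ContingencyTable(0, 5, 5, 0)
        res = fragility_index(t)
        assert res.fi == 2
        assert res.modified_arm == "intervention"
        assert not res.exhausted
        assert res.p_initial == pytest.approx(2 / 252, rel=1e-12)
        assert _fisher_p(1, 4, 5, 0) == pytest.approx(12 / 252, rel=1e-12)
        assert res.p_terminal == pytest.approx(42 / 252, rel=1e-12)
        assert res.fq == pytest.approx(0.2)

    def test_already_non_significant(self):
        res = fragility_index(ContingencyTable(5, 5, 5, 5))
        assert (res.fi, res.modified_arm, res.exhausted) == (0, "none", False)
        assert res.fq == 0.0
        assert res.p_initial == res.p_terminal == 1.0

    def test_golden_regression(self):
        """Frozen from the exhaustive-increment exact-arithmetic oracle."""
        res = fragility_index(ContingencyTable(10, 90, 25, 75))
        assert res.fi == 4
        assert res.modified_arm == "intervention"
        assert res.p_initial == pytest.approx(0.008503571478624, rel=1e-9)
        assert res.p_terminal == pytest.approx(0.073419335741083, rel=1e-9)
        assert res.fq == pytest.approx(4 / 200)

    @pytest.mark.parametrize(
        "cells, fi, exhausted",
        [
            ((3, 0, 10, 90), 0, True),   # modifiable arm starts with no non-events
            ((2, 1, 5, 95), 1, True),    # arm saturates while still significant
        ],
    )
    def test_exhaustion_flagged(self, cells, fi, exhausted):
        res = fragility_index(ContingencyTable(*cells))
        assert (res.fi, res.exhausted) == (fi, exhausted)

    def test_equal_event_counts_scan_both_arms(self):
        # 5/5 vs 5/100 events: intervention arm has no non-events, so the
        # usable direction is the control arm.
        res = fragility_index(ContingencyTable(5, 0, 5, 95))
        fi_oracle, exhausted_oracle = fragility_scan_exact(5, 0, 5, 95)
        assert (res.fi, res.exhausted) == (fi_oracle, exhausted_oracle)
        assert res.modified_arm == "control"
        assert not res.exhausted

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            fragility_index(ContingencyTable(0, 5, 5, 0), alpha=0.0)
        with pytest.raises(ValueError):
            fragility_index(ContingencyTable(0, 5, 5, 0), alpha=1.0)

    @given(tables())
    @settings(max_examples=200)
    def test_matches_rebuild_oracle_and_boundary(self, cells):
        """The iteration agrees with a naive rebuild-and-retest oracle, and
        the returned index sits exactly on the significance boundary."""
        res = fragility_index(ContingencyTable(*cells))
        fi_oracle, exhausted_oracle = fragility_scan_exact(*cells)
        assert (res.fi, res.exhausted) == (fi_oracle, exhausted_oracle)
        if not res.exhausted and res.fi > 0:
            t = ContingencyTable(*cells)
            assert _fisher_p(*t.with_events_moved(res.modified_arm, res.fi).cells()) >= 0.05
            assert _fisher_p(*t.with_events_moved(res.modified_arm, res.fi - 1).cells()) < 0.05

    @given(tables())
    def test_margin_conservation(self, cells):
        t = ContingencyTable(*cells)
        res = fragility_index(t)
        if res.modified_arm != "none":
            for k in range(res.fi + 1):
                m = t.with_events_moved(res.modified_arm, k)
                assert m.n_intervention == t.n_intervention
                assert m.n_control == t.n_control
                assert m.n_total == t.n_total


class TestFragilityQuotient:
    @pytest.mark.parametrize(
        "fi, n, expected", [(0, 100, 0.0), (3, 200, 0.015), (2, 10, 0.2)]
    )
    def test_direct_division(self, fi, n, expected):
        assert fragility_quotient(fi, n) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fragility_quotient(1, 0)
        with pytest.raises(ValueError):
            fragility_quotient(11, 10)

    @given(st.integers(1, 500), st.integers(0, 500), st.integers(0, 500))
    def test_monotone_in_fi_at_fixed_n(self, n, f1, f2):
        f1, f2 = min(f1, n), min(f2, n)
        if f1 <= f2:
            assert fragility_quotient(f1, n) <= fragility_quotient(f2, n)


@pytest.mark.parametrize(
    "n_lost, fi, expected", [(4, 3, True), (3, 3, False), (0, 0, False)]
)
def test_nplfu_strictly_greater(n_lost, fi, expected):
    assert nplfu_exceeds_fi(n_lost, fi) is expected
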