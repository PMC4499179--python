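import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cometh.pattern_analysis import (
    cpg_pair_dependency,
    group_patterns,
    pattern_set_from_signatures,
    pattern_zscore,
    reads_covering_window,
    select_window,
    significant_patterns,
)
from cometh.reference_io import ReferenceRegion

from conftest import make_call, make_window


class TestSelectWindow:
    def test_default_window_is_70bp_from_first_cpg(self):
        seq = "A" * 10 + "CG" + "A" * 50 + "CG" + "A" * 136
        region = ReferenceRegion.from_sequence("r", seq)
        window = select_window(region)
        assert (window.start, window.end) == (10, 80)
        assert window.sites == (10, 62)

    def test_default_window_clipped_to_region_end(self):
        region = ReferenceRegion.from_sequence("r", "A" * 30 + "CG" + "A" * 8)
        window = select_window(region)
        assert (window.start, window.end) == (30, 40)

    def test_user_window_is_clipped_and_sited(self):
        region = ReferenceRegion.from_sequence("r", "TTCGTT" * 20)
        window = select_window(region, (0, 50))
        assert (window.start, window.end) == (0, 50)
        assert all(0 <= s and s + 1 < 50 for s in window.sites)

    def test_no_cpg_and_no_window_is_an_error(self):
        region = ReferenceRegion.from_sequence("r", "ATATAT")
        with pytest.raises(ValueError, match="no CpG"):
            select_window(region)

    def test_window_with_no_complete_cpg_is_an_error(self):
        region = ReferenceRegion.from_sequence("r", "ATATATCG")
        with pytest.raises(ValueError, match="complete CpG"):
            select_window(region, (0, 5))


class TestCoverage:
    def test_only_fully_covering_unambiguous_reads_kept(self):
        window = make_window([2, 8, 14])
        full = make_call("MUM", [2, 8, 14], read_id="full")
        partial = make_call("MU", [2, 8], read_id="partial")
        ambiguous = make_call("M?M", [2, 8, 14], read_id="amb")
        wider = make_call("MUMU", [2, 8, 14, 20], read_id="wider")
        kept = reads_covering_window([full, partial, ambiguous, wider], window)
        assert [c.read_id for c in kept] == ["full", "wider"]


class TestGrouping:
    def test_hand_grouped_example(self):
        window = make_window([2, 8])
        reads = [make_call(s, [2, 8], read_id=f"r{i}")
                 for i, s in enumerate(["MM", "MM", "UU", "MU"])]
        ps = group_patterns(reads, window)
        assert ps.n == 4
        assert {p.signature: p.support for p in ps.patterns} == {"MM": 2, "UU": 1, "MU": 1}
        assert ps.p0 == pytest.approx(1 / 3)
        assert {p.signature: p.fraction for p in ps.patterns} == {
            "MM": 0.5, "UU": 0.25, "MU": 0.25,
        }

    def test_unanimous_reads_form_single_pattern(self):
        ps = pattern_set_from_signatures(["MM"] * 50)
        assert ps.n == 50 and ps.p0 == 1.0
        (pat,) = ps.patterns
        assert pat.fraction == 1.0 and pat.z == 0.0 and pat.p_value == 1.0

    def test_zero_reads_gives_empty_set(self):
        ps = pattern_set_from_signatures([])
        assert (ps.n, ps.patterns) == (0, ())

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.text(alphabet="MU", min_size=3, max_size=3), max_size=60))
    def test_matches_bruteforce_tally_and_conserves_mass(self, sigs):
        ps = pattern_set_from_signatures(sigs)
        brute = Counter(sigs)
        assert {p.signature: p.support for p in ps.patterns} == dict(brute)
        assert sum(p.support for p in ps.patterns) == ps.n == len(sigs)
        if sigs:
            assert sum(p.fraction for p in ps.patterns) == pytest.approx(1.0)
            assert ps.p0 * len(ps.patterns) == pytest.approx(1.0)


class TestZScore:
    def test_null_value_is_zero(self):
        z, p = pattern_zscore(0.25, 0.25, 50)
        assert z == 0.0 and p == pytest.approx(0.5)

    def test_direct_evaluation_example(self):
        z, p = pattern_zscore(0.5, 0.25, 100)
        assert z == pytest.approx(5.0)
        assert p == pytest.approx(float(stats.norm.sf(5.0)))

    def test_unanimity_with_alternatives_is_significant(self):
        z, p = pattern_zscore(1.0, 0.5, 10)
        assert math.isinf(z) and p == 0.0

    def test_sole_conceivable_pattern_is_not_significant(self):
        assert pattern_zscore(1.0, 1.0, 10) == (0.0, 1.0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            pattern_zscore(0.5, 0.5, 0)
        with pytest.raises(ValueError):
            pattern_zscore(0.0, 0.5, 10)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0.01, 0.98), st.floats(0.01, 1.0),
        st.integers(1, 10_000), st.floats(0.001, 0.01),
    )
    def test_monotonic_in_p_hat_and_n(self, p_hat, p0, n, eps):
        z1, _ = pattern_zscore(p_hat, p0, n)
        z2, _ = pattern_zscore(min(p_hat + eps, 0.99), p0, n)
        assert z2 >= z1
        if p_hat > p0:
            z3, _ = pattern_zscore(p_hat, p0, n * 4)
            assert z3 > z1


class TestSignificance:
    def test_alpha_and_fraction_filters(self):
        ps = pattern_set_from_signatures(["MM"] * 60 + ["UU"] * 25 + ["MU"] * 10 + ["UM"] * 5)
        sig = significant_patterns(ps, alpha=0.05)
        assert [p.signature for p in sig] == ["MM"]
        assert significant_patterns(ps, alpha=0.05, min_fraction=0.7) == []

    def test_equal_z_ties_break_by_support_then_signature(self):
        # two distinct PatternSets cannot hold equal-support duplicate rows,
        # so craft patterns directly through sorting of an equal-(p,n) pair
        ps = pattern_set_from_signatures(["MM"] * 40 + ["UU"] * 40 + ["MU"] * 20)
        sig = significant_patterns(ps, alpha=1.0)  # keep all, test ordering
        assert [p.signature for p in sig] == ["MM", "UU", "MU"]
        mm, uu = sig[0], sig[1]
        assert mm.z == uu.z and mm.support == uu.support
        assert sig[0].signature < sig[1].signature

    def test_bonferroni_divides_alpha(self):
        ps = pattern_set_from_signatures(["MM"] * 60 + ["UU"] * 25 + ["MU"] * 15)
        plain = significant_patterns(ps, alpha=0.05)
        bonf = significant_patterns(ps, alpha=0.05, bonferroni=True)
        assert {p.signature for p in bonf} <= {p.signature for p in plain}


class TestPairDependency:
    def test_perfect_association_chi2_equals_n(self):
        ps = pattern_set_from_signatures(["MM"] * 50 + ["UU"] * 50)
        chi2, p, table = cpg_pair_dependency(ps, 0, 1)
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-20
        assert table == [[50, 0], [0, 50]]

    def test_independence_gives_zero(self):
        ps = pattern_set_from_signatures(["MM"] * 25 + ["MU"] * 25 + ["UM"] * 25 + ["UU"] * 25)
        chi2, p, _ = cpg_pair_dependency(ps, 0, 1)
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_is_degenerate(self):
        ps = pattern_set_from_signatures(["MM"] * 30 + ["MU"] * 20)
        chi2, p, _ = cpg_pair_dependency(ps, 0, 1)
        assert (chi2, p) == (0.0, 1.0)

    def test_agrees_with_scipy_on_nondegenerate_table(self):
        rng = np.random.default_rng(4)
        sigs = (["MM"] * 40 + ["MU"] * 25 + ["UM"] * 15 + ["UU"] * 30)
        ps = pattern_set_from_signatures(sigs)
        chi2, p, table = cpg_pair_dependency(ps, 0, 1)
        ref = stats.chi2_contingency(np.array(table), correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_invalid_site_index_raises(self):
        ps = pattern_set_from_signatures(["MM"] * 10)
        with pytest.raises(IndexError):
            cpg_pair_dependency(ps, 0, 2)
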