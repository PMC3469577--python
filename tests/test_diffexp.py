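"""TPM, the Audic-Claverie test, signed fold change, and significance calls."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirseed.curated import DE_TABLE_DAY2, DE_TABLE_DAY4, FC_RECOMPUTATION_EXCLUDED
from mirseed.diffexp import (
    ExpressionRecord,
    audic_claverie_p,
    call_differential,
    round_half_up,
    signed_fold_change,
    tpm,
)


def ac_oracle(x, y, n1, n2):
    """Arbitrary-precision direct summation of both tails."""
    mpmath.mp.dps = 50
    r = mpmath.mpf(n2) / n1

    def term(k):
        return (
            (r**k)
            * mpmath.gamma(x + k + 1)
            / (mpmath.gamma(x + 1) * mpmath.gamma(k + 1) * (1 + r) ** (x + k + 1))
        )

    lower = mpmath.fsum(term(k) for k in range(0, y + 1))
    upper = mpmath.mpf(0)
    k, mode = y, float(r * (x + 1))
    while True:
        t = term(k)
        upper += t
        k += 1
        if k > mode and t < upper * mpmath.mpf("1e-40"):
            break
    return min(mpmath.mpf(1), 2 * min(lower, upper))


class TestTpm:
    @pytest.mark.parametrize("count,n,expected", [(0, 10**6, 0.0), (1, 10**6, 1.0)])
    def test_basic(self, count, n, expected):
        assert tpm(count, n) == expected

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            tpm(5, 0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=10**6),
        st.integers(min_value=1, max_value=10**6),
        st.integers(min_value=1, max_value=10**8),
    )
    def test_tpm_ratio_equals_count_ratio(self, x, y, n):
        assert tpm(x, n) / tpm(y, n) == pytest.approx(x / y, rel=1e-12)


class TestAudicClaverie:
    def test_kernel_normalizes(self):
        """The conditional distribution over y sums to 1 (equal libraries)."""
        mpmath.mp.dps = 30
        x, r = 7, mpmath.mpf(1)
        total = mpmath.fsum(
            (r**k)
            * mpmath.gamma(x + k + 1)
            / (mpmath.gamma(x + 1) * mpmath.gamma(k + 1) * (1 + r) ** (x + k + 1))
            for k in range(0, 300)
        )
        assert float(total) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_counts_give_p_one(self):
        assert audic_claverie_p(50, 50, 10**6, 10**6) == 1.0

    def test_matches_high_precision_oracle(self):
        p = audic_claverie_p(20, 80, 10**6, 10**6)
        assert p == pytest.approx(float(ac_oracle(20, 80, 10**6, 10**6)), rel=1e-9)

    def test_oracle_grid(self, rng):
        """Random (x, y, N1, N2) grid agrees with the mpmath oracle to 1e-9."""
        for _ in range(40):
            x = int(rng.integers(0, 250))
            y = int(rng.integers(0, 250))
            n1 = int(rng.integers(10**4, 10**7))
            n2 = int(rng.integers(max(10**4, n1 // 4), min(10**7, n1 * 4)))
            p = audic_claverie_p(x, y, n1, n2)
            assert p == pytest.approx(float(ac_oracle(x, y, n1, n2)), rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=10**3, max_value=10**6),
        st.integers(min_value=10**3, max_value=10**6),
        st.integers(min_value=1, max_value=50),
    )
    def test_library_ratio_scale_invariance(self, x, y, n1, n2, c):
        """p depends on the library sizes only through their ratio, so
        scaling both sizes by a common factor leaves it unchanged."""
        assert audic_claverie_p(x, y, n1, n2) == pytest.approx(
            audic_claverie_p(x, y, c * n1, c * n2), rel=1e-9
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=10**3, max_value=10**7),
    )
    def test_equal_counts_equal_sizes_maximal(self, x, n):
        """Identical counts in identical libraries are maximally unsurprising
        (each tail holds exactly half the mass, so the doubled tail is 1)."""
        assert audic_claverie_p(x, x, n, n) == pytest.approx(1.0, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            audic_claverie_p(-1, 5, 100, 100)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [(95.07, 38.57, 2.46), (45.43, 95.28, -2.10), (5.0, 5.0, 1.00)],
    )
    def test_worked_examples(self, treated, control, expected):
        assert round_half_up(signed_fold_change(treated, control), 2) == expected

    def test_zero_sentinels(self):
        assert signed_fold_change(5.0, 0.0) == math.inf
        assert signed_fold_change(0.0, 5.0) == -math.inf
        with pytest.raises(ValueError):
            signed_fold_change(0.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.01, max_value=10**5),
        st.floats(min_value=0.01, max_value=10**5),
    )
    def test_antisymmetry(self, a, b):
        fc = signed_fold_change(a, b)
        rev = signed_fold_change(b, a)
        if abs(fc) > 1 + 1e-12:
            assert rev == pytest.approx(-fc, rel=1e-9)


def test_published_fold_changes_recompute():
    """Every published TPM pair reproduces its printed signed fold change,
    apart from the one contrast known to have been formed from unrounded
    counts."""
    for day, table in (("day2", DE_TABLE_DAY2), ("day4", DE_TABLE_DAY4)):
        for row in table:
            name, htd, hti, ltd, lti, fc_ht, fc_lt = (
                row[1], row[3], row[4], row[5], row[6], row[7], row[8],
            )
            for genotype, treated, control, printed in (
                ("HT", htd, hti, fc_ht),
                ("LT", ltd, lti, fc_lt),
            ):
                if (name, day, genotype) in FC_RECOMPUTATION_EXCLUDED:
                    continue
                assert round_half_up(signed_fold_change(treated, control), 2) == printed


class TestCallDifferential:
    def test_fc_boundary_strict(self):
        """|FC| exactly 2.00 is not significant (strict > 2.00 filter)."""
        rec = ExpressionRecord("m", 2000, 1000, 10**6, 10**6)
        res = call_differential([rec])[0]
        assert res.fold_change == pytest.approx(2.0)
        assert res.p_value < 0.05
        assert not res.significant

    def test_strong_change_flagged_with_sign(self):
        rec = ExpressionRecord("m", 500, 2000, 10**6, 10**6)
        res = call_differential([rec])[0]
        assert res.significant
        assert res.fold_change == pytest.approx(-4.0)

    def test_double_zero_not_significant(self):
        res = call_differential([ExpressionRecord("m", 0, 0, 10**6, 10**6)])[0]
        assert math.isnan(res.fold_change)
        assert not res.significant

    def test_single_zero_excluded_from_fc_filter(self):
        res = call_differential([ExpressionRecord("m", 50, 0, 10**6, 10**6)])[0]
        assert math.isinf(res.fold_change)
        assert not res.significant
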