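import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infiltra import hla_assoc, synthgen
from infiltra.errors import InputError, ResolutionError


def _genotype_frame(subject_alleles, locus="A"):
    """subject_alleles: list of (allele1, allele2)."""
    return pd.DataFrame(
        {
            "subject": [f"S{i}" for i in range(len(subject_alleles))],
            "locus": locus,
            "allele1": [a for a, _ in subject_alleles],
            "allele2": [b for _, b in subject_alleles],
        }
    )


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration over the hypergeometric support, applying
    the same <= p_obs * (1 + 1e-7) tie rule."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        return 1.0
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    gate = probs[a] * (1 + Fraction(1, 10**7))
    return float(sum(p for p in probs.values() if p <= gate))


def hwe_oracle(n_aa, n_het, n_bb):
    """Exact-rational enumeration of heterozygote counts given allele counts."""
    n_a = 2 * n_aa + n_het
    n_b = 2 * n_bb + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    weights = {}
    for het in range(n_a % 2, min(n_a, n_b) + 1, 2):
        aa, bb = (n_a - het) // 2, (n_b - het) // 2
        weights[het] = Fraction(
            2**het,
            math.factorial(aa) * math.factorial(het) * math.factorial(bb),
        )
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    return float(sum(p for p in probs.values() if p <= probs[n_het]))


class TestCarrierTable:
    def test_printed_carrier_counts(self):
        # 104 genotyped cases of whom 25 carry A*03:01
        cases = _genotype_frame(
            [("A*03:01", "A*02:01")] * 25 + [("A*02:01", "A*01:01")] * 79
        )
        controls = _genotype_frame([("A*02:01", "A*02:01")] * 10)
        t = hla_assoc.carrier_table(cases, controls, "A*03:01")
        assert (t.a, t.b) == (25, 79)
        assert round(100 * t.a / (t.a + t.b)) == 24

    def test_homozygote_counted_once(self):
        cases = _genotype_frame([("A*03:01", "A*03:01"), ("A*02:01", "A*01:01")])
        controls = _genotype_frame([("A*02:01", "A*02:01")])
        t = hla_assoc.carrier_table(cases, controls, "A*03:01")
        assert t.a == 1

    def test_no_carriers_valid_with_finite_or(self):
        cases = _genotype_frame([("A*02:01", "A*02:01")] * 5)
        controls = _genotype_frame([("A*02:01", "A*01:01")] * 5)
        t = hla_assoc.carrier_table(cases, controls, "A*01:01")
        assert t.a == 0
        or_, (lo, hi) = hla_assoc.woolf_haldane_or(t)
        assert 0 < or_ < math.inf and 0 < lo < hi < math.inf

    def test_resolution_mismatch(self):
        cases = _genotype_frame([("A*03:01", "A*02:01")])
        controls = _genotype_frame([("A*02:01", "A*02:01")])
        with pytest.raises(ResolutionError):
            hla_assoc.carrier_table(cases, controls, "A*03")

    def test_frequency_backed_controls(self):
        cases = _genotype_frame([("A*03:01", "A*02:01")] * 10)
        t = hla_assoc.carrier_table_from_freq(
            cases, "A*03:01", freq=0.128, n_controls=1000, freq_type="allele"
        )
        assert t.c == round((1 - (1 - 0.128) ** 2) * 1000)
        assert t.c + t.d == 1000


class TestHWE:
    def test_modal_configuration_p_one(self):
        assert hla_assoc.hwe_exact_test(1, 2, 1) == pytest.approx(hwe_oracle(1, 2, 1))
        assert hla_assoc.hwe_exact_test(1, 2, 1) == pytest.approx(1.0)

    def test_extreme_disequilibrium(self):
        assert hla_assoc.hwe_exact_test(50, 0, 50) < 1e-10

    def test_monomorphic_p_one(self):
        assert hla_assoc.hwe_exact_test(20, 0, 0) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n_aa, n_het, n_bb = rng.integers(0, 15, size=3)
            if n_aa + n_het + n_bb == 0:
                continue
            got = hla_assoc.hwe_exact_test(int(n_aa), int(n_het), int(n_bb))
            assert got == pytest.approx(hwe_oracle(int(n_aa), int(n_het), int(n_bb)), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            hla_assoc.hwe_exact_test(-1, 2, 3)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected_2dp",
        [
            ([[18, 28], [30, 17]], 0.02),
            ([[39, 11], [39, 12]], 1.0),
            ([[29, 21], [24, 27]], 0.32),
            ([[5, 5], [5, 5]], 1.0),
        ],
    )
    def test_printed_values(self, table, expected_2dp):
        assert round(hla_assoc.fisher_exact_2x2(table), 2) == expected_2dp

    def test_empty_margin_p_one(self):
        assert hla_assoc.fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert hla_assoc.fisher_exact_2x2([[0, 3], [0, 4]]) == 1.0

    @given(
        st.tuples(
            st.integers(0, 25), st.integers(0, 25),
            st.integers(0, 25), st.integers(0, 25),
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_transpose_invariance(self, cells):
        a, b, c, d = cells
        p1 = hla_assoc.fisher_exact_2x2([[a, b], [c, d]])
        p2 = hla_assoc.fisher_exact_2x2([[a, c], [b, d]])
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(17)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            got = hla_assoc.fisher_exact_2x2([[a, b], [c, d]])
            want = fisher_exact([[a, b], [c, d]]).pvalue
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)

    def test_non_integer_rejected(self):
        with pytest.raises(InputError):
            hla_assoc.fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestSidak:
    def test_single_test_identity(self):
        assert hla_assoc.sidak_correct(0.0421, 1) == pytest.approx(0.0421)

    def test_closed_form_example(self):
        assert hla_assoc.sidak_correct(0.01, 10) == pytest.approx(1 - 0.99**10)

    def test_endpoints(self):
        assert hla_assoc.sidak_correct(0.0, 7) == 0.0
        assert hla_assoc.sidak_correct(1.0, 7) == 1.0

    @given(st.floats(1e-12, 1.0), st.integers(1, 50), st.integers(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p_and_n(self, p, n, dn):
        base = hla_assoc.sidak_correct(p, n)
        assert hla_assoc.sidak_correct(min(1.0, p * 1.5), n) >= base - 1e-15
        assert hla_assoc.sidak_correct(p, n + dn) >= base - 1e-15

    @given(st.floats(1e-9, 1e-3), st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_bonferroni_first_order(self, p, n):
        np_ = n * p
        if np_ >= 0.1:
            return
        assert abs(hla_assoc.sidak_correct(p, n) - np_) <= np_**2


class TestWoolfHaldane:
    def test_printed_table(self):
        or_, (lo, hi) = hla_assoc.woolf_haldane_or([[18, 28], [30, 17]])
        assert or_ == pytest.approx(0.372, abs=5e-4)
        assert lo == pytest.approx(0.163, abs=5e-4)
        assert hi == pytest.approx(0.854, abs=5e-4)

    def test_symmetric_table_or_one(self):
        or_, _ = hla_assoc.woolf_haldane_or([[5, 5], [5, 5]])
        assert or_ == pytest.approx(1.0)

    def test_zero_cell_finite(self):
        or_, (lo, hi) = hla_assoc.woolf_haldane_or([[0, 5], [10, 5]])
        assert or_ == pytest.approx(0.047619, rel=1e-4)
        assert math.isfinite(lo) and math.isfinite(hi)

    @given(
        st.tuples(st.integers(0, 40), st.integers(0, 40),
                  st.integers(0, 40), st.integers(0, 40))
    )
    @settings(max_examples=80, deadline=None)
    def test_row_swap_reciprocal(self, cells):
        a, b, c, d = cells
        or1, _ = hla_assoc.woolf_haldane_or([[a, b], [c, d]])
        or2, _ = hla_assoc.woolf_haldane_or([[c, d], [a, b]])
        assert or1 == pytest.approx(1.0 / or2, rel=1e-9)

    def test_ci_brackets_or(self):
        or_, (lo, hi) = hla_assoc.woolf_haldane_or([[3, 17], [9, 11]])
        assert lo <= or_ <= hi


class TestStandardization:
    @pytest.mark.parametrize("n_cases,expected", [(94, 376), (1, 4), (104, 416)])
    def test_control_size_rule(self, n_cases, expected):
        assert hla_assoc.standard_control_size(n_cases) == expected

    def test_identity_when_not_oversized(self):
        assert hla_assoc.good_standardized_p(0.1, 376, 376) == 0.1
        assert hla_assoc.good_standardized_p(0.1, 100, 376) == 0.1

    def test_sqrt_ratio_example(self):
        got = hla_assoc.good_standardized_p(0.01, 5604, 376)
        assert got == pytest.approx(0.01 * math.sqrt(5604 / 376), rel=1e-9)
        assert got == pytest.approx(0.0386, abs=5e-4)

    def test_cap_at_half(self):
        assert hla_assoc.good_standardized_p(0.4, 400, 100) == 0.5

    def test_invariant_bound(self):
        for p in (0.001, 0.2, 0.7):
            got = hla_assoc.good_standardized_p(p, 2000, 100)
            assert got <= max(p, 0.5)


class TestScan:
    def test_single_allele_locus(self):
        cases = _genotype_frame([("A*03:01", "A*03:01")] * 6)
        controls = _genotype_frame([("A*03:01", "A*03:01")] * 6)
        results = hla_assoc.run_association_scan(cases, controls=controls)
        assert len(results) == 1
        r = results[0]
        assert r.n_tests == 1
        assert r.p_sidak == pytest.approx(r.p_raw)

    def test_no_testable_alleles_rejected(self):
        cases = _genotype_frame([("A*03:01", "A*03:01")])
        controls = _genotype_frame([("B*07:02", "B*07:02")], locus="B")
        with pytest.raises(InputError):
            hla_assoc.run_association_scan(cases, controls=controls)

    def test_planted_association_ranks_first(self):
        # one allele planted at carrier odds ratio 3 in cases
        base = {f"A*{i:02d}:01": 0.04 for i in range(1, 21)}
        target = "A*05:01"
        q = 1 - (1 - base[target]) ** 2  # control carrier fraction
        odds = 3 * q / (1 - q)
        q_case = odds / (1 + odds)
        f_case = 1 - math.sqrt(1 - q_case)  # allele freq giving that carrier fraction
        case_freqs = dict(base)
        case_freqs[target] = f_case
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            cases = synthgen.generate_genotypes(case_freqs, 500, seed=rep)
            controls = synthgen.generate_genotypes(base, 2000, seed=10_000 + rep)
            results = hla_assoc.run_association_scan(cases, controls=controls)
            if results[0].allele == target:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_results_frame_columns(self):
        cases = synthgen.generate_genotypes({"A*03:01": 0.2, "A*02:01": 0.3}, 50, seed=1)
        controls = synthgen.generate_genotypes({"A*03:01": 0.2, "A*02:01": 0.3}, 200, seed=2)
        df = hla_assoc.results_to_frame(hla_assoc.run_association_scan(cases, controls=controls))
        assert {"allele", "odds_ratio", "p_raw", "p_sidak", "p_standardized"} <= set(df.columns)
        assert (df["p_sidak"] >= df["p_raw"] - 1e-12).all()
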