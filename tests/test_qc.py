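"""QC filters: HWE exact test, differential missingness, kinship, stages."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raregene.containers import GenotypeMatrix, make_sample_frame, make_variant_frame
from raregene.qc import (
    QCThresholds,
    apply_imputation_qc,
    apply_scaffold_qc,
    differential_missingness_test,
    hwe_exact_test,
    kinship_estimate,
)


def hwe_enumeration_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact-rational HWE p by direct enumeration of heterozygote counts.

    Conditional probability of h heterozygotes given n genotypes and n_a
    minor alleles: 2^h n! n_a! n_b! / (h! n_aa! n_bb! (2n)!), summed over
    configurations no more probable than the observed one.
    """
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * min(n_hom1, n_hom2) + n_het
    n_b = 2 * n - n_a

    from math import factorial

    def prob(h: int) -> Fraction:
        n_aa = (n_a - h) // 2
        n_bb = n - h - n_aa
        # 2^h * multinomial n!/(h! naa! nbb!) * na! nb! / (2n)!
        return (
            Fraction(2**h)
            * Fraction(factorial(n))
            / (Fraction(factorial(h)) * factorial(n_aa) * factorial(n_bb))
            * Fraction(factorial(n_a))
            * Fraction(factorial(n_b))
            / Fraction(factorial(2 * n))
        )

    hets = range(n_a % 2, n_a + 1, 2)
    probs = {h: prob(h) for h in hets}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_modal_configuration_is_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_no_heterozygotes_enumeration(self):
        # (5,0,5): all 10 minor alleles in homozygotes, extreme table
        assert hwe_exact_test(5, 0, 5) == pytest.approx(
            hwe_enumeration_oracle(5, 0, 5), abs=1e-12
        )

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle_small_tables(self, a, h, b):
        """Exact agreement with rational enumeration for all n <= 20 shapes."""
        if a + h + b == 0 or a + h + b > 20:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_enumeration_oracle(a, h, b), abs=1e-12
        )

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestDifferentialMissingness:
    def test_no_missing_data_is_one(self):
        assert differential_missingness_test(0, 100, 0, 100) == 1.0

    def test_equal_rates_large_n(self):
        assert differential_missingness_test(50, 950, 50, 950) > 0.5

    def test_extreme_differential_below_cutoff(self):
        p = differential_missingness_test(50, 950, 0, 1000)
        assert p < 1e-5

    def test_small_expected_uses_exact(self, rng):
        # expected missing cells < 5 -> Fisher; compare to scipy directly
        from scipy.stats import fisher_exact

        p = differential_missingness_test(3, 200, 0, 200)
        assert p == pytest.approx(fisher_exact([[3, 200], [0, 200]])[1])

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            differential_missingness_test(0, 0, 0, 0)


class TestKinship:
    def test_duplicate_sample_is_half(self, rng):
        d = rng.binomial(2, 0.3, 500).astype(float)
        phi, reliable = kinship_estimate(d, d)
        assert reliable
        assert phi == pytest.approx(0.5)

    def test_unrelated_near_zero(self, rng):
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.3, 10_000).astype(float)
        phi, reliable = kinship_estimate(a, b)
        assert reliable
        assert abs(phi) < 0.02

    def test_insufficient_overlap_flagged(self, rng):
        a = rng.binomial(2, 0.3, 50).astype(float)
        b = rng.binomial(2, 0.3, 50).astype(float)
        _, reliable = kinship_estimate(a, b)
        assert not reliable


def _clean_matrix(rng, n=60, m=40, maf=0.3):
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)
    # guarantee polymorphic common columns in HWE proportions
    samples = make_sample_frame(
        [f"S{i}" for i in range(n)], status=[1] * (n // 2) + [0] * (n - n // 2)
    )
    variants = make_variant_frame("1", np.arange(1, m + 1), info_score=np.ones(m))
    return GenotypeMatrix(dosages, samples, variants)


class TestScaffoldQC:
    def test_clean_cohort_no_removals(self, rng):
        geno = _clean_matrix(rng)
        out, report = apply_scaffold_qc(geno)
        frame = report.to_frame()
        assert frame["n_removed"].sum() == 0
        assert out.n_samples == geno.n_samples
        assert out.n_variants == geno.n_variants

    def test_sample_call_rate_boundary(self, rng):
        geno = _clean_matrix(rng, n=50, m=100)
        # sample 0: call rate 0.89 (removed); sample 1: 0.90 (kept)
        geno.dosages[0, :11] = np.nan
        geno.dosages[1, :10] = np.nan
        out, report = apply_scaffold_qc(
            geno, QCThresholds(variant_call_rate_min=0.0, diff_missing_p_max=0.0)
        )
        kept = set(out.samples["sample_id"])
        assert "S0" not in kept and "S1" in kept

    def test_maf_filter_removes_rare_at_scaffold(self, rng):
        geno = _clean_matrix(rng, n=100, m=30)
        geno.dosages[:, 0] = 0.0
        geno.dosages[0, 0] = 1.0  # MAF 0.005 < 1%
        out, _ = apply_scaffold_qc(geno)
        assert out.variants["id"].iloc[0] != geno.variants["id"].iloc[0]
        assert out.n_variants == geno.n_variants - 1

    def test_report_reconciles(self, rng):
        geno = _clean_matrix(rng, n=80, m=50)
        geno.dosages[0, :30] = np.nan
        out, report = apply_scaffold_qc(geno)
        assert geno.n_samples - report.total_removed("samples") == out.n_samples
        assert geno.n_variants - report.total_removed("variants") == out.n_variants

    def test_rerun_is_noop(self, rng):
        geno = _clean_matrix(rng)
        once, _ = apply_scaffold_qc(geno)
        twice, rep = apply_scaffold_qc(once)
        assert rep.to_frame()["n_removed"].sum() == 0
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_related_pair_one_removed(self, rng):
        geno = _clean_matrix(rng, n=40, m=6000)
        geno.dosages[1, :] = geno.dosages[0, :]  # duplicate pair, phi = 0.5
        out, report = apply_scaffold_qc(geno)
        assert report.total_removed("samples") == 1
        kept = set(out.samples["sample_id"])
        assert ("S0" in kept) != ("S1" in kept)


class TestImputationQC:
    def test_info_boundary_inclusive(self, rng):
        geno = _clean_matrix(rng, m=10)
        geno.variants.loc[0, "info_score"] = 0.74
        geno.variants.loc[1, "info_score"] = 0.75
        out, _ = apply_imputation_qc(geno)
        ids = set(out.variants["id"])
        assert geno.variants["id"].iloc[0] not in ids
        assert geno.variants["id"].iloc[1] in ids

    def test_no_maf_restriction(self, rng):
        geno = _clean_matrix(rng, n=100, m=10)
        geno.dosages[:, 0] = 0.0
        geno.dosages[0, 0] = 1.0  # MAF 0.005, info 1.0 -> kept
        out, _ = apply_imputation_qc(geno)
        assert geno.variants["id"].iloc[0] in set(out.variants["id"])

    def test_identity_on_perfect_data(self, rng):
        geno = _clean_matrix(rng)
        out, report = apply_imputation_qc(geno)
        assert report.to_frame()["n_removed"].sum() == 0
        np.testing.assert_array_equal(out.dosages, geno.dosages)

    def test_missing_info_errors(self, rng):
        geno = _clean_matrix(rng, m=5)
        geno.variants.loc[2, "info_score"] = np.nan
        with pytest.raises(ValueError):
            apply_imputation_qc(geno)
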