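"""Synthetic-cohort generator: determinism, SFS fidelity, spiked effects."""

import numpy as np
import pytest

from raregene.genetests import burden_test, minor_oriented
from raregene.synthcohort import (
    CohortSpec,
    ConfigurationError,
    EffectSpec,
    simulate_annotations,
    simulate_cohort,
    spike_effects,
    subsample_case_control,
)
from raregene.varclass import column_macs, variant_stats_table


class TestSimulateCohort:
    def test_deterministic_for_fixed_seed(self):
        spec = CohortSpec(n_cases=50, n_controls=50, n_genes=3,
                          sfs_weights=(0.2, 0.0, 0.4, 0.4), missing_rate=0.02, seed=9)
        g1, r1 = simulate_cohort(spec)
        g2, r2 = simulate_cohort(spec)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert g1.samples.equals(g2.samples)
        assert all(
            np.array_equal(a.variant_idx, b.variant_idx) for a, b in zip(r1, r2)
        )

    def test_panmictic_maf_tracks_ancestral(self):
        """fst=0, one subpop: realized MAF within binomial error of drawn AF."""
        spec = CohortSpec(
            n_cases=500, n_controls=500, n_genes=60, variants_per_gene=(20, 30),
            sfs_weights=(0.0, 0.0, 0.5, 0.5), ld_copy_prob=0.0,
            enforce_categories=False, seed=3,
        )
        geno, _ = simulate_cohort(spec)
        n_hap = 2 * geno.n_samples
        p = geno.variants["true_af"].to_numpy()
        realized = np.nansum(geno.dosages, axis=0) / n_hap
        se = np.sqrt(p * (1 - p) / n_hap)
        z = (realized - p) / np.maximum(se, 1e-9)
        assert len(p) >= 1000
        assert np.mean(np.abs(z) < 3.5) > 0.99

    def test_realized_sfs_matches_weights(self):
        """Rare-only spectrum realizes its target proportions within 3 points."""
        weights = (0.145, 0.518, 0.337, 0.0)
        spec = CohortSpec(
            n_cases=1500, n_controls=1500, n_genes=60, variants_per_gene=(20, 30),
            sfs_weights=weights, seed=5,
        )
        geno, _ = simulate_cohort(spec)
        stats = variant_stats_table(geno.dosages)
        counts = stats["category"].value_counts(normalize=True)
        for cat, target in zip(("singleton", "very_rare", "rare_strict"), weights):
            assert abs(counts.get(cat, 0.0) - target) < 0.03, cat

    def test_singletons_have_mac_exactly_one(self):
        spec = CohortSpec(n_cases=200, n_controls=200, n_genes=10,
                          sfs_weights=(1.0, 0.0, 0.0, 0.0), seed=1)
        geno, _ = simulate_cohort(spec)
        assert (column_macs(geno.dosages) == 1).all()

    def test_infeasible_sfs_raises(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_cases=5, n_controls=5, sfs_weights=(0.0, 0.5, 0.25, 0.25))

    def test_ld_blocks_raise_neighbor_correlation(self):
        spec = CohortSpec(
            n_cases=400, n_controls=400, n_genes=20, variants_per_gene=(20, 20),
            sfs_weights=(0.0, 0.0, 0.0, 1.0), ld_block_size=5, ld_copy_prob=0.9,
            seed=2,
        )
        geno, regions = simulate_cohort(spec)
        within, across = [], []
        for reg in regions:
            idx = reg.variant_idx
            for j in range(1, len(idx)):
                r = abs(np.corrcoef(geno.dosages[:, idx[j - 1]],
                                    geno.dosages[:, idx[j]])[0, 1])
                (across if j % 5 == 0 else within).append(r)
        assert np.mean(within) > 5 * np.mean(across)

    def test_missingness_rate_realized(self):
        spec = CohortSpec(n_cases=300, n_controls=300, n_genes=10,
                          sfs_weights=(0.1, 0.0, 0.4, 0.5), missing_rate=0.05, seed=4)
        geno, _ = simulate_cohort(spec)
        assert np.isnan(geno.dosages).mean() == pytest.approx(0.05, abs=0.01)

    def test_info_scores_within_interval(self):
        spec = CohortSpec(n_cases=50, n_controls=50, n_genes=4,
                          sfs_weights=(0.2, 0.0, 0.4, 0.4),
                          info_score_dist=(0.7, 0.95), seed=6)
        geno, _ = simulate_cohort(spec)
        info = geno.variants["info_score"].to_numpy()
        assert info.min() >= 0.7 and info.max() <= 0.95


class TestSpikeEffects:
    @staticmethod
    def _pool(seed=11, n=2000):
        spec = CohortSpec(
            n_cases=n // 2, n_controls=n // 2, n_genes=4,
            variants_per_gene=(20, 20), sfs_weights=(0.1, 0.0, 0.5, 0.4), seed=seed,
        )
        return simulate_cohort(spec)

    def test_null_effects_recover_prevalence(self):
        geno, regions = self._pool()
        pheno = spike_effects(geno, regions, [], baseline_prevalence=0.3, seed=1)
        prev = pheno["status"].mean()
        se = np.sqrt(0.3 * 0.7 / len(pheno))
        assert abs(prev - 0.3) < 4 * se

    def test_risk_effect_recovered_by_burden_test(self):
        """beta = ln 2 spiked on one gene: its own 95% CI covers OR 2."""
        geno, regions = self._pool(seed=12, n=4000)
        eff = [EffectSpec(gene_id=regions[0].gene_id, beta=np.log(2.0))]
        pheno = spike_effects(geno, regions, eff, baseline_prevalence=0.5, seed=2)
        geno.samples = pheno
        scores = minor_oriented(geno.dosages[:, regions[0].variant_idx]).sum(axis=1)
        res = burden_test(scores, pheno["status"].to_numpy())
        assert res.ci95_lo < 2.0 < res.ci95_hi

    def test_protective_effect_gives_or_below_one(self):
        geno, regions = self._pool(seed=13, n=4000)
        eff = [EffectSpec(gene_id=regions[0].gene_id, beta=-np.log(2.0))]
        pheno = spike_effects(geno, regions, eff, baseline_prevalence=0.5, seed=3)
        scores = minor_oriented(geno.dosages[:, regions[0].variant_idx]).sum(axis=1)
        res = burden_test(scores, pheno["status"].to_numpy())
        assert res.or_ < 1.0

    def test_unknown_gene_errors(self):
        geno, regions = self._pool(n=200)
        with pytest.raises(KeyError):
            spike_effects(geno, regions, [EffectSpec("NOPE", 0.5)], 0.5, seed=1)

    def test_direction_consistency_enforced(self):
        with pytest.raises(ValueError):
            EffectSpec("G", beta=0.5, direction="protective")

    def test_subsample_errors_when_pool_too_small(self):
        geno, regions = self._pool(n=200)
        pheno = spike_effects(geno, regions, [], 0.1, seed=1)
        with pytest.raises(ValueError, match="larger pool"):
            subsample_case_control(geno, pheno, 150, 50, seed=1)


class TestSimulateAnnotations:
    def test_zero_probability_empty_table(self):
        t = simulate_annotations([f"G{i}" for i in range(100)], 0.0, 1.0, seed=1)
        assert len(t) == 0

    def test_causal_boost_raises_annotation_rate(self):
        genes = [f"G{i}" for i in range(4000)]
        causal = genes[:2000]
        t = simulate_annotations(genes, 0.2, 2.5, seed=2, causal_genes=causal)
        ann = set(t["gene_id"])
        rate_causal = np.mean([g in ann for g in causal])
        rate_other = np.mean([g in ann for g in genes[2000:]])
        assert rate_causal > 1.8 * rate_other

    def test_pairs_unique(self):
        t = simulate_annotations(
            [f"G{i}" for i in range(300)], 0.5, 1.0, seed=3, diseases_per_gene=(1, 4)
        )
        assert not t.duplicated().any()

    def test_invalid_boost_errors(self):
        with pytest.raises(ValueError):
            simulate_annotations(["A"], 0.6, 2.0, seed=1)
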