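"""Quality control: GWAS-scaffold filters and post-imputation filters.

Two stages are distinguished.  The scaffold stage applies the classical
case-control GWAS filters (sample/variant call rate, MAF >= 1%,
Hardy-Weinberg equilibrium, differential missingness between cases and
controls, relatedness).  The post-imputation stage keeps reliably imputed
variants (info score >= 0.75, variant call rate >= 99%, sample call rate
>= 95%) with deliberately NO allele-frequency restriction, so rare and
low-frequency variants enter the association tests.

All thresholds are inclusive on the "keep" side (>= for rates and
p-values, < for kinship).  Missing dosages are excluded from every count
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency, fisher_exact

from raregene.containers import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """All QC cutoffs, defaulting to the stringent values used genome-wide."""

    sample_call_rate_min: float = 0.90
    variant_call_rate_min: float = 0.98
    maf_min: float = 0.01  # scaffold stage only
    hwe_p_min_all: float = 1e-4
    hwe_p_min_controls: float = 0.01
    diff_missing_p_max: float = 1e-5
    kinship_max: float = 0.055
    imp_info_min: float = 0.75
    imp_variant_call_min: float = 0.99
    imp_sample_call_min: float = 0.95

    def __post_init__(self) -> None:
        for name, val in self.__dict__.items():
            if name == "kinship_max":
                continue
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1]")


@dataclass
class QCReport:
    """Ordered log of filter application with per-step removal counts."""

    steps: list[dict] = field(default_factory=list)

    def record(
        self,
        stage: str,
        axis: str,
        n_removed: int,
        n_samples: int,
        n_variants: int,
    ) -> None:
        self.steps.append(
            {
                "stage": stage,
                "axis": axis,
                "n_removed": int(n_removed),
                "n_samples_after": int(n_samples),
                "n_variants_after": int(n_variants),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps,
            columns=["stage", "axis", "n_removed", "n_samples_after", "n_variants_after"],
        )

    def total_removed(self, axis: str) -> int:
        return sum(s["n_removed"] for s in self.steps if s["axis"] == axis)


def hwe_exact_test(n_aa_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test for one biallelic variant.

    Conditions on the total sample size and minor-allele count and sums
    the probabilities of every heterozygote configuration whose
    probability does not exceed that of the observed one.  Returns a
    p-value in (0, 1].
    """
    counts = (n_aa_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = 2 * min(n_aa_hom_major, n_hom_minor) + n_het
    # minor-allele copies; orient so `rare` is the smaller allele count
    if rare > n:
        rare = 2 * n - rare

    def log_prob(h: int) -> float:
        # P(n_het = h | n, rare) under HWE, via log factorials
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
            + h * np.log(2.0)
            + gammaln(rare + 1)
            + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    log_p = np.array([log_prob(int(h)) for h in hets])
    probs = np.exp(log_p - log_p.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def differential_missingness_test(
    miss_cases: int, obs_cases: int, miss_controls: int, obs_controls: int
) -> float:
    """2x2 test of genotype missingness versus case/control status.

    Uses Fisher's exact test when any expected cell count is below 5,
    otherwise a 1-df chi-square without continuity correction.
    """
    table = np.array([[miss_cases, obs_cases], [miss_controls, obs_controls]])
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        raise ValueError("all counts are zero")
    if miss_cases + miss_controls == 0:
        return 1.0  # no missing data, nothing to test
    if table.sum(axis=1).min() == 0:
        return 1.0  # one status stratum absent
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        return float(fisher_exact(table)[1])
    return float(chi2_contingency(table, correction=False)[1])


def kinship_estimate(
    dosages_i: np.ndarray, dosages_j: np.ndarray, min_overlap: int = 100
) -> tuple[float, bool]:
    """Robust pairwise kinship coefficient from two dosage vectors.

    phi_hat = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j)),
    evaluated over jointly called sites.  Returns ``(phi, reliable)``;
    pairs with fewer than ``min_overlap`` jointly called genotypes are
    flagged unreliable (and retained by the filter).
    """
    a = np.asarray(dosages_i, dtype=float)
    b = np.asarray(dosages_j, dtype=float)
    joint = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[joint], b[joint]
    het_a, het_b = a == 1, b == 1
    n_hh = int((het_a & het_b).sum())
    n_opp = int(((a == 0) & (b == 2)).sum() + ((a == 2) & (b == 0)).sum())
    denom = int(het_a.sum() + het_b.sum())
    phi = (n_hh - 2.0 * n_opp) / denom if denom else 0.0
    return float(phi), bool(joint.sum() >= min_overlap)


def _kinship_matrix(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs kinship and overlap counts, vectorized."""
    called = ~np.isnan(dosages)
    d = np.nan_to_num(dosages, nan=-9.0)
    het = (d == 1).astype(float)
    hom0 = (d == 0).astype(float)
    hom2 = (d == 2).astype(float)
    m = called.astype(float)
    n_hh = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_joint = het @ m.T  # het sites of i that are called in j
    denom = het_joint + het_joint.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hh - 2.0 * n_opp) / np.where(denom, denom, 1), 0.0)
    overlap = m @ m.T
    return phi, overlap


def _check_nonempty(geno: GenotypeMatrix, stage: str) -> None:
    if geno.n_samples == 0 or geno.n_variants == 0:
        raise RuntimeError(f"QC stage {stage!r} removed every sample or variant")


def apply_scaffold_qc(
    geno: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    min_kinship_overlap: int = 100,
) -> tuple[GenotypeMatrix, QCReport]:
    """GWAS-scaffold QC in fixed, logged order.

    Samples by call rate -> variants by call rate -> MAF -> HWE (whole
    sample at ``hwe_p_min_all`` AND controls only at
    ``hwe_p_min_controls``) -> differential missingness -> relatedness
    (from each flagged pair, the lower-call-rate member is removed; ties
    broken by sample order).
    """
    t = thresholds or QCThresholds()
    report = QCReport()
    g = geno

    # 1. sample call rate
    keep = g.sample_call_rates() >= t.sample_call_rate_min
    report.record("sample_call_rate", "samples", (~keep).sum(), keep.sum(), g.n_variants)
    g = g.take_samples(np.flatnonzero(keep))
    _check_nonempty(g, "sample_call_rate")

    # 2. variant call rate
    keep = g.variant_call_rates() >= t.variant_call_rate_min
    report.record("variant_call_rate", "variants", (~keep).sum(), g.n_samples, keep.sum())
    g = g.take_variants(np.flatnonzero(keep))
    _check_nonempty(g, "variant_call_rate")

    # 3. MAF (scaffold stage only)
    mafs = np.array(
        [_maf_of_column(g.dosages[:, j]) for j in range(g.n_variants)]
    )
    keep = mafs >= t.maf_min
    report.record("maf", "variants", (~keep).sum(), g.n_samples, keep.sum())
    g = g.take_variants(np.flatnonzero(keep))
    _check_nonempty(g, "maf")

    # 4. HWE: whole sample and controls only
    status = g.status
    controls = np.flatnonzero(status == 0)
    keep = np.ones(g.n_variants, dtype=bool)
    for j in range(g.n_variants):
        p_all = hwe_exact_test(*_genotype_counts(g.dosages[:, j]))
        p_ctl = hwe_exact_test(*_genotype_counts(g.dosages[controls, j]))
        keep[j] = p_all >= t.hwe_p_min_all and p_ctl >= t.hwe_p_min_controls
    report.record("hwe", "variants", (~keep).sum(), g.n_samples, keep.sum())
    g = g.take_variants(np.flatnonzero(keep))
    _check_nonempty(g, "hwe")

    # 5. differential missingness
    cases = status == 1
    keep = np.ones(g.n_variants, dtype=bool)
    for j in range(g.n_variants):
        miss = np.isnan(g.dosages[:, j])
        p = differential_missingness_test(
            int((miss & cases).sum()),
            int((~miss & cases).sum()),
            int((miss & ~cases).sum()),
            int((~miss & ~cases).sum()),
        )
        keep[j] = p >= t.diff_missing_p_max
    report.record("diff_missingness", "variants", (~keep).sum(), g.n_samples, keep.sum())
    g = g.take_variants(np.flatnonzero(keep))
    _check_nonempty(g, "diff_missingness")

    # 6. relatedness
    phi, overlap = _kinship_matrix(g.dosages)
    call = g.sample_call_rates()
    n = g.n_samples
    drop = np.zeros(n, dtype=bool)
    iu = np.triu_indices(n, k=1)
    flagged = (phi[iu] >= t.kinship_max) & (overlap[iu] >= min_kinship_overlap)
    for i, j in zip(iu[0][flagged], iu[1][flagged]):
        if drop[i] or drop[j]:
            continue
        # drop lower call rate; tie -> later sample
        drop[j if call[j] <= call[i] else i] = True
    report.record("kinship", "samples", drop.sum(), (~drop).sum(), g.n_variants)
    g = g.take_samples(np.flatnonzero(~drop))
    _check_nonempty(g, "kinship")

    return g, report


def apply_imputation_qc(
    geno: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Post-imputation QC: info score and call rates, NO MAF restriction."""
    t = thresholds or QCThresholds()
    report = QCReport()
    info = geno.variants["info_score"].to_numpy(dtype=float)
    if np.isnan(info).any():
        raise ValueError("imputation QC requires an info score for every variant")

    keep = (info >= t.imp_info_min) & (
        geno.variant_call_rates() >= t.imp_variant_call_min
    )
    report.record(
        "imputation_variant", "variants", (~keep).sum(), geno.n_samples, keep.sum()
    )
    g = geno.take_variants(np.flatnonzero(keep))
    _check_nonempty(g, "imputation_variant")

    keep = g.sample_call_rates() >= t.imp_sample_call_min
    report.record("imputation_sample", "samples", (~keep).sum(), keep.sum(), g.n_variants)
    g = g.take_samples(np.flatnonzero(keep))
    _check_nonempty(g, "imputation_sample")
    return g, report


def _maf_of_column(col: np.ndarray) -> float:
    called = col[~np.isnan(col)]
    if called.size == 0:
        return 0.0
    freq = called.sum() / (2 * called.size)
    return float(min(freq, 1.0 - freq))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    called = col[~np.isnan(col)]
    return int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())
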