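"""Synthetic case-control cohorts with population structure and rare variation.

The generator emulates the statistical structure a gene-centered
rare-variant association analysis assumes: a stratified cohort whose
subpopulations diverge under a Balding-Nichols model, a rare-skewed site
frequency spectrum (singletons, very rare, strict-sense rare and common
variants), block-diagonal linkage disequilibrium induced by latent-uniform
haplotype copying, genotype missingness, fabricated imputation info
scores, spiked per-gene risk or protective burden effects, and a
gene-disease annotation table enriched for causal genes.

Nothing here attempts demographic realism (no recombination maps, no
sequencing error); the goal is a cohort whose ground truth is known so
every downstream stage can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from raregene.containers import (
    GeneRegion,
    GenotypeMatrix,
    make_sample_frame,
    make_variant_frame,
)

#: SFS category labels, ordered from rarest to common
SFS_CATEGORIES = ("singleton", "very_rare", "rare_strict", "common")

#: MAF bounds separating very rare / strict-sense rare / common variation
VERY_RARE_MAF_MAX = 0.001
RARE_MAF_MAX = 0.01


class ConfigurationError(ValueError):
    """Raised when a cohort specification is internally infeasible."""


@dataclass
class CohortSpec:
    """Configuration of a synthetic case-control cohort.

    Defaults describe a single-population European-like cohort at reduced
    scale with the rare-skewed spectrum observed in dense imputed data
    (roughly half the polymorphic sites rare, and among those rare sites
    singletons : very rare : strict-rare close to 14.5 : 51.8 : 33.7).
    """

    n_cases: int = 600
    n_controls: int = 600
    n_subpops: int = 1
    fst: float = 0.0
    #: per-status subpop proportions; rows = (controls, cases).  None means
    #: uniform in both strata (no stratification confounding).
    subpop_mixing: np.ndarray | None = None
    n_genes: int = 20
    variants_per_gene: tuple[int, int] = (10, 30)
    #: target proportions for (singleton, very_rare, rare_strict, common)
    sfs_weights: tuple[float, float, float, float] = (0.074, 0.264, 0.172, 0.490)
    ld_block_size: int = 5
    #: probability a haplotype reuses the previous variant's latent uniform
    #: within an LD block (0 = linkage equilibrium)
    ld_copy_prob: float = 0.8
    missing_rate: float = 0.0
    info_score_dist: tuple[float, float] = (0.6, 1.0)
    #: redraw genotypes until the realized frequency category matches the
    #: drawn one (singletons are always exact); keeps realized SFS close to
    #: ``sfs_weights``
    enforce_categories: bool = True
    gene_length: int = 50_000
    gene_gap: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("n_cases and n_controls must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ConfigurationError("fst must lie in [0, 1)")
        w = np.asarray(self.sfs_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ConfigurationError(
                "sfs_weights must be 4 nonnegative proportions summing to 1"
            )
        lo, hi = self.variants_per_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError("variants_per_gene range must satisfy 1 <= lo <= hi")
        if self.subpop_mixing is not None:
            mix = np.atleast_2d(np.asarray(self.subpop_mixing, dtype=float))
            if mix.shape != (2, self.n_subpops):
                raise ConfigurationError(
                    "subpop_mixing must be a (2, n_subpops) array of proportions"
                )
            if not np.allclose(mix.sum(axis=1), 1.0):
                raise ConfigurationError("subpop_mixing rows must sum to 1")
            self.subpop_mixing = mix
        n_hap = 2 * (self.n_cases + self.n_controls)
        if w[0] > 0 and n_hap < 2:
            raise ConfigurationError("singleton category requires at least 1 sample")
        # very-rare category needs room for MAC >= 2 strictly below the MAF bound
        if w[1] > 0 and int(np.ceil(VERY_RARE_MAF_MAX * n_hap)) - 1 < 2:
            raise ConfigurationError(
                "very_rare category infeasible: fewer than 2 copies fit below "
                f"MAF {VERY_RARE_MAF_MAX:g} with {n_hap} chromosomes; "
                "increase the sample size or zero this weight"
            )


@dataclass
class EffectSpec:
    """A per-gene burden effect: log-odds per minor allele of burden."""

    gene_id: str
    beta: float
    direction: str = ""

    def __post_init__(self) -> None:
        implied = "risk" if self.beta > 0 else "protective" if self.beta < 0 else "null"
        if not self.direction:
            self.direction = implied
        elif self.direction != implied:
            raise ValueError(
                f"{self.gene_id}: direction {self.direction!r} inconsistent "
                f"with beta={self.beta}"
            )


def _sample_inverse_freq(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Draw from the density proportional to 1/p truncated to [lo, hi]."""
    return float(lo * (hi / lo) ** rng.random())


def _balding_nichols(
    rng: np.random.Generator, p: float, fst: float, k: int
) -> np.ndarray:
    """Per-subpop allele frequencies diverged from ancestral frequency p."""
    if fst == 0.0 or k == 1:
        return np.full(k, p)
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b, size=k)


def _category_of(mac: int, maf: float) -> str:
    """Frequency category of a realized variant (mirrors varclass rules)."""
    if mac == 0:
        return "non_polymorphic"
    if mac == 1:
        return "singleton"
    if maf > RARE_MAF_MAX:
        return "common"
    if maf >= VERY_RARE_MAF_MAX:
        return "rare_strict"
    return "very_rare"


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[GenotypeMatrix, list[GeneRegion]]:
    """Generate a cohort: genotypes, phenotype labels and gene regions.

    Variants are laid out gene by gene on chromosome "1".  For each variant
    an SFS category is drawn from ``spec.sfs_weights``; its ancestral minor
    allele frequency is drawn from an inverse-frequency density truncated
    to the category's bounds; subpopulation frequencies diverge under
    Balding-Nichols; haplotypes are sampled through latent uniforms that
    are copied along LD blocks with probability ``ld_copy_prob``.
    Singletons are placed as exactly one minor-allele copy.  Deterministic
    for a fixed ``spec.seed``.

    Returns the genotype matrix (phenotype labels in ``.samples``) and the
    gene regions with assigned variant indices.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    n_hap = 2 * n
    status = np.concatenate([np.ones(spec.n_cases, int), np.zeros(spec.n_controls, int)])

    # subpop per sample, drawn per status stratum
    if spec.n_subpops == 1:
        subpop = np.zeros(n, dtype=int)
    else:
        mix = (
            spec.subpop_mixing
            if spec.subpop_mixing is not None
            else np.full((2, spec.n_subpops), 1.0 / spec.n_subpops)
        )
        subpop = np.empty(n, dtype=int)
        for s in (0, 1):
            rows = np.flatnonzero(status == s)
            subpop[rows] = rng.choice(spec.n_subpops, size=rows.size, p=mix[s])
    hap_subpop = np.repeat(subpop, 2)  # haplotypes interleaved per sample

    maf_lo = {
        "very_rare": 2.0 / n_hap,
        "rare_strict": VERY_RARE_MAF_MAX,
        "common": RARE_MAF_MAX,
    }
    maf_hi = {
        "very_rare": VERY_RARE_MAF_MAX,
        "rare_strict": RARE_MAF_MAX,
        "common": 0.5,
    }

    dosage_cols: list[np.ndarray] = []
    true_afs: list[float] = []
    positions: list[int] = []
    regions: list[GeneRegion] = []
    lo, hi = spec.variants_per_gene
    cursor = 1
    vcursor = 0
    for g in range(spec.n_genes):
        m_g = int(rng.integers(lo, hi + 1))
        start = cursor
        end = start + spec.gene_length - 1
        pos_g = np.sort(
            rng.choice(np.arange(start, end + 1), size=m_g, replace=False)
        )
        prev_u: np.ndarray | None = None
        for j in range(m_g):
            in_block = j % spec.ld_block_size != 0 and prev_u is not None
            cat = SFS_CATEGORIES[int(rng.choice(4, p=np.asarray(spec.sfs_weights)))]
            if cat == "singleton":
                col = np.zeros(n)
                col[rng.integers(n)] = 1.0
                dosage_cols.append(col)
                true_afs.append(1.0 / n_hap)
                prev_u = None  # singletons break LD chains
            else:
                max_tries = 50 if spec.enforce_categories else 1
                for attempt in range(max_tries):
                    p = _sample_inverse_freq(rng, maf_lo[cat], maf_hi[cat])
                    p_sub = _balding_nichols(rng, p, spec.fst, spec.n_subpops)
                    if attempt == 0 and in_block:
                        copy = rng.random(n_hap) < spec.ld_copy_prob
                        u = np.where(copy, prev_u, rng.random(n_hap))
                    else:
                        u = rng.random(n_hap)
                    hap = (u < p_sub[hap_subpop]).astype(float)
                    col = hap[0::2] + hap[1::2]
                    mac = int(min(col.sum(), n_hap - col.sum()))
                    if not spec.enforce_categories or _category_of(
                        mac, mac / n_hap
                    ) == cat:
                        break
                dosage_cols.append(col)
                true_afs.append(p)
                prev_u = u
        positions.extend(pos_g.tolist())
        regions.append(
            GeneRegion(
                gene_id=f"GENE{g:04d}",
                chrom="1",
                start=start,
                end=end,
                variant_idx=np.arange(vcursor, vcursor + m_g),
            )
        )
        vcursor += m_g
        cursor = end + spec.gene_gap + 1

    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((n, 0))

    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages = np.where(mask, np.nan, dosages)

    info = rng.uniform(*spec.info_score_dist, size=dosages.shape[1])
    variants = make_variant_frame(
        chrom="1",
        pos=np.asarray(positions, dtype=int),
        ids=[f"1:{p}" for p in positions],
        info_score=info,
    )
    variants["true_af"] = np.asarray(true_afs)
    samples = make_sample_frame(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        status=status,
        subpop=[f"POP{k}" for k in subpop],
    )
    return GenotypeMatrix(dosages, samples, variants), regions


def _minor_dosages(geno: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Minor-allele-oriented dosage submatrix (missing -> 0)."""
    sub = geno.dosages[:, idx]
    sub = np.nan_to_num(sub, nan=0.0)
    n_called = (~np.isnan(geno.dosages[:, idx])).sum(axis=0)
    flip = sub.sum(axis=0) > n_called  # ALT frequency > 0.5
    sub[:, flip] = 2.0 - sub[:, flip]
    return sub


def spike_effects(
    geno: GenotypeMatrix,
    regions: Sequence[GeneRegion],
    effects: Sequence[EffectSpec],
    baseline_prevalence: float,
    seed: int,
) -> pd.DataFrame:
    """Redraw case/control status under a logistic burden-effect model.

    logit P(case_i) = alpha + sum_g beta_g * burden_g(i), where burden_g
    is sample i's minor-allele sum over gene g's variants and alpha is
    solved numerically so the population prevalence equals
    ``baseline_prevalence``.  Returns a new phenotype table (sample frame)
    aligned with ``geno.samples``.
    """
    if not (0.0 < baseline_prevalence < 1.0):
        raise ValueError("baseline_prevalence must lie in (0, 1)")
    by_id = {r.gene_id: r for r in regions}
    eta = np.zeros(geno.n_samples)
    for eff in effects:
        if eff.gene_id not in by_id:
            raise KeyError(f"effect gene {eff.gene_id!r} has no GeneRegion")
        burden = _minor_dosages(geno, by_id[eff.gene_id].variant_idx).sum(axis=1)
        eta += eff.beta * burden

    def mean_prev(alpha: float) -> float:
        return float(expit(alpha + eta).mean()) - baseline_prevalence

    alpha = brentq(mean_prev, -30.0, 30.0)
    rng = np.random.default_rng(seed)
    status = (rng.random(geno.n_samples) < expit(alpha + eta)).astype(int)
    pheno = geno.samples.copy()
    pheno["status"] = status
    return pheno


def subsample_case_control(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    seed: int,
) -> GenotypeMatrix:
    """Subsample a spiked pool to fixed case/control counts.

    Raises if the pool holds too few of either status (generate a larger
    pool and retry).
    """
    status = pheno["status"].to_numpy(dtype=int)
    cases = np.flatnonzero(status == 1)
    controls = np.flatnonzero(status == 0)
    if cases.size < n_cases or controls.size < n_controls:
        raise ValueError(
            f"pool holds {cases.size} cases / {controls.size} controls, "
            f"need {n_cases}/{n_controls}; simulate a larger pool"
        )
    rng = np.random.default_rng(seed)
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(cases, size=n_cases, replace=False),
                rng.choice(controls, size=n_controls, replace=False),
            ]
        )
    )
    out = geno.take_samples(keep)
    out.samples = pheno.iloc[keep].reset_index(drop=True)
    return out


def simulate_annotations(
    genes: Sequence[str],
    p_annotated: float,
    causal_boost: float,
    seed: int,
    causal_genes: Sequence[str] = (),
    diseases_per_gene: int | tuple[int, int] = 1,
) -> pd.DataFrame:
    """Fabricate a gene-disease annotation table.

    Each gene is annotated with probability ``p_annotated``
    (``p_annotated * causal_boost`` for genes in ``causal_genes``); an
    annotated gene receives between 1 and ``diseases_per_gene`` disease
    entries.  Returns a DataFrame with unique (gene_id, disease_id) pairs.
    """
    p_causal = p_annotated * causal_boost
    if not (0.0 <= p_causal <= 1.0) or not (0.0 <= p_annotated <= 1.0):
        raise ValueError("p_annotated * causal_boost must lie in [0, 1]")
    if isinstance(diseases_per_gene, int):
        d_lo = d_hi = diseases_per_gene
    else:
        d_lo, d_hi = diseases_per_gene
    causal = set(causal_genes)
    rng = np.random.default_rng(seed)
    rows = []
    disease_no = 0
    for gene in genes:
        p = p_causal if gene in causal else p_annotated
        if rng.random() < p:
            for _ in range(int(rng.integers(d_lo, d_hi + 1))):
                rows.append((gene, f"DIS{disease_no:05d}"))
                disease_no += 1
    return pd.DataFrame(rows, columns=["gene_id", "disease_id"])
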