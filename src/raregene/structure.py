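"""Population-structure covariates and genomic-control correction.

Stratification is handled twice: principal components of a standardized
genotype matrix enter the association models as covariates, and any
residual inflation of the gene-level test statistics is removed by
genomic control — the median observed 1-df chi-square divided by its
theoretical median (0.4549) gives the inflation factor lambda, and every
statistic is deflated by lambda before conversion back to a p-value.
Lambda is estimated separately per test family (burden, SKAT) because the
two statistics inflate differently under the same structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from raregene.ldprune import pairwise_r2

logger = logging.getLogger(__name__)

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(chi2.ppf(0.5, df=1))


@dataclass
class PCSet:
    """Principal-component coordinates and diagnostics."""

    coords: np.ndarray  # (n_samples, k)
    variance_explained: np.ndarray  # fraction per component
    marker_idx: np.ndarray  # markers the PCA used


@dataclass
class LambdaGC:
    """Genomic inflation factor for one family of tests."""

    lam: float
    n_tests: int
    source: str = ""

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lambda must be positive")
        logger.info("lambda_GC(%s) = %.2f over %d tests", self.source, self.lam, self.n_tests)


def select_informative_markers(
    dosages: np.ndarray,
    group_labels: np.ndarray,
    k: int,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Pick ancestry-informative, mutually independent markers.

    Markers are ranked by the maximum pairwise absolute allele-frequency
    difference across groups and accepted greedily subject to pairwise
    r^2 < ``r2_max`` with already-accepted markers, until ``k`` are
    accepted or candidates are exhausted (then all accepted are returned
    with a warning).
    """
    groups = np.unique(np.asarray(group_labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    m = dosages.shape[1]
    freqs = np.empty((len(groups), m))
    for gi, g in enumerate(groups):
        sub = dosages[np.asarray(group_labels) == g, :]
        with np.errstate(invalid="ignore"):
            freqs[gi] = np.nanmean(sub, axis=0) / 2.0
    max_diff = np.zeros(m)
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            max_diff = np.maximum(max_diff, np.abs(freqs[a] - freqs[b]))
    order = np.argsort(-max_diff, kind="stable")
    accepted: list[int] = []
    for j in order:
        if all(
            pairwise_r2(dosages[:, j], dosages[:, a]) < r2_max for a in accepted
        ):
            accepted.append(int(j))
        if len(accepted) == k:
            return np.asarray(accepted)
    logger.warning(
        "only %d of %d requested informative markers acceptable", len(accepted), k
    )
    return np.asarray(accepted)


def pca(dosages: np.ndarray, k: int = 10, marker_idx: np.ndarray | None = None) -> PCSet:
    """Standardized-genotype PCA (plain SVD, no outlier iterations).

    Each marker column is centered by twice its allele frequency and
    scaled by sqrt(2 p (1-p)); missing genotypes become 0 after
    centering.  Constant markers are skipped with a log entry.  The sign
    of each component is fixed by forcing its largest-magnitude sample
    loading positive.
    """
    if marker_idx is not None:
        dosages = dosages[:, np.asarray(marker_idx)]
    else:
        marker_idx = np.arange(dosages.shape[1])
    n, m = dosages.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k} components")
    with np.errstate(invalid="ignore"):
        p_hat = np.nanmean(dosages, axis=0) / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    with np.errstate(invalid="ignore"):
        col_var = np.nanvar(dosages, axis=0)
    usable = np.isfinite(scale) & (scale > 0) & (col_var > 0)
    if not usable.all():
        logger.info("pca: skipping %d constant/all-missing markers", (~usable).sum())
    x = (dosages[:, usable] - 2.0 * p_hat[usable]) / scale[usable]
    x = np.nan_to_num(x, nan=0.0)
    k_eff = min(k, n - 1, int(usable.sum()))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k_eff] * s[:k_eff]
    # deterministic sign: largest-magnitude coordinate positive
    for c in range(k_eff):
        top = np.argmax(np.abs(coords[:, c]))
        if coords[top, c] < 0:
            coords[:, c] *= -1.0
    total_var = float((s**2).sum())
    var_exp = (s[:k_eff] ** 2) / total_var if total_var > 0 else np.zeros(k_eff)
    return PCSet(
        coords=coords,
        variance_explained=var_exp,
        marker_idx=np.asarray(marker_idx)[usable],
    )


def genomic_lambda(p_values: np.ndarray, source: str = "") -> LambdaGC:
    """Genomic inflation factor from a family of raw p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, df=1)
    lam = float(np.median(stats) / CHI2_1DF_MEDIAN)
    return LambdaGC(lam=lam, n_tests=int(p.size), source=source)


def gc_correct(p_values: np.ndarray, lam: float) -> np.ndarray:
    """Deflate p-values by lambda through the 1-df chi-square scale.

    Each p maps to its chi-square quantile, is divided by lambda, and
    maps back.  lambda = 1 is the identity; lambda > 1 strictly
    increases every p < 1; ordering is preserved.
    """
    if not lam > 0:
        raise ValueError("lambda must be positive")
    p = np.asarray(p_values, dtype=float)
    if lam == 1.0:
        return p.copy()
    stats = chi2.isf(p, df=1)
    return chi2.sf(stats / lam, df=1)
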