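"""Pairwise r-squared and greedy LD pruning to an independent marker set.

Association tests that aggregate several markers are vulnerable to
collinearity from linkage disequilibrium, so the pipeline works on a set
of mutually independent markers defined by a restrictive threshold of
r^2 < 0.1.  r^2 here is the squared Pearson correlation of unphased
dosage vectors (composite LD) over jointly called samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_R2 = 0.1


@dataclass
class PruneResult:
    """Outcome of greedy pruning: kept and removed variant indices."""

    kept: np.ndarray
    removed: np.ndarray
    #: for each removed index, the kept index whose LD triggered removal
    trigger: dict[int, int] = field(default_factory=dict)


def pairwise_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Composite-LD r^2 between two dosage columns.

    Computed over jointly called samples; a column monomorphic on the
    joint support has undefined correlation and is treated as r^2 = 0.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    joint = ~np.isnan(a) & ~np.isnan(b)
    if joint.sum() < 2:
        raise ValueError("need at least 2 jointly called samples")
    a, b = a[joint], b[joint]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        logger.debug("monomorphic column on joint support; r^2 treated as 0")
        return 0.0
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def _window_r2(dosages: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """r^2 matrix among the given columns (missing-aware, vectorized)."""
    sub = dosages[:, idx]
    k = len(idx)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            try:
                out[a, b] = out[b, a] = pairwise_r2(sub[:, a], sub[:, b])
            except ValueError:
                out[a, b] = out[b, a] = 0.0
    return out


def prune(
    dosages: np.ndarray,
    mafs: np.ndarray | None = None,
    threshold: float = DEFAULT_R2,
    window: int = 50,
    step: int = 5,
) -> PruneResult:
    """Sliding-window greedy pruning of position-sorted variants.

    Within each window, for any kept pair with r^2 >= threshold the
    member with the lower MAF is removed (tie: later position); the
    window then slides by ``step`` variants.  Stable for fixed input.
    """
    from raregene.varclass import minor_allele_stats

    m = dosages.shape[1]
    if mafs is None:
        mafs = np.array([minor_allele_stats(dosages[:, j]).maf for j in range(m)])
    keep = np.ones(m, dtype=bool)
    trigger: dict[int, int] = {}
    start = 0
    while start < m:
        idx = np.flatnonzero(keep[start : start + window]) + start
        if len(idx) > 1:
            r2 = _window_r2(dosages, idx)
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if not keep[idx[b]]:
                        continue
                    if r2[a, b] >= threshold:
                        # drop lower MAF; tie -> later position
                        if mafs[idx[a]] < mafs[idx[b]]:
                            victim, holder = idx[a], idx[b]
                        else:
                            victim, holder = idx[b], idx[a]
                        keep[victim] = False
                        trigger[int(victim)] = int(holder)
                        if victim == idx[a]:
                            break
        if start + window >= m:
            break
        start += step
    return PruneResult(
        kept=np.flatnonzero(keep),
        removed=np.flatnonzero(~keep),
        trigger=trigger,
    )
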