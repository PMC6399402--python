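"""Core in-memory containers shared by every pipeline stage.

Genotypes live in a samples x variants dosage matrix (float64; 0/1/2 minor
allele... strictly ALT-allele counts; ``NaN`` marks a missing genotype).
Variant and sample metadata ride along as pandas DataFrames so that
filtering stages can subset rows/columns while keeping everything aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: columns every variant table carries
VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "info_score", "annotation"]

#: columns every sample table carries (subpop is synthetic-only, may be "")
SAMPLE_COLUMNS = ["sample_id", "status", "subpop"]


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-dosage matrix with aligned metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` float array with values in {0, 1, 2}
        and ``NaN`` for missing genotypes.
    samples
        DataFrame with columns ``sample_id``, ``status`` (0 control /
        1 case), ``subpop``.
    variants
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``id``,
        ``ref``, ``alt``, ``info_score`` (NaN if unknown), ``annotation``
        (functional category label, "" if absent).
    """

    dosages: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(
                f"sample table has {len(self.samples)} rows for {n} dosage rows"
            )
        if len(self.variants) != m:
            raise ValueError(
                f"variant table has {len(self.variants)} rows for {m} dosage columns"
            )
        called = self.dosages[~np.isnan(self.dosages)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be in {0, 1, 2} or NaN")
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def status(self) -> np.ndarray:
        """Case/control status as an int array (1 = case)."""
        return self.samples["status"].to_numpy(dtype=int)

    # -- subsetting ------------------------------------------------------
    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample indices."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            samples=self.samples.iloc[index].reset_index(drop=True),
            variants=self.variants.copy(),
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given variant indices."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            samples=self.samples.copy(),
            variants=self.variants.iloc[index].reset_index(drop=True),
        )

    # -- call rates ------------------------------------------------------
    def sample_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def variant_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), self.samples.copy(), self.variants.copy()
        )


@dataclass
class GeneRegion:
    """A named 1-based inclusive genomic interval with assigned variants.

    The ``buffer`` records the flank used when extracting genotypes for
    imputation context; association testing uses only the gene body
    ``[start, end]``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    buffer: int = 500_000
    variant_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        self.variant_idx = np.asarray(self.variant_idx, dtype=int)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def with_variants(self, idx: np.ndarray) -> "GeneRegion":
        return replace(self, variant_idx=np.asarray(idx, dtype=int))


def make_variant_frame(
    chrom,
    pos,
    ids=None,
    ref=None,
    alt=None,
    info_score=None,
    annotation=None,
) -> pd.DataFrame:
    """Assemble a variant metadata frame, filling optional columns."""
    pos = np.asarray(pos, dtype=int)
    m = len(pos)
    chrom = np.broadcast_to(np.asarray(chrom, dtype=object), (m,))
    frame = pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "pos": pos,
            "id": ids if ids is not None else [f"var{i}" for i in range(m)],
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["G"] * m,
            "info_score": info_score if info_score is not None else np.nan,
            "annotation": annotation if annotation is not None else "",
        }
    )
    return frame[VARIANT_COLUMNS]


def make_sample_frame(sample_ids, status, subpop=None) -> pd.DataFrame:
    """Assemble a sample metadata frame."""
    n = len(sample_ids)
    frame = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "status": np.asarray(status, dtype=int),
            "subpop": subpop if subpop is not None else [""] * n,
        }
    )
    return frame[SAMPLE_COLUMNS]
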