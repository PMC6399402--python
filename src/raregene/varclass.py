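"""Minor-allele accounting and rare-variant categorization.

Rare variation (MAF < 1%) is split into three categories that differ
sharply in imputation reliability and in how many minor alleles they
contribute to aggregate tests:

* ``singleton`` — minor allele observed on exactly one chromosome
  (MAC = 1);
* ``very_rare`` — MAC > 1 with MAF below 0.1%;
* ``rare_strict`` — 0.1% <= MAF <= 1% ("rare in a strict sense").

MAF exactly 0.1% is assigned to ``rare_strict`` so the two intervals
partition.  Variants with MAF > 1% are ``common``; monomorphic columns
get the distinct ``non_polymorphic`` label.  MAF/MAC are computed over
called genotypes of the combined case+control sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VERY_RARE_MAF_MAX = 0.001  # 0.1%
RARE_MAF_MAX = 0.01  # 1%

RARE_CATEGORIES = ("singleton", "very_rare", "rare_strict")
ALL_CATEGORIES = RARE_CATEGORIES + ("common",)
NON_POLYMORPHIC = "non_polymorphic"


@dataclass
class VariantStats:
    """Per-variant minor-allele summary over called genotypes."""

    maf: float
    mac: int
    n_called: int
    call_rate: float
    category: str
    minor_is_alt: bool


def minor_allele_stats(dosages: np.ndarray) -> VariantStats:
    """Summarize one dosage column (ALT counts, NaN missing).

    The minor allele is the lower-frequency allele over the combined
    sample; at a 0.5 tie the ALT allele is designated minor.  MAC and MAF
    use called genotypes only.
    """
    col = np.asarray(dosages, dtype=float)
    called = col[~np.isnan(col)]
    if called.size == 0:
        raise ValueError("variant has no called genotypes")
    n_chrom = 2 * called.size
    alt_count = int(round(called.sum()))
    minor_is_alt = alt_count <= n_chrom - alt_count  # tie -> ALT minor
    mac = alt_count if minor_is_alt else n_chrom - alt_count
    maf = mac / n_chrom
    return VariantStats(
        maf=maf,
        mac=mac,
        n_called=int(called.size),
        call_rate=called.size / col.size,
        category=classify_rare(mac, maf),
        minor_is_alt=minor_is_alt,
    )


def column_mafs(dosages: np.ndarray) -> np.ndarray:
    """Vectorized per-column MAF over called genotypes (NaN if none)."""
    d = np.asarray(dosages, dtype=float)
    called = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(d, axis=0) / (2.0 * called)
    return np.where(called > 0, np.minimum(freq, 1.0 - freq), np.nan)


def column_macs(dosages: np.ndarray) -> np.ndarray:
    """Vectorized per-column minor-allele count over called genotypes."""
    d = np.asarray(dosages, dtype=float)
    called = (~np.isnan(d)).sum(axis=0)
    alt = np.round(np.nansum(d, axis=0)).astype(int)
    return np.minimum(alt, 2 * called - alt)


def classify_rare(mac: int, maf: float) -> str:
    """Assign the frequency category for a (MAC, MAF) pair.

    Categories are exhaustive and mutually exclusive for polymorphic
    variants; MAF exactly at the 0.1% boundary falls in ``rare_strict``.
    """
    if mac < 0:
        raise ValueError("mac must be nonnegative")
    if mac == 0:
        return NON_POLYMORPHIC
    if mac == 1:
        return "singleton"
    if maf > RARE_MAF_MAX:
        return "common"
    if maf >= VERY_RARE_MAF_MAX:
        return "rare_strict"
    return "very_rare"


def variant_stats_table(geno_dosages: np.ndarray) -> pd.DataFrame:
    """Per-variant stats for a dosage matrix, as a DataFrame."""
    rows = [minor_allele_stats(geno_dosages[:, j]) for j in range(geno_dosages.shape[1])]
    return pd.DataFrame(
        {
            "maf": [r.maf for r in rows],
            "mac": [r.mac for r in rows],
            "n_called": [r.n_called for r in rows],
            "call_rate": [r.call_rate for r in rows],
            "category": [r.category for r in rows],
            "minor_is_alt": [r.minor_is_alt for r in rows],
        }
    )


def tally_categories(stats: pd.DataFrame) -> pd.DataFrame:
    """Tally rare-variant counts and minor-allele sums per category.

    ``stats`` is a :func:`variant_stats_table` frame restricted to
    polymorphic rare variants (MAF <= 1%).  Returns one row per rare
    category plus a "total" row, with variant counts, minor-allele sums
    (sum of MAC) and column percentages.  Singleton minor-allele sum
    equals the singleton count by construction.
    """
    bad = stats[~stats["category"].isin(RARE_CATEGORIES)]
    if len(bad):
        raise ValueError(
            f"{len(bad)} variants are not polymorphic-rare; filter before tallying"
        )
    counts = {c: int((stats["category"] == c).sum()) for c in RARE_CATEGORIES}
    allele_sums = {
        c: int(stats.loc[stats["category"] == c, "mac"].sum()) for c in RARE_CATEGORIES
    }
    return tally_from_counts(counts, allele_sums)


def tally_from_counts(
    counts: dict[str, int], allele_sums: dict[str, int]
) -> pd.DataFrame:
    """Build the category tally (with percentages) from raw counts.

    Percentages are of each column total; an empty input yields an
    all-zero tally.
    """
    total_n = sum(counts.values())
    total_a = sum(allele_sums.values())
    rows = []
    for c in RARE_CATEGORIES:
        n = counts.get(c, 0)
        a = allele_sums.get(c, 0)
        rows.append(
            {
                "category": c,
                "n_variants": n,
                "pct_variants": 100.0 * n / total_n if total_n else 0.0,
                "n_minor_alleles": a,
                "pct_minor_alleles": 100.0 * a / total_a if total_a else 0.0,
            }
        )
    rows.append(
        {
            "category": "total",
            "n_variants": total_n,
            "pct_variants": 100.0 if total_n else 0.0,
            "n_minor_alleles": total_a,
            "pct_minor_alleles": 100.0 if total_a else 0.0,
        }
    )
    return pd.DataFrame(rows)


def functional_tally(
    annotations: pd.Series | np.ndarray,
    independent: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tally functional-annotation categories, full vs pruned set.

    Parameters
    ----------
    annotations
        Functional category label per variant ("" or NaN counted as
        "unannotated").
    independent
        Optional boolean mask of variants surviving LD pruning; when
        given, a second pair of columns restricted to that set is added.

    Returns a frame with per-category counts and percentages (of the
    respective column total), sorted by descending full-set count.
    """
    ann = pd.Series(annotations, dtype=object).fillna("").replace("", "unannotated")

    def one(labels: pd.Series, suffix: str) -> pd.DataFrame:
        counts = labels.value_counts()
        total = int(counts.sum())
        return pd.DataFrame(
            {
                f"n{suffix}": counts,
                f"pct{suffix}": 100.0 * counts / total if total else 0.0,
            }
        )

    out = one(ann, "_all")
    if independent is not None:
        pruned = one(ann[np.asarray(independent, dtype=bool)], "_pruned")
        out = out.join(pruned, how="outer").fillna(0.0)
        out[["n_all", "n_pruned"]] = out[["n_all", "n_pruned"]].astype(int)
    out.index.name = "annotation"
    return out.sort_values("n_all", ascending=False).reset_index()
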