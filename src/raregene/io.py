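"""Readers and writers for the standard interchange formats.

Conventions, applied once at the boundary:

* VCF v4.2 — GT genotypes mapped to ALT-dosage {0, 1, 2}; ``./.`` is
  missing; the per-variant imputation quality rides in the INFO field
  under the key ``INFO`` (float); multi-allelic records are split into
  biallelic records with a warning.  Positions are 1-based as in VCF.
* BED — 0-based half-open on disk, converted to 1-based inclusive
  :class:`~raregene.containers.GeneRegion` internally.
* Phenotype table — TSV with columns sample_id, status (0 control /
  1 case), subpop.
* Dosage TSV — samples x variants matrix, ``NA`` missing; a convenient
  dialect for tests that bypass VCF.
* Gene-disease table — TSV with columns gene_id, disease_id.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from raregene.containers import (
    GeneRegion,
    GenotypeMatrix,
    make_sample_frame,
    make_variant_frame,
)
from raregene.qc import QCThresholds

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed VCF v4.2 with GT genotypes."""
    path = Path(path)
    v = geno.variants
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=INFO,Number=1,Type=Float,Description='
            '"Imputation info score">\n'
        )
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples["sample_id"].astype(str))
            + "\n"
        )
        for j in range(geno.n_variants):
            info = v["info_score"].iat[j]
            info_str = "." if pd.isna(info) else f"INFO={float(info):.4f}"
            gts = "\t".join(
                "./." if np.isnan(d) else _GT_STRINGS[d] for d in geno.dosages[:, j]
            )
            fh.write(
                f"{v['chrom'].iat[j]}\t{v['pos'].iat[j]}\t{v['id'].iat[j]}\t"
                f"{v['ref'].iat[j]}\t{v['alt'].iat[j]}\t.\t.\t{info_str}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path, pheno: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    Multi-allelic records are split into one biallelic record per ALT
    allele (with a warning); duplicate variant IDs are suffixed.  If a
    phenotype table is given, statuses are joined on sample_id (every
    VCF sample must appear).
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    dosage_cols: list[np.ndarray] = []
    rows: list[dict] = []
    n_multi = 0
    for rec in vcf:
        alts = rec.ALT or ["."]
        if len(alts) > 1:
            n_multi += 1
        gts = np.array([g[:2] for g in rec.genotypes], dtype=int)
        info = rec.INFO.get("INFO")
        for k, alt in enumerate(alts, start=1):
            col = (gts == k).sum(axis=1).astype(float)
            col[(gts[:, 0] < 0) | (gts[:, 1] < 0)] = np.nan
            dosage_cols.append(col)
            rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            if len(alts) > 1:
                rid = f"{rid}_alt{k}"
            rows.append(
                {
                    "chrom": str(rec.CHROM),
                    "pos": int(rec.POS),
                    "id": rid,
                    "ref": rec.REF,
                    "alt": alt,
                    "info_score": np.nan if info is None else float(info),
                    "annotation": "",
                }
            )
    if n_multi:
        logger.warning("split %d multi-allelic records into biallelic records", n_multi)
    variants = pd.DataFrame(rows) if rows else make_variant_frame("1", [])
    dup = variants["id"].duplicated(keep=False)
    if dup.any():
        logger.info("suffixing %d duplicate variant IDs", int(dup.sum()))
        counts: dict[str, int] = {}
        new_ids = []
        for vid, is_dup in zip(variants["id"], dup):
            if is_dup:
                counts[vid] = counts.get(vid, 0) + 1
                new_ids.append(f"{vid}.{counts[vid]}")
            else:
                new_ids.append(vid)
        variants["id"] = new_ids
    dosages = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(sample_ids), 0))
    )
    if pheno is not None:
        lookup = pheno.set_index("sample_id")
        missing = [s for s in sample_ids if s not in lookup.index]
        if missing:
            raise ValueError(f"samples absent from phenotype table: {missing[:5]}")
        status = lookup.loc[sample_ids, "status"].to_numpy(dtype=int)
        subpop = (
            lookup.loc[sample_ids, "subpop"].astype(str).tolist()
            if "subpop" in lookup.columns
            else None
        )
    else:
        status = np.zeros(len(sample_ids), dtype=int)
        subpop = None
    samples = make_sample_frame(sample_ids, status, subpop)
    return GenotypeMatrix(dosages, samples, variants)


# ---------------------------------------------------------------------------
# dosage TSV dialect
# ---------------------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        geno.dosages,
        index=geno.samples["sample_id"],
        columns=geno.variants["id"],
    )
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(
    path: str | Path,
    variants: pd.DataFrame | None = None,
    pheno: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    dosages = frame.to_numpy(dtype=float)
    if variants is None:
        variants = make_variant_frame(
            "1", np.arange(1, frame.shape[1] + 1), ids=list(frame.columns)
        )
    if pheno is not None:
        lookup = pheno.set_index("sample_id")
        status = lookup.loc[frame.index, "status"].to_numpy(dtype=int)
    else:
        status = np.zeros(frame.shape[0], dtype=int)
    samples = make_sample_frame(list(frame.index), status)
    return GenotypeMatrix(dosages, samples, variants)


# ---------------------------------------------------------------------------
# phenotype / annotation / gene-disease TSVs
# ---------------------------------------------------------------------------

def write_phenotypes(samples: pd.DataFrame, path: str | Path) -> None:
    samples[["sample_id", "status", "subpop"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "status"} <= set(frame.columns):
        raise ValueError("phenotype table needs sample_id and status columns")
    return frame


def write_gene_disease(table: pd.DataFrame, path: str | Path) -> None:
    table[["gene_id", "disease_id"]].to_csv(path, sep="\t", index=False)


def read_gene_disease(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "disease_id"} <= set(frame.columns):
        raise ValueError("gene-disease table needs gene_id and disease_id columns")
    return frame.drop_duplicates()


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Variant functional annotations: TSV (variant_id, category)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"variant_id", "category"} <= set(frame.columns):
        raise ValueError("annotation table needs variant_id and category columns")
    return frame


# ---------------------------------------------------------------------------
# BED gene regions
# ---------------------------------------------------------------------------

def write_bed(regions: list[GeneRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open)."""
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\n")


def read_bed(path: str | Path, buffer: int = 500_000) -> list[GeneRegion]:
    """Read BED regions, converting to 1-based inclusive coordinates."""
    regions = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED line needs 4 columns")
            chrom, start0, end0, name = parts[:4]
            regions.append(
                GeneRegion(
                    gene_id=name,
                    chrom=chrom,
                    start=int(start0) + 1,
                    end=int(end0),
                    buffer=buffer,
                )
            )
    return regions


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the stringent analysis
    thresholds (QC cutoffs, r^2 < 0.1, 10 PCs, 1,000 permutations,
    alpha = 0.05)."""

    genotypes: str = ""
    phenotypes: str = ""
    regions: str = ""
    annotations: str = ""
    gene_disease: str = ""
    out_dir: str = "raregene_out"
    #: when set, simulate a cohort with these CohortSpec overrides
    #: instead of reading genotype inputs
    simulate: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    run_scaffold_qc: bool = False
    r2_threshold: float = 0.1
    prune_window: int = 50
    prune_step: int = 5
    prune_scope: str = "gene"  # gene | global
    k_pcs: int = 10
    skat_weights: str = "beta:1,25"
    maf_max: float = 0.01
    n_perm: int = 1000
    alpha: float = 0.05
    enrich_replicates: int = 1000
    seed: int = 0

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(**self.thresholds)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def write_table(frame: pd.DataFrame, path: str | Path, header: dict | None = None) -> None:
    """Write a TSV with '#'-prefixed provenance header lines."""
    with Path(path).open("w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
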