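"""End-to-end driver: QC -> prune -> test -> correct -> select -> enrich.

The driver consumes already-imputed genotypes (or simulates a cohort),
applies post-imputation QC, computes stratification covariates, prunes
to the independent marker set, runs both per-gene tests, applies
genomic-control and pooled-permutation corrections, selects candidates
by the SKAT-AND-burden rule and, when a gene-disease table is available,
tests the candidate list for annotation enrichment.  Every output table
carries a provenance header with the thresholds and seeds that produced
it, and a machine-readable manifest records the whole run.

The classical GWAS-scaffold QC stage targets the genotyping-array
scaffold that precedes imputation (its MAF >= 1% filter would be wrong
for imputed rare variants); it is therefore off by default here and can
be enabled for scaffold-stage inputs with ``run_scaffold_qc``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from raregene import __version__
from raregene.containers import GeneRegion, GenotypeMatrix
from raregene.correction import (
    apply_genomic_control,
    build_pooled_table,
    candidate_table,
    empirical_correct,
    select_candidates,
)
from raregene.enrichment import EnrichmentResult, enrichment_test
from raregene.genetests import assign_variants, run_all_genes
from raregene.io import (
    RunConfig,
    read_annotations,
    read_bed,
    read_gene_disease,
    read_phenotypes,
    read_vcf,
    write_table,
)
from raregene.ldprune import prune
from raregene.qc import apply_imputation_qc, apply_scaffold_qc
from raregene.results import GeneAssociationResult
from raregene.structure import pca
from raregene.synthcohort import (
    CohortSpec,
    EffectSpec,
    simulate_cohort,
    spike_effects,
    subsample_case_control,
)
from raregene.varclass import tally_categories, functional_tally, variant_stats_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory bundle of everything a pipeline run produced."""

    geno: GenotypeMatrix
    regions: list[GeneRegion]
    results: list[GeneAssociationResult]
    candidates: list[GeneAssociationResult]
    lambda_burden: float
    lambda_skat: float
    tally: pd.DataFrame
    enrichment: EnrichmentResult | None
    manifest: dict
    kept_variants: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def simulate_inputs(
    config: RunConfig,
) -> tuple[GenotypeMatrix, list[GeneRegion]]:
    """Materialize a synthetic cohort from the config's ``simulate`` block.

    Optional keys ``effects`` (list of {gene_id, beta}) and
    ``prevalence`` spike per-gene burden effects: a pool three times the
    requested size is generated, statuses are redrawn under the logistic
    burden model, and cases/controls are subsampled to the requested
    counts.
    """
    sim = dict(config.simulate)
    effects = [EffectSpec(**e) for e in sim.pop("effects", [])]
    prevalence = sim.pop("prevalence", 0.5)
    pool_factor = sim.pop("pool_factor", 3)
    sim.setdefault("seed", config.seed)
    if not effects:
        return simulate_cohort(CohortSpec(**sim))
    target = CohortSpec(**sim)
    pool_spec = CohortSpec(
        **{
            **sim,
            "n_cases": int(pool_factor * (target.n_cases + target.n_controls) / 2),
            "n_controls": int(pool_factor * (target.n_cases + target.n_controls) / 2),
        }
    )
    pool, regions = simulate_cohort(pool_spec)
    pheno = spike_effects(pool, regions, effects, prevalence, seed=pool_spec.seed + 1)
    geno = subsample_case_control(
        pool, pheno, target.n_cases, target.n_controls, seed=pool_spec.seed + 2
    )
    return geno, regions


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in order, writing per-stage artifacts.

    A stage failure aborts with the stage name; artifacts written by
    earlier stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "raregene_version": __version__,
        "seed": config.seed,
        "r2_threshold": config.r2_threshold,
        "k_pcs": config.k_pcs,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
    }
    manifest: dict = {
        "config": {k: v for k, v in vars(config).items()},
        "versions": {
            "raregene": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            try:
                value = fn()
            except Exception as exc:
                _write_manifest(manifest, out)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
            return value

        return deco

    # ---- input ---------------------------------------------------------
    @stage("input")
    def loaded():
        if config.simulate:
            return simulate_inputs(config)
        pheno = read_phenotypes(config.phenotypes) if config.phenotypes else None
        geno = read_vcf(config.genotypes, pheno)
        regions = read_bed(config.regions)
        if config.annotations:
            ann = read_annotations(config.annotations).set_index("variant_id")
            geno.variants["annotation"] = (
                geno.variants["id"].map(ann["category"]).fillna("")
            )
        return geno, regions

    geno, regions = loaded

    # ---- QC ------------------------------------------------------------
    @stage("qc")
    def qc_out():
        g = geno
        reports = []
        if config.run_scaffold_qc:
            g, rep = apply_scaffold_qc(g, config.qc_thresholds())
            reports.append(rep.to_frame().assign(block="scaffold"))
        g, rep = apply_imputation_qc(g, config.qc_thresholds())
        reports.append(rep.to_frame().assign(block="imputation"))
        write_table(pd.concat(reports), out / "qc_report.tsv", provenance)
        return g

    geno = qc_out
    regions = assign_variants(regions, geno.variants)
    manifest["post_qc"] = {"n_samples": geno.n_samples, "n_variants": geno.n_variants}

    # ---- structure covariates -----------------------------------------
    @stage("structure")
    def pcs():
        stats = variant_stats_table(geno.dosages)
        common = np.flatnonzero(stats["category"] == "common")
        if common.size > 5000:
            common = common[:: common.size // 5000 + 1]
        k = min(config.k_pcs, geno.n_samples - 1, max(int(common.size) - 1, 1))
        pcset = pca(geno.dosages, k=k, marker_idx=common)
        frame = pd.DataFrame(
            pcset.coords, columns=[f"PC{i+1}" for i in range(pcset.coords.shape[1])]
        )
        frame.insert(0, "sample_id", geno.samples["sample_id"])
        write_table(frame, out / "pcs.tsv", provenance)
        return pcset

    covariates = pcs.coords

    # ---- LD pruning ----------------------------------------------------
    @stage("prune")
    def kept():
        if config.prune_scope == "global":
            res = prune(
                geno.dosages,
                threshold=config.r2_threshold,
                window=config.prune_window,
                step=config.prune_step,
            )
            keep = res.kept
        else:  # per gene region; markers outside every gene are kept
            in_gene = np.zeros(geno.n_variants, dtype=bool)
            keep_mask = np.ones(geno.n_variants, dtype=bool)
            for region in regions:
                idx = region.variant_idx
                if idx.size == 0:
                    continue
                fresh = idx[~in_gene[idx]]  # overlapping genes: prune once
                in_gene[idx] = True
                if fresh.size < 2:
                    continue
                res = prune(
                    geno.dosages[:, fresh],
                    threshold=config.r2_threshold,
                    window=config.prune_window,
                    step=config.prune_step,
                )
                removed = fresh[res.removed]
                keep_mask[removed] = False
            keep = np.flatnonzero(keep_mask)
        pd.Series(geno.variants["id"].iloc[keep]).to_csv(
            out / "kept_markers.list", index=False, header=False
        )
        return keep

    pruned = geno.take_variants(kept)
    regions_p = assign_variants(regions, pruned.variants, log_empty=False)
    manifest["post_prune"] = {"n_variants": pruned.n_variants}

    # ---- variant accounting -------------------------------------------
    @stage("classify")
    def tally():
        stats = variant_stats_table(pruned.dosages)
        rare = stats[stats["category"].isin(("singleton", "very_rare", "rare_strict"))]
        t = tally_categories(rare)
        write_table(t, out / "tally_rare.tsv", provenance)
        if (geno.variants["annotation"] != "").any():
            keep_mask = np.zeros(geno.n_variants, dtype=bool)
            keep_mask[kept] = True
            ft = functional_tally(geno.variants["annotation"], keep_mask)
            write_table(ft, out / "functional_tally.tsv", provenance)
        return t

    # ---- association tests --------------------------------------------
    @stage("test")
    def tested():
        res = run_all_genes(
            pruned,
            regions_p,
            covariates,
            weights=config.skat_weights,
            maf_max=config.maf_max,
        )
        if not res:
            logger.warning("no testable genes")
        return res

    results = tested
    if not results:
        _write_manifest(manifest, out)
        return PipelineResult(
            pruned, regions_p, [], [], np.nan, np.nan, tally, None, manifest, kept
        )

    # ---- corrections ---------------------------------------------------
    @stage("correct")
    def lambdas():
        lam_b, lam_s = apply_genomic_control(results)
        pooled = build_pooled_table(pruned, regions_p, config.maf_max)
        empirical_correct(
            results,
            pooled,
            pruned.status,
            covariates,
            lam_b.lam,
            lam_s.lam,
            n_perm=config.n_perm,
            seed=config.seed,
            weights=config.skat_weights,
        )
        return lam_b.lam, lam_s.lam

    lam_burden, lam_skat = lambdas
    manifest["lambda_gc"] = {"burden": lam_burden, "skat": lam_skat}

    # ---- selection -----------------------------------------------------
    @stage("select")
    def selected():
        if config.alpha >= 1.0:  # no filtering: keep every testable gene
            for r in results:
                r.selected = r.burden.testable and r.skat.testable
            chosen = [r for r in results if r.selected]
        else:
            chosen = select_candidates(results, config.alpha)
        write_table(
            candidate_table(results, config.n_perm),
            out / "results.tsv",
            {**provenance, "lambda_burden": f"{lam_burden:.2f}",
             "lambda_skat": f"{lam_skat:.2f}"},
        )
        write_table(
            candidate_table(chosen, config.n_perm), out / "candidates.tsv", provenance
        )
        return chosen

    # ---- enrichment ----------------------------------------------------
    @stage("enrich")
    def enrich():
        if not config.gene_disease or not selected:
            return None
        table = read_gene_disease(config.gene_disease)
        universe = [r.gene_id for r in results]
        cand = [r.gene_id for r in selected]
        if len(cand) >= len(universe):
            logger.warning("candidate list equals universe; enrichment skipped")
            return None
        er = enrichment_test(
            cand, universe, table, n_replicates=config.enrich_replicates,
            seed=config.seed,
        )
        write_table(
            pd.DataFrame([vars(er)]), out / "enrichment.tsv", provenance
        )
        return er

    manifest["n_candidates"] = len(selected)
    _write_manifest(manifest, out)
    config.to_yaml(out / "config_used.yaml")
    return PipelineResult(
        geno=pruned,
        regions=regions_p,
        results=results,
        candidates=selected,
        lambda_burden=lam_burden,
        lambda_skat=lam_skat,
        tally=tally,
        enrichment=enrich,
        manifest=manifest,
        kept_variants=kept,
    )


def _write_manifest(manifest: dict, out: Path) -> None:
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
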