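"""End-to-end pipeline: phenotyping -> markers -> scan -> matrix -> crosses.

Runs the full analysis either on a simulated panel (when the run config
carries a simulation config) or on genotype/phenotype/metadata files, and
writes every result table plus a machine-readable run summary into the
output directory.  All randomness flows from the single seed recorded in the
summary, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as hio
from .allele_matrix import (QtlAlleleMatrix, build_matrix, change_accounting,
                            new_locus_detection, presence_sets, venn_summary)
from .association import AssociationResult, run_scan, stage1_scan
from .config import ConfigError, RunConfig
from .cross_sim import (GeneticMapConfig, cross_potential, enumerate_crosses,
                        predict_progeny_phenotype, simulate_derived_lines,
                        summarize_groups)
from .phenotyping import (accession_means, adjust_block_means,
                          compare_subpopulations, distribution_summary,
                          heritability_by_timepoint, select_best_measurement)
from .simulate import simulate_phenotypes, simulate_population
from .snpldb import (SnpPanel, assemble_snpldb, eigen_covariates, filter_maf,
                     partition_blocks, similarity_matrix)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-labelled and re-raised
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the result bundle.

    The bundle maps stage names to in-memory results; all artifact files are
    written under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": {
            "maf_floor": config.maf_floor,
            "alpha1": config.alpha1,
            "alpha": config.alpha,
            "eigen_share": config.eigen_share,
            "cm_per_mb": config.cm_per_mb,
            "n_progeny": config.n_progeny,
        },
        "counts": {},
    }
    bundle: dict = {}

    # ---- inputs ------------------------------------------------------------
    panel, phenotypes, truth = _load_inputs(config)
    bundle["panel"], bundle["truth"] = panel, truth
    summary["counts"]["n_accessions"] = panel.n_accessions
    summary["counts"]["n_snps_input"] = panel.n_snps

    # ---- phenotyping -------------------------------------------------------
    pheno = _phenotyping_stage(phenotypes, out)
    bundle["phenotyping"] = pheno
    summary["counts"]["best_timepoint"] = pheno["best_timepoint"]
    summary["h2_best"] = pheno["h2_by_timepoint"][pheno["best_timepoint"]]

    # ---- genotype processing ----------------------------------------------
    geno = _genotype_stage(config, panel, out)
    bundle["genotypes"] = geno
    summary["counts"]["n_snps_removed_maf"] = geno["n_removed"]
    summary["counts"]["n_snps_kept"] = geno["panel"].n_snps
    summary["counts"]["n_markers"] = len(geno["markers"])
    summary["counts"]["n_eigenvectors"] = geno["covariates"].m

    # ---- association -------------------------------------------------------
    y = pheno["means"].reindex(panel.accession_ids).to_numpy()
    if np.isnan(y).any():
        raise PipelineError("stage 'association' failed: accessions without "
                            "phenotype means")
    assoc = _association_stage(config, y, geno, out)
    bundle["association"] = assoc
    summary["counts"]["n_preselected"] = assoc.n_preselected
    summary["counts"]["n_qtls"] = len(assoc.records)
    summary["model_r2_pct"] = assoc.model_r2_pct

    # ---- allele matrix & evolution accounting ------------------------------
    matrix_stage = _matrix_stage(panel, assoc, out)
    bundle["allele_matrix"] = matrix_stage
    summary["counts"]["n_alleles"] = sum(r.n_alleles for r in assoc.records)

    # ---- cross simulation --------------------------------------------------
    crosses = _cross_stage(config, panel, assoc, matrix_stage["matrix"], out)
    bundle["crosses"] = crosses
    summary["counts"]["n_crosses"] = len(crosses["predictions"])

    if truth is not None:
        hio.write_json(truth.to_dict(), out / "ground_truth.json")
    hio.write_json(summary, out / "summary.json")
    bundle["summary"] = summary
    return bundle


# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig):
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        panel, truth = simulate_population(sim)
        phenotypes = simulate_phenotypes(panel, truth, sim)
        return panel, phenotypes, truth
    panel = hio.read_genotypes(config.genotype_path, config.genotype_format)
    if config.metadata_path is not None:
        meta = hio.read_metadata(config.metadata_path)
        lookup = dict(zip(meta["accession_id"], meta["subpop"]))
        panel.subpop = np.array([lookup.get(a, "") for a in panel.accession_ids])
    if config.phenotype_path is None:
        raise ConfigError("file-based runs need a phenotype table")
    phenotypes = hio.read_phenotypes(config.phenotype_path)
    return panel, phenotypes, None


@_stage("phenotyping")
def _phenotyping_stage(phenotypes: pd.DataFrame, out: Path) -> dict:
    h2s = heritability_by_timepoint(phenotypes)
    best = select_best_measurement(h2s)
    means = accession_means(phenotypes, best)
    best_rows = phenotypes[phenotypes["timepoint"] == best]
    acc = (best_rows.groupby("accession_id", observed=True)
           .agg(value=("value", "mean"), subpop=("subpop", "first"))
           .reset_index())
    lo, hi = acc["value"].min(), acc["value"].max()
    midpoints = np.round(np.linspace(lo, hi, 11), 4)
    dist = distribution_summary(acc["value"], acc["subpop"], midpoints)
    comparison = compare_subpopulations(acc["value"], acc["subpop"])
    pd.DataFrame({"timepoint": range(len(h2s)), "h2": h2s}).to_csv(
        out / "heritability_by_timepoint.tsv", sep="\t", index=False)
    dist.to_csv(out / "trait_distribution.tsv", sep="\t", index=False)
    comparison.to_csv(out / "subpop_comparison.tsv", sep="\t", index=False)
    hio.write_phenotypes(phenotypes, out / "phenotypes.csv")
    return {"h2_by_timepoint": h2s, "best_timepoint": best, "means": means,
            "distribution": dist, "comparison": comparison}


@_stage("genotype_processing")
def _genotype_stage(config: RunConfig, panel: SnpPanel, out: Path) -> dict:
    filtered, n_removed = filter_maf(panel, config.maf_floor)
    blocks = partition_blocks(
        filtered,
        max_span_bp=config.max_block_span_bp,
        strong_ci_low=config.strong_ci_low,
        strong_ci_high=config.strong_ci_high,
        recomb_ci_high=config.recomb_ci_high,
        strong_fraction=config.strong_fraction,
    )
    markers = assemble_snpldb(filtered, blocks, maf_floor=config.maf_floor)
    sim = similarity_matrix(markers)
    cov = eigen_covariates(sim, share=config.eigen_share)
    hio.write_marker_definitions(markers, out / "marker_definitions.tsv")
    hio.write_marker_codes(markers, panel.accession_ids, out / "marker_codes.tsv")
    return {"panel": filtered, "blocks": blocks, "markers": markers,
            "similarity": sim, "covariates": cov, "n_removed": n_removed}


@_stage("association")
def _association_stage(config: RunConfig, y: np.ndarray, geno: dict,
                       out: Path) -> AssociationResult:
    markers = geno["markers"]
    W = geno["covariates"].W
    result = run_scan(y, W, markers, alpha1=config.alpha1, alpha=config.alpha)
    rows = [{
        "qtl": r.marker_id, "chrom": r.chrom, "start": r.start, "end": r.end,
        "n_alleles": r.n_alleles, "neg_lg_p": round(r.neg_lg_p, 2),
        "r2_pct": round(r.r2_pct, 2),
    } for r in result.records]
    pd.DataFrame(rows, columns=["qtl", "chrom", "start", "end", "n_alleles",
                                "neg_lg_p", "r2_pct"]).to_csv(
        out / "qtl_table.tsv", sep="\t", index=False)
    eff_rows = [
        {"qtl": r.marker_id, "allele": a, "effect": e}
        for r in result.records for a, e in r.effects.items()
    ]
    pd.DataFrame(eff_rows, columns=["qtl", "allele", "effect"]).to_csv(
        out / "allele_effects.tsv", sep="\t", index=False)
    # Manhattan / QQ data: stage-1 marginal scan over all markers
    hits = stage1_scan(y, W, markers, alpha1=1.0)
    man = pd.DataFrame([{
        "marker_id": h.marker.marker_id, "chrom": h.marker.chrom,
        "pos": h.marker.start, "neg_lg_p": -np.log10(max(h.p_value, 1e-300)),
    } for h in hits])
    man.to_csv(out / "manhattan.tsv", sep="\t", index=False)
    if len(man):
        obs = np.sort(man["neg_lg_p"].to_numpy())[::-1]
        exp = -np.log10((np.arange(1, len(obs) + 1) - 0.5) / len(obs))
        pd.DataFrame({"expected": exp, "observed": obs}).to_csv(
            out / "qq.tsv", sep="\t", index=False)
    (out / "scan_trace.txt").write_text("\n".join(result.trace) + "\n")
    return result


@_stage("allele_matrix")
def _matrix_stage(panel: SnpPanel, assoc: AssociationResult, out: Path) -> dict:
    codes = {m.marker_id: m.codes for m in assoc.markers}
    matrix = build_matrix(assoc.records, codes, panel.accession_ids,
                          panel.subpop)
    presence = presence_sets(matrix)
    ledgers = {
        "LR_vs_WA": change_accounting(presence, ["WA"], ["LR"]),
        "RC_vs_LR": change_accounting(presence, ["LR"], ["RC"]),
        "LRRC_vs_WA": change_accounting(presence, ["WA"], ["LR", "RC"]),
    }
    venn = venn_summary(presence)
    new_loci = new_locus_detection(presence)
    cells = pd.DataFrame(matrix.cells, index=matrix.locus_ids,
                         columns=matrix.accession_ids)
    cells.index.name = "locus"
    cells.to_csv(out / "qtl_allele_matrix.tsv", sep="\t")
    pd.concat([l.to_frame() for l in ledgers.values()]).to_csv(
        out / "change_ledgers.tsv", sep="\t", index=False)
    pd.DataFrame([{"region": k, "n_alleles": v} for k, v in venn.items()]).to_csv(
        out / "venn_regions.tsv", sep="\t", index=False)
    pd.DataFrame(new_loci, columns=["locus", "emerged_in"]).to_csv(
        out / "new_loci.tsv", sep="\t", index=False)
    return {"matrix": matrix, "presence": presence, "ledgers": ledgers,
            "venn": venn, "new_loci": new_loci}


@_stage("cross_sim")
def _cross_stage(config: RunConfig, panel: SnpPanel, assoc: AssociationResult,
                 matrix: QtlAlleleMatrix, out: Path) -> dict:
    rng = np.random.default_rng(config.seed + 7_777_777)
    preds = []
    if len(matrix.locus_ids) == 0:
        pd.DataFrame(columns=["parent_a", "parent_b", "p50", "p99"]).to_csv(
            out / "cross_predictions.tsv", sep="\t", index=False)
        return {"predictions": [], "groups": pd.DataFrame()}
    pairs = enumerate_crosses(matrix.accession_ids, "all")
    if config.n_crosses_sample is not None and len(pairs) > config.n_crosses_sample:
        idx = rng.choice(len(pairs), size=config.n_crosses_sample, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    chrom = np.array([r.chrom for r in assoc.records])
    pos = np.array([r.start for r in assoc.records])
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    carried = matrix.carried[order]
    locus_ids = [matrix.locus_ids[i] for i in order]
    map_config = GeneticMapConfig(cm_per_mb=config.cm_per_mb)
    mu_hat = assoc.mu_hat
    acc_index = {a: i for i, a in enumerate(matrix.accession_ids)}
    subpop_of = dict(zip(matrix.accession_ids, matrix.subpop))
    for a, b in pairs:
        ga, gb = carried[:, acc_index[a]], carried[:, acc_index[b]]
        if (ga < 0).any() or (gb < 0).any():
            continue
        progeny = simulate_derived_lines(ga, gb, chrom, pos, map_config,
                                         n=config.n_progeny, seed=rng)
        values = predict_progeny_phenotype(progeny, matrix, mu_hat, locus_ids)
        preds.append(cross_potential(values, config.percentiles, a, b))
    grouping = {}
    for p in preds:
        sa, sb = subpop_of[p.parent_a], subpop_of[p.parent_b]
        grouping[(p.parent_a, p.parent_b)] = (
            sa if sa == sb else " x ".join(sorted((sa, sb))))
    groups = summarize_groups(preds, grouping)
    per_cross = pd.DataFrame([{
        "parent_a": p.parent_a, "parent_b": p.parent_b,
        "p50": p.p50, "p99": p.p99, "progeny_mean": p.progeny_mean,
    } for p in preds]).sort_values("p50", kind="mergesort")
    per_cross.to_csv(out / "cross_predictions.tsv", sep="\t", index=False)
    groups.to_csv(out / "cross_groups.tsv", sep="\t", index=False)
    return {"predictions": preds, "groups": groups}
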