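"""End-to-end orchestration: QC -> relationships -> environmental gradient ->
reaction-norm fit -> SNP effects -> annotation, with TSV outputs and a
per-stage record-count log.

All outputs are deterministic for a fixed configuration (fixed float format,
no timestamps), so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann_mod
from .config import RunConfig
from .ec import estimate_cg_blues, standardize_ec
from .gwas import (
    inflation_factor,
    inflation_factor_literal,
    ratio_fdr_estimate,
    snp_effect_table,
    stratify_shared_specific,
)
from .io import read_genotypes, read_pedigree, read_phenotypes
from .qc import filter_genotypes, filter_phenotypes
from .reaction_norm import (
    fit_ssgrn,
    genetic_correlation,
    genetic_variance_at,
    heritability_at,
)
from .relationships import build_relationships

FLOAT_FMT = "%.6g"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    outdir: Path
    files: dict
    log: list


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig, paths: dict, outdir: str | Path) -> PipelineResult:
    """Run the full analysis from input files.

    ``paths`` must provide ``pedigree``, ``genotypes``, ``descriptor_phenos``
    and ``target_phenos``; optional keys ``genes`` (BED or GFF3), ``qtl``
    (BED with trait names) and ``gene_sets`` (GMT) enable the annotation
    stage.  Writes the gradient, variance components, the per-level SNP
    table, significant-SNP windows and enrichment TSVs plus a stage log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    files: dict[str, Path] = {}

    def note(msg: str) -> None:
        log.append(msg)
        print(msg, file=sys.stderr)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, et, ev, tb):
                if et is not None:
                    raise PipelineStageError(name, ev) from ev
                return False

        return _Ctx()

    with stage("read_inputs"):
        ped = read_pedigree(paths["pedigree"])
        dialect = "ped_map" if str(paths["genotypes"]).endswith(".ped") else "raw_additive"
        geno, orphans = read_genotypes(paths["genotypes"], dialect=dialect, pedigree=ped)
        desc = read_phenotypes(paths["descriptor_phenos"])
        target = read_phenotypes(paths["target_phenos"])
        note(f"inputs: {ped.n} pedigree animals, {geno.n_animals} genotyped x "
             f"{geno.n_snps} SNPs, {len(desc)} descriptor and {len(target)} target records"
             + (f", {len(orphans)} genotyped ids outside pedigree" if orphans else ""))

    with stage("qc"):
        desc_f, rep_d = filter_phenotypes(desc)
        target_f, rep_t = filter_phenotypes(target)
        geno_f, rep_g = filter_genotypes(geno)
        qc_rows = pd.concat(
            [
                rep_d.to_frame().assign(table="descriptor_phenos"),
                rep_t.to_frame().assign(table="target_phenos"),
                rep_g.to_frame().assign(table="genotypes"),
            ]
        )
        files["qc_report"] = outdir / "qc_report.tsv"
        _write(qc_rows, files["qc_report"])
        for label, rep in (("descriptor", rep_d), ("target", rep_t), ("genotypes", rep_g)):
            for s in rep.stages:
                note(f"qc[{label}] {s.stage}: {s.n_in} -> {s.n_out}")

    with stage("relationships"):
        keep = [a for a in geno_f.animal_ids if a in set(ped.ids)]
        keep_idx = [list(geno_f.animal_ids).index(a) for a in keep]
        geno_f = geno_f.subset(animals=keep_idx)
        rel = build_relationships(ped, geno_f, blend_weight=config.blend_weight)
        note(f"relationships: A {rel['A'].n}x{rel['A'].n}, "
             f"genotyped block {geno_f.n_animals}")

    with stage("ec_descriptor"):
        blues, _ = estimate_cg_blues(desc_f, rel["H_inverse"])
        ecd = standardize_ec(blues)
        files["ec_descriptor"] = outdir / "ec_descriptor.tsv"
        _write(ecd.to_frame(), files["ec_descriptor"])
        note(f"gradient: {len(ecd.cg_ids)} CGs, ec range "
             f"[{ecd.ec.min():.3f}, {ecd.ec.max():.3f}]")

    with stage("reaction_norm"):
        target_f = target_f[target_f["cg"].isin(set(ecd.cg_ids))].reset_index(drop=True)
        if len(target_f) == 0:
            raise ValueError("no target records with a gradient level")
        rn = fit_ssgrn(target_f, ecd, rel["H_inverse"], order=config.legendre_order)
        rows = [("K_intercept_var", rn.K[0, 0])]
        if rn.K.shape[0] > 1:
            rows += [("K_cov", rn.K[0, 1]), ("K_slope_var", rn.K[1, 1])]
        for c, v in enumerate(rn.residual_class_vars, start=1):
            rows.append((f"residual_var_class{c}", v))
        for e in config.ec_levels:
            rows.append((f"genetic_var_ec{e:g}", genetic_variance_at(rn.K, e)))
            try:
                rows.append(
                    (f"h2_ec{e:g}", heritability_at(rn.K, rn.residual_class_vars, e))
                )
            except (ValueError, IndexError):
                pass
        for i, e1 in enumerate(config.ec_levels):
            for e2 in config.ec_levels[i + 1:]:
                rows.append(
                    (f"genetic_corr_ec{e1:g}_ec{e2:g}", genetic_correlation(rn.K, e1, e2))
                )
        vc = pd.DataFrame(rows, columns=["parameter", "value"])
        files["variance_components"] = outdir / "variance_components.tsv"
        _write(vc, files["variance_components"])
        note(f"reaction norm: K = {rn.K.tolist()}, converged={rn.converged}")

    with stage("snp_gwas"):
        level_names = _level_names(config.ec_levels)
        table = snp_effect_table(
            rn,
            geno_f,
            config.ec_levels,
            level_names=level_names,
            accuracy_min=config.accuracy_min,
            G=rel.get("G_blended"),
            threshold_neglog10p=config.sig_threshold_neglog10p,
            fdr_level=config.fdr_level,
        )
        files["snp_effects"] = outdir / "snp_effects.tsv"
        _write(table, files["snp_effects"])
        lam_rows = []
        sig_sets = {}
        for name in level_names:
            lam = inflation_factor(table[f"z_{name}"].to_numpy())
            lam_lit = inflation_factor_literal(table[f"p_{name}"].to_numpy())
            fdr_est = ratio_fdr_estimate(table[f"p_{name}"].to_numpy())
            n_sig = int(table[f"sig_{name}"].sum())
            sig_sets[name] = set(table.loc[table[f"sig_{name}"], "snp"])
            lam_rows.append((name, lam, lam_lit, fdr_est, n_sig))
            note(f"gwas[{name}]: lambda={lam:.3f}, n_significant={n_sig}")
        files["gwas_summary"] = outdir / "gwas_summary.tsv"
        _write(
            pd.DataFrame(
                lam_rows,
                columns=["level", "lambda", "lambda_median_p", "fdr_estimate",
                         "n_significant"],
            ),
            files["gwas_summary"],
        )
        # regional LD around the strongest marker, for association plots
        pcols = table[[f"p_{n}" for n in level_names]].min(axis=1)
        top_snp = table.loc[pcols.idxmin(), "snp"]
        ld = ann_mod.pairwise_r2(geno_f, top_snp, window_bp=2 * config.window_bp)
        files["ld_top_snp"] = outdir / "ld_top_snp.tsv"
        _write(ld, files["ld_top_snp"])
        venn = stratify_shared_specific(sig_sets)
        venn_df = pd.DataFrame(
            [("+".join(k), len(v), ";".join(sorted(v))) for k, v in sorted(venn.items())],
            columns=["levels", "n_snps", "snps"],
        )
        files["venn"] = outdir / "significant_overlap.tsv"
        _write(venn_df, files["venn"])

    if "genes" in paths:
        with stage("annotation"):
            gene_path = str(paths["genes"])
            genes = (
                ann_mod.read_gff3(gene_path)
                if gene_path.endswith((".gff", ".gff3"))
                else ann_mod.read_bed(gene_path)
            )
            qtl = None
            if "qtl" in paths:
                qtl = ann_mod.read_bed(paths["qtl"]).rename(columns={"gene_id": "trait"})
            gene_sets = ann_mod.read_gmt(paths["gene_sets"]) if "gene_sets" in paths else {}
            annset = ann_mod.AnnotationSet(genes, qtl=qtl, gene_sets=gene_sets)
            any_sig = table[[f"sig_{n}" for n in level_names]].any(axis=1)
            sig = table.loc[any_sig, ["snp", "chrom", "pos"]]
            windows = ann_mod.map_windows(sig, annset, window_bp=config.window_bp)
            files["significant_windows"] = outdir / "significant_windows.tsv"
            _write(windows, files["significant_windows"])
            hits = set(windows.loc[windows["feature"] == "gene", "id"]) & annset.background
            enr = ann_mod.hypergeom_enrichment(hits, annset, fdr_level=config.fdr_level)
            files["enrichment"] = outdir / "enrichment.tsv"
            _write(enr, files["enrichment"])
            note(f"annotation: {len(sig)} significant SNPs, {len(hits)} genes in windows, "
                 f"{int(enr['enriched'].sum()) if len(enr) else 0} enriched sets")

    files["log"] = outdir / "pipeline_log.txt"
    with open(files["log"], "w") as fh:
        fh.write("\n".join(log) + "\n")
    return PipelineResult(outdir, {k: Path(v) for k, v in files.items()}, log)


def _level_names(ec_levels) -> list[str]:
    named = {-3.0: "low", 0.0: "medium", 3.0: "high"}
    out = []
    for e in ec_levels:
        out.append(named.get(float(e), f"ec{str(float(e)).replace('-', 'm')}"))
    return out


def simulate_and_run(config: RunConfig, sim_cfg=None, outdir: str | Path = "results"):
    """Simulate a study with the generator, write its inputs, run the pipeline."""
    from .simulate import SimConfig, simulate_study, write_bundle

    outdir = Path(outdir)
    if sim_cfg is None:
        sim_cfg = SimConfig(seed=config.rng_seed)
    bundle = simulate_study(sim_cfg)
    inputs = write_bundle(bundle, outdir / "inputs")
    result = run_pipeline(config, inputs, outdir)
    return bundle, result
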