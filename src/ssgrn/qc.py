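"""Phenotype and genotype quality control with per-stage reporting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    removed: dict = field(default_factory=dict)  # reason -> list of ids


@dataclass
class QCReport:
    stages: list = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, removed: dict) -> None:
        if n_out > n_in:
            raise ValueError("n_out cannot exceed n_in")
        self.stages.append(StageReport(stage, n_in, n_out, removed))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            for reason, ids in s.removed.items():
                rows.append((s.stage, s.n_in, s.n_out, reason, len(ids)))
            if not s.removed:
                rows.append((s.stage, s.n_in, s.n_out, "", 0))
        return pd.DataFrame(rows, columns=["stage", "n_in", "n_out", "reason", "n_removed"])

    def all_removed(self) -> dict:
        out: dict = {}
        for s in self.stages:
            for reason, ids in s.removed.items():
                out.setdefault(reason, []).extend(ids)
        return out


def filter_phenotypes(
    pheno: pd.DataFrame,
    sd_bound: float = 3.5,
    min_cg: int = 5,
    value_col: str = "y",
    cg_col: str = "cg",
) -> tuple[pd.DataFrame, QCReport]:
    """Trim records beyond ``sd_bound`` SDs of their CG mean (single pass,
    moments from the incoming data, population-sd convention), then drop CGs
    left with fewer than ``min_cg`` records."""
    if cg_col not in pheno.columns:
        raise ValueError(f"phenotype table lacks CG column {cg_col!r}")
    if len(pheno) == 0:
        raise ValueError("empty phenotype table")
    report = QCReport()
    df = pheno.reset_index(drop=True)
    grp = df.groupby(cg_col)[value_col]
    mean = grp.transform("mean")
    sd = grp.transform(lambda v: v.std(ddof=0))
    out = np.abs(df[value_col] - mean) > sd_bound * sd
    removed_trim = df.loc[out, "animal"].tolist() if "animal" in df.columns else df.index[out].tolist()
    kept = df.loc[~out]
    report.add("sd_trim", len(df), len(kept), {"outside_sd_bound": removed_trim})

    sizes = kept.groupby(cg_col)[value_col].transform("size")
    small = sizes < min_cg
    removed_small = kept.loc[small, "animal"].tolist() if "animal" in kept.columns else kept.index[small].tolist()
    kept2 = kept.loc[~small]
    report.add("min_cg", len(kept), len(kept2), {"small_cg": removed_small})
    if len(kept2) == 0:
        raise ValueError("phenotype QC removed every record")
    return kept2.reset_index(drop=True), report


def exact_hwe_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact (mid-p off) two-sided Hardy-Weinberg test for a biallelic SNP.

    Enumerates all heterozygote counts compatible with the allele counts and
    sums probabilities no larger than the observed configuration's.
    """
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n = n_hom1 + n_het + n_hom2
    if n == 0 or n_rare == 0:
        return 1.0
    # recurrence over heterozygote counts of the same parity as n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i]
        hom_r = (n_rare - h) // 2  # rare homozygotes at this h
        hom_c = n - h - hom_r
        # P(h)/P(h-2) = 4*hom_r(h-2)*hom_c(h-2) / (h*(h-1)) with counts at h-2
        logp[i] = logp[i - 1] + np.log(4.0 * (hom_r + 1) * (hom_c + 1)) - np.log(h * (h - 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.where(hets == n_het)[0]
    if len(obs) == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[obs[0]]
    return float(np.minimum(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_genotypes(
    geno: GenotypeMatrix,
    maf_min: float = 0.03,
    hwe_p: float = 1e-5,
    callrate_min: float = 0.95,
    autosomes=None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Marker and sample QC in a fixed, documented order.

    1. non-autosomal SNPs removed (``autosomes`` defaults to chromosome
       labels 1..29); 2. samples with call rate < ``callrate_min``; then SNPs
       failing 3. call rate, 4. MAF < ``maf_min`` or 5. exact HWE test with
       P <= ``hwe_p``.
    """
    if geno.n_snps == 0 or geno.n_animals == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport()
    autosomes = set(str(c) for c in (autosomes or range(1, 30)))
    chrom_str = np.array([str(c) for c in geno.chrom])
    keep_snp = np.isin(chrom_str, list(autosomes))
    report.add(
        "autosomal", geno.n_snps, int(keep_snp.sum()),
        {"non_autosomal": list(geno.snp_ids[~keep_snp])},
    )
    g = geno.subset(snps=np.where(keep_snp)[0])

    cr_sample = g.sample_call_rate()
    keep_s = cr_sample >= callrate_min
    report.add(
        "sample_call_rate", g.n_animals, int(keep_s.sum()),
        {"low_sample_call_rate": list(g.animal_ids[~keep_s])},
    )
    g = g.subset(animals=np.where(keep_s)[0])
    if g.n_animals == 0:
        raise ValueError("sample call-rate filter removed every animal")

    cr_snp = g.snp_call_rate()
    keep1 = cr_snp >= callrate_min
    report.add(
        "snp_call_rate", g.n_snps, int(keep1.sum()),
        {"low_snp_call_rate": list(g.snp_ids[~keep1])},
    )
    g = g.subset(snps=np.where(keep1)[0])

    p = g.allele_freq
    maf = np.minimum(p, 1 - p)
    keep2 = np.isfinite(maf) & (maf >= maf_min)
    report.add("maf", g.n_snps, int(keep2.sum()), {"low_maf": list(g.snp_ids[~keep2])})
    g = g.subset(snps=np.where(keep2)[0])

    pvals = np.ones(g.n_snps)
    for k in range(g.n_snps):
        c = g.calls[:, k]
        pvals[k] = exact_hwe_pvalue(
            int(np.sum(c == 1)), int(np.sum(c == 0)), int(np.sum(c == 2))
        )
    keep3 = pvals > hwe_p
    report.add("hwe", g.n_snps, int(keep3.sum()), {"hwe_fail": list(g.snp_ids[~keep3])})
    g = g.subset(snps=np.where(keep3)[0])
    if g.n_snps == 0:
        raise ValueError("genotype QC removed every SNP")
    return g, report
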