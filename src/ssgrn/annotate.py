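"""Offline post-GWAS annotation: LD around top markers, gene/QTL window
mapping, and hypergeometric gene-set enrichment.

All resources are user-supplied local files (BED/GFF3 intervals, GMT gene
sets); coordinates are 1-based inclusive internally, BED input is converted
on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GenotypeMatrix


@dataclass
class AnnotationSet:
    """Gene intervals, optional QTL intervals, and named gene sets over a
    background universe."""

    genes: pd.DataFrame  # chrom, start, end, gene_id (1-based inclusive)
    qtl: pd.DataFrame | None = None  # chrom, start, end, trait
    gene_sets: dict = field(default_factory=dict)
    background: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for df, label in ((self.genes, "gene"), (self.qtl, "QTL")):
            if df is not None and len(df) and (df["start"] > df["end"]).any():
                raise ValueError(f"{label} interval with start > end")
        if not self.background:
            self.background = set(self.genes["gene_id"])
        for name, members in self.gene_sets.items():
            extra = set(members) - self.background
            if extra:
                raise ValueError(f"gene set {name!r} has members outside the background")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError("BED needs >= 4 columns (chrom, start, end, name)")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
            "gene_id": df[3],
        }
    )
    return out


def read_gff3(path: str | Path, feature_types=("gene",)) -> pd.DataFrame:
    """Gene intervals from GFF3 (already 1-based inclusive); the gene id is
    taken from the ID=, gene_id= or Name= attribute."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            if gid is None:
                continue
            rows.append((f[0], int(f[3]), int(f[4]), gid.removeprefix("gene:")))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def read_gmt(path: str | Path) -> dict:
    """Named gene sets from a GMT file (name, description, members...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            tok = line.rstrip("\n").split("\t")
            if len(tok) >= 3:
                sets[tok[0]] = set(t for t in tok[2:] if t)
    return sets


def pairwise_r2(
    geno: GenotypeMatrix, focal: str, window_bp: int
) -> pd.DataFrame:
    """Composite-LD r^2 of the focal SNP with every SNP within the window.

    r^2 is the squared correlation of dosage vectors over animals with both
    calls observed; monomorphic comparators are skipped with a note.
    """
    snp_pos = {s: k for k, s in enumerate(geno.snp_ids)}
    if focal not in snp_pos:
        raise KeyError(f"focal SNP {focal!r} not present")
    kf = snp_pos[focal]
    chrom, pos = geno.chrom[kf], geno.pos[kf]
    in_win = (np.array([str(c) for c in geno.chrom]) == str(chrom)) & (
        np.abs(geno.pos - pos) <= window_bp
    )
    xf = geno.calls[:, kf].astype(float)
    rows = []
    skipped = 0
    for k in np.where(in_win)[0]:
        xk = geno.calls[:, k].astype(float)
        both = (geno.calls[:, kf] >= 0) & (geno.calls[:, k] >= 0)
        a, b = xf[both], xk[both]
        if len(a) < 2 or a.std() == 0 or b.std() == 0:
            skipped += 1
            continue
        r = np.corrcoef(a, b)[0, 1]
        rows.append((geno.snp_ids[k], geno.chrom[k], int(geno.pos[k]), r * r))
    if skipped:
        warnings.warn(f"{skipped} monomorphic/uninformative comparators skipped")
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "r2"])


def map_windows(
    sig_snps: pd.DataFrame,
    ann: AnnotationSet,
    window_bp: int = 200_000,
) -> pd.DataFrame:
    """Genes and QTL whose interval intersects [pos - w, pos + w] (closed)
    around each significant SNP.  SNPs on chromosomes absent from the
    annotation are skipped with a warning."""
    known = set(ann.genes["chrom"].astype(str))
    if ann.qtl is not None:
        known |= set(ann.qtl["chrom"].astype(str))
    rows = []
    skipped = []
    for _, snp in sig_snps.iterrows():
        c = str(snp["chrom"])
        if c not in known:
            skipped.append(snp["snp"])
            continue
        lo, hi = snp["pos"] - window_bp, snp["pos"] + window_bp
        g = ann.genes
        hit = g[(g["chrom"].astype(str) == c) & (g["start"] <= hi) & (g["end"] >= lo)]
        for _, gene in hit.iterrows():
            rows.append((snp["snp"], c, int(snp["pos"]), "gene", gene["gene_id"]))
        if ann.qtl is not None:
            qd = ann.qtl
            qh = qd[(qd["chrom"].astype(str) == c) & (qd["start"] <= hi) & (qd["end"] >= lo)]
            for _, q in qh.iterrows():
                rows.append((snp["snp"], c, int(snp["pos"]), "qtl", q["trait"]))
    if skipped:
        warnings.warn(f"SNPs on unannotated chromosomes skipped: {skipped[:5]}")
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "feature", "id"])


def hypergeom_enrichment(
    hits: set,
    ann: AnnotationSet,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene set in the hits.

    With background size N, set size K, n hits and overlap k the p-value is
    P(X >= k); BH across sets; enriched iff q <= ``fdr_level``.
    """
    from statsmodels.stats.multitest import multipletests

    N = len(ann.background)
    if N == 0:
        raise ValueError("empty background universe")
    hits = set(hits) & ann.background
    if set(hits) - ann.background:
        raise ValueError("hits outside the background universe")
    n = len(hits)
    rows = []
    for name, members in ann.gene_sets.items():
        K = len(members)
        k = len(hits & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p_value"])
    if len(df):
        _, q, _, _ = multipletests(df["p_value"], alpha=fdr_level, method="fdr_bh")
        df["fdr_q"] = q
        df["enriched"] = df["fdr_q"] <= fdr_level
    else:
        df["fdr_q"] = []
        df["enriched"] = []
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
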