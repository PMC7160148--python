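"""Synthetic populations with the statistical structure the analysis assumes.

The generator emulates a multi-generation beef-cattle breeding scheme:
discrete generations with heavily reused sires (so contemporary groups stay
connected), gene-dropped biallelic SNPs on 29 autosomes, contemporary groups
whose mean environment varies, a growth descriptor trait (yearling body
weight scale) and a reaction-norm target trait (age at first calving scale)
with QTLs carrying correlated intercept/slope effects and residual variance
heterogeneous over five environment classes.  Truth tables sufficient for
recovery tests accompany every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, Pedigree, write_genotypes, write_pedigree
from .reaction_norm import legendre_basis

N_AUTOSOMES = 29


@dataclass
class SimConfig:
    """Population and trait parameters for one synthetic study.

    Defaults are chosen to mirror a desk-scale version of a tropical beef
    breeding program: a few discrete generations, ~half the animals
    genotyped, CG effects on the descriptor spread so the standardized
    gradient spans about +/-3 sd, target-trait heritability near 0.17 at the
    gradient center, and a mild negative intercept-slope covariance.
    """

    n_founders: int = 80
    n_generations: int = 4
    offspring_per_mating: int = 2
    n_sires: int | None = None  # default n_founders // 25 (heavy AI-style reuse)
    n_snps: int = 1200
    n_qtl: int = 30
    maf_range: tuple = (0.05, 0.5)
    n_cg: int = 8  # contemporary groups per generation
    cg_mean_spread: float = 30.0  # sd (kg) of CG effects on the descriptor
    genotyped_fraction: float = 0.5
    missing_rate: float = 0.0
    seed: int = 1

    # descriptor trait (yearling body weight, kg)
    descriptor_mean: float = 230.0
    descriptor_age_slope: float = 0.6  # kg per day of age at recording
    descriptor_sigma2_a: float = 120.0
    descriptor_sigma2_e: float = 280.0

    # target trait (age at first calving, days)
    target_mean: float = 1050.0
    target_cg_sd: float = 40.0
    target_ec_trend: float = -15.0  # days per sd of environment
    true_K: tuple = ((800.0, -200.0), (-200.0, 200.0))
    residual_class_vars: tuple = (2500.0, 2250.0, 2000.0, 1800.0, 1600.0)
    qtl_variance_fraction: float = 0.4
    qtl_structure: str = "proportional"  # proportional | slope_only | intercept_only
    qtl_fixed_effects: bool = False  # fixed |effect| (random sign): oracle mode

    def __post_init__(self) -> None:
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        for name in ("n_founders", "n_generations", "offspring_per_mating", "n_snps", "n_cg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0 <= self.genotyped_fraction <= 1:
            raise ValueError("genotyped_fraction must be in [0, 1]")
        K = np.asarray(self.true_K, dtype=float)
        if not np.allclose(K, K.T) or np.any(np.linalg.eigvalsh(K) < -1e-8):
            raise ValueError("true_K must be symmetric positive semidefinite")
        if np.any(np.asarray(self.residual_class_vars) < 0):
            raise ValueError("residual class variances must be >= 0")
        if self.qtl_structure not in ("proportional", "slope_only", "intercept_only"):
            raise ValueError(f"unknown qtl_structure {self.qtl_structure!r}")

    @property
    def K(self) -> np.ndarray:
        return np.asarray(self.true_K, dtype=float)

    def expected_pedigree_size(self) -> int:
        return self.n_founders + (self.n_generations - 1) * (
            self.n_founders // 2
        ) * self.offspring_per_mating


@dataclass
class SimTruth:
    """Everything a recovery test needs: the generating K, per-QTL effects,
    residual-class variances, CG effects on both trait scales with the true
    standardized gradient, and per-animal reaction-norm coefficients."""

    true_K: np.ndarray
    residual_class_vars: np.ndarray
    qtl_effects: pd.DataFrame  # snp, effect_intercept, effect_slope
    cg_table: pd.DataFrame  # cg, generation, desc_effect, target_effect, true_ec, residual_class
    coefficients: pd.DataFrame  # animal, intercept, slope

    def genetic_variance_at(self, ec: float) -> float:
        phi = legendre_basis(ec, self.true_K.shape[0] - 1)
        return float(phi @ self.true_K @ phi)


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Discrete-generation pedigree with sires reused across contemporary groups.

    Each generation after the founders has exactly ``n_founders // 2``
    matings; dams are drawn (with replacement) from the previous generation's
    females, sires from a small reused panel of earlier-generation males, and
    each sire's offspring are spread round-robin over the generation's CGs.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ids, sire, dam, sex, gen, cg = [], [], [], [], [], []
    for i in range(cfg.n_founders):
        ids.append(f"F{i:04d}")
        sire.append(-1)
        dam.append(-1)
        sex.append("M" if i % 2 == 0 else "F")
        gen.append(0)
        cg.append(None)
    n_matings = cfg.n_founders // 2
    n_sires = cfg.n_sires or max(2, cfg.n_founders // 25)
    counter = 0
    for g in range(1, cfg.n_generations):
        # AI-style usage: sires drawn from every earlier generation's males,
        # so the same large half-sib families span many CGs and EC levels
        prev_mal = [i for i in range(len(ids)) if sex[i] == "M" and gen[i] < g]
        prev_fem = [i for i in range(len(ids)) if sex[i] == "F" and gen[i] == g - 1]
        if not prev_mal or not prev_fem:
            raise RuntimeError("a generation ran out of sires or dams")
        sires = rng.choice(prev_mal, size=min(n_sires, len(prev_mal)), replace=False)
        gen_counter = 0  # consecutive offspring cycle the generation's CGs,
        for m in range(n_matings):  # spreading every sire over >= 2 groups
            s = int(sires[m % len(sires)])
            d = int(rng.choice(prev_fem))
            for _ in range(cfg.offspring_per_mating):
                ids.append(f"G{g}A{counter:05d}")
                counter += 1
                sire.append(s)
                dam.append(d)
                sex.append("M" if rng.random() < 0.5 else "F")
                gen.append(g)
                cg.append(f"g{g}c{gen_counter % cfg.n_cg}")
                gen_counter += 1
    meta = pd.DataFrame({"animal": ids, "sex": sex, "generation": gen, "cg": cg})
    return Pedigree(np.array(ids, dtype=object), np.array(sire), np.array(dam), meta=meta)


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Founder genotypes Binomial(2, p), descendants by gene dropping, SNPs
    evenly laid over 29 autosomes.  ``genotyped_fraction`` and
    ``missing_rate`` are applied downstream when the bundle is assembled; the
    returned matrix covers every pedigree animal."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n, m = ped.n, cfg.n_snps
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    calls = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            calls[i] = rng.binomial(2, p)
        else:
            pat = rng.binomial(1, calls[s] / 2.0) if s >= 0 else rng.binomial(1, p)
            mat = rng.binomial(1, calls[d] / 2.0) if d >= 0 else rng.binomial(1, p)
            calls[i] = pat + mat
    per_chrom = int(np.ceil(m / N_AUTOSOMES))
    chrom = (np.arange(m) // per_chrom + 1).astype(np.int64)
    pos = ((np.arange(m) % per_chrom + 1) * 100_000).astype(np.int64)
    snp_ids = np.array([f"snp{k:06d}" for k in range(m)], dtype=object)
    return GenotypeMatrix(ped.ids.copy(), snp_ids, chrom, pos, calls)


def _simulate_cg_table(ped: Pedigree, cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """CG effects on both trait scales plus the true standardized gradient."""
    from .ec import assign_residual_class

    cgs = sorted(set(c for c in ped.meta["cg"] if c is not None))
    desc = cfg.descriptor_mean + rng.normal(0.0, cfg.cg_mean_spread, size=len(cgs))
    sd = desc.std()
    true_ec = np.clip((desc - desc.mean()) / sd, -3.0, 3.0) if sd > 0 else np.zeros(len(cgs))
    target = cfg.target_mean + rng.normal(0.0, cfg.target_cg_sd, size=len(cgs))
    target = target + cfg.target_ec_trend * true_ec
    return pd.DataFrame(
        {
            "cg": cgs,
            "desc_effect": desc,
            "target_effect": target,
            "true_ec": true_ec,
            "residual_class": assign_residual_class(true_ec),
        }
    )


def _polygenic_coefficients(
    ped: Pedigree, K_poly: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Pedigree-correlated (intercept, slope) coefficients: founders from
    N(0, K_poly), offspring as the parent average plus Mendelian sampling
    with half the founder covariance."""
    q = K_poly.shape[0]
    L_f = np.linalg.cholesky(K_poly + 1e-12 * np.eye(q))
    L_m = np.linalg.cholesky(0.5 * K_poly + 1e-12 * np.eye(q))
    a = np.zeros((ped.n, q))
    z = rng.standard_normal((ped.n, q))
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            a[i] = L_f @ z[i]
        else:
            par = (a[s] if s >= 0 else 0) + (a[d] if d >= 0 else 0)
            a[i] = 0.5 * par + L_m @ z[i]
    return a


def simulate_reaction_norm_phenotypes(
    geno: GenotypeMatrix,
    ped: Pedigree,
    cfg: SimConfig,
    true_K: np.ndarray | None = None,
    residual_class_vars=None,
    cg_table: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Target-trait records under the reaction-norm model.

    Per-animal coefficients are a pedigree polygenic part plus centered QTL
    dosages times bivariate-normal QTL effects, partitioned so QTLs carry
    ``qtl_variance_fraction`` of ``true_K``.  Each record is

        y = CG effect + a*Phi0(EC) + b*Phi1(EC) + e,

    with Var(e) set by the residual class of the CG's gradient level.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    K = cfg.K if true_K is None else np.asarray(true_K, dtype=float)
    if not np.allclose(K, K.T) or np.any(np.linalg.eigvalsh(K) < -1e-10):
        raise ValueError("true_K must be symmetric positive semidefinite")
    rcv = np.asarray(
        cfg.residual_class_vars if residual_class_vars is None else residual_class_vars,
        dtype=float,
    )
    if cg_table is None:
        cg_table = _simulate_cg_table(ped, cfg, rng)
    q = K.shape[0]

    n_qtl = min(cfg.n_qtl, geno.n_snps)
    qtl_frac = cfg.qtl_variance_fraction if n_qtl > 0 else 0.0
    coeff = _polygenic_coefficients(ped, (1.0 - qtl_frac) * K, rng)
    if n_qtl > 0 and qtl_frac > 0:
        qtl_idx = np.sort(rng.choice(geno.n_snps, size=n_qtl, replace=False))
        p = geno.allele_freq[qtl_idx]
        het = 2.0 * np.sum(p * (1 - p))
        scale = qtl_frac / het if het > 0 else 0.0
        Kq = scale * K
        if q > 1 and cfg.qtl_structure == "slope_only":
            Kq = Kq.copy()
            Kq[0, :] = Kq[:, 0] = 0.0
        elif q > 1 and cfg.qtl_structure == "intercept_only":
            Kq = Kq.copy()
            Kq[1:, :] = Kq[:, 1:] = 0.0
        L = np.linalg.cholesky(Kq + 1e-14 * np.eye(q))
        if cfg.qtl_fixed_effects:
            # every QTL carries exactly its share of variance; sign random
            share = np.diag(Kq) * het / (2.0 * n_qtl * p * (1 - p))[:, None]
            beta = np.sign(rng.standard_normal((n_qtl, q))) * np.sqrt(share)
        else:
            beta = rng.standard_normal((n_qtl, q)) @ L.T
        Mc = geno.calls[:, qtl_idx].astype(float) - 2.0 * p
        coeff = coeff + Mc @ beta
        qtl_df = pd.DataFrame(
            {
                "snp": geno.snp_ids[qtl_idx],
                "effect_intercept": beta[:, 0],
                "effect_slope": beta[:, 1] if q > 1 else 0.0,
            }
        )
    else:
        qtl_df = pd.DataFrame(columns=["snp", "effect_intercept", "effect_slope"])

    meta = ped.meta
    rec = meta[meta["cg"].notna()].reset_index(drop=True)
    cg_lut = cg_table.set_index("cg")
    ecs = cg_lut.loc[rec["cg"], "true_ec"].to_numpy(float)
    cg_eff = cg_lut.loc[rec["cg"], "target_effect"].to_numpy(float)
    classes = cg_lut.loc[rec["cg"], "residual_class"].to_numpy(int)
    phi = legendre_basis(ecs, q - 1)
    aidx = ped.index_of(rec["animal"])
    genetic = np.sum(phi * coeff[aidx], axis=1)
    e = rng.standard_normal(len(rec)) * np.sqrt(rcv[classes - 1])
    pheno = pd.DataFrame(
        {
            "animal": rec["animal"],
            "cg": rec["cg"],
            "y": cg_eff + genetic + e,
        }
    )
    truth = SimTruth(
        true_K=K,
        residual_class_vars=rcv,
        qtl_effects=qtl_df,
        cg_table=cg_table,
        coefficients=pd.DataFrame(
            {"animal": ped.ids, "intercept": coeff[:, 0],
             "slope": coeff[:, 1] if q > 1 else 0.0}
        ),
    )
    return pheno, truth


def simulate_descriptor_trait(
    geno: GenotypeMatrix,
    ped: Pedigree,
    cfg: SimConfig,
    cg_table: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Descriptor-trait records: y = CG effect + age slope + additive value +
    residual, additive values pedigree-correlated (polygenic)."""
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    if cg_table is None:
        cg_table = _simulate_cg_table(ped, cfg, rng)
    u = _polygenic_coefficients(ped, np.array([[cfg.descriptor_sigma2_a]]), rng)[:, 0]
    meta = ped.meta
    rec = meta[meta["cg"].notna()].reset_index(drop=True)
    cg_lut = cg_table.set_index("cg")
    cg_eff = cg_lut.loc[rec["cg"], "desc_effect"].to_numpy(float)
    age = rng.integers(300, 420, size=len(rec)).astype(float)
    e = rng.standard_normal(len(rec)) * np.sqrt(cfg.descriptor_sigma2_e)
    age_c = age - age.mean()
    u_rec = u[ped.index_of(rec["animal"])]
    y = cg_eff + cfg.descriptor_age_slope * age_c + u_rec + e
    return pd.DataFrame(
        {"animal": rec["animal"], "cg": rec["cg"], "y": y, "age": age, "true_u": u_rec}
    )


@dataclass
class SimBundle:
    """One complete synthetic study plus its generating truth."""

    ped: Pedigree
    geno: GenotypeMatrix  # genotyped subset only, missing calls applied
    geno_full: GenotypeMatrix  # every animal, no missingness (for truth checks)
    descriptor_phenos: pd.DataFrame
    target_phenos: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def simulate_study(cfg: SimConfig) -> SimBundle:
    """Generate a full study: pedigree, genotypes on a part-genotyped subset,
    descriptor and target phenotypes, and the truth tables."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    geno_full = simulate_genotypes(ped, cfg, rng)
    cg_table = _simulate_cg_table(ped, cfg, rng)
    desc = simulate_descriptor_trait(geno_full, ped, cfg, cg_table=cg_table, rng=rng)
    target, truth = simulate_reaction_norm_phenotypes(
        geno_full, ped, cfg, cg_table=cg_table, rng=rng
    )
    # part-genotyped subset: prefer sires and recorded animals
    n_geno = int(round(cfg.genotyped_fraction * ped.n))
    sire_ids = set(ped.ids[np.unique(ped.sire[ped.sire >= 0])])
    sire_flag = np.array([0 if a in sire_ids else 1 for a in ped.ids])
    # sires first, then the most recent generations
    priority = np.lexsort((-np.arange(ped.n), sire_flag))
    chosen = np.sort(priority[:n_geno])
    geno = geno_full.subset(animals=chosen)
    if cfg.missing_rate > 0:
        mask = rng.random(geno.calls.shape) < cfg.missing_rate
        calls = geno.calls.copy()
        calls[mask] = -1
        geno = GenotypeMatrix(geno.animal_ids, geno.snp_ids, geno.chrom, geno.pos, calls)
    return SimBundle(ped, geno, geno_full, desc, target, truth, cfg)


def write_synthetic_annotation(
    geno: GenotypeMatrix,
    outdir: str | Path,
    seed: int = 0,
    genes_per_chrom: int = 8,
    n_gene_sets: int = 12,
) -> dict:
    """Synthetic gene/QTL annotation over the simulated genome.

    Writes a BED of gene intervals tiled over each chromosome, a BED of
    broader QTL intervals with trait labels, and a GMT of random gene sets —
    a stand-in for real genome resources, usable offline.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_rows, qtl_rows = [], []
    gid = 0
    for c in np.unique(geno.chrom):
        span = int(geno.pos[geno.chrom == c].max())
        for start in np.linspace(1, max(span - 50_000, 1), genes_per_chrom).astype(int):
            gene_rows.append((c, start - 1, start + int(rng.integers(5_000, 60_000)),
                              f"GENE{gid:04d}"))
            gid += 1
        q0 = int(rng.integers(1, max(span // 2, 2)))
        qtl_rows.append((c, q0 - 1, q0 + int(rng.integers(100_000, 500_000)),
                         f"trait{int(rng.integers(1, 5))}"))
    genes_bed = outdir / "genes.bed"
    with open(genes_bed, "w") as fh:
        for r in gene_rows:
            fh.write("\t".join(map(str, r)) + "\n")
    qtl_bed = outdir / "qtl.bed"
    with open(qtl_bed, "w") as fh:
        for r in qtl_rows:
            fh.write("\t".join(map(str, r)) + "\n")
    all_genes = [r[3] for r in gene_rows]
    gmt = outdir / "gene_sets.gmt"
    with open(gmt, "w") as fh:
        for s in range(n_gene_sets):
            size = int(rng.integers(5, max(6, len(all_genes) // 4)))
            members = rng.choice(all_genes, size=size, replace=False)
            fh.write(f"SET{s:03d}\tsynthetic\t" + "\t".join(members) + "\n")
    return {"genes": str(genes_bed), "qtl": str(qtl_bed), "gene_sets": str(gmt)}


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict:
    """Write the pipeline's own input formats plus truth TSVs; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "genotypes": outdir / "genotypes.raw",
        "descriptor_phenos": outdir / "pheno_descriptor.csv",
        "target_phenos": outdir / "pheno_target.csv",
        "truth_qtl": outdir / "truth_qtl.tsv",
        "truth_cg": outdir / "truth_cg.tsv",
        "truth_coefficients": outdir / "truth_coefficients.tsv",
        "truth_K": outdir / "truth_K.tsv",
    }
    write_pedigree(bundle.ped, paths["pedigree"])
    write_genotypes(bundle.geno, paths["genotypes"], dialect="raw_additive")
    bundle.descriptor_phenos.to_csv(paths["descriptor_phenos"], index=False)
    bundle.target_phenos.to_csv(paths["target_phenos"], index=False)
    bundle.truth.qtl_effects.to_csv(paths["truth_qtl"], sep="\t", index=False)
    bundle.truth.cg_table.to_csv(paths["truth_cg"], sep="\t", index=False)
    bundle.truth.coefficients.to_csv(paths["truth_coefficients"], sep="\t", index=False)
    K = bundle.truth.true_K
    pd.DataFrame(K).to_csv(paths["truth_K"], sep="\t", index=False, header=False)
    return {k: str(v) for k, v in paths.items()}
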