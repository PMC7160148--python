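"""Replicated simulation experiments that characterize the method.

These are the package's own validation studies, shared by the analysis
drivers and the acceptance checks: variance-component recovery under the
generating model, null calibration of the SNP test, and the asymmetry of
GxE detection across the gradient.  Problem sizes are desk-scale versions
of the study design (a few thousand pedigree animals, a few thousand SNPs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ec import ECDescriptor
from .gwas import backsolve_snp_coefficients, inflation_factor, project_effect, snp_test
from .reaction_norm import fit_ssgrn, genetic_correlation
from .relationships import build_relationships
from .simulate import SimConfig, simulate_study


def truth_ecd(cg_table: pd.DataFrame) -> ECDescriptor:
    """ECDescriptor built from the simulator's true gradient (skips stage 1)."""
    return ECDescriptor(
        cg_table["cg"].to_numpy(object),
        cg_table["desc_effect"].to_numpy(float),
        cg_table["true_ec"].to_numpy(float),
        cg_table["true_ec"].to_numpy(float),
        cg_table["residual_class"].to_numpy(int),
    )


def recovery_sim_config(seed: int, **overrides) -> SimConfig:
    """Study conditions for the recovery experiments: 2,000 pedigree animals
    over four generations, 5,000 SNPs, 200 QTLs, ~40% genotyped; CG sizes
    follow the source population's ~28 records per contemporary group."""
    base = dict(
        n_founders=500,
        n_generations=4,
        offspring_per_mating=2,
        n_snps=5000,
        n_qtl=200,
        n_cg=18,
        genotyped_fraction=0.4,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class RecoveryResult:
    K_true: np.ndarray
    K_estimates: np.ndarray  # (n_reps, q, q)
    gcorr_true: float
    gcorr_estimates: np.ndarray

    @property
    def K_mean(self) -> np.ndarray:
        return self.K_estimates.mean(axis=0)

    @property
    def K_se(self) -> np.ndarray:
        n = self.K_estimates.shape[0]
        return self.K_estimates.std(axis=0, ddof=1) / np.sqrt(n)

    def within_se(self, n_se: float = 2.0) -> np.ndarray:
        return np.abs(self.K_mean - self.K_true) <= n_se * self.K_se

    def to_frame(self) -> pd.DataFrame:
        pairs = [("intercept_var", 0, 0), ("covariance", 0, 1), ("slope_var", 1, 1)]
        rows = [
            (name, self.K_true[i, j], self.K_mean[i, j], self.K_se[i, j])
            for name, i, j in pairs
        ]
        rows.append(
            ("genetic_corr_m3_p3", self.gcorr_true,
             float(np.mean(self.gcorr_estimates)),
             float(np.std(self.gcorr_estimates, ddof=1) / np.sqrt(len(self.gcorr_estimates))))
        )
        return pd.DataFrame(rows, columns=["parameter", "truth", "estimate_mean", "se"])


def parameter_recovery(
    n_reps: int = 10,
    seed: int = 2026,
    reml_tol: float = 1e-3,
    sim_overrides: dict | None = None,
) -> RecoveryResult:
    """Fit the reaction-norm model to replicated simulations with known K
    (negative intercept-slope covariance) and collect the REML estimates."""
    Ks, gcs = [], []
    K_true = None
    for r in range(n_reps):
        cfg = recovery_sim_config(seed + 1000 * r, **(sim_overrides or {}))
        bundle = simulate_study(cfg)
        K_true = bundle.truth.true_K
        rel = build_relationships(bundle.ped, bundle.geno, blend_weight=0.95)
        ecd = truth_ecd(bundle.truth.cg_table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rn = fit_ssgrn(
                bundle.target_phenos, ecd, rel["H_inverse"],
                reml_tol=reml_tol, reml_max_iter=25,
            )
        Ks.append(rn.K)
        gcs.append(genetic_correlation(rn.K, -3.0, 3.0))
    return RecoveryResult(
        K_true=K_true,
        K_estimates=np.array(Ks),
        gcorr_true=genetic_correlation(K_true, -3.0, 3.0),
        gcorr_estimates=np.array(gcs),
    )


def _fit_known_varcomps(bundle, blend_weight: float = 0.95):
    """Solve the reaction-norm MME at the generating variance components."""
    rel = build_relationships(bundle.ped, bundle.geno, blend_weight=blend_weight)
    ecd = truth_ecd(bundle.truth.cg_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rn = fit_ssgrn(
            bundle.target_phenos, ecd, rel["H_inverse"],
            start_K=bundle.truth.true_K,
            start_res=bundle.truth.residual_class_vars,
            estimate_varcomps=False,
        )
    return rn, rel


@dataclass
class NullCalibrationResult:
    lambdas: pd.DataFrame  # replicate x level
    typeI_by_level: pd.Series  # pooled P(p < alpha) per level
    alpha: float
    n_snps_per_rep: int
    n_reps: int

    def binomial_se(self) -> float:
        n = self.n_snps_per_rep * self.n_reps
        return float(np.sqrt(self.alpha * (1 - self.alpha) / n))


def null_calibration(
    n_reps: int = 10,
    seed: int = 2026,
    alpha: float = 0.01,
    ec_levels=(-3.0, 0.0, 3.0),
    sim_overrides: dict | None = None,
) -> NullCalibrationResult:
    """Polygenic-only (no-QTL) simulations: genomic inflation of the SNP test
    and pooled type-I error at nominal ``alpha`` per gradient level."""
    overrides = dict(n_qtl=0, n_founders=300, n_snps=3000, genotyped_fraction=0.5)
    overrides.update(sim_overrides or {})
    lam_rows = []
    pvals = {e: [] for e in ec_levels}
    n_snps = None
    for r in range(n_reps):
        cfg = recovery_sim_config(seed + 1000 * r, **overrides)
        bundle = simulate_study(cfg)
        rn, rel = _fit_known_varcomps(bundle)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alpha_mat, _, _ = backsolve_snp_coefficients(
                rn, bundle.geno, G=rel["G_blended"]
            )
        p_k = bundle.geno.allele_freq
        poly = np.isfinite(p_k) & (p_k > 0) & (p_k < 1)
        n_snps = int(poly.sum())
        row = {}
        for e in ec_levels:
            u = project_effect(alpha_mat, e)
            res = snp_test(u[poly], freqs=p_k[poly])
            row[e] = inflation_factor(res["z"].to_numpy())
            pvals[e].append(res["p_value"].to_numpy())
        lam_rows.append(row)
    typeI = pd.Series(
        {e: float(np.mean(np.concatenate(pvals[e]) < alpha)) for e in ec_levels}
    )
    return NullCalibrationResult(
        lambdas=pd.DataFrame(lam_rows),
        typeI_by_level=typeI,
        alpha=alpha,
        n_snps_per_rep=n_snps,
        n_reps=n_reps,
    )


@dataclass
class AsymmetryResult:
    slope_only_frac_larger_at_extremes: float
    intercept_only_mean_abs_z: pd.Series  # per level
    n_qtl_total: int


def gxe_asymmetry(
    n_reps: int = 5,
    seed: int = 2026,
    sim_overrides: dict | None = None,
) -> AsymmetryResult:
    """Detection asymmetry across the gradient.

    Slope-only QTLs (zero intercept effect) should test stronger at the
    gradient extremes than at its center; intercept-only QTLs should test
    evenly across levels.  QTLs are simulated at fixed magnitude, each
    carrying 5% of the genetic variance, so the direction of the contrast is
    identified rather than drowned in effect-size sampling noise.
    """
    overrides = dict(
        n_founders=300, n_snps=3000, n_qtl=10, genotyped_fraction=0.5,
        qtl_variance_fraction=0.5, qtl_fixed_effects=True,
    )
    overrides.update(sim_overrides or {})
    frac_num = frac_den = 0
    int_absz = {-3.0: [], 0.0: [], 3.0: []}
    for r in range(n_reps):
        for mode in ("slope_only", "intercept_only"):
            cfg = recovery_sim_config(
                seed + 1000 * r, qtl_structure=mode, **overrides
            )
            bundle = simulate_study(cfg)
            rn, rel = _fit_known_varcomps(bundle)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                alpha_mat, _, _ = backsolve_snp_coefficients(
                    rn, bundle.geno, G=rel["G_blended"]
                )
            p_k = bundle.geno.allele_freq
            poly = np.isfinite(p_k) & (p_k > 0) & (p_k < 1)
            kept_ids = bundle.geno.snp_ids[poly]
            snp_pos = {s: k for k, s in enumerate(kept_ids)}
            qtl_idx = np.array(
                [snp_pos[s] for s in bundle.truth.qtl_effects["snp"] if s in snp_pos]
            )
            z = {}
            for e in (-3.0, 0.0, 3.0):
                u = project_effect(alpha_mat, e)
                z[e] = snp_test(u[poly], freqs=p_k[poly])["z"].to_numpy()
            if mode == "slope_only":
                big = np.maximum(np.abs(z[-3.0][qtl_idx]), np.abs(z[3.0][qtl_idx]))
                frac_num += int(np.sum(big > np.abs(z[0.0][qtl_idx])))
                frac_den += len(qtl_idx)
            else:
                for e in (-3.0, 0.0, 3.0):
                    int_absz[e].append(np.abs(z[e][qtl_idx]))
    return AsymmetryResult(
        slope_only_frac_larger_at_extremes=frac_num / frac_den,
        intercept_only_mean_abs_z=pd.Series(
            {e: float(np.mean(np.concatenate(v))) for e, v in int_absz.items()}
        ),
        n_qtl_total=frac_den,
    )
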