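import numpy as np
import pandas as pd
import pytest

from ssgrn.experiments import truth_ecd
from ssgrn.gwas import (
    backsolve_snp_coefficients,
    inflation_factor,
    inflation_factor_literal,
    literal_z,
    ratio_fdr_estimate,
    project_effect,
    snp_test,
    stratify_shared_specific,
    variance_explained,
)
from ssgrn.reaction_norm import fit_ssgrn, genetic_variance_at, legendre_basis
from ssgrn.relationships import build_relationships
from ssgrn.simulate import SimConfig, simulate_study


def fit_known(bundle):
    rel = build_relationships(bundle.ped, bundle.geno, blend_weight=0.95)
    return fit_ssgrn(
        bundle.target_phenos, truth_ecd(bundle.truth.cg_table), rel["H_inverse"],
        start_K=bundle.truth.true_K, start_res=bundle.truth.residual_class_vars,
        estimate_varcomps=False,
    ), rel


class TestBacksolve:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = SimConfig(seed=55, n_founders=120, n_generations=3, n_snps=500,
                        n_qtl=8, genotyped_fraction=0.6, qtl_variance_fraction=0.6)
        bundle = simulate_study(cfg)
        rn, rel = fit_known(bundle)
        return bundle, rn, rel

    def test_zero_breeding_values_give_zero_effects(self, fitted):
        bundle, rn, _ = fitted
        from dataclasses import replace

        rn0 = replace(rn, coefficients=np.zeros_like(rn.coefficients))
        alpha, _, _ = backsolve_snp_coefficients(rn0, bundle.geno)
        assert np.allclose(alpha, 0.0)

    def test_reconstruction_identity_unblended(self, fitted):
        bundle, rn, _ = fitted
        alpha, retained, p = backsolve_snp_coefficients(rn, bundle.geno)
        gi = {a: i for i, a in enumerate(bundle.geno.animal_ids)}
        ri = {a: i for i, a in enumerate(rn.animal_ids)}
        rows = [gi[a] for a in retained]
        poly = np.isfinite(p) & (p > 0) & (p < 1)
        Mc = bundle.geno.dosage_matrix(freqs=p)[np.ix_(rows, np.where(poly)[0])] - 2 * p[poly]
        ahat = rn.coefficients[[ri[a] for a in retained]]
        recon = Mc @ alpha[poly]
        assert np.abs(recon - ahat).max() < 1e-6

    def test_large_qtl_is_genomewide_maximum(self):
        # one large intercept QTL should top the back-solved effects in
        # nearly every replicate (after marker QC, blended G)
        from ssgrn.qc import filter_genotypes

        hits, total = 0, 0
        for seed in range(200, 210):
            cfg = SimConfig(seed=seed, n_founders=200, n_generations=4, n_snps=300,
                            n_qtl=1, genotyped_fraction=0.9,
                            qtl_variance_fraction=0.8,
                            qtl_structure="intercept_only", qtl_fixed_effects=True)
            bundle = simulate_study(cfg)
            geno, _ = filter_genotypes(bundle.geno)
            rel = build_relationships(bundle.ped, geno, blend_weight=0.95)
            rn = fit_ssgrn(
                bundle.target_phenos, truth_ecd(bundle.truth.cg_table),
                rel["H_inverse"], start_K=bundle.truth.true_K,
                start_res=bundle.truth.residual_class_vars,
                estimate_varcomps=False,
            )
            alpha, _, _ = backsolve_snp_coefficients(rn, geno, G=rel["G_blended"])
            if bundle.truth.qtl_effects["snp"].iloc[0] not in set(geno.snp_ids):
                continue
            total += 1
            top = geno.snp_ids[np.argmax(np.abs(alpha[:, 0]))]
            hits += int(top == bundle.truth.qtl_effects["snp"].iloc[0])
        assert hits >= 0.9 * total

    def test_accuracy_filter_can_exclude_everyone(self, fitted):
        bundle, rn, _ = fitted
        with pytest.raises(ValueError, match="accuracy"):
            backsolve_snp_coefficients(rn, bundle.geno, accuracy_min=1.0)


class TestProjection:
    def test_zero_slope_constant_across_levels(self):
        a = np.array([[1.7, 0.0]])
        assert project_effect(a, -3.0) == pytest.approx(project_effect(a, 3.0))

    def test_pure_slope_at_edge(self):
        assert project_effect(np.array([0.0, 1.0]), 3.0) == pytest.approx(1.22474, abs=1e-5)

    def test_zero_intercept_antisymmetric(self):
        a = np.array([[0.0, 0.9]])
        assert project_effect(a, -3.0) == pytest.approx(-project_effect(a, 3.0))


class TestVarianceExplained:
    def test_zero_effect_zero_percent(self):
        assert variance_explained(0.0, 0.3, 10.0) == 0.0

    def test_half_frequency_unit_ratio_gives_fifty(self):
        assert variance_explained(np.sqrt(10.0), 0.5, 10.0) == pytest.approx(50.0)

    def test_sums_to_hundred_under_linkage_equilibrium(self):
        # founders only (LE): causal contributions should account for ~100%
        cfg = SimConfig(seed=60, n_founders=3000, n_generations=1, n_snps=300,
                        n_qtl=40, qtl_variance_fraction=1.0)
        bundle = simulate_study(cfg)
        truth = bundle.truth
        geno = bundle.geno_full
        snp_pos = {s: k for k, s in enumerate(geno.snp_ids)}
        qtl_idx = np.array([snp_pos[s] for s in truth.qtl_effects["snp"]])
        p = geno.allele_freq[qtl_idx]
        for ec in (-3.0, 0.0, 3.0):
            phi = legendre_basis(ec)
            beta = truth.qtl_effects[["effect_intercept", "effect_slope"]].to_numpy()
            u = beta @ phi
            coeff = truth.coefficients[["intercept", "slope"]].to_numpy()
            s2a = np.var(coeff @ phi)
            total = float(np.sum(variance_explained(u, p, s2a)))
            assert total == pytest.approx(100.0, abs=12.0)

    def test_literal_standardization_collapses(self):
        u = np.array([0.5, -1.0, 2.0])
        z = literal_z(u, np.full(3, 0.25), 10.0)
        assert np.allclose(np.abs(z), np.abs(z[0]))


def bh_oracle(p):
    """Brute-force BH q-values: scan every threshold."""
    p = np.asarray(p)
    n = len(p)
    q = np.empty(n)
    for i, pi in enumerate(p):
        cands = []
        for pj in p:
            if pj >= pi:
                rank = np.sum(p <= pj)
                cands.append(n * pj / rank)
        q[i] = min(min(cands), 1.0)
    return q


class TestSnpTest:
    def test_constant_effects_rejected(self):
        with pytest.raises(ValueError, match="zero sd"):
            snp_test(np.full(10, 1.3))

    def test_pvalues_are_two_sided_normal(self, rng):
        u = rng.standard_normal(500)
        res = snp_test(u)
        from scipy.stats import norm

        assert np.allclose(res["p_value"], 2 * norm.sf(np.abs(res["z"])), atol=1e-12)
        i196 = np.argmin(np.abs(res["z"] - 1.96))
        assert res["p_value"][i196] == pytest.approx(0.05, abs=0.01)

    def test_bh_qvalues_match_brute_force(self, rng):
        p = np.array([0.001, 0.004, 0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 0.9])
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh_oracle(p), atol=1e-12)
        # and on random p-values through the public interface
        u = rng.standard_normal(80)
        res = snp_test(u)
        assert np.allclose(res["fdr_q"], bh_oracle(res["p_value"].to_numpy()), atol=1e-10)

    def test_bh_monotone_in_p(self, rng):
        res = snp_test(rng.standard_normal(200))
        srt = res.sort_values("p_value")
        assert (np.diff(srt["fdr_q"]) >= -1e-12).all()

    def test_significance_flag_is_threshold_rule(self, rng):
        u = rng.standard_normal(100)
        u[0] = 50.0
        res = snp_test(u, threshold_neglog10p=6.0)
        assert bool(res["significant"][0]) is True
        assert res["significant"][1:].sum() == 0

    def test_ratio_fdr_estimate(self):
        p = np.concatenate([np.full(4, 0.001), np.full(96, 0.5)])
        assert ratio_fdr_estimate(p, p_sig=0.01) == pytest.approx(100 * 0.01 / 4)


class TestInflation:
    def test_unit_lambda_at_null_median(self):
        z = np.full(200, np.sqrt(0.456))
        assert inflation_factor(z) == pytest.approx(1.0)

    def test_standard_normal_lambda_near_one(self, rng):
        z = rng.standard_normal(100_000)
        assert 0.97 < inflation_factor(z) < 1.03

    def test_scaling_property(self, rng):
        z = rng.standard_normal(100_000)
        assert inflation_factor(1.2 * z) == pytest.approx(
            1.44 * inflation_factor(z), rel=0.02
        )

    def test_literal_variant_is_uninformative(self, rng):
        from scipy.stats import norm

        z = rng.standard_normal(100_000)
        p = 2 * norm.sf(np.abs(z))
        assert inflation_factor_literal(p) == pytest.approx(0.5 / 0.456, rel=0.02)


class TestVennPartition:
    def test_identical_sets_all_shared(self):
        out = stratify_shared_specific({"L": {1, 2}, "M": {1, 2}, "H": {1, 2}})
        assert out[("L", "M", "H")] == {1, 2}
        assert all(not v for k, v in out.items() if k != ("L", "M", "H"))

    def test_disjoint_sets_all_specific(self):
        out = stratify_shared_specific({"L": {1}, "M": {2}, "H": {3}})
        assert out[("L",)] == {1} and out[("M",)] == {2} and out[("H",)] == {3}
        assert not out[("L", "M")] and not out[("L", "M", "H")]

    def test_mixed_example(self):
        out = stratify_shared_specific(
            {"L": {"A", "B", "C"}, "M": {"B", "C", "D"}, "H": {"C"}}
        )
        assert out[("L", "M", "H")] == {"C"}
        assert out[("L", "M")] == {"B"}
        assert out[("L",)] == {"A"}
        assert out[("M",)] == {"D"}
        assert not out[("H",)]
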