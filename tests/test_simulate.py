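import numpy as np
import pandas as pd
import pytest

from ssgrn.reaction_norm import legendre_basis
from ssgrn.simulate import (
    SimConfig,
    simulate_descriptor_trait,
    simulate_genotypes,
    simulate_pedigree,
    simulate_reaction_norm_phenotypes,
    simulate_study,
)


class TestPedigree:
    def test_single_generation_all_founders(self):
        ped = simulate_pedigree(SimConfig(seed=1, n_founders=12, n_generations=1))
        assert ped.n == 12
        assert (ped.sire == -1).all() and (ped.dam == -1).all()

    def test_size_matches_closed_form(self):
        cfg = SimConfig(seed=2, n_founders=10, n_generations=3, offspring_per_mating=2)
        ped = simulate_pedigree(cfg)
        assert ped.n == cfg.expected_pedigree_size() == 10 + 2 * 5 * 2

    def test_parents_precede_offspring(self):
        ped = simulate_pedigree(SimConfig(seed=3, n_founders=30, n_generations=4))
        for i in range(ped.n):
            assert ped.sire[i] < i and ped.dam[i] < i

    @pytest.mark.parametrize("seed", [0, 5])
    def test_sires_span_multiple_cgs(self, seed):
        cfg = SimConfig(seed=seed, n_founders=40, n_generations=3, n_cg=4)
        ped = simulate_pedigree(cfg)
        meta = ped.meta
        used = np.unique(ped.sire[ped.sire >= 0])
        for s in used:
            kids = meta.iloc[np.where(ped.sire == s)[0]]
            assert kids["cg"].nunique() >= 2

    def test_reproducible_for_fixed_seed(self):
        cfg = SimConfig(seed=9)
        p1, p2 = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert list(p1.ids) == list(p2.ids)
        assert np.array_equal(p1.sire, p2.sire)


class TestGenotypes:
    def test_mendelian_consistency_for_every_trio(self, small_bundle):
        geno, ped = small_bundle.geno_full, small_bundle.ped
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s < 0 or d < 0:
                continue
            kid, sire, dam = geno.calls[i], geno.calls[s], geno.calls[d]
            # paternal contribution constrained by sire dosage, same for dam
            low = (sire == 2).astype(int) + (dam == 2).astype(int)
            high = 2 - (sire == 0).astype(int) - (dam == 0).astype(int)
            assert (kid >= low).all() and (kid <= high).all()

    def test_founder_frequencies_within_binomial_error(self):
        cfg = SimConfig(seed=13, n_founders=500, n_generations=1, n_snps=400)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        # reconstruct the drawn frequencies from the generator's own stream
        p = np.random.default_rng(cfg.seed + 1).uniform(
            cfg.maf_range[0], cfg.maf_range[1], cfg.n_snps
        )
        realized = geno.allele_freq
        se = np.sqrt(p * (1 - p) / (2 * cfg.n_founders))
        frac_outside = np.mean(np.abs(realized - p) > 3 * se)
        assert frac_outside < 0.02  # ~0.3% expected under normality

    def test_positions_on_29_autosomes(self, small_bundle):
        geno = small_bundle.geno_full
        assert set(np.unique(geno.chrom)) <= set(range(1, 30))
        for c in np.unique(geno.chrom):
            assert (np.diff(geno.pos[geno.chrom == c]) > 0).all()

    def test_bit_reproducible(self):
        cfg = SimConfig(seed=4, n_founders=20, n_generations=2, n_snps=50)
        ped = simulate_pedigree(cfg)
        g1 = simulate_genotypes(ped, cfg)
        g2 = simulate_genotypes(ped, cfg)
        assert np.array_equal(g1.calls, g2.calls)


class TestReactionNormPhenotypes:
    def test_no_gxe_truth_constant_genetic_values(self):
        cfg = SimConfig(seed=6, n_founders=60, n_generations=3, n_snps=100, n_qtl=5,
                        true_K=((300.0, 0.0), (0.0, 0.0)))
        bundle = simulate_study(cfg)
        coeff = bundle.truth.coefficients
        assert np.abs(coeff["slope"]).max() < 1e-4
        g1 = coeff["intercept"] * legendre_basis(-3.0)[0] + coeff["slope"] * legendre_basis(-3.0)[1]
        g2 = coeff["intercept"] * legendre_basis(3.0)[0] + coeff["slope"] * legendre_basis(3.0)[1]
        assert np.corrcoef(g1, g2)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_phenotypes_reproduce_genetic_plus_cg(self):
        cfg = SimConfig(seed=7, n_founders=60, n_generations=3, n_snps=100, n_qtl=5,
                        residual_class_vars=(0.0,) * 5)
        bundle = simulate_study(cfg)
        ph = bundle.target_phenos
        truth = bundle.truth
        lut = truth.cg_table.set_index("cg")
        coeff = truth.coefficients.set_index("animal")
        phi = legendre_basis(lut.loc[ph["cg"], "true_ec"].to_numpy())
        genetic = (
            coeff.loc[ph["animal"], "intercept"].to_numpy() * phi[:, 0]
            + coeff.loc[ph["animal"], "slope"].to_numpy() * phi[:, 1]
        )
        expected = lut.loc[ph["cg"], "target_effect"].to_numpy() + genetic
        assert np.abs(ph["y"].to_numpy() - expected).max() < 1e-9

    def test_coefficient_covariance_matches_true_k(self):
        cfg = SimConfig(seed=8, n_founders=5000, n_generations=1, n_snps=300, n_qtl=40)
        bundle = simulate_study(cfg)
        coeff = bundle.truth.coefficients[["intercept", "slope"]].to_numpy()
        emp = np.cov(coeff.T)
        K = bundle.truth.true_K
        assert np.abs(emp - K).max() < 0.10 * np.abs(K).max()

    def test_non_psd_truth_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_reaction_norm_phenotypes(
                small_bundle.geno_full, small_bundle.ped,
                small_bundle.config, true_K=np.array([[1.0, 2.0], [2.0, 1.0]]),
            )


class TestDescriptorTrait:
    def test_zero_spread_gives_flat_cg_effects(self):
        cfg = SimConfig(seed=10, n_founders=40, n_generations=3, cg_mean_spread=0.0)
        bundle = simulate_study(cfg)
        ct = bundle.truth.cg_table
        assert ct["desc_effect"].nunique() == 1
        assert np.allclose(ct["true_ec"], 0.0)

    def test_realized_heritability_matches_configuration(self):
        cfg = SimConfig(seed=12, n_founders=5000, n_generations=1)
        ped = simulate_pedigree(cfg)
        # founders have no CG; give everyone one so records exist
        ped.meta["cg"] = "c0"
        cg_table = pd.DataFrame(
            {"cg": ["c0"], "desc_effect": [cfg.descriptor_mean],
             "target_effect": [0.0], "true_ec": [0.0], "residual_class": [4]}
        )
        pheno = simulate_descriptor_trait(None, ped, cfg, cg_table=cg_table)
        resid = pheno["y"] - cg_table["desc_effect"][0] - pheno["true_u"] \
            - cfg.descriptor_age_slope * (pheno["age"] - pheno["age"].mean())
        h2_real = pheno["true_u"].var() / (pheno["true_u"].var() + resid.var())
        h2_cfg = cfg.descriptor_sigma2_a / (cfg.descriptor_sigma2_a + cfg.descriptor_sigma2_e)
        assert h2_real == pytest.approx(h2_cfg, rel=0.10)

    def test_standardized_gradient_spans_about_three_sd(self):
        cfg = SimConfig(seed=14, n_founders=400, n_generations=4, n_cg=40)
        bundle = simulate_study(cfg)
        ec = bundle.truth.cg_table["true_ec"]
        assert ec.mean() == pytest.approx(0.0, abs=1e-9)
        assert ec.std(ddof=0) == pytest.approx(1.0, abs=0.02)
        assert ec.min() < -1.8 and ec.max() > 1.8


class TestStudyBundle:
    def test_seeded_reproducibility(self):
        b1 = simulate_study(SimConfig(seed=33, n_founders=40, n_snps=80))
        b2 = simulate_study(SimConfig(seed=33, n_founders=40, n_snps=80))
        assert np.array_equal(b1.geno.calls, b2.geno.calls)
        pd.testing.assert_frame_equal(b1.target_phenos, b2.target_phenos)
        pd.testing.assert_frame_equal(b1.descriptor_phenos, b2.descriptor_phenos)

    def test_truth_supports_per_level_variance(self, small_bundle):
        t = small_bundle.truth
        v = t.genetic_variance_at(0.0)
        assert v == pytest.approx(0.5 * t.true_K[0, 0])

    def test_genotyped_subset_and_missingness(self):
        cfg = SimConfig(seed=44, n_founders=60, n_generations=3,
                        genotyped_fraction=0.3, missing_rate=0.05, n_snps=200)
        b = simulate_study(cfg)
        assert b.geno.n_animals == round(0.3 * b.ped.n)
        miss = (b.geno.calls == -1).mean()
        assert 0.03 < miss < 0.07
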