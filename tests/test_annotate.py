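import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ssgrn.annotate import (
    AnnotationSet,
    hypergeom_enrichment,
    map_windows,
    pairwise_r2,
    read_bed,
    read_gff3,
    read_gmt,
)
from ssgrn.io import GenotypeMatrix


def toy_geno(calls, pos=None, chrom=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        [f"a{i}" for i in range(n)],
        [f"s{k}" for k in range(m)],
        chrom if chrom is not None else np.ones(m, dtype=int),
        pos if pos is not None else np.arange(1, m + 1) * 1000,
        calls,
    )


class TestPairwiseR2:
    def test_self_is_one(self, rng):
        g = toy_geno(rng.binomial(2, 0.4, (50, 3)))
        out = pairwise_r2(g, "s1", window_bp=10_000)
        assert out.set_index("snp").loc["s1", "r2"] == pytest.approx(1.0)

    def test_duplicated_column_is_one(self, rng):
        x = rng.binomial(2, 0.4, 50)
        g = toy_geno(np.column_stack([x, x]))
        out = pairwise_r2(g, "s0", window_bp=10_000)
        assert out.set_index("snp").loc["s1", "r2"] == pytest.approx(1.0)

    def test_perfect_repulsion_is_one(self, rng):
        x = rng.binomial(2, 0.5, 60)
        g = toy_geno(np.column_stack([x, 2 - x]))
        out = pairwise_r2(g, "s0", window_bp=10_000)
        assert out.set_index("snp").loc["s1", "r2"] == pytest.approx(1.0)

    def test_independent_pairs_mean_near_one_over_n_minus_one(self, rng):
        n = 40
        calls = rng.binomial(2, 0.5, (n, 400))
        g = toy_geno(calls)
        out = pairwise_r2(g, "s0", window_bp=10**9)
        others = out[out["snp"] != "s0"]["r2"]
        assert others.mean() == pytest.approx(1 / (n - 1), rel=0.25)

    def test_allele_flip_invariance(self, rng):
        a = rng.binomial(2, 0.4, 50)
        b = rng.binomial(2, 0.4, 50)
        g1 = toy_geno(np.column_stack([a, b]))
        g2 = toy_geno(np.column_stack([a, 2 - b]))
        r1 = pairwise_r2(g1, "s0", 10_000).loc[1, "r2"]
        r2 = pairwise_r2(g2, "s0", 10_000).loc[1, "r2"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_monomorphic_comparator_skipped(self, rng):
        a = rng.binomial(2, 0.4, 30)
        g = toy_geno(np.column_stack([a, np.zeros(30, dtype=int)]))
        with pytest.warns(UserWarning, match="monomorphic"):
            out = pairwise_r2(g, "s0", 10_000)
        assert "s1" not in set(out["snp"])

    def test_missing_handled_pairwise(self, rng):
        a = rng.binomial(2, 0.5, 40)
        b = a.copy()
        b[:5] = -1
        g = toy_geno(np.column_stack([a, b]))
        out = pairwise_r2(g, "s0", 10_000)
        assert out.set_index("snp").loc["s1", "r2"] == pytest.approx(1.0)


def genes_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


class TestWindows:
    def test_closed_boundary_included(self):
        ann = AnnotationSet(genes_df([("1", 100, 800_000, "g1")]))
        sig = pd.DataFrame({"snp": ["s"], "chrom": ["1"], "pos": [1_000_000]})
        out = map_windows(sig, ann, window_bp=200_000)
        assert list(out["id"]) == ["g1"]  # gene end exactly 200 kb away

    def test_one_bp_beyond_excluded(self):
        ann = AnnotationSet(genes_df([("1", 100, 799_999, "g1")]))
        sig = pd.DataFrame({"snp": ["s"], "chrom": ["1"], "pos": [1_000_000]})
        assert len(map_windows(sig, ann, window_bp=200_000)) == 0

    def test_unknown_chromosome_skipped_with_warning(self):
        ann = AnnotationSet(genes_df([("1", 100, 200, "g1")]))
        sig = pd.DataFrame({"snp": ["s"], "chrom": ["99"], "pos": [150]})
        with pytest.warns(UserWarning, match="unannotated"):
            out = map_windows(sig, ann)
        assert len(out) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_interval_scan(self, seed):
        rng = np.random.default_rng(seed)
        genes = genes_df(
            [(str(rng.integers(1, 3)), int(s), int(s + rng.integers(1, 5000)), f"g{i}")
             for i, s in enumerate(rng.integers(1, 10**6, 12))]
        )
        sig = pd.DataFrame(
            {"snp": [f"s{i}" for i in range(5)],
             "chrom": [str(c) for c in rng.integers(1, 3, 5)],
             "pos": rng.integers(1, 10**6, 5)}
        )
        w = 50_000
        out = map_windows(sig, AnnotationSet(genes), window_bp=w)
        got = set(zip(out["snp"], out["id"]))
        expected = set()
        for _, s in sig.iterrows():
            for _, g in genes.iterrows():
                if g["chrom"] == s["chrom"] and g["start"] <= s["pos"] + w and g["end"] >= s["pos"] - w:
                    expected.add((s["snp"], g["gene_id"]))
        assert got == expected

    def test_qtl_intervals_reported(self):
        ann = AnnotationSet(
            genes_df([("1", 600, 700, "g1")]),
            qtl=pd.DataFrame({"chrom": ["1"], "start": [900], "end": [1200],
                              "trait": ["weight"]}),
        )
        sig = pd.DataFrame({"snp": ["s"], "chrom": ["1"], "pos": [1000]})
        out = map_windows(sig, ann, window_bp=500)
        assert set(out["feature"]) == {"gene", "qtl"}


def hypergeom_pmf_sum_oracle(N, K, n, k):
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestEnrichment:
    def make_ann(self, sets, background):
        genes = genes_df([("1", i + 1, i + 1, g) for i, g in enumerate(sorted(background))])
        return AnnotationSet(genes, gene_sets=sets)

    def test_whole_background_set_p_one(self):
        bg = {f"g{i}" for i in range(10)}
        ann = self.make_ann({"all": set(bg)}, bg)
        out = hypergeom_enrichment({"g0", "g1"}, ann)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_exact_extreme_configuration(self):
        bg = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(5)}
        ann = self.make_ann({"t": target}, bg)
        out = hypergeom_enrichment(target, ann)
        assert out.loc[0, "p_value"] == pytest.approx(1 / 15504, rel=1e-9)

    @pytest.mark.parametrize("N", [5, 9, 14, 21, 30])
    def test_tail_formula_matches_pmf_summation(self, N):
        for K in range(0, N + 1, max(1, N // 4)):
            for n in range(0, N + 1, max(1, N // 4)):
                for k in range(0, min(K, n) + 1):
                    assert float(hypergeom.sf(k - 1, N, K, n)) == pytest.approx(
                        hypergeom_pmf_sum_oracle(N, K, n, k), rel=1e-9, abs=1e-12
                    )

    def test_p_monotone_in_overlap(self):
        vals = [hypergeom_pmf_sum_oracle(30, 10, 8, k) for k in range(0, 9)]
        assert (np.diff(vals) <= 1e-15).all()

    def test_member_outside_background_rejected(self):
        bg = {"g0", "g1"}
        with pytest.raises(ValueError, match="outside the background"):
            self.make_ann({"bad": {"zz"}}, bg)

    def test_enriched_flag_uses_bh(self):
        bg = {f"g{i}" for i in range(40)}
        sets = {"hit": {f"g{i}" for i in range(5)},
                "null": {f"g{i}" for i in range(20, 30)}}
        ann = self.make_ann(sets, bg)
        out = hypergeom_enrichment({f"g{i}" for i in range(5)}, ann, fdr_level=0.05)
        row = out.set_index("gene_set")
        assert bool(row.loc["hit", "enriched"]) is True
        assert bool(row.loc["null", "enriched"]) is False


class TestReaders:
    def test_bed_zero_based_converted(self, tmp_path):
        f = tmp_path / "g.bed"
        f.write_text("1\t0\t100\tgeneA\n2\t499\t600\tgeneB\n")
        df = read_bed(f)
        assert df.loc[0, "start"] == 1 and df.loc[0, "end"] == 100
        assert df.loc[1, "start"] == 500

    def test_gff3_gene_features(self, tmp_path):
        f = tmp_path / "g.gff3"
        f.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=gene:ENSG1;Name=ABC\n"
            "1\tsrc\texon\t1000\t1100\t.\t+\t.\tID=exon1\n"
        )
        df = read_gff3(f)
        assert len(df) == 1
        assert df.loc[0, "gene_id"] == "ENSG1"
        assert df.loc[0, "start"] == 1000

    def test_gmt_parse(self, tmp_path):
        f = tmp_path / "s.gmt"
        f.write_text("setA\tdesc\tg1\tg2\ng3\nsetB\tdesc\tg4\n")
        sets = read_gmt(f)
        assert sets["setA"] == {"g1", "g2"}
        assert sets["setB"] == {"g4"}
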