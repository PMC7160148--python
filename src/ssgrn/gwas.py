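"""SNP effects back-solved from reaction-norm breeding values, projected to
environment levels, and tested.

Per-SNP intercept/slope effects come from the genomic-BLUP identity

    alpha = Mc' G^-1 a_hat / (2 sum p q)

over the genotyped animals retained by the accuracy filter, where Mc is the
dosage matrix centered by 2p and G the VanRaden relationship built from the
same markers.  Projection to a gradient level is the dot product with the
Legendre basis row.  Effects are standardized genome-wide within each level
to form z-scores (the literal per-SNP standardization, which collapses to a
constant magnitude, is available for inspection), converted to two-sided
normal p-values, and flagged at -log10(p) > 6 with BH q-values and the
classic ratio-form FDR estimate reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix
from .reaction_norm import RNSolution, genetic_variance_at, legendre_basis
from .relationships import RelationshipMatrix

CHI2_1_MEDIAN = 0.456  # conventional null median of a 1-df chi-square


def backsolve_snp_coefficients(
    rn: RNSolution,
    geno: GenotypeMatrix,
    accuracy_min: float = 0.40,
    G: RelationshipMatrix | None = None,
    freqs: np.ndarray | None = None,
):
    """Back-solve per-SNP (intercept, slope) effects from coefficient BLUPs.

    Animals below ``accuracy_min`` on either reaction-norm coefficient are
    excluded.  ``G`` (possibly blended) is subset to the retained animals and
    inverted; when absent, an unblended VanRaden matrix is built from the
    retained animals with frequencies from the full genotyped set.

    Returns (alpha (n_snps, q), retained animal ids, allele freqs used).
    """
    rn_index = {a: i for i, a in enumerate(rn.animal_ids)}
    geno_rows, rn_rows = [], []
    for gi, a in enumerate(geno.animal_ids):
        i = rn_index.get(a)
        if i is not None:
            geno_rows.append(gi)
            rn_rows.append(i)
    if not geno_rows:
        raise ValueError("no genotyped animal appears in the fitted model")
    geno_rows = np.array(geno_rows)
    rn_rows = np.array(rn_rows)
    ok = np.all(rn.accuracy[rn_rows] >= accuracy_min, axis=1)
    if not ok.any():
        raise ValueError(
            f"no genotyped animal reaches accuracy {accuracy_min} on both coefficients"
        )
    geno_rows, rn_rows = geno_rows[ok], rn_rows[ok]
    p = geno.allele_freq if freqs is None else np.asarray(freqs, dtype=float)
    sub = geno.subset(animals=geno_rows)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    Mc = sub.dosage_matrix(freqs=p)[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    if G is None:
        if Mc.shape[0] > Mc.shape[1]:
            raise ValueError(
                "unblended G is singular with more retained animals than SNPs; "
                "pass a blended G"
            )
        Gmat = (Mc @ Mc.T) / denom
    else:
        order = {a: i for i, a in enumerate(G.animal_ids)}
        gidx = np.array([order[a] for a in sub.animal_ids])
        Gmat = G.values[np.ix_(gidx, gidx)]
    Ginv_a = np.linalg.solve(Gmat, rn.coefficients[rn_rows])
    alpha = np.full((geno.n_snps, rn.coefficients.shape[1]), 0.0)
    alpha[poly] = (Mc.T @ Ginv_a) / denom
    return alpha, sub.animal_ids, p


def project_effect(alpha_k: np.ndarray, ec: float) -> float | np.ndarray:
    """SNP effect at one gradient level: alpha_k . phi(ec).

    ``alpha_k`` may be a single coefficient vector or an (n_snps, q) array.
    """
    alpha_k = np.asarray(alpha_k, dtype=float)
    q = alpha_k.shape[-1]
    phi = legendre_basis(ec, q - 1)
    out = alpha_k @ phi
    return float(out) if out.ndim == 0 else out


def variance_explained(u_hat, p_k, sigma2_a_ec: float) -> np.ndarray | float:
    """Percent of the level's genetic variance explained by a SNP:
    100 * 2 p q u^2 / sigma2_a(EC)."""
    if sigma2_a_ec <= 0:
        raise ValueError("genetic variance at the level must be positive")
    u = np.asarray(u_hat, dtype=float)
    p = np.asarray(p_k, dtype=float)
    return 100.0 * 2.0 * p * (1.0 - p) * u**2 / sigma2_a_ec


def literal_z(u_hat, p_k, sigma2_a_ec: float) -> np.ndarray:
    """The printed per-SNP standardization u / sqrt(2 p q u^2 / s2a * 100).

    Collapses to a constant magnitude by construction; kept for inspection
    only and never used for p-values.
    """
    var_pct = variance_explained(u_hat, p_k, sigma2_a_ec)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.asarray(u_hat) / np.sqrt(var_pct)


def snp_test(
    effects: np.ndarray,
    threshold_neglog10p: float = 6.0,
    fdr_level: float = 0.05,
    freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Genome-wide test of back-solved effects at one gradient level.

    z-scores standardize the effects by their genome-wide mean and sd within
    the level; p-values are two-sided normal; BH q-values and the fixed
    -log10(p) threshold decision are both reported.

    When allele frequencies are supplied the effects are first scaled by
    sqrt(2 p q): the sampling variance of a back-solved effect is
    proportional to its marker's heterozygosity, and pooling unscaled
    effects across frequencies produces a heavy-tailed scale mixture that
    deflates the median statistic while inflating the tails.
    """
    from statsmodels.stats.multitest import multipletests

    u = np.asarray(effects, dtype=float)
    if len(u) < 2:
        raise ValueError("need >= 2 SNP effects")
    if not np.all(np.isfinite(u)):
        raise ValueError("effects must be finite")
    if freqs is not None:
        p_k = np.asarray(freqs, dtype=float)
        het = 2.0 * p_k * (1.0 - p_k)
        if np.any(~np.isfinite(het)) or np.any(het <= 0):
            raise ValueError("allele frequencies must be strictly inside (0, 1)")
        u = u / np.sqrt(het)
    sd = u.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(u).max())):
        raise ValueError("zero sd of SNP effects; z-scores undefined")
    z = (u - u.mean()) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    _, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    sig = -np.log10(p) > threshold_neglog10p
    return pd.DataFrame({"effect": u, "z": z, "p_value": p, "fdr_q": q, "significant": sig})


def ratio_fdr_estimate(p_values: np.ndarray, p_sig: float = 0.01) -> float:
    """Ratio-form FDR estimate n_m * p_sig / n_sig at threshold ``p_sig``
    (NaN when nothing is significant)."""
    p = np.asarray(p_values, dtype=float)
    n_sig = int(np.sum(p < p_sig))
    if n_sig == 0:
        return float("nan")
    return len(p) * p_sig / n_sig


def inflation_factor(z: np.ndarray, constant: float = CHI2_1_MEDIAN) -> float:
    """Genomic inflation lambda = median(z^2) / 0.456 (1-df chi-square
    median convention)."""
    z = np.asarray(z, dtype=float)
    if len(z) == 0:
        raise ValueError("no z-scores")
    return float(np.median(z**2) / constant)


def inflation_factor_literal(p_values: np.ndarray, constant: float = CHI2_1_MEDIAN) -> float:
    """The printed variant median(p)/0.456; ~1.096 for any null set, reported
    for comparison only."""
    return float(np.median(np.asarray(p_values, dtype=float)) / constant)


def stratify_shared_specific(sig_sets: dict) -> dict:
    """Partition significant SNP ids into the 7 Venn cells of three levels.

    Keys of the result are tuples of level names (singletons = specific,
    pairs = shared by exactly those two, the full tuple = shared by all).
    """
    names = list(sig_sets)
    sets = {k: set(v) for k, v in sig_sets.items()}
    out = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[c] for c in combo))
            others = [sets[k] for k in names if k not in combo]
            if others:
                inter = inter - set.union(*others)
            out[combo] = inter
    return out


def snp_effect_table(
    rn: RNSolution,
    geno: GenotypeMatrix,
    ec_levels,
    level_names=None,
    accuracy_min: float = 0.40,
    G: RelationshipMatrix | None = None,
    threshold_neglog10p: float = 6.0,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Full per-SNP table across gradient levels, Manhattan-plot ready.

    Columns: snp, chrom, pos, p_k, alpha coefficients, then per level the
    projected effect, percent variance explained, z, p, q and the
    significance flag.
    """
    levels = list(ec_levels)
    if level_names is None:
        level_names = [f"ec{str(e).replace('-', 'm')}" for e in levels]
    alpha, retained, p = backsolve_snp_coefficients(
        rn, geno, accuracy_min=accuracy_min, G=G
    )
    df = pd.DataFrame(
        {"snp": geno.snp_ids, "chrom": geno.chrom, "pos": geno.pos, "p_k": p}
    )
    for j in range(alpha.shape[1]):
        df[f"alpha{j}"] = alpha[:, j]
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    for e, name in zip(levels, level_names):
        u = project_effect(alpha, e)
        s2a = genetic_variance_at(rn.K, e)
        res = snp_test(
            u[poly], threshold_neglog10p=threshold_neglog10p,
            fdr_level=fdr_level, freqs=p[poly],
        )
        df[f"effect_{name}"] = u
        df[f"pctvar_{name}"] = 0.0
        df.loc[poly, f"pctvar_{name}"] = variance_explained(u[poly], p[poly], s2a)
        for col, fill in (("z", 0.0), ("p", 1.0), ("q", 1.0)):
            full = np.full(len(df), fill)
            full[poly] = res[{"z": "z", "p": "p_value", "q": "fdr_q"}[col]]
            df[f"{col}_{name}"] = full
        sig = np.zeros(len(df), dtype=bool)
        sig[poly] = res["significant"]
        df[f"sig_{name}"] = sig
    df.attrs["retained_animals"] = list(retained)
    df.attrs["level_names"] = list(level_names)
    return df
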