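"""Pedigree (A), genomic (G) and single-step blended (H) relationship matrices.

All algebra is dense; the intended scale is up to ~10,000 animals.  The
single-step inverse follows

    H^-1 = A^-1 + [0 0; 0 Gb^-1 - A22^-1]

on the genotyped block, with Gb = w*G + (1-w)*A22 to guarantee invertibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .io import GenotypeMatrix, Pedigree


@dataclass
class RelationshipMatrix:
    animal_ids: np.ndarray
    values: np.ndarray
    kind: str  # A | A_inverse | A22 | G | G_blended | H_inverse

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.animal_ids, columns=self.animal_ids)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method (with inbreeding).

    A_ii = 1 + F_i where F_i is half the relationship between the parents.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return RelationshipMatrix(ped.ids, A, "A")


def inbreeding(ped: Pedigree) -> np.ndarray:
    return np.diag(build_A(ped).values) - 1.0


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> RelationshipMatrix:
    """A^-1 by Henderson's rules with inbreeding accounted for.

    Mendelian-sampling variances d_i use parental inbreeding coefficients
    (computed via the tabular method unless supplied).
    """
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        alpha = 1.0 / di
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= 0.5 * alpha
                Ainv[p, i] -= 0.5 * alpha
                Ainv[p, p] += 0.25 * alpha
        if s >= 0 and d >= 0:
            Ainv[s, d] += 0.25 * alpha
            Ainv[d, s] += 0.25 * alpha
    return RelationshipMatrix(ped.ids, Ainv, "A_inverse")


def build_G(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = Mc Mc' / (2 * sum p q).

    Mc is the dosage matrix column-centered by 2p; missing calls are
    mean-imputed at construction time.  Frequencies default to the observed
    genotyped set.
    """
    p = geno.allele_freq if freqs is None else np.asarray(freqs, dtype=float)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; G denominator is zero")
    M = geno.dosage_matrix(freqs=p)[:, poly]
    pk = p[poly]
    Mc = M - 2.0 * pk
    denom = 2.0 * np.sum(pk * (1.0 - pk))
    G = (Mc @ Mc.T) / denom
    return RelationshipMatrix(geno.animal_ids, G, "G")


def subset_matrix(rel: RelationshipMatrix, animal_ids) -> RelationshipMatrix:
    order = {a: i for i, a in enumerate(rel.animal_ids)}
    idx = np.array([order[a] for a in animal_ids], dtype=np.int64)
    return RelationshipMatrix(
        np.asarray(animal_ids, dtype=object), rel.values[np.ix_(idx, idx)], rel.kind
    )


def _chol_inverse(M: np.ndarray, label: str) -> np.ndarray:
    try:
        c = cho_factor(M, lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"{label} is singular or not positive definite: {e}")
    return cho_solve(c, np.eye(M.shape[0]))


def build_H_inverse(
    Ainv: RelationshipMatrix,
    A22: RelationshipMatrix,
    G: RelationshipMatrix,
    blend_weight: float = 0.95,
) -> RelationshipMatrix:
    """Single-step relationship inverse on the full pedigree ordering.

    The genotyped-block correction Gb^-1 - A22^-1 (Gb = w G + (1-w) A22) is
    added on the indices of the genotyped animals; with no genotyped animals
    H^-1 = A^-1 exactly.
    """
    if A22.n != G.n or list(A22.animal_ids) != list(G.animal_ids):
        raise ValueError("A22 and G must cover the same genotyped animals in order")
    H = Ainv.values.copy()
    if G.n > 0:
        order = {a: i for i, a in enumerate(Ainv.animal_ids)}
        try:
            gidx = np.array([order[a] for a in G.animal_ids])
        except KeyError as e:
            raise ValueError(f"genotyped animal {e.args[0]!r} not in pedigree")
        Gb = blend_weight * G.values + (1.0 - blend_weight) * A22.values
        try:
            Gb_inv = _chol_inverse(Gb, "blended G")
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "blended G is singular; lower blend_weight to add more pedigree weight"
            )
        A22_inv = _chol_inverse(A22.values, "A22")
        H[np.ix_(gidx, gidx)] += Gb_inv - A22_inv
    return RelationshipMatrix(Ainv.animal_ids, H, "H_inverse")


def build_relationships(
    ped: Pedigree,
    geno: GenotypeMatrix | None,
    blend_weight: float = 0.95,
) -> dict[str, RelationshipMatrix]:
    """Convenience: A, A^-1 and (when genotypes are present) A22, G, H^-1."""
    A = build_A(ped)
    Ainv = build_A_inverse(ped, F=np.diag(A.values) - 1.0)
    out = {"A": A, "A_inverse": Ainv}
    if geno is not None and geno.n_animals > 0:
        in_ped = [a for a in geno.animal_ids if a in set(ped.ids)]
        g = geno.subset(animals=[list(geno.animal_ids).index(a) for a in in_ped])
        A22 = subset_matrix(A, g.animal_ids)
        A22.kind = "A22"
        G = build_G(g)
        Gb = RelationshipMatrix(
            G.animal_ids,
            blend_weight * G.values + (1.0 - blend_weight) * A22.values,
            "G_blended",
        )
        out.update(
            {"A22": A22, "G": G, "G_blended": Gb,
             "H_inverse": build_H_inverse(Ainv, A22, G, blend_weight)}
        )
    else:
        out["H_inverse"] = RelationshipMatrix(ped.ids, Ainv.values.copy(), "H_inverse")
    return out
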