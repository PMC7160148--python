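"""Reaction-norm model on Legendre polynomials of the environmental gradient.

The target trait is modelled as

    y_ij = F_cg + sum_f w_f Phi_f(EC_j) + sum_f a_fi Phi_f(EC_j) + e_ij

with per-animal random regression coefficients (intercept, slope at order 1)
whose covariance is K under the single-step relationship structure, and
residual variances heterogeneous over five classes of the gradient.  The
basis maps the +/-3 sd gradient onto [-1, 1] and uses normalized Legendre
polynomials Phi_f(x) = sqrt((2f+1)/2) P_f(x), the animal-breeding
convention; at order 1 any other affine mapping of EC only reparameterizes K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg

from .ec import ECDescriptor, assign_residual_class
from .mixed_model import (
    ModelSpec,
    accuracy_from_pev,
    build_fixed_design,
    reml_estimate,
    solve_mme,
)
from .relationships import RelationshipMatrix

EC_HALF_RANGE = 3.0


def legendre_basis(ec, order: int = 1) -> np.ndarray:
    """Normalized Legendre basis row(s) Phi_0..Phi_order at gradient value(s).

    Values beyond +/-3 sd are clamped to the domain edge with a warning.
    Returns shape (order+1,) for a scalar input, (n, order+1) for an array.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    arr = np.atleast_1d(np.asarray(ec, dtype=float))
    x = arr / EC_HALF_RANGE
    if np.any(np.abs(x) > 1 + 1e-12):
        warnings.warn("EC values beyond +/-3 sd clamped to the basis domain edge")
        x = np.clip(x, -1.0, 1.0)
    cols = []
    for f in range(order + 1):
        coef = np.zeros(f + 1)
        coef[f] = 1.0
        cols.append(np.sqrt((2 * f + 1) / 2.0) * npleg.legval(x, coef))
    out = np.column_stack(cols)
    return out[0] if np.ndim(ec) == 0 else out


@dataclass
class RNSolution:
    """Fitted reaction-norm model: per-animal coefficient BLUPs with PEV and
    accuracy, fixed effects, K estimate and residual-class variances."""

    animal_ids: np.ndarray
    coefficients: np.ndarray  # (m, q)
    pev: np.ndarray  # (m, q, q)
    accuracy: np.ndarray  # (m, q)
    K: np.ndarray
    residual_class_vars: np.ndarray
    fixed_effects: pd.Series
    order: int
    log_likelihood: float
    converged: bool = True

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def breeding_value_at(self, ec: float) -> np.ndarray:
        """Genomic breeding values projected to one gradient level."""
        return self.coefficients @ legendre_basis(ec, self.order)

    def coefficients_frame(self) -> pd.DataFrame:
        cols = {"animal": self.animal_ids}
        names = ["intercept", "slope"] + [f"coef{f}" for f in range(2, self.order + 1)]
        for j in range(self.coefficients.shape[1]):
            cols[names[j]] = self.coefficients[:, j]
            cols[f"acc_{names[j]}"] = self.accuracy[:, j]
        return pd.DataFrame(cols)


def fit_ssgrn(
    target_phenos: pd.DataFrame,
    ecd: ECDescriptor,
    Hinv: RelationshipMatrix,
    start_K: np.ndarray | None = None,
    start_res: np.ndarray | None = None,
    order: int = 1,
    estimate_varcomps: bool = True,
    reml_tol: float = 1e-4,
    reml_max_iter: int = 100,
) -> RNSolution:
    """Fit the single-step reaction-norm model to the target trait.

    Every record's CG must have an environmental level in ``ecd``; the five
    residual classes are taken from it.  When ``estimate_varcomps`` is False
    the supplied (K, residual variances) are used as known.
    """
    df = target_phenos.reset_index(drop=True)
    missing = set(df["cg"]) - set(ecd.cg_ids)
    if missing:
        raise ValueError(f"no environmental level for CG(s): {sorted(missing)[:5]}")
    ec = ecd.level_of(df["cg"].to_numpy())
    if len(np.unique(ec)) == 1 and order >= 1:
        raise ValueError("single environmental level: reaction-norm slope unidentifiable")
    Phi = legendre_basis(ec, order)
    classes = assign_residual_class(ec) - 1
    X, names, _ = build_fixed_design(
        factors={"cg": df["cg"].to_numpy()},
        covariates={f"phi{f}": Phi[:, f] for f in range(order + 1)},
    )
    aidx = {a: i for i, a in enumerate(Hinv.animal_ids)}
    try:
        animal_index = np.array([aidx[a] for a in df["animal"]])
    except KeyError as e:
        raise KeyError(f"phenotyped animal {e.args[0]!r} missing from relationship matrix")
    q = order + 1
    vy = float(np.var(df["y"]))
    if start_K is None:
        start_K = np.eye(q) * vy / (2 * q)
    if start_res is None:
        start_res = np.full(5, 0.5 * vy)
    start_res = np.asarray(start_res, dtype=float)
    present = np.unique(classes)
    # keep only classes that occur; remap indices
    remap = -np.ones(5, dtype=int)
    remap[present] = np.arange(len(present))
    spec = ModelSpec(
        y=df["y"].to_numpy(float),
        X=X,
        rel_inv=Hinv,
        animal_index=animal_index,
        coef_design=Phi,
        K=np.asarray(start_K, dtype=float),
        residual_vars=start_res[present],
        residual_class=remap[classes],
        fixed_names=names,
    )
    if estimate_varcomps:
        res = reml_estimate(spec, method="AI", tol=reml_tol, max_iter=reml_max_iter)
        sol, K, rv_present, converged = res.solution, res.K, res.residual_vars, res.converged
    else:
        sol = solve_mme(spec)
        K, rv_present, converged = spec.K, spec.residual_vars, True
    rv_full = np.full(5, np.nan)
    rv_full[present] = rv_present
    acc = accuracy_from_pev(sol, K)
    return RNSolution(
        animal_ids=np.asarray(Hinv.animal_ids, dtype=object),
        coefficients=sol.coefficients,
        pev=sol.pev,
        accuracy=acc,
        K=K,
        residual_class_vars=rv_full,
        fixed_effects=sol.fixed_as_series(),
        order=order,
        log_likelihood=sol.log_likelihood,
        converged=converged,
    )


def genetic_variance_at(K: np.ndarray, ec: float, order: int | None = None) -> float:
    """Additive genetic variance at one gradient level: phi(ec) K phi(ec)'."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    order = K.shape[0] - 1 if order is None else order
    phi = legendre_basis(ec, order)
    return float(phi @ K @ phi)


def genetic_correlation(K: np.ndarray, ec1: float, ec2: float) -> float:
    """Genetic correlation of the trait expressed at two gradient levels."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    order = K.shape[0] - 1
    v1 = genetic_variance_at(K, ec1, order)
    v2 = genetic_variance_at(K, ec2, order)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero genetic variance at a level; correlation undefined")
    p1, p2 = legendre_basis(ec1, order), legendre_basis(ec2, order)
    return float(p1 @ K @ p2 / np.sqrt(v1 * v2))


def heritability_at(K: np.ndarray, residual_class_vars, ec: float) -> float:
    """h^2(ec) using the residual variance of the class containing ec."""
    rv = np.asarray(residual_class_vars, dtype=float)
    cls = assign_residual_class(float(ec)) - 1
    s2a = genetic_variance_at(K, ec)
    s2e = rv[cls]
    if s2e < 0 or not np.isfinite(s2e):
        raise ValueError(f"no residual variance for class {cls + 1}")
    return s2a / (s2a + s2e)
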