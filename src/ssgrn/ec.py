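"""Environmental gradient from contemporary-group effects (stage 1).

Contemporary-group (CG) BLUEs for the descriptor trait (e.g. yearling body
weight) are estimated under a single-step animal model, standardized to mean
0 / sd 1 over CGs, winsorized to the +/-3 sd range, and mapped to five
residual-variance classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_model import ModelSpec, build_fixed_design, reml_estimate, solve_mme
from .relationships import RelationshipMatrix

#: fixed residual-class boundaries on the standardized gradient
CLASS_EDGES = np.array([-1.5, -0.5, 0.0, 1.5])


@dataclass
class ECDescriptor:
    """Per-CG environmental levels: raw BLUE, standardized (clipped) value,
    unclipped z-score and residual class."""

    cg_ids: np.ndarray
    blue_raw: np.ndarray
    ec: np.ndarray
    ec_unclipped: np.ndarray
    residual_class: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cg_id": self.cg_ids,
                "blue_raw": self.blue_raw,
                "ec": self.ec,
                "ec_unclipped": self.ec_unclipped,
                "residual_class": self.residual_class,
            }
        )

    def level_of(self, cgs) -> np.ndarray:
        lut = dict(zip(self.cg_ids, self.ec))
        try:
            return np.array([lut[c] for c in cgs], dtype=float)
        except KeyError as e:
            raise KeyError(f"no environmental level for CG {e.args[0]!r}") from None


def estimate_cg_blues(
    phenos: pd.DataFrame,
    Hinv: RelationshipMatrix,
    varcomps: tuple[float, float] | None = None,
    age_col: str = "age",
    reml_tol: float = 1e-4,
) -> tuple[pd.Series, object]:
    """BLUEs of CG effects for the descriptor trait.

    Fits y = CG + age*b + animal + e with the supplied relationship inverse;
    variance components (sigma2_a, sigma2_e) are used as given or estimated
    by AI-REML when absent.  Returns (BLUE per CG, fitted solution).
    """
    df = phenos.reset_index(drop=True)
    covars = {age_col: df[age_col].to_numpy(float)} if age_col in df.columns else None
    X, names, _ = build_fixed_design(factors={"cg": df["cg"].to_numpy()}, covariates=covars)
    aidx = {a: i for i, a in enumerate(Hinv.animal_ids)}
    try:
        animal_index = np.array([aidx[a] for a in df["animal"]])
    except KeyError as e:
        raise KeyError(f"phenotyped animal {e.args[0]!r} missing from relationship matrix")
    if varcomps is None:
        vy = float(np.var(df["y"]))
        spec = ModelSpec(
            y=df["y"].to_numpy(float), X=X, rel_inv=Hinv, animal_index=animal_index,
            K=np.array([[vy / 3]]), residual_vars=2 * vy / 3, fixed_names=names,
        )
        res = reml_estimate(spec, method="AI", tol=reml_tol)
        sol = res.solution
    else:
        s2a, s2e = varcomps
        spec = ModelSpec(
            y=df["y"].to_numpy(float), X=X, rel_inv=Hinv, animal_index=animal_index,
            K=np.array([[s2a]]), residual_vars=s2e, fixed_names=names,
        )
        sol = solve_mme(spec)
    fixed = sol.fixed_as_series()
    cg_rows = fixed[fixed.index.str.startswith("cg[")]
    cg_ids = [ix[3:-1] for ix in cg_rows.index]
    return pd.Series(cg_rows.to_numpy(), index=cg_ids, name="blue"), sol


def standardize_ec(blues: pd.Series | np.ndarray, clip: float = 3.0) -> ECDescriptor:
    """Standardize CG BLUEs to mean 0 / sd 1 (population sd, unweighted over
    CGs) and winsorize beyond +/-clip; both raw and clipped values are kept."""
    if isinstance(blues, pd.Series):
        cg_ids = np.asarray(blues.index, dtype=object)
        vals = blues.to_numpy(float)
    else:
        vals = np.asarray(blues, dtype=float)
        cg_ids = np.arange(len(vals)).astype(object)
    if len(np.unique(vals)) < 2:
        raise ValueError("need >= 2 distinct CG BLUEs to standardize")
    sd = vals.std()  # population convention (divide by n)
    if sd == 0:
        raise ValueError("zero sd of CG BLUEs")
    z = (vals - vals.mean()) / sd
    ec = np.clip(z, -clip, clip)
    return ECDescriptor(cg_ids, vals, ec, z, assign_residual_class(ec))


def assign_residual_class(ec) -> np.ndarray | int:
    """Residual class 1..5 from the standardized level.

    1: ec < -1.5; 2: [-1.5, -0.5); 3: [-0.5, 0); 4: [0, 1.5); 5: ec >= 1.5
    (the 1.5 boundary is assigned upward).
    """
    arr = np.atleast_1d(np.asarray(ec, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("ec must be finite")
    cls = 1 + np.searchsorted(CLASS_EDGES, arr, side="right")
    return cls if np.ndim(ec) else int(cls[0])


def kmeans_residual_classes(ec_values, k: int = 5, seed: int = 0) -> np.ndarray:
    """1-D k-means alternative to the fixed class map.

    Returns the sorted k-1 boundaries (midpoints between adjacent cluster
    centers).  Deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans

    vals = np.asarray(ec_values, dtype=float).reshape(-1, 1)
    if len(np.unique(vals)) < k:
        raise ValueError(f"need >= {k} distinct values for {k}-means")
    if k == 1:
        return np.array([])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(vals)
    centers = np.sort(km.cluster_centers_.ravel())
    return (centers[:-1] + centers[1:]) / 2.0
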