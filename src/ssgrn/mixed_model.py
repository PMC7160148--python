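"""Dense mixed-model engine for animal models with random-regression blocks.

The model is

    y = X b + Z a + e,   a ~ N(0, Arel (x) K),   e ~ N(0, R)

where ``Arel`` is a relationship matrix supplied through its inverse (pedigree
A or single-step H), ``K`` is the q x q covariance of the per-animal
coefficient block (q = 1 for a plain animal model, q = 2 for an
intercept+slope reaction norm), and R is diagonal with either a single
residual variance or one variance per residual class.

Z is held in structured form: each record points at one animal and carries a
q-vector of covariates (the Legendre basis row), so Z'R^-1 Z is block
diagonal per animal.  Random-effect equations are ordered animal-major
(animal i occupies rows i*q .. i*q+q-1), which makes the covariance penalty
kron(Arel^-1, K^-1).

Variance components are estimated by REML, either with EM steps (guaranteed
ascent) or average-information (AI) updates with EM fallback.  Reported
log-likelihoods omit the additive constant -q/2 log|Arel| (constant across
iterations), so only differences are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.linalg.lapack import dpotri

from .relationships import RelationshipMatrix


def _inverse_from_factor(fac) -> np.ndarray:
    """Full inverse from a cho_factor result via LAPACK dpotri."""
    c, lower = fac
    inv, info = dpotri(c, lower=lower)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed with info={info}")
    # dpotri fills only one triangle
    if lower:
        return np.tril(inv) + np.tril(inv, -1).T
    return np.triu(inv) + np.triu(inv, 1).T


@dataclass
class ModelSpec:
    """Data and design for one mixed-model fit.

    ``animal_index`` maps each record to a row of the relationship matrix;
    ``coef_design`` holds the q covariates multiplying that animal's random
    coefficients (a column of ones for a plain animal model).  ``rel_inv``
    may be a raw array or a :class:`RelationshipMatrix`.  Residuals are
    homogeneous when ``residual_class`` is None.
    """

    y: np.ndarray
    X: np.ndarray
    rel_inv: np.ndarray | RelationshipMatrix | None = None
    animal_index: np.ndarray | None = None
    coef_design: np.ndarray | None = None
    K: np.ndarray | None = None
    residual_vars: np.ndarray | float = 1.0
    residual_class: np.ndarray | None = None
    fixed_names: list[str] | None = None
    animal_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X rows must match len(y)")
        if isinstance(self.rel_inv, RelationshipMatrix):
            if self.animal_ids is None:
                self.animal_ids = self.rel_inv.animal_ids
            self.rel_inv = self.rel_inv.values
        if self.rel_inv is not None:
            self.rel_inv = np.asarray(self.rel_inv, dtype=float)
            self.animal_index = np.asarray(self.animal_index, dtype=np.int64)
            if self.coef_design is None:
                self.coef_design = np.ones((n, 1))
            self.coef_design = np.atleast_2d(np.asarray(self.coef_design, dtype=float))
            if self.coef_design.shape != (n, self.q):
                raise ValueError("coef_design must be (n_records, q)")
            self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
            if self.K.shape != (self.q, self.q):
                raise ValueError("K must be q x q")
            if not np.allclose(self.K, self.K.T):
                raise ValueError("K must be symmetric")
        if np.isscalar(self.residual_vars):
            self.residual_vars = np.array([float(self.residual_vars)])
        else:
            self.residual_vars = np.asarray(self.residual_vars, dtype=float)
        if self.residual_class is None:
            self.residual_class = np.zeros(n, dtype=np.int64)
        else:
            self.residual_class = np.asarray(self.residual_class, dtype=np.int64)
        if self.residual_class.max() >= len(self.residual_vars):
            raise ValueError("a residual class has no variance")
        if np.any(self.residual_vars <= 0):
            raise ValueError("residual variances must be positive")

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return 0 if self.rel_inv is None else self.rel_inv.shape[0]

    @property
    def q(self) -> int:
        if self.coef_design is not None:
            return self.coef_design.shape[1]
        return 0 if self.K is None else np.atleast_2d(self.K).shape[0]


@dataclass
class MMESolution:
    """BLUE/BLUP solutions with prediction-error variances."""

    fixed_effects: np.ndarray
    fixed_names: list[str] | None
    aliased: np.ndarray
    coefficients: np.ndarray  # (m, q)
    pev: np.ndarray  # (m, q, q)
    residuals: np.ndarray
    log_likelihood: float
    animal_ids: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def fixed_as_series(self):
        import pandas as pd

        names = self.fixed_names or [f"b{i}" for i in range(len(self.fixed_effects))]
        return pd.Series(self.fixed_effects, index=names)


def build_fixed_design(
    factors: dict | None = None,
    covariates: dict | None = None,
    intercept: bool = False,
    drop_first: bool = False,
):
    """Assemble a dense fixed-effect design from factors and covariates.

    The first factor is coded with all its levels when ``intercept`` is
    False (cell-means coding); subsequent factors (or all, when
    ``drop_first``) drop their first level.  Returns (X, names, level_maps).
    """
    blocks, names = [], []
    level_maps = {}
    n = None
    if intercept:
        blocks.append(None)  # placeholder, fixed below
        names.append("(intercept)")
    first_full = not intercept and not drop_first
    for fname, codes in (factors or {}).items():
        codes = np.asarray(codes)
        n = len(codes)
        levels = list(dict.fromkeys(codes))  # stable order of appearance
        level_maps[fname] = levels
        keep = levels if first_full else levels[1:]
        first_full = False
        ind = np.zeros((n, len(keep)))
        pos = {lv: j for j, lv in enumerate(keep)}
        for r, c in enumerate(codes):
            if c in pos:
                ind[r, pos[c]] = 1.0
        blocks.append(ind)
        names.extend([f"{fname}[{lv}]" for lv in keep])
    for cname, vals in (covariates or {}).items():
        v = np.asarray(vals, dtype=float).reshape(-1, 1)
        n = len(v)
        blocks.append(v)
        names.append(cname)
    if intercept:
        blocks[0] = np.ones((n, 1))
    X = np.hstack([b for b in blocks])
    return X, names, level_maps


class _MMEngine:
    """Workspace shared across REML iterations for one ModelSpec."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        X = spec.X
        # identifiability: keep a maximal independent column set (QR, pivoted)
        if X.shape[1] > 0:
            _, Rq, piv = qr(X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(Rq))
            tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
            rank = int(np.sum(diag > tol))
            keep = np.sort(piv[:rank])
        else:
            keep = np.array([], dtype=int)
        self.keep = keep
        self.aliased = np.ones(X.shape[1], dtype=bool)
        self.aliased[keep] = False
        if self.aliased.any() and spec.fixed_names:
            dropped = [spec.fixed_names[i] for i in np.where(self.aliased)[0]]
            warnings.warn(f"aliased fixed-effect columns constrained to zero: {dropped}")
        self.Xr = X[:, keep]
        self.pr = self.Xr.shape[1]
        self.m = spec.n_animals
        self.q = spec.q if self.m else 0
        self.has_random = self.m > 0 and self.q > 0
        if self.has_random:
            self.ai = spec.animal_index
            self.Phi = spec.coef_design
            self.relinv = spec.rel_inv
            # per-record column indices into the random block (animal-major)
            self.rand_cols = self.ai[:, None] * self.q + np.arange(self.q)[None, :]

    # -- assembly ---------------------------------------------------------

    def _rinv(self, res_vars):
        return 1.0 / res_vars[self.spec.residual_class]

    def assemble(self, K, res_vars):
        y = self.spec.y
        r = self._rinv(res_vars)
        pr, m, q = self.pr, self.m, self.q
        ntot = pr + m * q
        C = np.zeros((ntot, ntot))
        rhs = np.zeros(ntot)
        Xw = self.Xr * r[:, None]
        C[:pr, :pr] = Xw.T @ self.Xr
        rhs[:pr] = Xw.T @ y
        if self.has_random:
            Kinv = np.linalg.inv(K)
            Crand = np.kron(self.relinv, Kinv)
            # Z'R^-1 Z is block diagonal per animal
            outer = self.Phi[:, :, None] * self.Phi[:, None, :] * r[:, None, None]
            zz = np.zeros((m, q, q))
            np.add.at(zz, self.ai, outer)
            Cr4 = Crand.reshape(m, q, m, q)
            idx = np.arange(m)
            Cr4[idx, :, idx, :] += zz
            C[pr:, pr:] = Crand
            xz = np.zeros((m, q, pr))
            np.add.at(xz, self.ai, self.Phi[:, :, None] * Xw[:, None, :])
            C[:pr, pr:] = xz.reshape(m * q, pr).T
            C[pr:, :pr] = C[:pr, pr:].T
            rz = np.zeros((m, q))
            np.add.at(rz, self.ai, self.Phi * (r * y)[:, None])
            rhs[pr:] = rz.ravel()
        return C, rhs, r

    def solve(self, K, res_vars, want_cinv=False, want_quad=False):
        """Solve the MME; optionally return the full coefficient inverse and
        per-record quadratic forms w_r' C^-1 w_r (used by REML traces)."""
        spec = self.spec
        C, rhs, r = self.assemble(K, res_vars)
        try:
            fac = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "mixed-model equations are singular (confounded fixed effects "
                f"or non-PD K): {e}"
            )
        sol = cho_solve(fac, rhs)
        pr, m, q = self.pr, self.m, self.q
        beta = sol[:pr]
        U = sol[pr:].reshape(m, q) if self.has_random else np.zeros((0, q or 1))
        fitted = self.Xr @ beta
        if self.has_random:
            fitted = fitted + np.sum(self.Phi * U[self.ai], axis=1)
        ehat = spec.y - fitted
        yPy = float(spec.y @ (r * spec.y) - sol @ rhs)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(fac[0]))))
        logdetR = float(np.sum(np.log(res_vars[spec.residual_class])))
        logdetK = float(np.linalg.slogdet(K)[1]) * m if self.has_random else 0.0
        logL = -0.5 * (logdetR + logdetK + logdetC + yPy)
        out = {
            "beta": beta,
            "U": U,
            "ehat": ehat,
            "yPy": yPy,
            "logL": logL,
            "fac": fac,
            "rinv": r,
        }
        if want_cinv or want_quad:
            Cinv = _inverse_from_factor(fac)
            out["Cinv"] = Cinv
            out["pev"] = self._pev_blocks(Cinv)
            if want_quad:
                out["quad"] = self._record_quad(Cinv, out["pev"])
        return out

    def _pev_blocks(self, Cinv):
        pr, m, q = self.pr, self.m, self.q
        if not self.has_random:
            return np.zeros((0, 1, 1))
        Czz = Cinv[pr:, pr:].reshape(m, q, m, q)
        idx = np.arange(m)
        return Czz[idx, :, idx, :].copy()

    def _record_quad(self, Cinv, pev):
        """w_r' C^-1 w_r for each record r (w_r = the record's row of [X Z])."""
        pr = self.pr
        Xr = self.Xr
        t1 = np.einsum("ri,ij,rj->r", Xr, Cinv[:pr, :pr], Xr, optimize=True)
        if not self.has_random:
            return t1
        B = Xr @ Cinv[:pr, pr:]
        vals = np.take_along_axis(B, self.rand_cols, axis=1)
        t2 = 2.0 * np.sum(vals * self.Phi, axis=1)
        t3 = np.einsum("rl,rlm,rm->r", self.Phi, pev[self.ai], self.Phi, optimize=True)
        return t1 + t2 + t3

    def solve_rhs_only(self, f, K, res_vars, fac, r):
        """Given a stored factorization, compute P f = R^-1 (f - W sol_f)."""
        pr, m, q = self.pr, self.m, self.q
        rhs = np.zeros(pr + m * q)
        rf = r * f
        rhs[:pr] = self.Xr.T @ rf
        if self.has_random:
            rz = np.zeros((m, q))
            np.add.at(rz, self.ai, self.Phi * rf[:, None])
            rhs[pr:] = rz.ravel()
        sol = cho_solve(fac, rhs)
        fitted = self.Xr @ sol[:pr]
        if self.has_random:
            U = sol[pr:].reshape(m, q)
            fitted = fitted + np.sum(self.Phi * U[self.ai], axis=1)
        return r * (f - fitted)

    def full_fixed(self, beta):
        full = np.zeros(self.spec.X.shape[1])
        full[self.keep] = beta
        return full


def solve_mme(spec: ModelSpec, compute_pev: bool = True) -> MMESolution:
    """Solve Henderson's equations at the variance components held in ``spec``.

    Aliased (confounded) fixed-effect columns are detected by pivoted QR and
    constrained to zero with a warning naming them; estimable contrasts are
    unaffected by that choice.
    """
    eng = _MMEngine(spec)
    st = eng.solve(spec.K, spec.residual_vars, want_cinv=compute_pev)
    pev = st.get("pev")
    if pev is None:
        pev = np.zeros((eng.m, max(eng.q, 1), max(eng.q, 1)))
    return MMESolution(
        fixed_effects=eng.full_fixed(st["beta"]),
        fixed_names=spec.fixed_names,
        aliased=eng.aliased,
        coefficients=st["U"],
        pev=pev,
        residuals=st["ehat"],
        log_likelihood=st["logL"],
        animal_ids=spec.animal_ids,
        extras={"yPy": st["yPy"]},
    )


@dataclass
class REMLResult:
    K: np.ndarray
    residual_vars: np.ndarray
    solution: MMESolution
    converged: bool
    n_iter: int
    logL_path: list


def _floor_pd(K: np.ndarray, floor: float = 1e-8):
    w, V = np.linalg.eigh(K)
    if np.all(w > floor):
        return K, False
    w = np.maximum(w, floor)
    return (V * w) @ V.T, True


def _tri_pairs(q: int):
    return [(l, m) for l in range(q) for m in range(l + 1)]


def reml_estimate(
    spec: ModelSpec,
    method: str = "AI",
    tol: float = 1e-8,
    max_iter: int = 200,
    n_em_warmup: int = 2,
    verbose: bool = False,
) -> REMLResult:
    """REML estimation of K and the residual-class variances.

    ``method='EM'`` uses expectation-maximisation updates only (monotone in
    the REML log-likelihood); ``method='AI'`` runs EM warm-up steps followed
    by average-information updates with step halving and EM fallback.
    Convergence is declared when the largest relative parameter change drops
    below ``tol``.  A K update leaving the PD cone is floored at eigenvalue
    1e-8 with a warning.
    """
    if method not in ("EM", "AI"):
        raise ValueError("method must be 'EM' or 'AI'")
    eng = _MMEngine(spec)
    if not eng.has_random:
        raise ValueError("REML requires a random effect")
    if eng.pr >= spec.n_records:
        raise ValueError("more fixed-effect levels than records; data uninformative")
    q, m = eng.q, eng.m
    K = spec.K.astype(float).copy()
    rv = spec.residual_vars.astype(float).copy()
    classes = spec.residual_class
    n_class = len(rv)
    class_masks = [classes == c for c in range(n_class)]
    n_per_class = np.array([msk.sum() for msk in class_masks], dtype=float)
    if np.any(n_per_class == 0):
        raise ValueError("a residual class has no records")
    pairs = _tri_pairs(q)
    logL_path: list[float] = []
    converged = False
    floored = False
    it = 0
    prev_em = None  # (K_em, rv_em, logL) of the previous iterate
    last_was_ai = False

    for it in range(1, max_iter + 1):
        st = eng.solve(K, rv, want_cinv=True, want_quad=True)
        # an AI step that overshot shows up as a likelihood drop: back off to
        # the previous iterate's EM update (monotone) and continue
        if last_was_ai and prev_em is not None and st["logL"] < prev_em[2] - 1e-8:
            K, rv = prev_em[0], prev_em[1]
            last_was_ai = False
            st = eng.solve(K, rv, want_cinv=True, want_quad=True)
        logL_path.append(st["logL"])
        U, ehat, quad, Cinv = st["U"], st["ehat"], st["quad"], st["Cinv"]
        pr = eng.pr
        Caa = Cinv[pr:, pr:].reshape(m, q, m, q)
        S = np.empty((q, q))
        for l in range(q):
            for mm in range(q):
                S[l, mm] = float(np.sum(eng.relinv * Caa[:, l, :, mm]))
        S = 0.5 * (S + S.T)
        K_em = (U.T @ eng.relinv @ U + S) / m
        rv_em = np.array(
            [
                (np.sum(ehat[msk] ** 2) + np.sum(quad[msk])) / nc
                for msk, nc in zip(class_masks, n_per_class)
            ]
        )

        prev_em = (K_em, rv_em, st["logL"])
        use_em = method == "EM" or it <= n_em_warmup
        if use_em:
            K_new, rv_new = K_em, rv_em
            last_was_ai = False
        else:
            Kinv = np.linalg.inv(K)
            rinv = st["rinv"]
            Py = ehat * rinv
            fs, scores = [], []
            for (l, mm) in pairs:
                E = np.zeros((q, q))
                E[l, mm] = E[mm, l] = 1.0
                Mlm = E @ Kinv
                Sanim = U @ Mlm.T
                f = np.sum(eng.Phi * Sanim[eng.ai], axis=1)
                fs.append(f)
                T = Kinv @ E @ Kinv
                trPV = m * float(np.trace(Mlm)) - float(np.sum(S * T))
                scores.append(-0.5 * (trPV - float(f @ Py)))
            for c in range(n_class):
                msk = class_masks[c]
                f = np.where(msk, Py, 0.0)
                fs.append(f)
                trPV = n_per_class[c] / rv[c] - float(np.sum(quad[msk])) / rv[c] ** 2
                scores.append(-0.5 * (trPV - float(np.sum(Py[msk] ** 2))))
            npar = len(fs)
            Pf = [eng.solve_rhs_only(f, K, rv, st["fac"], rinv) for f in fs]
            AI = np.empty((npar, npar))
            for i in range(npar):
                for j in range(i, npar):
                    AI[i, j] = AI[j, i] = 0.5 * float(fs[i] @ Pf[j])
            scores = np.asarray(scores)
            try:
                delta = np.linalg.solve(AI + 1e-12 * np.eye(npar), scores)
            except np.linalg.LinAlgError:
                delta = None
            theta = np.concatenate([[K[l, mm] for (l, mm) in pairs], rv])
            # variance entries may move at most one order of magnitude per
            # iteration: an unrestricted AI step can crash a weakly informed
            # variance to ~0, from which recovery is EM-slow
            var_idx = np.array(
                [i for i, (l, mm) in enumerate(pairs) if l == mm]
                + list(range(len(pairs), len(theta)))
            )
            accepted = False
            if delta is not None:
                step = 1.0
                for _ in range(8):
                    cand = theta + step * delta
                    cand[var_idx] = np.clip(
                        cand[var_idx], theta[var_idx] / 10.0, theta[var_idx] * 10.0
                    )
                    K_try = K.copy()
                    for val, (l, mm) in zip(cand[: len(pairs)], pairs):
                        K_try[l, mm] = K_try[mm, l] = val
                    rv_try = cand[len(pairs):]
                    # accept the first candidate inside the parameter space;
                    # likelihood decreases are caught at the next iteration
                    if np.all(np.linalg.eigvalsh(K_try) > 0) and np.all(rv_try > 0):
                        K_new, rv_new, accepted = K_try, rv_try, True
                        break
                    step *= 0.5
            if not accepted:
                K_new, rv_new = K_em, rv_em
            last_was_ai = accepted
        K_new, did_floor = _floor_pd(K_new)
        floored = floored or did_floor
        # snap effectively-zero variance components to the boundary: EM decay
        # toward zero is geometric and would otherwise stall above tol
        scale = np.trace(K_new) / q + float(np.mean(rv_new))
        at_floor = np.diag(K_new) < 1e-5 * scale
        if at_floor.any():
            K_new = K_new.copy()
            for i in np.where(at_floor)[0]:
                K_new[i, :] = K_new[:, i] = 0.0
                K_new[i, i] = 1e-9 * scale
            floored = True
        theta_old = np.concatenate([[K[l, mm] for (l, mm) in pairs], rv])
        theta_new = np.concatenate([[K_new[l, mm] for (l, mm) in pairs], rv_new])
        rel = np.max(np.abs(theta_new - theta_old) / (np.abs(theta_old) + 1e-8))
        K, rv = K_new, rv_new
        if verbose:
            print(f"iter {it:3d}  logL {st['logL']:.6f}  rel-change {rel:.3e}")
        if rel < tol:
            converged = True
            break

    if floored:
        warnings.warn("K update left the PD cone; eigenvalues floored at 1e-8")
    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations; returning last iterate")
    final_spec = ModelSpec(
        y=spec.y,
        X=spec.X,
        rel_inv=spec.rel_inv,
        animal_index=spec.animal_index,
        coef_design=spec.coef_design,
        K=K,
        residual_vars=rv,
        residual_class=spec.residual_class,
        fixed_names=spec.fixed_names,
        animal_ids=spec.animal_ids,
    )
    sol = solve_mme(final_spec, compute_pev=True)
    return REMLResult(K=K, residual_vars=rv, solution=sol, converged=converged,
                      n_iter=it, logL_path=logL_path)


def accuracy_from_pev(sol: MMESolution, K: np.ndarray) -> np.ndarray:
    """Per-animal, per-coefficient accuracy sqrt(1 - PEV_qq / K_qq).

    PEV exceeding the prior variance by more than 1e-6 (numerically possible
    for animals with no information) is clamped to accuracy 0 with a warning.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    kd = np.diag(K)
    if np.any(kd <= 0):
        raise ValueError("K diagonal must be positive")
    pev_d = np.diagonal(sol.pev, axis1=1, axis2=2)
    over = pev_d > kd[None, :] + 1e-6
    if over.any():
        warnings.warn(f"{int(over.sum())} PEV values exceed the prior variance; accuracy clamped to 0")
    ratio = np.clip(1.0 - pev_d / kd[None, :], 0.0, 1.0)
    return np.sqrt(ratio)
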