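import numpy as np
import pytest

from ssgrn.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_bundle():
    """One small but complete synthetic study shared across tests."""
    cfg = SimConfig(seed=20260901, n_founders=120, n_generations=4,
                    n_snps=600, n_qtl=15, genotyped_fraction=0.5)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(17)


def make_random_mme_instance(seed, n_max=30, with_classes=True):
    """A small random mixed-model instance plus its dense GLS ingredients."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, n_max + 1))
    m = int(rng.integers(3, max(4, n // 2)))
    q = int(rng.integers(1, 3))
    B = rng.standard_normal((m, m))
    Arel = B @ B.T / m + np.eye(m)
    L = rng.standard_normal((q, q)) * 0.5
    K = L @ L.T + np.eye(q)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    ai = rng.integers(0, m, n)
    Phi = rng.standard_normal((n, q))
    if with_classes:
        nc = int(rng.integers(1, 4))
        classes = rng.integers(0, nc, n)
        rv = rng.uniform(0.5, 2.0, nc)
    else:
        classes, rv = np.zeros(n, dtype=int), np.array([1.0])
    y = rng.standard_normal(n) * 2.0
    Z = np.zeros((n, m * q))
    for r in range(n):
        Z[r, ai[r] * q:(ai[r] + 1) * q] = Phi[r]
    return dict(y=y, X=X, Arel=Arel, Ainv=np.linalg.inv(Arel), K=K, ai=ai,
                Phi=Phi, classes=classes, rv=rv, Z=Z, n=n, m=m, q=q)


def gls_oracle(inst):
    """Direct BLUE/BLUP through dense V^-1 (the independent route)."""
    Z, K, Arel = inst["Z"], inst["K"], inst["Arel"]
    G0 = np.kron(Arel, K)
    R = np.diag(inst["rv"][inst["classes"]])
    V = Z @ G0 @ Z.T + R
    Vi = np.linalg.inv(V)
    X, y = inst["X"], inst["y"]
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = G0 @ Z.T @ Vi @ (y - X @ beta)
    return beta, u
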