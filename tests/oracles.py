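"""Independent reference implementations used only to check the package.

These deliberately re-derive results by different routes: a textbook
NIPALS loop written without reference to the package internals, and a
brute-force grid optimizer for the tiny SVR dual.
"""

import numpy as np


def nipals_pls1_predict(X, y, X_new, n_components):
    """Textbook PLS1: NIPALS deflation, prediction via b = W (P'W)^-1 q.

    Written in the plainest possible style (explicit lists, no shared
    code with the package) so it can serve as an independent oracle.
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float).ravel()
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    E = X - x_mean
    f = y - y_mean
    Ws, Ps, qs = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        w = w / np.sqrt(w @ w)
        t = E @ w
        p = (E.T @ t) / (t @ t)
        q = (f @ t) / (t @ t)
        E = E - np.outer(t, p)
        f = f - q * t
        Ws.append(w)
        Ps.append(p)
        qs.append(q)
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.array(qs)
    b = W @ np.linalg.solve(P.T @ W, q)
    return (np.asarray(X_new, dtype=float) - x_mean) @ b + y_mean


def svr_dual_objective(beta, K, y, eps):
    """Maximization-form dual value at beta (= alpha - alpha*)."""
    beta = np.asarray(beta, dtype=float)
    return float(-0.5 * beta @ K @ beta - eps * np.abs(beta).sum() + y @ beta)


def brute_force_svr_dual(K, y, eps, C, n_grid=201):
    """Exhaustive grid search of the 3-sample SVR dual.

    beta_1 and beta_2 range over a uniform grid in [-C, C]; the equality
    constraint fixes beta_3 = -(beta_1 + beta_2), and points violating
    the box are discarded.  Returns the best dual value found.
    """
    assert K.shape == (3, 3) and y.shape == (3,)
    g = np.linspace(-C, C, n_grid)
    b1, b2 = np.meshgrid(g, g, indexing="ij")
    b3 = -(b1 + b2)
    ok = np.abs(b3) <= C
    B = np.stack([b1[ok], b2[ok], b3[ok]], axis=1)  # (m, 3)
    quad = -0.5 * np.einsum("mi,ij,mj->m", B, K, B)
    lin = B @ y
    l1 = -eps * np.abs(B).sum(axis=1)
    return float((quad + lin + l1).max())
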