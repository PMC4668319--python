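"""Inner solver kernel for the epsilon-SVR dual.

Maximal-violating-pair SMO on the single-variable form of the dual
(beta_i = alpha_i - alpha*_i):

    min  1/2 b' K b - y' b + eps ||b||_1,   sum b = 0,  |b_i| <= C.

Each iteration selects the feasible pair (i, j) whose direction
e_i - e_j has the most negative directional derivative (the L1 term
contributes its subgradient, +eps when moving a coefficient away from
zero, -eps when moving it toward zero) and takes the exact minimizing
step of the piecewise-quadratic restriction.  Optimality is declared
when no pair's directional derivative is below ``-tol``.

The kernel is written loop-wise so numba can compile it; without numba
the same function runs as plain Python.
"""

from __future__ import annotations

import numpy as np

__all__ = ["solve_dual", "NUMBA_COMPILED"]


def _solve_dual_kernel(K, y, eps, C, tol, max_iter):
    n = y.shape[0]
    beta = np.zeros(n)
    Kb = np.zeros(n)  # K @ beta, maintained incrementally
    inf = np.inf
    violation = inf

    # objective improvements below `floor` are at the resolution of the
    # accumulated objective; a long run of them with no decrease of the
    # KKT violation means the iterate is converged at float precision
    ymax = 0.0
    for k in range(n):
        if abs(y[k]) > ymax:
            ymax = abs(y[k])
    floor = 1e-14 * (1.0 + C * ymax)
    stalled = 0
    viol_ref = inf

    for it in range(max_iter):
        if it % 4096 == 4095:  # refresh Kb: incremental updates drift
            for k in range(n):
                acc = 0.0
                for m in range(n):
                    acc += K[k, m] * beta[m]
                Kb[k] = acc
        # directional derivatives along +e_i (up) and -e_i (dn)
        best_up = inf
        best_up2 = inf
        i_up = -1
        i_up2 = -1
        best_dn = inf
        best_dn2 = inf
        i_dn = -1
        i_dn2 = -1
        for k in range(n):
            g = Kb[k] - y[k]
            if beta[k] < C:
                u = g + eps if beta[k] >= 0.0 else g - eps
                if u < best_up:
                    best_up2 = best_up
                    i_up2 = i_up
                    best_up = u
                    i_up = k
                elif u < best_up2:
                    best_up2 = u
                    i_up2 = k
            if beta[k] > -C:
                d = -g + eps if beta[k] <= 0.0 else -g - eps
                if d < best_dn:
                    best_dn2 = best_dn
                    i_dn2 = i_dn
                    best_dn = d
                    i_dn = k
                elif d < best_dn2:
                    best_dn2 = d
                    i_dn2 = k

        if i_up < 0 or i_dn < 0:
            return beta, 0, 0.0
        i = i_up
        j = i_dn
        if i == j:
            # best distinct combination among runners-up
            alt_i = best_up2 + best_dn if i_up2 >= 0 else inf
            alt_j = best_up + best_dn2 if i_dn2 >= 0 else inf
            if alt_i <= alt_j:
                if i_up2 < 0:
                    return beta, 0, 0.0
                i = i_up2
                violation = -alt_i
            else:
                if i_dn2 < 0:
                    return beta, 0, 0.0
                j = i_dn2
                violation = -alt_j
        else:
            violation = -(best_up + best_dn)
        if violation <= tol:
            return beta, 0, violation

        # second-order refinement of j (LIBSVM-style): among partners of i
        # with a descent direction, pick the largest estimated decrease
        # s^2 / (2 kappa) instead of the steepest first-order partner
        g_i = Kb[i] - y[i]
        up_i = g_i + eps if beta[i] >= 0.0 else g_i - eps
        best_gain = -1.0
        for k in range(n):
            if k == i or beta[k] <= -C:
                continue
            g_k = Kb[k] - y[k]
            dn_k = -g_k + eps if beta[k] <= 0.0 else -g_k - eps
            s = up_i + dn_k
            if s >= 0.0:
                continue
            kap = K[i, i] + K[k, k] - 2.0 * K[i, k]
            if kap < 1e-12:
                kap = 1e-12
            gain = s * s / kap
            if gain > best_gain:
                best_gain = gain
                j = k

        # exact line search along beta + d * (e_i - e_j)
        bi = beta[i]
        bj = beta[j]
        g = (Kb[i] - y[i]) - (Kb[j] - y[j])
        kappa = K[i, i] + K[j, j] - 2.0 * K[i, j]
        lo = -C - bi if -C - bi > bj - C else bj - C
        hi = C - bi if C - bi < bj + C else bj + C
        if hi <= lo:
            return beta, 0, violation

        d_best = 0.0
        f_best = 0.0
        for c_idx in range(7):
            if c_idx == 0:
                d = lo
            elif c_idx == 1:
                d = hi
            elif c_idx == 2:
                d = -bi
            elif c_idx == 3:
                d = bj
            elif kappa > 0.0:
                s = (c_idx - 5.0) * 2.0  # -2, 0, 2
                d = -(g + eps * s) / kappa
            else:
                continue
            if d < lo or d > hi:
                continue
            f = (d * g + 0.5 * d * d * kappa
                 + eps * (abs(bi + d) - abs(bi) + abs(bj - d) - abs(bj)))
            if f < f_best:
                d_best = d
                f_best = f
        if f_best >= 0.0:
            # flat direction (duplicate points): no pair can improve
            return beta, 0, violation
        if -f_best < floor:
            if violation < 0.9 * viol_ref:
                viol_ref = violation
                stalled = 0
            else:
                stalled += 1
                if stalled > 4096:
                    return beta, 0, violation
        else:
            stalled = 0
            viol_ref = inf
        beta[i] += d_best
        beta[j] -= d_best
        for k in range(n):
            Kb[k] += d_best * (K[k, i] - K[k, j])

    return beta, 1, violation


try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _kernel = njit(cache=False, fastmath=False)(_solve_dual_kernel)
    NUMBA_COMPILED = True
except ImportError:  # pragma: no cover
    _kernel = _solve_dual_kernel
    NUMBA_COMPILED = False


def solve_dual(K: np.ndarray, y: np.ndarray, eps: float, C: float,
               tol: float, max_iter: int):
    """Solve the beta-form dual; returns (beta, converged, kkt_violation)."""
    beta, status, violation = _kernel(
        np.ascontiguousarray(K, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        float(eps), float(C), float(tol), int(max_iter),
    )
    return beta, status == 0, float(violation)
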