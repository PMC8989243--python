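"""Independent reference computations used to validate the implementation.

These are deliberately naive: dense Riemann sums for integrals, an SLSQP
solve of the second-order-cone reformulation for the group Elastic-Net
objective, and a plain proximal-gradient loop.  They share no code path with
the solvers they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def riemann_gram(basis, deriv: int = 0, n_points: int = 100_001) -> np.ndarray:
    """Dense trapezoid-rule Gram matrix of a basis (or derivative)."""
    a, b = basis.domain
    t = np.linspace(a, b, n_points)
    e = basis.evaluate(t, deriv=deriv)
    m = basis.m
    out = np.empty((m, m))
    for i in range(m):
        for k in range(i, m):
            out[i, k] = out[k, i] = np.trapezoid(e[:, i] * e[:, k], t)
    return out


def en_objective(b, Z, y, slices, lam, alpha, loss_scale, lam_der=0.0, P=None):
    """Group Elastic-Net objective with Euclidean block norms.

    ``loss_scale * 0.5 * ||y - Z^T b||^2 + lam(1-alpha) sum ||b_j||
    + alpha lam sum ||b_j||^2 + 0.5 * lam_der * b^T P b``.
    """
    r = y - Z.T @ b
    val = 0.5 * loss_scale * float(r @ r)
    if lam_der > 0:
        val += 0.5 * lam_der * float(b @ P @ b)
    for sl in slices:
        nrm = np.linalg.norm(b[sl])
        val += lam * (1 - alpha) * nrm + alpha * lam * nrm * nrm
    return val


def socp_solve(Z, y, slices, lam, alpha, loss_scale, lam_der=0.0, P=None,
               x0=None):
    """Minimize the group Elastic-Net objective via SLSQP on the equivalent
    smooth program with auxiliary bounds t_j >= ||b_j||.

    Generic constrained optimization; independent of ADMM and GMD.
    """
    M = Z.shape[0]
    p = len(slices)
    H = loss_scale * (Z @ Z.T)
    if lam_der > 0:
        H = H + lam_der * P
    c = loss_scale * (Z @ y)
    y2 = 0.5 * loss_scale * float(y @ y)

    def obj(x):
        b, t = x[:M], x[M:]
        return (0.5 * b @ H @ b - c @ b + y2
                + lam * (1 - alpha) * t.sum() + alpha * lam * (t ** 2).sum())

    def obj_grad(x):
        b, t = x[:M], x[M:]
        return np.concatenate([H @ b - c,
                               lam * (1 - alpha) + 2 * alpha * lam * t])

    cons = []
    for j, sl in enumerate(slices):
        def con(x, j=j, sl=sl):
            return x[M + j] ** 2 - float(x[sl] @ x[sl])

        def con_grad(x, j=j, sl=sl):
            g = np.zeros(M + p)
            g[sl] = -2 * x[sl]
            g[M + j] = 2 * x[M + j]
            return g
        cons.append({"type": "ineq", "fun": con, "jac": con_grad})
    bounds = [(None, None)] * M + [(0, None)] * p

    if x0 is None:
        b0 = np.linalg.solve(H + 1e-6 * np.eye(M), c)
    else:
        b0 = np.asarray(x0, float)
    t0 = np.array([np.linalg.norm(b0[sl]) + 1e-6 for sl in slices])
    res = minimize(obj, np.concatenate([b0, t0]), jac=obj_grad,
                   constraints=cons, bounds=bounds, method="SLSQP",
                   options={"maxiter": 2000, "ftol": 1e-14})
    b = res.x[:M]
    return b, en_objective(b, Z, y, slices, lam, alpha, loss_scale, lam_der, P)


def prox_gradient_solve(Z, y, slices, lam, alpha, loss_scale, lam_der=0.0,
                        P=None, iters=200_000, tol=1e-13):
    """ISTA on the same objective: a second independent route to the optimum."""
    M = Z.shape[0]
    H = loss_scale * (Z @ Z.T)
    if lam_der > 0:
        H = H + lam_der * P
    c = loss_scale * (Z @ y)
    step = 1.0 / (np.linalg.eigvalsh(H)[-1] + 2 * alpha * lam + 1e-12)
    b = np.zeros(M)
    for _ in range(iters):
        g = H @ b - c + 2 * alpha * lam * b
        z = b - step * g
        b_new = np.empty_like(b)
        thr = step * lam * (1 - alpha)
        for sl in slices:
            nrm = np.linalg.norm(z[sl])
            b_new[sl] = 0.0 if nrm <= thr else (1 - thr / nrm) * z[sl]
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b = b_new
    return b, en_objective(b, Z, y, slices, lam, alpha, loss_scale, lam_der, P)
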