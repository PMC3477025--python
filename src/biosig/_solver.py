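"""Jitted inner loop for the L1-logistic proximal-gradient solver.

The kernel mirrors the model definition in :mod:`biosig.sparse`: accelerated
proximal gradient (FISTA) with backtracking line search and function-value
restart, stopping on the KKT residual of the penalized problem.  Kept in a
separate module so the public API stays plain numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _loss_from_margins(m):
    total = 0.0
    for i in range(m.shape[0]):
        v = m[i]
        if v >= 0.0:
            total += np.log1p(np.exp(-v))
        else:
            total += -v + np.log1p(np.exp(v))
    return total / m.shape[0]


@njit(cache=True, fastmath=False)
def _grad(X, y, w, c):
    """Returns (loss, grad_w, grad_c) of the average logistic loss."""
    n = X.shape[0]
    m = y * (X @ w + c)
    loss = _loss_from_margins(m)
    u = np.empty(n)
    for i in range(n):
        v = m[i]
        if v >= 0.0:
            e = np.exp(-v)
            s = e / (1.0 + e)
        else:
            s = 1.0 / (1.0 + np.exp(v))
        u[i] = -(y[i] * s) / n
    gw = X.T @ u
    gc = u.sum()
    return loss, gw, gc


@njit(cache=True, fastmath=False)
def _kkt(X, y, w, c, lam):
    _, gw, gc = _grad(X, y, w, c)
    res = abs(gc)
    for j in range(w.shape[0]):
        if w[j] > 0.0:
            r = abs(gw[j] + lam)
        elif w[j] < 0.0:
            r = abs(gw[j] - lam)
        else:
            r = abs(gw[j]) - lam
            if r < 0.0:
                r = 0.0
        if r > res:
            res = r
    return res


@njit(cache=True, fastmath=False)
def _prox_step(X, y, zw, zc, gz, gw_z, gc_z, lam, L):
    """One backtracked proximal step from (zw, zc); returns new point, its
    smooth loss and the (possibly increased) L."""
    p = zw.shape[0]
    while True:
        w_new = np.empty(p)
        for j in range(p):
            v = zw[j] - gw_z[j] / L
            t = lam / L
            if v > t:
                w_new[j] = v - t
            elif v < -t:
                w_new[j] = v + t
            else:
                w_new[j] = 0.0
        c_new = zc - gc_z / L
        m = y * (X @ w_new + c_new)
        g_new = _loss_from_margins(m)
        quad = gz + gc_z * (c_new - zc) + 0.5 * L * (c_new - zc) ** 2
        for j in range(p):
            d = w_new[j] - zw[j]
            quad += gw_z[j] * d + 0.5 * L * d * d
        if g_new <= quad + 1e-15:
            return w_new, c_new, g_new, L
        L *= 2.0


@njit(cache=True, fastmath=False)
def fista_solve(X, y, w0, c0, lam, tol, max_iter, L0):
    """Minimize g(w,c) + lam*||w||_1; returns (w, c, n_iter, converged, L).

    Monotone: the accepted objective never increases (momentum restarts on
    an increase).  Terminates when the KKT residual <= tol*max(1, lam).
    """
    threshold = tol * max(1.0, lam)
    L = L0
    fw = w0.copy()
    fc = c0
    zw = w0.copy()
    zc = c0
    t_mom = 1.0
    obj = _loss_from_margins(y * (X @ fw + fc)) + lam * np.abs(fw).sum()
    converged = False
    n_iter = 0
    if _kkt(X, y, fw, fc, lam) <= threshold:
        return fw, fc, 0, True, L
    for n_iter in range(1, max_iter + 1):
        gz, gw_z, gc_z = _grad(X, y, zw, zc)
        w_new, c_new, g_new, L = _prox_step(X, y, zw, zc, gz, gw_z, gc_z, lam, L)
        obj_new = g_new + lam * np.abs(w_new).sum()
        if obj_new > obj:
            gf, gw_f, gc_f = _grad(X, y, fw, fc)
            w_new, c_new, g_new, L = _prox_step(X, y, fw, fc, gf, gw_f, gc_f, lam, L)
            obj_new = g_new + lam * np.abs(w_new).sum()
            t_mom = 1.0
            zw = w_new.copy()
            zc = c_new
        else:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
            beta = (t_mom - 1.0) / t_next
            zw = w_new + beta * (w_new - fw)
            zc = c_new + beta * (c_new - fc)
            t_mom = t_next
        fw = w_new
        fc = c_new
        if obj_new < obj:
            obj = obj_new
        if n_iter % 2 == 0 or n_iter <= 2:
            if _kkt(X, y, fw, fc, lam) <= threshold:
                converged = True
                break
    return fw, fc, n_iter, converged, L
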