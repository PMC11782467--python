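"""Compiled adaptive Runge-Kutta core for long equilibrium runs.

Equilibration of the strategy competition is slow: near Table-1
parameters the minority lineage decays at only ~1e-4 per year, so a
single run can require ~1e5 simulated years and a phase-diagram sweep
runs thousands of such simulations.  The Dormand-Prince 5(4) stepper
below is numba-compiled so the whole run, including the convergence
check, executes without per-step Python overhead.

Status codes returned by the solvers:
0 converged, 1 horizon reached, 2 negative component beyond tolerance,
3 non-finite state, 4 step size collapse.
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG_TOL = 1e-10

# Densities this far below the O(1) population scale are roundoff remnants
# of an extinguished lineage (every flux is proportional to its source
# compartment, so exact zeros are invariant).  Without snapping, a dying
# lineage floors at ~1e-15 of mixed sign and its residual never settles.
SNAP_TOL = 1e-14

# Dormand-Prince 5(4) tableau; the 5th-order weights are row a7 (FSAL).
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_E = np.array([35 / 384 - 5179 / 57600, 0.0, 500 / 1113 - 7571 / 16695,
               125 / 192 - 393 / 640, -2187 / 6784 + 92097 / 339200,
               11 / 84 - 187 / 2100, -1 / 40])


@njit(cache=True)
def rhs_compiled(y, c):
    """Time derivative of the 17 compartments; y in COMPARTMENTS order."""
    rho = c[0]
    beta = c[1]
    delta_m = c[2]
    delta_g = c[3]
    chi = c[4]
    q_star = c[5]
    omega_F = c[6]
    omega_M = c[7]
    L = c[8]
    male_factor = c[9]

    FM = y[0]
    FG = y[1]
    M = y[2]
    G = y[3]
    FMm = y[4]
    FGg = y[5]
    FGm = y[6]
    FMg = y[7]
    PGg = y[8]
    PG = y[9]
    PMm = y[10]
    PMg = y[11]
    PM = y[12]
    X = y[13]
    Xm = y[14]
    Xg = y[15]
    Y = y[16]

    carers = FMm + FGg + FGm + FMg + PGg + PMm + PMg + Xg + Xm
    muF = 1.0 / L
    dens = 0.5 * beta * carers
    if dens > muF:
        muF = dens
    muM = male_factor * muF

    MG = M + G
    if MG > 0.0:
        fM = M / MG
        fG = G / MG
        rho_free = rho  # free females find a mate in the unpaired pool
    else:
        fM = 0.0
        fG = 0.0
        rho_free = 0.0  # no unpaired males: free-female matings vanish
    q = fM * q_star

    m_carers = FMm + FGm + PMm + Xm
    g_carers = FGg + FMg + PGg + PMg + Xg

    d = np.empty(17)
    d[0] = (-rho_free * FM + 0.5 * beta * m_carers
            + (beta + delta_m) * FMm + (beta + delta_g) * FMg
            + (chi + muM) * PM - (omega_F + muF) * FM)
    d[1] = (-rho_free * FG + 0.5 * beta * g_carers
            + (beta + delta_g) * FGg + (beta + delta_m) * FGm
            + (chi + muM) * PG - (omega_F + muF) * FG)
    d[2] = (0.5 * beta * m_carers + 0.5 * q * beta * g_carers
            - (omega_M + muM) * M)
    d[3] = (-rho * fG * (FM + FG) + 0.5 * (1.0 - q) * beta * g_carers
            + (chi + omega_F + muF) * (PM + PG + PMg + PGg + PMm)
            - (omega_M + muM) * G)
    d[4] = (rho * fM * FM + (chi + muM) * PMm
            - (beta + delta_m + omega_F + muF) * FMm)
    d[5] = (0.5 * rho * fM * FG + (chi + muM) * PGg
            - (beta + delta_g + omega_F + muF) * FGg)
    d[6] = 0.5 * rho * fM * FG - (beta + delta_m + omega_F + muF) * FGm
    d[7] = (chi + muM) * PMg - (beta + delta_g + omega_F + muF) * FMg
    d[8] = (rho * fG * FG + rho * PG
            - (beta + delta_g + chi + omega_F + muM + muF) * PGg)
    d[9] = (-rho * PG + (beta + delta_g) * PGg
            - (chi + omega_F + muM + muF) * PG)
    d[10] = (0.5 * rho * fG * FM + 0.5 * rho * PM
             - (beta + delta_m + chi + omega_F + muM + muF) * PMm)
    d[11] = (0.5 * rho * fG * FM + 0.5 * rho * PM
             - (beta + delta_g + chi + omega_F + muM + muF) * PMg)
    d[12] = (-rho * PM + (beta + delta_m) * PMm + (beta + delta_g) * PMg
             - (chi + omega_F + muM + muF) * PM)
    d[13] = (omega_F * (FM + FG + PM + PG)
             + (beta + delta_m) * Xm + (beta + delta_g) * Xg - muF * X)
    d[14] = omega_F * (FMm + FGm + PMm) - (beta + delta_m + muF) * Xm
    d[15] = (omega_F * (FGg + FMg + PGg + PMg)
             - (beta + delta_g + muF) * Xg)
    d[16] = omega_M * (M + G) - muM * Y
    return d


@njit(cache=True)
def _err_norm(err, y_old, y_new, rtol, atol):
    acc = 0.0
    for i in range(err.shape[0]):
        sc = atol + rtol * max(abs(y_old[i]), abs(y_new[i]))
        e = err[i] / sc
        acc += e * e
    return np.sqrt(acc / err.shape[0])


@njit(cache=True)
def _check_state(y):
    """0 ok, 2 negative beyond tolerance, 3 non-finite."""
    for i in range(y.shape[0]):
        v = y[i]
        if not np.isfinite(v):
            return 3
        if v < -NEG_TOL:
            return 2
    return 0


@njit(cache=True)
def _residual(y, dy):
    r = 0.0
    for i in range(y.shape[0]):
        v = abs(dy[i]) / (abs(y[i]) + 1e-12)
        if v > r:
            r = v
    return r


@njit(cache=True)
def _step(y, k1, t, h, c, A, C, E):
    """One Dormand-Prince trial step; returns (y_new, k_last, err_norm_vec)."""
    n = y.shape[0]
    K = np.empty((7, n))
    K[0] = k1
    for s in range(1, 7):
        acc = np.zeros(n)
        for j in range(s):
            a = A[s, j]
            if a != 0.0:
                for i in range(n):
                    acc[i] += a * K[j, i]
        ys = np.empty(n)
        for i in range(n):
            ys[i] = y[i] + h * acc[i]
        K[s] = rhs_compiled(ys, c)
    y_new = ys  # stage 7 argument equals the 5th-order solution (FSAL)
    err = np.zeros(n)
    for j in range(7):
        e = E[j]
        if e != 0.0:
            for i in range(n):
                err[i] += e * K[j, i]
    for i in range(n):
        err[i] *= h
    return y_new, K[6], err


@njit(cache=True)
def solve_equilibrium(y0, c, t_max, rtol, atol, conv_tol, window):
    """Integrate until the relative derivative norm stays below
    ``conv_tol`` for ``window`` years, or until ``t_max``.

    Returns (y, t, residual, status).
    """
    y = y0.copy()
    t = 0.0
    k1 = rhs_compiled(y, c)
    resid = _residual(y, k1)
    clean_start = t if resid < conv_tol else -1.0
    h = 0.01
    h_max = 50.0
    n_reject = 0
    while t < t_max:
        if t + h > t_max:
            h = t_max - t
        y_new, k_last, err = _step(y, k1, t, h, c, _A, _C, _E)
        en = _err_norm(err, y, y_new, rtol, atol)
        if en <= 1.0:
            st = _check_state(y_new)
            if st != 0:
                return y, t, resid, st
            t += h
            y = y_new
            snapped = False
            for i in range(y.shape[0]):
                if y[i] != 0.0 and abs(y[i]) < SNAP_TOL:
                    y[i] = 0.0
                    snapped = True
            if snapped:
                k1 = rhs_compiled(y, c)
            else:
                k1 = k_last
            resid = _residual(y, k1)
            if resid < conv_tol:
                if clean_start < 0.0:
                    clean_start = t
                elif t - clean_start >= window:
                    return y, t, resid, 0
            else:
                clean_start = -1.0
            n_reject = 0
        else:
            n_reject += 1
            if n_reject > 50 or h < 1e-12:
                return y, t, resid, 4
        # PI-free standard controller
        if en == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * en ** (-0.2)
            if fac > 5.0:
                fac = 5.0
            elif fac < 0.2:
                fac = 0.2
        h *= fac
        if h > h_max:
            h = h_max
    return y, t, resid, 1


@njit(cache=True)
def solve_dense(y0, c, t_eval, rtol, atol):
    """Integrate and record the state at each requested output time.

    Returns (states, status, t_fail); states has one row per t_eval.
    """
    n = y0.shape[0]
    m = t_eval.shape[0]
    out = np.empty((m, n))
    y = y0.copy()
    t = t_eval[0]
    out[0] = y
    k1 = rhs_compiled(y, c)
    h = 0.01
    h_max = 50.0
    idx = 1
    n_reject = 0
    while idx < m:
        target = t_eval[idx]
        truncated = False
        if t + h >= target:
            h_try = target - t
            truncated = True
        else:
            h_try = h
        if h_try <= 0.0:
            out[idx] = y
            idx += 1
            continue
        y_new, k_last, err = _step(y, k1, t, h_try, c, _A, _C, _E)
        en = _err_norm(err, y, y_new, rtol, atol)
        if en <= 1.0:
            st = _check_state(y_new)
            if st != 0:
                return out, st, t
            t += h_try
            y = y_new
            snapped = False
            for i in range(n):
                if y[i] != 0.0 and abs(y[i]) < SNAP_TOL:
                    y[i] = 0.0
                    snapped = True
            if snapped:
                k1 = rhs_compiled(y, c)
            else:
                k1 = k_last
            if truncated:
                out[idx] = y
                idx += 1
            n_reject = 0
        else:
            n_reject += 1
            if n_reject > 50 or h_try < 1e-12:
                return out, 4, t
        if en == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * en ** (-0.2)
            if fac > 5.0:
                fac = 5.0
            elif fac < 0.2:
                fac = 0.2
        if not truncated:
            h = min(h_try * fac, h_max)
        elif en > 1.0:
            h = h_try * fac  # truncated step rejected: shrink from it
    return out, 0, t
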