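"""Numba-compiled inner loops shared by the simulation and control solvers.

Parameters travel through these kernels as a flat float64 vector (see
``pack_params``); the two apoptosis thresholds ride at the end of the same
vector.  The apoptosis switch comes in two flavours selected by ``mode``:
0 = sharp binary indicator (the model as stated), 1 = logistic smoothing
with steepness ``ks`` (used to differentiate through the switch in the
optimal-control adjoint).  Everything here is deterministic fixed-step
arithmetic so the sweeps and schedule scans are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import ModelParams, Thresholds

_PACK_FIELDS = (
    "lambda_S1", "k1", "k2", "alpha",
    "lambda_k", "lambda_J", "K", "lambda_S2", "k3", "k4", "beta", "mu3",
    "lambda1", "k5", "k6", "gamma", "lambda3", "muB",
    "lambda2", "k7", "k8", "delta", "muX",
    "r", "k9", "k10", "T0", "muT",
    "muS", "Js", "gammaD", "muJ", "muD",
)
NPAR = len(_PACK_FIELDS)  # thresholds are appended at NPAR, NPAR + 1

SHARP = 0
SMOOTH = 1


def pack_params(params: ModelParams, thresholds: Thresholds) -> np.ndarray:
    out = np.empty(NPAR + 2)
    for i, name in enumerate(_PACK_FIELDS):
        out[i] = getattr(params, name)
    out[NPAR] = thresholds.B_th
    out[NPAR + 1] = thresholds.X_th
    return out


@njit(cache=False)
def _sigmoid(z):
    if z > 30.0:
        return 1.0
    if z < -30.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=False)
def indicator_value(B, X, B_th, X_th, mode, ks):
    """Apoptosis switch: sharp {0,1} or logistic-smoothed product."""
    if mode == 0:
        return 1.0 if (B < B_th and X > X_th) else 0.0
    return _sigmoid(ks * (B_th - B)) * _sigmoid(ks * (X - X_th))


@njit(cache=False)
def rhs8(y, uS, uD, p, mode, ks):
    """Right-hand side of the full eight-variable system."""
    S1, S3, B, X, T, S, J, D = y
    lS1, k1, k2, alpha = p[0], p[1], p[2], p[3]
    lk, lJ, K, lS2, k3, k4, beta, mu3 = p[4], p[5], p[6], p[7], p[8], p[9], p[10], p[11]
    l1, k5, k6, gamma, l3, muB = p[12], p[13], p[14], p[15], p[16], p[17]
    l2, k7, k8, delta, muX = p[18], p[19], p[20], p[21], p[22]
    r, k9, k10, T0, muT = p[23], p[24], p[25], p[26], p[27]
    muS, Js, gD, muJ, muD = p[28], p[29], p[30], p[31], p[32]
    I = indicator_value(B, X, p[33], p[34], mode, ks)
    phi = S1 * S1 / (k10 * k10 + S1 * S1)
    out = np.empty(8)
    out[0] = lS1 * S + k1 * k2 * k2 / (k2 * k2 + alpha * S3 * S3) - S1
    out[1] = (lk + lJ * J) / (K + lS2 * S) + k3 * k4 * k4 / (k4 * k4 + beta * S1 * S1) - mu3 * S3
    out[2] = l1 + k5 * k6 * k6 / (k6 * k6 + gamma * S1 * S1) + l3 * S3 - muB * B
    out[3] = l2 + k7 * k8 * k8 / (k8 * k8 + delta * B * B) - muX * X
    out[4] = r * (1.0 - k9 * phi * I) * T * (1.0 - T / T0) - muT * T * I
    out[5] = uS - muS * S
    out[6] = Js - gD * D * J - muJ * J
    out[7] = uD - muD * D
    return out


@njit(cache=False)
def jac8(y, p, mode, ks, I_frozen):
    """Analytic state Jacobian of rhs8.

    mode 0: the indicator is treated as an exogenous constant ``I_frozen``
    (its value on the current forward pass), so the switch contributes no
    partials.  mode 1: the logistic switch is differentiated through,
    adding dI/dB and dI/dX terms to the tumour row.
    """
    S1, S3, B, X, T, S, J, D = y
    lS1, k1, k2, alpha = p[0], p[1], p[2], p[3]
    lk, lJ, K, lS2, k3, k4, beta, mu3 = p[4], p[5], p[6], p[7], p[8], p[9], p[10], p[11]
    l1, k5, k6, gamma, l3, muB = p[12], p[13], p[14], p[15], p[16], p[17]
    l2, k7, k8, delta, muX = p[18], p[19], p[20], p[21], p[22]
    r, k9, k10, T0, muT = p[23], p[24], p[25], p[26], p[27]
    muS, Js, gD, muJ, muD = p[28], p[29], p[30], p[31], p[32]
    B_th, X_th = p[33], p[34]
    if mode == 0:
        I = I_frozen
        dIdB = 0.0
        dIdX = 0.0
    else:
        sB = _sigmoid(ks * (B_th - B))
        sX = _sigmoid(ks * (X - X_th))
        I = sB * sX
        dIdB = -ks * sB * (1.0 - sB) * sX
        dIdX = ks * sX * (1.0 - sX) * sB
    Jm = np.zeros((8, 8))
    d1 = k2 * k2 + alpha * S3 * S3
    Jm[0, 0] = -1.0
    Jm[0, 1] = -2.0 * alpha * S3 * k1 * k2 * k2 / (d1 * d1)
    Jm[0, 5] = lS1
    d2 = k4 * k4 + beta * S1 * S1
    Jm[1, 0] = -2.0 * beta * S1 * k3 * k4 * k4 / (d2 * d2)
    Jm[1, 1] = -mu3
    d2s = K + lS2 * S
    Jm[1, 5] = -lS2 * (lk + lJ * J) / (d2s * d2s)
    Jm[1, 6] = lJ / d2s
    d3 = k6 * k6 + gamma * S1 * S1
    Jm[2, 0] = -2.0 * gamma * S1 * k5 * k6 * k6 / (d3 * d3)
    Jm[2, 1] = l3
    Jm[2, 2] = -muB
    d4 = k8 * k8 + delta * B * B
    Jm[3, 2] = -2.0 * delta * B * k7 * k8 * k8 / (d4 * d4)
    Jm[3, 3] = -muX
    phi = S1 * S1 / (k10 * k10 + S1 * S1)
    dphi = 2.0 * S1 * k10 * k10 / ((k10 * k10 + S1 * S1) ** 2)
    growth = r * T * (1.0 - T / T0)
    Jm[4, 0] = -growth * k9 * dphi * I
    Jm[4, 2] = -growth * k9 * phi * dIdB - muT * T * dIdB
    Jm[4, 3] = -growth * k9 * phi * dIdX - muT * T * dIdX
    Jm[4, 4] = r * (1.0 - k9 * phi * I) * (1.0 - 2.0 * T / T0) - muT * I
    Jm[5, 5] = -muS
    Jm[6, 6] = -gD * D - muJ
    Jm[6, 7] = -gD * J
    Jm[7, 7] = -muD
    return Jm


@njit(cache=False)
def rk4_forward(y0, uS_half, uD_half, dt, p, mode, ks):
    """Classic RK4 on a uniform grid.

    ``uS_half``/``uD_half`` hold the controls sampled on the half-step grid
    (2N + 1 values for N steps) so each RK4 stage sees the control at its
    own time.  Returns the (N + 1) x 8 state history.
    """
    N = (len(uS_half) - 1) // 2
    Y = np.zeros((N + 1, 8))
    Y[0] = y0
    for i in range(N):
        u0 = uS_half[2 * i]
        um = uS_half[2 * i + 1]
        u1 = uS_half[2 * i + 2]
        d0 = uD_half[2 * i]
        dm = uD_half[2 * i + 1]
        d1 = uD_half[2 * i + 2]
        y = Y[i]
        a = rhs8(y, u0, d0, p, mode, ks)
        b = rhs8(y + 0.5 * dt * a, um, dm, p, mode, ks)
        c = rhs8(y + 0.5 * dt * b, um, dm, p, mode, ks)
        d = rhs8(y + dt * c, u1, d1, p, mode, ks)
        ynew = y + dt / 6.0 * (a + 2.0 * b + 2.0 * c + d)
        for j in range(8):
            if ynew[j] < 0.0:
                ynew[j] = 0.0
        Y[i + 1] = ynew
    return Y


@njit(cache=False)
def adjoint_rhs_packed(lam, y, p, mode, ks, A1, A2, A3, Tbar):
    """Costate derivative -dH/dx at a single point."""
    g = np.zeros(8)
    g[2] = 2.0 * A2 * y[2]
    g[3] = -2.0 * A3 * y[3]
    g[4] = 2.0 * A1 * (y[4] - Tbar)
    I = indicator_value(y[2], y[3], p[33], p[34], 0, ks)
    Jm = jac8(y, p, mode, ks, I)
    return -(g + Jm.T @ lam)


@njit(cache=False)
def rk4_backward(Y, dt, p, mode, ks, A1, A2, A3, Tbar):
    """Backward RK4 for the costates; terminal condition lambda(t_e) = 0."""
    N = Y.shape[0] - 1
    L = np.zeros((N + 1, 8))
    for i in range(N, 0, -1):
        y1 = Y[i]
        y0 = Y[i - 1]
        ym = 0.5 * (y1 + y0)
        lam = L[i]
        a = adjoint_rhs_packed(lam, y1, p, mode, ks, A1, A2, A3, Tbar)
        b = adjoint_rhs_packed(lam - 0.5 * dt * a, ym, p, mode, ks, A1, A2, A3, Tbar)
        c = adjoint_rhs_packed(lam - 0.5 * dt * b, ym, p, mode, ks, A1, A2, A3, Tbar)
        d = adjoint_rhs_packed(lam - dt * c, y0, p, mode, ks, A1, A2, A3, Tbar)
        L[i - 1] = lam - dt / 6.0 * (a + 2.0 * b + 2.0 * c + d)
    return L
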