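"""Numba kernels for the recurrent cells: forward steps, truncated-window
semi-gradient TD(0) backprop, and RTRL influence-matrix propagation.

Parameter conventions (input dim m, hidden size n, L = m + n + 1):

* vanilla RNN: ``W`` of shape (n, L) acting on u = [o; h_prev; 1];
  h = tanh(W u).
* LSTM: ``W`` of shape (4n, L), gate rows ordered [input, forget, candidate,
  output]; c = f*c_prev + i*g, h = o * tanh(c).
* GRU: ``Wz``, ``Wr``, ``Wc`` each (n, L); update gate z, reset gate r,
  candidate tanh(Wc [o; r*h_prev; 1]); h = (1-z)*h_prev + z*candidate.

Flattened recurrent-parameter vectors (RTRL influence columns) are row-major
over the weight matrices, GRU blocks in the order [Wz, Wr, Wc].

The window-gradient kernels implement the truncated protocol: unroll from the
stored (stale) boundary hidden state over observations o_{t-T}..o_{t-1},
score each window value against the semi-gradient TD(0) target
US_{k+1} + gamma * stopgrad(V_{k+1}), with the newest bootstrap supplied by
the caller (the online V_t), and sum the per-step losses.  Returned gradients
are of the summed loss, i.e. sum_k(-delta_k * dV_k/dtheta).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "rnn_cell", "lstm_cell", "gru_cell",
    "rnn_window_grads", "lstm_window_grads", "gru_window_grads",
    "rnn_rtrl_step", "lstm_rtrl_step", "gru_rtrl_step",
]


@njit(cache=True)
def _build_u(o, h):
    m = o.shape[0]
    n = h.shape[0]
    u = np.empty(m + n + 1)
    u[:m] = o
    u[m:m + n] = h
    u[m + n] = 1.0
    return u


@njit(cache=True)
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Single-step forwards (online behavior state)
# ---------------------------------------------------------------------------

@njit(cache=True)
def rnn_cell(W, h, o):
    return np.tanh(W @ _build_u(o, h))


@njit(cache=True)
def lstm_cell(W, h, c, o):
    n = h.shape[0]
    z = W @ _build_u(o, h)
    i = _sigmoid(z[:n])
    f = _sigmoid(z[n:2 * n])
    g = np.tanh(z[2 * n:3 * n])
    og = _sigmoid(z[3 * n:])
    c_new = f * c + i * g
    h_new = og * np.tanh(c_new)
    return h_new, c_new


@njit(cache=True)
def gru_cell(Wz, Wr, Wc, h, o):
    u = _build_u(o, h)
    z = _sigmoid(Wz @ u)
    r = _sigmoid(Wr @ u)
    ct = np.tanh(Wc @ _build_u(o, r * h))
    return (1.0 - z) * h + z * ct


# ---------------------------------------------------------------------------
# Truncated-window semi-gradient TD(0) gradients
# ---------------------------------------------------------------------------

@njit(cache=True)
def _deltas(V, us_next, gamma, v_boot):
    T = V.shape[0]
    delta = np.empty(T)
    for k in range(T):
        v_next = V[k + 1] if k < T - 1 else v_boot
        delta[k] = us_next[k] + gamma * v_next - V[k]
    return delta


@njit(cache=True)
def rnn_window_grads(W, w_out, b_out, h0, obs, us_next, gamma, v_boot):
    T, m = obs.shape
    n = h0.shape[0]
    L = m + n + 1
    H = np.empty((T + 1, n))
    H[0] = h0
    U = np.empty((T, L))
    for k in range(T):
        U[k] = _build_u(obs[k], H[k])
        H[k + 1] = np.tanh(W @ U[k])
    V = H[1:] @ w_out + b_out
    delta = _deltas(V, us_next, gamma, v_boot)
    dW = np.zeros_like(W)
    dw_out = np.zeros_like(w_out)
    db_out = 0.0
    dh = np.zeros(n)
    for k in range(T - 1, -1, -1):
        dv = -delta[k]
        dw_out += dv * H[k + 1]
        db_out += dv
        dh = dh + dv * w_out
        da = dh * (1.0 - H[k + 1] ** 2)
        dW += np.outer(da, U[k])
        dh = (W.T @ da)[m:m + n]
    return dW, dw_out, db_out, V


@njit(cache=True)
def lstm_window_grads(W, w_out, b_out, h0, c0, obs, us_next, gamma, v_boot):
    T, m = obs.shape
    n = h0.shape[0]
    L = m + n + 1
    H = np.empty((T + 1, n))
    C = np.empty((T + 1, n))
    H[0] = h0
    C[0] = c0
    U = np.empty((T, L))
    I = np.empty((T, n))
    F = np.empty((T, n))
    G = np.empty((T, n))
    Og = np.empty((T, n))
    Tc = np.empty((T, n))
    for k in range(T):
        U[k] = _build_u(obs[k], H[k])
        z = W @ U[k]
        i = _sigmoid(z[:n])
        f = _sigmoid(z[n:2 * n])
        g = np.tanh(z[2 * n:3 * n])
        og = _sigmoid(z[3 * n:])
        c = f * C[k] + i * g
        I[k] = i
        F[k] = f
        G[k] = g
        Og[k] = og
        C[k + 1] = c
        Tc[k] = np.tanh(c)
        H[k + 1] = og * Tc[k]
    V = H[1:] @ w_out + b_out
    delta = _deltas(V, us_next, gamma, v_boot)
    dW = np.zeros_like(W)
    dw_out = np.zeros_like(w_out)
    db_out = 0.0
    dh = np.zeros(n)
    dc = np.zeros(n)
    dz = np.empty(4 * n)
    for k in range(T - 1, -1, -1):
        dv = -delta[k]
        dw_out += dv * H[k + 1]
        db_out += dv
        dh = dh + dv * w_out
        dog = dh * Tc[k]
        dcc = dc + dh * Og[k] * (1.0 - Tc[k] ** 2)
        dz[:n] = (dcc * G[k]) * I[k] * (1.0 - I[k])
        dz[n:2 * n] = (dcc * C[k]) * F[k] * (1.0 - F[k])
        dz[2 * n:3 * n] = (dcc * I[k]) * (1.0 - G[k] ** 2)
        dz[3 * n:] = dog * Og[k] * (1.0 - Og[k])
        dW += np.outer(dz, U[k])
        dh = (W.T @ dz)[m:m + n]
        dc = dcc * F[k]
    return dW, dw_out, db_out, V


@njit(cache=True)
def gru_window_grads(Wz, Wr, Wc, w_out, b_out, h0, obs, us_next, gamma, v_boot):
    T, m = obs.shape
    n = h0.shape[0]
    L = m + n + 1
    H = np.empty((T + 1, n))
    H[0] = h0
    U = np.empty((T, L))
    Uc = np.empty((T, L))
    Z = np.empty((T, n))
    R = np.empty((T, n))
    Ct = np.empty((T, n))
    for k in range(T):
        U[k] = _build_u(obs[k], H[k])
        z = _sigmoid(Wz @ U[k])
        r = _sigmoid(Wr @ U[k])
        Uc[k] = _build_u(obs[k], r * H[k])
        ct = np.tanh(Wc @ Uc[k])
        Z[k] = z
        R[k] = r
        Ct[k] = ct
        H[k + 1] = (1.0 - z) * H[k] + z * ct
    V = H[1:] @ w_out + b_out
    delta = _deltas(V, us_next, gamma, v_boot)
    dWz = np.zeros_like(Wz)
    dWr = np.zeros_like(Wr)
    dWc = np.zeros_like(Wc)
    dw_out = np.zeros_like(w_out)
    db_out = 0.0
    dh = np.zeros(n)
    for k in range(T - 1, -1, -1):
        dv = -delta[k]
        dw_out += dv * H[k + 1]
        db_out += dv
        dh = dh + dv * w_out
        dac = (dh * Z[k]) * (1.0 - Ct[k] ** 2)
        daz = (dh * (Ct[k] - H[k])) * Z[k] * (1.0 - Z[k])
        dh_prev = dh * (1.0 - Z[k])
        dWc += np.outer(dac, Uc[k])
        drh = (Wc.T @ dac)[m:m + n]
        dh_prev = dh_prev + drh * R[k]
        dar = (drh * H[k]) * R[k] * (1.0 - R[k])
        dWr += np.outer(dar, U[k])
        dh_prev = dh_prev + (Wr.T @ dar)[m:m + n]
        dWz += np.outer(daz, U[k])
        dh_prev = dh_prev + (Wz.T @ daz)[m:m + n]
        dh = dh_prev
    return dWz, dWr, dWc, dw_out, db_out, V


# ---------------------------------------------------------------------------
# RTRL influence-matrix propagation
# ---------------------------------------------------------------------------
#
# J rows span the cell's state (h, and c for the LSTM); columns span the
# flattened recurrent parameters.  Each step applies
# J <- (dstate_t/dstate_{t-1}) J + dstate_t/dtheta with the local Jacobians
# evaluated during the forward pass at the current parameters; the caller
# never resets J after a parameter update (the stale-Jacobian protocol).

@njit(cache=True)
def rnn_rtrl_step(W, h, Jh, o):
    """Updates Jh in place; returns the new hidden state."""
    m = o.shape[0]
    n = h.shape[0]
    L = m + n + 1
    u = _build_u(o, h)
    h_new = np.tanh(W @ u)
    Wh = np.ascontiguousarray(W[:, m:m + n])
    M = Wh @ Jh
    n_p = Jh.shape[1]
    for j in range(n):
        base = j * L
        s = 1.0 - h_new[j] ** 2
        for p in range(n_p):
            Jh[j, p] = s * M[j, p]
        for q in range(L):
            Jh[j, base + q] += s * u[q]
    return h_new


@njit(cache=True)
def lstm_rtrl_step(W, h, c, Jh, Jc, o):
    """Updates Jh and Jc in place; returns (h_new, c_new)."""
    m = o.shape[0]
    n = h.shape[0]
    L = m + n + 1
    n_p = Jh.shape[1]
    u = _build_u(o, h)
    z = W @ u
    i = _sigmoid(z[:n])
    f = _sigmoid(z[n:2 * n])
    g = np.tanh(z[2 * n:3 * n])
    og = _sigmoid(z[3 * n:])
    c_new = f * c + i * g
    tc = np.tanh(c_new)
    h_new = og * tc
    Wh = np.ascontiguousarray(W[:, m:m + n])
    dz = Wh @ Jh
    for j in range(4 * n):
        base = j * L
        for q in range(L):
            dz[j, base + q] += u[q]
    # Fused influence update:
    #   Jc <- f*Jc + (c_prev*sf)*dz_f + (g*si)*dz_i + (i*sg)*dz_g
    #   Jh <- (tc*so)*dz_o + og*(1 - tc^2)*Jc
    for r in range(n):
        a_i = g[r] * i[r] * (1.0 - i[r])
        a_f = c[r] * f[r] * (1.0 - f[r])
        a_g = i[r] * (1.0 - g[r] ** 2)
        a_o = tc[r] * og[r] * (1.0 - og[r])
        fr = f[r]
        qc = og[r] * (1.0 - tc[r] ** 2)
        for p in range(n_p):
            jc = (fr * Jc[r, p] + a_f * dz[n + r, p]
                  + a_i * dz[r, p] + a_g * dz[2 * n + r, p])
            Jc[r, p] = jc
            Jh[r, p] = a_o * dz[3 * n + r, p] + qc * jc
    return h_new, c_new


@njit(cache=True)
def gru_rtrl_step(Wz, Wr, Wc, h, Jh, o):
    """Updates Jh in place; returns the new hidden state."""
    m = o.shape[0]
    n = h.shape[0]
    L = m + n + 1
    nL = n * L
    n_p = Jh.shape[1]
    u = _build_u(o, h)
    z = _sigmoid(Wz @ u)
    r = _sigmoid(Wr @ u)
    uc = _build_u(o, r * h)
    ct = np.tanh(Wc @ uc)
    h_new = (1.0 - z) * h + z * ct
    Wzh = np.ascontiguousarray(Wz[:, m:m + n])
    Wrh = np.ascontiguousarray(Wr[:, m:m + n])
    Wch = np.ascontiguousarray(Wc[:, m:m + n])
    daz = Wzh @ Jh
    dar = Wrh @ Jh
    for j in range(n):
        base = j * L
        for q in range(L):
            daz[j, base + q] += u[q]
            dar[j, nL + base + q] += u[q]
    # d(r o h_prev)/dtheta = r*Jh + h_prev * sigmoid'(a_r) * dar
    drh = np.empty((n, n_p))
    for j in range(n):
        sr = h[j] * r[j] * (1.0 - r[j])
        rj = r[j]
        for p in range(n_p):
            drh[j, p] = rj * Jh[j, p] + sr * dar[j, p]
    dac = Wch @ drh
    for j in range(n):
        base = 2 * nL + j * L
        for q in range(L):
            dac[j, base + q] += uc[q]
    for j in range(n):
        sz = (ct[j] - h[j]) * z[j] * (1.0 - z[j])
        sc = z[j] * (1.0 - ct[j] ** 2)
        oz = 1.0 - z[j]
        for p in range(n_p):
            Jh[j, p] = oz * Jh[j, p] + sz * daz[j, p] + sc * dac[j, p]
    return h_new
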