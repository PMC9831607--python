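"""Vectorized mass-action solver for the dimer-monomer-inhibitor(-substrate) network.

The network couples an obligate homodimer M2 <-> 2M to inhibitor binding on
the monomer (MI) and on the two interface sites of the dimer (M2I, M2I2),
and optionally to substrate binding on the three dimeric species (M2S,
M2IS, M2I2S).  All constants are dissociation constants in molar:

    K_D  = [M]^2 / [M2]          K_I  = [M][I] / [MI]
    K_I1 = [M2][I] / [M2I]       K_I2 = [M2I][I] / [M2I2]
    K1   = [M2][S] / [M2S]       K2   = [M2I][S] / [M2IS]
    K3   = [M2I2][S] / [M2I2S]

Inhibitor affinity for substrate-bound dimers is not independent: detailed
balance around each binding cycle fixes it to K_I1*K2/K1 and K_I2*K3/K2.

The key reduction: at fixed free inhibitor I and free substrate S, the
protein mass balance is a quadratic in the free monomer M,

    (2 P / K_D) M^2 + Q M - E = 0,
    Q = 1 + I/K_I,
    P = 1 + I/K_I1 + I^2/(K_I1 K_I2) + S/K1 + I S/(K_I1 K2)
          + I^2 S/(K_I1 K_I2 K3),

with the single physical root M = 2E / (Q + sqrt(Q^2 + 8 P E / K_D)).
The remaining one or two unknowns (free I, free S) are found by a damped
Newton iteration in log-concentration space with a nested-bisection
fallback, so the solver is deterministic and positivity-preserving.

Infinite constants are the sanctioned sentinel for "no binding": they are
carried as zero reciprocal affinities, so every term they enter vanishes
and the corresponding species is excluded exactly.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

_LOG_STEP_CAP = 3.0  # max |change| per Newton step in ln-concentration
_FD_EPS = 1e-7


class Recip(NamedTuple):
    """Reciprocal dissociation constants; zero encodes 'no binding' (K = inf)."""

    kd: float  # kept as-is (0, finite or inf); handled in the quadratic
    r_ki: float
    r_ki1: float
    r_ki2: float
    r_k1: float
    r_k2: float
    r_k3: float

    @classmethod
    def from_constants(cls, kd, ki, ki1, ki2, k1=np.inf, k2=np.inf, k3=np.inf):
        inv = lambda K: 0.0 if np.isinf(K) else 1.0 / K
        return cls(float(kd), inv(ki), inv(ki1), inv(ki2), inv(k1), inv(k2), inv(k3))


def _multipliers(I, S, rc: Recip):
    """Monomer (Q) and dimer (P) binding polynomials at free (I, S)."""
    Q = 1.0 + I * rc.r_ki
    a1 = I * rc.r_ki1
    a2 = a1 * I * rc.r_ki2
    P = 1.0 + a1 + a2 + S * (rc.r_k1 + a1 * rc.r_k2 + a2 * rc.r_k3)
    return Q, P


def _monomer_dimer(E, Q, P, kd):
    """Free monomer M and free dimer D satisfying the protein balance exactly."""
    if kd == 0.0:
        M = np.zeros(np.broadcast(E, Q).shape)
    elif np.isinf(kd):
        return E / Q, np.zeros(np.broadcast(E, Q, P).shape)
    else:
        M = 2.0 * E / (Q + np.sqrt(Q * Q + 8.0 * P * E / kd))
    D = np.maximum(E - Q * M, 0.0) / (2.0 * P)
    return M, D


def _balances(I, S, E, I_tot, S_tot, rc: Recip):
    """Scaled inhibitor/substrate mass-balance residuals at free (I, S)."""
    Q, P = _multipliers(I, S, rc)
    M, D = _monomer_dimer(E, Q, P, rc.kd)
    a1 = I * rc.r_ki1
    a2 = a1 * I * rc.r_ki2
    bI = M * I * rc.r_ki + D * (a1 + 2.0 * a2 + S * (a1 * rc.r_k2 + 2.0 * a2 * rc.r_k3))
    bS = D * S * (rc.r_k1 + a1 * rc.r_k2 + a2 * rc.r_k3)
    rI = (I + bI - I_tot) / np.where(I_tot > 0, I_tot, 1.0)
    rS = (S + bS - S_tot) / np.where(S_tot > 0, S_tot, 1.0)
    return rI, rS


def solve_free(E, I_tot, S_tot, kd, ki, ki1, ki2, k1=np.inf, k2=np.inf, k3=np.inf,
               tol=1e-12, maxiter=200):
    """Free (I, S) closing the inhibitor and substrate balances.

    ``E``, ``I_tot``, ``S_tot`` broadcast to arrays; the constants are
    scalars.  Returns arrays ``(I, S)`` of the broadcast shape.
    """
    rc = Recip.from_constants(kd, ki, ki1, ki2, k1, k2, k3)
    E, I_tot, S_tot = np.broadcast_arrays(
        np.asarray(E, float), np.asarray(I_tot, float), np.asarray(S_tot, float)
    )
    shape = E.shape
    E, I_tot, S_tot = E.ravel(), I_tot.ravel(), S_tot.ravel()

    act_I = I_tot > 0.0
    act_S = S_tot > 0.0
    any_I = bool(act_I.any())
    any_S = bool(act_S.any())
    if not (any_I or any_S):
        return np.zeros(shape), np.zeros(shape)

    x = np.where(act_I, np.log(np.where(act_I, 0.5 * I_tot, 1.0)), 0.0)
    y = np.where(act_S, np.log(np.where(act_S, 0.5 * S_tot, 1.0)), 0.0)

    def residual(xv, yv):
        Iv = np.where(act_I, np.exp(xv), 0.0)
        Sv = np.where(act_S, np.exp(yv), 0.0)
        rI, rS = _balances(Iv, Sv, E, I_tot, S_tot, rc)
        return np.where(act_I, rI, 0.0), np.where(act_S, rS, 0.0)

    rI, rS = residual(x, y)
    norm = np.maximum(np.abs(rI), np.abs(rS))
    for _ in range(maxiter):
        todo = norm > tol
        if not todo.any():
            break
        # forward-difference Jacobian in ln space (skip inactive directions)
        if any_I:
            rI_x, rS_x = residual(x + _FD_EPS, y)
            J11 = np.where(act_I, (rI_x - rI) / _FD_EPS, 1.0)
            J21 = (rS_x - rS) / _FD_EPS
        else:
            J11, J21 = np.ones_like(rI), np.zeros_like(rI)
        if any_S:
            rI_y, rS_y = residual(x, y + _FD_EPS)
            J12 = (rI_y - rI) / _FD_EPS
            J22 = np.where(act_S, (rS_y - rS) / _FD_EPS, 1.0)
        else:
            J12, J22 = np.zeros_like(rI), np.ones_like(rI)
        det = J11 * J22 - J12 * J21
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dx = -(J22 * rI - J12 * rS) / det
        dy = -(J11 * rS - J21 * rI) / det
        dx = np.clip(np.where(act_I, dx, 0.0), -_LOG_STEP_CAP, _LOG_STEP_CAP)
        dy = np.clip(np.where(act_S, dy, 0.0), -_LOG_STEP_CAP, _LOG_STEP_CAP)
        # damping: halve the step until the residual norm does not grow
        alpha = np.where(todo, 1.0, 0.0)
        for _half in range(40):
            xt, yt = x + alpha * dx, y + alpha * dy
            rI_t, rS_t = residual(xt, yt)
            norm_t = np.maximum(np.abs(rI_t), np.abs(rS_t))
            worse = todo & (norm_t > norm) & (alpha > 1e-12)
            if not worse.any():
                break
            alpha = np.where(worse, 0.5 * alpha, alpha)
        x, y = xt, yt
        rI, rS, norm = rI_t, rS_t, norm_t

    bad = np.flatnonzero(norm > tol)
    for j in bad:  # nested-bisection fallback on the free-inhibitor variable
        I_j, S_j = _solve_scalar_bisect(E[j], I_tot[j], S_tot[j], rc)
        if act_I[j]:
            x[j] = np.log(max(I_j, 1e-300))
        if act_S[j]:
            y[j] = np.log(max(S_j, 1e-300))

    I = np.where(act_I, np.exp(x), 0.0)
    S = np.where(act_S, np.exp(y), 0.0)
    return I.reshape(shape), S.reshape(shape)


def _solve_scalar_bisect(E, I_tot, S_tot, rc: Recip):
    """Robust scalar fallback: bisection on free I with inner bisection on free S."""

    def free_S(I):
        if S_tot <= 0.0:
            return 0.0

        def gS(S):
            _, rS = _balances(I, S, E, I_tot, S_tot, rc)
            return float(rS)

        lo = S_tot * 1e-16
        if gS(lo) > 0.0:
            return lo
        return brentq(gS, lo, S_tot, xtol=1e-300, rtol=8.9e-16, maxiter=300)

    if I_tot <= 0.0:
        return 0.0, free_S(0.0)

    def gI(I):
        S = free_S(I)
        rI, _ = _balances(I, S, E, I_tot, S_tot, rc)
        return float(rI)

    lo = I_tot * 1e-16
    if gI(lo) > 0.0:
        I = lo
    else:
        I = brentq(gI, lo, I_tot, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    return I, free_S(I)


def species_from_free(I, S, E, kd, ki, ki1, ki2, k1=np.inf, k2=np.inf, k3=np.inf):
    """All species concentrations given free (I, S) and total protein E."""
    rc = Recip.from_constants(kd, ki, ki1, ki2, k1, k2, k3)
    I = np.asarray(I, float)
    S = np.asarray(S, float)
    E = np.asarray(E, float)
    Q, P = _multipliers(I, S, rc)
    M, D = _monomer_dimer(E, Q, P, rc.kd)
    a1 = I * rc.r_ki1
    a2 = a1 * I * rc.r_ki2
    return {
        "M": M,
        "MI": M * I * rc.r_ki,
        "M2": D,
        "M2I": D * a1,
        "M2I2": D * a2,
        "M2S": D * S * rc.r_k1,
        "M2IS": D * S * a1 * rc.r_k2,
        "M2I2S": D * S * a2 * rc.r_k3,
        "I": I,
        "S": S,
    }
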