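"""Independent numerical oracles for the mass-action network.

These deliberately avoid the package's quadratic-reduction solver: species
are written straight from the pairwise equilibrium relations and the
balances are closed with generic root finders (progressive grid
refinement, or scipy's hybrid Powell method on log unknowns), so
agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import fsolve


def species_raw(M, I, S, kd, ki, ki1, ki2, k1=np.inf, k2=np.inf, k3=np.inf):
    """Species from free (M, I, S) via the raw equilibrium relations."""
    div = lambda num, K: 0.0 * num if np.isinf(K) else num / K
    M2 = div(M * M, kd)
    MI = div(M * I, ki)
    M2I = div(M2 * I, ki1)
    M2I2 = div(M2I * I, ki2)
    M2S = div(M2 * S, k1)
    M2IS = div(M2I * S, k2)
    M2I2S = div(M2I2 * S, k3)
    return dict(M=M, MI=MI, M2=M2, M2I=M2I, M2I2=M2I2,
                M2S=M2S, M2IS=M2IS, M2I2S=M2I2S, I=I, S=S)


def balance_residuals(sp, E, I_tot, S_tot):
    prot = (sp["M"] + sp["MI"]
            + 2 * (sp["M2"] + sp["M2I"] + sp["M2I2"] + sp["M2S"] + sp["M2IS"] + sp["M2I2S"]))
    inh = sp["I"] + sp["MI"] + sp["M2I"] + 2 * sp["M2I2"] + sp["M2IS"] + 2 * sp["M2I2S"]
    sub = sp["S"] + sp["M2S"] + sp["M2IS"] + sp["M2I2S"]
    rp = (prot - E) / E
    ri = (inh - I_tot) / np.where(np.asarray(I_tot) > 0, I_tot, 1.0)
    rs = (sub - S_tot) / np.where(np.asarray(S_tot) > 0, S_tot, 1.0)
    return rp, ri, rs


def grid_refine_solve(E, I_tot, kd, ki, ki1, ki2, rounds=14, n=60):
    """Dense progressive grid search over (free M, free I), substrate-free."""
    lo_m, hi_m = np.log10(E) - 16, np.log10(E) + 0.001
    lo_i, hi_i = np.log10(I_tot) - 16, np.log10(I_tot) + 0.001
    best = None
    for _ in range(rounds):
        m = np.logspace(lo_m, hi_m, n)
        i = np.logspace(lo_i, hi_i, n)
        Mg, Ig = np.meshgrid(m, i, indexing="ij")
        sp = species_raw(Mg, Ig, 0.0, kd, ki, ki1, ki2)
        rp, ri, _ = balance_residuals(sp, E, I_tot, 0.0)
        err = np.abs(rp) + np.abs(ri)
        j = np.unravel_index(np.argmin(err), err.shape)
        best = (m[j[0]], i[j[1]], err[j])
        wm = (hi_m - lo_m) / n
        wi = (hi_i - lo_i) / n
        lo_m, hi_m = np.log10(best[0]) - 2 * wm, np.log10(best[0]) + 2 * wm
        lo_i, hi_i = np.log10(best[1]) - 2 * wi, np.log10(best[1]) + 2 * wi
    return species_raw(best[0], best[1], 0.0, kd, ki, ki1, ki2)


def fsolve_network(E, I_tot, S_tot, kd, ki, ki1, ki2, k1=np.inf, k2=np.inf, k3=np.inf):
    """Full-network solve on log free (M, I, S) with scipy's hybrid method."""
    act_i = I_tot > 0
    act_s = S_tot > 0

    def unpack(z):
        j = 1
        M = np.exp(z[0])
        I = np.exp(z[j]) if act_i else 0.0
        j += act_i
        S = np.exp(z[j]) if act_s else 0.0
        return M, I, S

    def func(z):
        M, I, S = unpack(z)
        sp = species_raw(M, I, S, kd, ki, ki1, ki2, k1, k2, k3)
        rp, ri, rs = balance_residuals(sp, E, I_tot, S_tot)
        out = [rp]
        if act_i:
            out.append(ri)
        if act_s:
            out.append(rs)
        return out

    starts = []
    for fm in (0.3, 1e-4, 0.999, 1e-8):
        for fi in (0.5, 1e-4, 0.999):
            for fs in (0.5, 1e-4, 0.999):
                z0 = [np.log(E * fm)]
                if act_i:
                    z0.append(np.log(I_tot * fi))
                if act_s:
                    z0.append(np.log(S_tot * fs))
                starts.append(z0)
    for z0 in starts:
        z, info, ier, _ = fsolve(func, z0, full_output=True, xtol=1e-13)
        if ier == 1 and max(abs(np.atleast_1d(info["fvec"]))) < 1e-10:
            M, I, S = unpack(z)
            return species_raw(M, I, S, kd, ki, ki1, ki2, k1, k2, k3)
    return _nested_bisect(E, I_tot, S_tot, kd, ki, ki1, ki2, k1, k2, k3)


def _nested_bisect(E, I_tot, S_tot, kd, ki, ki1, ki2, k1, k2, k3):
    """Slow but guaranteed triple-nested bisection (protein innermost)."""
    from scipy.optimize import brentq

    def free_M(I, S):
        def g(M):
            sp = species_raw(M, I, S, kd, ki, ki1, ki2, k1, k2, k3)
            return balance_residuals(sp, E, max(I_tot, 1.0), max(S_tot, 1.0))[0]

        return brentq(g, 0.0, E, xtol=1e-300, rtol=8.9e-16, maxiter=300)

    def free_S(I):
        if S_tot <= 0:
            return 0.0

        def g(S):
            sp = species_raw(free_M(I, S), I, S, kd, ki, ki1, ki2, k1, k2, k3)
            return sp["S"] + sp["M2S"] + sp["M2IS"] + sp["M2I2S"] - S_tot

        return brentq(g, 0.0, S_tot, xtol=1e-300, rtol=8.9e-16, maxiter=300)

    def g_I(I):
        S = free_S(I)
        sp = species_raw(free_M(I, S), I, S, kd, ki, ki1, ki2, k1, k2, k3)
        return sp["I"] + sp["MI"] + sp["M2I"] + 2 * sp["M2I2"] + sp["M2IS"] + 2 * sp["M2I2S"] - I_tot

    I = brentq(g_I, 0.0, I_tot, xtol=1e-300, rtol=8.9e-16, maxiter=300) if I_tot > 0 else 0.0
    S = free_S(I)
    return species_raw(free_M(I, S), I, S, kd, ki, ki1, ki2, k1, k2, k3)


def oracle_rate(E, I_tot, S_tot, k, kp, kpp, k1, k2, k3, kd, ki, ki1, ki2):
    sp = fsolve_network(E, I_tot, S_tot, kd, ki, ki1, ki2, k1, k2, k3)
    return k * sp["M2S"] + kp * sp["M2IS"] + kpp * sp["M2I2S"]
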