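"""Fast-equilibrium steady-state kinetics of dissociative inhibition.

All binding steps (dimerization, inhibitor binding, substrate binding)
are taken to equilibrate fast on the catalytic timescale, so the initial
rate is a weighted sum over the productive dimeric complexes::

    v = k [M2S] + k' [M2IS] + k'' [M2I2S]

Monomers are catalytically inactive and do not bind substrate (each
active site comprises residues from both subunits).  The nucleotide
substrate is saturating and absorbed into the constants; the varied
substrate S is the folate cofactor, with an exact free-substrate
(depletion) correction.

At fixed free inhibitor I and free substrate S the protein balance is a
quadratic in ``x = sqrt([M2])`` whose only acceptable root ``x_r``
(positive, within the mass-balance bound ``x_r^2 <= E/2``) gives the
closed-form rate ``v = x_r^2 * S * D(I)`` with the composite constant::

    D(I) = k/K1 + k' I/(K_I1 K2) + k'' I^2/(K_I1 K_I2 K3)

The full-numeric network solution and this closed form agree by
construction and are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from . import _network
from .equilibrium import (
    EquilibriumConstants,
    SpeciesState,
    Totals,
    _state_from_species,
)


class FitQualityError(RuntimeError):
    """Raised when dose-response data cannot support the requested estimate."""


@dataclass(frozen=True)
class KineticParameters:
    """Catalytic and substrate-binding constants joined to the equilibrium scheme.

    ``k``, ``k_prime``, ``k_dblprime`` are the turnover rate constants
    (s^-1) of M2S, M2IS and M2I2S; ``K1``-``K3`` their substrate
    dissociation constants (molar).  Inhibitor affinity for the
    substrate-bound dimers is cycle-derived (``K_I1 K2/K1`` and
    ``K_I2 K3/K2``), never an independent parameter.
    """

    k: float
    k_prime: float
    k_dblprime: float
    K1: float
    K2: float
    K3: float
    eq: EquilibriumConstants

    def __post_init__(self):
        for name in ("k", "k_prime", "k_dblprime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("K1", "K2", "K3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def with_(self, **changes) -> "KineticParameters":
        eq_changes = {k: v for k, v in changes.items()
                      if k in ("K_D", "K_I", "K_I1", "K_I2", "temperature")}
        own = {k: v for k, v in changes.items() if k not in eq_changes}
        eq = self.eq.with_(**eq_changes) if eq_changes else self.eq
        return replace(self, eq=eq, **own)


@dataclass(frozen=True)
class RatePoint:
    """One initial-rate measurement (molar/s) at total substrate and inhibitor."""

    S_total: float
    I_total: float
    v: float
    sigma_rel: float | None = None

    def __post_init__(self):
        if self.S_total < 0 or self.I_total < 0 or self.v < 0:
            raise ValueError("concentrations and rates must be non-negative")
        if self.sigma_rel is not None and not self.sigma_rel > 0:
            raise ValueError("sigma_rel must be positive when present")


@dataclass(frozen=True)
class KineticDataset:
    """Initial-rate curves at one total enzyme concentration (monomer-equivalents)."""

    E_mono: float
    points: tuple[RatePoint, ...]
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def S_total(self) -> np.ndarray:
        return np.array([p.S_total for p in self.points])

    @property
    def I_total(self) -> np.ndarray:
        return np.array([p.I_total for p in self.points])

    @property
    def v(self) -> np.ndarray:
        return np.array([p.v for p in self.points])

    def require_fittable(self):
        if len(self.points) < 4 or len(set(p.S_total for p in self.points)) < 2:
            raise ValueError(
                "fitting requires at least 4 points spanning at least 2 substrate levels"
            )


def _recip(params: KineticParameters) -> _network.Recip:
    eq = params.eq
    return _network.Recip.from_constants(
        eq.K_D, eq.K_I, eq.K_I1, eq.K_I2, params.K1, params.K2, params.K3
    )


def rate_coefficient(I_free, params: KineticParameters):
    """Composite constant D(I) such that v = [M2] * S_free * D(I)."""
    rc = _recip(params)
    I = np.asarray(I_free, dtype=float)
    return (
        params.k * rc.r_k1
        + params.k_prime * I * rc.r_ki1 * rc.r_k2
        + params.k_dblprime * I * I * rc.r_ki1 * rc.r_ki2 * rc.r_k3
    )


def rate_at_free(S_free, I_free, E_mono: float, params: KineticParameters):
    """Closed-form rate at given *free* S and I.

    Resolves the protein balance as a quadratic in ``x = sqrt([M2])`` and
    keeps the only acceptable root (positive with ``x^2 <= E/2``).
    """
    eq = params.eq
    S = np.asarray(S_free, dtype=float)
    I = np.asarray(I_free, dtype=float)
    Q, P = _network._multipliers(I, S, _recip(params))
    # 2 P x^2 + Q sqrt(K_D) x - E = 0
    b = Q * math.sqrt(eq.K_D)
    x = 2.0 * E_mono / (b + np.sqrt(b * b + 8.0 * P * E_mono))
    x2 = x * x
    if np.any(x2 < 0) or np.any(x2 > E_mono / 2.0 * (1 + 1e-12)):
        raise ArithmeticError("no acceptable quadratic root")
    return x2 * S * rate_coefficient(I, params)


def solve_with_substrate(totals: Totals, params: KineticParameters) -> SpeciesState:
    """Full nine-species network with exact mass balances including free substrate."""
    eq = params.eq
    I, S = _network.solve_free(
        totals.E_mono, totals.I_total, totals.S_total,
        eq.K_D, eq.K_I, eq.K_I1, eq.K_I2, params.K1, params.K2, params.K3,
    )
    sp = _network.species_from_free(
        I, S, totals.E_mono,
        eq.K_D, eq.K_I, eq.K_I1, eq.K_I2, params.K1, params.K2, params.K3,
    )
    return _state_from_species(sp, totals)


def predict_initial_rate(S_total, I_total, E_mono: float, params: KineticParameters):
    """Initial rate (molar/s) at total substrate and inhibitor concentrations.

    Vectorized over ``S_total``/``I_total``; scalar inputs return a float.
    """
    eq = params.eq
    S_arr = np.asarray(S_total, dtype=float)
    I_arr = np.asarray(I_total, dtype=float)
    scalar = S_arr.ndim == 0 and I_arr.ndim == 0
    I, S = _network.solve_free(
        E_mono, I_arr, S_arr,
        eq.K_D, eq.K_I, eq.K_I1, eq.K_I2, params.K1, params.K2, params.K3,
    )
    sp = _network.species_from_free(
        I, S, E_mono,
        eq.K_D, eq.K_I, eq.K_I1, eq.K_I2, params.K1, params.K2, params.K3,
    )
    v = (params.k * sp["M2S"] + params.k_prime * sp["M2IS"]
         + params.k_dblprime * sp["M2I2S"])
    return float(v) if scalar else np.asarray(v)


def predict_dataset(S_grid, I_levels, E_mono: float, params: KineticParameters,
                    label: str = "") -> KineticDataset:
    """Noise-free rate curves over a substrate grid at several inhibitor levels."""
    S_grid = np.asarray(S_grid, dtype=float)
    pts = []
    for I in np.atleast_1d(np.asarray(I_levels, dtype=float)):
        v = predict_initial_rate(S_grid, np.full_like(S_grid, I), E_mono, params)
        pts.extend(RatePoint(float(s), float(I), float(r)) for s, r in zip(S_grid, v))
    return KineticDataset(E_mono=float(E_mono), points=tuple(pts), label=label)


def limiting_rate_ratio(params: KineticParameters, S_total: float, E_mono: float) -> float:
    """v at saturating inhibitor over v without inhibitor.

    "Saturating" is taken as 1e4 times the largest finite inhibitor
    constant.  A noncompetitive signature leaves this ratio nonzero but
    well below one.
    """
    v0 = predict_initial_rate(S_total, 0.0, E_mono, params)
    if v0 == 0:
        raise ZeroDivisionError("rate without inhibitor is zero; ratio undefined")
    eq = params.eq
    kmax = max(k for k in (eq.K_I, eq.K_I1, eq.K_I2) if np.isfinite(k))
    vinf = predict_initial_rate(S_total, 1e4 * kmax, E_mono, params)
    return float(vinf / v0)


# ---------------------------------------------------------------------------
# IC50


@dataclass(frozen=True)
class Ic50Result:
    ic50: float
    stderr: float | None
    top: float
    bottom: float
    hill: float


def estimate_ic50(I_totals, response) -> Ic50Result:
    """Four-parameter logistic fit of a rate (or inhibition-fraction) curve.

    ``response`` is fit against ``bottom + (top - bottom) / (1 + (I/IC50)^h)``
    in log-inhibitor space; the midpoint concentration and its standard
    error are returned.
    """
    import lmfit

    I = np.asarray(I_totals, dtype=float)
    y = np.asarray(response, dtype=float)
    if I.shape != y.shape or I.ndim != 1:
        raise ValueError("I_totals and response must be 1-d arrays of equal length")
    if np.count_nonzero(I > 0) < 5:
        raise ValueError("at least 5 positive inhibitor levels spanning the transition")
    order = np.argsort(I)
    I, y = I[order], y[order]
    span = y.max() - y.min()
    if span <= 0 or np.polyfit(np.log10(np.maximum(I, I[I > 0].min() / 10)), y, 1)[0] > 0:
        raise FitQualityError("response does not decrease with inhibitor; no transition to fit")

    def model(p, I):
        return p["bottom"] + (p["top"] - p["bottom"]) / (
            1.0 + (I / p["ic50"]) ** p["hill"]
        )

    p = lmfit.Parameters()
    p.add("top", value=float(y.max()), min=0.0)
    p.add("bottom", value=float(max(y.min(), 0.0)), min=0.0)
    p.add("log_ic50", value=float(np.log10(np.median(I[I > 0]))),
          min=np.log10(I[I > 0].min()) - 3, max=np.log10(I.max()) + 3)
    p.add("ic50", expr="10**log_ic50")
    p.add("hill", value=1.0, min=0.1, max=8.0)
    out = lmfit.minimize(lambda p: model(p, I) - y, p)
    if not out.success:
        raise FitQualityError("logistic fit did not converge")
    ic50 = float(out.params["ic50"].value)
    if not (I[I > 0].min() / 10 <= ic50 <= I.max() * 10):
        raise FitQualityError("fitted midpoint lies far outside the dosed range")
    stderr = out.params["ic50"].stderr
    return Ic50Result(
        ic50=ic50,
        stderr=float(stderr) if stderr is not None else None,
        top=float(out.params["top"].value),
        bottom=float(out.params["bottom"].value),
        hill=float(out.params["hill"].value),
    )


def model_ic50(params: KineticParameters, E_mono: float = 600e-9,
               S_total: float = 55e-6, I_max: float = 1e-1) -> float:
    """Inhibitor concentration halving the model rate under assay conditions.

    Defaults mirror the enzymatic assay: 300 nM enzyme dimer (600 nM
    monomer-equivalents) and 55 uM folate cofactor.  Found by bisection
    on the predicted initial rate; raises if the rate never falls to
    half, e.g. for a weakly coupled inhibitor.
    """
    v0 = predict_initial_rate(S_total, 0.0, E_mono, params)
    if v0 <= 0:
        raise ZeroDivisionError("uninhibited rate is zero")

    def g(I):
        return predict_initial_rate(S_total, I, E_mono, params) - 0.5 * v0

    if g(I_max) > 0:
        raise FitQualityError("rate never falls to half the uninhibited value")
    return float(brentq(g, 0.0, I_max, xtol=1e-300, rtol=8.9e-16))
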