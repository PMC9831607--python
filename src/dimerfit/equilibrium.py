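"""Dimer-monomer-inhibitor equilibria of an obligate homodimeric enzyme.

The model describes a dissociative inhibitor: a small molecule that binds
both the free monomer (dissociation constant ``K_I``) and the two
symmetric monomer-monomer interface sites of the dimer (macroscopic
constants ``K_I1`` and ``K_I2``), thereby shifting the dimerization
equilibrium ``M2 <-> 2M`` (constant ``K_D``) toward the catalytically
inactive monomers.  Thermodynamic-cycle closure makes the dissociation
constants of the inhibitor-bound dimers derived quantities::

    K_D'  = K_D * K_I1 / K_I        (M2I   <-> M + MI)
    K_D'' = K_D * K_I1 * K_I2 / K_I**2   (M2I2 <-> 2 MI)

All concentrations are molar.  Internally everything is carried in
monomer-equivalents; :meth:`Totals.from_dimer` is the one sanctioned
conversion from dimer-equivalent counts (``E_mono = 2 * E_dimer``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _network

#: molar gas constant, J mol^-1 K^-1
R_GAS = 8.31446261815324

#: default thermodynamic temperature (K) used to convert constants to
#: standard free energies.  The fluorescence work was done near room
#: temperature; 298.15 K is the convention used for all printed Delta-G
#: values in this package.
T_STANDARD = 298.15


def _check_constant(name: str, value: float) -> float:
    value = float(value)
    if not value > 0.0 or math.isnan(value):
        raise ValueError(f"{name} must be strictly positive (inf = no binding); got {value!r}")
    return value


@dataclass(frozen=True)
class EquilibriumConstants:
    """Binding/dissociation constants of the dissociative-inhibition scheme.

    Parameters
    ----------
    K_D : float
        Dimer dissociation constant, ``[M]^2/[M2]`` (molar).
    K_I : float
        Monomer-inhibitor dissociation constant (molar).
    K_I1, K_I2 : float
        Macroscopic inhibitor dissociation constants of the first and
        second dimer interface site (molar).  No statistical factor for
        the two symmetric sites is applied.
    temperature : float
        Temperature in kelvin used for free-energy bookkeeping.

    ``float('inf')`` in any constant means the corresponding species is
    absent from the network.
    """

    K_D: float
    K_I: float = np.inf
    K_I1: float = np.inf
    K_I2: float = np.inf
    temperature: float = T_STANDARD

    def __post_init__(self):
        for name in ("K_D", "K_I", "K_I1", "K_I2"):
            object.__setattr__(self, name, _check_constant(name, getattr(self, name)))
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    @property
    def K_D_prime(self) -> float:
        """Dissociation constant of the singly inhibitor-bound dimer."""
        return self.K_D * self.K_I1 / self.K_I

    @property
    def K_D_dblprime(self) -> float:
        """Dissociation constant of the doubly inhibitor-bound dimer."""
        return self.K_D * self.K_I1 * self.K_I2 / (self.K_I * self.K_I)

    def with_(self, **changes) -> "EquilibriumConstants":
        return replace(self, **changes)


def derive_cycle_constants(constants: EquilibriumConstants) -> tuple[float, float]:
    """``(K_D', K_D'')`` forced by thermodynamic-cycle closure."""
    return constants.K_D_prime, constants.K_D_dblprime


@dataclass(frozen=True)
class Totals:
    """Total (analytic) concentrations in molar, protein in monomer-equivalents."""

    E_mono: float
    I_total: float = 0.0
    S_total: float = 0.0

    def __post_init__(self):
        for name in ("E_mono", "I_total", "S_total"):
            v = float(getattr(self, name))
            if v < 0 or math.isnan(v):
                raise ValueError(f"{name} must be non-negative; got {v!r}")
            object.__setattr__(self, name, v)

    @classmethod
    def from_dimer(cls, E_dimer: float, I_total: float = 0.0, S_total: float = 0.0) -> "Totals":
        """Build totals from protein counted in dimer equivalents."""
        return cls(E_mono=2.0 * float(E_dimer), I_total=I_total, S_total=S_total)


_PROTEIN_WEIGHTS = {"M": 1, "MI": 1, "M2": 2, "M2I": 2, "M2I2": 2, "M2S": 2, "M2IS": 2, "M2I2S": 2}
_INHIBITOR_WEIGHTS = {"MI": 1, "M2I": 1, "M2I2": 2, "M2IS": 1, "M2I2S": 2, "I": 1}
_SUBSTRATE_WEIGHTS = {"M2S": 1, "M2IS": 1, "M2I2S": 1, "S": 1}


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (molar) of every species in the network."""

    M: float
    MI: float
    M2: float
    M2I: float
    M2I2: float
    I: float
    M2S: float = 0.0
    M2IS: float = 0.0
    M2I2S: float = 0.0
    S: float = 0.0
    #: maximum relative mass-balance violation over protein/inhibitor/substrate
    residual: float = field(default=0.0, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("M", "MI", "M2", "M2I", "M2I2", "M2S", "M2IS", "M2I2S", "I", "S")}

    @property
    def dimer_total(self) -> float:
        """Summed concentration of all dimeric species (dimer units)."""
        return self.M2 + self.M2I + self.M2I2 + self.M2S + self.M2IS + self.M2I2S

    def dimeric_fraction(self, E_mono: float) -> float:
        """Mole fraction of protein residing in any dimeric species."""
        if E_mono <= 0:
            raise ValueError("E_mono must be positive")
        return 2.0 * self.dimer_total / E_mono

    def mass_balances(self) -> tuple[float, float, float]:
        """(protein, inhibitor, substrate) totals implied by the state."""
        d = self.as_dict()
        prot = sum(w * d[s] for s, w in _PROTEIN_WEIGHTS.items())
        inh = sum(w * d[s] for s, w in _INHIBITOR_WEIGHTS.items())
        sub = sum(w * d[s] for s, w in _SUBSTRATE_WEIGHTS.items())
        return prot, inh, sub


def _state_from_species(sp: dict, totals: Totals) -> SpeciesState:
    vals = {k: float(np.asarray(v).item()) for k, v in sp.items()}
    state = SpeciesState(**vals)
    prot, inh, sub = state.mass_balances()
    res = abs(prot - totals.E_mono) / max(totals.E_mono, 1e-300)
    if totals.I_total > 0:
        res = max(res, abs(inh - totals.I_total) / totals.I_total)
    if totals.S_total > 0:
        res = max(res, abs(sub - totals.S_total) / totals.S_total)
    return replace(state, residual=res)


def solve_dimer_monomer(E_mono: float, K_D: float) -> SpeciesState:
    """Inhibitor-free dimer-monomer equilibrium.

    The free monomer is the unique non-negative root of
    ``M^2 + (K_D/2) M - K_D E/2 = 0`` and the dimer is ``(E - M)/2``.
    """
    E_mono = float(E_mono)
    K_D = float(K_D)
    if E_mono < 0 or K_D < 0:
        raise ValueError("E_mono and K_D must be non-negative")
    if K_D == 0.0 or E_mono == 0.0:
        M = 0.0
    elif math.isinf(K_D):
        M = E_mono
    else:
        # cancellation-free form of (-K_D/2 + sqrt(K_D^2/4 + 2 K_D E)) / 2
        M = 2.0 * E_mono / (1.0 + math.sqrt(1.0 + 8.0 * E_mono / K_D))
    D = (E_mono - M) / 2.0
    return _state_from_species(
        {"M": M, "MI": 0.0, "M2": D, "M2I": 0.0, "M2I2": 0.0,
         "M2S": 0.0, "M2IS": 0.0, "M2I2S": 0.0, "I": 0.0, "S": 0.0},
        Totals(E_mono),
    )


def solve_coupled_equilibria(totals: Totals, constants: EquilibriumConstants) -> SpeciesState:
    """Simultaneous solution of the five-species inhibitor network.

    Deterministic: damped Newton iteration in log-concentration space on
    the free-inhibitor variable (protein balance eliminated in closed
    form), with a bisection fallback.  Substrate-containing networks live
    in :mod:`dimerfit.kinetics`.
    """
    if totals.S_total != 0.0:
        raise ValueError("substrate-containing networks are handled by the kinetics module")
    I, _ = _network.solve_free(
        totals.E_mono, totals.I_total, 0.0,
        constants.K_D, constants.K_I, constants.K_I1, constants.K_I2,
    )
    sp = _network.species_from_free(
        I, 0.0, totals.E_mono,
        constants.K_D, constants.K_I, constants.K_I1, constants.K_I2,
    )
    return _state_from_species(sp, totals)


def delta_g_of_k(K: float, T: float = T_STANDARD) -> float:
    """Standard free energy (kJ/mol) required to disrupt a complex.

    ``-R T ln(K / 1 M)``: positive for sub-molar dissociation constants.
    """
    K = float(K)
    T = float(T)
    if not K > 0 or math.isinf(K):
        raise ValueError("K must be positive and finite")
    if not T > 0:
        raise ValueError("T must be positive")
    return -R_GAS * T * math.log(K) / 1000.0
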