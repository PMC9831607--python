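"""FRET observable of the dimer-monomer equilibrium.

In the dimerization assay one monomer pool carries a fluorescein donor
and the other a tetramethylrhodamine acceptor.  Energy transfer occurs
only within assembled dimers, so the observed efficiency ``phi`` is read
as the mole fraction of protein residing in any dimeric species (unit
proportionality; labeling statistics are not modeled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _network
from .equilibrium import EquilibriumConstants, SpeciesState, Totals


@dataclass(frozen=True)
class FretCurvePoint:
    """One dose-response point: efficiency at a total inhibitor concentration."""

    I_total: float
    phi: float
    sigma: float | None = None

    def __post_init__(self):
        if self.I_total < 0:
            raise ValueError("I_total must be non-negative")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1]; got {self.phi}")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be positive when present")


@dataclass(frozen=True)
class FretDataset:
    """A FRET dose-response curve at one total protein concentration.

    ``E_mono`` is in monomer-equivalents (molar); ``e_unit`` records the
    convention of the original data source ('monomer' or 'dimer').
    """

    E_mono: float
    points: tuple[FretCurvePoint, ...]
    label: str = ""
    e_unit: str = "monomer"

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        I = [p.I_total for p in self.points]
        if any(b <= a for a, b in zip(I, I[1:])):
            raise ValueError("I_total must be strictly increasing")

    @property
    def I_grid(self) -> np.ndarray:
        return np.array([p.I_total for p in self.points])

    @property
    def phi(self) -> np.ndarray:
        return np.array([p.phi for p in self.points])

    @property
    def sigma(self) -> np.ndarray | None:
        s = [p.sigma for p in self.points]
        return None if any(v is None for v in s) else np.array(s)

    def require_fittable(self):
        if len(self.points) < 3:
            raise ValueError("at least 3 points are required for fitting")


def phi_from_state(state: SpeciesState, totals: Totals) -> float:
    """Efficiency = mole fraction of protein in dimeric species."""
    if totals.E_mono <= 0:
        raise ValueError("E_mono must be positive")
    return state.dimeric_fraction(totals.E_mono)


def self_consistent_phi(E_dimer: float, K: float) -> float:
    """The dilution-curve efficiency solving phi = 1 - 0.5 sqrt(phi/E) sqrt(K).

    ``E_dimer`` is the total protein in dimer equivalents.  Substituting
    ``y = sqrt(phi)`` gives ``y^2 + 0.5 sqrt(K/E) y - 1 = 0`` whose
    positive root is returned; the result coincides with the direct
    mass-action solution of the dimer-monomer equilibrium.
    """
    if not E_dimer > 0:
        raise ValueError("E_dimer must be positive")
    if K < 0:
        raise ValueError("K must be non-negative")
    if K == 0.0:
        return 1.0
    b = 0.5 * math.sqrt(K / E_dimer)
    y = 2.0 / (b + math.sqrt(b * b + 4.0))
    return y * y


def predict_dose_response(
    E_mono: float,
    I_grid,
    constants: EquilibriumConstants,
    label: str = "",
) -> FretDataset:
    """Model FRET efficiency over a grid of total inhibitor concentrations."""
    I_grid = np.asarray(I_grid, dtype=float)
    phi = predict_phi(E_mono, I_grid, constants)
    pts = [FretCurvePoint(float(i), float(p)) for i, p in zip(I_grid, phi)]
    return FretDataset(E_mono=float(E_mono), points=tuple(pts), label=label)


def predict_phi(E_mono, I_grid, constants: EquilibriumConstants) -> np.ndarray:
    """Vectorized dimeric mole fraction over a total-inhibitor grid.

    ``E_mono`` may be a scalar or an array broadcasting against ``I_grid``,
    which lets a global fit evaluate several protein levels in one solve.
    """
    I_grid = np.atleast_1d(np.asarray(I_grid, dtype=float))
    E = np.asarray(E_mono, dtype=float)
    I, _ = _network.solve_free(
        E, I_grid, 0.0,
        constants.K_D, constants.K_I, constants.K_I1, constants.K_I2,
    )
    sp = _network.species_from_free(
        I, 0.0, np.broadcast_to(E, I.shape),
        constants.K_D, constants.K_I, constants.K_I1, constants.K_I2,
    )
    dimer = sp["M2"] + sp["M2I"] + sp["M2I2"]
    return np.clip(2.0 * dimer / np.broadcast_to(E, I.shape), 0.0, 1.0)


@dataclass(frozen=True)
class DilutionSeries:
    """Efficiency vs total protein (dimer equivalents) without inhibitor."""

    E_dimer: tuple[float, ...]
    phi: tuple[float, ...]
    sigma: float | None = None
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "E_dimer", tuple(float(e) for e in self.E_dimer))
        object.__setattr__(self, "phi", tuple(float(p) for p in self.phi))
        if len(self.E_dimer) != len(self.phi):
            raise ValueError("E_dimer and phi must have equal length")
        if any(e <= 0 for e in self.E_dimer):
            raise ValueError("protein concentrations must be positive")

    @property
    def E_array(self) -> np.ndarray:
        return np.array(self.E_dimer)

    @property
    def phi_array(self) -> np.ndarray:
        return np.array(self.phi)


# ---------------------------------------------------------------------------
# ratiometric plate readout


@dataclass(frozen=True)
class IntensityPair:
    """Acceptor/donor band intensities from one well (arbitrary units)."""

    I_A: float
    I_D: float
    role: str = "sample"  # sample | control_protein | control_no_fret

    def __post_init__(self):
        if self.I_A < 0 or self.I_D < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def ratio(self) -> float:
        if self.I_D == 0:
            raise ZeroDivisionError("donor-band intensity is zero; ratio undefined")
        return self.I_A / self.I_D


@dataclass(frozen=True)
class FretCalibration:
    """Two-anchor linear map from intensity ratio to efficiency.

    ``ratio_zero`` is the no-FRET control ratio (phi = 0) and
    ``ratio_protein`` the untreated-protein control, assigned the model
    efficiency ``phi_protein`` of protein alone at the assay
    concentration.
    """

    ratio_zero: float
    ratio_protein: float
    phi_protein: float

    @classmethod
    def from_controls(
        cls,
        controls: list[IntensityPair],
        phi_protein: float,
    ) -> "FretCalibration":
        zero = [p.ratio for p in controls if p.role == "control_no_fret"]
        prot = [p.ratio for p in controls if p.role == "control_protein"]
        if not zero or not prot:
            raise ValueError(
                "calibration requires at least one no-FRET and one protein control well"
            )
        return cls(
            ratio_zero=float(np.mean(zero)),
            ratio_protein=float(np.mean(prot)),
            phi_protein=float(phi_protein),
        )


def phi_from_intensities(pair: IntensityPair, calibration: FretCalibration) -> float:
    """Efficiency of a sample well by linear two-anchor normalization."""
    span = calibration.ratio_protein - calibration.ratio_zero
    if span == 0:
        raise ValueError("degenerate calibration: control ratios coincide")
    return calibration.phi_protein * (pair.ratio - calibration.ratio_zero) / span


def delta_phi(pair: IntensityPair, calibration: FretCalibration) -> float:
    """Efficiency change of a sample relative to the untreated control."""
    return phi_from_intensities(pair, calibration) - calibration.phi_protein
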