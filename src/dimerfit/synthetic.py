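"""Seeded synthetic datasets with the statistical structure the fits assume.

Every generator is a pure function of (parameters, design, seed) built on
numpy's PCG64 ``default_rng``, so identical calls are bit-identical across
platforms.  Noise is additive Gaussian on FRET efficiency and
multiplicative Gaussian on initial rates; the magnitudes are configurable
because the experiments report none.  Defaults reproduce the study
designs: FRET dose-response at 50/100/250/490 nM protein (dimer
equivalents) over the 0-100 uM inhibitor grid, and rate curves over a
1-100 uM substrate grid at 0/12/24/36 uM inhibitor with 300 nM enzyme
dimer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibrium import EquilibriumConstants
from .fret import DilutionSeries, FretCurvePoint, FretDataset, predict_phi, self_consistent_phi
from .kinetics import KineticDataset, KineticParameters, RatePoint, predict_initial_rate
from . import presets


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian error model for generated curves.

    ``sigma_phi`` is the additive s.d. on FRET efficiency, ``sigma_rel_rate``
    the relative s.d. on rates.  ``clip_phi`` keeps generated efficiencies
    inside [0, 1] (disable only for distribution-purity checks; the raw
    values are then returned as plain arrays, not validated points).
    """

    sigma_phi: float = 0.03
    sigma_rel_rate: float = 0.03
    seed: int = 0
    clip_phi: bool = True

    def __post_init__(self):
        if self.sigma_phi < 0 or self.sigma_rel_rate < 0:
            raise ValueError("noise magnitudes must be non-negative")


NOISELESS = NoiseModel(sigma_phi=0.0, sigma_rel_rate=0.0)


def gen_fret_dose_response(
    constants: EquilibriumConstants,
    E_dimer_levels=None,
    I_grid=None,
    noise: NoiseModel = NoiseModel(),
) -> list[FretDataset]:
    """FRET dose-response curves, one dataset per protein level.

    ``E_dimer_levels`` are total protein in dimer equivalents (molar).
    """
    E_levels = presets.FRET_E_DIMER_LEVELS if E_dimer_levels is None else tuple(E_dimer_levels)
    I_grid = np.asarray(presets.FRET_I_GRID if I_grid is None else I_grid, dtype=float)
    rng = np.random.default_rng(noise.seed)
    out = []
    for E_dimer in E_levels:
        E_mono = 2.0 * float(E_dimer)
        phi = predict_phi(E_mono, I_grid, constants)
        if noise.sigma_phi > 0:
            phi = phi + rng.normal(0.0, noise.sigma_phi, size=phi.shape)
        if noise.clip_phi:
            phi = np.clip(phi, 0.0, 1.0)
        sigma = noise.sigma_phi if noise.sigma_phi > 0 else None
        pts = tuple(
            FretCurvePoint(float(i), float(p), sigma) for i, p in zip(I_grid, phi)
        )
        out.append(FretDataset(E_mono=E_mono, points=pts,
                               label=f"E_dimer={E_dimer * 1e9:g}nM", e_unit="monomer"))
    return out


def gen_kinetics(
    params: KineticParameters,
    S_grid=None,
    I_levels=None,
    E_mono: float = presets.KINETIC_E_MONO,
    noise: NoiseModel = NoiseModel(),
    label: str = "",
) -> KineticDataset:
    """Initial-rate curves vs substrate at several inhibitor levels."""
    S_grid = np.asarray(
        np.logspace(-6, -4, 12) if S_grid is None else S_grid, dtype=float
    )
    I_levels = np.asarray(
        presets.KINETIC_I_LEVELS if I_levels is None else I_levels, dtype=float
    )
    rng = np.random.default_rng(noise.seed)
    pts = []
    for I in I_levels:
        v = predict_initial_rate(S_grid, np.full_like(S_grid, I), E_mono, params)
        if noise.sigma_rel_rate > 0:
            v = v * (1.0 + rng.normal(0.0, noise.sigma_rel_rate, size=v.shape))
            v = np.maximum(v, 0.0)
        sig = noise.sigma_rel_rate if noise.sigma_rel_rate > 0 else None
        pts.extend(
            RatePoint(float(s), float(I), float(r), sig) for s, r in zip(S_grid, v)
        )
    return KineticDataset(E_mono=float(E_mono), points=tuple(pts), label=label)


def gen_dilution_series(
    K_D: float,
    E_dimer_grid=None,
    noise: NoiseModel = NoiseModel(),
):
    """Efficiency vs protein concentration without inhibitor.

    Noise-free points satisfy the self-consistent dilution relation to
    machine precision.  With ``clip_phi`` disabled the raw (possibly
    out-of-range) efficiencies are returned as ``(E_array, phi_array)``.
    """
    E_grid = np.asarray(
        presets.FRET_E_DIMER_LEVELS if E_dimer_grid is None else E_dimer_grid, dtype=float
    )
    phi = np.array([self_consistent_phi(float(e), float(K_D)) for e in E_grid])
    rng = np.random.default_rng(noise.seed)
    if noise.sigma_phi > 0:
        phi = phi + rng.normal(0.0, noise.sigma_phi, size=phi.shape)
    if not noise.clip_phi:
        return E_grid, phi
    phi = np.clip(phi, 0.0, 1.0)
    return DilutionSeries(
        E_dimer=tuple(E_grid),
        phi=tuple(phi),
        sigma=noise.sigma_phi if noise.sigma_phi > 0 else None,
    )
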