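"""Named parameter presets for the C3-class interface destabilizers of hTS.

Two parameterizations of the same compound ship side by side and are
deliberately not reconciled:

``c3-fret``
    The dilution-curve view: free-dimer ``K_D`` = 80 nM and a 5-fold
    larger dissociation constant for the inhibitor-saturated dimer
    (``K_D'' = 400 nM``), encoded through ``K_I`` = 1 uM on the monomer
    and equal interface-site constants ``K_I1 = K_I2 = sqrt(5) uM``.

``c3-kinetics``
    The kinetic view: turnover ``k = k' = 0.9 s^-1`` for the free and
    singly inhibited dimer, a nearly dead doubly inhibited complex
    ``k'' = 0.1 s^-1``, substrate constants ``K1 = K2 = 10 uM``,
    ``K3 = 20 uM``, and inhibitor constants ``K_I = 1 uM``,
    ``K_I1 = K_I2 = 10 uM`` (a 10 x 10 progressive destabilization,
    ``K_D''/K_D = 100``).

``c3-kinetics-alt``
    As ``c3-kinetics`` but with the alternative first interface-site
    constant ``K_I1 = 17 uM`` that was also reported for this compound.
"""

from __future__ import annotations

import math

from .equilibrium import EquilibriumConstants
from .kinetics import KineticParameters

#: free-dimer dissociation constant of the enzyme (molar)
KD_FREE_DIMER = 80e-9

#: fold increase of the dimer dissociation constant at saturating inhibitor
#: seen in the dilution analysis
SATURATED_FOLD = 5.0

EQ_FRET = EquilibriumConstants(
    K_D=KD_FREE_DIMER,
    K_I=1e-6,
    K_I1=math.sqrt(SATURATED_FOLD) * 1e-6,
    K_I2=math.sqrt(SATURATED_FOLD) * 1e-6,
)

EQ_KINETICS = EquilibriumConstants(K_D=KD_FREE_DIMER, K_I=1e-6, K_I1=1e-5, K_I2=1e-5)

KIN_C3 = KineticParameters(
    k=0.9, k_prime=0.9, k_dblprime=0.1,
    K1=1e-5, K2=1e-5, K3=2e-5,
    eq=EQ_KINETICS,
)

KIN_C3_ALT = KineticParameters(
    k=0.9, k_prime=0.9, k_dblprime=0.1,
    K1=1e-5, K2=1e-5, K3=2e-5,
    eq=EquilibriumConstants(K_D=KD_FREE_DIMER, K_I=1e-6, K_I1=1.7e-5, K_I2=1e-5),
)

#: assay design constants
FRET_E_DIMER_LEVELS = (50e-9, 100e-9, 250e-9, 490e-9)  # dimer equivalents, molar
FRET_I_GRID = (0.0, 4.5e-6, 9.5e-6, 15e-6, 25e-6, 100e-6)  # molar
KINETIC_I_LEVELS = (0.0, 12e-6, 24e-6, 36e-6)  # molar
KINETIC_E_MONO = 600e-9  # 300 nM enzyme dimer in monomer equivalents
IC50_ASSAY_S_TOTAL = 55e-6  # folate cofactor in the inhibition assay

PRESETS = {
    "c3-fret": EQ_FRET,
    "c3-kinetics": KIN_C3,
    "c3-kinetics-alt": KIN_C3_ALT,
}


def get_preset(name: str):
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
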