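# dimerfit

Quantitative modeling of **dissociative inhibition** of obligate
homodimeric enzymes — the mechanism by which a small molecule binding at
a monomer–monomer interface shifts the dimerization equilibrium of an
enzyme like human thymidylate synthase (hTS) toward its catalytically
inactive monomers.

The package is aimed at biophysicists and medicinal chemists analyzing
dimer-destabilizer campaigns: it turns FRET dimerization titrations and
steady-state inhibition kinetics into binding constants, free energies
and IC50s, with a seeded synthetic-data generator so every stage of the
analysis can be validated by parameter-recovery simulation.

## The model

An obligate homodimer `M2 <-> 2M` (dissociation constant `K_D`) is
coupled to inhibitor binding on the free monomer (`K_I`) and on the two
symmetric interface sites of the dimer (macroscopic `K_I1`, `K_I2`).
Thermodynamic-cycle closure makes the dissociation constants of the
inhibitor-bound dimers derived quantities:

    K_D'  = K_D · K_I1 / K_I            (M2I  <-> M + MI)
    K_D'' = K_D · K_I1 · K_I2 / K_I²    (M2I2 <-> 2 MI)

A destabilizer has `K_I < K_I1, K_I2` (it prefers the monomer), hence
`K_D'' > K_D`: saturating inhibitor weakens the dimer.

**FRET observable.** With donor- and acceptor-labeled monomer pools,
transfer occurs only inside dimers, so the efficiency Φ is the dimeric
mole fraction, `Φ = 2([M2]+[M2I]+[M2I2]) / E_T` (protein in
monomer-equivalents). A dilution series without inhibitor obeys the
self-consistent relation `Φ = 1 − 0.5·√(Φ/E_T)·√K`, which is how `K_D`
(and, at saturating inhibitor, `K_D''`) is read off titration data.

**Kinetics.** Under the fast-equilibrium approximation with substrate S
binding the three dimeric species (`K1`–`K3`, turnover `k`, `k'`, `k''`)
the initial rate is

    v = k·[M2S] + k'·[M2IS] + k''·[M2I2S]
      = x_r² · [S] · ( k/K1 + k'·I/(K_I1·K2) + k''·I²/(K_I1·K_I2·K3) )

where `x_r = √[M2]` is the only physically acceptable root of the
quadratic protein balance, and free [S] and [I] are resolved exactly
(including substrate depletion). `k'' ≪ k` gives the noncompetitive
signature: a nonzero rate plateau well below the uninhibited rate.

All species networks are solved by a damped Newton iteration in
log-concentration space with bisection fallback — deterministic,
positivity-preserving, and exact in reductions (no inhibitor, no
substrate, infinite constants = no binding).

## Worked example

Thermodynamics of dimer disruption with the kinetic constant preset of
the interface destabilizer C3 (`K_D = 80 nM`, `K_I = 1 µM`,
`K_I' = K_I'' = 10 µM`):

```text
$ dimerfit thermo --preset c3-kinetics
K_D = 8e-08 M  delta_G = 40.5 kJ/mol
K_D' = 8e-07 M  K_D'' = 8e-06 M
K_D'/K_D = 10  K_D''/K_D' = 10
ddG(saturated) = -11.4 kJ/mol
```

40.5 kJ/mol is the standard free energy needed to disrupt the free
dimer at 298.15 K; the 10×10 cycle ratios say each successive inhibitor
binding destabilizes the dimer another order of magnitude.

Parameter recovery on synthetic FRET dose–response data (four protein
levels 50–490 nM dimer, inhibitor 0–100 µM, efficiency noise 0.03),
fitting the coupled model with `K_D` fixed and the two interface sites
tied:

```python
import dimerfit as dm
from dimerfit.presets import EQ_FRET  # K_D = 80 nM, K_D''/K_D = 5

data = dm.gen_fret_dose_response(EQ_FRET, noise=dm.NoiseModel(seed=42))
fit = dm.fit_fret_global(data, dm.FitSpec(
    free=("K_I", "K_I1"), fixed={"K_D": 80e-9}, ties={"K_I2": "K_I1"},
    multistart=8, seed=1, weighting="sigma"))
```

prints, for this seed:

```text
K_I  = 1.12e-06 M
K_I1 = 2.55e-06 M (= K_I2, tied)
K_D''/K_D = 5.16
```

i.e. the generating 5-fold destabilization of the saturated dimer and
the µM-scale monomer/interface constants are recovered from noisy data.
On the kinetics side, with the C3 preset at 300 nM enzyme dimer and
25 µM substrate:

```text
v(0) = 1.68e-07 M/s
limiting rate ratio = 0.0209
model IC50 = 8.62 uM
```

`v(0)` is the uninhibited initial rate; the limiting ratio is the
residual activity of the inhibitor-saturated enzyme (the computed value
for this parameter set — the doubly bound complex is almost dead); the
model-based IC50 is the inhibitor concentration halving the rate under
the standard assay conditions (55 µM cofactor).

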