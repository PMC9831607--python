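# Methods

## Scope and model

`dimerfit` models an obligate homodimeric enzyme whose activity is
inhibited *dissociatively*: a ligand I binds the monomer–monomer
interface, preferring the free monomer, and thereby pulls the
dimerization equilibrium toward inactive monomers. Nine species are
carried at most — M, MI, M2, M2I, M2I2 and, when the varied substrate S
is present, M2S, M2IS, M2I2S — linked by seven dissociation constants:

| constant | reaction | units | C3 presets |
|---|---|---|---|
| `K_D` | M2 ⇌ 2M | M | 8·10⁻⁸ |
| `K_I` | MI ⇌ M + I | M | 10⁻⁶ |
| `K_I1` | M2I ⇌ M2 + I (first interface site, macroscopic) | M | √5·10⁻⁶ (FRET) / 10⁻⁵ (kinetics) |
| `K_I2` | M2I2 ⇌ M2I + I (second site, macroscopic) | M | as `K_I1` |
| `K1, K2, K3` | substrate off M2S / M2IS / M2I2S | M | 10⁻⁵, 10⁻⁵, 2·10⁻⁵ |

plus turnover numbers `k = k' = 0.9 s⁻¹`, `k'' = 0.1 s⁻¹` for the three
substrate-bound dimers. Two closures are imposed rather than fit:

- **Thermodynamic cycles.** `K_D' = K_D·K_I1/K_I` and
  `K_D'' = K_D·K_I1·K_I2/K_I²` exactly, and the inhibitor affinity for
  substrate-bound dimers is `K_I1·K2/K1` and `K_I2·K3/K2`. Only six
  independent binding constants exist; every other edge of the network
  follows from detailed balance or the network would be inconsistent.
- **Obligate-dimer biology.** Monomers neither turn over nor bind
  substrate (each active site spans both subunits). The nucleotide
  substrate is saturating and absorbed into the constants; `K_I1`,
  `K_I2` are macroscopic (no statistical factor for the two symmetric
  sites), matching how such constants are reported.

Two preset parameterizations of the same compound class ship side by
side (`presets.py`) and are deliberately not reconciled: the
dilution-curve view (5-fold increase of the saturated-dimer `K_D`) and
the kinetic view (progressive 10×10 destabilization). They answer
different experiments; choosing between them is a scientific question
the data, not the software, must settle. An alternative first-site
constant of 1.7·10⁻⁵ M reported for the same compound is kept as
`c3-kinetics-alt`.

## Numerics

All totals are carried in molar monomer-equivalents;
`Totals.from_dimer` is the single sanctioned ×2 conversion (assays
commonly state protein in dimer units, and silent factor-of-2 errors
are the classic failure mode here).

At fixed free (I, S) the protein balance is a quadratic in √[M2]
(equivalently the free monomer), solved in cancellation-free form; the
remaining one or two unknowns are found by a damped Newton iteration on
ln-concentration (step cap 3 ln-units, step-halving on residual
increase, iteration cap 200, convergence at relative residual ≤ 10⁻¹²)
with a nested-bisection fallback on the free-inhibitor variable.
Log-space iteration guarantees positivity; the quadratic elimination
makes the protein balance exact to rounding at every step. Infinite
constants are carried as zero reciprocal affinities, so "no binding" is
an exact reduction, not a limit. Residual mass-balance violations are
reported on every solved state and stay below 10⁻⁹ relative over
10⁴ random draws spanning 10⁻¹⁰–10⁻² M (tested).

Temperature enters only through ΔG° = −RT·ln(K/1 M), default
298.15 K. The fluorescence experiments the model mirrors were read near
room temperature (20 ± 3 °C), but 298.15 K is the convention that makes
`K = 80 nM` correspond to 40.5 kJ/mol, and is therefore the package
default; pass `T` explicitly for anything else.

The FRET efficiency is taken *equal* to the dimeric mole fraction
(proportionality 1): labeling statistics (donor-only or acceptor-only
dimers) and photophysics are out of scope. Plate-reader ratios are
mapped to efficiencies by a declared two-anchor linear normalization —
the no-FRET control defines Φ = 0 and the untreated-protein control is
assigned the model Φ of protein alone at the assay concentration. The
underlying instrument combination of band intensities is not uniquely
determined by the assay description, so this map is a convention of the
package, stated rather than inferred.

One further documented tension: at 300 nM protein the closed form with
`K_D = 80 nM` gives a 69–77% dimeric fraction (unit convention
depending), not the >95% sometimes quoted for that assay
concentration. The implementation follows `K_D = 80 nM` everywhere.

## Fitting

Concentration-like parameters are fit in log₁₀ space (default bounds
[−9, −2] M), rate constants in log₁₀ [−3, 2] s⁻¹ — positivity by
construction and uniform scaling across decades. Each fit is a
multistart (default 32 log-uniform draws; the first start at the bound
center) of `scipy.optimize.least_squares` (TRF, tolerances 10⁻¹⁴), and
the whole procedure is a pure function of (data, spec, seed). Weighting
options: none, per-point σ, or relative (for multiplicative rate
noise).

Identifiability is diagnosed from the singular values of the Jacobian
at the optimum: directions below 10⁻⁶ of the leading singular value are
flagged as near-flat warnings, never errors. This matters here: in a
FRET dose–response with both interface sites free, only the combination
`K_I1·K_I2/K_I²` (= `K_D''/K_D`) is well identified. The recommended
analysis ties the symmetric sites (`FitSpec(ties={"K_I2": "K_I1"})`),
after which monomer and interface constants are individually
recoverable (medians within ~20–35% at efficiency noise 0.03 over the
four-level design — measured by the recovery simulations in the test
suite, and the basis for the tolerance used there).

Uncertainty is by residual-resampling bootstrap (percentile intervals,
default 500 resamples), refit from the point estimate with a single
start — appropriate for small bounded curve fits where asymptotic
covariance is unreliable. Coverage of the 95% interval is verified by
simulation (≥90% over 50 replicates) in the tests.

IC50s come from a four-parameter logistic fit (lmfit) of rate vs
log-inhibitor, requiring ≥5 positive inhibitor levels and a decreasing
response; a model-based IC50 (bisection on the predicted rate for the
half-rate concentration at 300 nM enzyme dimer and 55 µM cofactor) is
provided for comparison. The limiting-rate ratio at "saturating"
inhibitor uses 10⁴× the largest finite inhibitor constant as the proxy
for I → ∞ and is reported, not asserted against any target: for the
kinetic preset it evaluates to ≈ 0.02 at 25 µM total substrate, while
visual readings of such data have put the plateau nearer 1/5 — the
parameter set and the eyeballed plateau are not the same claim.

## Synthetic data

The generator reproduces the study designs: FRET dose–response at
50/100/250/490 nM protein (dimer equivalents) over inhibitor
0/4.5/9.5/15/25/100 µM; initial-rate curves on a 12-point log grid of
1–100 µM substrate at 0/12/24/36 µM inhibitor with 600 nM
monomer-equivalent enzyme; dilution series at the four FRET protein
levels. Noise is additive Gaussian on efficiency (default σ = 0.03)
and multiplicative Gaussian on rates (default 3% relative) — the
simplest error model adequate for recovery testing, since no empirical
noise magnitudes are available; both defaults are configurable.
Efficiencies are clipped to [0, 1] after noise (a flag disables
clipping for distribution-purity checks, in which case raw arrays are
returned rather than validated datasets). All generation is a pure
function of (parameters, design, seed) on numpy's PCG64 generator.

What passing recovery tests on these data do **not** show: robustness
to correlated or heteroscedastic instrument noise, labeling-statistics
bias in Φ, slow binding kinetics (the model is equilibrium-only; the
measured efficiency can drift for minutes after inhibitor addition),
compound solubility limits at the top of the dose range, or absorbance-
trace artifacts in rate estimation. The generator emulates the model,
so recovery tests validate the estimator, not the mechanism.

## Problem sizes

Defaults were chosen so the full analysis runs interactively on one
CPU: 20-replicate FRET recovery ensembles with 8 multistarts (~10 s),
10-replicate kinetic ensembles (~4 s), 50-replicate bootstrap coverage
with 100 resamples (~2 min), and 200-draw oracle cross-checks of the
rate law. Larger ensembles change none of the conclusions, only the
decimal places of the medians.

## Known limitations

- No Bayesian posteriors or model selection beyond fixed/free/tied
  parameter specifications.
- No treatment of conformational (active/inactive) substates or of the
  monomer-binding nucleotide explicitly; those are folded into the
  constants.
- The closed algebraic dose–response expression used historically for
  such fits is realized numerically through the species solver rather
  than as a formula; any closed form must agree with the solver, which
  is the ground truth here (cross-checked against independent oracles
  in the tests).
- The CLI writes tables, reports and logs but no plot files.
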