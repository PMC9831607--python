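"""Global nonlinear least-squares estimation for FRET and kinetic curves.

All concentration-like parameters are fit in log10 space (default bounds
[-9, -2] in molar), rate constants in log10 [-3, 2] (s^-1): positivity
by construction, and constants spanning decades become well scaled.
Because the coupled model has plateaued regions, every fit is a
multistart over log-uniform draws within the bounds; the best start is
returned and the whole procedure is a pure function of (data, spec,
seed).  Uncertainty is quantified by residual-resampling bootstrap
rather than asymptotic covariance, which is unreliable for small bounded
curve fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .equilibrium import EquilibriumConstants
from .fret import FretDataset, predict_phi, self_consistent_phi
from .kinetics import KineticDataset, KineticParameters, predict_initial_rate

FRET_PARAMS = ("K_D", "K_I", "K_I1", "K_I2")
KINETIC_PARAMS = ("k", "k_prime", "k_dblprime", "K1", "K2", "K3") + FRET_PARAMS
_RATE_NAMES = {"k", "k_prime", "k_dblprime"}

DEFAULT_CONC_BOUNDS = (-9.0, -2.0)
DEFAULT_RATE_BOUNDS = (-3.0, 2.0)

#: singular-value ratio below which a fit direction is flagged near-flat
_FLAT_SV_RATIO = 1e-6


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free`` and ``fixed`` must together cover the model's parameter
    list exactly once.  Bounds are per-parameter ``(lo, hi)`` in log10.
    """

    free: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    bounds_log10: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: dependent -> source parameter equalities (e.g. tie the two symmetric
    #: interface sites with {"K_I2": "K_I1"})
    ties: dict[str, str] = field(default_factory=dict)
    multistart: int = 32
    seed: int = 0
    loss: str = "linear"  # linear | soft_l1
    weighting: str = "none"  # none | sigma | relative

    def __post_init__(self):
        object.__setattr__(self, "free", tuple(self.free))
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        if self.loss not in ("linear", "soft_l1"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.weighting not in ("none", "sigma", "relative"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    def resolve(self, theta) -> dict[str, float]:
        """Full parameter dict from a log10 vector of the free parameters."""
        p = dict(self.fixed)
        p.update({n: 10.0 ** t for n, t in zip(self.free, theta)})
        for dep, src in self.ties.items():
            p[dep] = p[src]
        return p

    def validate_against(self, full: tuple[str, ...]):
        groups = [set(self.free), set(self.fixed), set(self.ties)]
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                if a & b:
                    raise ValueError(f"parameters declared twice: {sorted(a & b)}")
        for dep, src in self.ties.items():
            if src not in set(self.free) | set(self.fixed):
                raise ValueError(f"tie target {src!r} is neither free nor fixed")
        names = set(self.free) | set(self.fixed) | set(self.ties)
        if names != set(full):
            missing = set(full) - names
            extra = names - set(full)
            raise ValueError(
                f"free+fixed must cover {full} exactly; missing {sorted(missing)}, "
                f"unknown {sorted(extra)}"
            )
        for lo, hi in self.bounds_log10.values():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lo < hi")

    def bounds_for(self, name: str) -> tuple[float, float]:
        if name in self.bounds_log10:
            return self.bounds_log10[name]
        return DEFAULT_RATE_BOUNDS if name in _RATE_NAMES else DEFAULT_CONC_BOUNDS


@dataclass(frozen=True)
class FitResult:
    """Point estimates with diagnostics; intervals filled in by bootstrap_ci."""

    params: dict[str, float]  # full parameter set, fixed values included
    free: tuple[str, ...]
    objective: float  # sum of squared (weighted) residuals
    success: bool
    warnings: tuple[str, ...] = ()
    ci: dict[str, tuple[float, float]] | None = None
    # context for bootstrapping (not part of equality)
    _residual_fn: object = field(default=None, compare=False, repr=False)
    _spec: FitSpec | None = field(default=None, compare=False, repr=False)
    _n_points: int = field(default=0, compare=False, repr=False)

    def estimate(self, name: str) -> float:
        return self.params[name]


def _run_multistart(residual_fn, spec: FitSpec, full: tuple[str, ...]) -> FitResult:
    spec.validate_against(full)
    lo = np.array([spec.bounds_for(n)[0] for n in spec.free])
    hi = np.array([spec.bounds_for(n)[1] for n in spec.free])
    rng = np.random.default_rng(spec.seed)
    starts = [0.5 * (lo + hi)] if spec.free else [np.array([])]
    starts += [rng.uniform(lo, hi) for _ in range(spec.multistart - 1)]

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residual_fn, x0, bounds=(lo, hi), loss=spec.loss,
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400 * (len(x0) + 1),
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ConvergenceError("all multistart fits failed")

    warn: list[str] = []
    if spec.free:
        jac = np.atleast_2d(best.jac)
        sv = np.linalg.svd(jac, compute_uv=False)
        vt = np.linalg.svd(jac)[2]
        top = sv.max() if sv.size else 0.0
        if top == 0.0:
            warn.append("objective is flat in all free parameters: "
                        + ", ".join(spec.free))
        else:
            for i, s in enumerate(sv):
                if s < _FLAT_SV_RATIO * top:
                    j = int(np.argmax(np.abs(vt[i])))
                    warn.append(f"near-flat direction dominated by {spec.free[j]}; "
                                f"parameter poorly identified")
    params = spec.resolve(best.x)
    return FitResult(
        params=params,
        free=spec.free,
        objective=float(2.0 * best.cost),
        success=True,
        warnings=tuple(warn),
        _residual_fn=residual_fn,
        _spec=spec,
        _n_points=len(np.atleast_1d(best.fun)),
    )


# ---------------------------------------------------------------------------
# model-specific residual builders


def constants_from_params(p: dict[str, float]) -> EquilibriumConstants:
    return EquilibriumConstants(K_D=p["K_D"], K_I=p["K_I"], K_I1=p["K_I1"], K_I2=p["K_I2"])


def kinetic_params_from_dict(p: dict[str, float]) -> KineticParameters:
    return KineticParameters(
        k=p["k"], k_prime=p["k_prime"], k_dblprime=p["k_dblprime"],
        K1=p["K1"], K2=p["K2"], K3=p["K3"], eq=constants_from_params(p),
    )


def _fret_residual_builder(datasets: list[FretDataset], spec: FitSpec):
    # flatten all curves into one batched solve per evaluation
    E = np.concatenate([np.full(len(ds.points), ds.E_mono) for ds in datasets])
    I = np.concatenate([ds.I_grid for ds in datasets])
    obs = np.concatenate([ds.phi for ds in datasets])
    if spec.weighting == "sigma":
        sig = [ds.sigma for ds in datasets]
        if any(s is None for s in sig):
            raise ValueError("sigma weighting requested but sigmas are missing")
        weights = np.concatenate(sig)
    elif spec.weighting == "relative":
        weights = np.maximum(obs, 1e-12)
    else:
        weights = None

    def residuals(theta, y_obs=None):
        c = constants_from_params(spec.resolve(theta))
        phi = predict_phi(E, I, c)
        r = phi - (obs if y_obs is None else y_obs)
        return r / weights if weights is not None else r

    return residuals, obs


def fit_fret_global(datasets: list[FretDataset], spec: FitSpec) -> FitResult:
    """Fit the coupled-equilibrium model jointly to several FRET curves.

    Parameters (``K_D``, ``K_I``, ``K_I1``, ``K_I2``) are shared across
    the protein-concentration series, which is what makes a dissociative
    mechanism distinguishable from plain site-binding.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    for ds in datasets:
        ds.require_fittable()
    residuals, _ = _fret_residual_builder(list(datasets), spec)
    return _run_multistart(residuals, spec, FRET_PARAMS)


def fit_kinetics(dataset: KineticDataset, spec: FitSpec) -> FitResult:
    """Fit the dissociative rate law to an initial-rate dataset."""
    dataset.require_fittable()
    S, I, v = dataset.S_total, dataset.I_total, dataset.v
    sig = np.array([p.sigma_rel for p in dataset.points], dtype=object)
    have_sigma = not any(s is None for s in sig)
    sigma_abs = (sig.astype(float) * v) if have_sigma else None

    def residuals(theta, y_obs=None):
        kp = kinetic_params_from_dict(spec.resolve(theta))
        model = predict_initial_rate(S, I, dataset.E_mono, kp)
        y = v if y_obs is None else y_obs
        r = model - y
        if spec.weighting == "sigma":
            if sigma_abs is None:
                raise ValueError("sigma weighting requested but sigmas are missing")
            r = r / sigma_abs
        elif spec.weighting == "relative":
            r = r / np.maximum(np.abs(y), 1e-300)
        return r

    return _run_multistart(residuals, spec, KINETIC_PARAMS)


def bootstrap_ci(fit: FitResult, resamples: int = 500, seed: int = 0,
                 level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Residual-resampling percentile intervals for the free parameters.

    Refits are started from the point estimate (single start), which is
    the standard fast bootstrap for smooth least-squares problems.
    """
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    if fit._residual_fn is None or fit._spec is None:
        raise ValueError("fit carries no bootstrap context")
    spec = fit._spec
    if fit._n_points <= len(fit.free):
        raise ValueError("fewer residual points than free parameters")

    theta_hat = np.array([np.log10(fit.params[n]) for n in fit.free])
    r_hat = np.asarray(fit._residual_fn(theta_hat))
    # y_hat in the weighting-free data space is only needed implicitly:
    # resampled data are y* = y + (r* - r_hat) expressed through residuals.
    lo_b = np.array([spec.bounds_for(n)[0] for n in fit.free])
    hi_b = np.array([spec.bounds_for(n)[1] for n in fit.free])
    rng = np.random.default_rng(seed)
    draws = np.empty((resamples, len(fit.free)))
    n = r_hat.size
    for b in range(resamples):
        idx = rng.integers(0, n, size=n)
        shift = r_hat[idx] - r_hat

        def boot_res(theta, shift=shift):
            return np.asarray(fit._residual_fn(theta)) - shift

        res = least_squares(boot_res, theta_hat, bounds=(lo_b, hi_b),
                            loss=spec.loss, method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        draws[b] = res.x
    alpha = 0.5 * (1.0 - level)
    lo_q = 10.0 ** np.quantile(draws, alpha, axis=0)
    hi_q = 10.0 ** np.quantile(draws, 1.0 - alpha, axis=0)
    ci = {}
    for j, name in enumerate(fit.free):
        est = fit.params[name]
        ci[name] = (min(lo_q[j], est), max(hi_q[j], est))
    return ci


def estimate_kd_from_dilution(E_dimer, phi) -> float:
    """Dimer dissociation constant from a dilution series.

    Least-squares fit of the self-consistent efficiency relation
    ``phi = 1 - 0.5 sqrt(phi/E_T) sqrt(K)`` over (E_T, phi) pairs; this
    is the analysis applied to the titration without inhibitor (K = K_D)
    and at saturating inhibitor (K = K_D'').
    """
    E = np.asarray(E_dimer, dtype=float)
    y = np.asarray(phi, dtype=float)
    if E.shape != y.shape or E.size < 2:
        raise ValueError("need matching E and phi arrays with >= 2 points")

    def res(logk):
        return np.array([self_consistent_phi(e, 10.0 ** logk[0]) for e in E]) - y

    out = least_squares(res, x0=[np.log10(np.median(E))], bounds=([-12.0], [0.0]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return float(10.0 ** out.x[0])
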