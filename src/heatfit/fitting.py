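"""Global least-squares fitting of one or more titrations to a scheme.

Thermodynamic parameters (equilibrium constants, enthalpies) are shared
across all datasets; each dataset additionally carries local nuisance
parameters — a multiplicative activity factor on its stated concentrations
and an additive per-injection heat of dilution.  Equilibrium constants are
optimized in log10 space (guaranteeing positivity), enthalpies in kcal/mol,
and the objective is the unweighted sum of squared ucal residuals unless
per-dataset weights are supplied.

Because biphasic multi-equilibrium surfaces can be multimodal, the fit uses
a seeded multistart strategy around the initial guesses and keeps the
lowest-chi2 solution; results are deterministic for a given seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitFailureError,
    InvalidComparisonError,
    InvalidParameterError,
    SolverFailureError,
)
from .model import Isotherm, TitrationExperiment, injection_heats
from .thermo import (
    ACTIVE_CONSTANTS,
    CONSTANT_UNITS,
    KCAL,
    SchemeId,
    ThermoScheme,
    dh_name_for,
)

logger = logging.getLogger(__name__)

_PENALTY = 1.0e6  # ucal residual used when the equilibrium solver fails

LOG10_K_BOUNDS = (0.0, 16.0)
DH_KCAL_BOUNDS = (-100.0, 100.0)
ACTIVITY_BOUNDS = (0.5, 1.1)
DILUTION_BOUNDS = (-1.0e6, 1.0e6)


def _is_k(name: str) -> bool:
    return name.startswith("K")


@dataclass
class FitSpec:
    """Specification of a global fit.

    Parameters
    ----------
    datasets : (experiment, observed isotherm) pairs.
    scheme_id : reaction scheme to fit.
    free_parameters : names of globally fitted parameters (K's in natural
        units, dH's in cal/mol, matching ThermoScheme fields).
    fixed_parameters : values for the remaining active parameters.
    tied_parameters : optional constraints computed from the other
        parameters after each update, e.g. the no-cooperativity alternative
        where the dimer-Kap constants are dictated by the monomer 1:1
        constant (K1 = 2*K3, K2 = K3**2).
    fit_activity / fit_dilution : enable the per-dataset nuisance
        parameters (activity in [0.5, 1.1] starting at 0.9; dilution heat
        in ucal per injection, unbounded, starting at 0).
    initial : optional starting guesses for free parameters; sensible
        defaults are derived from the designs and the observed heats.
    weights : optional per-dataset residual weights (default 1).
    """

    datasets: list[tuple[TitrationExperiment, Isotherm]]
    scheme_id: SchemeId
    free_parameters: tuple[str, ...]
    fixed_parameters: dict[str, float] = field(default_factory=dict)
    tied_parameters: dict[str, Callable[[dict[str, float]], float]] = field(
        default_factory=dict
    )
    fit_activity: bool = False
    fit_dilution: bool = False
    initial: dict[str, float] = field(default_factory=dict)
    weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not self.datasets:
            raise InvalidParameterError("at least one dataset is required")
        if not self.free_parameters:
            raise InvalidParameterError("at least one free parameter is required")
        self.free_parameters = tuple(self.free_parameters)
        free = set(self.free_parameters)
        fixed = set(self.fixed_parameters)
        tied = set(self.tied_parameters)
        if free & fixed or free & tied or fixed & tied:
            raise InvalidParameterError(
                "free, fixed and tied parameter sets must be disjoint"
            )
        ks = ACTIVE_CONSTANTS[self.scheme_id]
        active = set(ks) | {dh_name_for(k) for k in ks}
        missing = active - free - fixed - tied
        extra = (free | fixed | tied) - active
        if missing:
            raise InvalidParameterError(
                f"scheme-active parameters not assigned: {sorted(missing)}"
            )
        if extra:
            raise InvalidParameterError(
                f"parameters not active in {self.scheme_id.value}: {sorted(extra)}"
            )
        if self.weights is not None and len(self.weights) != len(self.datasets):
            raise InvalidParameterError("one weight per dataset is required")

    # -- parameter vector layout ------------------------------------------
    @property
    def n_local(self) -> int:
        return int(self.fit_activity) + int(self.fit_dilution)

    @property
    def n_free(self) -> int:
        return len(self.free_parameters) + self.n_local * len(self.datasets)

    def default_initial(self) -> dict[str, float]:
        """Heuristic starting values for the free thermodynamic parameters.

        K guesses put the Wiseman parameter c = K * [hub] near 10 for the
        typical cell concentration of the designs (squared for M^-2
        constants); enthalpy guesses take the first-injection normalized
        heat of the first dataset, clipped to a plausible range.
        """
        cells = [max(exp.cell) for exp, _ in self.datasets if max(exp.cell) > 0]
        c_hub = float(np.mean(cells)) if cells else 15e-6
        k_guess = 10.0 / c_hub
        obs = self.datasets[0][1]
        dh_guess = float(obs.normalized_q[0]) * KCAL  # cal/mol
        mag = min(max(abs(dh_guess), 500.0), 20_000.0)
        dh_guess = math.copysign(mag, dh_guess if dh_guess != 0 else -1.0)
        out: dict[str, float] = {}
        for name in self.free_parameters:
            if _is_k(name):
                out[name] = k_guess**2 if CONSTANT_UNITS[name] == "M^-2" else k_guess
            else:
                out[name] = dh_guess
        out.update(self.initial)
        return out

    def pack(self, params: dict[str, float], locals_: list[dict[str, float]]) -> np.ndarray:
        x = []
        for name in self.free_parameters:
            v = params[name]
            x.append(math.log10(v) if _is_k(name) else v / KCAL)
        for loc in locals_:
            if self.fit_activity:
                x.append(loc["activity"])
            if self.fit_dilution:
                x.append(loc["dilution_ucal"])
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray) -> tuple[dict[str, float], list[dict[str, float]]]:
        params = dict(self.fixed_parameters)
        for i, name in enumerate(self.free_parameters):
            params[name] = 10.0 ** x[i] if _is_k(name) else x[i] * KCAL
        for name, func in self.tied_parameters.items():
            params[name] = func(params)
        locals_ = []
        j = len(self.free_parameters)
        for _ in self.datasets:
            loc = {"activity": 1.0, "dilution_ucal": 0.0}
            if self.fit_activity:
                loc["activity"] = x[j]
                j += 1
            if self.fit_dilution:
                loc["dilution_ucal"] = x[j]
                j += 1
            locals_.append(loc)
        return params, locals_

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.free_parameters:
            b = LOG10_K_BOUNDS if _is_k(name) else DH_KCAL_BOUNDS
            lo.append(b[0])
            hi.append(b[1])
        for _ in self.datasets:
            if self.fit_activity:
                lo.append(ACTIVITY_BOUNDS[0])
                hi.append(ACTIVITY_BOUNDS[1])
            if self.fit_dilution:
                lo.append(DILUTION_BOUNDS[0])
                hi.append(DILUTION_BOUNDS[1])
        return np.asarray(lo), np.asarray(hi)

    def build_scheme(self, params: dict[str, float], T: float | None = None) -> ThermoScheme:
        kwargs = dict(params)
        if T is not None:
            kwargs["T"] = T
        return ThermoScheme(scheme_id=self.scheme_id, **kwargs)


def residuals(spec: FitSpec, x: np.ndarray) -> np.ndarray:
    """Stacked (simulated - observed) heats in ucal across all datasets."""
    params, locals_ = spec.unpack(np.asarray(x, dtype=float))
    out = []
    for k, (exp, obs) in enumerate(spec.datasets):
        w = 1.0 if spec.weights is None else float(spec.weights[k])
        loc = locals_[k]
        try:
            scheme = spec.build_scheme(params, T=exp.T)
            sim = injection_heats(exp.scaled(loc["activity"]), scheme)
            r = sim.q + loc["dilution_ucal"] - obs.q
        except (SolverFailureError, InvalidParameterError) as exc:
            logger.warning("dataset %d: solver failure during fit (%s)", k, exc)
            r = np.full(len(obs), _PENALTY)
        out.append(math.sqrt(w) * r)
    return np.concatenate(out)


@dataclass
class FitResult:
    """Outcome of a global fit.

    ``estimates`` holds the fitted free parameters in natural units (K in
    M^-1 / M^-2, dH in cal/mol); ``sd`` their standard deviations on the
    same scale, from the residual-variance-scaled covariance at the
    optimum.  ``chi2`` is the sum of squared ucal residuals.
    """

    estimates: dict[str, float]
    local_estimates: list[dict[str, float]]
    sd: dict[str, float]
    chi2: float
    residuals_by_dataset: list[np.ndarray]
    all_parameters: dict[str, float]
    spec: FitSpec
    x_opt: np.ndarray
    jac: np.ndarray
    n_obs: int
    unidentifiable: list[str] = field(default_factory=list)
    start_diagnostics: list[dict] = field(default_factory=list)

    @property
    def dof(self) -> int:
        return max(self.n_obs - len(self.x_opt), 1)

    def dataset_signature(self) -> tuple:
        return tuple(
            (len(obs), float(np.sum(obs.q))) for _, obs in self.spec.datasets
        )


def fit_global(
    spec: FitSpec,
    seed: int = 0,
    n_starts: int = 8,
    perturb_decades: float = 2.0,
    early_stop_chi2: float = 1.0e-10,
) -> FitResult:
    """Multistart trust-region least squares over all datasets.

    The first start uses the (heuristic or user-supplied) initial guesses;
    subsequent starts perturb K's uniformly within ``perturb_decades``
    decades and enthalpies within +/-10 kcal/mol, using a generator seeded
    by ``seed``.  The lowest-chi2 converged start wins; a start that
    reaches ``early_stop_chi2`` (an essentially exact fit) short-circuits
    the remaining starts.
    """
    rng = np.random.default_rng(seed)
    init_params = spec.default_initial()
    locals0 = [
        {"activity": 0.9, "dilution_ucal": 0.0} for _ in spec.datasets
    ]
    x0 = spec.pack({**spec.fixed_parameters, **init_params}, locals0)
    lo, hi = spec.bounds()
    x0 = np.clip(x0, lo, hi)
    n_glob = len(spec.free_parameters)

    best = None
    diagnostics: list[dict] = []
    for s in range(max(1, n_starts)):
        xs = x0.copy()
        if s > 0:
            for i, name in enumerate(spec.free_parameters):
                if _is_k(name):
                    xs[i] += rng.uniform(-perturb_decades, perturb_decades)
                else:
                    xs[i] += rng.uniform(-10.0, 10.0)
            xs = np.clip(xs, lo, hi)
        try:
            res = least_squares(
                lambda x: residuals(spec, x),
                xs,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                ftol=1e-12,
                xtol=1e-12,
            )
            chi2 = float(2.0 * res.cost)
            diagnostics.append(
                {"start": s, "chi2": chi2, "status": res.status, "nfev": res.nfev}
            )
            if best is None or chi2 < best[0]:
                best = (chi2, res)
            if chi2 < early_stop_chi2:
                break
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            diagnostics.append({"start": s, "error": str(exc)})
    if best is None:
        raise FitFailureError(f"all starts failed: {diagnostics}")

    chi2, res = best
    params, locals_ = spec.unpack(res.x)
    estimates = {name: params[name] for name in spec.free_parameters}
    r = residuals(spec, res.x)
    per_ds = []
    i = 0
    for _, obs in spec.datasets:
        per_ds.append(r[i : i + len(obs)])
        i += len(obs)
    result = FitResult(
        estimates=estimates,
        local_estimates=locals_,
        sd={},
        chi2=chi2,
        residuals_by_dataset=per_ds,
        all_parameters=params,
        spec=spec,
        x_opt=res.x,
        jac=res.jac,
        n_obs=len(r),
        start_diagnostics=diagnostics,
    )
    sd, unident = estimate_uncertainties(result, spec)
    result.sd = sd
    result.unidentifiable = unident
    return result


def estimate_uncertainties(
    result: FitResult, spec: FitSpec
) -> tuple[dict[str, float], list[str]]:
    """Parameter SDs from the variance-covariance matrix at the optimum.

    cov = s^2 (J^T J)^-1 with s^2 = chi2/(N - p); SDs are propagated to the
    natural parameter scale (for a constant fitted as log10 K the natural
    SD is K * ln(10) * sd(log10 K)).  Directions with near-zero curvature
    are reported as unidentifiable by parameter name.
    """
    J = result.jac
    n, p = J.shape
    s2 = result.chi2 / max(n - p, 1)
    u, sv, vt = np.linalg.svd(J, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    names = list(spec.free_parameters)
    for k in range(len(spec.datasets)):
        if spec.fit_activity:
            names.append(f"activity[{k}]")
        if spec.fit_dilution:
            names.append(f"dilution_ucal[{k}]")
    unidentifiable = []
    if sv.size and sv[-1] <= tol:
        for j in np.where(sv <= tol)[0]:
            weights = np.abs(vt[j])
            unidentifiable.append(names[int(np.argmax(weights))])
    sv_inv = np.array([1.0 / s if s > tol else 0.0 for s in sv])
    cov = (vt.T * sv_inv**2) @ vt * s2
    sd_internal = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    sd: dict[str, float] = {}
    params, _ = spec.unpack(result.x_opt)
    for i, name in enumerate(spec.free_parameters):
        if _is_k(name):
            sd[name] = params[name] * math.log(10.0) * sd_internal[i]
        else:
            sd[name] = sd_internal[i] * KCAL
    j = len(spec.free_parameters)
    for k in range(len(spec.datasets)):
        if spec.fit_activity:
            sd[f"activity[{k}]"] = sd_internal[j]
            j += 1
        if spec.fit_dilution:
            sd[f"dilution_ucal[{k}]"] = sd_internal[j]
            j += 1
    return sd, sorted(set(unidentifiable))


@dataclass(frozen=True)
class ModelComparison:
    """chi2 ratio between two fits of the same data, with a per-dataset
    breakdown locating where the misfit of the worse model concentrates."""

    chi2_ratio: float
    chi2_a: float
    chi2_b: float
    per_dataset: list[dict]

    def report(self) -> str:
        lines = [
            f"chi2(model B) / chi2(model A) = {self.chi2_ratio:.3g}"
            f"  (A: {self.chi2_a:.4g}, B: {self.chi2_b:.4g} ucal^2)"
        ]
        for d in self.per_dataset:
            lines.append(
                f"  dataset {d['dataset']}: ss_a={d['ss_a']:.4g}, "
                f"ss_b={d['ss_b']:.4g}, worst injection of B: "
                f"#{d['worst_injection_b']} (|r|={d['worst_residual_b']:.3g} ucal)"
            )
        return "\n".join(lines)


def compare_models(fit_a: FitResult, fit_b: FitResult) -> ModelComparison:
    """Goodness-of-fit ratio of two fits on identical datasets (B vs A)."""
    if fit_a.dataset_signature() != fit_b.dataset_signature():
        raise InvalidComparisonError("fits were not performed on identical datasets")
    if fit_a.chi2 <= 0 and fit_b.chi2 <= 0:
        ratio = 1.0
    else:
        ratio = fit_b.chi2 / fit_a.chi2 if fit_a.chi2 > 0 else math.inf
    per = []
    for k, (ra, rb) in enumerate(
        zip(fit_a.residuals_by_dataset, fit_b.residuals_by_dataset)
    ):
        worst = int(np.argmax(np.abs(rb)))
        per.append(
            {
                "dataset": k,
                "ss_a": float(np.sum(ra**2)),
                "ss_b": float(np.sum(rb**2)),
                "worst_injection_b": worst + 1,
                "worst_residual_b": float(np.abs(rb[worst])),
            }
        )
    return ModelComparison(
        chi2_ratio=ratio, chi2_a=fit_a.chi2, chi2_b=fit_b.chi2, per_dataset=per
    )
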