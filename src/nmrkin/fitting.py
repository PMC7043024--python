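"""Global least-squares estimation of micro-kinetic parameters.

Several progression curves (different initial substrate concentrations, same
rate constants) are fit jointly.  Free parameters are the selected micro-rates
plus, by default, one initial substrate concentration per curve; the
second-order association rate k1 is fixed unless explicitly freed.  All free
parameters are positive and are optimized in log-space.  The residual vector
is block-sparse: a per-curve S0 only touches its own curve's residuals, and
the numerical Jacobian exploits that.

chi^2 = sum over curves i and time points k of
        ([S]_calc(t_k; S0_i, {k_j}) - [S]_exp(t_k))^2 / sigma^2
with sigma = 1 uM by default.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .integrate import ProgressionCurve, progression_curve
from .model import RateParameters, build_single_substrate_scheme

__all__ = [
    "FitProblem",
    "FitResult",
    "SingleSubstrateModel",
    "CoupledModel",
    "UnidentifiableParameterError",
    "chi_square",
    "fit_lm",
    "grid_search_init",
    "covariance_stderr",
    "bootstrap_stderr",
]

DEFAULT_BOUNDS = (1e-7, 1e4)


class UnidentifiableParameterError(RuntimeError):
    pass


class SingleSubstrateModel:
    """Alternate-state single-substrate scheme as a fit model.

    ``base`` supplies every rate not being fitted (k1 in particular).
    """

    def __init__(self, base: RateParameters, method: str = "lsoda",
                 rel_tol: float = 1e-7, abs_tol: float = 1e-9):
        self.base = base
        self.method = method
        self.rel_tol = rel_tol
        self.abs_tol = abs_tol

    def params_from(self, values: dict[str, float]) -> RateParameters:
        rate_fields = {k: v for k, v in values.items()
                       if k in RateParameters.__dataclass_fields__}
        return self.base.replace(**rate_fields)

    def simulate(self, values: dict[str, float], s0: float,
                 curve: ProgressionCurve) -> dict[str, np.ndarray]:
        params = self.params_from(values)
        scheme = build_single_substrate_scheme(params)
        sim = progression_curve(
            scheme, s0, curve.E0, curve.times, deadtime=curve.deadtime,
            substrate="S", observed=tuple(curve.data),
            method=self.method, rel_tol=self.rel_tol, abs_tol=self.abs_tol,
        )
        return sim.data


class CoupledModel:
    """Dual-substrate scheme as a fit model.

    Free parameters are namespaced, e.g. ``me.kcat_E`` or ``ac_dual.k_off``;
    the namespaces are ``me``, ``ac`` and (unless kinetics are shared)
    ``me_dual``, ``ac_dual``.  Each curve's ``substrate`` attribute selects
    the initially present peptide species.
    """

    NAMESPACES = ("me", "ac", "me_dual", "ac_dual")

    def __init__(self, base, method: str = "lsoda",
                 rel_tol: float = 1e-7, abs_tol: float = 1e-9):
        self.base = base  # synth.CoupledTruth
        self.method = method
        self.rel_tol = rel_tol
        self.abs_tol = abs_tol

    def truth_from(self, values: dict[str, float]):
        by_ns: dict[str, dict[str, float]] = {}
        for name, v in values.items():
            if "." not in name:
                continue
            ns, _, f = name.partition(".")
            if ns not in self.NAMESPACES:
                raise KeyError(f"unknown parameter namespace in {name!r}")
            by_ns.setdefault(ns, {})[f] = v
        b = self.base
        kw = {}
        mapping = {
            "me": "params_me", "ac": "params_ac",
            "me_dual": "params_me_on_dual", "ac_dual": "params_ac_on_dual",
        }
        for ns, overrides in by_ns.items():
            attr = mapping[ns]
            current = getattr(b, attr)
            if current is None:
                raise ValueError(f"cannot override {ns!r}: base has no such set")
            kw[attr] = current.replace(**overrides)
        return replace(b, **kw)

    def simulate(self, values: dict[str, float], s0: float,
                 curve: ProgressionCurve) -> dict[str, np.ndarray]:
        truth = self.truth_from(values)
        scheme = truth.scheme()
        sim = progression_curve(
            scheme, s0, curve.E0, curve.times, deadtime=curve.deadtime,
            substrate=curve.substrate, observed=tuple(curve.data),
            method=self.method, rel_tol=self.rel_tol, abs_tol=self.abs_tol,
        )
        return sim.data


@dataclass
class FitProblem:
    """One global fit: curves sharing rate constants + what is free."""

    curves: list[ProgressionCurve]
    model: object                      # SingleSubstrateModel / CoupledModel / ...
    free_rates: tuple[str, ...]
    fit_s0: bool = True
    sigma: float = 1.0
    include_products: bool = False     # substrate-only chi^2 by default
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = list(self.free_rates)
        if self.fit_s0:
            names += [f"S0[{i}]" for i in range(len(self.curves))]
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    @property
    def n_obs(self) -> int:
        return sum(len(self._residual_columns(c)) * c.times.size
                   for c in self.curves)

    def _residual_columns(self, curve: ProgressionCurve) -> list[str]:
        if self.include_products:
            return list(curve.data)
        return [curve.substrate]

    def bounds_for(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS)

    def default_init(self) -> dict[str, float]:
        """Base-model rates plus per-curve S0 from curve metadata."""
        init: dict[str, float] = {}
        for name in self.free_rates:
            init[name] = _lookup_base(self.model, name)
        if self.fit_s0:
            for i, c in enumerate(self.curves):
                s0 = c.S0
                if not np.isfinite(s0):
                    s0 = float(np.max(c.substrate_conc))
                init[f"S0[{i}]"] = s0
        return init

    # -- vector <-> dict ---------------------------------------------------
    def pack(self, values: dict[str, float]) -> np.ndarray:
        return np.array([math.log(values[n]) for n in self.param_names])

    def unpack(self, x: np.ndarray) -> dict[str, float]:
        return {n: math.exp(v) for n, v in zip(self.param_names, x)}

    def s0_for(self, values: dict[str, float], i: int) -> float:
        if self.fit_s0:
            return values[f"S0[{i}]"]
        c = self.curves[i]
        return c.S0 if np.isfinite(c.S0) else float(np.max(c.substrate_conc))

    def residuals(self, values: dict[str, float]) -> np.ndarray:
        blocks = []
        for i, curve in enumerate(self.curves):
            sim = self.model.simulate(values, self.s0_for(values, i), curve)
            for col in self._residual_columns(curve):
                blocks.append((sim[col] - curve.data[col]) / self.sigma)
        return np.concatenate(blocks)

    def jac_sparsity(self) -> np.ndarray:
        """Boolean structure of the Jacobian: S0_i only hits curve i's block."""
        names = self.param_names
        rows = []
        for i, curve in enumerate(self.curves):
            n_rows = len(self._residual_columns(curve)) * curve.times.size
            row = np.ones((n_rows, len(names)), dtype=bool)
            for j, name in enumerate(names):
                if name.startswith("S0[") and name != f"S0[{i}]":
                    row[:, j] = False
            rows.append(row)
        return np.vstack(rows)


def _lookup_base(model, name: str) -> float:
    if hasattr(model, "base_values"):
        return model.base_values[name]
    if isinstance(model, SingleSubstrateModel):
        return getattr(model.base, name)
    if isinstance(model, CoupledModel):
        ns, _, f = name.partition(".")
        mapping = {
            "me": model.base.params_me, "ac": model.base.params_ac,
            "me_dual": model.base.params_me_on_dual,
            "ac_dual": model.base.params_ac_on_dual,
        }
        return getattr(mapping[ns], f)
    raise TypeError(f"cannot derive defaults for model {type(model).__name__}")


@dataclass
class FitResult:
    """Outcome of one global least-squares fit."""

    values: dict[str, float]
    chi2: float
    n_obs: int
    n_free: int
    stderr: dict[str, float] | None
    converged: bool
    n_iterations: int
    problem: FitProblem
    jacobian: np.ndarray | None = None      # natural units, at the optimum
    bootstrap_stderr_: dict[str, float] | None = None
    bootstrap_replicates: np.ndarray | None = None

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_free

    def rate_parameters(self) -> RateParameters:
        """Best-fit RateParameters (single-substrate models only)."""
        return self.problem.model.params_from(self.values)


def chi_square(problem: FitProblem, values: dict[str, float]) -> float:
    """Sum of squared sigma-scaled residuals over all curves and times."""
    r = problem.residuals(values)
    return float(r @ r)


def fit_lm(
    problem: FitProblem,
    init: dict[str, float] | None = None,
    max_iter: int = 500,
    ftol: float = 1e-10,
    xtol: float = 1e-12,
    diff_step: float = 1e-4,
) -> FitResult:
    """Levenberg-Marquardt-style local minimization of chi^2.

    Parameters are transformed to log-space (all positive); bounds are applied
    there.  The finite-difference Jacobian honours the residual-block sparsity.
    Hitting the iteration cap flags the result as non-converged instead of
    raising.
    """
    if problem.n_obs <= problem.n_free:
        raise ValueError(
            f"dof = {problem.n_obs - problem.n_free} <= 0: nothing to fit"
        )
    values0 = dict(problem.default_init())
    if init:
        values0.update(init)
    names = problem.param_names
    lo = np.array([math.log(problem.bounds_for(n)[0]) for n in names])
    hi = np.array([math.log(problem.bounds_for(n)[1]) for n in names])
    x0 = np.clip(problem.pack(values0), lo, hi)
    pinned = lo == hi

    def fun(x):
        return problem.residuals(problem.unpack(x))

    if np.all(pinned):
        raise ValueError("all parameters pinned: nothing to fit")

    # least_squares rejects lo == hi; nudge pinned parameters by epsilon
    hi_eff = np.where(pinned, hi + 1e-12, hi)
    sparsity = problem.jac_sparsity()
    if sparsity.all() or len(names) < 2:
        sparsity = None  # dense FD; also sidesteps a scipy lsmr edge case
    sol = least_squares(
        fun, x0, method="trf", bounds=(lo, hi_eff),
        jac_sparsity=sparsity,
        ftol=ftol, xtol=xtol, gtol=1e-14, diff_step=diff_step,
        max_nfev=max_iter * (len(names) + 1),
    )
    values = problem.unpack(sol.x)
    chi2 = float(2.0 * sol.cost)
    converged = sol.status > 0

    # Jacobian in natural units: dr/dp = (dr/dlog p) / p
    jac_log = np.asarray(sol.jac.todense() if hasattr(sol.jac, "todense") else sol.jac)
    p = np.exp(sol.x)
    jac_nat = jac_log / p[None, :]

    result = FitResult(
        values=values, chi2=chi2, n_obs=problem.n_obs, n_free=len(names),
        stderr=None, converged=converged, n_iterations=int(sol.nfev),
        problem=problem, jacobian=jac_nat,
    )
    try:
        result.stderr = covariance_stderr(result)
    except UnidentifiableParameterError:
        result.stderr = None
    return result


def grid_search_init(
    problem: FitProblem,
    grid: dict[str, "np.ndarray | list[float]"],
    base: dict[str, float] | None = None,
) -> dict[str, float]:
    """Exhaustive chi^2 evaluation over a finite grid; returns the best point.

    ``grid`` maps a subset of parameter names to candidate values; parameters
    not on the grid stay at ``base`` (default: the problem's default init).
    """
    if not grid:
        raise ValueError("empty grid")
    for name, vals in grid.items():
        if name not in problem.param_names:
            raise KeyError(f"grid parameter {name!r} is not free in this problem")
        if len(vals) == 0:
            raise ValueError(f"empty grid axis {name!r}")
    values = dict(problem.default_init())
    if base:
        values.update(base)
    names = list(grid)
    best, best_chi2 = None, np.inf
    for combo in itertools.product(*(grid[n] for n in names)):
        trial = dict(values)
        trial.update(dict(zip(names, combo)))
        c2 = chi_square(problem, trial)
        if c2 < best_chi2:
            best, best_chi2 = trial, c2
    return best


def covariance_stderr(result: FitResult) -> dict[str, float]:
    """Standard errors from the inverse curvature (J^T J) at the optimum.

    Residuals are already sigma-scaled, so no additional variance scaling is
    applied.  A singular curvature raises, naming the flattest direction.
    """
    j = result.jacobian
    if j is None:
        raise ValueError("fit carries no Jacobian")
    jtj = j.T @ j
    eigval, eigvec = np.linalg.eigh(jtj)
    names = result.problem.param_names
    if eigval[0] <= max(eigval[-1], 1.0) * 1e-12:
        null = eigvec[:, 0]
        worst = names[int(np.argmax(np.abs(null)))]
        raise UnidentifiableParameterError(
            f"singular curvature; flattest direction dominated by {worst!r} "
            f"(null-space vector {np.round(null, 4).tolist()})"
        )
    cov = eigvec @ np.diag(1.0 / eigval) @ eigvec.T
    se = np.sqrt(np.diag(cov))
    return dict(zip(names, se))


def bootstrap_stderr(
    problem: FitProblem,
    result: FitResult,
    n_runs: int = 500,
    seed: int = 0,
    max_iter: int = 100,
) -> FitResult:
    """Residual-resampling bootstrap standard errors (in place on ``result``).

    Residuals of the base fit are resampled with replacement within each
    curve/column block and added back onto the base-fit model curves; each
    replicate is refit starting from the base optimum.  Deterministic given
    ``seed``.  A replicate non-convergence rate above 20% emits a warning.
    """
    rng = np.random.default_rng(seed)
    base_values = result.values
    base_sims = []
    for i, curve in enumerate(problem.curves):
        sim = problem.model.simulate(base_values, problem.s0_for(base_values, i), curve)
        base_sims.append(sim)

    names = problem.param_names
    replicates = np.empty((n_runs, len(names)))
    n_fail = 0
    for r in range(n_runs):
        new_curves = []
        for i, curve in enumerate(problem.curves):
            data = dict(curve.data)
            for col in problem._residual_columns(curve):
                resid = curve.data[col] - base_sims[i][col]
                data[col] = base_sims[i][col] + rng.choice(resid, size=resid.size,
                                                          replace=True)
            new_curves.append(ProgressionCurve(
                times=curve.times, data=data, S0=curve.S0, E0=curve.E0,
                deadtime=curve.deadtime, substrate=curve.substrate,
            ))
        rep_problem = replace(problem, curves=new_curves)
        rep = fit_lm(rep_problem, init=dict(base_values), max_iter=max_iter)
        if not rep.converged:
            n_fail += 1
        replicates[r] = [rep.values[n] for n in names]

    if n_fail > 0.2 * n_runs:
        warnings.warn(
            f"bootstrap: {n_fail}/{n_runs} replicates did not converge",
            RuntimeWarning,
        )
    se = replicates.std(axis=0, ddof=1)
    result.bootstrap_stderr_ = dict(zip(names, se))
    result.bootstrap_replicates = replicates
    return result
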