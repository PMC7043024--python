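"""Nested-model F-tests, condition summaries, limiting-rate overlays, pipeline.

The F-tail probability is computed from the regularized incomplete beta
function implemented here (continued-fraction evaluation); tests compare it
against an independent high-precision evaluation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fitting import FitProblem, FitResult
from .integrate import ProgressionCurve
from .model import (
    RateParameters,
    apparent_post_params,
    initial_rate_short_time,
    rates_to_eq,
)

__all__ = [
    "ModelComparison",
    "ConditionSummary",
    "regularized_incomplete_beta",
    "f_tail_probability",
    "f_test",
    "summarize_condition",
    "limiting_overlays",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Regularized incomplete beta function (continued fraction, in-package)
# ---------------------------------------------------------------------------

def _beta_cf(a: float, b: float, x: float, max_iter: int = 500,
             eps: float = 1e-16) -> float:
    """Continued fraction for the incomplete beta function (modified Lentz)."""
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1.0 / d
    h = d
    for m in range(1, max_iter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            return h
    raise RuntimeError(f"incomplete beta continued fraction did not converge "
                       f"(a={a}, b={b}, x={x})")


def regularized_incomplete_beta(a: float, b: float, x: float) -> float:
    """I_x(a, b) for a, b > 0 and x in [0, 1]."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be > 0")
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_front = (math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
                + a * math.log(x) + b * math.log1p(-x))
    front = math.exp(ln_front)
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _beta_cf(a, b, x) / a
    return 1.0 - front * _beta_cf(b, a, 1.0 - x) / b


def f_tail_probability(f_value: float, dof_num: float, dof_den: float) -> float:
    """P(F >= f_value) for an F(dof_num, dof_den) distribution."""
    if f_value <= 0.0:
        return 1.0
    x = dof_den / (dof_den + dof_num * f_value)
    return regularized_incomplete_beta(dof_den / 2.0, dof_num / 2.0, x)


# ---------------------------------------------------------------------------
# Nested-model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelComparison:
    chi2_restricted: float
    dof_restricted: int
    chi2_full: float
    dof_full: int
    f_statistic: float
    dof_num: int
    dof_den: int
    p_value: float


def f_test(chi2_r: float, dof_r: int, chi2_f: float, dof_f: int) -> ModelComparison:
    """F-test of a restricted model against the nested full model.

    F = ((chi2_r - chi2_f)/(dof_r - dof_f)) / (chi2_f/dof_f); the tail
    probability comes from :func:`f_tail_probability`.  If the restricted
    model fits better (possible with local optima), p is reported as 1 with a
    warning.
    """
    if not dof_r > dof_f > 0:
        raise ValueError(f"models not nested: dof_r={dof_r}, dof_f={dof_f}")
    if chi2_f < 0 or chi2_r < 0:
        raise ValueError("chi^2 must be >= 0")
    d_num = dof_r - dof_f
    if chi2_r < chi2_f:
        warnings.warn(
            "restricted model fits better than full model; p set to 1",
            RuntimeWarning,
        )
        f_stat = 0.0
        p = 1.0
    else:
        f_stat = ((chi2_r - chi2_f) / d_num) / (chi2_f / dof_f)
        p = f_tail_probability(f_stat, d_num, dof_f)
    return ModelComparison(
        chi2_restricted=chi2_r, dof_restricted=dof_r,
        chi2_full=chi2_f, dof_full=dof_f,
        f_statistic=f_stat, dof_num=d_num, dof_den=dof_f, p_value=p,
    )


def compare_fits(restricted: FitResult, full: FitResult) -> ModelComparison:
    return f_test(restricted.chi2, restricted.dof, full.chi2, full.dof)


# ---------------------------------------------------------------------------
# Condition summaries
# ---------------------------------------------------------------------------

#: Canonical row order of a condition summary.
SUMMARY_KEYS = ("kcat_post", "KM_post", "efficiency",
                "Keq_E", "kex_E", "Keq_ES", "kex_ES")


@dataclass
class ConditionSummary:
    """Derived (apparent + exchange) parameters of one fitted condition."""

    label: str
    values: dict[str, float]
    errors: dict[str, float | None] = field(default_factory=dict)

    def as_rows(self) -> list[tuple[str, float, float | None]]:
        return [(k, self.values[k], self.errors.get(k)) for k in SUMMARY_KEYS]


def _derived_map(params: RateParameters) -> dict[str, float]:
    app = apparent_post_params(params)
    eq_e = rates_to_eq(params.kE_fwd, params.kE_rev)
    eq_es = rates_to_eq(params.kES_fwd, params.kES_rev)
    return {
        "kcat_post": app.kcat_app,
        "KM_post": app.KM_app,
        "efficiency": app.efficiency,
        "Keq_E": eq_e.Keq,
        "kex_E": eq_e.kex,
        "Keq_ES": eq_es.Keq,
        "kex_ES": eq_es.kex,
    }


def summarize_condition(fit: FitResult, label: str) -> ConditionSummary:
    """Apparent + exchange parameters with propagated errors.

    Uses bootstrap replicates when present, otherwise first-order
    (delta-method) propagation from the covariance of the free parameters.
    """
    params = fit.rate_parameters()
    values = _derived_map(params)
    errors: dict[str, float | None] = {k: None for k in values}

    names = fit.problem.param_names
    rate_names = [n for n in names if not n.startswith("S0[")]

    if fit.bootstrap_replicates is not None:
        reps = fit.bootstrap_replicates
        derived = np.empty((reps.shape[0], len(SUMMARY_KEYS)))
        for r in range(reps.shape[0]):
            vals = dict(zip(names, reps[r]))
            p = fit.problem.model.params_from(vals)
            d = _derived_map(p)
            derived[r] = [d[k] for k in SUMMARY_KEYS]
        sd = derived.std(axis=0, ddof=1)
        errors = dict(zip(SUMMARY_KEYS, sd))
    elif fit.jacobian is not None and rate_names:
        j = fit.jacobian
        jtj = j.T @ j
        try:
            cov = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = None
        if cov is not None:
            # numerical gradient of each derived quantity w.r.t. free params
            grad = np.zeros((len(SUMMARY_KEYS), len(names)))
            base_vals = dict(fit.values)
            for jcol, n in enumerate(names):
                if n.startswith("S0["):
                    continue
                h = max(abs(base_vals[n]) * 1e-6, 1e-12)
                up, dn = dict(base_vals), dict(base_vals)
                up[n] += h
                dn[n] = max(dn[n] - h, 0.0)
                d_up = _derived_map(fit.problem.model.params_from(up))
                d_dn = _derived_map(fit.problem.model.params_from(dn))
                for irow, k in enumerate(SUMMARY_KEYS):
                    grad[irow, jcol] = (d_up[k] - d_dn[k]) / (up[n] - dn[n])
            var = np.einsum("ij,jk,ik->i", grad, cov, grad)
            errors = {k: float(np.sqrt(max(v, 0.0)))
                      for k, v in zip(SUMMARY_KEYS, var)}
    return ConditionSummary(label=label, values=values, errors=errors)


def summary_table(summaries: list[ConditionSummary]) -> str:
    """Delimited text table, conditions as columns."""
    lines = ["parameter\t" + "\t".join(s.label for s in summaries)]
    for key in SUMMARY_KEYS:
        cells = []
        for s in summaries:
            v = s.values[key]
            e = s.errors.get(key)
            cells.append(f"{v:.6g} +/- {e:.2g}" if e is not None else f"{v:.6g}")
        lines.append(key + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Limiting-rate overlays
# ---------------------------------------------------------------------------

def limiting_overlays(params: RateParameters, S0: float, E0: float, t_grid):
    """(initial-rate line, post-equilibrium curve) over ``t_grid``.

    The dotted short-time overlay is S0 - v0*t (clipped at zero); the dashed
    long-time overlay integrates the one-enzyme Michaelis-Menten system with
    the post-equilibrium apparent parameters.
    """
    from scipy.integrate import solve_ivp

    t_grid = np.asarray(t_grid, dtype=float)
    v0 = initial_rate_short_time(params, S0, E0)
    dotted = np.clip(S0 - v0 * t_grid, 0.0, None)

    app = apparent_post_params(params)

    def mm_rhs(t, y):
        return [-app.kcat_app * E0 * y[0] / (app.KM_app + y[0])]

    sol = solve_ivp(mm_rhs, (t_grid[0], t_grid[-1]) if t_grid[0] < t_grid[-1]
                    else (0.0, t_grid[-1]), [S0], t_eval=t_grid,
                    rtol=1e-10, atol=1e-12, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"overlay integration failed: {sol.message}")
    dashed = sol.y[0]
    return dotted, dashed


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class ConfigurationError(ValueError):
    pass


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Synthetic fixture (or curve files) -> grid init -> fit -> summary.

    Returns a fully deterministic, JSON-serializable report; optionally writes
    ``summary.tsv`` and ``report.json`` under ``out_dir``.
    """
    from . import synth
    from .fitting import SingleSubstrateModel, bootstrap_stderr, fit_lm, grid_search_init

    scheme_name = config.get("scheme", "single_substrate")
    if scheme_name not in ("single_substrate", "coupled"):
        raise ConfigurationError(f"unknown scheme {scheme_name!r}")
    if scheme_name == "coupled":
        raise ConfigurationError(
            "the pipeline front-end currently drives single-substrate fits; "
            "assemble coupled fits through the fitting API"
        )

    label = config.get("label", "condition")
    sigma = float(config.get("sigma", 1.0))

    if "fixture" in config:
        fx = config["fixture"]
        design, truth = synth.paperlike_fixture(
            fx["condition"], fx["reaction"], seed=int(fx.get("seed", 0)),
            sigma=sigma,
        )
        curves = synth.make_experiment(design, truth)
        base = truth
    elif "curves" in config:
        curves = [ProgressionCurve.from_table(p) for p in config["curves"]]
        if "base_rates" not in config:
            raise ConfigurationError("curve-file input requires base_rates")
        base = RateParameters.from_dict(config["base_rates"])
    else:
        raise ConfigurationError("config must name either a fixture or curve files")

    free = tuple(config.get(
        "free_rates",
        ("kcat_E", "kcat_Estar", "kE_fwd", "kE_rev", "kES_fwd", "kES_rev"),
    ))
    problem = FitProblem(
        curves=curves,
        model=SingleSubstrateModel(base),
        free_rates=free,
        sigma=sigma,
        bounds={k: tuple(v) for k, v in config.get("bounds", {}).items()},
    )

    init = None
    if config.get("grid"):
        init = grid_search_init(problem, {k: list(v) for k, v in config["grid"].items()})
    fit = fit_lm(problem, init=init)
    if int(config.get("bootstrap_runs", 0)) > 0:
        bootstrap_stderr(problem, fit, n_runs=int(config["bootstrap_runs"]),
                         seed=int(config.get("bootstrap_seed", 0)))
    summary = summarize_condition(fit, label)

    report = {
        "label": label,
        "config": {k: v for k, v in config.items() if k != "curves"},
        "chi2": fit.chi2,
        "dof": fit.dof,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "best_fit": fit.values,
        "stderr": fit.stderr,
        "summary": {"values": summary.values, "errors": summary.errors},
        "versions": _versions(),
    }
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(os.path.join(out_dir, "summary.tsv"), "w") as fh:
            fh.write(summary_table([summary]))
    return report


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__

    return {"nmrkin": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__}


def significance_label(p: float) -> str:
    """Cosmetic significance marker (*** p<0.001, **** p<0.0001)."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
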