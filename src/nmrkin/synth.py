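"""Synthetic experiments: noisy progression curves and pseudo-2D spectra.

Everything downstream (quantification, fitting, model selection) is testable
offline against data generated here.  ``paperlike_fixture`` returns designs
and micro-rates constructed so that the derived observables (post-equilibrium
apparent parameters and exchange Keq/kex pairs) reproduce the published
summary values for each modulator condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrate import ProgressionCurve, progression_curve
from .model import (
    EquilibriumParams,
    RateParameters,
    SchemeSpec,
    build_coupled_scheme,
    build_single_substrate_scheme,
    eq_to_rates,
)
from .quantify import DEFAULT_FIELD_MHZ, PeakSpec, SpectrumSeries, mixed_lineshape

__all__ = [
    "ExperimentDesign",
    "CoupledTruth",
    "UnsupportedConditionError",
    "make_experiment",
    "synth_spectrum_series",
    "paperlike_fixture",
    "invert_observables",
    "CONDITIONS",
]


class UnsupportedConditionError(ValueError):
    """No reliable published parameters exist for this condition."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Acquisition design of one real-time NMR kinetics experiment."""

    substrate: str                 # K4meK9 | K4K9ac | K4meK9ac
    S0: tuple[float, ...]          # initial substrate concentrations, uM
    E0: float                      # enzyme concentration, uM
    interval: float = 61.0         # sampling interval, s
    duration: float = 15000.0      # observed time span, s
    deadtime: float = 80.0         # s between reaction start and first point
    sigma: float = 1.0             # additive concentration noise sd, uM
    seed: int = 0
    enforce_ranges: bool = True    # published-design ranges for S0 and E0

    def __post_init__(self) -> None:
        if self.substrate not in ("K4meK9", "K4K9ac", "K4meK9ac"):
            raise ValueError(f"unknown substrate {self.substrate!r}")
        for s0 in self.S0:
            if not 0 < s0:
                raise ValueError("S0 must be positive")
            if self.enforce_ranges and not 50.0 <= s0 <= 800.0:
                raise ValueError(
                    f"S0 = {s0} uM outside the experimental range [50, 800]; "
                    "pass enforce_ranges=False to override")
        if self.enforce_ranges and not 0.05 <= self.E0 <= 0.2:
            raise ValueError(
                f"E0 = {self.E0} uM outside the experimental range "
                "[0.05, 0.2]; pass enforce_ranges=False to override")
        if self.sigma < 0 or self.interval <= 0 or self.deadtime < 0:
            raise ValueError("invalid design")

    @property
    def t_grid(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 0.5 * self.interval, self.interval)


@dataclass(frozen=True)
class CoupledTruth:
    """Ground truth of a dual-substrate experiment."""

    params_me: RateParameters
    params_ac: RateParameters
    params_me_on_dual: RateParameters | None = None
    params_ac_on_dual: RateParameters | None = None
    single_occupancy: bool = True
    shared_kinetics: bool = False
    with_alternate_state: bool = True

    def scheme(self) -> SchemeSpec:
        return build_coupled_scheme(
            self.params_me,
            self.params_ac,
            self.params_me_on_dual,
            self.params_ac_on_dual,
            single_occupancy=self.single_occupancy,
            shared_kinetics=self.shared_kinetics,
            with_alternate_state=self.with_alternate_state,
        )


def make_experiment(
    design: ExperimentDesign,
    truth: RateParameters | CoupledTruth,
    method: str = "lsoda",
    observed: tuple[str, ...] | None = None,
) -> list[ProgressionCurve]:
    """Noise-free simulation plus i.i.d. additive noise, one curve per S0.

    Deterministic given ``design.seed``; the generating parameters are
    recorded in each curve's ``meta`` for recovery tests.
    """
    rng = np.random.default_rng(design.seed)
    curves = []
    if isinstance(truth, RateParameters):
        scheme = build_single_substrate_scheme(truth)
        substrate_species = "S"
        if observed is None:
            observed = ("S", "P") if design.substrate == "K4K9ac" else ("S",)
        truth_meta = truth.to_dict()
    else:
        scheme = truth.scheme()
        substrate_species = design.substrate
        if observed is None:
            observed = ("K4meK9", "K4K9ac", "K4meK9ac", "acetate")
        truth_meta = {"coupled": True}

    for s0 in design.S0:
        clean = progression_curve(
            scheme, s0, design.E0, design.t_grid,
            deadtime=design.deadtime, substrate=substrate_species,
            observed=observed, method=method,
        )
        noisy_data = {
            sp: v + rng.normal(0.0, design.sigma, size=v.shape)
            for sp, v in clean.data.items()
        }
        curves.append(ProgressionCurve(
            times=clean.times, data=noisy_data, S0=s0, E0=design.E0,
            deadtime=design.deadtime, substrate=substrate_species,
            meta={"substrate_id": design.substrate, "sigma": design.sigma,
                  "truth": truth_meta},
        ))
    return curves


def synth_spectrum_series(
    curve: ProgressionCurve,
    peaks: dict[str, PeakSpec],
    noise_sd: float = 0.0,
    seed: int = 0,
    ppm_window: tuple[float, float] = (2.4, 1.4),
    n_points: int = 2048,
    field_mhz: float = DEFAULT_FIELD_MHZ,
) -> SpectrumSeries:
    """Render a progression curve into a pseudo-2D spectral series.

    Each time slice is a sum of mixed Gaussian/Lorentzian peaks with height
    ``response * concentration(t)``; shape parameters are constant across the
    series.  White noise of sd ``noise_sd`` is added per point.
    """
    ppm = np.linspace(ppm_window[0], ppm_window[1], n_points)
    n_t = curve.times.size
    mat = np.zeros((n_points, n_t))
    for species, pk in peaks.items():
        conc = curve.data[species]
        shape = mixed_lineshape(ppm, pk.center, pk.width_hz,
                                pk.gaussian_fraction, field_mhz)
        mat += shape[:, None] * (pk.response * conc)[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    return SpectrumSeries(
        ppm=ppm, intensity=mat, times=curve.times.copy(),
        meta={"peaks": {sp: vars(pk).copy() for sp, pk in peaks.items()},
              "field_mhz": field_mhz},
    )


# ---------------------------------------------------------------------------
# Published condition regimes
# ---------------------------------------------------------------------------

#: Summary observables per (reaction, condition): post-equilibrium apparent
#: parameters and the two exchange (Keq, kex) pairs.  Entries flagged
#: ``kex_E_upper_bound`` were published only as upper bounds; the bound value
#: is used directly.
CONDITIONS: dict[tuple[str, str], dict] = {
    ("demethylation", "APO"): dict(
        kcat_post=0.032, KM_post=2.3, Keq_E=7.0, kex_E=0.0074,
        Keq_ES=76.0, kex_ES=0.0055),
    ("demethylation", "PCPA"): dict(
        kcat_post=0.0077, KM_post=26.0, Keq_E=7.4, kex_E=5e-4,
        Keq_ES=129.0, kex_ES=0.0050, kex_E_upper_bound=True),
    ("demethylation", "MS275"): dict(
        kcat_post=0.023, KM_post=9.2, Keq_E=1.7, kex_E=0.0028,
        Keq_ES=146.0, kex_ES=0.0060),
    ("demethylation", "InsP6"): dict(
        kcat_post=0.093, KM_post=190.0, Keq_E=3.0, kex_E=0.0015,
        Keq_ES=49.0, kex_ES=0.047),
    ("deacetylation", "APO"): dict(
        kcat_post=0.70, KM_post=33.0, Keq_E=6.8, kex_E=1e-7,
        Keq_ES=2560.0, kex_ES=0.077, kex_E_upper_bound=True),
    ("deacetylation", "PCPA"): dict(
        kcat_post=0.52, KM_post=22.0, Keq_E=5.5, kex_E=0.0031,
        Keq_ES=280.0, kex_ES=0.0028),
    ("deacetylation", "InsP6"): dict(
        kcat_post=0.78, KM_post=12.0, Keq_E=1.9, kex_E=0.14,
        Keq_ES=1990.0, kex_ES=0.09),
}

_DESIGNS = {
    # (substrate id, S0 set from the published progression-curve figures, E0)
    "demethylation": ("K4meK9", (300.0, 80.0), 0.2),
    "deacetylation": ("K4K9ac", (660.0, 100.0), 0.05),
}


def invert_observables(
    kcat_post: float,
    KM_post: float,
    Keq_E: float,
    kex_E: float,
    Keq_ES: float,
    kex_ES: float,
    k1: float = 0.2,
    k_off: float | None = None,
    **_ignored,
) -> RateParameters:
    """Micro-rates reproducing the given derived observables exactly.

    The observables under-determine the seven free micro-rates by one degree
    of freedom.  By default ``kcat_Estar`` is set to zero (the E*S branch is
    catalytically dead), which fixes ``k_off``; pass ``k_off`` explicitly to
    choose a different point on the degeneracy line (``kcat_Estar`` is then
    solved for, and must come out non-negative).
    """
    kE_fwd, kE_rev = eq_to_rates(EquilibriumParams(Keq=Keq_E, kex=kex_E))
    kES_fwd, kES_rev = eq_to_rates(EquilibriumParams(Keq=Keq_ES, kex=kex_ES))
    km_e = KM_post * (1.0 + Keq_ES) / (1.0 + Keq_E)
    total = k1 * km_e  # = kcat_E + k_off
    kcat_e_for_dead_estar = kcat_post * (1.0 + Keq_ES)
    if k_off is None:
        kcat_e = kcat_e_for_dead_estar
        k_off = total - kcat_e
        kcat_estar = 0.0
        if k_off < 0:
            raise ValueError(
                "observables infeasible with kcat_Estar = 0: "
                f"needs k_off = {k_off:.4g} < 0; pass k_off explicitly"
            )
    else:
        kcat_e = total - k_off
        if kcat_e < 0:
            raise ValueError(
                f"k_off = {k_off} exceeds k1*KM_E = {total:.4g}; kcat_E would be negative"
            )
        kcat_estar = (kcat_post * (1.0 + Keq_ES) - kcat_e) / Keq_ES
        if kcat_estar < 0:
            raise ValueError(
                f"k_off = {k_off} too small: kcat_Estar would be negative "
                f"(feasible k_off range is [{total - kcat_e_for_dead_estar:.4g}, {total:.4g}])"
            )
    return RateParameters(
        k1=k1, k_off=k_off, kcat_E=kcat_e, kcat_Estar=kcat_estar,
        kE_fwd=kE_fwd, kE_rev=kE_rev, kES_fwd=kES_fwd, kES_rev=kES_rev,
    )


def paperlike_fixture(
    condition: str,
    reaction: str,
    seed: int = 0,
    sigma: float = 1.0,
    max_points: int = 1200,
) -> tuple[ExperimentDesign, RateParameters]:
    """Design + ground-truth micro-rates emulating one published condition.

    Raises :class:`UnsupportedConditionError` for (MS275, deacetylation),
    for which no reliable parameters were obtained.
    """
    key = (reaction, condition)
    if reaction not in _DESIGNS:
        raise ValueError(f"unknown reaction {reaction!r}")
    if key not in CONDITIONS:
        raise UnsupportedConditionError(
            f"no published kinetic parameters for condition {condition!r} "
            f"({reaction})"
        )
    obs = CONDITIONS[key]
    truth = invert_observables(**obs)
    substrate, s0_set, e0 = _DESIGNS[reaction]
    # run until every curve is (over-)depleted, capped for desk scale; the
    # KM information lives in the final rolloff of each progression curve
    v_max = obs["kcat_post"] * e0
    duration = 1.3 * max(s0_set) / v_max
    interval = 61.0
    duration = min(duration, max_points * interval)
    design = ExperimentDesign(
        substrate=substrate, S0=s0_set, E0=e0, interval=interval,
        duration=duration, deadtime=80.0, sigma=sigma, seed=seed,
    )
    return design, truth
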