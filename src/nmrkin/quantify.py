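"""Pseudo-2D spectral quantification: shared-lineshape peak fitting.

A time series of 1D spectra is fit jointly: every peak has one center, one
width, and one Gaussian fraction for the whole series, while its amplitude is
free per time slice.  Given the shapes, the per-slice amplitudes (plus a local
linear baseline) enter linearly, so they are solved by linear least squares
inside an outer optimization over the shape parameters (variable projection).
Amplitudes are converted to concentrations against a reference sample of
known concentration.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .integrate import ProgressionCurve

__all__ = [
    "PeakSpec",
    "SpectrumSeries",
    "PeakFitResult",
    "DegeneratePeaksError",
    "mixed_lineshape",
    "lineshape_area_factor",
    "fit_peak_series",
    "intensities_to_concentrations",
]

#: Spectrometer frequency used for Hz <-> ppm conversion, MHz.
DEFAULT_FIELD_MHZ = 500.0


class DegeneratePeaksError(RuntimeError):
    """Two peaks collapsed onto (nearly) the same center during fitting."""


@dataclass(frozen=True)
class PeakSpec:
    """Mixed Gaussian/Lorentzian peak: unit height, FWHM ``width_hz``."""

    center: float             # ppm
    width_hz: float           # FWHM, Hz
    gaussian_fraction: float  # 0 (pure Lorentzian) .. 1 (pure Gaussian)
    response: float = 1.0     # peak height per uM

    def __post_init__(self) -> None:
        if not self.width_hz > 0:
            raise ValueError("width must be > 0")
        if not 0.0 <= self.gaussian_fraction <= 1.0:
            raise ValueError("gaussian_fraction must be in [0, 1]")


def mixed_lineshape(ppm, center, width_hz, gaussian_fraction,
                    field_mhz=DEFAULT_FIELD_MHZ):
    """Unit-height mixed lineshape f*Gaussian + (1-f)*Lorentzian."""
    w_ppm = width_hz / field_mhz
    x = (np.asarray(ppm, dtype=float) - center) / w_ppm
    gauss = np.exp(-4.0 * math.log(2.0) * x * x)
    lor = 1.0 / (1.0 + 4.0 * x * x)
    f = gaussian_fraction
    return f * gauss + (1.0 - f) * lor


def lineshape_area_factor(width_hz, gaussian_fraction):
    """Analytic area (in Hz) under a unit-height mixed lineshape."""
    a_gauss = width_hz * math.sqrt(math.pi / (4.0 * math.log(2.0)))
    a_lor = width_hz * math.pi / 2.0
    f = gaussian_fraction
    return f * a_gauss + (1.0 - f) * a_lor


@dataclass
class SpectrumSeries:
    """Stack of 1D spectra: ppm axis (decreasing) x acquisition times."""

    ppm: np.ndarray          # (n_ppm,), strictly decreasing
    intensity: np.ndarray    # (n_ppm, n_times)
    times: np.ndarray        # (n_times,), s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        d = np.diff(self.ppm)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if self.intensity.shape != (self.ppm.size, self.times.size):
            raise ValueError("intensity matrix shape inconsistent with axes")

    # -- delimited-matrix serialization -----------------------------------
    def to_table(self) -> str:
        lines = ["# times_s = " + ",".join(f"{t:.6f}" for t in self.times)]
        header = "ppm\t" + "\t".join(f"t{i}" for i in range(self.times.size))
        lines.append(header)
        for i, p in enumerate(self.ppm):
            row = "\t".join(f"{v:.8e}" for v in self.intensity[i])
            lines.append(f"{p:.6f}\t{row}")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_table())

    @classmethod
    def from_table(cls, text_or_path) -> "SpectrumSeries":
        import pandas as pd

        if isinstance(text_or_path, str) and "\n" in text_or_path:
            fh = io.StringIO(text_or_path)
        else:
            fh = open(text_or_path)
        try:
            line = fh.readline()
            if not line.startswith("#"):
                raise ValueError("missing times metadata line")
            times = np.array([float(v) for v in line.split("=", 1)[1].split(",")])
            df = pd.read_csv(fh, sep="\t")
        finally:
            fh.close()
        ppm = df["ppm"].to_numpy()
        mat = df.drop(columns="ppm").to_numpy()
        return cls(ppm=ppm, intensity=mat, times=times)


@dataclass
class PeakFitResult:
    """Joint fit of a spectral series with time-invariant peak shapes."""

    centers: np.ndarray            # (n_peaks,), ppm
    widths_hz: np.ndarray          # (n_peaks,)
    gaussian_fractions: np.ndarray  # (n_peaks,)
    amplitudes: np.ndarray         # (n_peaks, n_times), peak heights
    residual_norm: float
    converged: bool
    n_iterations: int
    field_mhz: float = DEFAULT_FIELD_MHZ

    @property
    def areas(self) -> np.ndarray:
        """Per-peak-per-time integrated intensities (height x area factor)."""
        factors = np.array([
            lineshape_area_factor(w, f)
            for w, f in zip(self.widths_hz, self.gaussian_fractions)
        ])
        return self.amplitudes * factors[:, None]


def _design_matrix(ppm, centers, widths, fracs, field_mhz, baseline):
    cols = [mixed_lineshape(ppm, c, w, f, field_mhz)
            for c, w, f in zip(centers, widths, fracs)]
    if baseline:
        cols.append(np.ones_like(ppm))
        cols.append(ppm - ppm.mean())
    return np.column_stack(cols)


def fit_peak_series(
    series: SpectrumSeries,
    initial_peaks: list[PeakSpec],
    field_mhz: float = DEFAULT_FIELD_MHZ,
    baseline: bool = True,
    max_iter: int = 200,
    min_separation_hz: float | None = None,
) -> PeakFitResult:
    """Least-squares fit with shape parameters shared across all time slices.

    ``min_separation_hz`` (default: half the narrowest initial width) guards
    against peaks collapsing onto one another.
    """
    if not initial_peaks:
        raise ValueError("need at least one peak")
    lo, hi = min(series.ppm.min(), series.ppm.max()), max(series.ppm.min(), series.ppm.max())
    for pk in initial_peaks:
        if not lo <= pk.center <= hi:
            raise ValueError(f"initial center {pk.center} ppm outside window [{lo}, {hi}]")
    n_pk = len(initial_peaks)
    if min_separation_hz is None:
        min_separation_hz = 0.5 * min(p.width_hz for p in initial_peaks)

    y = series.intensity  # (n_ppm, n_times)
    if not np.any(y):
        return PeakFitResult(
            centers=np.array([p.center for p in initial_peaks]),
            widths_hz=np.array([p.width_hz for p in initial_peaks]),
            gaussian_fractions=np.array([p.gaussian_fraction for p in initial_peaks]),
            amplitudes=np.zeros((n_pk, series.times.size)),
            residual_norm=0.0, converged=True, n_iterations=0,
            field_mhz=field_mhz,
        )

    def unpack(theta):
        c = theta[:n_pk]
        w = np.exp(theta[n_pk:2 * n_pk])
        f = theta[2 * n_pk:]
        return c, w, f

    def solve_amplitudes(theta):
        c, w, f = unpack(theta)
        a = _design_matrix(series.ppm, c, w, f, field_mhz, baseline)
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        return a, coef

    def residual(theta):
        a, coef = solve_amplitudes(theta)
        return (a @ coef - y).ravel()

    theta0 = np.concatenate([
        [p.center for p in initial_peaks],
        [math.log(p.width_hz) for p in initial_peaks],
        [p.gaussian_fraction for p in initial_peaks],
    ])
    span = abs(hi - lo)
    t_lo = np.concatenate([
        np.full(n_pk, lo), np.full(n_pk, math.log(1e-3)), np.zeros(n_pk)])
    t_hi = np.concatenate([
        np.full(n_pk, hi), np.full(n_pk, math.log(1e4)), np.ones(n_pk)])
    # centers move on a much finer scale (linewidths) than the ppm window
    x_scale = np.concatenate([
        np.full(n_pk, 0.01 * span), np.ones(n_pk), np.ones(n_pk)])
    sol = least_squares(
        residual, theta0, method="trf", bounds=(t_lo, t_hi),
        x_scale=x_scale, diff_step=1e-6,
        max_nfev=max_iter * theta0.size,
    )
    centers, widths, fracs = unpack(sol.x)

    order = np.argsort(centers)
    sep_ppm = min_separation_hz / field_mhz
    cs = centers[order]
    if n_pk > 1 and np.any(np.diff(cs) < sep_ppm):
        raise DegeneratePeaksError(
            f"fitted peak centers closer than {min_separation_hz} Hz: {sorted(centers)}"
        )

    a, coef = solve_amplitudes(sol.x)
    amplitudes = coef[:n_pk]
    resid = a @ coef - y
    return PeakFitResult(
        centers=centers,
        widths_hz=widths,
        gaussian_fractions=fracs,
        amplitudes=amplitudes,
        residual_norm=float(np.linalg.norm(resid)),
        converged=bool(sol.status > 0 and sol.nfev < max_iter * theta0.size),
        n_iterations=int(sol.nfev),
        field_mhz=field_mhz,
    )


def intensities_to_concentrations(
    fit: PeakFitResult,
    times,
    reference_amplitude: float,
    reference_concentration: float,
    peak_names: list[str] | None = None,
    substrate: str | None = None,
    S0: float = float("nan"),
    E0: float = float("nan"),
    deadtime: float = 0.0,
) -> ProgressionCurve:
    """Linear amplitude -> concentration calibration against a reference.

    concentration(t) = amplitude(t) * reference_concentration / reference_amplitude
    """
    if not reference_amplitude > 0:
        raise ValueError("reference amplitude must be > 0")
    if not reference_concentration > 0:
        raise ValueError("reference concentration must be > 0")
    n_pk = fit.amplitudes.shape[0]
    if peak_names is None:
        peak_names = [f"peak{i}" for i in range(n_pk)]
    scale = reference_concentration / reference_amplitude
    data = {name: fit.amplitudes[i] * scale for i, name in enumerate(peak_names)}
    return ProgressionCurve(
        times=np.asarray(times, dtype=float),
        data=data,
        S0=S0,
        E0=E0,
        deadtime=deadtime,
        substrate=substrate or peak_names[0],
    )
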