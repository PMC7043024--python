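# nmrkin

Progression-curve enzyme kinetics for real-time NMR assays of a bifunctional
demethylase/deacetylase complex that interconverts between two enzyme states
(E and E*). The package covers the complete analysis chain:

- **`nmrkin.model`** — rate parameterizations with thermodynamic cycle
  closure (the E → ES → E*S → E* → E cycle leaves only seven independent
  rates), reaction-scheme construction (single-substrate and coupled
  dual-substrate networks with single-occupancy / shared-kinetics /
  alternate-state switches), and the closed-form short-time initial rate and
  post-equilibrium apparent Michaelis–Menten parameters.
- **`nmrkin.integrate`** — adaptive Runge–Kutta Cash–Karp integration of any
  scheme (numba-accelerated when available), with scipy LSODA/Radau as
  stiff/workhorse and reference methods under the same tolerance contract;
  deadtime-aware progression curves with delimited-table I/O.
- **`nmrkin.synth`** — synthetic experiments: noisy progression curves for
  published-like conditions (APO / 2-PCPA / MS275 / InsP6, demethylation and
  deacetylation) whose ground-truth micro-rates reproduce the published
  derived observables exactly, plus pseudo-2D spectral series rendering.
- **`nmrkin.quantify`** — shared-lineshape (mixed Gaussian/Lorentzian) joint
  peak fitting of pseudo-2D series (shape parameters time-invariant,
  amplitudes per slice, variable-projection inner solve) and linear
  reference calibration to concentrations.
- **`nmrkin.fitting`** — global least-squares estimation of micro-rates over
  multiple curves (log-space parameters, fixed k1, per-curve S0, sparse
  finite-difference Jacobian), grid-search initialization, covariance and
  residual-resampling bootstrap standard errors.
- **`nmrkin.report`** — nested-model F-tests with an in-package regularized
  incomplete beta function, condition summaries (apparent + exchange
  parameters with delta-method or bootstrap errors), limiting-rate overlays,
  and the configuration-driven pipeline.

Units throughout: time s, concentration uM, first-order rates 1/s, k1 in
1/(s*uM).

## Command line

```sh
# generate noisy synthetic curves (and optional spectra) for one condition
nmrkin simulate --condition APO --reaction demethylation --seed 1 --out-dir sim/

# quantify a pseudo-2D spectral series into concentrations
nmrkin quantify sim/spectra_S0_300uM.tsv --peaks peaks.yaml \
    --reference-amplitude 3300 --reference-concentration 330 --out curve.tsv

# fit a configuration (fixture- or file-based), then compare/summarize
nmrkin fit config.yaml --out-dir fit_full/
nmrkin compare fit_restricted/report.json fit_full/report.json
nmrkin report fit_full/report.json --out summary.tsv
```

A minimal fit configuration:

```yaml
label: APO
fixture: {condition: APO, reaction: demethylation, seed: 2}
free_rates: [kcat_E, kES_fwd, kES_rev]
sigma: 1.0
```

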