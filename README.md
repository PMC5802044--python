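# tdfspec

Analysis of time-resolved and steady-state fluorescence of
polarity-sensitive membrane probes (laurdan, di-4-ANEPPDHQ): TCSPC decay
fitting by iterative reconvolution, time-resolved emission spectra (TRES)
reconstruction, time-dependent fluorescence shift (TDFS) observables, and
generalized polarization (GP) spectroscopy and imaging — plus a
synthetic-data generator with known ground truth for validating the whole
chain.

## Who this is for

Membrane biophysicists and fluorescence spectroscopists who record
per-wavelength TCSPC decays of environment-sensitive dyes in liposomes,
GPMVs or cells and want a tested, scriptable implementation of the
standard solvent-relaxation analysis instead of vendor black boxes.

## The science in brief

After excitation, the polar environment of a membrane probe reorients
around its new dipole moment, continuously red-shifting the emission band
ν(t). Reconstructing the time-resolved emission spectra from
per-wavelength decay fits D_k(t) normalized by the steady-state spectrum,

    I(λ_k, t) = D_k(t) · S(λ_k) / ∫₀^∞ D_k(t′) dt′ ,

and band-fitting each time slice yields the band maximum ν_max(t) and
width Γ(t), from which the package computes

* Δν = ν(0) − ν(∞) — total fluorescence shift, a polarity (hydration)
  measure; ν(0) via the Fee–Maroncelli time-zero estimate, ν(∞) from the
  trajectory asymptote;
* τ_r = ∫₀^∞ (ν(t) − ν(∞))/Δν dt — integrated relaxation time, a mobility
  measure;
* the times at which Γ(t) passes through transient maxima — a relaxation-
  time proxy usable when ν(0) is unavailable (e.g. dyes insoluble in
  non-polar solvents), including the multi-maximum case of heterogeneous
  probes;
* GP = (I_blue − I_red)/(I_blue + I_red) from spectra (440/490 nm for
  laurdan, 560/650 nm for di-4-ANEPPDHQ) and per-pixel GP maps with
  per-phase spectra from spectral image stacks of phase-separated
  vesicles.

See `docs/methods.md` for models, estimators, defaults and limitations.

## Worked example

Simulate a laurdan-like POPC liposome measurement at 23 °C (16 wavelengths
400–550 nm, 78 ps IRF, 5000 peak counts) and run the full analysis:

```sh
tdfspec run --dye laurdan --scenario popc-23C --seed 1 --out out/
```

prints

```
nu(inf) = 20993 cm^-1
Delta nu = 4102 cm^-1
FWHM maximum at 1.11 ns (3744 cm^-1)
```

The scenario's ground truth is ν(∞) = 21000 cm⁻¹ and Δν = 4095 cm⁻¹ with a
width bump peaking at 1.06 ns, so the pipeline recovered the relaxed-state
energy within 7 cm⁻¹, the total shift within 8 cm⁻¹ and the width-maximum
time within 0.05 ns. `out/` holds every intermediate: simulated decays and
IRF (TSV), the steady-state spectrum, per-wavelength fit reports (YAML),
the TRES surface, the ν_max/Γ trajectory, and the relaxation result
(JSON). The same stages are available individually (`tdfspec simulate`,
`fit-decays`, `tres`, `tdfs`, `gp-spectrum`, `gp-map`) and as library
functions:

```python
from tdfspec import scenario_config, run_pipeline

result = run_pipeline(scenario_config("di4", "popcchol-23C", seed=1))
result.relaxation.nu_infinity        # asymptote of the band trajectory
result.relaxation.nu_zero_available  # False: no non-polar reference spectra
result.relaxation.fwhm_maxima        # [(time_ns, width_cm1), ...]
```

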