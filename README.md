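# aggphot

Quantitative photophysics for aggregated near-infrared-II (NIR-II,
900–1700 nm) fluorophores — the analysis chain used to characterize
organic-dye nanoparticles whose brightness is limited by
aggregation-caused quenching (ACQ).

When planar NIR-II dyes aggregate into nanoparticles, part of the
population forms close-packed **dimers** with red-shifted absorption and
emission, weak radiative decay, and an ultrafast intermolecular
nonradiative (interNR) quenching channel; the rest remain **monomers**
that carry the useful fluorescence. `aggphot` quantifies this monomer/dimer
balance and its downstream consequences:

- **Spectral decomposition** — Gaussian mixture fits of absorption/emission
  spectra into monomer and dimer bands; population weights are analytic
  area fractions w_i = a_i σ_i √(2π) / Σ_j a_j σ_j √(2π), with BIC-based
  band-count selection and water-fraction (f_w) titration analysis.
- **Relative quantum yield** — the dilution-series slope method,
  Φ_s = Φ_ref · (slope_s / slope_ref) · (η_s / η_ref)², with Beer–Lambert
  extinction ε = A/(c·l) and brightness B = ε·Φ (M⁻¹cm⁻¹).
- **Transient-absorption kinetics** — ground-state-bleach traces fit as a
  sum of exponentials convolved with a Gaussian instrument response
  (FWHM 120 fs) using the closed form
  (A/2)·exp(s²/2τ² − t′/τ)·erfc(s/√2τ − t′/√2s), optimized by variable
  projection; amplitude fractions |Aᵢ|/Σ|Aⱼ| are per-channel populations,
  classified into interNR / dimer-emission / monomer-fluorescence by τ.
- **In vivo image metrics** — vessel cross-section FWHM (Gaussian + linear
  baseline profile fit, FWHM = 2√(2 ln 2)·σ), ROI signal-to-background
  ratio, and tumor-uptake time courses.
- **Synthetic data** — seeded generators for every input (mixture spectra,
  titrations, dilution series, IRF-convolved traces, Gaussian-ridge vessel
  images, uptake series), with a named preset registry of study conditions,
  so the whole pipeline is testable without instrument or animal data.

## Worked example

Generate a synthetic aggregate-like emission spectrum (dimer area fraction
0.643, 1% noise) and decompose it:

```sh
$ aggphot synth np1s_emission --seed 7 --out fx
$ aggphot decompose --in fx/np1s_emission.csv --kind emission --n 2
{
  "bands": [
    {"center_nm": 939.56, "sigma_nm": 39.74, "area": 352.7, "label": "monomer", ...},
    {"center_nm": 1049.42, "sigma_nm": 60.34, "area": 648.2, "label": "dimer", ...}
  ],
  "weights": {"dimer": 0.6476, "monomer": 0.3524},
  "residual_rms": 0.0351
}
```

The two fitted bands sit at the monomer (~940 nm) and dimer (~1050 nm)
emission positions and the recovered dimer area fraction, 64.8%, matches
the generating truth of 64.3% to within the noise. Brightness is a direct
product:

```sh
$ aggphot brightness --epsilon 9.5e4 --phi 0.075
{"brightness_M1cm1": 7125.0, "epsilon_M1cm1": 95000.0, "phi": 0.075}
```

i.e. a nanoparticle with ε = 9.5×10⁴ M⁻¹cm⁻¹ and Φ = 7.5% has a NIR-II
brightness of 7125 M⁻¹cm⁻¹. An end-to-end run over all stages:

```sh
$ aggphot run --preset np3s_full --seed 1 --out report.json
```

From Python the same operations are plain functions:

```python
from aggphot import fit_gaussian_mixture
from aggphot.synthetic import gen_mixture_spectrum, preset

spec = fit_gaussian_mixture(gen_mixture_spectrum(preset("np1s_emission"), seed=7), 2)
print(spec.weights)   # {'monomer': 0.352..., 'dimer': 0.647...}
```

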