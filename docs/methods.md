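# Methods

This note documents the models behind each `aggphot` stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want recorded.

## Spectra and elementary numerics

Spectra are wavelength-indexed (nm) intensity records; absorption in OD,
emission in arbitrary counts. All interpolation is linear and all
integration trapezoidal with linearly interpolated window endpoints, which
makes band integrals exactly additive over adjacent windows and keeps every
operation testable against closed forms. Spectra are kept on the
wavelength axis throughout; the λ²-Jacobian correction required for
energy-domain lineshape analysis is deliberately omitted, since band areas
are only ever compared between bands fitted on the same axis. Readers
accept comma- or whitespace-separated two-column text with `#` comments,
sort by wavelength, and collapse duplicate wavelengths by mean; the writer
emits full-precision (17 significant digits) CSV so round-trips are exact
to 1e-12 relative. Emission integration for quantum-yield work uses the
900–1500 nm window of the measurement protocol.

## Gaussian spectral decomposition

**Model.** y(λ) = Σᵢ aᵢ·exp(−(λ−μᵢ)²/2σᵢ²) + b₀ + b₁λ. The linear
baseline is enabled by default for emission (NIR-II detector offsets) and
disabled for absorption. Population weights are analytic **area**
fractions, aᵢσᵢ√(2π) normalized over bands — areas, not amplitudes, count
photons. Weights sum to 1 within 1e-9 by construction.

**Priors.** Band centers are bounded to disjoint windows reflecting the
known band positions: emission monomer 900–980 nm / dimer 1000–1120 nm;
absorption monomer 720–800 nm / dimer 810–880 nm. σ is bounded to
[2, 200] nm to exclude delta-spike and plateau degeneracies; amplitudes
are non-negative. A fitted band is labelled by the window containing its
center; bands outside both windows are `unassigned`.

**Determinism.** Initialization is derived from the data, not an RNG: the
spectrum is smoothed with a 5-point moving average, the highest local
maximum inside each prior window seeds the center, σ seeds at a quarter of
the window width, and the amplitude seeds at the smoothed value at the
center seed. If the trust-region solver fails to converge, up to three
restarts are taken from a fixed jitter table (center shifts of ±25% of the
window width, σ scales 0.5/1.5/2). The same input therefore always yields
the same fit.

**Band-count selection** fits n = 1…max_components and minimizes
BIC = m·ln(RSS/m) + k·ln(m) with k = 3n (+2 with baseline); ties go to the
smaller n. For single-band fits the seed window is whichever labelled
window holds the stronger smoothed peak. Titration analysis applies
selection per spectrum and reports dimer weight 0 whenever one band is
selected, plus the 900–1500 nm integrated intensity.

**Open choices.** Whether measured-instrument Gaussian fits of this kind
include a baseline term is a judgement call; the default here (emission
yes, absorption no) is documented rather than claimed canonical. Two
dimer-fraction presets are carried (0.643 and 0.735) because published
decompositions of closely related nanoparticle preparations report both;
the `np1s_emission` preset uses 0.643 and the 0.735 value is kept as
`high_dimer_emission` without asserting which preparation owns it. The
`np3s_emission` preset uses a reduced fraction of 0.45 as a package
default for a low-aggregation particle, since no unambiguous printed value
exists for that emission decomposition.

## Quantum yield, extinction, brightness

The slope method regresses integrated emission on absorbance at the
excitation wavelength over ≥3 dilutions (absorbance capped at 0.2;
protocol targets ≤0.1 so inner-filter corrections are unnecessary) and
applies Φ_s = Φ_ref·(slope_s/slope_ref)·(η_s/η_ref)² against the IR-26
standard (Φ_ref = 0.5% in 1,2-dichloroethane). OLS uses a **free
intercept** by default — a constant emission background then cannot bias
the slope — with a through-origin flag for sensitivity checks. Slope
standard errors propagate to Φ in quadrature. Refractive-index defaults
(water 1.333, THF 1.407, DCE 1.444) live in a constants table and are
overridable per sample. Φ is a fraction internally; percent only at
display. Extinction is Beer–Lambert ε = A/(c·l); brightness is the product
ε·Φ, enforced as an invariant of the record type.

## IRF-convolved multi-exponential kinetics

**Model.** A ground-state-bleach trace at one representative probe
wavelength is Σᵢ (Aᵢ/2)·exp(s²/2τᵢ² − t′/τᵢ)·erfc(s/√2τᵢ − t′/√2s) + c,
t′ = t − t₀, s = FWHM/2√(2 ln 2), the exact Gaussian ⊗ exponential
convolution. Direct evaluation overflows once t′ ≫ s; the implementation
evaluates through erfcx (the scaled complementary error function), using
`½·erfcx(x)·exp(−t′²/2s²)` for x ≥ 0 and
`exp(s²/2τ² − t′/τ) − ½·erfcx(−x)·exp(−t′²/2s²)` for x < 0, whose
exponents are non-positive in their respective regions. The delta-IRF
limit and a brute-force numerical convolution both validate the closed
form to 1e-6.

**Fitting** is variable projection: log-τ's, t₀ (and log-FWHM when the
IRF is not fixed) are the nonlinear parameters; amplitudes and the
constant offset are solved by linear least squares at every residual
evaluation. τ is bounded to [0.05, 5000] ps; t₀ is initialized from the
half-rise of |signal| and bounded to ±max(5s, 2Δt, 0.2 ps) around that.
Starting τ's are the best n-subset (by projected linear residual) of an
8-point log grid from 2·median(Δt) to half the delay span — cheap because
each subset is one linear solve. Fits are unweighted (no noise model is
assumed); τ pairs collapsing within 10% raise a degeneracy warning
suggesting n−1. Component-count selection minimizes the same BIC with
k = 2n + 2 (+1 for a free IRF width).

**Classification** labels components by τ window: interNR < 2 ps ≤
dimer emission < 50 ps ≤ monomer fluorescence. The thresholds are config
values; the defaults bracket the observed constants (0.43–0.98 ps
interNR, 7.7–11.6 ps dimer emission, ≥134 ps monomer fluorescence).
`lifetime_consistency` compares the longest component against an
independently measured fluorescence lifetime with a default tolerance of
20%, accommodating the typical ~13% disagreement between
transient-absorption long components and TCSPC lifetimes.

## Imaging metrics

Pixels are 0-based with centers at integer coordinates; physical position
is index × pixel size. Line profiles sample at pixel-size steps along the
segment by bilinear interpolation, averaging an odd number of parallel
samples perpendicular to it. Vessel width comes from a Gaussian + linear
baseline fit; FWHM = 2√(2 ln 2)·σ is a derived property, so the ratio is
exact by construction, and fits whose amplitude falls below the residual
noise floor are rejected. SBR is the ratio of ROI means (an
amplitude-over-baseline variant can be derived from the profile fit);
being a ratio it is invariant under detector gain, as FWHM is under gain
and offset. Time courses are ROI means over geometry-matched images, peak
time by argmax.

## Synthetic generators

Each generator is a pure function of a frozen config plus an integer seed
(`numpy` Generator; derived per-item seeds use fixed offsets, never global
state), and its zero-noise output satisfies the defining closed form
exactly — which is what lets recovery tests measure estimator bias rather
than generator error.

Defaults encode the study conditions: emission bands at 940/1050 nm with
σ = 40/60 nm and absorption at 760/840 nm with σ = 25/20 nm (σ chosen as
realistic NIR-II widths; they are package choices, not measured values);
dilution series at absorbances 0.02–0.10 with the sample gain inverted
from the slope formula so the estimator is exact at zero noise; GSB delay
grids of 60 linear points over ±1 ps plus 120 log points to 1500 ps with a
120 fs IRF; vessel images of 128×128 px at 0.05 mm/px (a 0.25 mm vessel
spans 5 px) with Poisson shot noise plus Gaussian read noise (σ = 5
counts) over a 250-count background; and a gamma-shaped uptake model
I(t) = I_max·(t/t_peak)^a·exp(a(1 − t/t_peak)) peaking at 24 h with
a = 2 on the 0/6/12/24/36/48 h schedule. The titration schedule holds the
dimer fraction at 0 up to f_w = 0.1 and ramps linearly to 0.643 at
f_w = 1 while total intensity falls linearly by 70% — the aggregation
onset and quenching trends of a water-fraction series. Trace amplitude
fractions default to 0.60/0.30/0.10 (ascending τ) except where a printed
fraction exists (the 0.202 monomer-fluorescence share of the
low-aggregation preset, remainder split 2:1); the two-component solvent
preset uses 0.60/0.40.

**What the generators do not emulate:** asymmetric vibronic band shapes
(real spectra are not sums of pure Gaussians — the generator matches the
fitting model, not raw data), wavelength-dependent chirp or coherent
artifacts in TA traces, re-absorption and inner-filter effects in dilution
series, tissue scattering, depth attenuation, vessel curvature, and motion
in images. Passing recovery tests therefore demonstrate estimator
correctness under the assumed models, not robustness to every real-data
pathology.

## Problem sizes

Recovery statistics average over seeded replicates: 20 spectra for dimer
weights, 50 dilution-series pairs for Φ, 20 traces per kinetic preset, 10
vessel images for FWHM/SBR — enough to estimate means well inside the
tolerances while keeping the whole suite and the acceptance script in the
seconds-to-minutes range on one CPU.

## Known limitations

- Decomposition supports at most 4 Gaussian components and no vibronic
  progression or exciton-splitting lineshape theory.
- Kinetics fits a single probe wavelength; no global (wavelength-resolved)
  or target analysis, chirp correction, or anisotropy.
- Quantum yield is relative only; no integrating-sphere absolute mode.
- Imaging assumes straight vessels and axis-free ROIs; no segmentation,
  registration, or spectral unmixing.
- The BIC selectors assume approximately white residuals; strongly
  correlated noise would bias them toward extra components.
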