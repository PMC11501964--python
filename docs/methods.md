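# Methods

## Scope and model

The package analyzes two co-registered per-pixel measurements from
two-photon microscopy of tissue sections:

1. a **spectral stack** — nonnegative photon counts in ω uniformly spaced
   emission channels (default 16 channels, centers 447.5–635 nm, spacing
   12.5 nm, ±6.25 nm half-width);
2. a **decay stack** — TCSPC photon-arrival histograms over a fixed time
   window (default 12.5 ns, the repetition period of an 80 MHz excitation
   laser, split into 256 bins).

Three analysis channels are named: Ch 2 (460 nm) carries collagen SHG for
920 nm excitation, Ch 7 (522.5 nm) is the TPEF intensity maximum
(dominated by FAD), Ch 4 (485 nm) is the short-wavelength TPEF reference.
Channel indices are 1-based in all user-facing interfaces; arrays are
0-based internally.

## Spectral phasor

The per-pixel transform is the discrete first-harmonic Fourier projection
over the channel index k = 0…ω−1:

    G = Σ_k I_k cos(2πnk/ω) / Σ_k I_k
    S = Σ_k I_k sin(2πnk/ω) / Σ_k I_k

For a uniformly spaced channel grid this is the standard spectral-phasor
form: the wavelength-integral notation sometimes used for it reduces to
exactly this sum because the channel spacing Δλ cancels between numerator
and denominator. The phase origin is channel 1 (k = 0); any other origin
convention is a rigid rotation of the phasor plot and does not change
distances or gating topology. Default harmonic n = 1.

Consequences used as test invariants: the phasor of any nonnegative
spectrum is a convex combination of unit vectors (|phasor| ≤ 1); it is
invariant to intensity scaling; and a sum of two spectra lands on the
chord between their phasors at fractional position Σ I_B / Σ (I_A + I_B).

Zero-intensity pixels have no defined phasor and are masked invalid rather
than mapped to the origin, which would fabricate a cluster at (0, 0).
Gates are circles or polygons in (G, S); overlapping gates resolve by
declared order (first match wins), with an optional strict mode that
raises instead. Automated clustering is deliberately out of core: the
workflow this implements is manual gating, and `auto_gates` merely centers
circles on the known class phasors of a synthetic phantom (capping each
radius at 0.45× the nearest-neighbor distance so nearly coincident classes
produce unassigned pixels, not silent cross-labels).

## Lifetime fitting

The decay model is `I(t) = I0 (a1 e^(−t/τ1) + a2 e^(−t/τ2))` with
amplitudes parameterized as fractions (a2 = 1 − a1, scale in I0), so the
fit has four free parameters and the reduced χ² uses dof = T − 4.
Weighted least squares with Poisson weights (variance `max(counts, 1)`)
via `scipy.optimize.least_squares` with box bounds (a1 ∈ [0, 1], τ > 0).
Amplitudes are referenced to the excitation time t = 0.

- **IRF.** When an instrument-response kernel is supplied the model curve
  is convolved with it before comparison; otherwise bins before the
  histogram peak are excluded (tail fit). The synthetic IRF is a causal
  Gaussian (default FWHM 0.2 ns, centered 4σ after t = 0) normalized on
  the bin grid. Tail fits of IRF-blurred data carry a small, documented
  bias in the amplitude split; analyses of simulated data therefore fit
  with the known kernel.
- **Initialization.** τ2 from a log-linear fit of the tail half, τ1 from
  the early-time slope (clipped to τ2), equal amplitudes, I0 at the peak;
  overridable.
- **Canonicalization.** Estimates are reported with τ1 ≤ τ2; swapping
  component labels leaves the curve unchanged, so this is pure
  relabeling.
- **Guards.** Histograms under `min_photons` (default 100) raise a typed
  error at the single-fit level and are masked in image fits;
  non-convergence is reported honestly via the `converged` flag.
- `τ_mean = (a1 τ1 + a2 τ2)/(a1 + a2)` is invariant to amplitude
  rescaling and bounded by [τ1, τ2]. For truly monoexponential input the
  individual amplitudes are unidentifiable but τ_mean remains stable —
  this is tested as a contract.
- **Spatial binning.** `fit_image` pools each pixel with its (2r+1)²
  neighborhood (default r = 1), the usual TCSPC trade of resolution for
  photon statistics.

Standard errors come from the Gauss-Newton covariance `(JᵀJ)⁻¹ σ̂²`; they
are conditional on the model and the usual caveat about bound-active
solutions applies.

## Synthetic tissue generator

The generator defines the study conditions for all recovery tests.

- **Geometry.** Preset layouts: `two_band` (epidermis over dermis) and
  `bcc` (epidermis band, dermis, and a concentric tumor: NOIR outer ring,
  NEIR ring, IR core). Explicit label arrays are accepted.
- **Fluorophores.** Gaussian emission profiles sampled on the channel grid
  (FWHM 60 nm for the FAD-like species); an SHG-like species is a
  single-channel line at 460 nm with a 0.05 ns pseudo-lifetime. Decays are
  multi-exponential with amplitude fractions summing to 1.
- **Class models.** One FAD-like species per class with shared lifetimes
  τ1 = 0.4 ns (free) and τ2 = 2.4 ns (bound); contrasts are carried by the
  free fraction a1 and the emission center:

  | class | a1 | τ_mean (ns) | emission center (nm) | SHG |
  |---|---|---|---|---|
  | epidermis | 0.78 | 0.90 | 500 | – |
  | dermis (normal) | 0.80 | 0.80 | 500 | yes |
  | NOIR | 0.62 | 1.16 | 505 | yes |
  | NEIR | 0.68 | 1.04 | 510 | – |
  | IR | 0.52 | 1.36 | 515 | – |

  These encode the qualitative effect directions the analysis is expected
  to recover: normal tissue has the shortest τ_mean and the highest a1/a2;
  among lesion classes NEIR is shorter-lived than NOIR and IR; the red
  shift makes the Ch4/Ch7 ratio decrease normal → NOIR → NEIR → IR; SHG is
  present only where collagen is intact (dermis, NOIR), and the dermis
  collagen weight is solved so the *expected* SHG/TPEF ratio equals the
  NOIR one — normal vs NOIR should differ only by sampling noise, i.e. a
  true null contrast.
- **Noise.** Photon counts are Poisson with the class-mixture expectation;
  per-pixel brightness defaults are 1200–1600 photons. Optical blur,
  scattering, photobleaching, detector dark counts and incomplete-decay
  wrap-around (lifetimes comparable to the 12.5 ns window) are not
  modeled; recovery results on phantoms therefore bound what is achievable
  on real tissue from counting statistics alone, not from optical
  confounds.
- **Spectral gating of decays.** Lifetimes in the real workflow are
  measured on the peak TPEF channel (Ch 7); `render_decay_stack(...,
  channel=7)` reproduces this by weighting each species by its emission in
  that channel, which removes SHG contamination from the decay. In the
  default ungated mode the expected total photons per pixel equal the
  summed weighted brightness.
- All randomness flows through explicit `numpy` Generator seeds; derived
  seeds come from `SeedSequence` spawning.

## Region classification

Deterministic, mutually exclusive rules on congruent maps: inside the
tumor-boundary mask with τ_mean ≥ τ_long → IR; outside the boundary with
SHG present → NOIR; remaining pixels with τ_mean ≤ τ_short → NEIR; else
unassigned. The boundary mask is an input (boundaries are expert-drawn in
practice); "SHG present" defaults to exceeding the 90th percentile of the
SHG-channel image. The lifetime thresholds have no canonical values and
must be calibrated per dataset; the defaults (τ_long = 1.26 ns, τ_short =
1.10 ns) are midpoints between adjacent synthetic class lifetimes and are
meaningful only for the shipped phantoms.

## Group statistics

The statistical unit is a field of view, never a pixel (pixels within a
field are strongly correlated; pixel-level inference would be
pseudo-replicated). `fov_study` renders n = 8 independent fields per group
by default (group sizes behind the original bar charts are unknown, so
this is a package choice) and reduces each to four scalars: τ_mean and
a1/a2 from one fit of the field-aggregated Ch 7-gated histogram, and the
two spectral ratios from the field-integrated spectrum. Inference is
one-way ANOVA (`scipy.stats.f_oneway`) plus Tukey HSD
(`scipy.stats.tukey_hsd`); star labels are `****` p < 10⁻⁵, `***` to
10⁻⁴, `**` to 10⁻², `*` to 0.05, `ns` otherwise, with boundary values in
the less-significant bin. Undefined ratios (zero denominator) are recorded
as missing and dropped with a warning, never as infinities.

## Numerical and design choices

- Wavelength → RGB uses a documented piecewise-linear visible-spectrum
  approximation; it affects display only, never statistics.
- Spectrally encoded images are frame-normalized (invariant to global
  intensity scaling); lifetime-coded images use the continuous `turbo`
  colormap over a clipped range with intensity-weighted value.
- Stitching assumes known grid positions (default 20% overlap) and blends
  overlap zones by separable linear feathering normalized by accumulated
  weight, so constants are preserved exactly; no registration search is
  performed.
- TIFF (page per channel/time bin) with JSON sidecars is the interchange
  format; proprietary TCSPC vendor formats are an extension point.
- Problem sizes in the test suite (frames of 20–110 px, 64–256 time bins,
  8 fields of view, 200 fit replicates) are chosen so the whole suite
  completes in well under a minute per module while keeping every
  statistical margin at ≥3σ.

## Known limitations

- Biexponential fits on mixtures of more than two decay components return
  effective parameters; only τ_mean is then interpretable.
- The phasor phase origin and gate geometry are conventions; gates drawn
  under one convention do not transfer to another.
- Recovery rates quoted by the tests are for Poisson-limited synthetic
  data and are upper bounds on real-tissue performance.
- Incomplete-decay wrap-around at 80 MHz is unmodeled; lifetimes above
  ~1/10 of the window trigger a warning at render time but real long-lived
  species would bias fits.
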