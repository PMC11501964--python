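# phasorflim

Analysis pipeline for multidimensional two-photon imaging of skin tissue:
spectral phasor segmentation, biexponential fluorescence-lifetime (FLIM)
fitting, spectral ratio statistics, and tumor-region classification —
plus a synthetic-tissue generator that provides ground truth for every
stage.

## Who this is for

Label-free two-photon microscopes can record, for every pixel, both a
16-channel emission spectrum (447.5–635 nm in 12.5 nm steps) and a TCSPC
photon-arrival histogram over the 12.5 ns window set by an 80 MHz
excitation laser. This package turns those two per-pixel measurements into
the quantities used to delineate basal cell carcinoma (BCC): invasive
(IR), near-invasive (NEIR) and non-invasive (NOIR) tumor regions are told
apart by their mean fluorescence lifetime, the presence of collagen
second-harmonic generation (SHG), and two spectral ratios. Since no public
patient data accompany the method, a first-class simulator renders
phantoms with known class layouts, Gaussian emission spectra, biexponential
decays and Poisson photon noise, so every operation can be validated by
recovery of ground truth.

## The core quantities

**Spectral phasor.** Each pixel's spectrum `I_k` (k = 0…ω−1 channels) maps
to a point in the unit disk via the first Fourier harmonic,

    G = Σ I_k cos(2πnk/ω) / Σ I_k,    S = Σ I_k sin(2πnk/ω) / Σ I_k,

with harmonic n = 1 by default. Similar spectra cluster; geometric gates
drawn in (G, S) segment the image without prior spectral knowledge.

**Biexponential FLIM.** Per-pixel decays follow

    I(t) = I0 (a1 e^(−t/τ1) + a2 e^(−t/τ2)),

with the amplitude-weighted mean lifetime
`τ_mean = (a1 τ1 + a2 τ2)/(a1 + a2)` as a metabolic readout and `a1/a2`
as the free-to-bound fluorophore fraction ratio (FAD). Fitting is
Poisson-weighted least squares, optionally IRF-convolved.

**Spectral ratios.** From a region's integrated spectrum:
`SHG/TPEF = Ch2/Ch7` (460/522.5 nm — collagen integrity) and the
`TPEF spectral ratio = Ch4/Ch7` (485/522.5 nm — spectral blue/red shift).

**Statistics.** Per-field-of-view summaries are compared by one-way ANOVA
and Tukey's HSD with the conventional star labels.

## Worked example

```python
import numpy as np
from phasorflim import (AcquisitionConfig, fit_decay, make_phantom,
                        render_decay_stack, render_spectral_stack,
                        extract_region_spectrum, tpef_spectral_ratio,
                        TissueClass)
from phasorflim.simulate import gaussian_irf

acq = AcquisitionConfig()                       # 16 channels, 256 bins / 12.5 ns
phantom = make_phantom("bcc", seed=7, shape=(64, 64))
stack = render_spectral_stack(phantom, acq, seed=7)
decay = render_decay_stack(phantom, acq, seed=8,
                           channel=acq.channel_map.tpef_max_channel)

ir_mask = phantom.label_map == TissueClass.IR
spectrum = extract_region_spectrum(stack, ir_mask)
print("IR TPEF spectral ratio (Ch4/Ch7):",
      round(tpef_spectral_ratio(spectrum, acq.channel_map), 3))

irf = gaussian_irf(acq.irf_fwhm, acq)
hist = decay[ir_mask].sum(axis=0)
fit = fit_decay(hist, acq.bin_width, irf=irf)
print(fit.summary())
```

prints

```
IR TPEF spectral ratio (Ch4/Ch7): 0.529
Biexponential decay fit
==============================================
photons                  78146
converged                 True
reduced chi2            1.0693
----------------------------------------------
I0                        2822       38.24
a1                      0.5091    0.007587
tau1 (ns)               0.3897     0.01647
a2                      0.4909    0.007587
tau2 (ns)                2.354     0.01589
----------------------------------------------
tau_mean (ns)            1.354
```

The invasive-region phantom was built with a free-FAD fraction a1 = 0.52,
τ1 = 0.4 ns, τ2 = 2.4 ns — so τ_mean ≈ 1.36 ns and a Ch4/Ch7 ratio near
0.52 are the ground truth the fit and ratio recover. The reduced χ² near 1
says the Poisson-weighted fit is noise-consistent.

The full chain (simulate → phasor → gates → FLIM → encode → ratios →
regions → stats) runs from the command line:

```sh
phasorflim run --out results/demo
phasorflim stats --seed 1 --n-fov 8
```

and writes TIFF stacks, label maps, CSV tables and a JSON report, all
reproducible from the single config seed.

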