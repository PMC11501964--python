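"""Spectral phasor transform, histograms, and gating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phasorflim import (PhasorGate, apply_gates, make_phantom, phasor_field,
                        phasor_histogram, render_spectral_stack, segmented_rgb,
                        spectrum_to_phasor)
from phasorflim.phasor import UNASSIGNED
from phasorflim.simulate import (AcquisitionConfig, FluorophoreModel,
                                 TissueClass)

spectra = arrays(np.float64, 16, elements=st.floats(0.0, 1e4)).filter(
    lambda s: s.sum() > 1e-6)


def test_flat_spectrum_maps_to_origin():
    g, s = spectrum_to_phasor(np.ones(16))
    assert abs(g) < 1e-12 and abs(s) < 1e-12


def test_delta_spectra_on_unit_circle():
    d = np.zeros(16)
    d[0] = 2.5
    assert spectrum_to_phasor(d) == pytest.approx((1.0, 0.0), abs=1e-12)
    d = np.zeros(16)
    d[4] = 1.0  # quarter turn: 2*pi*4/16 = pi/2
    assert spectrum_to_phasor(d) == pytest.approx((0.0, 1.0), abs=1e-12)
    d = np.zeros(16)
    d[0] = d[8] = 1.0  # antipodal deltas cancel
    assert spectrum_to_phasor(d) == pytest.approx((0.0, 0.0), abs=1e-12)


def test_zero_spectrum_rejected():
    with pytest.raises(ValueError):
        spectrum_to_phasor(np.zeros(16))
    with pytest.raises(ValueError):
        spectrum_to_phasor(np.ones(1))


@settings(derandomize=True, max_examples=100)
@given(spectra, st.floats(1e-6, 1e6))
def test_phasor_scale_invariant_and_bounded(spec, c):
    g, s = spectrum_to_phasor(spec)
    assert g * g + s * s <= 1 + 1e-9
    gc, sc = spectrum_to_phasor(c * spec)
    assert (gc, sc) == pytest.approx((g, s), abs=1e-9)


@settings(derandomize=True, max_examples=100)
@given(spectra, spectra)
def test_phasor_mixture_linearity(sa, sb):
    """phasor(A+B) sits on the chord at fractional position sum(B)/sum(A+B)."""
    pa = np.array(spectrum_to_phasor(sa))
    pb = np.array(spectrum_to_phasor(sb))
    f = sb.sum() / (sa.sum() + sb.sum())
    pm = np.array(spectrum_to_phasor(sa + sb))
    assert np.allclose(pm, (1 - f) * pa + f * pb, atol=1e-12)


def test_field_matches_per_pixel_oracle(rng):
    """Vectorized field equals a brute-force per-pixel loop to 1e-12."""
    stack = rng.uniform(0, 100, size=(32, 32, 16))
    field = phasor_field(stack, harmonic=1)
    for i in range(0, 32, 5):
        for j in range(0, 32, 7):
            g, s = spectrum_to_phasor(stack[i, j])
            assert field.g[i, j] == pytest.approx(g, abs=1e-12)
            assert field.s[i, j] == pytest.approx(s, abs=1e-12)
    # full oracle over every pixel
    ks = np.arange(16)
    ph = 2 * np.pi * ks / 16
    g_ref = np.empty((32, 32))
    s_ref = np.empty((32, 32))
    for i in range(32):
        for j in range(32):
            tot = stack[i, j].sum()
            g_ref[i, j] = np.sum(stack[i, j] * np.cos(ph)) / tot
            s_ref[i, j] = np.sum(stack[i, j] * np.sin(ph)) / tot
    assert np.allclose(field.g, g_ref, atol=1e-12)
    assert np.allclose(field.s, s_ref, atol=1e-12)


def test_field_masks_zero_pixels():
    stack = np.zeros((4, 4, 16))
    field = phasor_field(stack)
    assert not field.valid_mask.any()
    assert np.isnan(field.g).all()
    stack[1, 2, 3] = 5.0
    field = phasor_field(stack)
    assert field.valid_mask.sum() == 1
    # spatially uniform stack -> one shared coordinate
    uniform = np.tile(np.linspace(1, 2, 16), (4, 4, 1))
    field = phasor_field(uniform)
    assert np.ptp(field.g) < 1e-15 and np.ptp(field.s) < 1e-15


def test_histogram_conserves_counts(rng):
    stack = rng.uniform(0, 10, size=(16, 16, 16))
    stack[:4] = 0.0
    field = phasor_field(stack)
    counts, _, _ = phasor_histogram(field, n_bins=64)
    assert counts.sum() == field.valid_mask.sum()
    uniform = np.tile(np.linspace(1, 2, 16), (8, 8, 1))
    counts, _, _ = phasor_histogram(phasor_field(uniform), n_bins=32)
    assert (counts > 0).sum() == 1
    with pytest.raises(ValueError):
        phasor_histogram(field, n_bins=1)


def test_histogram_modes_match_analytic_phasors(acq):
    """Two well-separated species produce modes at their analytic phasors."""
    fa = FluorophoreModel("a", 470.0, 40.0, brightness=2e4)
    fb = FluorophoreModel("b", 580.0, 40.0, brightness=2e4)
    cmap = acq.channel_map
    layout = np.ones((32, 32), dtype=np.int32)
    layout[16:] = 2
    phantom = make_phantom(layout=layout,
                           class_models={1: [(fa, 1.0)], 2: [(fb, 1.0)]},
                           seed=0)
    stack = render_spectral_stack(phantom, acq, seed=5)
    n_bins = 40
    counts, ge, se = phasor_histogram(phasor_field(stack), n_bins=n_bins)
    bin_w = 2.0 / n_bins
    modes = []
    for _ in range(2):  # two largest well-separated modes
        i, j = np.unravel_index(np.argmax(counts), counts.shape)
        modes.append((ge[i] + bin_w / 2, se[j] + bin_w / 2))
        counts[max(i - 2, 0):i + 3, max(j - 2, 0):j + 3] = 0
    for fluor in (fa, fb):
        g, s = spectrum_to_phasor(fluor.emission_profile(cmap))
        dist = min(max(abs(mg - g), abs(ms - s)) for mg, ms in modes)
        assert dist <= bin_w


def test_gate_geometry_and_precedence():
    uniform = np.tile(np.linspace(1, 2, 16), (4, 4, 1))
    field = phasor_field(uniform)
    disk = PhasorGate(label=1, shape="circle", center=(0, 0), radius=1.01)
    labels = apply_gates(field, [disk])
    assert np.all(labels == 1)
    far = PhasorGate(label=2, shape="circle", center=(5, 5), radius=0.1)
    assert np.all(apply_gates(field, [far]) == UNASSIGNED)
    # first match wins for overlapping gates; strict mode raises
    labels = apply_gates(field, [disk, PhasorGate(label=3, shape="circle",
                                                  center=(0, 0), radius=1.01)])
    assert np.all(labels == 1)
    with pytest.raises(ValueError):
        apply_gates(field, [disk, PhasorGate(label=3, shape="circle",
                                             center=(0, 0), radius=1.01)],
                    strict=True)
    with pytest.raises(ValueError):
        apply_gates(field, [])


def test_polygon_gate_contains_square():
    square = PhasorGate(label=1, shape="polygon",
                        vertices=[(-0.5, -0.5), (0.5, -0.5), (0.5, 0.5),
                                  (-0.5, 0.5)])
    g = np.array([0.0, 0.9, np.nan])
    s = np.array([0.0, 0.0, 0.0])
    assert square.contains(g, s).tolist() == [True, False, False]
    with pytest.raises(ValueError):
        PhasorGate(label=1, shape="polygon", vertices=[(0, 0), (1, 1)])


def test_gating_recovers_two_fluorophore_phantom(acq):
    """Disjoint gates around analytic phasors: >=99% pixel accuracy."""
    fa = FluorophoreModel("a", 497.5, 50.0, brightness=2e4)
    fb = FluorophoreModel("b", 522.5, 50.0, brightness=2e4)  # 2 channels apart
    cmap = acq.channel_map
    layout = np.ones((64, 64), dtype=np.int32)
    layout[32:] = 2
    phantom = make_phantom(layout=layout,
                           class_models={1: [(fa, 1.0)], 2: [(fb, 1.0)]},
                           seed=0)
    stack = render_spectral_stack(phantom, acq, seed=6)
    pa = spectrum_to_phasor(fa.emission_profile(cmap))
    pb = spectrum_to_phasor(fb.emission_profile(cmap))
    radius = 0.45 * np.hypot(pa[0] - pb[0], pa[1] - pb[1])
    gates = [PhasorGate(label=1, center=pa, radius=radius),
             PhasorGate(label=2, center=pb, radius=radius)]
    labels = apply_gates(phasor_field(stack), gates)
    assert np.mean(labels == phantom.label_map) >= 0.99


def test_segmented_rgb_contract(rng):
    stack = rng.uniform(1, 2, size=(8, 8, 16))
    gates = [PhasorGate(label=1, center=(0, 0), radius=1.0,
                        color=(0.2, 0.4, 0.8))]
    black = segmented_rgb(stack, np.zeros((8, 8), int), gates)
    assert np.all(black == 0)
    uniform = np.tile(np.linspace(1, 2, 16), (8, 8, 1))
    img = segmented_rgb(uniform, np.ones((8, 8), int), gates)
    assert np.ptp(img.reshape(-1, 3), axis=0).max() < 1e-12
    # doubling intensity preserves hue (color direction), scales value
    labels = np.ones((8, 8), int)
    i1 = segmented_rgb(stack, labels, gates)
    i2 = segmented_rgb(2 * stack, labels, gates)
    assert np.allclose(i1, i2)  # frame-normalized
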