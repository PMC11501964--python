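"""Synthetic phantoms and the Poisson forward model."""

import numpy as np
import pytest

from phasorflim import (AcquisitionConfig, FluorophoreModel, TissueClass,
                        fit_decay, gaussian_irf, make_phantom,
                        render_decay_stack, render_spectral_stack)
from phasorflim.simulate import default_class_models


def test_two_band_partition():
    phantom = make_phantom("two_band", seed=0, shape=(64, 64))
    counts = phantom.class_counts()
    assert set(counts) == {int(TissueClass.EPIDERMIS), int(TissueClass.DERMIS)}
    assert sum(counts.values()) == 64 * 64


def test_phantom_determinism():
    a = make_phantom("bcc", seed=42, shape=(48, 48))
    b = make_phantom("bcc", seed=42, shape=(48, 48))
    assert np.array_equal(a.label_map, b.label_map)
    acq = AcquisitionConfig(n_time_bins=32)
    assert np.array_equal(render_spectral_stack(a, acq, seed=9),
                          render_spectral_stack(b, acq, seed=9))
    assert np.array_equal(render_decay_stack(a, acq, seed=9),
                          render_decay_stack(b, acq, seed=9))


def test_bcc_preset_has_all_five_classes():
    phantom = make_phantom("bcc", seed=1, shape=(128, 128))
    counts = phantom.class_counts()
    expected = {int(TissueClass.EPIDERMIS), int(TissueClass.DERMIS),
                int(TissueClass.NOIR), int(TissueClass.NEIR),
                int(TissueClass.IR)}
    assert set(counts) == expected
    total = sum(counts.values())
    for cls in expected:
        assert counts[cls] / total >= 0.01


def test_phantom_validation():
    with pytest.raises(ValueError):
        make_phantom("no_such_layout")
    layout = np.full((8, 8), 77, dtype=np.int32)
    with pytest.raises(ValueError):
        make_phantom(layout=layout)
    with pytest.raises(ValueError):
        FluorophoreModel("bad", 500.0, 50.0, components=((0.5, 1.0), (0.6, 2.0)))
    with pytest.raises(ValueError):
        FluorophoreModel("bad", 500.0, 50.0, components=((1.0, -2.0),))


def test_background_renders_zero():
    layout = np.zeros((8, 8), dtype=np.int32)
    phantom = make_phantom(layout=layout, seed=0)
    acq = AcquisitionConfig(n_time_bins=32)
    assert not render_spectral_stack(phantom, acq, seed=0).any()
    assert not render_decay_stack(phantom, acq, seed=0).any()


def test_spectral_poisson_mean(acq):
    """Per-pixel channel sums scatter around the brightness (5 sigma)."""
    fluor = FluorophoreModel("f", 520.0, 50.0, brightness=1e4)
    layout = np.ones((40, 40), dtype=np.int32)  # 1600 pixels
    phantom = make_phantom(layout=layout, class_models={1: [(fluor, 1.0)]},
                           seed=0)
    stack = render_spectral_stack(phantom, acq, seed=12)
    totals = stack.sum(axis=2)
    n = totals.size
    assert abs(totals.mean() - 1e4) <= 5 * np.sqrt(1e4 / n)


def test_mean_spectrum_matches_analytic(acq):
    """Law of large numbers: class mean spectrum within 1% over >=1e4 px."""
    layout = np.full((110, 110), int(TissueClass.DERMIS), dtype=np.int32)
    phantom = make_phantom(layout=layout, seed=0)
    stack = render_spectral_stack(phantom, acq, seed=13)
    mean = stack.reshape(-1, 16).mean(axis=0)
    analytic = phantom.expected_spectrum(int(TissueClass.DERMIS),
                                         acq.channel_map)
    assert np.allclose(mean, analytic, rtol=0.01, atol=0.01 * analytic.max())


def test_monoexponential_decay_is_geometric():
    """Noise-free single-exponential bins decay by exp(-dt/tau)."""
    acq = AcquisitionConfig(n_time_bins=64, irf_fwhm=0.0)
    fluor = FluorophoreModel("mono", 520.0, 50.0, components=((1.0, 1.5),),
                             brightness=1e4)
    layout = np.ones((2, 2), dtype=np.int32)
    phantom = make_phantom(layout=layout, class_models={1: [(fluor, 1.0)]},
                           seed=0)
    mean = render_decay_stack(phantom, acq, seed=0, noise=False)
    ratios = mean[0, 0, 1:] / mean[0, 0, :-1]
    assert np.allclose(ratios, np.exp(-acq.bin_width / 1.5), rtol=1e-9)
    # photon conservation in expectation
    assert mean[0, 0].sum() == pytest.approx(1e4, rel=1e-9)


def test_decay_round_trip_through_fit():
    """Rendered biexponential decays are recovered by the fitter."""
    acq = AcquisitionConfig(irf_fwhm=0.0)
    fluor = FluorophoreModel("fad", 520.0, 50.0,
                             components=((0.5, 0.5), (0.5, 2.5)),
                             brightness=1e5)
    layout = np.ones((5, 5), dtype=np.int32)
    phantom = make_phantom(layout=layout, class_models={1: [(fluor, 1.0)]},
                           seed=0)
    stack = render_decay_stack(phantom, acq, seed=21)
    errs = [abs(fit_decay(stack[i, j], acq.bin_width).tau_mean - 1.5) / 1.5
            for i in range(5) for j in range(5)]
    assert np.median(errs) <= 0.05


def test_unresolvable_lifetime_warns():
    acq = AcquisitionConfig(n_time_bins=32)
    slow = FluorophoreModel("slow", 520.0, 50.0,
                            components=((1.0, 200.0),), brightness=100.0)
    layout = np.ones((2, 2), dtype=np.int32)
    phantom = make_phantom(layout=layout, class_models={1: [(slow, 1.0)]},
                           seed=0)
    with pytest.warns(UserWarning, match="unresolvable"):
        render_decay_stack(phantom, acq, seed=0, noise=False)


def test_gaussian_irf_properties(acq):
    delta = gaussian_irf(0.0, acq)
    assert delta[0] == 1.0 and not delta[1:].any()
    for fwhm in (0.1, 0.3, 2 * acq.bin_width):
        kernel = gaussian_irf(fwhm, acq)
        assert kernel.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(kernel >= 0)
    with pytest.raises(ValueError):
        gaussian_irf(-0.1, acq)
    # moment check: sample std of the kernel matches sigma = fwhm/2.355
    fwhm = 10 * acq.bin_width  # well resolved on the grid
    kernel = gaussian_irf(fwhm, acq)
    t = acq.bin_centers
    mu = np.sum(kernel * t)
    std = np.sqrt(np.sum(kernel * (t - mu) ** 2))
    assert std == pytest.approx(fwhm / 2.355, rel=0.02)


def test_default_models_encode_study_contrasts(channel_map):
    """The shipped class models carry the intended effect directions."""
    models = default_class_models()

    def fad(cls):
        return models[int(cls)][0][0]

    tm = {c: fad(c).tau_mean() for c in (TissueClass.DERMIS, TissueClass.NOIR,
                                         TissueClass.NEIR, TissueClass.IR)}
    # normal shortest; NEIR below NOIR and IR; IR longest
    assert tm[TissueClass.DERMIS] < tm[TissueClass.NEIR] < tm[TissueClass.NOIR]
    assert tm[TissueClass.NOIR] < tm[TissueClass.IR]
    ar = {c: fad(c).amplitude_ratio() for c in tm}
    assert ar[TissueClass.DERMIS] == max(ar.values())
    assert ar[TissueClass.NEIR] > ar[TissueClass.IR]
    # expected SHG/TPEF identical for dermis and NOIR by construction
    from phasorflim import shg_tpef_ratio

    def spectrum(cls):
        out = np.zeros(channel_map.n_channels)
        for f, w in models[int(cls)]:
            out += w * f.brightness * f.emission_profile(channel_map)
        return out

    assert shg_tpef_ratio(spectrum(TissueClass.DERMIS), channel_map) == (
        pytest.approx(shg_tpef_ratio(spectrum(TissueClass.NOIR), channel_map),
                      rel=1e-9))
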