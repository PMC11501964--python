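"""Synthetic tissue phantoms and forward rendering of spectral/decay stacks.

The generator emulates the statistical structure of multichannel two-photon
tissue data so that every downstream operation can be exercised against
known ground truth:

* a **phantom** is an integer label map (epidermis, dermis, tumor
  NOIR/NEIR/IR rings, background) plus, per class, a mixture of
  fluorophore models;
* each **fluorophore** has a Gaussian emission profile sampled onto the
  spectral channel grid (an SHG-like species is a single-channel line at
  460 nm, where collagen second harmonic appears for 920 nm excitation)
  and a multi-exponential decay (amplitude fractions and lifetimes in ns);
* **rendering** draws per-pixel Poisson photon counts whose expectation is
  the class mixture's spectrum (spectral stack) or its IRF-convolved decay
  binned over the 12.5 ns window set by the 80 MHz repetition rate
  (decay stack).

Noise is Poisson only; optical blur, photobleaching, detector dark counts
and incomplete-decay wrap-around are deliberately not modeled.  All
randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np

from .channels import SpectralChannelMap

__all__ = [
    "TissueClass",
    "FluorophoreModel",
    "AcquisitionConfig",
    "TissuePhantom",
    "make_phantom",
    "default_class_models",
    "gaussian_irf",
    "render_spectral_stack",
    "render_decay_stack",
]


class TissueClass(IntEnum):
    """Phantom ground-truth classes."""

    BACKGROUND = 0
    EPIDERMIS = 1
    DERMIS = 2
    NOIR = 3
    NEIR = 4
    IR = 5


@dataclass(frozen=True)
class FluorophoreModel:
    """A fluorescent (or SHG-like) species in the forward model.

    ``emission_center``/``emission_fwhm`` define a Gaussian emission
    profile in nm sampled onto the channel grid; ``emission_fwhm = 0``
    gives a single-channel line at the nearest channel (SHG).
    ``components`` is a list of ``(amplitude_fraction, lifetime_ns)``
    pairs with fractions summing to 1.  ``brightness`` is the expected
    number of detected photons per pixel.
    """

    name: str
    emission_center: float
    emission_fwhm: float
    components: tuple = ((1.0, 2.0),)
    brightness: float = 1000.0

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(t)) for a, t in self.components)
        object.__setattr__(self, "components", comps)
        fractions = sum(a for a, _ in comps)
        if abs(fractions - 1.0) > 1e-9:
            raise ValueError("amplitude fractions must sum to 1")
        if any(a < 0 for a, _ in comps):
            raise ValueError("amplitude fractions must be nonnegative")
        if any(t <= 0 for _, t in comps):
            raise ValueError("lifetimes must be positive")
        if self.emission_fwhm < 0 or self.brightness < 0:
            raise ValueError("emission_fwhm and brightness must be >= 0")

    def emission_profile(self, cmap: SpectralChannelMap) -> np.ndarray:
        """Normalized (sum = 1) emission weights on the channel grid."""
        centers = cmap.centers
        if self.emission_fwhm == 0:
            profile = np.zeros(centers.size)
            profile[int(np.argmin(np.abs(centers - self.emission_center)))] = 1.0
            return profile
        sigma = self.emission_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        profile = np.exp(-0.5 * ((centers - self.emission_center) / sigma) ** 2)
        total = profile.sum()
        if total <= 0:
            raise ValueError("emission profile vanishes on the channel grid")
        return profile / total

    def tau_mean(self) -> float:
        """Ground-truth amplitude-weighted mean lifetime (ns)."""
        return sum(a * t for a, t in self.components)

    def amplitude_ratio(self) -> float:
        """a1/a2 for a two-component species (short/long ordering)."""
        comps = sorted(self.components, key=lambda c: c[1])
        if len(comps) != 2 or comps[1][0] == 0:
            raise ValueError("amplitude ratio defined for 2 components with a2 > 0")
        return comps[0][0] / comps[1][0]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Detector geometry and TCSPC timing.

    Defaults: 16 spectral channels 447.5–635 nm (12.5 nm spacing); a
    12.5 ns time window (the 80 MHz excitation repetition period) split
    into 256 bins; a Gaussian IRF of 0.2 ns FWHM.
    """

    n_channels: int = 16
    first_center: float = 447.5
    channel_spacing: float = 12.5
    time_window: float = 12.5
    n_time_bins: int = 256
    irf_fwhm: float = 0.2

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need >= 2 spectral channels")
        if self.n_time_bins < 8:
            raise ValueError("need >= 8 time bins")
        if self.time_window <= 0 or self.channel_spacing <= 0:
            raise ValueError("time_window and channel_spacing must be positive")
        if self.irf_fwhm < 0:
            raise ValueError("irf_fwhm must be >= 0")

    @property
    def channel_map(self) -> SpectralChannelMap:
        return SpectralChannelMap.from_grid(
            self.n_channels, self.first_center, self.channel_spacing
        )

    @property
    def bin_width(self) -> float:
        """TCSPC bin width in ns."""
        return self.time_window / self.n_time_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "first_center": self.first_center,
            "channel_spacing": self.channel_spacing,
            "time_window": self.time_window,
            "n_time_bins": self.n_time_bins,
            "irf_fwhm": self.irf_fwhm,
        }


@dataclass
class TissuePhantom:
    """Ground-truth label map plus per-class fluorophore mixtures."""

    label_map: np.ndarray
    class_models: Mapping[int, Sequence[tuple[FluorophoreModel, float]]]
    pixel_size: float = 0.62
    seed: int = 0

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=np.int32)
        present = set(np.unique(self.label_map).tolist())
        present.discard(int(TissueClass.BACKGROUND))
        missing = present - set(int(k) for k in self.class_models)
        if missing:
            raise ValueError(f"no fluorophore model for classes {sorted(missing)}")
        for cls, mixture in self.class_models.items():
            if len(mixture) == 0:
                raise ValueError(f"class {cls} has an empty mixture")
            if any(w < 0 for _, w in mixture):
                raise ValueError("mixture weights must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.label_map, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def expected_spectrum(self, cls: int, cmap: SpectralChannelMap) -> np.ndarray:
        """Expected photons per channel for one pixel of class ``cls``."""
        if cls == TissueClass.BACKGROUND:
            return np.zeros(cmap.n_channels)
        out = np.zeros(cmap.n_channels)
        for fluor, weight in self.class_models[cls]:
            out += weight * fluor.brightness * fluor.emission_profile(cmap)
        return out

    def expected_decay(self, cls: int, config: AcquisitionConfig,
                       channel: int | None = None) -> np.ndarray:
        """Expected photons per time bin for one pixel of class ``cls``.

        With ``channel = None`` every species contributes its full
        brightness (total expected photons per pixel equals the summed
        weighted brightness).  With a 1-based ``channel`` the decay is the
        spectrally gated measurement in that detection channel: each
        species is weighted by its emission there, which is how lifetimes
        are measured on the peak TPEF channel without SHG contamination.
        """
        if cls == TissueClass.BACKGROUND:
            return np.zeros(config.n_time_bins)
        t = config.bin_centers
        out = np.zeros(config.n_time_bins)
        kernel = (gaussian_irf(config.irf_fwhm, config)
                  if config.irf_fwhm > 0 else None)
        cmap = config.channel_map
        for fluor, weight in self.class_models[cls]:
            if channel is not None:
                weight = weight * fluor.emission_profile(cmap)[cmap.channel_index(channel)]
                if weight == 0:
                    continue
            decay = np.zeros_like(t)
            for frac, tau in fluor.components:
                if tau >= 10.0 * config.time_window:
                    warnings.warn(
                        f"lifetime {tau} ns unresolvable in a "
                        f"{config.time_window} ns window", stacklevel=2)
                decay += frac * np.exp(-t / tau)
            if kernel is not None:
                decay = np.convolve(decay, kernel)[: t.size]
            total = decay.sum()
            if total > 0:
                decay = decay / total
            out += weight * fluor.brightness * decay
        return out


def gaussian_irf(fwhm: float, config: AcquisitionConfig) -> np.ndarray:
    """Normalized Gaussian instrument-response kernel on the time-bin grid.

    The kernel is causal (centered a few sigma after t = 0) and sums to 1;
    ``fwhm = 0`` returns a discrete delta in the first bin.
    """
    if fwhm < 0:
        raise ValueError("IRF fwhm must be >= 0")
    n = config.n_time_bins
    kernel = np.zeros(n)
    if fwhm == 0:
        kernel[0] = 1.0
        return kernel
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = config.bin_centers
    center = 4.0 * sigma
    kernel = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return kernel / kernel.sum()


# ---------------------------------------------------------------------------
# default tissue optical models
# ---------------------------------------------------------------------------

# FAD-like biexponential: free fraction ~0.4 ns, protein-bound ~2.4 ns.
_TAU_FREE = 0.4
_TAU_BOUND = 2.4
_SHG = FluorophoreModel("collagen_shg", emission_center=460.0, emission_fwhm=0.0,
                        components=((1.0, 0.05),), brightness=800.0)


def _fad(name: str, center: float, a1: float, brightness: float) -> FluorophoreModel:
    return FluorophoreModel(name, emission_center=center, emission_fwhm=60.0,
                            components=((a1, _TAU_FREE), (1.0 - a1, _TAU_BOUND)),
                            brightness=brightness)


def default_class_models() -> dict[int, list[tuple[FluorophoreModel, float]]]:
    """Per-class fluorophore mixtures emulating the reported contrasts.

    Normal tissue (epidermis/dermis) has the highest free-FAD fraction
    (shortest tau_mean, highest a1/a2); tumor classes are red-shifted in
    emission in the order NOIR -> NEIR -> IR (so the Ch4/Ch7 ratio
    decreases normal -> NOIR -> NEIR -> IR) and carry progressively longer
    tau_mean (NEIR < NOIR < IR among lesion classes).  Collagen SHG is
    present in normal dermis and NOIR, absent in NEIR and IR where fibers
    are degraded; the dermis collagen weight is solved so the expected
    SHG/TPEF (Ch2/Ch7) ratio equals the NOIR one, since fibers are equally
    intact in both and only sampling noise should separate them.
    """
    cmap = SpectralChannelMap.default()
    fad_dermis = _fad("fad_dermis", 500.0, 0.80, 1200.0)
    fad_noir = _fad("fad_noir", 505.0, 0.62, 1400.0)
    i2, i7 = cmap.channel_index(2), cmap.channel_index(7)
    p_d, p_n = fad_dermis.emission_profile(cmap), fad_noir.emission_profile(cmap)
    noir_ratio = (fad_noir.brightness * p_n[i2] + _SHG.brightness) / (
        fad_noir.brightness * p_n[i7])
    dermis_shg_w = (noir_ratio * fad_dermis.brightness * p_d[i7]
                    - fad_dermis.brightness * p_d[i2]) / _SHG.brightness
    return {
        int(TissueClass.EPIDERMIS): [(_fad("fad_epidermis", 500.0, 0.78, 1500.0), 1.0)],
        int(TissueClass.DERMIS): [
            (fad_dermis, 1.0),
            (_SHG, dermis_shg_w),
        ],
        int(TissueClass.NOIR): [
            (fad_noir, 1.0),
            (_SHG, 1.0),
        ],
        int(TissueClass.NEIR): [(_fad("fad_neir", 510.0, 0.68, 1400.0), 1.0)],
        int(TissueClass.IR): [(_fad("fad_ir", 515.0, 0.52, 1600.0), 1.0)],
    }


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def _two_band_layout(shape: tuple[int, int]) -> np.ndarray:
    """Epidermis over dermis, split horizontally at 1/3 height."""
    h, w = shape
    labels = np.full(shape, int(TissueClass.DERMIS), dtype=np.int32)
    labels[: h // 3] = int(TissueClass.EPIDERMIS)
    return labels


def _bcc_layout(shape: tuple[int, int]) -> np.ndarray:
    """Epidermis band over dermis with a concentric tumor:
    IR core, NEIR ring, NOIR outer ring."""
    h, w = shape
    labels = _two_band_layout(shape)
    cy, cx = int(h * 0.62), int(w * 0.5)
    yy, xx = np.ogrid[:h, :w]
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    rmax = min(h, w) * 0.32
    labels[r <= rmax] = int(TissueClass.NOIR)
    labels[r <= rmax * 0.72] = int(TissueClass.NEIR)
    labels[r <= rmax * 0.45] = int(TissueClass.IR)
    return labels


_LAYOUTS = {"two_band": _two_band_layout, "bcc": _bcc_layout}


def make_phantom(layout="bcc", class_models=None, pixel_size=0.62,
                 seed=0, shape=(128, 128)) -> TissuePhantom:
    """Build a ground-truth phantom.

    ``layout`` is a preset name (``"two_band"``, ``"bcc"``) or an explicit
    integer label array; every pixel receives exactly one class.
    Deterministic for a fixed seed.
    """
    if isinstance(layout, str):
        if layout not in _LAYOUTS:
            raise ValueError(f"unknown layout preset {layout!r}")
        label_map = _LAYOUTS[layout](shape)
    else:
        label_map = np.asarray(layout, dtype=np.int32)
        if label_map.ndim != 2:
            raise ValueError("explicit layout must be a 2-D label array")
    if class_models is None:
        class_models = default_class_models()
    known = set(int(k) for k in class_models) | {int(TissueClass.BACKGROUND)}
    present = set(np.unique(label_map).tolist())
    if not present <= known:
        raise ValueError(f"layout contains unknown classes {sorted(present - known)}")
    return TissuePhantom(label_map=label_map, class_models=class_models,
                         pixel_size=pixel_size, seed=seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_spectral_stack(phantom: TissuePhantom, config: AcquisitionConfig,
                          seed: int, noise: bool = True) -> np.ndarray:
    """Render an (H, W, n_channels) Poisson photon-count spectral stack."""
    cmap = config.channel_map
    h, w = phantom.shape
    mean = np.zeros((h, w, cmap.n_channels))
    for cls in np.unique(phantom.label_map):
        mean[phantom.label_map == cls] = phantom.expected_spectrum(int(cls), cmap)
    if not noise:
        return mean
    rng = np.random.default_rng(seed)
    return rng.poisson(mean).astype(np.int64)


def render_decay_stack(phantom: TissuePhantom, config: AcquisitionConfig,
                       seed: int, noise: bool = True,
                       channel: int | None = None) -> np.ndarray:
    """Render an (H, W, n_time_bins) Poisson TCSPC decay stack.

    ``channel`` optionally restricts the measurement to one spectral
    channel (see :meth:`TissuePhantom.expected_decay`).
    """
    h, w = phantom.shape
    mean = np.zeros((h, w, config.n_time_bins))
    for cls in np.unique(phantom.label_map):
        mean[phantom.label_map == cls] = phantom.expected_decay(
            int(cls), config, channel=channel)
    if not noise:
        return mean
    rng = np.random.default_rng(seed)
    return rng.poisson(mean).astype(np.int64)
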