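"""Spectral channel geometry, RGB encoding, region spectra, and ratio statistics.

The detection path splits emission into a fixed grid of spectral channels
(by default 16 channels with centers from 447.5 nm to 635 nm in 12.5 nm
steps).  Channel indices in user-facing interfaces are 1-based to match the
conventional "Ch 7" naming; internal arrays are 0-based.

Two scalar statistics are defined on a region spectrum:

* ``shg_tpef_ratio`` — second-harmonic channel (Ch 2, 460 nm, collagen)
  divided by the peak two-photon fluorescence channel (Ch 7, 522.5 nm),
  a readout of collagen content relative to cellular autofluorescence.
* ``tpef_spectral_ratio`` — short-wavelength TPEF (Ch 4, 485 nm) divided by
  the peak TPEF channel (Ch 7), sensitive to spectral blue/red shifts of
  the endogenous fluorophore pool.

Both ratios are invariant under global intensity scaling.  A zero
denominator yields ``nan`` (recorded as undefined, never silent infinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralChannelMap",
    "wavelength_to_rgb",
    "spectral_encode",
    "extract_region_spectrum",
    "shg_tpef_ratio",
    "tpef_spectral_ratio",
]


@dataclass(frozen=True)
class SpectralChannelMap:
    """Uniform grid of spectral detection channels.

    Parameters
    ----------
    centers : array of float
        Channel center wavelengths in nm, strictly increasing and uniformly
        spaced.
    half_width : float
        Half bandwidth of each channel in nm (default ±6.25 nm).
    shg_channel, ratio_channel, tpef_max_channel : int
        1-based indices of the SHG channel (Ch 2), the short-wavelength TPEF
        ratio numerator (Ch 4), and the TPEF intensity maximum (Ch 7).
    """

    centers: np.ndarray
    half_width: float = 6.25
    shg_channel: int = 2
    ratio_channel: int = 4
    tpef_max_channel: int = 7

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("channel map needs at least 2 centers")
        diffs = np.diff(centers)
        if np.any(diffs <= 0):
            raise ValueError("channel centers must be strictly increasing")
        if np.max(np.abs(diffs - diffs[0])) > 1e-9:
            raise ValueError("channel centers must be uniformly spaced")

    @classmethod
    def default(cls) -> "SpectralChannelMap":
        """The 16-channel grid: 447.5–635 nm, 12.5 nm spacing."""
        return cls(centers=447.5 + 12.5 * np.arange(16))

    @classmethod
    def from_grid(
        cls, n_channels: int, first_center: float, spacing: float, **kwargs
    ) -> "SpectralChannelMap":
        return cls(centers=first_center + spacing * np.arange(n_channels), **kwargs)

    @property
    def n_channels(self) -> int:
        return int(self.centers.size)

    @property
    def spacing(self) -> float:
        return float(self.centers[1] - self.centers[0])

    def channel_center(self, k: int) -> float:
        """Center wavelength (nm) of 1-based channel ``k``."""
        if not 1 <= k <= self.n_channels:
            raise IndexError(
                f"channel {k} out of range 1..{self.n_channels}"
            )
        return float(self.centers[k - 1])

    def channel_index(self, k: int) -> int:
        """0-based array index for 1-based channel ``k``."""
        if not 1 <= k <= self.n_channels:
            raise IndexError(f"channel {k} out of range 1..{self.n_channels}")
        return k - 1


def wavelength_to_rgb(wavelength: float) -> np.ndarray:
    """Map a wavelength (nm) to an RGB triple in [0, 1]^3.

    Piecewise-linear approximation of the visible spectrum (380–780 nm,
    clipped outside); the standard hue progression
    violet → blue → cyan → green → yellow → orange → red with linear
    attenuation toward both ends of visibility.
    """
    w = float(np.clip(wavelength, 380.0, 780.0))
    if w < 440:
        r, g, b = -(w - 440) / (440 - 380), 0.0, 1.0
    elif w < 490:
        r, g, b = 0.0, (w - 440) / (490 - 440), 1.0
    elif w < 510:
        r, g, b = 0.0, 1.0, -(w - 510) / (510 - 490)
    elif w < 580:
        r, g, b = (w - 510) / (580 - 510), 1.0, 0.0
    elif w < 645:
        r, g, b = 1.0, -(w - 645) / (645 - 580), 0.0
    else:
        r, g, b = 1.0, 0.0, 0.0
    # intensity falloff near the edges of visibility
    if w < 420:
        f = 0.3 + 0.7 * (w - 380) / (420 - 380)
    elif w > 700:
        f = 0.3 + 0.7 * (780 - w) / (780 - 700)
    else:
        f = 1.0
    return np.array([r * f, g * f, b * f])


def channel_colors(cmap: SpectralChannelMap) -> np.ndarray:
    """RGB color of every channel, shape (omega, 3)."""
    return np.stack([wavelength_to_rgb(c) for c in cmap.centers])


def spectral_encode(stack: np.ndarray, cmap: SpectralChannelMap) -> np.ndarray:
    """Spectrally encoded color image of an (H, W, omega) stack.

    Each channel's grayscale image is multiplied by that channel's RGB
    color, the colored layers are summed, and the result is normalized to
    [0, 1] by the frame maximum.  An all-zero stack maps to black.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[2] != cmap.n_channels:
        raise ValueError(
            f"stack shape {stack.shape} does not match {cmap.n_channels} channels"
        )
    rgb = stack @ channel_colors(cmap)
    peak = rgb.max()
    if peak > 0:
        rgb /= peak
    return rgb


def extract_region_spectrum(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Channel-wise integrated counts over a boolean region mask."""
    stack = np.asarray(stack)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape[:2]:
        raise ValueError("mask shape does not match stack")
    if not mask.any():
        raise ValueError("region mask is empty")
    return stack[mask].sum(axis=0)


def _channel_ratio(spectrum: np.ndarray, cmap: SpectralChannelMap,
                   num_ch: int, den_ch: int) -> float:
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (cmap.n_channels,):
        raise ValueError("spectrum length does not match channel map")
    den = spectrum[cmap.channel_index(den_ch)]
    if den <= 0:
        return float("nan")
    return float(spectrum[cmap.channel_index(num_ch)] / den)


def shg_tpef_ratio(spectrum: np.ndarray, cmap: SpectralChannelMap) -> float:
    """SHG/TPEF ratio: Ch 2 counts over Ch 7 counts (nan if Ch 7 is zero)."""
    return _channel_ratio(spectrum, cmap, cmap.shg_channel, cmap.tpef_max_channel)


def tpef_spectral_ratio(spectrum: np.ndarray, cmap: SpectralChannelMap) -> float:
    """TPEF spectral ratio: Ch 4 counts over Ch 7 counts (nan if Ch 7 is zero)."""
    return _channel_ratio(spectrum, cmap, cmap.ratio_channel, cmap.tpef_max_channel)
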