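"""Spectral phasor transform, phasor histograms, and geometric gating.

Each pixel's emission spectrum I_k (k = 0..omega-1 over the channel grid)
is mapped to a point in the unit disk by the first Fourier coefficient:

    G = sum_k I_k cos(2*pi*n*k/omega) / sum_k I_k
    S = sum_k I_k sin(2*pi*n*k/omega) / sum_k I_k

with harmonic n (default 1).  Because every channel contributes a unit
vector on the circle weighted by its nonnegative intensity, the phasor of
any spectrum is a convex combination of points on the unit circle: it lies
inside the unit disk, is invariant to intensity scaling, and mixtures fall
on the chord between the component phasors.  Similar spectra cluster
together in (G, S), so structures can be segmented by drawing geometric
gates (circles or polygons) in phasor space and back-projecting the gate
labels onto the image.

Zero-intensity pixels have no defined phasor; they are masked invalid and
never mapped to the origin (which would fabricate a cluster at (0, 0)).
The phase origin is channel 1 (k = 0); a different origin convention only
rotates the phasor plot rigidly and does not affect gating topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib.path import Path

UNASSIGNED = 0

__all__ = [
    "PhasorField",
    "PhasorGate",
    "spectrum_to_phasor",
    "phasor_field",
    "phasor_histogram",
    "apply_gates",
    "segmented_rgb",
    "UNASSIGNED",
]


def _phases(n_channels: int, harmonic: int) -> np.ndarray:
    if n_channels < 2:
        raise ValueError("need at least 2 spectral channels")
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    k = np.arange(n_channels)
    return 2.0 * np.pi * harmonic * k / n_channels


def spectrum_to_phasor(spectrum: np.ndarray, harmonic: int = 1) -> tuple[float, float]:
    """Phasor coordinates (G, S) of a single nonnegative spectrum.

    Raises ``ValueError`` on an all-zero spectrum; at field level such
    pixels are masked instead (see :func:`phasor_field`).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1:
        raise ValueError("spectrum must be 1-D")
    total = spectrum.sum()
    if total <= 0:
        raise ValueError("phasor undefined for an all-zero spectrum")
    phase = _phases(spectrum.size, harmonic)
    g = float(spectrum @ np.cos(phase) / total)
    s = float(spectrum @ np.sin(phase) / total)
    return g, s


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates of a spectral stack.

    ``g`` and ``s`` are (H, W) arrays (nan where invalid),
    ``total_intensity`` the per-pixel channel sum, and ``valid_mask`` is
    False wherever the total intensity is zero.
    """

    g: np.ndarray
    s: np.ndarray
    total_intensity: np.ndarray
    harmonic: int
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape


def phasor_field(stack: np.ndarray, harmonic: int = 1) -> PhasorField:
    """Apply the phasor transform to every pixel of an (H, W, omega) stack."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (H, W, n_channels)")
    if np.any(stack < 0):
        raise ValueError("spectral stack must be nonnegative")
    phase = _phases(stack.shape[2], harmonic)
    total = stack.sum(axis=2)
    valid = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (stack @ np.cos(phase)) / total
        s = (stack @ np.sin(phase)) / total
    g[~valid] = np.nan
    s[~valid] = np.nan
    return PhasorField(g=g, s=s, total_intensity=total,
                       harmonic=harmonic, valid_mask=valid)


def phasor_histogram(field: PhasorField, n_bins: int = 128) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of valid phasor points over [-1, 1]^2.

    Returns ``(counts, g_edges, s_edges)``; counts sum to the number of
    valid pixels.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    g = field.g[field.valid_mask]
    s = field.s[field.valid_mask]
    counts, ge, se = np.histogram2d(g, s, bins=n_bins, range=[[-1, 1], [-1, 1]])
    return counts, ge, se


@dataclass
class PhasorGate:
    """A geometric gate in phasor space.

    ``shape`` is ``"circle"`` (center ``(g, s)``, ``radius``) or
    ``"polygon"`` (``vertices`` as an (m, 2) list in (G, S)).  ``label``
    must be a nonzero integer unique within a gate set; label 0 is reserved
    for UNASSIGNED.  ``color`` is an RGB triple for back-projection.
    """

    label: int
    shape: str = "circle"
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 0.0
    vertices: Sequence[tuple[float, float]] | None = None
    color: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = ""

    def __post_init__(self) -> None:
        if self.label == UNASSIGNED:
            raise ValueError("gate label 0 is reserved for UNASSIGNED")
        if self.shape == "circle":
            if not self.radius > 0:
                raise ValueError("circle gate needs radius > 0")
        elif self.shape == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError("polygon gate needs >= 3 vertices")
        else:
            raise ValueError(f"unknown gate shape {self.shape!r}")

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Boolean membership of points (g, s); nan points are outside."""
        g = np.asarray(g, dtype=float)
        s = np.asarray(s, dtype=float)
        if self.shape == "circle":
            cg, cs = self.center
            with np.errstate(invalid="ignore"):
                # nan (invalid pixel) compares False -> outside
                return (g - cg) ** 2 + (s - cs) ** 2 <= self.radius**2
        pts = np.column_stack([g.ravel(), s.ravel()])
        finite = np.isfinite(pts).all(axis=1)
        inside = np.zeros(pts.shape[0], dtype=bool)
        if finite.any():
            inside[finite] = Path(np.asarray(self.vertices, float)).contains_points(pts[finite])
        return inside.reshape(g.shape)


def apply_gates(field: PhasorField, gates: Sequence[PhasorGate],
                strict: bool = False) -> np.ndarray:
    """Label each valid pixel with the first gate containing its phasor.

    Gates are tested in order; the first match wins (the declared order is
    the precedence).  With ``strict=True`` a pixel falling inside two gates
    raises instead.  Invalid pixels and pixels in no gate get UNASSIGNED.
    """
    if not gates:
        raise ValueError("need at least one gate")
    labels = [gt.label for gt in gates]
    if len(set(labels)) != len(labels):
        raise ValueError("gate labels must be unique")
    out = np.full(field.shape, UNASSIGNED, dtype=np.int32)
    claimed = np.zeros(field.shape, dtype=bool)
    for gate in gates:
        inside = gate.contains(field.g, field.s) & field.valid_mask
        if strict and np.any(inside & claimed):
            raise ValueError(f"gate {gate.label} overlaps an earlier gate")
        take = inside & (out == UNASSIGNED)
        out[take] = gate.label
        claimed |= inside
    return out


def segmented_rgb(stack: np.ndarray, label_map: np.ndarray,
                  gates: Sequence[PhasorGate]) -> np.ndarray:
    """Back-project gate labels onto the image as a color overlay.

    Each pixel takes its gate's color scaled by the pixel's total intensity
    normalized to the frame maximum; UNASSIGNED pixels are black.
    """
    stack = np.asarray(stack, dtype=float)
    label_map = np.asarray(label_map)
    if label_map.shape != stack.shape[:2]:
        raise ValueError("label map shape does not match stack")
    total = stack.sum(axis=2)
    peak = total.max()
    norm = total / peak if peak > 0 else total
    out = np.zeros(label_map.shape + (3,), dtype=float)
    for gate in gates:
        sel = label_map == gate.label
        out[sel] = np.asarray(gate.color, float) * norm[sel, None]
    return out
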