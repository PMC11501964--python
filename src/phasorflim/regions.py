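"""Tumor-region classification and group statistics.

Tissue is partitioned into three lesion classes from the mean-lifetime map,
the collagen (SHG) mask, and an expert-drawn tumor-boundary mask:

* **IR** (invasive region): inside the tumor boundary with a long mean
  lifetime;
* **NOIR** (non-invasive region): outside the boundary where SHG signal
  (intact collagen) is present;
* **NEIR** (near-invasive region): the remaining tissue between them with
  a distinctly short mean lifetime.

The lifetime thresholds separating "long" and "short" are explicit inputs:
no printed values exist for them, so they must be calibrated per dataset
(defaults shipped with the synthetic phantoms are for testing).

Group inference is run on per-field-of-view summaries, never per pixel
(pixels within a field are strongly correlated, so pixel-level tests would
be pseudo-replicated).  The statistics mirror the standard workflow:
one-way ANOVA followed by Tukey's honestly-significant-difference multiple
comparisons, with the conventional star labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionLabel",
    "classify_regions",
    "shg_presence_mask",
    "roi_metrics",
    "region_summary",
    "one_way_anova",
    "tukey_hsd",
    "significance_stars",
    "GroupStats",
    "group_stats",
]


class RegionLabel(IntEnum):
    UNASSIGNED = 0
    NORMAL = 1
    NOIR = 2
    NEIR = 3
    IR = 4


def classify_regions(tau_mean_map, shg_mask, boundary_mask,
                     tau_threshold_long, tau_threshold_short) -> np.ndarray:
    """Label pixels IR / NOIR / NEIR from lifetime, SHG, and boundary.

    Rules, applied deterministically and mutually exclusively:
    inside ``boundary_mask`` with ``tau >= tau_threshold_long`` -> IR;
    outside the boundary with SHG present -> NOIR; remaining pixels with
    ``tau <= tau_threshold_short`` -> NEIR; everything else UNASSIGNED.
    """
    tau = np.asarray(tau_mean_map, dtype=float)
    shg = np.asarray(shg_mask, dtype=bool)
    boundary = np.asarray(boundary_mask, dtype=bool)
    if not (tau.shape == shg.shape == boundary.shape):
        raise ValueError("tau map, SHG mask and boundary mask must share a shape")
    if tau_threshold_short > tau_threshold_long:
        raise ValueError("tau_threshold_short must be <= tau_threshold_long")
    labels = np.full(tau.shape, int(RegionLabel.UNASSIGNED), dtype=np.int32)
    with np.errstate(invalid="ignore"):
        ir = boundary & (tau >= tau_threshold_long)
        noir = ~boundary & shg & ~ir
        rest = ~ir & ~noir
        neir = rest & (tau <= tau_threshold_short)
    labels[ir] = int(RegionLabel.IR)
    labels[noir] = int(RegionLabel.NOIR)
    labels[neir] = int(RegionLabel.NEIR)
    return labels


def shg_presence_mask(shg_channel_image, background_quantile=0.90) -> np.ndarray:
    """Boolean "SHG present" mask: intensity above a background quantile.

    The threshold is the given quantile of the image itself (a proxy for
    the background level when collagen covers a minority of the frame);
    pass a precomputed mask instead when a calibrated threshold exists.
    """
    img = np.asarray(shg_channel_image, dtype=float)
    return img > np.quantile(img, background_quantile)


def roi_metrics(value_map, label_map, legend=None, reduce=np.nanmean) -> dict:
    """Summarize one field of view: one scalar per labeled class.

    Classes named via ``legend`` (id -> name mapping, default
    :class:`RegionLabel` names); UNASSIGNED pixels are skipped.
    """
    value_map = np.asarray(value_map, dtype=float)
    label_map = np.asarray(label_map)
    if legend is None:
        legend = {int(m): m.name for m in RegionLabel}
    out = {}
    for cls in np.unique(label_map):
        cls = int(cls)
        if cls == int(RegionLabel.UNASSIGNED):
            continue
        name = legend.get(cls, str(cls))
        vals = value_map[label_map == cls]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[name] = float(reduce(vals))
    return out


def region_summary(records) -> dict[str, np.ndarray]:
    """Collect per-ROI scalars into per-group sample vectors.

    ``records`` is either a mapping ``group -> sequence of values``, a
    sequence of per-ROI dicts (as from :func:`roi_metrics`), or a
    DataFrame with ``group``/``value`` columns.  Undefined values (nan)
    and empty groups are dropped with a warning.
    """
    if isinstance(records, pd.DataFrame):
        grouped = {g: df["value"].to_numpy(float)
                   for g, df in records.groupby("group", sort=False)}
    elif isinstance(records, Mapping):
        grouped = {g: np.asarray(v, dtype=float) for g, v in records.items()}
    else:
        grouped = {}
        for rec in records:
            for g, v in rec.items():
                grouped.setdefault(g, []).append(v)
        grouped = {g: np.asarray(v, dtype=float) for g, v in grouped.items()}
    out = {}
    for g, vals in grouped.items():
        n_bad = int(np.sum(~np.isfinite(vals)))
        if n_bad:
            warnings.warn(f"group {g!r}: dropping {n_bad} undefined value(s)",
                          stacklevel=2)
            vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"group {g!r} is empty and was dropped", stacklevel=2)
            continue
        out[g] = vals
    return out


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA: returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def tukey_hsd(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Tukey HSD pairwise adjusted p-values (symmetric matrix, diag 1)."""
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    res = stats.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
    return np.asarray(res.pvalue, dtype=float)


def significance_stars(p: float) -> str:
    """Star label for a p-value.

    ``****`` p < 0.00001; ``***`` 0.00001 <= p < 0.0001; ``**`` 0.0001 <=
    p < 0.01; ``*`` 0.01 <= p < 0.05; ``ns`` otherwise.  Boundary values
    fall in the less-significant bin.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 1e-5:
        return "****"
    if p < 1e-4:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


@dataclass
class GroupStats:
    """Per-group descriptives plus ANOVA/Tukey inference."""

    names: list
    n: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    anova_f: float
    anova_p: float
    tukey_p: np.ndarray

    def pairwise_stars(self) -> dict[tuple, str]:
        out = {}
        for i in range(len(self.names)):
            for j in range(i + 1, len(self.names)):
                out[(self.names[i], self.names[j])] = significance_stars(
                    self.tukey_p[i, j])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.names, "n": self.n,
                             "mean": self.mean, "sem": self.sem})

    def summary(self) -> str:
        lines = ["Group comparison", "=" * 52]
        for name, n, m, s in zip(self.names, self.n, self.mean, self.sem):
            lines.append(f"{str(name):<14}n={n:<5d}mean={m:>10.4g}  sem={s:>9.3g}")
        lines.append("-" * 52)
        lines.append(f"one-way ANOVA: F = {self.anova_f:.4g}, "
                     f"p = {self.anova_p:.3g} [{significance_stars(self.anova_p)}]")
        for (a, b), star in self.pairwise_stars().items():
            i, j = self.names.index(a), self.names.index(b)
            lines.append(f"  {a} vs {b}: Tukey p = {self.tukey_p[i, j]:.3g} [{star}]")
        return "\n".join(lines)


def group_stats(samples: Mapping[str, np.ndarray]) -> GroupStats:
    """Full group comparison: descriptives, one-way ANOVA, Tukey HSD."""
    names = list(samples)
    groups = [np.asarray(samples[g], dtype=float) for g in names]
    f, p = one_way_anova(groups)
    tk = tukey_hsd(groups)
    n = np.array([g.size for g in groups])
    mean = np.array([g.mean() for g in groups])
    sem = np.array([g.std(ddof=1) / np.sqrt(g.size) for g in groups])
    return GroupStats(names=names, n=n, mean=mean, sem=sem,
                      anova_f=f, anova_p=p, tukey_p=tk)
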