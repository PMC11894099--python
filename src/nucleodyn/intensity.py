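"""Fluorescence quantification arithmetic.

Implements the manual immunostaining protocol as deterministic operations:
nuclear-lamina rim intensities are sampled along line profiles (three lines
averaged over three z-slices), a same-z background line average is
subtracted, hemocyte values are normalised to the epithelial average of
the same age group, and Lamin stoichiometry is expressed as the relative
A-type/B-type ratio of age-normalised channel medians.  Also covers 3D
nuclear mean intensities with negative-control correction (DNA-damage
scoring), phagosome counting, and nuclear-instability event rates.

Negative background-corrected intensities are retained and flagged rather
than clamped, so group means stay unbiased.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "IntensityRecord",
    "NuclearDamageRecord",
    "rim_intensity",
    "auto_rim_lines",
    "normalize_to_reference",
    "lamin_stoichiometry",
    "nuclear_mean_3d",
    "quantify_phagosomes",
    "instability_rate",
]


@dataclass
class IntensityRecord:
    """One nucleus's background-corrected rim fluorescence."""

    nucleus_id: int
    cell_class: str
    age_group: str
    raw: float
    background: float
    corrected: float
    negative_flag: bool
    normalized: float = float("nan")


@dataclass
class NuclearDamageRecord:
    nucleus_id: int
    mean_intensity: float
    control_mean: float
    corrected: float
    negative_flag: bool


def _line_mean(stack: np.ndarray, line, z_indices) -> float:
    """Mean intensity along one line, averaged over the given z-slices.

    ``line`` is ((x0, y0), (x1, y1)); samples are taken at ~1 px spacing
    with nearest-pixel lookup (deterministic, mirrors a 1 px wide manual
    line tool).
    """
    (x0, y0), (x1, y1) = line
    nz, ny, nx = stack.shape
    length = round(math.hypot(x1 - x0, y1 - y0), 6)
    n = max(2, int(math.ceil(length)) + 1)
    # sample positions are quantized to 1e-6 px before half-up rounding so
    # that translated copies of the same line geometry sample identical
    # pixel offsets (ulp-level float error cannot flip a boundary pixel)
    xs = np.floor(np.round(np.linspace(x0, x1, n), 6) + 0.5).astype(int)
    ys = np.floor(np.round(np.linspace(y0, y1, n), 6) + 0.5).astype(int)
    if (xs < 0).any() or (xs >= nx).any() or (ys < 0).any() or (ys >= ny).any():
        raise ValueError("line extends outside the image")
    vals = [stack[z, ys, xs].mean() for z in z_indices]
    return float(np.mean(vals))


def rim_intensity(
    stack: np.ndarray,
    rim_lines,
    background_lines,
    z_indices=None,
    *,
    nucleus_id: int = 0,
    cell_class: str = "hemocyte",
    age_group: str = "",
) -> IntensityRecord:
    """Background-corrected rim intensity of one nucleus.

    ``raw`` is the mean of per-line mean intensities of the rim lines over
    ``z_indices`` (default: the 3 central z-slices); ``background`` the same
    for the background lines at the same z; ``corrected = raw - background``
    with negative values retained and flagged.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (z, y, x)")
    if not rim_lines or not background_lines:
        raise ValueError("need at least one rim line and one background line")
    if z_indices is None:
        mid = stack.shape[0] // 2
        z_indices = [z for z in (mid - 1, mid, mid + 1) if 0 <= z < stack.shape[0]]
    raw = float(np.mean([_line_mean(stack, ln, z_indices) for ln in rim_lines]))
    bg = float(np.mean([_line_mean(stack, ln, z_indices) for ln in background_lines]))
    corrected = raw - bg
    return IntensityRecord(
        nucleus_id=nucleus_id,
        cell_class=cell_class,
        age_group=age_group,
        raw=raw,
        background=bg,
        corrected=corrected,
        negative_flag=corrected < 0,
    )


def auto_rim_lines(center_xy, radius_px: float, n_lines: int = 3):
    """Evenly spaced chords through the lamina annulus (automated analogue
    of hand-placed rim lines): ``n_lines`` diameters through the nucleus
    centre at angles k*pi/n, each extending just past the rim."""
    cx, cy = center_xy
    half = radius_px + 2.0
    lines = []
    for k in range(n_lines):
        ang = math.pi * k / n_lines
        dx, dy = half * math.cos(ang), half * math.sin(ang)
        lines.append(((cx - dx, cy - dy), (cx + dx, cy + dy)))
    return lines


def normalize_to_reference(
    records: list[IntensityRecord],
    reference_class: str = "epithelial",
) -> list[IntensityRecord]:
    """Normalise corrected intensities to the reference-class mean per age.

    ``normalized = corrected / mean(corrected of reference class, same age
    group)``.  Age groups without any reference record are skipped with a
    warning (normalized stays NaN).
    """
    by_age: dict[str, list[float]] = {}
    for r in records:
        if r.cell_class == reference_class:
            by_age.setdefault(r.age_group, []).append(r.corrected)
    ref_mean = {age: float(np.mean(v)) for age, v in by_age.items()}
    for r in records:
        if r.age_group not in ref_mean:
            warnings.warn(
                f"no {reference_class} reference for age group {r.age_group!r}; "
                "skipped",
                stacklevel=2,
            )
            continue
        r.normalized = r.corrected / ref_mean[r.age_group]
    return records


def lamin_stoichiometry(
    corrected: pd.DataFrame,
    reference_age: str,
    channel_a: str = "dLamC",
    channel_b: str = "dLamB",
) -> pd.DataFrame:
    """Relative A-type/B-type Lamin ratio table across age groups.

    ``corrected`` has columns ``age_group, channel, corrected`` (one row per
    nucleus).  Per channel, the per-age median is normalised to the
    reference age's median; the relative ratio is the normalised A-channel
    median divided by the normalised B-channel median of the same age, so
    the reference age has ratio 1 by construction.

    Returns a table with columns ``age_group, median_a, median_b,
    norm_median_a, norm_median_b, ratio``.
    """
    med = corrected.groupby(["age_group", "channel"])["corrected"].median()
    ages = sorted(corrected["age_group"].unique())
    for ch in (channel_a, channel_b):
        if (reference_age, ch) not in med.index:
            raise ValueError(f"channel {ch!r} missing at reference age {reference_age!r}")
    ref_a = med[(reference_age, channel_a)]
    ref_b = med[(reference_age, channel_b)]
    rows = []
    for age in ages:
        ma = med.get((age, channel_a), float("nan"))
        mb = med.get((age, channel_b), float("nan"))
        if ref_a == 0 or ref_b == 0:
            warnings.warn("zero reference median; ratio undefined", stacklevel=2)
            na = nb = ratio = float("nan")
        else:
            na = ma / ref_a
            nb = mb / ref_b
            ratio = na / nb if nb and not math.isnan(nb) else float("nan")
        rows.append(
            dict(
                age_group=age,
                median_a=ma,
                median_b=mb,
                norm_median_a=na,
                norm_median_b=nb,
                ratio=ratio,
            )
        )
    return pd.DataFrame(rows)


def nuclear_mean_3d(
    labels: np.ndarray,
    volume: np.ndarray,
    negative_control_mean: float,
) -> list[NuclearDamageRecord]:
    """Mean 3D intensity per labelled nucleus, negative-control corrected."""
    labels = np.asarray(labels)
    volume = np.asarray(volume, dtype=float)
    if labels.shape != volume.shape:
        raise ValueError("labels and image volume must be co-registered")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return []
    means = ndimage.mean(volume, labels=labels, index=ids)
    out = []
    for lab, m in zip(ids, np.atleast_1d(means)):
        corr = float(m) - negative_control_mean
        out.append(
            NuclearDamageRecord(
                nucleus_id=int(lab),
                mean_intensity=float(m),
                control_mean=float(negative_control_mean),
                corrected=corr,
                negative_flag=corr < 0,
            )
        )
    return out


def quantify_phagosomes(
    cell_mask: np.ndarray,
    phagosome_labels: np.ndarray,
    pixel_size_um: float,
) -> tuple[int, float]:
    """Count phagosomes and their total area within a cell mask.

    Only pixels inside the cell mask count; a label with no in-mask pixels
    does not contribute to the count.
    """
    cell_mask = np.asarray(cell_mask).astype(bool)
    labels = np.asarray(phagosome_labels)
    if labels.shape != cell_mask.shape:
        raise ValueError("cell mask and phagosome labels must share a shape")
    inside = np.where(cell_mask, labels, 0)
    ids, counts = np.unique(inside[inside > 0], return_counts=True)
    total_area = float(counts.sum()) * pixel_size_um**2
    return int(ids.size), total_area


def instability_rate(event_count: int, hemocyte_total: int) -> float:
    """Nuclear-instability events per 100 hemocytes (a percentage)."""
    if hemocyte_total <= 0:
        raise ValueError("hemocyte_total must be positive")
    if event_count < 0:
        raise ValueError("event_count must be non-negative")
    return 100.0 * event_count / hemocyte_total
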