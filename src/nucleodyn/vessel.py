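"""Vessel diameter dynamics during nuclear transit.

The vessel wall channel shows two bright, roughly parallel wall lines; the
diameter is the distance between the two outermost intensity peaks along a
measurement line crossing both walls, with 3-point parabolic subpixel
refinement, optionally averaged over several parallel lines.  Transit
metrics relate the diameter before, during and after nuclear occupation:
``relative_change = D_during / D_pre`` and
``residual_space = D_during - D_nucleus``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.signal import find_peaks

from .shape import min_diameter

__all__ = [
    "UnmeasurableError",
    "TransitMeasurement",
    "diameter_from_profile",
    "transit_metrics",
    "transit_correlations",
    "detect_transit_frames",
    "measure_transit",
]


class UnmeasurableError(ValueError):
    """The intensity profile does not show two qualifying wall peaks."""


@dataclass
class TransitMeasurement:
    transit_id: int
    d_pre_um: float
    d_during_um: float
    d_post_um: float
    d_nucleus_um: float
    relative_change: float
    residual_um: float
    frame_pre: int = -1
    frame_during: int = -1
    frame_post: int = -1


def _profile(image: np.ndarray, p0, p1) -> np.ndarray:
    """Bilinear intensity profile sampled at 1 px spacing from p0 to p1."""
    (x0, y0), (x1, y1) = p0, p1
    length = math.hypot(x1 - x0, y1 - y0)
    n = max(2, int(round(length)) + 1)
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    return ndimage.map_coordinates(
        np.asarray(image, dtype=float), [ys, xs], order=1, mode="nearest"
    )


def _peak_distance_px(profile: np.ndarray) -> float:
    """Distance between the outermost wall peaks with parabolic refinement.

    Qualifying peaks are local maxima exceeding half the profile's dynamic
    range above its minimum.
    """
    lo, hi = float(profile.min()), float(profile.max())
    height = lo + 0.5 * (hi - lo)
    peaks, _ = find_peaks(profile, height=height)
    if peaks.size < 2:
        raise UnmeasurableError("fewer than two wall peaks on the profile")

    def refine(i: int) -> float:
        if i == 0 or i == profile.size - 1:
            return float(i)
        y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom == 0:
            return float(i)
        return i + 0.5 * (y0 - y2) / denom

    return refine(int(peaks[-1])) - refine(int(peaks[0]))


def diameter_from_profile(
    image: np.ndarray,
    line,
    pixel_size_um: float,
    n_average: int = 1,
    spacing_px: float = 2.0,
) -> float:
    """Vessel diameter along a measurement line, in micrometres.

    ``line`` is ((x0, y0), (x1, y1)) crossing both walls.  With
    ``n_average`` > 1 the measurement is repeated on parallel lines offset
    along the wall direction (perpendicular to the measurement line) at
    ``spacing_px`` and averaged.
    """
    (x0, y0), (x1, y1) = line
    length = math.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise ValueError("degenerate measurement line")
    # unit vector perpendicular to the line = along the vessel axis
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    px_, py_ = -uy, ux
    offsets = (np.arange(n_average) - (n_average - 1) / 2.0) * spacing_px
    step = length / (max(2, int(round(length)) + 1) - 1)
    vals = []
    for off in offsets:
        p0 = (x0 + off * px_, y0 + off * py_)
        p1 = (x1 + off * px_, y1 + off * py_)
        d_samples = _peak_distance_px(_profile(image, p0, p1))
        vals.append(d_samples * step * pixel_size_um)
    return float(np.mean(vals))


def transit_metrics(
    d_pre_um: float,
    d_during_um: float,
    d_post_um: float,
    d_nucleus_um: float,
    transit_id: int = 0,
    frames: tuple[int, int, int] | None = None,
) -> TransitMeasurement:
    """Derived dilation/residual-space statistics of one transit."""
    for name, v in (
        ("d_pre_um", d_pre_um),
        ("d_during_um", d_during_um),
        ("d_post_um", d_post_um),
        ("d_nucleus_um", d_nucleus_um),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive; got {v}")
    f = frames if frames is not None else (-1, -1, -1)
    return TransitMeasurement(
        transit_id=transit_id,
        d_pre_um=d_pre_um,
        d_during_um=d_during_um,
        d_post_um=d_post_um,
        d_nucleus_um=d_nucleus_um,
        relative_change=d_during_um / d_pre_um,
        residual_um=d_during_um - d_nucleus_um,
        frame_pre=f[0],
        frame_during=f[1],
        frame_post=f[2],
    )


def transit_correlations(measurements: list[TransitMeasurement]) -> dict:
    """Pearson correlations of the transit cohort.

    Reports r, two-sided t-approximate p, regression slope/intercept and R^2
    for (D_pre vs relative change) and (D_during vs nuclear diameter).
    """
    if len(measurements) < 3:
        raise ValueError("need at least 3 measurements")
    out = {}
    pairs = {
        "pre_vs_relative_change": (
            [m.d_pre_um for m in measurements],
            [m.relative_change for m in measurements],
        ),
        "during_vs_nucleus": (
            [m.d_during_um for m in measurements],
            [m.d_nucleus_um for m in measurements],
        ),
    }
    for key, (x, y) in pairs.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"zero variance in {key}; undefined", stacklevel=2)
            out[key] = dict(
                r=float("nan"), p=float("nan"), slope=float("nan"),
                intercept=float("nan"), r_squared=float("nan"),
            )
            continue
        r, p = stats.pearsonr(x, y)
        reg = stats.linregress(x, y)
        out[key] = dict(
            r=float(r),
            p=float(p),
            slope=float(reg.slope),
            intercept=float(reg.intercept),
            r_squared=float(reg.rvalue**2),
        )
    return out


def detect_transit_frames(
    nuclear_movie,
    line,
    background_box=((0, 8), (0, 8)),
    n_sd: float = 3.0,
) -> np.ndarray:
    """Frames during which the nucleus occupies the measurement line.

    Occupation is flagged when the nuclear-channel mean intensity along the
    line (between the walls) exceeds the background mean + ``n_sd`` SDs;
    background statistics are pooled from a nucleus-free corner box.
    """
    (y0, y1), (x0, x1) = background_box
    bg = nuclear_movie.data[:, :, y0:y1, x0:x1]
    thresh = float(bg.mean()) + n_sd * float(bg.std())
    flags = []
    for t in range(nuclear_movie.n_frames):
        # in-focus z-plane: the slice with the brightest nuclear signal
        z = int(np.argmax(nuclear_movie.data[t].max(axis=(1, 2))))
        prof = _profile(nuclear_movie.data[t, z], *line)
        flags.append(prof.mean() > thresh)
    return np.nonzero(flags)[0]


def measure_transit(
    fixture,
    n_average: int = 4,
    transit_id: int = 0,
) -> TransitMeasurement:
    """End-to-end transit measurement on a two-channel transit fixture.

    Uses the fixture's measurement line to find the transit interval from
    the nuclear channel, measures the wall-to-wall diameter before, during
    and after occupation, and takes the nuclear diameter as the min-Feret
    of the thresholded nucleus in the central transit frame.
    """
    walls, nuclei = fixture.walls, fixture.nuclei
    ny = walls.data.shape[2]
    xm = fixture.measurement_x_px
    line = ((xm, 0.0), (xm, float(ny - 1)))
    transit = detect_transit_frames(nuclei, line)
    if transit.size == 0:
        raise UnmeasurableError("no transit detected on the measurement line")
    t_in, t_out = int(transit[0]), int(transit[-1])
    t_mid = int(transit[transit.size // 2])
    pre_frames = range(0, t_in)
    post_frames = range(t_out + 1, walls.n_frames)
    if not len(pre_frames) or not len(post_frames):
        raise UnmeasurableError("transit interval touches the movie boundary")

    def mean_diam(frames) -> float:
        vals = []
        for t in frames:
            z = int(np.argmax(nuclei.data[t].max(axis=(1, 2))))
            vals.append(
                diameter_from_profile(
                    walls.data[t, z], line, walls.pixel_size_um, n_average
                )
            )
        return float(np.mean(vals))

    d_pre = mean_diam(pre_frames)
    d_post = mean_diam(post_frames)
    d_during = mean_diam(transit)

    z = int(np.argmax(nuclei.data[t_mid].max(axis=(1, 2))))
    img = nuclei.data[t_mid, z]
    thr = float(img.min()) + 0.5 * (float(img.max()) - float(img.min()))
    lab, n = ndimage.label(img >= thr)
    if n == 0:
        raise UnmeasurableError("no nucleus found in the transit frame")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    nucleus_mask = lab == (int(np.argmax(sizes)) + 1)
    d_nuc = min_diameter(nucleus_mask, nuclei.pixel_size_um)
    return transit_metrics(
        d_pre,
        d_during,
        d_post,
        d_nuc,
        transit_id=transit_id,
        frames=(max(pre_frames), t_mid, min(post_frames)),
    )
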