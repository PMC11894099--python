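"""Event, migration, correlation and spatial statistics of nuclear tracks.

A nucleus is classed as "squeezing" in any frame in which its Shape Factor
is at or above the threshold (default 0.4, inclusive).  A squeezing *event*
is a maximal run of consecutive observed frames above threshold; frames
missing due to gap closing break runs rather than being interpolated, so an
event is never built from fabricated measurements.

Track-level migration statistics (path length, Euclidean distance,
persistence) are standardised to a fixed time window (default 15 min):
longer tracks are truncated to the first window, shorter tracks are
linearly rescaled by ``window / duration`` and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SQUEEZE_THRESHOLD",
    "SqueezeEvent",
    "TrackSummary",
    "detect_squeezing",
    "summarize_track",
    "summarize_tracks",
    "CorrelationMatrix",
    "correlation_matrix",
    "HeatmapGrid",
    "sf_heatmap",
]

#: Default SF threshold defining a squeezing frame (inclusive).  Coupled to
#: the default "axis_diff" SF formula; if the alternative formula is used a
#: matching threshold must be supplied explicitly.
SQUEEZE_THRESHOLD = 0.4


@dataclass(frozen=True)
class SqueezeEvent:
    """One maximal run of consecutive squeezing frames (end inclusive)."""

    start_frame: int
    end_frame: int
    duration_min: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class TrackSummary:
    track_id: int
    n_timepoints: int
    mean_sf: float
    max_sf: float
    squeeze_proportion: float
    n_events: int
    mean_event_duration_min: float  # NaN when no events
    mean_speed_um_min: float
    path_length_um: float  # standardised to the window
    euclidean_um: float  # standardised to the window
    persistence: float  # NaN when path length is 0 (excluded, not zero)
    window_rescaled: bool = field(default=False)


def detect_squeezing(
    sf_series,
    threshold: float = SQUEEZE_THRESHOLD,
    frame_interval_s: float = 30.0,
) -> tuple[list[SqueezeEvent], float]:
    """Find squeezing events and the proportion of frames spent squeezing.

    Parameters
    ----------
    sf_series : sequence of float
        Per-frame SF values; NaN marks a gap-closed (missing) frame.  Gaps
        break runs and are excluded from the proportion denominator.
    threshold : float
        Inclusive SF threshold.
    frame_interval_s : float
        Used to express event durations in minutes.

    Returns
    -------
    (events, proportion)
        ``proportion`` = squeezing frames / observed frames.
    """
    sf = np.asarray(sf_series, dtype=float)
    if sf.ndim != 1 or sf.size == 0:
        raise ValueError("sf_series must be a non-empty 1D sequence")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    observed = ~np.isnan(sf)
    above = observed & (sf >= threshold)
    events: list[SqueezeEvent] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            events.append(_make_event(start, i - 1, frame_interval_s))
            start = None
    if start is not None:
        events.append(_make_event(start, sf.size - 1, frame_interval_s))
    n_obs = int(observed.sum())
    proportion = float(above.sum()) / n_obs if n_obs else float("nan")
    return events, proportion


def _make_event(start: int, end: int, frame_interval_s: float) -> SqueezeEvent:
    return SqueezeEvent(
        start_frame=start,
        end_frame=end,
        duration_min=(end - start + 1) * frame_interval_s / 60.0,
    )


def summarize_track(
    track_df: pd.DataFrame,
    frame_interval_s: float,
    threshold: float = SQUEEZE_THRESHOLD,
    standard_window_min: float = 15.0,
) -> TrackSummary:
    """Summarise one track's SF dynamics and migration statistics.

    ``track_df`` holds one track's observations (rows sorted by frame) with
    columns ``frame, x_um, y_um, sf`` and optionally ``track_id``.  Missing
    frames need not be materialised as rows; they are reconstructed from the
    ``frame`` column for run breaking.
    """
    if track_df.empty:
        raise ValueError("track has no observations")
    df = track_df.sort_values("frame")
    frames = df["frame"].to_numpy(int)
    track_id = int(df["track_id"].iloc[0]) if "track_id" in df else -1

    # dense SF series with NaN at gap frames so gaps break runs
    span = frames[-1] - frames[0] + 1
    dense = np.full(span, np.nan)
    dense[frames - frames[0]] = df["sf"].to_numpy(float)
    events, proportion = detect_squeezing(dense, threshold, frame_interval_s)

    x = df["x_um"].to_numpy(float)
    y = df["y_um"].to_numpy(float)
    steps = np.hypot(np.diff(x), np.diff(y))
    dt_s = np.diff(frames) * frame_interval_s
    mean_speed = float(np.mean(steps / (dt_s / 60.0))) if steps.size else 0.0

    # standardised window: first contiguous window of the requested length
    window_s = standard_window_min * 60.0
    t_rel = (frames - frames[0]) * frame_interval_s
    in_window = t_rel <= window_s + 1e-9
    duration = float(t_rel[-1])
    rescaled = False
    if duration >= window_s - 1e-9:
        xs, ys_ = x[in_window], y[in_window]
        path = float(np.hypot(np.diff(xs), np.diff(ys_)).sum())
        euclid = float(np.hypot(xs[-1] - xs[0], ys_[-1] - ys_[0]))
    else:
        path = float(steps.sum())
        euclid = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
        if duration > 0:
            scale = window_s / duration
            path *= scale
            euclid *= scale
            rescaled = True
        else:  # single observation: no motion measurable
            path = euclid = float("nan")
            rescaled = True
    persistence = euclid / path if path and path > 0 else float("nan")

    sf_obs = df["sf"].to_numpy(float)
    sf_obs = sf_obs[~np.isnan(sf_obs)]
    durations = [e.duration_min for e in events]
    return TrackSummary(
        track_id=track_id,
        n_timepoints=len(df),
        mean_sf=float(sf_obs.mean()) if sf_obs.size else float("nan"),
        max_sf=float(sf_obs.max()) if sf_obs.size else float("nan"),
        squeeze_proportion=proportion,
        n_events=len(events),
        mean_event_duration_min=float(np.mean(durations)) if durations else float("nan"),
        mean_speed_um_min=mean_speed,
        path_length_um=path,
        euclidean_um=euclid,
        persistence=persistence,
        window_rescaled=rescaled,
    )


def summarize_tracks(
    tracks_df: pd.DataFrame,
    frame_interval_s: float,
    threshold: float = SQUEEZE_THRESHOLD,
    standard_window_min: float = 15.0,
) -> pd.DataFrame:
    """Per-track summaries of a tracks table (one row per track)."""
    rows = []
    for _, grp in tracks_df.groupby("track_id", sort=True):
        s = summarize_track(grp, frame_interval_s, threshold, standard_window_min)
        rows.append(vars(s))
    return pd.DataFrame(rows)


@dataclass
class CorrelationMatrix:
    attributes: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    method: str


def correlation_matrix(
    summaries: pd.DataFrame,
    attributes: list[str],
    method: str = "spearman",
) -> CorrelationMatrix:
    """Pairwise correlations between track attributes.

    Spearman: rank transform (average ranks for ties) then product-moment.
    Two-sided p-values use the t-approximation with n - 2 df.  Pairs are
    handled pairwise-complete; a zero-variance attribute yields NaN with a
    warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    k = len(attributes)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = summaries[[attributes[i], attributes[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 complete records for {attributes[i]}/{attributes[j]}"
                )
            a = pair.iloc[:, 0].to_numpy(float)
            b = pair.iloc[:, 1].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(
                    f"zero variance in correlation pair "
                    f"({attributes[i]}, {attributes[j]}); reported as NaN",
                    stacklevel=2,
                )
                rij, pij = np.nan, np.nan
            elif method == "spearman":
                rij, pij = stats.spearmanr(a, b)
            else:
                rij, pij = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    ridx = pd.DataFrame(r, index=attributes, columns=attributes)
    pidx = pd.DataFrame(p, index=attributes, columns=attributes)
    return CorrelationMatrix(attributes=list(attributes), r=ridx, p=pidx, method=method)


@dataclass
class HeatmapGrid:
    """Spatially binned mean SF; NaN marks bins with no observations."""

    bin_size_px: int
    bin_size_um: float
    mean_sf: np.ndarray  # (ny_bins, nx_bins), NaN = no data
    counts: np.ndarray  # (ny_bins, nx_bins) int


def sf_heatmap(
    tracks_df: pd.DataFrame,
    bin_size_px: int,
    field_shape: tuple[int, int],
    pixel_size_um: float,
) -> HeatmapGrid:
    """Bin every observation's SF by its centroid into a square grid.

    Bins use half-open intervals ``[k*s, (k+1)*s)`` in pixel coordinates
    (an exact boundary falls in the higher-index bin); centroids outside the
    field are clipped into the edge bin with a warning.
    """
    if bin_size_px < 1:
        raise ValueError("bin_size_px must be >= 1")
    ny, nx = field_shape
    nby = int(np.ceil(ny / bin_size_px))
    nbx = int(np.ceil(nx / bin_size_px))
    sums = np.zeros((nby, nbx))
    counts = np.zeros((nby, nbx), dtype=int)
    xs = tracks_df["x_um"].to_numpy(float) / pixel_size_um
    ys = tracks_df["y_um"].to_numpy(float) / pixel_size_um
    sf = tracks_df["sf"].to_numpy(float)
    keep = ~np.isnan(sf)
    xs, ys, sf = xs[keep], ys[keep], sf[keep]
    bx = np.floor(xs / bin_size_px).astype(int)
    by = np.floor(ys / bin_size_px).astype(int)
    if (bx < 0).any() or (by < 0).any() or (bx >= nbx).any() or (by >= nby).any():
        warnings.warn("centroids outside field clipped to edge bins", stacklevel=2)
        bx = np.clip(bx, 0, nbx - 1)
        by = np.clip(by, 0, nby - 1)
    np.add.at(sums, (by, bx), sf)
    np.add.at(counts, (by, bx), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return HeatmapGrid(
        bin_size_px=int(bin_size_px),
        bin_size_um=bin_size_px * pixel_size_um,
        mean_sf=mean,
        counts=counts,
    )
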